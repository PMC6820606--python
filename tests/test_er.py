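"""Exposure-response logistic analysis: fits, quartiles, pooling, subgroups."""

import numpy as np
import pandas as pd
import pytest

from dosematch.er import (
    ExposureResponseLogit,
    SeparationError,
    assign_quartiles,
    fit_logistic,
    pool_check,
    pooled_proportion,
    quartile_summary,
    subgroup_safety_summary,
    weight_quartile_groups,
)


def _two_by_two(a, b, c, d):
    """Exposure 0 with a events / b non-events; exposure 1 with c / d."""
    exposure = np.r_[np.zeros(a + b), np.ones(c + d)]
    outcome = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    return pd.DataFrame({"exposure": exposure, "outcome": outcome})


class TestLogisticFit:
    def test_binary_exposure_slope_equals_log_odds_ratio(self):
        a, b, c, d = 30, 70, 50, 50
        res = fit_logistic(_two_by_two(a, b, c, d), "exposure", "outcome")
        assert res.slope == pytest.approx(np.log((c / d) / (a / b)), rel=1e-6)
        assert res.intercept == pytest.approx(np.log(a / b), rel=1e-6)

    def test_slope_rescales_inversely_with_exposure_units_p_invariant(self, rng):
        x = rng.lognormal(7, 0.3, 400)
        y = (rng.uniform(size=400) < 1 / (1 + np.exp(-(-2 + 0.0005 * x)))).astype(int)
        df = pd.DataFrame({"x": x, "y": y})
        res1 = fit_logistic(df, "x", "y")
        res2 = fit_logistic(df.assign(x=x / 1000.0), "x", "y")
        assert res2.slope == pytest.approx(res1.slope * 1000.0, rel=1e-5)
        assert res2.wald_p == pytest.approx(res1.wald_p, rel=1e-5)

    def test_all_outcomes_identical_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [1, 1, 1]})
        with pytest.raises(ValueError, match="identical"):
            fit_logistic(df, "x", "y")

    def test_constant_exposure_rejected(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0], "y": [0, 1, 0, 1]})
        with pytest.raises(ValueError, match="distinct"):
            fit_logistic(df, "x", "y")

    def test_complete_separation_flagged_not_reported(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4, 10, 11, 12, 13.0],
                           "y": [0, 0, 0, 0, 1, 1, 1, 1]})
        with pytest.raises(SeparationError):
            fit_logistic(df, "x", "y")

    def test_power_increases_with_slope_magnitude(self):
        """Monotone power over three slope values (seeded replicates)."""
        rng = np.random.default_rng(2024)
        n, reps = 300, 200
        power = []
        for slope in (0.0, 0.5, 1.0):
            hits = 0
            for _ in range(reps):
                x = rng.standard_normal(n)
                p = 1 / (1 + np.exp(-(-1.5 + slope * x)))
                y = (rng.uniform(size=n) < p).astype(int)
                res = ExposureResponseLogit(y, x).fit()
                hits += res.wald_p < 0.05
            power.append(hits / reps)
        assert power[0] < power[1] < power[2]
        assert power[2] > 0.9


class TestQuartileSummary:
    def test_hand_countable_example(self):
        """8 equally spaced exposures, one event in the top quartile."""
        df = pd.DataFrame({"x": np.arange(1.0, 9.0),
                           "y": [0, 0, 0, 0, 0, 0, 1, 0]})
        qs = quartile_summary(df, "x", "y")
        assert list(qs.proportion[:4]) == [0.0, 0.0, 0.0, 0.5]

    def test_quartile_counts_sum_to_pooled(self, rng):
        df = pd.DataFrame({"x": rng.lognormal(size=403),
                           "y": rng.integers(0, 2, 403)})
        qs = quartile_summary(df, "x", "y")
        assert qs.n[:4].sum() == qs.n.iloc[-1] == 403
        assert qs.events[:4].sum() == qs.events.iloc[-1]
        assert qs.n[:4].max() - qs.n[:4].min() <= 1

    def test_ties_at_edges_assigned_to_lower_quartile(self):
        x = np.array([1.0, 1, 2, 2, 3, 3, 4, 4])
        q = assign_quartiles(x)
        edges = np.percentile(x, [25, 50, 75])
        for xi, qi in zip(x, q):
            if xi in edges:
                assert qi == np.searchsorted(edges, xi, side="left") + 1

    def test_pooled_proportions_match_printed_percentages(self):
        assert pooled_proportion(164, 1042) == 15.7
        assert pooled_proportion(209, 1228) == 17.0
        assert pooled_proportion(298, 1228) == 24.3

    def test_clopper_pearson_interval_covers_proportion(self, rng):
        df = pd.DataFrame({"x": rng.lognormal(size=100),
                           "y": rng.integers(0, 2, 100)})
        qs = quartile_summary(df, "x", "y")
        assert ((qs.ci_lo <= qs.proportion) & (qs.proportion <= qs.ci_hi)).all()


class TestPooling:
    def test_similar_tumor_type_frequencies_pooled(self):
        """15.6% vs 15.9% (and 14.9% vs 19.6%) are pooled at the default
        5-percentage-point threshold."""
        nsclc = pd.DataFrame({"tt": "NSCLC", "y": [1] * 78 + [0] * 423})
        uc = pd.DataFrame({"tt": "UC", "y": [1] * 86 + [0] * 455})
        rep = pool_check(pd.concat([nsclc, uc]), "tt", "y")
        assert rep.attrs["pooled"]
        assert rep.attrs["max_difference_pct"] == pytest.approx(0.33, abs=0.05)

    def test_difference_just_below_threshold_pooled(self):
        a = pd.DataFrame({"tt": "A", "y": [1] * 149 + [0] * 851})
        b = pd.DataFrame({"tt": "B", "y": [1] * 196 + [0] * 804})
        rep = pool_check(pd.concat([a, b]), "tt", "y", threshold_pct=5.0)
        assert rep.attrs["max_difference_pct"] == pytest.approx(4.7)
        assert rep.attrs["pooled"]

    def test_identical_strata_difference_zero(self):
        df = pd.DataFrame({"tt": ["A"] * 10 + ["B"] * 10, "y": [0, 1] * 10})
        rep = pool_check(df, "tt", "y")
        assert rep.attrs["max_difference_pct"] == 0.0

    def test_single_stratum_rejected(self):
        df = pd.DataFrame({"tt": ["A"] * 10, "y": [0, 1] * 5})
        with pytest.raises(ValueError):
            pool_check(df, "tt", "y")


class TestSubgroupSafety:
    def test_hand_countable_subgroup_frequencies(self):
        df = pd.DataFrame({
            "grp": ["A"] * 4 + ["B"] * 6,
            "ae": [1, 1, 0, 0, 1, 0, 0, 0, 0, 0],
        })
        out = subgroup_safety_summary(df, "grp", ["ae"]).set_index("subgroup")
        assert out.loc["A", "ae_pct"] == 50.0
        assert out.loc["B", "ae_events"] == 1

    def test_weight_quartile_grouping_splits_at_printed_bound(self):
        w = np.array([50.0, 63.7, 63.8, 100.0])
        assert list(weight_quartile_groups(w)) == ["lowest", "lowest",
                                                   "upper3", "upper3"]

    def test_flat_er_cmax_subgroups_have_similar_frequencies(self):
        """Under a flat exposure-safety relationship, AE frequency above vs
        below a predicted reference Cmax differs only by binomial noise."""
        rng = np.random.default_rng(5)
        n = 2000
        cmax = rng.lognormal(6, 0.3, n)
        ae = rng.uniform(size=n) < 0.17
        df = pd.DataFrame({"ae": ae.astype(int)})
        groups = np.where(cmax > np.median(cmax), "above", "below")
        out = subgroup_safety_summary(df, pd.Series(groups, index=df.index),
                                      ["ae"])
        diff = abs(out.ae_pct.iloc[0] - out.ae_pct.iloc[1])
        # 3-sigma band on the difference of two proportions (n/2 each)
        band = 3.0 * 100 * np.sqrt(2 * 0.17 * 0.83 / (n / 2))
        assert diff < band
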