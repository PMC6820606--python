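"""Published summary statistics used as inputs to comparison arithmetic.

These are the printed geometric means (with 90% prediction intervals, 500
simulated patients) of atezolizumab exposure for the four candidate
regimens, and the printed pooled endpoint counts from the exposure-response
analyses.  They serve as fixed reference inputs for regimen-comparison and
pooled-frequency arithmetic — they are not recomputed by this package.
"""

from __future__ import annotations

import pandas as pd

#: geometric mean (90% PI) exposure summaries per regimen and cycle.
#: metrics: cmax (ug/mL), cmin (ug/mL), weekly_auc (ug*day/mL, interval AUC
#: normalised to 7 days).
_ROWS = [
    # regimen, cycle, metric, geomean, pi_lo, pi_hi
    ("1200mg_q3w", "cycle1", "cmax", 403, 274, 581),
    ("1200mg_q3w", "cycle1", "cmin", 85, 55, 133),
    ("1200mg_q3w", "cycle1", "weekly_auc", 1048, 763, 1471),
    ("1200mg_q3w", "steady_state", "cmax", 610, 414, 891),
    ("1200mg_q3w", "steady_state", "cmin", 194, 89, 383),
    ("1200mg_q3w", "steady_state", "weekly_auc", 2115, 1264, 3507),
    ("840mg_q2w", "cycle1", "cmax", 281, 187, 420),
    ("840mg_q2w", "cycle1", "cmin", 74, 48, 116),
    ("840mg_q2w", "cycle1", "weekly_auc", 860, 617, 1237),
    ("840mg_q2w", "steady_state", "cmax", 517, 334, 801),
    ("840mg_q2w", "steady_state", "cmin", 226, 118, 426),
    ("840mg_q2w", "steady_state", "weekly_auc", 2188, 1336, 3733),
    ("1680mg_q4w", "cycle1", "cmax", 563, 379, 822),
    ("1680mg_q4w", "cycle1", "cmin", 97, 58, 159),
    ("1680mg_q4w", "cycle1", "weekly_auc", 1288, 887, 1845),
    ("1680mg_q4w", "steady_state", "cmax", 759, 514, 1106),
    ("1680mg_q4w", "steady_state", "cmin", 182, 87, 369),
    ("1680mg_q4w", "steady_state", "weekly_auc", 2217, 1357, 3705),
    ("20mgkg_q3w", "cycle1", "cmax", 501, 378, 665),
    ("20mgkg_q3w", "cycle1", "cmin", 107, 70, 149),
    ("20mgkg_q3w", "cycle1", "weekly_auc", 1305, 1002, 1683),
    ("20mgkg_q3w", "steady_state", "cmax", 753, 544, 1038),
    ("20mgkg_q3w", "steady_state", "cmin", 238, 115, 443),
    ("20mgkg_q3w", "steady_state", "weekly_auc", 2596, 1592, 4140),
]

PUBLISHED_EXPOSURE_SUMMARY = pd.DataFrame(
    _ROWS, columns=["regimen", "cycle", "metric", "geomean", "pi_lo", "pi_hi"]
)

#: pooled endpoint counts: (events, n)
PUBLISHED_POOLED_COUNTS = {
    "orr": (164, 1042),
    "ae_grade3plus": (209, 1228),
    "aesi": (298, 1228),
}

#: per-tumor-type observed endpoint frequencies (%, n) used in pooling checks
PUBLISHED_STRATUM_FREQUENCIES = {
    "orr": {"NSCLC": (15.6, 501), "UC": (15.9, 541)},
    "ae_grade3plus": {"NSCLC": (14.9, None), "UC": (19.6, None)},
    "aesi": {"NSCLC": (24.6, None), "UC": (23.9, None)},
}


def published_summary(regimen: str, cycle: str) -> pd.DataFrame:
    """Summary rows for one regimen and cycle, in the shape accepted by
    :func:`dosematch.simulate.compare_regimens` (metric/geomean columns)."""
    df = PUBLISHED_EXPOSURE_SUMMARY
    sel = df[(df.regimen == regimen) & (df.cycle == cycle)]
    if sel.empty:
        raise KeyError(f"no published summary for {regimen!r} / {cycle!r}")
    return sel[["metric", "geomean", "pi_lo", "pi_hi"]].reset_index(drop=True)
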