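"""Event-record dataset I/O (NONMEM-dialect rectangular CSV) and run
manifests.

Event-record semantics: one row per event, columns ID, TIME, AMT, RATE, DV,
EVID, MDV.  EVID 1 marks a dose (AMT in mg, RATE in mg/day — an infusion of
duration AMT/RATE days); EVID 0 marks an observation whose DV (ug/mL) is
valid unless MDV is 1.  Covariate columns are carried through unchanged.
Files are comma-separated UTF-8 with a header row and '.' decimals; time is
in days.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

MANDATORY_COLUMNS = ["ID", "TIME", "AMT", "RATE", "DV", "EVID", "MDV"]


class ValidationError(ValueError):
    """An event-record dataset violates the format contract."""


def validate_event_records(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an event-record table; raise ValidationError on violations.

    Checks: mandatory columns present; TIME nonnegative and nondecreasing
    within each ID; EVID in {0, 1}; dose rows carry AMT > 0.  Returns the
    input (for chaining).
    """
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing mandatory column(s): {missing}")
    if (df["TIME"] < 0).any():
        raise ValidationError("negative TIME values present")
    if not df["EVID"].isin([0, 1]).all():
        raise ValidationError("EVID must be 0 (observation) or 1 (dose)")
    for pid, g in df.groupby("ID", sort=False):
        t = g["TIME"].to_numpy()
        if (t[1:] < t[:-1]).any():
            raise ValidationError(f"non-monotone TIME within ID {pid}")
    doses = df[df["EVID"] == 1]
    if (doses["AMT"] <= 0).any():
        raise ValidationError("dose records must have AMT > 0")
    return df


def read_event_records(path) -> pd.DataFrame:
    """Read and validate an event-record CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"event-record file not found: {path}")
    df = pd.read_csv(path)
    return validate_event_records(df)


def write_event_records(df: pd.DataFrame, path) -> None:
    validate_event_records(df)
    df.to_csv(path, index=False)


def split_events(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a validated dataset into (doses, usable observations).

    Observations with MDV == 1 are dropped (missing DV)."""
    validate_event_records(df)
    doses = df[df["EVID"] == 1].copy()
    obs = df[(df["EVID"] == 0) & (df["MDV"] == 0)].copy()
    return doses, obs


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Provenance record for one pipeline run: enough to reproduce it."""

    command: str
    seed: int | None
    inputs: dict
    outputs: dict
    config_hash: str | None
    package_version: str
    timestamp: str

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def make_manifest(command: str, seed: int | None = None,
                  inputs: dict | None = None, outputs: dict | None = None,
                  config_path=None) -> RunManifest:
    from dosematch import __version__

    return RunManifest(
        command=command,
        seed=seed,
        inputs=dict(inputs or {}),
        outputs=dict(outputs or {}),
        config_hash=file_sha256(config_path) if config_path else None,
        package_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
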