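"""CSV/JSON round-trips for the pipeline artifacts.

Daily and weekly panels are plain CSV with missing values encoded as
empty fields (never zero).  Every write helper can embed a provenance
hash of the configuration that produced the artifact.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
import pandas as pd

from .errors import IntegrityError, SchemaError

__all__ = [
    "read_daily_panel",
    "write_daily_panel",
    "read_weekly_panel",
    "write_weekly_panel",
    "config_hash",
]

DAILY_COLUMNS = [
    "participant_id",
    "study_day",
    "week_index",
    "arm",
    "delivered",
    "message_id",
    "mood",
    "steps",
    "sleep_minutes",
]


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping, for provenance."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_daily_panel(daily: pd.DataFrame, path) -> None:
    missing = [c for c in DAILY_COLUMNS if c not in daily.columns]
    if missing:
        raise SchemaError(f"daily panel lacks columns: {missing}")
    out = daily[DAILY_COLUMNS].copy()
    out["delivered"] = out["delivered"].astype(int)
    out.to_csv(path, index=False, na_rep="")


def read_daily_panel(path) -> pd.DataFrame:
    """Read a daily panel CSV, validating its structure.

    Empty fields parse as missing (NaN), never zero.  Duplicate
    (participant, study_day) pairs and week/day inconsistencies raise
    :class:`IntegrityError`.
    """
    daily = pd.read_csv(
        path,
        dtype={
            "participant_id": int,
            "study_day": int,
            "week_index": int,
            "arm": str,
        },
        keep_default_na=True,
    )
    missing = [c for c in DAILY_COLUMNS if c not in daily.columns]
    if missing:
        raise SchemaError(f"daily panel lacks columns: {missing}")
    dup = daily.duplicated(["participant_id", "study_day"])
    if dup.any():
        raise IntegrityError(
            f"{int(dup.sum())} duplicate (participant_id, study_day) rows"
        )
    expected_week = np.ceil(daily["study_day"] / 7.0).astype(int)
    bad = daily["week_index"].to_numpy() != expected_week.to_numpy()
    if bad.any():
        raise IntegrityError(
            f"{int(bad.sum())} rows violate week_index == ceil(study_day / 7)"
        )
    daily["delivered"] = daily["delivered"].astype(bool)
    if "message_id" in daily.columns:
        daily["message_id"] = daily["message_id"].where(
            daily["message_id"].notna(), None
        )
    return daily


def write_weekly_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False, na_rep="")


def read_weekly_panel(path) -> pd.DataFrame:
    panel = pd.read_csv(path)
    for col in ("participant_id", "week", "arm", "y", "moderator"):
        if col not in panel.columns:
            raise SchemaError(f"weekly panel lacks column {col!r}")
    return panel
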