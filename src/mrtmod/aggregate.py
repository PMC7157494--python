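"""Daily-to-weekly aggregation and design-matrix construction.

The analysis unit is the participant-week: the outcome is the 7-day
average of the (possibly square-root transformed) daily measure, the
moderator is the previous week's average of the same quantity, and the
controls are the baseline-week average plus the previous week's averages
of all three measures on their analysis scales.  Treatment indicators are
centered at the known randomization probabilities, which is what makes
the moderation coefficients causally interpretable even when the control
part of the model is misspecified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ACTIVE_ARMS, ARMS, REFERENCE_ARM
from .errors import ConfigurationError, DataError

__all__ = ["weekly_panel", "build_design_matrix", "DesignMatrix", "LAG_COLUMNS"]

#: Analysis-scale lagged weekly averages attached as control candidates.
LAG_COLUMNS = {
    "mood": "lag_mood",
    "steps": "lag_sqrt_steps",
    "sleep_minutes": "lag_sqrt_sleep",
}

_TRANSFORMS = {"none", "sqrt"}

#: Full control-candidate set: intercept is implicit, the rest are panel
#: columns.  The outcome's own lagged average duplicates the moderator and
#: must not appear in both roles; use :func:`default_controls`.
DEFAULT_CONTROLS = ("baseline", "lag_mood", "lag_sqrt_steps", "lag_sqrt_sleep")


def default_controls(measure: str) -> tuple[str, ...]:
    """Controls for one outcome: baseline plus the other measures' lags.

    The outcome's own lagged weekly average serves as the moderator and is
    excluded here to keep the design matrix full rank.
    """
    own_lag = LAG_COLUMNS.get(measure)
    return tuple(c for c in DEFAULT_CONTROLS if c != own_lag)


def _analysis_values(daily: pd.DataFrame, measure: str, transform: str) -> pd.Series:
    vals = daily[measure].astype(float)
    if transform == "sqrt":
        if (vals.dropna() < 0).any():
            raise DataError(f"negative {measure} values under sqrt transform")
        return np.sqrt(vals)
    return vals


def weekly_panel(
    daily: pd.DataFrame,
    measure: str,
    transform: str = "none",
) -> pd.DataFrame:
    """Aggregate a daily panel into the weekly analysis panel.

    The transform (``"none"`` or ``"sqrt"``) is applied to each daily value
    *before* averaging; weekly averages use the available (non-missing)
    days and are NaN for weeks with no observed day.  Week ``t`` carries as
    moderator the week ``t-1`` average of the outcome's analysis-scale
    measure; week 1 uses the baseline week (week 0).  Lagged averages of
    all three measures and the baseline average of the outcome are attached
    as control-variable candidates.

    Returns one row per participant and study week (week >= 1) with columns
    participant_id, week, arm, y, n_days, moderator, baseline, lag_mood,
    lag_sqrt_steps, lag_sqrt_sleep.
    """
    if transform not in _TRANSFORMS:
        raise ConfigurationError(f"transform must be one of {_TRANSFORMS}")
    if measure not in LAG_COLUMNS:
        raise DataError(f"unknown measure {measure!r}")

    work = daily.copy()
    # analysis-scale columns for all three measures (steps/sleep on sqrt)
    analysis_cols = {}
    for m, lag_name in LAG_COLUMNS.items():
        t = "sqrt" if m != "mood" else "none"
        col = f"_a_{m}"
        work[col] = _analysis_values(work, m, t)
        analysis_cols[m] = col
    # the outcome's own analysis scale follows the requested transform
    work["_a_y"] = _analysis_values(work, measure, transform)

    grouped = work.groupby(["participant_id", "week_index"], sort=True)
    wk = grouped.agg(
        y=("_a_y", "mean"),
        n_days=("_a_y", "count"),
        arm=("arm", "first"),
        **{
            LAG_COLUMNS[m]: (analysis_cols[m], "mean")
            for m in LAG_COLUMNS
        },
    ).reset_index()

    # lag within participant: week t sees week t-1 averages
    wk = wk.sort_values(["participant_id", "week_index"], kind="stable")
    by_p = wk.groupby("participant_id", sort=False)
    shifted = by_p[["y", *LAG_COLUMNS.values()]].shift(1)
    wk["moderator"] = shifted["y"]
    for name in LAG_COLUMNS.values():
        wk[name] = shifted[name]

    # baseline = week-0 average of the outcome measure (analysis scale)
    base = (
        wk.loc[wk["week_index"] == 0, ["participant_id", "y"]]
        .rename(columns={"y": "baseline"})
    )
    wk = wk.merge(base, on="participant_id", how="left")

    panel = wk.loc[wk["week_index"] >= 1].rename(columns={"week_index": "week"})
    cols = [
        "participant_id",
        "week",
        "arm",
        "y",
        "n_days",
        "moderator",
        "baseline",
        *LAG_COLUMNS.values(),
    ]
    panel = panel[cols].reset_index(drop=True)
    panel.loc[panel["n_days"] == 0, "y"] = np.nan
    return panel


@dataclass
class DesignMatrix:
    """Regression-ready arrays for the weighted-centered least-squares fit."""

    y: np.ndarray
    X: np.ndarray
    columns: list[str]
    clusters: np.ndarray
    weights: np.ndarray
    arm_probs: dict[str, float]
    treatment_columns: list[str] = field(default_factory=list)
    n_dropped: int = 0

    @property
    def n_obs(self) -> int:
        return len(self.y)


def build_design_matrix(
    panel: pd.DataFrame,
    arm_probs: dict[str, float],
    moderator: str = "moderator",
    controls: tuple[str, ...] = DEFAULT_CONTROLS,
    treatment: str = "multi",
    weights: np.ndarray | None = None,
) -> DesignMatrix:
    """Build the centered design matrix for the moderation model.

    For ``treatment="multi"`` each active category k gets a centered
    indicator ``I(Z=k) - p_k`` and its interaction with the moderator;
    ``treatment="binary"`` collapses the three active arms into a single
    indicator centered at their total probability.  Weights default to 1,
    appropriate when centering uses the true randomization probabilities.

    Rows with any missing outcome, moderator or control are dropped
    (``n_dropped`` records how many); pass a post-imputation panel for a
    complete-data fit.
    """
    unknown = set(panel["arm"].unique()) - set(ARMS)
    if unknown:
        raise DataError(f"unknown arm labels: {sorted(unknown)}")
    probs = np.array([arm_probs.get(a, np.nan) for a in ARMS], dtype=float)
    if np.isnan(probs).any():
        raise ConfigurationError(f"arm_probs must have the keys {ARMS}")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ConfigurationError("arm probabilities must sum to 1")
    if treatment not in ("multi", "binary"):
        raise ConfigurationError("treatment must be 'multi' or 'binary'")

    needed = ["y", moderator, *controls]
    missing_cols = [c for c in needed if c not in panel.columns]
    if missing_cols:
        raise DataError(f"panel lacks required columns: {missing_cols}")

    keep = panel[needed].notna().all(axis=1).to_numpy()
    sub = panel.loc[keep]
    n_dropped = int((~keep).sum())

    m = sub[moderator].to_numpy(dtype=float)
    cols: list[np.ndarray] = [np.ones(len(sub))]
    names: list[str] = ["intercept"]
    for c in controls:
        cols.append(sub[c].to_numpy(dtype=float))
        names.append(c)
    cols.append(m)
    names.append(moderator)

    treat_names: list[str] = []
    arm = sub["arm"].to_numpy()
    if treatment == "multi":
        for k in ACTIVE_ARMS:
            p_k = arm_probs[k]
            centered = (arm == k).astype(float) - p_k
            cols.append(centered)
            names.append(f"trt_{k}")
            cols.append(centered * m)
            names.append(f"trt_{k}:{moderator}")
            treat_names += [f"trt_{k}", f"trt_{k}:{moderator}"]
    else:
        p_any = sum(arm_probs[k] for k in ACTIVE_ARMS)
        centered = (arm != REFERENCE_ARM).astype(float) - p_any
        cols.append(centered)
        names.append("trt_any")
        cols.append(centered * m)
        names.append(f"trt_any:{moderator}")
        treat_names += ["trt_any", f"trt_any:{moderator}"]

    X = np.column_stack(cols)
    y = sub["y"].to_numpy(dtype=float)
    clusters = sub["participant_id"].to_numpy()
    w = np.ones(len(sub)) if weights is None else np.asarray(weights, float)[keep]
    return DesignMatrix(
        y=y,
        X=X,
        columns=names,
        clusters=clusters,
        weights=w,
        arm_probs=dict(arm_probs),
        treatment_columns=treat_names,
        n_dropped=n_dropped,
    )
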