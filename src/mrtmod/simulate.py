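"""Synthetic micro-randomized trial generator.

Generates every layer of the trial with known ground truth: weekly arm
randomization, daily Bernoulli delivery, alternating tip/insight message
draws from without-replacement buckets, daily outcomes driven by a lag-1
moderation model, and logistic missing-at-random attrition.

The emitted daily panel includes a fully observed baseline week
(``week_index`` 0, study days -6..0) whose average supplies the week-1
moderator and the baseline control variable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import (
    ARMS,
    ARM_CODES,
    MEASURES,
    REFERENCE_ARM,
    DesignConfig,
    MissingnessSpec,
    TruthParams,
    _as_rng,
    default_missingness,
    default_truths,
)
from .errors import ConfigurationError, DataError

__all__ = [
    "randomize_weekly",
    "schedule_daily",
    "draw_messages",
    "generate_outcomes",
    "impose_missingness",
    "simulate_trial",
]


def randomize_weekly(config: DesignConfig, seed=None) -> pd.DataFrame:
    """Assign one notification arm per participant-week.

    In ``independent`` mode each week is an i.i.d. draw from
    ``config.arm_probs``.  In ``block`` mode the four arms are permuted
    within consecutive 4-week blocks (without-replacement randomization);
    a trailing partial block uses the leading arms of a fresh permutation.

    Returns a DataFrame with columns participant_id, week_index, arm.
    """
    rng = _as_rng(config.seed if seed is None else seed)
    n, T = config.n_participants, config.n_weeks

    if config.assignment_mode == "independent":
        codes = rng.choice(len(ARMS), size=(n, T), p=config.prob_vector)
    else:
        n_blocks = -(-T // 4)
        perms = np.argsort(
            rng.random((n, n_blocks, 4)), axis=2
        )  # independent 4-permutations
        codes = perms.reshape(n, n_blocks * 4)[:, :T]

    pid = np.repeat(np.arange(1, n + 1), T)
    week = np.tile(np.arange(1, T + 1), n)
    arm = np.asarray(ARMS, dtype=object)[codes.ravel()]
    return pd.DataFrame(
        {"participant_id": pid, "week_index": week, "arm": arm}
    )


def schedule_daily(
    assignments: pd.DataFrame, daily_prob: float, seed=None
) -> pd.DataFrame:
    """Expand weekly assignments to days and draw delivery flags.

    Within an active week each day delivers independently with probability
    ``daily_prob``; "none" weeks never deliver.  Study days are 1-based
    and satisfy week_index == ceil(study_day / 7).
    """
    if not 0.0 <= daily_prob <= 1.0:
        raise ConfigurationError("daily_prob must lie in [0, 1]")
    rng = _as_rng(seed)

    idx = assignments.index.repeat(7)
    daily = assignments.loc[idx].reset_index(drop=True)
    day_in_week = np.tile(np.arange(1, 8), len(assignments))
    daily["study_day"] = (daily["week_index"] - 1) * 7 + day_in_week
    active = (daily["arm"] != REFERENCE_ARM).to_numpy()
    delivered = np.zeros(len(daily), dtype=bool)
    delivered[active] = rng.random(active.sum()) < daily_prob
    daily["delivered"] = delivered
    return daily[["participant_id", "study_day", "week_index", "arm", "delivered"]]


def draw_messages(
    daily: pd.DataFrame, bucket_size: int, seed=None
) -> pd.DataFrame:
    """Attach message identifiers to delivered days.

    Per participant and category, consecutive delivered messages alternate
    between the two framing types ("tip", "insight").  Within each
    (category, type) bucket of ``bucket_size`` distinct messages, draws are
    without replacement; an emptied bucket is reshuffled and refilled.
    Message ids look like ``"mood-tip-3"``.
    """
    if bucket_size < 1:
        raise ConfigurationError("bucket_size must be >= 1")
    rng = _as_rng(seed)

    out = daily.sort_values(["participant_id", "study_day"], kind="stable")
    message_id = np.full(len(out), None, dtype=object)

    delivered_mask = out["delivered"].to_numpy()
    pids = out["participant_id"].to_numpy()
    arms = out["arm"].to_numpy()
    positions = np.flatnonzero(delivered_mask)

    # per-participant mutable draw state
    alternation: dict[tuple, int] = {}
    buckets: dict[tuple, list] = {}
    types = ("tip", "insight")

    for pos in positions:
        pid, cat = pids[pos], arms[pos]
        k = (pid, cat)
        turn = alternation.get(k, 0)
        mtype = types[turn % 2]
        alternation[k] = turn + 1
        bk = (pid, cat, mtype)
        bucket = buckets.get(bk)
        if not bucket:
            bucket = list(rng.permutation(bucket_size))
            buckets[bk] = bucket
        message_id[pos] = f"{cat}-{mtype}-{bucket.pop()}"

    out = out.copy()
    out["message_id"] = message_id
    return out.reset_index(drop=True)


def _to_analysis_scale(values: np.ndarray, params: TruthParams) -> np.ndarray:
    """Apply clipping/rounding on the generation (analysis) scale."""
    v = values
    if params.integer_scale:
        v = np.rint(v)
    if params.clip_range is not None:
        lo, hi = params.clip_range
        v = np.clip(v, lo if lo is not None else -np.inf,
                    hi if hi is not None else np.inf)
    if params.outcome_scale == "sqrt":
        v = np.maximum(v, 0.0)  # sqrt scale must stay real
    return v


def generate_outcomes(
    assignments: pd.DataFrame,
    params: TruthParams,
    seed=None,
    n_days: int = 7,
) -> np.ndarray:
    """Generate daily raw-scale outcome values for one measure.

    Returns an array of shape ``(n_participants, n_weeks + 1, n_days)``
    on the natural (raw) scale; index 0 along the week axis is the
    baseline week.  The weekly mean follows the lag-1 moderation model in
    :class:`~mrtmod.design.TruthParams`, with the moderator being the
    *realized* previous-week average on the analysis scale.  The baseline
    week is drawn from the stationary distribution of the untreated
    process.
    """
    rng = _as_rng(seed)
    wide = assignments.pivot(
        index="participant_id", columns="week_index", values="arm"
    ).sort_index()
    T = wide.shape[1]
    n = wide.shape[0]
    codes = wide.to_numpy()
    code_mat = np.vectorize(ARM_CODES.__getitem__)(codes)

    c, gamma = params.a0
    rho = params.a1
    # per-arm effect lookup, code order (none, activity, sleep, mood)
    b0 = np.concatenate([[0.0], np.asarray(params.b0, dtype=float)])
    b1 = np.concatenate([[0.0], np.asarray(params.b1, dtype=float)])

    u = rng.normal(0.0, params.subject_sd, size=n)
    # stationary within-person variance of the weekly mean, accounting for
    # the daily noise that feeds back through the realized moderator
    v_noise = params.resid_sd**2 + rho**2 * params.daily_sd**2 / n_days
    v_within = v_noise / (1.0 - rho**2)
    mu0 = (c + u) / (1.0 - rho) + rng.normal(0.0, np.sqrt(v_within), size=n)

    daily = np.empty((n, T + 1, n_days))
    week0 = mu0[:, None] + rng.normal(0.0, params.daily_sd, size=(n, n_days))
    obs0 = _to_analysis_scale(week0, params)
    daily[:, 0, :] = obs0**2 if params.outcome_scale == "sqrt" else obs0

    M = obs0.mean(axis=1)
    B = M.copy()  # baseline control variable (realized week-0 average)

    for t in range(1, T + 1):
        z = code_mat[:, t - 1]
        mu = (
            c
            + gamma * B
            + rho * M
            + b0[z]
            + b1[z] * M
            + u
            + rng.normal(0.0, params.resid_sd, size=n)
        )
        d = mu[:, None] + rng.normal(0.0, params.daily_sd, size=(n, n_days))
        obs = _to_analysis_scale(d, params)
        daily[:, t, :] = obs**2 if params.outcome_scale == "sqrt" else obs
        M = obs.mean(axis=1)

    return daily


def _weekly_observed_avg(values: np.ndarray, params: TruthParams) -> np.ndarray:
    """Analysis-scale weekly averages over non-missing days; NaN if none."""
    import warnings

    analysis = np.sqrt(values) if params.outcome_scale == "sqrt" else values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(analysis, axis=-1)


def impose_missingness(
    daily: pd.DataFrame,
    specs: dict[str, MissingnessSpec] | None = None,
    truths: dict[str, TruthParams] | None = None,
    seed=None,
) -> pd.DataFrame:
    """Blank daily values under a logistic missing-at-random mechanism.

    Missingness of each measure on each study day depends only on the week
    index and the previous week's observed average of that measure (carried
    forward across fully missing weeks); the baseline week stays fully
    observed.  Returns a copy with NaNs in place of missing values.
    """
    specs = default_missingness() if specs is None else specs
    truths = default_truths() if truths is None else truths
    rng = _as_rng(seed)

    out = daily.sort_values(["participant_id", "study_day"], kind="stable").copy()
    pids = out["participant_id"].to_numpy()
    weeks = out["week_index"].to_numpy()
    n = len(np.unique(pids))
    T = int(weeks.max())
    if weeks.min() != 0 or len(out) != n * (T + 1) * 7:
        raise DataError(
            "impose_missingness expects a complete daily panel including "
            "the baseline week (7 rows per participant-week, weeks 0..T)"
        )

    for measure, spec in specs.items():
        if measure not in out.columns:
            continue
        params = truths[measure]
        # (participant, week, day) value cube; baseline week at index 0
        vals = out[measure].to_numpy(dtype=float).reshape(n, T + 1, 7)
        observed = vals.copy()
        prev_avg = _weekly_observed_avg(observed[:, 0, :], params)
        last_avg = prev_avg.copy()
        for t in range(1, T + 1):
            p = spec.rate(np.full(n, t), last_avg)
            if np.any((p < 0) | (p > 1)):
                raise ConfigurationError("missingness rates must lie in [0, 1]")
            miss = rng.random((n, 7)) < p[:, None]
            observed[:, t, :][miss] = np.nan
            wk_avg = _weekly_observed_avg(observed[:, t, :], params)
            last_avg = np.where(np.isnan(wk_avg), last_avg, wk_avg)
        out[measure] = observed.reshape(-1)
    return out


def simulate_trial(
    config: DesignConfig,
    truths: dict[str, TruthParams] | None = None,
    missingness: dict[str, MissingnessSpec] | None = None,
    seed=None,
) -> pd.DataFrame:
    """Run the full generator and return a complete daily panel.

    Columns: participant_id, study_day, week_index, arm, delivered,
    message_id, mood, steps, sleep_minutes.  Week 0 is the fully observed
    baseline week (study days -6..0, arm "none", no deliveries).  Pass
    ``missingness=None`` with ``config`` defaults for attrition-shaped
    missing data, or ``missingness={}`` for a complete panel.
    """
    truths = default_truths() if truths is None else truths
    rng = _as_rng(config.seed if seed is None else seed)

    assignments = randomize_weekly(config, rng)
    daily = schedule_daily(assignments, config.daily_prob, rng)
    daily = draw_messages(daily, config.bucket_size, rng)

    # prepend the baseline week
    n = config.n_participants
    base = pd.DataFrame(
        {
            "participant_id": np.repeat(np.arange(1, n + 1), 7),
            "study_day": np.tile(np.arange(-6, 1), n),
            "week_index": 0,
            "arm": REFERENCE_ARM,
            "delivered": False,
            "message_id": None,
        }
    )
    daily = (
        pd.concat([base, daily], ignore_index=True)
        .sort_values(["participant_id", "study_day"], kind="stable")
        .reset_index(drop=True)
    )

    for measure in MEASURES:
        cube = generate_outcomes(assignments, truths[measure], rng)
        daily[measure] = cube.reshape(-1)

    if missingness is None:
        missingness = default_missingness()
    if missingness:
        daily = impose_missingness(daily, missingness, truths, rng)
    return daily
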