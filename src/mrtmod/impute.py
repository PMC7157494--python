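"""Daily-level multiple imputation and Rubin's-rules pooling.

Missing daily values are imputed on each measure's analysis scale (raw
mood, square-root steps/sleep) from a normal linear model with
participant baseline average, week index, day of week, current-week arm,
and the previous week's average as predictors.  Draws are stochastic and
"proper": each imputation stream draws the residual variance from its
scaled inverse-chi-square posterior and the coefficients from their
normal posterior before imputing, so between-imputation variance reflects
parameter uncertainty.  Imputation proceeds week by week so that imputed
values feed forward into the next week's lagged predictor, honoring the
longitudinal and sequentially randomized structure of the trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import ACTIVE_ARMS, MEASURES, _as_rng
from .errors import DataError, UsageError

__all__ = ["impute", "rubin_combine", "pool_coefficient", "CombinedEstimate"]

_Z975 = 1.96

#: Analysis-scale value bounds per measure: (low, high) on the scale the
#: imputation model works on; None = unbounded on that side.
_BOUNDS = {
    "mood": (1.0, 10.0),
    "steps": (0.0, None),
    "sleep_minutes": (0.0, None),
}

_SQRT_SCALE = {"mood": False, "steps": True, "sleep_minutes": True}


def _panel_cube(daily: pd.DataFrame, measure: str):
    """Reshape one measure into a (participant, week, day) cube on the
    analysis scale, verifying the complete 7-rows-per-week structure."""
    out = daily.sort_values(["participant_id", "study_day"], kind="stable")
    pids = out["participant_id"].to_numpy()
    weeks = out["week_index"].to_numpy()
    uniq = np.unique(pids)
    n = len(uniq)
    T = int(weeks.max())
    if weeks.min() != 0 or len(out) != n * (T + 1) * 7:
        raise DataError(
            "impute expects a structurally complete daily panel "
            "(weeks 0..T, 7 rows each) with NaN marking missing values"
        )
    vals = out[measure].to_numpy(dtype=float).reshape(n, T + 1, 7)
    if _SQRT_SCALE[measure]:
        vals = np.sqrt(vals)
    arms = out["arm"].to_numpy().reshape(n, T + 1, 7)[:, :, 0]
    return out, uniq, vals, arms, n, T


def _nanmean_rows(a: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(a, axis=-1)


def _build_rows(vals, arms, n, T):
    """Assemble the regression frame from observed study-week days."""
    prev_avg = np.empty((n, T + 1))
    prev_avg[:, 0] = np.nan
    last = _nanmean_rows(vals[:, 0, :])
    for t in range(1, T + 1):
        prev_avg[:, t] = last
        cur = _nanmean_rows(vals[:, t, :])
        last = np.where(np.isnan(cur), last, cur)
    baseline = _nanmean_rows(vals[:, 0, :])
    return prev_avg, baseline


def _design_rows(week, dow, prev, base, arm):
    """Predictor matrix: intercept, scaled week, prev avg, baseline,
    day-of-week dummies (ref day 1), active-arm dummies (ref none), and
    arm x prev-avg interactions.

    The interactions keep the imputation model congenial with the
    moderation analysis: without them, values imputed in treated weeks
    carry no moderation signal and the pooled moderation coefficient is
    attenuated toward zero.
    """
    cols = [
        np.ones_like(week, dtype=float),
        week / 26.0,
        prev,
        base,
    ]
    for d in range(2, 8):
        cols.append((dow == d).astype(float))
    for k in ACTIVE_ARMS:
        ind = (arm == k).astype(float)
        cols.append(ind)
        cols.append(ind * prev)
    return np.column_stack(cols)


def impute(
    daily: pd.DataFrame,
    M: int = 20,
    seed=None,
    measures: tuple[str, ...] = MEASURES,
) -> list[pd.DataFrame]:
    """Create ``M`` completed copies of a daily panel.

    With no missing values the result is ``M`` identical copies.  A
    participant whose baseline week is entirely missing for a measure
    falls back to the cohort baseline mean (with a warning).  All ``M``
    streams derive from one seed and are mutually independent.
    """
    if M < 1:
        raise UsageError("M must be >= 1")
    rng = _as_rng(seed)

    any_missing = daily[list(measures)].isna().any().any()
    if not any_missing:
        return [daily.copy() for _ in range(M)]

    completed = [
        daily.sort_values(["participant_id", "study_day"], kind="stable")
        .reset_index(drop=True)
        .copy()
        for _ in range(M)
    ]
    # one independent child stream per imputation
    streams = rng.spawn(M)

    for measure in measures:
        _, _, vals, arms, n, T = _panel_cube(daily, measure)
        if not np.isnan(vals).any():
            continue

        lo, hi = _BOUNDS[measure]
        prev_avg, baseline = _build_rows(vals, arms, n, T)
        if np.isnan(baseline).any():
            n_bad = int(np.isnan(baseline).sum())
            warnings.warn(
                f"{n_bad} participant(s) have a fully missing baseline week "
                f"for {measure}; falling back to the cohort baseline mean",
                stacklevel=2,
            )
            baseline = np.where(
                np.isnan(baseline), np.nanmean(baseline), baseline
            )

        # --- fit the conditional model on observed study-week days ---
        rows_X, rows_y = [], []
        for t in range(1, T + 1):
            wk_vals = vals[:, t, :]
            obs = ~np.isnan(wk_vals)
            if not obs.any():
                continue
            pi, di = np.nonzero(obs)
            ok = ~np.isnan(prev_avg[pi, t])
            pi, di = pi[ok], di[ok]
            X = _design_rows(
                np.full(len(pi), float(t)),
                di + 1,
                prev_avg[pi, t],
                baseline[pi],
                arms[pi, t],
            )
            rows_X.append(X)
            rows_y.append(wk_vals[pi, di])
        X_obs = np.vstack(rows_X)
        y_obs = np.concatenate(rows_y)
        XtX = X_obs.T @ X_obs
        beta_hat = np.linalg.lstsq(X_obs, y_obs, rcond=None)[0]
        resid = y_obs - X_obs @ beta_hat
        df = max(len(y_obs) - X_obs.shape[1], 1)
        s2 = float(resid @ resid) / df
        XtX_inv = np.linalg.pinv(XtX)

        for m_idx in range(M):
            srng = streams[m_idx]
            # posterior draws (proper imputation)
            sigma2 = s2 * df / srng.chisquare(df)
            beta = srng.multivariate_normal(
                beta_hat, sigma2 * XtX_inv, method="cholesky"
            )
            cube = vals.copy()
            # baseline week: fill from participant baseline mean + noise
            miss0 = np.isnan(cube[:, 0, :])
            if miss0.any():
                pi, di = np.nonzero(miss0)
                draw = baseline[pi] + srng.normal(0.0, np.sqrt(sigma2), len(pi))
                cube[pi, 0, di] = np.clip(
                    draw, lo if lo is not None else -np.inf,
                    hi if hi is not None else np.inf,
                )
            last = _nanmean_rows(cube[:, 0, :])
            for t in range(1, T + 1):
                wk = cube[:, t, :]
                miss = np.isnan(wk)
                if miss.any():
                    pi, di = np.nonzero(miss)
                    X = _design_rows(
                        np.full(len(pi), float(t)),
                        di + 1,
                        last[pi],
                        baseline[pi],
                        arms[pi, t],
                    )
                    draw = X @ beta + srng.normal(0.0, np.sqrt(sigma2), len(pi))
                    wk[pi, di] = np.clip(
                        draw, lo if lo is not None else -np.inf,
                        hi if hi is not None else np.inf,
                    )
                last = wk.mean(axis=1)
            filled = cube**2 if _SQRT_SCALE[measure] else cube
            completed[m_idx][measure] = filled.reshape(-1)

    return completed


@dataclass
class CombinedEstimate:
    """Rubin's-rules pooled scalar estimate across M imputations."""

    m: int
    estimate: float        # pooled point estimate Q-bar
    within: float          # mean within-imputation variance U-bar
    between: float         # between-imputation variance B
    total: float           # T = U-bar + (1 + 1/M) B
    df: float              # Rubin degrees of freedom (inf when B == 0)
    se: float
    statistic: float
    p_value: float
    ci_low: float
    ci_high: float

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "estimate": self.estimate,
            "within_variance": self.within,
            "between_variance": self.between,
            "total_variance": self.total,
            "df": self.df,
            "se": self.se,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "ci": [self.ci_low, self.ci_high],
        }


def rubin_combine(
    estimates,
    variances,
    df_method: str = "rubin",
    df_complete: float | None = None,
) -> CombinedEstimate:
    """Pool per-imputation estimates and variances with Rubin's rules.

    Q-bar is the mean estimate, B the sample variance of the estimates
    (denominator M-1), U-bar the mean of the variances, and
    T = U-bar + (1 + 1/M) B.  Degrees of freedom default to the classic
    nu = (M-1) (1 + U-bar / ((1+1/M) B))^2; ``df_method="barnard-rubin"``
    applies the small-sample adjustment and requires ``df_complete``.
    Inference uses Student's t with nu df (normal when B = 0).
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape or q.ndim != 1:
        raise UsageError("estimates and variances must be 1-d and equal length")
    m = len(q)
    if m < 2:
        raise UsageError("pooling needs >= 2 imputations")
    if (u < 0).any():
        raise UsageError("variances must be nonnegative")

    qbar = float(q.mean())
    ubar = float(u.mean())
    b = float(q.var(ddof=1))
    total = ubar + (1.0 + 1.0 / m) * b

    if b > 0.0:
        rel = ubar / ((1.0 + 1.0 / m) * b)
        with np.errstate(over="ignore"):
            nu = float((m - 1) * np.square(1.0 + np.float64(rel)))
        if df_method == "barnard-rubin":
            if df_complete is None:
                raise UsageError("barnard-rubin df needs df_complete")
            lam = (1.0 + 1.0 / m) * b / total
            nu_obs = (
                (1.0 - lam)
                * df_complete
                * (df_complete + 1.0)
                / (df_complete + 3.0)
            )
            nu = 1.0 / (1.0 / nu + 1.0 / nu_obs)
        elif df_method != "rubin":
            raise UsageError("df_method must be 'rubin' or 'barnard-rubin'")
    else:
        nu = np.inf

    se = float(np.sqrt(total))
    if se == 0.0:
        stat = 0.0 if qbar == 0.0 else np.sign(qbar) * np.inf
    else:
        stat = qbar / se
    if np.isinf(nu):
        p = 2.0 * stats.norm.sf(abs(stat))
        crit = _Z975
    else:
        p = 2.0 * stats.t.sf(abs(stat), nu)
        crit = float(stats.t.ppf(0.975, nu))
    return CombinedEstimate(
        m=m,
        estimate=qbar,
        within=ubar,
        between=b,
        total=total,
        df=float(nu),
        se=se,
        statistic=float(stat),
        p_value=float(min(p, 1.0)),
        ci_low=qbar - crit * se,
        ci_high=qbar + crit * se,
    )


def pool_coefficient(fits, name: str, **kwargs) -> CombinedEstimate:
    """Pool one named coefficient across a list of WCLS fits."""
    ests = [fit.coef(name) for fit in fits]
    varis = [fit.coef_se(name) ** 2 for fit in fits]
    return rubin_combine(ests, varis, **kwargs)
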