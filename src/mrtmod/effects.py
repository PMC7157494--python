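"""Moderated effect curves, retransformation, and report rendering.

A fitted moderation model gives, for each notification category k, a
linear effect line on the analysis scale,

    delta_k(m) = b0_k + b1_k * g(m),

where m is the moderator in natural units and g is the analysis
transform (identity for mood, square root for steps and sleep).  For
sqrt-scale outcomes the line is mapped back to natural units by
anchoring the no-notification mean at sqrt(m):

    natural effect(m) = (sqrt(m) + delta_k(sqrt(m)))^2 - m.

Standardized effect sizes divide the natural-scale effect by the
observed SD of the weekly-average outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ACTIVE_ARMS
from .errors import UsageError
from .wcls import WCLSFit

__all__ = [
    "EffectCurve",
    "effect_curve",
    "retransform_sqrt",
    "standardized_effect",
    "exploratory_curves",
    "render_report",
]


@dataclass
class EffectCurve:
    """One category's moderated treatment-effect line."""

    category: str
    grid: np.ndarray            # moderator values, natural units
    delta: np.ndarray           # analysis-scale effects delta(m)
    natural: np.ndarray         # natural-scale effects
    se: np.ndarray | None = None           # SE of delta on the analysis scale
    ci_low: np.ndarray | None = None       # analysis-scale CI for delta
    ci_high: np.ndarray | None = None
    transform: str = "none"
    b0: float = 0.0
    b1: float = 0.0

    @property
    def crossing(self) -> float | None:
        """Moderator value m* (natural units) where the effect is zero."""
        if self.b1 == 0.0:
            return None
        g_star = -self.b0 / self.b1
        if self.transform == "sqrt":
            return float(g_star**2) if g_star >= 0 else None
        return float(g_star)


def _delta_line(b0: float, b1: float, grid: np.ndarray, transform: str):
    g = np.sqrt(grid) if transform == "sqrt" else grid
    return b0 + b1 * g, g


def retransform_sqrt(delta, m):
    """Map a sqrt-scale effect back to natural units at moderator m.

    The no-notification weekly mean on the sqrt scale is anchored at
    sqrt(m), so the natural-scale effect is (sqrt(m) + delta)^2 - m.
    ``delta`` may be a scalar or an array aligned with ``m``.
    """
    m = np.asarray(m, dtype=float)
    if (m < 0).any():
        raise UsageError("moderator values must be nonnegative on a sqrt scale")
    root = np.sqrt(m)
    out = (root + np.asarray(delta, dtype=float)) ** 2 - m
    return out if out.ndim else float(out)


def standardized_effect(natural_effect: float, outcome_sd: float) -> float:
    """Effect divided by the weekly-average outcome SD."""
    if outcome_sd <= 0:
        raise UsageError("outcome SD must be positive")
    return float(natural_effect) / float(outcome_sd)


def _curve_from_coefs(
    b0, b1, grid, transform, category, cov=None
) -> EffectCurve:
    grid = np.asarray(grid, dtype=float)
    delta, g = _delta_line(b0, b1, grid, transform)
    natural = (
        retransform_sqrt(delta, grid) if transform == "sqrt" else delta.copy()
    )
    se = ci_low = ci_high = None
    if cov is not None:
        # var(delta(m)) = v00 + g^2 v11 + 2 g v01
        var = cov[0, 0] + g**2 * cov[1, 1] + 2.0 * g * cov[0, 1]
        se = np.sqrt(np.maximum(var, 0.0))
        ci_low = delta - 1.96 * se
        ci_high = delta + 1.96 * se
    return EffectCurve(
        category=category,
        grid=grid,
        delta=np.asarray(delta),
        natural=np.asarray(natural),
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        transform=transform,
        b0=float(b0),
        b1=float(b1),
    )


def effect_curve(
    fit: WCLSFit,
    category: str,
    grid,
    transform: str = "none",
    moderator: str = "moderator",
    plausible_range: tuple[float, float] | None = None,
) -> EffectCurve:
    """Evaluate one category's effect line over a moderator grid.

    ``category`` is an active arm name, or ``"any"`` for a binary-coded
    fit.  The grid is in natural units; for sqrt outcomes it is mapped
    through the transform before entering the line and the returned
    ``natural`` effects are retransformed back.  A grid outside
    ``plausible_range`` warns but still evaluates.
    """
    if plausible_range is not None:
        lo, hi = plausible_range
        g = np.asarray(grid, dtype=float)
        if (g < lo).any() or (g > hi).any():
            warnings.warn(
                f"grid extends beyond the plausible moderator range "
                f"[{lo}, {hi}]",
                stacklevel=2,
            )
    b0_name = f"trt_{category}"
    b1_name = f"trt_{category}:{moderator}"
    i, j = fit._index(b0_name), fit._index(b1_name)
    cov = fit.cov[np.ix_([i, j], [i, j])]
    return _curve_from_coefs(
        fit.coef(b0_name), fit.coef(b1_name), grid, transform, category, cov
    )


def exploratory_curves(
    fit: WCLSFit,
    grid,
    transform: str = "none",
    moderator: str = "moderator",
) -> dict[str, EffectCurve]:
    """Per-category effect lines plus a pooled reference line.

    Requires a multicategorical fit.  The pooled line uses the
    randomization-probability-weighted average of the category
    coefficients, so with uniform probabilities it lies inside the convex
    hull of the three category lines.
    """
    curves = {
        k: effect_curve(fit, k, grid, transform, moderator)
        for k in ACTIVE_ARMS
    }
    probs = np.array([fit.arm_probs[k] for k in ACTIVE_ARMS], dtype=float)
    wts = probs / probs.sum()
    b0_pool = float(sum(w * curves[k].b0 for w, k in zip(wts, ACTIVE_ARMS)))
    b1_pool = float(sum(w * curves[k].b1 for w, k in zip(wts, ACTIVE_ARMS)))
    curves["pooled"] = _curve_from_coefs(
        b0_pool, b1_pool, grid, transform, "pooled"
    )
    return curves


def render_report(
    curves: dict[str, EffectCurve] | EffectCurve,
    panel: pd.DataFrame,
    table_path,
    figure_path=None,
    moderator: str = "moderator",
    natural_moderator=None,
    n_bins: int = 30,
):
    """Write the effect table (CSV) and optional figure for a set of curves.

    The table has one row per (category, grid value) with the
    analysis-scale effect, its CI and the natural-scale effect.  The
    figure overlays the effect lines on a scaled histogram of the observed
    moderator (one bar set, drawn from the weekly panel).  Output is
    deterministic for fixed inputs.
    """
    if isinstance(curves, EffectCurve):
        curves = {curves.category: curves}
    if panel is None or len(panel) == 0:
        raise UsageError("render_report needs a non-empty weekly panel")

    rows = []
    for name, c in curves.items():
        for i, m in enumerate(c.grid):
            rows.append(
                {
                    "category": name,
                    "moderator": m,
                    "effect_analysis_scale": c.delta[i],
                    "ci_low": np.nan if c.ci_low is None else c.ci_low[i],
                    "ci_high": np.nan if c.ci_high is None else c.ci_high[i],
                    "effect_natural_scale": c.natural[i],
                }
            )
    table = pd.DataFrame(rows)
    table.to_csv(table_path, index=False, float_format="%.6g")

    mod_vals = (
        panel[moderator].dropna().to_numpy(dtype=float)
        if natural_moderator is None
        else np.asarray(natural_moderator, dtype=float)
    )
    counts, edges = np.histogram(mod_vals, bins=n_bins)

    if figure_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4.5))
        for name, c in curves.items():
            ax.plot(c.grid, c.natural, label=name)
            if c.ci_low is not None and c.transform == "none":
                ax.fill_between(c.grid, c.ci_low, c.ci_high, alpha=0.15)
        ax.axhline(0.0, color="grey", lw=0.8)
        # scaled moderator histogram along the x-axis
        span = max(
            float(np.nanmax([c.natural.max() for c in curves.values()])), 0.0
        ) - min(float(np.nanmin([c.natural.min() for c in curves.values()])), 0.0)
        base = min(float(np.nanmin([c.natural.min() for c in curves.values()])), 0.0)
        if counts.max() > 0:
            heights = counts / counts.max() * 0.15 * (span or 1.0)
            ax.bar(
                (edges[:-1] + edges[1:]) / 2.0,
                heights,
                width=np.diff(edges),
                bottom=base,
                color="lightsteelblue",
                alpha=0.6,
                zorder=0,
            )
        ax.set_xlabel("previous week's average (moderator)")
        ax.set_ylabel("estimated treatment effect")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(figure_path, dpi=150)
        plt.close(fig)

    return table
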