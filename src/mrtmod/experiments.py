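"""Replicated simulation experiments for estimator validation.

These are the operating-characteristic studies a trialist runs before
trusting the estimator: parameter recovery (bias), confidence-interval
coverage, and type-I error under a null moderation effect.  Each
replicate simulates a fresh trial, aggregates it, fits the
weighted-centered least-squares model, and records the moderation
coefficients with their cluster-robust intervals.

The outcome process used here is the continuous linear model the
estimator targets (no scale clipping or integer rounding), so that the
true coefficients are exactly defined; robustness to the bounded mood
scale is a separate, documented concern.
"""

from __future__ import annotations

import numpy as np

from .aggregate import build_design_matrix, default_controls, weekly_panel
from .design import (
    ACTIVE_ARMS,
    DesignConfig,
    TruthParams,
    _as_rng,
    default_truths,
)
from .simulate import simulate_trial
from .wcls import fit_wcls, test_coefficient

__all__ = ["moderation_coefficients", "replicate_experiment", "linear_truth"]

#: Moderation-coefficient column names, active-arm order.
MODERATION_COEFS = tuple(f"trt_{k}:moderator" for k in ACTIVE_ARMS)


def linear_truth(
    b1: tuple[float, float, float] = (-0.052, -0.075, -0.039),
    b0: tuple[float, float, float] | None = None,
) -> TruthParams:
    """Mood-calibrated truth on a continuous, unclipped scale.

    Used by the recovery/coverage/type-I experiments: without the bounded
    integer mood scale the generative mean is exactly linear, so the true
    moderation coefficients are the supplied ``b1``.
    """
    base = default_truths()["mood"]
    return base.with_(
        b1=tuple(b1),
        b0=base.b0 if b0 is None else tuple(b0),
        clip_range=None,
        integer_scale=False,
    )


def moderation_coefficients(
    daily, outcome: str = "mood", transform: str = "none", arm_probs=None
):
    """Aggregate, fit, and return the per-category moderation tests."""
    if arm_probs is None:
        arm_probs = {a: 0.25 for a in ("none", *ACTIVE_ARMS)}
    panel = weekly_panel(daily, outcome, transform)
    design = build_design_matrix(
        panel, arm_probs, controls=default_controls(outcome)
    )
    fit = fit_wcls(design)
    return {name: test_coefficient(fit, name) for name in MODERATION_COEFS}


def replicate_experiment(
    n_reps: int,
    n_participants: int = 300,
    n_weeks: int = 26,
    truth: TruthParams | None = None,
    seed: int = 0,
) -> dict:
    """Run ``n_reps`` simulate-aggregate-fit replicates on the mood outcome.

    Returns, per moderation coefficient: the vector of estimates, mean
    bias against the truth, empirical CI coverage of the truth, and the
    rejection rate of the nominal-0.05 test of a zero coefficient.
    """
    truth = linear_truth() if truth is None else truth
    others = default_truths()
    true_b1 = dict(zip(MODERATION_COEFS, truth.b1))
    rng = _as_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_reps)

    est = {n: np.empty(n_reps) for n in MODERATION_COEFS}
    covered = {n: np.zeros(n_reps, dtype=bool) for n in MODERATION_COEFS}
    rejected = {n: np.zeros(n_reps, dtype=bool) for n in MODERATION_COEFS}
    for r in range(n_reps):
        cfg = DesignConfig(
            n_participants=n_participants, n_weeks=n_weeks, seed=int(seeds[r])
        )
        daily = simulate_trial(
            cfg,
            {
                "mood": truth,
                "steps": others["steps"],
                "sleep_minutes": others["sleep_minutes"],
            },
            missingness={},
        )
        tests = moderation_coefficients(daily)
        for name, t in tests.items():
            est[name][r] = t.estimate
            covered[name][r] = t.ci_low <= true_b1[name] <= t.ci_high
            rejected[name][r] = t.p_value < 0.05

    return {
        name: {
            "estimates": est[name],
            "true": true_b1[name],
            "bias": float(est[name].mean() - true_b1[name]),
            "coverage": float(covered[name].mean()),
            "rejection_rate": float(rejected[name].mean()),
        }
        for name in MODERATION_COEFS
    }
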