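"""Trial design and generative-truth configuration.

The trial emulated here is a 26-week micro-randomized trial (MRT): every
week each participant is randomized to one of four notification arms
(activity, sleep, mood, or none), and on every day of an active week a
notification is independently delivered with probability 0.5.  Outcomes are
daily mood valence (integer 1-10 scale), daily step count, and daily sleep
minutes; analyses use 7-day weekly averages, with steps and sleep analysed
on the square-root scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError

#: Active notification categories, in the coefficient-dimension order used
#: throughout (dimension 1 = activity, 2 = sleep, 3 = mood).
ACTIVE_ARMS: tuple[str, ...] = ("activity", "sleep", "mood")

#: Reference (control) arm: a week with no notifications.
REFERENCE_ARM: str = "none"

#: All arms. Integer codes used internally: none=0, activity=1, sleep=2, mood=3.
ARMS: tuple[str, ...] = (REFERENCE_ARM,) + ACTIVE_ARMS

ARM_CODES: dict[str, int] = {arm: i for i, arm in enumerate(ARMS)}

#: Outcome measures and the scale each is analysed on.
MEASURES: tuple[str, ...] = ("mood", "steps", "sleep_minutes")

_PROB_TOL = 1e-12


def _as_rng(seed) -> np.random.Generator:
    """Accept an int seed, a Generator, or None (fresh entropy)."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class DesignConfig:
    """Randomization design of the trial.

    Parameters
    ----------
    n_participants:
        Number of participants (the trial enrolled 1565).
    n_weeks:
        Number of randomized weeks; at least 2 so that a lagged moderator
        exists for every analysed week.
    arm_probs:
        Weekly randomization probability for each arm, keyed by arm name.
        Must sum to 1.  Default is uniform over the four arms.
    daily_prob:
        Probability of delivering a notification on each day of an active
        week (independent across days).  The trial used 0.5, giving an
        average of 3.5 notifications in an active week.
    bucket_size:
        Number of distinct messages per (category, type) bucket; messages
        are drawn without replacement and the bucket refills when empty.
    assignment_mode:
        ``"independent"`` draws each week i.i.d. from ``arm_probs``;
        ``"block"`` permutes the four arms within consecutive 4-week blocks
        (randomization without replacement, the deviation the trial
        actually ran).
    seed:
        Default seed for simulation entry points that are not handed one.
    """

    n_participants: int = 1565
    n_weeks: int = 26
    arm_probs: dict[str, float] = field(
        default_factory=lambda: {arm: 0.25 for arm in ARMS}
    )
    daily_prob: float = 0.5
    bucket_size: int = 7
    assignment_mode: str = "independent"
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if self.n_weeks < 2:
            raise ConfigurationError(
                "n_weeks must be >= 2 (the moderator is the previous week)"
            )
        if set(self.arm_probs) != set(ARMS):
            raise ConfigurationError(
                f"arm_probs must have exactly the keys {ARMS}"
            )
        probs = np.array([self.arm_probs[a] for a in ARMS], dtype=float)
        if (probs < 0).any() or (probs > 1).any():
            raise ConfigurationError("arm probabilities must lie in [0, 1]")
        if abs(probs.sum() - 1.0) > _PROB_TOL:
            raise ConfigurationError(
                f"arm probabilities must sum to 1 (got {probs.sum()!r})"
            )
        if not 0.0 <= self.daily_prob <= 1.0:
            raise ConfigurationError("daily_prob must lie in [0, 1]")
        if self.bucket_size < 1:
            raise ConfigurationError("bucket_size must be >= 1")
        if self.assignment_mode not in ("independent", "block"):
            raise ConfigurationError(
                "assignment_mode must be 'independent' or 'block'"
            )

    @property
    def prob_vector(self) -> np.ndarray:
        """Arm probabilities in code order (none, activity, sleep, mood)."""
        return np.array([self.arm_probs[a] for a in ARMS], dtype=float)


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth generative parameters for one outcome measure.

    The weekly mean on the analysis scale follows

        mu_t = a0[0] + a0[1] * B + a1 * M_t
               + sum_k (b0[k] + b1[k] * M_t) * I(Z_t = k)
               + u_i + eps_t

    where ``M_t`` is the realized previous-week average on the analysis
    scale, ``B`` the baseline-week average, ``u_i ~ N(0, subject_sd^2)`` a
    participant intercept and ``eps_t ~ N(0, resid_sd^2)`` weekly noise.
    Daily values add ``N(0, daily_sd^2)`` around the weekly mean; for
    ``outcome_scale="sqrt"`` generation happens on the square-root scale
    and daily values are squared back to natural units.

    ``b0``/``b1`` are indexed in the active-arm order (activity, sleep,
    mood); the "none" arm is the reference and contributes nothing.
    """

    a0: tuple[float, float] = (0.0, 0.0)  # (intercept, baseline coefficient)
    a1: float = 0.5                       # lag-1 autoregressive pull
    b0: tuple[float, float, float] = (0.0, 0.0, 0.0)
    b1: tuple[float, float, float] = (0.0, 0.0, 0.0)
    subject_sd: float = 0.0
    resid_sd: float = 0.0
    daily_sd: float = 0.0
    outcome_scale: str = "raw"            # "raw" | "sqrt"
    clip_range: tuple[float, float] | None = None
    integer_scale: bool = False           # round daily values (mood EMA)

    def __post_init__(self):
        for name in ("subject_sd", "resid_sd", "daily_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if len(self.b0) != len(ACTIVE_ARMS) or len(self.b1) != len(ACTIVE_ARMS):
            raise ConfigurationError(
                f"b0 and b1 need one entry per active arm {ACTIVE_ARMS}"
            )
        if self.outcome_scale not in ("raw", "sqrt"):
            raise ConfigurationError("outcome_scale must be 'raw' or 'sqrt'")
        if not -1.0 < self.a1 < 1.0:
            raise ConfigurationError(
                "a1 must lie in (-1, 1) for a stationary lag-1 process"
            )

    def with_(self, **kwargs) -> "TruthParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def default_truth(measure: str) -> TruthParams:
    """Calibrated ground truth for one of the three outcome measures.

    Intercepts and noise components are calibrated so that simulated
    weekly-average marginals at the study's size reproduce the observed
    summary statistics (mood mean 7.21, SD 1.43; steps mean 8274, SD 3285;
    sleep mean 6.54 h, SD 1.25 h), and the moderation coefficients equal
    the study's estimates: mood slopes about -0.05 per category, steps
    b1 = -0.039 (activity dimension, sqrt scale), sleep b1 = -0.075
    (sleep dimension, sqrt-minutes scale).
    """
    if measure == "mood":
        # Effect lines per category pass through (m=3, +0.19/0.16/0.23)
        # and (m=9, -0.12/-0.14/-0.09) for mood/activity/sleep messages.
        return TruthParams(
            a0=(3.667, 0.0),
            a1=0.5,
            b0=(0.31, 0.39, 0.345),        # activity, sleep, mood
            b1=(-0.05, -0.16 / 3, -0.31 / 6),
            subject_sd=0.68,
            resid_sd=0.68,
            daily_sd=1.20,
            outcome_scale="raw",
            clip_range=(1.0, 10.0),
            integer_scale=True,
        )
    if measure == "steps":
        # sqrt scale; mean weekly sqrt-steps ~ 90.96 = sqrt(8274).
        return TruthParams(
            a0=(44.06, 0.0),
            a1=0.5,
            b0=(4.017, 0.0, 0.0),          # activity dimension only
            b1=(-0.039, 0.0, 0.0),
            subject_sd=7.25,
            resid_sd=8.78,
            daily_sd=12.0,
            outcome_scale="sqrt",
            clip_range=(0.0, None),
        )
    if measure == "sleep_minutes":
        # sqrt-minutes scale; mean weekly sqrt-minutes ~ 19.81 = sqrt(392.4).
        return TruthParams(
            a0=(9.79, 0.0),
            a1=0.5,
            b0=(0.0, 1.5284, 0.0),         # sleep dimension only
            b1=(0.0, -0.075, 0.0),
            subject_sd=0.73,
            resid_sd=0.80,
            daily_sd=2.0,
            outcome_scale="sqrt",
            clip_range=(0.0, None),
        )
    raise ConfigurationError(f"unknown measure {measure!r}; expected one of {MEASURES}")


def default_truths() -> dict[str, TruthParams]:
    """Calibrated truth for all three measures."""
    return {m: default_truth(m) for m in MEASURES}


@dataclass(frozen=True)
class MissingnessSpec:
    """Logistic missing-at-random mechanism for one measure.

    The probability that a given day's value is missing is

        logit p = intercept + week_slope * (week - 1)
                  + prev_slope * (prev_week_avg - center)

    where ``prev_week_avg`` is the previous week's *observed* average on
    the analysis scale (carried forward over fully missing weeks, falling
    back to the baseline week).  Missingness never depends on the current
    unobserved value, so the mechanism is MAR by construction.
    """

    intercept: float = -np.inf  # -inf => never missing
    week_slope: float = 0.0
    prev_slope: float = 0.0
    center: float = 0.0

    def rate(self, week: np.ndarray, prev_avg: np.ndarray) -> np.ndarray:
        eta = (
            self.intercept
            + self.week_slope * (np.asarray(week, dtype=float) - 1.0)
            + self.prev_slope * (np.asarray(prev_avg, dtype=float) - self.center)
        )
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + np.exp(-eta))


def default_missingness() -> dict[str, MissingnessSpec]:
    """Attrition-shaped defaults: response rates decline over the study.

    Mood (a self-report survey) is missing more often than the wearable
    streams, and all three streams become sparser late in the trial.
    """
    return {
        "mood": MissingnessSpec(
            intercept=-1.10, week_slope=0.040, prev_slope=-0.05, center=7.21
        ),
        "steps": MissingnessSpec(
            intercept=-1.90, week_slope=0.035, prev_slope=0.0, center=91.0
        ),
        "sleep_minutes": MissingnessSpec(
            intercept=-1.90, week_slope=0.035, prev_slope=0.0, center=19.8
        ),
    }
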