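"""Weighted-and-centered least squares with cluster-robust inference.

The estimator regresses the weekly outcome on controls, the moderator,
probability-centered treatment indicators and their moderator
interactions, then assesses uncertainty with the participant-clustered
sandwich covariance B^{-1} M B^{-1} (bread B = sum_i X_i' W_i X_i, meat
M = sum_i X_i' W_i r_i r_i' W_i X_i).  Because each week's treatment is
randomized with known probabilities, the coefficients on the centered
columns estimate causal (excursion) effects relative to no-notification
weeks, and remain unbiased even when the control part of the model is
misspecified.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .aggregate import DesignMatrix
from .errors import InferenceError, RankDeficiencyError, UsageError

__all__ = ["WCLSFit", "CoefficientTest", "fit_wcls", "test_coefficient"]

_Z975 = 1.96  # normal 97.5% point, as conventionally reported


@dataclass
class WCLSFit:
    """A fitted moderation model with cluster-sandwich covariance."""

    params: np.ndarray
    cov: np.ndarray
    columns: list[str]
    n_clusters: int
    n_obs: int
    arm_probs: dict[str, float]

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def coef(self, name: str) -> float:
        return float(self.params[self._index(name)])

    def coef_se(self, name: str) -> float:
        return float(self.se[self._index(name)])

    def _index(self, name: str) -> int:
        try:
            return self.columns.index(name)
        except ValueError:
            raise UsageError(
                f"unknown coefficient {name!r}; available: {self.columns}"
            ) from None

    def to_dict(self) -> dict:
        """JSON-ready summary of the fit (round-trippable)."""
        tests = {name: test_coefficient(self, name).to_dict() for name in self.columns}
        return {
            "columns": list(self.columns),
            "coefficients": dict(zip(self.columns, map(float, self.params))),
            "covariance": self.cov.tolist(),
            "tests": tests,
            "n_clusters": self.n_clusters,
            "n_obs": self.n_obs,
            "arm_probs": self.arm_probs,
        }

    def to_json(self, path, extra: dict | None = None) -> None:
        payload = self.to_dict()
        if extra:
            payload.update(extra)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "WCLSFit":
        cols = list(d["columns"])
        return cls(
            params=np.array([d["coefficients"][c] for c in cols], dtype=float),
            cov=np.asarray(d["covariance"], dtype=float),
            columns=cols,
            n_clusters=int(d["n_clusters"]),
            n_obs=int(d["n_obs"]),
            arm_probs=dict(d["arm_probs"]),
        )

    @classmethod
    def from_json(cls, path) -> "WCLSFit":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class CoefficientTest:
    """Wald test of one coefficient against zero."""

    name: str
    estimate: float
    se: float
    statistic: float
    p_value: float
    ci_low: float
    ci_high: float

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "se": self.se,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "ci": [self.ci_low, self.ci_high],
        }


def _collinear_columns(X: np.ndarray, columns: list[str]) -> list[str]:
    """Name the columns beyond the numerical rank, via pivoted QR."""
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    return [columns[j] for j in sorted(piv[rank:])]


def fit_wcls(design: DesignMatrix) -> WCLSFit:
    """Solve the weighted least-squares normal equations and the sandwich.

    Raises :class:`RankDeficiencyError` naming the collinear columns when
    the normal equations are singular, and :class:`InferenceError` when
    fewer than two participant clusters are present.
    """
    X, y, w = design.X, design.y, design.weights
    if np.isnan(X).any() or np.isnan(y).any():
        raise UsageError("design matrix contains missing cells")
    clusters = design.clusters
    uniq = np.unique(clusters)
    if len(uniq) < 2:
        raise InferenceError("cluster-robust inference needs >= 2 clusters")

    Xw = X * w[:, None]
    bread = X.T @ Xw
    p = X.shape[1]
    rank = np.linalg.matrix_rank(bread)
    if rank < p:
        raise RankDeficiencyError(_collinear_columns(X * np.sqrt(w)[:, None],
                                                     design.columns))
    beta = np.linalg.solve(bread, Xw.T @ y)
    resid = y - X @ beta

    # meat: sum over clusters of (X' W r)(X' W r)'
    wr = w * resid
    order = np.argsort(clusters, kind="stable")
    sorted_scores = (X[order] * wr[order, None])
    _, starts = np.unique(clusters[order], return_index=True)
    cluster_scores = np.add.reduceat(sorted_scores, starts, axis=0)
    meat = cluster_scores.T @ cluster_scores

    bread_inv = np.linalg.inv(bread)
    cov = bread_inv @ meat @ bread_inv
    cov = (cov + cov.T) / 2.0  # enforce symmetry against roundoff

    return WCLSFit(
        params=beta,
        cov=cov,
        columns=list(design.columns),
        n_clusters=len(uniq),
        n_obs=len(y),
        arm_probs=design.arm_probs,
    )


def test_coefficient(
    fit: WCLSFit, which: str, reference: str = "normal"
) -> CoefficientTest:
    """Two-sided Wald test of one coefficient against zero.

    ``reference="normal"`` (default, appropriate for the trial's 1565
    clusters) uses the standard normal and a +/- 1.96 SE interval;
    ``reference="t"`` uses Student's t with clusters - parameters degrees
    of freedom for small-sample work.
    """
    est = fit.coef(which)
    se = fit.coef_se(which)
    if se == 0.0:
        stat = 0.0 if est == 0.0 else np.sign(est) * np.inf
    else:
        stat = est / se
    if reference == "normal":
        p = 2.0 * stats.norm.sf(abs(stat))
        crit = _Z975
    elif reference == "t":
        df = fit.n_clusters - len(fit.columns)
        if df <= 0:
            raise InferenceError("no degrees of freedom for the t reference")
        p = 2.0 * stats.t.sf(abs(stat), df)
        crit = stats.t.ppf(0.975, df)
    else:
        raise UsageError("reference must be 'normal' or 't'")
    return CoefficientTest(
        name=which,
        estimate=est,
        se=se,
        statistic=float(stat),
        p_value=float(min(p, 1.0)),
        ci_low=est - crit * se,
        ci_high=est + crit * se,
    )
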