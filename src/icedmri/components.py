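"""Variance components of the reliability model and derived quantities.

The model splits the total variance of a repeated measurement into four
orthogonal compartments: true-score variance ``var_t`` (stable
between-person differences), day-specific error ``var_d``, session-
specific error ``var_s`` (the effect of repositioning), and residual
error ``var_e``.  ICC is the share of true-score variance in the total;
ICC2 is the construct-level reliability of the whole design, using the
effective error of the optimal composite of all occasions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import StudyDesign

__all__ = [
    "VarianceComponents",
    "rescale_components",
    "icc",
    "model_covariance",
    "error_covariance",
    "effective_error",
    "icc2",
]

COMPONENT_NAMES = ("var_t", "var_d", "var_s", "var_e")


@dataclass(frozen=True)
class VarianceComponents:
    """The four variance compartments, on the scale of the data (units²)."""

    var_t: float
    var_d: float
    var_s: float
    var_e: float

    def __post_init__(self):
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("variance components must be finite")
        if np.any(arr < 0):
            raise ValueError("variance components must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.var_t, self.var_d, self.var_s, self.var_e], float)

    @classmethod
    def from_array(cls, arr) -> "VarianceComponents":
        t, d, s, e = (float(x) for x in arr)
        return cls(t, d, s, e)

    @property
    def total(self) -> float:
        return float(self.as_array().sum())


def rescale_components(vc: VarianceComponents) -> VarianceComponents:
    """Rescale the components so they sum to one.

    The rescaled values are interpretable as relative contributions to
    the total observed variance; the true-score proportion equals the
    ICC.  Raises on an all-zero input.
    """
    total = vc.total
    if total <= 0:
        raise ValueError("cannot rescale all-zero variance components")
    return VarianceComponents.from_array(vc.as_array() / total)


def icc(vc: VarianceComponents) -> float:
    """Ratio of between-person (true-score) variance to total variance."""
    total = vc.total
    if total <= 0:
        raise ValueError("total variance is zero; ICC undefined")
    return vc.var_t / total


def model_covariance(vc: VarianceComponents, design: StudyDesign) -> np.ndarray:
    """Model-implied k x k covariance of one person's occasion vector.

    Sigma = var_t * J + var_d * C_day + var_s * C_session + var_e * I,
    with J the all-ones matrix and C the binary co-membership
    indicators.  Always positive semidefinite for non-negative
    components.
    """
    k = design.k
    return (
        vc.var_t * np.ones((k, k))
        + vc.var_d * design.comembership("day")
        + vc.var_s * design.comembership("session")
        + vc.var_e * np.eye(k)
    )


def error_covariance(vc: VarianceComponents, design: StudyDesign) -> np.ndarray:
    """The error part of the model covariance (everything but var_t)."""
    k = design.k
    return (
        vc.var_d * design.comembership("day")
        + vc.var_s * design.comembership("session")
        + vc.var_e * np.eye(k)
    )


def effective_error(vc: VarianceComponents, design: StudyDesign) -> float:
    """Error variance of the optimal composite of all k occasions.

    The best linear unbiased (precision-weighted) estimate of a
    person's true score from the k occasions has error variance
    1 / sum(inv(E)) where E is the error covariance.  With only
    residual error present this reduces to var_e / k.
    """
    E = error_covariance(vc, design)
    if np.allclose(E, 0):
        return 0.0
    try:
        Einv = np.linalg.inv(E)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "error covariance is singular; effective error undefined"
        ) from exc
    denom = float(Einv.sum())
    if denom <= 0:
        raise np.linalg.LinAlgError("error covariance is not positive definite")
    return 1.0 / denom


def icc2(vc: VarianceComponents, design: StudyDesign) -> float:
    """Construct-level reliability of the whole design.

    var_t / (var_t + effective_error); reduces to the classical
    k-occasion ICC2 = var_t / (var_t + var_e/k) when day and session
    variances are zero.
    """
    eff = effective_error(vc, design)
    denom = vc.var_t + eff
    if denom <= 0:
        raise ValueError("var_t + effective error is zero; ICC2 undefined")
    return vc.var_t / denom
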