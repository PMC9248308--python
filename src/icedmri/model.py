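"""Maximum-likelihood variance-component reliability model (ICED).

The model assumes each person's vector of k repeated measurements is
multivariate normal with a saturated mean structure (one free mean per
occasion) and a linearly structured covariance

    Sigma(theta) = var_t * J + var_d * C_day + var_s * C_sess + var_e * I

where J is all-ones and the C matrices are binary co-membership
indicators derived from the study design.  Estimation maximises the
full-information Gaussian likelihood under a lower bound on each free
component (0.0001 on the scale of the data by default).  The saturated
means are profiled out analytically as the occasion-wise sample means,
so the likelihood reduces to a function of the ML sample covariance S:

    loglik = -N/2 * (k*log(2*pi) + log|Sigma| + tr(S Sigma^-1)).

Component significance uses likelihood-ratio tests against null models
with the component pinned at zero (true/day/session variance) and a
Wald test from the observed information (residual variance, whose null
model is not estimable).  Confidence intervals for ICC and ICC2 come
from a person-level nonparametric bootstrap with percentile intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .components import (
    COMPONENT_NAMES,
    VarianceComponents,
    effective_error,
    icc as _icc,
    icc2 as _icc2,
    model_covariance,
    rescale_components,
)
from .dataset import ReliabilityDataset
from .design import StudyDesign

__all__ = [
    "ICEDModel",
    "ICEDResults",
    "FitStats",
    "ModelComparison",
    "fit_iced",
    "log_likelihood",
]

DEFAULT_LOWER_BOUND = 1e-4
_ALL = frozenset(COMPONENT_NAMES)


@dataclass(frozen=True)
class FitStats:
    """Exact-fit statistics of the structured covariance model.

    chisq is (N-1) times the ML discrepancy between the fitted and the
    saturated covariance model; df = k(k+1)/2 minus the number of free
    variance components; RMSEA = sqrt(max(chisq - df, 0) / (df*(N-1))).
    """

    chisq: float
    df: int
    rmsea: float


@dataclass(frozen=True)
class ModelComparison:
    """A single-component significance test (df = 1)."""

    component: str
    statistic: float
    df: int
    p_value: float
    kind: str  # "lrt" or "wald"

    @property
    def delta_chisq(self) -> float:
        return self.statistic


def _component_matrices(design: StudyDesign) -> list[np.ndarray]:
    k = design.k
    return [
        np.ones((k, k)),
        design.comembership("day"),
        design.comembership("session"),
        np.eye(k),
    ]


class ICEDModel:
    """Reliability variance-decomposition model for one ROI/modality.

    Parameters
    ----------
    data
        A :class:`ReliabilityDataset`, or an (n_persons, k) array when
        ``design`` is given.
    design
        Required when ``data`` is a bare array.

    Examples
    --------
    >>> from icedmri import simulate_roi_dataset, SyntheticSpec
    >>> from icedmri.design import default_mpm_design
    >>> from icedmri.components import VarianceComponents
    >>> spec = SyntheticSpec(100, default_mpm_design(), [0.87] * 4,
    ...                      VarianceComponents(0.6, 0.1, 0.1, 0.2), seed=7)
    >>> res = ICEDModel(simulate_roi_dataset(spec)).fit()
    >>> 0 <= res.icc <= 1
    True
    """

    def __init__(self, data, design: Optional[StudyDesign] = None):
        if isinstance(data, ReliabilityDataset):
            self.data = data
        else:
            if design is None:
                raise ValueError("design is required when data is an array")
            self.data = ReliabilityDataset(data, design)
        self.design = self.data.design
        self.k = self.design.k
        self.n_persons = self.data.n_persons
        # sufficient statistics under the saturated (profiled) means
        self.occasion_means = self.data.values.mean(axis=0)
        centred = self.data.values - self.occasion_means
        self._S = centred.T @ centred / self.n_persons  # ML (divisor N)
        self._G = _component_matrices(self.design)

    # -- likelihood --------------------------------------------------------

    def loglike(self, vc: VarianceComponents, means=None) -> float:
        """Gaussian log-likelihood of the data at (vc, means).

        With ``means=None`` the occasion-wise sample means (their ML
        values) are used.
        """
        Sigma = model_covariance(vc, self.design)
        sign, logdet = np.linalg.slogdet(Sigma)
        if sign <= 0:
            raise np.linalg.LinAlgError("model covariance is singular")
        if means is None:
            quad = float(np.trace(np.linalg.solve(Sigma, self._S))) * self.n_persons
        else:
            means = np.asarray(means, float)
            resid = self.data.values - means
            quad = float(np.einsum("ij,ij->", resid @ np.linalg.inv(Sigma), resid))
        n, k = self.n_persons, self.k
        return -0.5 * (n * k * np.log(2 * np.pi) + n * logdet + quad)

    def _negll_grad(self, theta: np.ndarray, S: np.ndarray):
        """Negative profiled log-likelihood and gradient (constants dropped).

        Works on whatever scale S is provided on; theta holds all four
        components in the order of COMPONENT_NAMES.
        """
        Sigma = sum(t * G for t, G in zip(theta, self._G))
        try:
            L = np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError:
            return 1e12, np.zeros(4)
        A = np.linalg.inv(Sigma)  # k is tiny; explicit inverse is fine
        logdet = 2.0 * float(np.log(np.diag(L)).sum())
        f = 0.5 * self.n_persons * (logdet + float(np.sum(A * S)))
        ASA = A @ S @ A
        R = A - ASA
        g = np.array([0.5 * self.n_persons * float(np.sum(R * G)) for G in self._G])
        return f, g

    def _hessian(self, theta: np.ndarray, S: np.ndarray) -> np.ndarray:
        """Analytic observed information (Hessian of the negative loglik)."""
        Sigma = sum(t * G for t, G in zip(theta, self._G))
        A = np.linalg.inv(Sigma)
        ASA = A @ S @ A
        H = np.empty((4, 4))
        for i, Gi in enumerate(self._G):
            for j, Gj in enumerate(self._G):
                H[i, j] = 0.5 * self.n_persons * (
                    -np.sum((A @ Gi) * (A @ Gj).T)
                    + np.sum((A @ Gj) * (ASA @ Gi).T)
                    + np.sum((ASA @ Gj) * (A @ Gi).T)
                )
        return 0.5 * (H + H.T)

    # -- starting values ---------------------------------------------------

    def _moment_start(self, S: np.ndarray) -> np.ndarray:
        """Method-of-moments start from mean covariances by pair type."""
        day = self.design.comembership("day")
        sess = self.design.comembership("session")
        iu = np.triu_indices(self.k, 1)
        same_sess = sess[iu] > 0
        same_day = (day[iu] > 0) & ~same_sess
        cross = ~(same_sess | (day[iu] > 0))
        offdiag = S[iu]
        t0 = float(offdiag[cross].mean()) if cross.any() else float(offdiag.mean())
        d0 = (float(offdiag[same_day].mean()) - t0) if same_day.any() else 0.0
        s0 = (
            (float(offdiag[same_sess].mean()) - t0 - d0) if same_sess.any() else 0.0
        )
        e0 = float(np.diag(S).mean()) - t0 - d0 - s0
        return np.array([t0, d0, s0, e0])

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        lower_bound: float = DEFAULT_LOWER_BOUND,
        free: Iterable[str] = COMPONENT_NAMES,
        max_restarts: int = 3,
        standardize: bool = False,
    ) -> "ICEDResults":
        """Bound-constrained ML fit of the free variance components.

        Components not in ``free`` are pinned at zero (null models for
        likelihood-ratio testing).  The lower bound applies to each free
        component on the scale of the fitted data.  With
        ``standardize=True`` the values are first divided by their grand
        SD, so the bound acts on the proportional (unit-variance) scale;
        raw estimates are then in standardized units, while proportions,
        ICC, ICC2 and the tests are unaffected by the choice.  Use this
        for modalities whose absolute variance is far from 1.  On
        non-convergence the fit is retried from jittered starts; the
        result always carries a ``converged`` flag.
        """
        if standardize:
            grand_sd = float(self.data.values.std(ddof=1))
            if not np.isfinite(grand_sd) or grand_sd <= 0:
                raise ValueError("grand SD is zero; cannot standardize")
            std_data = ReliabilityDataset(
                self.data.values / grand_sd,
                self.design,
                self.data.person_ids,
                self.data.roi_label,
                self.data.modality_label,
            )
            res = ICEDModel(std_data).fit(
                lower_bound=lower_bound, free=free, max_restarts=max_restarts
            )
            res.standardized = True
            return res
        free = frozenset(free)
        unknown = free - _ALL
        if unknown:
            raise ValueError(f"unknown components: {sorted(unknown)}")
        if "var_e" not in free:
            raise ValueError(
                "var_e must remain free: without residual error the model "
                "covariance is singular"
            )
        if self.n_persons < 3:
            raise ValueError("at least 3 persons are required for estimation")
        if lower_bound <= 0:
            raise ValueError("lower_bound must be positive")

        free_idx = [i for i, n in enumerate(COMPONENT_NAMES) if n in free]

        # fit on a scale-free version of the problem so results are
        # invariant to affine transforms of the data
        scale = float(np.trace(self._S)) / self.k
        if not np.isfinite(scale) or scale <= 0:
            scale = 1.0
        S = self._S / scale
        lb = lower_bound / scale

        def pack(th_free):
            th = np.zeros(4)
            th[free_idx] = th_free
            return th

        def objective(th_free):
            f, g = self._negll_grad(pack(th_free), S)
            return f, g[free_idx]

        bounds = [(lb, None)] * len(free_idx)
        total = max(float(np.trace(S)) / self.k, lb)
        # method-of-moments start; at very small n the profiled objective
        # can be multimodal, so add two deterministic fallback starts there
        starts = [self._moment_start(S)]
        if self.n_persons < 30:
            starts += [np.full(4, total / 4.0), np.array([lb, lb, lb, total])]
        rng = np.random.default_rng(1234)  # deterministic restart jitter
        best = None
        attempts = 0
        while starts:
            x0 = np.clip(np.asarray(starts.pop(0))[free_idx], lb, None)
            res = optimize.minimize(
                objective,
                x0,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500},
            )
            if best is None or (res.success and not best.success) or (
                res.success == best.success and res.fun < best.fun
            ):
                best = res
            if not res.success and attempts < max_restarts:
                attempts += 1
                starts.append(
                    np.clip(
                        self._moment_start(S) * rng.lognormal(0.0, 0.5, 4),
                        lb,
                        None,
                    )
                )
        converged = bool(best.success)

        theta = pack(best.x) * scale
        vc = VarianceComponents.from_array(theta)
        at_bound = np.zeros(4, bool)
        at_bound[free_idx] = best.x <= lb * (1 + 1e-9)
        llf = self.loglike(vc)
        return ICEDResults(
            model=self,
            params=vc,
            llf=llf,
            converged=converged,
            lower_bound=lower_bound,
            free=frozenset(free),
            at_bound=at_bound,
            optimizer_message=str(best.message),
        )


class ICEDResults:
    """Fitted variance components with reliability summaries and tests."""

    def __init__(
        self,
        model: ICEDModel,
        params: VarianceComponents,
        llf: float,
        converged: bool,
        lower_bound: float,
        free: frozenset,
        at_bound: np.ndarray,
        optimizer_message: str = "",
    ):
        self.model = model
        self.params = params
        self.llf = llf
        self.converged = converged
        self.lower_bound = lower_bound
        self.free = free
        self.at_bound = at_bound
        self.optimizer_message = optimizer_message
        self.n_persons = model.n_persons
        self.occasion_means = model.occasion_means
        self.standardized = False  # set by ICEDModel.fit(standardize=True)

    # -- reliability summaries --------------------------------------------

    @property
    def proportions(self) -> VarianceComponents:
        """Components rescaled to sum to one (relative contributions)."""
        return rescale_components(self.params)

    @property
    def icc(self) -> float:
        """Single-measurement reliability: true-score share of total variance."""
        return _icc(self.params)

    @property
    def icc2(self) -> float:
        """Design-level reliability from the effective error of all occasions."""
        return _icc2(self.params, self.model.design)

    @property
    def effective_error(self) -> float:
        return effective_error(self.params, self.model.design)

    # -- model fit ---------------------------------------------------------

    def fit_stats(self) -> FitStats:
        """Chi-square, df and RMSEA against the saturated covariance model."""
        n, k = self.n_persons, self.model.k
        sign, logdetS = np.linalg.slogdet(self.model._S)
        if sign <= 0:
            raise np.linalg.LinAlgError(
                "sample covariance is singular; fit statistics undefined"
            )
        df = k * (k + 1) // 2 - len(self.free)
        if df <= 0:
            raise ValueError("saturated comparison needs positive df")
        llf_sat = -0.5 * n * (k * np.log(2 * np.pi) + logdetS + k)
        discrepancy = max(2.0 * (llf_sat - self.llf) / n, 0.0)
        chisq = (n - 1) * discrepancy
        rmsea = float(np.sqrt(max(chisq - df, 0.0) / (df * (n - 1))))
        return FitStats(chisq=float(chisq), df=df, rmsea=rmsea)

    # -- component tests ---------------------------------------------------

    def lrt(self, component: str, boundary_correction: bool = False) -> ModelComparison:
        """Likelihood-ratio test of one component against its null model.

        The null model re-fits with the component pinned at zero; the
        statistic is twice the log-likelihood difference (clipped at 0)
        on 1 df.  The naive chi-square(1) p-value is the default; with
        ``boundary_correction=True`` a 50:50 chi-square(0)/chi-square(1)
        mixture is used because the null lies on the parameter boundary.
        """
        if component == "var_e":
            raise ValueError(
                "var_e cannot be tested by LRT (null model not estimable); "
                "use wald_residual()"
            )
        if component not in _ALL:
            raise ValueError(f"unknown component {component!r}")
        null = self.model.fit(
            lower_bound=self.lower_bound, free=self.free - {component}
        )
        if not (self.converged and null.converged):
            raise RuntimeError(
                f"LRT for {component} unavailable: full or null model did "
                "not converge"
            )
        delta = max(2.0 * (self.llf - null.llf), 0.0)
        p = float(stats.chi2.sf(delta, df=1))
        if boundary_correction:
            p = 0.5 * p if delta > 0 else 1.0
        return ModelComparison(component, float(delta), 1, p, "lrt")

    def wald_residual(self) -> ModelComparison:
        """Wald test of the residual error variance.

        Uses the observed-information SE at the ML solution; statistic
        (estimate/SE)^2 on 1 df.
        """
        if not self.converged:
            raise RuntimeError("Wald test requires a converged fit")
        cov = self.params_cov()
        free_order = self.free_names()
        se2 = cov[free_order.index("var_e"), free_order.index("var_e")]
        if not np.isfinite(se2) or se2 <= 0:
            raise np.linalg.LinAlgError("observed information is singular")
        stat = self.params.var_e**2 / se2
        return ModelComparison(
            "var_e", float(stat), 1, float(stats.chi2.sf(stat, df=1)), "wald"
        )

    def free_names(self) -> list[str]:
        return [n for n in COMPONENT_NAMES if n in self.free]

    def params_cov(self) -> np.ndarray:
        """Asymptotic covariance of the free components (inverse observed information)."""
        free_idx = [i for i, n in enumerate(COMPONENT_NAMES) if n in self.free]
        H = self.model._hessian(self.params.as_array(), self.model._S)
        Hf = H[np.ix_(free_idx, free_idx)]
        return np.linalg.inv(Hf)

    def bse(self) -> pd.Series:
        cov = self.params_cov()
        return pd.Series(np.sqrt(np.diag(cov)), index=self.free_names())

    # -- bootstrap ---------------------------------------------------------

    def bootstrap_ci(
        self,
        statistic: str = "icc",
        n_boot: int = 1000,
        level: float = 0.95,
        seed: Optional[int] = None,
        max_drop_frac: float = 0.2,
    ) -> tuple[float, float]:
        """Percentile bootstrap CI for ICC or ICC2, resampling persons.

        Non-convergent replicates are dropped and counted; more than
        ``max_drop_frac`` dropped replicates is an error.  Identical
        seeds give identical intervals.
        """
        if statistic not in ("icc", "icc2"):
            raise ValueError("statistic must be 'icc' or 'icc2'")
        if n_boot < 50:
            raise ValueError("n_boot must be at least 50")
        values = self.model.data.values
        n = self.n_persons
        rng = np.random.default_rng(seed)
        stats_: list[float] = []
        dropped = 0
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            try:
                m = ICEDModel(values[idx], self.model.design)
                r = m.fit(lower_bound=self.lower_bound, free=self.free)
                if not r.converged:
                    dropped += 1
                    continue
                stats_.append(getattr(r, statistic))
            except (np.linalg.LinAlgError, ValueError):
                dropped += 1
        if dropped > max_drop_frac * n_boot:
            raise RuntimeError(
                f"bootstrap failed: {dropped}/{n_boot} replicates dropped"
            )
        alpha = (1.0 - level) / 2.0
        lo, hi = np.percentile(stats_, [100 * alpha, 100 * (1 - alpha)])
        return float(lo), float(hi)

    # -- reporting ---------------------------------------------------------

    def proportions_reported(self) -> VarianceComponents:
        """Rescaled components with bound-pinned estimates reported as 0."""
        raw = self.params.as_array().copy()
        raw[self.at_bound] = 0.0
        if raw.sum() <= 0:
            return self.proportions
        return VarianceComponents.from_array(raw / raw.sum())

    def summary(self) -> str:
        ds = self.model.data
        prop = self.proportions_reported()
        fs = None
        try:
            fs = self.fit_stats()
        except (np.linalg.LinAlgError, ValueError):
            pass
        lines = [
            "ICED variance decomposition",
            "=" * 46,
            f"ROI / modality : {ds.roi_label or '-'} / {ds.modality_label or '-'}",
            f"persons        : {self.n_persons}   occasions: {self.model.k}",
            f"log-likelihood : {self.llf:.4f}   converged: {self.converged}",
        ]
        if fs is not None:
            lines.append(
                f"chisq (df={fs.df})   : {fs.chisq:.3f}   RMSEA: {fs.rmsea:.3f}"
            )
        lines += [
            "-" * 46,
            "component     raw estimate   proportion",
        ]
        for name, raw, p in zip(
            COMPONENT_NAMES, self.params.as_array(), prop.as_array()
        ):
            tag = "" if name in self.free else " (fixed 0)"
            lines.append(f"{name:<10} {raw:>14.6g} {p:>12.3f}{tag}")
        lines += [
            "-" * 46,
            f"ICC  : {self.icc:.3f}",
            f"ICC2 : {self.icc2:.3f}   effective error: {self.effective_error:.6g}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<ICEDResults icc={self.icc:.3f} icc2={self.icc2:.3f} "
            f"converged={self.converged}>"
        )


# -- functional wrappers ---------------------------------------------------


def fit_iced(
    data: ReliabilityDataset,
    lower_bound: float = DEFAULT_LOWER_BOUND,
    free: Iterable[str] = COMPONENT_NAMES,
    standardize: bool = False,
) -> ICEDResults:
    """Fit the variance-decomposition model to a dataset (convenience)."""
    return ICEDModel(data).fit(
        lower_bound=lower_bound, free=free, standardize=standardize
    )


def log_likelihood(
    data: ReliabilityDataset, vc: VarianceComponents, means=None
) -> float:
    """Gaussian log-likelihood of a dataset at given components and means."""
    return ICEDModel(data).loglike(vc, means=means)
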