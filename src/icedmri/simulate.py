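"""Synthetic study data: ROI tables, voxel maps, and multi-echo signals.

The ROI generator inverts the variance-decomposition model: for person
p and occasion o,

    y[p, o] = mean[o] + T_p + D_{p, day(o)} + S_{p, session(o)} + E_{p, o}

with all effects independent zero-mean Gaussians at the specified
variances.  Defaults mirror the study that motivated the package:
15 persons, the four-occasion two-day design, and occasion means at
the whole-brain gray-matter levels of the four MPM modalities
(MT 0.874 p.u., PD 80.61 p.u., R1 0.622 1/s, R2* 16.9 1/s).  All
randomness flows from one explicit per-call seed; there is no global
state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .components import VarianceComponents
from .dataset import ReliabilityDataset
from .design import StudyDesign, default_mpm_design
from .signal import (
    PROTOCOL_FLIP_DEG,
    PROTOCOL_TE_MS,
    PROTOCOL_TE_PDW_MS,
    PROTOCOL_TR_MS,
    EchoSeries,
    MultiEchoSet,
)

__all__ = [
    "SyntheticSpec",
    "default_study_spec",
    "simulate_roi_dataset",
    "simulate_voxel_maps",
    "simulate_multiecho",
    "STUDY_MODALITY_MEANS",
]

#: Whole-brain gray-matter levels of the four MPM modalities (study units).
STUDY_MODALITY_MEANS = {"MT": 0.874, "PD": 80.61, "R1": 0.622, "R2s": 16.9}

#: Default total variance for the MT default spec.  Chosen so that the
#: within-person spread yields group-mean CoVs near the ~1% the study
#: reports for whole gray matter.
_DEFAULT_TOTAL_VAR_MT = 6.5e-4


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic reliability dataset."""

    n_persons: int
    design: StudyDesign
    occasion_means: Sequence[float]
    components: VarianceComponents
    seed: int = 0

    def __post_init__(self):
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        if len(self.occasion_means) != self.design.k:
            raise ValueError("occasion_means length must equal design.k")


def default_study_spec(
    modality: str = "MT",
    n_persons: int = 15,
    proportions: Sequence[float] = (0.883, 0.0, 0.003, 0.114),
    total_variance: Optional[float] = None,
    seed: int = 0,
) -> SyntheticSpec:
    """A spec that mirrors the study: 15 persons, 4 occasions, study-level means.

    ``proportions`` default to the whole-gray-matter MT decomposition;
    ``total_variance`` defaults to a modality-scaled value that keeps
    the within-person CoV near the study's ~1%.
    """
    if modality not in STUDY_MODALITY_MEANS:
        raise ValueError(f"unknown modality {modality!r}")
    mean = STUDY_MODALITY_MEANS[modality]
    if total_variance is None:
        # scale the MT default with the squared mean so CoV is preserved
        total_variance = _DEFAULT_TOTAL_VAR_MT * (mean / STUDY_MODALITY_MEANS["MT"]) ** 2
    props = np.asarray(proportions, float)
    if props.min() < 0 or props.sum() <= 0:
        raise ValueError("proportions must be non-negative with positive sum")
    comps = VarianceComponents.from_array(props / props.sum() * total_variance)
    design = default_mpm_design()
    return SyntheticSpec(n_persons, design, [mean] * design.k, comps, seed)


def _draw_effects(rng, spec: SyntheticSpec, extra_shape=()):
    """Draw the per-person effect terms; returns (n, k, *extra) totals."""
    design = spec.design
    n, k = spec.n_persons, design.k
    vc = spec.components
    Ld = design.loading_matrix("day")
    Ls = design.loading_matrix("session")
    t = rng.normal(0.0, np.sqrt(vc.var_t), (n, 1) + extra_shape)
    d = rng.normal(0.0, np.sqrt(vc.var_d), (n, Ld.shape[1]) + extra_shape)
    s = rng.normal(0.0, np.sqrt(vc.var_s), (n, Ls.shape[1]) + extra_shape)
    e = rng.normal(0.0, np.sqrt(vc.var_e), (n, k) + extra_shape)
    # broadcast factor draws onto occasions through the loading matrices
    d_occ = np.einsum("kl,nl...->nk...", Ld, d)
    s_occ = np.einsum("kl,nl...->nk...", Ls, s)
    return t + d_occ + s_occ + e


def simulate_roi_dataset(spec: SyntheticSpec) -> ReliabilityDataset:
    """One persons x occasions dataset drawn from the generative model."""
    rng = np.random.default_rng(spec.seed)
    noise = _draw_effects(rng, spec)
    values = np.asarray(spec.occasion_means, float)[None, :] + noise
    return ReliabilityDataset(values, spec.design, roi_label="synthetic")


def simulate_voxel_maps(
    spec: SyntheticSpec,
    shape: tuple[int, int, int],
    component_fields: Optional[dict] = None,
    mask: Optional[np.ndarray] = None,
):
    """Per-person per-occasion 3-D maps following the voxel-wise model.

    Parameters
    ----------
    spec
        Baseline spec; ``spec.components`` are used for any component
        without an entry in ``component_fields``, and
        ``spec.occasion_means`` set the occasion-level offsets
        (spatially constant).
    shape
        3-D volume shape (keep small; this is a desk-scale generator).
    component_fields
        Optional per-voxel variance maps, keys among
        ``var_t/var_d/var_s/var_e``; scalars or arrays of ``shape``.
    mask
        Optional boolean volume; out-of-mask voxels are NaN.

    Returns
    -------
    (maps, mask) where maps has shape (n_persons, k, *shape).
    """
    from .voxelwise import VoxelMapSet  # deferred: avoid an import cycle

    shape = tuple(int(x) for x in shape)
    if len(shape) != 3:
        raise ValueError("shape must be 3-D")
    if mask is None:
        mask = np.ones(shape, bool)
    mask = np.asarray(mask, bool)
    if mask.shape != shape:
        raise ValueError("mask shape mismatch")

    fields = {}
    base = dict(zip(("var_t", "var_d", "var_s", "var_e"), spec.components.as_array()))
    for name, val in base.items():
        f = (component_fields or {}).get(name, val)
        f = np.broadcast_to(np.asarray(f, float), shape)
        if np.any(f < 0):
            raise ValueError(f"{name} field must be non-negative")
        fields[name] = f

    rng = np.random.default_rng(spec.seed)
    design = spec.design
    n, k = spec.n_persons, design.k
    Ld = design.loading_matrix("day")
    Ls = design.loading_matrix("session")
    # unit-variance draws scaled per voxel by the local component SDs
    t = rng.standard_normal((n, 1) + shape) * np.sqrt(fields["var_t"])
    d = rng.standard_normal((n, Ld.shape[1]) + shape) * np.sqrt(fields["var_d"])
    s = rng.standard_normal((n, Ls.shape[1]) + shape) * np.sqrt(fields["var_s"])
    e = rng.standard_normal((n, k) + shape) * np.sqrt(fields["var_e"])
    maps = (
        t
        + np.einsum("kl,nl...->nk...", Ld, d)
        + np.einsum("kl,nl...->nk...", Ls, s)
        + e
        + np.asarray(spec.occasion_means, float)[None, :, None, None, None]
    )
    maps[:, :, ~mask] = np.nan
    return VoxelMapSet(maps=maps, mask=mask, design=design)


def simulate_multiecho(
    intercepts: Sequence[float],
    r2star: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> MultiEchoSet:
    """Mono-exponential protocol echo trains for the three MPM contrasts.

    ``intercepts`` are the TE=0 signals of (T1w, PDw, MTw).  The PDw
    train carries the two extra late echoes of the protocol.  Gaussian
    noise of SD ``noise_sd`` is added when requested; a draw that takes
    a signal non-positive is an error rather than silently floored.
    """
    intercepts = np.asarray(intercepts, float)
    if intercepts.size != 3:
        raise ValueError("intercepts must be (T1w, PDw, MTw)")
    if np.any(intercepts <= 0):
        raise ValueError("intercepts must be positive")
    if r2star <= 0:
        raise ValueError("r2star must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    te_by_contrast = {
        "T1w": PROTOCOL_TE_MS,
        "PDw": PROTOCOL_TE_PDW_MS,
        "MTw": PROTOCOL_TE_MS,
    }
    contrasts = {}
    for amp, lab in zip(intercepts, ("T1w", "PDw", "MTw")):
        te = np.asarray(te_by_contrast[lab], float)
        sig = amp * np.exp(-r2star * te / 1000.0)
        if noise_sd > 0:
            sig = sig + rng.normal(0.0, noise_sd, sig.size)
        if np.any(sig <= 0):
            raise ValueError(
                "noise drew a non-positive signal; reduce noise_sd or "
                "increase the intercepts"
            )
        contrasts[lab] = EchoSeries(
            tuple(te), tuple(sig), PROTOCOL_FLIP_DEG[lab], PROTOCOL_TR_MS
        )
    return MultiEchoSet(contrasts)
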