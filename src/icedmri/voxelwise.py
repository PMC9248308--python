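"""Voxel-wise reliability maps: the ROI model applied at every voxel.

Aligned per-person per-occasion 3-D volumes are fitted independently at
each in-mask voxel, producing maps of the rescaled variance proportions
and of ICC/ICC2.  Voxels where the fit fails are flagged and set to NaN
rather than aborting the run; out-of-mask voxels are NaN everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import nibabel as nib
import numpy as np

from .dataset import ReliabilityDataset
from .design import StudyDesign
from .model import DEFAULT_LOWER_BOUND, ICEDModel

__all__ = ["VoxelMapSet", "voxelwise_iced", "roi_extract"]

_MAP_NAMES = ("icc", "icc2", "var_t", "var_d", "var_s", "var_e", "converged")


@dataclass
class VoxelMapSet:
    """Aligned per-person per-occasion volumes plus mask and affine.

    ``maps`` has shape (n_persons, k, nx, ny, nz), occasion order
    matching ``design.occasions``.
    """

    maps: np.ndarray
    mask: np.ndarray
    design: StudyDesign
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    person_ids: Optional[list] = None

    def __post_init__(self):
        self.maps = np.asarray(self.maps, float)
        self.mask = np.asarray(self.mask, bool)
        if self.maps.ndim != 5:
            raise ValueError("maps must be (persons, occasions, x, y, z)")
        if self.maps.shape[1] != self.design.k:
            raise ValueError("occasion axis does not match the design")
        if self.mask.shape != self.maps.shape[2:]:
            raise ValueError("mask shape does not match the volumes")
        self.affine = np.asarray(self.affine, float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.person_ids is None:
            self.person_ids = [f"p{i + 1}" for i in range(self.maps.shape[0])]

    @property
    def n_persons(self) -> int:
        return self.maps.shape[0]

    @property
    def shape(self) -> tuple:
        return self.maps.shape[2:]

    # -- NIfTI round trip --------------------------------------------------

    @classmethod
    def from_nifti(cls, paths, mask_path, design: StudyDesign) -> "VoxelMapSet":
        """Load from per-person lists of per-occasion NIfTI paths.

        ``paths`` is a sequence (persons) of sequences (occasions in
        design order) of filenames; all volumes must share shape and
        affine with the mask.
        """
        mask_img = nib.load(str(mask_path))
        mask = np.asarray(mask_img.dataobj) > 0
        vols = []
        for person in paths:
            row = []
            for p in person:
                img = nib.load(str(p))
                if img.shape != mask.shape:
                    raise ValueError(f"{p}: shape differs from the mask")
                if not np.allclose(img.affine, mask_img.affine, atol=1e-4):
                    raise ValueError(f"{p}: affine differs from the mask")
                row.append(np.asarray(img.dataobj, float))
            vols.append(row)
        return cls(np.asarray(vols), mask, design, mask_img.affine)

    def write_nifti(self, volume: np.ndarray, path) -> None:
        nib.save(nib.Nifti1Image(np.asarray(volume, np.float32), self.affine), str(path))


def voxelwise_iced(
    mapset: VoxelMapSet,
    lower_bound: float = DEFAULT_LOWER_BOUND,
    chunk_size: int = 4096,
) -> dict:
    """Fit the variance-decomposition model at every in-mask voxel.

    Returns a dict of 3-D arrays: rescaled proportions ``var_t/d/s/e``,
    ``icc``, ``icc2``, and a ``converged`` flag map (1 converged,
    0 failed, NaN outside the mask).  Voxels are independent, so the
    result does not depend on traversal order; processing is chunked to
    bound memory.
    """
    if not mapset.mask.any():
        raise ValueError("mask is empty")
    if mapset.n_persons < 3:
        raise ValueError("at least 3 persons are required")
    shape = mapset.shape
    out = {name: np.full(shape, np.nan) for name in _MAP_NAMES}
    flat_idx = np.flatnonzero(mapset.mask.ravel())
    data = mapset.maps.reshape(mapset.n_persons, mapset.design.k, -1)
    for start in range(0, flat_idx.size, chunk_size):
        for j in flat_idx[start : start + chunk_size]:
            values = data[:, :, j]
            try:
                res = ICEDModel(values, mapset.design).fit(lower_bound=lower_bound)
            except (np.linalg.LinAlgError, ValueError):
                out["converged"].ravel()[j] = 0.0
                continue
            pos = np.unravel_index(j, shape)
            prop = res.proportions.as_array()
            for name, val in zip(("var_t", "var_d", "var_s", "var_e"), prop):
                out[name][pos] = val
            out["icc"][pos] = res.icc
            out["icc2"][pos] = res.icc2
            out["converged"][pos] = float(res.converged)
    return out


def roi_extract(
    mapset: VoxelMapSet,
    labels: np.ndarray,
    modality_label: str = "",
    required_labels=None,
):
    """Average maps over each labelled region into ReliabilityDatasets.

    ``labels`` is an integer volume aligned with the maps; every
    positive label becomes one dataset of per-person per-occasion ROI
    means (NaN voxels are ignored).  Also returns the matching ROI SDs.

    Returns
    -------
    dict label -> (means ReliabilityDataset, sds ndarray)
    """
    labels = np.asarray(labels)
    if labels.shape != mapset.shape:
        raise ValueError("label volume shape does not match the maps")
    out = {}
    present = np.unique(labels)
    present = present[present > 0]
    if present.size == 0:
        raise ValueError("no positive labels in the label volume")
    if required_labels is not None:
        missing = sorted(set(int(x) for x in required_labels) - set(present.tolist()))
        if missing:
            raise ValueError(f"labels absent from the volume: {missing}")
    flat = mapset.maps.reshape(mapset.n_persons, mapset.design.k, -1)
    lab_flat = labels.ravel()
    for lab in present:
        sel = flat[:, :, lab_flat == lab]
        means = np.nanmean(sel, axis=2)
        sds = np.nanstd(sel, axis=2, ddof=1) if sel.shape[2] > 1 else np.zeros_like(means)
        out[int(lab)] = (
            ReliabilityDataset(
                means,
                mapset.design,
                mapset.person_ids,
                roi_label=str(int(lab)),
                modality_label=modality_label,
            ),
            sds,
        )
    return out
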