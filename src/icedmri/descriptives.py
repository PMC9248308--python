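"""Coefficient-of-variation and mean/SD aggregation conventions.

Per-person CoV divides the SD of a person's k occasion values (sample
SD, denominator k-1) by that person's mean; group summaries average
those CoVs across persons.  The occasion-level mean/SD summary averages
over all persons and occasions and takes the SD across the k occasion
means (denominator k-1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .dataset import ReliabilityDataset

__all__ = ["CoVSummary", "participant_cov", "cov_summary", "cov_table", "occasion_mean_sd"]


@dataclass(frozen=True)
class CoVSummary:
    """Per-person CoVs (fractions) with their cross-person mean and SD."""

    per_person_cov: dict
    group_mean_cov: float
    group_sd_cov: float


def participant_cov(values) -> float:
    """SD (denominator k-1) over a person's occasion values, divided by the mean.

    Dimensionless; multiply by 100 to report as percent.  Errors on a
    non-positive mean or fewer than two values.
    """
    values = np.asarray(values, float)
    if values.size < 2:
        raise ValueError("CoV needs at least 2 values")
    mean = values.mean()
    if mean <= 0:
        raise ValueError("CoV undefined for non-positive mean")
    return float(values.std(ddof=1) / mean)


def cov_summary(data: ReliabilityDataset) -> CoVSummary:
    """Per-person CoVs and their mean/SD across persons for one dataset."""
    covs = {
        pid: participant_cov(row)
        for pid, row in zip(data.person_ids, data.values)
    }
    arr = np.array(list(covs.values()))
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return CoVSummary(covs, float(arr.mean()), sd)


def cov_table(datasets: Iterable[ReliabilityDataset]) -> pd.DataFrame:
    """CoV summary rows (mean/SD as percent) for a collection of datasets."""
    rows = []
    for ds in datasets:
        s = cov_summary(ds)
        rows.append(
            {
                "roi": ds.roi_label,
                "modality": ds.modality_label,
                "cov_mean_pct": 100 * s.group_mean_cov,
                "cov_sd_pct": 100 * s.group_sd_cov,
                "n_persons": ds.n_persons,
            }
        )
    return pd.DataFrame(rows)


def occasion_mean_sd(data: ReliabilityDataset) -> tuple[float, float]:
    """Grand mean, plus the SD across the k occasion-level means (ddof=1)."""
    if data.k < 2:
        raise ValueError("need at least 2 occasions")
    occ_means = data.values.mean(axis=0)
    return float(data.values.mean()), float(occ_means.std(ddof=1))
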