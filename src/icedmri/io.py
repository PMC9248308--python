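"""CSV readers and result-table writers with stable formatting.

Input tables come in two shapes: *long* (person, day, session,
measurement, roi, modality, value; one row per cell) and *wide*
(person plus one column per occasion, one ROI/modality per file).
Output mirrors the study's result-table layout: one row per
ROI x modality with RMSEA, the four rescaled variance proportions,
ICC/ICC2 with bootstrap CIs, and component p-values; a JSON sidecar
records seeds and conventions.
"""

from __future__ import annotations

import json
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .dataset import ReliabilityDataset
from .design import StudyDesign

__all__ = [
    "read_wide_csv",
    "read_long_csv",
    "results_table",
    "write_results",
    "provenance",
]

LONG_COLUMNS = ["person", "day", "session", "measurement", "roi", "modality", "value"]

CONVENTIONS = {
    "chisq": "(N-1) * ML discrepancy vs the saturated covariance model",
    "rmsea": "sqrt(max(chisq - df, 0) / (df * (N-1)))",
    "bootstrap_ci": "percentile, person-level resampling",
    "effective_error": "precision-weighted composite: 1 / sum(inv(error covariance))",
    "cov_sd": "sample SD, denominator n-1",
    "lower_bound_scale": "scale of the fitted data",
    "bound_reporting": "estimates at the lower bound shown as 0.000 in proportions",
}


def read_wide_csv(path, design: StudyDesign, **kwargs) -> ReliabilityDataset:
    """Read a wide per-occasion CSV into a dataset."""
    df = pd.read_csv(path)
    return ReliabilityDataset.from_wide_df(df, design, **kwargs)


def read_long_csv(path, design: StudyDesign) -> dict:
    """Read a long CSV; returns {(roi, modality): ReliabilityDataset}.

    The occasion of each row is identified as D{day}M{measurement},
    which must match the design's occasion ids.
    """
    df = pd.read_csv(path)
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"long CSV is missing required columns: {missing}")
    df = df.copy()
    df["occasion"] = "D" + df["day"].astype(str) + "M" + df["measurement"].astype(str)
    out = {}
    for (roi, modality), grp in df.groupby(["roi", "modality"]):
        out[(str(roi), str(modality))] = ReliabilityDataset.from_long_df(
            grp,
            design,
            roi_label=str(roi),
            modality_label=str(modality),
        )
    return out


def results_table(results: Iterable, decimals: int = 3) -> pd.DataFrame:
    """One row per fitted dataset, mirroring the study's summary table.

    ``results`` yields dicts with keys ``result`` (ICEDResults) and
    optionally ``icc_ci``, ``icc2_ci``, ``p_values``.  Proportions,
    ICC and ICC2 are rounded to ``decimals``; estimates pinned at the
    lower bound are reported as zero.
    """
    rows = []
    for entry in results:
        res = entry["result"]
        ds = res.model.data
        prop = res.proportions_reported().as_array()
        try:
            fs = res.fit_stats()
            rmsea = round(fs.rmsea, decimals)
        except (np.linalg.LinAlgError, ValueError):
            rmsea = np.nan
        row = {
            "roi": ds.roi_label,
            "modality": ds.modality_label,
            "rmsea": rmsea,
            "var_t": round(prop[0], decimals),
            "var_d": round(prop[1], decimals),
            "var_s": round(prop[2], decimals),
            "var_e": round(prop[3], decimals),
            "icc": round(res.icc, decimals),
            "icc2": round(res.icc2, decimals),
            "converged": res.converged,
            "n_persons": res.n_persons,
        }
        for stat in ("icc", "icc2"):
            ci = entry.get(f"{stat}_ci")
            row[f"{stat}_ci_low"] = round(ci[0], decimals) if ci else np.nan
            row[f"{stat}_ci_high"] = round(ci[1], decimals) if ci else np.nan
        for comp, p in (entry.get("p_values") or {}).items():
            row[f"p_{comp}"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def provenance(seed: Optional[int] = None, **extra) -> dict:
    from . import __version__

    return {
        "package": "icedmri",
        "version": __version__,
        "seed": seed,
        "conventions": CONVENTIONS,
        **extra,
    }


def write_results(table: pd.DataFrame, out_csv, sidecar_json=None, **prov_kwargs):
    """Write the results CSV plus a provenance JSON sidecar."""
    table.to_csv(out_csv, index=False)
    if sidecar_json is not None:
        with open(sidecar_json, "w") as fh:
            json.dump(provenance(**prov_kwargs), fh, indent=2, sort_keys=True)
            fh.write("\n")
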