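"""Person x occasion measurement tables for one ROI and modality."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design import StudyDesign

__all__ = ["ReliabilityDataset"]


class ReliabilityDataset:
    """A persons x occasions table of measurements for one ROI/modality.

    Parameters
    ----------
    values
        Array-like of shape (n_persons, k); column order must match
        ``design.occasions``.
    design
        The study design describing the occasions.
    person_ids
        Optional person labels (default ``p1..pN``).
    roi_label, modality_label
        Free-text labels carried through to output tables.
    allow_missing
        If False (default), any NaN cell is a hard error.  If True,
        persons with missing cells are dropped (listwise deletion).
    """

    def __init__(
        self,
        values,
        design: StudyDesign,
        person_ids: Optional[Sequence[str]] = None,
        roi_label: str = "",
        modality_label: str = "",
        allow_missing: bool = False,
    ):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D persons x occasions array")
        if values.shape[1] != design.k:
            raise ValueError(
                f"values has {values.shape[1]} columns but the design has "
                f"{design.k} occasions"
            )
        if person_ids is None:
            person_ids = [f"p{i + 1}" for i in range(values.shape[0])]
        person_ids = [str(p) for p in person_ids]
        if len(person_ids) != values.shape[0]:
            raise ValueError("person_ids length does not match values")
        missing = ~np.isfinite(values)
        if missing.any():
            if not allow_missing:
                raise ValueError(
                    "dataset contains missing cells; pass allow_missing=True "
                    "for listwise deletion"
                )
            keep = ~missing.any(axis=1)
            values = values[keep]
            person_ids = [p for p, k_ in zip(person_ids, keep) if k_]
        self.values = values
        self.design = design
        self.person_ids = list(person_ids)
        self.roi_label = roi_label
        self.modality_label = modality_label

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.design.k

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_wide_df(
        cls,
        df: pd.DataFrame,
        design: StudyDesign,
        person_col: str = "person",
        **kwargs,
    ) -> "ReliabilityDataset":
        """Build from a wide table: one row per person, one column per occasion."""
        missing = [c for c in design.occasion_ids if c not in df.columns]
        if missing:
            raise ValueError(f"wide table is missing occasion columns: {missing}")
        persons = (
            df[person_col].astype(str).tolist()
            if person_col in df.columns
            else None
        )
        return cls(
            df[design.occasion_ids].to_numpy(float), design, persons, **kwargs
        )

    @classmethod
    def from_long_df(
        cls,
        df: pd.DataFrame,
        design: StudyDesign,
        person_col: str = "person",
        occasion_col: str = "occasion",
        value_col: str = "value",
        **kwargs,
    ) -> "ReliabilityDataset":
        """Build from a long table with person / occasion / value columns."""
        for c in (person_col, occasion_col, value_col):
            if c not in df.columns:
                raise ValueError(f"long table is missing required column {c!r}")
        wide = df.pivot_table(
            index=person_col, columns=occasion_col, values=value_col, aggfunc="mean"
        )
        missing = [c for c in design.occasion_ids if c not in wide.columns]
        if missing:
            raise ValueError(f"long table is missing occasions: {missing}")
        wide = wide[design.occasion_ids]
        return cls(
            wide.to_numpy(float), design, [str(p) for p in wide.index], **kwargs
        )

    def to_wide_df(self) -> pd.DataFrame:
        out = pd.DataFrame(self.values, columns=self.design.occasion_ids)
        out.insert(0, "person", self.person_ids)
        return out

    def to_long_df(self) -> pd.DataFrame:
        long = self.to_wide_df().melt(
            id_vars="person", var_name="occasion", value_name="value"
        )
        occ = {o.occasion_id: o for o in self.design.occasions}
        long["day"] = [occ[o].day_id for o in long["occasion"]]
        long["session"] = [occ[o].session_id for o in long["occasion"]]
        long["roi"] = self.roi_label
        long["modality"] = self.modality_label
        return long[
            ["person", "occasion", "day", "session", "roi", "modality", "value"]
        ]

    def transform(self, a: float = 1.0, b: float = 0.0) -> "ReliabilityDataset":
        """Affinely transformed copy (y -> a*y + b)."""
        return ReliabilityDataset(
            a * self.values + b,
            self.design,
            self.person_ids,
            self.roi_label,
            self.modality_label,
        )

    def __repr__(self) -> str:
        lbl = "/".join(x for x in (self.roi_label, self.modality_label) if x)
        lbl = f" [{lbl}]" if lbl else ""
        return f"ReliabilityDataset(n={self.n_persons}, k={self.k}){lbl}"
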