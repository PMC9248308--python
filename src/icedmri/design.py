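"""Repeated-measures study designs with day/session factor structure.

A scan-rescan study is described as an ordered list of measurement
occasions.  Each occasion belongs to exactly one *day* and one *session*
(a contiguous period inside the scanner without repositioning); sessions
are nested within days.  The factor memberships define the loading
matrices used to build structured covariance matrices for the
variance-component model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "MeasurementOccasion",
    "StudyDesign",
    "default_mpm_design",
    "loading_matrix",
]


@dataclass(frozen=True)
class MeasurementOccasion:
    """One measurement occasion, labelled by day and session membership."""

    occasion_id: str
    day_id: str
    session_id: str


class StudyDesign:
    """An ordered collection of measurement occasions.

    Parameters
    ----------
    occasions
        Ordered occasions.  Occasion ids must be unique, every session
        must belong to exactly one day (nesting), and at least two
        occasions are required.
    """

    def __init__(self, occasions: Sequence[MeasurementOccasion]):
        occasions = list(occasions)
        if len(occasions) < 2:
            raise ValueError("a design needs at least 2 occasions")
        ids = [o.occasion_id for o in occasions]
        if len(set(ids)) != len(ids):
            raise ValueError("occasion_id values must be unique")
        session_day: dict[str, str] = {}
        for o in occasions:
            prev = session_day.setdefault(o.session_id, o.day_id)
            if prev != o.day_id:
                raise ValueError(
                    f"session {o.session_id!r} spans days {prev!r} and "
                    f"{o.day_id!r}; sessions must be nested within days"
                )
        self.occasions: tuple[MeasurementOccasion, ...] = tuple(occasions)

    @property
    def k(self) -> int:
        return len(self.occasions)

    @property
    def occasion_ids(self) -> list[str]:
        return [o.occasion_id for o in self.occasions]

    def levels(self, factor: str) -> list[str]:
        """Factor levels in order of first appearance."""
        attr = self._factor_attr(factor)
        seen: list[str] = []
        for o in self.occasions:
            lab = getattr(o, attr)
            if lab not in seen:
                seen.append(lab)
        return seen

    @staticmethod
    def _factor_attr(factor: str) -> str:
        if factor == "day":
            return "day_id"
        if factor == "session":
            return "session_id"
        raise ValueError(f"unknown factor {factor!r}; expected 'day' or 'session'")

    def loading_matrix(self, factor: str) -> np.ndarray:
        """Binary k x n_levels membership matrix for ``factor``.

        Row i has a single 1 in the column of the level occasion i
        belongs to, so row sums are all one.
        """
        attr = self._factor_attr(factor)
        levels = self.levels(factor)
        L = np.zeros((self.k, len(levels)), dtype=float)
        for i, o in enumerate(self.occasions):
            L[i, levels.index(getattr(o, attr))] = 1.0
        return L

    def comembership(self, factor: str) -> np.ndarray:
        """k x k indicator: 1 where two occasions share the factor level."""
        L = self.loading_matrix(factor)
        return L @ L.T

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "occasions": [
                {"occasion": o.occasion_id, "day": o.day_id, "session": o.session_id}
                for o in self.occasions
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyDesign":
        occs = [
            MeasurementOccasion(str(e["occasion"]), str(e["day"]), str(e["session"]))
            for e in d["occasions"]
        ]
        return cls(occs)

    @classmethod
    def from_yaml(cls, path) -> "StudyDesign":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def __eq__(self, other) -> bool:
        return isinstance(other, StudyDesign) and self.occasions == other.occasions

    def __repr__(self) -> str:
        return (
            f"StudyDesign(k={self.k}, days={len(self.levels('day'))}, "
            f"sessions={len(self.levels('session'))})"
        )


def default_mpm_design() -> StudyDesign:
    """The two-day scan-rescan design of the multiparameter-mapping study.

    Four occasions: two back-to-back measurements on Day 1 without
    repositioning (one shared session), and two measurements on Day 2
    with the participant repositioned in between (two sessions).
    """
    return StudyDesign(
        [
            MeasurementOccasion("D1M1", "day1", "s1"),
            MeasurementOccasion("D1M2", "day1", "s1"),
            MeasurementOccasion("D2M1", "day2", "s2"),
            MeasurementOccasion("D2M2", "day2", "s3"),
        ]
    )


def loading_matrix(design: StudyDesign, factor: str) -> np.ndarray:
    """Functional alias for :meth:`StudyDesign.loading_matrix`."""
    return design.loading_matrix(factor)
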