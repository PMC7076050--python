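"""Row-level data model for a smear study.

One :class:`SmearRecord` holds everything measured on a single mid-vaginal
smear: clinical group by Amsel criteria (noBV / aBV / sBV), optional Nugent
score, the microbiota community state type (CST), three per-field complete
epithelial cell counts at 100X, three cell-aggregate outline areas in µm²,
and — for sparse smears only — the superficial / total cell counts behind
the superficial cell index (SCI).

The SCI is gated: it is scored only when the mean of the three field counts
is at or below :data:`SCI_COUNT_GATE` cells per field, so the superficial
and total counts must be absent above the gate and paired below it.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

from .errors import IntegrityError

#: Mean complete-cell count (per 100X field) at or below which the SCI is scored.
SCI_COUNT_GATE = 50.0

#: Scheduled clinic visits (weeks since enrolment) in the emulated design.
SCHEDULED_WEEKS = (0, 5, 10)


class AmselGroup(str, enum.Enum):
    """Clinical diagnostic group by Amsel criteria.

    ``sBV`` and ``aBV`` both satisfy >= 3 of the 4 Amsel criteria and differ
    only in whether the participant reported symptoms; ``noBV`` fails the
    criteria.
    """

    noBV = "noBV"
    aBV = "aBV"
    sBV = "sBV"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class CSTLabel(str, enum.Enum):
    """Vaginal microbiota community state type.

    CST IV denotes a diverse community of strict and facultative anaerobes
    lacking *Lactobacillus* dominance; I/II/III/V are dominated by single
    *Lactobacillus* species.
    """

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class SmearRecord:
    """One sample's measurements plus clinical/microbiota metadata."""

    subject_id: str
    visit_week: int
    amsel_group: AmselGroup
    cst: CSTLabel
    field_counts: tuple[int, int, int]
    aggregate_areas_um2: tuple[float, float, float]
    interim: bool = False
    nugent_score: Optional[int] = None
    superficial_count: Optional[int] = None
    total_cells_scored: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "amsel_group", AmselGroup(self.amsel_group))
        object.__setattr__(self, "cst", CSTLabel(self.cst))
        object.__setattr__(self, "field_counts", tuple(int(c) for c in self.field_counts))
        object.__setattr__(
            self, "aggregate_areas_um2", tuple(float(a) for a in self.aggregate_areas_um2)
        )
        self.validate()

    # -- derived quantities -------------------------------------------------
    @property
    def mean_count(self) -> float:
        """Mean complete-cell count over the three 100X fields."""
        return sum(self.field_counts) / 3.0

    @property
    def mean_aggregate_area_um2(self) -> float:
        """Mean of the three representative cell-aggregate areas (µm²)."""
        return sum(self.aggregate_areas_um2) / 3.0

    @property
    def sci(self) -> Optional[float]:
        """Superficial cell index: superficial / total scored cells, or None."""
        if self.superficial_count is None or self.total_cells_scored is None:
            return None
        return self.superficial_count / self.total_cells_scored

    @property
    def sci_eligible(self) -> bool:
        return self.mean_count <= SCI_COUNT_GATE

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if not self.subject_id:
            raise IntegrityError("subject_id must be a non-empty string")
        if len(self.field_counts) != 3:
            raise IntegrityError("exactly three per-field counts are required")
        if any(c < 0 for c in self.field_counts):
            raise IntegrityError(f"field counts must be non-negative: {self.field_counts}")
        if len(self.aggregate_areas_um2) != 3:
            raise IntegrityError("exactly three aggregate areas are required")
        if any(not math.isfinite(a) or a <= 0 for a in self.aggregate_areas_um2):
            raise IntegrityError(
                f"aggregate areas must be strictly positive: {self.aggregate_areas_um2}"
            )
        if not self.interim and self.visit_week not in SCHEDULED_WEEKS:
            raise IntegrityError(
                f"non-interim visit_week must be one of {SCHEDULED_WEEKS}, "
                f"got {self.visit_week}"
            )
        if self.nugent_score is not None and not 0 <= self.nugent_score <= 10:
            raise IntegrityError(f"nugent_score out of range 0-10: {self.nugent_score}")
        has_sup = self.superficial_count is not None
        has_tot = self.total_cells_scored is not None
        if has_sup != has_tot:
            raise IntegrityError(
                "superficial_count and total_cells_scored must be present together"
            )
        if has_sup:
            if self.superficial_count < 0 or self.total_cells_scored < 0:
                raise IntegrityError("SCI counts must be non-negative")
            if self.superficial_count > self.total_cells_scored:
                raise IntegrityError(
                    f"superficial_count ({self.superficial_count}) exceeds "
                    f"total_cells_scored ({self.total_cells_scored})"
                )
            if not self.sci_eligible:
                raise IntegrityError(
                    f"SCI counts present but mean field count {self.mean_count:.1f} "
                    f"exceeds the gate ({SCI_COUNT_GATE})"
                )

    def replace(self, **changes) -> "SmearRecord":
        return replace(self, **changes)


@dataclass
class StudyTable:
    """An ordered, validated collection of :class:`SmearRecord`.

    (subject_id, visit_week) pairs are unique; every record has passed
    :meth:`SmearRecord.validate` on construction.
    """

    records: list[SmearRecord] = field(default_factory=list)
    source: Optional[str] = None
    schema_version: str = "1"

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for rec in self.records:
            key = (rec.subject_id, rec.visit_week)
            if key in seen:
                raise IntegrityError(f"duplicate (subject_id, visit_week): {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SmearRecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StudyTable):
            return NotImplemented
        return self.records == other.records

    def subjects(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.subject_id not in out:
                out.append(rec.subject_id)
        return out

    def filter(self, predicate) -> "StudyTable":
        return StudyTable(
            [r for r in self.records if predicate(r)],
            source=self.source,
            schema_version=self.schema_version,
        )

    def to_frame(self):
        """Flat :class:`pandas.DataFrame` view with derived analysis columns.

        Adds ``mean_count``, ``mean_aggregate_area_um2`` and ``sci`` on top of
        the raw stored fields.
        """
        import pandas as pd

        rows = []
        for rec in self.records:
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "visit_week": rec.visit_week,
                    "interim": rec.interim,
                    "amsel_group": rec.amsel_group.value,
                    "nugent_score": rec.nugent_score,
                    "cst": rec.cst.value,
                    "field_count_1": rec.field_counts[0],
                    "field_count_2": rec.field_counts[1],
                    "field_count_3": rec.field_counts[2],
                    "aggregate_area_um2_1": rec.aggregate_areas_um2[0],
                    "aggregate_area_um2_2": rec.aggregate_areas_um2[1],
                    "aggregate_area_um2_3": rec.aggregate_areas_um2[2],
                    "superficial_count": rec.superficial_count,
                    "total_cells_scored": rec.total_cells_scored,
                    "mean_count": rec.mean_count,
                    "mean_aggregate_area_um2": rec.mean_aggregate_area_um2,
                    "sci": rec.sci,
                }
            )
        return pd.DataFrame(rows)


def build_table(records: Iterable[SmearRecord], source: str | None = None) -> StudyTable:
    return StudyTable(list(records), source=source)
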