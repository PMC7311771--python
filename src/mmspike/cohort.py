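"""Age binning and (age bin x diagnosis) cell assignment.

The default binning splits each diagnosis group into seven age ranges:
5-10, 11-15, 16-20, 21-25, 26-30, 31-40 and 41-65 years.  Fractional ages
are floored before matching the inclusive integer bounds, so a 10.9-year-old
falls in 5-10.  Ages outside every bin are left unassigned and excluded with
a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from mmspike.errors import ValidationError
from mmspike.motion_io import SubjectRecord

__all__ = ["AgeBin", "DEFAULT_AGE_BINS", "assign_age_group", "assign_cells", "cell_counts"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AgeBin:
    """Inclusive integer age range with a display label."""

    label: str
    low: int
    high: int

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValidationError(f"bin {self.label}: low > high")

    def contains(self, age_floor: int) -> bool:
        return self.low <= age_floor <= self.high


DEFAULT_AGE_BINS: tuple[AgeBin, ...] = (
    AgeBin("5-10", 5, 10),
    AgeBin("11-15", 11, 15),
    AgeBin("16-20", 16, 20),
    AgeBin("21-25", 21, 25),
    AgeBin("26-30", 26, 30),
    AgeBin("31-40", 31, 40),
    AgeBin("41-65", 41, 65),
)


def _check_disjoint(bins: Sequence[AgeBin]) -> None:
    ordered = sorted(bins, key=lambda b: b.low)
    for left, right in zip(ordered, ordered[1:]):
        if right.low <= left.high:
            raise ValidationError(
                f"overlapping age bins: {left.label} and {right.label}"
            )


def assign_age_group(
    record: SubjectRecord, bins: Sequence[AgeBin] = DEFAULT_AGE_BINS
) -> str | None:
    """Bin label for a subject, or None when the age falls outside all bins."""
    _check_disjoint(bins)
    age_floor = int(record.age)
    for b in bins:
        if b.contains(age_floor):
            return b.label
    return None


def assign_cells(
    records: Iterable[SubjectRecord], bins: Sequence[AgeBin] = DEFAULT_AGE_BINS
) -> dict[tuple[str, str], list[SubjectRecord]]:
    """Partition subjects into (age-bin label, diagnosis) cells.

    Every assigned subject lands in exactly one cell; unassigned subjects are
    dropped with a logged count.
    """
    _check_disjoint(bins)
    cells: dict[tuple[str, str], list[SubjectRecord]] = {}
    unassigned = 0
    for rec in records:
        label = assign_age_group(rec, bins)
        if label is None:
            unassigned += 1
            continue
        cells.setdefault((label, rec.diagnosis), []).append(rec)
    if unassigned:
        logger.info("excluded %d subjects with ages outside all bins", unassigned)
    return cells


def cell_counts(cells: dict[tuple[str, str], list[SubjectRecord]]) -> dict[tuple[str, str], int]:
    return {cell: len(members) for cell, members in cells.items()}
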