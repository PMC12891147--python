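"""Vertebral morphometry: height-loss estimation and extended semi-quantitative grading.

Each vertebra from T3 to L5 is graded on a seven-category scale (none
through collapsed) according to its fractional height loss relative to the
expected height at that level.  Expected heights are reconstructed from
morphologically normal neighbouring vertebrae by linear interpolation.

Reader judgements enter as two boolean flags: ``fracture_like`` (the
deformity shows a distinct fracture-like morphology, required for the
minimal grade) and ``non_fracture_cause`` (the deformity is wholly
attributable to osteoarthritic wedging or endplatitis-type short vertebra,
which forces a grade of none).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

__all__ = [
    "VertebralLevel",
    "VertebraHeights",
    "VertebraFinding",
    "EsqGrade",
    "ReferenceLevelError",
    "estimate_height_loss",
    "assign_esq_grade",
    "ESQ_SCORES",
]


class VertebralLevel(enum.IntEnum):
    """The 15 thoracolumbar levels T3..T12, L1..L5 in anatomical order.

    The integer value is the position in the craniocaudal order, so
    adjacency is ``abs(a - b) == 1`` (T12 and L1 are adjacent).
    """

    T3 = 0
    T4 = 1
    T5 = 2
    T6 = 3
    T7 = 4
    T8 = 5
    T9 = 6
    T10 = 7
    T11 = 8
    T12 = 9
    L1 = 10
    L2 = 11
    L3 = 12
    L4 = 13
    L5 = 14

    @classmethod
    def from_label(cls, label: str) -> "VertebralLevel":
        """Parse a level label such as ``"T12"`` or ``"l4"``."""
        try:
            return cls[str(label).strip().upper()]
        except KeyError:
            raise ValueError(
                f"unknown vertebral level {label!r}; expected one of "
                f"{[m.name for m in cls]}"
            ) from None

    def is_adjacent_to(self, other: "VertebralLevel") -> bool:
        return abs(int(self) - int(other)) == 1


class EsqGrade(enum.Enum):
    """Extended semi-quantitative grade; the enum value is the per-vertebra score."""

    NONE = 0.0
    MINIMAL = -0.5
    MILD = -1.0
    MODERATE = -1.5
    MODERATELY_SEVERE = -2.0
    SEVERE = -2.5
    COLLAPSED = -3.0

    @property
    def score(self) -> float:
        return self.value

    @classmethod
    def from_score(cls, score: float) -> "EsqGrade":
        for member in cls:
            if member.value == score:
                return member
        raise ValueError(f"{score!r} is not a valid eSQ score")


ESQ_SCORES: tuple[float, ...] = tuple(g.value for g in EsqGrade)

# Height-loss band lower edges (closed on the left) for MILD..COLLAPSED.
# 33% and 66% are exact thirds.
_GRADE_EDGES: tuple[tuple[float, EsqGrade], ...] = (
    (2.0 / 3.0, EsqGrade.COLLAPSED),
    (0.40, EsqGrade.SEVERE),
    (1.0 / 3.0, EsqGrade.MODERATELY_SEVERE),
    (0.25, EsqGrade.MODERATE),
    (0.20, EsqGrade.MILD),
)


class ReferenceLevelError(ValueError):
    """No morphologically normal reference vertebra is available."""


@dataclass(frozen=True)
class VertebraHeights:
    """Measured anterior/middle/posterior heights of one vertebra, in mm."""

    level: VertebralLevel
    anterior_mm: float
    middle_mm: float
    posterior_mm: float

    def __post_init__(self) -> None:
        for name in ("anterior_mm", "middle_mm", "posterior_mm"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v!r}")

    @property
    def heights(self) -> tuple[float, float, float]:
        return (self.anterior_mm, self.middle_mm, self.posterior_mm)


@dataclass(frozen=True)
class VertebraFinding:
    """One vertebra's height-loss fraction plus reader-judgement flags."""

    level: VertebralLevel
    height_loss: float
    fracture_like: bool = False
    non_fracture_cause: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.height_loss <= 1.0:
            raise ValueError(
                f"height_loss must lie in [0, 1], got {self.height_loss!r}"
            )


def estimate_height_loss(
    spine: list[VertebraHeights],
    target: VertebralLevel,
    normal_levels: set[VertebralLevel] | frozenset[VertebralLevel],
) -> float:
    """Estimate the fractional height loss of ``target`` from normal neighbours.

    For each of the three height positions the expected height is linearly
    interpolated (by level position) between the nearest normal-shaped
    level above and below the target; if normal levels exist on one side
    only, the nearest one's height is carried over.  The returned loss is
    the maximum over positions of ``1 - h_target / h_expected``, floored
    at zero.

    Raises
    ------
    ReferenceLevelError
        If ``normal_levels`` contains no level present in ``spine``.
    ValueError
        If ``target`` has no row in ``spine``.
    """
    levels = [vh.level for vh in spine]
    by_level = {vh.level: vh for vh in spine}
    if len(by_level) != len(spine):
        dupes = sorted({lvl.name for lvl in levels if levels.count(lvl) > 1})
        raise ValueError(f"duplicate levels in spine: {dupes}")
    if target not in by_level:
        raise ValueError(f"target level {target.name} not present in spine")

    refs = sorted(
        lvl for lvl in normal_levels if lvl in by_level and lvl != target
    )
    if not refs:
        raise ReferenceLevelError(
            f"no normal reference level available for {target.name}"
        )
    above = [lvl for lvl in refs if lvl < target]
    below = [lvl for lvl in refs if lvl > target]

    worst = 0.0
    for pos in range(3):
        if above and below:
            lo, hi = above[-1], below[0]
            h_lo = by_level[lo].heights[pos]
            h_hi = by_level[hi].heights[pos]
            frac = (int(target) - int(lo)) / (int(hi) - int(lo))
            expected = h_lo + frac * (h_hi - h_lo)
        elif above:
            expected = by_level[above[-1]].heights[pos]
        else:
            expected = by_level[below[0]].heights[pos]
        loss = max(0.0, 1.0 - by_level[target].heights[pos] / expected)
        worst = max(worst, loss)
    return worst


def assign_esq_grade(finding: VertebraFinding) -> EsqGrade:
    """Map a vertebra finding to its eSQ grade.

    A deformity wholly attributed to a non-fracture cause grades as NONE
    regardless of height loss.  Losses below 20% grade as MINIMAL only when
    the reader judged the change fracture-like and the loss is strictly
    positive; losses of 20% or more are banded by the fixed height-loss
    intervals irrespective of the fracture-like flag.
    """
    if finding.non_fracture_cause:
        return EsqGrade.NONE
    loss = finding.height_loss
    for edge, grade in _GRADE_EDGES:
        if loss >= edge:
            return grade
    if loss > 0.0 and finding.fracture_like:
        return EsqGrade.MINIMAL
    return EsqGrade.NONE
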