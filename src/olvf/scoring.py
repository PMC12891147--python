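"""OLVF sum score (OLVFss) over T3-L5 with adjacency adjustments.

The sum score is the total of per-vertebra eSQ scores after two
adjustments, applied in this order:

* suppression: a minimal-grade vertebra (-0.5) anatomically adjacent to a
  vertebra scored -1.0 or worse contributes nothing;
* run merging: each maximal run of k >= 2 surviving adjacent minimal-grade
  vertebrae contributes ``-0.5 * ceil(k / 2)`` instead of ``-0.5 * k``
  (so two adjacent minimals count -0.5 and three count -1.0).

All non-minimal scores contribute their face value.  The most-severe-OLVF
metric, by contrast, is the minimum *raw* per-vertebra score, before any
adjustment: severity thresholds describe individual deformities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, Mapping

from .morphometry import ESQ_SCORES, VertebralLevel

__all__ = ["SpineAssessment", "compute_olvfss", "most_severe_olvf", "default_run_rule"]

_MINIMAL = -0.5
_ALLOWED = frozenset(ESQ_SCORES)


@dataclass(frozen=True)
class SpineAssessment:
    """Per-level eSQ scores for one subject; absent levels are score 0."""

    scores: Mapping[VertebralLevel, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[VertebralLevel, float] = {}
        for level, score in self.scores.items():
            if not isinstance(level, VertebralLevel):
                level = VertebralLevel.from_label(level)
            score = float(score)
            if score not in _ALLOWED:
                raise ValueError(
                    f"score {score!r} at {level.name} is not one of {sorted(_ALLOWED)}"
                )
            clean[level] = score
        object.__setattr__(self, "scores", clean)

    def score_at(self, level: VertebralLevel) -> float:
        return self.scores.get(level, 0.0)

    def deformed_levels(self) -> list[VertebralLevel]:
        return sorted(lvl for lvl, s in self.scores.items() if s < 0.0)

    @property
    def n_olvf(self) -> int:
        return sum(1 for s in self.scores.values() if s < 0.0)

    def __iter__(self) -> Iterator[tuple[VertebralLevel, float]]:
        return iter(sorted(self.scores.items()))


def default_run_rule(k: int) -> float:
    """Contribution of a maximal run of k adjacent surviving minimal grades."""
    return _MINIMAL * math.ceil(k / 2)


def compute_olvfss(
    assessment: SpineAssessment,
    run_rule: Callable[[int], float] = default_run_rule,
) -> float:
    """Compute the adjusted sum score; 0 for an empty spine, floor -45."""
    dense = [assessment.score_at(lvl) for lvl in VertebralLevel]
    n = len(dense)

    # Suppression pass: minimal next to a score <= -1.0 contributes 0.
    surviving = [
        dense[i] == _MINIMAL
        and not any(
            0 <= j < n and dense[j] <= -1.0 for j in (i - 1, i + 1)
        )
        for i in range(n)
    ]

    total = sum(s for s in dense if s != _MINIMAL)

    # Run-merging pass over surviving minimals.
    i = 0
    while i < n:
        if surviving[i]:
            k = 1
            while i + k < n and surviving[i + k]:
                k += 1
            total += _MINIMAL * k if k == 1 else run_rule(k)
            i += k
        else:
            i += 1
    return total


def most_severe_olvf(assessment: SpineAssessment) -> float:
    """Minimum raw per-vertebra score; 0 when no deformity is present."""
    return min(assessment.scores.values(), default=0.0)
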