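"""Sex-specific baseline positivity metrics and subject classification.

Each metric pairs a quantity (a DXA T-score or an OLVF-derived score) with
a cutpoint and a comparison direction.  T-scores may be missing; a subject
missing the metric's quantity is UNEVALUABLE and is dropped from both the
numerator and the denominator of downstream performance statistics.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

from .scoring import SpineAssessment, compute_olvfss, most_severe_olvf

__all__ = [
    "Sex",
    "Comparison",
    "Classification",
    "FollowUpOutcome",
    "SubjectRecord",
    "MetricDefinition",
    "QUANTITIES",
    "builtin_metrics",
    "classify",
]

QUANTITIES = ("fn_tscore", "ls_tscore", "olvfss", "most_severe_olvf")


class Sex(enum.Enum):
    FEMALE = "female"
    MALE = "male"

    @classmethod
    def parse(cls, value) -> "Sex":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown sex {value!r}; expected 'female' or 'male'"
            ) from None


class Comparison(enum.Enum):
    AT_OR_BELOW = "at_or_below"
    EXACTLY = "exactly"


class Classification(enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNEVALUABLE = "unevaluable"


@dataclass(frozen=True)
class FollowUpOutcome:
    """Follow-up result: hip-fracture and death times from baseline, in years.

    ``fx_time_years`` is present iff ``hip_fx``; a death recorded before the
    fracture would contradict ``hip_fx`` describing pre-death events and is
    rejected.
    """

    hip_fx: bool = False
    fx_time_years: Optional[float] = None
    death_time_years: Optional[float] = None
    followup_years: float = 5.0

    def __post_init__(self) -> None:
        if self.hip_fx != (self.fx_time_years is not None):
            raise ValueError("fx_time_years must be present iff hip_fx is true")
        for name in ("fx_time_years", "death_time_years", "followup_years"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v!r}")
        if (
            self.fx_time_years is not None
            and self.death_time_years is not None
            and self.death_time_years < self.fx_time_years
        ):
            raise ValueError("death before the recorded hip fracture is inconsistent")


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    sex: Sex
    age_years: float
    fn_tscore: Optional[float] = None
    ls_tscore: Optional[float] = None
    spine: SpineAssessment = SpineAssessment()
    outcome: FollowUpOutcome = FollowUpOutcome()

    def quantity(self, name: str) -> Optional[float]:
        """Return the named baseline quantity, or None when missing."""
        if name == "fn_tscore":
            return _none_if_nan(self.fn_tscore)
        if name == "ls_tscore":
            return _none_if_nan(self.ls_tscore)
        if name == "olvfss":
            return compute_olvfss(self.spine)
        if name == "most_severe_olvf":
            return most_severe_olvf(self.spine)
        raise ValueError(f"unknown quantity {name!r}; expected one of {QUANTITIES}")


def _none_if_nan(v: Optional[float]) -> Optional[float]:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return v


@dataclass(frozen=True)
class MetricDefinition:
    """A named baseline test: quantity, cutpoint and comparison direction."""

    name: str
    quantity: str
    cutpoint: float
    comparison: Comparison = Comparison.AT_OR_BELOW

    def __post_init__(self) -> None:
        if self.quantity not in QUANTITIES:
            raise ValueError(
                f"unknown quantity {self.quantity!r}; expected one of {QUANTITIES}"
            )


_FEMALE_METRICS = (
    MetricDefinition("neck T -2.7", "fn_tscore", -2.7),
    MetricDefinition("spine T -3.7", "ls_tscore", -3.7),
    MetricDefinition("spine T -2.5", "ls_tscore", -2.5),
    MetricDefinition("OLVFss -1.5", "olvfss", -1.5),
    MetricDefinition("OLVF hi-3", "most_severe_olvf", -3.0, Comparison.EXACTLY),
    MetricDefinition("OLVF hi-2.5", "most_severe_olvf", -2.5),
)

_MALE_METRICS = (
    MetricDefinition("neck T -2.1", "fn_tscore", -2.1),
    MetricDefinition("spine T -2.5", "ls_tscore", -2.5),
    MetricDefinition("OLVFss -2", "olvfss", -2.0),
    MetricDefinition("OLVFss -2.5", "olvfss", -2.5),
    MetricDefinition("OLVFss -3", "olvfss", -3.0),
    MetricDefinition("OLVF hi-2.0", "most_severe_olvf", -2.0),
    MetricDefinition("OLVF hi-2.5", "most_severe_olvf", -2.5),
    MetricDefinition("OLVF hi-3", "most_severe_olvf", -3.0, Comparison.EXACTLY),
)


def builtin_metrics(sex: Sex | str) -> list[MetricDefinition]:
    """The sex-specific built-in metric set, in reporting order."""
    sex = Sex.parse(sex)
    return list(_FEMALE_METRICS if sex is Sex.FEMALE else _MALE_METRICS)


def classify(subject: SubjectRecord, metric: MetricDefinition) -> Classification:
    """Classify a subject against one metric; missing quantity -> UNEVALUABLE."""
    value = subject.quantity(metric.quantity)
    if value is None:
        return Classification.UNEVALUABLE
    if metric.comparison is Comparison.EXACTLY:
        positive = value == metric.cutpoint
    else:
        positive = value <= metric.cutpoint
    return Classification.POSITIVE if positive else Classification.NEGATIVE
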