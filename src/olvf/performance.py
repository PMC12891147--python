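"""Analysis-set construction and screening operating characteristics.

The analysis set at a horizon keeps every subject who either sustained a
hip fracture at or before the horizon, or survived (no recorded death) to
the horizon; subjects who died before the horizon without a prior hip
fracture are excluded.  All statistics are crude percentages over the
analysis set — no person-time denominators and no survival modelling.

PPV = 100 * true positives / baseline positives;
sensitivity = 100 * true positives / fracture cases;
incidence = 100 * fracture cases / analysis-set size;
risk ratio = PPV / incidence.

Empty denominators give NaN (undefined), never 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .classification import (
    Classification,
    MetricDefinition,
    SubjectRecord,
    classify,
)

__all__ = [
    "PerformanceResult",
    "analysis_set",
    "evaluate_metric",
    "incidence",
    "risk_ratio",
    "performance_table",
]

# Printed precision: 3 decimals for PPV/incidence, 2 for sensitivity.
PPV_DECIMALS = 3
SENSITIVITY_DECIMALS = 2


@dataclass(frozen=True)
class PerformanceResult:
    metric_name: str
    horizon_years: float
    n_analysis: int
    n_positive: int
    n_fx: int
    n_true_positive: int

    def __post_init__(self) -> None:
        if self.n_true_positive > min(self.n_positive, self.n_fx):
            raise ValueError("true positives exceed positives or fracture cases")
        if max(self.n_positive, self.n_fx) > self.n_analysis:
            raise ValueError("counts exceed analysis-set size")

    @property
    def ppv(self) -> float:
        """Percentage of baseline positives who fractured; NaN if no positives."""
        if self.n_positive == 0:
            return math.nan
        return 100.0 * self.n_true_positive / self.n_positive

    @property
    def sensitivity(self) -> float:
        """Percentage of fracture cases positive at baseline; NaN if no cases."""
        if self.n_fx == 0:
            return math.nan
        return 100.0 * self.n_true_positive / self.n_fx

    @property
    def incidence(self) -> float:
        if self.n_analysis == 0:
            return math.nan
        return 100.0 * self.n_fx / self.n_analysis

    @property
    def risk_ratio(self) -> float:
        return risk_ratio(self.ppv, self.incidence)

    @property
    def ppv_counts(self) -> str:
        return f"{self.n_true_positive}/{self.n_positive}"

    @property
    def sensitivity_counts(self) -> str:
        return f"{self.n_true_positive}/{self.n_fx}"


def risk_ratio(ppv: float, incidence: float) -> float:
    """Fracture risk among test positives relative to the whole population."""
    if not incidence or math.isnan(ppv) or math.isnan(incidence):
        return math.nan
    return ppv / incidence


def _fx_within(subject: SubjectRecord, horizon_years: float) -> bool:
    o = subject.outcome
    return o.hip_fx and o.fx_time_years is not None and o.fx_time_years <= horizon_years


def analysis_set(
    cohort: Sequence[SubjectRecord], horizon_years: float
) -> list[SubjectRecord]:
    """Subjects who fractured by the horizon or survived to it."""
    if horizon_years < 0:
        raise ValueError(f"horizon must be >= 0, got {horizon_years!r}")
    kept = []
    for subject in cohort:
        if _fx_within(subject, horizon_years):
            kept.append(subject)
            continue
        death = subject.outcome.death_time_years
        if death is not None and death < horizon_years:
            continue
        kept.append(subject)
    return kept


def incidence(cohort: Sequence[SubjectRecord], horizon_years: float) -> float:
    """Crude percentage of analysis-set subjects fracturing by the horizon."""
    subjects = analysis_set(cohort, horizon_years)
    if not subjects:
        raise ValueError("analysis set is empty")
    n_fx = sum(_fx_within(s, horizon_years) for s in subjects)
    return 100.0 * n_fx / len(subjects)


def evaluate_metric(
    cohort: Sequence[SubjectRecord],
    metric: MetricDefinition,
    horizon_years: float,
) -> PerformanceResult:
    """Counts and operating characteristics of one metric at one horizon.

    Subjects unevaluable for the metric (missing quantity) are removed from
    every denominator before counting.
    """
    evaluable: list[tuple[SubjectRecord, Classification]] = []
    for subject in analysis_set(cohort, horizon_years):
        status = classify(subject, metric)
        if status is not Classification.UNEVALUABLE:
            evaluable.append((subject, status))
    if not evaluable:
        raise ValueError(
            f"no evaluable subjects for metric {metric.name!r} at {horizon_years}y"
        )
    n_positive = sum(st is Classification.POSITIVE for _, st in evaluable)
    n_fx = sum(_fx_within(s, horizon_years) for s, _ in evaluable)
    n_tp = sum(
        st is Classification.POSITIVE and _fx_within(s, horizon_years)
        for s, st in evaluable
    )
    return PerformanceResult(
        metric_name=metric.name,
        horizon_years=horizon_years,
        n_analysis=len(evaluable),
        n_positive=n_positive,
        n_fx=n_fx,
        n_true_positive=n_tp,
    )


def performance_table(
    cohort: Sequence[SubjectRecord],
    metrics: Sequence[MetricDefinition],
    horizons: Sequence[float],
) -> list[PerformanceResult]:
    """One result per metric x horizon, metric order then horizon ascending."""
    return [
        evaluate_metric(cohort, metric, horizon)
        for metric in metrics
        for horizon in sorted(horizons)
    ]
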