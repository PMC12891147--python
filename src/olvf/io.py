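"""CSV input/output, pipeline configuration and report rendering.

Exchange schemas (UTF-8, header row, '.' decimal separator):

``subjects.csv``
    subject_id, sex, age_years, fn_tscore, ls_tscore (blank = missing),
    plus the follow-up columns hip_fx (0/1), fx_time_years,
    death_time_years (blank = alive), followup_years.

``vertebrae.csv``
    subject_id, level (T3..L5), then either the three height columns
    anterior_mm/middle_mm/posterior_mm or a height_loss column (supplying
    both is an error), plus fracture_like (0/1) and non_fracture_cause
    (0/1).  For height-based rows the reference set for interpolation is
    the subject's levels flagged neither fracture-like nor
    non-fracture-cause.

``subject_scores.csv``
    subject_id, olvfss, most_severe_olvf, n_olvf.

``performance.csv``
    one row per metric x horizon with all counts, the derived
    percentages, and the "k/n" count pairs used in figure legends.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .classification import (
    Comparison,
    FollowUpOutcome,
    MetricDefinition,
    SubjectRecord,
    Sex,
    builtin_metrics,
)
from .morphometry import (
    VertebraFinding,
    VertebraHeights,
    VertebralLevel,
    assign_esq_grade,
    estimate_height_loss,
)
from .performance import (
    PPV_DECIMALS,
    SENSITIVITY_DECIMALS,
    PerformanceResult,
    analysis_set,
    performance_table,
)
from .scoring import SpineAssessment, compute_olvfss, most_severe_olvf

__all__ = [
    "PipelineConfig",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "write_subject_scores",
    "performance_frame",
    "write_performance",
    "render_report",
    "run_pipeline",
]

logger = logging.getLogger("olvf")


class CohortValidationError(ValueError):
    """Malformed cohort input; the message lists offending rows."""


@dataclass(frozen=True)
class PipelineConfig:
    subjects_path: Path
    vertebrae_path: Optional[Path] = None
    output_dir: Path = Path(".")
    horizons: tuple[float, ...] = (5.0,)
    metric_overrides: tuple[MetricDefinition, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.horizons:
            raise ValueError("horizons must be nonempty")
        if any(h <= 0 for h in self.horizons):
            raise ValueError("all horizons must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        overrides = tuple(
            MetricDefinition(
                name=m["name"],
                quantity=m["quantity"],
                cutpoint=float(m["cutpoint"]),
                comparison=Comparison(m.get("comparison", "at_or_below")),
            )
            for m in raw.get("metrics", [])
        )
        return cls(
            subjects_path=Path(raw["subjects"]),
            vertebrae_path=Path(raw["vertebrae"]) if raw.get("vertebrae") else None,
            output_dir=Path(raw.get("output_dir", ".")),
            horizons=tuple(float(h) for h in raw.get("horizons", [5.0])),
            metric_overrides=overrides,
            seed=int(raw.get("seed", 0)),
        )


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, str) and not value.strip()):
        return None
    v = float(value)
    return None if math.isnan(v) else v


def _read_spines(vertebrae_path: Path) -> dict[str, SpineAssessment]:
    df = pd.read_csv(vertebrae_path, dtype={"subject_id": str})
    errors: list[str] = []
    has_heights = {"anterior_mm", "middle_mm", "posterior_mm"} <= set(df.columns)
    has_loss = "height_loss" in df.columns

    parsed: dict[str, list] = {}
    seen: set[tuple[str, VertebralLevel]] = set()
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            level = VertebralLevel.from_label(row["level"])
        except ValueError as exc:
            errors.append(f"line {line}: {exc}")
            continue
        sid = row["subject_id"]
        key = (sid, level)
        if key in seen:
            errors.append(f"line {line}: duplicate ({sid}, {level.name})")
            continue
        seen.add(key)

        loss = _opt_float(row.get("height_loss")) if has_loss else None
        heights = None
        if has_heights:
            triple = [_opt_float(row.get(c)) for c in ("anterior_mm", "middle_mm", "posterior_mm")]
            if any(v is not None for v in triple):
                if loss is not None:
                    errors.append(
                        f"line {line}: both heights and height_loss supplied"
                    )
                    continue
                if any(v is None for v in triple):
                    errors.append(f"line {line}: incomplete height triple")
                    continue
                heights = triple
        if heights is None and loss is None:
            errors.append(f"line {line}: neither heights nor height_loss supplied")
            continue
        parsed.setdefault(sid, []).append(
            (
                line,
                level,
                loss,
                heights,
                bool(int(row.get("fracture_like", 0) or 0)),
                bool(int(row.get("non_fracture_cause", 0) or 0)),
            )
        )
    if errors:
        raise CohortValidationError(
            "vertebrae.csv validation failed:\n  " + "\n  ".join(errors)
        )

    spines: dict[str, SpineAssessment] = {}
    for sid, rows in parsed.items():
        measured = [
            VertebraHeights(level, *heights)
            for _, level, _, heights, _, _ in rows
            if heights is not None
        ]
        normal = {
            level
            for _, level, _, heights, frac, nonfrac in rows
            if heights is not None and not frac and not nonfrac
        }
        scores: dict[VertebralLevel, float] = {}
        for line, level, loss, heights, frac, nonfrac in rows:
            if heights is not None:
                if not frac and not nonfrac:
                    continue  # normal-shaped reference vertebra
                loss = estimate_height_loss(measured, level, normal)
            grade = assign_esq_grade(
                VertebraFinding(level, loss, fracture_like=frac, non_fracture_cause=nonfrac)
            )
            if grade.score != 0.0:
                scores[level] = grade.score
        spines[sid] = SpineAssessment(scores)
    return spines


def read_cohort(
    subjects_path: str | Path, vertebrae_path: str | Path | None = None
) -> list[SubjectRecord]:
    """Read subjects and (optionally) vertebra rows into SubjectRecords.

    Subjects without vertebra rows get an empty spine (OLVFss 0).
    """
    df = pd.read_csv(subjects_path, dtype={"subject_id": str})
    spines = _read_spines(Path(vertebrae_path)) if vertebrae_path else {}

    orphans = set(spines) - set(df["subject_id"])
    if orphans:
        raise CohortValidationError(
            f"vertebra rows for unknown subjects: {sorted(orphans)[:10]}"
        )
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if not dup.empty:
        raise CohortValidationError(f"duplicate subject_id: {sorted(set(dup))[:10]}")

    cohort: list[SubjectRecord] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2
        try:
            fx_time = _opt_float(row.get("fx_time_years"))
            outcome = FollowUpOutcome(
                hip_fx=bool(int(row.get("hip_fx", 0) or 0)),
                fx_time_years=fx_time,
                death_time_years=_opt_float(row.get("death_time_years")),
                followup_years=_opt_float(row.get("followup_years")) or 5.0,
            )
            cohort.append(
                SubjectRecord(
                    subject_id=row["subject_id"],
                    sex=Sex.parse(row["sex"]),
                    age_years=float(row["age_years"]),
                    fn_tscore=_opt_float(row.get("fn_tscore")),
                    ls_tscore=_opt_float(row.get("ls_tscore")),
                    spine=spines.get(row["subject_id"], SpineAssessment()),
                    outcome=outcome,
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise CohortValidationError(
            "subjects.csv validation failed:\n  " + "\n  ".join(errors)
        )
    logger.info("read %d subjects from %s", len(cohort), subjects_path)
    return cohort


def write_cohort(
    cohort: Sequence[SubjectRecord],
    subjects_path: str | Path,
    vertebrae_path: str | Path | None = None,
) -> None:
    """Write subjects.csv (and optionally vertebrae.csv with height_loss rows)."""
    rows = []
    for s in cohort:
        rows.append(
            {
                "subject_id": s.subject_id,
                "sex": s.sex.value,
                "age_years": round(s.age_years, 2),
                "fn_tscore": "" if s.fn_tscore is None else round(s.fn_tscore, 3),
                "ls_tscore": "" if s.ls_tscore is None else round(s.ls_tscore, 3),
                "hip_fx": int(s.outcome.hip_fx),
                "fx_time_years": (
                    "" if s.outcome.fx_time_years is None
                    else round(s.outcome.fx_time_years, 3)
                ),
                "death_time_years": (
                    "" if s.outcome.death_time_years is None
                    else round(s.outcome.death_time_years, 3)
                ),
                "followup_years": s.outcome.followup_years,
            }
        )
    pd.DataFrame(rows).to_csv(subjects_path, index=False)

    if vertebrae_path is not None:
        # Emit score-bearing vertebrae as height_loss rows: a representative
        # loss at the centre of each grade's height-loss band.
        loss_for_score = {-0.5: 0.10, -1.0: 0.225, -1.5: 0.29,
                         -2.0: 0.3667, -2.5: 0.53, -3.0: 0.83}
        vrows = []
        for s in cohort:
            for level, score in s.spine:
                vrows.append(
                    {
                        "subject_id": s.subject_id,
                        "level": level.name,
                        "height_loss": loss_for_score[score],
                        "fracture_like": 1,
                        "non_fracture_cause": 0,
                    }
                )
        pd.DataFrame(
            vrows,
            columns=["subject_id", "level", "height_loss", "fracture_like", "non_fracture_cause"],
        ).to_csv(vertebrae_path, index=False)


def write_subject_scores(cohort: Sequence[SubjectRecord], path: str | Path) -> None:
    rows = [
        {
            "subject_id": s.subject_id,
            "olvfss": compute_olvfss(s.spine),
            "most_severe_olvf": most_severe_olvf(s.spine),
            "n_olvf": s.spine.n_olvf,
        }
        for s in cohort
    ]
    pd.DataFrame(
        rows, columns=["subject_id", "olvfss", "most_severe_olvf", "n_olvf"]
    ).to_csv(path, index=False)


def performance_frame(results: Sequence[PerformanceResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "metric": r.metric_name,
                "horizon_years": r.horizon_years,
                "n_analysis": r.n_analysis,
                "n_positive": r.n_positive,
                "n_fx": r.n_fx,
                "n_true_positive": r.n_true_positive,
                "ppv_pct": round(r.ppv, PPV_DECIMALS) if not math.isnan(r.ppv) else math.nan,
                "sensitivity_pct": (
                    round(r.sensitivity, SENSITIVITY_DECIMALS)
                    if not math.isnan(r.sensitivity)
                    else math.nan
                ),
                "incidence_pct": round(r.incidence, PPV_DECIMALS),
                "risk_ratio": (
                    round(r.risk_ratio, 2) if not math.isnan(r.risk_ratio) else math.nan
                ),
                "ppv_counts": r.ppv_counts,
                "sensitivity_counts": r.sensitivity_counts,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "metric", "horizon_years", "n_analysis", "n_positive", "n_fx",
            "n_true_positive", "ppv_pct", "sensitivity_pct", "incidence_pct",
            "risk_ratio", "ppv_counts", "sensitivity_counts",
        ],
    )


def write_performance(results: Sequence[PerformanceResult], path: str | Path) -> None:
    performance_frame(results).to_csv(path, index=False)


def render_report(
    sex: Sex, results: Sequence[PerformanceResult], n_enrolled: int
) -> str:
    """Human-readable summary echoing the k/n count pairs."""
    lines = [f"## {sex.value.capitalize()} cohort ({n_enrolled} enrolled)", ""]
    for horizon in sorted({r.horizon_years for r in results}):
        at_h = [r for r in results if r.horizon_years == horizon]
        n_analysis = max(r.n_analysis for r in at_h)
        n_fx = max(r.n_fx for r in at_h)
        inc = 100.0 * n_fx / n_analysis
        lines.append(
            f"### {horizon:g}-year horizon: {n_fx} hip fractures / "
            f"{n_analysis} analysed (incidence {inc:.{PPV_DECIMALS}f}%)"
        )
        for r in at_h:
            ppv = (
                f"{r.ppv:.{PPV_DECIMALS}f}% ({r.ppv_counts})"
                if not math.isnan(r.ppv)
                else f"undefined ({r.ppv_counts})"
            )
            sens = (
                f"{r.sensitivity:.{SENSITIVITY_DECIMALS}f}% ({r.sensitivity_counts})"
                if not math.isnan(r.sensitivity)
                else f"undefined ({r.sensitivity_counts})"
            )
            rr = f"{r.risk_ratio:.2f}" if not math.isnan(r.risk_ratio) else "undefined"
            lines.append(
                f"- {r.metric_name}: PPV {ppv}, sensitivity {sens}, risk ratio {rr}"
            )
        lines.append("")
    return "\n".join(lines)


def run_pipeline(config: PipelineConfig) -> tuple[pd.DataFrame, str]:
    """score -> classify -> evaluate per sex; writes performance.csv + report."""
    cohort = read_cohort(config.subjects_path, config.vertebrae_path)
    config.output_dir.mkdir(parents=True, exist_ok=True)
    write_subject_scores(cohort, config.output_dir / "subject_scores.csv")

    all_results: list[PerformanceResult] = []
    report_parts: list[str] = []
    for sex in (Sex.FEMALE, Sex.MALE):
        sub = [s for s in cohort if s.sex is sex]
        if not sub:
            continue
        metrics = [m for m in config.metric_overrides] or builtin_metrics(sex)
        for h in config.horizons:
            kept = analysis_set(sub, h)
            logger.info(
                "%s %gy: %d enrolled -> %d analysed", sex.value, h, len(sub), len(kept)
            )
        results = performance_table(sub, metrics, list(config.horizons))
        results = [
            PerformanceResult(
                metric_name=f"{sex.value}:{r.metric_name}",
                horizon_years=r.horizon_years,
                n_analysis=r.n_analysis,
                n_positive=r.n_positive,
                n_fx=r.n_fx,
                n_true_positive=r.n_true_positive,
            )
            for r in results
        ]
        all_results.extend(results)
        report_parts.append(render_report(sex, results, len(sub)))

    frame = performance_frame(all_results)
    frame.to_csv(config.output_dir / "performance.csv", index=False)
    report = "\n".join(report_parts)
    (config.output_dir / "report.md").write_text(report)
    return frame, report
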