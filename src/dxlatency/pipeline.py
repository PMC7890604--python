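"""End-to-end study orchestration and report assembly.

Stages: load CDM tables -> window filtering -> daily aggregation and signal
detection -> computed diagnoses -> first structured diagnosis -> temporal
classification -> survival summaries.  Every percentage in the report names
its denominator explicitly, because the two natural denominators (the
computed-diagnosis cohort vs the new-diagnosis cohort) are easy to confuse.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from pydantic import BaseModel, Field, field_validator

from . import cdm_io
from .cdm_io import CdmTables, StudyWindow, filter_window
from .classification import (
    Category,
    PatientClassification,
    category_counts,
    classify,
    exclusion_filter,
)
from .diagnosis_matching import (
    CodeGroupTable,
    default_code_groups,
    first_structured_dx_by_patient,
)
from .phenotyping import Condition, compute_all, default_condition_specs
from .survival import (
    KMCurve,
    SurvivalInput,
    km_estimate,
    mean_censoring_time,
    mean_delay,
    probability_undiagnosed_at,
    write_km_csv,
)

logger = logging.getLogger(__name__)


class StudyConfig(BaseModel):
    """Study configuration (typically loaded from YAML)."""

    tables: dict[str, Path]
    columns: dict[str, dict[str, str]] = {}
    outpatient_enc_types: list[str] = ["AV", "OA"]
    data_start: dt.date
    measurement_cutoff: dt.date
    diagnosis_cutoff: dt.date
    require_followup_gap: bool = False
    conditions: list[Condition] = [Condition.HTN, Condition.HLD, Condition.DM]
    extra_lab_codes: dict[str, list[str]] = {}
    plot: bool = False

    @field_validator("conditions", mode="before")
    @classmethod
    def _coerce(cls, v):
        return [Condition(c) for c in v]

    @property
    def window(self) -> StudyWindow:
        return StudyWindow(
            self.data_start,
            self.measurement_cutoff,
            self.diagnosis_cutoff,
            require_followup_gap=self.require_followup_gap,
        )


@dataclass
class ConditionReport:
    condition: str
    n_computed: int
    counts: dict[str, int]
    pct_of_computed_cohort: dict[str, float]
    n_new_diagnoses: int  # early + eventual (structured dx, not pre-existing)
    early_pct_of_new_diagnoses: float | None
    first_source_counts_new_diagnoses: dict[str, int]
    mean_delay_days: float | None
    mean_delay_days_by_source: dict[str, float | None]
    mean_censoring_days: float | None
    n_structured_without_computed: int
    undiagnosed_probability_at_730d: float | None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass
class StudyReport:
    conditions: dict[str, ConditionReport] = field(default_factory=dict)
    load_report: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "conditions": {k: v.to_dict() for k, v in self.conditions.items()},
            "load_report": self.load_report,
        }


def last_encounter_by_patient(
    encounters: Sequence[cdm_io.EncounterRecord],
) -> dict[str, dt.date]:
    out: dict[str, dt.date] = {}
    for e in encounters:
        if e.patient_id not in out or e.encounter_date > out[e.patient_id]:
            out[e.patient_id] = e.encounter_date
    return out


def analyze_condition(
    data: CdmTables,
    condition: Condition,
    window: StudyWindow,
    code_groups: CodeGroupTable | None = None,
    extra_lab_codes: Mapping[str, Sequence[str]] | None = None,
) -> tuple[list[PatientClassification], KMCurve | None, int]:
    """Run the full per-condition analysis.

    Returns classifications for the computed-diagnosis cohort, the KM curve
    over the survival cohort (None when empty), and the count of patients
    holding a matching structured diagnosis without ever meeting the computed
    rule (reported separately, excluded from all denominators).
    """
    spec = default_condition_specs(extra_lab_codes)[condition]
    table = code_groups or default_code_groups()

    vitals = filter_window(data.vitals, window, "measurement")
    labs = filter_window(data.labs, window, "measurement")
    dx = filter_window(data.diagnoses, window, "diagnosis")
    encounters = filter_window(data.encounters, window, "diagnosis")
    last_enc = last_encounter_by_patient(encounters)

    _, computed = compute_all(vitals, labs, spec)
    structured = first_structured_dx_by_patient(dx, condition, table)

    classifications = [
        classify(cd, structured.get(pid), last_enc.get(pid))
        for pid, cd in sorted(computed.items())
    ]
    n_structured_only = sum(1 for pid in structured if pid not in computed)

    cohort = exclusion_filter(classifications)
    curve = None
    if cohort:
        surv = SurvivalInput.from_pairs([(c.duration_days, c.event) for c in cohort])
        curve = km_estimate(surv)
    return classifications, curve, n_structured_only


def summarize_condition(
    condition: Condition,
    classifications: Sequence[PatientClassification],
    curve: KMCurve | None,
    n_structured_without_computed: int,
) -> ConditionReport:
    counts = {cat.value: n for cat, n in category_counts(classifications).items()}
    n = len(classifications)
    pct = {cat: (100.0 * c / n if n else 0.0) for cat, c in counts.items()}

    new_dx = [c for c in classifications if c.category in (Category.EARLY, Category.EVENTUAL)]
    n_new = len(new_dx)
    early_pct = (
        100.0 * counts[Category.EARLY.value] / n_new if n_new else None
    )
    src_counts: dict[str, int] = {"provider": 0, "billing": 0, "claims": 0}
    for c in new_dx:
        src_counts[c.dx_source.value] += 1

    cohort = exclusion_filter(classifications)
    delay = censor_mean = None
    by_source: dict[str, float | None] = {}
    p730 = None
    if cohort:
        surv = SurvivalInput.from_pairs([(c.duration_days, c.event) for c in cohort])
        delay = mean_delay(surv)
        censor_mean = mean_censoring_time(surv)
        for src in ("provider", "billing", "claims"):
            ds = [c.duration_days for c in cohort if c.event and c.dx_source.value == src]
            by_source[src] = float(sum(ds)) / len(ds) if ds else None
        if curve is not None:
            p730 = probability_undiagnosed_at(curve, 730.0)

    return ConditionReport(
        condition=condition.value,
        n_computed=n,
        counts=counts,
        pct_of_computed_cohort=pct,
        n_new_diagnoses=n_new,
        early_pct_of_new_diagnoses=early_pct,
        first_source_counts_new_diagnoses=src_counts,
        mean_delay_days=delay,
        mean_delay_days_by_source=by_source,
        mean_censoring_days=censor_mean,
        n_structured_without_computed=n_structured_without_computed,
        undiagnosed_probability_at_730d=p730,
    )


def write_classifications_csv(
    classifications: Sequence[PatientClassification], path: str | Path
) -> Path:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["patient_id", "condition", "category", "first_signal_date", "second_signal_date",
             "dx_date", "dx_source", "last_encounter_date", "duration_days", "event"]
        )
        for c in classifications:
            w.writerow(
                [c.patient_id, c.condition.value, c.category.value,
                 c.first_signal_date.isoformat(), c.second_signal_date.isoformat(),
                 c.dx_date.isoformat() if c.dx_date else "",
                 c.dx_source.value if c.dx_source else "",
                 c.last_encounter_date.isoformat() if c.last_encounter_date else "",
                 "" if c.duration_days is None else c.duration_days,
                 int(c.event)]
            )
    return path


def run_study(config: StudyConfig, out_dir: str | Path) -> StudyReport:
    """Execute all stages and write the report plus per-condition artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = cdm_io.read_tables(
        config.tables, config.columns, outpatient_enc_types=config.outpatient_enc_types
    )
    window = config.window

    report = StudyReport(
        load_report={
            "loaded": dict(data.report.loaded),
            "dropped": {t: dict(c) for t, c in data.report.dropped.items()},
        }
    )
    curves: dict[str, KMCurve] = {}
    for condition in config.conditions:
        logger.info("analyzing %s", condition.value)
        classifications, curve, n_structured_only = analyze_condition(
            data, condition, window, extra_lab_codes=config.extra_lab_codes
        )
        cond_report = summarize_condition(condition, classifications, curve, n_structured_only)
        # cross-check: report counts must match the exported classification table
        path = write_classifications_csv(
            classifications, out / f"classification_{condition.value}.csv"
        )
        with open(path, encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
        assert len(rows) == cond_report.n_computed
        for cat, cnt in cond_report.counts.items():
            assert sum(1 for r in rows if r["category"] == cat) == cnt
        if curve is not None:
            write_km_csv(curve, out / f"km_{condition.value}.csv")
            curves[condition.value] = curve
        report.conditions[condition.value] = cond_report

    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2, default=str)
    if config.plot and curves:
        from .survival import plot_km

        plot_km(curves, out / "km_curves.png")
    logger.info("report written to %s", out / "report.json")
    return report
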