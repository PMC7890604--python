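"""Synthetic PCORnet-CDM-shaped extracts with a known ground-truth ledger.

The generator emits ``vital``, ``lab_result_cm``, ``diagnosis``, ``encounter``
and ``demographic`` tables readable by :mod:`dxlatency.cdm_io`, together with
one :class:`TruthRecord` per patient-condition stating the intended temporal
category.  Replaying the analysis pipeline over the emitted tables must
reproduce the intended categories except for draws flagged as *degenerate*:

* ``delay_clipped``      — the drawn recording delay lands past the diagnosis
  cutoff, so the diagnosis record is suppressed and the subject is observed
  as censored (exactly as in real data);
* ``healthy_false_pair`` — a healthy patient's random threshold exceedances
  happen to satisfy the two-signal rule;
* ``pre_existing_no_room`` — the first signal falls on the first day of the
  window, leaving no earlier day for a pre-existing diagnosis.

Encounters drive everything: no measurement is emitted without an encounter
row on that day, so the most recent encounter is always well defined.  All
randomness flows from one seed through per-patient ``SeedSequence``
substreams, so runs are reproducible and patient subsets stable.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .cdm_io import (
    CdmTables,
    CodeType,
    DiagnosisRecord,
    DxSource,
    EncounterRecord,
    EncounterSetting,
    LabRecord,
    StudyWindow,
    VitalRecord,
    write_tables,
)
from .phenotyping import A1C_LOINC, Condition, LDL_LOINC

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

# raw code strings as a CDM extract might carry them (dotted and dotless)
_CODE_POOL: dict[Condition, list[tuple[str, CodeType]]] = {
    Condition.HTN: [
        ("I10", CodeType.ICD10CM),
        ("401.9", CodeType.ICD9CM),
        ("4011", CodeType.ICD9CM),
        ("I11.9", CodeType.ICD10CM),
    ],
    Condition.DM: [
        ("E11.9", CodeType.ICD10CM),
        ("25000", CodeType.ICD9CM),
        ("E08.1", CodeType.ICD10CM),
        ("250.01", CodeType.ICD9CM),
    ],
    Condition.HLD: [
        ("E78.0", CodeType.ICD10CM),
        ("2720", CodeType.ICD9CM),
        ("E78.5", CodeType.ICD10CM),
        ("272.4", CodeType.ICD9CM),
    ],
}

_SOURCES = [DxSource.PROVIDER, DxSource.BILLING, DxSource.CLAIMS]
_SETTINGS = [
    EncounterSetting.OUTPATIENT,
    EncounterSetting.INPATIENT,
    EncounterSetting.EMERGENCY,
    EncounterSetting.OTHER,
]


class DelayModel(BaseModel):
    """Distribution of the diagnosis recording delay, in days."""

    kind: Literal["exponential", "lognormal"] = "exponential"
    mean_days: float = Field(200.0, gt=0)  # exponential mean
    mu: float = 5.0  # lognormal log-scale
    sigma: float = Field(0.75, gt=0)

    def draw(self, rng: np.random.Generator) -> int:
        if self.kind == "exponential":
            return int(round(rng.exponential(self.mean_days)))
        return int(round(rng.lognormal(self.mu, self.sigma)))


class ConditionModel(BaseModel):
    prevalence: float = Field(ge=0, le=1)
    measurement_probability: float = Field(0.5, ge=0, le=1)
    p_abnormal: float = Field(0.85, ge=0, le=1)
    healthy_exceedance: float = Field(0.02, ge=0, le=1)
    p_pre_existing: float = Field(0.2, ge=0, le=1)
    p_never: float = Field(0.2, ge=0, le=1)
    delay: DelayModel = DelayModel()
    source_mix: dict[str, float] = {"provider": 0.70, "billing": 0.25, "claims": 0.05}

    @model_validator(mode="after")
    def _check(self) -> "ConditionModel":
        if self.p_pre_existing + self.p_never > 1:
            raise ValueError("p_pre_existing + p_never must be <= 1")
        tot = sum(self.source_mix.get(s.value, 0.0) for s in _SOURCES)
        if abs(tot - 1.0) > 1e-9:
            raise ValueError("source_mix must sum to 1 over provider/billing/claims")
        return self


class SyntheticConfig(BaseModel):
    n_patients: int = Field(gt=0)
    seed: int = 0
    data_start: dt.date = dt.date(2012, 1, 1)
    measurement_cutoff: dt.date = dt.date(2018, 8, 11)
    diagnosis_cutoff: dt.date = dt.date(2019, 2, 10)
    encounters_per_year: float = Field(6.0, gt=0)
    setting_mix: dict[str, float] = {
        "outpatient": 0.80,
        "inpatient": 0.08,
        "emergency": 0.06,
        "other": 0.06,
    }
    conditions: dict[Condition, ConditionModel] = {}

    @field_validator("conditions", mode="before")
    @classmethod
    def _coerce_keys(cls, v):
        if isinstance(v, dict):
            return {Condition(k): m for k, m in v.items()}
        return v

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        if not self.data_start < self.measurement_cutoff < self.diagnosis_cutoff:
            raise ValueError("window dates must be strictly increasing")
        if (self.measurement_cutoff - self.data_start).days <= 30:
            raise ValueError(
                "measurement window too short for any 30-day signal pair"
            )
        tot = sum(self.setting_mix.get(s.value, 0.0) for s in _SETTINGS)
        if abs(tot - 1.0) > 1e-9:
            raise ValueError("setting_mix must sum to 1")
        if not self.conditions:
            raise ValueError("at least one condition model is required")
        return self

    @property
    def window(self) -> StudyWindow:
        return StudyWindow(self.data_start, self.measurement_cutoff, self.diagnosis_cutoff)


@dataclass(frozen=True, slots=True)
class TruthRecord:
    """Ground truth for one patient-condition.

    ``intended_category`` is the category the pipeline should recover
    (``None`` when no computed diagnosis is expected);
    ``degenerate``/``reason`` flag draws where the observed category will
    legitimately differ.
    """

    patient_id: str
    condition: str
    diseased: bool
    n_signal_days: int
    first_signal: dt.date | None
    second_signal: dt.date | None
    intended_category: str | None
    dx_date: dt.date | None
    delay_days: int | None
    source: str | None
    last_encounter: dt.date | None
    degenerate: bool
    reason: str | None


def _two_signal_dates(days: Sequence[int], sep: int) -> tuple[int, int] | None:
    """Brute-force all-ordered-pairs application of the two-signal rule.

    Deliberately independent of :func:`dxlatency.phenotyping.compute_diagnosis`
    so the end-to-end replay exercises both implementations.
    """
    qualifying = [d for d in days for d0 in days if d0 < d and d - d0 >= sep]
    if not qualifying:
        return None
    return min(days), min(qualifying)


def _vital_values(rng: np.random.Generator, abnormal: bool) -> tuple[float, float]:
    if abnormal:
        if rng.random() < 0.5:
            return 140.0 + rng.exponential(12.0), min(88.0, 70.0 + rng.normal(5.0, 5.0))
        return min(138.0, 118.0 + rng.normal(0.0, 8.0)), 90.0 + rng.exponential(6.0)
    sys_v = float(np.clip(118.0 + rng.normal(0.0, 8.0), 80.0, 139.0))
    dia_v = float(np.clip(72.0 + rng.normal(0.0, 6.0), 45.0, 89.0))
    return sys_v, dia_v


def _lab_value(rng: np.random.Generator, condition: Condition, abnormal: bool) -> float:
    if condition is Condition.HLD:
        if abnormal:
            return 130.0 + rng.exponential(20.0)
        return float(np.clip(105.0 + rng.normal(0.0, 12.0), 20.0, 129.5))
    if abnormal:
        return round(6.5 + rng.exponential(0.8), 1)
    return float(np.clip(round(5.4 + rng.normal(0.0, 0.4), 1), 3.5, 6.4))


def generate(
    config: SyntheticConfig, out_dir: str | Path | None = None
) -> tuple[CdmTables, list[TruthRecord]]:
    """Generate CDM tables and the truth ledger; deterministic given the seed.

    When ``out_dir`` is given the tables are also written as CSV along with
    ``truth.csv`` and ``truth_summary.json``.
    """
    window_days = (config.diagnosis_cutoff - config.data_start).days
    meas_days = (config.measurement_cutoff - config.data_start).days
    setting_p = [config.setting_mix.get(s.value, 0.0) for s in _SETTINGS]
    start = config.data_start

    data = CdmTables()
    truth: list[TruthRecord] = []
    children = np.random.SeedSequence(config.seed).spawn(config.n_patients)
    width = len(str(config.n_patients))

    for i in range(config.n_patients):
        rng = np.random.default_rng(children[i])
        pid = f"P{i:0{width}d}"
        data.demographics.append({"PATID": pid, "BIRTH_DATE": "1960-01-01", "SEX": "F" if rng.random() < 0.5 else "M"})

        n_enc = rng.poisson(config.encounters_per_year * (window_days + 1) / DAYS_PER_YEAR)
        if n_enc == 0:
            for cond in config.conditions:
                truth.append(
                    TruthRecord(pid, cond.value, False, 0, None, None, None, None, None, None, None, False, None)
                )
            continue
        enc_offsets = np.sort(rng.integers(0, window_days + 1, size=n_enc))
        enc_settings = rng.choice(len(_SETTINGS), size=n_enc, p=setting_p)
        last_encounter = start + dt.timedelta(days=int(enc_offsets[-1]))
        for off, si in zip(enc_offsets, enc_settings):
            data.encounters.append(
                EncounterRecord(pid, start + dt.timedelta(days=int(off)), _SETTINGS[si])
            )
        meas_mask = enc_offsets <= meas_days

        for cond, model in config.conditions.items():
            diseased = bool(rng.random() < model.prevalence)
            p_abn = model.p_abnormal if diseased else model.healthy_exceedance
            take = meas_mask & (rng.random(n_enc) < model.measurement_probability)
            counted_days: dict[int, list[tuple[float, float]] | list[float]] = {}
            if cond is Condition.HTN:
                for j in np.flatnonzero(take):
                    abnormal = rng.random() < p_abn
                    sys_v, dia_v = _vital_values(rng, abnormal)
                    setting = _SETTINGS[enc_settings[j]]
                    day = int(enc_offsets[j])
                    data.vitals.append(
                        VitalRecord(pid, start + dt.timedelta(days=day), round(sys_v, 1), round(dia_v, 1), setting)
                    )
                    if setting is EncounterSetting.OUTPATIENT:
                        counted_days.setdefault(day, []).append((round(sys_v, 1), round(dia_v, 1)))
                signal_days = sorted(
                    day
                    for day, readings in counted_days.items()
                    if min(r[0] for r in readings) >= 140.0 or min(r[1] for r in readings) >= 90.0
                )
            else:
                codes = sorted(LDL_LOINC if cond is Condition.HLD else A1C_LOINC)
                threshold = 130.0 if cond is Condition.HLD else 6.5
                for j in np.flatnonzero(take):
                    abnormal = rng.random() < p_abn
                    value = _lab_value(rng, cond, abnormal)
                    day = int(enc_offsets[j])
                    code = codes[int(rng.integers(len(codes)))]
                    data.labs.append(LabRecord(pid, start + dt.timedelta(days=day), code, value))
                    counted_days.setdefault(day, []).append(value)
                signal_days = sorted(
                    day for day, vals in counted_days.items() if min(vals) >= threshold
                )

            pair = _two_signal_dates(signal_days, 30)
            if pair is None:
                truth.append(
                    TruthRecord(
                        pid, cond.value, diseased, len(signal_days), None, None, None,
                        None, None, None, last_encounter, False, None,
                    )
                )
                continue

            first_off, second_off = pair
            first = start + dt.timedelta(days=first_off)
            second = start + dt.timedelta(days=second_off)

            if not diseased:
                truth.append(
                    TruthRecord(
                        pid, cond.value, False, len(signal_days), first, second, None,
                        None, None, None, last_encounter, True, "healthy_false_pair",
                    )
                )
                continue

            u = rng.random()
            dx_date: dt.date | None = None
            delay: int | None = None
            source: str | None = None
            degenerate, reason = False, None
            if u < model.p_pre_existing:
                intended = "pre_existing"
                room = first_off  # days strictly before the first signal, within window
                if room >= 1:
                    dx_date = start + dt.timedelta(days=int(rng.integers(0, room)))
                else:
                    dx_date = start  # collides with first signal -> observed early
                    degenerate, reason = True, "pre_existing_no_room"
            elif u < model.p_pre_existing + model.p_never:
                intended = "never"
            else:
                intended = "eventual"
                delay = model.delay.draw(rng)
                dx_date = second + dt.timedelta(days=delay)
                if dx_date > config.diagnosis_cutoff:
                    degenerate, reason = True, "delay_clipped"
                    dx_date = None  # observed as never/censored

            if dx_date is not None:
                source = str(rng.choice([s.value for s in _SOURCES],
                                        p=[model.source_mix[s.value] for s in _SOURCES]))
                code, code_type = _CODE_POOL[cond][int(rng.integers(len(_CODE_POOL[cond])))]
                data.diagnoses.append(
                    DiagnosisRecord(pid, dx_date, code, code_type, DxSource(source))
                )
            truth.append(
                TruthRecord(
                    pid, cond.value, True, len(signal_days), first, second, intended,
                    dx_date, delay, source, last_encounter, degenerate, reason,
                )
            )

    logger.info(
        "generated %d patients: %d encounters, %d vitals, %d labs, %d diagnoses",
        config.n_patients, len(data.encounters), len(data.vitals), len(data.labs), len(data.diagnoses),
    )
    if out_dir is not None:
        out = Path(out_dir)
        write_tables(data, out)
        write_truth(truth, out)
        with open(out / "truth_summary.json", "w", encoding="utf-8") as fh:
            json.dump(truth_report(truth), fh, indent=2)
    return data, truth


def write_truth(truth: Sequence[TruthRecord], out_dir: str | Path) -> Path:
    import csv

    path = Path(out_dir) / "truth.csv"
    fields = [f.name for f in TruthRecord.__dataclass_fields__.values()]  # type: ignore[attr-defined]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(fields)
        for t in truth:
            row = []
            for f in fields:
                v = getattr(t, f)
                row.append(v.isoformat() if isinstance(v, dt.date) else ("" if v is None else v))
            w.writerow(row)
    return path


def truth_report(truth: Sequence[TruthRecord]) -> dict:
    """Machine-readable summary of ground-truth category counts."""
    report: dict = {"n_records": len(truth), "conditions": {}}
    for t in truth:
        c = report["conditions"].setdefault(
            t.condition,
            {
                "n_subjects": 0,
                "n_diseased": 0,
                "n_computed_expected": 0,
                "intended_categories": {},
                "degenerate": {},
            },
        )
        c["n_subjects"] += 1
        c["n_diseased"] += int(t.diseased)
        if t.second_signal is not None:
            c["n_computed_expected"] += 1
        if t.intended_category is not None:
            c["intended_categories"][t.intended_category] = (
                c["intended_categories"].get(t.intended_category, 0) + 1
            )
        if t.degenerate:
            c["degenerate"][t.reason] = c["degenerate"].get(t.reason, 0) + 1
    return report
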