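"""Rule-based disease detection from vitals and labs.

A day is a *signal* when the per-day minimum measurement meets the condition's
threshold (inclusive).  A *computed diagnosis* exists once two signal days are
at least ``min_separation_days`` apart; it is dated at the second such signal.
"""

from __future__ import annotations

import datetime as dt
import enum
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .cdm_io import EncounterSetting, LabRecord, VitalRecord


class Condition(str, enum.Enum):
    HTN = "HTN"
    HLD = "HLD"
    DM = "DM"


@dataclass(frozen=True)
class ConditionSpec:
    """Signal rule for one condition.

    Exactly one of the vital-sign thresholds (HTN) or the lab threshold
    (HLD, DM) applies; lab conditions carry the code set identifying the
    relevant results (LOINC plus any configured local codes).
    """

    name: Condition
    systolic_threshold: float | None = None
    diastolic_threshold: float | None = None
    outpatient_only: bool = True
    lab_threshold: float | None = None
    lab_codes: frozenset[str] = frozenset()
    min_separation_days: int = 30

    def __post_init__(self) -> None:
        if self.min_separation_days < 0:
            raise ValueError("min_separation_days must be >= 0")
        if self.uses_labs and not self.lab_codes:
            raise ValueError(f"{self.name}: lab condition requires a non-empty code set")

    @property
    def uses_labs(self) -> bool:
        return self.lab_threshold is not None


#: LOINC codes from the default configuration: LDL cholesterol and HbA1c.
LDL_LOINC = frozenset({"13457-7", "18262-6"})
A1C_LOINC = frozenset({"4548-4"})


def default_condition_specs(
    extra_lab_codes: Mapping[str, Iterable[str]] | None = None,
) -> dict[Condition, ConditionSpec]:
    """Default rules: BP >= 140/90 outpatient, LDL >= 130, A1c >= 6.5.

    ``extra_lab_codes`` maps condition names to institution-local lab codes,
    unioned with the LOINC defaults.
    """
    extra = {Condition(k): frozenset(v) for k, v in (extra_lab_codes or {}).items()}
    return {
        Condition.HTN: ConditionSpec(
            Condition.HTN, systolic_threshold=140.0, diastolic_threshold=90.0, outpatient_only=True
        ),
        Condition.HLD: ConditionSpec(
            Condition.HLD, lab_threshold=130.0, lab_codes=LDL_LOINC | extra.get(Condition.HLD, frozenset())
        ),
        Condition.DM: ConditionSpec(
            Condition.DM, lab_threshold=6.5, lab_codes=A1C_LOINC | extra.get(Condition.DM, frozenset())
        ),
    }


@dataclass(frozen=True, slots=True)
class DailyObservation:
    """Per (patient, day) aggregate after the same-day-minimum rule.

    For HTN ``systolic``/``diastolic`` hold the independent minima across that
    day's qualifying readings; for lab conditions ``value`` holds the minimum
    matching result.
    """

    patient_id: str
    date: dt.date
    condition: Condition
    systolic: float | None = None
    diastolic: float | None = None
    value: float | None = None


@dataclass(frozen=True)
class SignalSeries:
    patient_id: str
    condition: Condition
    dates: tuple[dt.date, ...]

    def __post_init__(self) -> None:
        if list(self.dates) != sorted(set(self.dates)):
            raise ValueError("signal dates must be unique and ascending")


@dataclass(frozen=True, slots=True)
class ComputedDiagnosis:
    patient_id: str
    condition: Condition
    first_signal_date: dt.date
    second_signal_date: dt.date


def aggregate_daily(
    vitals: Sequence[VitalRecord],
    labs: Sequence[LabRecord],
    spec: ConditionSpec,
) -> list[DailyObservation]:
    """Collapse measurements to one observation per patient-day.

    Multiple same-day measurements are reduced to their minimum ("the most
    restrictive threshold"); HTN takes systolic and diastolic minima
    independently and uses outpatient readings only.  Records with null
    values for the needed fields are ignored.  Output order is sorted by
    (patient, date) and therefore invariant to input row order.
    """
    out: list[DailyObservation] = []
    if spec.uses_labs:
        best: dict[tuple[str, dt.date], float] = {}
        for r in labs:
            if r.code not in spec.lab_codes:
                continue
            key = (r.patient_id, r.specimen_date)
            if key not in best or r.value < best[key]:
                best[key] = r.value
        for (pid, day), v in best.items():
            out.append(DailyObservation(pid, day, spec.name, value=v))
    else:
        mins: dict[tuple[str, dt.date], list[float | None]] = defaultdict(lambda: [None, None])
        for r in vitals:
            if spec.outpatient_only and r.encounter_setting is not EncounterSetting.OUTPATIENT:
                continue
            key = (r.patient_id, r.measure_date)
            cur = mins[key]
            if r.systolic is not None and (cur[0] is None or r.systolic < cur[0]):
                cur[0] = r.systolic
            if r.diastolic is not None and (cur[1] is None or r.diastolic < cur[1]):
                cur[1] = r.diastolic
        for (pid, day), (s, d) in mins.items():
            if s is None and d is None:
                continue
            out.append(DailyObservation(pid, day, spec.name, systolic=s, diastolic=d))
    out.sort(key=lambda o: (o.patient_id, o.date))
    return out


def is_signal(obs: DailyObservation, spec: ConditionSpec) -> bool:
    """Threshold test on a daily observation; all thresholds inclusive (>=)."""
    if spec.uses_labs:
        return obs.value is not None and obs.value >= spec.lab_threshold
    hit_sys = obs.systolic is not None and obs.systolic >= spec.systolic_threshold
    hit_dia = obs.diastolic is not None and obs.diastolic >= spec.diastolic_threshold
    return hit_sys or hit_dia


def detect_signals(
    daily: Sequence[DailyObservation], spec: ConditionSpec
) -> dict[str, SignalSeries]:
    """Map patient_id -> ascending series of signal dates."""
    dates: dict[str, list[dt.date]] = defaultdict(list)
    for obs in daily:
        if is_signal(obs, spec):
            dates[obs.patient_id].append(obs.date)
    return {
        pid: SignalSeries(pid, spec.name, tuple(sorted(set(ds)))) for pid, ds in dates.items()
    }


def compute_diagnosis(series: SignalSeries, spec: ConditionSpec) -> ComputedDiagnosis | None:
    """Apply the two-signals->=30-days rule to a signal series.

    Returns ``None`` unless some pair of signal dates d' < d satisfies
    d - d' >= ``min_separation_days``.  Otherwise the first signal is the
    series minimum and the second signal is the earliest date with ANY
    qualifying earlier signal.  Because the series is ascending, the earliest
    possible partner is always the first date, so the scan below is exact
    (the brute-force all-pairs oracle in the test suite checks this).
    """
    ds = series.dates
    if len(ds) < 2:
        return None
    first = ds[0]
    sep = spec.min_separation_days
    for d in ds[1:]:
        if (d - first).days >= sep:
            return ComputedDiagnosis(series.patient_id, series.condition, first, d)
    return None


def compute_all(
    vitals: Sequence[VitalRecord],
    labs: Sequence[LabRecord],
    spec: ConditionSpec,
) -> tuple[dict[str, SignalSeries], dict[str, ComputedDiagnosis]]:
    """Convenience: daily aggregation -> signals -> computed diagnoses."""
    daily = aggregate_daily(vitals, labs, spec)
    signals = detect_signals(daily, spec)
    computed = {}
    for pid, series in signals.items():
        cd = compute_diagnosis(series, spec)
        if cd is not None:
            computed[pid] = cd
    return signals, computed
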