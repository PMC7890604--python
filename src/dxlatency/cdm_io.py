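"""Read/write the minimal PCORnet-CDM-shaped tables and normalize vocabulary.

Tables handled: ``vital``, ``lab_result_cm``, ``diagnosis`` (and optionally
``condition``, loaded into the same diagnosis record type), ``encounter``,
``demographic``.  Files are plain CSV (UTF-8, header row, ISO-8601 dates).
Column names are config-driven with PCORnet CDM v3.1 defaults so non-CDM
extracts can be adapted.
"""

from __future__ import annotations

import csv
import datetime as dt
import enum
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)


class EncounterSetting(str, enum.Enum):
    OUTPATIENT = "outpatient"
    INPATIENT = "inpatient"
    EMERGENCY = "emergency"
    OTHER = "other"


class CodeType(str, enum.Enum):
    ICD9CM = "ICD9CM"
    ICD10CM = "ICD10CM"


class DxSource(str, enum.Enum):
    """Source category of a structured diagnosis entry.

    CDM ``DX_SOURCE`` values OD / BI / CL are relabelled provider / billing /
    claims on load.
    """

    PROVIDER = "provider"
    BILLING = "billing"
    CLAIMS = "claims"


#: Precedence used to break same-date ties: provider > billing > claims.
SOURCE_PRECEDENCE: Mapping[DxSource, int] = {
    DxSource.PROVIDER: 0,
    DxSource.BILLING: 1,
    DxSource.CLAIMS: 2,
}

DX_SOURCE_MAP: Mapping[str, DxSource] = {
    "OD": DxSource.PROVIDER,
    "BI": DxSource.BILLING,
    "CL": DxSource.CLAIMS,
    "PROVIDER": DxSource.PROVIDER,
    "BILLING": DxSource.BILLING,
    "CLAIMS": DxSource.CLAIMS,
}

DX_TYPE_MAP: Mapping[str, CodeType] = {
    "09": CodeType.ICD9CM,
    "9": CodeType.ICD9CM,
    "ICD9": CodeType.ICD9CM,
    "ICD9CM": CodeType.ICD9CM,
    "10": CodeType.ICD10CM,
    "ICD10": CodeType.ICD10CM,
    "ICD10CM": CodeType.ICD10CM,
}


@dataclass(frozen=True, slots=True)
class VitalRecord:
    patient_id: str
    measure_date: dt.date
    systolic: float | None
    diastolic: float | None
    encounter_setting: EncounterSetting

    def __post_init__(self) -> None:
        for v in (self.systolic, self.diastolic):
            if v is not None and not (0 < v < 400):
                raise ValueError(f"blood pressure out of range: {v}")

    @property
    def event_date(self) -> dt.date:
        return self.measure_date


@dataclass(frozen=True, slots=True)
class LabRecord:
    patient_id: str
    specimen_date: dt.date
    code: str
    value: float

    def __post_init__(self) -> None:
        if not (self.value >= 0 and self.value == self.value and self.value != float("inf")):
            raise ValueError(f"lab value must be finite and >= 0: {self.value}")

    @property
    def event_date(self) -> dt.date:
        return self.specimen_date


@dataclass(frozen=True, slots=True)
class DiagnosisRecord:
    patient_id: str
    dx_date: dt.date
    code: str
    code_type: CodeType
    source: DxSource

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("diagnosis code must be non-empty")

    @property
    def event_date(self) -> dt.date:
        return self.dx_date


@dataclass(frozen=True, slots=True)
class EncounterRecord:
    patient_id: str
    encounter_date: dt.date
    encounter_setting: EncounterSetting

    @property
    def event_date(self) -> dt.date:
        return self.encounter_date


@dataclass(frozen=True, slots=True)
class StudyWindow:
    """Date bounds for the analysis.

    Measurements (vitals, labs) are kept in ``[data_start, measurement_cutoff]``;
    diagnoses and encounters in ``[data_start, diagnosis_cutoff]``.  Both ends
    inclusive.
    """

    data_start: dt.date
    measurement_cutoff: dt.date
    diagnosis_cutoff: dt.date
    #: When True, enforce the >= 26-week gap between measurement and diagnosis
    #: cutoffs used by the reference configuration.
    require_followup_gap: bool = False

    def __post_init__(self) -> None:
        if not (self.data_start < self.measurement_cutoff < self.diagnosis_cutoff):
            raise ValueError(
                "require data_start < measurement_cutoff < diagnosis_cutoff, got "
                f"{self.data_start} / {self.measurement_cutoff} / {self.diagnosis_cutoff}"
            )
        if self.require_followup_gap:
            gap = (self.diagnosis_cutoff - self.measurement_cutoff).days
            if gap < 26 * 7:
                raise ValueError(f"follow-up gap {gap}d is shorter than 26 weeks")


@dataclass
class LoadReport:
    """Per-table counts of rows dropped on load, by reason."""

    dropped: dict[str, Counter] = field(default_factory=dict)
    loaded: dict[str, int] = field(default_factory=dict)

    def drop(self, table: str, reason: str) -> None:
        self.dropped.setdefault(table, Counter())[reason] += 1

    def n_dropped(self, table: str | None = None) -> int:
        if table is not None:
            return sum(self.dropped.get(table, Counter()).values())
        return sum(sum(c.values()) for c in self.dropped.values())


@dataclass
class CdmTables:
    """In-memory typed representation of the CDM extract."""

    vitals: list[VitalRecord] = field(default_factory=list)
    labs: list[LabRecord] = field(default_factory=list)
    diagnoses: list[DiagnosisRecord] = field(default_factory=list)
    encounters: list[EncounterRecord] = field(default_factory=list)
    demographics: list[dict] = field(default_factory=list)
    report: LoadReport = field(default_factory=LoadReport)


# -- column configuration ----------------------------------------------------

CDM_DEFAULT_COLUMNS: dict[str, dict[str, str]] = {
    "vital": {
        "patient_id": "PATID",
        "date": "MEASURE_DATE",
        "systolic": "SYSTOLIC",
        "diastolic": "DIASTOLIC",
        "enc_type": "ENC_TYPE",
    },
    "lab_result_cm": {
        "patient_id": "PATID",
        "date": "SPECIMEN_DATE",
        "code": "LAB_LOINC",
        "value": "RESULT_NUM",
    },
    "diagnosis": {
        "patient_id": "PATID",
        "date": "ADMIT_DATE",
        "code": "DX",
        "code_type": "DX_TYPE",
        "source": "DX_SOURCE",
    },
    "encounter": {
        "patient_id": "PATID",
        "date": "ADMIT_DATE",
        "enc_type": "ENC_TYPE",
    },
    "demographic": {
        "patient_id": "PATID",
    },
}

#: CDM encounter-type codes treated as outpatient ("AV" ambulatory visit,
#: "OA" other ambulatory); override via config when local codes differ.
DEFAULT_OUTPATIENT_ENC_TYPES = frozenset({"AV", "OA"})
DEFAULT_INPATIENT_ENC_TYPES = frozenset({"IP", "EI", "IS"})
DEFAULT_EMERGENCY_ENC_TYPES = frozenset({"ED"})


def classify_enc_type(
    enc_type: str,
    outpatient_codes: frozenset[str] = DEFAULT_OUTPATIENT_ENC_TYPES,
) -> EncounterSetting:
    code = enc_type.strip().upper()
    if code in outpatient_codes:
        return EncounterSetting.OUTPATIENT
    if code in DEFAULT_INPATIENT_ENC_TYPES:
        return EncounterSetting.INPATIENT
    if code in DEFAULT_EMERGENCY_ENC_TYPES:
        return EncounterSetting.EMERGENCY
    return EncounterSetting.OTHER


SETTING_TO_ENC_TYPE = {
    EncounterSetting.OUTPATIENT: "AV",
    EncounterSetting.INPATIENT: "IP",
    EncounterSetting.EMERGENCY: "ED",
    EncounterSetting.OTHER: "OT",
}


def _parse_date(raw: str) -> dt.date | None:
    """Parse an ISO date, truncating any timestamp part to day granularity."""
    s = raw.strip()
    if not s:
        return None
    s = s.split("T")[0].split(" ")[0]
    try:
        return dt.date.fromisoformat(s)
    except ValueError:
        return None


def _parse_float(raw: str) -> float | None:
    s = raw.strip()
    if not s:
        return None
    try:
        v = float(s)
    except ValueError:
        return None
    if v != v or v in (float("inf"), float("-inf")):
        return None
    return v


def _open_table(path: Path, required: Sequence[str]) -> tuple[list[dict], list[str]]:
    if not path.exists():
        raise FileNotFoundError(f"table file not found: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in required:
            if col not in header:
                raise ValueError(f"missing required column {col!r} in {path}")
        rows = list(reader)
    if not rows:
        logger.warning("table %s is empty", path)
    return rows, header


def read_tables(
    paths: Mapping[str, str | Path],
    columns: Mapping[str, Mapping[str, str]] | None = None,
    outpatient_enc_types: Iterable[str] = DEFAULT_OUTPATIENT_ENC_TYPES,
) -> CdmTables:
    """Load typed records from per-table CSV paths.

    ``paths`` maps table names (``vital``, ``lab_result_cm``, ``diagnosis``,
    ``condition``, ``encounter``, ``demographic``) to files; absent tables are
    simply skipped.  Rows with unparseable dates, non-numeric values where a
    number is required, or unmapped vocabulary are dropped and counted in the
    returned :class:`LoadReport` — never silently coerced.
    """
    colmap = {t: dict(CDM_DEFAULT_COLUMNS.get(t.replace("condition", "diagnosis"), {})) for t in paths}
    if columns:
        for t, overrides in columns.items():
            colmap.setdefault(t, {}).update(overrides)
    out_codes = frozenset(c.strip().upper() for c in outpatient_enc_types)
    data = CdmTables()

    if "vital" in paths:
        c = colmap["vital"]
        rows, _ = _open_table(Path(paths["vital"]), [c["patient_id"], c["date"]])
        for row in rows:
            d = _parse_date(row[c["date"]] or "")
            if d is None:
                data.report.drop("vital", "bad_date")
                continue
            sys_v = _parse_float(row.get(c["systolic"], "") or "")
            dia_v = _parse_float(row.get(c["diastolic"], "") or "")
            if sys_v is None and dia_v is None:
                data.report.drop("vital", "no_numeric_value")
                continue
            try:
                rec = VitalRecord(
                    patient_id=row[c["patient_id"]].strip(),
                    measure_date=d,
                    systolic=sys_v,
                    diastolic=dia_v,
                    encounter_setting=classify_enc_type(row.get(c["enc_type"], "") or "", out_codes),
                )
            except ValueError:
                data.report.drop("vital", "out_of_range")
                continue
            data.vitals.append(rec)
        data.report.loaded["vital"] = len(data.vitals)

    if "lab_result_cm" in paths:
        c = colmap["lab_result_cm"]
        rows, _ = _open_table(Path(paths["lab_result_cm"]), [c["patient_id"], c["date"], c["value"]])
        for row in rows:
            d = _parse_date(row[c["date"]] or "")
            if d is None:
                data.report.drop("lab_result_cm", "bad_date")
                continue
            v = _parse_float(row[c["value"]] or "")
            if v is None or v < 0:
                data.report.drop("lab_result_cm", "bad_value")
                continue
            data.labs.append(
                LabRecord(
                    patient_id=row[c["patient_id"]].strip(),
                    specimen_date=d,
                    code=(row.get(c["code"], "") or "").strip(),
                    value=v,
                )
            )
        data.report.loaded["lab_result_cm"] = len(data.labs)

    for table in ("diagnosis", "condition"):
        if table not in paths:
            continue
        c = colmap.get(table) or colmap.get("diagnosis") or CDM_DEFAULT_COLUMNS["diagnosis"]
        rows, _ = _open_table(Path(paths[table]), [c["patient_id"], c["date"], c["code"]])
        n0 = len(data.diagnoses)
        for row in rows:
            d = _parse_date(row[c["date"]] or "")
            if d is None:
                data.report.drop(table, "bad_date")
                continue
            code = (row[c["code"]] or "").strip()
            if not code:
                data.report.drop(table, "empty_code")
                continue
            ct = DX_TYPE_MAP.get((row.get(c["code_type"], "") or "").strip().upper())
            if ct is None:
                data.report.drop(table, "unknown_code_type")
                continue
            src = DX_SOURCE_MAP.get((row.get(c["source"], "") or "").strip().upper())
            if src is None:
                data.report.drop(table, "unmapped_source")
                continue
            data.diagnoses.append(
                DiagnosisRecord(
                    patient_id=row[c["patient_id"]].strip(),
                    dx_date=d,
                    code=code,
                    code_type=ct,
                    source=src,
                )
            )
        data.report.loaded[table] = len(data.diagnoses) - n0

    if "encounter" in paths:
        c = colmap["encounter"]
        rows, _ = _open_table(Path(paths["encounter"]), [c["patient_id"], c["date"]])
        for row in rows:
            d = _parse_date(row[c["date"]] or "")
            if d is None:
                data.report.drop("encounter", "bad_date")
                continue
            data.encounters.append(
                EncounterRecord(
                    patient_id=row[c["patient_id"]].strip(),
                    encounter_date=d,
                    encounter_setting=classify_enc_type(row.get(c["enc_type"], "") or "", out_codes),
                )
            )
        data.report.loaded["encounter"] = len(data.encounters)

    if "demographic" in paths:
        rows, _ = _open_table(Path(paths["demographic"]), [colmap["demographic"]["patient_id"]])
        data.demographics = rows
        data.report.loaded["demographic"] = len(rows)

    for table, n in data.report.loaded.items():
        logger.info("loaded %d rows from %s (%d dropped)", n, table, data.report.n_dropped(table))
    return data


def write_tables(data: CdmTables, out_dir: str | Path) -> dict[str, Path]:
    """Write typed record collections back to CDM-named CSV files.

    Inverse of :func:`read_tables` under the default column map; the
    round-trip ``read_tables(write_tables(x))`` reproduces ``x``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _write(name: str, header: list[str], rows: Iterable[list]) -> None:
        p = out / f"{name}.csv"
        with open(p, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(header)
            w.writerows(rows)
        paths[name] = p

    _write(
        "vital",
        ["PATID", "MEASURE_DATE", "SYSTOLIC", "DIASTOLIC", "ENC_TYPE"],
        (
            [r.patient_id, r.measure_date.isoformat(),
             "" if r.systolic is None else _fmt_num(r.systolic),
             "" if r.diastolic is None else _fmt_num(r.diastolic),
             SETTING_TO_ENC_TYPE[r.encounter_setting]]
            for r in data.vitals
        ),
    )
    _write(
        "lab_result_cm",
        ["PATID", "SPECIMEN_DATE", "LAB_LOINC", "RESULT_NUM"],
        ([r.patient_id, r.specimen_date.isoformat(), r.code, _fmt_num(r.value)] for r in data.labs),
    )
    _write(
        "diagnosis",
        ["PATID", "ADMIT_DATE", "DX", "DX_TYPE", "DX_SOURCE"],
        (
            [r.patient_id, r.dx_date.isoformat(), r.code,
             "09" if r.code_type is CodeType.ICD9CM else "10",
             {DxSource.PROVIDER: "OD", DxSource.BILLING: "BI", DxSource.CLAIMS: "CL"}[r.source]]
            for r in data.diagnoses
        ),
    )
    _write(
        "encounter",
        ["PATID", "ADMIT_DATE", "ENC_TYPE"],
        ([r.patient_id, r.encounter_date.isoformat(), SETTING_TO_ENC_TYPE[r.encounter_setting]]
         for r in data.encounters),
    )
    if data.demographics:
        cols = list(data.demographics[0].keys())
        _write("demographic", cols, ([row.get(c, "") for c in cols] for row in data.demographics))
    else:
        _write("demographic", ["PATID"], [])
    for name, p in paths.items():
        logger.info("wrote %s", p)
    return paths


def _fmt_num(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def filter_window(records: Sequence, window: StudyWindow, kind: str) -> list:
    """Keep dated records inside the study window (inclusive both ends).

    ``kind`` is ``"measurement"`` (upper bound ``measurement_cutoff``) or
    ``"diagnosis"`` (upper bound ``diagnosis_cutoff``).  Order-preserving and
    idempotent.
    """
    if kind == "measurement":
        hi = window.measurement_cutoff
    elif kind == "diagnosis":
        hi = window.diagnosis_cutoff
    else:
        raise ValueError(f"unknown window kind: {kind!r}")
    lo = window.data_start
    return [r for r in records if lo <= r.event_date <= hi]
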