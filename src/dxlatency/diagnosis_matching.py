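"""Match structured diagnosis codes to condition code groups.

Matching compares the first 3 or 5 characters of a normalized (dotted) code
string against per-condition parent prefixes, separately per code system.
The first structured diagnosis per patient-condition is the earliest matching
date, with same-date ties broken provider > billing > claims.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .cdm_io import CodeType, DiagnosisRecord, DxSource, SOURCE_PRECEDENCE
from .phenotyping import Condition


@dataclass(frozen=True)
class CodeGroupTable:
    """Per-condition parent code prefixes, keyed by code system.

    Prefixes are either 3 characters or 5 characters with a dot at
    position 4 (e.g. ``"272.0"``).
    """

    groups: Mapping[Condition, Mapping[CodeType, frozenset[str]]]

    def __post_init__(self) -> None:
        for cond, per_type in self.groups.items():
            for ct, prefixes in per_type.items():
                for p in prefixes:
                    ok = len(p) == 3 or (len(p) == 5 and p[3] == ".")
                    if not ok:
                        raise ValueError(f"{cond}/{ct}: bad parent prefix {p!r}")

    def prefixes(self, condition: Condition, code_type: CodeType) -> frozenset[str]:
        return self.groups.get(condition, {}).get(code_type, frozenset())


def default_code_groups() -> CodeGroupTable:
    return CodeGroupTable(
        {
            Condition.HTN: {
                CodeType.ICD9CM: frozenset({"401", "402", "403", "404", "405", "642"}),
                CodeType.ICD10CM: frozenset({"I10", "I11", "I12", "I13", "I15", "I16", "I27", "O13"}),
            },
            Condition.DM: {
                CodeType.ICD9CM: frozenset({"249", "250"}),
                CodeType.ICD10CM: frozenset({"E08", "E09", "E10", "E11", "E13"}),
            },
            Condition.HLD: {
                CodeType.ICD9CM: frozenset({"272.0", "272.2", "272.3", "272.4", "272.9"}),
                CodeType.ICD10CM: frozenset(
                    {"E78.0", "E78.2", "E78.3", "E78.4", "E78.5", "E78.7", "E78.8", "E78.9"}
                ),
            },
        }
    )


@dataclass(frozen=True, slots=True)
class StructuredDiagnosis:
    patient_id: str
    condition: Condition
    first_dx_date: dt.date
    source: DxSource


def normalize_code(code: str) -> str | None:
    """Uppercase, strip, and repair dotless-dialect codes.

    A code of >= 4 characters with no dot gets a dot inserted after the third
    character (``"e780" -> "E78.0"``).  Returns ``None`` when the code is
    empty after stripping (caller drops and counts the record).
    """
    s = code.strip().upper()
    if not s:
        return None
    if len(s) >= 4 and "." not in s:
        s = s[:3] + "." + s[3:]
    return s


def match_code(
    code: str, code_type: CodeType, condition: Condition, table: CodeGroupTable
) -> bool:
    """True iff the normalized code falls under a parent prefix of its own
    code system: first 3 characters equal a 3-character parent, or first 5
    characters equal a dotted 5-character parent.  Never matches across code
    systems."""
    prefixes = table.prefixes(condition, code_type)
    return code[:3] in prefixes or code[:5] in prefixes


def first_structured_dx(
    dx: Sequence[DiagnosisRecord],
    condition: Condition,
    table: CodeGroupTable,
    patient_id: str | None = None,
) -> StructuredDiagnosis | None:
    """Earliest matching structured diagnosis for one patient.

    Ties on the earliest date are broken by source precedence
    provider > billing > claims; precedence never overrides date order.
    Returns ``None`` when no record matches.
    """
    best: tuple[dt.date, int] | None = None
    best_rec: DiagnosisRecord | None = None
    for rec in dx:
        if patient_id is not None and rec.patient_id != patient_id:
            continue
        norm = normalize_code(rec.code)
        if norm is None or not match_code(norm, rec.code_type, condition, table):
            continue
        key = (rec.dx_date, SOURCE_PRECEDENCE[rec.source])
        if best is None or key < best:
            best = key
            best_rec = rec
    if best_rec is None:
        return None
    return StructuredDiagnosis(best_rec.patient_id, condition, best_rec.dx_date, best_rec.source)


def first_structured_dx_by_patient(
    dx: Sequence[DiagnosisRecord], condition: Condition, table: CodeGroupTable
) -> dict[str, StructuredDiagnosis]:
    """Vector form of :func:`first_structured_dx` over a mixed-patient table."""
    best: dict[str, tuple[tuple[dt.date, int], DiagnosisRecord]] = {}
    for rec in dx:
        norm = normalize_code(rec.code)
        if norm is None or not match_code(norm, rec.code_type, condition, table):
            continue
        key = (rec.dx_date, SOURCE_PRECEDENCE[rec.source])
        cur = best.get(rec.patient_id)
        if cur is None or key < cur[0]:
            best[rec.patient_id] = (key, rec)
    return {
        pid: StructuredDiagnosis(pid, condition, rec.dx_date, rec.source)
        for pid, (_, rec) in best.items()
    }
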