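"""Temporal categorization of structured diagnoses relative to computed ones.

Each patient-condition with a computed diagnosis falls in exactly one of four
categories:

* ``pre_existing`` — structured dx strictly before the first signal;
* ``early``        — on the first signal or later, but before the second signal;
* ``eventual``     — on or after the second signal (the computed-diagnosis date);
* ``never``        — no structured dx at all.

Durations feed the survival analysis: for ``eventual`` the days from second
signal to the structured dx (event observed); for ``never`` the days from
second signal to the most recent encounter (censored).
"""

from __future__ import annotations

import datetime as dt
import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .cdm_io import DxSource
from .diagnosis_matching import StructuredDiagnosis
from .phenotyping import ComputedDiagnosis, Condition

logger = logging.getLogger(__name__)


class Category(str, enum.Enum):
    PRE_EXISTING = "pre_existing"
    EARLY = "early"
    EVENTUAL = "eventual"
    NEVER = "never"


@dataclass(frozen=True, slots=True)
class PatientClassification:
    patient_id: str
    condition: Condition
    category: Category
    first_signal_date: dt.date
    second_signal_date: dt.date
    dx_date: dt.date | None
    dx_source: DxSource | None
    last_encounter_date: dt.date | None
    #: Defined only for eventual/never; days, always >= 0.
    duration_days: int | None
    #: True iff the structured diagnosis was observed after the computed one.
    event: bool


def classify(
    computed: ComputedDiagnosis,
    structured: StructuredDiagnosis | None,
    last_encounter: dt.date | None,
) -> PatientClassification:
    """Assign the temporal category and survival duration for one subject.

    Boundary reads: a dx dated on the first-signal day is ``early`` (strictly
    "prior to" is required for pre-existing); a dx on the second-signal day is
    ``eventual`` with duration 0.  A never-diagnosed subject whose last
    encounter precedes the second signal gets duration floored at 0.
    """
    first, second = computed.first_signal_date, computed.second_signal_date
    if structured is None:
        if last_encounter is None:
            logger.warning(
                "%s/%s: never-diagnosed subject has no encounter; duration floored at 0",
                computed.patient_id, computed.condition.value,
            )
            duration = 0
        else:
            duration = (last_encounter - second).days
            if duration < 0:
                logger.warning(
                    "%s/%s: last encounter precedes second signal; duration floored at 0",
                    computed.patient_id, computed.condition.value,
                )
                duration = 0
        return PatientClassification(
            computed.patient_id, computed.condition, Category.NEVER,
            first, second, None, None, last_encounter, duration, event=False,
        )

    dx = structured.first_dx_date
    if dx < first:
        category, duration, event = Category.PRE_EXISTING, None, False
    elif dx < second:
        category, duration, event = Category.EARLY, None, False
    else:
        category, event = Category.EVENTUAL, True
        duration = (dx - second).days
        assert duration >= 0
    return PatientClassification(
        computed.patient_id, computed.condition, category,
        first, second, dx, structured.source, last_encounter, duration, event,
    )


def exclusion_filter(
    classifications: Iterable[PatientClassification],
) -> list[PatientClassification]:
    """Survival cohort: drop pre-existing and early, keep eventual and never."""
    kept = [c for c in classifications if c.category in (Category.EVENTUAL, Category.NEVER)]
    if not kept:
        logger.warning("survival cohort is empty after exclusions")
    return kept


def category_counts(
    classifications: Sequence[PatientClassification],
) -> dict[Category, int]:
    counts = {cat: 0 for cat in Category}
    for c in classifications:
        counts[c.category] += 1
    assert sum(counts.values()) == len(classifications)
    return counts
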