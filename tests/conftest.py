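import datetime as dt

import pytest

from dxlatency.cdm_io import (
    CdmTables,
    CodeType,
    DiagnosisRecord,
    DxSource,
    EncounterRecord,
    EncounterSetting,
    LabRecord,
    StudyWindow,
    VitalRecord,
)
from dxlatency.phenotyping import Condition, default_condition_specs

D = dt.date


def day(offset: int, origin: dt.date = D(2015, 1, 1)) -> dt.date:
    return origin + dt.timedelta(days=offset)


def vital(pid="p1", date=D(2015, 1, 1), sys=150.0, dia=85.0,
          setting=EncounterSetting.OUTPATIENT) -> VitalRecord:
    return VitalRecord(pid, date, sys, dia, setting)


def lab(pid="p1", date=D(2015, 1, 1), code="4548-4", value=7.0) -> LabRecord:
    return LabRecord(pid, date, code, value)


def dx(pid="p1", date=D(2015, 1, 1), code="I10", code_type=CodeType.ICD10CM,
       source=DxSource.PROVIDER) -> DiagnosisRecord:
    return DiagnosisRecord(pid, date, code, code_type, source)


def enc(pid="p1", date=D(2015, 1, 1), setting=EncounterSetting.OUTPATIENT) -> EncounterRecord:
    return EncounterRecord(pid, date, setting)


@pytest.fixture
def window() -> StudyWindow:
    return StudyWindow(D(2012, 1, 1), D(2018, 8, 11), D(2019, 2, 10))


@pytest.fixture
def specs():
    return default_condition_specs()


@pytest.fixture
def htn_spec(specs):
    return specs[Condition.HTN]


@pytest.fixture
def dm_spec(specs):
    return specs[Condition.DM]


@pytest.fixture
def hld_spec(specs):
    return specs[Condition.HLD]
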