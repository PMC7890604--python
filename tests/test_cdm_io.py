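import datetime as dt

import pytest

from dxlatency.cdm_io import (
    CdmTables,
    CodeType,
    DxSource,
    EncounterSetting,
    StudyWindow,
    VitalRecord,
    filter_window,
    read_tables,
    write_tables,
)

from conftest import D, dx, enc, lab, vital


def _write(path, text):
    path.write_text(text, encoding="utf-8")
    return path


class TestReadTables:
    def test_malformed_date_dropped_and_counted(self, tmp_path):
        p = _write(
            tmp_path / "vital.csv",
            "PATID,MEASURE_DATE,SYSTOLIC,DIASTOLIC,ENC_TYPE\n"
            "p1,2015-01-01,150,90,AV\n"
            "p1,not-a-date,140,85,AV\n"
            "p2,2015-02-01,120,80,AV\n",
        )
        data = read_tables({"vital": p})
        assert len(data.vitals) == 2
        assert data.report.n_dropped("vital") == 1
        assert data.report.dropped["vital"]["bad_date"] == 1

    def test_dx_source_relabelling(self, tmp_path):
        p = _write(
            tmp_path / "diagnosis.csv",
            "PATID,ADMIT_DATE,DX,DX_TYPE,DX_SOURCE\n"
            "p1,2015-01-01,I10,10,OD\n"
            "p1,2015-01-02,I10,10,BI\n"
            "p1,2015-01-03,401.9,09,CL\n",
        )
        data = read_tables({"diagnosis": p})
        assert [r.source for r in data.diagnoses] == [
            DxSource.PROVIDER, DxSource.BILLING, DxSource.CLAIMS,
        ]
        assert data.diagnoses[2].code_type is CodeType.ICD9CM

    def test_unmapped_source_dropped_not_coerced(self, tmp_path):
        p = _write(
            tmp_path / "diagnosis.csv",
            "PATID,ADMIT_DATE,DX,DX_TYPE,DX_SOURCE\n"
            "p1,2015-01-01,I10,10,XX\n"
            "p1,2015-01-02,I10,10,OD\n",
        )
        data = read_tables({"diagnosis": p})
        assert len(data.diagnoses) == 1
        assert data.report.dropped["diagnosis"]["unmapped_source"] == 1
        assert all(r.source in set(DxSource) for r in data.diagnoses)

    def test_missing_file_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_tables({"vital": tmp_path / "nope.csv"})

    def test_missing_column_fatal_names_column(self, tmp_path):
        p = _write(tmp_path / "vital.csv", "PATID,SYSTOLIC\np1,150\n")
        with pytest.raises(ValueError, match="MEASURE_DATE"):
            read_tables({"vital": p})

    def test_empty_table_gives_empty_collection(self, tmp_path):
        p = _write(tmp_path / "vital.csv", "PATID,MEASURE_DATE,SYSTOLIC,DIASTOLIC,ENC_TYPE\n")
        data = read_tables({"vital": p})
        assert data.vitals == []

    def test_timestamp_truncated_to_date(self, tmp_path):
        p = _write(
            tmp_path / "lab_result_cm.csv",
            "PATID,SPECIMEN_DATE,LAB_LOINC,RESULT_NUM\np1,2015-06-01T13:45:00,4548-4,6.9\n",
        )
        data = read_tables({"lab_result_cm": p})
        assert data.labs[0].specimen_date == D(2015, 6, 1)

    def test_custom_column_map(self, tmp_path):
        p = _write(tmp_path / "vital.csv", "id,when,sbp,dbp,etype\np1,2015-01-01,150,90,AV\n")
        data = read_tables(
            {"vital": p},
            columns={"vital": {"patient_id": "id", "date": "when", "systolic": "sbp",
                              "diastolic": "dbp", "enc_type": "etype"}},
        )
        assert data.vitals[0].systolic == 150
        assert data.vitals[0].encounter_setting is EncounterSetting.OUTPATIENT

    def test_condition_table_loaded_as_diagnoses(self, tmp_path):
        p = _write(
            tmp_path / "condition.csv",
            "PATID,ADMIT_DATE,DX,DX_TYPE,DX_SOURCE\np1,2015-01-01,I10,10,OD\n",
        )
        data = read_tables({"condition": p})
        assert len(data.diagnoses) == 1


class TestRoundTrip:
    def test_round_trip_identity(self, tmp_path):
        data = CdmTables(
            vitals=[vital(), vital("p2", D(2016, 2, 3), 120.5, None, EncounterSetting.INPATIENT)],
            labs=[lab(), lab("p2", D(2016, 2, 3), "13457-7", 131.2)],
            diagnoses=[dx(), dx("p2", D(2016, 2, 3), "4019", CodeType.ICD9CM, DxSource.CLAIMS)],
            encounters=[enc(), enc("p2", D(2016, 2, 3), EncounterSetting.EMERGENCY)],
        )
        paths = write_tables(data, tmp_path)
        back = read_tables(paths)
        assert back.vitals == data.vitals
        assert back.labs == data.labs
        assert back.diagnoses == data.diagnoses
        assert back.encounters == data.encounters
        assert back.report.n_dropped() == 0

    def test_empty_collections_write_header_only(self, tmp_path):
        paths = write_tables(CdmTables(), tmp_path)
        for name in ("vital", "lab_result_cm", "diagnosis", "encounter"):
            lines = paths[name].read_text().strip().splitlines()
            assert len(lines) == 1

    def test_iso_dates_on_disk(self, tmp_path):
        paths = write_tables(CdmTables(vitals=[vital(date=D(2015, 3, 7))]), tmp_path)
        assert "2015-03-07" in paths["vital"].read_text()


class TestRecordInvariants:
    @pytest.mark.parametrize("sys_v", [0.0, -10.0, 400.0, 500.0])
    def test_bp_range_enforced(self, sys_v):
        with pytest.raises(ValueError):
            VitalRecord("p1", D(2015, 1, 1), sys_v, 80.0, EncounterSetting.OUTPATIENT)

    def test_lab_value_nonnegative(self):
        with pytest.raises(ValueError):
            lab(value=-1.0)

    def test_window_order_enforced(self):
        with pytest.raises(ValueError):
            StudyWindow(D(2015, 1, 1), D(2014, 1, 1), D(2016, 1, 1))

    def test_followup_gap_enforced_when_requested(self):
        StudyWindow(D(2012, 1, 1), D(2018, 8, 11), D(2019, 2, 10), require_followup_gap=True)
        with pytest.raises(ValueError, match="26 weeks"):
            StudyWindow(D(2012, 1, 1), D(2018, 8, 11), D(2018, 9, 1), require_followup_gap=True)


class TestFilterWindow:
    def test_measurement_before_start_excluded(self, window):
        recs = [vital(date=D(2011, 12, 31))]
        assert filter_window(recs, window, "measurement") == []

    def test_measurement_on_cutoff_included(self, window):
        recs = [vital(date=window.measurement_cutoff)]
        assert filter_window(recs, window, "measurement") == recs

    def test_diagnosis_after_cutoff_excluded(self, window):
        recs = [dx(date=D(2019, 2, 11))]
        assert filter_window(recs, window, "diagnosis") == []

    def test_diagnosis_between_cutoffs_kept(self, window):
        recs = [dx(date=D(2018, 12, 1))]
        assert filter_window(recs, window, "diagnosis") == recs

    def test_idempotent_and_order_preserving(self, window):
        recs = [vital(date=D(2015, 5, 1)), vital(date=D(2013, 2, 1)), vital(date=D(2020, 1, 1))]
        once = filter_window(recs, window, "measurement")
        assert filter_window(once, window, "measurement") == once
        assert once == [recs[0], recs[1]]

    def test_unknown_kind_rejected(self, window):
        with pytest.raises(ValueError):
            filter_window([], window, "bogus")
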