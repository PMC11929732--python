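import datetime as dt

import numpy as np
import pytest

from srcohort import concepts as C
from srcohort.clinical import (ECGMeasurementSet, OutcomeSource,
                               PatientHistoryRecord, ProcedureOutcomeRecord,
                               TobaccoStatus, ecg_report,
                               history_records_from_table, measurement_report,
                               outcome_records_from_table, patient_history,
                               procedure_outcome)
from srcohort.coding import code
from srcohort.content import ValueKind
from srcohort.document import validate
from srcohort.ecg import ECGRecord, ecg_to_waveform
from srcohort.uids import UIDGenerator


@pytest.fixture
def ecg_rec():
    rng = np.random.default_rng(0)
    leads = [(n, np.round(rng.uniform(-200, 200, 50))) for n in C.STANDARD_LEADS]
    return ECGRecord("P1", dt.datetime(2019, 3, 2, 8, 0), 500.0, leads,
                     dt.date(2019, 3, 2))


def _items(doc):
    return {path: item for path, item in doc.iter_items()}


def test_ecg_report_contains_rate_num(ecg_rec, uid_gen, registry):
    wf = ecg_to_waveform(ecg_rec, uid_generator=uid_gen)
    doc = ecg_report(ecg_rec, ECGMeasurementSet(ventricular_rate=72.0),
                     waveform=wf, uid_generator=uid_gen)
    assert validate(doc, registry) == []
    (item,) = [i for _, i in doc.iter_items() if i.name == C.VENTRICULAR_RATE]
    assert item.value.as_float == 72.0
    assert item.value.unit == C.BEATS_PER_MINUTE
    assert len(doc.evidence) == 1
    assert doc.evidence[0].sop_instance_uid == wf.sop_uid
    assert doc.study_date == ecg_rec.study_date


def test_ecg_report_empty_measurements_still_validates(ecg_rec, uid_gen,
                                                       registry):
    doc = ecg_report(ecg_rec, ECGMeasurementSet(),
                     waveform=ecg_to_waveform(ecg_rec, uid_generator=uid_gen),
                     uid_generator=uid_gen)
    assert validate(doc, registry) == []


def test_ecg_report_encodes_waveform_on_the_fly(ecg_rec, uid_gen, registry):
    # a record with only a raw signal still yields a report with evidence
    doc = ecg_report(ecg_rec, ECGMeasurementSet(), uid_generator=uid_gen)
    assert validate(doc, registry) == []
    assert len(doc.evidence) == 1


def test_ecg_report_requires_patient_id(ecg_rec, uid_gen):
    object.__setattr__(ecg_rec, "patient_id", "")
    with pytest.raises(ValueError):
        ecg_report(ecg_rec, ECGMeasurementSet(), uid_generator=uid_gen)


def test_tobacco_path_matches_quoted_hierarchy(uid_gen, registry):
    doc = patient_history(
        PatientHistoryRecord("P1", tobacco_smoker=TobaccoStatus.YES),
        uid_generator=uid_gen)
    assert validate(doc, registry) == []
    items = _items(doc)
    key = ("Cardiovascular Patient History", "Social History",
           "Tobacco Smoker")
    assert key in items
    assert items[key].value_kind is ValueKind.CODE
    assert items[key].value == C.YES


def test_history_minimal_record(uid_gen, registry):
    doc = patient_history(PatientHistoryRecord("P1"), uid_generator=uid_gen)
    assert validate(doc, registry) == []
    assert len(list(doc.iter_items())) == 1  # just the root


def test_history_free_text_discoverable(uid_gen):
    doc = patient_history(PatientHistoryRecord("P1", free_text_notes="hello"),
                          uid_generator=uid_gen)
    texts = [i.value for _, i in doc.iter_items()
             if i.value_kind is ValueKind.TEXT]
    assert "hello" in texts


def test_patient_id_required():
    with pytest.raises(ValueError):
        PatientHistoryRecord("")


def test_outcome_pacemaker_yes_item(uid_gen, registry):
    doc = procedure_outcome(
        ProcedureOutcomeRecord("P1", dt.date(2020, 6, 1),
                               OutcomeSource.BILLING, pacemaker_implanted=True),
        uid_generator=uid_gen)
    assert validate(doc, registry) == []
    (item,) = [i for _, i in doc.iter_items()
               if i.name == C.PACEMAKER_IMPLANTATION]
    assert item.value == C.YES
    assert doc.study_date == dt.date(2020, 6, 1)
    assert doc.root.name == C.TITLE_QA_INFORMATION


def test_outcome_prosthesis_document(uid_gen, registry):
    model = code("M-X", "99SRC", "Model X")
    doc = procedure_outcome(
        ProcedureOutcomeRecord("P1", dt.date(2020, 6, 1),
                               OutcomeSource.QUALITY_ASSURANCE,
                               prosthesis_info=(model, 26.0)),
        uid_generator=uid_gen)
    assert validate(doc, registry) == []
    assert doc.root.name == C.TITLE_PROSTHESIS_INFORMATION
    names = {i.name for _, i in doc.iter_items()}
    assert C.PROSTHESIS_MODEL in names and C.PROSTHESIS_SIZE in names
    assert C.PACEMAKER_IMPLANTATION not in names


def test_pacemaker_label_requires_billing_source():
    with pytest.raises(ValueError):
        ProcedureOutcomeRecord("P1", dt.date(2020, 1, 1),
                               OutcomeSource.QUALITY_ASSURANCE,
                               pacemaker_implanted=True)


def test_measurement_set_rejects_nonpositive():
    with pytest.raises(ValueError):
        ECGMeasurementSet(ventricular_rate=-3.0)


def test_measurement_report_validates(uid_gen, registry):
    doc = measurement_report(
        "P1", dt.date(2020, 2, 2), frame_of_reference_uid=uid_gen(),
        hinge_points=((C.RIGHT_CORONARY_CUSP, (1.0, 2.0, 3.0)),),
        membranous_septum_mm=4.2, notes="n", uid_generator=uid_gen)
    assert validate(doc, registry) == []
    kinds = {i.value_kind for _, i in doc.iter_items()}
    assert ValueKind.SCOORD3D in kinds and ValueKind.NUM in kinds


def test_builders_deterministic(uid_gen):
    a = patient_history(PatientHistoryRecord("P1"),
                        uid_generator=UIDGenerator(3))
    b = patient_history(PatientHistoryRecord("P1"),
                        uid_generator=UIDGenerator(3))
    assert a == b


def test_history_table_ingestion(tmp_path, registry):
    p = tmp_path / "hist.csv"
    p.write_text("patient_id,tobacco_smoker,diabetes_mellitus,free_text_notes\n"
                 "A1,yes,true,hello\n"
                 "A2,unknown,,\n")
    recs = list(history_records_from_table(p))
    assert [r.patient_id for r in recs] == ["A1", "A2"]
    assert recs[0].tobacco_smoker is TobaccoStatus.YES
    assert recs[0].diabetes_mellitus is True
    assert recs[1].tobacco_smoker is TobaccoStatus.UNKNOWN
    assert recs[1].diabetes_mellitus is None
    for r in recs:
        assert validate(patient_history(r), registry) == []


def test_outcome_table_ingestion(tmp_path):
    p = tmp_path / "out.csv"
    p.write_text(
        "patient_id,procedure_date,source,pacemaker_implanted,"
        "prosthesis_model,prosthesis_size\n"
        "A1,2020-02-02,billing,1,,\n"
        "A2,2020-03-03,quality_assurance,,ModelX,26\n")
    recs = list(outcome_records_from_table(p))
    assert recs[0].pacemaker_implanted is True
    assert recs[0].source is OutcomeSource.BILLING
    assert recs[1].prosthesis_info[1] == 26.0
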