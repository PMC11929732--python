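import datetime as dt

import pytest

from srcohort import concepts as C
from srcohort.clinical import (OutcomeSource, PatientHistoryRecord,
                               ProcedureOutcomeRecord, TobaccoStatus,
                               patient_history, procedure_outcome)
from srcohort.indexing import (AnnotationKind, AttributePathSpec, CreatorType,
                               Index, IndexIntegrityError, LeafKind,
                               OrphanAnnotationError, SeriesRecord, build_index,
                               default_spec_set, export_bulk, extract,
                               flatten_annotation, import_bulk,
                               series_record_from_dicom, spec_set_from_yaml,
                               spec_set_to_yaml)
from srcohort.seg import (SegAlgorithmType, Segment, SegmentationObject)
from srcohort.uids import UIDGenerator

import numpy as np


def _parent(uid="S1", pid="P1", modality="CT", desc="CorCTA 40% cardiac phase",
            date=dt.date(2020, 1, 1)):
    return SeriesRecord(pid, f"STUDY-{uid}", uid, modality, desc, date)


def _history_doc(uid_gen, **kw):
    return patient_history(PatientHistoryRecord("P1", **kw),
                           uid_generator=uid_gen)


def test_extract_tobacco_value(uid_gen, spec_set):
    doc = _history_doc(uid_gen, tobacco_smoker=TobaccoStatus.YES)
    (spec,) = [s for s in spec_set if s.field_name == "tobacco_smoker"]
    vals = extract(doc, spec)
    assert len(vals) == 1
    name, value = vals[0]
    assert name == C.TOBACCO_SMOKER and value == C.YES


def test_extract_wrong_template_returns_empty(uid_gen, spec_set):
    doc = _history_doc(uid_gen, tobacco_smoker=TobaccoStatus.YES)
    (spec,) = [s for s in spec_set if s.field_name == "ventricular_rate"]
    assert extract(doc, spec) == []


def test_extract_strict_uses_code_path(uid_gen):
    doc = _history_doc(uid_gen, tobacco_smoker=TobaccoStatus.NO)
    spec = AttributePathSpec(
        "3802",
        (C.CARDIOVASCULAR_PATIENT_HISTORY.meaning, C.SOCIAL_HISTORY.meaning,
         C.TOBACCO_SMOKER.meaning),
        LeafKind.QUALITATIVE, "tobacco_smoker",
        code_path=(
            (C.CARDIOVASCULAR_PATIENT_HISTORY.value,
             C.CARDIOVASCULAR_PATIENT_HISTORY.scheme),
            (C.SOCIAL_HISTORY.value, C.SOCIAL_HISTORY.scheme),
            (C.TOBACCO_SMOKER.value, C.TOBACCO_SMOKER.scheme),
        ))
    vals = extract(doc, spec, strict=True)
    assert vals and vals[0][1] == C.NO
    # strict with a wrong scheme finds nothing
    bad = AttributePathSpec(spec.tid, spec.path, spec.leaf_kind, "x",
                            code_path=((spec.code_path[0][0], "WRONG"),
                                       spec.code_path[1], spec.code_path[2]))
    assert extract(doc, bad, strict=True) == []


def test_flatten_sr_child(uid_gen, spec_set):
    doc = _history_doc(uid_gen, tobacco_smoker=TobaccoStatus.YES,
                       free_text_notes="long smoker")
    child = flatten_annotation(doc, spec_set, attach_series_uid="S9")
    assert child.kind is AnnotationKind.SR
    assert child.referenced_series_uid == "S9"
    assert child.doc_title == C.CARDIOVASCULAR_PATIENT_HISTORY
    assert child.fields["tobacco_smoker"] == [C.YES.meaning]
    assert child.fields["history_notes"] == ["long smoker"]
    assert "Tobacco Smoker" in child.name_meanings()
    assert "Yes" in child.name_meanings()


def test_flatten_seg_child(rng, spec_set):
    seg = SegmentationObject(
        "S1",
        [Segment(1, C.LEFT_VENTRICLE, SegAlgorithmType.AUTOMATIC),
         Segment(2, C.RIGHT_VENTRICLE, SegAlgorithmType.AUTOMATIC)],
        [rng.random((2, 8, 8)) > 0.5 for _ in range(2)], sop_uid="1.2.3")
    child = flatten_annotation(seg, spec_set)
    assert child.kind is AnnotationKind.SEG
    assert child.creator_type is CreatorType.AUTOMATIC
    assert child.segment_labels == [C.LEFT_VENTRICLE, C.RIGHT_VENTRICLE]
    assert child.referenced_series_uid == "S1"


def test_build_index_attaches_and_sorts(uid_gen, spec_set):
    parents = [_parent("S2", pid="P2", date=dt.date(2020, 2, 2)),
               _parent("S1", pid="P1")]
    doc = _history_doc(uid_gen)
    idx = build_index(parents, [(doc, "S1")], spec_set)
    assert [d.series_uid for d in idx.documents] == ["S1", "S2"]
    assert len(idx.by_series()["S1"].annotations) == 1
    assert idx.patients() == {"P1", "P2"}


def test_orphan_policy_skip_logs_and_drops(uid_gen, spec_set):
    doc = _history_doc(uid_gen)
    idx = build_index([_parent("S1")], [(doc, "MISSING")], spec_set,
                      orphan_policy="skip")
    assert idx.dropped_orphans == [doc.sop_uid]
    assert all(not d.annotations for d in idx.documents)


def test_orphan_policy_synthetic_parent(uid_gen, spec_set):
    doc = _history_doc(uid_gen)
    idx = build_index([_parent("S1")], [(doc, "MISSING")], spec_set,
                      orphan_policy="synthetic-parent")
    assert len(idx.documents) == 2
    orphan_parent = idx.by_series()["MISSING"]
    assert orphan_parent.patient_id == "ORPHANS"
    assert len(orphan_parent.annotations) == 1


def test_orphan_policy_error(uid_gen, spec_set):
    doc = _history_doc(uid_gen)
    with pytest.raises(OrphanAnnotationError):
        build_index([_parent("S1")], [(doc, "MISSING")], spec_set,
                    orphan_policy="error")


def test_duplicate_series_uid_rejected(spec_set):
    with pytest.raises(IndexIntegrityError):
        build_index([_parent("S1"), _parent("S1", pid="P2")], [], spec_set)


def test_bulk_round_trip(rng, uid_gen, spec_set):
    doc1 = _history_doc(uid_gen, tobacco_smoker=TobaccoStatus.NO)
    doc2 = procedure_outcome(
        ProcedureOutcomeRecord("P1", dt.date(2020, 3, 3),
                               OutcomeSource.BILLING, pacemaker_implanted=True),
        uid_generator=uid_gen)
    seg = SegmentationObject(
        "S1", [Segment(1, C.CALCIFICATION, SegAlgorithmType.AUTOMATIC)],
        [rng.random((2, 8, 8)) > 0.5], sop_uid="1.2.9")
    idx = build_index([_parent("S1"), _parent("S2", pid="P2")],
                      [(doc1, "S1"), (doc2, "S2"), seg], spec_set)
    back = import_bulk(export_bulk(idx), spec_set)
    assert back.documents == idx.documents
    # and a second export is byte-identical
    assert export_bulk(back) == export_bulk(idx)


def test_bulk_empty_index(spec_set):
    idx = Index([], list(spec_set))
    assert import_bulk(export_bulk(idx), spec_set).documents == []


def test_spec_set_yaml_round_trip(tmp_path, spec_set):
    p = tmp_path / "specs.yaml"
    spec_set_to_yaml(spec_set, p)
    back = spec_set_from_yaml(p)
    assert back == list(spec_set)


def test_spec_set_yaml_duplicate_field_rejected(tmp_path, spec_set):
    dup = list(spec_set) + [AttributePathSpec(
        "3802", ("A",), LeafKind.TEXT, spec_set[0].field_name)]
    p = tmp_path / "bad.yaml"
    spec_set_to_yaml(dup, p)
    with pytest.raises(ValueError):
        spec_set_from_yaml(p)


def test_series_record_from_dicom_header(rng):
    import datetime as dtm
    from srcohort.ecg import ECGRecord, ecg_to_waveform
    leads = [(n, np.zeros(8)) for n in C.STANDARD_LEADS]
    rec = ECGRecord("P7", dtm.datetime(2020, 6, 6, 9), 250.0, leads,
                    dtm.date(2020, 6, 6))
    wf = ecg_to_waveform(rec, uid_generator=UIDGenerator(2))
    sr = series_record_from_dicom(wf.data)
    assert sr.patient_id == "P7"
    assert sr.modality == "ECG"
    assert sr.study_date == dtm.date(2020, 6, 6)
    assert sr.series_uid == wf.series_uid


def test_default_spec_set_field_names_unique(spec_set):
    names = [s.field_name for s in spec_set]
    assert len(set(names)) == len(names)
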