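import datetime as dt
import sqlite3

import numpy as np
import pytest

from srcohort import concepts as C
from srcohort.indexing import (AnnotationChild, AnnotationKind, IndexDocument,
                               Index, SeriesRecord, build_index,
                               default_spec_set)
from srcohort.query import (AND, NESTED, NOT, OR, Mode, PredKind, Predicate,
                            QueryParseError, QueryValidationError, Scope,
                            SQLCapabilityError, evaluate, evaluate_patient,
                            load_sql, oracle_evaluate, parse_query,
                            render_query, render_sql, select_pre_procedure_ecg,
                            validate_query)
from srcohort.randgen import random_index, random_query, random_sql_query
from srcohort.seg import SegAlgorithmType, Segment, SegmentationObject
from srcohort.uids import UIDGenerator


def _seg(series_uid, labels, rng, sop):
    segs = [Segment(i + 1, lab, SegAlgorithmType.AUTOMATIC)
            for i, lab in enumerate(labels)]
    return SegmentationObject(series_uid,
                              segs,
                              [rng.random((2, 4, 4)) > 0.5 for _ in labels],
                              sop_uid=sop)


@pytest.fixture
def lvrv_index(rng, spec_set):
    """Canonical fixture: S-BOTH has one SEG child labelled LV and RV;
    S-SPLIT has two SEG children, one labelled LV and one RV."""
    parents = [
        SeriesRecord("P1", "ST1", "S-BOTH", "CT", "CorCTA 40% cardiac phase",
                     dt.date(2020, 1, 1)),
        SeriesRecord("P2", "ST2", "S-SPLIT", "CT", "CorCTA 40% cardiac phase",
                     dt.date(2020, 1, 2)),
        SeriesRecord("P3", "ST3", "S-NONE", "CT", "CorCTA 70% cardiac phase",
                     dt.date(2020, 1, 3)),
    ]
    anns = [
        _seg("S-BOTH", [C.LEFT_VENTRICLE, C.RIGHT_VENTRICLE], rng, "1.1"),
        _seg("S-SPLIT", [C.LEFT_VENTRICLE], rng, "1.2"),
        _seg("S-SPLIT", [C.RIGHT_VENTRICLE], rng, "1.3"),
    ]
    return build_index(parents, anns, spec_set)


LVRV = NESTED(
    Predicate(Scope.ANNOTATION, PredKind.HAS_SEGMENT_LABEL,
              value=C.LEFT_VENTRICLE.meaning),
    Predicate(Scope.ANNOTATION, PredKind.HAS_SEGMENT_LABEL,
              value=C.RIGHT_VENTRICLE.meaning),
)


def test_lvrv_nested_vs_flattened(lvrv_index):
    nested = evaluate(lvrv_index, LVRV, Mode.NESTED)
    flat = evaluate(lvrv_index, LVRV, Mode.FLATTENED)
    assert nested.ids == {"S-BOTH"}
    assert flat.ids == {"S-BOTH", "S-SPLIT"}
    # oracle agrees on both
    assert oracle_evaluate(lvrv_index, LVRV, Mode.NESTED).ids == nested.ids
    assert oracle_evaluate(lvrv_index, LVRV, Mode.FLATTENED).ids == flat.ids


def test_lvrv_provenance_points_at_witnesses(lvrv_index):
    res = evaluate(lvrv_index, LVRV, Mode.NESTED)
    doc = lvrv_index.by_series()["S-BOTH"]
    (i,) = res.provenance["S-BOTH"]
    assert set(doc.annotations[i].segment_labels) >= {C.LEFT_VENTRICLE,
                                                      C.RIGHT_VENTRICLE}


def test_engine_matches_oracle_random(rng):
    disagreements = 0
    for i in range(120):
        index = random_index(np.random.default_rng(1000 + i))
        q = random_query(np.random.default_rng(5000 + i), index)
        for mode in (Mode.NESTED, Mode.FLATTENED):
            if evaluate(index, q, mode).ids != oracle_evaluate(index, q, mode).ids:
                disagreements += 1
    assert disagreements == 0


def test_patient_level_matches_oracle_random(rng):
    for i in range(60):
        index = random_index(np.random.default_rng(2000 + i))
        q = random_query(np.random.default_rng(6000 + i), index)
        for mode in (Mode.NESTED, Mode.FLATTENED):
            got = evaluate_patient(index, q, mode).ids
            want = oracle_evaluate(index, q, mode, level="PATIENT").ids
            assert got == want


def test_patient_level_per_conjunct_witnesses(spec_set):
    # CT in one study, ECG in another: the patient still satisfies CT AND ECG
    parents = [
        SeriesRecord("P1", "ST1", "S1", "CT", "", dt.date(2020, 1, 1)),
        SeriesRecord("P1", "ST2", "S2", "ECG", "", dt.date(2020, 2, 1)),
        SeriesRecord("P2", "ST3", "S3", "CT", "", dt.date(2020, 1, 1)),
    ]
    idx = build_index(parents, [], spec_set)
    q = AND(Predicate(Scope.SERIES, PredKind.HAS_MODALITY, value="CT"),
            Predicate(Scope.SERIES, PredKind.HAS_MODALITY, value="ECG"))
    assert evaluate_patient(idx, q).ids == {"P1"}
    # NOT complements within indexed patients
    assert evaluate_patient(idx, NOT(q)).ids == {"P2"}


def test_validate_rejects_unknown_field(lvrv_index):
    q = Predicate(Scope.SERIES, PredKind.TERM, field="nope", value="x")
    with pytest.raises(QueryValidationError):
        validate_query(q, lvrv_index)


def test_validate_rejects_series_pred_inside_nested(lvrv_index):
    q = NESTED(Predicate(Scope.SERIES, PredKind.HAS_MODALITY, value="CT"))
    with pytest.raises(QueryValidationError):
        validate_query(q, lvrv_index)


def test_validate_rejects_patient_scope_at_series_level(lvrv_index):
    q = Predicate(Scope.PATIENT, PredKind.HAS_MODALITY, value="CT")
    with pytest.raises(QueryValidationError):
        evaluate(lvrv_index, q)


def test_validate_rejects_empty_range(lvrv_index):
    q = Predicate(Scope.SERIES, PredKind.RANGE, field="study_date")
    with pytest.raises(QueryValidationError):
        validate_query(q, lvrv_index)


# --- JSON exchange dialect ---------------------------------------------------

def test_exchange_round_trip_random(rng):
    for i in range(50):
        index = random_index(np.random.default_rng(3000 + i))
        q = random_query(np.random.default_rng(7000 + i), index)
        back = parse_query(render_query(q))
        for mode in (Mode.NESTED, Mode.FLATTENED):
            assert evaluate(index, back, mode).ids == evaluate(index, q, mode).ids


def test_exchange_text_is_deterministic(lvrv_index):
    assert render_query(LVRV) == render_query(LVRV)


def test_parse_rejects_bad_json():
    with pytest.raises(QueryParseError, match="offset"):
        parse_query("{not json")


def test_parse_rejects_wrong_version():
    with pytest.raises(QueryParseError, match="version"):
        parse_query('{"v": 99, "query": {"op": "AND", "children": []}}')


def test_parse_rejects_unknown_op():
    with pytest.raises(QueryParseError, match="query"):
        parse_query('{"v": 1, "query": {"op": "XOR", "children": []}}')


def test_parse_reports_nested_path():
    bad = ('{"v": 1, "query": {"op": "AND", "children": '
           '[{"neither": 1}]}}')
    with pytest.raises(QueryParseError, match=r"query\.children\[0\]"):
        parse_query(bad)


# --- SQL subset --------------------------------------------------------------

def _sql_ids(index, sql):
    conn = sqlite3.connect(":memory:")
    try:
        load_sql(index, conn)
        return {row[0] for row in conn.execute(sql)}
    finally:
        conn.close()


def test_sql_lvrv_nested_join(lvrv_index):
    sql = render_sql(LVRV)
    assert _sql_ids(lvrv_index, sql) == {"S-BOTH"}


def test_sql_matches_oracle_random(rng):
    mismatches = 0
    for i in range(80):
        index = random_index(np.random.default_rng(4000 + i))
        level = "series" if i % 2 == 0 else "patient"
        q = random_sql_query(np.random.default_rng(8000 + i), index, level)
        sql = render_sql(q, level)
        got = _sql_ids(index, sql)
        want = oracle_evaluate(index, q, Mode.NESTED, level=level.upper()).ids
        if got != want:
            mismatches += 1
    assert mismatches == 0


def test_sql_rejects_three_way_nested_join(lvrv_index):
    q = NESTED(
        Predicate(Scope.ANNOTATION, PredKind.HAS_SEGMENT_LABEL,
                  value=C.LEFT_VENTRICLE.meaning),
        Predicate(Scope.ANNOTATION, PredKind.HAS_SEGMENT_LABEL,
                  value=C.RIGHT_VENTRICLE.meaning),
        Predicate(Scope.ANNOTATION, PredKind.HAS_SEGMENT_LABEL,
                  value=C.CALCIFICATION.meaning),
    )
    with pytest.raises(SQLCapabilityError, match="join"):
        render_sql(q)


def test_sql_rejects_two_nested_groups():
    q = AND(NESTED(Predicate(Scope.ANNOTATION, PredKind.EXISTS, field="SR")),
            NESTED(Predicate(Scope.ANNOTATION, PredKind.EXISTS, field="SEG")))
    with pytest.raises(SQLCapabilityError, match="join"):
        render_sql(q)


def test_sql_rejects_three_patient_conjuncts():
    p = Predicate(Scope.SERIES, PredKind.HAS_MODALITY, value="CT")
    with pytest.raises(SQLCapabilityError, match="join"):
        render_sql(AND(p, p, p), level="patient")


def test_sql_rejects_negation_inside_nested():
    q = NESTED(NOT(Predicate(Scope.ANNOTATION, PredKind.EXISTS, field="SR")))
    with pytest.raises(SQLCapabilityError):
        render_sql(q)


def test_sql_like_escapes_wildcards(spec_set):
    parents = [SeriesRecord("P1", "ST1", "S1", "CT", "100% literal",
                            dt.date(2020, 1, 1)),
               SeriesRecord("P1", "ST1b", "S2", "CT", "100x literal",
                            dt.date(2020, 1, 1))]
    idx = build_index(parents, [], spec_set)
    q = Predicate(Scope.SERIES, PredKind.SUBSTRING, field="series_description",
                  value="100%")
    assert _sql_ids(idx, render_sql(q)) == {"S1"}
    assert evaluate(idx, q).ids == {"S1"}


# --- temporal selection ------------------------------------------------------

def test_pre_procedure_ecg_latest_and_tie_break(spec_set):
    parents = [
        SeriesRecord("P1", "ST1", "E-B", "ECG", "", dt.date(2020, 3, 1)),
        SeriesRecord("P1", "ST2", "E-A", "ECG", "", dt.date(2020, 3, 1)),
        SeriesRecord("P1", "ST3", "E-OLD", "ECG", "", dt.date(2019, 1, 1)),
        SeriesRecord("P1", "ST4", "E-POST", "ECG", "", dt.date(2020, 6, 1)),
        SeriesRecord("P1", "ST5", "CT-1", "CT", "", dt.date(2020, 2, 1)),
    ]
    idx = build_index(parents, [], spec_set)
    # ties on the date break to the lexicographically smaller series UID
    assert select_pre_procedure_ecg(idx, "P1", dt.date(2020, 4, 1)) == "E-A"
    # the procedure day itself is included
    assert select_pre_procedure_ecg(idx, "P1", dt.date(2020, 3, 1)) == "E-A"
    assert select_pre_procedure_ecg(idx, "P1", dt.date(2019, 6, 1)) == "E-OLD"
    assert select_pre_procedure_ecg(idx, "P1", dt.date(2018, 1, 1)) is None
    assert select_pre_procedure_ecg(idx, "P-UNKNOWN", dt.date(2020, 1, 1)) is None


def test_pre_procedure_ecg_matches_brute_force(rng):
    for i in range(30):
        index = random_index(np.random.default_rng(9000 + i))
        for pid in index.patients():
            for d in (dt.date(2017, 6, 1), dt.date(2019, 6, 1),
                      dt.date(2022, 6, 1)):
                got = select_pre_procedure_ecg(index, pid, d)
                cands = [x for x in index.documents
                         if x.patient_id == pid and x.modality == "ECG"
                         and x.study_date and x.study_date <= d]
                if not cands:
                    assert got is None
                else:
                    best_date = max(x.study_date for x in cands)
                    want = min(x.series_uid for x in cands
                               if x.study_date == best_date)
                    assert got == want
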