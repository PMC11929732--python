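"""Random generators for property-based testing of the whole pipeline.

Everything here is driven by a caller-supplied :class:`numpy.random.Generator`
so the properties are reproducible. The generators produce *valid* artefacts
by construction (template-conforming documents, consistent indices); the
mutation helpers then derive minimally-broken variants with the path of the
defect, so validation sensitivity can be asserted precisely.
"""

from __future__ import annotations

import copy
import datetime as _dt
from typing import List, Optional, Tuple

import numpy as np

from . import concepts as C
from .clinical import (ECGMeasurementSet, OutcomeSource, PatientHistoryRecord,
                       ProcedureOutcomeRecord, TobaccoStatus, ecg_report,
                       measurement_report, patient_history, procedure_outcome)
from .coding import CodedConcept, code
from .content import ContentItem, ValueKind
from .document import EvidenceRef, SRDocument
from .ecg import TWELVE_LEAD_ECG_SOP_CLASS, ECGRecord
from .indexing import Index, SeriesRecord, build_index, default_spec_set
from .query import (AND, NESTED, NOT, OR, PredKind, Predicate, Query, Scope)
from .seg import SegAlgorithmType, Segment, SegmentationObject
from .synthetic import PROSTHESIS_MODELS
from .uids import UIDGenerator, new_uid

Rng = np.random.Generator

_RHYTHMS = (C.SINUS_RHYTHM, C.ATRIAL_FIBRILLATION, C.LEFT_BUNDLE_BRANCH_BLOCK)
_SEG_LABELS = (C.LEFT_VENTRICLE, C.RIGHT_VENTRICLE, C.CALCIFICATION,
               C.AORTIC_ROOT)
_CUSPS = (C.RIGHT_CORONARY_CUSP, C.LEFT_CORONARY_CUSP, C.NON_CORONARY_CUSP)
_NOTES = ("follow-up advised", "no complications", "reviewed by board",
          "incidental finding", "")


def _pick(rng: Rng, seq):
    return seq[int(rng.integers(0, len(seq)))]


def _date(rng: Rng, start=_dt.date(2016, 1, 1), span_days=1800) -> _dt.date:
    return start + _dt.timedelta(days=int(rng.integers(0, span_days)))


# ---------------------------------------------------------------------------
# random template-conforming documents
# ---------------------------------------------------------------------------

def random_history_doc(rng: Rng, gen: UIDGenerator,
                       patient_id: Optional[str] = None) -> SRDocument:
    rec = PatientHistoryRecord(
        patient_id or f"P{int(rng.integers(0, 10_000)):05d}",
        prior_cardiac_surgery=_pick(rng, (None, True, False)),
        diabetes_mellitus=_pick(rng, (None, True, False)),
        tobacco_smoker=_pick(rng, (None,) + tuple(TobaccoStatus)),
        medical_device_use=(
            ((C.CARDIAC_PACEMAKER, _date(rng)),) if rng.random() < 0.3 else ()),
        free_text_notes=_pick(rng, _NOTES) or None,
        acquisition_year=int(rng.integers(2004, 2021)) if rng.random() < 0.5
        else None)
    return patient_history(rec, uid_generator=gen)


def random_outcome_doc(rng: Rng, gen: UIDGenerator,
                       patient_id: Optional[str] = None) -> SRDocument:
    if rng.random() < 0.5:
        rec = ProcedureOutcomeRecord(
            patient_id or f"P{int(rng.integers(0, 10_000)):05d}", _date(rng),
            OutcomeSource.BILLING, pacemaker_implanted=bool(rng.random() < 0.3))
    else:
        rec = ProcedureOutcomeRecord(
            patient_id or f"P{int(rng.integers(0, 10_000)):05d}", _date(rng),
            OutcomeSource.QUALITY_ASSURANCE,
            prosthesis_info=(_pick(rng, PROSTHESIS_MODELS),
                             _pick(rng, (23.0, 26.0, 29.0))))
    return procedure_outcome(rec, uid_generator=gen)


def random_ecg_doc(rng: Rng, gen: UIDGenerator,
                   patient_id: Optional[str] = None) -> SRDocument:
    pid = patient_id or f"P{int(rng.integers(0, 10_000)):05d}"
    d = _date(rng)
    fs = _pick(rng, (250.0, 500.0, 1000.0))
    n = 40
    leads = [(name, np.round(rng.uniform(-3000, 3000, n) / 10) * 10)
             for name in C.STANDARD_LEADS]
    rec = ECGRecord(pid, _dt.datetime.combine(d, _dt.time(9, 30)), fs, leads, d,
                    waveform_ref=EvidenceRef(gen(), gen(),
                                             TWELVE_LEAD_ECG_SOP_CLASS, gen()))
    meas = ECGMeasurementSet(
        ventricular_rate=(float(rng.integers(40, 120))
                          if rng.random() < 0.8 else None),
        qt_interval=(float(rng.integers(330, 490))
                     if rng.random() < 0.6 else None),
        pr_interval=(float(rng.integers(110, 210))
                     if rng.random() < 0.4 else None),
        qrs_duration=(float(rng.integers(70, 140))
                      if rng.random() < 0.4 else None),
        rhythm_codes=tuple(r for r in _RHYTHMS if rng.random() < 0.3))
    return ecg_report(rec, meas, uid_generator=gen)


def random_measurement_doc(rng: Rng, gen: UIDGenerator,
                           patient_id: Optional[str] = None,
                           evidence: Tuple[EvidenceRef, ...] = (),
                           study_uid: Optional[str] = None) -> SRDocument:
    pts = tuple((c, tuple(float(x) for x in rng.uniform(-80, 80, 3)))
                for c in _CUSPS if rng.random() < 0.6)
    septum = (round(float(rng.uniform(1.5, 13.0)), 1)
              if rng.random() < 0.5 else None)
    notes = _pick(rng, _NOTES) or None
    return measurement_report(
        patient_id or f"P{int(rng.integers(0, 10_000)):05d}", _date(rng),
        frame_of_reference_uid=gen(), hinge_points=pts,
        membranous_septum_mm=septum, notes=notes, evidence=evidence,
        study_uid=study_uid, uid_generator=gen)


DOC_FAMILIES = ("3700", "3802", "outcome", "1500")


def random_document(rng: Rng, gen: UIDGenerator,
                    family: Optional[str] = None) -> SRDocument:
    """One random template-conforming document from a random family."""
    family = family or _pick(rng, DOC_FAMILIES)
    if family == "3700":
        return random_ecg_doc(rng, gen)
    if family == "3802":
        return random_history_doc(rng, gen)
    if family == "outcome":
        return random_outcome_doc(rng, gen)
    return random_measurement_doc(rng, gen)


# ---------------------------------------------------------------------------
# document mutations (for validation-sensitivity properties)
# ---------------------------------------------------------------------------

def _walk(item: ContentItem, path):
    yield path + (item.name.meaning,), item
    for c in item.children:
        yield from _walk(c, path + (item.name.meaning,))


def mutate_document(rng: Rng, doc: SRDocument):
    """Return (mutated copy, defect path, mutation kind) or None.

    The defect path is the meaning path of the mutated/removed node; a
    validator is *sensitive* if it reports at least one issue whose path ends
    at (or contains) that node. ``None`` means no mutation of the drawn kind
    applies to this document; the caller should redraw.
    """
    doc = copy.deepcopy(doc)
    kind = _pick(rng, ("drop-mandatory", "wrong-kind", "break-root",
                       "unknown-concept"))

    if kind == "break-root":
        doc.root.name = code("XXX-BROKEN", "99SRC", "Broken Title")
        return doc, (doc.root.name.meaning,), kind

    if kind == "unknown-concept":
        doc.root.children.append(ContentItem.code(
            code("XXX-UNDECLARED", "99SRC", "Undeclared Concept"), C.YES))
        return doc, (doc.root.name.meaning, "Undeclared Concept"), kind

    if kind == "drop-mandatory":
        # mandatory rows in the shipped templates: the waveform-information
        # container of TID 3700 and the device item of a device-use block
        if doc.tid == "3700":
            doc.root.children = [c for c in doc.root.children
                                 if c.name != C.WAVEFORM_INFORMATION]
            return doc, (doc.root.name.meaning,
                         C.WAVEFORM_INFORMATION.meaning), kind
        for path, item in _walk(doc.root, ()):
            if item.name == C.MEDICAL_DEVICE_USE:
                item.children = [c for c in item.children
                                 if c.name != C.DEVICE_ITEM]
                return doc, path + (C.DEVICE_ITEM.meaning,), kind
        return None

    # wrong-kind: swap a concept-matched non-container leaf to TEXT
    candidates = []
    for path, item in _walk(doc.root, ()):
        if item.value_kind in (ValueKind.CODE, ValueKind.NUM, ValueKind.DATE) \
                and doc.tid != "1500":
            candidates.append((path, item))
    if not candidates:
        return None
    path, item = candidates[int(rng.integers(0, len(candidates)))]
    item.value_kind = ValueKind.TEXT
    item.value = "mutant"
    return doc, path, kind


def issue_addresses(issue_path: Tuple[str, ...],
                    defect_path: Tuple[str, ...]) -> bool:
    """An issue addresses a defect when either path prefixes the other."""
    n = min(len(issue_path), len(defect_path))
    return tuple(issue_path[:n]) == tuple(defect_path[:n])


# ---------------------------------------------------------------------------
# random indices
# ---------------------------------------------------------------------------

_MODALITIES = ("CT", "ECG", "MR", "SR")
_DESCRIPTIONS = ("CorCTA 40% cardiac phase", "CorCTA 70% cardiac phase",
                 "native thorax", "12-lead resting ECG", "report",
                 "CorCTA 0% cardiac phase")
_MANUFACTURERS = ("ACME CT", "MedScan", "")


def random_index(rng: Rng, seed_hint: Optional[int] = None) -> Index:
    """A small consistent index: random parents with random SR/SEG children."""
    gen = UIDGenerator(int(rng.integers(0, 2**63 - 1))
                       if seed_hint is None else seed_hint)
    spec_set = default_spec_set()
    parents: List[SeriesRecord] = []
    annotations: List = []
    n_patients = int(rng.integers(2, 5))
    for p in range(n_patients):
        pid = f"R{p:03d}"
        for _ in range(int(rng.integers(1, 4))):
            series_uid = gen()
            rec = SeriesRecord(pid, gen(), series_uid, _pick(rng, _MODALITIES),
                               _pick(rng, _DESCRIPTIONS), _date(rng),
                               _pick(rng, _MANUFACTURERS))
            parents.append(rec)
            for _ in range(int(rng.integers(0, 3))):
                roll = rng.random()
                if roll < 0.25:
                    ann = random_history_doc(rng, gen, pid)
                elif roll < 0.45:
                    ann = random_outcome_doc(rng, gen, pid)
                elif roll < 0.65:
                    ann = random_measurement_doc(rng, gen, pid)
                else:
                    labels = [lab for lab in _SEG_LABELS if rng.random() < 0.5]
                    if not labels:
                        labels = [_pick(rng, _SEG_LABELS)]
                    mask = np.zeros((1, 2, 2), bool)
                    mask[0, 0, 0] = True
                    ann = SegmentationObject(
                        series_uid,
                        [Segment(i + 1, lab,
                                 _pick(rng, tuple(SegAlgorithmType)))
                         for i, lab in enumerate(labels)],
                        [mask] * len(labels))
                    ann.sop_uid = gen()
                annotations.append((ann, series_uid))
    return build_index(parents, annotations, spec_set)


# ---------------------------------------------------------------------------
# random queries
# ---------------------------------------------------------------------------

def _series_values(index: Index, field: str) -> List[str]:
    vals = sorted({str(getattr(d, field)) for d in index.documents
                   if getattr(d, field)})
    return vals or ["nothing"]


def _field_values(index: Index, field: str) -> List:
    out = []
    for d in index.documents:
        for ch in d.annotations:
            out.extend(ch.fields.get(field, []))
    return sorted(set(map(str, out))) or ["nothing"]


def _random_series_pred(rng: Rng, index: Index) -> Predicate:
    roll = rng.random()
    if roll < 0.3:
        return Predicate(Scope.SERIES, PredKind.HAS_MODALITY,
                         value=_pick(rng, _MODALITIES))
    if roll < 0.55:
        desc = _pick(rng, _series_values(index, "series_description")
                     + ["40%", "70%", "ECG", "zzz"])
        if len(desc) > 4 and rng.random() < 0.5:
            lo = int(rng.integers(0, len(desc) - 3))
            desc = desc[lo:lo + int(rng.integers(2, 6))]
        return Predicate(Scope.SERIES, PredKind.SUBSTRING,
                         field="series_description", value=desc)
    if roll < 0.75:
        d1, d2 = sorted((_date(rng).isoformat(), _date(rng).isoformat()))
        return Predicate(Scope.SERIES, PredKind.RANGE, field="study_date",
                         low=d1, high=d2)
    if roll < 0.9:
        return Predicate(Scope.SERIES, PredKind.TERM, field="manufacturer",
                         value=_pick(rng, _MANUFACTURERS + ("ghost",)))
    return Predicate(Scope.SERIES, PredKind.EXISTS, field="manufacturer")


_NUM_FIELDS = ("ventricular_rate", "qt_interval_ms", "membranous_septum_mm",
               "prosthesis_size_mm")
_QUAL_FIELDS = ("tobacco_smoker", "diabetes_mellitus", "pacemaker_implanted",
                "prosthesis_model", "rhythm")
_TEXT_FIELDS = ("history_notes", "annotation_notes")


def _random_annotation_pred(rng: Rng, index: Index) -> Predicate:
    roll = rng.random()
    if roll < 0.25:
        return Predicate(Scope.ANNOTATION, PredKind.HAS_SEGMENT_LABEL,
                         value=_pick(rng, tuple(c.meaning for c in _SEG_LABELS)
                                     + ("no such label",)))
    if roll < 0.4:
        f = _pick(rng, _QUAL_FIELDS)
        return Predicate(Scope.ANNOTATION, PredKind.TERM, field=f,
                         value=_pick(rng, _field_values(index, f) + ["ghost"]))
    if roll < 0.55:
        f = _pick(rng, _NUM_FIELDS)
        lo = float(rng.integers(0, 200))
        return Predicate(Scope.ANNOTATION, PredKind.RANGE, field=f,
                         low=lo, high=lo + float(rng.integers(1, 300)))
    if roll < 0.7:
        return Predicate(
            Scope.ANNOTATION, PredKind.EXISTS,
            field=_pick(rng, _NUM_FIELDS + _QUAL_FIELDS + ("SR", "SEG")))
    if roll < 0.8:
        f = _pick(rng, _TEXT_FIELDS)
        return Predicate(Scope.ANNOTATION, PredKind.SUBSTRING, field=f,
                         value=_pick(rng, ("advised", "complica", "zzz")))
    if roll < 0.9:
        names = (C.TOBACCO_SMOKER.meaning, C.VENTRICULAR_RATE.meaning,
                 C.MEMBRANOUS_SEPTUM.meaning, C.LEFT_VENTRICLE.meaning,
                 "no such name")
        return Predicate(Scope.ANNOTATION, PredKind.HAS_ANNOTATION_NAME,
                         value=_pick(rng, names))
    titles = (C.ECG_REPORT.meaning, C.CARDIOVASCULAR_PATIENT_HISTORY.meaning,
              C.TITLE_QA_INFORMATION.meaning,
              C.IMAGING_MEASUREMENT_REPORT.meaning)
    return Predicate(Scope.ANNOTATION, PredKind.HAS_DOCUMENT_TITLE,
                     value=_pick(rng, titles))


def _random_annotation_tree(rng: Rng, index: Index, depth: int):
    if depth <= 0 or rng.random() < 0.6:
        return _random_annotation_pred(rng, index)
    op = rng.random()
    kids = [_random_annotation_tree(rng, index, depth - 1)
            for _ in range(int(rng.integers(1, 4)))]
    if op < 0.45:
        return AND(*kids)
    if op < 0.85:
        return OR(*kids)
    return NOT(kids[0])


def random_query(rng: Rng, index: Index, depth: int = 2) -> Query:
    """A random valid series-level query mixing scopes and boolean structure."""
    if depth <= 0 or rng.random() < 0.4:
        if rng.random() < 0.5:
            return _random_series_pred(rng, index)
        return NESTED(_random_annotation_tree(rng, index,
                                              int(rng.integers(1, 3))))
    op = rng.random()
    kids = [random_query(rng, index, depth - 1)
            for _ in range(int(rng.integers(1, 4)))]
    if op < 0.4:
        return AND(*kids)
    if op < 0.8:
        return OR(*kids)
    return NOT(kids[0])


def random_sql_query(rng: Rng, index: Index, level: str = "series") -> Query:
    """A random query inside the documented SQL subset."""
    if level == "patient":
        kids = [_random_series_pred(rng, index)
                for _ in range(int(rng.integers(1, 3)))]
        return kids[0] if len(kids) == 1 else AND(*kids)
    series = [_random_series_pred(rng, index)
              for _ in range(int(rng.integers(0, 3)))]
    parts: List = list(series)
    if rng.random() < 0.75:
        preds = [_random_annotation_pred(rng, index)
                 for _ in range(int(rng.integers(1, 3)))]
        # restrict to positive conjunctions (substring strict-tuple forms are
        # already positive); HAS_SEGMENT_LABEL tuple matching is out of subset
        preds = [p if not isinstance(p.value, tuple) else
                 Predicate(p.scope, p.kind, p.field, p.value[0], p.low, p.high)
                 for p in preds]
        parts.append(NESTED(*preds))
    if not parts:
        parts = [_random_series_pred(rng, index)]
    return parts[0] if len(parts) == 1 else AND(*parts)
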