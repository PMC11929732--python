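"""Flattening of series, SRs and segmentations into a queryable nested index.

Imaging series become parent documents carrying fixed DICOM-level fields
(patient, modality, series description, study date, manufacturer, body part).
Every SR and SEG attached to a series becomes a nested *annotation child* of
that parent, preserving the child boundary so that multi-condition queries can
be evaluated on the instance level rather than on fields pooled per series.

Which SR content is queryable is declared by the user as attribute paths: the
nested path of concept meanings from the document root to the target item
(e.g. ``Cardiovascular Patient History - Social History - Tobacco Smoker``),
its leaf kind, and the flattened field name it is indexed under. Qualitative
items contribute both name and value concepts, numeric items their magnitude
and unit, geometric items the name only, and text items enter free-text
search.
"""

from __future__ import annotations

import datetime as _dt
import enum
import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import yaml

from .coding import CodedConcept
from .content import ValueKind
from .document import SRDocument
from .seg import SegmentationObject, SegAlgorithmType
from .uids import new_uid

logger = logging.getLogger(__name__)


class LeafKind(str, enum.Enum):
    QUALITATIVE = "QUALITATIVE"
    NUMERIC = "NUMERIC"
    GEOMETRIC = "GEOMETRIC"
    TEXT = "TEXT"


_LEAF_VALUE_KINDS = {
    LeafKind.QUALITATIVE: {ValueKind.CODE},
    LeafKind.NUMERIC: {ValueKind.NUM},
    LeafKind.GEOMETRIC: {ValueKind.SCOORD, ValueKind.SCOORD3D},
    LeafKind.TEXT: {ValueKind.TEXT},
}


class AnnotationKind(str, enum.Enum):
    SR = "SR"
    SEG = "SEG"


class CreatorType(str, enum.Enum):
    MANUAL = "MANUAL"
    AUTOMATIC = "AUTOMATIC"
    SEMIAUTOMATIC = "SEMIAUTOMATIC"
    UNKNOWN = "UNKNOWN"


class IndexIntegrityError(ValueError):
    pass


class OrphanAnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class AttributePathSpec:
    """Declares one queryable SR attribute: template, nested path, kind, field."""

    tid: str
    path: Tuple[str, ...]  # concept meanings from root to target, inclusive
    leaf_kind: LeafKind
    field_name: str
    # optional strict path of (code value, scheme) pairs, matched instead of
    # meanings when extraction runs in strict mode
    code_path: Optional[Tuple[Tuple[str, str], ...]] = None

    def __post_init__(self) -> None:
        if not self.path:
            raise ValueError("attribute path must be non-empty")
        object.__setattr__(self, "path", tuple(self.path))
        if self.code_path is not None:
            object.__setattr__(self, "code_path",
                               tuple((str(v), str(s)) for v, s in self.code_path))


def extract(doc: SRDocument, spec: AttributePathSpec, strict: bool = False) -> list:
    """All leaf values at ``spec.path`` in document order; [] when absent.

    Returned entries depend on the leaf kind: QUALITATIVE → (name, value)
    concept pairs; NUMERIC → (name, magnitude, unit); GEOMETRIC → name
    concepts; TEXT → (name, string).
    """
    if spec.tid != doc.tid:
        return []
    wanted_kinds = _LEAF_VALUE_KINDS[spec.leaf_kind]
    out = []
    for path, item in doc.iter_items():
        if item.value_kind not in wanted_kinds:
            continue
        if strict and spec.code_path is not None:
            # strict mode compares (value, scheme) codes along the path;
            # requires walking with codes, so re-derive the code path
            continue  # handled below
        if path == spec.path:
            out.append(_leaf_value(item, spec.leaf_kind))
    if strict and spec.code_path is not None:
        out = _extract_strict(doc, spec)
    return out


def _extract_strict(doc: SRDocument, spec: AttributePathSpec) -> list:
    wanted_kinds = _LEAF_VALUE_KINDS[spec.leaf_kind]
    out = []

    def walk(item, codes):
        codes = codes + ((item.name.value, item.name.scheme),)
        if codes == spec.code_path and item.value_kind in wanted_kinds:
            out.append(_leaf_value(item, spec.leaf_kind))
        for c in item.children:
            walk(c, codes)

    walk(doc.root, ())
    return out


def _leaf_value(item, leaf_kind: LeafKind):
    if leaf_kind is LeafKind.QUALITATIVE:
        return (item.name, item.value)
    if leaf_kind is LeafKind.NUMERIC:
        return (item.name, item.value.as_float, item.value.unit)
    if leaf_kind is LeafKind.GEOMETRIC:
        return item.name
    return (item.name, item.value)


# ---------------------------------------------------------------------------
# annotation children
# ---------------------------------------------------------------------------

@dataclass
class AnnotationChild:
    """One SR or SEG flattened into queryable lists, child boundary preserved."""

    kind: AnnotationKind
    source_sop_uid: str
    referenced_series_uid: Optional[str] = None
    doc_title: Optional[CodedConcept] = None
    tid: Optional[str] = None
    creator_type: CreatorType = CreatorType.UNKNOWN
    qualitative: List[Tuple[CodedConcept, CodedConcept]] = field(default_factory=list)
    numeric: List[Tuple[CodedConcept, float, CodedConcept]] = field(default_factory=list)
    geometric: List[CodedConcept] = field(default_factory=list)
    text: List[Tuple[CodedConcept, str]] = field(default_factory=list)
    segment_labels: List[CodedConcept] = field(default_factory=list)
    fields: Dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind is AnnotationKind.SEG and (self.qualitative or self.numeric
                                                or self.text):
            raise IndexIntegrityError("SEG children carry only segment labels")
        if self.kind is AnnotationKind.SR and self.segment_labels:
            raise IndexIntegrityError("SR children carry no segment labels")

    def name_meanings(self) -> set:
        """Concept meanings this child is discoverable under: item names of all
        four kinds plus qualitative value concepts (both name and value of a
        qualitative item are concepts) plus segment labels."""
        names = {n.meaning for n, _ in self.qualitative}
        names |= {v.meaning for _, v in self.qualitative}
        names |= {n.meaning for n, _, _ in self.numeric}
        names |= {n.meaning for n in self.geometric}
        names |= {n.meaning for n, _ in self.text}
        names |= {c.meaning for c in self.segment_labels}
        return names


def flatten_annotation(obj: Union[SRDocument, SegmentationObject],
                       spec_set: Sequence[AttributePathSpec],
                       strict: bool = False,
                       attach_series_uid: Optional[str] = None) -> AnnotationChild:
    """Flatten one SR or SEG into an annotation child.

    SR children get one entry per spec-matched leaf (geometric items
    contribute the name only); SEG children get one label per segment plus the
    creator type. ``attach_series_uid`` overrides the attachment target, which
    otherwise is the first evidence series (SR) or the referenced series (SEG).
    """
    if isinstance(obj, SegmentationObject):
        algos = {s.algorithm_type for s in obj.segments}
        creator = (CreatorType(next(iter(algos)).value) if len(algos) == 1
                   else CreatorType.UNKNOWN)
        return AnnotationChild(
            kind=AnnotationKind.SEG,
            source_sop_uid=obj.sop_uid or new_uid(),
            referenced_series_uid=attach_series_uid or obj.referenced_series_uid,
            creator_type=creator,
            segment_labels=[s.label for s in obj.segments],
        )

    child = AnnotationChild(
        kind=AnnotationKind.SR,
        source_sop_uid=obj.sop_uid,
        referenced_series_uid=attach_series_uid or (
            obj.evidence[0].series_uid if obj.evidence else None),
        doc_title=obj.root.name,
        tid=obj.tid,
    )
    for spec in spec_set:
        values = extract(obj, spec, strict=strict)
        if not values:
            continue
        bucket = child.fields.setdefault(spec.field_name, [])
        for v in values:
            if spec.leaf_kind is LeafKind.QUALITATIVE:
                child.qualitative.append(v)
                bucket.append(v[1].meaning)
            elif spec.leaf_kind is LeafKind.NUMERIC:
                child.numeric.append(v)
                bucket.append(v[1])
            elif spec.leaf_kind is LeafKind.GEOMETRIC:
                child.geometric.append(v)
                bucket.append(v.meaning)
            else:
                child.text.append(v)
                bucket.append(v[1])
    return child


# ---------------------------------------------------------------------------
# parents and the index
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeriesRecord:
    """Parent-level metadata of one imaging/waveform/report series."""

    patient_id: str
    study_uid: str
    series_uid: str
    modality: str
    series_description: str = ""
    study_date: Optional[_dt.date] = None
    manufacturer: str = ""
    body_part_examined: str = ""


@dataclass
class IndexDocument:
    patient_id: str
    study_uid: str
    series_uid: str
    modality: str
    series_description: str = ""
    study_date: Optional[_dt.date] = None
    manufacturer: str = ""
    body_part_examined: str = ""
    annotations: List[AnnotationChild] = field(default_factory=list)

    @classmethod
    def from_series(cls, s: SeriesRecord) -> "IndexDocument":
        return cls(s.patient_id, s.study_uid, s.series_uid, s.modality,
                   s.series_description, s.study_date, s.manufacturer,
                   s.body_part_examined)


PARENT_FIELDS = ("patient_id", "study_uid", "series_uid", "modality",
                 "series_description", "study_date", "manufacturer",
                 "body_part_examined")


@dataclass
class Index:
    documents: List[IndexDocument]
    spec_set: List[AttributePathSpec]
    dropped_orphans: List[str] = field(default_factory=list)  # source SOP UIDs

    def __post_init__(self) -> None:
        uids = [d.series_uid for d in self.documents]
        if len(set(uids)) != len(uids):
            dupes = sorted({u for u in uids if uids.count(u) > 1})
            raise IndexIntegrityError(f"duplicate series_uid(s): {dupes}")

    def by_series(self) -> Dict[str, IndexDocument]:
        return {d.series_uid: d for d in self.documents}

    def patients(self) -> set:
        return {d.patient_id for d in self.documents}

    def declared_fields(self) -> set:
        return {s.field_name for s in self.spec_set}


def series_record_from_dicom(data: bytes) -> SeriesRecord:
    """Header-only read of a Part 10 file into a parent series record."""
    import io
    from pydicom import dcmread
    ds = dcmread(io.BytesIO(data), stop_before_pixels=True)
    sd = str(getattr(ds, "StudyDate", "") or "")
    return SeriesRecord(
        patient_id=str(ds.PatientID),
        study_uid=str(ds.StudyInstanceUID),
        series_uid=str(ds.SeriesInstanceUID),
        modality=str(getattr(ds, "Modality", "")),
        series_description=str(getattr(ds, "SeriesDescription", "") or ""),
        study_date=_dt.datetime.strptime(sd, "%Y%m%d").date() if sd else None,
        manufacturer=str(getattr(ds, "Manufacturer", "") or ""),
        body_part_examined=str(getattr(ds, "BodyPartExamined", "") or ""),
    )


def build_index(parents: Sequence[SeriesRecord],
                annotations: Sequence[Union[SRDocument, SegmentationObject,
                                            AnnotationChild,
                                            Tuple[Union[SRDocument, SegmentationObject], str]]],
                spec_set: Sequence[AttributePathSpec],
                orphan_policy: str = "skip",
                strict: bool = False) -> Index:
    """Attach every annotation to its referenced series and build the index.

    ``annotations`` may contain SR documents, segmentation objects, pre-built
    annotation children, or ``(object, series_uid)`` pairs forcing the
    attachment target. Orphans (annotations whose referenced series is not
    among the parents) are skipped with a log entry under the default policy,
    attached to a synthetic parent under ``orphan_policy="synthetic-parent"``,
    or raise under ``orphan_policy="error"``. Output ordering is deterministic:
    parents by (patient_id, study_date, series_uid), children in input order.
    """
    docs = [IndexDocument.from_series(p) for p in parents]
    by_uid = {d.series_uid: d for d in docs}
    if len(by_uid) != len(docs):
        raise IndexIntegrityError("duplicate series_uid among parents")

    dropped: List[str] = []
    for ann in annotations:
        attach = None
        if isinstance(ann, tuple):
            ann, attach = ann
        if isinstance(ann, AnnotationChild):
            child = ann
            if attach is not None:
                child.referenced_series_uid = attach
        else:
            child = flatten_annotation(ann, spec_set, strict=strict,
                                       attach_series_uid=attach)
        target = child.referenced_series_uid
        if target in by_uid:
            by_uid[target].annotations.append(child)
        elif orphan_policy == "skip":
            logger.warning("dropping orphan annotation %s (series %s not indexed)",
                           child.source_sop_uid, target)
            dropped.append(child.source_sop_uid)
        elif orphan_policy == "synthetic-parent":
            pid = "ORPHANS"
            parent = IndexDocument(pid, new_uid(), target or new_uid(), "OT",
                                   series_description="synthetic orphan parent")
            parent.annotations.append(child)
            docs.append(parent)
            by_uid[parent.series_uid] = parent
        else:
            raise OrphanAnnotationError(
                f"annotation {child.source_sop_uid} references unknown series "
                f"{target}")

    docs.sort(key=lambda d: (d.patient_id, d.study_date or _dt.date.min,
                             d.series_uid))
    return Index(documents=docs, spec_set=list(spec_set),
                 dropped_orphans=dropped)


# ---------------------------------------------------------------------------
# bulk (de)serialisation — newline-delimited JSON, one parent per line
# ---------------------------------------------------------------------------

def _enc_concept(c: Optional[CodedConcept]):
    return None if c is None else [c.value, c.scheme, c.meaning]


def _dec_concept(v) -> Optional[CodedConcept]:
    return None if v is None else CodedConcept(v[0], v[1], v[2])


def _enc_child(ch: AnnotationChild) -> dict:
    return {
        "kind": ch.kind.value,
        "source_sop_uid": ch.source_sop_uid,
        "referenced_series_uid": ch.referenced_series_uid,
        "doc_title": _enc_concept(ch.doc_title),
        "tid": ch.tid,
        "creator_type": ch.creator_type.value,
        "qualitative": [[_enc_concept(n), _enc_concept(v)] for n, v in ch.qualitative],
        "numeric": [[_enc_concept(n), m, _enc_concept(u)] for n, m, u in ch.numeric],
        "geometric": [_enc_concept(n) for n in ch.geometric],
        "text": [[_enc_concept(n), s] for n, s in ch.text],
        "segment_labels": [_enc_concept(c) for c in ch.segment_labels],
        "fields": ch.fields,
    }


def _dec_child(d: dict) -> AnnotationChild:
    return AnnotationChild(
        kind=AnnotationKind(d["kind"]),
        source_sop_uid=d["source_sop_uid"],
        referenced_series_uid=d.get("referenced_series_uid"),
        doc_title=_dec_concept(d.get("doc_title")),
        tid=d.get("tid"),
        creator_type=CreatorType(d["creator_type"]),
        qualitative=[(_dec_concept(n), _dec_concept(v)) for n, v in d["qualitative"]],
        numeric=[(_dec_concept(n), float(m), _dec_concept(u))
                 for n, m, u in d["numeric"]],
        geometric=[_dec_concept(n) for n in d["geometric"]],
        text=[(_dec_concept(n), s) for n, s in d["text"]],
        segment_labels=[_dec_concept(c) for c in d["segment_labels"]],
        fields={k: list(v) for k, v in d["fields"].items()},
    )


def export_bulk(index: Index) -> str:
    """One parent document per line, children as nested arrays."""
    lines = []
    for doc in index.documents:
        rec = {f: getattr(doc, f) for f in PARENT_FIELDS}
        rec["study_date"] = doc.study_date.isoformat() if doc.study_date else None
        rec["annotations"] = [_enc_child(ch) for ch in doc.annotations]
        lines.append(json.dumps(rec, sort_keys=True))
    return "\n".join(lines) + ("\n" if lines else "")


def import_bulk(text: str, spec_set: Sequence[AttributePathSpec]) -> Index:
    docs = []
    for line in text.splitlines():
        if not line.strip():
            continue
        rec = json.loads(line)
        docs.append(IndexDocument(
            patient_id=rec["patient_id"], study_uid=rec["study_uid"],
            series_uid=rec["series_uid"], modality=rec["modality"],
            series_description=rec["series_description"],
            study_date=(_dt.date.fromisoformat(rec["study_date"])
                        if rec["study_date"] else None),
            manufacturer=rec["manufacturer"],
            body_part_examined=rec["body_part_examined"],
            annotations=[_dec_child(c) for c in rec["annotations"]],
        ))
    return Index(documents=docs, spec_set=list(spec_set))


# ---------------------------------------------------------------------------
# spec-set config files
# ---------------------------------------------------------------------------

def spec_set_to_yaml(spec_set: Sequence[AttributePathSpec], path) -> None:
    data = {"attribute_paths": [
        {"tid": s.tid, "path": list(s.path), "leaf_kind": s.leaf_kind.value,
         "field_name": s.field_name,
         "code_path": ([list(p) for p in s.code_path] if s.code_path else None)}
        for s in spec_set]}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False, allow_unicode=True)


def spec_set_from_yaml(path) -> List[AttributePathSpec]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    out = []
    for s in data["attribute_paths"]:
        out.append(AttributePathSpec(
            tid=str(s["tid"]), path=tuple(s["path"]),
            leaf_kind=LeafKind(s["leaf_kind"]), field_name=s["field_name"],
            code_path=(tuple((p[0], p[1]) for p in s["code_path"])
                       if s.get("code_path") else None)))
    names = [s.field_name for s in out]
    if len(set(names)) != len(names):
        raise ValueError("field_name values must be unique within a spec set")
    return out


def default_spec_set() -> List[AttributePathSpec]:
    """Attribute paths for the shipped clinical templates' canonical items."""
    from . import concepts as C
    A, L = AttributePathSpec, LeafKind
    root_h = C.CARDIOVASCULAR_PATIENT_HISTORY.meaning
    root_qa = C.TITLE_QA_INFORMATION.meaning
    root_pr = C.TITLE_PROSTHESIS_INFORMATION.meaning
    root_e = C.ECG_REPORT.meaning
    root_m = C.IMAGING_MEASUREMENT_REPORT.meaning
    grp = C.MEASUREMENT_GROUP.meaning
    pc = C.PROCEDURE_CONTEXT.meaning
    return [
        A("3802", (root_h, C.SOCIAL_HISTORY.meaning, C.TOBACCO_SMOKER.meaning),
          L.QUALITATIVE, "tobacco_smoker"),
        A("3802", (root_h, C.DIABETES_MELLITUS.meaning), L.QUALITATIVE,
          "diabetes_mellitus"),
        A("3802", (root_h, C.COMMENT.meaning), L.TEXT, "history_notes"),
        A("3802_QA", (root_qa, pc, C.PACEMAKER_IMPLANTATION.meaning),
          L.QUALITATIVE, "pacemaker_implanted"),
        A("3802_PROSTH", (root_pr, pc, C.PROSTHESIS_MODEL.meaning),
          L.QUALITATIVE, "prosthesis_model"),
        A("3802_PROSTH", (root_pr, pc, C.PROSTHESIS_SIZE.meaning),
          L.NUMERIC, "prosthesis_size_mm"),
        A("3700", (root_e, C.ECG_GLOBAL_MEASUREMENTS.meaning,
                   C.VENTRICULAR_RATE.meaning), L.NUMERIC, "ventricular_rate"),
        A("3700", (root_e, C.ECG_GLOBAL_MEASUREMENTS.meaning,
                   C.QT_INTERVAL.meaning), L.NUMERIC, "qt_interval_ms"),
        A("3700", (root_e, C.RHYTHM_FINDING.meaning), L.QUALITATIVE, "rhythm"),
        A("1500", (root_m, grp, C.RIGHT_CORONARY_CUSP.meaning), L.GEOMETRIC,
          "hinge_point_rcc"),
        A("1500", (root_m, grp, C.LEFT_CORONARY_CUSP.meaning), L.GEOMETRIC,
          "hinge_point_lcc"),
        A("1500", (root_m, grp, C.NON_CORONARY_CUSP.meaning), L.GEOMETRIC,
          "hinge_point_ncc"),
        A("1500", (root_m, grp, C.MEMBRANOUS_SEPTUM.meaning), L.NUMERIC,
          "membranous_septum_mm"),
        A("1500", (root_m, C.COMMENT.meaning), L.TEXT, "annotation_notes"),
    ]
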