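"""Serialisation of SR documents to/from DICOM Part 10 (Comprehensive 3D SR).

Writes Explicit VR Little Endian; reading accepts implicit VR as well (pydicom
handles both). The round trip is an identity on the document model: tree
structure, codes, decimal strings of NUM values, coordinates, references and
evidence all survive unchanged.
"""

from __future__ import annotations

import datetime as _dt
import io
from typing import List, Optional

from pydicom import dcmread, dcmwrite
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .coding import CodedConcept
from .content import (ContentItem, GraphicType, NumValue, Relationship, ScoordValue,
                      SopReference, ValueKind)
from .document import EvidenceRef, PatientContext, SRDocument

COMPREHENSIVE_3D_SR = "1.2.840.10008.5.1.4.1.1.88.34"


class SRParseError(ValueError):
    """Raised when a byte stream cannot be decoded as a Comprehensive 3D SR."""


# ---------------------------------------------------------------------------
# encoding helpers
# ---------------------------------------------------------------------------

def _code_ds(c: CodedConcept) -> Dataset:
    ds = Dataset()
    ds.CodeValue = c.value
    ds.CodingSchemeDesignator = c.scheme
    ds.CodeMeaning = c.meaning
    return ds


def _da(d: _dt.date) -> str:
    return d.strftime("%Y%m%d")


def _encode_item(item: ContentItem, is_root: bool = False) -> Dataset:
    ds = Dataset()
    if not is_root:
        ds.RelationshipType = item.relationship.value
    ds.ValueType = item.value_kind.value
    ds.ConceptNameCodeSequence = [_code_ds(item.name)]
    k, v = item.value_kind, item.value
    if k is ValueKind.CONTAINER:
        ds.ContinuityOfContent = "SEPARATE"
        if item.children:
            ds.ContentSequence = [_encode_item(c) for c in item.children]
    elif k is ValueKind.CODE:
        ds.ConceptCodeSequence = [_code_ds(v)]
    elif k is ValueKind.NUM:
        mv = Dataset()
        mv.NumericValue = v.magnitude  # DS keeps the decimal string verbatim
        mv.MeasurementUnitsCodeSequence = [_code_ds(v.unit)]
        ds.MeasuredValueSequence = [mv]
    elif k is ValueKind.TEXT:
        ds.TextValue = v
    elif k is ValueKind.DATE:
        ds.Date = _da(v)
    elif k is ValueKind.DATETIME:
        ds.DateTime = v.strftime("%Y%m%d%H%M%S")
    elif k is ValueKind.UIDREF:
        ds.UID = v
    elif k is ValueKind.PNAME:
        ds.PersonName = v
    elif k in (ValueKind.SCOORD, ValueKind.SCOORD3D):
        ds.GraphicType = v.graphic_type.value
        ds.GraphicData = list(v.coordinates)
        if k is ValueKind.SCOORD3D:
            ds.ReferencedFrameOfReferenceUID = v.frame_of_reference_uid
    else:  # IMAGE / WAVEFORM / COMPOSITE
        rs = Dataset()
        rs.ReferencedSOPClassUID = v.sop_class_uid
        rs.ReferencedSOPInstanceUID = v.sop_instance_uid
        ds.ReferencedSOPSequence = [rs]
    return ds


def to_dicom(doc: SRDocument) -> bytes:
    """Serialise a (template-valid) document to a Part 10 byte stream."""
    ds = Dataset()
    ds.SpecificCharacterSet = "ISO_IR 192"
    ds.SOPClassUID = COMPREHENSIVE_3D_SR
    ds.SOPInstanceUID = doc.sop_uid
    ds.StudyInstanceUID = doc.study_uid
    ds.SeriesInstanceUID = doc.series_uid
    ds.Modality = "SR"
    ds.SeriesNumber = 1
    ds.InstanceNumber = 1
    ds.StudyDate = _da(doc.study_date)
    ds.ContentDate = _da(doc.study_date)
    ds.ContentTime = "000000"
    ds.StudyTime = "000000"
    ds.AccessionNumber = ""
    ds.ReferringPhysicianName = ""
    ds.StudyID = "1"
    ds.CompletionFlag = "COMPLETE"
    ds.VerificationFlag = "UNVERIFIED"
    ds.PatientID = doc.patient_id
    pc = doc.patient_context
    ds.PatientName = (pc.name if pc and pc.name else "")
    ds.PatientBirthDate = (_da(pc.birth_date) if pc and pc.birth_date else "")
    ds.PatientSex = (pc.sex if pc and pc.sex else "")
    ds.Manufacturer = "srcohort"

    # root container lives on the top-level dataset
    root = _encode_item(doc.root, is_root=True)
    for elem in root:
        ds[elem.tag] = elem
    ct = Dataset()
    ct.MappingResource = "DCMR" if doc.tid.isdigit() else "99SRC"
    ct.TemplateIdentifier = doc.tid
    ds.ContentTemplateSequence = [ct]

    if doc.evidence:
        studies = {}
        for ev in doc.evidence:
            studies.setdefault(ev.study_uid, {}).setdefault(ev.series_uid, []).append(ev)
        seq = []
        for study_uid, series_map in studies.items():
            st = Dataset()
            st.StudyInstanceUID = study_uid
            st.ReferencedSeriesSequence = []
            for series_uid, refs in series_map.items():
                se = Dataset()
                se.SeriesInstanceUID = series_uid
                se.ReferencedSOPSequence = []
                for ev in refs:
                    rs = Dataset()
                    rs.ReferencedSOPClassUID = ev.sop_class_uid
                    rs.ReferencedSOPInstanceUID = ev.sop_instance_uid
                    se.ReferencedSOPSequence.append(rs)
                st.ReferencedSeriesSequence.append(se)
            seq.append(st)
        ds.CurrentRequestedProcedureEvidenceSequence = seq

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = COMPREHENSIVE_3D_SR
    meta.MediaStorageSOPInstanceUID = doc.sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta = meta

    buf = io.BytesIO()
    dcmwrite(buf, ds, enforce_file_format=True)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def _decode_code(seq) -> CodedConcept:
    c = seq[0]
    return CodedConcept(str(c.CodeValue), str(c.CodingSchemeDesignator),
                        str(getattr(c, "CodeMeaning", "")))


def _decode_date(s: str) -> _dt.date:
    return _dt.datetime.strptime(str(s)[:8], "%Y%m%d").date()


def _ds_string(v) -> str:
    orig = getattr(v, "original_string", None)
    if orig:
        return orig if isinstance(orig, str) else orig.decode()
    return str(v)


def _decode_item(ds: Dataset, is_root: bool = False) -> ContentItem:
    try:
        kind = ValueKind(str(ds.ValueType))
    except (AttributeError, ValueError) as exc:
        raise SRParseError(f"bad or missing ValueType: {exc}") from exc
    name = _decode_code(ds.ConceptNameCodeSequence)
    rel = None if is_root else Relationship(str(ds.RelationshipType))

    value = None
    if kind is ValueKind.CODE:
        value = _decode_code(ds.ConceptCodeSequence)
    elif kind is ValueKind.NUM:
        mv = ds.MeasuredValueSequence[0]
        value = NumValue(_ds_string(mv["NumericValue"].value),
                         _decode_code(mv.MeasurementUnitsCodeSequence))
    elif kind is ValueKind.TEXT:
        value = str(ds.TextValue)
    elif kind is ValueKind.DATE:
        value = _decode_date(ds.Date)
    elif kind is ValueKind.DATETIME:
        value = _dt.datetime.strptime(str(ds.DateTime)[:14], "%Y%m%d%H%M%S")
    elif kind is ValueKind.UIDREF:
        value = str(ds.UID)
    elif kind is ValueKind.PNAME:
        value = str(ds.PersonName)
    elif kind in (ValueKind.SCOORD, ValueKind.SCOORD3D):
        gd = ds.GraphicData
        coords = tuple(float(x) for x in (gd if isinstance(gd, (list, tuple)) else [gd]))
        value = ScoordValue(
            GraphicType(str(ds.GraphicType)), coords,
            str(ds.ReferencedFrameOfReferenceUID)
            if kind is ValueKind.SCOORD3D else None)
    elif kind in (ValueKind.IMAGE, ValueKind.WAVEFORM, ValueKind.COMPOSITE):
        rs = ds.ReferencedSOPSequence[0]
        value = SopReference(str(rs.ReferencedSOPClassUID),
                             str(rs.ReferencedSOPInstanceUID))

    item = ContentItem(name, kind, value, rel)
    if kind is ValueKind.CONTAINER:
        for child in getattr(ds, "ContentSequence", []):
            item.children.append(_decode_item(child))
    return item


def from_dicom(data: bytes) -> SRDocument:
    """Parse a Comprehensive 3D SR Part 10 byte stream back into a document."""
    try:
        ds = dcmread(io.BytesIO(data))
    except Exception as exc:  # pydicom raises several types on malformed input
        raise SRParseError(f"not a readable DICOM stream: {exc}") from exc
    sop_class = str(getattr(ds, "SOPClassUID", ""))
    if sop_class != COMPREHENSIVE_3D_SR:
        raise SRParseError(
            f"SOPClassUID {sop_class!r} is not Comprehensive 3D SR")
    try:
        root = _decode_item(ds, is_root=True)
        tid = str(ds.ContentTemplateSequence[0].TemplateIdentifier)
        evidence: List[EvidenceRef] = []
        for st in getattr(ds, "CurrentRequestedProcedureEvidenceSequence", []):
            for se in st.ReferencedSeriesSequence:
                for rs in se.ReferencedSOPSequence:
                    evidence.append(EvidenceRef(
                        str(st.StudyInstanceUID), str(se.SeriesInstanceUID),
                        str(rs.ReferencedSOPClassUID),
                        str(rs.ReferencedSOPInstanceUID)))
        pc = None
        if getattr(ds, "PatientName", "") or getattr(ds, "PatientBirthDate", "") \
                or getattr(ds, "PatientSex", ""):
            pc = PatientContext(
                name=str(ds.PatientName) or None,
                birth_date=(_decode_date(ds.PatientBirthDate)
                            if getattr(ds, "PatientBirthDate", "") else None),
                sex=str(getattr(ds, "PatientSex", "")) or None)
        return SRDocument(
            patient_id=str(ds.PatientID),
            study_uid=str(ds.StudyInstanceUID),
            series_uid=str(ds.SeriesInstanceUID),
            sop_uid=str(ds.SOPInstanceUID),
            study_date=_decode_date(ds.StudyDate),
            tid=tid,
            root=root,
            evidence=evidence,
            patient_context=pc,
        )
    except SRParseError:
        raise
    except Exception as exc:
        raise SRParseError(f"malformed SR content: {exc}") from exc
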