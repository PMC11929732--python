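"""The structured-report document: header context + content tree + evidence."""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .content import ContentItem, SopReference, StructureError, ValueKind, iter_items
from .templates import TemplateRegistry, ValidationIssue, validate_tree
from .uids import UIDGenerator, is_valid_uid, new_uid


@dataclass(frozen=True)
class PatientContext:
    name: Optional[str] = None
    birth_date: Optional[_dt.date] = None
    sex: Optional[str] = None  # DICOM PatientSex: M/F/O


@dataclass(frozen=True)
class EvidenceRef:
    """One composite object this report draws on (referenced by IMAGE/WAVEFORM
    items), located by its study/series and SOP class/instance UIDs."""

    study_uid: str
    series_uid: str
    sop_class_uid: str
    sop_instance_uid: str


@dataclass
class SRDocument:
    patient_id: str
    study_uid: str
    series_uid: str
    sop_uid: str
    study_date: _dt.date
    tid: str
    root: ContentItem
    evidence: List[EvidenceRef] = field(default_factory=list)
    patient_context: Optional[PatientContext] = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise StructureError("SRDocument requires a patient id")
        if self.root.value_kind is not ValueKind.CONTAINER:
            raise StructureError("document root must be a CONTAINER item")
        for uid in (self.study_uid, self.series_uid, self.sop_uid):
            if not is_valid_uid(uid):
                raise StructureError(f"invalid DICOM UID: {uid!r}")
        referenced = self.referenced_sops()
        known = {e.sop_instance_uid for e in self.evidence}
        missing = [r for r in referenced if r.sop_instance_uid not in known]
        if missing:
            raise StructureError(
                "IMAGE/WAVEFORM references without evidence entries: "
                + ", ".join(m.sop_instance_uid for m in missing))

    def referenced_sops(self) -> List[SopReference]:
        return [item.value for _, item in iter_items(self.root)
                if item.value_kind in (ValueKind.IMAGE, ValueKind.WAVEFORM,
                                       ValueKind.COMPOSITE)]

    def iter_items(self):
        """Depth-first (meaning path, item) pairs; see :func:`content.iter_items`."""
        return iter_items(self.root)

    @classmethod
    def create(cls, patient_id: str, study_date: _dt.date, tid: str,
               root: ContentItem, evidence: List[EvidenceRef] = (),
               patient_context: Optional[PatientContext] = None,
               study_uid: Optional[str] = None,
               uid_generator: Optional[UIDGenerator] = None) -> "SRDocument":
        """Build a document, minting series/SOP (and optionally study) UIDs."""
        gen = uid_generator
        return cls(
            patient_id=patient_id,
            study_uid=study_uid or new_uid(gen),
            series_uid=new_uid(gen),
            sop_uid=new_uid(gen),
            study_date=study_date,
            tid=tid,
            root=root,
            evidence=list(evidence),
            patient_context=patient_context,
        )


def validate(doc: SRDocument, registry: TemplateRegistry) -> List[ValidationIssue]:
    """Validate a document's content tree against its registered template.

    Returns an empty list iff every mandatory row is matched with the correct
    value kind and cardinality and all relationships are permitted. Raises
    :class:`~srcohort.templates.UnknownTemplateError` for an unregistered tid.
    """
    template = registry.get(doc.tid)
    return validate_tree(doc.root, template, registry)
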