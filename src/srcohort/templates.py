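"""SR templates: row declarations, a loadable registry, and tree validation.

A template constrains which content items a report may or must contain. Each
row names a concept (or is a wildcard over a value kind), its value kind, a
requirement level, a cardinality, the relationship the item must carry, and —
for CONTAINER rows — the template governing the container's children.

The registry ships the ECG report family (TID 3700 with its embedded TID 3708
waveform-information block), the cardiovascular patient history (TID 3802) and
its two procedure-outcome variants, and a measurement-report template in the
TID 1500 style for image annotations. It is extensible at run time and
(de)serialisable to YAML, so new templates need no code changes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from . import concepts as C
from .coding import CodedConcept, code
from .content import ContentItem, Relationship, ValueKind


class Requirement(str, enum.Enum):
    MANDATORY = "MANDATORY"
    USER_OPTIONAL = "USER_OPTIONAL"
    CONDITIONAL = "CONDITIONAL"


class Cardinality(str, enum.Enum):
    ONE = "ONE"
    ONE_TO_N = "ONE_TO_N"


class IssueCode(str, enum.Enum):
    MISSING_MANDATORY = "MISSING_MANDATORY"
    WRONG_VALUE_KIND = "WRONG_VALUE_KIND"
    WRONG_CARDINALITY = "WRONG_CARDINALITY"
    UNKNOWN_CONCEPT = "UNKNOWN_CONCEPT"
    BAD_RELATIONSHIP = "BAD_RELATIONSHIP"
    BAD_ROOT = "BAD_ROOT"


class UnknownTemplateError(KeyError):
    pass


@dataclass(frozen=True)
class RowCondition:
    """A CONDITIONAL row is enforced only when a sibling named
    ``sibling_meaning`` is present in the same container."""

    sibling_meaning: str


@dataclass(frozen=True)
class TemplateRow:
    concept: Optional[CodedConcept]  # None = wildcard: matches by kind+relationship
    value_kind: ValueKind
    requirement: Requirement = Requirement.USER_OPTIONAL
    cardinality: Cardinality = Cardinality.ONE
    relationship: Relationship = Relationship.CONTAINS
    child_template: Optional[str] = None
    condition: Optional[RowCondition] = None


@dataclass(frozen=True)
class SRTemplate:
    tid: str
    title: CodedConcept
    rows: Tuple[TemplateRow, ...]
    allow_extra: bool = False

    def __init__(self, tid: str, title: CodedConcept, rows: Sequence[TemplateRow],
                 allow_extra: bool = False):
        object.__setattr__(self, "tid", tid)
        object.__setattr__(self, "title", title)
        object.__setattr__(self, "rows", tuple(rows))
        object.__setattr__(self, "allow_extra", allow_extra)


@dataclass(frozen=True)
class ValidationIssue:
    path: Tuple[str, ...]  # concept meanings from root to offending/expected node
    code: IssueCode
    detail: str

    def __str__(self) -> str:
        return f"{self.code.value} at {' - '.join(self.path)}: {self.detail}"


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _match_row(child: ContentItem, rows: Sequence[TemplateRow]) -> Optional[TemplateRow]:
    for row in rows:
        if row.concept is not None and row.concept == child.name:
            return row
    for row in rows:
        if row.concept is None and row.value_kind is child.value_kind \
                and row.relationship is child.relationship:
            return row
    return None


def _validate_container(container: ContentItem, template: SRTemplate,
                        registry: "TemplateRegistry", path: Tuple[str, ...],
                        issues: List[ValidationIssue]) -> None:
    rows = template.rows
    matched: Dict[int, List[ContentItem]] = {i: [] for i in range(len(rows))}
    sibling_meanings = {c.name.meaning for c in container.children}

    for child in container.children:
        cpath = path + (child.name.meaning,)
        row = _match_row(child, rows)
        if row is None:
            if not template.allow_extra:
                issues.append(ValidationIssue(
                    cpath, IssueCode.UNKNOWN_CONCEPT,
                    f"concept {child.name!r} not declared by template {template.tid}"))
            continue
        matched[rows.index(row)].append(child)
        if child.value_kind is not row.value_kind:
            issues.append(ValidationIssue(
                cpath, IssueCode.WRONG_VALUE_KIND,
                f"expected {row.value_kind.value}, found {child.value_kind.value}"))
            continue
        if child.relationship is not row.relationship:
            issues.append(ValidationIssue(
                cpath, IssueCode.BAD_RELATIONSHIP,
                f"expected {row.relationship.value}, found "
                f"{child.relationship.value if child.relationship else None}"))
        if row.child_template is not None and child.value_kind is ValueKind.CONTAINER:
            sub = registry.get(row.child_template)
            _validate_container(child, sub, registry, cpath, issues)

    for i, row in enumerate(rows):
        n = len(matched[i])
        required = row.requirement is Requirement.MANDATORY or (
            row.requirement is Requirement.CONDITIONAL
            and row.condition is not None
            and row.condition.sibling_meaning in sibling_meanings)
        label = row.concept.meaning if row.concept else f"<any {row.value_kind.value}>"
        if required and n == 0:
            issues.append(ValidationIssue(
                path + (label,), IssueCode.MISSING_MANDATORY,
                f"template {template.tid} requires {label!r}"))
        if row.cardinality is Cardinality.ONE and n > 1:
            issues.append(ValidationIssue(
                path + (label,), IssueCode.WRONG_CARDINALITY,
                f"{label!r} occurs {n} times but cardinality is ONE"))


def validate_tree(root: ContentItem, template: SRTemplate,
                  registry: "TemplateRegistry") -> List[ValidationIssue]:
    """Validate a content tree against a template; one issue per violation."""
    issues: List[ValidationIssue] = []
    if root.value_kind is not ValueKind.CONTAINER:
        issues.append(ValidationIssue(
            (root.name.meaning,), IssueCode.BAD_ROOT,
            f"document root must be CONTAINER, found {root.value_kind.value}"))
        return issues
    if root.name != template.title:
        issues.append(ValidationIssue(
            (root.name.meaning,), IssueCode.BAD_ROOT,
            f"root concept {root.name!r} does not match template title {template.title!r}"))
    _validate_container(root, template, registry, (root.name.meaning,), issues)
    return issues


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

class TemplateRegistry:
    """Mutable tid → template mapping, YAML-(de)serialisable."""

    def __init__(self, templates: Sequence[SRTemplate] = ()):
        self._templates: Dict[str, SRTemplate] = {}
        for t in templates:
            self.register(t)

    def register(self, template: SRTemplate) -> None:
        if template.tid in self._templates:
            raise ValueError(f"template {template.tid!r} already registered")
        self._templates[template.tid] = template

    def get(self, tid: str) -> SRTemplate:
        try:
            return self._templates[tid]
        except KeyError:
            raise UnknownTemplateError(f"unknown template id {tid!r}") from None

    def __contains__(self, tid: str) -> bool:
        return tid in self._templates

    def __iter__(self):
        return iter(self._templates.values())

    def __len__(self) -> int:
        return len(self._templates)

    # -- declarative config ------------------------------------------------

    def to_dict(self) -> dict:
        def enc_code(c: Optional[CodedConcept]):
            return None if c is None else {"value": c.value, "scheme": c.scheme,
                                           "meaning": c.meaning}

        return {"templates": [
            {"tid": t.tid, "title": enc_code(t.title), "allow_extra": t.allow_extra,
             "rows": [
                 {"concept": enc_code(r.concept), "value_kind": r.value_kind.value,
                  "requirement": r.requirement.value, "cardinality": r.cardinality.value,
                  "relationship": r.relationship.value, "child_template": r.child_template,
                  "condition": ({"sibling_present": r.condition.sibling_meaning}
                                if r.condition else None)}
                 for r in t.rows]}
            for t in self._templates.values()]}

    @classmethod
    def from_dict(cls, d: dict) -> "TemplateRegistry":
        def dec_code(c):
            return None if c is None else code(c["value"], c["scheme"], c["meaning"])

        reg = cls()
        for td in d["templates"]:
            rows = [TemplateRow(
                concept=dec_code(r.get("concept")),
                value_kind=ValueKind(r["value_kind"]),
                requirement=Requirement(r.get("requirement", "USER_OPTIONAL")),
                cardinality=Cardinality(r.get("cardinality", "ONE")),
                relationship=Relationship(r.get("relationship", "CONTAINS")),
                child_template=r.get("child_template"),
                condition=(RowCondition(r["condition"]["sibling_present"])
                           if r.get("condition") else None),
            ) for r in td.get("rows", [])]
            reg.register(SRTemplate(td["tid"], dec_code(td["title"]), rows,
                                    allow_extra=td.get("allow_extra", False)))
        return reg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TemplateRegistry":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# shipped templates
# ---------------------------------------------------------------------------

WAVEFORM_ACQUISITION = code("WAVEFORM-ACQ", "99SRC", "Waveform Acquisition")
PROCEDURE_REPORTED = code("121058", "DCM", "Procedure Reported")

_R, _K, _Q, _N = TemplateRow, ValueKind, Requirement, Cardinality
_REL = Relationship


def _ecg_templates() -> List[SRTemplate]:
    tid_3708 = SRTemplate("3708", C.WAVEFORM_INFORMATION, [
        _R(WAVEFORM_ACQUISITION, _K.WAVEFORM, _Q.MANDATORY, _N.ONE),
        _R(C.LEAD_SYSTEM, _K.CODE, relationship=_REL.HAS_ACQ_CONTEXT),
        _R(C.SAMPLING_FREQUENCY, _K.NUM, relationship=_REL.HAS_ACQ_CONTEXT),
    ])
    tid_3700_meas = SRTemplate("3700_MEAS", C.ECG_GLOBAL_MEASUREMENTS, [
        _R(C.VENTRICULAR_RATE, _K.NUM),
        _R(C.QT_INTERVAL, _K.NUM),
        _R(C.PR_INTERVAL, _K.NUM),
        _R(C.QRS_DURATION, _K.NUM),
    ])
    tid_3700 = SRTemplate("3700", C.ECG_REPORT, [
        _R(C.WAVEFORM_INFORMATION, _K.CONTAINER, _Q.MANDATORY, _N.ONE,
           child_template="3708"),
        _R(C.ECG_GLOBAL_MEASUREMENTS, _K.CONTAINER, child_template="3700_MEAS"),
        _R(C.RHYTHM_FINDING, _K.CODE, cardinality=_N.ONE_TO_N),
        _R(C.COMMENT, _K.TEXT),
    ])
    return [tid_3708, tid_3700_meas, tid_3700]


def _history_rows() -> List[TemplateRow]:
    # shared body of the patient-history family (TID 3802 and outcome variants)
    return [
        _R(C.PROCEDURE_CONTEXT, _K.CONTAINER, relationship=_REL.HAS_OBS_CONTEXT,
           child_template="3802_PROC"),
        _R(C.SOCIAL_HISTORY, _K.CONTAINER, child_template="3802_SOC"),
        _R(C.SURGICAL_HISTORY, _K.CONTAINER, child_template="3802_SURG"),
        _R(C.DIABETES_MELLITUS, _K.CODE),
        _R(C.MEDICAL_DEVICE_USE, _K.CONTAINER, cardinality=_N.ONE_TO_N,
           child_template="3802_DEV"),
        _R(C.COMMENT, _K.TEXT),
        _R(C.ACQUISITION_YEAR, _K.TEXT, relationship=_REL.HAS_ACQ_CONTEXT),
    ]


def _history_templates() -> List[SRTemplate]:
    proc = SRTemplate("3802_PROC", C.PROCEDURE_CONTEXT, [
        _R(PROCEDURE_REPORTED, _K.CODE),
        _R(C.PROCEDURE_DATE, _K.DATE),
        _R(C.RECORD_SOURCE, _K.CODE),
        _R(C.PACEMAKER_IMPLANTATION, _K.CODE),
        _R(C.PROSTHESIS_MODEL, _K.CODE),
        # size is meaningful only alongside a model
        _R(C.PROSTHESIS_SIZE, _K.NUM, _Q.CONDITIONAL,
           condition=RowCondition("Prosthesis Model")),
    ])
    soc = SRTemplate("3802_SOC", C.SOCIAL_HISTORY, [
        _R(C.TOBACCO_SMOKER, _K.CODE),
    ])
    surg = SRTemplate("3802_SURG", C.SURGICAL_HISTORY, [
        _R(C.PRIOR_CARDIAC_SURGERY, _K.CODE),
    ])
    dev = SRTemplate("3802_DEV", C.MEDICAL_DEVICE_USE, [
        _R(C.DEVICE_ITEM, _K.CODE, _Q.MANDATORY),
        _R(C.DEVICE_DATE, _K.DATE),
    ])
    hist = SRTemplate("3802", C.CARDIOVASCULAR_PATIENT_HISTORY, _history_rows())
    qa = SRTemplate("3802_QA", C.TITLE_QA_INFORMATION, _history_rows())
    prosth = SRTemplate("3802_PROSTH", C.TITLE_PROSTHESIS_INFORMATION, _history_rows())
    return [proc, soc, surg, dev, hist, qa, prosth]


def _measurement_templates() -> List[SRTemplate]:
    grp = SRTemplate("1500_GRP", C.MEASUREMENT_GROUP, [
        _R(None, _K.NUM, cardinality=_N.ONE_TO_N),
        _R(None, _K.CODE, cardinality=_N.ONE_TO_N),
        _R(None, _K.SCOORD3D, cardinality=_N.ONE_TO_N),
        _R(None, _K.SCOORD, cardinality=_N.ONE_TO_N),
        _R(None, _K.TEXT, cardinality=_N.ONE_TO_N),
        _R(None, _K.IMAGE, cardinality=_N.ONE_TO_N),
    ])
    rep = SRTemplate("1500", C.IMAGING_MEASUREMENT_REPORT, [
        _R(C.MEASUREMENT_GROUP, _K.CONTAINER, cardinality=_N.ONE_TO_N,
           child_template="1500_GRP"),
        _R(C.COMMENT, _K.TEXT),
    ])
    return [grp, rep]


def default_registry() -> TemplateRegistry:
    """Registry with the shipped clinical templates."""
    return TemplateRegistry(
        _ecg_templates() + _history_templates() + _measurement_templates())
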