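"""The structured-report content tree: name-value pairs with typed values.

A structured report encodes findings as an ordered tree of *content items*.
Each item pairs a coded concept (the name) with a value, which is one of a
small set of kinds: a nested container, another coded concept, a number with a
unit, plain text, a date, spatial coordinates, or a reference to another DICOM
object (image, waveform, composite). Children hang off CONTAINER items only
and each child records its relationship to the parent.
"""

from __future__ import annotations

import datetime as _dt
import enum
import math
from dataclasses import dataclass, field as _field
from typing import Iterator, List, Optional, Sequence, Tuple, Union

from .coding import CodedConcept


class ValueKind(str, enum.Enum):
    CONTAINER = "CONTAINER"
    CODE = "CODE"
    NUM = "NUM"
    TEXT = "TEXT"
    DATE = "DATE"
    DATETIME = "DATETIME"
    UIDREF = "UIDREF"
    PNAME = "PNAME"
    SCOORD = "SCOORD"
    SCOORD3D = "SCOORD3D"
    IMAGE = "IMAGE"
    WAVEFORM = "WAVEFORM"
    COMPOSITE = "COMPOSITE"


class Relationship(str, enum.Enum):
    CONTAINS = "CONTAINS"
    HAS_CONCEPT_MOD = "HAS CONCEPT MOD"
    HAS_OBS_CONTEXT = "HAS OBS CONTEXT"
    HAS_ACQ_CONTEXT = "HAS ACQ CONTEXT"
    HAS_PROPERTIES = "HAS PROPERTIES"
    INFERRED_FROM = "INFERRED FROM"
    SELECTED_FROM = "SELECTED FROM"


class GraphicType(str, enum.Enum):
    POINT = "POINT"
    MULTIPOINT = "MULTIPOINT"
    POLYLINE = "POLYLINE"
    POLYGON = "POLYGON"
    ELLIPSE = "ELLIPSE"


class StructureError(ValueError):
    """Violation of the content-tree invariants (e.g. children on a non-container)."""


@dataclass(frozen=True)
class NumValue:
    """A measurement: decimal magnitude (kept as its string form) plus a unit.

    The magnitude is stored as a decimal string so that serialisation to the
    DICOM DS value representation and back never drifts through binary floats.
    """

    magnitude: str
    unit: CodedConcept

    def __post_init__(self) -> None:
        try:
            v = float(self.magnitude)
        except (TypeError, ValueError):
            raise StructureError(f"NUM magnitude {self.magnitude!r} is not decimal")
        if not math.isfinite(v):
            raise StructureError("NUM magnitude must be finite")

    @property
    def as_float(self) -> float:
        return float(self.magnitude)


@dataclass(frozen=True)
class ScoordValue:
    graphic_type: GraphicType
    # flat coordinate list: (col,row)* for 2D, (x,y,z)* for 3D
    coordinates: Tuple[float, ...]
    frame_of_reference_uid: Optional[str] = None  # 3D only

    def __post_init__(self) -> None:
        # DICOM graphic data is 32-bit float; coerce up front so serialisation
        # is lossless thereafter
        import numpy as _np
        object.__setattr__(
            self, "coordinates",
            tuple(float(_np.float32(c)) for c in self.coordinates))


@dataclass(frozen=True)
class SopReference:
    sop_class_uid: str
    sop_instance_uid: str


ItemValue = Union[None, CodedConcept, NumValue, str, _dt.date, _dt.datetime,
                  ScoordValue, SopReference]


@dataclass
class ContentItem:
    """One node of the content tree.

    ``value`` holds the variant appropriate for ``value_kind``; CONTAINER
    items have ``value=None`` and may carry children. ``relationship`` is the
    relationship to the parent and is ``None`` only on the document root.
    """

    name: CodedConcept
    value_kind: ValueKind
    value: ItemValue = None
    relationship: Optional[Relationship] = None
    children: List["ContentItem"] = _field(default_factory=list)

    def __post_init__(self) -> None:
        self._check_value()
        if self.children and self.value_kind is not ValueKind.CONTAINER:
            raise StructureError("only CONTAINER items may have children")

    def _check_value(self) -> None:
        k, v = self.value_kind, self.value
        if k is ValueKind.CONTAINER:
            if v is not None:
                raise StructureError("CONTAINER items carry no value")
        elif k is ValueKind.CODE:
            if not isinstance(v, CodedConcept):
                raise StructureError("CODE value must be a CodedConcept")
        elif k is ValueKind.NUM:
            if not isinstance(v, NumValue):
                raise StructureError("NUM value must be a NumValue")
        elif k in (ValueKind.TEXT, ValueKind.UIDREF, ValueKind.PNAME):
            if not isinstance(v, str):
                raise StructureError(f"{k.value} value must be a string")
        elif k is ValueKind.DATE:
            if not isinstance(v, _dt.date) or isinstance(v, _dt.datetime):
                raise StructureError("DATE value must be a datetime.date")
        elif k is ValueKind.DATETIME:
            if not isinstance(v, _dt.datetime):
                raise StructureError("DATETIME value must be a datetime.datetime")
        elif k in (ValueKind.SCOORD, ValueKind.SCOORD3D):
            if not isinstance(v, ScoordValue):
                raise StructureError("SCOORD/SCOORD3D value must be a ScoordValue")
            if k is ValueKind.SCOORD3D:
                if len(v.coordinates) % 3 != 0:
                    raise StructureError("SCOORD3D coordinate count must be a multiple of 3")
                if not v.frame_of_reference_uid:
                    raise StructureError("SCOORD3D requires a frame-of-reference UID")
            elif len(v.coordinates) % 2 != 0:
                raise StructureError("SCOORD coordinate count must be a multiple of 2")
        elif k in (ValueKind.IMAGE, ValueKind.WAVEFORM, ValueKind.COMPOSITE):
            if not isinstance(v, SopReference):
                raise StructureError(f"{k.value} value must be a SopReference")

    # -- constructors -------------------------------------------------------

    @classmethod
    def container(cls, name: CodedConcept,
                  relationship: Optional[Relationship] = None) -> "ContentItem":
        return cls(name, ValueKind.CONTAINER, None, relationship)

    @classmethod
    def code(cls, name: CodedConcept, value: CodedConcept,
             relationship: Relationship = Relationship.CONTAINS) -> "ContentItem":
        return cls(name, ValueKind.CODE, value, relationship)

    @classmethod
    def num(cls, name: CodedConcept, magnitude, unit: CodedConcept,
            relationship: Relationship = Relationship.CONTAINS) -> "ContentItem":
        return cls(name, ValueKind.NUM, NumValue(str(magnitude), unit), relationship)

    @classmethod
    def text(cls, name: CodedConcept, value: str,
             relationship: Relationship = Relationship.CONTAINS) -> "ContentItem":
        return cls(name, ValueKind.TEXT, value, relationship)

    @classmethod
    def date(cls, name: CodedConcept, value: _dt.date,
             relationship: Relationship = Relationship.CONTAINS) -> "ContentItem":
        return cls(name, ValueKind.DATE, value, relationship)

    @classmethod
    def scoord3d(cls, name: CodedConcept, graphic_type: GraphicType,
                 coordinates: Sequence[float], frame_of_reference_uid: str,
                 relationship: Relationship = Relationship.CONTAINS) -> "ContentItem":
        return cls(name, ValueKind.SCOORD3D,
                   ScoordValue(graphic_type, tuple(coordinates), frame_of_reference_uid),
                   relationship)

    @classmethod
    def waveform_ref(cls, name: CodedConcept, sop_class_uid: str, sop_instance_uid: str,
                     relationship: Relationship = Relationship.CONTAINS) -> "ContentItem":
        return cls(name, ValueKind.WAVEFORM, SopReference(sop_class_uid, sop_instance_uid),
                   relationship)

    @classmethod
    def image_ref(cls, name: CodedConcept, sop_class_uid: str, sop_instance_uid: str,
                  relationship: Relationship = Relationship.CONTAINS) -> "ContentItem":
        return cls(name, ValueKind.IMAGE, SopReference(sop_class_uid, sop_instance_uid),
                   relationship)


def add_child(parent: ContentItem, child: ContentItem,
              relationship: Optional[Relationship] = None) -> ContentItem:
    """Append ``child`` under ``parent`` (a CONTAINER), recording the relationship.

    Returns the child for chaining. The child's existing relationship is kept
    when ``relationship`` is ``None``.
    """
    if parent.value_kind is not ValueKind.CONTAINER:
        raise StructureError(
            f"cannot add children to a {parent.value_kind.value} item "
            f"({parent.name.meaning!r}); only CONTAINER items nest"
        )
    if relationship is not None:
        child.relationship = relationship
    if child.relationship is None:
        raise StructureError("every child must carry a relationship to its parent")
    parent.children.append(child)
    return child


def iter_items(root: ContentItem) -> Iterator[Tuple[Tuple[str, ...], ContentItem]]:
    """Depth-first, parents before children; yields (meaning path, item).

    The path runs from the root to the node inclusive, e.g. the tobacco-status
    item of a patient-history report is yielded under
    ``("Cardiovascular Patient History", "Social History", "Tobacco Smoker")``.
    """
    stack: List[Tuple[Tuple[str, ...], ContentItem]] = [((root.name.meaning,), root)]
    while stack:
        path, item = stack.pop()
        yield path, item
        for child in reversed(item.children):
            stack.append((path + (child.name.meaning,), child))


def count_items(root: ContentItem) -> int:
    return sum(1 for _ in iter_items(root))
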