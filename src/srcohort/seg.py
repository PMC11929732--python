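"""DICOM segmentation (SEG) objects with coded per-segment labels.

Each segment of a label mask carries a coded anatomical/finding concept and an
algorithm type (manual / automatic / semiautomatic), so segmentations are
queryable on the individual segment level after indexing. Masks are binary,
aligned to the referenced series' frame grid, one stack of frames per segment,
bit-packed into PixelData.
"""

from __future__ import annotations

import datetime as _dt
import enum
import io
import logging
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from pydicom import dcmread, dcmwrite
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian

from . import concepts as C
from .coding import CodedConcept
from .uids import UIDGenerator, new_uid

SEGMENTATION_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.66.4"

logger = logging.getLogger(__name__)

try:  # pydicom >= 3 moved the bit-packing helpers
    from pydicom.pixels import pack_bits, unpack_bits
except ImportError:  # pragma: no cover
    from pydicom.pixel_data_handlers.util import pack_bits, unpack_bits


class SegAlgorithmType(str, enum.Enum):
    MANUAL = "MANUAL"
    AUTOMATIC = "AUTOMATIC"
    SEMIAUTOMATIC = "SEMIAUTOMATIC"


class SegStructureError(ValueError):
    pass


@dataclass(frozen=True)
class Segment:
    number: int
    label: CodedConcept
    algorithm_type: SegAlgorithmType = SegAlgorithmType.MANUAL

    def __post_init__(self) -> None:
        if self.number < 1:
            raise SegStructureError("segment numbers start at 1")


@dataclass
class SegmentationObject:
    """Segments plus their binary volumes, referencing one image series."""

    referenced_series_uid: str
    segments: List[Segment]
    masks: List[np.ndarray]  # one (frames, rows, cols) bool array per segment
    sop_uid: Optional[str] = None  # set on round trip

    def __post_init__(self) -> None:
        nums = [s.number for s in self.segments]
        if nums != list(range(1, len(nums) + 1)):
            raise SegStructureError(
                f"segment numbers must be consecutive from 1, got {nums}")
        if len(self.masks) != len(self.segments):
            raise SegStructureError(
                f"{len(self.segments)} segments but {len(self.masks)} masks")
        self.masks = [np.asarray(m, dtype=bool) for m in self.masks]
        shapes = {m.shape for m in self.masks}
        if len(shapes) > 1:
            raise SegStructureError(f"inconsistent mask shapes: {sorted(shapes)}")
        if self.masks and self.masks[0].ndim != 3:
            raise SegStructureError("masks must be (frames, rows, cols) volumes")

    @property
    def segment_labels(self) -> List[CodedConcept]:
        return [s.label for s in self.segments]


@dataclass(frozen=True)
class SegContext:
    patient_id: str
    study_date: _dt.date
    study_uid: Optional[str] = None
    frame_of_reference_uid: Optional[str] = None


def build_seg(seg: SegmentationObject, context: SegContext,
              uid_generator: Optional[UIDGenerator] = None) -> bytes:
    """Serialise a segmentation to a DICOM SEG Part 10 byte stream."""
    gen = uid_generator
    sop = new_uid(gen)
    n_slices, rows, cols = seg.masks[0].shape if seg.masks else (0, 0, 0)

    ds = Dataset()
    ds.SOPClassUID = SEGMENTATION_SOP_CLASS
    ds.SOPInstanceUID = sop
    ds.StudyInstanceUID = context.study_uid or new_uid(gen)
    ds.SeriesInstanceUID = new_uid(gen)
    ds.FrameOfReferenceUID = context.frame_of_reference_uid or new_uid(gen)
    ds.Modality = "SEG"
    ds.SeriesNumber = 1
    ds.InstanceNumber = 1
    ds.PatientID = context.patient_id
    ds.PatientName = ""
    ds.StudyDate = context.study_date.strftime("%Y%m%d")
    ds.ContentDate = context.study_date.strftime("%Y%m%d")
    ds.ContentTime = "000000"
    ds.StudyTime = "000000"
    ds.AccessionNumber = ""
    ds.ReferringPhysicianName = ""
    ds.StudyID = "1"
    ds.Manufacturer = "srcohort"
    ds.SegmentationType = "BINARY"
    ds.ContentLabel = "SEGMENTATION"
    ds.ImageType = ["DERIVED", "PRIMARY"]
    ds.LossyImageCompression = "00"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 1
    ds.BitsStored = 1
    ds.HighBit = 0
    ds.PixelRepresentation = 0
    ds.Rows = rows
    ds.Columns = cols
    ds.NumberOfFrames = n_slices * len(seg.segments)

    rser = Dataset()
    rser.SeriesInstanceUID = seg.referenced_series_uid
    ds.ReferencedSeriesSequence = [rser]

    ds.SegmentSequence = []
    for s, mask in zip(seg.segments, seg.masks):
        if not mask.any():
            logger.warning("segment %d (%s) has an empty mask",
                           s.number, s.label.meaning)
        sd = Dataset()
        sd.SegmentNumber = s.number
        sd.SegmentLabel = s.label.meaning[:64]
        cat = Dataset()
        cat.CodeValue = C.ANATOMICAL_STRUCTURE.value
        cat.CodingSchemeDesignator = C.ANATOMICAL_STRUCTURE.scheme
        cat.CodeMeaning = C.ANATOMICAL_STRUCTURE.meaning
        sd.SegmentedPropertyCategoryCodeSequence = [cat]
        typ = Dataset()
        typ.CodeValue = s.label.value
        typ.CodingSchemeDesignator = s.label.scheme
        typ.CodeMeaning = s.label.meaning
        sd.SegmentedPropertyTypeCodeSequence = [typ]
        sd.SegmentAlgorithmType = s.algorithm_type.value
        if s.algorithm_type is not SegAlgorithmType.MANUAL:
            sd.SegmentAlgorithmName = "srcohort"
        ds.SegmentSequence.append(sd)

    ds.PerFrameFunctionalGroupsSequence = []
    for s in seg.segments:
        for k in range(n_slices):
            fg = Dataset()
            sid = Dataset()
            sid.ReferencedSegmentNumber = s.number
            fg.SegmentIdentificationSequence = [sid]
            fc = Dataset()
            fc.DimensionIndexValues = [s.number, k + 1]
            fg.FrameContentSequence = [fc]
            ds.PerFrameFunctionalGroupsSequence.append(fg)

    frames = np.concatenate([m for m in seg.masks], axis=0) if seg.masks \
        else np.zeros((0, 0, 0), bool)
    ds.PixelData = pack_bits(frames.reshape(-1).astype(np.uint8))

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SEGMENTATION_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = sop
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta = meta

    buf = io.BytesIO()
    dcmwrite(buf, ds, enforce_file_format=True)
    return buf.getvalue()


def read_seg(data: bytes) -> SegmentationObject:
    """Parse a SEG byte stream back into segments, labels and masks."""
    try:
        ds = dcmread(io.BytesIO(data))
    except Exception as exc:
        raise SegStructureError(f"not a readable DICOM stream: {exc}") from exc
    if str(getattr(ds, "SOPClassUID", "")) != SEGMENTATION_SOP_CLASS:
        raise SegStructureError("not a DICOM segmentation object")
    rows, cols = int(ds.Rows), int(ds.Columns)
    n_frames = int(ds.NumberOfFrames)
    bits = unpack_bits(ds.PixelData)[: n_frames * rows * cols]
    frames = np.asarray(bits, dtype=bool).reshape(n_frames, rows, cols)

    segments = []
    for sd in ds.SegmentSequence:
        typ = sd.SegmentedPropertyTypeCodeSequence[0]
        segments.append(Segment(
            int(sd.SegmentNumber),
            CodedConcept(str(typ.CodeValue), str(typ.CodingSchemeDesignator),
                         str(typ.CodeMeaning)),
            SegAlgorithmType(str(sd.SegmentAlgorithmType)),
        ))
    segments.sort(key=lambda s: s.number)

    frame_idx_by_segment = {s.number: [] for s in segments}
    for i, fg in enumerate(ds.PerFrameFunctionalGroupsSequence):
        num = int(fg.SegmentIdentificationSequence[0].ReferencedSegmentNumber)
        frame_idx_by_segment[num].append(i)
    masks = [frames[frame_idx_by_segment[s.number]] for s in segments]

    ref_series = str(ds.ReferencedSeriesSequence[0].SeriesInstanceUID)
    return SegmentationObject(ref_series, segments, masks,
                              sop_uid=str(ds.SOPInstanceUID))
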