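"""Builders for the clinical report templates used in TAVI cohort curation.

Three document families are produced here:

* **TID 3700 ECG report** — global ECG measurements (ventricular rate, QT/PR
  intervals, QRS duration), rhythm findings, and a TID 3708 waveform-
  information block referencing the DICOM waveform object as evidence.
* **TID 3802 cardiovascular patient history** — social history (tobacco
  status), surgical history, diabetes, medical device use, free-text notes.
  German quality-assurance questionnaires changed mandatory fields over the
  years, so every clinical field is optional and the acquisition year is kept
  as context.
* **Procedure outcome documents** — the post-TAVI pacemaker label (from
  billing/reimbursement coding) and prosthesis model/size (from quality
  assurance), built on the patient-history template family with a procedure
  context block. The document title distinguishes "Quality Assurance
  Information" (carries the pacemaker label) from "Prosthesis Information",
  so cohort queries can target either, and the StudyDate is set to the
  procedure date so temporal queries work.

All builders are pure functions of (record, context, UID seed): identical
inputs yield byte-identical DICOM output.
"""

from __future__ import annotations

import datetime as _dt
import enum
import json
from dataclasses import dataclass, field
from typing import List, Optional, Tuple, Union

import pandas as pd

from . import concepts as C
from .coding import CodedConcept
from .content import ContentItem, Relationship, add_child
from .document import EvidenceRef, PatientContext, SRDocument
from .ecg import ECGRecord, EncodedWaveform, ecg_to_waveform
from .templates import PROCEDURE_REPORTED, WAVEFORM_ACQUISITION
from .uids import UIDGenerator


class TobaccoStatus(str, enum.Enum):
    YES = "YES"
    NO = "NO"
    UNKNOWN = "UNKNOWN"


class OutcomeSource(str, enum.Enum):
    QUALITY_ASSURANCE = "QUALITY_ASSURANCE"
    BILLING = "BILLING"


_TOBACCO_CODES = {TobaccoStatus.YES: C.YES, TobaccoStatus.NO: C.NO,
                  TobaccoStatus.UNKNOWN: C.UNKNOWN}
_SOURCE_CODES = {OutcomeSource.QUALITY_ASSURANCE: C.SOURCE_QUALITY_ASSURANCE,
                 OutcomeSource.BILLING: C.SOURCE_BILLING}


@dataclass(frozen=True)
class PatientHistoryRecord:
    patient_id: str
    prior_cardiac_surgery: Optional[bool] = None
    diabetes_mellitus: Optional[bool] = None
    tobacco_smoker: Optional[TobaccoStatus] = None
    medical_device_use: Tuple[Tuple[CodedConcept, Optional[_dt.date]], ...] = ()
    free_text_notes: Optional[str] = None
    acquisition_year: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id is required")
        object.__setattr__(self, "medical_device_use",
                           tuple(self.medical_device_use))


@dataclass(frozen=True)
class ProcedureOutcomeRecord:
    patient_id: str
    procedure_date: _dt.date
    source: OutcomeSource
    prosthesis_info: Optional[Tuple[CodedConcept, float]] = None  # (model, size mm)
    pacemaker_implanted: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id is required")
        # the pacemaker label originates from reimbursement (billing) coding
        if self.pacemaker_implanted is not None \
                and self.source is not OutcomeSource.BILLING:
            raise ValueError(
                "pacemaker_implanted is only carried by BILLING-sourced records")


@dataclass(frozen=True)
class ECGMeasurementSet:
    ventricular_rate: Optional[float] = None  # beats/min
    qt_interval: Optional[float] = None       # ms
    pr_interval: Optional[float] = None       # ms
    qrs_duration: Optional[float] = None      # ms
    rhythm_codes: Tuple[CodedConcept, ...] = ()

    def __post_init__(self) -> None:
        for name in ("ventricular_rate", "qt_interval", "pr_interval",
                     "qrs_duration"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        object.__setattr__(self, "rhythm_codes", tuple(self.rhythm_codes))


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def ecg_report(rec: ECGRecord, meas: ECGMeasurementSet,
               *, waveform: Optional[Union[EncodedWaveform, EvidenceRef]] = None,
               uid_generator: Optional[UIDGenerator] = None,
               patient_context: Optional[PatientContext] = None) -> SRDocument:
    """Build a TID 3700 ECG report with an embedded waveform-information block.

    The waveform evidence reference is taken from ``waveform`` if given, else
    from ``rec.waveform_ref``; a record with only a raw signal is encoded on
    the fly. The report shares the waveform's study so DICOM-level matching
    holds, and its StudyDate is the ECG's study date.
    """
    if not rec.patient_id:
        raise ValueError("ECG record lacks a patient id")
    if waveform is None:
        waveform = rec.waveform_ref
    if waveform is None:
        waveform = ecg_to_waveform(rec, uid_generator=uid_generator).evidence
    ref = waveform.evidence if isinstance(waveform, EncodedWaveform) else waveform

    root = ContentItem.container(C.ECG_REPORT)
    wf = add_child(root, ContentItem.container(C.WAVEFORM_INFORMATION),
                   Relationship.CONTAINS)
    add_child(wf, ContentItem.waveform_ref(WAVEFORM_ACQUISITION,
                                           ref.sop_class_uid, ref.sop_instance_uid))
    add_child(wf, ContentItem.code(C.LEAD_SYSTEM, C.STANDARD_12_LEAD,
                                   Relationship.HAS_ACQ_CONTEXT))
    add_child(wf, ContentItem.num(C.SAMPLING_FREQUENCY, rec.sampling_frequency,
                                  C.HERTZ, Relationship.HAS_ACQ_CONTEXT))

    pairs = [(C.VENTRICULAR_RATE, meas.ventricular_rate, C.BEATS_PER_MINUTE),
             (C.QT_INTERVAL, meas.qt_interval, C.MILLISECOND),
             (C.PR_INTERVAL, meas.pr_interval, C.MILLISECOND),
             (C.QRS_DURATION, meas.qrs_duration, C.MILLISECOND)]
    present = [(n, v, u) for n, v, u in pairs if v is not None]
    if present:
        grp = add_child(root, ContentItem.container(C.ECG_GLOBAL_MEASUREMENTS),
                        Relationship.CONTAINS)
        for name, value, unit in present:
            add_child(grp, ContentItem.num(name, value, unit))
    for rhythm in meas.rhythm_codes:
        add_child(root, ContentItem.code(C.RHYTHM_FINDING, rhythm))

    return SRDocument.create(
        patient_id=rec.patient_id, study_date=rec.study_date, tid="3700",
        root=root, evidence=[ref], patient_context=patient_context,
        study_uid=ref.study_uid, uid_generator=uid_generator)


def patient_history(rec: PatientHistoryRecord,
                    *, study_date: Optional[_dt.date] = None,
                    uid_generator: Optional[UIDGenerator] = None,
                    patient_context: Optional[PatientContext] = None) -> SRDocument:
    """Build a TID 3802 cardiovascular patient history document.

    The tobacco status is a CODE item reachable at the path ending
    ("Social History", "Tobacco Smoker"). ``study_date`` is a placeholder
    (records carry no date of their own) defaulting to 2000-01-01.
    """
    root = ContentItem.container(C.CARDIOVASCULAR_PATIENT_HISTORY)
    if rec.tobacco_smoker is not None:
        soc = add_child(root, ContentItem.container(C.SOCIAL_HISTORY),
                        Relationship.CONTAINS)
        add_child(soc, ContentItem.code(C.TOBACCO_SMOKER,
                                        _TOBACCO_CODES[rec.tobacco_smoker]))
    if rec.prior_cardiac_surgery is not None:
        surg = add_child(root, ContentItem.container(C.SURGICAL_HISTORY),
                         Relationship.CONTAINS)
        add_child(surg, ContentItem.code(
            C.PRIOR_CARDIAC_SURGERY, C.YES if rec.prior_cardiac_surgery else C.NO))
    if rec.diabetes_mellitus is not None:
        add_child(root, ContentItem.code(
            C.DIABETES_MELLITUS, C.YES if rec.diabetes_mellitus else C.NO))
    for device, when in rec.medical_device_use:
        dev = add_child(root, ContentItem.container(C.MEDICAL_DEVICE_USE),
                        Relationship.CONTAINS)
        add_child(dev, ContentItem.code(C.DEVICE_ITEM, device))
        if when is not None:
            add_child(dev, ContentItem.date(C.DEVICE_DATE, when))
    if rec.free_text_notes is not None:
        add_child(root, ContentItem.text(C.COMMENT, rec.free_text_notes))
    if rec.acquisition_year is not None:
        add_child(root, ContentItem.text(C.ACQUISITION_YEAR, str(rec.acquisition_year),
                                         Relationship.HAS_ACQ_CONTEXT))

    return SRDocument.create(
        patient_id=rec.patient_id,
        study_date=study_date or _dt.date(2000, 1, 1), tid="3802",
        root=root, patient_context=patient_context, uid_generator=uid_generator)


def procedure_outcome(rec: ProcedureOutcomeRecord,
                      *, uid_generator: Optional[UIDGenerator] = None,
                      patient_context: Optional[PatientContext] = None) -> SRDocument:
    """Build a post-TAVI procedure-outcome document.

    Carries a yes/no CODE item for the pacemaker label and/or prosthesis
    model+size items inside a procedure-context block. The document title is
    "Quality Assurance Information" when the pacemaker label is present (the
    cohort queries' name for the label documents), else "Prosthesis
    Information". StudyDate is the procedure date.
    """
    if rec.pacemaker_implanted is not None or rec.prosthesis_info is None:
        tid, title = "3802_QA", C.TITLE_QA_INFORMATION
    else:
        tid, title = "3802_PROSTH", C.TITLE_PROSTHESIS_INFORMATION

    root = ContentItem.container(title)
    ctx = add_child(root, ContentItem.container(C.PROCEDURE_CONTEXT),
                    Relationship.HAS_OBS_CONTEXT)
    add_child(ctx, ContentItem.code(PROCEDURE_REPORTED, C.TAVI_PROCEDURE))
    add_child(ctx, ContentItem.date(C.PROCEDURE_DATE, rec.procedure_date))
    add_child(ctx, ContentItem.code(C.RECORD_SOURCE, _SOURCE_CODES[rec.source]))
    if rec.pacemaker_implanted is not None:
        add_child(ctx, ContentItem.code(
            C.PACEMAKER_IMPLANTATION, C.YES if rec.pacemaker_implanted else C.NO))
    if rec.prosthesis_info is not None:
        model, size_mm = rec.prosthesis_info
        add_child(ctx, ContentItem.code(C.PROSTHESIS_MODEL, model))
        add_child(ctx, ContentItem.num(C.PROSTHESIS_SIZE, size_mm, C.MILLIMETRE))

    return SRDocument.create(
        patient_id=rec.patient_id, study_date=rec.procedure_date, tid=tid,
        root=root, patient_context=patient_context, uid_generator=uid_generator)


def measurement_report(patient_id: str, study_date: _dt.date,
                       *, frame_of_reference_uid: str,
                       hinge_points: Tuple[Tuple[CodedConcept,
                                                 Tuple[float, float, float]], ...] = (),
                       membranous_septum_mm: Optional[float] = None,
                       notes: Optional[str] = None,
                       evidence: Tuple[EvidenceRef, ...] = (),
                       study_uid: Optional[str] = None,
                       uid_generator: Optional[UIDGenerator] = None,
                       patient_context: Optional[PatientContext] = None) -> SRDocument:
    """Build an image-annotation measurement report (TID 1500 style).

    Hinge points are POINT SCOORD3D items named by their cusp concept; the
    membranous septum length is a NUM item in mm. All measurements share one
    measurement group; free-text notes go next to the group at the root.
    """
    from .content import GraphicType  # local import avoids a module-level cycle

    root = ContentItem.container(C.IMAGING_MEASUREMENT_REPORT)
    grp = add_child(root, ContentItem.container(C.MEASUREMENT_GROUP),
                    Relationship.CONTAINS)
    for concept, xyz in hinge_points:
        add_child(grp, ContentItem.scoord3d(concept, GraphicType.POINT,
                                            tuple(xyz), frame_of_reference_uid))
    if membranous_septum_mm is not None:
        add_child(grp, ContentItem.num(C.MEMBRANOUS_SEPTUM,
                                       membranous_septum_mm, C.MILLIMETRE))
    if notes is not None:
        add_child(root, ContentItem.text(C.COMMENT, notes))

    return SRDocument.create(
        patient_id=patient_id, study_date=study_date, tid="1500", root=root,
        evidence=list(evidence), study_uid=study_uid,
        patient_context=patient_context, uid_generator=uid_generator)


# ---------------------------------------------------------------------------
# tabular record ingestion
# ---------------------------------------------------------------------------

HISTORY_COLUMNS = ("patient_id", "prior_cardiac_surgery", "diabetes_mellitus",
                   "tobacco_smoker", "free_text_notes", "acquisition_year")
OUTCOME_COLUMNS = ("patient_id", "procedure_date", "source",
                   "pacemaker_implanted", "prosthesis_model", "prosthesis_size")

_TRUTHY = {"1", "true", "yes", "y"}
_FALSY = {"0", "false", "no", "n"}


def _parse_bool(v) -> Optional[bool]:
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return None
    if isinstance(v, bool):
        return v
    if isinstance(v, (int, float)):  # CSV readers surface 0/1 as numbers
        if v in (0, 1):
            return bool(v)
        raise ValueError(f"cannot interpret {v!r} as a boolean")
    s = str(v).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"cannot interpret {v!r} as a boolean")


def _load_table(source, mapping: Optional[dict]) -> pd.DataFrame:
    """Read CSV (path/buffer) or JSON records; rename via field→column mapping."""
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    elif isinstance(source, (str,)) and source.lstrip().startswith(("[", "{")):
        df = pd.DataFrame(json.loads(source))
    elif hasattr(source, "read") or str(source).endswith(".csv"):
        df = pd.read_csv(source)
    elif str(source).endswith(".json"):
        with open(source) as fh:
            df = pd.DataFrame(json.load(fh))
    else:
        df = pd.read_csv(source)
    if mapping:
        df = df.rename(columns={col: fld for fld, col in mapping.items()})
    return df


def history_records_from_table(source, mapping: Optional[dict] = None
                               ) -> List[PatientHistoryRecord]:
    """Load patient-history records from CSV/JSON.

    ``mapping`` maps record field names to source column names; unmapped
    fields use the canonical names in :data:`HISTORY_COLUMNS`.
    """
    df = _load_table(source, mapping)
    records = []
    for _, row in df.iterrows():
        tob = row.get("tobacco_smoker")
        records.append(PatientHistoryRecord(
            patient_id=str(row["patient_id"]),
            prior_cardiac_surgery=_parse_bool(row.get("prior_cardiac_surgery")),
            diabetes_mellitus=_parse_bool(row.get("diabetes_mellitus")),
            tobacco_smoker=(TobaccoStatus(str(tob).upper())
                            if tob is not None and not pd.isna(tob) else None),
            free_text_notes=(str(row["free_text_notes"])
                             if "free_text_notes" in row
                             and not pd.isna(row.get("free_text_notes")) else None),
            acquisition_year=(int(row["acquisition_year"])
                              if "acquisition_year" in row
                              and not pd.isna(row.get("acquisition_year")) else None),
        ))
    return records


def outcome_records_from_table(source, mapping: Optional[dict] = None
                               ) -> List[ProcedureOutcomeRecord]:
    """Load procedure-outcome records (pacemaker label, prosthesis) from CSV/JSON."""
    df = _load_table(source, mapping)
    records = []
    for _, row in df.iterrows():
        prosth = None
        model = row.get("prosthesis_model")
        if model is not None and not pd.isna(model):
            prosth = (CodedConcept(str(model), "99SRC", str(model)),
                      float(row["prosthesis_size"]))
        records.append(ProcedureOutcomeRecord(
            patient_id=str(row["patient_id"]),
            procedure_date=_dt.date.fromisoformat(str(row["procedure_date"])),
            source=OutcomeSource(str(row["source"]).upper()),
            prosthesis_info=prosth,
            pacemaker_implanted=_parse_bool(row.get("pacemaker_implanted")),
        ))
    return records
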