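"""Synthetic multi-site TAVI-like cohort with an exact ground-truth manifest.

Each site draws, per patient, which data types exist (CT series, pre-procedure
ECG, prosthesis report, pacemaker label, hinge-point and membranous-septum
annotations, calcification and ventricle segmentations) from configurable
availability probabilities, so consortiums reproduce the qualitative pattern
of heterogeneous multi-site data holdings: some sites imaging-heavy, some
label-poor. CT series descriptions carry cardiac-phase percentage strings,
ECG dates fall before the procedure date (with optional post-procedure
distractors), and annotations always reference existing CT series.

Everything is deterministic given the site config (including its seed), and
every site ships a manifest whose truth sets are computed by exhaustive
recount of the generated objects — never from the sampling flags — so any
query result over the generated data is assertable exactly.
"""

from __future__ import annotations

import datetime as _dt
import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from . import concepts as C
from .coding import CodedConcept, code
from .clinical import (ECGMeasurementSet, OutcomeSource, PatientHistoryRecord,
                       ProcedureOutcomeRecord, TobaccoStatus, ecg_report,
                       measurement_report, patient_history, procedure_outcome)
from .dicom_io import to_dicom
from .document import EvidenceRef, SRDocument
from .ecg import ECGRecord, ecg_to_waveform
from .indexing import SeriesRecord
from .seg import (Segment, SegAlgorithmType, SegContext, SegmentationObject,
                  build_seg, read_seg)
from .uids import UIDGenerator

CT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.2"

PROSTHESIS_MODELS = (
    code("PROSTH-M1", "99SRC", "Valve Model S3"),
    code("PROSTH-M2", "99SRC", "Valve Model ER"),
    code("PROSTH-M3", "99SRC", "Valve Model AN"),
)
PROSTHESIS_SIZES_MM = (23.0, 26.0, 29.0)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SiteConfig:
    """Availability probabilities and vocabularies for one site."""

    site_name: str
    n_patients: int
    seed: int = 0
    p_ct: float = 0.9
    p_ecg: float = 0.75
    p_prosthesis: float = 0.6
    p_pacemaker_label: float = 0.5
    p_hinge_annotation: float = 0.35
    p_septum_annotation: float = 0.3
    p_calcification_seg: float = 0.25
    p_lvrv_seg: float = 0.25
    p_post_procedure_ecg: float = 0.2
    p_pacemaker_positive: float = 0.2  # label value given the label exists
    ct_series_choices: Tuple[int, ...] = (1, 2, 3)
    phase_percentages: Tuple[str, ...] = ("0%", "40%", "70%")
    manufacturers: Tuple[str, ...] = ("ACME CT", "MedScan")
    ecg_sampling_frequencies: Tuple[float, ...] = (250.0, 500.0)
    date_start: _dt.date = _dt.date(2018, 1, 1)
    date_end: _dt.date = _dt.date(2020, 12, 31)

    def __post_init__(self) -> None:
        if not self.site_name:
            raise ConfigError("site_name must be non-empty")
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be positive")
        for f in ("p_ct", "p_ecg", "p_prosthesis", "p_pacemaker_label",
                  "p_hinge_annotation", "p_septum_annotation",
                  "p_calcification_seg", "p_lvrv_seg", "p_post_procedure_ecg",
                  "p_pacemaker_positive"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{f} must be in [0, 1], got {v}")
        if not self.ct_series_choices or min(self.ct_series_choices) < 1:
            raise ConfigError("ct_series_choices must be positive counts")
        if self.date_end < self.date_start:
            raise ConfigError("date window is empty")
        object.__setattr__(self, "ct_series_choices",
                           tuple(self.ct_series_choices))
        object.__setattr__(self, "phase_percentages",
                           tuple(self.phase_percentages))
        object.__setattr__(self, "manufacturers", tuple(self.manufacturers))
        object.__setattr__(self, "ecg_sampling_frequencies",
                           tuple(self.ecg_sampling_frequencies))


# qualitative heterogeneity presets: imaging-heavy, balanced, and label-poor
SITE_PRESETS: Dict[str, dict] = {
    "imaging-heavy": dict(p_ct=1.0, p_ecg=0.4, p_prosthesis=0.3,
                          p_pacemaker_label=0.3, p_hinge_annotation=0.6,
                          p_septum_annotation=0.5, p_calcification_seg=0.5,
                          p_lvrv_seg=0.5),
    "balanced": dict(),
    "label-poor": dict(p_ct=0.8, p_ecg=0.8, p_prosthesis=0.2,
                       p_pacemaker_label=0.15, p_hinge_annotation=0.05,
                       p_septum_annotation=0.05, p_calcification_seg=0.05,
                       p_lvrv_seg=0.05),
}


@dataclass(frozen=True)
class GeneratedObject:
    """One generated artefact, as recorded in the manifest."""

    patient_id: str
    kind: str            # CT | ECG | ECG_SR | HISTORY_SR | OUTCOME_QA_SR |
    #                      OUTCOME_BILLING_SR | ANNOTATION_SR | SEG
    series_uid: str      # attachment series for annotations, own for parents
    sop_uid: str = ""
    study_date: Optional[str] = None  # ISO
    description: str = ""
    detail: Tuple[str, ...] = ()  # e.g. segment labels, annotation fields


@dataclass
class SiteData:
    """Everything one site generated, in memory plus serialised bytes."""

    config: SiteConfig
    parents: List[SeriesRecord]
    annotations: List  # build_index-compatible entries
    files: Dict[str, bytes]
    objects: List[GeneratedObject]
    manifest: dict


def _ct_file(patient_id: str, study_uid: str, series_uid: str, sop_uid: str,
             frame_uid: str, study_date: _dt.date, description: str,
             manufacturer: str) -> bytes:
    ds = Dataset()
    ds.SOPClassUID = CT_SOP_CLASS
    ds.SOPInstanceUID = sop_uid
    ds.StudyInstanceUID = study_uid
    ds.SeriesInstanceUID = series_uid
    ds.FrameOfReferenceUID = frame_uid
    ds.Modality = "CT"
    ds.PatientID = patient_id
    ds.PatientName = ""
    ds.StudyDate = study_date.strftime("%Y%m%d")
    ds.StudyTime = "000000"
    ds.SeriesDescription = description
    ds.Manufacturer = manufacturer
    ds.BodyPartExamined = "HEART"
    ds.AccessionNumber = ""
    ds.ReferringPhysicianName = ""
    ds.StudyID = "1"
    ds.SeriesNumber = 1
    ds.InstanceNumber = 1
    ds.ImageType = ["ORIGINAL", "PRIMARY"]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows = 2
    ds.Columns = 2
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = (b"\x00\x00" * 4)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CT_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta = meta
    buf = io.BytesIO()
    from pydicom import dcmwrite
    dcmwrite(buf, ds, enforce_file_format=True)
    return buf.getvalue()


def _synthetic_leads(rng: np.random.Generator, n_samples: int,
                     fs: float) -> List[Tuple[str, np.ndarray]]:
    t = np.arange(n_samples) / fs
    leads = []
    for i, name in enumerate(C.STANDARD_LEADS):
        f = 0.8 + 0.2 * i + float(rng.uniform(0, 0.3))
        amp = float(rng.integers(30, 150)) * 10.0  # µV, on the 10 µV grid
        sig = np.round(amp * np.sin(2 * np.pi * f * t) / 10.0) * 10.0
        leads.append((name, sig))
    return leads


def _rand_date(rng: np.random.Generator, start: _dt.date,
               end: _dt.date) -> _dt.date:
    span = (end - start).days
    return start + _dt.timedelta(days=int(rng.integers(0, span + 1)))


def generate_site(cfg: SiteConfig) -> SiteData:
    """Generate one site's objects, files, and exact-truth manifest."""
    rng = np.random.default_rng(cfg.seed)
    gen = UIDGenerator(int(rng.integers(0, 2**63 - 1)))

    parents: List[SeriesRecord] = []
    annotations: List = []
    files: Dict[str, bytes] = {}
    objects: List[GeneratedObject] = []
    procedure_dates: Dict[str, str] = {}

    def bern(p: float) -> bool:
        return bool(rng.random() < p)

    for i in range(cfg.n_patients):
        pid = f"{cfg.site_name}-{i:04d}"
        proc_date = _rand_date(rng, cfg.date_start, cfg.date_end)
        procedure_dates[pid] = proc_date.isoformat()

        # --- CT series ---------------------------------------------------
        ct_series: List[SeriesRecord] = []
        ct_sop: Dict[str, str] = {}
        frame_uid = None
        if bern(cfg.p_ct):
            study_uid = gen()
            frame_uid = gen()
            ct_date = proc_date - _dt.timedelta(days=int(rng.integers(5, 90)))
            n_series = int(rng.choice(np.asarray(cfg.ct_series_choices)))
            for _ in range(n_series):
                phase = cfg.phase_percentages[
                    int(rng.integers(0, len(cfg.phase_percentages)))]
                manu = cfg.manufacturers[
                    int(rng.integers(0, len(cfg.manufacturers)))]
                series_uid, sop_uid = gen(), gen()
                desc = f"CorCTA {phase} cardiac phase"
                rec = SeriesRecord(pid, study_uid, series_uid, "CT", desc,
                                   ct_date, manu, "HEART")
                ct_series.append(rec)
                ct_sop[series_uid] = sop_uid
                parents.append(rec)
                files[f"{pid}/ct_{series_uid}.dcm"] = _ct_file(
                    pid, study_uid, series_uid, sop_uid, frame_uid, ct_date,
                    desc, manu)
                objects.append(GeneratedObject(pid, "CT", series_uid, sop_uid,
                                               ct_date.isoformat(), desc))

        # --- ECGs ----------------------------------------------------------
        def make_ecg(ecg_date: _dt.date, tag: str) -> None:
            fs = cfg.ecg_sampling_frequencies[
                int(rng.integers(0, len(cfg.ecg_sampling_frequencies)))]
            leads = _synthetic_leads(rng, int(fs * 2), fs)
            rec = ECGRecord(pid, _dt.datetime.combine(ecg_date, _dt.time(8, 0)),
                            fs, leads, ecg_date)
            wf = ecg_to_waveform(rec, uid_generator=gen)
            parents.append(SeriesRecord(pid, wf.study_uid, wf.series_uid,
                                        "ECG", f"12-lead resting ECG {tag}",
                                        ecg_date))
            files[f"{pid}/ecg_{wf.series_uid}.dcm"] = wf.data
            objects.append(GeneratedObject(pid, "ECG", wf.series_uid,
                                           wf.sop_uid, ecg_date.isoformat()))
            meas = ECGMeasurementSet(
                ventricular_rate=float(rng.integers(45, 110)),
                qt_interval=float(rng.integers(340, 480)),
                rhythm_codes=((C.LEFT_BUNDLE_BRANCH_BLOCK,)
                              if bern(0.2) else (C.SINUS_RHYTHM,)))
            sr = ecg_report(rec, meas, waveform=wf, uid_generator=gen)
            annotations.append((sr, wf.series_uid))
            files[f"{pid}/ecg_sr_{sr.sop_uid}.dcm"] = to_dicom(sr)
            objects.append(GeneratedObject(
                pid, "ECG_SR", wf.series_uid, sr.sop_uid,
                ecg_date.isoformat(),
                detail=tuple(c.meaning for c in meas.rhythm_codes)))

        if bern(cfg.p_ecg):
            make_ecg(proc_date - _dt.timedelta(days=int(rng.integers(1, 60))),
                     "pre")
        if bern(cfg.p_post_procedure_ecg):
            make_ecg(proc_date + _dt.timedelta(days=int(rng.integers(1, 30))),
                     "post")

        # --- quality-assurance history (every patient) ----------------------
        hist_rec = PatientHistoryRecord(
            pid,
            diabetes_mellitus=bern(0.3),
            tobacco_smoker=[TobaccoStatus.YES, TobaccoStatus.NO,
                            TobaccoStatus.UNKNOWN][int(rng.integers(0, 3))],
            acquisition_year=proc_date.year)
        hist = patient_history(hist_rec, uid_generator=gen)
        parents.append(SeriesRecord(pid, hist.study_uid, hist.series_uid, "SR",
                                    "patient history", hist.study_date))
        annotations.append((hist, hist.series_uid))
        files[f"{pid}/history_{hist.sop_uid}.dcm"] = to_dicom(hist)
        objects.append(GeneratedObject(
            pid, "HISTORY_SR", hist.series_uid, hist.sop_uid,
            hist.study_date.isoformat(),
            detail=(hist_rec.tobacco_smoker.value,)))

        # --- outcome documents ----------------------------------------------
        if bern(cfg.p_prosthesis):
            model = PROSTHESIS_MODELS[int(rng.integers(0, len(PROSTHESIS_MODELS)))]
            size = PROSTHESIS_SIZES_MM[int(rng.integers(0, len(PROSTHESIS_SIZES_MM)))]
            out = procedure_outcome(
                ProcedureOutcomeRecord(pid, proc_date,
                                       OutcomeSource.QUALITY_ASSURANCE,
                                       prosthesis_info=(model, size)),
                uid_generator=gen)
            parents.append(SeriesRecord(pid, out.study_uid, out.series_uid,
                                        "SR", "prosthesis info", proc_date))
            annotations.append((out, out.series_uid))
            files[f"{pid}/prosthesis_{out.sop_uid}.dcm"] = to_dicom(out)
            objects.append(GeneratedObject(
                pid, "OUTCOME_QA_SR", out.series_uid, out.sop_uid,
                proc_date.isoformat(), detail=(model.meaning, str(size))))
        if bern(cfg.p_pacemaker_label):
            implanted = bern(cfg.p_pacemaker_positive)
            out = procedure_outcome(
                ProcedureOutcomeRecord(pid, proc_date, OutcomeSource.BILLING,
                                       pacemaker_implanted=implanted),
                uid_generator=gen)
            parents.append(SeriesRecord(pid, out.study_uid, out.series_uid,
                                        "SR", "billing outcome", proc_date))
            annotations.append((out, out.series_uid))
            files[f"{pid}/billing_{out.sop_uid}.dcm"] = to_dicom(out)
            objects.append(GeneratedObject(
                pid, "OUTCOME_BILLING_SR", out.series_uid, out.sop_uid,
                proc_date.isoformat(),
                detail=("Yes" if implanted else "No",)))

        # --- annotations on CT series ---------------------------------------
        if ct_series:
            target = ct_series[int(rng.integers(0, len(ct_series)))]
            target_ev = (EvidenceRef(target.study_uid, target.series_uid,
                                     CT_SOP_CLASS, ct_sop[target.series_uid]),)
            if bern(cfg.p_hinge_annotation):
                cusps = ((C.RIGHT_CORONARY_CUSP, C.LEFT_CORONARY_CUSP,
                          C.NON_CORONARY_CUSP))
                pts = tuple((c, tuple(float(x) for x in rng.uniform(-50, 50, 3)))
                            for c in cusps)
                sr = measurement_report(pid, target.study_date,
                                        frame_of_reference_uid=frame_uid,
                                        hinge_points=pts,
                                        evidence=target_ev,
                                        study_uid=target.study_uid,
                                        uid_generator=gen)
                annotations.append((sr, target.series_uid))
                files[f"{pid}/hinge_{sr.sop_uid}.dcm"] = to_dicom(sr)
                objects.append(GeneratedObject(
                    pid, "ANNOTATION_SR", target.series_uid, sr.sop_uid,
                    target.study_date.isoformat(),
                    detail=tuple(c.meaning for c, _ in pts)))
            if bern(cfg.p_septum_annotation):
                sr = measurement_report(
                    pid, target.study_date,
                    frame_of_reference_uid=frame_uid,
                    membranous_septum_mm=round(float(rng.uniform(2, 12)), 1),
                    evidence=target_ev, study_uid=target.study_uid,
                    uid_generator=gen)
                annotations.append((sr, target.series_uid))
                files[f"{pid}/septum_{sr.sop_uid}.dcm"] = to_dicom(sr)
                objects.append(GeneratedObject(
                    pid, "ANNOTATION_SR", target.series_uid, sr.sop_uid,
                    target.study_date.isoformat(),
                    detail=(C.MEMBRANOUS_SEPTUM.meaning,)))

            mask = np.zeros((1, 4, 4), bool)
            mask[0, 1:3, 1:3] = True
            ctx = SegContext(pid, target.study_date,
                             study_uid=target.study_uid,
                             frame_of_reference_uid=frame_uid)
            if bern(cfg.p_calcification_seg):
                seg = SegmentationObject(target.series_uid,
                                         [Segment(1, C.CALCIFICATION,
                                                  SegAlgorithmType.AUTOMATIC)],
                                         [mask])
                blob = build_seg(seg, ctx, gen)
                seg = read_seg(blob)
                annotations.append(seg)
                files[f"{pid}/seg_calc_{seg.sop_uid}.dcm"] = blob
                objects.append(GeneratedObject(
                    pid, "SEG", target.series_uid, seg.sop_uid,
                    target.study_date.isoformat(),
                    detail=(C.CALCIFICATION.meaning,)))
            if bern(cfg.p_lvrv_seg):
                # sometimes both ventricles in one object, sometimes split
                # across two children of the same series — the two cases
                # separate nested from flattened query semantics
                if bern(0.5):
                    groups = [[C.LEFT_VENTRICLE, C.RIGHT_VENTRICLE]]
                else:
                    groups = [[C.LEFT_VENTRICLE], [C.RIGHT_VENTRICLE]]
                for labels in groups:
                    seg = SegmentationObject(
                        target.series_uid,
                        [Segment(n + 1, lab) for n, lab in enumerate(labels)],
                        [mask] * len(labels))
                    blob = build_seg(seg, ctx, gen)
                    seg = read_seg(blob)
                    annotations.append(seg)
                    files[f"{pid}/seg_vent_{seg.sop_uid}.dcm"] = blob
                    objects.append(GeneratedObject(
                        pid, "SEG", target.series_uid, seg.sop_uid,
                        target.study_date.isoformat(),
                        detail=tuple(lab.meaning for lab in labels)))

    manifest = _build_manifest(cfg, parents, objects, procedure_dates)
    return SiteData(cfg, parents, annotations, files, objects, manifest)


def _build_manifest(cfg: SiteConfig, parents: Sequence[SeriesRecord],
                    objects: Sequence[GeneratedObject],
                    procedure_dates: Dict[str, str]) -> dict:
    """Truth sets by exhaustive recount of the generated object list."""
    pids = sorted(procedure_dates)
    ct_patients = {o.patient_id for o in objects if o.kind == "CT"}
    ecg_patients = {o.patient_id for o in objects if o.kind == "ECG"}

    series_with_phase = {
        phase: sorted({p.series_uid for p in parents
                       if phase in p.series_description})
        for phase in cfg.phase_percentages}

    hinge = sorted({o.series_uid for o in objects
                    if o.kind == "ANNOTATION_SR"
                    and C.RIGHT_CORONARY_CUSP.meaning in o.detail})
    septum = sorted({o.series_uid for o in objects
                     if o.kind == "ANNOTATION_SR"
                     and C.MEMBRANOUS_SEPTUM.meaning in o.detail})
    calc = sorted({o.series_uid for o in objects
                   if o.kind == "SEG" and C.CALCIFICATION.meaning in o.detail})

    lv, rv = C.LEFT_VENTRICLE.meaning, C.RIGHT_VENTRICLE.meaning
    lvrv_nested = sorted({o.series_uid for o in objects
                          if o.kind == "SEG" and lv in o.detail
                          and rv in o.detail})
    pooled: Dict[str, set] = {}
    for o in objects:
        if o.kind == "SEG":
            pooled.setdefault(o.series_uid, set()).update(o.detail)
    lvrv_flattened = sorted(s for s, labels in pooled.items()
                            if lv in labels and rv in labels)

    pacemaker_patients = sorted({o.patient_id for o in objects
                                 if o.kind == "OUTCOME_BILLING_SR"})

    pre_ecg: Dict[str, Optional[str]] = {}
    for pid in pids:
        proc = _dt.date.fromisoformat(procedure_dates[pid])
        cands = [(p.study_date, p.series_uid) for p in parents
                 if p.patient_id == pid and p.modality == "ECG"
                 and p.study_date is not None and p.study_date <= proc]
        pre_ecg[pid] = (min(cands, key=lambda c: (-c[0].toordinal(), c[1]))[1]
                        if cands else None)

    return {
        "site_name": cfg.site_name,
        "seed": cfg.seed,
        "patient_ids": pids,
        "procedure_dates": procedure_dates,
        "objects": [asdict(o) for o in objects],
        "truth": {
            "patients_ct_and_ecg": sorted(ct_patients & ecg_patients),
            "series_with_phase": series_with_phase,
            "series_with_hinge_annotation": hinge,
            "series_with_septum_annotation": septum,
            "series_with_calcification_seg": calc,
            "series_with_lv_and_rv_nested": lvrv_nested,
            "series_with_lv_and_rv_flattened": lvrv_flattened,
            "patients_with_pacemaker_label": pacemaker_patients,
            "pre_procedure_ecg": pre_ecg,
        },
    }


def generate_consortium(cfgs: Sequence[SiteConfig]) -> List[SiteData]:
    """Generate all sites; site names double as patient-id namespaces."""
    names = [c.site_name for c in cfgs]
    if len(set(names)) != len(names):
        raise ConfigError(f"duplicate site names: {sorted(names)}")
    for a in names:
        for b in names:
            if a != b and (a.startswith(b + "-") or b.startswith(a + "-")):
                raise ConfigError(
                    f"site names {a!r} and {b!r} produce overlapping patient "
                    "id namespaces")
    return [generate_site(c) for c in cfgs]


def write_site(site: SiteData, out_dir) -> Path:
    """Write the site's DICOM tree plus ``manifest.json``; returns its root."""
    root = Path(out_dir) / site.config.site_name
    for rel, blob in site.files.items():
        p = root / rel
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_bytes(blob)
    (root / "manifest.json").write_text(
        json.dumps(site.manifest, indent=2, sort_keys=True))
    return root


_DATE_FIELDS = ("date_start", "date_end")
_TUPLE_FIELDS = ("ct_series_choices", "phase_percentages", "manufacturers",
                 "ecg_sampling_frequencies")


def consortium_from_yaml(path) -> List[SiteConfig]:
    """Load a consortium config: ``sites:`` list, optional ``preset`` names."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "sites" not in data:
        raise ConfigError("consortium config needs a top-level 'sites' list")
    cfgs = []
    for s in data["sites"]:
        s = dict(s)
        preset = s.pop("preset", None)
        if preset is not None:
            if preset not in SITE_PRESETS:
                raise ConfigError(f"unknown preset {preset!r}; "
                                  f"available: {sorted(SITE_PRESETS)}")
            merged = dict(SITE_PRESETS[preset])
            merged.update(s)
            s = merged
        for f in _DATE_FIELDS:
            if f in s and isinstance(s[f], str):
                s[f] = _dt.date.fromisoformat(s[f])
        for f in _TUPLE_FIELDS:
            if f in s:
                s[f] = tuple(s[f])
        try:
            cfgs.append(SiteConfig(**s))
        except TypeError as exc:
            raise ConfigError(f"bad site config: {exc}") from exc
    if not cfgs:
        raise ConfigError("consortium config has no sites")
    names = [c.site_name for c in cfgs]
    if len(set(names)) != len(names):
        raise ConfigError(f"duplicate site names: {sorted(names)}")
    return cfgs
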