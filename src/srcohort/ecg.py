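"""ECG ingestion from heterogeneous dialects and DICOM waveform encoding.

Clinical ECG exports arrive in wildly different containers — vendor XML,
SCP-ECG style binaries, HDF5, plain CSV. :func:`read_ecg` normalizes all of
them into one :class:`ECGRecord` (signals in microvolts, canonical 12-lead
order preserved as given). :func:`ecg_to_waveform` encodes a record as a DICOM
12-lead ECG waveform object with 16-bit signed samples and per-lead
power-of-ten sensitivity, so a round trip reproduces every sample within one
quantization step; the temporal placement of the ECG is carried by the
StudyDate attribute.

Dialect schemas (all fixtures are generated by the paired writers):

* ``CSV`` — header row of lead names, one sample per row; metadata in a JSON
  sidecar: ``patient_id``, ``sampling_frequency_hz``, ``amplitude_unit``
  (``microvolt``/``millivolt``), ``acquisition_datetime``, ``study_date``.
* ``XML`` — ``<ecg patient_id=… sampling_frequency_hz=… amplitude_unit=…
  acquisition_datetime=… study_date=…>`` with one ``<lead name=…>`` element of
  whitespace-separated samples per lead.
* ``HDF5`` — root attributes as above; datasets ``signals`` (leads × samples)
  and ``lead_names``.
* ``SCP`` — the documented binary subset in :mod:`srcohort.scp` (always µV).
"""

from __future__ import annotations

import datetime as _dt
import enum
import io
import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import h5py
import numpy as np
from lxml import etree
from pydicom import dcmread, dcmwrite
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian

from . import concepts as C
from . import scp as _scp
from .coding import CodedConcept
from .document import EvidenceRef
from .uids import UIDGenerator, new_uid

TWELVE_LEAD_ECG_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.9.1.1"
STANDARD_LEADS = C.STANDARD_LEADS


class ECGDialect(str, enum.Enum):
    XML = "XML"
    SCP = "SCP"
    HDF5 = "HDF5"
    CSV = "CSV"


class AmplitudeUnit(str, enum.Enum):
    MICROVOLT = "microvolt"
    MILLIVOLT = "millivolt"


class ECGParseError(ValueError):
    pass


class AmplitudeRangeError(ValueError):
    """Signal exceeds the representable 16-bit range at the requested sensitivity."""


@dataclass(eq=False)
class ECGRecord:
    """A normalized 12-lead ECG: per-lead sample arrays in a common unit."""

    patient_id: str
    acquisition_datetime: _dt.datetime
    sampling_frequency: float
    leads: List[Tuple[str, np.ndarray]]
    study_date: _dt.date
    amplitude_unit: AmplitudeUnit = AmplitudeUnit.MICROVOLT
    waveform_ref: Optional[EvidenceRef] = None

    def __post_init__(self) -> None:
        if self.sampling_frequency <= 0:
            raise ECGParseError("sampling frequency must be positive")
        names = [n for n, _ in self.leads]
        if len(set(names)) != len(names):
            raise ECGParseError("lead names must be unique")
        unknown = [n for n in names if n not in STANDARD_LEADS]
        if unknown:
            raise ECGParseError(f"unknown lead name(s): {unknown}")
        lengths = {len(s) for _, s in self.leads}
        if len(lengths) > 1:
            raise ECGParseError(f"leads have inconsistent lengths: {sorted(lengths)}")
        self.leads = [(n, np.asarray(s, dtype=float)) for n, s in self.leads]

    @property
    def lead_names(self) -> List[str]:
        return [n for n, _ in self.leads]

    @property
    def n_samples(self) -> int:
        return len(self.leads[0][1]) if self.leads else 0

    def in_microvolts(self) -> "ECGRecord":
        if self.amplitude_unit is AmplitudeUnit.MICROVOLT:
            return self
        return ECGRecord(self.patient_id, self.acquisition_datetime,
                         self.sampling_frequency,
                         [(n, s * 1000.0) for n, s in self.leads],
                         self.study_date, AmplitudeUnit.MICROVOLT,
                         self.waveform_ref)

    def signal_matrix(self) -> np.ndarray:
        return np.asarray([s for _, s in self.leads], dtype=float)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ECGRecord):
            return NotImplemented
        return (self.patient_id == other.patient_id
                and self.acquisition_datetime == other.acquisition_datetime
                and self.sampling_frequency == other.sampling_frequency
                and self.study_date == other.study_date
                and self.amplitude_unit == other.amplitude_unit
                and self.lead_names == other.lead_names
                and all(np.array_equal(a, b) for (_, a), (_, b)
                        in zip(self.leads, other.leads)))


# ---------------------------------------------------------------------------
# dialect readers / writers
# ---------------------------------------------------------------------------

def _require(meta: dict, key: str, dialect: str):
    if key not in meta or meta[key] in (None, ""):
        raise ECGParseError(f"{dialect}: missing required metadata field {key!r}")
    return meta[key]


def _meta_fields(meta: dict, dialect: str) -> dict:
    return {
        "patient_id": str(_require(meta, "patient_id", dialect)),
        "sampling_frequency": float(_require(meta, "sampling_frequency_hz", dialect)),
        "amplitude_unit": AmplitudeUnit(str(meta.get("amplitude_unit", "microvolt"))),
        "acquisition_datetime": _dt.datetime.fromisoformat(
            str(_require(meta, "acquisition_datetime", dialect))),
        "study_date": _dt.date.fromisoformat(str(_require(meta, "study_date", dialect))),
    }


def _check_leads(names: Sequence[str], dialect: str) -> None:
    missing = [n for n in STANDARD_LEADS if n not in names]
    if missing:
        raise ECGParseError(f"{dialect}: missing standard lead(s): {missing}")


def read_ecg(source: bytes, dialect: ECGDialect | str,
             sidecar: Optional[bytes | dict] = None) -> ECGRecord:
    """Parse a dialect-conformant byte stream into a µV-normalized record.

    ``sidecar`` carries the CSV metadata JSON (bytes or pre-parsed dict); the
    other dialects are self-contained.
    """
    dialect = ECGDialect(str(dialect).upper())
    if dialect is ECGDialect.CSV:
        if sidecar is None:
            raise ECGParseError("CSV: metadata sidecar JSON is required")
        meta = sidecar if isinstance(sidecar, dict) else json.loads(sidecar)
        fields = _meta_fields(meta, "CSV")
        text = source.decode()
        lines = [ln for ln in text.splitlines() if ln.strip()]
        names = [h.strip() for h in lines[0].split(",")]
        _check_leads(names, "CSV")
        try:
            data = np.array([[float(x) for x in ln.split(",")] for ln in lines[1:]])
        except ValueError as exc:
            raise ECGParseError(f"CSV: bad sample value: {exc}") from exc
        if data.ndim != 2 or data.shape[1] != len(names):
            raise ECGParseError("CSV: ragged sample rows")
        leads = [(n, data[:, i]) for i, n in enumerate(names)]
    elif dialect is ECGDialect.XML:
        try:
            root = etree.fromstring(source)
        except etree.XMLSyntaxError as exc:
            raise ECGParseError(f"XML: not well-formed: {exc}") from exc
        fields = _meta_fields(dict(root.attrib), "XML")
        leads = []
        for el in root.findall("lead"):
            name = el.get("name")
            samples = np.array([float(x) for x in (el.text or "").split()])
            leads.append((name, samples))
        _check_leads([n for n, _ in leads], "XML")
    elif dialect is ECGDialect.HDF5:
        try:
            with h5py.File(io.BytesIO(source), "r") as f:
                meta = {k: (v.decode() if isinstance(v, bytes) else v)
                        for k, v in f.attrs.items()}
                fields = _meta_fields(meta, "HDF5")
                names = [n.decode() if isinstance(n, bytes) else str(n)
                         for n in f["lead_names"][()]]
                signals = np.asarray(f["signals"][()], dtype=float)
        except (OSError, KeyError) as exc:
            raise ECGParseError(f"HDF5: unreadable layout: {exc}") from exc
        _check_leads(names, "HDF5")
        if signals.shape[0] != len(names):
            raise ECGParseError("HDF5: signals/lead_names shape mismatch")
        leads = list(zip(names, signals))
    elif dialect is ECGDialect.SCP:
        try:
            parsed = _scp.read_scp(source)
        except _scp.SCPFormatError as exc:
            raise ECGParseError(f"SCP: {exc}") from exc
        _check_leads([n for n, _ in parsed["leads"]], "SCP")
        fields = {
            "patient_id": parsed["patient_id"],
            "sampling_frequency": parsed["sampling_frequency"],
            "amplitude_unit": AmplitudeUnit.MICROVOLT,
            "acquisition_datetime": parsed["acquisition_datetime"],
            "study_date": parsed["study_date"],
        }
        leads = parsed["leads"]
    else:  # pragma: no cover
        raise ECGParseError(f"unsupported dialect {dialect}")

    rec = ECGRecord(fields["patient_id"], fields["acquisition_datetime"],
                    fields["sampling_frequency"], list(leads), fields["study_date"],
                    fields["amplitude_unit"])
    return rec.in_microvolts()


def write_ecg(rec: ECGRecord, dialect: ECGDialect | str) -> Tuple[bytes, Optional[bytes]]:
    """Serialise a record into a dialect; returns (stream, sidecar-or-None).

    The writers exist so that fixtures and synthetic cohorts can be produced
    programmatically; together with :func:`read_ecg` they make the dialect
    contract testable (same signal through every dialect → equal records).
    """
    dialect = ECGDialect(str(dialect).upper())
    rec = rec.in_microvolts()
    meta = {
        "patient_id": rec.patient_id,
        "sampling_frequency_hz": rec.sampling_frequency,
        "amplitude_unit": "microvolt",
        "acquisition_datetime": rec.acquisition_datetime.isoformat(),
        "study_date": rec.study_date.isoformat(),
    }
    if dialect is ECGDialect.CSV:
        header = ",".join(rec.lead_names)
        mat = rec.signal_matrix().T
        body = "\n".join(",".join(format(x, ".17g") for x in row) for row in mat)
        return (header + "\n" + body + "\n").encode(), json.dumps(meta).encode()
    if dialect is ECGDialect.XML:
        root = etree.Element("ecg", {k: str(v) for k, v in meta.items()})
        for name, sig in rec.leads:
            el = etree.SubElement(root, "lead", name=name)
            el.text = " ".join(format(x, ".17g") for x in sig)
        return etree.tostring(root, xml_declaration=True, encoding="UTF-8"), None
    if dialect is ECGDialect.HDF5:
        buf = io.BytesIO()
        with h5py.File(buf, "w") as f:
            for k, v in meta.items():
                f.attrs[k] = v
            f.create_dataset("lead_names",
                             data=np.array(rec.lead_names, dtype="S"))
            f.create_dataset("signals", data=rec.signal_matrix())
        return buf.getvalue(), None
    if dialect is ECGDialect.SCP:
        return _scp.write_scp(rec.patient_id, rec.acquisition_datetime,
                              rec.study_date, rec.sampling_frequency,
                              rec.leads), None
    raise ECGParseError(f"unsupported dialect {dialect}")  # pragma: no cover


# ---------------------------------------------------------------------------
# DICOM waveform encoding
# ---------------------------------------------------------------------------

def pick_sensitivity(signal_uv: np.ndarray) -> float:
    """Smallest power-of-ten µV/LSB step representing the signal in int16."""
    peak = float(np.max(np.abs(signal_uv))) if signal_uv.size else 0.0
    step = 0.001  # 1 nV floor
    while peak / step > 32767:
        step *= 10.0
    return step


@dataclass(frozen=True)
class EncodedWaveform:
    """A serialised 12-lead waveform object plus its locating UIDs."""

    data: bytes
    study_uid: str
    series_uid: str
    sop_uid: str
    sop_class_uid: str = TWELVE_LEAD_ECG_SOP_CLASS

    @property
    def evidence(self) -> EvidenceRef:
        return EvidenceRef(self.study_uid, self.series_uid,
                           self.sop_class_uid, self.sop_uid)


def _fmt_ds(x: float) -> str:
    s = format(x, ".10g")
    return s


def ecg_to_waveform(rec: ECGRecord, *, uid_generator: Optional[UIDGenerator] = None,
                    study_uid: Optional[str] = None,
                    sensitivity: Optional[float] = None) -> EncodedWaveform:
    """Encode a record as a DICOM 12-lead ECG waveform object.

    Samples are stored as 16-bit signed integers with a per-lead sensitivity
    (µV per LSB), chosen as the smallest power of ten covering each lead's
    range unless ``sensitivity`` forces a common value. A forced sensitivity
    that cannot represent the signal raises :class:`AmplitudeRangeError`
    rather than clipping.
    """
    rec = rec.in_microvolts()
    if not np.all(np.isfinite(rec.signal_matrix())):
        raise AmplitudeRangeError("signal contains non-finite samples")
    gen = uid_generator
    study = study_uid or new_uid(gen)
    series = new_uid(gen)
    sop = new_uid(gen)

    mux = Dataset()
    mux.WaveformOriginality = "ORIGINAL"
    mux.NumberOfWaveformChannels = len(rec.leads)
    mux.NumberOfWaveformSamples = rec.n_samples
    mux.SamplingFrequency = _fmt_ds(rec.sampling_frequency)
    mux.MultiplexGroupLabel = "RHYTHM"
    mux.ChannelDefinitionSequence = []
    quantized = np.empty((len(rec.leads), rec.n_samples), dtype="<i2")
    for i, (name, sig) in enumerate(rec.leads):
        step = sensitivity if sensitivity is not None else pick_sensitivity(sig)
        ints = np.round(sig / step)
        if np.any(np.abs(ints) > 32767):
            raise AmplitudeRangeError(
                f"lead {name}: amplitude exceeds int16 range at sensitivity "
                f"{step} µV/LSB")
        quantized[i] = ints.astype("<i2")
        ch = Dataset()
        src = Dataset()
        lead = C.LEAD_CODES[name]
        src.CodeValue = lead.value
        src.CodingSchemeDesignator = lead.scheme
        src.CodeMeaning = lead.meaning
        ch.ChannelSourceSequence = [src]
        ch.ChannelSensitivity = _fmt_ds(step)
        unit = Dataset()
        unit.CodeValue = C.MICROVOLT.value
        unit.CodingSchemeDesignator = C.MICROVOLT.scheme
        unit.CodeMeaning = C.MICROVOLT.meaning
        ch.ChannelSensitivityUnitsSequence = [unit]
        ch.ChannelBaseline = "0"
        ch.ChannelSensitivityCorrectionFactor = "1"
        ch.ChannelSampleSkew = "0"
        ch.WaveformBitsStored = 16
        mux.ChannelDefinitionSequence.append(ch)
    mux.WaveformBitsAllocated = 16
    mux.WaveformSampleInterpretation = "SS"
    mux.WaveformData = quantized.T.tobytes()  # channel-interleaved, sample-major

    ds = Dataset()
    ds.SOPClassUID = TWELVE_LEAD_ECG_SOP_CLASS
    ds.SOPInstanceUID = sop
    ds.StudyInstanceUID = study
    ds.SeriesInstanceUID = series
    ds.Modality = "ECG"
    ds.SeriesNumber = 1
    ds.InstanceNumber = 1
    ds.PatientID = rec.patient_id
    ds.PatientName = ""
    ds.StudyDate = rec.study_date.strftime("%Y%m%d")
    ds.StudyTime = "000000"
    ds.ContentDate = rec.acquisition_datetime.strftime("%Y%m%d")
    ds.ContentTime = rec.acquisition_datetime.strftime("%H%M%S")
    ds.AcquisitionDateTime = rec.acquisition_datetime.strftime("%Y%m%d%H%M%S")
    ds.AccessionNumber = ""
    ds.ReferringPhysicianName = ""
    ds.StudyID = "1"
    ds.Manufacturer = "srcohort"
    ds.WaveformSequence = [mux]

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = TWELVE_LEAD_ECG_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = sop
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta = meta

    buf = io.BytesIO()
    dcmwrite(buf, ds, enforce_file_format=True)
    return EncodedWaveform(buf.getvalue(), study, series, sop)


def waveform_to_ecg(data: bytes) -> ECGRecord:
    """Decode a DICOM 12-lead waveform object back into a µV record."""
    try:
        ds = dcmread(io.BytesIO(data))
    except Exception as exc:
        raise ECGParseError(f"not a readable DICOM stream: {exc}") from exc
    if str(getattr(ds, "SOPClassUID", "")) != TWELVE_LEAD_ECG_SOP_CLASS:
        raise ECGParseError("not a 12-lead ECG waveform object")
    mux = ds.WaveformSequence[0]
    n_ch = int(mux.NumberOfWaveformChannels)
    n = int(mux.NumberOfWaveformSamples)
    raw = np.frombuffer(mux.WaveformData, dtype="<i2").reshape(n, n_ch).T
    name_by_code = {(c.value, c.scheme): n for n, c in C.LEAD_CODES.items()}
    leads = []
    for i, ch in enumerate(mux.ChannelDefinitionSequence):
        src = ch.ChannelSourceSequence[0]
        key = (str(src.CodeValue), str(src.CodingSchemeDesignator))
        if key not in name_by_code:
            raise ECGParseError(f"unknown channel source code {key}")
        step = float(ch.ChannelSensitivity)
        leads.append((name_by_code[key], raw[i].astype(float) * step))
    acq = _dt.datetime.strptime(str(ds.AcquisitionDateTime)[:14], "%Y%m%d%H%M%S")
    rec = ECGRecord(
        patient_id=str(ds.PatientID),
        acquisition_datetime=acq,
        sampling_frequency=float(mux.SamplingFrequency),
        leads=leads,
        study_date=_dt.datetime.strptime(str(ds.StudyDate), "%Y%m%d").date(),
    )
    rec.waveform_ref = EvidenceRef(str(ds.StudyInstanceUID),
                                   str(ds.SeriesInstanceUID),
                                   str(ds.SOPClassUID), str(ds.SOPInstanceUID))
    return rec
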