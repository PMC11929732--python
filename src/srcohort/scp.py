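"""Minimal SCP-ECG style binary dialect (reader + writer).

Real-world SCP-ECG has many sections and compression modes; clinical exports
in this family vary widely. This module implements a documented, self-
consistent subset sufficient for rhythm-signal exchange:

``file  = crc16(2, little endian) | size(4) | sections``

Each section starts with a 16-byte header::

    crc16 over bytes 2..end (2) | section id (2) | length incl. header (4) |
    section version (1) | protocol version (1) | reserved b"SCPECG" (6)

Sections used:

* **0** — pointer table: ``id(2) | length(4) | offset(4)`` per section.
* **1** — tagged header data: ``tag(1) | len(2) | payload``; tag 2 = patient
  id (UTF-8), tag 25 = acquisition date (year u16, month u8, day u8), tag 26 =
  acquisition time (h, m, s), tag 203 (manufacturer range) = study date
  (year u16, month u8, day u8), tag 255 = terminator.
* **3** — lead table: ``n(1) | flags(1)`` then per lead
  ``start(4) | end(4) | lead id(1)`` with the standard SCP lead identifiers
  (I=1, II=2, V1..V6=3..8, III=61, aVR=62, aVL=63, aVF=64).
* **6** — rhythm data: ``avm in nV (u16) | sample interval in µs (u16) |
  encoding(1)=0 | compression(1)=0`` then per lead ``nbytes(u16)`` + raw
  little-endian int16 samples.

Amplitudes are quantized by the amplitude value multiplier (AVM, nanovolts);
the writer picks the smallest power-of-ten AVM that covers the signal range in
16 bits. The sample interval must be an integral number of microseconds.
"""

from __future__ import annotations

import datetime as _dt
import struct
from typing import Dict, List, Tuple

import numpy as np

SCP_LEAD_IDS = {"I": 1, "II": 2, "V1": 3, "V2": 4, "V3": 5, "V4": 6,
                "V5": 7, "V6": 8, "III": 61, "aVR": 62, "aVL": 63, "aVF": 64}
SCP_LEAD_NAMES = {v: k for k, v in SCP_LEAD_IDS.items()}

_RESERVED = b"SCPECG"


class SCPFormatError(ValueError):
    pass


def crc16_ccitt(data: bytes, crc: int = 0xFFFF) -> int:
    for byte in data:
        crc ^= byte << 8
        for _ in range(8):
            crc = ((crc << 1) ^ 0x1021) if crc & 0x8000 else (crc << 1)
        crc &= 0xFFFF
    return crc


def _section(sec_id: int, payload: bytes) -> bytes:
    length = 16 + len(payload)
    body = struct.pack("<HI", sec_id, length) + bytes([20, 20]) + _RESERVED + payload
    return struct.pack("<H", crc16_ccitt(body)) + body


def pick_avm_nv(signals_uv: np.ndarray) -> int:
    """Smallest power-of-ten AVM (nV) representing the signal in int16."""
    peak_nv = float(np.max(np.abs(signals_uv))) * 1000.0 if signals_uv.size else 0.0
    avm = 1
    while peak_nv / avm > 32767:
        avm *= 10
    return avm


def write_scp(patient_id: str, acquisition: _dt.datetime, study_date: _dt.date,
              sampling_frequency: float, leads: List[Tuple[str, np.ndarray]]) -> bytes:
    """Encode microvolt signals into the SCP subset described above."""
    interval_us = 1e6 / sampling_frequency
    if abs(interval_us - round(interval_us)) > 1e-9:
        raise SCPFormatError(
            f"sampling frequency {sampling_frequency} Hz has a non-integral "
            "microsecond sample interval; unsupported by this SCP subset")
    sig = np.asarray([s for _, s in leads], dtype=float)
    avm = pick_avm_nv(sig)
    quant = np.round(sig * 1000.0 / avm).astype(np.int16)

    def tag(t: int, payload: bytes) -> bytes:
        return bytes([t]) + struct.pack("<H", len(payload)) + payload

    s1 = (tag(2, patient_id.encode())
          + tag(25, struct.pack("<HBB", acquisition.year, acquisition.month,
                                acquisition.day))
          + tag(26, bytes([acquisition.hour, acquisition.minute, acquisition.second]))
          + tag(203, struct.pack("<HBB", study_date.year, study_date.month,
                                 study_date.day))
          + tag(255, b""))

    n = quant.shape[1] if quant.size else 0
    s3 = bytes([len(leads), 0])
    for name, _ in leads:
        if name not in SCP_LEAD_IDS:
            raise SCPFormatError(f"unknown SCP lead name {name!r}")
        s3 += struct.pack("<IIB", 1, n, SCP_LEAD_IDS[name])

    s6 = struct.pack("<HHBB", avm, int(round(interval_us)), 0, 0)
    for row in quant:
        raw = row.astype("<i2").tobytes()
        s6 += struct.pack("<H", len(raw)) + raw

    sections = [(1, _section(1, s1)), (3, _section(3, s3)), (6, _section(6, s6))]
    # pointer table (section 0) references every section including itself
    n_entries = len(sections) + 1
    s0_len = 16 + 10 * n_entries
    offset = 6 + s0_len
    entries = [struct.pack("<HII", 0, s0_len, 6)]
    for sec_id, blob in sections:
        entries.append(struct.pack("<HII", sec_id, len(blob), offset))
        offset += len(blob)
    s0 = _section(0, b"".join(entries))

    body = s0 + b"".join(blob for _, blob in sections)
    total = struct.pack("<I", len(body) + 6) + body
    return struct.pack("<H", crc16_ccitt(total)) + total


def _parse_sections(data: bytes) -> Dict[int, bytes]:
    if len(data) < 6:
        raise SCPFormatError("truncated SCP stream")
    crc, size = struct.unpack("<HI", data[:6])
    if size != len(data):
        raise SCPFormatError(f"size field {size} != stream length {len(data)}")
    if crc16_ccitt(data[2:]) != crc:
        raise SCPFormatError("file CRC mismatch")
    sections: Dict[int, bytes] = {}
    pos = 6
    while pos < len(data):
        if pos + 16 > len(data):
            raise SCPFormatError("truncated section header")
        sec_crc, sec_id, length = struct.unpack("<HHI", data[pos:pos + 8])
        blob = data[pos:pos + length]
        if len(blob) != length:
            raise SCPFormatError(f"section {sec_id} truncated")
        if crc16_ccitt(blob[2:]) != sec_crc:
            raise SCPFormatError(f"section {sec_id} CRC mismatch")
        sections[sec_id] = blob[16:]
        pos += length
    return sections


def read_scp(data: bytes) -> dict:
    """Decode the SCP subset; returns a dict of record fields (signals in µV)."""
    sections = _parse_sections(data)
    for required in (1, 3, 6):
        if required not in sections:
            raise SCPFormatError(f"missing required SCP section {required}")

    tags: Dict[int, bytes] = {}
    s1, pos = sections[1], 0
    while pos < len(s1):
        t = s1[pos]
        ln = struct.unpack("<H", s1[pos + 1:pos + 3])[0]
        tags[t] = s1[pos + 3:pos + 3 + ln]
        pos += 3 + ln
        if t == 255:
            break
    if 2 not in tags or 25 not in tags or 203 not in tags:
        raise SCPFormatError("SCP section 1 lacks patient id / date tags")
    y, m, d = struct.unpack("<HBB", tags[25])
    hh, mm, ss = tags.get(26, b"\0\0\0")[:3]
    sy, sm, sd = struct.unpack("<HBB", tags[203])

    s3 = sections[3]
    n_leads = s3[0]
    lead_names = []
    pos = 2
    for _ in range(n_leads):
        _start, _end, lid = struct.unpack("<IIB", s3[pos:pos + 9])
        if lid not in SCP_LEAD_NAMES:
            raise SCPFormatError(f"unknown SCP lead id {lid}")
        lead_names.append(SCP_LEAD_NAMES[lid])
        pos += 9

    s6 = sections[6]
    avm, interval_us, encoding, compression = struct.unpack("<HHBB", s6[:6])
    if encoding != 0 or compression != 0:
        raise SCPFormatError("only uncompressed raw rhythm data is supported")
    if interval_us == 0:
        raise SCPFormatError("missing sample interval (sampling frequency)")
    leads: List[Tuple[str, np.ndarray]] = []
    pos = 6
    for name in lead_names:
        nbytes = struct.unpack("<H", s6[pos:pos + 2])[0]
        raw = np.frombuffer(s6[pos + 2:pos + 2 + nbytes], dtype="<i2")
        leads.append((name, raw.astype(float) * avm / 1000.0))  # nV -> µV
        pos += 2 + nbytes
    lengths = {len(s) for _, s in leads}
    if len(lengths) > 1:
        raise SCPFormatError(f"leads have inconsistent lengths: {sorted(lengths)}")

    return {
        "patient_id": tags[2].decode(),
        "acquisition_datetime": _dt.datetime(y, m, d, hh, mm, ss),
        "study_date": _dt.date(sy, sm, sd),
        "sampling_frequency": 1e6 / interval_us,
        "leads": leads,
    }
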