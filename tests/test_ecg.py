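import datetime as dt

import numpy as np
import pytest

from srcohort import concepts as C
from srcohort.ecg import (AmplitudeRangeError, ECGParseError, ECGRecord,
                          ecg_to_waveform, pick_sensitivity, read_ecg,
                          waveform_to_ecg, write_ecg)
from srcohort.scp import SCPFormatError, crc16_ccitt, read_scp
from srcohort.uids import UIDGenerator

DIALECTS = ("csv", "xml", "hdf5", "scp")


def _record(rng, n=500, fs=500.0, grid=10.0):
    # signals on a coarse amplitude grid so every dialect round-trips exactly
    leads = [(name, np.round(rng.uniform(-3000, 3000, n) / grid) * grid)
             for name in C.STANDARD_LEADS]
    return ECGRecord("P1", dt.datetime(2019, 3, 2, 8, 15), fs, leads,
                     dt.date(2019, 3, 2))


@pytest.mark.parametrize("dialect", DIALECTS)
def test_dialect_round_trip(rng, dialect):
    rec = _record(rng)
    data, sidecar = write_ecg(rec, dialect)
    back = read_ecg(data, dialect, sidecar)
    assert back == rec


def test_all_dialects_agree_on_one_signal(rng):
    rec = _record(rng)
    records = []
    for dialect in DIALECTS:
        data, sidecar = write_ecg(rec, dialect)
        records.append(read_ecg(data, dialect, sidecar))
    assert all(r == records[0] for r in records[1:])


def test_csv_requires_sidecar(rng):
    data, _ = write_ecg(_record(rng), "csv")
    with pytest.raises(ECGParseError):
        read_ecg(data, "csv")


def test_truncated_scp_rejected(rng):
    data, _ = write_ecg(_record(rng), "scp")
    with pytest.raises(SCPFormatError):
        read_scp(data[:40])


def test_corrupted_scp_crc_rejected(rng):
    data, _ = write_ecg(_record(rng), "scp")
    corrupted = bytearray(data)
    corrupted[-10] ^= 0xFF
    with pytest.raises(SCPFormatError):
        read_scp(bytes(corrupted))


def test_crc16_reference_value():
    # CRC-16/CCITT-FALSE check value for "123456789"
    assert crc16_ccitt(b"123456789") == 0x29B1


def test_unknown_lead_rejected():
    with pytest.raises(ECGParseError):
        ECGRecord("P", dt.datetime(2020, 1, 1), 100.0,
                  [("X9", np.zeros(4))], dt.date(2020, 1, 1))


def test_inconsistent_lengths_rejected():
    with pytest.raises(ECGParseError):
        ECGRecord("P", dt.datetime(2020, 1, 1), 100.0,
                  [("I", np.zeros(4)), ("II", np.zeros(5))],
                  dt.date(2020, 1, 1))


def test_pick_sensitivity_power_of_ten():
    for peak, expected in ((31000.0, 1.0), (3100.0, 0.1), (200.0, 0.01)):
        s = pick_sensitivity(np.array([peak, -peak]))
        assert s == expected
        assert peak / s <= 32767


def test_waveform_round_trip_error_within_quantization(rng):
    for _ in range(10):
        n = int(rng.integers(100, 800))
        fs = float(rng.choice([250.0, 500.0, 1000.0]))
        leads = [(name, rng.uniform(-3200, 3200, n))
                 for name in C.STANDARD_LEADS]
        rec = ECGRecord("P1", dt.datetime(2020, 4, 4, 7), fs, leads,
                        dt.date(2020, 4, 4))
        wf = ecg_to_waveform(rec, uid_generator=UIDGenerator(1))
        back = waveform_to_ecg(wf.data)
        assert back.sampling_frequency == fs
        assert back.study_date == rec.study_date
        assert [n1 for n1, _ in back.leads] == [n2 for n2, _ in rec.leads]
        for (_, orig), (_, rt) in zip(rec.leads, back.leads):
            step = pick_sensitivity(orig)
            assert np.max(np.abs(orig - rt)) <= step / 2 + 1e-9


def test_waveform_sine_waves_one_step(rng):
    t = np.arange(5000) / 500.0
    leads = [(name, 1000.0 * np.sin(2 * np.pi * (1 + i) * t))
             for i, name in enumerate(C.STANDARD_LEADS)]
    rec = ECGRecord("P1", dt.datetime(2020, 1, 1), 500.0, leads,
                    dt.date(2020, 1, 1))
    wf = ecg_to_waveform(rec, uid_generator=UIDGenerator(2))
    back = waveform_to_ecg(wf.data)
    for (_, orig), (_, rt) in zip(rec.leads, back.leads):
        assert np.max(np.abs(orig - rt)) <= pick_sensitivity(orig)


def test_forced_sensitivity_overflow_raises(rng):
    rec = _record(rng)
    with pytest.raises(AmplitudeRangeError):
        ecg_to_waveform(rec, sensitivity=0.01,
                        uid_generator=UIDGenerator(3))


def test_millivolt_source_normalized(rng):
    n = 100
    vals = np.round(np.linspace(-2.0, 2.0, n), 3)
    leads_mv = [(name, vals) for name in C.STANDARD_LEADS]
    rec = ECGRecord("P1", dt.datetime(2020, 1, 1), 250.0, leads_mv,
                    dt.date(2020, 1, 1), amplitude_unit="millivolt")
    uv = rec.in_microvolts()
    assert np.allclose(uv.leads[0][1], vals * 1000.0)


def test_waveform_encoding_deterministic(rng):
    rec = _record(rng)
    a = ecg_to_waveform(rec, uid_generator=UIDGenerator(7))
    b = ecg_to_waveform(rec, uid_generator=UIDGenerator(7))
    assert a.data == b.data
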