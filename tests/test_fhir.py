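import copy
import datetime as dt
import json

import numpy as np
import pytest

from srcohort import concepts as C
from srcohort.clinical import (ECGMeasurementSet, PatientHistoryRecord,
                               TobaccoStatus, ecg_report, measurement_report,
                               patient_history)
from srcohort.ecg import ECGRecord
from srcohort.fhir import (FHIR_VERSION, FhirValidationError, check_bundle,
                           conservation, sr_to_fhir)
from srcohort.randgen import random_document
from srcohort.uids import UIDGenerator


def _history(uid_gen, **kw):
    return patient_history(PatientHistoryRecord("P1", **kw),
                           uid_generator=uid_gen)


def test_conservation_random_documents(rng):
    gen = UIDGenerator(3)
    violations = 0
    for _ in range(40):
        doc = random_document(rng, gen)
        result = sr_to_fhir(doc)
        leaves, observations, skipped = conservation(doc, result)
        if observations + skipped != leaves:
            violations += 1
        check_bundle(result.bundle)
    assert violations == 0


def test_coded_triples_survive(uid_gen):
    doc = _history(uid_gen, tobacco_smoker=TobaccoStatus.YES)
    result = sr_to_fhir(doc)
    obs = [e["resource"] for e in result.bundle["entry"]
           if e["resource"]["resourceType"] == "Observation"]
    (tob,) = [o for o in obs
              if o["code"]["coding"][0]["code"] == C.TOBACCO_SMOKER.value]
    coding = tob["code"]["coding"][0]
    assert coding["display"] == C.TOBACCO_SMOKER.meaning
    val = tob["valueCodeableConcept"]["coding"][0]
    assert (val["code"], val["display"]) == (C.YES.value, C.YES.meaning)
    # scheme is carried via the system URI
    assert C.TOBACCO_SMOKER.scheme in coding["system"] \
        or coding["system"].startswith("http")


def test_quantity_readback(rng, uid_gen):
    leads = [(n, np.zeros(8)) for n in C.STANDARD_LEADS]
    rec = ECGRecord("P1", dt.datetime(2020, 1, 1, 9), 250.0, leads,
                    dt.date(2020, 1, 1))
    doc = ecg_report(rec, ECGMeasurementSet(ventricular_rate=66.0),
                     uid_generator=uid_gen)
    result = sr_to_fhir(doc)
    check_bundle(result.bundle)
    obs = [e["resource"] for e in result.bundle["entry"]
           if e["resource"]["resourceType"] == "Observation"]
    (rate,) = [o for o in obs
               if o["code"]["coding"][0]["code"] == C.VENTRICULAR_RATE.value]
    q = rate["valueQuantity"]
    assert q["value"] == 66.0
    assert q["code"] == C.BEATS_PER_MINUTE.value
    assert q["unit"] == C.BEATS_PER_MINUTE.meaning


def test_geometric_items_skipped_and_counted(uid_gen):
    doc = measurement_report(
        "P1", dt.date(2020, 2, 2), frame_of_reference_uid=uid_gen(),
        hinge_points=((C.RIGHT_CORONARY_CUSP, (1.0, 2.0, 3.0)),),
        membranous_septum_mm=4.0, uid_generator=uid_gen)
    result = sr_to_fhir(doc)
    leaves, observations, skipped = conservation(doc, result)
    assert skipped == 1  # the SCOORD3D hinge point
    assert result.skipped[0].value_kind == "SCOORD3D"
    assert C.RIGHT_CORONARY_CUSP.meaning in result.skipped[0].path
    assert observations + skipped == leaves


def test_empty_document_yields_no_observations(uid_gen):
    doc = _history(uid_gen)
    result = sr_to_fhir(doc)
    leaves, observations, skipped = conservation(doc, result)
    assert (leaves, observations, skipped) == (0, 0, 0)
    check_bundle(result.bundle)
    report = [e["resource"] for e in result.bundle["entry"]
              if e["resource"]["resourceType"] == "DiagnosticReport"][0]
    assert report["result"] == []


def test_bundle_metadata(uid_gen):
    doc = _history(uid_gen, free_text_notes="x")
    bundle = sr_to_fhir(doc).bundle
    assert bundle["type"] == "collection"
    assert bundle["meta"]["tag"][0]["code"] == FHIR_VERSION
    report = [e["resource"] for e in bundle["entry"]
              if e["resource"]["resourceType"] == "DiagnosticReport"][0]
    assert report["identifier"][0]["value"] == f"urn:oid:{doc.sop_uid}"
    assert report["effectiveDateTime"] == doc.study_date.isoformat()


def test_to_json_round_trips(uid_gen):
    result = sr_to_fhir(_history(uid_gen, free_text_notes="x"))
    assert json.loads(result.to_json()) == result.bundle


def _good_bundle(uid_gen):
    return sr_to_fhir(_history(uid_gen, tobacco_smoker=TobaccoStatus.NO,
                               free_text_notes="n")).bundle


def test_check_bundle_rejects_two_values(uid_gen):
    bundle = copy.deepcopy(_good_bundle(uid_gen))
    for e in bundle["entry"]:
        if e["resource"]["resourceType"] == "Observation":
            e["resource"]["valueString"] = "extra"
            break
    with pytest.raises(FhirValidationError, match="value"):
        check_bundle(bundle)


def test_check_bundle_rejects_dangling_result_reference(uid_gen):
    bundle = copy.deepcopy(_good_bundle(uid_gen))
    for e in bundle["entry"]:
        if e["resource"]["resourceType"] == "DiagnosticReport":
            e["resource"]["result"].append({"reference": "urn:id:obs-missing"})
    with pytest.raises(FhirValidationError):
        check_bundle(bundle)


def test_check_bundle_rejects_incomplete_coding(uid_gen):
    bundle = copy.deepcopy(_good_bundle(uid_gen))
    for e in bundle["entry"]:
        if e["resource"]["resourceType"] == "Observation":
            del e["resource"]["code"]["coding"][0]["display"]
            break
    with pytest.raises(FhirValidationError, match="display"):
        check_bundle(bundle)


def test_check_bundle_rejects_missing_patient(uid_gen):
    bundle = copy.deepcopy(_good_bundle(uid_gen))
    bundle["entry"] = [e for e in bundle["entry"]
                       if e["resource"]["resourceType"] != "Patient"]
    with pytest.raises(FhirValidationError):
        check_bundle(bundle)


def test_check_bundle_rejects_wrong_type(uid_gen):
    bundle = copy.deepcopy(_good_bundle(uid_gen))
    bundle["type"] = "transaction"
    with pytest.raises(FhirValidationError, match="collection"):
        check_bundle(bundle)
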