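"""SR → FHIR (R4-style) conversion with an explicit conservation contract.

One SR document becomes a collection Bundle holding a Patient, a
DiagnosticReport whose code is the document title, and one Observation per
non-CONTAINER content leaf. Concept triples survive as codings, numeric
measurements as quantities with UCUM codes, text and dates as their native
FHIR value types. Leaf kinds FHIR has no lossless primitive for at this
granularity (spatial coordinates, image/waveform references) are *not*
silently dropped: they are returned in a skipped-items report with their
content path, and conversion guarantees

    observations + skipped == content leaves.

The conversion is pure: identical documents yield identical JSON. Emitted
bundles are checked by :func:`check_bundle`, a structural validator encoding
the subset of resource constraints this exporter relies on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .coding import CodedConcept
from .content import ValueKind
from .document import SRDocument

FHIR_VERSION = "4.0.1"

CODING_SYSTEMS: Dict[str, str] = {
    "DCM": "http://dicom.nema.org/resources/ontology/DCM",
    "LN": "http://loinc.org",
    "SCT": "http://snomed.info/sct",
    "UCUM": "http://unitsofmeasure.org",
}

_MAPPED_KINDS = {ValueKind.CODE, ValueKind.NUM, ValueKind.TEXT, ValueKind.DATE,
                 ValueKind.DATETIME}


class FhirValidationError(ValueError):
    pass


@dataclass(frozen=True)
class SkippedItem:
    path: Tuple[str, ...]
    value_kind: str


@dataclass
class FhirExportResult:
    bundle: dict
    skipped: List[SkippedItem] = field(default_factory=list)

    def to_json(self, indent: Optional[int] = 2) -> str:
        return json.dumps(self.bundle, indent=indent, sort_keys=True)


def _system(scheme: str) -> str:
    # private schemes fall back to a URN so codings stay round-trippable
    return CODING_SYSTEMS.get(scheme, f"urn:scheme:{scheme}")


def _codeable(concept: CodedConcept) -> dict:
    return {"coding": [{"system": _system(concept.scheme),
                        "code": concept.value,
                        "display": concept.meaning}],
            "text": concept.meaning}


def sr_to_fhir(doc: SRDocument) -> FhirExportResult:
    """Convert one SR document to a FHIR collection bundle.

    Returns the bundle plus the skipped-items report; see the module
    docstring for the conservation contract.
    """
    patient_fullurl = f"urn:id:patient:{doc.patient_id}"
    patient = {
        "resourceType": "Patient",
        "id": f"patient-{doc.patient_id}",
        "identifier": [{"system": "urn:srcohort:patient-id",
                        "value": doc.patient_id}],
    }
    if doc.patient_context is not None:
        ctx = doc.patient_context
        if getattr(ctx, "birth_date", None):
            patient["birthDate"] = ctx.birth_date.isoformat()
        if getattr(ctx, "sex", None):
            patient["gender"] = {"M": "male", "F": "female"}.get(
                str(ctx.sex), "unknown")

    observations: List[dict] = []
    skipped: List[SkippedItem] = []
    for path, item in doc.iter_items():
        if item.value_kind is ValueKind.CONTAINER:
            continue
        if item.value_kind not in _MAPPED_KINDS:
            skipped.append(SkippedItem(tuple(path), item.value_kind.value))
            continue
        n = len(observations) + 1
        obs = {
            "resourceType": "Observation",
            "id": f"obs-{doc.sop_uid}-{n}",
            "status": "final",
            "code": _codeable(item.name),
            "subject": {"reference": patient_fullurl},
        }
        if item.value_kind is ValueKind.CODE:
            obs["valueCodeableConcept"] = _codeable(item.value)
        elif item.value_kind is ValueKind.NUM:
            obs["valueQuantity"] = {
                "value": item.value.as_float,
                "unit": item.value.unit.meaning,
                "system": _system(item.value.unit.scheme),
                "code": item.value.unit.value,
            }
        elif item.value_kind is ValueKind.TEXT:
            obs["valueString"] = item.value
        else:  # DATE / DATETIME
            obs["valueDateTime"] = item.value.isoformat()
        observations.append(obs)

    report = {
        "resourceType": "DiagnosticReport",
        "id": f"report-{doc.sop_uid}",
        "status": "final",
        "code": _codeable(doc.root.name),
        "subject": {"reference": patient_fullurl},
        "effectiveDateTime": doc.study_date.isoformat(),
        "identifier": [{"system": "urn:dicom:uid",
                        "value": f"urn:oid:{doc.sop_uid}"}],
        "result": [{"reference": f"urn:id:{o['id']}"} for o in observations],
    }

    entries = [{"fullUrl": patient_fullurl, "resource": patient},
               {"fullUrl": f"urn:id:report-{doc.sop_uid}", "resource": report}]
    entries += [{"fullUrl": f"urn:id:{o['id']}", "resource": o}
                for o in observations]
    bundle = {
        "resourceType": "Bundle",
        "id": f"bundle-{doc.sop_uid}",
        "type": "collection",
        "meta": {"tag": [{"system": "urn:srcohort:fhir-version",
                          "code": FHIR_VERSION}]},
        "entry": entries,
    }
    return FhirExportResult(bundle=bundle, skipped=skipped)


def conservation(doc: SRDocument, result: FhirExportResult) -> Tuple[int, int, int]:
    """(content leaves, observations, skipped) — the first equals the sum of
    the other two for every successful conversion."""
    leaves = sum(1 for _, item in doc.iter_items()
                 if item.value_kind is not ValueKind.CONTAINER)
    observations = sum(1 for e in result.bundle["entry"]
                       if e["resource"]["resourceType"] == "Observation")
    return leaves, observations, len(result.skipped)


# ---------------------------------------------------------------------------
# structural validation of emitted bundles
# ---------------------------------------------------------------------------

def _fail(path: str, msg: str) -> None:
    raise FhirValidationError(f"{path}: {msg}")


def _check_codeable(cc, path: str) -> None:
    if not isinstance(cc, dict) or not cc.get("coding"):
        _fail(path, "codeable concept needs a non-empty 'coding' list")
    for i, c in enumerate(cc["coding"]):
        for key in ("system", "code", "display"):
            if not isinstance(c.get(key), str) or not c[key]:
                _fail(f"{path}.coding[{i}].{key}", "missing or empty")


def check_bundle(bundle: dict) -> None:
    """Validate the structural constraints this exporter's bundles satisfy.

    Checks resource types, required fields, value[x] exclusivity on
    observations, and that every report result reference resolves to an
    observation entry in the same bundle. Raises
    :class:`FhirValidationError` naming the offending path.
    """
    if bundle.get("resourceType") != "Bundle":
        _fail("resourceType", "must be 'Bundle'")
    if bundle.get("type") != "collection":
        _fail("type", "must be 'collection'")
    entries = bundle.get("entry")
    if not isinstance(entries, list) or not entries:
        _fail("entry", "must be a non-empty list")

    by_fullurl: Dict[str, dict] = {}
    n_patients = n_reports = 0
    for i, e in enumerate(entries):
        p = f"entry[{i}]"
        if not isinstance(e.get("fullUrl"), str) or not e["fullUrl"]:
            _fail(f"{p}.fullUrl", "missing")
        res = e.get("resource")
        if not isinstance(res, dict):
            _fail(f"{p}.resource", "missing")
        if e["fullUrl"] in by_fullurl:
            _fail(f"{p}.fullUrl", f"duplicate {e['fullUrl']!r}")
        by_fullurl[e["fullUrl"]] = res
        rt = res.get("resourceType")
        if rt == "Patient":
            n_patients += 1
            idents = res.get("identifier")
            if not idents or not idents[0].get("value"):
                _fail(f"{p}.resource.identifier", "patient identifier required")
        elif rt == "DiagnosticReport":
            n_reports += 1
            if res.get("status") != "final":
                _fail(f"{p}.resource.status", "must be 'final'")
            _check_codeable(res.get("code"), f"{p}.resource.code")
            if not res.get("subject", {}).get("reference"):
                _fail(f"{p}.resource.subject", "missing reference")
        elif rt == "Observation":
            if res.get("status") != "final":
                _fail(f"{p}.resource.status", "must be 'final'")
            _check_codeable(res.get("code"), f"{p}.resource.code")
            values = [k for k in res if k.startswith("value")]
            if len(values) != 1:
                _fail(f"{p}.resource", f"exactly one value[x], got {values}")
            k = values[0]
            if k == "valueQuantity":
                q = res[k]
                if not isinstance(q.get("value"), (int, float)):
                    _fail(f"{p}.resource.valueQuantity.value", "must be a number")
                for key in ("unit", "system", "code"):
                    if not q.get(key):
                        _fail(f"{p}.resource.valueQuantity.{key}", "missing")
            elif k == "valueCodeableConcept":
                _check_codeable(res[k], f"{p}.resource.{k}")
            elif k == "valueString":
                if not isinstance(res[k], str):
                    _fail(f"{p}.resource.{k}", "must be a string")
            elif k == "valueDateTime":
                if not isinstance(res[k], str) or not res[k]:
                    _fail(f"{p}.resource.{k}", "must be a date string")
            else:
                _fail(f"{p}.resource", f"unsupported value type {k}")
        else:
            _fail(f"{p}.resource.resourceType", f"unexpected {rt!r}")

    if n_patients != 1:
        _fail("entry", f"expected exactly one Patient, got {n_patients}")
    if n_reports != 1:
        _fail("entry", f"expected exactly one DiagnosticReport, got {n_reports}")

    report = next(r for r in by_fullurl.values()
                  if r["resourceType"] == "DiagnosticReport")
    for j, ref in enumerate(report.get("result", [])):
        target = by_fullurl.get(ref.get("reference", ""))
        if target is None or target.get("resourceType") != "Observation":
            _fail(f"DiagnosticReport.result[{j}]",
                  f"unresolved reference {ref.get('reference')!r}")
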