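# srcohort

Tooling for building multi-modal clinical cohorts around DICOM Structured
Reports (SR). It converts heterogeneous source data (vendor ECG dialects,
tabular clinical records, binary label masks) into standard DICOM objects,
indexes them into a queryable parent/child document model, evaluates boolean
queries under two well-defined nesting semantics, exchanges queries between
sites as versioned JSON, renders a documented query subset to SQL, exports SR
content to FHIR bundles, and generates fully synthetic multi-site cohorts with
exact ground-truth manifests for end-to-end verification.

## Package tour

| Module | Purpose |
| --- | --- |
| `srcohort.coding` / `concepts` | Coded concepts (value, scheme, meaning) and the fixed concept catalog |
| `srcohort.content` / `document` / `templates` / `dicom_io` | SR content trees, document envelope, template validation, Part 10 round trip |
| `srcohort.clinical` | Builders: ECG report, patient history, procedure outcomes, imaging measurement report; CSV/JSON table ingestion |
| `srcohort.ecg` / `scp` | 12-lead record model, four interchange dialects (XML, SCP subset, HDF5, CSV+sidecar), DICOM waveform encoding |
| `srcohort.seg` | Binary DICOM segmentations with coded per-segment labels |
| `srcohort.indexing` | Attribute-path extraction, parent/child flattening, index construction, NDJSON bulk round trip |
| `srcohort.query` | Boolean queries, NESTED vs FLATTENED semantics, brute-force oracle, JSON exchange dialect, SQL subset, pre-procedure ECG selection |
| `srcohort.fhir` | SR → FHIR collection bundle with a conservation report and structural validator |
| `srcohort.synthetic` | Configurable multi-site synthetic cohort generator with exact truth manifests |
| `srcohort.randgen` | Randomized documents, indices and queries shared by the test suite and the acceptance script |
| `srcohort.cli` | `srcohort` command group (convert, build, validate, index, query, export, generate) |

## Quick start

```python
import datetime as dt
from srcohort import (PatientHistoryRecord, TobaccoStatus, patient_history,
                      build_index, default_spec_set, evaluate, Mode,
                      NESTED, Predicate, PredKind, Scope)

doc = patient_history(PatientHistoryRecord("P1", tobacco_smoker=TobaccoStatus.YES))
# ... build SeriesRecord parents, attach SR/SEG annotations ...
# index = build_index(parents, annotations, default_spec_set())

query = NESTED(
    Predicate(Scope.ANNOTATION, PredKind.HAS_SEGMENT_LABEL, value="Left ventricle"),
    Predicate(Scope.ANNOTATION, PredKind.HAS_SEGMENT_LABEL, value="Right ventricle"),
)
# evaluate(index, query, Mode.NESTED)     -> one child carries both labels
# evaluate(index, query, Mode.FLATTENED)  -> labels may come from different children
```

Command-line pipeline:

```
srcohort gen-synthetic --config consortium.yaml --out data/
srcohort index --input-dir data/siteA -o siteA.ndjson
srcohort query --index siteA.ndjson --query '{"v":1,"query":{...}}' --mode nested
srcohort export-fhir data/siteA/P-0001/history_*.dcm -o bundle.json
```

## Verification

```
python -m pytest -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds one property-based test per release criterion
(SR round-trip identity, validator mutation sensitivity, engine-vs-oracle
agreement, cross-site query exchange, SQL equivalence and capability limits,
waveform fidelity, consortium truth-set closure, pre-procedure ECG selection,
FHIR conservation). The acceptance script reports the same quantities as JSON.
See `docs/methods.md` for the underlying design decisions.
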