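# Methods

This note records the design decisions behind `srcohort` and the properties the
test suite enforces.

## SR document model

Content items form a tree of (coded name, value kind, value, relationship)
nodes; only CONTAINER items take children. Numeric values keep their decimal
string form (`NumValue.magnitude`) alongside the float so DICOM DS strings like
`"4.10"` survive a round trip byte-exactly. SCOORD3D values require a frame of
reference UID, coordinate counts that are multiples of three, and coordinates
already representable in 32-bit floats (DICOM GraphicData precision), so
serialisation never silently changes a value.

Documents are serialised as Comprehensive 3D SR (SOP class
`1.2.840.10008.5.1.4.1.1.88.34`) with the template id recorded in
`ContentTemplateSequence` and evidence in the current-requested-procedure
evidence sequence. `from_dicom(to_dicom(doc)) == doc` is enforced structurally
(names, kinds, values, relationships, order, evidence, patient context).

## Templates and validation

Templates are row tables (concept, value kind, relationship, cardinality,
requirement) with nested sub-templates and wildcard rows (any concept of a
given kind, used by the measurement-group template). Requirements are
MANDATORY, USER_OPTIONAL, and CONDITIONAL with a sibling-presence condition
(e.g. "Prosthesis Size" requires "Prosthesis Model"). The validator reports
coded issues (`MISSING_MANDATORY`, `WRONG_VALUE_KIND`, `UNKNOWN_CONCEPT`,
`BAD_ROOT`, `BAD_RELATIONSHIP`, `WRONG_CARDINALITY`) with the content-item
meaning path, so an issue can be traced to the offending node.

The mutation-sensitivity property (criterion 2) mutates one node per document
(drop a mandatory row, change a leaf's value kind, break the root title, append
an undeclared concept) and requires at least one issue whose path prefixes or
equals the defect path, while the unmutated twin validates cleanly.

## ECG dialects and waveform encoding

`ECGRecord` holds 12 standard leads in microvolts (a millivolt-sourced record
can be normalised explicitly). Four interchange dialects are implemented:
XML, an SCP-ECG binary subset, HDF5, and CSV with a JSON sidecar. The SCP
subset uses sections 0 (pointers), 1 (patient/acquisition), 3 (lead
identification) and 6 (rhythm data) with CRC-16/CCITT protection; section 3 is
included beyond the minimal trio because lead names are otherwise not
recoverable from the stream.

DICOM waveform encoding stores int16 samples with a per-lead power-of-ten
channel sensitivity chosen as the smallest power of ten whose quantisation
keeps the peak inside ±32767. Round-trip error is therefore bounded by half a
quantisation step; the acceptance property asserts ≤ one step and exact
StudyDate, sampling frequency and lead order. A forced sensitivity that would
overflow raises `AmplitudeRangeError` rather than clipping.

## Segmentations

SEG objects are binary, bit-packed, one frame stack per segment, with a coded
`SegmentedPropertyType` per segment and the algorithm type (manual /
automatic / semiautomatic) that the index exposes as the annotation's creator
type. Segment numbers must be consecutive from 1 and mask shapes consistent;
empty masks are legal but logged.

## Index model

The index is a list of parent series documents (patient, study, series,
modality, description, date, manufacturer, body part), each carrying flattened
annotation children. A child preserves its source boundary (one SR document or
one SEG object) and exposes: the document title, coded qualitative pairs,
numeric values with units, geometric item names, free text, segment labels,
and per-field value lists extracted via declarative attribute-path specs
(template id + meaning path + leaf kind + field name; optional strict
code-path matching). Annotations attach to the series named by their evidence
(or explicitly); orphans are skipped with a log entry, attached to a synthetic
parent, or rejected, by policy. Bulk serialisation is NDJSON, one parent per
line, round-trip exact.

`AnnotationChild.doc_title` is an addition over the minimal child shape so
document-title queries ("series has a quality-assurance SR") are expressible.

## Query semantics

Predicates are scoped to SERIES, ANNOTATION or PATIENT. The central semantic
distinction (criterion 3):

- **NESTED**: a `NESTED(...)` group is satisfied only if a *single* annotation
  child satisfies every predicate in the group (instance-level AND).
- **FLATTENED**: each annotation predicate may be satisfied independently by
  any child of the parent — equivalent to evaluating the group against one
  pooled pseudo-child built from the concatenation of all children.

The engine is verified against `oracle_evaluate`, a deliberately naive
implementation: NESTED iterates every child literally; FLATTENED builds the
pooled pseudo-child. Patient-level evaluation applies the boolean combinators
to patient sets, so each conjunct may be witnessed by a different series (a CT
in one study and an ECG in another satisfy "has CT AND has ECG"); NOT
complements within the indexed patients.

Queries exchange between sites as versioned JSON (`{"v": 1, "query": ...}`),
rendered with sorted keys so the text is deterministic; parsing reports the
JSON offset or node path of the failure. Evaluation depends only on the query
object and the local index plus the shared attribute-spec set, which the
exchange property (criterion 4) exercises across independently generated
indices.

## SQL subset

`load_sql` materialises two tables: `parent` (eight series columns) and
`child` fact rows (child id, series, kind, title, creator, attribute,
text/numeric value). The documented subset mirrors a two-index join limit:

- series level: any boolean tree of series predicates, plus at most one nested
  group of at most two positive annotation predicates — instance-level AND is
  a self-join on `child.child_id`;
- patient level: a conjunction of at most two series-level conditions — a
  self-join on `parent.patient_id`.

Anything beyond (three-way nested conjunctions, two nested groups, three
patient conjuncts, negation inside a nested group, strict (code, scheme)
label matching) raises `SQLCapabilityError` naming the limit. Substring
predicates escape `%`/`_` and use `ESCAPE`. Equivalence against the oracle is
property-checked on randomized queries drawn from inside the subset.

## Temporal selection

`select_pre_procedure_ecg` returns the patient's ECG series with the maximal
StudyDate ≤ the procedure date (the procedure day inclusive); ties break to
the lexicographically smaller series UID; no candidate returns `None`. The
acceptance property checks it exhaustively against a brute-force recount and
against the synthetic manifests.

## Synthetic cohort

`generate_site(SiteConfig)` draws one patient timeline per patient id
(`<site>-<nnnn>`): optional CT study with 1–3 phase-labelled series, optional
pre- and post-procedure 12-lead ECGs with ECG report SRs, a patient-history SR
for everyone, optional prosthesis (quality-assurance) and pacemaker (billing)
outcome SRs, and optional CT annotations: hinge-point/membranous-septum
measurement reports, calcification segmentations, and LV/RV segmentations that
are randomly emitted either as one two-segment object or as two single-segment
children of the same series — the case that separates NESTED from FLATTENED
results. All randomness flows from `SiteConfig.seed`, so generation is
reproducible byte-for-byte.

The manifest's truth sets are computed by exhaustive recount over the emitted
object list — never from the sampling flags — so closure checks (criterion 7)
compare an independent count against query results. Pacemaker label presence
(`p_pacemaker_label`) is sampled separately from the label's Yes/No value
(`p_pacemaker_positive`).

## FHIR export

`sr_to_fhir` emits a collection bundle: one Patient, one DiagnosticReport, and
one Observation per mapped content leaf (CODE → valueCodeableConcept, NUM →
valueQuantity with unit triple, TEXT → valueString, DATE/DATETIME →
valueDateTime). Unmappable kinds (SCOORD3D, IMAGE/WAVEFORM references) are
returned in a skipped-items report, and the conservation contract
`observations + skipped == content leaves` holds for every conversion
(criterion 9). Coding schemes map to canonical system URIs where known (DCM,
LOINC, SNOMED CT, UCUM) and to `urn:scheme:<designator>` otherwise, so private
triples survive. `check_bundle` validates the exporter's structural
invariants (resource types, required fields, exactly one value[x] per
observation, resolvable report references); it is an internal validator, not a
full FHIR R4 conformance check, because no FHIR schema tooling is available in
the target environment.

## Verification strategy

Oracles were written before the engines they check: template validation is
tested by mutation sensitivity, the query engine against a brute-force
evaluator, SQL against the same oracle through an embedded SQLite database,
the generator against recounted manifests, and every serialisation by
round-trip identity. `tests/test_acceptance.py` contains one test per release
criterion at full sample sizes; `scripts/acceptance.py --seed N --out f.json`
recomputes the same quantities from any seed and writes
`{"name": {"value": ..., "n": ...}}` entries.
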