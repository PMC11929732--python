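"""Cohort queries over a nested index: two evaluation semantics, exchange
format, SQL rendering, and temporal ECG selection.

A query is a boolean tree of scoped predicates. SERIES-scoped predicates test
the parent document's fixed fields; ANNOTATION-scoped predicates test the
nested children. The engine offers the two semantics that differ precisely on
multi-condition child filters:

* **NESTED** — a NESTED group matches a parent iff at least one *single* child
  satisfies the whole group (instance-level AND). Asking for segmentations
  that include both the left and the right ventricle returns only parents with
  one child carrying both labels.
* **FLATTENED** — child fields are pooled per parent before evaluation, the
  default behaviour of JSON search engines: the same query then also returns
  parents whose children carry one label each (an effective OR).

Negation over the annotation scope means "no child satisfies" (safe negation).
Queries serialise to a versioned JSON dialect so that the textual query built
at one site can be copied to another site and, given a shared attribute-path
spec set, evaluate identically there. A documented SQL subset mirrors the
two-table (parent/child) restriction of the target engine: at most one nested
group of at most two positive annotation conditions (a child-table self-join)
and patient-level conjunctions of at most two series conditions.
"""

from __future__ import annotations

import datetime as _dt
import enum
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

from .indexing import (AnnotationChild, AnnotationKind, Index, IndexDocument,
                       PARENT_FIELDS)


class Scope(str, enum.Enum):
    SERIES = "SERIES"
    ANNOTATION = "ANNOTATION"
    PATIENT = "PATIENT"


class PredKind(str, enum.Enum):
    TERM = "TERM"
    SUBSTRING = "SUBSTRING"
    RANGE = "RANGE"
    EXISTS = "EXISTS"
    HAS_MODALITY = "HAS_MODALITY"
    HAS_ANNOTATION_NAME = "HAS_ANNOTATION_NAME"
    HAS_SEGMENT_LABEL = "HAS_SEGMENT_LABEL"
    HAS_DOCUMENT_TITLE = "HAS_DOCUMENT_TITLE"


class Mode(str, enum.Enum):
    NESTED = "NESTED"
    FLATTENED = "FLATTENED"


class Op(str, enum.Enum):
    AND = "AND"
    OR = "OR"
    NOT = "NOT"
    NESTED = "NESTED"


class QueryValidationError(ValueError):
    pass


class QueryParseError(ValueError):
    pass


class SQLCapabilityError(ValueError):
    """The query exceeds the documented SQL subset (e.g. a >2-index join)."""


_SERIES_PRED_KINDS = {PredKind.TERM, PredKind.SUBSTRING, PredKind.RANGE,
                      PredKind.EXISTS, PredKind.HAS_MODALITY}
_ANNOTATION_PRED_KINDS = {PredKind.TERM, PredKind.SUBSTRING, PredKind.RANGE,
                          PredKind.EXISTS, PredKind.HAS_ANNOTATION_NAME,
                          PredKind.HAS_SEGMENT_LABEL, PredKind.HAS_DOCUMENT_TITLE}


@dataclass(frozen=True)
class Predicate:
    scope: Scope
    kind: PredKind
    field: Optional[str] = None
    value: Union[None, str, float, int, Tuple[str, str]] = None
    low: Union[None, float, str] = None
    high: Union[None, float, str] = None
    case_sensitive: bool = False  # clinical series descriptions are case-chaotic


@dataclass(frozen=True)
class QueryNode:
    op: Op
    children: Tuple[Union["QueryNode", Predicate], ...]

    def __init__(self, op: Op, children: Sequence[Union["QueryNode", Predicate]]):
        object.__setattr__(self, "op", op)
        object.__setattr__(self, "children", tuple(children))


def AND(*children) -> QueryNode:
    return QueryNode(Op.AND, children)


def OR(*children) -> QueryNode:
    return QueryNode(Op.OR, children)


def NOT(child) -> QueryNode:
    return QueryNode(Op.NOT, (child,))


def NESTED(*children) -> QueryNode:
    return QueryNode(Op.NESTED, children)


Query = Union[QueryNode, Predicate]


@dataclass
class QueryResult:
    level: str  # "SERIES" | "PATIENT"
    ids: Set[str]
    provenance: Dict[str, List[int]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_query(query: Query, index: Index, *, patient_level: bool = False) -> None:
    """Reject malformed or unknown-field queries before any evaluation."""
    known_fields = set(PARENT_FIELDS) | index.declared_fields() \
        | {"SR", "SEG", None}

    def check(node, inside_nested: bool):
        if isinstance(node, Predicate):
            if node.scope is Scope.PATIENT and not patient_level:
                raise QueryValidationError(
                    "PATIENT-scoped predicates require patient-level evaluation")
            if inside_nested and node.scope is not Scope.ANNOTATION:
                raise QueryValidationError(
                    "NESTED groups may contain only ANNOTATION-scoped predicates")
            if node.scope is Scope.ANNOTATION \
                    and node.kind not in _ANNOTATION_PRED_KINDS:
                raise QueryValidationError(
                    f"{node.kind.value} is not an annotation-level predicate")
            if node.scope in (Scope.SERIES, Scope.PATIENT) \
                    and node.kind not in _SERIES_PRED_KINDS:
                raise QueryValidationError(
                    f"{node.kind.value} is not a series-level predicate")
            if node.kind in (PredKind.TERM, PredKind.SUBSTRING, PredKind.RANGE):
                pool = (set(PARENT_FIELDS) if node.scope in (Scope.SERIES,
                                                             Scope.PATIENT)
                        else index.declared_fields())
                if node.field not in pool:
                    raise QueryValidationError(
                        f"unknown field {node.field!r} for scope "
                        f"{node.scope.value}")
            if node.kind is PredKind.EXISTS and node.scope is Scope.ANNOTATION:
                if node.field not in known_fields:
                    raise QueryValidationError(f"unknown field {node.field!r}")
            if node.kind is PredKind.RANGE and node.low is None and node.high is None:
                raise QueryValidationError("RANGE requires low and/or high")
            return
        if node.op is Op.NOT and len(node.children) != 1:
            raise QueryValidationError("NOT takes exactly one child")
        for c in node.children:
            check(c, inside_nested or node.op is Op.NESTED)

    check(query, False)


# ---------------------------------------------------------------------------
# predicate evaluation primitives
# ---------------------------------------------------------------------------

def _as_comparable(v):
    if isinstance(v, _dt.date):
        return v.isoformat()
    return v


def _series_pred(pred: Predicate, doc: IndexDocument) -> bool:
    if pred.kind is PredKind.HAS_MODALITY:
        return doc.modality == pred.value
    val = _as_comparable(getattr(doc, pred.field)) if pred.field else None
    if pred.kind is PredKind.TERM:
        return val == _as_comparable(pred.value)
    if pred.kind is PredKind.SUBSTRING:
        hay, needle = str(val or ""), str(pred.value)
        if not pred.case_sensitive:
            hay, needle = hay.lower(), needle.lower()
        return needle in hay
    if pred.kind is PredKind.RANGE:
        if val in (None, ""):
            return False
        lo, hi = _as_comparable(pred.low), _as_comparable(pred.high)
        return (lo is None or val >= lo) and (hi is None or val <= hi)
    if pred.kind is PredKind.EXISTS:
        if pred.field == "annotations":
            return bool(doc.annotations)
        return val not in (None, "")
    raise QueryValidationError(f"{pred.kind} not valid at series scope")


def _num_eq(a, b) -> bool:
    try:
        return float(a) == float(b)
    except (TypeError, ValueError):
        return False


def _child_pred(pred: Predicate, child: AnnotationChild) -> bool:
    if pred.kind is PredKind.HAS_ANNOTATION_NAME:
        return str(pred.value) in child.name_meanings()
    if pred.kind is PredKind.HAS_SEGMENT_LABEL:
        if isinstance(pred.value, (tuple, list)):
            v, s = pred.value
            return any(c.value == v and c.scheme == s for c in child.segment_labels)
        return any(c.meaning == pred.value for c in child.segment_labels)
    if pred.kind is PredKind.HAS_DOCUMENT_TITLE:
        return child.doc_title is not None and child.doc_title.meaning == pred.value
    if pred.kind is PredKind.EXISTS:
        if pred.field in (None, ""):
            return True
        if pred.field in ("SR", "SEG"):
            return child.kind is AnnotationKind(pred.field)
        return bool(child.fields.get(pred.field))
    values = child.fields.get(pred.field, [])
    if pred.kind is PredKind.TERM:
        if isinstance(pred.value, (int, float)):
            return any(_num_eq(v, pred.value) for v in values)
        return any(v == pred.value for v in values)
    if pred.kind is PredKind.SUBSTRING:
        needle = str(pred.value)
        if pred.case_sensitive:
            return any(needle in str(v) for v in values)
        return any(needle.lower() in str(v).lower() for v in values)
    if pred.kind is PredKind.RANGE:
        def ok(v):
            try:
                v = float(v)
            except (TypeError, ValueError):
                return False
            return ((pred.low is None or v >= float(pred.low))
                    and (pred.high is None or v <= float(pred.high)))
        return any(ok(v) for v in values)
    raise QueryValidationError(f"{pred.kind} not valid at annotation scope")


# ---------------------------------------------------------------------------
# engine evaluation
# ---------------------------------------------------------------------------

def _eval_on_child(node, child: AnnotationChild) -> bool:
    """Evaluate a (sub)tree of annotation predicates against one child."""
    if isinstance(node, Predicate):
        return _child_pred(node, child)
    if node.op in (Op.AND, Op.NESTED):
        return all(_eval_on_child(c, child) for c in node.children)
    if node.op is Op.OR:
        return any(_eval_on_child(c, child) for c in node.children)
    return not _eval_on_child(node.children[0], child)  # NOT


def _eval_node(node, doc: IndexDocument, mode: Mode,
               witnesses: Optional[Set[int]]) -> bool:
    if isinstance(node, Predicate):
        if node.scope is Scope.ANNOTATION:
            hits = [i for i, ch in enumerate(doc.annotations)
                    if _child_pred(node, ch)]
            if hits and witnesses is not None:
                witnesses.update(hits)
            return bool(hits)
        return _series_pred(node, doc)
    if node.op is Op.NESTED:
        if mode is Mode.NESTED:
            hits = [i for i, ch in enumerate(doc.annotations)
                    if _eval_on_child(node, ch)]
            if hits and witnesses is not None:
                witnesses.update(hits)
            return bool(hits)
        # flattened: every annotation predicate is satisfied independently by
        # pooled child fields, i.e. each predicate may use a different child
        return _eval_flattened(node, doc, witnesses)
    if node.op is Op.AND:
        return all(_eval_node(c, doc, mode, witnesses) for c in node.children)
    if node.op is Op.OR:
        return any(_eval_node(c, doc, mode, witnesses) for c in node.children)
    return not _eval_node(node.children[0], doc, mode, None)


def _eval_flattened(node, doc: IndexDocument, witnesses) -> bool:
    if isinstance(node, Predicate):
        hits = [i for i, ch in enumerate(doc.annotations) if _child_pred(node, ch)]
        if hits and witnesses is not None:
            witnesses.update(hits)
        return bool(hits)
    if node.op in (Op.AND, Op.NESTED):
        return all(_eval_flattened(c, doc, witnesses) for c in node.children)
    if node.op is Op.OR:
        return any(_eval_flattened(c, doc, witnesses) for c in node.children)
    return not _eval_flattened(node.children[0], doc, None)


def _coerce_mode(mode: Mode | str) -> Mode:
    return mode if isinstance(mode, Mode) else Mode(str(mode).upper())


def evaluate(index: Index, query: Query, mode: Mode | str = Mode.NESTED) -> QueryResult:
    """Evaluate a series-level query under NESTED or FLATTENED semantics."""
    mode = _coerce_mode(mode)
    validate_query(query, index)
    ids: Set[str] = set()
    provenance: Dict[str, List[int]] = {}
    for doc in index.documents:
        witnesses: Set[int] = set()
        if _eval_node(query, doc, mode, witnesses):
            ids.add(doc.series_uid)
            if witnesses:
                provenance[doc.series_uid] = sorted(witnesses)
    return QueryResult("SERIES", ids, provenance)


def evaluate_patient(index: Index, query: Query,
                     mode: Mode | str = Mode.NESTED) -> QueryResult:
    """Patient-level evaluation: boolean combinators act on patient sets.

    Each leaf (predicate or NESTED group) contributes the set of patients
    with at least one satisfying series; witnesses may differ per conjunct,
    so a patient with a CT in one study and an ECG in another satisfies
    "has modality CT AND ECG". NOT complements within the indexed patients.
    """
    mode = _coerce_mode(mode)
    validate_query(query, index, patient_level=True)
    all_patients = index.patients()

    def leaf_patients(leaf) -> Set[str]:
        out = set()
        for doc in index.documents:
            if _eval_node(leaf, doc, mode, None):
                out.add(doc.patient_id)
        return out

    def combine(node) -> Set[str]:
        if isinstance(node, Predicate) or node.op is Op.NESTED:
            return leaf_patients(node)
        if node.op is Op.AND:
            sets = [combine(c) for c in node.children]
            return set.intersection(*sets) if sets else set(all_patients)
        if node.op is Op.OR:
            sets = [combine(c) for c in node.children]
            return set.union(*sets) if sets else set()
        return all_patients - combine(node.children[0])

    return QueryResult("PATIENT", combine(query))


# ---------------------------------------------------------------------------
# reference oracle — exhaustive scan, defined as ground truth
# ---------------------------------------------------------------------------

def _pooled_child(doc: IndexDocument) -> AnnotationChild:
    """Union of all children's content: the flattened per-parent pool."""
    pool = AnnotationChild(kind=AnnotationKind.SR, source_sop_uid="POOL")
    labels = []
    titles = set()
    for ch in doc.annotations:
        pool.qualitative.extend(ch.qualitative)
        pool.numeric.extend(ch.numeric)
        pool.geometric.extend(ch.geometric)
        pool.text.extend(ch.text)
        labels.extend(ch.segment_labels)
        if ch.doc_title is not None:
            titles.add(ch.doc_title)
        for k, v in ch.fields.items():
            pool.fields.setdefault(k, []).extend(v)
    pool._pool_labels = labels          # bypass SR/SEG exclusivity on purpose
    pool._pool_titles = titles
    pool._pool_kinds = {ch.kind for ch in doc.annotations}
    pool._n_children = len(doc.annotations)
    return pool


def _oracle_child_pred(pred: Predicate, pool: AnnotationChild) -> bool:
    # pooled evaluation; segment labels / titles / kinds live in side channels
    if pred.kind is PredKind.HAS_SEGMENT_LABEL:
        labels = getattr(pool, "_pool_labels", pool.segment_labels)
        if isinstance(pred.value, (tuple, list)):
            v, s = pred.value
            return any(c.value == v and c.scheme == s for c in labels)
        return any(c.meaning == pred.value for c in labels)
    if pred.kind is PredKind.HAS_DOCUMENT_TITLE:
        return any(t.meaning == pred.value for t in getattr(pool, "_pool_titles", ()))
    if pred.kind is PredKind.HAS_ANNOTATION_NAME:
        names = pool.name_meanings()
        names |= {c.meaning for c in getattr(pool, "_pool_labels", ())}
        return str(pred.value) in names
    if pred.kind is PredKind.EXISTS:
        if pred.field in (None, ""):
            return getattr(pool, "_n_children", 0) > 0
        if pred.field in ("SR", "SEG"):
            return AnnotationKind(pred.field) in getattr(pool, "_pool_kinds", set())
        return bool(pool.fields.get(pred.field))
    return _child_pred(pred, pool)


def oracle_evaluate(index: Index, query: Query, mode: Mode | str = Mode.NESTED,
                    level: str = "SERIES") -> QueryResult:
    """Brute-force reference evaluation, mechanically independent of the engine.

    NESTED groups are checked by literally iterating every child; FLATTENED
    mode evaluates the whole annotation subtree against a single pooled
    pseudo-child built from the concatenation of all children.
    """
    mode = _coerce_mode(mode)

    def doc_satisfies(node, doc: IndexDocument) -> bool:
        if isinstance(node, Predicate):
            if node.scope is Scope.ANNOTATION:
                if mode is Mode.FLATTENED:
                    return _oracle_child_pred(node, _pooled_child(doc))
                return any(_child_pred(node, ch) for ch in doc.annotations)
            return _series_pred(node, doc)
        if node.op is Op.NESTED:
            if mode is Mode.FLATTENED:
                pool = _pooled_child(doc)

                def on_pool(n):
                    if isinstance(n, Predicate):
                        return _oracle_child_pred(n, pool)
                    if n.op in (Op.AND, Op.NESTED):
                        return all(on_pool(c) for c in n.children)
                    if n.op is Op.OR:
                        return any(on_pool(c) for c in n.children)
                    return not on_pool(n.children[0])

                return on_pool(node)
            satisfied = False
            for ch in doc.annotations:
                if _eval_on_child(node, ch):
                    satisfied = True
            return satisfied
        if node.op is Op.AND:
            return all(doc_satisfies(c, doc) for c in node.children)
        if node.op is Op.OR:
            return any(doc_satisfies(c, doc) for c in node.children)
        return not doc_satisfies(node.children[0], doc)

    if level.upper() == "SERIES":
        ids = {d.series_uid for d in index.documents if doc_satisfies(query, d)}
        return QueryResult("SERIES", ids)

    by_patient: Dict[str, List[IndexDocument]] = {}
    for d in index.documents:
        by_patient.setdefault(d.patient_id, []).append(d)

    def patient_satisfies(node, docs) -> bool:
        if isinstance(node, Predicate) or node.op is Op.NESTED:
            return any(doc_satisfies(node, d) for d in docs)
        if node.op is Op.AND:
            return all(patient_satisfies(c, docs) for c in node.children)
        if node.op is Op.OR:
            return any(patient_satisfies(c, docs) for c in node.children)
        return not patient_satisfies(node.children[0], docs)

    ids = {pid for pid, docs in by_patient.items() if patient_satisfies(query, docs)}
    return QueryResult("PATIENT", ids)


# ---------------------------------------------------------------------------
# JSON exchange dialect (versioned)
# ---------------------------------------------------------------------------

DIALECT_VERSION = 1


def _enc_node(node) -> dict:
    if isinstance(node, Predicate):
        d = {"scope": node.scope.value, "pred": node.kind.value}
        if node.field is not None:
            d["field"] = node.field
        if node.value is not None:
            d["value"] = (list(node.value) if isinstance(node.value, tuple)
                          else node.value)
        if node.low is not None:
            d["low"] = node.low
        if node.high is not None:
            d["high"] = node.high
        if node.case_sensitive:
            d["case_sensitive"] = True
        return d
    return {"op": node.op.value, "children": [_enc_node(c) for c in node.children]}


def render_query(query: Query) -> str:
    """Serialise a query to the exchange dialect (location-independent text)."""
    return json.dumps({"v": DIALECT_VERSION, "query": _enc_node(query)},
                      sort_keys=True)


def _dec_node(d, path: str):
    if not isinstance(d, dict):
        raise QueryParseError(f"expected object at {path}, got {type(d).__name__}")
    if "op" in d:
        try:
            op = Op(d["op"])
        except ValueError:
            raise QueryParseError(f"unknown op {d['op']!r} at {path}") from None
        children = d.get("children", [])
        if not isinstance(children, list):
            raise QueryParseError(f"children must be a list at {path}")
        return QueryNode(op, [_dec_node(c, f"{path}.children[{i}]")
                              for i, c in enumerate(children)])
    if "pred" in d:
        try:
            kind = PredKind(d["pred"])
            scope = Scope(d.get("scope", "SERIES"))
        except ValueError as exc:
            raise QueryParseError(f"bad predicate at {path}: {exc}") from None
        value = d.get("value")
        if isinstance(value, list):
            value = tuple(value)
        return Predicate(scope, kind, d.get("field"), value,
                         d.get("low"), d.get("high"),
                         bool(d.get("case_sensitive", False)))
    raise QueryParseError(f"node at {path} has neither 'op' nor 'pred'")


def parse_query(text: str) -> Query:
    """Parse the JSON exchange dialect; raises with the offending position."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise QueryParseError(f"invalid JSON at offset {exc.pos}: {exc.msg}") from exc
    if not isinstance(doc, dict) or "query" not in doc:
        raise QueryParseError("top level must be an object with a 'query' key")
    v = doc.get("v")
    if v != DIALECT_VERSION:
        raise QueryParseError(f"unsupported dialect version {v!r}")
    return _dec_node(doc["query"], "query")


# ---------------------------------------------------------------------------
# SQL rendering over the two-table (parent, child-facts) relational view
# ---------------------------------------------------------------------------

PARENT_TABLE_SQL = """\
CREATE TABLE parent (
    patient_id TEXT, study_uid TEXT, series_uid TEXT PRIMARY KEY,
    modality TEXT, series_description TEXT, study_date TEXT,
    manufacturer TEXT, body_part_examined TEXT
)"""

CHILD_TABLE_SQL = """\
CREATE TABLE child (
    child_id TEXT, series_uid TEXT, kind TEXT, doc_title TEXT,
    creator_type TEXT, attr TEXT, value_text TEXT, value_num REAL
)"""


def load_sql(index: Index, conn) -> None:
    """Create and populate the parent/child tables in a DB-API connection."""
    cur = conn.cursor()
    cur.execute(PARENT_TABLE_SQL)
    cur.execute(CHILD_TABLE_SQL)
    for d in index.documents:
        cur.execute("INSERT INTO parent VALUES (?,?,?,?,?,?,?,?)",
                    (d.patient_id, d.study_uid, d.series_uid, d.modality,
                     d.series_description,
                     d.study_date.isoformat() if d.study_date else None,
                     d.manufacturer, d.body_part_examined))
        for ch in d.annotations:
            base = (ch.source_sop_uid, d.series_uid, ch.kind.value,
                    ch.doc_title.meaning if ch.doc_title else None,
                    ch.creator_type.value)
            facts: List[Tuple[str, Optional[str], Optional[float]]] = [
                ("kind", ch.kind.value, None)]
            for n in ch.name_meanings():
                facts.append(("name", n, None))
            for c in ch.segment_labels:
                facts.append(("segment_label", c.meaning, None))
            for fname, values in ch.fields.items():
                for v in values:
                    if isinstance(v, (int, float)):
                        facts.append((fname, str(v), float(v)))
                    else:
                        facts.append((fname, str(v), None))
            for attr, vt, vn in facts:
                cur.execute("INSERT INTO child VALUES (?,?,?,?,?,?,?,?)",
                            base + (attr, vt, vn))
    conn.commit()


def _sql_quote(v) -> str:
    if isinstance(v, (int, float)) and not isinstance(v, bool):
        return repr(v)
    return "'" + str(v).replace("'", "''") + "'"


def _series_where(node, alias: str = "p") -> str:
    if isinstance(node, Predicate):
        if node.scope is not Scope.SERIES:
            raise SQLCapabilityError(
                "only SERIES predicates may appear in boolean sub-trees of the "
                "SQL subset")
        if node.kind is PredKind.HAS_MODALITY:
            return f"{alias}.modality = {_sql_quote(node.value)}"
        col = f"{alias}.{node.field}"
        if node.kind is PredKind.TERM:
            return f"{col} = {_sql_quote(_as_comparable(node.value))}"
        if node.kind is PredKind.SUBSTRING:
            pat = str(node.value).replace("%", r"\%").replace("_", r"\_")
            if node.case_sensitive:
                return f"{col} LIKE {_sql_quote('%' + pat + '%')} ESCAPE '\\'"
            return (f"LOWER({col}) LIKE {_sql_quote('%' + pat.lower() + '%')} "
                    "ESCAPE '\\'")
        if node.kind is PredKind.RANGE:
            parts = [f"{col} IS NOT NULL"]
            if node.low is not None:
                parts.append(f"{col} >= {_sql_quote(_as_comparable(node.low))}")
            if node.high is not None:
                parts.append(f"{col} <= {_sql_quote(_as_comparable(node.high))}")
            return "(" + " AND ".join(parts) + ")"
        if node.kind is PredKind.EXISTS:
            return f"({col} IS NOT NULL AND {col} <> '')"
        raise SQLCapabilityError(f"{node.kind.value} unsupported in SQL subset")
    if node.op is Op.AND:
        if not node.children:
            return "1=1"
        return "(" + " AND ".join(_series_where(c, alias)
                                  for c in node.children) + ")"
    if node.op is Op.OR:
        if not node.children:
            return "1=0"
        return "(" + " OR ".join(_series_where(c, alias)
                                 for c in node.children) + ")"
    if node.op is Op.NOT:
        return f"NOT ({_series_where(node.children[0], alias)})"
    raise SQLCapabilityError("NESTED groups may not be nested in boolean trees")


def _child_fact_where(pred: Predicate, alias: str) -> str:
    if pred.kind is PredKind.HAS_SEGMENT_LABEL:
        if isinstance(pred.value, (tuple, list)):
            raise SQLCapabilityError(
                "strict (code,scheme) label matching is not in the SQL view")
        return (f"({alias}.attr = 'segment_label' AND "
                f"{alias}.value_text = {_sql_quote(pred.value)})")
    if pred.kind is PredKind.HAS_ANNOTATION_NAME:
        return (f"({alias}.attr IN ('name','segment_label') AND "
                f"{alias}.value_text = {_sql_quote(pred.value)})")
    if pred.kind is PredKind.HAS_DOCUMENT_TITLE:
        return f"{alias}.doc_title = {_sql_quote(pred.value)}"
    if pred.kind is PredKind.EXISTS:
        if pred.field in (None, ""):
            return f"{alias}.attr = 'kind'"
        if pred.field in ("SR", "SEG"):
            return (f"({alias}.attr = 'kind' AND "
                    f"{alias}.value_text = {_sql_quote(pred.field)})")
        return f"{alias}.attr = {_sql_quote(pred.field)}"
    if pred.kind is PredKind.TERM:
        if isinstance(pred.value, (int, float)) and not isinstance(pred.value, bool):
            return (f"({alias}.attr = {_sql_quote(pred.field)} AND "
                    f"{alias}.value_num = {_sql_quote(pred.value)})")
        return (f"({alias}.attr = {_sql_quote(pred.field)} AND "
                f"{alias}.value_text = {_sql_quote(pred.value)})")
    if pred.kind is PredKind.SUBSTRING:
        pat = str(pred.value).replace("%", r"\%").replace("_", r"\_")
        if pred.case_sensitive:
            like = f"{alias}.value_text LIKE {_sql_quote('%' + pat + '%')}"
        else:
            like = (f"LOWER({alias}.value_text) LIKE "
                    f"{_sql_quote('%' + pat.lower() + '%')}")
        return (f"({alias}.attr = {_sql_quote(pred.field)} AND {like} "
                "ESCAPE '\\')")
    if pred.kind is PredKind.RANGE:
        parts = [f"{alias}.attr = {_sql_quote(pred.field)}",
                 f"{alias}.value_num IS NOT NULL"]
        if pred.low is not None:
            parts.append(f"{alias}.value_num >= {_sql_quote(float(pred.low))}")
        if pred.high is not None:
            parts.append(f"{alias}.value_num <= {_sql_quote(float(pred.high))}")
        return "(" + " AND ".join(parts) + ")"
    raise SQLCapabilityError(f"{pred.kind.value} unsupported in SQL subset")


def _split_top_and(query: Query) -> Tuple[List, List]:
    """Split a query into (series sub-trees, nested groups) at the top AND."""
    series_parts: List = []
    nested_groups: List[QueryNode] = []

    def is_pure_series(node) -> bool:
        if isinstance(node, Predicate):
            return node.scope is Scope.SERIES
        if node.op is Op.NESTED:
            return False
        return all(is_pure_series(c) for c in node.children)

    def classify(node):
        if isinstance(node, Predicate):
            if node.scope is Scope.ANNOTATION:
                nested_groups.append(QueryNode(Op.NESTED, (node,)))
            else:
                series_parts.append(node)
        elif node.op is Op.NESTED:
            nested_groups.append(node)
        elif is_pure_series(node):
            series_parts.append(node)
        elif node.op is Op.AND:
            for c in node.children:
                classify(c)
        else:
            raise SQLCapabilityError(
                "annotation conditions must form a single top-level nested "
                "conjunction in the SQL subset")

    classify(query)
    return series_parts, nested_groups


def render_sql(query: Query, level: str = "series") -> str:
    """Render a query to SQL over the parent/child view, within the documented
    subset limits; raises :class:`SQLCapabilityError` beyond them.

    Series level: a boolean tree of series predicates plus at most one nested
    group of at most two positive annotation predicates (instance-level AND is
    expressed as a self-join on the child table constrained to one child row).
    Patient level: a conjunction of at most two series-level conditions
    (self-join on the parent table); three or more would need a >2-way join.
    """
    if level.lower() == "patient":
        if isinstance(query, Predicate) or query.op is not Op.AND:
            conjuncts = [query]
        else:
            conjuncts = list(query.children)
        if len(conjuncts) > 2:
            raise SQLCapabilityError(
                f"patient-level conjunction of {len(conjuncts)} conditions "
                "needs a >2-index join; join queries are restricted to two "
                "indices")
        if len(conjuncts) == 1:
            where = _series_where(conjuncts[0], "p")
            return ("SELECT DISTINCT p.patient_id FROM parent p "
                    f"WHERE {where} ORDER BY p.patient_id")
        w1 = _series_where(conjuncts[0], "p1")
        w2 = _series_where(conjuncts[1], "p2")
        return ("SELECT DISTINCT p1.patient_id FROM parent p1 "
                "JOIN parent p2 ON p2.patient_id = p1.patient_id "
                f"WHERE {w1} AND {w2} ORDER BY p1.patient_id")

    series_parts, nested_groups = _split_top_and(query)
    if len(nested_groups) > 1:
        raise SQLCapabilityError(
            "more than one nested group needs a >2-index join; join queries "
            "are restricted to two indices")
    where = " AND ".join(_series_where(p, "p") for p in series_parts) or "1=1"
    if not nested_groups:
        return (f"SELECT p.series_uid FROM parent p WHERE {where} "
                "ORDER BY p.series_uid")

    group = nested_groups[0]
    preds: List[Predicate] = []

    def collect(node):
        if isinstance(node, Predicate):
            preds.append(node)
        elif node.op in (Op.AND, Op.NESTED):
            for c in node.children:
                collect(c)
        else:
            raise SQLCapabilityError(
                "nested groups in the SQL subset are conjunctions of positive "
                "annotation predicates")

    collect(group)
    if len(preds) > 2:
        raise SQLCapabilityError(
            f"nested conjunction of {len(preds)} annotation conditions needs "
            "a >2-index join; join queries are restricted to two indices")

    joins = ["JOIN child c1 ON c1.series_uid = p.series_uid"]
    conds = [_child_fact_where(preds[0], "c1")]
    if len(preds) == 2:
        joins.append("JOIN child c2 ON c2.series_uid = p.series_uid "
                     "AND c2.child_id = c1.child_id")
        conds.append(_child_fact_where(preds[1], "c2"))
    return ("SELECT DISTINCT p.series_uid FROM parent p "
            + " ".join(joins)
            + f" WHERE {where} AND " + " AND ".join(conds)
            + " ORDER BY p.series_uid")


# ---------------------------------------------------------------------------
# temporal ECG selection
# ---------------------------------------------------------------------------

def select_pre_procedure_ecg(index: Index, patient_id: str,
                             procedure_date: _dt.date) -> Optional[str]:
    """The patient's ECG series with maximal StudyDate ≤ procedure date.

    Ties on the date are broken by lexicographically smaller series UID;
    returns ``None`` when the patient has no pre-procedure ECG.
    """
    candidates = [d for d in index.documents
                  if d.patient_id == patient_id and d.modality == "ECG"
                  and d.study_date is not None
                  and d.study_date <= procedure_date]
    if not candidates:
        return None
    best = min(candidates, key=lambda d: (-d.study_date.toordinal(), d.series_uid))
    return best.series_uid
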