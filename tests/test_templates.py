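import pytest

from srcohort import concepts as C
from srcohort.coding import code
from srcohort.content import ContentItem, Relationship, ValueKind, add_child
from srcohort.templates import (IssueCode, TemplateRegistry,
                                UnknownTemplateError, default_registry,
                                validate_tree)


@pytest.fixture(scope="module")
def reg():
    return default_registry()


def _history_root():
    root = ContentItem.container(C.CARDIOVASCULAR_PATIENT_HISTORY)
    soc = add_child(root, ContentItem.container(C.SOCIAL_HISTORY),
                    Relationship.CONTAINS)
    add_child(soc, ContentItem.code(C.TOBACCO_SMOKER, C.YES))
    return root


def test_conforming_tree_validates_clean(reg):
    assert validate_tree(_history_root(), reg.get("3802"), reg) == []


def test_bad_root_title(reg):
    root = ContentItem.container(C.SOCIAL_HISTORY)
    issues = validate_tree(root, reg.get("3802"), reg)
    assert [i.code for i in issues] == [IssueCode.BAD_ROOT]


def test_non_container_root(reg):
    root = ContentItem.text(C.COMMENT, "x")
    issues = validate_tree(root, reg.get("3802"), reg)
    assert issues[0].code is IssueCode.BAD_ROOT


def test_unknown_concept_reported_with_path(reg):
    root = _history_root()
    add_child(root, ContentItem.code(code("X1", "99SRC", "Mystery"), C.YES))
    issues = validate_tree(root, reg.get("3802"), reg)
    assert len(issues) == 1
    assert issues[0].code is IssueCode.UNKNOWN_CONCEPT
    assert issues[0].path == ("Cardiovascular Patient History", "Mystery")


def test_missing_mandatory_in_nested_template(reg):
    root = _history_root()
    add_child(root, ContentItem.container(C.MEDICAL_DEVICE_USE),
              Relationship.CONTAINS)  # empty: lacks the mandatory device item
    issues = validate_tree(root, reg.get("3802"), reg)
    assert [i.code for i in issues] == [IssueCode.MISSING_MANDATORY]
    assert issues[0].path[-1] == "Device"


def test_wrong_value_kind(reg):
    root = _history_root()
    add_child(root, ContentItem.text(C.DIABETES_MELLITUS, "yes"))
    issues = validate_tree(root, reg.get("3802"), reg)
    assert [i.code for i in issues] == [IssueCode.WRONG_VALUE_KIND]
    assert issues[0].path[-1] == "Diabetes Mellitus"


def test_bad_relationship(reg):
    root = _history_root()
    add_child(root, ContentItem.code(C.DIABETES_MELLITUS, C.NO,
                                     Relationship.HAS_ACQ_CONTEXT))
    issues = validate_tree(root, reg.get("3802"), reg)
    assert [i.code for i in issues] == [IssueCode.BAD_RELATIONSHIP]


def test_wrong_cardinality(reg):
    root = _history_root()
    add_child(root, ContentItem.code(C.DIABETES_MELLITUS, C.NO))
    add_child(root, ContentItem.code(C.DIABETES_MELLITUS, C.YES))
    issues = validate_tree(root, reg.get("3802"), reg)
    assert [i.code for i in issues] == [IssueCode.WRONG_CARDINALITY]


def test_conditional_row_fires_only_with_sibling(reg):
    proc = reg.get("3802_PROC")
    root = ContentItem.container(C.PROCEDURE_CONTEXT)
    # no prosthesis model: size not required
    assert validate_tree(root, proc, reg) == []
    add_child(root, ContentItem.code(C.PROSTHESIS_MODEL,
                                     code("M1", "99SRC", "model")))
    issues = validate_tree(root, proc, reg)
    assert [i.code for i in issues] == [IssueCode.MISSING_MANDATORY]
    assert issues[0].path[-1] == "Prosthesis Size"


def test_wildcard_rows_match_by_kind(reg):
    root = ContentItem.container(C.IMAGING_MEASUREMENT_REPORT)
    grp = add_child(root, ContentItem.container(C.MEASUREMENT_GROUP),
                    Relationship.CONTAINS)
    add_child(grp, ContentItem.num(code("ANY1", "99SRC", "anything"),
                                   "4.2", C.MILLIMETRE))
    add_child(grp, ContentItem.text(code("ANY2", "99SRC", "other"), "note"))
    assert validate_tree(root, reg.get("1500"), reg) == []


def test_unknown_template_id(reg):
    with pytest.raises(UnknownTemplateError):
        reg.get("9999")


def test_registry_yaml_round_trip(tmp_path, reg):
    p = tmp_path / "registry.yaml"
    reg.to_yaml(p)
    reg2 = TemplateRegistry.from_yaml(p)
    assert len(reg2) == len(reg)
    for t in reg:
        t2 = reg2.get(t.tid)
        assert t2 == t


def test_registry_rejects_duplicate_tid(reg):
    r = TemplateRegistry([reg.get("3700")])
    with pytest.raises(ValueError):
        r.register(reg.get("3700"))
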