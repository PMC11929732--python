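import datetime as dt
import json

import pytest

from srcohort import concepts as C
from srcohort.indexing import build_index, default_spec_set
from srcohort.query import (AND, NESTED, Mode, PredKind, Predicate, Scope,
                            evaluate, evaluate_patient,
                            select_pre_procedure_ecg)
from srcohort.synthetic import (ConfigError, SITE_PRESETS, SiteConfig,
                                consortium_from_yaml, generate_consortium,
                                generate_site, write_site)


def _index(site, spec_set):
    return build_index(site.parents, site.annotations, spec_set)


@pytest.fixture(scope="module")
def site():
    return generate_site(SiteConfig("siteT", n_patients=40, seed=7))


@pytest.fixture(scope="module")
def site_index(site):
    return _index(site, default_spec_set())


def test_generation_deterministic():
    cfg = SiteConfig("siteD", n_patients=15, seed=3)
    a, b = generate_site(cfg), generate_site(cfg)
    assert a.manifest == b.manifest
    assert a.files == b.files


def test_different_seeds_differ():
    a = generate_site(SiteConfig("siteD", n_patients=15, seed=3))
    b = generate_site(SiteConfig("siteD", n_patients=15, seed=4))
    assert a.manifest != b.manifest


def test_config_validation():
    with pytest.raises(ConfigError):
        SiteConfig("", n_patients=10)
    with pytest.raises(ConfigError):
        SiteConfig("s", n_patients=0)
    with pytest.raises(ConfigError):
        SiteConfig("s", n_patients=5, p_ct=1.5)
    with pytest.raises(ConfigError):
        SiteConfig("s", n_patients=5, date_start=dt.date(2020, 1, 1),
                   date_end=dt.date(2019, 1, 1))
    with pytest.raises(ConfigError):
        SiteConfig("s", n_patients=5, ct_series_choices=(0,))


def test_phase_truth_matches_query(site, site_index):
    q = Predicate(Scope.SERIES, PredKind.SUBSTRING, field="series_description",
                  value="40%")
    got = evaluate(site_index, q).ids
    assert sorted(got) == site.manifest["truth"]["series_with_phase"]["40%"]


def test_lvrv_truth_nested_and_flattened(site, site_index):
    q = NESTED(
        Predicate(Scope.ANNOTATION, PredKind.HAS_SEGMENT_LABEL,
                  value=C.LEFT_VENTRICLE.meaning),
        Predicate(Scope.ANNOTATION, PredKind.HAS_SEGMENT_LABEL,
                  value=C.RIGHT_VENTRICLE.meaning))
    truth = site.manifest["truth"]
    assert sorted(evaluate(site_index, q, Mode.NESTED).ids) == \
        truth["series_with_lv_and_rv_nested"]
    assert sorted(evaluate(site_index, q, Mode.FLATTENED).ids) == \
        truth["series_with_lv_and_rv_flattened"]


def test_ct_and_ecg_truth(site, site_index):
    q = AND(Predicate(Scope.SERIES, PredKind.HAS_MODALITY, value="CT"),
            Predicate(Scope.SERIES, PredKind.HAS_MODALITY, value="ECG"))
    got = evaluate_patient(site_index, q).ids
    assert sorted(got) == site.manifest["truth"]["patients_ct_and_ecg"]


def test_pre_procedure_ecg_truth(site, site_index):
    for pid, proc in site.manifest["procedure_dates"].items():
        want = site.manifest["truth"]["pre_procedure_ecg"][pid]
        got = select_pre_procedure_ecg(site_index, pid,
                                       dt.date.fromisoformat(proc))
        assert got == want


def test_zero_probability_empties_truth():
    site = generate_site(SiteConfig("siteZ", n_patients=25, seed=2,
                                    p_ecg=0.0, p_post_procedure_ecg=0.0,
                                    p_lvrv_seg=0.0))
    truth = site.manifest["truth"]
    assert truth["patients_ct_and_ecg"] == []
    assert truth["series_with_lv_and_rv_nested"] == []
    assert all(v is None for v in truth["pre_procedure_ecg"].values())


def test_certain_probability_fills_truth():
    site = generate_site(SiteConfig("siteO", n_patients=25, seed=2,
                                    p_ct=1.0, p_ecg=1.0))
    truth = site.manifest["truth"]
    assert truth["patients_ct_and_ecg"] == site.manifest["patient_ids"]


def test_pacemaker_label_frequency_in_binomial_band():
    # p=0.5, n=200: a 6-sigma band is ~[58, 142]; a miss means a broken sampler
    site = generate_site(SiteConfig("siteB", n_patients=200, seed=9,
                                    p_pacemaker_label=0.5))
    k = len(site.manifest["truth"]["patients_with_pacemaker_label"])
    assert 58 <= k <= 142


def test_consortium_distinct_namespaces():
    sites = generate_consortium([SiteConfig("a", 5, seed=1),
                                 SiteConfig("b", 5, seed=2)])
    ids = [o.patient_id for s in sites for o in s.objects]
    assert all(i.startswith(("a-", "b-")) for i in ids)
    with pytest.raises(ConfigError):
        generate_consortium([SiteConfig("a", 5), SiteConfig("a", 5)])
    with pytest.raises(ConfigError):
        generate_consortium([SiteConfig("a", 5), SiteConfig("a-1", 5)])


def test_write_site_layout(tmp_path):
    site = generate_site(SiteConfig("siteW", n_patients=5, seed=1))
    root = write_site(site, tmp_path)
    assert root == tmp_path / "siteW"
    manifest = json.loads((root / "manifest.json").read_text())
    # JSON round-trips tuples as lists; compare in the JSON value domain
    assert manifest == json.loads(json.dumps(site.manifest))
    written = {p.name for p in root.rglob("*.dcm")}
    assert len(written) == len(site.files)


def test_consortium_from_yaml_presets(tmp_path):
    p = tmp_path / "c.yaml"
    p.write_text(
        "sites:\n"
        "  - {site_name: a, n_patients: 5, seed: 1, preset: imaging-heavy}\n"
        "  - {site_name: b, n_patients: 5, seed: 2, preset: label-poor,\n"
        "     p_ct: 0.5}\n")
    cfgs = consortium_from_yaml(p)
    assert cfgs[0].p_ct == SITE_PRESETS["imaging-heavy"]["p_ct"]
    assert cfgs[1].p_ct == 0.5  # explicit value overrides the preset
    assert cfgs[1].p_lvrv_seg == SITE_PRESETS["label-poor"]["p_lvrv_seg"]


def test_consortium_from_yaml_errors(tmp_path):
    p = tmp_path / "bad.yaml"
    p.write_text("sites: []\n")
    with pytest.raises(ConfigError):
        consortium_from_yaml(p)
    p.write_text("sites:\n  - {site_name: a, n_patients: 5, preset: nope}\n")
    with pytest.raises(ConfigError, match="preset"):
        consortium_from_yaml(p)
    p.write_text("sites:\n  - {site_name: a, n_patients: 5, bogus_key: 1}\n")
    with pytest.raises(ConfigError, match="bad site config"):
        consortium_from_yaml(p)


def test_index_builds_cleanly_without_orphans(site, site_index):
    assert site_index.dropped_orphans == []
    assert site_index.patients() == set(site.manifest["patient_ids"])
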