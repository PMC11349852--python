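"""Bundle loading, layout equivalence and referential integrity."""

import copy
import json
import random

import pytest

from luxmeta import (
    BundleLoadError,
    FixtureSpec,
    MetadataBundle,
    check_crossrefs,
    check_study_dataset_closure,
    generate_bundle,
    load_bundle,
    validate_bundle,
    write_bundle,
)
from luxmeta.bundle import write_combined


def test_directory_layout_round_trip(tmp_path, registry, clean_bundle):
    write_bundle(clean_bundle, tmp_path, registry)
    loaded, report = load_bundle(tmp_path, registry)
    assert loaded == clean_bundle
    assert report.valid


def test_combined_document_equals_directory_layout(tmp_path, registry, clean_bundle):
    dir_root = tmp_path / "dir"
    combined = tmp_path / "bundle.json"
    write_bundle(clean_bundle, dir_root, registry)
    write_combined(clean_bundle, combined)
    b1, r1 = load_bundle(dir_root, registry)
    b2, r2 = load_bundle(combined, registry)
    assert b1 == b2
    assert [i.to_json_obj() for i in r1.issues] == [i.to_json_obj() for i in r2.issues]


def test_missing_study_document_is_fatal(tmp_path):
    (tmp_path / "participants").mkdir()
    with pytest.raises(BundleLoadError, match="study"):
        load_bundle(tmp_path)


def test_malformed_json_is_fatal_with_position(tmp_path):
    (tmp_path / "study.json").write_text('{"study_internal_id": }', encoding="utf-8")
    with pytest.raises(BundleLoadError, match=r"line 1"):
        load_bundle(tmp_path)


def test_dangling_device_reference_named(clean_bundle):
    mutated = copy.deepcopy(clean_bundle)
    mutated.datasets[0]["dataset_crossref"]["dataset_crossref_device_id"] = "devX"
    issues = check_crossrefs(mutated)
    dangling = [i for i in issues if i.rule_id == "dangling-crossref"]
    assert len(dangling) == 1 and "devX" in dangling[0].message


def test_duplicate_participant_id_error(clean_bundle):
    mutated = copy.deepcopy(clean_bundle)
    mutated.participants.append(copy.deepcopy(mutated.participants[0]))
    rules = [i.rule_id for i in check_crossrefs(mutated) if i.severity == "error"]
    assert rules == ["duplicate-id"]


def test_consistent_bundle_has_no_crossref_issues(clean_bundle):
    assert check_crossrefs(clean_bundle) == []


def test_study_dataset_closure_both_directions(clean_bundle):
    m = copy.deepcopy(clean_bundle)
    m.study["study_datasets"] = list(m.study["study_datasets"]) + ["d-extra"]
    issues = check_study_dataset_closure(m)
    assert [(i.severity, i.rule_id) for i in issues] == [("error", "dataset-not-in-study")]

    m = copy.deepcopy(clean_bundle)
    m.study["study_datasets"] = m.study["study_datasets"][:-1]
    issues = check_study_dataset_closure(m)
    assert [(i.severity, i.rule_id) for i in issues] == [("warning", "unlisted-dataset")]

    assert check_study_dataset_closure(clean_bundle) == []


def _crossref_oracle(bundle):
    """Brute-force reference-graph enumeration (independent of check_crossrefs)."""
    errors = []
    for kind, records, idf in (("participant", bundle.participants, "participant_internal_id"),
                               ("dataset", bundle.datasets, "dataset_internal_id"),
                               ("device", bundle.devices, "device_internal_id")):
        ids = [r.get(idf) for r in records if isinstance(r.get(idf), str)]
        for rid in set(ids):
            errors += [("duplicate-id", kind, rid)] * (ids.count(rid) - 1)
    pids = {r.get("participant_internal_id") for r in bundle.participants}
    dids = {r.get("device_internal_id") for r in bundle.devices}
    sid = bundle.study.get("study_internal_id")
    for ds in bundle.datasets:
        cr = ds.get("dataset_crossref", {})
        if cr.get("dataset_crossref_study_id") != sid:
            errors.append(("dangling-crossref", "dataset", "study"))
        if cr.get("dataset_crossref_participant_id") not in pids:
            errors.append(("dangling-crossref", "dataset", "participant"))
        if cr.get("dataset_crossref_device_id") not in dids:
            errors.append(("dangling-crossref", "dataset", "device"))
    return sorted(e[0] for e in errors)


def test_crossrefs_agree_with_bruteforce_oracle(registry):
    """Randomly perturbed bundles: error multiset matches graph enumeration."""
    for seed in range(60):
        rng = random.Random(seed)
        bundle = generate_bundle(
            FixtureSpec(seed=seed, n_participants=rng.randint(1, 4),
                        n_devices=rng.randint(1, 3),
                        datasets_per_participant=rng.randint(1, 2)), registry)
        mutated = MetadataBundle(study=copy.deepcopy(bundle.study),
                                 participants=copy.deepcopy(bundle.participants),
                                 datasets=copy.deepcopy(bundle.datasets),
                                 devices=copy.deepcopy(bundle.devices))
        for _ in range(rng.randint(0, 3)):
            op = rng.choice(("dangle-p", "dangle-d", "dup-p", "dup-dev", "noop"))
            if op == "dangle-p":
                ds = rng.choice(mutated.datasets)
                ds["dataset_crossref"]["dataset_crossref_participant_id"] = f"ghost{rng.randint(0, 9)}"
            elif op == "dangle-d":
                ds = rng.choice(mutated.datasets)
                ds["dataset_crossref"]["dataset_crossref_device_id"] = f"ghost{rng.randint(0, 9)}"
            elif op == "dup-p":
                mutated.participants.append(copy.deepcopy(rng.choice(mutated.participants)))
            elif op == "dup-dev":
                mutated.devices.append(copy.deepcopy(rng.choice(mutated.devices)))
        got = sorted(i.rule_id for i in check_crossrefs(mutated) if i.severity == "error")
        assert got == _crossref_oracle(mutated), seed


def test_combined_document_without_study_key(tmp_path):
    path = tmp_path / "b.json"
    path.write_text(json.dumps({"participants": []}), encoding="utf-8")
    with pytest.raises(BundleLoadError, match="study"):
        load_bundle(path)


def test_file_level_timezone_conflict_is_warning(registry, clean_bundle):
    m = copy.deepcopy(clean_bundle)
    m.datasets[0]["dataset_file"][0]["dataset_file_timezone"] = "Europe/Paris"
    report = validate_bundle(m, registry)
    assert report.valid
    assert "timezone-conflict" in [i.rule_id for i in report.warnings()]
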