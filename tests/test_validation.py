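"""Record validation: formats, conditionals and the registry-driven walk."""

import random

import pytest
from hypothesis import given, strategies as st

from luxmeta import (
    check_contributor_roles,
    check_datetime_spec,
    check_preprocessing,
    check_spectral_sensitivity,
    validate_datetime_format,
    validate_email,
    validate_orcid,
    validate_record,
    validate_timezone,
)

# --- ORCID ---------------------------------------------------------------

def orcid_check_char_oracle(digits15: str) -> str:
    """Independent ISO 7064 mod-11-2 formulation via powers of two mod 11.

    A full identifier d1..d15 c is valid iff
    sum(d_i * 2^(16-i)) + c == 1 (mod 11), with c = 10 written as 'X'.
    """
    total = sum(int(d) * pow(2, 16 - i, 11) for i, d in enumerate(digits15, start=1))
    c = (1 - total) % 11
    return "X" if c == 10 else str(c)


def _fmt(body16: str) -> str:
    return "-".join(body16[i:i + 4] for i in range(0, 16, 4))


def test_orcid_known_example_and_perturbation():
    assert validate_orcid("0000-0002-1825-0097") is True
    assert validate_orcid("0000-0002-1825-0098") is False
    assert validate_orcid("") is False
    assert validate_orcid("0000-0002-1825-009") is False
    assert validate_orcid("0000 0002 1825 0097") is False


def test_orcid_agrees_with_independent_oracle():
    rng = random.Random(20240817)
    for _ in range(2000):
        digits = "".join(str(rng.randrange(10)) for _ in range(15))
        check = orcid_check_char_oracle(digits)
        good = _fmt(digits + check)
        assert validate_orcid(good), good
        wrong = "0" if check == "X" else ("X" if rng.random() < 0.2 else
                                          str((int(check) + rng.randrange(1, 10)) % 10))
        if wrong != check:
            assert not validate_orcid(_fmt(digits + wrong))


# --- email / timezone ----------------------------------------------------

@pytest.mark.parametrize(
    "text, ok",
    [
        ("a@b.org", True),
        ("jürgen.münch@uni-liège.example", True),
        ("a.b.org", False),
        ("@b.org", False),
        ("a@borg", False),
        ("a@@b.org", False),
        ("a@b..org", False),
        ("a b@c.org", False),
    ],
)
def test_email_syntax(text, ok):
    assert validate_email(text) is ok


@pytest.mark.parametrize(
    "zone, ok",
    [("Europe/Berlin", True), ("UTC", True), ("America/Argentina/Ushuaia", True),
     ("Mars/Olympus", False), ("europe/berlin", False), ("", False)],
)
def test_timezone_membership(zone, ok):
    assert validate_timezone(zone) is ok


# --- datetime formats ----------------------------------------------------

@pytest.mark.parametrize(
    "fmt, role, ok",
    [
        ("YYYY/MM/DD", "date", True),
        ("YYYY-MM-DD", "date", True),
        ("DD.MM.YYYY", "date", True),
        ("YY/MM/DD", "date", True),
        ("HH:MM:SS", "time", True),
        ("HH:MM", "time", True),
        ("HH:MM:SS.SSS", "time", True),
        ("YYYY/MM/DD HH:MM:SS", "datetime", True),
        ("YYYY/QQ", "date", False),
        ("YYYY/MM", "date", False),           # no day token
        ("YYYY/MM/DD", "time", False),
        ("HH:MM:SS", "date", False),
        ("YYYY/MM/DD HH:MM:SS", "date", False),
        ("", "date", False),
    ],
)
def test_datetime_format_grammar(fmt, role, ok):
    assert validate_datetime_format(fmt, role) is ok


# --- conditional truth tables --------------------------------------------

def test_preprocessing_truth_table():
    assert check_preprocessing({"dataset_file_preprocessing_bol": True,
                                "dataset_file_preprocessing_desc": ["resampled to 60 s"]}) == []
    issues = check_preprocessing({"dataset_file_preprocessing_bol": True})
    assert [i.rule_id for i in issues] == ["conditional-preprocessing"]
    assert check_preprocessing({"dataset_file_preprocessing_bol": False}) == []
    # empty-string descriptions do not satisfy the requirement
    issues = check_preprocessing({"dataset_file_preprocessing_bol": True,
                                  "dataset_file_preprocessing_desc": ["  "]})
    assert [i.rule_id for i in issues] == ["conditional-preprocessing"]


def test_datetime_spec_presence_truth_table():
    base = {"dataset_datetime_date": "date", "dataset_datetime_dateformat": "YYYY/MM/DD"}
    for has_time in (False, True):
        for has_fmt in (False, True):
            spec = dict(base)
            if has_time:
                spec["dataset_datetime_time"] = "time"
            if has_fmt:
                spec["dataset_datetime_timeformat"] = "HH:MM:SS"
            issues = [i.rule_id for i in check_datetime_spec(spec)]
            expect_error = has_time != has_fmt
            assert ("datetime-spec-incomplete" in issues) == expect_error, (has_time, has_fmt)


def test_datetime_spec_combined_format_accepted():
    spec = {"dataset_datetime_date": "datetime",
            "dataset_datetime_dateformat": "YYYY/MM/DD HH:MM:SS"}
    assert check_datetime_spec(spec) == []
    # a datetime-shaped format is wrong once a separate time column exists
    spec.update({"dataset_datetime_time": "t", "dataset_datetime_timeformat": "HH:MM:SS"})
    assert "bad-datetime-format" in [i.rule_id for i in check_datetime_spec(spec)]


# --- spectral sensitivity ------------------------------------------------

def _pts(pairs):
    return [{"datasheet_calibration_spectral_sensitivity_wavelength": w,
             "datasheet_calibration_spectral_sensitivity_relative": r} for w, r in pairs]


def test_spectral_sensitivity_rules():
    assert check_spectral_sensitivity(_pts([(400, 0.2), (500, 1.0), (600, 0.3)])) == []
    rules = [i.rule_id for i in check_spectral_sensitivity(_pts([(500, 1.0), (400, 0.2)]))]
    assert "non-ascending-spectral" in rules
    rules = [i.rule_id for i in check_spectral_sensitivity(_pts([(400, 0.1), (500, 0.5)]))]
    assert rules == ["spectral-peak-unnormalized"]
    assert [i.rule_id for i in check_spectral_sensitivity([])] == ["spectral-empty"]
    rules = [i.rule_id for i in check_spectral_sensitivity(_pts([(400, -0.1), (500, 1.0)]))]
    assert "negative-spectral" in rules


# --- contributor roles ---------------------------------------------------

def test_data_curation_role_requirement():
    ok = [{"contributor_roles": ["Data curation"]}]
    assert check_contributor_roles(ok) == []
    assert check_contributor_roles([{"contributor_roles": ["data CURATION"]}]) == []
    bad = [{"contributor_roles": ["Conceptualization"]},
           {"contributor_roles": ["Software"]}]
    assert [i.rule_id for i in check_contributor_roles(bad)] == ["missing-data-curation"]
    assert [i.rule_id for i in check_contributor_roles([])] == ["missing-data-curation"]


# --- validate_record -----------------------------------------------------

def test_empty_participant_record_reports_both_required_fields(registry):
    report = validate_record({"participant_sex": "female"}, "participant", registry)
    missing = {i.field_path for i in report.errors() if i.rule_id == "missing-required"}
    assert missing == {"participant_internal_id", "participant_age"}


def test_participant_age_type_mismatch(registry):
    rec = {"participant_internal_id": "p1", "participant_age": "forty-two"}
    report = validate_record(rec, "participant", registry)
    assert [i.rule_id for i in report.errors()] == ["type-mismatch"]
    # booleans are not integers
    rec["participant_age"] = True
    report = validate_record(rec, "participant", registry)
    assert [i.rule_id for i in report.errors()] == ["type-mismatch"]


def test_participant_extra_field_is_anonymity_error(registry):
    rec = {"participant_internal_id": "p1", "participant_age": 30,
           "participant_full_name": "Jane Doe"}
    report = validate_record(rec, "participant", registry)
    assert [i.rule_id for i in report.errors()] == ["participant-extra-field"]


def test_unknown_field_elsewhere_is_warning(registry, clean_bundle):
    rec = dict(clean_bundle.devices[0])
    rec["device_firmware"] = "2.1.0"
    report = validate_record(rec, "device", registry)
    assert report.valid
    assert [i.rule_id for i in report.warnings()] == ["unknown-field"]


def test_fully_populated_fixture_records_validate(registry, clean_bundle):
    cases = [("study", clean_bundle.study),
             ("contributor", clean_bundle.study["study_contributors"][0]),
             ("participant", clean_bundle.participants[0]),
             ("dataset", clean_bundle.datasets[0]),
             ("device", clean_bundle.devices[0]),
             ("datasheet", clean_bundle.devices[0]["device_datasheet"])]
    for kind, rec in cases:
        report = validate_record(rec, kind, registry)
        assert report.valid, (kind, [i.to_json_obj() for i in report.errors()])


def test_issue_order_follows_document_order(registry):
    report = validate_record({}, "dataset", registry)
    paths = [i.field_path for i in report.errors()]
    assert paths.index("dataset_internal_id") < paths.index("dataset_timezone")


def test_funding_sources_must_be_nonempty_when_present(registry, clean_bundle):
    study = dict(clean_bundle.study)
    study["study_funding_sources"] = []
    report = validate_record(study, "study", registry)
    assert "empty-funding" in [i.rule_id for i in report.errors()]


@given(st.integers(0, 2 ** 31 - 1))
def test_valid_generated_records_always_validate(registry, seed):
    from luxmeta import FixtureSpec, generate_bundle

    bundle = generate_bundle(FixtureSpec(seed=seed, n_participants=1, n_devices=1), registry)
    assert validate_record(bundle.study, "study", registry).valid
    assert validate_record(bundle.datasets[0], "dataset", registry).valid
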