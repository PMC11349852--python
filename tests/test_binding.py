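"""Metadata-driven parsing of light-logger tables."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from luxmeta import (
    AuditError,
    BindingError,
    CalibrationError,
    apply_calibration,
    audit_sampling,
    bind_variables,
    load_light_table,
    parse_datetimes,
    read_delimited,
)

SPLIT_SPEC = {
    "dataset_datetime_date": "date",
    "dataset_datetime_dateformat": "YYYY/MM/DD",
    "dataset_datetime_time": "time",
    "dataset_datetime_timeformat": "HH:MM:SS",
}
COMBINED_SPEC = {
    "dataset_datetime_date": "datetime",
    "dataset_datetime_dateformat": "YYYY/MM/DD HH:MM:SS",
}


def test_split_datetime_parse_with_summer_offset():
    table = pd.DataFrame({"date": ["2021/06/21"], "time": ["08:30:00"]})
    instants, issues = parse_datetimes(table, SPLIT_SPEC, "Europe/Berlin")
    assert issues == []
    assert instants[0].isoformat() == "2021-06-21T08:30:00+02:00"


def test_split_and_combined_forms_agree():
    dates = ["2021/06/21", "2021/06/21", "2021/06/22"]
    times = ["08:30:00", "23:59:59", "00:00:59"]
    split = pd.DataFrame({"date": dates, "time": times})
    combined = pd.DataFrame({"datetime": [f"{d} {t}" for d, t in zip(dates, times)]})
    a, _ = parse_datetimes(split, SPLIT_SPEC, "Europe/Berlin")
    b, _ = parse_datetimes(combined, COMBINED_SPEC, "Europe/Berlin")
    assert list(a) == list(b)


def test_impossible_date_names_row():
    table = pd.DataFrame({"date": ["2021/06/21", "2021/13/40"], "time": ["01:00:00"] * 2})
    with pytest.raises(BindingError, match="row 1"):
        parse_datetimes(table, SPLIT_SPEC, "Europe/Berlin")


def test_missing_declared_column_is_binding_error():
    table = pd.DataFrame({"DATE": ["2021/06/21"]})
    with pytest.raises(BindingError, match="'date'"):
        parse_datetimes(table, SPLIT_SPEC, "Europe/Berlin")


def test_ambiguous_dst_fold_resolves_to_earlier_offset_with_warning():
    # Europe/Berlin fell back on 2021-10-31; 02:30 occurred twice
    table = pd.DataFrame({"datetime": ["2021/10/31 02:30:00"]})
    instants, issues = parse_datetimes(table, COMBINED_SPEC, "Europe/Berlin")
    assert [i.rule_id for i in issues] == ["ambiguous-local-time"]
    assert instants[0].utcoffset().total_seconds() == 7200  # earlier (summer) offset


def test_nonexistent_local_time_is_error():
    # Europe/Berlin sprang forward on 2021-03-28; 02:30 never existed
    table = pd.DataFrame({"datetime": ["2021/03/28 02:30:00"]})
    with pytest.raises(BindingError, match="onexistent"):
        parse_datetimes(table, COMBINED_SPEC, "Europe/Berlin")


# --- calibration ---------------------------------------------------------

@pytest.mark.parametrize(
    "expr, expected",
    [
        ("1.10*x + 0.5", [11.5, 22.5]),
        ("x", [10.0, 20.0]),
        ("", [10.0, 20.0]),
        (None, [10.0, 20.0]),
        ("2*x", [20.0, 40.0]),
        ("x - 1", [9.0, 19.0]),
        ("0.5 + 2*x", [20.5, 40.5]),
        ("x*2 + 1", [21.0, 41.0]),
    ],
)
def test_affine_calibration(expr, expected):
    out = apply_calibration(np.array([10.0, 20.0]), expr)
    assert np.allclose(out, expected)


@pytest.mark.parametrize("expr", ["log10(x)+2", "x**2", "a*x", "x + y", "2x"])
def test_calibration_outside_grammar_raises(expr):
    with pytest.raises(CalibrationError):
        apply_calibration(np.array([1.0]), expr)


def test_identity_calibration_is_noop_series():
    s = pd.Series([1.5, 2.5])
    assert apply_calibration(s, "x") is s


# --- sampling audit ------------------------------------------------------

def _stamps(deltas_s, start="2024-03-04T00:00:00+01:00"):
    base = pd.Timestamp(start)
    out = [base]
    for d in deltas_s:
        out.append(out[-1] + pd.Timedelta(seconds=d))
    return pd.DatetimeIndex(out)


def test_exact_spacing_passes():
    audit = audit_sampling(_stamps([60] * 99), 60)
    assert audit.pass_ and audit.gap_indices == () and audit.median_observed_s == 60


def test_single_gap_detected_at_position():
    deltas = [60] * 99
    deltas[49] = 120
    audit = audit_sampling(_stamps(deltas), 60)
    assert audit.gap_indices == (50,)
    assert not audit.pass_


def test_declared_interval_mismatch_fails():
    audit = audit_sampling(_stamps([60] * 99), 30)
    assert not audit.pass_ and audit.median_observed_s == 60


def test_audit_requires_two_timestamps():
    with pytest.raises(AuditError):
        audit_sampling(_stamps([])[:1], 60)


@given(st.lists(st.integers(30, 200), min_size=1, max_size=60), st.integers(40, 120))
def test_audit_agrees_with_bruteforce_scan(deltas, declared):
    audit = audit_sampling(_stamps(deltas), declared)
    # brute force over successive pairs
    med = float(np.median(sorted(deltas)[len(deltas) // 2:len(deltas) // 2 + 1])) \
        if len(deltas) % 2 else float(np.median(deltas))
    med = float(np.median(deltas))
    gaps = tuple(i + 1 for i, d in enumerate(deltas) if d > 1.5 * declared)
    assert audit.gap_indices == gaps
    assert audit.median_observed_s == pytest.approx(med)
    assert audit.pass_ == (abs(med - declared) <= 0.05 * declared and not gaps)


# --- variable binding ----------------------------------------------------

def _descriptor():
    return {
        "dataset_file_auxiliary": False,
        "dataset_file_variables": [
            {"dataset_file_variables_name": "lux",
             "dataset_file_variables_labels": "illuminance",
             "dataset_file_variables_units": "lx"},
            {"dataset_file_variables_name": "mEDI",
             "dataset_file_variables_labels": "melanopic_edi",
             "dataset_file_variables_units": "lx"},
        ],
    }


def _dataset():
    return {"dataset_illuminance": "lux", "dataset_meledi": "mEDI",
            "dataset_datetime": COMBINED_SPEC}


def test_bind_role_tags_columns():
    table = pd.DataFrame({"lux": ["10.0"], "mEDI": ["9.0"]})
    lt = bind_variables(table, _descriptor(), _dataset())
    assert lt.roles == {"illuminance": "illuminance", "melEDI": "melanopic_edi"}
    assert lt.units == {"illuminance": "lx", "melanopic_edi": "lx"}
    assert lt.column("melanopic_edi").iloc[0] == pytest.approx(9.0)


def test_bind_without_meledi_role():
    ds = _dataset()
    del ds["dataset_meledi"]
    desc = _descriptor()
    desc["dataset_file_variables"].pop()
    table = pd.DataFrame({"lux": ["10.0"]})
    lt = bind_variables(table, desc, ds)
    assert "melEDI" not in lt.roles


def test_case_mismatch_is_binding_error():
    table = pd.DataFrame({"LUX": ["10.0"], "mEDI": ["9.0"]})
    with pytest.raises(BindingError, match="lux"):
        bind_variables(table, _descriptor(), _dataset())


def test_delimiter_autodetection():
    for delim in (",", ";", "\t"):
        text = f"a{delim}b\n1{delim}2\n"
        frame = read_delimited(io.StringIO(text))
        assert list(frame.columns) == ["a", "b"]


def test_fixture_file_binds_against_generating_record(fixture_tree):
    root, bundle, spec = fixture_tree
    for ds in bundle.datasets:
        table, audit = load_light_table(ds, root / "data")
        assert len(table.frame) == 1440
        assert audit.pass_
        assert [i for i in table.issues if i.severity == "error"] == []


def test_missing_data_file_reported(fixture_tree, tmp_path):
    _, bundle, _ = fixture_tree
    with pytest.raises(BindingError, match="missing on disk"):
        load_light_table(bundle.datasets[0], tmp_path / "nowhere")
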