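"""Metadata-driven parsing of light-logger data files.

A dataset record fully describes the tabular exports of one participant's
light logger: which files belong to it, their delimiter-text dialect and
encoding, which column holds the timestamp and in what format, which
columns hold photopic illuminance and (optionally) melanopic EDI, the units
of every variable, an optional affine calibration per variable, the Olson
timezone, and the nominal sampling interval.  This module turns that
description plus the raw file into a :class:`LightTable` — timezone-aware
timestamps and unit-annotated columns — and audits the observed sampling
interval against the declared one.

Column-name matching is exact and case-sensitive: logger export headers are
machine-written, and silent case-folding would hide export drift.
"""

from __future__ import annotations

import csv
import io
import json
import os
import re
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .validation import (
    ValidationIssue,
    format_to_strftime,
    validate_timezone,
)

__all__ = [
    "LightTable",
    "IntervalAudit",
    "BindingError",
    "CalibrationError",
    "AuditError",
    "read_delimited",
    "parse_datetimes",
    "bind_variables",
    "apply_calibration",
    "audit_sampling",
    "load_light_table",
    "GAP_FACTOR",
    "INTERVAL_REL_TOL",
]

#: A successive difference larger than this multiple of the declared
#: interval counts as a recording gap.
GAP_FACTOR = 1.5
#: Relative tolerance on the median observed interval vs. the declared one.
INTERVAL_REL_TOL = 0.05


class BindingError(ValueError):
    """Declared columns/files and the actual data disagree."""


class CalibrationError(ValueError):
    """Calibration expression falls outside the affine mini-grammar."""


class AuditError(ValueError):
    """Sampling audit is impossible (fewer than two timestamps)."""


@dataclass
class LightTable:
    """A parsed light-exposure time series.

    ``frame`` is indexed by timezone-aware timestamps; ``units`` maps each
    column label to its declared unit; ``roles`` maps the semantic roles
    ``illuminance`` and ``melEDI`` to column labels where declared.
    """

    frame: pd.DataFrame
    units: dict
    roles: dict = dc_field(default_factory=dict)
    source_file: str = ""
    auxiliary: bool = False
    issues: list = dc_field(default_factory=list)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.frame.index

    def column(self, label: str) -> pd.Series:
        return self.frame[label]

    def to_csv_with_units(self, path: Union[str, os.PathLike]) -> None:
        """Write a tidy CSV plus a JSON sidecar holding units and roles."""
        path = os.fspath(path)
        out = self.frame.copy()
        out.insert(0, "timestamp", self.frame.index.map(lambda t: t.isoformat()))
        out.to_csv(path, index=False)
        sidecar = {
            "source_file": self.source_file,
            "auxiliary": self.auxiliary,
            "units": self.units,
            "roles": self.roles,
        }
        with open(path + ".units.json", "w", encoding="utf-8") as fh:
            json.dump(sidecar, fh, indent=2, ensure_ascii=False)
            fh.write("\n")


@dataclass(frozen=True)
class IntervalAudit:
    declared_s: float
    median_observed_s: float
    gap_indices: tuple
    pass_: bool

    def to_json_obj(self) -> dict:
        return {
            "declared_s": self.declared_s,
            "median_observed_s": self.median_observed_s,
            "gap_indices": list(self.gap_indices),
            "pass": self.pass_,
        }


# --- delimited text ------------------------------------------------------

_DELIMITERS = (",", ";", "\t")


def read_delimited(source: Union[str, os.PathLike, io.StringIO],
                   encoding: str = "UTF-8",
                   delimiter: Optional[str] = None) -> pd.DataFrame:
    """Read a delimited light-logger export with all cells as text.

    The delimiter is auto-detected among comma, semicolon and tab unless
    given.  Values are left as strings; typed parsing happens under the
    dataset record's declarations.
    """
    if isinstance(source, io.StringIO):
        text = source.getvalue()
        origin = "<buffer>"
    else:
        path = os.fspath(source)
        origin = path
        try:
            with open(path, encoding=encoding) as fh:
                text = fh.read()
        except OSError as exc:
            raise BindingError(f"cannot read {path}: {exc}") from exc
    if delimiter is None:
        header = text.splitlines()[0] if text else ""
        counts = {d: header.count(d) for d in _DELIMITERS}
        delimiter = max(counts, key=counts.get)
        if counts[delimiter] == 0:
            raise BindingError(f"{origin}: could not detect a delimiter in the header line")
    frame = pd.read_csv(io.StringIO(text), sep=delimiter, dtype=str,
                        skipinitialspace=True, engine="python")
    frame.columns = [str(c) for c in frame.columns]
    return frame


# --- timestamps ----------------------------------------------------------

def parse_datetimes(table: pd.DataFrame, spec: Mapping, zone: str):
    """Parse the declared date(/time) columns into timezone-aware instants.

    Returns ``(DatetimeIndex, issues)``.  Local times that are ambiguous
    during a daylight-saving fold resolve to the earlier offset with a
    warning issue; nonexistent local times and unparseable cells raise
    :class:`BindingError` naming the first offending row.
    """
    if not validate_timezone(zone):
        raise BindingError(f"{zone!r} is not a valid Olson/IANA timezone")
    date_col = spec.get("dataset_datetime_date")
    date_fmt = spec.get("dataset_datetime_dateformat")
    time_col = spec.get("dataset_datetime_time")
    time_fmt = spec.get("dataset_datetime_timeformat")
    if date_col not in table.columns:
        raise BindingError(f"declared datetime column {date_col!r} is missing from the file")
    issues: list[ValidationIssue] = []
    if time_col is not None:
        if time_col not in table.columns:
            raise BindingError(f"declared time column {time_col!r} is missing from the file")
        strp = format_to_strftime(date_fmt, "date") + " " + format_to_strftime(time_fmt, "time")
        text = table[date_col].str.strip() + " " + table[time_col].str.strip()
    else:
        try:
            strp = format_to_strftime(date_fmt, "datetime")
        except ValueError:
            strp = format_to_strftime(date_fmt, "date")
        text = table[date_col].str.strip()
    try:
        naive = pd.to_datetime(text, format=strp, errors="raise")
    except (ValueError, TypeError):
        parsed = pd.to_datetime(text, format=strp, errors="coerce")
        bad = int(np.flatnonzero(parsed.isna().to_numpy())[0])
        raise BindingError(
            f"row {bad}: cannot parse {text.iloc[bad]!r} with format {date_fmt!r}"
            + (f" + {time_fmt!r}" if time_fmt else "")) from None
    index = pd.DatetimeIndex(naive)
    try:
        localized = index.tz_localize(zone, ambiguous="raise", nonexistent="raise")
    except Exception as exc:
        name = type(exc).__name__
        if "Ambiguous" in name:
            localized = index.tz_localize(zone, ambiguous=np.ones(len(index), dtype=bool),
                                          nonexistent="raise")
            issues.append(ValidationIssue(
                "warning", "dataset", "", date_col, "ambiguous-local-time",
                f"ambiguous local times during a DST fold in zone {zone}; "
                "resolved to the earlier offset"))
        elif "NonExistent" in name:
            raise BindingError(
                f"nonexistent local time(s) during a DST gap in zone {zone}: {exc}") from exc
        else:
            raise
    return localized, issues


# --- variables and calibration ------------------------------------------

_NUM = r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?"
_AFFINE_RES = tuple(
    re.compile(p)
    for p in (
        rf"^(?P<a>{_NUM})\s*\*\s*x\s*(?:(?P<sign>[+-])\s*(?P<b>{_NUM}))?$",
        rf"^x\s*\*\s*(?P<a>{_NUM})\s*(?:(?P<sign>[+-])\s*(?P<b>{_NUM}))?$",
        rf"^x\s*(?:(?P<sign>[+-])\s*(?P<b>{_NUM}))?$",
        rf"^(?P<b0>{_NUM})\s*\+\s*(?P<a>{_NUM})\s*\*\s*x$",
        rf"^(?P<b1>{_NUM})$",
    )
)


def parse_calibration(expression: Optional[str]):
    """Parse an affine calibration ``a*x + b`` into ``(a, b)``.

    Either term may be omitted; ``x`` alone (or an empty expression) is the
    identity.  Anything outside this grammar raises
    :class:`CalibrationError` — an unintelligible calibration is never
    silently ignored.
    """
    if expression is None or not str(expression).strip():
        return 1.0, 0.0
    expr = str(expression).strip()
    for rx in _AFFINE_RES:
        m = rx.match(expr)
        if not m:
            continue
        groups = m.groupdict()
        if "b1" in groups and groups.get("b1") is not None:
            return 0.0, float(groups["b1"])
        a = float(groups["a"]) if groups.get("a") is not None else 1.0
        if groups.get("b0") is not None:
            return a, float(groups["b0"])
        b = float(groups["b"]) if groups.get("b") is not None else 0.0
        if groups.get("sign") == "-":
            b = -b
        return a, b
    raise CalibrationError(
        f"calibration {expression!r} is outside the affine grammar 'a*x + b'")


def apply_calibration(values: Union[pd.Series, np.ndarray, Sequence],
                      expression: Optional[str]):
    """Apply an affine calibration elementwise; identity for ``x``/empty."""
    a, b = parse_calibration(expression)
    if isinstance(values, pd.Series):
        if a == 1.0 and b == 0.0:
            return values
        return values * a + b
    arr = np.asarray(values, dtype=float)
    if a == 1.0 and b == 0.0:
        return arr
    return arr * a + b


def bind_variables(table: pd.DataFrame, descriptor: Mapping, dataset: Mapping,
                   timestamps: Optional[pd.DatetimeIndex] = None,
                   issues: Optional[list] = None) -> LightTable:
    """Bind a raw table to its file descriptor: rename, unit-tag, calibrate.

    Columns named by ``dataset_file_variables`` are renamed to their clear
    labels with units attached; the columns the dataset record names as
    illuminance and (optionally) melanopic EDI are role-tagged.  Numeric
    parsing and calibration apply to the role-tagged photometric columns
    and to any column with a declared calibration.
    """
    variables = descriptor.get("dataset_file_variables") or []
    declared = [v.get("dataset_file_variables_name") for v in variables]
    datetime_cols = {dataset.get("dataset_datetime", {}).get("dataset_datetime_date"),
                     dataset.get("dataset_datetime", {}).get("dataset_datetime_time")}
    missing = [n for n in declared if n not in table.columns and n not in datetime_cols]
    if missing:
        raise BindingError(f"declared variable column(s) missing from file: {missing}")
    frame = pd.DataFrame(index=timestamps if timestamps is not None else table.index)
    units: dict = {}
    labels_by_name: dict = {}
    numeric_roles = {dataset.get("dataset_illuminance"), dataset.get("dataset_meledi")}
    for var in variables:
        name = var.get("dataset_file_variables_name")
        if name in datetime_cols and name not in table.columns:
            continue
        label = var.get("dataset_file_variables_labels") or name
        series = table[name]
        calibration = var.get("dataset_file_variables_calibration")
        if name in numeric_roles or calibration:
            series = pd.to_numeric(series, errors="raise")
            series = apply_calibration(series, calibration)
        frame[label] = series.to_numpy()
        units[label] = var.get("dataset_file_variables_units", "")
        labels_by_name[name] = label
    roles = {}
    illum = dataset.get("dataset_illuminance")
    if illum is not None:
        if illum not in labels_by_name:
            raise BindingError(
                f"dataset_illuminance names column {illum!r}, which is not a declared variable")
        roles["illuminance"] = labels_by_name[illum]
    meledi = dataset.get("dataset_meledi")
    if meledi is not None:
        if meledi not in labels_by_name:
            raise BindingError(
                f"dataset_meledi names column {meledi!r}, which is not a declared variable")
        roles["melEDI"] = labels_by_name[meledi]
    return LightTable(
        frame=frame,
        units=units,
        roles=roles,
        auxiliary=bool(descriptor.get("dataset_file_auxiliary", False)),
        issues=list(issues or []),
    )


# --- sampling audit ------------------------------------------------------

def audit_sampling(timestamps: Union[pd.DatetimeIndex, Sequence],
                   declared_s: float,
                   rel_tol: float = INTERVAL_REL_TOL,
                   gap_factor: float = GAP_FACTOR) -> IntervalAudit:
    """Compare observed successive intervals with the declared one.

    The audit passes iff the median observed interval is within *rel_tol*
    of *declared_s* and no successive difference exceeds
    ``gap_factor * declared_s``.
    """
    index = pd.DatetimeIndex(timestamps)
    if len(index) < 2:
        raise AuditError("sampling audit requires at least two timestamps")
    diffs = np.diff(index.asi8) / 1e9  # ns -> s
    median = float(np.median(diffs))
    gaps = tuple(int(i) + 1 for i in np.flatnonzero(diffs > gap_factor * declared_s))
    ok = abs(median - declared_s) <= rel_tol * declared_s and not gaps
    return IntervalAudit(declared_s=float(declared_s), median_observed_s=median,
                         gap_indices=gaps, pass_=bool(ok))


# --- high-level load -----------------------------------------------------

def load_light_table(dataset: Mapping, data_dir: Union[str, os.PathLike],
                     file_index: int = 0, name_index: int = 0) -> tuple:
    """Load one declared data file of a dataset record.

    Returns ``(LightTable, IntervalAudit)``.  The file-level timezone wins
    over the dataset-level one when they differ (a warning is attached to
    the table's issues).
    """
    files = dataset.get("dataset_file") or []
    if file_index >= len(files):
        raise BindingError(f"dataset declares {len(files)} file descriptor(s); "
                           f"index {file_index} out of range")
    descriptor = files[file_index]
    names = descriptor.get("dataset_file_names") or []
    if name_index >= len(names):
        raise BindingError("file descriptor names no data file at the requested index")
    path = os.path.join(os.fspath(data_dir), names[name_index])
    if not os.path.isfile(path):
        raise BindingError(f"declared data file missing on disk: {names[name_index]}")
    encodings = descriptor.get("dataset_file_encoding") or ["UTF-8"]
    raw = read_delimited(path, encoding=encodings[0])
    zone = descriptor.get("dataset_file_timezone") or dataset.get("dataset_timezone")
    issues: list[ValidationIssue] = []
    ds_zone = dataset.get("dataset_timezone")
    if ds_zone and zone != ds_zone:
        issues.append(ValidationIssue(
            "warning", "dataset", dataset.get("dataset_internal_id") or "",
            "dataset_file_timezone", "timezone-conflict",
            f"using file-level timezone {zone!r} over dataset-level {ds_zone!r}"))
    index, tz_issues = parse_datetimes(raw, dataset.get("dataset_datetime", {}), zone)
    issues.extend(tz_issues)
    if not index.is_monotonic_increasing or index.has_duplicates:
        raise BindingError("timestamps are not strictly increasing after parsing")
    table = bind_variables(raw, descriptor, dataset, timestamps=index, issues=issues)
    table.source_file = names[name_index]
    audit = audit_sampling(index, float(dataset.get("dataset_sampling_interval")))
    return table, audit
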