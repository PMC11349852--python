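"""Record-level validation against the field registry.

Every problem a metadata document can exhibit maps to a stable *rule id*
drawn from the closed set below.  Rules split into two classes:

* **structural** rules — presence, JSON types, array minima and the two
  conditional requirements (preprocessing description, split date/time
  columns).  These are exactly the rules an emitted JSON Schema can also
  enforce, which is what makes dual-validation (internal walker vs. an
  independent JSON Schema validator) a meaningful cross-check.
* **validator-only** rules — checks beyond JSON Schema's reach: the ORCID
  ISO 7064 mod-11-2 check digit, IANA/Olson timezone membership, calendar
  date and latitude/longitude parsing, datetime-format token grammar, the
  CRediT "Data curation" requirement, spectral-curve ordering, and all
  cross-file referential rules.

Severity model: a violated required/conditional/type rule is an ``error``;
unknown extra fields and advisory findings are ``warning``.  The one
exception is participant records, where anonymity demands a closed field
set, so an unknown participant field is an error.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from datetime import date
from typing import Iterable, Mapping, Optional
from zoneinfo import available_timezones

from .registry import (
    CONDITIONAL,
    REQUIRED,
    SchemaRegistry,
    canonicalize_field_name,
)

__all__ = [
    "ERROR_RULES",
    "WARNING_RULES",
    "STRUCTURAL_RULES",
    "VALIDATOR_ONLY_RULES",
    "CREDIT_ROLES",
    "ValidationIssue",
    "ValidationReport",
    "validate_record",
    "validate_orcid",
    "validate_email",
    "validate_timezone",
    "validate_datetime_format",
    "check_preprocessing",
    "check_datetime_spec",
    "check_spectral_sensitivity",
    "check_contributor_roles",
    "tz_snapshot_version",
]

# --- rule vocabulary -----------------------------------------------------

#: Error-severity rules.
ERROR_RULES = frozenset(
    {
        "missing-required",
        "type-mismatch",
        "conditional-preprocessing",
        "datetime-spec-incomplete",
        "empty-funding",
        "spectral-empty",
        "participant-extra-field",
        "bad-orcid",
        "bad-email",
        "bad-timezone",
        "bad-date",
        "bad-datetime-format",
        "bad-location",
        "non-ascending-spectral",
        "negative-spectral",
        "channel-duplicate-nr",
        "missing-data-curation",
        "dangling-crossref",
        "duplicate-id",
        "dataset-not-in-study",
    }
)

#: Warning-severity rules.
WARNING_RULES = frozenset(
    {
        "unknown-field",
        "unknown-credit-role",
        "spectral-peak-unnormalized",
        "orphan-record",
        "unlisted-dataset",
        "timezone-conflict",
        "ambiguous-local-time",
    }
)

#: Rules an emitted JSON Schema enforces identically.
STRUCTURAL_RULES = frozenset(
    {
        "missing-required",
        "type-mismatch",
        "conditional-preprocessing",
        "datetime-spec-incomplete",
        "empty-funding",
        "spectral-empty",
        "participant-extra-field",
    }
)

#: Rules only the package validator enforces (annotated, non-asserting, in
#: emitted schemas).
VALIDATOR_ONLY_RULES = (ERROR_RULES | WARNING_RULES) - STRUCTURAL_RULES

#: The 14 CRediT contributor roles.
CREDIT_ROLES = (
    "Conceptualization",
    "Data curation",
    "Formal analysis",
    "Funding acquisition",
    "Investigation",
    "Methodology",
    "Project administration",
    "Resources",
    "Software",
    "Supervision",
    "Validation",
    "Visualization",
    "Writing - original draft",
    "Writing - review & editing",
)

_CREDIT_LOOKUP = {r.lower(): r for r in CREDIT_ROLES}


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    component_kind: str
    record_id: str
    field_path: str
    rule_id: str
    message: str

    def to_json_obj(self) -> dict:
        return {
            "severity": self.severity,
            "component_kind": self.component_kind,
            "record_id": self.record_id,
            "field_path": self.field_path,
            "rule_id": self.rule_id,
            "message": self.message,
        }


@dataclass
class ValidationReport:
    """Ordered list of issues plus a validity verdict (no errors)."""

    issues: list = dc_field(default_factory=list)
    schema_version: str = ""
    tz_snapshot: str = ""

    @property
    def valid(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def errors(self) -> list:
        return [i for i in self.issues if i.severity == "error"]

    def warnings(self) -> list:
        return [i for i in self.issues if i.severity == "warning"]

    def extend(self, issues: Iterable[ValidationIssue]) -> None:
        self.issues.extend(issues)

    def to_json_obj(self) -> dict:
        return {
            "valid": self.valid,
            "schema_version": self.schema_version,
            "tz_snapshot": self.tz_snapshot,
            "n_errors": len(self.errors()),
            "n_warnings": len(self.warnings()),
            "issues": [i.to_json_obj() for i in self.issues],
        }

    def to_text(self) -> str:
        lines = [
            f"validation: {'PASS' if self.valid else 'FAIL'} "
            f"({len(self.errors())} errors, {len(self.warnings())} warnings)"
        ]
        if self.schema_version:
            lines.append(f"descriptor version: {self.schema_version}; tz snapshot: {self.tz_snapshot}")
        for i in self.issues:
            rid = f"[{i.record_id}]" if i.record_id else ""
            lines.append(f"  {i.severity.upper():7s} {i.component_kind}{rid} {i.field_path}: "
                         f"{i.message} ({i.rule_id})")
        return "\n".join(lines) + "\n"


def tz_snapshot_version() -> str:
    """Version label of the timezone database in use, best effort."""
    try:
        from importlib.metadata import version

        return version("tzdata")
    except Exception:
        pass
    import os

    for root in ("/usr/share/zoneinfo",):
        path = os.path.join(root, "tzdata.zi")
        try:
            with open(path) as fh:
                first = fh.readline()
            m = re.search(r"version\s+(\S+)", first)
            if m:
                return m.group(1)
        except OSError:
            continue
    return "unknown"


# --- atomic format validators -------------------------------------------

_ORCID_RE = re.compile(r"^(\d{4})-(\d{4})-(\d{4})-(\d{3})([\dX])$")


def validate_orcid(text: str) -> bool:
    """True iff *text* is a well-formed ORCID iD with a correct check digit.

    The final character is an ISO 7064 mod-11-2 check over the 15 preceding
    digits ('X' encodes the value 10).
    """
    if not isinstance(text, str):
        return False
    m = _ORCID_RE.match(text)
    if not m:
        return False
    digits = "".join(m.group(1, 2, 3, 4))
    total = 0
    for ch in digits:
        total = (total + int(ch)) * 2
    remainder = total % 11
    check = (12 - remainder) % 11
    expected = "X" if check == 10 else str(check)
    return m.group(5) == expected


def validate_email(text: str) -> bool:
    """Syntactic email check: one ``@``, non-empty local part, dotted domain.

    Internationalized labels are allowed (no ASCII restriction); no DNS
    lookup is performed.
    """
    if not isinstance(text, str) or text.count("@") != 1:
        return False
    local, _, domain = text.partition("@")
    if not local or not domain:
        return False
    if "." not in domain:
        return False
    labels = domain.split(".")
    if any(not lab for lab in labels):
        return False
    return not any(ch.isspace() for ch in text)


_TZ_CACHE: Optional[frozenset] = None


def validate_timezone(text: str) -> bool:
    """True iff *text* names a zone in the bundled IANA/Olson database."""
    global _TZ_CACHE
    if not isinstance(text, str):
        return False
    if _TZ_CACHE is None:
        _TZ_CACHE = frozenset(available_timezones())
    return text in _TZ_CACHE


_DATE_TOKENS = {"YYYY", "YY", "MM", "DD"}
_TIME_TOKENS = {"HH", "MM", "SS", "SSS"}
# Greedy tokenization order: longest tokens first so SSS is not read as SS+S.
_TOKEN_ORDER = ("YYYY", "SSS", "YY", "MM", "DD", "HH", "SS")


def _tokenize_format(fmt: str) -> Optional[list]:
    """Split a format string into (token | literal) pieces; None if invalid."""
    out = []
    i = 0
    while i < len(fmt):
        ch = fmt[i]
        if ch.isalpha():
            for tok in _TOKEN_ORDER:
                if fmt.startswith(tok, i):
                    # do not split a longer alpha run: "QQ" or trailing chars fail
                    end = i + len(tok)
                    if end < len(fmt) and fmt[end].isalpha() and not any(
                        fmt.startswith(t, end) for t in _TOKEN_ORDER
                    ):
                        return None
                    out.append(("tok", tok))
                    i = end
                    break
            else:
                return None
        else:
            out.append(("lit", ch))
            i += 1
    return out


def _classify_tokens(pieces: list) -> Optional[dict]:
    """Resolve the MM ambiguity (month before any HH, minute after)."""
    seen: dict[str, int] = {}
    hour_seen = False
    for kind, val in pieces:
        if kind != "tok":
            continue
        if val == "HH":
            hour_seen = True
            name = "hour"
        elif val == "MM":
            name = "minute" if hour_seen else "month"
        elif val in ("YYYY", "YY"):
            name = "year"
        elif val == "DD":
            name = "day"
        elif val == "SS":
            name = "second"
        else:
            name = "fraction"
        seen[name] = seen.get(name, 0) + 1
    if any(v > 1 for v in seen.values()):
        return None
    return seen


def validate_datetime_format(fmt: str, role: str) -> bool:
    """Check a date/time/datetime format string against the token grammar.

    The vocabulary is YYYY, YY, MM, DD, HH, MM (minute after an hour token),
    SS and SSS (fractional seconds), joined by literal separators.  *role*
    is ``"date"``, ``"time"`` or ``"datetime"`` and constrains which tokens
    must or must not appear.
    """
    if role not in ("date", "time", "datetime"):
        raise ValueError(f"unknown format role {role!r}")
    if not isinstance(fmt, str) or not fmt:
        return False
    pieces = _tokenize_format(fmt)
    if pieces is None:
        return False
    seen = _classify_tokens(pieces)
    if seen is None:
        return False
    has_date = {"year", "month", "day"} <= seen.keys()
    has_time = {"hour", "minute"} <= seen.keys()
    any_date = seen.keys() & {"year", "month", "day"}
    any_time = seen.keys() & {"hour", "minute", "second", "fraction"}
    if role == "date":
        return has_date and not any_time
    if role == "time":
        return has_time and not any_date
    return has_date and has_time


def format_to_strftime(fmt: str, role: str) -> str:
    """Translate a token format into a ``strftime``/``strptime`` pattern."""
    if not validate_datetime_format(fmt, role):
        raise ValueError(f"invalid {role} format {fmt!r}")
    pieces = _tokenize_format(fmt)
    out = []
    hour_seen = False
    mapping = {"YYYY": "%Y", "YY": "%y", "DD": "%d", "HH": "%H", "SS": "%S", "SSS": "%f"}
    for kind, val in pieces:  # type: ignore[union-attr]
        if kind == "lit":
            out.append(val.replace("%", "%%"))
        elif val == "HH":
            hour_seen = True
            out.append("%H")
        elif val == "MM":
            out.append("%M" if hour_seen else "%m")
        else:
            out.append(mapping[val])
    return "".join(out)


# --- compound checks -----------------------------------------------------

def _issue(severity, kind, record_id, path, rule, message) -> ValidationIssue:
    return ValidationIssue(severity, kind, record_id, path, rule, message)


def check_preprocessing(spec: Mapping, *, kind: str = "dataset", record_id: str = "",
                        path: str = "dataset_file_preprocessing") -> list:
    """Conditional requirement: a description must accompany ``bol=true``."""
    issues: list[ValidationIssue] = []
    bol = spec.get("dataset_file_preprocessing_bol")
    desc = spec.get("dataset_file_preprocessing_desc")
    if bol is True:
        ok = isinstance(desc, list) and len(desc) >= 1 and all(
            isinstance(d, str) and d.strip() for d in desc
        )
        if not ok:
            issues.append(_issue(
                "error", kind, record_id, f"{path}/dataset_file_preprocessing_desc",
                "conditional-preprocessing",
                "preprocessing was applied (bol=true) but no non-empty description is given",
            ))
    return issues


def check_datetime_spec(spec: Mapping, *, kind: str = "dataset", record_id: str = "",
                        path: str = "dataset_datetime") -> list:
    """Split date/time columns must be declared together, with valid formats."""
    issues: list[ValidationIssue] = []
    time_name = spec.get("dataset_datetime_time")
    time_fmt = spec.get("dataset_datetime_timeformat")
    if (time_name is None) != (time_fmt is None):
        missing = "dataset_datetime_timeformat" if time_fmt is None else "dataset_datetime_time"
        issues.append(_issue(
            "error", kind, record_id, f"{path}/{missing}", "datetime-spec-incomplete",
            "a separate time column requires both its name and its format (and vice versa)",
        ))
    date_fmt = spec.get("dataset_datetime_dateformat")
    if isinstance(date_fmt, str):
        if time_name is not None and time_fmt is not None:
            ok = validate_datetime_format(date_fmt, "date")
        else:
            ok = validate_datetime_format(date_fmt, "date") or validate_datetime_format(date_fmt, "datetime")
        if not ok:
            issues.append(_issue(
                "error", kind, record_id, f"{path}/dataset_datetime_dateformat",
                "bad-datetime-format", f"unrecognized date(/datetime) format {date_fmt!r}",
            ))
    if isinstance(time_fmt, str) and not validate_datetime_format(time_fmt, "time"):
        issues.append(_issue(
            "error", kind, record_id, f"{path}/dataset_datetime_timeformat",
            "bad-datetime-format", f"unrecognized time format {time_fmt!r}",
        ))
    return issues


_WL = "datasheet_calibration_spectral_sensitivity_wavelength"
_REL = "datasheet_calibration_spectral_sensitivity_relative"


def check_spectral_sensitivity(points, *, kind: str = "datasheet", record_id: str = "",
                               path: str = "datasheet_calibration_spectral_sensitivity") -> list:
    """Spectral curve sanity: non-empty, ascending wavelengths, peak near 1."""
    issues: list[ValidationIssue] = []
    if not isinstance(points, list) or len(points) == 0:
        issues.append(_issue("error", kind, record_id, path, "spectral-empty",
                             "spectral sensitivity calibration requires at least one point"))
        return issues
    numeric = []
    for idx, p in enumerate(points):
        if not isinstance(p, Mapping):
            continue
        wl, rel = p.get(_WL), p.get(_REL)
        if isinstance(wl, (int, float)) and not isinstance(wl, bool):
            numeric.append((idx, float(wl)))
        if isinstance(rel, (int, float)) and not isinstance(rel, bool) and rel < 0:
            issues.append(_issue("error", kind, record_id, f"{path}/{idx}/{_REL}",
                                 "negative-spectral", f"relative sensitivity {rel} < 0"))
    for (i0, w0), (i1, w1) in zip(numeric, numeric[1:]):
        if w1 <= w0:
            issues.append(_issue("error", kind, record_id, f"{path}/{i1}/{_WL}",
                                 "non-ascending-spectral",
                                 f"wavelength {w1} nm does not exceed preceding {w0} nm"))
    rels = [
        float(p.get(_REL))
        for p in points
        if isinstance(p, Mapping)
        and isinstance(p.get(_REL), (int, float))
        and not isinstance(p.get(_REL), bool)
    ]
    if rels and abs(max(rels) - 1.0) > 1e-6:
        issues.append(_issue("warning", kind, record_id, path, "spectral-peak-unnormalized",
                             f"peak relative sensitivity is {max(rels):g}, expected 1"))
    return issues


def check_contributor_roles(contributors, *, kind: str = "study", record_id: str = "",
                            path: str = "study_contributors") -> list:
    """At least one contributor must carry the CRediT 'Data curation' role."""
    contributors = contributors or []
    for c in contributors:
        if not isinstance(c, Mapping):
            continue
        roles = c.get("contributor_roles") or []
        if any(isinstance(r, str) and r.strip().lower() == "data curation" for r in roles):
            return []
    return [_issue("error", kind, record_id, path, "missing-data-curation",
                   'no contributor declares the CRediT "Data curation" role')]


# --- generic registry-driven walk ---------------------------------------

_JSON_TYPE_CHECKS = {
    "string": lambda v: isinstance(v, str),
    "email": lambda v: isinstance(v, str),
    "integer": lambda v: isinstance(v, int) and not isinstance(v, bool),
    "number": lambda v: isinstance(v, (int, float)) and not isinstance(v, bool),
    "boolean": lambda v: isinstance(v, bool),
    "object": lambda v: isinstance(v, Mapping),
    "array-of-strings": lambda v: isinstance(v, list),
    "array-of-objects": lambda v: isinstance(v, list),
}

_ID_FIELDS = {
    "study": "study_internal_id",
    "contributor": "contributor_full_name",
    "participant": "participant_internal_id",
    "dataset": "dataset_internal_id",
    "device": "device_internal_id",
    "datasheet": "datasheet_model",
}

_MIN_ITEMS_RULES = {
    "study_funding_sources": "empty-funding",
    "datasheet_calibration_spectral_sensitivity": "spectral-empty",
    "dataset_file_preprocessing_desc": None,  # covered by conditional-preprocessing
}


def canonicalize_record(record: Mapping) -> dict:
    """Deep-copy a record with all mapping keys canonicalized."""
    def conv(v):
        if isinstance(v, Mapping):
            return {canonicalize_field_name(k) if isinstance(k, str) else k: conv(val)
                    for k, val in v.items()}
        if isinstance(v, list):
            return [conv(x) for x in v]
        return v

    return conv(record)


def validate_record(record: Mapping, kind: str, registry: SchemaRegistry) -> ValidationReport:
    """Validate one component record; all problems are reported, none raised."""
    registry._check_kind(kind)
    rec = canonicalize_record(record)
    record_id = rec.get(_ID_FIELDS.get(kind, ""), "")
    record_id = record_id if isinstance(record_id, str) else ""
    report = ValidationReport(schema_version=registry.schema_version,
                              tz_snapshot=tz_snapshot_version())
    _walk_object(rec, kind, registry, None, "", record_id, report, top=True, top_kind=kind)
    return report


def _walk_object(obj: Mapping, kind: str, registry: SchemaRegistry,
                 parent: Optional[str], path: str, record_id: str,
                 report: ValidationReport, *, top: bool, top_kind: str) -> None:
    specs = registry.children(kind, parent)
    known = {s.name for s in specs}
    for spec in specs:
        fpath = f"{path}/{spec.name}" if path else spec.name
        present = spec.name in obj
        if not present:
            if spec.requiredness == REQUIRED:
                report.issues.append(_issue("error", top_kind, record_id, fpath,
                                            "missing-required",
                                            f"required field {spec.name!r} is missing"))
            continue
        value = obj[spec.name]
        if not _JSON_TYPE_CHECKS[spec.value_type](value):
            report.issues.append(_issue("error", top_kind, record_id, fpath, "type-mismatch",
                                        f"expected {spec.value_type}, got {type(value).__name__}"))
            continue
        if spec.value_type == "array-of-strings":
            bad = [i for i, v in enumerate(value) if not isinstance(v, str)]
            if bad:
                report.issues.append(_issue("error", top_kind, record_id,
                                            f"{fpath}/{bad[0]}", "type-mismatch",
                                            "array elements must be strings"))
            rule = _MIN_ITEMS_RULES.get(spec.name, "type-mismatch" if spec.min_items else None)
            if spec.min_items and len(value) < spec.min_items and rule:
                report.issues.append(_issue("error", top_kind, record_id, fpath, rule,
                                            f"array must have at least {spec.min_items} entries"))
        elif spec.value_type == "array-of-objects":
            if spec.name == "datasheet_calibration_spectral_sensitivity":
                report.extend(check_spectral_sensitivity(
                    value, kind=top_kind, record_id=record_id, path=fpath))
            item_kind = spec.ref_kind or kind
            item_specs_parent = None if spec.ref_kind else spec
            for idx, element in enumerate(value):
                epath = f"{fpath}/{idx}"
                if not isinstance(element, Mapping):
                    report.issues.append(_issue("error", top_kind, record_id, epath,
                                                "type-mismatch", "array elements must be objects"))
                    continue
                if spec.ref_kind:
                    _walk_object(element, spec.ref_kind, registry, None, epath,
                                 record_id, report, top=False, top_kind=top_kind)
                else:
                    _walk_array_item(element, kind, registry, spec, epath,
                                     record_id, report, top_kind)
        elif spec.value_type == "object":
            if spec.ref_kind:
                _walk_object(value, spec.ref_kind, registry, None, fpath,
                             record_id, report, top=False, top_kind=top_kind)
            else:
                _walk_object(value, kind, registry, spec.name, fpath,
                             record_id, report, top=False, top_kind=top_kind)
        _apply_field_hooks(spec, value, fpath, record_id, report, top_kind)
    # unknown keys
    for key in obj:
        if key in known or key == "_schema_version":
            continue
        fpath = f"{path}/{key}" if path else key
        if top and kind == "participant":
            report.issues.append(_issue("error", top_kind, record_id, fpath,
                                        "participant-extra-field",
                                        f"field {key!r} is outside the anonymity-preserving participant set"))
        else:
            report.issues.append(_issue("warning", top_kind, record_id, fpath, "unknown-field",
                                        f"field {key!r} is not part of the descriptor (extension?)"))
    # object-level compound rules
    if top and kind == "study":
        report.extend(check_contributor_roles(obj.get("study_contributors"),
                                              kind=top_kind, record_id=record_id))
    if parent is None and kind == "dataset" and isinstance(obj.get("dataset_datetime"), Mapping):
        report.extend(check_datetime_spec(obj["dataset_datetime"], kind=top_kind,
                                          record_id=record_id,
                                          path=f"{path}/dataset_datetime" if path else "dataset_datetime"))


def _walk_array_item(element: Mapping, kind: str, registry: SchemaRegistry,
                     array_spec, path: str, record_id: str,
                     report: ValidationReport, top_kind: str) -> None:
    item_specs = registry.item_fields(kind, array_spec)
    if not item_specs:
        return
    parent_name = item_specs[0].parent
    _walk_object(element, kind, registry, parent_name, path, record_id, report,
                 top=False, top_kind=top_kind)
    if array_spec.name == "dataset_file":
        pre = element.get("dataset_file_preprocessing")
        if isinstance(pre, Mapping):
            report.extend(check_preprocessing(pre, kind=top_kind, record_id=record_id,
                                              path=f"{path}/dataset_file_preprocessing"))
    if array_spec.name == "datasheet_channel":
        pass  # duplicate channel numbers detected at datasheet level below


def _apply_field_hooks(spec, value, path: str, record_id: str,
                       report: ValidationReport, top_kind: str) -> None:
    name = spec.name
    if name == "contributor_orcid" and isinstance(value, str):
        if not validate_orcid(value):
            report.issues.append(_issue("error", top_kind, record_id, path, "bad-orcid",
                                        f"{value!r} is not a valid ORCID iD (pattern or mod-11-2 check digit)"))
    elif name == "contributor_email" and isinstance(value, str):
        if not validate_email(value):
            report.issues.append(_issue("error", top_kind, record_id, path, "bad-email",
                                        f"{value!r} is not a plausible email address"))
    elif name == "contributor_roles" and isinstance(value, list):
        for idx, role in enumerate(value):
            if isinstance(role, str) and role.strip().lower() not in _CREDIT_LOOKUP:
                report.issues.append(_issue("warning", top_kind, record_id, f"{path}/{idx}",
                                            "unknown-credit-role",
                                            f"{role!r} is not one of the 14 CRediT roles"))
    elif name in ("dataset_timezone", "dataset_file_timezone") and isinstance(value, str):
        if not validate_timezone(value):
            report.issues.append(_issue("error", top_kind, record_id, path, "bad-timezone",
                                        f"{value!r} is not an IANA/Olson timezone name"))
    elif name == "device_calibration" and isinstance(value, str):
        try:
            date.fromisoformat(value)
        except ValueError:
            report.issues.append(_issue("error", top_kind, record_id, path, "bad-date",
                                        f"{value!r} is not an ISO 8601 calendar date"))
    elif name == "dataset_location" and isinstance(value, list):
        report.extend(_check_location(value, path, record_id, top_kind))
    elif name == "datasheet_channel" and isinstance(value, list):
        seen: dict = {}
        for idx, ch in enumerate(value):
            if isinstance(ch, Mapping):
                nr = ch.get("datasheet_channel_nr")
                if isinstance(nr, int) and not isinstance(nr, bool):
                    if nr in seen:
                        report.issues.append(_issue(
                            "error", top_kind, record_id, f"{path}/{idx}/datasheet_channel_nr",
                            "channel-duplicate-nr", f"channel number {nr} already used at index {seen[nr]}"))
                    else:
                        seen[nr] = idx


def _check_location(value: list, path: str, record_id: str, top_kind: str) -> list:
    issues: list[ValidationIssue] = []
    if len(value) != 2:
        issues.append(_issue("error", top_kind, record_id, path, "bad-location",
                             f"dataset_location must hold [latitude, longitude], got {len(value)} entries"))
        return issues
    bounds = ((-90.0, 90.0, "latitude"), (-180.0, 180.0, "longitude"))
    for element, (lo, hi, label) in zip(value, bounds):
        if not isinstance(element, str):
            continue  # type-mismatch already reported
        try:
            deg = float(element)
        except ValueError:
            issues.append(_issue("error", top_kind, record_id, path, "bad-location",
                                 f"{label} {element!r} is not a signed decimal degree value"))
            continue
        if not (lo <= deg <= hi):
            issues.append(_issue("error", top_kind, record_id, path, "bad-location",
                                 f"{label} {deg} outside [{lo}, {hi}]"))
    return issues
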