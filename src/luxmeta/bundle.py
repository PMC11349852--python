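"""Multi-file metadata bundles and cross-record referential integrity.

A *bundle* is one study's complete descriptor set: the study document plus
any number of participant, dataset and device documents (contributors are
embedded in the study record).  The canonical on-disk layout is::

    <root>/study.json
    <root>/participants/<id>.json
    <root>/datasets/<id>.json
    <root>/devices/<id>.json

A single combined JSON document with top-level keys ``study``,
``participants``, ``datasets`` and ``devices`` is accepted as an equivalent
layout; loading either form yields equal bundles and equal reports.

Referential rules: internal ids are unique per kind; every dataset
cross-reference (study, participant, device) resolves to an existing
record; the study's ``study_datasets`` list and the dataset records are in
one-to-one correspondence.  Matching is exact string comparison after
Unicode NFC normalization, case-sensitive.
"""

from __future__ import annotations

import json
import os
import unicodedata
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Optional, Union

from .jsonio import ParseError, read_component, write_component
from .registry import SchemaRegistry, build_registry
from .validation import ValidationIssue, ValidationReport, tz_snapshot_version, validate_record

__all__ = [
    "MetadataBundle",
    "BundleLoadError",
    "load_bundle",
    "write_bundle",
    "check_crossrefs",
    "check_study_dataset_closure",
    "validate_bundle",
]


class BundleLoadError(ValueError):
    """Fatal problem loading a bundle (missing study, malformed JSON)."""


@dataclass
class MetadataBundle:
    study: dict
    participants: list = dc_field(default_factory=list)
    datasets: list = dc_field(default_factory=list)
    devices: list = dc_field(default_factory=list)
    source_paths: dict = dc_field(default_factory=dict)

    def participant_ids(self) -> list:
        return [p.get("participant_internal_id") for p in self.participants]

    def dataset_ids(self) -> list:
        return [d.get("dataset_internal_id") for d in self.datasets]

    def device_ids(self) -> list:
        return [d.get("device_internal_id") for d in self.devices]

    def get_dataset(self, dataset_id: str) -> Optional[dict]:
        for d in self.datasets:
            if d.get("dataset_internal_id") == dataset_id:
                return d
        return None

    def __eq__(self, other) -> bool:  # source_paths are provenance, not content
        if not isinstance(other, MetadataBundle):
            return NotImplemented
        return (self.study, self.participants, self.datasets, self.devices) == (
            other.study, other.participants, other.datasets, other.devices)


def _nfc(value: str) -> str:
    return unicodedata.normalize("NFC", value) if isinstance(value, str) else value


def load_bundle(root: Union[str, os.PathLike],
                registry: Optional[SchemaRegistry] = None):
    """Load a bundle from a directory or a combined document.

    Returns ``(bundle, report)``; per-record validation and cross-reference
    checks are merged into the report.  A missing study document or
    malformed JSON is fatal (:class:`BundleLoadError`).
    """
    registry = registry or build_registry()
    path = os.fspath(root)
    if os.path.isdir(path):
        bundle = _load_directory(path)
    elif os.path.isfile(path):
        bundle = _load_combined(path)
    else:
        raise BundleLoadError(f"bundle root {path!r} does not exist")
    report = validate_bundle(bundle, registry)
    return bundle, report


def _read_record(path: str, expected_kind: str) -> dict:
    try:
        kind, record = read_component(path)
    except ParseError as exc:
        raise BundleLoadError(str(exc)) from exc
    if kind != expected_kind:
        raise BundleLoadError(f"{path}: expected a {expected_kind} record, found {kind}")
    return record


def _load_directory(path: str) -> MetadataBundle:
    study_path = os.path.join(path, "study.json")
    if not os.path.isfile(study_path):
        raise BundleLoadError(f"no study.json in {path!r}: a bundle must contain a study document")
    bundle = MetadataBundle(study=_read_record(study_path, "study"))
    bundle.source_paths["study"] = study_path
    for sub, kind, target in (
        ("participants", "participant", bundle.participants),
        ("datasets", "dataset", bundle.datasets),
        ("devices", "device", bundle.devices),
    ):
        subdir = os.path.join(path, sub)
        if not os.path.isdir(subdir):
            continue
        for name in sorted(os.listdir(subdir)):
            if not name.endswith(".json"):
                continue
            fpath = os.path.join(subdir, name)
            record = _read_record(fpath, kind)
            target.append(record)
            bundle.source_paths[f"{sub}/{name}"] = fpath
    return bundle


def _load_combined(path: str) -> MetadataBundle:
    try:
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
    except OSError as exc:
        raise BundleLoadError(f"cannot read {path}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise BundleLoadError(
            f"{path}: malformed JSON at line {exc.lineno}, column {exc.colno}: {exc.msg}") from exc
    if not isinstance(doc, Mapping) or "study" not in doc:
        raise BundleLoadError(f"{path}: combined bundle document must contain a 'study' object")
    from .validation import canonicalize_record

    def records(key):
        items = doc.get(key, [])
        if not isinstance(items, list):
            raise BundleLoadError(f"{path}: {key!r} must be an array of records")
        return [canonicalize_record(r) for r in items]

    bundle = MetadataBundle(
        study=canonicalize_record(doc["study"]),
        participants=records("participants"),
        datasets=records("datasets"),
        devices=records("devices"),
    )
    bundle.source_paths["study"] = path
    return bundle


def write_bundle(bundle: MetadataBundle, root: Union[str, os.PathLike],
                 registry: Optional[SchemaRegistry] = None) -> None:
    """Write a bundle in the canonical directory layout (UTF-8 JSON)."""
    registry = registry or build_registry()
    path = os.fspath(root)
    os.makedirs(path, exist_ok=True)
    with open(os.path.join(path, "study.json"), "w", encoding="utf-8") as fh:
        fh.write(write_component(bundle.study, "study", registry))
    for sub, kind, records, id_field in (
        ("participants", "participant", bundle.participants, "participant_internal_id"),
        ("datasets", "dataset", bundle.datasets, "dataset_internal_id"),
        ("devices", "device", bundle.devices, "device_internal_id"),
    ):
        subdir = os.path.join(path, sub)
        os.makedirs(subdir, exist_ok=True)
        for i, record in enumerate(records):
            rid = record.get(id_field) or f"{kind}{i}"
            with open(os.path.join(subdir, f"{rid}.json"), "w", encoding="utf-8") as fh:
                fh.write(write_component(record, kind, registry))


def write_combined(bundle: MetadataBundle, path: Union[str, os.PathLike]) -> None:
    """Write a bundle as a single combined JSON document."""
    doc = {
        "study": bundle.study,
        "participants": bundle.participants,
        "datasets": bundle.datasets,
        "devices": bundle.devices,
    }
    with open(os.fspath(path), "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, ensure_ascii=False)
        fh.write("\n")


# --- referential integrity ----------------------------------------------

def _iss(severity, kind, rid, path, rule, msg) -> ValidationIssue:
    return ValidationIssue(severity, kind, rid, path, rule, msg)


def check_crossrefs(bundle: MetadataBundle) -> list:
    """Duplicate-id errors, dangling-reference errors, orphan warnings."""
    issues: list[ValidationIssue] = []
    ids: dict[str, dict] = {}
    for kind, records, id_field in (
        ("participant", bundle.participants, "participant_internal_id"),
        ("dataset", bundle.datasets, "dataset_internal_id"),
        ("device", bundle.devices, "device_internal_id"),
    ):
        seen: dict[str, int] = {}
        for record in records:
            rid = record.get(id_field)
            if not isinstance(rid, str):
                continue  # missing/typed ids are reported by record validation
            rid = _nfc(rid)
            if rid in seen:
                issues.append(_iss("error", kind, rid, id_field, "duplicate-id",
                                   f"{id_field} {rid!r} used by more than one {kind} record"))
            seen[rid] = seen.get(rid, 0) + 1
        ids[kind] = seen
    study_id = bundle.study.get("study_internal_id")
    study_id = _nfc(study_id) if isinstance(study_id, str) else None
    referenced = {"participant": set(), "device": set()}
    for record in bundle.datasets:
        rid = record.get("dataset_internal_id") or ""
        cross = record.get("dataset_crossref")
        if not isinstance(cross, Mapping):
            continue
        targets = (
            ("dataset_crossref_study_id", "study", {study_id} if study_id else set()),
            ("dataset_crossref_participant_id", "participant", ids["participant"].keys()),
            ("dataset_crossref_device_id", "device", ids["device"].keys()),
        )
        for field, target_kind, pool in targets:
            value = cross.get(field)
            if not isinstance(value, str):
                continue
            value = _nfc(value)
            if value not in pool:
                issues.append(_iss("error", "dataset", rid, f"dataset_crossref/{field}",
                                   "dangling-crossref",
                                   f"{field} {value!r} does not match any {target_kind} record"))
            elif target_kind in referenced:
                referenced[target_kind].add(value)
    for kind, id_field, records in (
        ("participant", "participant_internal_id", bundle.participants),
        ("device", "device_internal_id", bundle.devices),
    ):
        for record in records:
            rid = record.get(id_field)
            if isinstance(rid, str) and _nfc(rid) not in referenced[kind]:
                issues.append(_iss("warning", kind, rid, id_field, "orphan-record",
                                   f"{kind} {rid!r} is not referenced by any dataset"))
    return issues


def check_study_dataset_closure(bundle: MetadataBundle) -> list:
    """study_datasets and the dataset records must list the same ids."""
    issues: list[ValidationIssue] = []
    listed = bundle.study.get("study_datasets")
    listed_ids = [_nfc(x) for x in listed if isinstance(x, str)] if isinstance(listed, list) else []
    present = {_nfc(d) for d in bundle.dataset_ids() if isinstance(d, str)}
    study_id = bundle.study.get("study_internal_id") or ""
    for ds_id in listed_ids:
        if ds_id not in present:
            issues.append(_iss("error", "study", study_id, "study_datasets",
                               "dataset-not-in-study",
                               f"study_datasets lists {ds_id!r} but no such dataset record exists"))
    for ds_id in sorted(present - set(listed_ids)):
        issues.append(_iss("warning", "dataset", ds_id, "dataset_internal_id",
                           "unlisted-dataset",
                           f"dataset {ds_id!r} is not listed in study_datasets"))
    return issues


def _check_timezone_conflicts(bundle: MetadataBundle) -> list:
    issues: list[ValidationIssue] = []
    for record in bundle.datasets:
        ds_tz = record.get("dataset_timezone")
        rid = record.get("dataset_internal_id") or ""
        files = record.get("dataset_file")
        if not isinstance(files, list):
            continue
        for idx, fd in enumerate(files):
            if not isinstance(fd, Mapping):
                continue
            f_tz = fd.get("dataset_file_timezone")
            if isinstance(ds_tz, str) and isinstance(f_tz, str) and f_tz != ds_tz:
                issues.append(_iss(
                    "warning", "dataset", rid, f"dataset_file/{idx}/dataset_file_timezone",
                    "timezone-conflict",
                    f"file timezone {f_tz!r} differs from dataset timezone {ds_tz!r}; "
                    "the file-level value wins for this file"))
    return issues


def validate_bundle(bundle: MetadataBundle,
                    registry: Optional[SchemaRegistry] = None) -> ValidationReport:
    """Full validation: every record, then cross-record integrity."""
    registry = registry or build_registry()
    report = ValidationReport(schema_version=registry.schema_version,
                              tz_snapshot=tz_snapshot_version())
    report.extend(validate_record(bundle.study, "study", registry).issues)
    for kind, records in (
        ("participant", bundle.participants),
        ("dataset", bundle.datasets),
        ("device", bundle.devices),
    ):
        for record in records:
            report.extend(validate_record(record, kind, registry).issues)
    report.extend(check_crossrefs(bundle))
    report.extend(check_study_dataset_closure(bundle))
    report.extend(_check_timezone_conflicts(bundle))
    return report
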