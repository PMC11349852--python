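"""JSON reading/writing of component records and JSON Schema emission.

Component documents are plain UTF-8 JSON.  On read, field names are
normalized to canonical form and the component kind is detected from the
field-name prefix (``study_``, ``contributor_``, ``participant_``,
``dataset_``, ``device_``, ``datasheet_``).  On write, output is canonical:
keys in table order, two-space indent, non-ASCII preserved, a trailing
newline, and a ``_schema_version`` annotation key recording the descriptor
version.

:func:`emit_json_schema` renders one component kind as a JSON Schema
(draft 2020-12).  Structural rules — required fields at every level, value
types, array minima, and the preprocessing and split-date/time conditional
requirements — are asserted in the schema.  Rules beyond JSON Schema's
reach (ORCID check digit, Olson timezone membership, calendar-date and
coordinate parsing, CRediT role coverage, spectral ordering, cross-file
references) are carried as non-asserting ``x-validator-only`` annotations.
"""

from __future__ import annotations

import json
import os
from typing import Mapping, Optional, Tuple, Union

from .registry import (
    COMPONENT_KINDS,
    SUPPORTED_VERSIONS,
    FieldSpec,
    SchemaRegistry,
    UnsupportedVersionError,
    build_registry,
    canonicalize_field_name,
    required_fields,
)
from .validation import VALIDATOR_ONLY_RULES, canonicalize_record

__all__ = [
    "read_component",
    "write_component",
    "emit_json_schema",
    "ParseError",
    "DetectionError",
    "SerializationError",
    "SCHEMA_VERSION_KEY",
    "REF_PATH_KEY",
]

SCHEMA_VERSION_KEY = "_schema_version"
#: A datasheet may be given inline or as ``{"$ref-path": "file.json"}``;
#: the reference form is resolved on read, embedding is canonical on write.
REF_PATH_KEY = "$ref-path"

_SCHEMA_ID_BASE = "https://luxmeta.readthedocs.io/schemas"


class ParseError(ValueError):
    """Malformed JSON, annotated with source name and position."""


class DetectionError(ValueError):
    """Component kind could not be inferred from field-name prefixes."""


class SerializationError(TypeError):
    """Record contains values JSON cannot represent."""


def _looks_like_text(source: str) -> bool:
    stripped = source.lstrip()
    return stripped.startswith("{") or stripped.startswith("[")


def read_component(source: Union[str, os.PathLike],
                   registry: Optional[SchemaRegistry] = None) -> Tuple[str, dict]:
    """Read one component document from a path or raw JSON text.

    Returns ``(kind, record)`` with canonicalized field names.  Datasheet
    references of the form ``{"$ref-path": name}`` are resolved relative to
    the source file's directory (path input only) and inlined.
    """
    base_dir: Optional[str] = None
    if isinstance(source, os.PathLike) or (isinstance(source, str) and not _looks_like_text(source)):
        path = os.fspath(source)
        base_dir = os.path.dirname(os.path.abspath(path))
        try:
            with open(path, encoding="utf-8") as fh:
                text = fh.read()
        except OSError as exc:
            raise ParseError(f"cannot read {path}: {exc}") from exc
        origin = path
    else:
        text = str(source)
        origin = "<text>"
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{origin}: malformed JSON at line {exc.lineno}, column {exc.colno}: {exc.msg}") from exc
    if not isinstance(raw, Mapping):
        raise ParseError(f"{origin}: component document must be a JSON object")
    record = canonicalize_record(raw)
    record.pop(SCHEMA_VERSION_KEY, None)
    kind = detect_kind(record, origin=origin)
    if base_dir is not None:
        record = _resolve_ref_paths(record, base_dir)
    return kind, record


def detect_kind(record: Mapping, origin: str = "<record>") -> str:
    """Infer the component kind from top-level field-name prefixes."""
    prefixes = set()
    for key in record:
        if key == SCHEMA_VERSION_KEY or not isinstance(key, str):
            continue
        head = key.split("_", 1)[0]
        if head in COMPONENT_KINDS:
            prefixes.add(head)
    if not prefixes:
        raise DetectionError(f"{origin}: no recognizable component field prefixes")
    if len(prefixes) > 1:
        raise DetectionError(f"{origin}: mixed component prefixes {sorted(prefixes)}")
    return prefixes.pop()


def _resolve_ref_paths(value, base_dir: str):
    if isinstance(value, Mapping):
        if set(value.keys()) == {REF_PATH_KEY}:
            ref = os.path.join(base_dir, value[REF_PATH_KEY])
            _, inner = read_component(ref)
            return inner
        return {k: _resolve_ref_paths(v, base_dir) for k, v in value.items()}
    if isinstance(value, list):
        return [_resolve_ref_paths(v, base_dir) for v in value]
    return value


# --- canonical writing ---------------------------------------------------

def _field_order(registry: SchemaRegistry, kind: str) -> dict:
    return {s.name: i for i, s in enumerate(registry.fields(kind))}


def _ordered(value, order: dict):
    if isinstance(value, Mapping):
        known = [k for k in value if k in order]
        unknown = [k for k in value if k not in order]
        keys = sorted(known, key=order.__getitem__) + unknown
        return {k: _ordered(value[k], order) for k in keys}
    if isinstance(value, list):
        return [_ordered(v, order) for v in value]
    return value


def write_component(record: Mapping, kind: str,
                    registry: Optional[SchemaRegistry] = None) -> str:
    """Serialize a record to canonical JSON text (deterministic bytes)."""
    registry = registry or build_registry()
    registry._check_kind(kind)
    rec = canonicalize_record(record)
    rec.pop(SCHEMA_VERSION_KEY, None)
    order = _field_order(registry, kind)
    body = {SCHEMA_VERSION_KEY: registry.schema_version}
    body.update(_ordered(rec, order))
    try:
        return json.dumps(body, indent=2, ensure_ascii=False, allow_nan=False) + "\n"
    except (TypeError, ValueError) as exc:
        raise SerializationError(f"record of kind {kind!r} is not JSON-serializable: {exc}") from exc


# --- JSON Schema emission ------------------------------------------------

def emit_json_schema(registry: SchemaRegistry, kind: str,
                     version: Optional[str] = None) -> dict:
    """Emit a draft 2020-12 JSON Schema for one component kind."""
    version = version or registry.schema_version
    if version not in SUPPORTED_VERSIONS or version != registry.schema_version:
        raise UnsupportedVersionError(f"registry does not provide version {version!r}")
    registry._check_kind(kind)
    schema = {
        "$schema": "https://json-schema.org/draft/2020-12/schema",
        "$id": f"{_SCHEMA_ID_BASE}/{version}/{kind}.schema.json",
        "title": f"Light-dosimetry metadata descriptor: {kind} (v{version})",
        "x-validator-only": sorted(VALIDATOR_ONLY_RULES),
    }
    schema.update(_object_schema(registry, kind, parent=None))
    schema["properties"][SCHEMA_VERSION_KEY] = {
        "type": "string",
        "description": "Descriptor version annotation added by writers.",
    }
    if kind == "participant":
        # anonymity: the participant field set is closed
        schema["additionalProperties"] = False
    defs = _collect_defs(registry, kind)
    if defs:
        schema["$defs"] = defs
    return schema


def _collect_defs(registry: SchemaRegistry, kind: str) -> dict:
    refs = sorted({s.ref_kind for s in registry.fields(kind) if s.ref_kind})
    defs = {}
    for ref in refs:
        defs[ref] = _object_schema(registry, ref, parent=None)
        nested = _collect_defs(registry, ref)
        for k, v in nested.items():
            defs.setdefault(k, v)
    return defs


def _object_schema(registry: SchemaRegistry, kind: str, parent: Optional[str]) -> dict:
    children = registry.children(kind, parent)
    props = {}
    req = []
    for spec in children:
        props[spec.name] = _field_schema(registry, kind, spec)
        if spec.requiredness == "required":
            req.append(spec.name)
    out: dict = {"type": "object", "properties": props}
    if req:
        out["required"] = req
    _attach_conditionals(out, kind, parent)
    return out


def _attach_conditionals(obj_schema: dict, kind: str, parent: Optional[str]) -> None:
    if kind != "dataset":
        return
    if parent == "dataset_datetime":
        obj_schema["dependentRequired"] = {
            "dataset_datetime_time": ["dataset_datetime_timeformat"],
            "dataset_datetime_timeformat": ["dataset_datetime_time"],
        }
    elif parent == "dataset_file_preprocessing":
        obj_schema["if"] = {
            "properties": {"dataset_file_preprocessing_bol": {"const": True}},
            "required": ["dataset_file_preprocessing_bol"],
        }
        obj_schema["then"] = {
            "required": ["dataset_file_preprocessing_desc"],
            "properties": {
                "dataset_file_preprocessing_desc": {
                    "type": "array",
                    "minItems": 1,
                    "items": {"type": "string", "minLength": 1},
                }
            },
        }


def _field_schema(registry: SchemaRegistry, kind: str, spec: FieldSpec) -> dict:
    base: dict = {}
    if spec.description:
        base["description"] = spec.description
    t = spec.value_type
    if t in ("string", "email"):
        base["type"] = "string"
        if t == "email":
            base["format"] = "idn-email"
        if spec.name == "contributor_orcid":
            base["x-validator-only-rule"] = "bad-orcid"
        if spec.name in ("dataset_timezone", "dataset_file_timezone"):
            base["x-validator-only-rule"] = "bad-timezone"
        if spec.name == "device_calibration":
            base["format"] = "date"
            base["x-validator-only-rule"] = "bad-date"
    elif t in ("integer", "number", "boolean"):
        base["type"] = t
    elif t == "object":
        if spec.ref_kind:
            base["$ref"] = f"#/$defs/{spec.ref_kind}"
        else:
            base.update(_object_schema(registry, kind, parent=spec.name))
    elif t == "array-of-strings":
        base["type"] = "array"
        base["items"] = {"type": "string"}
        if spec.min_items:
            base["minItems"] = spec.min_items
        if spec.name == "dataset_location":
            base["x-validator-only-rule"] = "bad-location"
    elif t == "array-of-objects":
        base["type"] = "array"
        if spec.ref_kind:
            base["items"] = {"$ref": f"#/$defs/{spec.ref_kind}"}
        else:
            item_specs = registry.item_fields(kind, spec)
            inner_parent = item_specs[0].parent if item_specs else spec.name
            base["items"] = _object_schema(registry, kind, parent=inner_parent)
        if spec.min_items:
            base["minItems"] = spec.min_items
        if spec.name == "datasheet_calibration_spectral_sensitivity":
            base["x-validator-only-rule"] = "non-ascending-spectral"
    return base


def registry_export_text(registry: SchemaRegistry) -> str:
    """The registry itself as versioned JSON, for consumption by other tools."""
    return json.dumps(registry.to_json_obj(), indent=2, ensure_ascii=False) + "\n"
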