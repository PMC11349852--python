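"""Field registry for the light-dosimetry metadata descriptor.

The descriptor documents a study's light-logging data collection across six
component kinds — study, contributor, participant, dataset, device and
device/sensor datasheet — each a JSON document with a fixed, versioned field
vocabulary.  This module holds the machine-readable transcription of that
vocabulary: one :class:`FieldSpec` per field row, assembled into an immutable
:class:`SchemaRegistry` that the validator, the JSON Schema emitter and the
fixture generator all consult.

Canonical field names are lower_snake_case.  Source documents occasionally
carry typographic variants (mixed case, stray spaces); readers normalize them
with :func:`canonicalize_field_name` before lookup.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from typing import Iterator, Optional

__all__ = [
    "COMPONENT_KINDS",
    "SUPPORTED_VERSIONS",
    "FieldSpec",
    "SchemaRegistry",
    "build_registry",
    "required_fields",
    "canonicalize_field_name",
    "UnsupportedVersionError",
    "UnknownKindError",
]

#: The six component kinds, in descriptor order.  Each corresponds to one
#: JSON document type (study.json, contributor.json, participant.json,
#: dataset.json, device.json, device_datasheet.json).
COMPONENT_KINDS = ("study", "contributor", "participant", "dataset", "device", "datasheet")

#: Descriptor versions this registry can materialize.
SUPPORTED_VERSIONS = ("1.0",)

REQUIRED = "required"
OPTIONAL = "optional"
CONDITIONAL = "conditional"

_REQUIREDNESS = frozenset({REQUIRED, OPTIONAL, CONDITIONAL})
_VALUE_TYPES = frozenset(
    {
        "string",
        "integer",
        "number",
        "boolean",
        "array-of-strings",
        "array-of-objects",
        "object",
        "email",
    }
)


class UnsupportedVersionError(ValueError):
    """Raised for a descriptor version the registry does not know."""


class UnknownKindError(KeyError):
    """Raised for a component kind outside the six descriptor kinds."""


@dataclass(frozen=True)
class FieldSpec:
    """One field row of the descriptor vocabulary.

    Parameters
    ----------
    component_kind:
        Which of the six component documents the field belongs to.
    name:
        Canonical lower_snake_case field name.
    level:
        Nesting depth; 1 is a top-level key of the component document.
    requiredness:
        ``required``, ``optional`` or ``conditional`` (present only when a
        sibling condition triggers; enforced by a dedicated rule, not by the
        blanket presence check).
    value_type:
        JSON-level type of the value.  ``email`` is a string with an
        address-format constraint.
    description:
        Human-readable meaning of the field.
    parent:
        Name of the enclosing object/array field, or ``None`` at top level.
    ref_kind:
        For fields whose value is (an array of) another component kind's
        record — e.g. a study's contributors, a device's datasheet.
    condition:
        Rule id of the conditional-requirement rule governing this field.
    min_items:
        Minimum array length when the field is present.
    """

    component_kind: str
    name: str
    level: int
    requiredness: str
    value_type: str
    description: str = ""
    parent: Optional[str] = None
    ref_kind: Optional[str] = None
    condition: Optional[str] = None
    min_items: Optional[int] = None

    def __post_init__(self) -> None:
        if self.requiredness not in _REQUIREDNESS:
            raise ValueError(f"bad requiredness {self.requiredness!r} for {self.name}")
        if self.value_type not in _VALUE_TYPES:
            raise ValueError(f"bad value_type {self.value_type!r} for {self.name}")
        if self.level < 1:
            raise ValueError(f"level must be >= 1, got {self.level} for {self.name}")


_CANON_RE = re.compile(r"[ \t]+")


def canonicalize_field_name(raw: str) -> str:
    """Normalize a field name to canonical lower_snake_case.

    Lower-cases, converts internal whitespace to underscores and collapses
    runs of underscores.  Idempotent; unknown names pass through unchanged in
    shape (validation flags them later).
    """
    name = _CANON_RE.sub("_", raw.strip().lower())
    return re.sub(r"_{2,}", "_", name)


# --- table transcription -------------------------------------------------
# One tuple per field row: (kind, name, level, requiredness, value_type,
# description, parent, ref_kind, condition, min_items).  Order follows the
# printed tables; this order is the document order used for canonical output
# and deterministic issue reporting.

_R, _O, _C = REQUIRED, OPTIONAL, CONDITIONAL

_ROWS: tuple = (
    # -- study ------------------------------------------------------------
    ("study", "study_title", 1, _R, "string", "Title of the study", None, None, None, None),
    ("study", "study_internal_id", 1, _R, "string", "Unique identifier for study", None, None, None, None),
    ("study", "study_preregistration", 1, _O, "string",
     "DOI (Digital Object Identifier) of pre-registration document describing data collection",
     None, None, None, None),
    ("study", "study_ethics", 1, _O, "string", "Name of ethics committee and approval number", None, None, None, None),
    ("study", "study_registration", 1, _O, "string", "Registry and ID of clinical trial registration", None, None, None, None),
    ("study", "study_short_description", 1, _R, "string", "Short narrative description of the study", None, None, None, None),
    ("study", "study_sample", 1, _R, "string", "Short description of the study sample", None, None, None, None),
    ("study", "study_groups", 1, _O, "array-of-objects", "Groups in the study", None, None, None, None),
    ("study", "study_group", 2, _O, "object", "Group descriptor object", "study_groups", None, None, None),
    ("study", "study_group_name", 3, _R, "string", "Group name", "study_group", None, None, None),
    ("study", "study_group_description", 3, _O, "string", "Group description", "study_group", None, None, None),
    ("study", "study_group_size", 3, _O, "integer", "Sample size", "study_group", None, None, None),
    ("study", "study_group_inclusion", 3, _O, "array-of-strings",
     "Inclusion criteria for sample group, given as an array of strings", "study_group", None, None, 0),
    ("study", "study_group_exclusion", 3, _O, "array-of-strings",
     "Exclusion criteria for sample group, given as an array of strings", "study_group", None, None, 0),
    ("study", "study_intervention", 1, _O, "string",
     "Short description of the study intervention, if any", None, None, None, None),
    ("study", "study_setting", 1, _R, "string", "Description of the study setting", None, None, None, None),
    ("study", "study_geographical_location", 1, _R, "string",
     "Geographical location and context (rural, urban)", None, None, None, None),
    ("study", "study_contributors", 1, _O, "array-of-objects", "Any contributors to the study",
     None, "contributor", None, None),
    ("study", "study_datasets", 1, _R, "array-of-strings", "Datasets contained within the study", None, None, None, None),
    ("study", "study_type", 1, _O, "string", "Type of the study", None, None, None, None),
    ("study", "study_funding_sources", 1, _O, "array-of-strings",
     "Any funding sources supporting the project. If the funding number is available, it should be given",
     None, None, None, 1),
    ("study", "study_keywords", 1, _O, "array-of-strings", "Key words describing the project", None, None, None, None),
    # -- contributor ------------------------------------------------------
    ("contributor", "contributor_full_name", 1, _R, "string", "Full name of the contributor", None, None, None, None),
    ("contributor", "contributor_roles", 1, _O, "array-of-strings", "Contributor roles (CRediT)", None, None, None, None),
    ("contributor", "contributor_email", 1, _O, "email", "Email address", None, None, None, None),
    ("contributor", "contributor_orcid", 1, _R, "string", "ORCID identifier", None, None, None, None),
    ("contributor", "contributor_institution", 1, _O, "object", "Institution", None, None, None, None),
    ("contributor", "contributor_institution_name", 2, _R, "string", "Name of institution",
     "contributor_institution", None, None, None),
    ("contributor", "contributor_institution_city", 2, _O, "string", "City of institution",
     "contributor_institution", None, None, None),
    ("contributor", "contributor_institution_country", 2, _R, "string", "Country of institution",
     "contributor_institution", None, None, None),
    # -- participant ------------------------------------------------------
    ("participant", "participant_internal_id", 1, _R, "string", "Unique ID for participant", None, None, None, None),
    ("participant", "participant_age", 1, _R, "integer",
     "Age of the participant at the time of first participation", None, None, None, None),
    ("participant", "participant_sex", 1, _O, "string", "Sex of participant, if recorded", None, None, None, None),
    ("participant", "participant_gender", 1, _O, "string", "Gender of participant, if required", None, None, None, None),
    ("participant", "participant_characteristic", 1, _O, "array-of-objects",
     "Biological and non-biological characteristics of participant", None, None, None, None),
    ("participant", "participant_characteristic_name", 2, _R, "string", "Name of the characteristic",
     "participant_characteristic", None, None, None),
    ("participant", "participant_characteristic_value", 2, _R, "string", "Value of the characteristic",
     "participant_characteristic", None, None, None),
    ("participant", "participant_characteristic_unit", 2, _O, "string", "Unit of the characteristic",
     "participant_characteristic", None, None, None),
    ("participant", "participant_characteristic_description", 2, _O, "string", "Description of the characteristic",
     "participant_characteristic", None, None, None),
    # -- dataset ----------------------------------------------------------
    ("dataset", "dataset_internal_id", 1, _R, "string", "Unique identifier of dataset", None, None, None, None),
    ("dataset", "dataset_instructions", 1, _R, "string",
     "Description of the instructions that were given to the study participants before or during the "
     "collection of this data set", None, None, None, None),
    ("dataset", "dataset_crossref", 1, _R, "object", "Crossreferencing information", None, None, None, None),
    ("dataset", "dataset_crossref_study_id", 2, _R, "string", "Internal ID for study",
     "dataset_crossref", None, None, None),
    ("dataset", "dataset_crossref_participant_id", 2, _R, "string", "Internal ID for participant",
     "dataset_crossref", None, None, None),
    ("dataset", "dataset_crossref_device_id", 2, _R, "string", "Internal ID for device",
     "dataset_crossref", None, None, None),
    ("dataset", "dataset_device_location", 1, _R, "string", "Anatomical location of the acquisition device",
     None, None, None, None),
    ("dataset", "dataset_sampling_interval", 1, _R, "number", "Sampling interval (seconds)", None, None, None, None),
    ("dataset", "dataset_datetime", 1, _R, "object", "Name of the datetime column", None, None, None, None),
    ("dataset", "dataset_datetime_date", 2, _R, "string", "Name of the date column or datetime column",
     "dataset_datetime", None, None, None),
    ("dataset", "dataset_datetime_dateformat", 2, _R, "string",
     'Formatting of the date column (e.g., "YYYY/MM/DD") or datetime column (e.g. "YYYY/MM/DD HH:MM:SS")',
     "dataset_datetime", None, None, None),
    ("dataset", "dataset_datetime_time", 2, _C, "string", "Name of the time column (only if separate from date)",
     "dataset_datetime", None, "datetime-spec-incomplete", None),
    ("dataset", "dataset_datetime_timeformat", 2, _C, "string",
     'Formatting of the time column (e.g., "HH:MM:SS") (only if separate from date)',
     "dataset_datetime", None, "datetime-spec-incomplete", None),
    ("dataset", "dataset_illuminance", 1, _R, "string",
     "Column name in the data that contains photopic illuminance", None, None, None, None),
    ("dataset", "dataset_meledi", 1, _O, "string",
     "Column name in the data that contains melanopic EDI (D65)", None, None, None, None),
    ("dataset", "dataset_timezone", 1, _R, "string", "Timezone of data collection (Olson database)",
     None, None, None, None),
    ("dataset", "dataset_location", 1, _R, "array-of-strings", "Latitude/Longitude of data collection",
     None, None, None, None),
    ("dataset", "dataset_file", 1, _R, "array-of-objects", "Dataset descriptors", None, None, None, None),
    ("dataset", "dataset_file_names", 2, _R, "array-of-strings", "File names corresponding",
     "dataset_file", None, None, None),
    ("dataset", "dataset_file_format", 2, _R, "string", "File format", "dataset_file", None, None, None),
    ("dataset", "dataset_file_encoding", 2, _R, "array-of-strings", "File text encoding (e.g., UTF-8)",
     "dataset_file", None, None, None),
    ("dataset", "dataset_file_timezone", 2, _R, "string", "Timezone of data (Olson database)",
     "dataset_file", None, None, None),
    ("dataset", "dataset_file_auxiliary", 2, _R, "boolean",
     "Indicator whether the data files contain light data (or auxiliary data)", "dataset_file", None, None, None),
    ("dataset", "dataset_file_preprocessing", 2, _R, "object", "Preprocessing Information",
     "dataset_file", None, None, None),
    ("dataset", "dataset_file_preprocessing_bol", 3, _R, "boolean", "Indicator whether preprocessing was applied",
     "dataset_file_preprocessing", None, None, None),
    ("dataset", "dataset_file_preprocessing_desc", 3, _C, "array-of-strings",
     "Description what preprocessing was applied (conditional requirement)",
     "dataset_file_preprocessing", None, "conditional-preprocessing", 1),
    ("dataset", "dataset_file_variables", 2, _R, "array-of-objects",
     "Variables contained in the data set, units and location (column)", "dataset_file", None, None, None),
    ("dataset", "dataset_file_variables_name", 3, _R, "string", "Variable name as contained in the dataset",
     "dataset_file_variables", None, None, None),
    ("dataset", "dataset_file_variables_labels", 3, _R, "string", "Variable name as clear name",
     "dataset_file_variables", None, None, None),
    ("dataset", "dataset_file_variables_units", 3, _R, "string", "Unit", "dataset_file_variables", None, None, None),
    ("dataset", "dataset_file_variables_calibration", 3, _O, "string",
     "Description of transformation that should be applied to the variable for calibration",
     "dataset_file_variables", None, None, None),
    # -- device -----------------------------------------------------------
    ("device", "device_internal_id", 1, _R, "string", "Unique ID of the device", None, None, None, None),
    ("device", "device_manufacturer", 1, _R, "string", "Manufacturer of the device", None, None, None, None),
    ("device", "device_model", 1, _R, "string", "Model of the device", None, None, None, None),
    ("device", "device_serial_number", 1, _R, "string", "Serial number of the device", None, None, None, None),
    ("device", "device_calibration", 1, _R, "string", "Date the device was last calibrated", None, None, None, None),
    ("device", "device_sensor", 1, _O, "array-of-objects", "Individual sensors", None, None, None, None),
    ("device", "device_sensor_type", 2, _R, "string", "Type of the sensor", "device_sensor", None, None, None),
    ("device", "device_sensor_datasheet", 2, _O, "object", "Sensor datasheet information",
     "device_sensor", "datasheet", None, None),
    ("device", "device_datasheet", 1, _R, "object", "Device datasheet information", None, "datasheet", None, None),
    # -- datasheet --------------------------------------------------------
    ("datasheet", "datasheet_manufacturer", 1, _R, "string", "Manufacturer of the sensor/device", None, None, None, None),
    ("datasheet", "datasheet_type", 1, _R, "string", "Type of the sensor/device", None, None, None, None),
    ("datasheet", "datasheet_model", 1, _R, "string", "Model of the sensor/device", None, None, None, None),
    ("datasheet", "datasheet_calibration_interval", 1, _R, "number",
     "Required device calibration interval (in days)", None, None, None, None),
    ("datasheet", "datasheet_calibration_spectral_sensitivity", 1, _R, "array-of-objects",
     "Information about spectral sensitivity calibration", None, None, None, 1),
    ("datasheet", "datasheet_calibration_spectral_sensitivity_wavelength", 2, _R, "number",
     "Wavelength (nm)", "datasheet_calibration_spectral_sensitivity", None, None, None),
    ("datasheet", "datasheet_calibration_spectral_sensitivity_relative", 2, _R, "number",
     "Relative spectral sensitivity at given wavelength",
     "datasheet_calibration_spectral_sensitivity", None, None, None),
    ("datasheet", "datasheet_calibration_linearity", 1, _R, "string", "Information about linearity calibration",
     None, None, None, None),
    ("datasheet", "datasheet_calibration_directional_response", 1, _R, "string",
     "Information about directional response calibration", None, None, None, None),
    ("datasheet", "datasheet_calibration_range", 1, _R, "string", "Information about response range",
     None, None, None, None),
    ("datasheet", "datasheet_channel", 1, _O, "array-of-objects", "Information on channels", None, None, None, None),
    ("datasheet", "datasheet_channel_nr", 2, _R, "integer", "Number of channel", "datasheet_channel", None, None, None),
    ("datasheet", "datasheet_channel_name", 2, _R, "string",
     "Name of the channel as appearing in the export (file)", "datasheet_channel", None, None, None),
    ("datasheet", "datasheet_channel_unit", 2, _O, "string", "Unit of channel", "datasheet_channel", None, None, None),
    ("datasheet", "datasheet_channel_description", 2, _O, "string", "Description of channel",
     "datasheet_channel", None, None, None),
)


@dataclass(frozen=True)
class SchemaRegistry:
    """Immutable collection of :class:`FieldSpec` entries for one version."""

    entries: tuple
    schema_version: str
    _by_kind: dict = dc_field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        by_kind: dict[str, dict[str, FieldSpec]] = {k: {} for k in COMPONENT_KINDS}
        for spec in self.entries:
            if spec.component_kind not in by_kind:
                raise UnknownKindError(spec.component_kind)
            kind_map = by_kind[spec.component_kind]
            if spec.name in kind_map:
                raise ValueError(f"duplicate field {spec.name} in {spec.component_kind}")
            if spec.level > 1:
                if spec.parent is None or spec.parent not in kind_map:
                    raise ValueError(f"field {spec.name} (level {spec.level}) lacks a known parent")
                if kind_map[spec.parent].level != spec.level - 1:
                    raise ValueError(f"field {spec.name} parent is not one level up")
            kind_map[spec.name] = spec
        object.__setattr__(self, "_by_kind", by_kind)

    # -- queries ----------------------------------------------------------
    def kinds(self) -> tuple:
        return COMPONENT_KINDS

    def fields(self, kind: str) -> list:
        """All field specs of *kind*, in table order."""
        self._check_kind(kind)
        return [s for s in self.entries if s.component_kind == kind]

    def lookup(self, kind: str, name: str) -> FieldSpec:
        self._check_kind(kind)
        try:
            return self._by_kind[kind][name]
        except KeyError:
            raise KeyError(f"no field {name!r} in component {kind!r}") from None

    def has_field(self, kind: str, name: str) -> bool:
        self._check_kind(kind)
        return name in self._by_kind[kind]

    def children(self, kind: str, parent: Optional[str]) -> list:
        """Direct child specs of *parent* (``None`` for top level), in table order."""
        return [s for s in self.fields(kind) if s.parent == parent]

    def item_fields(self, kind: str, spec: FieldSpec) -> list:
        """Field specs describing one element of an array-of-objects field.

        Children may be listed directly under the array field, or under a
        single intermediate item-definition row (an ``object`` child that
        itself has children), as the study-group table does.
        """
        kids = self.children(kind, spec.name)
        if len(kids) == 1 and kids[0].value_type == "object":
            inner = self.children(kind, kids[0].name)
            if inner:
                return inner
        return kids

    def _check_kind(self, kind: str) -> None:
        if kind not in self._by_kind:
            raise UnknownKindError(f"unknown component kind {kind!r}")

    def __iter__(self) -> Iterator[FieldSpec]:
        return iter(self.entries)

    def to_json_obj(self) -> dict:
        """Versioned, tool-neutral JSON export of the registry."""
        return {
            "schema_version": self.schema_version,
            "fields": [
                {
                    "component_kind": s.component_kind,
                    "name": s.name,
                    "level": s.level,
                    "requiredness": s.requiredness,
                    "value_type": s.value_type,
                    "description": s.description,
                    **({"parent": s.parent} if s.parent else {}),
                    **({"ref_kind": s.ref_kind} if s.ref_kind else {}),
                    **({"condition": s.condition} if s.condition else {}),
                    **({"min_items": s.min_items} if s.min_items is not None else {}),
                }
                for s in self.entries
            ],
        }


def build_registry(schema_version: str = "1.0") -> SchemaRegistry:
    """Materialize the full field registry for a descriptor version.

    Raises
    ------
    UnsupportedVersionError
        If *schema_version* is not one of :data:`SUPPORTED_VERSIONS`.
    """
    if schema_version not in SUPPORTED_VERSIONS:
        raise UnsupportedVersionError(
            f"unsupported descriptor version {schema_version!r}; supported: {', '.join(SUPPORTED_VERSIONS)}"
        )
    entries = tuple(
        FieldSpec(
            component_kind=k, name=n, level=lv, requiredness=req, value_type=vt,
            description=desc, parent=parent, ref_kind=ref, condition=cond, min_items=mi,
        )
        for (k, n, lv, req, vt, desc, parent, ref, cond, mi) in _ROWS
    )
    return SchemaRegistry(entries=entries, schema_version=schema_version)


def required_fields(registry: SchemaRegistry, kind: str) -> list:
    """Top-level (level-1) required field names of *kind*, in table order."""
    return [s.name for s in registry.children(kind, None) if s.requiredness == REQUIRED]
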