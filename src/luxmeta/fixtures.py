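"""Synthetic, schema-conformant metadata bundles and light-logger data.

The generator instantiates every component of the descriptor with
plausible chronobiology-study content: a field study of daily light
exposure with wrist- and spectacle-worn dosimeters, participants of
realistic ages, one dataset per participant per assigned device, devices
with short-wavelength-peaked (melanopsin-like, ~490 nm) spectral
sensitivity datasheets, and consistent cross-references throughout.  All
randomness flows from a single seeded generator, so identical
:class:`FixtureSpec` values give byte-identical serialized outputs.

:func:`inject_violation` produces single-edit mutants, one per documented
rule id, used as the validator's ground-truth oracle: re-validating a
mutant must flag exactly the injected rule, and the unmutated bundle must
validate clean.

Matching light-logger CSV files follow a diurnal illuminance profile —
night plateau 1 lx, day plateau 1000 lx, raised-cosine dawn/dusk
transitions, multiplicative log-normal noise — with melanopic EDI a fixed
0.9 of illuminance.  The profile exists to exercise schema and binding,
not to simulate photometric reality.
"""

from __future__ import annotations

import copy
import datetime as dt
import math
import os
import random
from dataclasses import dataclass, replace
from typing import Optional, Union

from .bundle import MetadataBundle
from .registry import SchemaRegistry, build_registry

__all__ = [
    "FixtureSpec",
    "FixtureError",
    "VIOLATION_RULES",
    "generate_bundle",
    "inject_violation",
    "generate_light_table",
    "write_fixture_tree",
    "NIGHT_LX",
    "DAY_LX",
    "MELEDI_RATIO",
]

NIGHT_LX = 1.0
DAY_LX = 1000.0
#: Fixed melanopic-EDI-to-illuminance ratio; < 1 so the melEDI column is
#: distinguishable from illuminance everywhere.
MELEDI_RATIO = 0.9
_DAWN_H, _DUSK_H, _TRANSITION_H = 7.0, 19.0, 2.0
_NOISE_SIGMA = 0.3
#: Start date chosen away from DST transitions in the fixture timezone.
_START_DATE = dt.date(2024, 3, 4)

#: The documented single-edit violation rules the oracle covers.
VIOLATION_RULES = (
    "missing-required",
    "type-mismatch",
    "conditional-preprocessing",
    "dangling-crossref",
    "duplicate-id",
    "bad-timezone",
    "bad-orcid",
    "missing-data-curation",
    "non-ascending-spectral",
    "datetime-spec-incomplete",
)


class FixtureError(ValueError):
    """Invalid fixture specification or unknown violation rule."""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters controlling synthetic bundle/data generation."""

    seed: int = 0
    n_participants: int = 3
    n_devices: int = 2
    datasets_per_participant: int = 1
    days: float = 1.0
    sampling_interval_s: float = 60.0
    violation: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_devices < 1 or self.datasets_per_participant < 1:
            raise FixtureError("counts must be >= 1")
        if self.days <= 0 or self.sampling_interval_s <= 0:
            raise FixtureError("days and sampling_interval_s must be > 0")


_GIVEN = ("Ada", "Erik", "Mira", "Jonas", "Lea", "Tomás", "Aiko", "Nora", "Ravi", "Selin")
_FAMILY = ("Keller", "Lindqvist", "Okafor", "Martins", "Svensson", "Tanaka", "Weber", "Novak")
_CITIES = (
    ("Munich", "Germany", "Europe/Berlin", ("48.137", "11.575")),
    ("Basel", "Switzerland", "Europe/Zurich", ("47.559", "7.588")),
    ("Umeå", "Sweden", "Europe/Stockholm", ("63.825", "20.263")),
    ("Guildford", "United Kingdom", "Europe/London", ("51.236", "-0.570")),
)
_LOCATIONS = ("wrist", "chest", "spectacle frame")
_MANUFACTURERS = ("LuxTrack", "OcuLight", "ChronoSense")


def _orcid(rng: random.Random) -> str:
    digits = [rng.randrange(10) for _ in range(15)]
    total = 0
    for d in digits:
        total = (total + d) * 2
    check = (12 - total % 11) % 11
    body = "".join(map(str, digits)) + ("X" if check == 10 else str(check))
    return "-".join(body[i:i + 4] for i in range(0, 16, 4))


def _spectral_curve() -> list:
    """Melanopsin-like relative sensitivity, peak 1.0 at 490 nm."""
    points = []
    for wl in range(400, 701, 20):
        rel = math.exp(-0.5 * ((wl - 490) / 45.0) ** 2)
        points.append({
            "datasheet_calibration_spectral_sensitivity_wavelength": float(wl),
            "datasheet_calibration_spectral_sensitivity_relative": round(rel, 6),
        })
    peak = max(p["datasheet_calibration_spectral_sensitivity_relative"] for p in points)
    for p in points:
        p["datasheet_calibration_spectral_sensitivity_relative"] = round(
            p["datasheet_calibration_spectral_sensitivity_relative"] / peak, 6)
    return points


def _datasheet(rng: random.Random, manufacturer: str, model: str) -> dict:
    return {
        "datasheet_manufacturer": manufacturer,
        "datasheet_type": "wearable light dosimeter",
        "datasheet_model": model,
        "datasheet_calibration_interval": float(rng.choice((180, 365))),
        "datasheet_calibration_spectral_sensitivity": _spectral_curve(),
        "datasheet_calibration_linearity": "linear within 2% over 0.1-100000 lx",
        "datasheet_calibration_directional_response": "cosine-corrected diffuser, f2 < 3%",
        "datasheet_calibration_range": "0.1-100000 lx",
        "datasheet_channel": [
            {
                "datasheet_channel_nr": 1,
                "datasheet_channel_name": "lux",
                "datasheet_channel_unit": "lx",
                "datasheet_channel_description": "photopic illuminance",
            },
            {
                "datasheet_channel_nr": 2,
                "datasheet_channel_name": "mEDI",
                "datasheet_channel_unit": "lx",
                "datasheet_channel_description": "melanopic equivalent daylight illuminance (D65)",
            },
        ],
    }


def _device(rng: random.Random, idx: int) -> dict:
    manufacturer = _MANUFACTURERS[idx % len(_MANUFACTURERS)]
    model = f"{manufacturer[:3].upper()}-{100 + idx}"
    cal = _START_DATE - dt.timedelta(days=rng.randrange(10, 90))
    return {
        "device_internal_id": f"dev{idx + 1:02d}",
        "device_manufacturer": manufacturer,
        "device_model": model,
        "device_serial_number": f"SN{rng.randrange(10 ** 6):06d}",
        "device_calibration": cal.isoformat(),
        "device_sensor": [
            {"device_sensor_type": "melanopic photodiode",
             "device_sensor_datasheet": _datasheet(rng, manufacturer, model + "-S")}
        ],
        "device_datasheet": _datasheet(rng, manufacturer, model),
    }


def _participant(rng: random.Random, idx: int) -> dict:
    return {
        "participant_internal_id": f"p{idx + 1:03d}",
        "participant_age": rng.randrange(18, 75),
        "participant_sex": rng.choice(("female", "male", "intersex")),
        "participant_characteristic": [
            {
                "participant_characteristic_name": "chronotype (MSFsc)",
                "participant_characteristic_value": f"{rng.uniform(2.0, 6.0):.2f}",
                "participant_characteristic_unit": "h",
                "participant_characteristic_description":
                    "mid-sleep on free days, sleep-debt corrected",
            }
        ],
    }


def _contributors(rng: random.Random) -> list:
    curator = {
        "contributor_full_name": f"{rng.choice(_GIVEN)} {rng.choice(_FAMILY)}",
        "contributor_roles": ["Data curation", "Investigation"],
        "contributor_email": "curation@chronolight.example.org",
        "contributor_orcid": _orcid(rng),
        "contributor_institution": {
            "contributor_institution_name": "Institute of Chronobiology",
            "contributor_institution_city": "Munich",
            "contributor_institution_country": "Germany",
        },
    }
    second = {
        "contributor_full_name": f"{rng.choice(_GIVEN)} {rng.choice(_FAMILY)}",
        "contributor_roles": ["Conceptualization", "Supervision"],
        "contributor_orcid": _orcid(rng),
    }
    return [curator, second]


def _dataset(rng: random.Random, idx: int, study_id: str, participant_id: str,
             device_id: str, spec: FixtureSpec, city) -> dict:
    ds_id = f"ds{idx + 1:03d}"
    split = idx % 2 == 0  # alternate split date/time and combined datetime layouts
    if split:
        datetime_spec = {
            "dataset_datetime_date": "date",
            "dataset_datetime_dateformat": "YYYY/MM/DD",
            "dataset_datetime_time": "time",
            "dataset_datetime_timeformat": "HH:MM:SS",
        }
    else:
        datetime_spec = {
            "dataset_datetime_date": "datetime",
            "dataset_datetime_dateformat": "YYYY-MM-DD HH:MM:SS",
        }
    tz = city[2]
    return {
        "dataset_internal_id": ds_id,
        "dataset_instructions":
            "Wear the dosimeter during all waking hours; place it on the nightstand, "
            "sensor up, while sleeping.",
        "dataset_crossref": {
            "dataset_crossref_study_id": study_id,
            "dataset_crossref_participant_id": participant_id,
            "dataset_crossref_device_id": device_id,
        },
        "dataset_device_location": _LOCATIONS[idx % len(_LOCATIONS)],
        "dataset_sampling_interval": float(spec.sampling_interval_s),
        "dataset_datetime": datetime_spec,
        "dataset_illuminance": "lux",
        "dataset_meledi": "mEDI",
        "dataset_timezone": tz,
        "dataset_location": list(city[3]),
        "dataset_file": [
            {
                "dataset_file_names": [f"light_{ds_id}.csv"],
                "dataset_file_format": "csv",
                "dataset_file_encoding": ["UTF-8"],
                "dataset_file_timezone": tz,
                "dataset_file_auxiliary": False,
                "dataset_file_preprocessing": {"dataset_file_preprocessing_bol": False},
                "dataset_file_variables": [
                    {
                        "dataset_file_variables_name": "lux",
                        "dataset_file_variables_labels": "illuminance",
                        "dataset_file_variables_units": "lx",
                        "dataset_file_variables_calibration": "x",
                    },
                    {
                        "dataset_file_variables_name": "mEDI",
                        "dataset_file_variables_labels": "melanopic_edi",
                        "dataset_file_variables_units": "lx",
                    },
                ],
            }
        ],
    }


def generate_bundle(spec: FixtureSpec,
                    registry: Optional[SchemaRegistry] = None) -> MetadataBundle:
    """Generate a valid-by-construction bundle, deterministic in the seed."""
    if spec.violation is not None:
        raise FixtureError("generate_bundle requires a spec without a violation; "
                           "use inject_violation on a clean bundle")
    registry = registry or build_registry()
    rng = random.Random(spec.seed)
    city = rng.choice(_CITIES)
    study_id = f"study{rng.randrange(10 ** 4):04d}"
    devices = [_device(rng, i) for i in range(spec.n_devices)]
    participants = [_participant(rng, i) for i in range(spec.n_participants)]
    datasets = []
    idx = 0
    for p in participants:
        for _ in range(spec.datasets_per_participant):
            device = devices[idx % spec.n_devices]
            datasets.append(_dataset(rng, idx, study_id, p["participant_internal_id"],
                                     device["device_internal_id"], spec, city))
            idx += 1
    # every device must end up referenced at least once to keep bundles warning-lean
    referenced = {d["dataset_crossref"]["dataset_crossref_device_id"] for d in datasets}
    for device in devices:
        if device["device_internal_id"] not in referenced and datasets:
            datasets[-1]["dataset_crossref"]["dataset_crossref_device_id"] = \
                device["device_internal_id"]
    study = {
        "study_title": "Daily light exposure and circadian timing in office and outdoor workers",
        "study_internal_id": study_id,
        "study_short_description":
            "Ambulatory light-dosimetry field study recording personal light exposure "
            "across work and rest days.",
        "study_sample": f"{spec.n_participants} healthy adults",
        "study_groups": [
            {
                "study_group_name": "all participants",
                "study_group_description": "single observational group",
                "study_group_size": spec.n_participants,
                "study_group_inclusion": ["age 18-75", "no photosensitive medication"],
                "study_group_exclusion": ["shift work in the last 3 months"],
            }
        ],
        "study_setting": "ambulatory field study under daily-life conditions",
        "study_geographical_location": f"{city[0]}, {city[1]} (urban)",
        "study_contributors": _contributors(rng),
        "study_datasets": [d["dataset_internal_id"] for d in datasets],
        "study_type": "observational",
        "study_funding_sources": ["Example Foundation grant EF-2024-017"],
        "study_keywords": ["light exposure", "dosimetry", "circadian", "melanopic EDI"],
    }
    return MetadataBundle(study=study, participants=participants,
                          datasets=datasets, devices=devices)


# --- violation injection -------------------------------------------------

def inject_violation(bundle: MetadataBundle, rule_id: str,
                     seed: int = 0) -> MetadataBundle:
    """Return a copy of *bundle* with exactly one minimal rule violation."""
    if rule_id not in VIOLATION_RULES:
        raise FixtureError(f"unknown violation rule {rule_id!r}; "
                           f"known: {', '.join(VIOLATION_RULES)}")
    rng = random.Random(seed)
    mutated = MetadataBundle(
        study=copy.deepcopy(bundle.study),
        participants=copy.deepcopy(bundle.participants),
        datasets=copy.deepcopy(bundle.datasets),
        devices=copy.deepcopy(bundle.devices),
    )
    if rule_id == "missing-required":
        del mutated.participants[0]["participant_age"]
    elif rule_id == "type-mismatch":
        mutated.participants[0]["participant_age"] = "forty-two"
    elif rule_id == "conditional-preprocessing":
        pre = mutated.datasets[0]["dataset_file"][0]["dataset_file_preprocessing"]
        pre["dataset_file_preprocessing_bol"] = True
        pre.pop("dataset_file_preprocessing_desc", None)
    elif rule_id == "dangling-crossref":
        mutated.datasets[0]["dataset_crossref"]["dataset_crossref_device_id"] = \
            f"dev-missing-{rng.randrange(100)}"
    elif rule_id == "duplicate-id":
        twin = copy.deepcopy(mutated.participants[0])
        mutated.participants.append(twin)
    elif rule_id == "bad-timezone":
        mutated.datasets[0]["dataset_timezone"] = "Mars/Olympus"
        # keep file-level timezone aligned so only the membership rule fires
        for fd in mutated.datasets[0]["dataset_file"]:
            fd["dataset_file_timezone"] = "Mars/Olympus"
    elif rule_id == "bad-orcid":
        contributor = mutated.study["study_contributors"][0]
        orcid = contributor["contributor_orcid"]
        last = orcid[-1]
        contributor["contributor_orcid"] = orcid[:-1] + (
            "0" if last == "X" else str((int(last) + 1) % 10))
    elif rule_id == "missing-data-curation":
        for c in mutated.study.get("study_contributors", []):
            roles = c.get("contributor_roles", [])
            c["contributor_roles"] = [r for r in roles if r.lower() != "data curation"]
    elif rule_id == "non-ascending-spectral":
        points = mutated.devices[0]["device_datasheet"][
            "datasheet_calibration_spectral_sensitivity"]
        points[0], points[1] = points[1], points[0]
    elif rule_id == "datetime-spec-incomplete":
        spec = _find_split_datetime(mutated)
        spec.pop("dataset_datetime_timeformat")
    return mutated


def _find_split_datetime(bundle: MetadataBundle) -> dict:
    for ds in bundle.datasets:
        spec = ds.get("dataset_datetime", {})
        if "dataset_datetime_time" in spec:
            return spec
    raise FixtureError("bundle has no dataset with split date/time columns")


# --- light-logger data ---------------------------------------------------

def _diurnal_weight(hour: float) -> float:
    """0 at night, 1 by day, raised-cosine transitions at dawn and dusk."""
    half = _TRANSITION_H / 2.0
    if hour < _DAWN_H - half or hour >= _DUSK_H + half:
        return 0.0
    if hour < _DAWN_H + half:
        t = (hour - (_DAWN_H - half)) / _TRANSITION_H
        return 0.5 * (1.0 - math.cos(math.pi * t))
    if hour < _DUSK_H - half:
        return 1.0
    t = (hour - (_DUSK_H - half)) / _TRANSITION_H
    return 0.5 * (1.0 + math.cos(math.pi * t))


def generate_light_table(dataset: dict, spec: FixtureSpec) -> str:
    """Render the CSV text of the light-logger file a dataset declares.

    Rows run at the declared sampling interval across ``spec.days`` days,
    headers match the dataset's datetime spec and variable names exactly,
    and values follow the diurnal profile with seeded log-normal noise.
    """
    rng = random.Random((spec.seed, dataset.get("dataset_internal_id")).__repr__())
    interval = float(dataset.get("dataset_sampling_interval", spec.sampling_interval_s))
    n_rows = int(round(spec.days * 86400.0 / interval))
    dt_spec = dataset["dataset_datetime"]
    split = "dataset_datetime_time" in dt_spec
    from .validation import format_to_strftime

    if split:
        date_fmt = format_to_strftime(dt_spec["dataset_datetime_dateformat"], "date")
        time_fmt = format_to_strftime(dt_spec["dataset_datetime_timeformat"], "time")
        header = [dt_spec["dataset_datetime_date"], dt_spec["dataset_datetime_time"]]
    else:
        fmt = dt_spec["dataset_datetime_dateformat"]
        date_fmt = format_to_strftime(fmt, "datetime")
        header = [dt_spec["dataset_datetime_date"]]
    variables = dataset["dataset_file"][0]["dataset_file_variables"]
    var_names = [v["dataset_file_variables_name"] for v in variables]
    header += var_names
    illum_name = dataset.get("dataset_illuminance")
    meledi_name = dataset.get("dataset_meledi")
    start = dt.datetime.combine(_START_DATE, dt.time(0, 0))
    lines = [",".join(header)]
    for i in range(n_rows):
        stamp = start + dt.timedelta(seconds=i * interval)
        hour = stamp.hour + stamp.minute / 60.0 + stamp.second / 3600.0
        weight = _diurnal_weight(hour)
        lux = (NIGHT_LX + (DAY_LX - NIGHT_LX) * weight) * math.exp(
            rng.gauss(0.0, _NOISE_SIGMA))
        values = {illum_name: f"{lux:.3f}"}
        if meledi_name:
            values[meledi_name] = f"{lux * MELEDI_RATIO:.3f}"
        if split:
            row = [stamp.strftime(date_fmt), stamp.strftime(time_fmt)]
        else:
            row = [stamp.strftime(date_fmt)]
        row += [values.get(name, "0") for name in var_names]
        lines.append(",".join(row))
    return "\n".join(lines) + "\n"


def write_fixture_tree(spec: FixtureSpec, root: Union[str, os.PathLike],
                       registry: Optional[SchemaRegistry] = None) -> MetadataBundle:
    """Write a complete example: bundle directory plus light CSVs.

    Data files are written into ``<root>/data/``, matching the file names
    each dataset record declares.  When ``spec.violation`` is set, the
    named single-edit mutation is applied before writing.
    """
    from .bundle import write_bundle

    registry = registry or build_registry()
    clean = replace(spec, violation=None)
    bundle = generate_bundle(clean, registry)
    if spec.violation is not None:
        bundle = inject_violation(bundle, spec.violation, seed=spec.seed)
    write_bundle(bundle, root, registry)
    data_dir = os.path.join(os.fspath(root), "data")
    os.makedirs(data_dir, exist_ok=True)
    for ds in bundle.datasets:
        text = generate_light_table(ds, clean)
        name = ds["dataset_file"][0]["dataset_file_names"][0]
        with open(os.path.join(data_dir, name), "w", encoding="utf-8") as fh:
            fh.write(text)
    return bundle
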