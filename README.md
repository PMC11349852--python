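# luxmeta

Metadata tooling for **wearable light-logging and dosimetry datasets**.

Studies of real-world ("ambulatory") personal light exposure hand
participants wearable dosimeters — worn at the wrist, on the chest, or on
spectacle frames — that record photopic illuminance and, increasingly,
melanopic equivalent daylight illuminance (melanopic EDI, the quantity
that drives the non-visual, circadian effects of light) over days to
weeks. Combining such datasets across cohorts, seasons and latitudes
requires that every dataset carry standardized, machine-checkable
metadata: who ran the study, who wore the device, what the device and its
sensors are, and exactly how the exported data files are laid out.

`luxmeta` implements a metadata descriptor for this domain as enforceable
software, for data curators, chronobiologists and platform maintainers:

- **Schema registry** — a versioned, machine-readable vocabulary of all 94
  metadata fields across six component kinds: *study*, *contributor*,
  *participant*, *dataset*, *device* and *device/sensor datasheet*
  (each a JSON document; `luxmeta.build_registry("1.0")`).
- **Validator** — presence, types, formats (ORCID with its ISO 7064
  mod-11-2 check digit, email, IANA/Olson timezones, ISO dates,
  latitude/longitude), conditional requirements (a preprocessing
  description whenever preprocessing is flagged; split date/time columns
  declared together), the CRediT "Data curation" role requirement, and
  cross-file referential integrity (unique internal ids, resolvable
  dataset→study/participant/device cross-references, study↔dataset
  closure). Every finding carries a stable rule id and a severity.
- **JSON I/O and Schema emission** — canonical, deterministic component
  JSON plus one JSON Schema (draft 2020-12) per component kind and
  version, so web forms and other tools can consume the schema without
  this package.
- **Data binding** — uses a validated dataset record to parse the
  light-logger CSV/TSV files it describes: declared datetime formats,
  timezone localization, unit-annotated variables, role-tagged
  illuminance/melanopic-EDI columns, affine calibration expressions, and
  an audit of the observed against the declared sampling interval.
- **Fixtures** — a seeded generator of schema-conformant synthetic
  bundles, matching diurnal light tables, and single-edit rule-violation
  mutants that serve as the validator's ground-truth oracle.

## Worked example

Generate a synthetic two-participant bundle, validate it, and bind one
dataset's light table:

```console
$ luxmeta fixtures -o demo --seed 42 --participants 2 --devices 1
INFO wrote bundle with 2 participants, 2 datasets, 1 devices to demo

$ luxmeta validate demo
validation: PASS (0 errors, 0 warnings)
descriptor version: 1.0; tz snapshot: 2026.3

$ luxmeta bind demo ds001 -o demo/tidy.csv
{
  "rows": 1440,
  "audit": {
    "declared_s": 60.0,
    "median_observed_s": 60.0,
    "gap_indices": [],
    "pass": true
  },
  "roles": {
    "illuminance": "illuminance",
    "melEDI": "melanopic_edi"
  },
  "units": {
    "illuminance": "lx",
    "melanopic_edi": "lx"
  }
}
```

1440 rows is one day at the declared 60-second sampling interval; the
audit passes because the median observed interval matches the declared
one (within 5%) and no successive gap exceeds 1.5× the interval. The
sidecar `demo/tidy.csv.units.json` records units and column roles.

Validation failures name the record, the field path and the violated
rule:

```console
$ luxmeta validate demo-bad
validation: FAIL (1 errors, 0 warnings)
descriptor version: 1.0; tz snapshot: 2026.3
  ERROR   study[study0409] study_contributors/0/contributor_orcid: '1338-9083-8637-9401' is not a valid ORCID iD (pattern or mod-11-2 check digit) (bad-orcid)
```

Exit codes are the machine contract: 0 valid, 1 validation/binding
failure, 2 usage or I/O failure. `luxmeta schema all -o schemas/` writes
the six `<kind>.schema.json` documents; `luxmeta scaffold <kind> -o f.json`
writes a required-fields template.

The same operations are available as library functions
(`luxmeta.load_bundle`, `validate_record`, `emit_json_schema`,
`load_light_table`, …).

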