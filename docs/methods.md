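# Methods

## The descriptor model

A light-dosimetry study is described by six JSON component kinds arranged
around the study: the **study** document (design, sample, groups,
embedded **contributor** records, and the list of its dataset ids),
**participant** documents (one per wearer), **dataset** documents (one
per participant-level recording, cross-referencing study, participant and
device by internal id and describing the data files column by column),
**device** documents (instrument identity and calibration date) and
**device/sensor datasheet** documents (spectral sensitivity, linearity,
directional response, range, channels). The registry transcribes this
vocabulary as 94 field specifications (study 22, contributor 8,
participant 9, dataset 31, device 9, datasheet 15), each with a component
kind, nesting level, parent, requiredness (required / optional /
conditional), JSON value type and description. The registry is versioned
(currently `1.0`) and immutable once built; schemas and reports carry the
version so future revisions can coexist.

Records are represented as plain dicts with canonical lower_snake_case
keys, and the registry drives everything — validation walk, canonical key
order on write, JSON Schema emission, template scaffolding. This is the
same single-source-of-truth design used by table-schema validators; it
keeps read→write round trips exact and makes adding a field a one-line
change. Source documents with typographic key variants (mixed case,
stray spaces) are normalized on read and emitted canonically on write.

## Validation rules and severities

Every finding carries one of a closed set of rule ids (see
`luxmeta.ERROR_RULES` / `WARNING_RULES`). Severity policy: a missing
required field, a type mismatch or a broken conditional is an **error**;
unknown extension fields and advisory findings are **warnings**, because
the descriptor is explicitly designed to be extensible. The single
exception is the participant record: its field set exists to guarantee
anonymity, so an unknown participant field is an error
(`participant-extra-field`), and the emitted participant schema sets
`additionalProperties: false`.

Choices where the format specification is silent:

- **ORCID** — pattern *and* ISO 7064 mod-11-2 check digit. The checksum
  catches transcription errors and is standard practice; it is verified
  in tests against an independent closed-form oracle
  (`Σ dᵢ·2^(16−i) + c ≡ 1 (mod 11)`).
- **Email** — syntactic only (one `@`, non-empty local part, dotted
  domain, internationalized labels allowed); no DNS, for offline
  determinism.
- **Timezones** — membership in the bundled IANA/Olson snapshot;
  the snapshot version is recorded in every report header so a verdict is
  reproducible even as the tz database evolves.
- **Dates** — `device_calibration` must be an ISO 8601 calendar date.
- **Coordinates** — `dataset_location` is exactly two strings parseable
  as signed decimal degrees, latitude in [−90, 90], longitude in
  [−180, 180]. Hemisphere-letter forms ("48.1N") are rejected.
- **Datetime formats** — a deliberately small token vocabulary
  (`YYYY`, `YY`, `MM`, `DD`, `HH`, `MM`, `SS`, `SSS` for fractional
  seconds, plus literal separators). `MM` is month before an hour token
  and minute after it. A date format must contain year+month+day and no
  time tokens; a time format hour+minute and no date tokens; a combined
  datetime format both.
- **CRediT roles** — matched case-insensitively against the 14-role
  vocabulary; unknown roles warn. At least one study contributor must
  hold "Data curation" (error `missing-data-curation` otherwise).
- **Split date/time columns** are conditional on each other: declaring a
  separate time column requires its format and vice versa
  (`datetime-spec-incomplete`); neither is required when a combined
  datetime column is used, so both are encoded as conditional rather
  than required.
- **`study_funding_sources`** is optional, but if present must be
  non-empty (`empty-funding`).
- **Spectral sensitivity** — required non-empty, strictly ascending
  wavelengths, non-negative relative values; a peak differing from 1 by
  more than 1e-6 warns (curves are conventionally peak-normalized).

### Bundle-level rules

Internal ids are unique per kind (`duplicate-id`); every dataset
cross-reference must resolve (`dangling-crossref`); `study_datasets` and
the dataset records must agree (missing record = error, unlisted record =
warning); participants/devices referenced by no dataset warn
(`orphan-record`) — a device may legitimately be registered before data
exist. Id matching is exact string comparison after Unicode NFC
normalization, case-sensitive. One bundle holds one study; a dataset may
not reference records outside its bundle. Two on-disk layouts are
accepted and load identically: a directory (`study.json` +
`participants/`, `datasets/`, `devices/`) and a single combined document
with those four top-level collections.

## JSON Schema emission

One draft 2020-12 schema per kind and version (`$id` carries the
version). Conditionals use `if`/`then` (preprocessing) and
`dependentRequired` (split date/time). Rules beyond JSON Schema — ORCID
checksum, timezone membership, date/coordinate parsing, CRediT coverage,
spectral ordering, and every cross-file rule — are carried as
non-asserting `x-validator-only` annotations. The split between
structural and validator-only rules is exported (`STRUCTURAL_RULES`,
`VALIDATOR_ONLY_RULES`) and is what makes dual validation (internal
walker vs. an independent `jsonschema` run) a meaningful cross-check
rather than a tautology. Datasheets may appear inline or as
`{"$ref-path": "file.json"}` on read; embedding is canonical on write.

## Data binding

Column matching is exact and case-sensitive: logger export headers are
machine-written, and silent case-folding would hide export drift.
Timestamps are parsed with the declared token formats and localized to
the file-level timezone (which wins over the dataset-level one, with a
warning, when they differ — no precedence is otherwise defined).
Ambiguous local times during a daylight-saving fold resolve to the
earlier offset with a warning; nonexistent local times are errors, as are
non-monotonic timestamp sequences. Calibration expressions are restricted
to the affine grammar `a*x + b` (either term omissible, `x` the sole
variable); anything richer must be pre-applied and documented in the
preprocessing fields, and an unintelligible expression is an error, never
ignored. The sampling audit compares the median successive difference to
the declared interval (relative tolerance 5%) and flags gaps larger than
1.5× the declared interval; both thresholds are arguments. The delimiter
is auto-detected among comma/semicolon/tab (overridable); decimal commas
are not interpreted.

## Synthetic fixtures

The generator emulates a small ambulatory field study: 3 participants,
2 devices and one dataset per participant-device assignment by default,
ages 18–75, European study sites with their true IANA zones and
coordinates, a contributor pair of which exactly one holds "Data
curation", generated ORCIDs with correct check digits, and
melanopsin-like datasheet spectral curves (Gaussian, peak 1.0 at 490 nm,
400–700 nm in 20 nm steps). Light tables span 1 day at 60 s by default,
starting 2024-03-04 (away from DST transitions), with a diurnal profile:
night plateau 1 lx, day plateau 1000 lx, raised-cosine dawn/dusk
transitions at 07:00/19:00 (2 h width), multiplicative log-normal noise
(σ = 0.3), and melanopic EDI fixed at 0.9× illuminance so the role-tagged
columns are distinguishable everywhere. These constants are documented
conventions, not photometric claims: the fixtures exercise schema,
referential integrity and binding — they contain no weather, spectra,
behaviour or device noise physics, so passing tests demonstrate metadata
machinery, not photometric realism. Datasets alternate between split
date/time and combined datetime layouts so both parsing paths are always
exercised. All randomness flows from one seeded generator; identical
specs give byte-identical serialized output.

`inject_violation` produces single-edit mutants for the ten documented
rule ids. Mutations are minimal so error attribution is unambiguous:
re-validating a mutant must yield errors carrying exactly the injected
rule id, and the untouched bundle must validate clean. The duplicate-id
mutant *appends* a second record under an existing id rather than
renaming one, since renaming would also dangle the datasets that
reference the old id and blur attribution.

## Problem sizes and numerical notes

The test suite validates 500 seeded bundles end-to-end, round-trips 500
seeds × 6 kinds, compares 100 mixed fixtures per kind against the
emitted schemas, and checks 10,000 randomized ORCID candidates against
the independent oracle; the acceptance script uses 200 bundles and 50
fixtures per kind. These sizes make the whole suite run in well under a
minute while leaving the statistical content (seed coverage, mutant
coverage of every rule) intact. Floating-point care is limited: the
spectral peak check uses a 1e-6 tolerance, interval audits compare
against explicit relative tolerances, and calibration is exact affine
arithmetic.

## Known limitations

- No semantic plausibility checks (e.g., whether instruction text is
  adequate) and no photometric computation — melanopic EDI is never
  derived from spectral channels; the descriptor only names columns.
- Email validation is syntactic; timezone verdicts depend on the bundled
  tz snapshot (recorded in reports).
- The registry covers descriptor version 1.0 only; unknown fields
  pass through as warnings by design, they are not registered extensions.
- One study per bundle; merging studies is out of scope.
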