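# Methods

This note records the models and procedures `phenotab` implements, the
choices made where the design was genuinely open, and what the synthetic
fixtures do and do not establish about real archives.

## The column-header grammar

Study and Assay tables are modelled as an ordered header sequence plus
rectangular rows.  Headers belong to a closed vocabulary: the data nodes
(`Source Name`, `Sample Name`, `Extract Name`, `Assay Name`) that identify
material at consecutive workflow stages, the qualified property categories
(`Characteristics[...]`, `Factor Value[...]`, `Parameter Value[...]`,
`Comment[...]`), `Protocol REF`, `Unit`, the annotation columns
(`Term Source REF`, `Term Accession Number`) and the data-file references
(`Raw Data File`, `Derived Data File`).  Matching is case-sensitive and
exact after trimming outer whitespace; unknown headers are rejected rather
than guessed at, so dialect drift fails fast instead of silently degrading
downstream checks.  Qualifiers are mandatory exactly for the four qualified
categories; `format(parse(h))` is the identity on canonical spellings
(property-tested over random valid headers).

One normalization: configuration tables are conventionally written with the
shorthand `Protocol REF[Rooting]`, but a conforming file has a plain
`Protocol REF` *column* whose cells carry the protocol name.  The parser
accepts the shorthand and normalizes it to a `Protocol REF` header plus an
*expected cell value*; emitted files are always in the conforming form.

## Configurations and additive extension

A configuration is an ordered plan of `(header, required, expected-value,
unit-follows)` entries.  The three builtin Study plans share the seven core
Characteristics (Organism, Infraspecific name, Seed origin, Study start,
Study duration, Growth facility, Geographic location) between `Source Name`
and `Sample Name`; Field and Greenhouse add five protocol blocks in fixed
order — Rooting, Aerial conditions, Nutrition, Watering, Sampling — and
differ only inside Rooting (plot size + sowing density vs. container
descriptors).  The Phenotyping Assay plan is `Sample Name`,
`Characteristics[Plant body of interest]`, a `Protocol REF` expecting
"Data transformation" with its `Parameter Value[Trait Definition File]`,
`Assay Name`, an optional `Raw Data File` and a required
`Derived Data File`.

Extension is additive only: derived plans may insert Characteristics,
Factor Values, Comments, Parameter Values or whole protocol blocks at
anchored positions, and must contain the base plan as an
identical-spelling subsequence.  Renaming, removal and shadowing
(duplicating an inherited header) are errors — this guarantees that any
consumer of the base schema can still read every derived archive.
Treatments are deliberately absent from the builtin plans: they are
experiment-specific and enter via extension, as either a Factor Value or a
protocol block with parameters; the package exposes both and does not
choose between them, since usage in the field genuinely varies.  Protocol
blocks may also be added under Basic, which the schema does not forbid.

Configurations serialize to a one-line-per-column plain-text format rather
than an XML dialect; the format is trivially diffable and versionable,
which suits the "data manager prepares a local configuration" workflow.

## Validation

Three layers, all findings returned rather than raised:

* **Table level.**  The plan's materialized headers (with `Unit` columns
  expanded) must appear as an in-order subsequence of the table's headers;
  a planned `Protocol REF` only matches a column whose cells carry its
  expected protocol name, so a deleted block is reported as a group of
  `MISSING_COLUMN` errors attributed to the right protocol.  Out-of-order
  columns are warnings (`COLUMN_ORDER`), extra well-formed columns are
  info (`EXTRA_COLUMN`) — extension is legal.  Duplicate qualified headers
  are errors; `Unit`/annotation columns must follow a column they can
  qualify; Study tables must begin with `Source Name` and end with
  `Sample Name`.
* **Link level.**  Assay `Sample Name`s must resolve in the study
  (`BROKEN_SAMPLE_LINK`), matrix columns in the Trait Definition File
  (`UNKNOWN_VARIABLE_ID`), matrix row ids in the linking data-node column
  (`ORPHAN_DATA_ROW`, a warning — aggregated or filtered exports
  legitimately drop rows), and referenced files must exist or be flagged
  external (`MISSING_FILE`).  When a referenced TDF is itself missing,
  column-id checks are suppressed so one defect yields one diagnosis, not
  a cascade.
* **Compliance level.**  See below.

Empty cells in *required columns* are warnings, not errors.  This is a
deliberate calibration: published archives routinely declare columns whose
values were not available, and remain useful; what downstream consumers
depend on is the column structure.  Absent required columns are errors.
The `--strict` CLI flag promotes the empty-cell warnings for repositories
that want hard gating.  Issue ordering is deterministic (file, row, column,
code); rows are 1-based counting the header row as row 1; columns are
addressed by canonical header text.

## Compliance scoring

Each essential checklist attribute is mapped to one ISA-Tab location:
an investigation field (identifier, title, description), a study or assay
Characteristics qualifier, a study protocol block (present iff a
`Protocol REF` column carries the protocol name and at least one of its
parameter columns has a non-empty value), the Trait/Method/Scale columns
of the Trait Definition File, or the `Derived Data File` reference.
An attribute is *present* iff its location holds at least one non-empty
value — the checklist speaks of attributes being provided, not of
cell-level completeness, so presence is existential and the score is
monotone under cell blanking (property-tested).  The score is the
unweighted fraction of applicable attributes present, reported per section
and overall; no weighting scheme is defined by the checklist, so none is
invented.

Applicability follows the configuration: the four environment protocols
and the experimental-unit attribute apply only under Field and Greenhouse
(Basic: 15 unconditional attributes; Field/Greenhouse: 20).  Environmental
variables' Trait/Method/Scale are a genuinely ambiguous case — starred in
the checklist but not part of any builtin plan — and are treated as
applicable only when the dataset's Trait Definition Files actually declare
an environmental variable.  Variable class (phenotypic vs environmental)
is itself carried by an optional `Comment[Variable class]` TDF column,
Comment columns being the sanctioned extension point; absent, the class is
"unspecified" and the variable counts toward the phenotypic attributes.

## Data files and linking

The default Derived Data File dialect is a plain tab-separated
`Assay Name x Variable ID` matrix; the first header cell names the linking
data node, and any other data node (`Sample Name`, `Source Name`,
`Extract Name`) is accepted under the extension rule, enabling per-organ
or aggregated matrices.  Empty cells and the literal `NA` are missing;
unparseable numerics remain categorical text.  A data file in any other
dialect is treated as opaque (info issue, presence checked only) —
non-default formats are required to be described in their Data
transformation protocol, which the package does not interpret.

Linking produces long-format records only for (row id, variable) pairs
that resolve; everything unresolved is reported, never silently dropped,
and the conservation identity `records = rows x variables - missing -
orphan cells` is enforced by exhaustive enumeration in tests.  Aggregation
concatenates long records across studies and datasets, attaching the
values of grouping Characteristics (e.g. `Study start`, `Geographic
location`) resolved per source row through the Sample Name chain; a study
missing the grouping characteristic warns and contributes the group
"unknown".  Environmental variables recorded once per study (period means)
are repeated per matrix row — a convention, not a rule, mirrored from
practice.  Per-time-point environmental series are generated as
time-suffixed variable ids; factor-based and separate-assay encodings are
accepted on read since all three are legitimate.

## Serialization

Tab-delimited UTF-8 without BOM, `\n` line endings on write, `\n`/`\r\n`
accepted on read.  Cells are quoted on write only when they contain a
quote character; tabs and newlines inside cells are rejected outright.
The Investigation file uses the standard section labels (ONTOLOGY SOURCE
REFERENCE through STUDY CONTACTS) with one value column per record.
Writing is deterministic — same dataset, same bytes — and all dataset
invariants are checked before the first file is written.  Trailing blank
rows/columns are stripped on read with an info entry.  File naming
(`i_*`/`s_*`/`a_*`) is enforced on write and warned about on read.

## Synthetic fixtures

The generators define the study conditions the test suite runs under;
their defaults are fixed, not tuning knobs:

* `field_multiyear`: 100 lines + 2 parents (102 biosources), 2
  year-studies, 8 phenotypic + 2 environmental variables, 1 replicate per
  line per year.
* `basic_gwas`: 107 phenotypic variables; 10 accessions x 2 replicates
  (source and replicate counts are not fixed by the emulated scenario and
  were chosen once as a typical desk scale).
* `greenhouse_hts`: 484 plants in a balanced 2x2 factorial (plant
  rotation x soil cover), one accession, 4 image-derived traits, raw image
  references flagged external.

All draws flow from one `random.Random` (Mersenne Twister) seeded per
dataset: quantitative traits are Normal(per-variable mean, sd) with means
drawn once per variable, qualitative traits uniform over a 5-level ordinal
set, environmental variables constant within a study, and 2% of matrix
cells missing — enough to exercise missing-value handling without
dominating the fixtures.  Identical (profile, parameters, seed) produce
byte-identical trees.  Greenhouse environment parameters are fixed
plausible constants (pH 6.0, 0.5 L pots, ...) marked `synthetic` in a
Comment column; they are placeholders, not biological claims.

What passing tests on these fixtures show: the schemas, the validator, the
linker and the serializer are mutually consistent, deterministic, and
complete with respect to the documented defect catalogue (each issue code
is triggered by a single-edit mutation of a clean fixture).  What they do
not show: robustness to the full variety of hand-edited real-world
archives — spreadsheet-mangled encodings, exotic investigation sections,
ontology annotations beyond the syntactic layer — nor any statistical
realism of the generated values (no genetic or genotype-by-environment
structure is simulated).

## Numerical and procedural choices

* Problem sizes in the test and acceptance runs are desk-scale (4-10
  sources, 2 years, 3-6 variables) except where a count is itself the
  point (102 biosources, 107 variables, 484 plants); the acceptance
  script's round-trip sweep uses 10 seeds x 3 profiles.
* The compliance score of a dataset with an empty applicable set is
  defined as 1.0 (nothing required, nothing missing); scaffolded templates
  score 0.0 because all their applicable attributes are empty.
* Duplicate qualified headers within one table are rejected; the format
  leaves this open, but permitting them would make cell addressing by
  header ambiguous.
* Ontology annotation handling is syntactic only: an accession requires a
  Term Source REF, and sources should be declared in the investigation;
  no term is resolved against a live service.
* Raw-data folder hierarchies (per-sensor/per-view image trees) are not
  walked; only files referenced in table cells are existence-checked.

## Known limitations

* Investigation parsing covers the standard section labels; custom
  sections are rejected rather than preserved.
* Only the default matrix dialect is parsed; opaque data files are
  presence-checked but their contents are invisible to link validation.
* High-throughput assay extensions (platform-specific imaging parameter
  blocks) are out of scope; the extension mechanism supports building
  them, but no builtin schema is shipped.
* No JSON/RDF export of the archive itself; the machine-readable output is
  the validation/compliance report (`report_schema.json`).
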