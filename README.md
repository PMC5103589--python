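# phenotab

Minimum-information compliance checking and ISA-Tab tooling for plant
phenotyping archives.

## The problem

Plant phenotyping experiments produce observations whose scientific value
depends on their metadata: which accession or line was grown, where and
when, under what rooting, aerial, nutrition and watering conditions, what
was measured and how.  Because phenotypic expression is shaped by
genotype-by-environment interaction, an observation matrix without this
context cannot be reused, combined across sites or years, or meaningfully
reanalysed.  Community practice addresses this with two instruments:

* a **minimum-information checklist** — eight sections of attributes
  (General metadata, Timing and location, Biosource, Environment,
  Treatments, Experimental design, Sample collection, Observed variables),
  a starred subset of which is *essential* for a minimally interpretable
  dataset; and
* the **ISA-Tab Phenotyping Configuration** — a concrete column schema for
  the tab-delimited Investigation–Study–Assay format, with three Study
  variants (**Basic**, **Field**, **Greenhouse**) and one **Phenotyping
  Assay** that links samples, via a "Data transformation" protocol's
  *Trait Definition File* parameter, to an `Assay Name x Variable`
  observation matrix.

`phenotab` turns both instruments into executable artifacts.  It reads and
writes ISA-Tab datasets with round-trip fidelity, scaffolds empty templates,
validates archives structurally (required columns, duplicate headers,
cross-file sample/variable/file links) and scores essential-attribute
coverage, links trait definitions to observation matrices and aggregates
observations across studies, and generates deterministic synthetic archives
for testing — a replicated-accession Basic archive, a 102-biosource
two-year Field archive, and a 484-plant factorial Greenhouse imaging
archive.

Observed variables follow the Trait/Method/Scale triplet convention: each
row of a Trait Definition File defines a variable by a local `Variable ID`,
the trait being measured, the measurement method, and the unit or scale,
each optionally annotated against an ontology (`Term Source REF` /
`Term Accession Number`).  The compliance score is the unweighted fraction
of applicable essential attributes with at least one non-empty value in
their mapped ISA-Tab location, reported per checklist section.

## Worked example

Generate the two-year field archive, summarize, validate, and aggregate the
observations by study year:

```sh
$ phenotab simulate --profile field_multiyear --seed 42 -o geh_field
field_multiyear dataset (seed 42) written to geh_field

$ phenotab summarize geh_field
geh_field:
  studies: 2
  sources_per_study: {'s_study1.txt': 102, 's_study2.txt': 102}
  samples: 204
  assays: 2
  variables: 10
  phenotypic_variables: 8
  environmental_variables: 2
  data_files: 2
  matrix_shapes: {'d_field2012.txt': [102, 10], 'd_field2013.txt': [102, 10]}

$ phenotab validate geh_field --config field
no issues
compliance (field): 23/23 essential attributes present, score 1.000
  [ok ] General metadata: 3/3
  [ok ] Timing and location: 3/3
  [ok ] Biosource: 3/3
  [ok ] Environment: 5/5
  [ok ] Experimental design: 1/1
  [ok ] Sample collection, processing, management: 1/1
  [ok ] Observed variables: 7/7

$ phenotab aggregate geh_field --by "Study start" -o observations.tsv
2010 observation records written to observations.tsv

$ head -3 observations.tsv
dataset	study	Study start	row_id	variable_id	variable_class	value
SYN-FIELD-1	s_study1.txt	2012-04-10	assay_RIL001_study1_1	PH	phenotypic	151.14
SYN-FIELD-1	s_study1.txt	2012-04-10	assay_RIL001_study1_1	DH	phenotypic	11.53
```

The archive holds 100 recombinant inbred lines plus two parental forms
(102 biosources) in each of two year-studies; eight phenotypic and two
environmental variables are defined in a shared Trait Definition File; the
2 010 long-format records (2 x 102 rows x 10 variables, minus the 2% of
cells generated missing) carry the `Study start` value of their source
study, which is how multi-year series are split downstream.  Exit status is
0 for a valid archive, 1 when validation errors are present (warnings alone
never fail), and 2 on usage or I/O errors.

The same functionality is available as a library:

```python
from phenotab import read_dataset, validate_dataset, summarize

ds = read_dataset("geh_field")
report, compliance = validate_dataset(ds, "field")
assert not report.errors and compliance.score == 1.0
```

## Layout

```
src/phenotab/
  model.py               # domain types + the column-header grammar
  isatab_io.py           # dataset reading/writing, round-trip fidelity
  phenotyping_config.py  # Basic/Field/Greenhouse + Phenotyping Assay schemas,
                         # additive extension, config diff/serialization
  validator.py           # structural + link validation, compliance scoring
  pheno_data.py          # Trait Definition Files, matrices, linking, aggregation
  synthetic_data.py      # deterministic fixture generators + defect injection
  cli.py                 # validate / scaffold / simulate / summarize / aggregate
docs/methods.md          # models, assumptions, design choices, limitations
```
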