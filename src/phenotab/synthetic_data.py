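"""Deterministic generators for minimum-information-compliant fixtures.

Three profiles emulate the archetypal phenotyping archive topologies:

* ``basic_gwas`` — a Basic-configuration archive exported from a GWAS
  platform: one study of replicated accessions, one phenotyping assay, one
  Trait Definition File and one Assay Name x Variable matrix (107 variables
  by default, the scale of a typical association-panel trait collection).
* ``field_multiyear`` — a Field-configuration multi-environment series: a
  biparental mapping population (100 recombinant inbred lines plus the two
  parents = 102 biosources) observed over two year-studies, with 8
  phenotypic and 2 environmental variables in a shared Trait Definition
  File and one data matrix per year.
* ``greenhouse_hts`` — a Greenhouse-configuration high-throughput imaging
  experiment: a balanced 2x2 factorial (plant rotation x soil cover) over
  484 plants, image file references flagged external, and image-derived
  traits in the matrix.

Every draw flows from one ``random.Random`` (Mersenne Twister) seeded per
dataset, so identical (profile, parameters, seed) produce byte-identical
directory trees.  Quantitative traits are Normal(per-variable mean, sd),
qualitative traits uniform over a small category set, environmental
variables constant within a study; 2% of matrix cells are set missing.
All constants (pH 6.0, soil types, ...) are arbitrary synthetic
placeholders, never biological claims.
"""

from __future__ import annotations

import copy
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .model import (
    AssayRecord,
    AssayTable,
    Dataset,
    FieldHeader,
    HeaderCategory,
    Investigation,
    OntologyAnnotation,
    OntologySource,
    ProtocolDecl,
    FactorDecl,
    StudyRecord,
    StudyTable,
    parse_header,
)
from .pheno_data import DataMatrix, TraitDefinition
from .phenotyping_config import (
    DATA_TRANSFORMATION_PROTOCOL,
    ORGAN_CHARACTERISTIC,
    TDF_PARAMETER,
    StudyConfig,
    builtin_config,
)
from .validator import (
    CODE_BROKEN_SAMPLE_LINK,
    CODE_DUPLICATE_HEADER,
    CODE_EMPTY_ESSENTIAL_CELL,
    CODE_MISSING_COLUMN,
    CODE_MISSING_FILE,
    CODE_ORPHAN_DATA_ROW,
    CODE_RAGGED_ROW,
    CODE_UNDECLARED_PROTOCOL,
    CODE_UNKNOWN_VARIABLE_ID,
)


class SyntheticError(ValueError):
    """Invalid profile parameters or unknown defect code."""


PROFILE_NAMES = ("basic_gwas", "field_multiyear", "greenhouse_hts")

#: Fraction of matrix cells set missing.
DEFAULT_MISSING_RATE = 0.02


@dataclass(frozen=True)
class Profile:
    """A named generator profile with its parameters and seed."""

    name: str
    parameters: dict = field(default_factory=dict)
    seed: int = 0


def basic_gwas(sources: int = 10, reps: int = 2, vars: int = 107, seed: int = 0) -> Profile:
    return Profile("basic_gwas", {"sources": sources, "reps": reps, "vars": vars}, seed)


def field_multiyear(lines: int = 100, parents: int = 2, years: int = 2,
                    pheno_vars: int = 8, env_vars: int = 2, seed: int = 0) -> Profile:
    return Profile(
        "field_multiyear",
        {"lines": lines, "parents": parents, "years": years,
         "pheno_vars": pheno_vars, "env_vars": env_vars},
        seed,
    )


def greenhouse_hts(plants: int = 484, pheno_vars: int = 4, seed: int = 0) -> Profile:
    return Profile("greenhouse_hts", {"plants": plants, "pheno_vars": pheno_vars}, seed)


# ---------------------------------------------------------------------------
# Variable pools
# ---------------------------------------------------------------------------

# (variable id, trait, method, scale, kind); kind "q" quantitative, "c" categorical
_PHENO_POOL = (
    ("PH", "Plant height", "ruler measurement", "cm", "q"),
    ("DH", "Days to heading", "visual scoring", "days", "q"),
    ("TGW", "Thousand grain weight", "weighing", "g", "q"),
    ("GY", "Grain yield", "plot harvest and weighing", "t/ha", "q"),
    ("TN", "Tiller number", "manual count", "count", "q"),
    ("LA", "Leaf area", "image analysis", "cm2", "q"),
    ("CHL", "Chlorophyll content", "SPAD meter", "SPAD units", "q"),
    ("LOD", "Lodging susceptibility", "visual scoring", "1-9 scale", "c"),
)

_ENV_POOL = (
    ("VPD", "Water vapor pressure deficit", "weather station record", "kPa"),
    ("PREC", "Total precipitation", "weather station record", "mm"),
    ("TMEAN", "Mean air temperature", "weather station record", "degC"),
)

_IMAGING_POOL = (
    ("PLA", "Projected leaf area", "top-view image segmentation", "px"),
    ("HEIGHT", "Plant height", "side-view image analysis", "px"),
    ("COMP", "Plant compactness", "image analysis", "ratio"),
    ("HUE", "Average hue", "image analysis", "degrees"),
)

_CATEGORY_SET = ("1", "3", "5", "7", "9")


@dataclass(frozen=True)
class _VarSpec:
    variable_id: str
    trait: str
    method: str
    scale: str
    vclass: str  # phenotypic / environmental
    kind: str  # q / c
    mean: float = 0.0
    sd: float = 1.0


def _pheno_specs(n: int, rng: random.Random) -> list[_VarSpec]:
    specs = []
    for i in range(n):
        if i < len(_PHENO_POOL):
            vid, trait, method, scale, kind = _PHENO_POOL[i]
        else:
            vid, trait, method, scale, kind = (
                f"V{i + 1:03d}", f"Synthetic trait {i + 1}",
                "synthetic measurement", "arbitrary unit", "q",
            )
        mean = round(rng.uniform(5.0, 200.0), 2)
        specs.append(_VarSpec(vid, trait, method, scale, "phenotypic", kind,
                              mean=mean, sd=round(0.1 * mean + 0.5, 2)))
    return specs


def _env_specs(n: int, rng: random.Random) -> list[_VarSpec]:
    specs = []
    for i in range(n):
        if i < len(_ENV_POOL):
            vid, trait, method, scale = _ENV_POOL[i]
        else:
            vid, trait, method, scale = (
                f"E{i + 1:03d}", f"Synthetic environmental variable {i + 1}",
                "synthetic record", "arbitrary unit",
            )
        mean = round(rng.uniform(1.0, 50.0), 2)
        specs.append(_VarSpec(vid, trait, method, scale, "environmental", "q",
                              mean=mean, sd=round(0.2 * mean + 0.1, 2)))
    return specs


def _imaging_specs(n: int, rng: random.Random) -> list[_VarSpec]:
    specs = []
    for i in range(n):
        if i < len(_IMAGING_POOL):
            vid, trait, method, scale = _IMAGING_POOL[i]
        else:
            vid, trait, method, scale = (
                f"IMG{i + 1:03d}", f"Synthetic image-derived trait {i + 1}",
                "image analysis", "arbitrary unit",
            )
        mean = round(rng.uniform(50.0, 5000.0), 2)
        specs.append(_VarSpec(vid, trait, method, scale, "phenotypic", "q",
                              mean=mean, sd=round(0.15 * mean + 1.0, 2)))
    return specs


def _tdf_rows(specs: Sequence[_VarSpec]) -> list[TraitDefinition]:
    return [
        TraitDefinition(
            variable_id=s.variable_id,
            trait=OntologyAnnotation(s.trait),
            method=OntologyAnnotation(s.method),
            scale=OntologyAnnotation(s.scale),
            variable_class=s.vclass,
        )
        for s in specs
    ]


def _draw_cell(spec: _VarSpec, rng: random.Random, missing_rate: float,
               constant: Optional[str] = None) -> str:
    if rng.random() < missing_rate:
        return ""
    if constant is not None:
        return constant
    if spec.kind == "c":
        return rng.choice(_CATEGORY_SET)
    return f"{rng.gauss(spec.mean, spec.sd):.2f}"


# ---------------------------------------------------------------------------
# Table builders
# ---------------------------------------------------------------------------


def _study_headers(config: StudyConfig, extra: Sequence[str] = ()) -> list[FieldHeader]:
    headers = [h for h, _ in config.materialized_headers()]
    # extra columns (Factor Values, Comments) go before the Sample Name node
    out = headers[:-1] + [parse_header(t) for t in extra] + [headers[-1]]
    return out


def _assay_headers() -> list[FieldHeader]:
    return [
        FieldHeader(HeaderCategory.SAMPLE_NAME),
        FieldHeader(HeaderCategory.CHARACTERISTICS, ORGAN_CHARACTERISTIC),
        FieldHeader(HeaderCategory.PROTOCOL_REF),
        FieldHeader(HeaderCategory.PARAMETER_VALUE, TDF_PARAMETER),
        FieldHeader(HeaderCategory.ASSAY_NAME),
        FieldHeader(HeaderCategory.RAW_DATA_FILE),
        FieldHeader(HeaderCategory.DERIVED_DATA_FILE),
    ]


def _assay_row(sample: str, organ: str, tdf_file: str, assay_name: str,
               raw_file: str, data_file: str) -> list[str]:
    return [sample, organ, DATA_TRANSFORMATION_PROTOCOL, tdf_file,
            assay_name, raw_file, data_file]


def _config_protocols(config: StudyConfig) -> list[ProtocolDecl]:
    decls = [
        ProtocolDecl(name, protocol_type="environment description", parameters=params)
        for name, params in config.declared_protocols()
    ]
    decls.append(ProtocolDecl(DATA_TRANSFORMATION_PROTOCOL,
                              protocol_type="data transformation",
                              parameters=[TDF_PARAMETER]))
    return decls


def _matrix(name: str, link_node: str, row_ids: Sequence[str],
            specs: Sequence[_VarSpec], rng: random.Random, missing_rate: float,
            constants: Optional[dict[str, str]] = None) -> DataMatrix:
    values = []
    for _ in row_ids:
        row = []
        for s in specs:
            const = constants.get(s.variable_id) if constants else None
            row.append(_draw_cell(s, rng, missing_rate, const))
        values.append(row)
    return DataMatrix(source_file=name, link_node=link_node,
                      row_ids=list(row_ids), variable_ids=[s.variable_id for s in specs],
                      values=values)


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------


def _generate_basic_gwas(p: Profile, rng: random.Random, missing_rate: float) -> Dataset:
    n_src, reps, n_vars = p.parameters["sources"], p.parameters["reps"], p.parameters["vars"]
    if n_src <= 0 or reps <= 0 or n_vars <= 0:
        raise SyntheticError("basic_gwas requires positive sources, reps and vars")
    specs = _pheno_specs(n_vars, rng)
    sources = [f"ACC{i + 1:03d}" for i in range(n_src)]
    samples = [f"{src}_study1_{r + 1}" for src in sources for r in range(reps)]

    config = builtin_config("basic")
    study = StudyTable("s_study1.txt", headers=_study_headers(config))
    for src, sample in ((s.rsplit("_", 2)[0], s) for s in samples):
        idx = sources.index(src) + 1
        study.rows.append([
            src, "Arabidopsis thaliana", f"accession {idx:03d}", "stock centre",
            "2010-03-01", "60 days", "growth chamber", "Vienna, Austria", sample,
        ])

    assay = AssayTable("a_study1.txt", headers=_assay_headers())
    assay_names = [f"assay_{s}" for s in samples]
    for sample, aname in zip(samples, assay_names):
        assay.rows.append(_assay_row(sample, "whole plant", "tdf.txt", aname,
                                     "", "d_data.txt"))

    matrix = _matrix("d_data.txt", "Assay Name", assay_names, specs, rng, missing_rate)

    inv = Investigation(
        identifier="SYN-BASIC-1",
        title="Synthetic replicated-accession phenotyping archive",
        description="Generated Basic-configuration fixture emulating a "
                    "GWAS-platform export of replicated accessions.",
        submission_date="2016-01-01",
        public_release_date="2016-06-01",
        ontology_sources=[OntologySource("PTO", "", "", "Plant Trait Ontology")],
        studies=[StudyRecord(
            file_name="s_study1.txt", identifier="study1",
            title="Replicated accession trial", description="Synthetic data.",
            assays=[AssayRecord("a_study1.txt")],
            protocols=[ProtocolDecl(DATA_TRANSFORMATION_PROTOCOL,
                                    protocol_type="data transformation",
                                    parameters=[TDF_PARAMETER])],
        )],
    )
    return Dataset(
        investigation=inv, studies=[study], assays=[assay],
        trait_definitions={"tdf.txt": _tdf_rows(specs)},
        data_files={"d_data.txt": matrix},
    )


_SOILS = ("clay soil", "sandy loam", "peat-sand mix", "silt loam")
_IRRIGATION = ("irrigation from top", "drip irrigation", "irrigation from bottom")


def _generate_field_multiyear(p: Profile, rng: random.Random, missing_rate: float) -> Dataset:
    lines, parents = p.parameters["lines"], p.parameters["parents"]
    years, n_pheno, n_env = (p.parameters["years"], p.parameters["pheno_vars"],
                             p.parameters["env_vars"])
    if lines <= 0 or years <= 0 or n_pheno <= 0 or parents < 0 or n_env < 0:
        raise SyntheticError("field_multiyear requires positive lines, years, pheno_vars")
    pheno = _pheno_specs(n_pheno, rng)
    env = _env_specs(n_env, rng)
    specs = pheno + env
    sources = [f"RIL{i + 1:03d}" for i in range(lines)] + [
        f"Parent{chr(ord('A') + i)}" for i in range(parents)
    ]

    config = builtin_config("field")
    tdf_file = "tdf_field.txt"
    inv = Investigation(
        identifier="SYN-FIELD-1",
        title="Synthetic multi-year field phenotyping archive",
        description="Generated Field-configuration fixture emulating a "
                    "biparental mapping population observed across years.",
        submission_date="2016-01-01",
        public_release_date="2016-06-01",
        ontology_sources=[OntologySource("PTO", "", "", "Plant Trait Ontology"),
                          OntologySource("XEO", "", "", "XEML Environment Ontology")],
    )
    ds = Dataset(investigation=inv,
                 trait_definitions={tdf_file: _tdf_rows(specs)})

    for y in range(years):
        year = 2012 + y
        sfile, afile, dfile = (f"s_study{y + 1}.txt", f"a_study{y + 1}_phenotyping.txt",
                               f"d_field{year}.txt")
        soil = rng.choice(_SOILS)
        plot = f"{rng.uniform(4.0, 12.0):.1f}"
        density = f"{rng.randint(250, 400)}"
        ph = f"{rng.uniform(5.5, 7.5):.1f}"
        humidity = f"{rng.uniform(55, 80):.0f}%"
        flux = f"{rng.uniform(20, 45):.1f}"
        light_h = f"{rng.uniform(12, 16):.1f}"
        t_day = f"{rng.uniform(16, 28):.1f}"
        t_night = f"{rng.uniform(6, 16):.1f}"
        n_soil = f"{rng.uniform(20, 80):.1f} kg/ha"
        fert = rng.choice(("NPK 15-15-15", "urea", "ammonium nitrate"))
        fert_amount = f"{rng.uniform(50, 150):.0f} kg/ha"
        irrigation = rng.choice(_IRRIGATION)
        water_vol = f"{rng.uniform(5, 20):.1f} L/m2"
        water_freq = rng.choice(("weekly", "twice weekly", "rain-fed"))

        study = StudyTable(sfile, headers=_study_headers(config))
        samples = [f"{src}_study{y + 1}_1" for src in sources]
        for src, sample in zip(sources, samples):
            infra = src if src.startswith("Parent") else f"GeH-{src[3:]}"
            study.rows.append([
                src, "Hordeum vulgare", infra, "institute collection",
                f"{year}-04-10", "120 days", "experimental field",
                "Poznan, Poland",
                # Rooting
                "Rooting", soil, plot, "m2", density, ph,
                # Aerial conditions
                "Aerial conditions", humidity, flux, light_h, t_day, t_night,
                # Nutrition
                "Nutrition", n_soil, fert, fert_amount,
                # Watering
                "Watering", irrigation, water_vol, water_freq,
                # Sampling
                "Sampling", "plot",
                sample,
            ])
        assay = AssayTable(afile, headers=_assay_headers())
        assay_names = [f"assay_{s}" for s in samples]
        for sample, aname in zip(samples, assay_names):
            assay.rows.append(_assay_row(sample, "whole plant", tdf_file, aname, "", dfile))
        env_constants = {s.variable_id: f"{rng.gauss(s.mean, s.sd):.2f}" for s in env}
        matrix = _matrix(dfile, "Assay Name", assay_names, specs, rng, missing_rate,
                         constants=env_constants)
        ds.studies.append(study)
        ds.assays.append(assay)
        ds.data_files[dfile] = matrix
        inv.studies.append(StudyRecord(
            file_name=sfile, identifier=f"study{y + 1}",
            title=f"Field trial {year}", description="Synthetic data.",
            assays=[AssayRecord(afile)],
            protocols=_config_protocols(config),
        ))
    return ds


_MOVEMENT_FACTOR = "Plant movement"
_COVER_FACTOR = "Soil cover"
_MOVEMENT_LEVELS = ("rotating", "stationary")
_COVER_LEVELS = ("covered", "uncovered")


def _generate_greenhouse_hts(p: Profile, rng: random.Random, missing_rate: float) -> Dataset:
    plants, n_vars = p.parameters["plants"], p.parameters["pheno_vars"]
    if plants <= 0 or n_vars <= 0:
        raise SyntheticError("greenhouse_hts requires positive plants and pheno_vars")
    specs = _imaging_specs(n_vars, rng)
    config = builtin_config("greenhouse")

    extra = [f"Factor Value[{_MOVEMENT_FACTOR}]", f"Factor Value[{_COVER_FACTOR}]",
             "Comment[Data provenance]"]
    study = StudyTable("s_study1.txt", headers=_study_headers(config, extra))
    samples = [f"plant_{i + 1:04d}" for i in range(plants)]
    for i, sample in enumerate(samples):
        movement = _MOVEMENT_LEVELS[i % 2]
        cover = _COVER_LEVELS[(i // 2) % 2]
        study.rows.append([
            "ARA001", "Arabidopsis thaliana", "Col-0", "stock centre",
            "2014-05-05", "40 days", "greenhouse", "Gatersleben, Germany",
            # Rooting (fixed plausible constants, flagged synthetic)
            "Rooting", "peat-sand substrate", "pot", "0.5 L", "10x10x11", "cm",
            "1", "6.0",
            # Aerial conditions
            "Aerial conditions", "60%", "15.0", "16.0", "21.0", "18.0",
            # Nutrition
            "Nutrition", "30.0 mg/L", "liquid fertiliser", "50 mL/week",
            # Watering
            "Watering", "irrigation from bottom", "0.1 L", "daily",
            # Sampling
            "Sampling", "single plant",
            movement, cover, "synthetic",
            sample,
        ])

    assay = AssayTable("a_study1_imaging.txt", headers=_assay_headers())
    assay_names = [f"assay_{s}" for s in samples]
    raw_files = [f"1135FA_images/vis/top/{s}.png" for s in samples]
    for sample, aname, raw in zip(samples, assay_names, raw_files):
        assay.rows.append(_assay_row(sample, "whole plant", "tdf_greenhouse.txt",
                                     aname, raw, "d_greenhouse.txt"))
    matrix = _matrix("d_greenhouse.txt", "Assay Name", assay_names, specs, rng, missing_rate)

    inv = Investigation(
        identifier="SYN-GH-1",
        title="Synthetic high-throughput greenhouse imaging archive",
        description="Generated Greenhouse-configuration fixture with a "
                    "balanced rotation x soil-cover factorial.",
        submission_date="2016-01-01",
        public_release_date="2016-06-01",
        ontology_sources=[OntologySource("PTO", "", "", "Plant Trait Ontology")],
        studies=[StudyRecord(
            file_name="s_study1.txt", identifier="study1",
            title="Imaging validation experiment", description="Synthetic data.",
            factors=[FactorDecl(_MOVEMENT_FACTOR, "treatment"),
                     FactorDecl(_COVER_FACTOR, "treatment")],
            assays=[AssayRecord("a_study1_imaging.txt", technology_type="imaging")],
            protocols=_config_protocols(config),
        )],
    )
    return Dataset(
        investigation=inv, studies=[study], assays=[assay],
        trait_definitions={"tdf_greenhouse.txt": _tdf_rows(specs)},
        data_files={"d_greenhouse.txt": matrix},
        external_files=set(raw_files),
    )


_GENERATORS = {
    "basic_gwas": _generate_basic_gwas,
    "field_multiyear": _generate_field_multiyear,
    "greenhouse_hts": _generate_greenhouse_hts,
}


def generate(profile: Profile, out_dir: Optional[Path] = None,
             missing_rate: float = DEFAULT_MISSING_RATE) -> Dataset:
    """Generate a complete dataset for a profile; write it when ``out_dir``
    is given.  The result validates with zero errors under the profile's
    configuration (basic / field / greenhouse respectively)."""
    if profile.name not in _GENERATORS:
        raise SyntheticError(f"unknown profile {profile.name!r}")
    rng = random.Random(profile.seed)
    ds = _GENERATORS[profile.name](profile, rng, missing_rate)
    if out_dir is not None:
        from .isatab_io import write_dataset

        write_dataset(ds, Path(out_dir))
        ds.root = Path(out_dir)
    return ds


def config_kind_for(profile_name: str) -> str:
    """The builtin configuration a profile's datasets are validated under."""
    return {"basic_gwas": "basic", "field_multiyear": "field",
            "greenhouse_hts": "greenhouse"}[profile_name]


# ---------------------------------------------------------------------------
# Defect injection (mutation-testing support)
# ---------------------------------------------------------------------------

DEFECT_CODES = (
    CODE_MISSING_COLUMN, CODE_EMPTY_ESSENTIAL_CELL, CODE_UNDECLARED_PROTOCOL,
    CODE_BROKEN_SAMPLE_LINK, CODE_UNKNOWN_VARIABLE_ID, CODE_ORPHAN_DATA_ROW,
    CODE_DUPLICATE_HEADER, CODE_RAGGED_ROW, CODE_MISSING_FILE,
)


def inject_defect(dataset: Dataset, code: str) -> Dataset:
    """Return a deep copy of the dataset with one minimal edit guaranteed to
    trigger the given issue code."""
    if code not in DEFECT_CODES:
        raise SyntheticError(f"unknown defect code {code!r}")
    ds = copy.deepcopy(dataset)
    study = ds.studies[0]
    assay = ds.assays[0]
    if code == CODE_MISSING_COLUMN:
        # drop a required Characteristics column (header + cells)
        idx = study.find_columns(HeaderCategory.CHARACTERISTICS, "Seed origin")[0]
        del study.headers[idx]
        for row in study.rows:
            del row[idx]
    elif code == CODE_EMPTY_ESSENTIAL_CELL:
        idx = study.find_columns(HeaderCategory.CHARACTERISTICS, "Organism")[0]
        study.rows[0][idx] = ""
    elif code == CODE_UNDECLARED_PROTOCOL:
        rec = ds.investigation.studies[0]
        rec.protocols = [p for p in rec.protocols
                         if p.name != DATA_TRANSFORMATION_PROTOCOL]
    elif code == CODE_BROKEN_SAMPLE_LINK:
        idx = assay.find_columns(HeaderCategory.SAMPLE_NAME)[0]
        assay.rows[0][idx] = "P999_unused"
    elif code == CODE_UNKNOWN_VARIABLE_ID:
        name = sorted(ds.data_files)[0]
        ds.data_files[name].variable_ids[0] = "XYZ_undefined"
    elif code == CODE_ORPHAN_DATA_ROW:
        name = sorted(ds.data_files)[0]
        ds.data_files[name].row_ids[0] = "orphan_row_id"
    elif code == CODE_DUPLICATE_HEADER:
        idx = study.find_columns(HeaderCategory.CHARACTERISTICS, "Organism")[0]
        insert_at = len(study.headers) - 1  # keep Sample Name last
        study.headers.insert(insert_at, study.headers[idx])
        for row in study.rows:
            row.insert(insert_at, row[idx])
    elif code == CODE_RAGGED_ROW:
        study.rows[0] = study.rows[0] + ["stray"]
    elif code == CODE_MISSING_FILE:
        name = sorted(ds.trait_definitions)[0]
        del ds.trait_definitions[name]
    return ds
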