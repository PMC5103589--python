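"""Generator determinism, soundness and profile structure."""

import pytest

from phenotab.isatab_io import read_dataset
from phenotab.model import HeaderCategory
from phenotab.synthetic_data import (
    SyntheticError,
    basic_gwas,
    config_kind_for,
    field_multiyear,
    generate,
    greenhouse_hts,
)
from phenotab.validator import validate_dataset


def test_generation_is_deterministic(tmp_path):
    p = field_multiyear(lines=3, parents=2, years=2, pheno_vars=3, env_vars=1, seed=99)
    generate(p, tmp_path / "a")
    generate(p, tmp_path / "b")
    fa = sorted((tmp_path / "a").iterdir())
    fb = sorted((tmp_path / "b").iterdir())
    assert [f.name for f in fa] == [f.name for f in fb]
    assert all(x.read_bytes() == y.read_bytes() for x, y in zip(fa, fb))


def test_different_seeds_differ():
    a = generate(basic_gwas(sources=3, reps=1, vars=3, seed=1))
    b = generate(basic_gwas(sources=3, reps=1, vars=3, seed=2))
    assert a.data_files["d_data.txt"].values != b.data_files["d_data.txt"].values


@pytest.mark.parametrize("seed", range(5))
@pytest.mark.parametrize("factory", [
    lambda s: basic_gwas(sources=3, reps=2, vars=4, seed=s),
    lambda s: field_multiyear(lines=3, parents=2, years=2,
                              pheno_vars=3, env_vars=1, seed=s),
    lambda s: greenhouse_hts(plants=8, pheno_vars=2, seed=s),
])
def test_generator_soundness_across_seeds(factory, seed):
    """Any seed yields a dataset with zero validation errors."""
    profile = factory(seed)
    ds = generate(profile)
    report, _ = validate_dataset(ds, config_kind_for(profile.name))
    assert report.errors == []
    assert report.warnings == []


def test_field_multiyear_default_scale_structure():
    """Default parameters: 2 year-studies, 102 distinct sources each,
    8 phenotypic + 2 environmental variables."""
    ds = generate(field_multiyear(seed=42))
    assert len(ds.studies) == 2
    for st in ds.studies:
        src = st.find_columns(HeaderCategory.SOURCE_NAME)[0]
        assert len(set(st.column_values(src))) == 102
    defs = ds.trait_definitions["tdf_field.txt"]
    assert len(defs) == 10
    assert sum(d.variable_class == "phenotypic" for d in defs) == 8
    assert sum(d.variable_class == "environmental" for d in defs) == 2


def test_environmental_variables_constant_within_study():
    ds = generate(field_multiyear(lines=4, parents=0, years=2,
                                  pheno_vars=2, env_vars=2, seed=8),
                  missing_rate=0.0)
    for name, matrix in ds.data_files.items():
        for vid in ("VPD", "PREC"):
            col = matrix.variable_ids.index(vid)
            vals = {row[col] for row in matrix.values}
            assert len(vals) == 1, (name, vid, vals)


def test_greenhouse_factorial_balanced():
    ds = generate(greenhouse_hts(plants=16, pheno_vars=2, seed=1))
    st = ds.studies[0]
    mv = st.find_columns(HeaderCategory.FACTOR_VALUE, "Plant movement")[0]
    cv = st.find_columns(HeaderCategory.FACTOR_VALUE, "Soil cover")[0]
    from collections import Counter

    combos = Counter((r[mv], r[cv]) for r in st.rows)
    assert set(combos) == {("rotating", "covered"), ("rotating", "uncovered"),
                           ("stationary", "covered"), ("stationary", "uncovered")}
    assert set(combos.values()) == {4}


def test_greenhouse_raw_images_flagged_external(tmp_path):
    ds = generate(greenhouse_hts(plants=4, pheno_vars=2, seed=2), tmp_path / "gh")
    assert ds.external_files
    back = read_dataset(tmp_path / "gh")
    assert back.external_files == ds.external_files


@pytest.mark.parametrize("profile", [
    basic_gwas(sources=0),
    basic_gwas(vars=0),
    field_multiyear(lines=0),
    greenhouse_hts(plants=0),
])
def test_invalid_parameters_rejected(profile):
    with pytest.raises(SyntheticError):
        generate(profile)


def test_missingness_rate_applied():
    ds = generate(basic_gwas(sources=20, reps=2, vars=20, seed=5))
    matrix = ds.data_files["d_data.txt"]
    rows, cols = matrix.shape
    frac = matrix.n_missing() / (rows * cols)
    assert 0.005 < frac < 0.05  # around the 2% default
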