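"""TDF parsing, matrix parsing, linking conservation, aggregation."""

import copy

import pytest

from phenotab.model import OntologyAnnotation
from phenotab.pheno_data import (
    LONG_COLUMNS,
    PhenoDataError,
    TraitDefinition,
    aggregate,
    link_observations,
    read_data_matrix,
    read_tdf,
    summarize,
    write_tdf,
)
from phenotab.synthetic_data import basic_gwas, field_multiyear, generate
from phenotab.validator import CODE_ORPHAN_DATA_ROW, CODE_UNKNOWN_VARIABLE_ID


# -- TDF --------------------------------------------------------------------


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


def test_read_tdf_minimal(tmp_path):
    p = _write(tmp_path, "tdf.txt",
               "Variable ID\tTrait\tMethod\tScale\n"
               "PH\tPlant height\truler\tcm\n"
               "DH\tDays to heading\tvisual\tdays\n")
    defs = read_tdf(p)
    assert [d.variable_id for d in defs] == ["PH", "DH"]
    assert defs[0].trait.term_label == "Plant height"
    assert not defs[0].trait.is_annotated
    assert all(d.variable_class == "unspecified" for d in defs)


def test_read_tdf_with_annotations_and_class(tmp_path):
    p = _write(tmp_path, "tdf.txt",
               "Variable ID\tTrait\tTerm Source REF\tTerm Accession Number"
               "\tMethod\tScale\tComment[Variable class]\n"
               "PH\tPlant height\tPTO\tPTO:0000207\truler\tcm\tphenotypic\n"
               "VPD\tVapor pressure deficit\t\t\tstation\tkPa\tenvironmental\n")
    defs = read_tdf(p)
    assert defs[0].trait == OntologyAnnotation("Plant height", "PTO", "PTO:0000207")
    assert defs[0].variable_class == "phenotypic"
    assert defs[1].variable_class == "environmental"


@pytest.mark.parametrize("text, match", [
    ("Variable ID\tTrait\tMethod\tScale\nPH\ta\tb\tc\nPH\td\te\tf\n", "duplicate"),
    ("Variable ID\tTrait\tMethod\n", "Scale"),
    ("", "empty"),
])
def test_read_tdf_errors(tmp_path, text, match):
    p = _write(tmp_path, "bad.txt", text)
    with pytest.raises(PhenoDataError, match=match):
        read_tdf(p)


def test_tdf_roundtrip(tmp_path):
    defs = [
        TraitDefinition("PH", OntologyAnnotation("Plant height", "PTO", "PTO:1"),
                        OntologyAnnotation("ruler"), OntologyAnnotation("cm"),
                        "phenotypic"),
        TraitDefinition("SC", OntologyAnnotation("Disease score"),
                        OntologyAnnotation("visual"), OntologyAnnotation("1-9"),
                        "unspecified"),
    ]
    path = tmp_path / "tdf.txt"
    write_tdf(defs, path)
    assert read_tdf(path) == defs


# -- data matrices ----------------------------------------------------------


def test_read_matrix_default_dialect(tmp_path):
    body = "Assay Name\tPH\tDH\na1\t10\t50\na2\t12\tNA\n"
    m = read_data_matrix(_write(tmp_path, "d.txt", body))
    assert m.link_node == "Assay Name"
    assert m.shape == (2, 2)
    assert m.n_missing() == 1
    df = m.to_dataframe()
    assert df.loc["a1", "PH"] == 10


def test_read_matrix_extended_link_node(tmp_path):
    body = "Sample Name\tPH\ns1\t10\n"
    m = read_data_matrix(_write(tmp_path, "d.txt", body))
    assert m.link_node == "Sample Name"


@pytest.mark.parametrize("text, match", [
    ("Assay Name\tPH\na1\t1\ta2\n", "ragged"),
    ("Assay Name\tPH\na1\t1\na1\t2\n", "duplicate"),
    ("Assay Name\tPH\n", "no data rows"),
    ("", "empty"),
])
def test_read_matrix_errors(tmp_path, text, match):
    with pytest.raises(PhenoDataError, match=match):
        read_data_matrix(_write(tmp_path, "bad.txt", text))


# -- linking ----------------------------------------------------------------


def test_link_conservation_exhaustive(tiny_basic):
    """Record count equals rows x variables - missing cells, checked against
    a cell-by-cell enumeration."""
    assay = tiny_basic.assays[0]
    tdf = tiny_basic.trait_definitions["tdf.txt"]
    matrix = tiny_basic.data_files["d_data.txt"]
    obs = link_observations(assay, tdf, matrix)
    expected = sum(
        1 for row in matrix.values for cell in row if cell not in ("", "NA")
    )
    assert len(obs) == expected
    assert obs.issues == []
    rows, cols = matrix.shape
    assert len(obs) == rows * cols - matrix.n_missing()


def test_link_full_matrix_counts(tmp_path):
    """6 rows x 4 variables with no missing cells -> 24 records."""
    ds = generate(basic_gwas(sources=3, reps=2, vars=4, seed=3), missing_rate=0.0)
    obs = link_observations(ds.assays[0], ds.trait_definitions["tdf.txt"],
                            ds.data_files["d_data.txt"])
    assert len(obs) == 24


def test_link_reports_orphans_and_unknown_variables(tiny_basic):
    ds = copy.deepcopy(tiny_basic)
    matrix = ds.data_files["d_data.txt"]
    matrix.row_ids[0] = "orphan"
    matrix.variable_ids[0] = "XYZ"
    obs = link_observations(ds.assays[0], ds.trait_definitions["tdf.txt"], matrix)
    codes = [i.code for i in obs.issues]
    assert CODE_ORPHAN_DATA_ROW in codes
    assert CODE_UNKNOWN_VARIABLE_ID in codes
    assert all("orphan" != r for r in obs.records["row_id"])
    assert "XYZ" not in set(obs.records["variable_id"])


def test_link_requires_link_node(tiny_basic):
    matrix = copy.deepcopy(tiny_basic.data_files["d_data.txt"])
    matrix.link_node = "Extract Name"
    with pytest.raises(PhenoDataError, match="Extract Name"):
        link_observations(tiny_basic.assays[0],
                          tiny_basic.trait_definitions["tdf.txt"], matrix)


# -- aggregation ------------------------------------------------------------


def test_aggregate_two_years_grouped_by_study_start(small_field):
    obs = aggregate([small_field], by=["Study start"])
    groups = set(obs.records["Study start"])
    assert groups == {"2012-04-10", "2013-04-10"}
    # every record resolved a concrete group value
    assert "unknown" not in groups


def test_aggregate_by_geographic_location(small_field):
    obs = aggregate([small_field], by=["Geographic location"])
    assert set(obs.records["Geographic location"]) == {"Poznan, Poland"}


def test_aggregate_missing_qualifier_warns_unknown(small_field):
    obs = aggregate([small_field], by=["Altitude"])
    assert any(i.code == "MISSING_GROUP_KEY" for i in obs.issues)
    assert set(obs.records["Altitude"]) == {"unknown"}


def test_aggregate_empty_by_equals_plain_linking(tiny_basic):
    agg = aggregate([tiny_basic], by=[])
    direct = link_observations(tiny_basic.assays[0],
                               tiny_basic.trait_definitions["tdf.txt"],
                               tiny_basic.data_files["d_data.txt"])
    assert len(agg) == len(direct)
    assert list(agg.records.columns) == list(LONG_COLUMNS)


def test_group_filter_commutes_with_single_linking(small_field):
    """Aggregating then filtering to one year equals linking that year's
    matrix alone."""
    obs = aggregate([small_field], by=["Study start"])
    year1 = obs.records[obs.records["Study start"] == "2012-04-10"]
    direct = link_observations(
        small_field.assays[0],
        small_field.trait_definitions["tdf_field.txt"],
        small_field.data_files["d_field2012.txt"],
        study=small_field.studies[0],
    )
    assert len(year1) == len(direct)
    assert set(year1["row_id"]) == set(direct.records["row_id"])


def test_aggregate_conflicting_tdf_reported():
    ds1 = generate(basic_gwas(sources=2, reps=1, vars=2, seed=1))
    ds2 = generate(basic_gwas(sources=2, reps=1, vars=2, seed=2))
    defs = ds2.trait_definitions["tdf.txt"]
    ds2.trait_definitions["tdf.txt"] = [
        TraitDefinition(defs[0].variable_id, OntologyAnnotation("Different trait"),
                        defs[0].method, defs[0].scale, defs[0].variable_class)
    ] + defs[1:]
    obs = aggregate([ds1, ds2], dataset_ids=["a", "b"])
    assert any(i.code == "TDF_CONFLICT" for i in obs.issues)


# -- summary ----------------------------------------------------------------


def test_summarize_counts(small_field):
    s = summarize(small_field)
    assert s.n_studies == 2
    assert set(s.sources_per_study.values()) == {6}  # 4 lines + 2 parents
    assert s.n_variables == 5
    assert s.n_phenotypic == 3
    assert s.n_environmental == 2
    assert s.n_samples == 12
    assert s.matrix_shapes["d_field2012.txt"] == (6, 5)


def test_summarize_empty_dataset():
    from phenotab.model import Dataset

    s = summarize(Dataset())
    assert s.n_studies == 0 and s.n_variables == 0 and s.n_samples == 0
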