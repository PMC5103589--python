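"""Validation and compliance: mutations, monotonicity, independent oracle."""

import copy

import pytest

from phenotab.cli import scaffold_dataset
from phenotab.model import HeaderCategory
from phenotab.synthetic_data import (
    DEFECT_CODES,
    SyntheticError,
    basic_gwas,
    field_multiyear,
    generate,
    inject_defect,
)
from phenotab.validator import (
    CODE_EMPTY_ESSENTIAL_CELL,
    CODE_MISSING_COLUMN,
    CODE_MISSING_FILE,
    Severity,
    combined_report_dict,
    miappe_compliance,
    validate_dataset,
)

SEVERITY_RANK = {Severity.INFO: 0, Severity.WARNING: 1, Severity.ERROR: 2}


def test_clean_fixtures_have_no_issues(tiny_basic, small_field, small_greenhouse):
    for ds, kind in ((tiny_basic, "basic"), (small_field, "field"),
                     (small_greenhouse, "greenhouse")):
        report, compliance = validate_dataset(ds, kind)
        assert report.errors == []
        assert report.warnings == []
        assert compliance.score == 1.0


def test_scaffold_validates_clean_with_zero_compliance():
    """An empty template has all columns and protocols but no content."""
    for kind in ("basic", "field", "greenhouse"):
        ds = scaffold_dataset(kind)
        report, compliance = validate_dataset(ds, kind)
        assert report.issues == []
        assert compliance.n_present == 0
        assert compliance.score == 0.0


@pytest.mark.parametrize("code", DEFECT_CODES)
def test_each_defect_triggers_its_code(small_field, code):
    """Every documented defect, injected singly into a clean fixture,
    yields at least one issue with its designated code and nothing of
    higher severity elsewhere."""
    mutated = inject_defect(small_field, code)
    report, _ = validate_dataset(mutated, "field")
    hits = [i for i in report.issues if i.code == code]
    assert hits, f"{code} not triggered"
    worst_hit = max(SEVERITY_RANK[i.severity] for i in hits)
    others = [i for i in report.issues if i.code != code]
    assert all(SEVERITY_RANK[i.severity] <= worst_hit for i in others), (
        f"{code}: unrelated higher-severity issues {others}"
    )


def test_unknown_defect_code_rejected(tiny_basic):
    with pytest.raises(SyntheticError):
        inject_defect(tiny_basic, "NOT_A_CODE")


def test_missing_watering_block_is_one_column_group(small_field):
    """Deleting the Watering protocol block yields exactly the
    protocol-plus-three-parameters group of missing-column errors."""
    ds = copy.deepcopy(small_field)
    st = ds.studies[0]
    cols = []
    for pcol, params in st.protocol_blocks():
        if st.rows[0][pcol] == "Watering":
            cols = [pcol] + [c for c in params
                             if st.headers[c].category is HeaderCategory.PARAMETER_VALUE]
    for c in sorted(cols, reverse=True):
        del st.headers[c]
        for row in st.rows:
            del row[c]
    report, _ = validate_dataset(ds, "field")
    missing = [i for i in report.issues if i.code == CODE_MISSING_COLUMN]
    assert len(missing) == 4
    assert all("Watering" in i.message for i in missing)
    assert report.codes() == {CODE_MISSING_COLUMN}


def test_empty_required_cells_warn_not_error(small_field):
    """Archives with declared-but-unfilled columns stay structurally valid."""
    ds = copy.deepcopy(small_field)
    st = ds.studies[0]
    idx = st.find_columns(HeaderCategory.CHARACTERISTICS, "Seed origin")[0]
    for row in st.rows:
        row[idx] = ""
    report, _ = validate_dataset(ds, "field")
    assert report.errors == []
    empties = [i for i in report.warnings if i.code == CODE_EMPTY_ESSENTIAL_CELL]
    assert len(empties) == len(st.rows)


def test_deleting_tdf_adds_exactly_missing_file_errors(small_field):
    base_report, _ = validate_dataset(small_field, "field")
    mutated = inject_defect(small_field, CODE_MISSING_FILE)
    report, _ = validate_dataset(mutated, "field")
    new = [i for i in report.issues if i not in base_report.issues]
    assert {i.code for i in new} == {CODE_MISSING_FILE}
    assert all(i.severity is Severity.ERROR for i in new)


def test_validation_is_idempotent(small_field):
    r1, c1 = validate_dataset(small_field, "field")
    r2, c2 = validate_dataset(small_field, "field")
    assert r1 == r2
    assert c1.to_dict() == c2.to_dict()


def test_report_ordering_deterministic(small_field):
    mutated = inject_defect(small_field, CODE_MISSING_FILE)
    report, _ = validate_dataset(mutated, "field")
    keys = [i.sort_key() for i in report.issues]
    assert keys == sorted(keys)


# ---------------------------------------------------------------------------
# Compliance
# ---------------------------------------------------------------------------


def test_blanking_geographic_location_reported_in_timing_section(tiny_basic):
    ds = copy.deepcopy(tiny_basic)
    st = ds.studies[0]
    idx = st.find_columns(HeaderCategory.CHARACTERISTICS, "Geographic location")[0]
    for row in st.rows:
        row[idx] = ""
    comp = miappe_compliance(ds, "basic")
    timing = comp.sections["Timing and location"]
    assert "Geographic location" in timing.missing
    assert comp.n_present == comp.n_applicable - 1


def test_blank_nutrition_parameters_lose_nutrients_attribute(small_field):
    ds = copy.deepcopy(small_field)
    for st in ds.studies:
        for pcol, params in st.protocol_blocks():
            if st.rows and st.rows[0][pcol] == "Nutrition":
                for c in params:
                    if st.headers[c].category is HeaderCategory.PARAMETER_VALUE:
                        for row in st.rows:
                            row[c] = ""
    comp = miappe_compliance(ds, "field")
    assert "Nutrients" in comp.sections["Environment"].missing
    assert comp.score < 1.0


def _brute_force_compliance(ds, kind):
    """Independent counter over the essential-attribute mapping, walking the
    in-memory tables directly.  (attribute, where, target) transcribed from
    the configuration mapping by hand."""
    table = [
        ("Unique identifier", "inv", "identifier", "BFG"),
        ("Title", "inv", "title", "BFG"),
        ("Description", "inv", "description", "BFG"),
        ("Study start", "schar", "Study start", "BFG"),
        ("Study duration", "schar", "Study duration", "BFG"),
        ("Geographic location", "schar", "Geographic location", "BFG"),
        ("Organism", "schar", "Organism", "BFG"),
        ("Infraspecific name", "schar", "Infraspecific name", "BFG"),
        ("Seed origin", "schar", "Seed origin", "BFG"),
        ("Growth facility", "schar", "Growth facility", "BFG"),
        ("Aerial conditions", "proto", "Aerial conditions", "FG"),
        ("Rooting conditions", "proto", "Rooting", "FG"),
        ("Nutrients", "proto", "Nutrition", "FG"),
        ("Watering", "proto", "Watering", "FG"),
        ("Experimental unit", "proto", "Sampling", "FG"),
        ("Plant body of interest", "achar", "Plant body of interest", "BFG"),
        ("Phenotypic Trait", "tdf", "trait", "BFG"),
        ("Phenotypic Method", "tdf", "method", "BFG"),
        ("Phenotypic Scale", "tdf", "scale", "BFG"),
        ("Derived data", "ddf", "", "BFG"),
        ("Environmental Trait", "etdf", "trait", "BFG"),
        ("Environmental Method", "etdf", "method", "BFG"),
        ("Environmental Scale", "etdf", "scale", "BFG"),
    ]
    flag = {"basic": "B", "field": "F", "greenhouse": "G"}[kind]
    has_env = any(d.variable_class == "environmental"
                  for defs in ds.trait_definitions.values() for d in defs)
    applicable = present = 0
    for _key, where, target, configs in table:
        if flag not in configs:
            continue
        if where == "etdf" and not has_env:
            continue
        applicable += 1
        ok = False
        if where == "inv":
            ok = bool(getattr(ds.investigation, target))
        elif where == "schar" or where == "achar":
            tables = ds.studies if where == "schar" else ds.assays
            for t in tables:
                for i, h in enumerate(t.headers):
                    if h.category is HeaderCategory.CHARACTERISTICS and h.qualifier == target:
                        ok = ok or any(r[i].strip() for r in t.rows if i < len(r))
        elif where == "proto":
            for t in ds.studies:
                for i, h in enumerate(t.headers):
                    if h.category is HeaderCategory.PROTOCOL_REF \
                            and any(r[i] == target for r in t.rows if i < len(r)):
                        j = i + 1
                        while j < len(t.headers) and t.headers[j].category in (
                                HeaderCategory.PARAMETER_VALUE, HeaderCategory.UNIT):
                            if t.headers[j].category is HeaderCategory.PARAMETER_VALUE \
                                    and any(r[j].strip() for r in t.rows if j < len(r)):
                                ok = True
                            j += 1
        elif where == "tdf":
            for defs in ds.trait_definitions.values():
                for d in defs:
                    if d.variable_class != "environmental" \
                            and getattr(d, target).term_label.strip():
                        ok = True
        elif where == "etdf":
            for defs in ds.trait_definitions.values():
                for d in defs:
                    if d.variable_class == "environmental" \
                            and getattr(d, target).term_label.strip():
                        ok = True
        elif where == "ddf":
            for t in ds.assays:
                for i, h in enumerate(t.headers):
                    if h.category is HeaderCategory.DERIVED_DATA_FILE:
                        ok = ok or any(r[i].strip() for r in t.rows if i < len(r))
        present += ok
    return present, applicable


@pytest.mark.parametrize("kind, ds_factory", [
    ("basic", lambda: generate(basic_gwas(sources=3, reps=2, vars=4, seed=21))),
    ("field", lambda: generate(field_multiyear(lines=3, parents=2, years=2,
                                               pheno_vars=3, env_vars=1, seed=21))),
])
def test_compliance_agrees_with_brute_force_counter(kind, ds_factory):
    ds = ds_factory()
    variants = [ds]
    # blank a characteristic column dataset-wide
    v = copy.deepcopy(ds)
    st = v.studies[0]
    idx = st.find_columns(HeaderCategory.CHARACTERISTICS, "Growth facility")[0]
    for row in st.rows:
        row[idx] = ""
    variants.append(v)
    # strip the investigation title
    v2 = copy.deepcopy(ds)
    v2.investigation.title = ""
    variants.append(v2)
    for variant in variants:
        comp = miappe_compliance(variant, kind)
        present, applicable = _brute_force_compliance(variant, kind)
        assert (comp.n_present, comp.n_applicable) == (present, applicable)
        assert comp.score == pytest.approx(present / applicable)


def test_blanking_never_raises_score_nor_lowers_issue_count(tiny_basic):
    """Degradation monotonicity over a sweep of single blanked cells."""
    base_report, base_comp = validate_dataset(tiny_basic, "basic")
    st = tiny_basic.studies[0]
    for col in range(len(st.headers)):
        ds = copy.deepcopy(tiny_basic)
        ds.studies[0].rows[0][col] = ""
        report, comp = validate_dataset(ds, "basic")
        assert len(report.issues) >= len(base_report.issues)
        assert comp.score <= base_comp.score + 1e-12


def test_complete_fixture_scores_exactly_one(small_field):
    comp = miappe_compliance(small_field, "field")
    assert comp.score == 1.0
    assert comp.missing() == []


def test_greenhouse_factors_reported_as_extended(small_greenhouse):
    comp = miappe_compliance(small_greenhouse, "greenhouse")
    assert "Factor Value[Plant movement]" in comp.extended_present
    assert "Factor Value[Soil cover]" in comp.extended_present


def test_combined_report_matches_schema_shape(small_field):
    """The JSON document carries the fields promised by the shipped schema."""
    import json
    from importlib import resources

    schema = json.loads(
        resources.files("phenotab").joinpath("report_schema.json").read_text()
    )
    report, comp = validate_dataset(inject_defect(small_field, CODE_MISSING_FILE), "field")
    doc = combined_report_dict(report, comp)
    assert set(schema["required"]) <= set(doc)
    for issue in doc["issues"]:
        assert set(schema["properties"]["issues"]["items"]["required"]) <= set(issue)
    assert 0.0 <= doc["compliance"]["score"] <= 1.0
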