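"""Column-header grammar: parsing, canonical formatting, invariants."""

import pytest
from hypothesis import given, settings, strategies as st

from phenotab.model import (
    FieldHeader,
    HeaderCategory,
    HeaderParseError,
    InvalidHeaderError,
    ModelError,
    OntologyAnnotation,
    QUALIFIED_CATEGORIES,
    format_header,
    parse_header,
    parse_header_extended,
)


@pytest.mark.parametrize(
    "text, category, qualifier",
    [
        ("Characteristics[Organism]", HeaderCategory.CHARACTERISTICS, "Organism"),
        ("Parameter Value[Daily photon flux]", HeaderCategory.PARAMETER_VALUE,
         "Daily photon flux"),
        ("Factor Value[Watering regime]", HeaderCategory.FACTOR_VALUE, "Watering regime"),
        ("Comment[Data provenance]", HeaderCategory.COMMENT, "Data provenance"),
        ("Source Name", HeaderCategory.SOURCE_NAME, ""),
        ("Sample Name", HeaderCategory.SAMPLE_NAME, ""),
        ("Assay Name", HeaderCategory.ASSAY_NAME, ""),
        ("Protocol REF", HeaderCategory.PROTOCOL_REF, ""),
        ("Term Source REF", HeaderCategory.TERM_SOURCE_REF, ""),
        ("Term Accession Number", HeaderCategory.TERM_ACCESSION_NUMBER, ""),
        ("Unit", HeaderCategory.UNIT, ""),
        ("Derived Data File", HeaderCategory.DERIVED_DATA_FILE, ""),
        ("  Raw Data File  ", HeaderCategory.RAW_DATA_FILE, ""),
        # inner whitespace of a qualifier is preserved, outer trimmed
        ("Characteristics[ Seed  origin ]", HeaderCategory.CHARACTERISTICS, "Seed  origin"),
    ],
)
def test_parse_header_examples(text, category, qualifier):
    header = parse_header(text)
    assert header.category is category
    assert header.qualifier == qualifier


def test_protocol_ref_shorthand_normalized():
    """'Protocol REF[Rooting]' is shorthand for a Protocol REF column whose
    cells carry the protocol name."""
    header, expected = parse_header_extended("Protocol REF[Rooting]")
    assert header == FieldHeader(HeaderCategory.PROTOCOL_REF)
    assert expected == "Rooting"
    assert format_header(header) == "Protocol REF"


@pytest.mark.parametrize(
    "text",
    ["", "   ", "Characteristics[Organism", "Characteristics Organism]",
     "Characteristics[]", "Banana", "Weird Header[x]", "Char[a]b[c]"],
)
def test_parse_header_rejects_malformed(text):
    with pytest.raises(HeaderParseError):
        parse_header(text)


def test_qualifier_rules_enforced():
    with pytest.raises(InvalidHeaderError):
        FieldHeader(HeaderCategory.SOURCE_NAME, "x")
    with pytest.raises(InvalidHeaderError):
        FieldHeader(HeaderCategory.CHARACTERISTICS, "")


def test_format_header_canonical():
    assert format_header(FieldHeader(HeaderCategory.FACTOR_VALUE, "Watering regime")) \
        == "Factor Value[Watering regime]"
    assert format_header(FieldHeader(HeaderCategory.PROTOCOL_REF)) == "Protocol REF"


def test_schema_headers_roundtrip(schema_transcription):
    """Every header string in the default schemas survives parse->format
    (after the Protocol REF shorthand normalization)."""
    for kind, headers in schema_transcription.items():
        if kind.startswith("_"):
            continue
        for text in headers:
            header, expected = parse_header_extended(text)
            if expected:  # Protocol REF[X] shorthand
                assert format_header(header) == "Protocol REF"
            else:
                assert format_header(header) == text


_QUALIFIER_CHARS = st.characters(
    whitelist_categories=("L", "N", "P", "Zs"),
    blacklist_characters="[]\t\n\r",
)


@st.composite
def field_headers(draw):
    category = draw(st.sampled_from(sorted(HeaderCategory, key=lambda c: c.value)))
    if category in QUALIFIED_CATEGORIES:
        qualifier = draw(
            st.text(_QUALIFIER_CHARS, min_size=1, max_size=30).filter(
                lambda s: s == s.strip() and s
            )
        )
        return FieldHeader(category, qualifier)
    return FieldHeader(category)


@given(field_headers())
@settings(max_examples=200, deadline=None)
def test_parse_format_identity(header):
    assert parse_header(format_header(header)) == header


def test_ontology_annotation_invariant():
    OntologyAnnotation("plant height", "PTO", "PTO:0000207")
    OntologyAnnotation("free text only")
    with pytest.raises(ModelError):
        OntologyAnnotation("x", "", "PTO:0000207")
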