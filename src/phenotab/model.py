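"""Domain model for ISA-Tab plant-phenotyping datasets.

The ISA-Tab format describes an experiment as a hierarchy of tab-delimited
files: one Investigation file (project-level metadata, sectioned key-value
layout), one or more Study files (biosources, environment, design) and Assay
files (samples, measuring procedures).  Study and Assay files are rectangular
tables whose columns follow a small grammar: "data node" columns (Source
Name, Sample Name, Extract Name, Assay Name) trace material through the
experimental workflow, and are qualified by Characteristics[...],
Factor Value[...], Protocol REF + Parameter Value[...], Comment[...], Unit
and ontology-annotation columns (Term Source REF / Term Accession Number).

This module holds the shared types and the column-header grammar; it performs
no file I/O.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterator, Optional

if TYPE_CHECKING:  # pragma: no cover
    from .pheno_data import DataMatrix, TraitDefinition


class ModelError(ValueError):
    """Base class for domain-model violations."""


class HeaderParseError(ModelError):
    """Raised when a raw column header cannot be parsed."""


class InvalidHeaderError(ModelError):
    """Raised when a FieldHeader violates its category/qualifier rules."""


class HeaderCategory(enum.Enum):
    """Closed vocabulary of ISA-Tab column categories."""

    SOURCE_NAME = "Source Name"
    SAMPLE_NAME = "Sample Name"
    EXTRACT_NAME = "Extract Name"
    ASSAY_NAME = "Assay Name"
    PROTOCOL_REF = "Protocol REF"
    CHARACTERISTICS = "Characteristics"
    FACTOR_VALUE = "Factor Value"
    PARAMETER_VALUE = "Parameter Value"
    UNIT = "Unit"
    TERM_SOURCE_REF = "Term Source REF"
    TERM_ACCESSION_NUMBER = "Term Accession Number"
    COMMENT = "Comment"
    RAW_DATA_FILE = "Raw Data File"
    DERIVED_DATA_FILE = "Derived Data File"


#: Categories that take a mandatory ``[qualifier]``.
QUALIFIED_CATEGORIES = frozenset(
    {
        HeaderCategory.CHARACTERISTICS,
        HeaderCategory.FACTOR_VALUE,
        HeaderCategory.PARAMETER_VALUE,
        HeaderCategory.COMMENT,
    }
)

#: Data-node categories: identifiers of material/data at workflow stages.
DATA_NODE_CATEGORIES = frozenset(
    {
        HeaderCategory.SOURCE_NAME,
        HeaderCategory.SAMPLE_NAME,
        HeaderCategory.EXTRACT_NAME,
        HeaderCategory.ASSAY_NAME,
    }
)

_PLAIN_SPELLINGS = {
    cat.value: cat for cat in HeaderCategory if cat not in QUALIFIED_CATEGORIES
}
_BRACKET_SPELLINGS = {cat.value: cat for cat in QUALIFIED_CATEGORIES}

_BRACKET_RE = re.compile(r"^(?P<prefix>[^\[\]]+?)\s*\[(?P<inner>[^\[\]]*)\]$")


@dataclass(frozen=True)
class FieldHeader:
    """A parsed column header: category plus bracket qualifier.

    The qualifier is mandatory for Characteristics / Factor Value /
    Parameter Value / Comment and forbidden elsewhere.
    """

    category: HeaderCategory
    qualifier: str = ""

    def __post_init__(self) -> None:
        if self.category in QUALIFIED_CATEGORIES:
            if not self.qualifier:
                raise InvalidHeaderError(
                    f"{self.category.value} requires a [qualifier]"
                )
        elif self.qualifier:
            raise InvalidHeaderError(
                f"{self.category.value} does not take a qualifier "
                f"(got {self.qualifier!r})"
            )

    def __str__(self) -> str:
        return format_header(self)


def parse_header(text: str) -> FieldHeader:
    """Parse a raw column header into a :class:`FieldHeader`.

    ``"Protocol REF[X]"`` (a documentation shorthand for a Protocol REF
    column whose cells hold the protocol name X) is normalized to a plain
    Protocol REF header; use :func:`parse_header_extended` to recover X.

    Raises :class:`HeaderParseError` on empty input, unbalanced brackets or
    an unknown category.  Matching is case-sensitive after trimming outer
    whitespace.
    """
    header, _ = parse_header_extended(text)
    return header


def parse_header_extended(text: str) -> tuple[FieldHeader, str]:
    """Like :func:`parse_header` but also returns the expected cell value
    carried by the ``Protocol REF[X]`` shorthand ("" otherwise)."""
    stripped = text.strip()
    if not stripped:
        raise HeaderParseError("empty column header")
    if "[" in stripped or "]" in stripped:
        m = _BRACKET_RE.match(stripped)
        if not m:
            raise HeaderParseError(f"malformed bracket syntax in {text!r}")
        prefix = m.group("prefix").strip()
        inner = m.group("inner").strip()
        if prefix == HeaderCategory.PROTOCOL_REF.value:
            # "Protocol REF[Rooting]" -> Protocol REF column, expected value.
            return FieldHeader(HeaderCategory.PROTOCOL_REF), inner
        cat = _BRACKET_SPELLINGS.get(prefix)
        if cat is None:
            raise HeaderParseError(f"unknown bracketed category {prefix!r}")
        if not inner:
            raise HeaderParseError(f"empty qualifier in {text!r}")
        return FieldHeader(cat, inner), ""
    cat = _PLAIN_SPELLINGS.get(stripped)
    if cat is None:
        raise HeaderParseError(f"unknown column header {stripped!r}")
    return FieldHeader(cat), ""


def format_header(header: FieldHeader) -> str:
    """Canonical spelling of a header; inverse of :func:`parse_header`."""
    if header.category in QUALIFIED_CATEGORIES:
        return f"{header.category.value}[{header.qualifier}]"
    return header.category.value


@dataclass(frozen=True)
class OntologyAnnotation:
    """A value with optional term annotation.

    ``source_ref`` names an ontology declared in the Investigation's
    ontology-source section; ``accession`` is the term accession within it.
    A bare label with empty source/accession is an unannotated value.
    """

    term_label: str = ""
    source_ref: str = ""
    accession: str = ""

    def __post_init__(self) -> None:
        if self.accession and not self.source_ref:
            raise ModelError(
                "an accession requires a Term Source REF "
                f"(accession={self.accession!r})"
            )

    @property
    def is_annotated(self) -> bool:
        return bool(self.source_ref or self.accession)


# ---------------------------------------------------------------------------
# Study / Assay tables
# ---------------------------------------------------------------------------


@dataclass
class Table:
    """A rectangular Study or Assay table: ordered headers plus rows."""

    source_file: str
    headers: list[FieldHeader] = field(default_factory=list)
    rows: list[list[str]] = field(default_factory=list)

    @property
    def n_cols(self) -> int:
        return len(self.headers)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def is_rectangular(self) -> bool:
        return all(len(r) == self.n_cols for r in self.rows)

    def header_texts(self) -> list[str]:
        return [format_header(h) for h in self.headers]

    def find_columns(
        self, category: HeaderCategory, qualifier: Optional[str] = None
    ) -> list[int]:
        """Indices of columns with the given category (and qualifier)."""
        return [
            i
            for i, h in enumerate(self.headers)
            if h.category is category
            and (qualifier is None or h.qualifier == qualifier)
        ]

    def column_values(self, index: int) -> list[str]:
        return [row[index] for row in self.rows]

    def values_for(
        self, category: HeaderCategory, qualifier: Optional[str] = None
    ) -> list[str]:
        """All cell values from all columns matching the header, in order."""
        out: list[str] = []
        for i in self.find_columns(category, qualifier):
            out.extend(self.column_values(i))
        return out

    def protocol_blocks(self) -> list[tuple[int, list[int]]]:
        """Spans of Protocol REF columns with their dependent columns.

        Returns (protocol column index, indices of Parameter Value / Unit /
        term columns up to the next Protocol REF or data node).
        """
        blocks: list[tuple[int, list[int]]] = []
        current: Optional[list[int]] = None
        for i, h in enumerate(self.headers):
            if h.category is HeaderCategory.PROTOCOL_REF:
                current = []
                blocks.append((i, current))
            elif h.category in DATA_NODE_CATEGORIES:
                current = None
            elif current is not None and h.category in (
                HeaderCategory.PARAMETER_VALUE,
                HeaderCategory.UNIT,
                HeaderCategory.TERM_SOURCE_REF,
                HeaderCategory.TERM_ACCESSION_NUMBER,
            ):
                current.append(i)
        return blocks

    def check_shape(self) -> list[str]:
        """Structural problems (free text); empty when well-formed."""
        problems = []
        for r, row in enumerate(self.rows, start=2):  # header row is row 1
            if len(row) != self.n_cols:
                problems.append(
                    f"{self.source_file}: row {r} has {len(row)} cells, "
                    f"expected {self.n_cols}"
                )
        return problems


class StudyTable(Table):
    """Physical form of an ``s_*.txt`` file.

    Begins with Source Name and ends with Sample Name (checked by the
    validator, not enforced at construction, so defective files can be
    represented and reported).
    """


class AssayTable(Table):
    """Physical form of an ``a_*.txt`` file; begins with Sample Name."""


# ---------------------------------------------------------------------------
# Investigation
# ---------------------------------------------------------------------------


@dataclass
class OntologySource:
    name: str
    file: str = ""
    version: str = ""
    description: str = ""


@dataclass
class Publication:
    pubmed_id: str = ""
    doi: str = ""
    authors: str = ""
    title: str = ""
    status: str = ""


@dataclass
class Contact:
    last_name: str = ""
    first_name: str = ""
    email: str = ""
    affiliation: str = ""
    roles: str = ""


@dataclass
class ProtocolDecl:
    """A protocol declared in a STUDY PROTOCOLS block."""

    name: str
    protocol_type: str = ""
    description: str = ""
    parameters: list[str] = field(default_factory=list)


@dataclass
class FactorDecl:
    name: str
    factor_type: str = ""


@dataclass
class AssayRecord:
    file_name: str
    measurement_type: str = "phenotyping"
    technology_type: str = ""


@dataclass
class StudyRecord:
    """One STUDY block of the Investigation file."""

    file_name: str
    identifier: str = ""
    title: str = ""
    description: str = ""
    design_descriptors: list[str] = field(default_factory=list)
    publications: list[Publication] = field(default_factory=list)
    factors: list[FactorDecl] = field(default_factory=list)
    assays: list[AssayRecord] = field(default_factory=list)
    protocols: list[ProtocolDecl] = field(default_factory=list)
    contacts: list[Contact] = field(default_factory=list)

    def protocol_names(self) -> set[str]:
        return {p.name for p in self.protocols}


@dataclass
class Investigation:
    identifier: str = ""
    title: str = ""
    description: str = ""
    submission_date: str = ""
    public_release_date: str = ""
    ontology_sources: list[OntologySource] = field(default_factory=list)
    publications: list[Publication] = field(default_factory=list)
    contacts: list[Contact] = field(default_factory=list)
    studies: list[StudyRecord] = field(default_factory=list)

    def check(self) -> list[str]:
        """Invariant violations (unique study/assay file names)."""
        problems = []
        seen: set[str] = set()
        for s in self.studies:
            names = [s.file_name] + [a.file_name for a in s.assays]
            for n in names:
                if n in seen:
                    problems.append(f"duplicate file name {n!r} in investigation")
                seen.add(n)
        return problems


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------


@dataclass
class Dataset:
    """A full ISA-Tab dataset held in memory.

    ``trait_definitions`` maps Trait Definition File names to their parsed
    rows; ``data_files`` maps Derived Data File names to matrices.  Files
    referenced from tables but deliberately not shipped (e.g. raw image
    files) are listed in ``external_files``.
    """

    root: Optional[Path] = field(compare=False, default=None)
    investigation: Investigation = field(default_factory=Investigation)
    studies: list[StudyTable] = field(default_factory=list)
    assays: list[AssayTable] = field(default_factory=list)
    trait_definitions: dict[str, list["TraitDefinition"]] = field(
        default_factory=dict
    )
    data_files: dict[str, "DataMatrix"] = field(default_factory=dict)
    external_files: set[str] = field(default_factory=set)
    #: problems met while reading (ValidationIssue list); not part of equality
    read_issues: list = field(default_factory=list, compare=False)

    def study_table(self, file_name: str) -> Optional[StudyTable]:
        for t in self.studies:
            if t.source_file == file_name:
                return t
        return None

    def assay_table(self, file_name: str) -> Optional[AssayTable]:
        for t in self.assays:
            if t.source_file == file_name:
                return t
        return None

    def study_record_for_assay(self, assay_file: str) -> Optional[StudyRecord]:
        for rec in self.investigation.studies:
            if any(a.file_name == assay_file for a in rec.assays):
                return rec
        return None

    def iter_tables(self) -> Iterator[Table]:
        yield from self.studies
        yield from self.assays
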