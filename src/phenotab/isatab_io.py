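"""Reading and writing ISA-Tab datasets with round-trip fidelity.

A dataset directory holds exactly one Investigation file (``i_*.txt``,
sectioned key-value layout), the Study (``s_*.txt``) and Assay (``a_*.txt``)
tables it declares, plus the Trait Definition Files and Derived Data Files
referenced from Assay cells.  Everything is tab-delimited UTF-8 text.

Serialization is deterministic — two writes of the same dataset are
byte-identical — and reading never mutates files.  Cells may be wrapped in
double quotes on input (common with the official tooling); quotes are
stripped on read and re-added on write only when the cell contains a quote
character.  Tabs and newlines inside cells are rejected on write.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .model import (
    AssayRecord,
    AssayTable,
    Contact,
    Dataset,
    FactorDecl,
    HeaderCategory,
    HeaderParseError,
    Investigation,
    OntologySource,
    ProtocolDecl,
    Publication,
    StudyRecord,
    StudyTable,
    Table,
    parse_header,
)
from .pheno_data import (
    DataMatrix,
    PhenoDataError,
    read_data_matrix,
    read_tdf,
    write_data_matrix,
    write_tdf,
)
from .phenotyping_config import TDF_PARAMETER
from .validator import (
    CODE_FILE_NAMING,
    CODE_OPAQUE_DATA_FILE,
    CODE_RAGGED_ROW,
    CODE_TRAILING_BLANK,
    Severity,
    ValidationIssue,
)


class IsaTabError(ValueError):
    """Unreadable dataset directory or unwritable dataset."""


@dataclass
class FileLayout:
    """The file names making up one dataset directory."""

    investigation: str
    studies: list[str] = field(default_factory=list)
    assays: list[str] = field(default_factory=list)
    trait_definition_files: list[str] = field(default_factory=list)
    data_files: list[str] = field(default_factory=list)


DEFAULT_INVESTIGATION_FILE = "i_investigation.txt"

# ---------------------------------------------------------------------------
# Low-level cells
# ---------------------------------------------------------------------------


def _check_cell(cell: str, context: str) -> str:
    if "\t" in cell or "\n" in cell or "\r" in cell:
        raise IsaTabError(f"{context}: tab or newline inside cell {cell!r}")
    return cell


def _format_cell(cell: str) -> str:
    if '"' in cell:
        return '"' + cell.replace('"', '""') + '"'
    return cell


def _write_rows(rows: list[list[str]], path: Path, context: str) -> None:
    lines = []
    for row in rows:
        lines.append("\t".join(_format_cell(_check_cell(c, context)) for c in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def _read_rows(path: Path) -> list[list[str]]:
    with path.open("r", encoding="utf-8", newline="") as fh:
        return [list(r) for r in csv.reader(fh, delimiter="\t")]


# ---------------------------------------------------------------------------
# Study / Assay tables
# ---------------------------------------------------------------------------


def _read_table(path: Path, cls: type) -> tuple[Table, list[ValidationIssue]]:
    issues: list[ValidationIssue] = []
    rows = _read_rows(path)
    name = path.name
    # strip trailing blank rows / columns
    while rows and not any(c.strip() for c in rows[-1]):
        rows.pop()
        issues.append(ValidationIssue(
            Severity.INFO, CODE_TRAILING_BLANK, (name, len(rows) + 1, "-"),
            "trailing blank row stripped",
        ))
    if not rows:
        raise IsaTabError(f"{name}: empty table file")
    header_row = rows[0]
    while header_row and not header_row[-1].strip():
        header_row.pop()
        issues.append(ValidationIssue(
            Severity.INFO, CODE_TRAILING_BLANK, (name, 1, "-"),
            "trailing blank column stripped",
        ))
    try:
        headers = [parse_header(h) for h in header_row]
    except HeaderParseError as exc:
        raise IsaTabError(f"{name}: {exc}") from exc
    n = len(headers)
    body: list[list[str]] = []
    for rno, row in enumerate(rows[1:], start=2):
        if len(row) > n and not any(c.strip() for c in row[n:]):
            row = row[:n]
        if len(row) != n:
            issues.append(ValidationIssue(
                Severity.ERROR, CODE_RAGGED_ROW, (name, rno, "-"),
                f"row has {len(row)} cells, expected {n}",
            ))
            row = (row + [""] * n)[:n]
        body.append(list(row))
    return cls(source_file=name, headers=headers, rows=body), issues


def _write_table(table: Table, directory: Path) -> None:
    rows = [table.header_texts()] + table.rows
    _write_rows(rows, directory / table.source_file, table.source_file)


# ---------------------------------------------------------------------------
# Investigation file
# ---------------------------------------------------------------------------

_INV_SECTIONS = (
    "ONTOLOGY SOURCE REFERENCE",
    "INVESTIGATION",
    "INVESTIGATION PUBLICATIONS",
    "INVESTIGATION CONTACTS",
    "STUDY",
    "STUDY DESIGN DESCRIPTORS",
    "STUDY PUBLICATIONS",
    "STUDY FACTORS",
    "STUDY ASSAYS",
    "STUDY PROTOCOLS",
    "STUDY CONTACTS",
)

_PARAM_SEP = ";"


def _records(values_by_key: dict[str, list[str]], keys: list[str]) -> list[list[str]]:
    """Transpose a key->values block into per-record value lists."""
    n = max((len(values_by_key.get(k, [])) for k in keys), default=0)
    out = []
    for i in range(n):
        rec = []
        for k in keys:
            vals = values_by_key.get(k, [])
            rec.append(vals[i] if i < len(vals) else "")
        if any(v.strip() for v in rec):
            out.append(rec)
    return out


def parse_investigation(path: Path) -> Investigation:
    """Parse the sectioned key-value Investigation file."""
    rows = _read_rows(path)
    sections: list[tuple[str, dict[str, list[str]]]] = []
    current: Optional[dict[str, list[str]]] = None
    for row in rows:
        if not any(c.strip() for c in row):
            continue
        key = row[0].strip()
        if key in _INV_SECTIONS and all(not c.strip() for c in row[1:]):
            current = {}
            sections.append((key, current))
        elif current is not None:
            current[key] = [c for c in row[1:]]
        else:
            raise IsaTabError(f"{path.name}: content before any section label: {key!r}")

    inv = Investigation()
    study: Optional[StudyRecord] = None
    for label, block in sections:
        if label == "ONTOLOGY SOURCE REFERENCE":
            for rec in _records(block, ["Term Source Name", "Term Source File",
                                        "Term Source Version", "Term Source Description"]):
                inv.ontology_sources.append(OntologySource(*rec))
        elif label == "INVESTIGATION":
            inv.identifier = _first(block, "Investigation Identifier")
            inv.title = _first(block, "Investigation Title")
            inv.description = _first(block, "Investigation Description")
            inv.submission_date = _first(block, "Investigation Submission Date")
            inv.public_release_date = _first(block, "Investigation Public Release Date")
        elif label == "INVESTIGATION PUBLICATIONS":
            for rec in _records(block, ["Investigation PubMed ID",
                                        "Investigation Publication DOI",
                                        "Investigation Publication Author List",
                                        "Investigation Publication Title",
                                        "Investigation Publication Status"]):
                inv.publications.append(Publication(*rec))
        elif label == "INVESTIGATION CONTACTS":
            for rec in _records(block, ["Investigation Person Last Name",
                                        "Investigation Person First Name",
                                        "Investigation Person Email",
                                        "Investigation Person Affiliation",
                                        "Investigation Person Roles"]):
                inv.contacts.append(Contact(*rec))
        elif label == "STUDY":
            study = StudyRecord(
                file_name=_first(block, "Study File Name"),
                identifier=_first(block, "Study Identifier"),
                title=_first(block, "Study Title"),
                description=_first(block, "Study Description"),
            )
            inv.studies.append(study)
        elif study is None:
            raise IsaTabError(f"{path.name}: {label} before any STUDY block")
        elif label == "STUDY DESIGN DESCRIPTORS":
            study.design_descriptors = [
                v for v in block.get("Study Design Type", []) if v.strip()
            ]
        elif label == "STUDY PUBLICATIONS":
            for rec in _records(block, ["Study PubMed ID", "Study Publication DOI",
                                        "Study Publication Author List",
                                        "Study Publication Title",
                                        "Study Publication Status"]):
                study.publications.append(Publication(*rec))
        elif label == "STUDY FACTORS":
            for rec in _records(block, ["Study Factor Name", "Study Factor Type"]):
                study.factors.append(FactorDecl(*rec))
        elif label == "STUDY ASSAYS":
            for rec in _records(block, ["Study Assay File Name",
                                        "Study Assay Measurement Type",
                                        "Study Assay Technology Type"]):
                study.assays.append(AssayRecord(*rec))
        elif label == "STUDY PROTOCOLS":
            for rec in _records(block, ["Study Protocol Name", "Study Protocol Type",
                                        "Study Protocol Description",
                                        "Study Protocol Parameters Name"]):
                params = [p for p in rec[3].split(_PARAM_SEP) if p]
                study.protocols.append(ProtocolDecl(rec[0], rec[1], rec[2], params))
        elif label == "STUDY CONTACTS":
            for rec in _records(block, ["Study Person Last Name", "Study Person First Name",
                                        "Study Person Email", "Study Person Affiliation",
                                        "Study Person Roles"]):
                study.contacts.append(Contact(*rec))
    return inv


def _first(block: dict[str, list[str]], key: str) -> str:
    vals = block.get(key, [])
    return vals[0] if vals else ""


def _kv(key: str, *values: str) -> list[str]:
    return [key, *values]


def write_investigation(inv: Investigation, path: Path) -> None:
    rows: list[list[str]] = []

    rows.append(["ONTOLOGY SOURCE REFERENCE"])
    rows.append(_kv("Term Source Name", *[o.name for o in inv.ontology_sources]))
    rows.append(_kv("Term Source File", *[o.file for o in inv.ontology_sources]))
    rows.append(_kv("Term Source Version", *[o.version for o in inv.ontology_sources]))
    rows.append(_kv("Term Source Description", *[o.description for o in inv.ontology_sources]))

    rows.append(["INVESTIGATION"])
    rows.append(_kv("Investigation Identifier", inv.identifier))
    rows.append(_kv("Investigation Title", inv.title))
    rows.append(_kv("Investigation Description", inv.description))
    rows.append(_kv("Investigation Submission Date", inv.submission_date))
    rows.append(_kv("Investigation Public Release Date", inv.public_release_date))

    rows.append(["INVESTIGATION PUBLICATIONS"])
    rows.append(_kv("Investigation PubMed ID", *[p.pubmed_id for p in inv.publications]))
    rows.append(_kv("Investigation Publication DOI", *[p.doi for p in inv.publications]))
    rows.append(_kv("Investigation Publication Author List", *[p.authors for p in inv.publications]))
    rows.append(_kv("Investigation Publication Title", *[p.title for p in inv.publications]))
    rows.append(_kv("Investigation Publication Status", *[p.status for p in inv.publications]))

    rows.append(["INVESTIGATION CONTACTS"])
    rows.append(_kv("Investigation Person Last Name", *[c.last_name for c in inv.contacts]))
    rows.append(_kv("Investigation Person First Name", *[c.first_name for c in inv.contacts]))
    rows.append(_kv("Investigation Person Email", *[c.email for c in inv.contacts]))
    rows.append(_kv("Investigation Person Affiliation", *[c.affiliation for c in inv.contacts]))
    rows.append(_kv("Investigation Person Roles", *[c.roles for c in inv.contacts]))

    for s in inv.studies:
        rows.append(["STUDY"])
        rows.append(_kv("Study Identifier", s.identifier))
        rows.append(_kv("Study Title", s.title))
        rows.append(_kv("Study Description", s.description))
        rows.append(_kv("Study File Name", s.file_name))
        rows.append(["STUDY DESIGN DESCRIPTORS"])
        rows.append(_kv("Study Design Type", *s.design_descriptors))
        rows.append(["STUDY PUBLICATIONS"])
        rows.append(_kv("Study PubMed ID", *[p.pubmed_id for p in s.publications]))
        rows.append(_kv("Study Publication DOI", *[p.doi for p in s.publications]))
        rows.append(_kv("Study Publication Author List", *[p.authors for p in s.publications]))
        rows.append(_kv("Study Publication Title", *[p.title for p in s.publications]))
        rows.append(_kv("Study Publication Status", *[p.status for p in s.publications]))
        rows.append(["STUDY FACTORS"])
        rows.append(_kv("Study Factor Name", *[fd.name for fd in s.factors]))
        rows.append(_kv("Study Factor Type", *[fd.factor_type for fd in s.factors]))
        rows.append(["STUDY ASSAYS"])
        rows.append(_kv("Study Assay File Name", *[a.file_name for a in s.assays]))
        rows.append(_kv("Study Assay Measurement Type", *[a.measurement_type for a in s.assays]))
        rows.append(_kv("Study Assay Technology Type", *[a.technology_type for a in s.assays]))
        rows.append(["STUDY PROTOCOLS"])
        rows.append(_kv("Study Protocol Name", *[p.name for p in s.protocols]))
        rows.append(_kv("Study Protocol Type", *[p.protocol_type for p in s.protocols]))
        rows.append(_kv("Study Protocol Description", *[p.description for p in s.protocols]))
        rows.append(_kv("Study Protocol Parameters Name",
                        *[_PARAM_SEP.join(p.parameters) for p in s.protocols]))
        rows.append(["STUDY CONTACTS"])
        rows.append(_kv("Study Person Last Name", *[c.last_name for c in s.contacts]))
        rows.append(_kv("Study Person First Name", *[c.first_name for c in s.contacts]))
        rows.append(_kv("Study Person Email", *[c.email for c in s.contacts]))
        rows.append(_kv("Study Person Affiliation", *[c.affiliation for c in s.contacts]))
        rows.append(_kv("Study Person Roles", *[c.roles for c in s.contacts]))

    _write_rows(rows, path, path.name)


# ---------------------------------------------------------------------------
# Dataset read / write
# ---------------------------------------------------------------------------


def read_dataset(directory: Path) -> Dataset:
    """Read a dataset directory into memory.

    Requires exactly one ``i_*.txt`` file.  Every study/assay file named in
    the investigation is parsed; referenced Trait Definition and Derived
    Data Files are loaded when present.  Raw data files (never tabular) are
    recorded as external.  Parse problems are collected on
    ``Dataset.read_issues``, not silently dropped.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise IsaTabError(f"{directory}: not a directory")
    inv_files = sorted(directory.glob("i_*.txt"))
    if len(inv_files) != 1:
        raise IsaTabError(
            f"{directory}: expected exactly one i_*.txt investigation file, "
            f"found {len(inv_files)}"
        )
    inv = parse_investigation(inv_files[0])
    ds = Dataset(root=directory, investigation=inv)
    issues: list[ValidationIssue] = []

    for rec in inv.studies:
        for file_name, cls, target, prefix in (
            [(rec.file_name, StudyTable, ds.studies, "s_")]
            + [(a.file_name, AssayTable, ds.assays, "a_") for a in rec.assays]
        ):
            if not file_name:
                continue
            if not file_name.startswith(prefix):
                issues.append(ValidationIssue(
                    Severity.WARNING, CODE_FILE_NAMING, (file_name, "-", "-"),
                    f"file name does not follow the {prefix}*.txt convention",
                ))
            path = directory / file_name
            if not path.exists():
                continue  # reported by link validation as MISSING_FILE
            table, t_issues = _read_table(path, cls)
            issues.extend(t_issues)
            target.append(table)

    for assay in ds.assays:
        for name in sorted({
            v for v in assay.values_for(HeaderCategory.PARAMETER_VALUE, TDF_PARAMETER) if v
        }):
            path = directory / name
            if name in ds.trait_definitions or not path.exists():
                continue
            try:
                ds.trait_definitions[name] = read_tdf(path)
            except PhenoDataError as exc:
                issues.append(ValidationIssue(
                    Severity.ERROR, CODE_OPAQUE_DATA_FILE, (name, "-", "-"),
                    f"unreadable Trait Definition File: {exc}",
                ))
        for name in sorted({v for v in assay.values_for(HeaderCategory.DERIVED_DATA_FILE) if v}):
            path = directory / name
            if name in ds.data_files or not path.exists():
                continue
            try:
                ds.data_files[name] = read_data_matrix(path)
            except PhenoDataError as exc:
                ds.external_files.add(name)
                issues.append(ValidationIssue(
                    Severity.INFO, CODE_OPAQUE_DATA_FILE, (name, "-", "-"),
                    f"non-default data file dialect, treated as opaque: {exc}",
                ))
        for name in sorted({v for v in assay.values_for(HeaderCategory.RAW_DATA_FILE) if v}):
            if not (directory / name).exists():
                ds.external_files.add(name)

    ds.read_issues = issues
    return ds


def write_dataset(dataset: Dataset, directory: Path,
                  investigation_file: str = DEFAULT_INVESTIGATION_FILE) -> FileLayout:
    """Write a dataset to a directory, deterministically.

    All invariants are checked before any file is written: rectangular
    tables, no tabs/newlines in cells, unique file names, conventional
    ``s_``/``a_`` prefixes.
    """
    directory = Path(directory)
    problems = dataset.investigation.check()
    for t in dataset.iter_tables():
        problems += t.check_shape()
        for row in [t.header_texts()] + t.rows:
            for c in row:
                if "\t" in c or "\n" in c or "\r" in c:
                    problems.append(f"{t.source_file}: tab or newline inside cell {c!r}")
    for t in dataset.studies:
        if not t.source_file.startswith("s_"):
            problems.append(f"study file {t.source_file!r} must be named s_*.txt")
    for t in dataset.assays:
        if not t.source_file.startswith("a_"):
            problems.append(f"assay file {t.source_file!r} must be named a_*.txt")
    if not investigation_file.startswith("i_"):
        problems.append(f"investigation file {investigation_file!r} must be named i_*.txt")
    if problems:
        raise IsaTabError("; ".join(problems))

    directory.mkdir(parents=True, exist_ok=True)
    write_investigation(dataset.investigation, directory / investigation_file)
    for t in dataset.iter_tables():
        _write_table(t, directory)
    for name in sorted(dataset.trait_definitions):
        write_tdf(dataset.trait_definitions[name], directory / name)
    for name in sorted(dataset.data_files):
        write_data_matrix(dataset.data_files[name], directory / name)
    return FileLayout(
        investigation=investigation_file,
        studies=[t.source_file for t in dataset.studies],
        assays=[t.source_file for t in dataset.assays],
        trait_definition_files=sorted(dataset.trait_definitions),
        data_files=sorted(dataset.data_files),
    )
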