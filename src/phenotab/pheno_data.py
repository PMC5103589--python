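"""Trait Definition Files, observation matrices and their linkage.

Observed variables — phenotypic traits and environmental covariates alike —
are defined once per dataset in a Trait Definition File (TDF): a
tab-delimited table with one row per variable and the mandatory columns
Variable ID, Trait, Method, Scale.  Trait/Method/Scale follow the
trait-dictionary triplet convention of the Crop Ontology platform; each may
carry ontology annotations in trailing Term Source REF / Term Accession
Number columns.

Observations live in Derived Data Files: plain tab-separated matrices whose
first column holds values of a data-node column of the Assay file (Assay
Name by default) and whose remaining column names are Variable IDs from the
linked TDF.  :func:`link_observations` joins the two into a long table of
(row id, variable, value) records; :func:`aggregate` concatenates such
records across studies or datasets, keyed by grouping Characteristics such
as Study start or Geographic location, which is how multi-year and
multi-site series are combined downstream.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import (
    AssayTable,
    Dataset,
    HeaderCategory,
    OntologyAnnotation,
    StudyTable,
    Table,
    format_header,
)
from .validator import (
    CODE_MISSING_GROUP_KEY,
    CODE_ORPHAN_DATA_ROW,
    CODE_TDF_CONFLICT,
    CODE_UNKNOWN_VARIABLE_ID,
    Severity,
    ValidationIssue,
)


class PhenoDataError(ValueError):
    """Malformed TDF or data matrix."""


#: Cell values treated as missing observations.
MISSING_TOKENS = frozenset({"", "NA"})

TDF_COLUMNS = ("Variable ID", "Trait", "Method", "Scale")
VARIABLE_CLASS_COLUMN = "Comment[Variable class]"


@dataclass(frozen=True)
class TraitDefinition:
    """One observed variable: id plus the Trait/Method/Scale triplet.

    ``variable_class`` distinguishes phenotypic from environmental variables;
    it is carried by an optional ``Comment[Variable class]`` column and
    defaults to "unspecified" when the column is absent.
    """

    variable_id: str
    trait: OntologyAnnotation
    method: OntologyAnnotation
    scale: OntologyAnnotation
    variable_class: str = "unspecified"

    def triplet(self) -> tuple[str, str, str]:
        return (self.trait.term_label, self.method.term_label, self.scale.term_label)


def read_tdf(path: Path) -> list[TraitDefinition]:
    """Read a Trait Definition File.

    Raises :class:`PhenoDataError` on a missing mandatory column, duplicate
    Variable ID, or an empty file.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    rows = [r for r in rows if any(c.strip() for c in r)]
    if not rows:
        raise PhenoDataError(f"{path.name}: empty Trait Definition File")
    header = [c.strip() for c in rows[0]]
    for col in TDF_COLUMNS:
        if col not in header:
            raise PhenoDataError(f"{path.name}: missing mandatory column {col!r}")
    idx = {c: header.index(c) for c in TDF_COLUMNS}
    class_idx = header.index(VARIABLE_CLASS_COLUMN) if VARIABLE_CLASS_COLUMN in header else None

    def annotation(row: list[str], col: str) -> OntologyAnnotation:
        i = idx[col]
        label = row[i] if i < len(row) else ""
        source = accession = ""
        # Term Source REF / Term Accession Number immediately after the column.
        if i + 2 < len(header) and header[i + 1] == "Term Source REF" \
                and header[i + 2] == "Term Accession Number":
            source = row[i + 1] if i + 1 < len(row) else ""
            accession = row[i + 2] if i + 2 < len(row) else ""
        return OntologyAnnotation(label, source, accession)

    defs: list[TraitDefinition] = []
    seen: set[str] = set()
    for row in rows[1:]:
        vid = row[idx["Variable ID"]].strip() if idx["Variable ID"] < len(row) else ""
        if not vid:
            raise PhenoDataError(f"{path.name}: empty Variable ID")
        if vid in seen:
            raise PhenoDataError(f"{path.name}: duplicate Variable ID {vid!r}")
        seen.add(vid)
        vclass = "unspecified"
        if class_idx is not None and class_idx < len(row) and row[class_idx].strip():
            vclass = row[class_idx].strip()
        defs.append(
            TraitDefinition(
                variable_id=vid,
                trait=annotation(row, "Trait"),
                method=annotation(row, "Method"),
                scale=annotation(row, "Scale"),
                variable_class=vclass,
            )
        )
    return defs


def write_tdf(defs: Sequence[TraitDefinition], path: Path) -> None:
    """Write a TDF with annotation columns after Trait/Method/Scale and a
    trailing Comment[Variable class] column."""
    header = ["Variable ID"]
    for col in ("Trait", "Method", "Scale"):
        header += [col, "Term Source REF", "Term Accession Number"]
    header.append(VARIABLE_CLASS_COLUMN)
    lines = ["\t".join(header)]
    for d in defs:
        row = [d.variable_id]
        for ann in (d.trait, d.method, d.scale):
            row += [ann.term_label, ann.source_ref, ann.accession]
        row.append("" if d.variable_class == "unspecified" else d.variable_class)
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Data matrices
# ---------------------------------------------------------------------------


@dataclass
class DataMatrix:
    """A sample-by-variable observation matrix.

    ``link_node`` is the data-node column name used for row identity (Assay
    Name in the default dialect; any other data node — Sample Name, Source
    Name, Extract Name — under the extension rule).  Cells are kept as text;
    :meth:`to_dataframe` yields a numeric view where cells parse as floats.
    """

    source_file: str
    link_node: str = "Assay Name"
    row_ids: list[str] = field(default_factory=list)
    variable_ids: list[str] = field(default_factory=list)
    values: list[list[str]] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.row_ids), len(self.variable_ids))

    def n_missing(self) -> int:
        return sum(1 for row in self.values for c in row if c in MISSING_TOKENS)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.row_ids, columns=self.variable_ids)
        df.index.name = self.link_node
        df = df.replace(list(MISSING_TOKENS), pd.NA)

        def maybe_numeric(col: pd.Series) -> pd.Series:
            try:
                return pd.to_numeric(col)
            except (ValueError, TypeError):
                return col

        return df.apply(maybe_numeric)


def read_data_matrix(path: Path, expected_link_node: Optional[str] = None) -> DataMatrix:
    """Read a tab-separated observation matrix.

    The link node is taken from the first header cell; ``expected_link_node``
    is checked when given.  Raises on ragged rows, duplicate row ids, or an
    empty header/body.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    rows = [r for r in rows if any(c.strip() for c in r)]
    if not rows or not rows[0] or not rows[0][0].strip():
        raise PhenoDataError(f"{path.name}: empty or headerless data matrix")
    if len(rows) < 2:
        raise PhenoDataError(f"{path.name}: data matrix has no data rows")
    header = rows[0]
    link_node = header[0].strip()
    if expected_link_node is not None and link_node != expected_link_node:
        raise PhenoDataError(
            f"{path.name}: link node {link_node!r}, expected {expected_link_node!r}"
        )
    matrix = DataMatrix(source_file=path.name, link_node=link_node,
                        variable_ids=[c.strip() for c in header[1:]])
    seen: set[str] = set()
    for rno, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise PhenoDataError(
                f"{path.name}: ragged row {rno} ({len(row)} cells, expected {len(header)})"
            )
        rid = row[0].strip()
        if rid in seen:
            raise PhenoDataError(f"{path.name}: duplicate row id {rid!r}")
        seen.add(rid)
        matrix.row_ids.append(rid)
        matrix.values.append(list(row[1:]))
    return matrix


def write_data_matrix(matrix: DataMatrix, path: Path) -> None:
    lines = ["\t".join([matrix.link_node] + matrix.variable_ids)]
    for rid, row in zip(matrix.row_ids, matrix.values):
        lines.append("\t".join([rid] + row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Linking and aggregation
# ---------------------------------------------------------------------------

LONG_COLUMNS = ("dataset", "study", "row_id", "variable_id", "variable_class", "value")


@dataclass
class LongObservations:
    """Long-format observation records plus the issues met while linking."""

    records: pd.DataFrame
    issues: list[ValidationIssue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)


def _empty_long(extra: Sequence[str] = ()) -> pd.DataFrame:
    cols = list(LONG_COLUMNS[:2]) + list(extra) + list(LONG_COLUMNS[2:])
    return pd.DataFrame(columns=cols)


def link_observations(
    assay: AssayTable,
    tdf: Sequence[TraitDefinition],
    matrix: DataMatrix,
    *,
    study: Optional[StudyTable] = None,
    dataset_id: str = "",
    study_file: str = "",
    group_values: Optional[dict[str, dict[str, str]]] = None,
) -> LongObservations:
    """Join a matrix to its assay rows and TDF definitions.

    Records are produced only for (row id, variable) pairs where the row id
    resolves against the matrix's link-node column (searched in the assay,
    then the study for extended nodes) and the variable is defined in the
    TDF; unresolved entries are reported as issues, never silently dropped.
    Missing cells ("" or NA) yield no record.
    """
    link_cols = _node_column(assay, matrix.link_node)
    if link_cols is None and study is not None:
        link_cols = _node_column(study, matrix.link_node)
    if link_cols is None:
        raise PhenoDataError(
            f"{matrix.source_file}: link node column {matrix.link_node!r} "
            f"absent from assay {assay.source_file!r}"
        )
    known_ids = set(link_cols)
    defined = {d.variable_id: d for d in tdf}

    issues: list[ValidationIssue] = []
    for vid in matrix.variable_ids:
        if vid not in defined:
            issues.append(
                ValidationIssue(
                    Severity.ERROR, CODE_UNKNOWN_VARIABLE_ID,
                    (matrix.source_file, "-", vid),
                    f"matrix column {vid!r} not defined in the Trait Definition File",
                )
            )
    rows_out: list[dict] = []
    for rno, (rid, row) in enumerate(zip(matrix.row_ids, matrix.values), start=2):
        if rid not in known_ids:
            issues.append(
                ValidationIssue(
                    Severity.WARNING, CODE_ORPHAN_DATA_ROW,
                    (matrix.source_file, rno, matrix.link_node),
                    f"row id {rid!r} absent from the {matrix.link_node!r} column",
                )
            )
            continue
        for vid, cell in zip(matrix.variable_ids, row):
            if vid not in defined or cell in MISSING_TOKENS:
                continue
            rec = {
                "dataset": dataset_id,
                "study": study_file,
                "row_id": rid,
                "variable_id": vid,
                "variable_class": defined[vid].variable_class,
                "value": cell,
            }
            if group_values:
                for key, per_row in group_values.items():
                    rec[key] = per_row.get(rid, "unknown")
            rows_out.append(rec)
    extra = list(group_values) if group_values else []
    df = pd.DataFrame(rows_out) if rows_out else _empty_long(extra)
    if rows_out and extra:
        df = df[list(LONG_COLUMNS[:2]) + extra + list(LONG_COLUMNS[2:])]
    return LongObservations(records=df, issues=issues)


def _node_column(table: Table, node_name: str) -> Optional[list[str]]:
    for i, h in enumerate(table.headers):
        if format_header(h) == node_name:
            return table.column_values(i)
    return None


def _assay_links(dataset: Dataset):
    """Yield (study record, assay table, tdf, matrix) for each linked pair."""
    from .phenotyping_config import TDF_PARAMETER

    for assay in dataset.assays:
        rec = dataset.study_record_for_assay(assay.source_file)
        tdf_names = {
            v
            for v in assay.values_for(HeaderCategory.PARAMETER_VALUE, TDF_PARAMETER)
            if v
        }
        tdf: list[TraitDefinition] = []
        for name in sorted(tdf_names):
            tdf.extend(dataset.trait_definitions.get(name, []))
        data_names = {
            v for v in assay.values_for(HeaderCategory.DERIVED_DATA_FILE) if v
        }
        for name in sorted(data_names):
            matrix = dataset.data_files.get(name)
            if matrix is not None:
                yield rec, assay, tdf, matrix


def aggregate(
    datasets: Sequence[Dataset],
    by: Sequence[str] = (),
    *,
    dataset_ids: Optional[Sequence[str]] = None,
) -> LongObservations:
    """Concatenate long observations across datasets/studies.

    ``by`` lists grouping Characteristics qualifiers (e.g. "Study start",
    "Geographic location"); each record carries the value resolved from its
    source row's study.  A study missing a grouping characteristic yields a
    warning and the group key "unknown".  The same variable_id defined with
    differing Trait/Method/Scale across TDFs is reported as a conflict.
    """
    frames: list[pd.DataFrame] = []
    issues: list[ValidationIssue] = []
    triplets: dict[str, tuple] = {}
    ids = list(dataset_ids) if dataset_ids is not None else [
        (d.investigation.identifier or f"dataset{i}") for i, d in enumerate(datasets, 1)
    ]
    for ds_id, ds in zip(ids, datasets):
        for name, defs in sorted(ds.trait_definitions.items()):
            for d in defs:
                prev = triplets.get(d.variable_id)
                if prev is not None and prev != d.triplet():
                    issues.append(
                        ValidationIssue(
                            Severity.WARNING, CODE_TDF_CONFLICT, (name, "-", d.variable_id),
                            f"variable {d.variable_id!r} has differing "
                            f"Trait/Method/Scale across Trait Definition Files",
                        )
                    )
                else:
                    triplets[d.variable_id] = d.triplet()
        for rec, assay, tdf, matrix in _assay_links(ds):
            study = ds.study_table(rec.file_name) if rec else None
            group_values: dict[str, dict[str, str]] = {}
            for q in by:
                per_row = _resolve_grouping(study, assay, matrix.link_node, q)
                if per_row is None:
                    issues.append(
                        ValidationIssue(
                            Severity.WARNING, CODE_MISSING_GROUP_KEY,
                            (study.source_file if study else assay.source_file, "-", q),
                            f"grouping characteristic {q!r} not found; group set to 'unknown'",
                        )
                    )
                    per_row = {}
                group_values[q] = per_row
            linked = link_observations(
                assay, tdf, matrix,
                study=study,
                dataset_id=ds_id,
                study_file=rec.file_name if rec else "",
                group_values=group_values if by else None,
            )
            frames.append(linked.records)
            issues.extend(linked.issues)
    if frames:
        records = pd.concat(frames, ignore_index=True)
    else:
        records = _empty_long(list(by))
    return LongObservations(records=records, issues=issues)


def _resolve_grouping(
    study: Optional[StudyTable],
    assay: AssayTable,
    link_node: str,
    qualifier: str,
) -> Optional[dict[str, str]]:
    """Map each matrix row id to the study's value of a grouping
    characteristic, via the assay's Sample Name chain."""
    if study is None:
        return None
    char_cols = study.find_columns(HeaderCategory.CHARACTERISTICS, qualifier)
    if not char_cols:
        return None
    char_vals = study.column_values(char_cols[0])
    sample_cols = study.find_columns(HeaderCategory.SAMPLE_NAME)
    if not sample_cols:
        return None
    sample_to_value = dict(zip(study.column_values(sample_cols[0]), char_vals))

    node_vals = _node_column(assay, link_node)
    assay_samples = _node_column(assay, "Sample Name")
    out: dict[str, str] = {}
    if node_vals is not None and assay_samples is not None:
        for rid, sample in zip(node_vals, assay_samples):
            out[rid] = sample_to_value.get(sample, "unknown")
    elif link_node == "Sample Name":
        out = sample_to_value
    return out


def export_long(obs: LongObservations, path: Path) -> None:
    """Tab-separated long-table export with a fixed column order."""
    obs.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------


@dataclass
class DatasetSummary:
    n_studies: int
    sources_per_study: dict[str, int]
    n_samples: int
    n_assays: int
    n_variables: int
    n_phenotypic: int
    n_environmental: int
    n_data_files: int
    matrix_shapes: dict[str, tuple[int, int]]

    def to_dict(self) -> dict:
        return {
            "studies": self.n_studies,
            "sources_per_study": dict(self.sources_per_study),
            "samples": self.n_samples,
            "assays": self.n_assays,
            "variables": self.n_variables,
            "phenotypic_variables": self.n_phenotypic,
            "environmental_variables": self.n_environmental,
            "data_files": self.n_data_files,
            "matrix_shapes": {k: list(v) for k, v in self.matrix_shapes.items()},
        }


def summarize(dataset: Dataset) -> DatasetSummary:
    """Structural counts: studies, distinct sources, samples, variables."""
    sources: dict[str, int] = {}
    n_samples = 0
    for s in dataset.studies:
        src_cols = s.find_columns(HeaderCategory.SOURCE_NAME)
        sources[s.source_file] = (
            len({v for v in s.column_values(src_cols[0]) if v}) if src_cols else 0
        )
        smp_cols = s.find_columns(HeaderCategory.SAMPLE_NAME)
        if smp_cols:
            n_samples += len({v for v in s.column_values(smp_cols[0]) if v})
    all_defs = [d for defs in dataset.trait_definitions.values() for d in defs]
    return DatasetSummary(
        n_studies=len(dataset.studies),
        sources_per_study=sources,
        n_samples=n_samples,
        n_assays=len(dataset.assays),
        n_variables=len(all_defs),
        n_phenotypic=sum(1 for d in all_defs if d.variable_class == "phenotypic"),
        n_environmental=sum(1 for d in all_defs if d.variable_class == "environmental"),
        n_data_files=len(dataset.data_files),
        matrix_shapes={k: m.shape for k, m in sorted(dataset.data_files.items())},
    )
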