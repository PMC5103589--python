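"""Structural validation, link integrity and minimum-information compliance.

Three layers of checking, mirroring how phenotyping archives break in
practice:

* *table level* — a Study/Assay file against its configuration: required
  columns present and in order, no duplicated qualified headers, cells of
  required columns filled, Protocol REF values declared in the Investigation;
* *link level* — cross-file integrity: assay samples resolve in their study,
  matrix columns resolve in the Trait Definition File, matrix rows resolve
  in the linking data-node column, referenced files exist;
* *compliance level* — coverage of the essential minimum-information
  attributes, per checklist section, with an overall score in [0, 1].

Empty cells in required columns are warnings, not errors: really published
archives ship with incomplete-but-declared columns, and a column's presence
is what downstream consumers depend on.  Missing required *columns* are
errors.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Sequence, Union

from .model import (
    Dataset,
    HeaderCategory,
    Table,
    format_header,
)
from .phenotyping_config import (
    AssayConfig,
    EssentialAttribute,
    MIAPPE_SECTIONS,
    StudyConfig,
    TDF_PARAMETER,
    builtin_config,
    essential_for,
    phenotyping_assay_config,
)

if TYPE_CHECKING:  # pragma: no cover
    from .pheno_data import TraitDefinition


class Severity(enum.Enum):
    ERROR = "error"
    WARNING = "warning"
    INFO = "info"


# Documented issue codes.
CODE_MISSING_COLUMN = "MISSING_COLUMN"
CODE_EMPTY_ESSENTIAL_CELL = "EMPTY_ESSENTIAL_CELL"
CODE_UNDECLARED_PROTOCOL = "UNDECLARED_PROTOCOL"
CODE_BROKEN_SAMPLE_LINK = "BROKEN_SAMPLE_LINK"
CODE_UNKNOWN_VARIABLE_ID = "UNKNOWN_VARIABLE_ID"
CODE_ORPHAN_DATA_ROW = "ORPHAN_DATA_ROW"
CODE_DUPLICATE_HEADER = "DUPLICATE_HEADER"
CODE_RAGGED_ROW = "RAGGED_ROW"
CODE_MISSING_FILE = "MISSING_FILE"
CODE_EXTRA_COLUMN = "EXTRA_COLUMN"
CODE_COLUMN_ORDER = "COLUMN_ORDER"
CODE_NODE_POSITION = "NODE_POSITION"
CODE_PROTOCOL_VALUE_MISMATCH = "PROTOCOL_VALUE_MISMATCH"
CODE_DUPLICATE_FILE_NAME = "DUPLICATE_FILE_NAME"
CODE_TDF_CONFLICT = "TDF_CONFLICT"
CODE_MISSING_GROUP_KEY = "MISSING_GROUP_KEY"
CODE_TRAILING_BLANK = "TRAILING_BLANK"
CODE_FILE_NAMING = "FILE_NAMING"
CODE_OPAQUE_DATA_FILE = "OPAQUE_DATA_FILE"
CODE_MISPLACED_QUALIFIER = "MISPLACED_QUALIFIER"

ALL_CODES = (
    CODE_MISSING_COLUMN, CODE_EMPTY_ESSENTIAL_CELL, CODE_UNDECLARED_PROTOCOL,
    CODE_BROKEN_SAMPLE_LINK, CODE_UNKNOWN_VARIABLE_ID, CODE_ORPHAN_DATA_ROW,
    CODE_DUPLICATE_HEADER, CODE_RAGGED_ROW, CODE_MISSING_FILE,
    CODE_EXTRA_COLUMN, CODE_COLUMN_ORDER, CODE_NODE_POSITION,
    CODE_PROTOCOL_VALUE_MISMATCH, CODE_DUPLICATE_FILE_NAME, CODE_TDF_CONFLICT,
    CODE_MISSING_GROUP_KEY, CODE_TRAILING_BLANK, CODE_FILE_NAMING,
    CODE_OPAQUE_DATA_FILE, CODE_MISPLACED_QUALIFIER,
)

#: Location: (file, row, column).  Rows are 1-based with the header row as
#: row 1; "-" when the issue is not row-addressable.  Columns are addressed
#: by canonical header text (plus occurrence index in the message when a
#: header legitimately repeats).
Location = tuple[str, Union[int, str], str]


@dataclass(frozen=True)
class ValidationIssue:
    severity: Severity
    code: str
    location: Location
    message: str

    def __post_init__(self) -> None:
        if self.code not in ALL_CODES:
            raise ValueError(f"undocumented issue code {self.code!r}")

    def sort_key(self) -> tuple:
        file, row, col = self.location
        row_key = row if isinstance(row, int) else -1
        return (file, row_key, col, self.code, self.message)

    def to_dict(self) -> dict:
        file, row, col = self.location
        return {
            "severity": self.severity.value,
            "code": self.code,
            "file": file,
            "row": row,
            "column": col,
            "message": self.message,
        }

    def format(self) -> str:
        file, row, col = self.location
        return f"{self.severity.value.upper():7s} {self.code} {file}:{row}:{col} {self.message}"


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    def sorted(self) -> "ValidationReport":
        return ValidationReport(sorted(self.issues, key=ValidationIssue.sort_key))

    def by_severity(self, severity: Severity) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity is severity]

    @property
    def errors(self) -> list[ValidationIssue]:
        return self.by_severity(Severity.ERROR)

    @property
    def warnings(self) -> list[ValidationIssue]:
        return self.by_severity(Severity.WARNING)

    def codes(self) -> set[str]:
        return {i.code for i in self.issues}

    def promote(self, code: str) -> "ValidationReport":
        """Return a report with warnings of the given code raised to errors."""
        out = []
        for i in self.issues:
            if i.code == code and i.severity is Severity.WARNING:
                i = ValidationIssue(Severity.ERROR, i.code, i.location, i.message)
            out.append(i)
        return ValidationReport(out)

    def to_text(self) -> str:
        if not self.issues:
            return "no issues\n"
        return "\n".join(i.format() for i in self.issues) + "\n"

    def to_dict(self) -> dict:
        return {"issues": [i.to_dict() for i in self.issues]}


# ---------------------------------------------------------------------------
# Table-level validation
# ---------------------------------------------------------------------------


def validate_table(
    table: Table,
    config: StudyConfig,
    declared_protocols: Optional[set[str]] = None,
) -> list[ValidationIssue]:
    """Validate one Study/Assay table against a configuration plan.

    Returns all findings; never raises.  Missing required columns are
    errors, empty cells in required columns are warnings, extra well-formed
    columns are info only.
    """
    issues: list[ValidationIssue] = []
    f = table.source_file

    # Rectangularity (header row = row 1, first data row = row 2).
    for rno, row in enumerate(table.rows, start=2):
        if len(row) != table.n_cols:
            issues.append(ValidationIssue(
                Severity.ERROR, CODE_RAGGED_ROW, (f, rno, "-"),
                f"row has {len(row)} cells, expected {table.n_cols}",
            ))

    # Duplicate qualified headers / data nodes.
    counts: dict[str, int] = {}
    for h in table.headers:
        if h.category in (HeaderCategory.UNIT, HeaderCategory.TERM_SOURCE_REF,
                          HeaderCategory.TERM_ACCESSION_NUMBER,
                          HeaderCategory.PROTOCOL_REF):
            continue  # these legitimately repeat
        text = format_header(h)
        counts[text] = counts.get(text, 0) + 1
    for text, n in counts.items():
        if n > 1:
            issues.append(ValidationIssue(
                Severity.ERROR, CODE_DUPLICATE_HEADER, (f, 1, text),
                f"header {text!r} occurs {n} times",
            ))

    # Node positions.
    if table.headers:
        if config.table_kind == "study":
            if table.headers[0].category is not HeaderCategory.SOURCE_NAME:
                issues.append(ValidationIssue(
                    Severity.ERROR, CODE_NODE_POSITION, (f, 1, format_header(table.headers[0])),
                    "a Study table must begin with Source Name",
                ))
            if table.headers[-1].category is not HeaderCategory.SAMPLE_NAME:
                issues.append(ValidationIssue(
                    Severity.ERROR, CODE_NODE_POSITION, (f, 1, format_header(table.headers[-1])),
                    "a Study table must end with Sample Name",
                ))
        elif config.table_kind == "assay":
            if table.headers[0].category is not HeaderCategory.SAMPLE_NAME:
                issues.append(ValidationIssue(
                    Severity.ERROR, CODE_NODE_POSITION, (f, 1, format_header(table.headers[0])),
                    "an Assay table must begin with Sample Name",
                ))

    # Unit / term columns must follow a property column they qualify.
    _check_qualifier_placement(table, issues)

    # Plan matching: the plan's materialized headers must appear as an
    # in-order subsequence of the table headers.  A planned Protocol REF
    # column matches only a Protocol REF column carrying its expected
    # protocol name (or no values at all), so a deleted block is reported
    # against the right protocol.
    texts = table.header_texts()
    matched: list[Optional[int]] = []  # plan position -> column index
    used: set[int] = set()
    cursor = 0
    plan = config.materialized_headers()
    blocks = dict_block_context(config)

    def acceptable(i: int, header: "FieldHeader", entry) -> bool:
        if texts[i] != format_header(header):
            return False
        if header.category is HeaderCategory.PROTOCOL_REF and entry.expected:
            vals = [r[i] for r in table.rows if i < len(r) and r[i].strip()]
            return not vals or vals[0] == entry.expected
        return True

    for pidx, (header, entry) in enumerate(plan):
        want = format_header(header)
        col = None
        for i in range(cursor, len(texts)):
            if i not in used and acceptable(i, header, entry):
                col = i
                break
        if col is not None:
            used.add(col)
            cursor = col + 1
        else:
            # out-of-order occurrence?
            for i in range(len(texts)):
                if i not in used and acceptable(i, header, entry):
                    col = i
                    break
            if col is not None:
                used.add(col)
                issues.append(ValidationIssue(
                    Severity.WARNING, CODE_COLUMN_ORDER, (f, 1, want),
                    f"column {want!r} present but out of the configured order",
                ))
            elif entry.required and header.category is not HeaderCategory.UNIT:
                ctx = blocks.get(pidx, "")
                issues.append(ValidationIssue(
                    Severity.ERROR, CODE_MISSING_COLUMN, (f, 1, want),
                    f"required column {want!r} missing" + (f" (protocol {ctx!r})" if ctx else ""),
                ))
        matched.append(col)

    # Cell-level checks on matched required columns.
    for (header, entry), col in zip(plan, matched):
        if col is None:
            continue
        text = format_header(header)
        is_protocol = header.category is HeaderCategory.PROTOCOL_REF
        for rno, row in enumerate(table.rows, start=2):
            if col >= len(row):
                continue  # already reported as ragged
            cell = row[col]
            if not cell.strip():
                if entry.required and header.category is not HeaderCategory.UNIT \
                        and header.category is not HeaderCategory.RAW_DATA_FILE:
                    issues.append(ValidationIssue(
                        Severity.WARNING, CODE_EMPTY_ESSENTIAL_CELL, (f, rno, text),
                        f"empty cell in required column {text!r}",
                    ))
            elif is_protocol and entry.expected and cell != entry.expected:
                issues.append(ValidationIssue(
                    Severity.WARNING, CODE_PROTOCOL_VALUE_MISMATCH, (f, rno, text),
                    f"Protocol REF value {cell!r}, configuration expects {entry.expected!r}",
                ))

    # Undeclared protocols.
    if declared_protocols is not None:
        seen: set[tuple[int, str]] = set()
        for col in table.find_columns(HeaderCategory.PROTOCOL_REF):
            for rno, row in enumerate(table.rows, start=2):
                if col < len(row) and row[col].strip() and row[col] not in declared_protocols:
                    if (col, row[col]) in seen:
                        continue
                    seen.add((col, row[col]))
                    issues.append(ValidationIssue(
                        Severity.WARNING, CODE_UNDECLARED_PROTOCOL, (f, rno, "Protocol REF"),
                        f"protocol {row[col]!r} not declared in the investigation",
                    ))

    # Extra well-formed columns -> info.
    for i, t in enumerate(texts):
        if i in used:
            continue
        h = table.headers[i]
        if h.category in (HeaderCategory.UNIT, HeaderCategory.TERM_SOURCE_REF,
                          HeaderCategory.TERM_ACCESSION_NUMBER):
            continue  # qualifies a neighbouring extra column
        issues.append(ValidationIssue(
            Severity.INFO, CODE_EXTRA_COLUMN, (f, 1, t),
            f"column {t!r} not in the configuration plan (allowed extension)",
        ))
    return issues


def _check_qualifier_placement(table: Table, issues: list[ValidationIssue]) -> None:
    """Unit follows a property column; Term Source REF follows a property or
    Unit column; Term Accession Number follows Term Source REF."""
    f = table.source_file
    property_cats = (HeaderCategory.CHARACTERISTICS, HeaderCategory.FACTOR_VALUE,
                     HeaderCategory.PARAMETER_VALUE)
    for i, h in enumerate(table.headers):
        prev = table.headers[i - 1].category if i > 0 else None
        text = format_header(h)
        if h.category is HeaderCategory.UNIT and prev not in property_cats:
            issues.append(ValidationIssue(
                Severity.ERROR, CODE_MISPLACED_QUALIFIER, (f, 1, text),
                "Unit column does not follow a property column",
            ))
        elif h.category is HeaderCategory.TERM_SOURCE_REF \
                and prev not in property_cats + (HeaderCategory.UNIT,):
            issues.append(ValidationIssue(
                Severity.ERROR, CODE_MISPLACED_QUALIFIER, (f, 1, text),
                "Term Source REF column does not follow a property or Unit column",
            ))
        elif h.category is HeaderCategory.TERM_ACCESSION_NUMBER \
                and prev is not HeaderCategory.TERM_SOURCE_REF:
            issues.append(ValidationIssue(
                Severity.ERROR, CODE_MISPLACED_QUALIFIER, (f, 1, text),
                "Term Accession Number column does not follow Term Source REF",
            ))


def dict_block_context(config: StudyConfig) -> dict[int, str]:
    """Map materialized-plan positions to their protocol block name."""
    ctx: dict[int, str] = {}
    current = ""
    for i, (header, entry) in enumerate(config.materialized_headers()):
        if header.category is HeaderCategory.PROTOCOL_REF:
            current = entry.expected
            ctx[i] = current
        elif header.category in (HeaderCategory.PARAMETER_VALUE, HeaderCategory.UNIT) and current:
            ctx[i] = current
        elif header.category not in (HeaderCategory.PARAMETER_VALUE, HeaderCategory.UNIT):
            current = ""
    return ctx


# ---------------------------------------------------------------------------
# Link-level validation
# ---------------------------------------------------------------------------


def validate_links(dataset: Dataset) -> list[ValidationIssue]:
    """Cross-file integrity: sample links, variable ids, row ids, files."""
    issues: list[ValidationIssue] = []
    for assay in dataset.assays:
        f = assay.source_file
        rec = dataset.study_record_for_assay(f)
        study = dataset.study_table(rec.file_name) if rec else None

        # Sample links.
        study_samples: set[str] = set()
        if study is not None:
            for c in study.find_columns(HeaderCategory.SAMPLE_NAME):
                study_samples.update(v for v in study.column_values(c) if v)
        for c in assay.find_columns(HeaderCategory.SAMPLE_NAME):
            for rno, row in enumerate(assay.rows, start=2):
                if c < len(row) and row[c] and row[c] not in study_samples:
                    issues.append(ValidationIssue(
                        Severity.ERROR, CODE_BROKEN_SAMPLE_LINK, (f, rno, "Sample Name"),
                        f"sample {row[c]!r} absent from the study's Sample Name column",
                    ))

        # Referenced files.
        tdf_names = sorted({
            v for v in assay.values_for(HeaderCategory.PARAMETER_VALUE, TDF_PARAMETER) if v
        })
        for name in tdf_names:
            if name not in dataset.trait_definitions and name not in dataset.external_files:
                issues.append(ValidationIssue(
                    Severity.ERROR, CODE_MISSING_FILE, (f, "-", f"Parameter Value[{TDF_PARAMETER}]"),
                    f"Trait Definition File {name!r} referenced but absent",
                ))
        data_names = sorted({v for v in assay.values_for(HeaderCategory.DERIVED_DATA_FILE) if v})
        for name in data_names:
            if name not in dataset.data_files and name not in dataset.external_files:
                issues.append(ValidationIssue(
                    Severity.ERROR, CODE_MISSING_FILE, (f, "-", "Derived Data File"),
                    f"Derived Data File {name!r} referenced but absent",
                ))
        for name in sorted({v for v in assay.values_for(HeaderCategory.RAW_DATA_FILE) if v}):
            if name not in dataset.external_files and dataset.root is not None \
                    and not (dataset.root / name).exists():
                issues.append(ValidationIssue(
                    Severity.WARNING, CODE_MISSING_FILE, (f, "-", "Raw Data File"),
                    f"Raw Data File {name!r} referenced but absent",
                ))

        # Matrix columns and rows.  Column ids can only be checked when every
        # referenced TDF was actually loaded; a missing or opaque TDF is
        # already reported and must not cascade into spurious unknown-id
        # errors for every column.
        defined: set[str] = set()
        tdfs_loaded = bool(tdf_names) and all(
            name in dataset.trait_definitions for name in tdf_names
        )
        for name in tdf_names:
            defined.update(d.variable_id for d in dataset.trait_definitions.get(name, []))
        for name in data_names:
            matrix = dataset.data_files.get(name)
            if matrix is None:
                continue
            if tdfs_loaded:
                for vid in matrix.variable_ids:
                    if vid not in defined:
                        issues.append(ValidationIssue(
                            Severity.ERROR, CODE_UNKNOWN_VARIABLE_ID, (name, 1, vid),
                            f"matrix column {vid!r} not defined in the Trait Definition File",
                        ))
            link_vals = _node_values(assay, matrix.link_node)
            if link_vals is None and study is not None:
                link_vals = _node_values(study, matrix.link_node)
            if link_vals is None:
                issues.append(ValidationIssue(
                    Severity.ERROR, CODE_MISSING_COLUMN, (f, 1, matrix.link_node),
                    f"link node column {matrix.link_node!r} absent from the assay",
                ))
                continue
            known = set(link_vals)
            for rno, rid in enumerate(matrix.row_ids, start=2):
                if rid not in known:
                    issues.append(ValidationIssue(
                        Severity.WARNING, CODE_ORPHAN_DATA_ROW, (name, rno, matrix.link_node),
                        f"row id {rid!r} absent from the {matrix.link_node!r} column",
                    ))
    return issues


def _node_values(table: Table, node_name: str) -> Optional[list[str]]:
    for i, h in enumerate(table.headers):
        if format_header(h) == node_name:
            return [v for v in table.column_values(i) if v]
    return None


# ---------------------------------------------------------------------------
# Compliance
# ---------------------------------------------------------------------------


@dataclass
class SectionCompliance:
    section: str
    applicable: list[str] = field(default_factory=list)
    present: list[str] = field(default_factory=list)
    missing: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "applicable": list(self.applicable),
            "present": list(self.present),
            "missing": list(self.missing),
        }


@dataclass
class ComplianceReport:
    """Essential-attribute coverage per checklist section.

    ``score`` is the unweighted fraction of applicable essential attributes
    with at least one non-empty value in their mapped location.
    """

    kind: str
    sections: dict[str, SectionCompliance] = field(default_factory=dict)
    extended_present: list[str] = field(default_factory=list)

    @property
    def n_applicable(self) -> int:
        return sum(len(s.applicable) for s in self.sections.values())

    @property
    def n_present(self) -> int:
        return sum(len(s.present) for s in self.sections.values())

    @property
    def score(self) -> float:
        return self.n_present / self.n_applicable if self.n_applicable else 1.0

    def missing(self) -> list[str]:
        return [a for s in self.sections.values() for a in s.missing]

    def to_dict(self) -> dict:
        return {
            "configuration": self.kind,
            "score": self.score,
            "applicable": self.n_applicable,
            "present": self.n_present,
            "sections": {name: s.to_dict() for name, s in self.sections.items()},
            "extended_present": list(self.extended_present),
        }

    def to_text(self) -> str:
        lines = [f"compliance ({self.kind}): {self.n_present}/{self.n_applicable} "
                 f"essential attributes present, score {self.score:.3f}"]
        for name, s in self.sections.items():
            if not s.applicable:
                continue
            flag = "ok " if not s.missing else "MISS"
            lines.append(f"  [{flag}] {name}: {len(s.present)}/{len(s.applicable)}")
            for a in s.missing:
                lines.append(f"         missing: {a}")
        return "\n".join(lines) + "\n"


def _attribute_present(dataset: Dataset, attr: EssentialAttribute) -> bool:
    if attr.locator == "investigation":
        return bool(getattr(dataset.investigation, attr.target, "").strip())
    if attr.locator == "study_characteristic":
        return any(
            any(v.strip() for v in t.values_for(HeaderCategory.CHARACTERISTICS, attr.target))
            for t in dataset.studies
        )
    if attr.locator == "assay_characteristic":
        return any(
            any(v.strip() for v in t.values_for(HeaderCategory.CHARACTERISTICS, attr.target))
            for t in dataset.assays
        )
    if attr.locator == "study_protocol":
        for t in dataset.studies:
            for proto_col, param_cols in t.protocol_blocks():
                vals = [v for v in t.column_values(proto_col) if v.strip()]
                if attr.target not in vals:
                    continue
                for c in param_cols:
                    if t.headers[c].category is HeaderCategory.PARAMETER_VALUE \
                            and any(v.strip() for v in t.column_values(c)):
                        return True
        return False
    if attr.locator == "tdf_column":
        target = attr.target
        want_class = None
        if target.startswith("env:"):
            want_class = "environmental"
            target = target.split(":", 1)[1]
        for defs in dataset.trait_definitions.values():
            for d in defs:
                if want_class is None and d.variable_class == "environmental":
                    continue  # phenotypic attributes cover phenotypic/unspecified
                if want_class is not None and d.variable_class != want_class:
                    continue
                ann = getattr(d, target)
                if ann.term_label.strip():
                    return True
        return False
    if attr.locator == "derived_data":
        return any(
            any(v.strip() for v in t.values_for(HeaderCategory.DERIVED_DATA_FILE))
            for t in dataset.assays
        )
    raise ValueError(f"unknown locator {attr.locator!r}")  # pragma: no cover


def _has_environmental_variables(dataset: Dataset) -> bool:
    return any(
        d.variable_class == "environmental"
        for defs in dataset.trait_definitions.values()
        for d in defs
    )


def miappe_compliance(dataset: Dataset, kind: str) -> ComplianceReport:
    """Score essential-attribute coverage under a configuration kind.

    Environmental-variable Trait/Method/Scale enter the applicable set only
    when the dataset's Trait Definition Files declare an environmental
    variable.
    """
    attrs = essential_for(kind, with_conditional=True)
    env_declared = _has_environmental_variables(dataset)
    report = ComplianceReport(kind=kind)
    for section in MIAPPE_SECTIONS:
        report.sections[section] = SectionCompliance(section=section)
    for attr in attrs:
        if attr.conditional and not env_declared:
            continue
        sec = report.sections[attr.section]
        sec.applicable.append(attr.key)
        if _attribute_present(dataset, attr):
            sec.present.append(attr.key)
        else:
            sec.missing.append(attr.key)
    report.extended_present = _extended_attributes(dataset, kind)
    return report


def _extended_attributes(dataset: Dataset, kind: str) -> list[str]:
    """Extra Characteristics / Factor Value qualifiers beyond the plan."""
    planned = {
        e.header.qualifier
        for e in builtin_config(kind).header_plan
        if e.header.category is HeaderCategory.CHARACTERISTICS
    }
    extra: set[str] = set()
    for t in dataset.studies:
        for h in t.headers:
            if h.category is HeaderCategory.CHARACTERISTICS and h.qualifier not in planned:
                if any(v.strip() for v in t.values_for(h.category, h.qualifier)):
                    extra.add(f"Characteristics[{h.qualifier}]")
            elif h.category is HeaderCategory.FACTOR_VALUE:
                if any(v.strip() for v in t.values_for(h.category, h.qualifier)):
                    extra.add(f"Factor Value[{h.qualifier}]")
    return sorted(extra)


# ---------------------------------------------------------------------------
# Orchestrator
# ---------------------------------------------------------------------------


def validate_dataset(
    dataset: Dataset,
    config: Union[str, StudyConfig],
    *,
    assay_config: Optional[AssayConfig] = None,
    extra_issues: Sequence[ValidationIssue] = (),
) -> tuple[ValidationReport, ComplianceReport]:
    """Run table, link and investigation checks plus the compliance report.

    ``config`` is a builtin kind name or a (possibly derived) StudyConfig.
    Issues are returned in deterministic (file, row, column) order.
    """
    study_cfg = builtin_config(config) if isinstance(config, str) else config
    assay_cfg = assay_config or phenotyping_assay_config()
    issues: list[ValidationIssue] = list(extra_issues)

    declared: dict[str, set[str]] = {}
    for rec in dataset.investigation.studies:
        names = rec.protocol_names()
        declared[rec.file_name] = names
        for a in rec.assays:
            declared[a.file_name] = names

    for t in dataset.studies:
        issues.extend(validate_table(t, study_cfg, declared.get(t.source_file)))
    for t in dataset.assays:
        issues.extend(validate_table(t, assay_cfg, declared.get(t.source_file)))
    issues.extend(validate_links(dataset))
    for problem in dataset.investigation.check():
        issues.append(ValidationIssue(
            Severity.ERROR, CODE_DUPLICATE_FILE_NAME, ("investigation", "-", "-"), problem,
        ))
    report = ValidationReport(issues).sorted()
    compliance = miappe_compliance(dataset, study_cfg.kind)
    return report, compliance


def combined_report_dict(report: ValidationReport, compliance: ComplianceReport) -> dict:
    """The machine-readable report document (see ``report_schema.json``)."""
    return {
        "issues": [i.to_dict() for i in report.issues],
        "compliance": compliance.to_dict(),
        "summary": {
            "errors": len(report.errors),
            "warnings": len(report.warnings),
            "infos": len(report.by_severity(Severity.INFO)),
        },
    }


def report_to_json(report: ValidationReport, compliance: ComplianceReport) -> str:
    return json.dumps(combined_report_dict(report, compliance), indent=2, sort_keys=True)
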