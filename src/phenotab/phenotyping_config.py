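"""The Phenotyping Configuration registry.

A *configuration* is a named column schema for a Study or Assay file.  The
Phenotyping Configuration ships three Study schemas — Basic, Field and
Greenhouse — plus one Phenotyping Assay schema:

* **Basic** carries only the seven core Characteristics (organism,
  infraspecific name, seed origin, study start/duration, growth facility,
  geographic location) between the Source Name and Sample Name nodes.  It
  suits legacy or database-exported data where little is known about the
  experiment.
* **Field** and **Greenhouse** extend Basic with environment protocol blocks
  (Rooting, Aerial conditions, Nutrition, Watering) and a Sampling protocol
  declaring the experimental unit.  They differ only inside the Rooting
  block: plot size and sowing density in the field, container descriptors in
  the greenhouse.
* The **Phenotyping Assay** links samples to observations: an organ
  characteristic, a "Data transformation" protocol whose Trait Definition
  File parameter names the variable dictionary, the Assay Name node and the
  raw/derived data file references.

Configurations are extensible *additively only*: derived schemas may insert
new Characteristics, Factor Values, Comments or protocol blocks, but may
never rename, remove or shadow an inherited column — this keeps every
derived dataset readable by consumers of the base schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .model import (
    DATA_NODE_CATEGORIES,
    FieldHeader,
    HeaderCategory,
    format_header,
    parse_header_extended,
)


class ConfigError(ValueError):
    """Unknown configuration kind or malformed config file."""


class ExtensionError(ValueError):
    """An extension tried to rename, remove or shadow an inherited field."""


# ---------------------------------------------------------------------------
# Plan entries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlanEntry:
    """One planned column.

    ``expected`` fixes the cell value for Protocol REF columns (the protocol
    name); empty means free text.  ``unit`` marks that a Unit column follows
    this one.
    """

    header: FieldHeader
    required: bool = True
    expected: str = ""
    unit: bool = False

    @property
    def text(self) -> str:
        return format_header(self.header)

    def key(self) -> tuple:
        """Identity used for shadowing/diff checks."""
        if self.header.category is HeaderCategory.PROTOCOL_REF:
            return (self.header.category.value, self.expected)
        return (self.header.category.value, self.header.qualifier)


def _col(category: HeaderCategory, qualifier: str = "", *, required: bool = True,
         expected: str = "", unit: bool = False) -> PlanEntry:
    return PlanEntry(FieldHeader(category, qualifier), required, expected, unit)


# ---------------------------------------------------------------------------
# Essential-attribute registry (the MIAPPE checklist's starred items)
# ---------------------------------------------------------------------------

#: The eight checklist sections.
MIAPPE_SECTIONS = (
    "General metadata",
    "Timing and location",
    "Biosource",
    "Environment",
    "Treatments",
    "Experimental design",
    "Sample collection, processing, management",
    "Observed variables",
)


@dataclass(frozen=True)
class EssentialAttribute:
    """One essential checklist attribute and where it lives in ISA-Tab.

    ``locator`` kinds: ``investigation`` (field name), ``study_characteristic``
    / ``assay_characteristic`` (qualifier), ``study_protocol`` (protocol
    name), ``tdf_column`` (column name + variable class), ``derived_data``.
    ``conditional`` attributes enter the applicable set only when the dataset
    declares a matching variable (environmental trait/method/scale).
    """

    key: str
    section: str
    locator: str
    target: str = ""
    configs: frozenset = frozenset({"basic", "field", "greenhouse"})
    conditional: bool = False


_ALL = frozenset({"basic", "field", "greenhouse"})
_FG = frozenset({"field", "greenhouse"})

ESSENTIAL_ATTRIBUTES: tuple[EssentialAttribute, ...] = (
    EssentialAttribute("Unique identifier", "General metadata", "investigation", "identifier", _ALL),
    EssentialAttribute("Title", "General metadata", "investigation", "title", _ALL),
    EssentialAttribute("Description", "General metadata", "investigation", "description", _ALL),
    EssentialAttribute("Study start", "Timing and location", "study_characteristic", "Study start", _ALL),
    EssentialAttribute("Study duration", "Timing and location", "study_characteristic", "Study duration", _ALL),
    EssentialAttribute("Geographic location", "Timing and location", "study_characteristic", "Geographic location", _ALL),
    EssentialAttribute("Organism", "Biosource", "study_characteristic", "Organism", _ALL),
    EssentialAttribute("Infraspecific name", "Biosource", "study_characteristic", "Infraspecific name", _ALL),
    EssentialAttribute("Seed origin", "Biosource", "study_characteristic", "Seed origin", _ALL),
    EssentialAttribute("Growth facility", "Environment", "study_characteristic", "Growth facility", _ALL),
    EssentialAttribute("Aerial conditions", "Environment", "study_protocol", "Aerial conditions", _FG),
    EssentialAttribute("Rooting conditions", "Environment", "study_protocol", "Rooting", _FG),
    EssentialAttribute("Nutrients", "Environment", "study_protocol", "Nutrition", _FG),
    EssentialAttribute("Watering", "Environment", "study_protocol", "Watering", _FG),
    EssentialAttribute("Experimental unit", "Experimental design", "study_protocol", "Sampling", _FG),
    EssentialAttribute("Plant body of interest", "Sample collection, processing, management",
                       "assay_characteristic", "Plant body of interest", _ALL),
    EssentialAttribute("Phenotypic variable: Trait", "Observed variables", "tdf_column", "trait", _ALL),
    EssentialAttribute("Phenotypic variable: Method", "Observed variables", "tdf_column", "method", _ALL),
    EssentialAttribute("Phenotypic variable: Scale", "Observed variables", "tdf_column", "scale", _ALL),
    EssentialAttribute("Derived data", "Observed variables", "derived_data", "", _ALL),
    EssentialAttribute("Environmental variable: Trait", "Observed variables", "tdf_column",
                       "env:trait", _ALL, conditional=True),
    EssentialAttribute("Environmental variable: Method", "Observed variables", "tdf_column",
                       "env:method", _ALL, conditional=True),
    EssentialAttribute("Environmental variable: Scale", "Observed variables", "tdf_column",
                       "env:scale", _ALL, conditional=True),
)


def essential_for(kind: str, *, with_conditional: bool = False) -> list[EssentialAttribute]:
    """Essential attributes applicable under a builtin configuration kind."""
    if kind not in _ALL:
        raise ConfigError(f"unknown configuration kind {kind!r}")
    return [
        a
        for a in ESSENTIAL_ATTRIBUTES
        if kind in a.configs and (with_conditional or not a.conditional)
    ]


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyConfig:
    """A named Study schema: ordered plan plus essential-attribute set."""

    name: str
    header_plan: tuple[PlanEntry, ...]
    essential_attributes: tuple[str, ...] = ()
    parent: Optional[str] = None
    table_kind: str = "study"

    @property
    def kind(self) -> str:
        """The builtin kind this config derives from (its root ancestor)."""
        return self.parent or self.name

    def protocol_blocks(self) -> list[tuple[str, list[PlanEntry]]]:
        """(protocol name, parameter entries) in plan order."""
        blocks: list[tuple[str, list[PlanEntry]]] = []
        current: Optional[list[PlanEntry]] = None
        for e in self.header_plan:
            if e.header.category is HeaderCategory.PROTOCOL_REF:
                current = []
                blocks.append((e.expected, current))
            elif e.header.category in DATA_NODE_CATEGORIES:
                current = None
            elif current is not None and e.header.category is HeaderCategory.PARAMETER_VALUE:
                current.append(e)
        return blocks

    def materialized_headers(self) -> list[tuple[FieldHeader, PlanEntry]]:
        """The physical column sequence, with Unit columns expanded."""
        out: list[tuple[FieldHeader, PlanEntry]] = []
        for e in self.header_plan:
            out.append((e.header, e))
            if e.unit:
                out.append((FieldHeader(HeaderCategory.UNIT), e))
        return out

    def declared_protocols(self) -> list[tuple[str, list[str]]]:
        return [
            (name, [p.header.qualifier for p in params])
            for name, params in self.protocol_blocks()
        ]


@dataclass(frozen=True)
class AssayConfig(StudyConfig):
    table_kind: str = "assay"


# -- builtin plans ----------------------------------------------------------

_BASIC_CHARACTERISTICS = (
    "Organism",
    "Infraspecific name",
    "Seed origin",
    "Study start",
    "Study duration",
    "Growth facility",
    "Geographic location",
)

# (protocol name, ((parameter qualifier, unit-follows), ...))
_FIELD_PROTOCOLS = (
    ("Rooting", (("Rooting medium", False), ("Plot size", True),
                 ("Sowing density", False), ("pH", False))),
    ("Aerial conditions", (("Air humidity", False), ("Daily photon flux", False),
                           ("Length of light period", False), ("Day temperature", False),
                           ("Night temperature", False))),
    ("Nutrition", (("N before fertilisation", False), ("Type of fertiliser", False),
                   ("Amount of fertiliser", False))),
    ("Watering", (("Irrigation type", False), ("Volume", False), ("Frequency", False))),
    ("Sampling", (("Experimental unit", False),)),
)

_GREENHOUSE_PROTOCOLS = (
    ("Rooting", (("Rooting medium", False), ("Container type", False),
                 ("Container volume", False), ("Container dimension", True),
                 ("Number of plants per container", False), ("pH", False))),
) + _FIELD_PROTOCOLS[1:]


def _study_plan(protocols: Sequence[tuple[str, Sequence[tuple[str, bool]]]]) -> tuple[PlanEntry, ...]:
    plan: list[PlanEntry] = [_col(HeaderCategory.SOURCE_NAME)]
    for q in _BASIC_CHARACTERISTICS:
        plan.append(_col(HeaderCategory.CHARACTERISTICS, q))
    for name, params in protocols:
        plan.append(_col(HeaderCategory.PROTOCOL_REF, expected=name))
        for q, unit in params:
            plan.append(_col(HeaderCategory.PARAMETER_VALUE, q, unit=unit))
    plan.append(_col(HeaderCategory.SAMPLE_NAME))
    return tuple(plan)


def builtin_config(kind: str) -> StudyConfig:
    """Return the builtin Basic / Field / Greenhouse Study schema."""
    if kind == "basic":
        plan = _study_plan(())
    elif kind == "field":
        plan = _study_plan(_FIELD_PROTOCOLS)
    elif kind == "greenhouse":
        plan = _study_plan(_GREENHOUSE_PROTOCOLS)
    else:
        raise ConfigError(f"unknown configuration kind {kind!r}")
    essentials = tuple(a.key for a in essential_for(kind))
    return StudyConfig(name=kind, header_plan=plan, essential_attributes=essentials)


#: Parameter naming the variable dictionary in the Phenotyping Assay.
TDF_PARAMETER = "Trait Definition File"
DATA_TRANSFORMATION_PROTOCOL = "Data transformation"
ORGAN_CHARACTERISTIC = "Plant body of interest"


def phenotyping_assay_config() -> AssayConfig:
    """The Phenotyping Assay schema shared by all three Study kinds."""
    plan = (
        _col(HeaderCategory.SAMPLE_NAME),
        _col(HeaderCategory.CHARACTERISTICS, ORGAN_CHARACTERISTIC),
        _col(HeaderCategory.PROTOCOL_REF, expected=DATA_TRANSFORMATION_PROTOCOL),
        _col(HeaderCategory.PARAMETER_VALUE, TDF_PARAMETER),
        _col(HeaderCategory.ASSAY_NAME),
        _col(HeaderCategory.RAW_DATA_FILE, required=False),
        _col(HeaderCategory.DERIVED_DATA_FILE),
    )
    return AssayConfig(name="phenotyping", header_plan=plan)


# ---------------------------------------------------------------------------
# Additive extension
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ColumnAddition:
    """Insert a single column after the anchor header (canonical text).

    ``after=None`` inserts before the trailing Sample Name of a study plan,
    or at the end of an assay plan.
    """

    entry: PlanEntry
    after: Optional[str] = None


@dataclass(frozen=True)
class ProtocolBlockAddition:
    """Insert a protocol block (Protocol REF + parameters).

    ``after`` names an existing protocol; ``None`` appends after the last
    block (before Sample Name).
    """

    name: str
    parameters: tuple[tuple[str, bool], ...] = ()
    after: Optional[str] = None


@dataclass(frozen=True)
class RemovalRequest:
    """Always rejected: fields may never be removed from a configuration."""

    header_text: str


Addition = Union[ColumnAddition, ProtocolBlockAddition, RemovalRequest]


def _insert_index(plan: list[PlanEntry], after: Optional[str], table_kind: str) -> int:
    if after is None:
        if table_kind == "study" and plan and plan[-1].header.category is HeaderCategory.SAMPLE_NAME:
            return len(plan) - 1
        return len(plan)
    for i, e in enumerate(plan):
        if e.text == after:
            # Skip past parameter columns when anchoring after a Protocol REF.
            return i + 1
    raise ExtensionError(f"anchor header {after!r} not found in plan")


def extend_config(
    base: StudyConfig,
    additions: Iterable[Addition],
    *,
    name: Optional[str] = None,
) -> StudyConfig:
    """Derive a configuration by additive extension.

    The derived plan contains the base plan as an identical-spelling
    subsequence.  Removal, renaming and shadowing (duplicating an inherited
    header) raise :class:`ExtensionError`.
    """
    plan = list(base.header_plan)
    existing = {e.key() for e in plan}
    for add in additions:
        if isinstance(add, RemovalRequest):
            raise ExtensionError(
                f"removal of {add.header_text!r} forbidden: no fields may be "
                "removed from a configuration, even if not used"
            )
        if isinstance(add, ColumnAddition):
            if add.entry.key() in existing:
                raise ExtensionError(
                    f"addition shadows inherited field {add.entry.text!r}"
                )
            idx = _insert_index(plan, add.after, base.table_kind)
            plan.insert(idx, add.entry)
            existing.add(add.entry.key())
        elif isinstance(add, ProtocolBlockAddition):
            key = (HeaderCategory.PROTOCOL_REF.value, add.name)
            if key in existing:
                raise ExtensionError(f"protocol block {add.name!r} already present")
            entries = [_col(HeaderCategory.PROTOCOL_REF, expected=add.name)]
            for q, unit in add.parameters:
                entries.append(_col(HeaderCategory.PARAMETER_VALUE, q, unit=unit))
            if add.after is None:
                idx = _insert_index(plan, None, base.table_kind)
            else:
                idx = _block_end(plan, add.after)
            plan[idx:idx] = entries
            existing.add(key)
        else:  # pragma: no cover - defensive
            raise TypeError(f"unknown addition {add!r}")
    # keep node-position invariant for study plans
    derived_name = name or f"{base.name}+custom"
    cls = AssayConfig if base.table_kind == "assay" else StudyConfig
    return cls(
        name=derived_name,
        header_plan=tuple(plan),
        essential_attributes=base.essential_attributes,
        parent=base.kind,
        table_kind=base.table_kind,
    )


def _block_end(plan: list[PlanEntry], protocol: str) -> int:
    """Index just past the named protocol block's parameters."""
    start = None
    for i, e in enumerate(plan):
        if e.header.category is HeaderCategory.PROTOCOL_REF and e.expected == protocol:
            start = i
            break
    if start is None:
        raise ExtensionError(f"anchor protocol {protocol!r} not found in plan")
    i = start + 1
    while i < len(plan) and plan[i].header.category is HeaderCategory.PARAMETER_VALUE:
        i += 1
    return i


# ---------------------------------------------------------------------------
# Diff
# ---------------------------------------------------------------------------


@dataclass
class ConfigDiff:
    """Headers present in ``b`` but not ``a`` (additions), headers only in
    ``a`` (conflict-free sibling branches), and genuine conflicts (same
    identity, different flags)."""

    additions: list[PlanEntry] = field(default_factory=list)
    only_in_a: list[PlanEntry] = field(default_factory=list)
    conflicts: list[tuple[PlanEntry, PlanEntry]] = field(default_factory=list)

    def added_protocol_blocks(self) -> list[str]:
        return [
            e.expected
            for e in self.additions
            if e.header.category is HeaderCategory.PROTOCOL_REF
        ]

    def is_empty(self) -> bool:
        return not (self.additions or self.only_in_a or self.conflicts)


def config_diff(a: StudyConfig, b: StudyConfig) -> ConfigDiff:
    """Structural diff of two plans, keyed on header identity."""
    a_map = {e.key(): e for e in a.header_plan}
    b_map = {e.key(): e for e in b.header_plan}
    diff = ConfigDiff()
    for e in b.header_plan:
        if e.key() not in a_map:
            diff.additions.append(e)
        elif a_map[e.key()] != e:
            diff.conflicts.append((a_map[e.key()], e))
    for e in a.header_plan:
        if e.key() not in b_map:
            diff.only_in_a.append(e)
    return diff


# ---------------------------------------------------------------------------
# Plain-text config serialization
# ---------------------------------------------------------------------------
#
# One line per planned column:
#   <canonical header>\t<required|optional>\t<expected-value-or-->\t<unit|nounit>
# Protocol blocks are introduced by:  protocol\t<name>
# A leading line:  config\t<name>\t<study|assay>\t<parent-or-->


def write_config(config: StudyConfig, path: Path) -> None:
    lines = [f"config\t{config.name}\t{config.table_kind}\t{config.parent or '-'}"]
    for e in config.header_plan:
        if e.header.category is HeaderCategory.PROTOCOL_REF:
            lines.append(f"protocol\t{e.expected}")
            continue
        req = "required" if e.required else "optional"
        unit = "unit" if e.unit else "nounit"
        lines.append(f"{e.text}\t{req}\t{e.expected or '-'}\t{unit}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_config(path: Path) -> StudyConfig:
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("config\t"):
        raise ConfigError(f"{path}: missing 'config' preamble line")
    _, name, table_kind, parent = (lines[0].split("\t") + ["-"])[:4]
    if table_kind not in ("study", "assay"):
        raise ConfigError(f"{path}: unknown table kind {table_kind!r}")
    plan: list[PlanEntry] = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        if parts[0] == "protocol":
            if len(parts) != 2 or not parts[1]:
                raise ConfigError(f"{path}: malformed protocol line {ln!r}")
            plan.append(_col(HeaderCategory.PROTOCOL_REF, expected=parts[1]))
            continue
        if len(parts) != 4:
            raise ConfigError(f"{path}: malformed plan line {ln!r}")
        header_text, req, expected, unit = parts
        header, proto_expected = parse_header_extended(header_text)
        plan.append(
            PlanEntry(
                header,
                required=(req == "required"),
                expected=(proto_expected or ("" if expected == "-" else expected)),
                unit=(unit == "unit"),
            )
        )
    parent_name = None if parent == "-" else parent
    kind = parent_name or name
    essentials: tuple[str, ...] = ()
    if kind in _ALL:
        essentials = tuple(a.key for a in essential_for(kind))
    cls = AssayConfig if table_kind == "assay" else StudyConfig
    return cls(
        name=name,
        header_plan=tuple(plan),
        essential_attributes=essentials,
        parent=parent_name,
        table_kind=table_kind,
    )
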