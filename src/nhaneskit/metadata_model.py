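"""Domain types for NHANES-style snapshot metadata.

A snapshot's metadata schema holds three documentation-derived tables plus a
two-field version table:

* ``QuestionnaireDescriptions`` — one row per released data table (its cycle
  years, data group, use constraints, file locations).
* ``QuestionnaireVariables`` — one row per (variable, table): the descriptive
  text printed above the value table on a documentation page.
* ``VariableCodebook`` — one row per possible value of each variable: the
  code, its English description, counts, and the skip target consulted during
  survey administration.
* ``VersionInfo`` — container version and data-collection date.

The accessors :func:`metadata_tab`, :func:`metadata_var` and
:func:`metadata_cb` filter these tables the way an analyst would: by use
constraint, by table, and by (table, variable) respectively.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Iterable, Sequence

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .dbbuild import SnapshotStore

#: Reserved sentinel normalizing the various "End of Section" phrasings a
#: codebook may use for a skip target that leaves the questionnaire section.
END_OF_SECTION = "<END_OF_SECTION>"

#: Code string conventionally used for the Missing row of a codebook.
MISSING_CODE = "."

_END_OF_SECTION_RE = re.compile(r"end\s+of\s+section", re.IGNORECASE)
_UPPER_ALNUM_RE = re.compile(r"^[A-Z][A-Z0-9]*$")


class UseConstraint(str, Enum):
    PUBLIC = "public"
    RESTRICTED = "restricted"


class MissingSchemaError(KeyError):
    """A snapshot store lacks a required schema (namespace)."""

    def __init__(self, schema: str):
        self.schema = schema
        super().__init__(f"store has no '{schema}' schema; build the snapshot first")


@dataclass(frozen=True)
class QuestionnaireDescription:
    """One row of QuestionnaireDescriptions: a released table and its cycle."""

    table_name: str
    description: str
    begin_year: int
    end_year: int
    data_group: str
    use_constraints: UseConstraint
    doc_file: str
    data_file: str
    date_published: str

    def __post_init__(self) -> None:
        if self.begin_year > self.end_year:
            raise ValueError(
                f"{self.table_name}: begin_year {self.begin_year} > end_year {self.end_year}"
            )

    @property
    def cycle(self) -> tuple[int, int]:
        return (self.begin_year, self.end_year)

    def cycle_span_ok(self, allowed: Sequence[int] = (1, 3)) -> bool:
        """Whether the cycle span matches a standard 2-year cycle (span 1) or a
        pandemic-extended one (span 3).  Configurable, advisory only."""
        return (self.end_year - self.begin_year) in tuple(allowed)


@dataclass(frozen=True)
class QuestionnaireVariable:
    """One row of QuestionnaireVariables: the per-variable descriptive text."""

    variable: str
    table_name: str
    sas_label: str = ""
    english_text: str = ""
    english_instructions: str = ""
    hard_edits: str = ""
    #: A block may print several Target lines (one per age/sex group); they
    #: are kept as a list rather than flattened.
    target: tuple[str, ...] = ()

    def name_warnings(self) -> list[str]:
        """Non-fatal naming checks: variable names are conventionally
        upper-case alphanumeric; anything else is worth a warning."""
        if not self.variable:
            return [f"{self.table_name}: empty variable name"]
        if not _UPPER_ALNUM_RE.match(self.variable):
            return [
                f"{self.table_name}.{self.variable}: variable name is not "
                "upper-case alphanumeric"
            ]
        return []


@dataclass(frozen=True)
class CodebookEntry:
    """One row of VariableCodebook: a single possible value of a variable.

    ``code_or_value`` is kept verbatim: an integer code for categorical
    levels, a textual range ``"X to Y"`` for continuous variables, or the
    missing sentinel ``"."``.  ``skip_to_item`` is the variable the interview
    jumps to when this value is the answer (or :data:`END_OF_SECTION`).
    """

    variable: str
    table_name: str
    code_or_value: str
    value_description: str
    count: int | None = None
    cumulative: int | None = None
    skip_to_item: str | None = None


@dataclass(frozen=True)
class VersionInfo:
    """The two-field version table of a built snapshot."""

    container_version: str
    collection_date: _dt.date

    def as_rows(self) -> list[tuple[str, str]]:
        return [
            ("CONTAINER_VERSION", self.container_version),
            ("COLLECTION_DATE", self.collection_date.isoformat()),
        ]


@dataclass
class WarningRecord:
    """A non-fatal anomaly surfaced by an accessor or parser."""

    source: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.source}] {self.message}"


def normalize_skip_target(raw: str | None) -> str | None:
    """Map the codebook's skip-target cell to a variable name, the
    end-of-section sentinel, or ``None`` when empty."""
    if raw is None:
        return None
    text = raw.strip()
    if not text:
        return None
    if _END_OF_SECTION_RE.search(text):
        return END_OF_SECTION
    return text


def validate_codebook_group(entries: Sequence[CodebookEntry]) -> list[str]:
    """Check the invariants of one (variable, table) codebook group.

    Returns a list of violation messages (empty when valid): cumulative must
    be nondecreasing in row order, the last cumulative must equal the sum of
    counts, and codes must be unique within the group.
    """
    problems: list[str] = []
    if not entries:
        return problems
    key = (entries[0].variable, entries[0].table_name)
    for e in entries:
        if (e.variable, e.table_name) != key:
            problems.append(f"mixed groups: {key} vs {(e.variable, e.table_name)}")
            return problems
    codes = [e.code_or_value for e in entries]
    if len(set(codes)) != len(codes):
        dupes = sorted({c for c in codes if codes.count(c) > 1})
        problems.append(f"{key}: duplicate codes {dupes}")
    counted = [e for e in entries if e.count is not None and e.cumulative is not None]
    prev = None
    for e in counted:
        if prev is not None and e.cumulative < prev:
            problems.append(
                f"{key}: cumulative decreases at code {e.code_or_value!r} "
                f"({prev} -> {e.cumulative})"
            )
        prev = e.cumulative
    if counted:
        total = sum(e.count for e in counted)  # type: ignore[misc]
        last = counted[-1].cumulative
        if last != total:
            problems.append(f"{key}: last cumulative {last} != sum of counts {total}")
    return problems


# ---------------------------------------------------------------------------
# Store accessors
# ---------------------------------------------------------------------------

def _require_metadata(store: "SnapshotStore") -> None:
    if not store.has_schema("metadata"):
        raise MissingSchemaError("metadata")


def metadata_tab(
    store: "SnapshotStore", include_restricted: bool = False
) -> list[QuestionnaireDescription]:
    """Return the table descriptions in a snapshot.

    By default only publicly available tables are returned; pass
    ``include_restricted=True`` for all of them.
    """
    _require_metadata(store)
    rows = store.read_metadata_rows("questionnaire_descriptions")
    out = []
    for r in rows:
        desc = QuestionnaireDescription(
            table_name=r["table_name"],
            description=r["description"],
            begin_year=int(r["begin_year"]),
            end_year=int(r["end_year"]),
            data_group=r["data_group"],
            use_constraints=UseConstraint(r["use_constraints"]),
            doc_file=r["doc_file"],
            data_file=r["data_file"],
            date_published=r["date_published"],
        )
        if include_restricted or desc.use_constraints is UseConstraint.PUBLIC:
            out.append(desc)
    return out


def _split_targets(packed: str) -> tuple[str, ...]:
    return tuple(t for t in packed.split("\x1f") if t) if packed else ()


def metadata_var(
    store: "SnapshotStore",
    table_names: Iterable[str] | None = None,
    warnings: list[WarningRecord] | None = None,
) -> list[QuestionnaireVariable]:
    """Return variable metadata, optionally restricted to a set of tables.

    An unknown table name in the filter yields no rows for that name and a
    :class:`WarningRecord` (appended to ``warnings`` when given) rather than
    an exception.
    """
    _require_metadata(store)
    rows = store.read_metadata_rows("questionnaire_variables")
    wanted = None if table_names is None else set(table_names)
    if wanted is not None and warnings is not None:
        known = {r["table_name"] for r in rows}
        for name in sorted(wanted - known):
            warnings.append(
                WarningRecord("metadata_var", f"unknown table name {name!r}")
            )
    out = [
        QuestionnaireVariable(
            variable=r["variable"],
            table_name=r["table_name"],
            sas_label=r["sas_label"],
            english_text=r["english_text"],
            english_instructions=r["english_instructions"],
            hard_edits=r["hard_edits"],
            target=_split_targets(r["target"]),
        )
        for r in rows
        if wanted is None or r["table_name"] in wanted
    ]
    out.sort(key=lambda v: (v.table_name, v.variable))
    return out


def metadata_cb(
    store: "SnapshotStore",
    table_names: Iterable[str] | None = None,
    variables: Iterable[str] | None = None,
    warnings: list[WarningRecord] | None = None,
) -> list[CodebookEntry]:
    """Return codebook rows, filtered conjunctively on table and variable.

    Rows come back in codebook document order (the order the documentation
    page lists them), which downstream skip-logic relies on.
    """
    _require_metadata(store)
    rows = store.read_metadata_rows("variable_codebook")
    tset = None if table_names is None else set(table_names)
    vset = None if variables is None else set(variables)
    if warnings is not None:
        if tset is not None:
            known_t = {r["table_name"] for r in rows}
            for name in sorted(tset - known_t):
                warnings.append(
                    WarningRecord("metadata_cb", f"unknown table name {name!r}")
                )
        if vset is not None:
            known_v = {r["variable"] for r in rows}
            for name in sorted(vset - known_v):
                warnings.append(
                    WarningRecord("metadata_cb", f"unknown variable {name!r}")
                )
    out = []
    for r in rows:
        if tset is not None and r["table_name"] not in tset:
            continue
        if vset is not None and r["variable"] not in vset:
            continue
        out.append(
            CodebookEntry(
                variable=r["variable"],
                table_name=r["table_name"],
                code_or_value=r["code_or_value"],
                value_description=r["value_description"],
                count=None if r["count"] is None else int(r["count"]),
                cumulative=None if r["cumulative"] is None else int(r["cumulative"]),
                skip_to_item=r["skip_to_item"] or None,
            )
        )
    return out
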