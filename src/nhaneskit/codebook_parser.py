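"""Parsing of NHANES-style documentation pages and manifests.

Each released table ships with one HTML documentation page listing its
variables.  A variable block carries key-value fields (Variable Name,
SAS Label, English Text, English Instructions, Target, Hard Edits) followed
by a value table with columns Code or Value / Value Description / Count /
Cumulative / Skip to Item.  This module turns such pages — and the manifest
listing the tables of a snapshot — into :mod:`nhaneskit.metadata_model`
values.

The supported dialect is structural, not tied to any particular site's
markup: a variable block is a ``<dl>`` definition list containing a
"Variable Name" field, and its value table is the next codebook-headed
``<table>`` in document order.  Adapters for other markups can preprocess
into this shape.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field

from lxml import html as lxml_html

from .metadata_model import (
    CodebookEntry,
    QuestionnaireDescription,
    QuestionnaireVariable,
    UseConstraint,
    normalize_skip_target,
)

# Field labels recognized in a variable block; anything else is recorded in
# parse_warnings rather than silently dropped.
FIELD_LABELS = {
    "variable name": "variable",
    "sas label": "sas_label",
    "english text": "english_text",
    "english instructions": "english_instructions",
    "target": "target",
    "hard edits": "hard_edits",
}

CODEBOOK_COLUMNS = {
    "code or value": "code_or_value",
    "value description": "value_description",
    "count": "count",
    "cumulative": "cumulative",
    "skip to item": "skip_to_item",
}

_WS_RE = re.compile(r"\s+")


class CodebookParseError(ValueError):
    """The document cannot be parsed; ``byte_offset`` locates the failure."""

    def __init__(self, message: str, byte_offset: int = 0):
        self.byte_offset = byte_offset
        super().__init__(f"{message} (byte offset {byte_offset})")


class UnsupportedDialectError(CodebookParseError):
    """The page is real documentation but not in the supported dialect.

    Mirrors the exclusion policy for non-standard documentation: the builder
    catches this and records the table as excluded instead of aborting.
    """


class ManifestError(ValueError):
    pass


@dataclass
class CodebookDoc:
    """A parsed documentation page: the table's variables in document order.

    Document order matters — it defines questionnaire order for skip-logic.
    """

    table_name: str
    variables: list[tuple[QuestionnaireVariable, list[CodebookEntry]]]
    source_path: str = ""
    parse_warnings: list[str] = field(default_factory=list)

    def variable_names(self) -> list[str]:
        return [v.variable for v, _ in self.variables]

    def entries_for(self, variable: str) -> list[CodebookEntry]:
        for v, entries in self.variables:
            if v.variable == variable:
                return entries
        raise KeyError(variable)


@dataclass(frozen=True)
class ManifestEntry:
    table_name: str
    doc_url: str
    data_url: str
    begin_year: int
    end_year: int
    use_constraints: UseConstraint = UseConstraint.PUBLIC
    description: str = ""
    data_group: str = ""
    date_published: str = ""


@dataclass
class Manifest:
    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        names = [e.table_name for e in self.entries]
        dupes = sorted({n for n in names if names.count(n) > 1})
        if dupes:
            raise ManifestError(f"duplicate table names in manifest: {dupes}")

    def get(self, table_name: str) -> ManifestEntry:
        for e in self.entries:
            if e.table_name == table_name:
                return e
        raise KeyError(table_name)

    def table_names(self) -> list[str]:
        return [e.table_name for e in self.entries]


def _norm(text: str | None) -> str:
    return _WS_RE.sub(" ", text or "").strip()


def _parse_int(cell: str) -> int | None:
    cell = cell.replace(",", "").strip()
    if not cell:
        return None
    return int(cell)


def _parse_dl(dl) -> tuple[dict[str, object], list[str]]:
    """Collect the field values of one <dl>.  Target may repeat."""
    fields: dict[str, object] = {"target": []}
    warnings: list[str] = []
    label = None
    for child in dl.iterchildren():
        tag = child.tag.lower() if isinstance(child.tag, str) else ""
        if tag == "dt":
            label = _norm(child.text_content()).rstrip(":").lower()
        elif tag == "dd" and label is not None:
            value = _norm(child.text_content())
            key = FIELD_LABELS.get(label)
            if key is None:
                warnings.append(f"unknown field label {label!r} (value kept in warnings: {value!r})")
            elif key == "target":
                fields["target"].append(value)
            else:
                fields[key] = value
    return fields, warnings


def _codebook_header_map(table) -> dict[int, str] | None:
    """Map column index -> canonical name if this <table> is a value table."""
    rows = table.findall(".//tr")
    if not rows:
        return None
    header = [_norm(c.text_content()).lower() for c in rows[0].findall("th")]
    if not header:
        header = [_norm(c.text_content()).lower() for c in rows[0].findall("td")]
    mapped = {i: CODEBOOK_COLUMNS[h] for i, h in enumerate(header) if h in CODEBOOK_COLUMNS}
    if "code_or_value" in mapped.values() and "value_description" in mapped.values():
        return mapped
    return None


def _parse_value_table(table, variable: str, table_name: str,
                       warnings: list[str]) -> list[CodebookEntry]:
    colmap = _codebook_header_map(table)
    assert colmap is not None
    entries: list[CodebookEntry] = []
    rows = table.findall(".//tr")
    for tr in rows[1:]:
        cells = [_norm(c.text_content()) for c in tr.findall("td")]
        if not cells:
            continue
        rec: dict[str, str] = {}
        for i, cell in enumerate(cells):
            name = colmap.get(i)
            if name is not None:
                rec[name] = cell
        if "code_or_value" not in rec:
            warnings.append(f"{table_name}.{variable}: value row without a code cell skipped")
            continue
        try:
            count = _parse_int(rec.get("count", ""))
            cumulative = _parse_int(rec.get("cumulative", ""))
        except ValueError:
            warnings.append(
                f"{table_name}.{variable}: non-numeric count in row {rec['code_or_value']!r}"
            )
            count = cumulative = None
        entries.append(
            CodebookEntry(
                variable=variable,
                table_name=table_name,
                code_or_value=rec["code_or_value"],
                value_description=rec.get("value_description", ""),
                count=count,
                cumulative=cumulative,
                skip_to_item=normalize_skip_target(rec.get("skip_to_item")),
            )
        )
    return entries


def parse_doc_page(html: str, source_path: str = "") -> CodebookDoc:
    """Parse one documentation page into a :class:`CodebookDoc`.

    Raises :class:`UnsupportedDialectError` when the page contains no
    recognizable variable block; the byte offset points at the first place
    scanning gave up.
    """
    if not html.strip():
        raise CodebookParseError("empty document", 0)
    root = lxml_html.fromstring(html)
    title = root.find(".//title")
    table_name = _norm(title.text_content()) if title is not None else ""

    warnings: list[str] = []
    blocks: list[tuple[QuestionnaireVariable, list[CodebookEntry]]] = []
    current: dict[str, object] | None = None
    current_entries: list[CodebookEntry] | None = None

    def flush() -> None:
        nonlocal current, current_entries
        if current is None:
            return
        var = QuestionnaireVariable(
            variable=str(current.get("variable", "")),
            table_name=table_name,
            sas_label=str(current.get("sas_label", "")),
            english_text=str(current.get("english_text", "")),
            english_instructions=str(current.get("english_instructions", "")),
            hard_edits=str(current.get("hard_edits", "")),
            target=tuple(current.get("target", [])),  # type: ignore[arg-type]
        )
        warnings.extend(var.name_warnings())
        blocks.append((var, current_entries or []))
        current = None
        current_entries = None

    for el in root.iter():
        tag = el.tag.lower() if isinstance(el.tag, str) else ""
        if tag == "dl":
            fields, wlist = _parse_dl(el)
            if "variable" in fields:
                flush()
                warnings.extend(wlist)
                current = fields
                current_entries = []
        elif tag == "table" and _codebook_header_map(el) is not None:
            if current is None:
                warnings.append(f"{table_name}: value table outside any variable block")
                continue
            current_entries = _parse_value_table(  # type: ignore[assignment]
                el, str(current["variable"]), table_name, warnings
            )
    flush()

    if not blocks:
        # Locate where scanning stopped: the body start, or 0.
        m = re.search(rb"<body", html.encode("utf-8", "replace"), re.IGNORECASE)
        raise UnsupportedDialectError(
            f"no recognizable variable block in document {source_path or table_name!r}",
            m.start() if m else 0,
        )
    if not table_name:
        warnings.append("page has no <title>; table name unknown")
    return CodebookDoc(
        table_name=table_name,
        variables=blocks,
        source_path=source_path,
        parse_warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

_MANIFEST_FIELDS = [
    "table_name", "doc_file", "data_file", "begin_year", "end_year",
    "use_constraints", "description", "data_group", "date_published",
]


def _manifest_entry(rec: dict[str, str]) -> ManifestEntry:
    missing = [k for k in ("table_name", "doc_file", "data_file", "begin_year", "end_year")
               if not rec.get(k)]
    if missing:
        raise ManifestError(f"manifest row missing required fields {missing}: {rec}")
    uc = rec.get("use_constraints", "").strip().lower() or "public"
    return ManifestEntry(
        table_name=rec["table_name"].strip(),
        doc_url=rec["doc_file"].strip(),
        data_url=rec["data_file"].strip(),
        begin_year=int(rec["begin_year"]),
        end_year=int(rec["end_year"]),
        use_constraints=UseConstraint(uc),
        description=rec.get("description", "").strip(),
        data_group=rec.get("data_group", "").strip(),
        date_published=rec.get("date_published", "").strip(),
    )


def parse_manifest(text: str) -> Manifest:
    """Parse a snapshot manifest, given as TSV or as an HTML table.

    Rows without a use-constraints value default to public.  Duplicate table
    names raise :class:`ManifestError` listing the duplicates.
    """
    stripped = text.strip()
    if not stripped:
        return Manifest(entries=[])
    if stripped.startswith("<"):
        root = lxml_html.fromstring(text)
        rows = root.findall(".//tr")
        if not rows:
            return Manifest(entries=[])
        header = [_norm(c.text_content()).lower().replace(" ", "_")
                  for c in rows[0].findall("th") or rows[0].findall("td")]
        entries = []
        for tr in rows[1:]:
            cells = [_norm(c.text_content()) for c in tr.findall("td")]
            if not any(cells):
                continue
            rec = dict(zip(header, cells))
            entries.append(_manifest_entry(rec))
        return Manifest(entries=entries)
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    entries = []
    for rec in reader:
        if not any((v or "").strip() for v in rec.values()):
            continue
        entries.append(_manifest_entry({k: (v or "") for k, v in rec.items()}))
    return Manifest(entries=entries)


def extract_metadata(
    docs: list[CodebookDoc], manifest: Manifest
) -> tuple[list[QuestionnaireDescription], list[QuestionnaireVariable], list[CodebookEntry]]:
    """Build the three metadata collections from parsed docs and a manifest.

    Every doc must have a manifest entry (error naming the table otherwise).
    Restricted tables contribute metadata like any other: documentation is
    available for all data even when the raw data are not distributed.
    """
    known = set(manifest.table_names())
    for doc in docs:
        if doc.table_name not in known:
            raise ManifestError(f"doc for table {doc.table_name!r} has no manifest entry")
    descriptions: list[QuestionnaireDescription] = []
    variables: list[QuestionnaireVariable] = []
    codebook: list[CodebookEntry] = []
    for doc in docs:
        m = manifest.get(doc.table_name)
        descriptions.append(
            QuestionnaireDescription(
                table_name=m.table_name,
                description=m.description or m.table_name,
                begin_year=m.begin_year,
                end_year=m.end_year,
                data_group=m.data_group,
                use_constraints=m.use_constraints,
                doc_file=m.doc_url,
                data_file=m.data_url,
                date_published=m.date_published,
            )
        )
        for var, entries in doc.variables:
            variables.append(var)
            codebook.extend(entries)
    return descriptions, variables, codebook
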