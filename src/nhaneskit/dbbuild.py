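"""Versioned snapshot store: three schemas plus VersionInfo.

A snapshot is an embedded relational store (SQLite) with three namespaces —

* ``raw``: the released tables, loaded verbatim;
* ``translated``: their labelled counterparts (codes replaced by value
  descriptions);
* ``metadata``: the documentation-derived tables
  (QuestionnaireDescriptions, QuestionnaireVariables, VariableCodebook),
  the VersionInfo table, the stored HTML pages, and the build log.

Namespaces are emulated portably through reserved table-name prefixes
hidden behind the registry; a server-backed deployment of the same contract
would use real schemas.  Restricted tables appear in metadata only — the
store carries public data only, but documentation for everything.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import os
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codebook_parser import (
    CodebookDoc,
    Manifest,
    UnsupportedDialectError,
    extract_metadata,
    parse_doc_page,
)
from .metadata_model import (
    CodebookEntry,
    MissingSchemaError,
    QuestionnaireDescription,
    QuestionnaireVariable,
    UseConstraint,
    VersionInfo,
)
from .translator import (
    DEFAULT_POLICY,
    RawTable,
    TranslationPolicy,
    translate_table,
)

NAMESPACES = ("raw", "translated", "metadata")
_PREFIX = {ns: f"{ns}__" for ns in NAMESPACES}

#: Fixed metadata-schema table names and the snake_case column mapping used
#: in the store (documentation spells them in CamelCase: TableName ->
#: table_name, SasLabel -> sas_label, CodeOrValue -> code_or_value, ...).
METADATA_TABLES = (
    "questionnaire_descriptions",
    "questionnaire_variables",
    "variable_codebook",
    "version_info",
)

# Environment-discovery contract: names are documented constants of this
# toolkit (only the documentation-base variable is fixed upstream).
ENV_DB_VARIANT = "NHANES_DB_VARIANT"
ENV_DB_PORT = "NHANES_DB_PORT"
ENV_TABLE_BASE = "NHANES_TABLE_BASE"


class DocNotFoundError(KeyError):
    def __init__(self, table_name: str):
        self.table_name = table_name
        super().__init__(f"no stored documentation for table {table_name!r}")


class VersionExistsError(RuntimeError):
    pass


class BuildMismatchError(RuntimeError):
    """Raw/translated disagreement detected during the build; carries a diff
    summary."""


@dataclass
class EnvContract:
    db_variant: str | None = None
    port: int | None = None
    doc_base: str | None = None
    present: bool = False
    warnings: list[str] = field(default_factory=list)


def discover_environment(env: dict[str, str] | None = None) -> EnvContract:
    """Read the container's discovery variables, if any.

    Tools call this at startup: when the full variable set is present they
    connect to the containerised database and local documentation; when it
    is not, they fall back to file-based access and behave identically.
    Partial variable sets yield ``present=False`` plus a warning naming what
    is missing.
    """
    if env is None:
        env = dict(os.environ)
    names = (ENV_DB_VARIANT, ENV_DB_PORT, ENV_TABLE_BASE)
    values = {n: env.get(n) for n in names}
    missing = [n for n, v in values.items() if not v]
    if len(missing) == len(names):
        return EnvContract()
    if missing:
        return EnvContract(
            warnings=[f"partial environment: missing {', '.join(missing)}"]
        )
    return EnvContract(
        db_variant=values[ENV_DB_VARIANT],
        port=int(values[ENV_DB_PORT]),  # type: ignore[arg-type]
        doc_base=values[ENV_TABLE_BASE],
        present=True,
    )


class SnapshotStore:
    """Namespaced relational snapshot, SQLite-backed (file or in-memory)."""

    def __init__(self, path: str | Path = ":memory:"):
        self.path = str(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.execute("PRAGMA foreign_keys = ON")

    def close(self) -> None:
        self.conn.close()

    # -- registry ----------------------------------------------------------

    def _store_name(self, namespace: str, table_name: str) -> str:
        if namespace not in NAMESPACES:
            raise ValueError(f"unknown namespace {namespace!r}")
        return _PREFIX[namespace] + table_name

    def list_tables(self, namespace: str) -> list[str]:
        prefix = _PREFIX[namespace]
        rows = self.conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table' AND name LIKE ?",
            (prefix + "%",),
        ).fetchall()
        names = [r[0][len(prefix):] for r in rows]
        if namespace == "metadata":
            names = [n for n in names if n in METADATA_TABLES]
        return sorted(names)

    def has_table(self, namespace: str, table_name: str) -> bool:
        row = self.conn.execute(
            "SELECT 1 FROM sqlite_master WHERE type='table' AND name=?",
            (self._store_name(namespace, table_name),),
        ).fetchone()
        return row is not None

    def has_schema(self, namespace: str) -> bool:
        if namespace == "metadata":
            return set(METADATA_TABLES) <= set(self.list_tables("metadata"))
        return namespace in NAMESPACES

    # -- data tables -------------------------------------------------------

    def write_table(self, namespace: str, table_name: str, data: pd.DataFrame) -> None:
        data.to_sql(self._store_name(namespace, table_name), self.conn,
                    index=False, if_exists="replace")

    def read_table(self, namespace: str, table_name: str) -> pd.DataFrame:
        if not self.has_table(namespace, table_name):
            raise KeyError(f"{namespace}.{table_name} not in store")
        return pd.read_sql_query(
            f'SELECT * FROM "{self._store_name(namespace, table_name)}"', self.conn
        )

    # -- metadata schema ---------------------------------------------------

    def write_metadata(
        self,
        descriptions: list[QuestionnaireDescription],
        variables: list[QuestionnaireVariable],
        codebook: list[CodebookEntry],
    ) -> None:
        desc = pd.DataFrame(
            [
                {
                    "table_name": d.table_name,
                    "description": d.description,
                    "begin_year": d.begin_year,
                    "end_year": d.end_year,
                    "data_group": d.data_group,
                    "use_constraints": d.use_constraints.value,
                    "doc_file": d.doc_file,
                    "data_file": d.data_file,
                    "date_published": d.date_published,
                }
                for d in descriptions
            ],
            columns=["table_name", "description", "begin_year", "end_year",
                     "data_group", "use_constraints", "doc_file", "data_file",
                     "date_published"],
        )
        var = pd.DataFrame(
            [
                {
                    "variable": v.variable,
                    "table_name": v.table_name,
                    "sas_label": v.sas_label,
                    "english_text": v.english_text,
                    "english_instructions": v.english_instructions,
                    "hard_edits": v.hard_edits,
                    "target": "\x1f".join(v.target),
                }
                for v in variables
            ],
            columns=["variable", "table_name", "sas_label", "english_text",
                     "english_instructions", "hard_edits", "target"],
        )
        cb = pd.DataFrame(
            [
                {
                    "variable": e.variable,
                    "table_name": e.table_name,
                    "code_or_value": e.code_or_value,
                    "value_description": e.value_description,
                    "count": e.count,
                    "cumulative": e.cumulative,
                    "skip_to_item": e.skip_to_item,
                }
                for e in codebook
            ],
            columns=["variable", "table_name", "code_or_value",
                     "value_description", "count", "cumulative", "skip_to_item"],
        )
        self.write_table("metadata", "questionnaire_descriptions", desc)
        self.write_table("metadata", "questionnaire_variables", var)
        self.write_table("metadata", "variable_codebook", cb)
        if not self.has_table("metadata", "version_info"):
            self.write_table(
                "metadata", "version_info",
                pd.DataFrame(columns=["variable", "value"]),
            )

    def read_metadata_rows(self, table: str) -> list[dict]:
        if table not in METADATA_TABLES:
            raise KeyError(table)
        if not self.has_table("metadata", table):
            raise MissingSchemaError("metadata")
        df = self.read_table("metadata", table)
        df = df.where(pd.notna(df), None)
        return df.to_dict("records")

    # -- version info ------------------------------------------------------

    def read_version_info(self) -> VersionInfo:
        df = self.read_table("metadata", "version_info")
        pairs = dict(zip(df["variable"], df["value"]))
        return VersionInfo(
            container_version=pairs["CONTAINER_VERSION"],
            collection_date=_dt.date.fromisoformat(pairs["COLLECTION_DATE"]),
        )

    # -- documentation pass-through ---------------------------------------

    def store_doc(self, table_name: str, html: str) -> None:
        self.conn.execute(
            "CREATE TABLE IF NOT EXISTS metadata__documents "
            "(table_name TEXT PRIMARY KEY, html TEXT)"
        )
        self.conn.execute(
            "INSERT OR REPLACE INTO metadata__documents VALUES (?, ?)",
            (table_name, html),
        )
        self.conn.commit()

    # -- build log ---------------------------------------------------------

    def log_build_event(self, kind: str, message: str) -> None:
        self.conn.execute(
            "CREATE TABLE IF NOT EXISTS metadata__build_log (kind TEXT, message TEXT)"
        )
        self.conn.execute(
            "INSERT INTO metadata__build_log VALUES (?, ?)", (kind, message)
        )
        self.conn.commit()

    def build_log(self) -> list[tuple[str, str]]:
        if not self.has_table("metadata", "build_log") and not self._raw_has("metadata__build_log"):
            return []
        return list(
            self.conn.execute("SELECT kind, message FROM metadata__build_log")
        )

    def _raw_has(self, name: str) -> bool:
        return self.conn.execute(
            "SELECT 1 FROM sqlite_master WHERE type='table' AND name=?", (name,)
        ).fetchone() is not None

    # -- integrity ---------------------------------------------------------

    def checksum(self) -> str:
        """Content hash over all tables; rebuild determinism and CLI
        read-only guarantees are tested against it."""
        h = hashlib.sha256()
        for (name,) in self.conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table' ORDER BY name"
        ):
            h.update(name.encode())
            for row in self.conn.execute(f'SELECT * FROM "{name}"'):
                h.update(repr(row).encode())
        return h.hexdigest()


def write_version_info(
    store: SnapshotStore,
    container_version: str,
    collection_date: _dt.date,
    overwrite: bool = False,
) -> None:
    """Record the snapshot's version table (two rows: container version and
    collection date).  A second write requires the explicit overwrite flag.
    A connected client can read both with a plain query — no environment
    variables needed."""
    existing = (
        store.has_table("metadata", "version_info")
        and len(store.read_table("metadata", "version_info")) > 0
    )
    if existing and not overwrite:
        raise VersionExistsError(
            "VersionInfo already written; pass overwrite=True to replace it"
        )
    vi = VersionInfo(container_version=container_version, collection_date=collection_date)
    store.write_table(
        "metadata", "version_info",
        pd.DataFrame(vi.as_rows(), columns=["variable", "value"]),
    )


def serve_doc(store_or_base: SnapshotStore | str | Path, table_name: str) -> str:
    """Return the stored HTML documentation for a table.

    Works against a built store or against a documentation base directory
    (the NHANES_TABLE_BASE contract).  Pages are stored byte-identically at
    build time, so the documentation shown always matches the data loaded.
    """
    if isinstance(store_or_base, SnapshotStore):
        row = None
        if store_or_base._raw_has("metadata__documents"):
            row = store_or_base.conn.execute(
                "SELECT html FROM metadata__documents WHERE table_name=?",
                (table_name,),
            ).fetchone()
        if row is None:
            raise DocNotFoundError(table_name)
        return row[0]
    base = Path(store_or_base)
    for ext in (".htm", ".html"):
        p = base / f"{table_name}{ext}"
        if p.exists():
            return p.read_text(encoding="utf-8")
    raise DocNotFoundError(table_name)


def load_raw_table(path: str | Path, table_name: str | None = None) -> RawTable:
    """Read a released raw table from SAS transport (XPT) or CSV."""
    p = Path(path)
    name = table_name or p.stem
    if p.suffix.lower() == ".xpt":
        df = pd.read_sas(p, format="xport")
    else:
        df = pd.read_csv(p)
    return RawTable(table_name=name, data=df)


def load_docs(
    doc_dir: str | Path, manifest: Manifest
) -> tuple[list[CodebookDoc], list[str]]:
    """Parse every manifest table's documentation page from a directory.

    Pages in an unsupported (non-standard) format are excluded and the
    table names returned separately, mirroring the policy of excluding
    files whose documentation cannot be processed.
    """
    docs: list[CodebookDoc] = []
    excluded: list[str] = []
    for entry in manifest.entries:
        html = serve_doc(doc_dir, entry.table_name)
        try:
            docs.append(parse_doc_page(html, source_path=entry.table_name))
        except UnsupportedDialectError:
            excluded.append(entry.table_name)
    return docs, excluded


def build_snapshot(
    manifest: Manifest,
    docs: list[CodebookDoc],
    raw_tables: list[RawTable],
    version: VersionInfo,
    exclusions: set[str] | None = None,
    path: str | Path = ":memory:",
    policy: TranslationPolicy = DEFAULT_POLICY,
    doc_html: dict[str, str] | None = None,
) -> SnapshotStore:
    """Assemble a complete snapshot store.

    Raw tables are loaded verbatim; translated counterparts are produced
    per-table from the matching documentation; metadata is extracted from
    all docs (restricted tables included); VersionInfo is written; excluded
    tables (config) are skipped and logged.  A shape mismatch between a raw
    table and its translation aborts the build with a diff summary.
    """
    exclusions = exclusions or set()
    store = SnapshotStore(path)
    docs_by_name = {d.table_name: d for d in docs}
    restricted = {
        e.table_name for e in manifest.entries
        if e.use_constraints is UseConstraint.RESTRICTED
    }

    kept_docs = [d for d in docs if d.table_name not in exclusions]
    descriptions, variables, codebook = extract_metadata(kept_docs, manifest)
    store.write_metadata(descriptions, variables, codebook)

    for raw in raw_tables:
        if raw.table_name in exclusions:
            store.log_build_event("excluded", f"{raw.table_name}: excluded by config")
            continue
        if raw.table_name in restricted:
            store.log_build_event(
                "restricted", f"{raw.table_name}: restricted data not loaded"
            )
            continue
        store.write_table("raw", raw.table_name, raw.data)
        doc = docs_by_name.get(raw.table_name)
        if doc is None:
            store.log_build_event(
                "warning", f"{raw.table_name}: no documentation; not translated"
            )
            continue
        translated = translate_table(raw, doc, policy)
        if translated.data.shape != raw.data.shape or list(
            translated.data.columns
        ) != list(raw.data.columns):
            raise BuildMismatchError(
                f"{raw.table_name}: translated shape {translated.data.shape} / columns "
                f"{list(translated.data.columns)} != raw {raw.data.shape} / "
                f"{list(raw.data.columns)}"
            )
        store.write_table("translated", raw.table_name, translated.data)
        for col, rep in translated.reports.items():
            for w in rep.warnings:
                store.log_build_event("translate-warning", f"{raw.table_name}.{col}: {w}")

    if doc_html:
        for name, html in doc_html.items():
            if name not in exclusions:
                store.store_doc(name, html)

    write_version_info(store, version.container_version, version.collection_date,
                       overwrite=True)
    return store
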