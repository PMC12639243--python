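"""Cross-table and cross-cycle consistency checks.

Long-running surveys drift: a label is reworded, a category is re-typed
with different capitalization, a measurement changes units, or a variable
name is recycled for an unrelated quantity.  Each of these silently
corrupts a pooled analysis — two byte-different spellings of the same level
become two different factor levels.  These checks compare a variable's
metadata across every table it appears in and report findings with
evidence; they never auto-correct anything, since deciding whether two
variants mean the same quantity takes a human.

``qc_var`` covers the four documentation-header consistency dimensions
(SAS label, target, English text, multiple tables within one cycle);
level-spelling, unit, name-reuse and presence checks are separate
operations with their own contracts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .dbbuild import SnapshotStore
from .metadata_model import (
    WarningRecord,
    metadata_cb,
    metadata_tab,
    metadata_var,
)


class CheckId(str, Enum):
    LABEL_MISMATCH = "label_mismatch"
    TARGET_MISMATCH = "target_mismatch"
    DESCRIPTION_MISMATCH = "description_mismatch"
    MULTI_TABLE_IN_CYCLE = "multi_table_in_cycle"
    LEVEL_VARIANT = "level_variant"
    UNIT_CHANGE = "unit_change"
    NAME_REUSE = "name_reuse"
    PRESENCE_GAP = "presence_gap"


class Severity(str, Enum):
    INFO = "info"
    WARN = "warn"
    ERROR = "error"


@dataclass
class QCFinding:
    """One detected inconsistency.

    ``variants`` partitions the affected tables by the value they carry:
    a list of (evidence value, tables holding it).  For presence gaps the
    evidence values are "present"/"absent".
    """

    check_id: CheckId
    variable: str
    variants: list[tuple[str, list[str]]]
    severity: Severity = Severity.WARN
    detail: str = ""

    @property
    def tables(self) -> list[str]:
        return sorted({t for _, ts in self.variants for t in ts})


_TRAILING_PUNCT = re.compile(r"[\s\.\,\;\:\!\?]+$")
_WS = re.compile(r"\s+")


def normalize_level(label: str) -> str:
    """Case-fold, collapse internal whitespace, strip trailing punctuation.

    Deliberately nothing stronger (no stemming or edit distance), so every
    finding stays explainable by eye.
    """
    return _TRAILING_PUNCT.sub("", _WS.sub(" ", label.strip())).casefold()


def _variants_from_groups(groups: dict[str, list[str]]) -> list[tuple[str, list[str]]]:
    return sorted(((v, sorted(ts)) for v, ts in groups.items()),
                  key=lambda p: (-len(p[1]), p[0]))


def _var_rows(store: SnapshotStore, variable: str,
              scope: set[str] | None) -> list:
    rows = metadata_var(store)
    return [
        r for r in rows
        if r.variable == variable and (scope is None or r.table_name in scope)
    ]


def qc_var(
    store: SnapshotStore,
    variable: str,
    scope: set[str] | None = None,
    warnings: list[WarningRecord] | None = None,
) -> list[QCFinding]:
    """Consistency of one variable's documentation header across tables.

    Emits a finding per header field (SAS label, target, English text)
    whose value differs across the tables carrying the variable, plus a
    finding when the variable occurs in more than one table of a single
    cycle.  An unknown variable yields an empty result and a warning.
    """
    rows = _var_rows(store, variable, scope)
    if not rows:
        if warnings is not None:
            warnings.append(WarningRecord("qc_var", f"variable {variable!r} not found"))
        return []
    findings: list[QCFinding] = []
    fields = [
        (CheckId.LABEL_MISMATCH, "SAS label", lambda v: v.sas_label),
        (CheckId.TARGET_MISMATCH, "target", lambda v: " | ".join(v.target)),
        (CheckId.DESCRIPTION_MISMATCH, "English text", lambda v: v.english_text),
    ]
    for check_id, label, get in fields:
        groups: dict[str, list[str]] = {}
        for r in rows:
            groups.setdefault(get(r), []).append(r.table_name)
        if len(groups) > 1:
            findings.append(
                QCFinding(
                    check_id=check_id,
                    variable=variable,
                    variants=_variants_from_groups(groups),
                    severity=Severity.WARN,
                    detail=f"{label} differs across {len(groups)} variants",
                )
            )
    cycles = {
        d.table_name: d.cycle
        for d in metadata_tab(store, include_restricted=True)
    }
    by_cycle: dict[tuple[int, int], list[str]] = {}
    for r in rows:
        cyc = cycles.get(r.table_name)
        if cyc is not None:
            by_cycle.setdefault(cyc, []).append(r.table_name)
    for cyc, tabs in sorted(by_cycle.items()):
        if len(tabs) > 1:
            findings.append(
                QCFinding(
                    check_id=CheckId.MULTI_TABLE_IN_CYCLE,
                    variable=variable,
                    variants=[(f"cycle {cyc[0]}-{cyc[1]}", sorted(tabs))],
                    severity=Severity.WARN,
                    detail=f"present in {len(tabs)} tables of one cycle",
                )
            )
    return findings


def qc_levels(store: SnapshotStore, variable: str) -> list[QCFinding]:
    """Detect level spellings that differ only typographically across tables.

    Labels that agree after normalization (case-fold + whitespace collapse +
    trailing punctuation strip) but are not byte-equal get a level_variant
    finding whose variants partition the tables by spelling.  Level sets
    that differ beyond normalization are reported at info severity — those
    may be genuine recodes, not typography.
    """
    entries = metadata_cb(store, variables=[variable])
    per_table: dict[str, list[str]] = {}
    for e in entries:
        per_table.setdefault(e.table_name, []).append(e.value_description)
    if len(per_table) < 1:
        return []
    findings: list[QCFinding] = []

    # spelling variants within a normalization class
    spellings: dict[str, dict[str, set[str]]] = {}  # norm -> spelling -> tables
    for table, labels in per_table.items():
        for lab in labels:
            spellings.setdefault(normalize_level(lab), {}).setdefault(lab, set()).add(table)
    for norm, variants in sorted(spellings.items()):
        if len(variants) > 1:
            findings.append(
                QCFinding(
                    check_id=CheckId.LEVEL_VARIANT,
                    variable=variable,
                    variants=_variants_from_groups(
                        {sp: sorted(ts) for sp, ts in variants.items()}
                    ),
                    severity=Severity.WARN,
                    detail=f"level {norm!r} spelled {len(variants)} ways",
                )
            )

    # level-set differences that survive normalization
    norm_sets: dict[str, list[str]] = {}
    for table, labels in per_table.items():
        key = " | ".join(sorted({normalize_level(x) for x in labels}))
        norm_sets.setdefault(key, []).append(table)
    if len(norm_sets) > 1:
        findings.append(
            QCFinding(
                check_id=CheckId.DESCRIPTION_MISMATCH,
                variable=variable,
                variants=_variants_from_groups(norm_sets),
                severity=Severity.INFO,
                detail="level sets differ beyond typographic normalization",
            )
        )
    return findings


_PAREN_RE = re.compile(r"\(([^()]*)\)")


def _unit_tokens(*texts: str) -> frozenset[str]:
    tokens = []
    for t in texts:
        tokens.extend(m.strip() for m in _PAREN_RE.findall(t))
    return frozenset(tok for tok in tokens if tok)


def qc_units(
    store: SnapshotStore, variable: str, range_factor: float = 10.0
) -> list[QCFinding]:
    """Flag likely unit changes across tables.

    Two signals: (1) the parenthesized unit tokens in the SAS label /
    English text differ across tables; (2) the codebook value-range
    midpoints differ by at least ``range_factor`` (default 10x) between
    tables, which catches unit rescalings that the labels do not admit.
    """
    rows = _var_rows(store, variable, None)
    if len(rows) < 2:
        return []
    findings: list[QCFinding] = []
    token_groups: dict[str, list[str]] = {}
    for r in rows:
        key = ", ".join(sorted(_unit_tokens(r.sas_label, r.english_text))) or "<none>"
        token_groups.setdefault(key, []).append(r.table_name)
    if len(token_groups) > 1:
        findings.append(
            QCFinding(
                check_id=CheckId.UNIT_CHANGE,
                variable=variable,
                variants=_variants_from_groups(token_groups),
                severity=Severity.WARN,
                detail="parenthesized unit tokens differ across tables",
            )
        )

    from .translator import is_range_code, parse_range

    mids: dict[str, float] = {}
    for e in metadata_cb(store, variables=[variable]):
        if is_range_code(e.code_or_value):
            lo, hi = parse_range(e.code_or_value)
            mids[e.table_name] = (lo + hi) / 2.0
    positive = {t: m for t, m in mids.items() if m > 0}
    if len(positive) >= 2:
        lo_t = min(positive, key=positive.get)  # type: ignore[arg-type]
        hi_t = max(positive, key=positive.get)  # type: ignore[arg-type]
        if positive[hi_t] / positive[lo_t] >= range_factor:
            groups = {f"midpoint {m:g}": [t] for t, m in sorted(positive.items())}
            findings.append(
                QCFinding(
                    check_id=CheckId.UNIT_CHANGE,
                    variable=variable,
                    variants=_variants_from_groups(groups),
                    severity=Severity.WARN,
                    detail=(
                        f"value-range midpoints differ {positive[hi_t] / positive[lo_t]:.0f}x "
                        f"between {lo_t} and {hi_t}"
                    ),
                )
            )
    return findings


_TOKEN_RE = re.compile(r"[a-z0-9]+")


def _jaccard(a: str, b: str) -> float:
    ta = set(_TOKEN_RE.findall(a.casefold()))
    tb = set(_TOKEN_RE.findall(b.casefold()))
    if not ta and not tb:
        return 1.0
    return len(ta & tb) / len(ta | tb)


def qc_name_reuse(
    store: SnapshotStore, variable: str, threshold: float = 0.2
) -> list[QCFinding]:
    """Detect one variable name covering two unrelated measurements.

    English-text descriptions are compared pairwise by token-set Jaccard
    similarity; any pair below the threshold means the name very likely
    denotes different quantities in different tables (error severity).
    Tables are partitioned into similarity clusters for the evidence.
    """
    rows = _var_rows(store, variable, None)
    if len(rows) < 2:
        return []
    low_pair = False
    n = len(rows)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _jaccard(rows[i].english_text, rows[j].english_text) >= threshold:
                parent[find(i)] = find(j)
            else:
                low_pair = True
    if not low_pair:
        return []
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    if len(clusters) < 2:
        return []  # dissimilar pair bridged transitively; not a clean split
    groups = {
        rows[members[0]].english_text or "<empty>": [rows[m].table_name for m in members]
        for members in clusters.values()
    }
    return [
        QCFinding(
            check_id=CheckId.NAME_REUSE,
            variable=variable,
            variants=_variants_from_groups(groups),
            severity=Severity.ERROR,
            detail=f"descriptions fall into {len(clusters)} dissimilar clusters "
                   f"(Jaccard < {threshold})",
        )
    ]


def qc_presence_matrix(
    store: SnapshotStore, tables: list[str]
) -> tuple[pd.DataFrame, list[QCFinding]]:
    """Variables-by-tables incidence over a set of related tables.

    A variable present in some but not all of the tables gets a
    presence_gap finding listing where it is absent — the automatable half
    of spotting per-file renames (whether the differently-named variables
    measure the same quantity still takes manual review, and the matrix is
    returned for exactly that).
    """
    if len(tables) < 2:
        raise ValueError("presence matrix needs at least two tables")
    rows = metadata_var(store, table_names=tables)
    variables = sorted({r.variable for r in rows})
    matrix = pd.DataFrame(False, index=variables, columns=tables)
    for r in rows:
        matrix.at[r.variable, r.table_name] = True
    findings = []
    for v in variables:
        present = [t for t in tables if matrix.at[v, t]]
        absent = [t for t in tables if not matrix.at[v, t]]
        if present and absent:
            findings.append(
                QCFinding(
                    check_id=CheckId.PRESENCE_GAP,
                    variable=v,
                    variants=[("present", present), ("absent", absent)],
                    severity=Severity.WARN,
                    detail=f"absent from {len(absent)} of {len(tables)} tables",
                )
            )
    return matrix, findings


_FAMILY_RE = re.compile(r"^(?P<base>.+?)(?:_(?P<suffix>[A-Z]))?$")


def table_families(store: SnapshotStore) -> dict[str, list[str]]:
    """Group table names into release families (DEMO, DEMO_B, ... -> DEMO)."""
    fams: dict[str, list[str]] = {}
    for d in metadata_tab(store, include_restricted=True):
        m = _FAMILY_RE.match(d.table_name)
        base = m.group("base") if m else d.table_name
        fams.setdefault(base, []).append(d.table_name)
    return {b: sorted(ts) for b, ts in fams.items()}


def qc_all(store: SnapshotStore) -> list[QCFinding]:
    """Run every check over every variable (plus per-family presence).

    This is the whole-snapshot sweep: on a consistent snapshot it returns
    nothing, so any finding is worth a look.
    """
    findings: list[QCFinding] = []
    names = sorted({r.variable for r in metadata_var(store)})
    for v in names:
        findings += qc_var(store, v)
        findings += qc_levels(store, v)
        findings += qc_units(store, v)
        findings += qc_name_reuse(store, v)
    for tables in table_families(store).values():
        if len(tables) >= 2:
            findings += qc_presence_matrix(store, tables)[1]
    return findings


def run_matching_check(
    store: SnapshotStore, check_id: CheckId | str, variable: str,
    tables: list[str] | None = None,
) -> list[QCFinding]:
    """Run the single check responsible for a given check id and return its
    findings for one variable (presence checks take the table set instead)."""
    check_id = CheckId(check_id)
    if check_id in (CheckId.LABEL_MISMATCH, CheckId.TARGET_MISMATCH,
                    CheckId.DESCRIPTION_MISMATCH, CheckId.MULTI_TABLE_IN_CYCLE):
        found = qc_var(store, variable)
    elif check_id is CheckId.LEVEL_VARIANT:
        found = qc_levels(store, variable)
    elif check_id is CheckId.UNIT_CHANGE:
        found = qc_units(store, variable)
    elif check_id is CheckId.NAME_REUSE:
        found = qc_name_reuse(store, variable)
    elif check_id is CheckId.PRESENCE_GAP:
        if not tables:
            raise ValueError("presence check needs the table set")
        found = qc_presence_matrix(store, tables)[1]
    else:  # pragma: no cover - exhaustive above
        raise ValueError(check_id)
    return [f for f in found if f.check_id is check_id]


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def findings_to_frame(findings: list[QCFinding]) -> pd.DataFrame:
    recs = [
        {
            "check_id": f.check_id.value,
            "variable": f.variable,
            "severity": f.severity.value,
            "detail": f.detail,
            "variants": "; ".join(
                f"{val!r}: {','.join(ts)}" for val, ts in f.variants
            ),
        }
        for f in findings
    ]
    return pd.DataFrame(
        recs, columns=["check_id", "variable", "severity", "detail", "variants"]
    )


def findings_to_tsv(findings: list[QCFinding]) -> str:
    return findings_to_frame(findings).to_csv(sep="\t", index=False)


def findings_to_html(findings: list[QCFinding], title: str = "QC report") -> str:
    body = findings_to_frame(findings).to_html(index=False, border=0)
    return (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        f"<title>{title}</title></head><body>\n<h1>{title}</h1>\n{body}\n</body></html>\n"
    )
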