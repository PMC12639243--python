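"""Raw-to-translated table conversion.

Raw tables hold the coded values exactly as released: categorical answers as
integer codes, continuous measurements as numbers, and missing as NaN.  The
translated counterpart replaces each categorical code by its English value
description from the codebook, leaves continuous values untouched, and maps
the special codes of mixed variables (Refused / Don't know sentinels living
alongside a numeric range) to missing by default.  Shape is preserved
exactly; SEQN is never modified.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .metadata_model import CodebookEntry
from .codebook_parser import CodebookDoc

SEQN = "SEQN"

_RANGE_RE = re.compile(r"^\s*-?[\d.eE+]+\s+to\s+-?[\d.eE+]+\s*$", re.IGNORECASE)


class VariableKind(str, Enum):
    CATEGORICAL = "categorical"
    CONTINUOUS = "continuous"
    MIXED = "mixed"


class AmbiguousCodebookError(ValueError):
    """A codebook group contains two distinct range rows."""


class DuplicateLevelError(ValueError):
    """Byte-identical value descriptions repeat within one codebook group."""


class MissingSeqnError(ValueError):
    pass


@dataclass(frozen=True)
class TranslationPolicy:
    """Knobs for the translation step.

    ``missing_codes`` are the codebook codes denoting a missing answer (the
    conventional ``"."`` row).  In mixed variables every discrete code whose
    description is not ``range_description`` is treated as special; with
    ``special_to_missing`` (the default) such values become missing in the
    translated table.  ``level_exclude_descriptions`` are dropped from
    :func:`ordered_levels`.
    """

    missing_codes: frozenset[str] = frozenset({"."})
    range_description: str = "Range of Values"
    special_to_missing: bool = True
    level_exclude_descriptions: frozenset[str] = frozenset({"Missing"})


DEFAULT_POLICY = TranslationPolicy()


@dataclass
class ColumnReport:
    variable: str
    kind: VariableKind
    n_translated: int = 0
    n_special_to_missing: int = 0
    n_unmapped: int = 0
    warnings: list[str] = field(default_factory=list)


@dataclass
class RawTable:
    """A coded table as released; SEQN must be present and unique."""

    table_name: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if SEQN not in self.data.columns:
            raise MissingSeqnError(f"{self.table_name}: no {SEQN} column")
        if self.data[SEQN].duplicated().any():
            dupes = self.data.loc[self.data[SEQN].duplicated(), SEQN].tolist()
            raise ValueError(f"{self.table_name}: duplicate {SEQN} values {dupes[:5]}")


@dataclass
class TranslatedTable:
    table_name: str
    data: pd.DataFrame
    reports: dict[str, ColumnReport]


def is_range_code(code: str) -> bool:
    return bool(_RANGE_RE.match(code))


def parse_range(code: str) -> tuple[float, float]:
    lo, hi = re.split(r"\s+to\s+", code.strip(), flags=re.IGNORECASE)
    return float(lo), float(hi)


def code_key(value) -> str | None:
    """Canonical string form of a raw coded value, for codebook lookup.

    SAS-sourced columns are floats, so integral floats collapse to their
    integer spelling ("1.0" -> "1").  Missing values map to None.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        return str(int(value)) if float(value).is_integer() else repr(float(value))
    return str(value).strip()


def _partition(entries: list[CodebookEntry], policy: TranslationPolicy):
    missing = [e for e in entries if e.code_or_value in policy.missing_codes]
    nonmissing = [e for e in entries if e.code_or_value not in policy.missing_codes]
    ranges = [e for e in nonmissing if is_range_code(e.code_or_value)]
    discrete = [e for e in nonmissing if not is_range_code(e.code_or_value)]
    return missing, ranges, discrete


def classify_variable(
    entries: list[CodebookEntry], policy: TranslationPolicy = DEFAULT_POLICY
) -> VariableKind:
    """Decide how a variable is coded, from its codebook group alone.

    Continuous: a single range row (plus missing sentinels).  Categorical:
    only discrete codes.  Mixed: a range row coexisting with discrete special
    codes.  Two distinct range rows are an ambiguous codebook and an error.
    """
    if not entries:
        raise ValueError("empty codebook group")
    _, ranges, discrete = _partition(entries, policy)
    if len(ranges) > 1:
        key = (entries[0].variable, entries[0].table_name)
        raise AmbiguousCodebookError(
            f"{key}: multiple range rows {[e.code_or_value for e in ranges]}"
        )
    if ranges and discrete:
        return VariableKind.MIXED
    if ranges:
        return VariableKind.CONTINUOUS
    return VariableKind.CATEGORICAL


def ordered_levels(
    entries: list[CodebookEntry], policy: TranslationPolicy = DEFAULT_POLICY
) -> list[str]:
    """Category labels in codebook document order.

    Document order is the ordering the codebook intends (e.g. ascending
    education levels), so it is what an ordered factor/categorical should
    use.  Missing-class sentinels are excluded per policy.  Byte-identical
    duplicate labels raise :class:`DuplicateLevelError`; case-variant
    near-duplicates pass here — detecting those is QC's job.
    """
    labels = [
        e.value_description
        for e in entries
        if e.code_or_value not in policy.missing_codes
        and e.value_description not in policy.level_exclude_descriptions
    ]
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise DuplicateLevelError(f"duplicate level labels {dupes}")
    return labels


def translate_column(
    values: pd.Series,
    entries: list[CodebookEntry],
    policy: TranslationPolicy = DEFAULT_POLICY,
) -> tuple[pd.Series, ColumnReport]:
    """Translate one column according to its codebook group.

    Nothing here is fatal: unmapped categorical codes become missing and are
    counted, special codes of mixed variables are handled per policy, and
    every anomaly lands in the report.
    """
    kind = classify_variable(entries, policy)
    report = ColumnReport(variable=entries[0].variable, kind=kind)
    _, ranges, discrete = _partition(entries, policy)

    if kind is VariableKind.CONTINUOUS:
        out = values.copy()
        report.n_translated = int(values.notna().sum())
        return out, report

    mapping = {e.code_or_value: e.value_description for e in discrete}

    if kind is VariableKind.CATEGORICAL:
        translated = []
        for v in values:
            key = code_key(v)
            if key is None:
                translated.append(None)
            elif key in mapping:
                translated.append(mapping[key])
                report.n_translated += 1
            else:
                translated.append(None)
                report.n_unmapped += 1
        if report.n_unmapped:
            report.warnings.append(
                f"{entries[0].variable}: {report.n_unmapped} values had no codebook entry"
            )
        return pd.Series(translated, index=values.index, dtype=object), report

    # mixed: keep in-range numerics, special codes -> policy
    special = set(mapping)
    out_vals = []
    for v in values:
        key = code_key(v)
        if key is None:
            out_vals.append(np.nan)
        elif key in special:
            if policy.special_to_missing:
                out_vals.append(np.nan)
                report.n_special_to_missing += 1
            else:
                out_vals.append(float(v))
        else:
            out_vals.append(float(v))
            report.n_translated += 1
    return pd.Series(out_vals, index=values.index, dtype=float), report


def translate_table(
    raw: RawTable,
    doc: CodebookDoc,
    policy: TranslationPolicy = DEFAULT_POLICY,
) -> TranslatedTable:
    """Translate a whole raw table using its documentation page.

    The doc must describe the same table.  A data column without a codebook
    block passes through untranslated with a warning; SEQN is copied as-is.
    """
    if doc.table_name != raw.table_name:
        raise ValueError(
            f"doc is for {doc.table_name!r}, data is {raw.table_name!r}"
        )
    blocks = {v.variable: entries for v, entries in doc.variables}
    out = pd.DataFrame(index=raw.data.index)
    reports: dict[str, ColumnReport] = {}
    for col in raw.data.columns:
        if col == SEQN:
            out[col] = raw.data[col]
            continue
        entries = blocks.get(col)
        if not entries:
            out[col] = raw.data[col]
            reports[col] = ColumnReport(
                variable=col,
                kind=VariableKind.CONTINUOUS,
                warnings=[f"{col}: no codebook block; passed through untranslated"],
            )
            continue
        out[col], reports[col] = translate_column(raw.data[col], entries, policy)
    assert out.shape == raw.data.shape
    return TranslatedTable(table_name=raw.table_name, data=out, reports=reports)
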