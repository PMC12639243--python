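"""Synthetic snapshot generator: the offline stand-in for the upstream source.

Emits everything a real snapshot build consumes — a manifest, one HTML
documentation page per table, and coded raw data files (CSV by default,
SAS transport behind a flag) — for a configurable number of 2-year cycles,
with questionnaire skip patterns, a survey population with known design
structure and known true subgroup means, and injectable cross-cycle
inconsistencies (typographic level variants, unit changes, description
rewrites, name reuse, per-file weight renames) whose ground truth is
written alongside for recall testing.

Everything is deterministic: the same spec and seed produce byte-identical
output trees, and every emitted codebook's Counts equal the realized
frequencies in the emitted data (so downstream count-reconciliation checks
are exact, not statistical).
"""

from __future__ import annotations

import dataclasses
import json
import math
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .codebook_parser import Manifest, parse_manifest
from .dbbuild import SnapshotStore, build_snapshot, load_docs, load_raw_table
from .metadata_model import END_OF_SECTION, VersionInfo

_SUFFIXES = ["", "_B", "_C", "_D", "_E", "_F", "_G", "_H", "_I", "_J",
             "_K", "_L", "_M", "_N"]

KNOWN_INJECTIONS = {
    "level_variant", "unit_change", "name_reuse", "presence_gap",
    "label_mismatch", "target_mismatch", "description_mismatch",
    "multi_table_in_cycle",
}


class FixtureSpecError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Spec types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariableSpec:
    """One questionnaire variable: how it is coded and how it is asked.

    ``skip`` maps an answer code to the variable asked next (or the
    end-of-section sentinel); everything in between is structurally skipped
    for respondents giving that answer.
    """

    name: str
    kind: str  # categorical | continuous | mixed
    sas_label: str
    english_text: str = ""
    instructions: str = ""
    hard_edits: str = ""
    target: tuple[str, ...] = ("Both males and females 0 YEARS - 150 YEARS",)
    levels: tuple[tuple[int, str], ...] = ()
    value_range: tuple[float, float] | None = None
    special: tuple[tuple[int, str], ...] = ()
    skip: tuple[tuple[int, str], ...] = ()
    missing_rate: float = 0.05
    special_rate: float = 0.08
    decimals: int = 1


@dataclass(frozen=True)
class TableSpec:
    family: str
    description: str
    data_group: str
    variables: tuple[VariableSpec, ...]
    use_constraints: str = "public"


@dataclass(frozen=True)
class PopulationSpec:
    """Survey population with known truth, for estimation tests.

    Outcome model per respondent i in PSU j of stratum h, cycle c:
    ``y = mu_c + b_hj + e``, with ``mu_c = base_mean + c * cycle_drift``,
    PSU effects ``b ~ N(0, psu_sd^2)`` and residuals ``e ~ N(0, resid_sd^2)``.
    Ages are uniform over ``age_range`` and weights lognormal, both
    independent of the outcome, so the true domain (age-restricted) mean is
    ``mu_c``.  Defaults emulate a BMI-like measurement with a slow upward
    secular drift.
    """

    n_strata: int = 15
    psus_per_stratum: int = 2
    n_per_psu: int = 10
    base_mean: float = 26.0
    cycle_drift: float = 0.5
    psu_sd: float = 0.8
    resid_sd: float = 4.5
    weight_sigma: float = 0.5
    age_range: tuple[int, int] = (20, 79)
    domain_ages: tuple[int, int] = (40, 59)


@dataclass(frozen=True)
class Injection:
    check_id: str
    variable: str
    params: dict = field(default_factory=dict)


def _default_tables() -> tuple[TableSpec, ...]:
    return (
        TableSpec(
            family="EDU",
            description="Demographic Background - Education",
            data_group="Demographics",
            variables=(
                VariableSpec(
                    name="DMDEDUC3",
                    kind="categorical",
                    sas_label="Education Level - Children/Youth 6-19",
                    english_text="What is the highest grade or level of school "
                                 "completed or the highest degree received?",
                    target=("Both males and females 6 YEARS - 19 YEARS",),
                    levels=(
                        (1, "Less Than 5th Grade"),
                        (2, "5th Grade"),
                        (3, "6th Grade"),
                        (4, "7th Grade"),
                        (5, "8th Grade"),
                        (6, "9th Grade"),
                        (7, "10th Grade"),
                        (8, "11th Grade"),
                        (77, "Refused"),
                        (99, "Don't know"),
                    ),
                ),
                VariableSpec(
                    name="INDFMPIR",
                    kind="mixed",
                    sas_label="Ratio of family income to poverty",
                    english_text="Ratio of family income to poverty threshold.",
                    value_range=(0.0, 5.0),
                    special=((777, "Refused"),),
                    decimals=2,
                ),
            ),
        ),
        TableSpec(
            family="SMQ",
            description="Smoking - Cigarette Use",
            data_group="Questionnaire",
            variables=(
                VariableSpec(
                    name="SMQ020",
                    kind="categorical",
                    sas_label="Smoked at least 100 cigarettes in life",
                    english_text="Have you smoked at least 100 cigarettes in "
                                 "your entire life?",
                    target=("Both males and females 20 YEARS - 150 YEARS",),
                    levels=((1, "Yes"), (2, "No"), (7, "Refused"), (9, "Don't know")),
                    skip=((2, "SMD070"), (7, "SMD070"), (9, "SMD070")),
                ),
                VariableSpec(
                    name="SMD030",
                    kind="mixed",
                    sas_label="Age started smoking cigarettes regularly",
                    english_text="How old were you when you started smoking "
                                 "cigarettes fairly regularly?",
                    value_range=(7.0, 76.0),
                    special=((777, "Refused"), (999, "Don't know")),
                    decimals=0,
                ),
                VariableSpec(
                    name="SMD055",
                    kind="continuous",
                    sas_label="Age last smoked cigarettes regularly",
                    english_text="How old were you when you last smoked "
                                 "cigarettes fairly regularly?",
                    value_range=(10.0, 79.0),
                    decimals=0,
                ),
                VariableSpec(
                    name="SMD070",
                    kind="categorical",
                    sas_label="Number of cigarettes smoked - category",
                    english_text="Do you now smoke cigarettes?",
                    levels=((1, "Every day"), (2, "Some days"), (3, "Not at all")),
                ),
            ),
        ),
        TableSpec(
            family="LAB",
            description="Cadmium and special-sample weights",
            data_group="Laboratory",
            variables=(
                VariableSpec(
                    name="LBXCAD",
                    kind="continuous",
                    sas_label="Cadmium (ug/L)",
                    english_text="Blood cadmium concentration (ug/L).",
                    value_range=(0.0, 5.0),
                    decimals=2,
                ),
                VariableSpec(
                    name="WTSAF2YR",
                    kind="continuous",
                    sas_label="Subsample weight - 2 years",
                    english_text="Special subsample examination weight.",
                    value_range=(1000.0, 90000.0),
                    decimals=0,
                    missing_rate=0.0,
                ),
            ),
        ),
    )


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    cycles: tuple[tuple[int, int], ...] = ((1999, 2000), (2001, 2002), (2003, 2004))
    tables: tuple[TableSpec, ...] = field(default_factory=_default_tables)
    n_per_cycle: int = 150
    population: PopulationSpec | None = field(default_factory=PopulationSpec)
    injections: tuple[Injection, ...] = ()


def default_spec(seed: int = 0, **overrides) -> FixtureSpec:
    return replace(FixtureSpec(seed=seed), **overrides)


# ---------------------------------------------------------------------------
# Spec validation and injection registration
# ---------------------------------------------------------------------------

#: Variables the population realization always emits (DEMO/BMX families).
POPULATION_VARIABLES = frozenset(
    {"RIDAGEYR", "WTMEC2YR", "SDMVSTRA", "SDMVPSU", "BMXBMI"}
)


def _all_variable_names(spec: FixtureSpec) -> set[str]:
    names = {v.name for t in spec.tables for v in t.variables}
    if spec.population is not None:
        names |= POPULATION_VARIABLES
    return names


def validate_spec(spec: FixtureSpec) -> None:
    """Fail before anything is written: undefined skip targets, duplicate
    variable names across families, unknown injections."""
    names = _all_variable_names(spec)
    seen: set[str] = set()
    for t in spec.tables:
        order = [v.name for v in t.variables]
        for v in t.variables:
            if v.name in seen:
                raise FixtureSpecError(f"variable {v.name} defined in two families")
            if v.kind not in ("categorical", "continuous", "mixed"):
                raise FixtureSpecError(f"{v.name}: unknown kind {v.kind!r}")
            if v.kind == "categorical" and not v.levels:
                raise FixtureSpecError(f"{v.name}: categorical without levels")
            if v.kind in ("continuous", "mixed") and v.value_range is None:
                raise FixtureSpecError(f"{v.name}: {v.kind} without value_range")
            for code, tgt in v.skip:
                if tgt != END_OF_SECTION and tgt not in order:
                    raise FixtureSpecError(
                        f"{v.name}: skip target {tgt!r} not defined in family {t.family}"
                    )
                if tgt != END_OF_SECTION and order.index(tgt) <= order.index(v.name):
                    raise FixtureSpecError(
                        f"{v.name}: skip target {tgt!r} is not a later question"
                    )
        seen.update(order)
    if spec.population is not None and spec.population.psus_per_stratum < 2:
        import warnings

        warnings.warn(
            "population requests strata with a single PSU; downstream variance "
            "estimation will need a lonely-PSU policy",
            UserWarning,
            stacklevel=2,
        )
    for inj in spec.injections:
        if inj.check_id not in KNOWN_INJECTIONS:
            raise FixtureSpecError(f"unknown injection check_id {inj.check_id!r}")
        if inj.variable not in names:
            raise FixtureSpecError(
                f"injection {inj.check_id}: variable {inj.variable!r} not in spec"
            )


def inject(spec: FixtureSpec, injection: Injection) -> FixtureSpec:
    """Register an inconsistency injection; validated up front."""
    out = replace(spec, injections=spec.injections + (injection,))
    validate_spec(out)
    return out


# ---------------------------------------------------------------------------
# Realization: in-memory tables before emission
# ---------------------------------------------------------------------------

@dataclass
class _VarBlock:
    name: str
    sas_label: str
    english_text: str
    instructions: str
    hard_edits: str
    targets: tuple[str, ...]
    # rows: (code_or_value, description, count, skip_target or None)
    rows: list[tuple[str, str, int, str | None]]


@dataclass
class _Realized:
    table_name: str
    family: str
    cycle: tuple[int, int]
    cycle_index: int
    description: str
    data_group: str
    use_constraints: str
    blocks: list[_VarBlock]
    data: pd.DataFrame


def _fmt_number(x: float, decimals: int) -> float:
    return round(float(x), decimals) if decimals > 0 else float(int(round(x)))


def _draw_answer(v: VariableSpec, rng: np.random.Generator) -> float | None:
    """One asked question's answer; None is item nonresponse."""
    if rng.random() < v.missing_rate:
        return None
    if v.kind == "categorical":
        codes = [c for c, _ in v.levels]
        # common levels front-loaded so tails stay plausible
        probs = np.array([1.0 / (i + 1) for i in range(len(codes))])
        probs /= probs.sum()
        return float(rng.choice(codes, p=probs))
    if v.kind == "mixed" and v.special and rng.random() < v.special_rate:
        return float(v.special[rng.integers(len(v.special))][0])
    lo, hi = v.value_range  # type: ignore[misc]
    return _fmt_number(rng.uniform(lo, hi), v.decimals)


def _simulate_table(
    t: TableSpec, seqn: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    order = list(t.variables)
    pos = {v.name: i for i, v in enumerate(order)}
    cols: dict[str, list] = {v.name: [] for v in order}
    for _ in seqn:
        answers: dict[str, float | None] = {}
        i = 0
        while i < len(order):
            v = order[i]
            ans = _draw_answer(v, rng)
            answers[v.name] = ans
            nxt = i + 1
            if ans is not None and float(ans).is_integer():
                jump = dict(v.skip).get(int(ans))
                if jump == END_OF_SECTION:
                    nxt = len(order)
                elif jump is not None:
                    nxt = pos[jump]
            i = nxt
        for v in order:
            cols[v.name].append(answers.get(v.name, None))
    df = pd.DataFrame({"SEQN": seqn})
    for v in order:
        df[v.name] = pd.array(
            [np.nan if x is None else x for x in cols[v.name]], dtype=float
        )
    return df


def _range_str(lo: float, hi: float, decimals: int) -> str:
    def f(x: float) -> str:
        return f"{x:.{decimals}f}" if decimals > 0 else str(int(round(x)))
    return f"{f(lo)} to {f(hi)}"


def _codebook_rows(v: VariableSpec, col: pd.Series) -> list[tuple[str, str, int, str | None]]:
    """Realized codebook rows: Counts always equal emitted frequencies."""
    n = len(col)
    skip = {c: t for c, t in v.skip}
    rows: list[tuple[str, str, int, str | None]] = []
    if v.kind == "categorical":
        for code, label in v.levels:
            count = int((col == code).sum())
            tgt = skip.get(code)
            rows.append((str(code), label, count,
                         "End of Section" if tgt == END_OF_SECTION else tgt))
    else:
        lo, hi = v.value_range  # type: ignore[misc]
        specials = {c for c, _ in v.special}
        numeric = col.dropna()
        in_range = numeric[~numeric.isin(list(specials))] if specials else numeric
        if len(in_range):
            # codebooks print the observed range, not the nominal one
            lo, hi = float(in_range.min()), float(in_range.max())
        rows.append((_range_str(lo, hi, v.decimals), "Range of Values",
                     int(len(in_range)), None))
        for code, label in v.special:
            rows.append((str(code), label, int((col == code).sum()), None))
    n_missing = int(col.isna().sum())
    rows.append((".", "Missing", n_missing, None))
    return rows


def _realize_clean(spec: FixtureSpec) -> tuple[list[_Realized], dict]:
    rng = np.random.default_rng(spec.seed)
    realized: list[_Realized] = []
    truth: dict = {"population": None, "injections": []}
    pop_truth: dict[str, float] = {}
    for ci, cycle in enumerate(spec.cycles):
        suffix = _SUFFIXES[ci]
        seqn = np.arange(1, spec.n_per_cycle + 1) + 100000 * (ci + 1)
        for t in spec.tables:
            data = _simulate_table(t, seqn, rng)
            blocks = [
                _VarBlock(
                    name=v.name,
                    sas_label=v.sas_label,
                    english_text=v.english_text,
                    instructions=v.instructions,
                    hard_edits=v.hard_edits,
                    targets=v.target,
                    rows=_codebook_rows(v, data[v.name]),
                )
                for v in t.variables
            ]
            realized.append(
                _Realized(
                    table_name=t.family + suffix,
                    family=t.family,
                    cycle=cycle,
                    cycle_index=ci,
                    description=t.description,
                    data_group=t.data_group,
                    use_constraints=t.use_constraints,
                    blocks=blocks,
                    data=data,
                )
            )
        if spec.population is not None:
            demo, bmx, mu = _realize_population(spec.population, ci, cycle, rng,
                                                spec.n_per_cycle, suffix)
            realized.extend([demo, bmx])
            pop_truth[f"{cycle[0]}-{cycle[1]}"] = mu
    if spec.population is not None:
        p = spec.population
        truth["population"] = {
            "true_domain_means": pop_truth,
            "domain_ages": list(p.domain_ages),
            "n_strata": p.n_strata,
            "psus_per_stratum": p.psus_per_stratum,
            "n_per_psu": p.n_per_psu,
        }
    return realized, truth


def _continuous_block(name: str, label: str, text: str, col: pd.Series,
                      decimals: int, lo: float, hi: float) -> _VarBlock:
    v = VariableSpec(name=name, kind="continuous", sas_label=label,
                     english_text=text, value_range=(lo, hi), decimals=decimals)
    return _VarBlock(name=name, sas_label=label, english_text=text,
                     instructions="", hard_edits="", targets=v.target,
                     rows=_codebook_rows(v, col))


def _realize_population(
    p: PopulationSpec, ci: int, cycle: tuple[int, int],
    rng: np.random.Generator, n_questionnaire: int, suffix: str
) -> tuple[_Realized, _Realized, float]:
    n = p.n_strata * p.psus_per_stratum * p.n_per_psu
    seqn = np.arange(1, n + 1) + 100000 * (ci + 1) + 50000
    strata = np.repeat(np.arange(1, p.n_strata + 1), p.psus_per_stratum * p.n_per_psu)
    psu = np.tile(np.repeat(np.arange(1, p.psus_per_stratum + 1), p.n_per_psu),
                  p.n_strata)
    mu = p.base_mean + ci * p.cycle_drift
    b_psu = rng.normal(0.0, p.psu_sd, size=p.n_strata * p.psus_per_stratum)
    y = (mu + np.repeat(b_psu, p.n_per_psu)
         + rng.normal(0.0, p.resid_sd, size=n)).round(1)
    age = rng.integers(p.age_range[0], p.age_range[1] + 1, size=n).astype(float)
    weight = np.round(10_000.0 * rng.lognormal(0.0, p.weight_sigma, size=n), 1)

    demo_df = pd.DataFrame({
        "SEQN": seqn, "RIDAGEYR": age, "WTMEC2YR": weight,
        "SDMVSTRA": strata.astype(float), "SDMVPSU": psu.astype(float),
    })
    bmx_df = pd.DataFrame({"SEQN": seqn, "BMXBMI": y})
    demo = _Realized(
        table_name="DEMO" + suffix, family="DEMO", cycle=cycle, cycle_index=ci,
        description="Demographic and design variables", data_group="Demographics",
        use_constraints="public",
        blocks=[
            _continuous_block("RIDAGEYR", "Age in years at screening",
                              "Age in years at the time of the screening interview.",
                              demo_df["RIDAGEYR"], 0, *map(float, p.age_range)),
            _continuous_block("WTMEC2YR", "Full sample 2 year MEC exam weight",
                              "Examination sampling weight.",
                              demo_df["WTMEC2YR"], 1, 1000.0, 90000.0),
            _continuous_block("SDMVSTRA", "Masked variance pseudo-stratum",
                              "Stratum identifier for variance estimation.",
                              demo_df["SDMVSTRA"], 0, 1.0, float(p.n_strata)),
            _continuous_block("SDMVPSU", "Masked variance pseudo-PSU",
                              "Primary sampling unit for variance estimation.",
                              demo_df["SDMVPSU"], 0, 1.0, float(p.psus_per_stratum)),
        ],
        data=demo_df,
    )
    bmx = _Realized(
        table_name="BMX" + suffix, family="BMX", cycle=cycle, cycle_index=ci,
        description="Body Measures", data_group="Examination",
        use_constraints="public",
        blocks=[
            _continuous_block("BMXBMI", "Body Mass Index (kg/m**2)",
                              "Body mass index.", bmx_df["BMXBMI"], 1, 10.0, 60.0),
        ],
        data=bmx_df,
    )
    return demo, bmx, mu


# ---------------------------------------------------------------------------
# Injection application
# ---------------------------------------------------------------------------

def _family_tables(realized: list[_Realized], variable: str) -> list[_Realized]:
    out = [r for r in realized if any(b.name == variable for b in r.blocks)]
    if not out:
        raise FixtureSpecError(f"variable {variable!r} not present in realization")
    return sorted(out, key=lambda r: r.cycle_index)

_RENAME_TAGS = ["CH", "GL", "BJ", "AA", "BB", "CC", "DD", "EE", "FF", "GG"]


def _apply_injection(realized: list[_Realized], inj: Injection) -> dict:
    tables = _family_tables(realized, inj.variable)
    n_aff = int(inj.params.get("n_affected", max(1, len(tables) // 2)))
    affected = tables[-n_aff:]
    rest = tables[:-n_aff]
    record: dict = {
        "check_id": inj.check_id,
        "variable": inj.variable,
        "tables_affected": [r.table_name for r in affected],
        "tables_unaffected": [r.table_name for r in rest],
        "tables": [r.table_name for r in tables],
    }

    def block(r: _Realized) -> _VarBlock:
        return next(b for b in r.blocks if b.name == inj.variable)

    if inj.check_id == "level_variant":
        label = inj.params.get("level")
        if label is None:
            label = next(
                (lab for _, lab, _, _ in block(tables[0]).rows
                 if lab.capitalize() != lab and lab != "Missing"),
                None,
            )
        if label is None:
            raise FixtureSpecError(
                f"level_variant: no capitalizable level for {inj.variable}"
            )
        variant = label.capitalize()
        for r in affected:
            b = block(r)
            b.rows = [(c, variant if d == label else d, n, s) for c, d, n, s in b.rows]
        record["level"] = label
        record["variant"] = variant
    elif inj.check_id == "unit_change":
        factor = float(inj.params.get("factor", 100.0))
        new_unit = inj.params.get("new_unit", "nmol/L")
        for r in affected:
            b = block(r)
            if "(" in b.sas_label:
                pre = b.sas_label[: b.sas_label.index("(")]
                b.sas_label = f"{pre}({new_unit})"
            b.english_text = b.english_text.replace("ug/L", new_unit)
            new_rows = []
            for c, d, n, s in b.rows:
                if " to " in c:
                    lo, hi = (float(x) for x in c.split(" to "))
                    c = _range_str(lo * factor, hi * factor, 2)
                new_rows.append((c, d, n, s))
            b.rows = new_rows
            col = r.data[inj.variable]
            r.data[inj.variable] = (col * factor).round(2)
        record["factor"] = factor
    elif inj.check_id == "name_reuse":
        new_text = inj.params.get(
            "new_text", "Hexachlorobenzene concentration in serum"
        )
        for r in affected:
            block(r).english_text = new_text
        record["new_text"] = new_text
    elif inj.check_id == "label_mismatch":
        for r in affected:
            b = block(r)
            b.sas_label = b.sas_label + " (revised)"
    elif inj.check_id == "description_mismatch":
        for r in affected:
            b = block(r)
            b.english_text = b.english_text + " Reworded for this release."
    elif inj.check_id == "target_mismatch":
        for r in affected:
            b = block(r)
            b.targets = tuple(t + " (revised target)" for t in b.targets)
    elif inj.check_id == "presence_gap":
        renamed: dict[str, str] = {}
        for i, r in enumerate(tables):
            new_name = inj.params.get("names", {}).get(r.table_name) if \
                isinstance(inj.params.get("names"), dict) else None
            if new_name is None:
                new_name = f"WTSS{_RENAME_TAGS[i % len(_RENAME_TAGS)]}2Y"
            b = block(r)
            b.name = new_name
            r.data = r.data.rename(columns={inj.variable: new_name})
            renamed[r.table_name] = new_name
        record["renamed"] = renamed
        record["tables_affected"] = [r.table_name for r in tables]
        record["tables_unaffected"] = []
    elif inj.check_id == "multi_table_in_cycle":
        src = tables[0]
        other = next(
            (r for r in realized
             if r.cycle_index == src.cycle_index and r.table_name != src.table_name
             and len(r.data) == len(src.data)
             and (r.data["SEQN"].to_numpy() == src.data["SEQN"].to_numpy()).all()),
            None,
        )
        if other is None:
            raise FixtureSpecError(
                "multi_table_in_cycle: no second table shares the cycle's respondents"
            )
        b = block(src)
        other.blocks.append(_VarBlock(
            name=b.name, sas_label=b.sas_label, english_text=b.english_text,
            instructions=b.instructions, hard_edits=b.hard_edits,
            targets=b.targets, rows=list(b.rows),
        ))
        other.data[inj.variable] = src.data[inj.variable].to_numpy()
        record["tables_affected"] = [src.table_name, other.table_name]
        record["tables"] = record["tables_affected"]
    else:  # pragma: no cover - validated upstream
        raise FixtureSpecError(inj.check_id)
    return record


# ---------------------------------------------------------------------------
# Emission
# ---------------------------------------------------------------------------

def _emit_doc_html(r: _Realized) -> str:
    parts = [
        "<!DOCTYPE html>",
        "<html><head><meta charset='utf-8'>",
        f"<title>{r.table_name}</title></head><body>",
        f"<h1>{r.table_name}: {r.description}</h1>",
        f"<p>Data group: {r.data_group}. Cycle {r.cycle[0]}-{r.cycle[1]}.</p>",
    ]
    for b in r.blocks:
        parts.append(f"<div class='pagebr' id='{b.name}'>")
        parts.append(f"<h3>{b.name} - {b.sas_label}</h3>")
        parts.append("<dl>")
        parts.append(f"<dt>Variable Name:</dt><dd>{b.name}</dd>")
        parts.append(f"<dt>SAS Label:</dt><dd>{b.sas_label}</dd>")
        parts.append(f"<dt>English Text:</dt><dd>{b.english_text}</dd>")
        if b.instructions:
            parts.append(f"<dt>English Instructions:</dt><dd>{b.instructions}</dd>")
        if b.hard_edits:
            parts.append(f"<dt>Hard Edits:</dt><dd>{b.hard_edits}</dd>")
        for t in b.targets:
            parts.append(f"<dt>Target:</dt><dd>{t}</dd>")
        parts.append("</dl>")
        parts.append("<table>")
        parts.append(
            "<tr><th>Code or Value</th><th>Value Description</th>"
            "<th>Count</th><th>Cumulative</th><th>Skip to Item</th></tr>"
        )
        cum = 0
        for code, desc, count, skip in b.rows:
            cum += count
            parts.append(
                f"<tr><td>{code}</td><td>{desc}</td><td>{count:,}</td>"
                f"<td>{cum:,}</td><td>{skip or ''}</td></tr>"
            )
        parts.append("</table>")
        parts.append("</div>")
    parts.append("</body></html>")
    return "\n".join(parts) + "\n"


def _emit_manifest_tsv(realized: list[_Realized], data_ext: str) -> str:
    header = ["table_name", "doc_file", "data_file", "begin_year", "end_year",
              "use_constraints", "description", "data_group", "date_published"]
    lines = ["\t".join(header)]
    for r in realized:
        lines.append("\t".join([
            r.table_name,
            f"docs/{r.table_name}.htm",
            f"data/{r.table_name}{data_ext}",
            str(r.cycle[0]),
            str(r.cycle[1]),
            r.use_constraints,
            r.description,
            r.data_group,
            f"{r.cycle[1] + 1}-06-01",
        ]))
    return "\n".join(lines) + "\n"


# -- minimal SAS transport (XPT v5) writer, numeric columns only ------------

def _ieee_to_ibm(x: float) -> bytes:
    if math.isnan(x):
        return b".\x00\x00\x00\x00\x00\x00\x00"
    if x == 0.0:
        return b"\x00" * 8
    sign = 0x80 if x < 0 else 0x00
    x = abs(x)
    m, e2 = math.frexp(x)          # x = m * 2**e2, m in [0.5, 1)
    q, r = divmod(e2, 4)
    if r:
        q += 1
        r -= 4
    mant = m * 2.0 ** r            # in [1/16, 1)
    frac = int(round(mant * (1 << 56)))
    if frac >= (1 << 56):
        frac >>= 4
        q += 1
    return bytes([sign | (q + 64)]) + frac.to_bytes(7, "big")


def _xpt_pad(record: bytes) -> bytes:
    return record + b" " * (-len(record) % 80)


def write_xpt(df: pd.DataFrame, path: Path, table_name: str,
              labels: dict[str, str] | None = None) -> None:
    """Write a numeric table in SAS transport (v5) format.

    Covers exactly what released raw tables need — numeric columns with
    8-byte IBM doubles and '.'-missing — and round-trips through standard
    XPT readers.
    """
    labels = labels or {}
    ts = "16JAN24:00:00:00"  # fixed timestamp: snapshot builds are deterministic
    out = bytearray()
    out += _xpt_pad(b"HEADER RECORD*******LIBRARY HEADER RECORD!!!!!!!"
                    b"000000000000000000000000000000")
    out += _xpt_pad(f"{'SAS':<8}{'SAS':<8}{'SASLIB':<8}{'9.4':<8}{'Linux':<8}"
                    f"{'':24}{ts:<16}".encode("ascii"))
    out += _xpt_pad(f"{ts:<16}".encode("ascii"))
    out += _xpt_pad(b"HEADER RECORD*******MEMBER  HEADER RECORD!!!!!!!"
                    b"000000000000000001600000000140")
    out += _xpt_pad(b"HEADER RECORD*******DSCRPTR HEADER RECORD!!!!!!!"
                    b"000000000000000000000000000000")
    out += _xpt_pad(f"{'SAS':<8}{table_name[:8]:<8}{'SASDATA':<8}{'9.4':<8}"
                    f"{'Linux':<8}{'':24}{ts:<16}".encode("ascii"))
    out += _xpt_pad(f"{ts:<16}{'':16}{table_name[:40]:<40}{'':8}".encode("ascii"))
    ncols = len(df.columns)
    # field count sits at bytes 54:58 of this record
    out += _xpt_pad(b"HEADER RECORD*******NAMESTR HEADER RECORD!!!!!!!"
                    + f"000000{ncols:04d}".encode("ascii") + b"0" * 20)
    namestrs = bytearray()
    pos = 0
    for i, col in enumerate(df.columns):
        ns = struct.pack(
            ">hhhh8s40s8shhh2s8shhl52s",
            1, 0, 8, i + 1,
            col[:8].ljust(8).encode("ascii"),
            labels.get(col, col)[:40].ljust(40).encode("ascii"),
            b"BEST    ", 0, 0, 0, b"  ", b"        ", 0, 0, pos, b" " * 52,
        )
        namestrs += ns
        pos += 8
    out += _xpt_pad(bytes(namestrs))
    out += _xpt_pad(b"HEADER RECORD*******OBS     HEADER RECORD!!!!!!!"
                    b"000000000000000000000000000000")
    obs = bytearray()
    for _, row in df.iterrows():
        for col in df.columns:
            obs += _ieee_to_ibm(float(row[col]) if pd.notna(row[col]) else math.nan)
    out += _xpt_pad(bytes(obs))
    path.write_bytes(bytes(out))


@dataclass
class FixtureSnapshot:
    """Paths and ground truth of one emitted fixture tree."""

    root: Path
    manifest_path: Path
    doc_dir: Path
    data_dir: Path
    ground_truth: dict
    table_names: list[str]


def make_snapshot(spec: FixtureSpec, out_dir: str | Path,
                  xpt: bool = False) -> FixtureSnapshot:
    """Emit a full synthetic snapshot tree: manifest, docs, data, truth.

    The tree is parseable by the codebook parser and loadable by the
    snapshot builder; with no injections it loads without warnings and
    passes every QC check.
    """
    validate_spec(spec)
    realized, truth = _realize_clean(spec)
    for inj in spec.injections:
        truth["injections"].append(_apply_injection(realized, inj))
    root = Path(out_dir)
    doc_dir = root / "docs"
    data_dir = root / "data"
    doc_dir.mkdir(parents=True, exist_ok=True)
    data_dir.mkdir(parents=True, exist_ok=True)
    ext = ".xpt" if xpt else ".csv"
    for r in realized:
        (doc_dir / f"{r.table_name}.htm").write_text(_emit_doc_html(r),
                                                     encoding="utf-8")
        if xpt:
            write_xpt(r.data, data_dir / f"{r.table_name}.xpt", r.table_name,
                      labels={b.name: b.sas_label for b in r.blocks})
        else:
            r.data.to_csv(data_dir / f"{r.table_name}.csv", index=False,
                          float_format="%.6g")
    manifest_path = root / "manifest.tsv"
    manifest_path.write_text(_emit_manifest_tsv(realized, ext), encoding="utf-8")
    (root / "ground_truth.json").write_text(
        json.dumps(truth, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return FixtureSnapshot(
        root=root,
        manifest_path=manifest_path,
        doc_dir=doc_dir,
        data_dir=data_dir,
        ground_truth=truth,
        table_names=[r.table_name for r in realized],
    )


def make_survey_population(
    spec: FixtureSpec,
) -> tuple[dict[tuple[int, int], dict[str, pd.DataFrame]], dict[tuple[int, int], float]]:
    """Per-cycle respondent tables with design columns and known truth.

    Returns ``{cycle: {"DEMO": frame, "BMX": frame}}`` plus the true
    domain mean per cycle.  Uses the same stream discipline as
    :func:`make_snapshot`, so a given seed yields the same SEQN assignment
    either way.
    """
    if spec.population is None:
        raise FixtureSpecError("spec has no population section")
    realized, truth = _realize_clean(spec)
    tables: dict[tuple[int, int], dict[str, pd.DataFrame]] = {}
    for r in realized:
        if r.family in ("DEMO", "BMX"):
            tables.setdefault(r.cycle, {})[r.family] = r.data
    means = {
        tuple(int(y) for y in k.split("-")): v
        for k, v in truth["population"]["true_domain_means"].items()
    }
    return tables, means  # type: ignore[return-value]


def load_fixture_snapshot(
    fixture: FixtureSnapshot | str | Path,
    store_path: str | Path = ":memory:",
    version: str = "0.1.0-fixture",
    exclusions: set[str] | None = None,
) -> SnapshotStore:
    """Parse an emitted fixture tree and build its snapshot store."""
    import datetime as _dt

    root = fixture.root if isinstance(fixture, FixtureSnapshot) else Path(fixture)
    manifest: Manifest = parse_manifest(
        (root / "manifest.tsv").read_text(encoding="utf-8")
    )
    docs, excluded = load_docs(root / "docs", manifest)
    raws = []
    doc_html = {}
    for e in manifest.entries:
        doc_html[e.table_name] = (root / e.doc_url).read_text(encoding="utf-8")
        data_path = root / e.data_url
        if data_path.exists():
            raws.append(load_raw_table(data_path, e.table_name))
    store = build_snapshot(
        manifest, docs, raws,
        VersionInfo(container_version=version,
                    collection_date=_dt.date(2024, 1, 16)),
        exclusions=(exclusions or set()) | set(excluded),
        path=store_path,
        doc_html=doc_html,
    )
    return store
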