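"""Design-based estimation for complex-survey snapshots.

National examination surveys use a stratified multi-stage design: strata,
primary sampling units (PSUs) within strata, and unequal selection
probabilities expressed as sampling weights.  Ignoring this structure gives
biased means and badly understated uncertainty.  This module provides the
standard public-use machinery:

* the Hájek ratio mean  ȳ_w = Σ wᵢyᵢ / Σ wᵢ,
* its Taylor-linearized variance under the stratified with-replacement
  first-stage approximation,

      z_i = w_i (y_i − ȳ_w) / Σ w,   Z_hj = Σ_{i ∈ PSU hj} z_i,
      Var = Σ_h n_h/(n_h−1) Σ_j (Z_hj − Z̄_h)²,

* t-based confidence intervals with df = (#PSUs − #strata),
* subgroup (domain) estimation done correctly: out-of-domain residuals are
  zeroed while the full PSU/stratum structure is retained — rows are never
  subset first,
* per-cycle series over a snapshot store, each cycle analyzed
  independently,
* a Rao–Wu rescaling bootstrap as an independent variance cross-check.

Pooling respondents across cycles is deliberately not offered: secular
trends make a common estimand dubious and the weights' reference
populations differ across cycles, so :func:`pooled_analysis_guard` warns
and refuses instead.
"""

from __future__ import annotations

import re
import warnings as _warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dbbuild import SnapshotStore
from .metadata_model import metadata_tab


class EmptyDomainError(ValueError):
    pass


class LonelyPsuError(ValueError):
    def __init__(self, strata: list):
        self.strata = strata
        super().__init__(
            f"stratum/strata {strata} have a single PSU; set lonely_psu='center' "
            "or collapse strata upstream"
        )


class SurveySpecError(ValueError):
    pass


class PooledAnalysisWarning(UserWarning):
    pass


@dataclass
class SurveyDesign:
    """One cycle's respondents with their design information.

    ``psu`` identifiers are interpreted within stratum (NHANES-style 1/2
    numbering recycles across strata), so the effective cluster key is the
    (stratum, psu) pair.  ``domain`` marks subgroup membership; it must
    already exclude rows with a missing analysis value.
    """

    weight: np.ndarray
    stratum: np.ndarray
    psu: np.ndarray
    value: np.ndarray
    domain: np.ndarray

    def __post_init__(self) -> None:
        self.weight = np.asarray(self.weight, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        self.stratum = np.asarray(self.stratum)
        self.psu = np.asarray(self.psu)
        self.domain = np.asarray(self.domain, dtype=bool)
        n = len(self.weight)
        for name in ("stratum", "psu", "value", "domain"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} has length {len(getattr(self, name))}, expected {n}")
        if n == 0:
            raise ValueError("empty design")
        if not np.all(self.weight > 0):
            raise ValueError("sampling weights must be positive")
        if np.any(np.isnan(self.value[self.domain])):
            raise ValueError("in-domain analysis values must be non-missing")

    def cluster_codes(self) -> tuple[np.ndarray, np.ndarray, int, int]:
        """Integer codes for strata and (stratum, psu) clusters."""
        strat_codes, strat_uniq = pd.factorize(self.stratum)
        pairs = pd.MultiIndex.from_arrays([self.stratum, self.psu])
        psu_codes, psu_uniq = pd.factorize(pairs)
        return strat_codes, psu_codes, len(strat_uniq), len(psu_uniq)


@dataclass(frozen=True)
class EstimateCI:
    mean: float
    se: float
    ci_low: float
    ci_high: float
    df: int
    n_effective: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.mean <= self.ci_high):
            raise ValueError("confidence interval does not bracket the mean")
        if self.se < 0:
            raise ValueError("negative standard error")


def weighted_mean(design: SurveyDesign) -> float:
    """Hájek ratio mean over the in-domain respondents."""
    d = design.domain
    if not d.any():
        raise EmptyDomainError("no in-domain respondents")
    w = design.weight[d]
    return float(np.sum(w * design.value[d]) / np.sum(w))


def _psu_residual_totals(design: SurveyDesign) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Per-PSU totals of the linearized residuals, full-design structure."""
    d = design.domain
    ybar = weighted_mean(design)
    wsum = float(np.sum(design.weight[d]))
    z = np.zeros(len(design.weight))
    z[d] = design.weight[d] * (design.value[d] - ybar) / wsum
    strat_codes, psu_codes, n_strata, n_psu = design.cluster_codes()
    psu_tot = np.bincount(psu_codes, weights=z, minlength=n_psu)
    # stratum of each PSU
    psu_stratum = np.zeros(n_psu, dtype=int)
    psu_stratum[psu_codes] = strat_codes
    return psu_tot, psu_stratum, n_strata, n_psu


def linearized_variance(
    design: SurveyDesign, lonely_psu: str = "fail"
) -> tuple[float, int]:
    """Taylor-linearized SE of the Hájek mean, and its degrees of freedom.

    With-replacement first-stage approximation: within each stratum, the
    between-PSU variance of the per-PSU residual totals, scaled by
    n_h/(n_h−1), summed over strata.  df = #PSUs − #strata, counting the
    full design.  Strata with a single PSU break the formula; the policy is
    either ``fail`` (default) or ``center`` (deviation measured from the
    grand mean of PSU totals, a conservative conventional fallback).
    """
    if lonely_psu not in ("fail", "center"):
        raise ValueError(f"unknown lonely-PSU policy {lonely_psu!r}")
    psu_tot, psu_stratum, n_strata, n_psu = _psu_residual_totals(design)
    lonely = [
        h for h in range(n_strata) if int(np.sum(psu_stratum == h)) == 1
    ]
    if lonely and lonely_psu == "fail":
        uniq = pd.unique(design.stratum)
        raise LonelyPsuError([uniq[h] for h in lonely])
    var = 0.0
    grand = float(psu_tot.mean())
    for h in range(n_strata):
        tot_h = psu_tot[psu_stratum == h]
        n_h = len(tot_h)
        if n_h == 1:
            var += float((tot_h[0] - grand) ** 2)
            continue
        var += n_h / (n_h - 1) * float(np.sum((tot_h - tot_h.mean()) ** 2))
    df = n_psu - n_strata
    return float(np.sqrt(var)), df


def estimate(
    design: SurveyDesign, level: float = 0.95, lonely_psu: str = "fail"
) -> EstimateCI:
    """Point estimate with a t-based confidence interval."""
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must be in (0, 1)")
    mean = weighted_mean(design)
    se, df = linearized_variance(design, lonely_psu=lonely_psu)
    if df <= 0:
        raise ValueError(f"nonpositive design degrees of freedom ({df})")
    t = float(stats.t.ppf(0.5 + level / 2.0, df))
    return EstimateCI(
        mean=mean,
        se=se,
        ci_low=mean - t * se,
        ci_high=mean + t * se,
        df=df,
        n_effective=int(design.domain.sum()),
    )


def bootstrap_se(
    design: SurveyDesign, n_reps: int = 10_000, seed: int | np.random.Generator = 0
) -> float:
    """Rao–Wu rescaling bootstrap SE: an independent variance route.

    Within each stratum, n_h−1 PSUs are resampled with replacement and
    weights rescaled by n_h/(n_h−1) times the selection multiplicity; the
    SE is the standard deviation of the Hájek mean over replicates.  This
    reproduces the with-replacement linearization variance in expectation
    and is used as the cross-check oracle in tests — never as the
    production estimator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = design.domain
    _, psu_codes, n_strata, n_psu = design.cluster_codes()
    strat_codes, _, _, _ = design.cluster_codes()
    psu_stratum = np.zeros(n_psu, dtype=int)
    psu_stratum[psu_codes] = strat_codes
    # per-PSU totals of domain-restricted w*y and w
    t_wy = np.bincount(psu_codes, weights=np.where(d, design.weight * design.value, 0.0),
                       minlength=n_psu)
    t_w = np.bincount(psu_codes, weights=np.where(d, design.weight, 0.0),
                      minlength=n_psu)
    num = np.zeros(n_reps)
    den = np.zeros(n_reps)
    for h in range(n_strata):
        members = np.flatnonzero(psu_stratum == h)
        n_h = len(members)
        if n_h == 1:
            num += t_wy[members[0]]
            den += t_w[members[0]]
            continue
        m_h = n_h - 1
        counts = rng.multinomial(m_h, np.full(n_h, 1.0 / n_h), size=n_reps)
        scale = counts * (n_h / m_h)
        num += scale @ t_wy[members]
        den += scale @ t_w[members]
    means = num / den
    return float(np.std(means, ddof=1))


# ---------------------------------------------------------------------------
# Store-level per-cycle series
# ---------------------------------------------------------------------------

_FAMILY_SUFFIX = re.compile(r"^(?P<base>.+?)(?:_(?P<suffix>[A-Z]))?$")


def resolve_family(store: SnapshotStore, family: str) -> dict[tuple[int, int], str]:
    """Map cycles to the table of a release family (DEMO, DEMO_B, ...).

    A family member is the bare base name or base + an underscore-letter
    release suffix, as surveys conventionally name per-cycle re-releases.
    """
    out: dict[tuple[int, int], str] = {}
    for desc in metadata_tab(store, include_restricted=True):
        m = _FAMILY_SUFFIX.match(desc.table_name)
        if m and m.group("base") == family:
            out[desc.cycle] = desc.table_name
    return out


def _domain_mask(df: pd.DataFrame, domain_spec) -> np.ndarray:
    if callable(domain_spec):
        return np.asarray(domain_spec(df), dtype=bool)
    return np.asarray(df.eval(domain_spec), dtype=bool)


def cycle_series(
    store: SnapshotStore,
    value: str,
    value_family: str,
    domain_spec,
    weight: str | dict[tuple[int, int], str],
    strata: str,
    psu: str,
    demo_family: str | None = None,
    level: float = 0.95,
    lonely_psu: str = "fail",
) -> list[tuple[tuple[int, int], EstimateCI]]:
    """Per-cycle subgroup means with confidence intervals.

    For every cycle the value table is resolved from ``value_family`` and,
    when ``demo_family`` is given, joined to that cycle's demographic table
    on SEQN (the within-cycle respondent key).  The domain is then applied
    — as a callable mask or a frame-expression string — and each cycle is
    estimated independently on its own design columns.

    ``weight`` may be a single column name or an explicit per-cycle mapping
    for families that rename their weight variable per file; a missing
    column with no mapping raises :class:`SurveySpecError` naming the cycle
    and column.
    """
    value_tables = resolve_family(store, value_family)
    if not value_tables:
        raise SurveySpecError(f"no tables found for family {value_family!r}")
    demo_tables = resolve_family(store, demo_family) if demo_family else {}
    results = []
    for cycle in sorted(value_tables):
        table = value_tables[cycle]
        df = store.read_table("raw", table)
        if demo_family:
            demo_name = demo_tables.get(cycle)
            if demo_name is None:
                raise SurveySpecError(
                    f"cycle {cycle}: no {demo_family!r} table to join"
                )
            df = df.merge(store.read_table("raw", demo_name), on="SEQN", how="inner")
        wcol = weight.get(cycle) if isinstance(weight, dict) else weight
        if wcol is None:
            raise SurveySpecError(f"cycle {cycle}: no weight column mapped")
        for col, what in ((value, "value"), (wcol, "weight"),
                          (strata, "strata"), (psu, "PSU")):
            if col not in df.columns:
                raise SurveySpecError(
                    f"cycle {cycle} ({table}): missing {what} column {col!r}"
                )
        mask = _domain_mask(df, domain_spec) & df[value].notna().to_numpy()
        design = SurveyDesign(
            weight=df[wcol].to_numpy(dtype=float),
            stratum=df[strata].to_numpy(),
            psu=df[psu].to_numpy(),
            value=df[value].to_numpy(dtype=float),
            domain=mask,
        )
        results.append((cycle, estimate(design, level=level, lonely_psu=lonely_psu)))
    return results


def pooled_analysis_guard(
    cycles: list[tuple[int, int]],
    weight_specs: dict[tuple[int, int], str] | str | None = None,
    acknowledge: bool = False,
) -> str | None:
    """Refuse pooled multi-cycle estimation; warn about why.

    Combining respondents across cycles needs (a) a defensible common
    estimand despite secular trends and (b) careful reconstruction of
    weights whose reference populations differ by cycle.  Neither is
    automated here: a pooling request over more than one cycle emits a
    non-suppressible warning and returns its text; no pooled estimate is
    ever produced.  ``acknowledge`` only records that the caller saw the
    warning.
    """
    if len(cycles) <= 1:
        return None
    msg = (
        f"pooled analysis over {len(cycles)} cycles requested: estimands may "
        "drift across cycles (secular trends), and sampling weights are "
        "derived against per-cycle reference populations that may differ — "
        "re-derive combined weights before pooling. No pooled estimate is "
        "computed."
    )
    if acknowledge:
        msg += " (acknowledged)"
    _warnings.warn(msg, PooledAnalysisWarning, stacklevel=2)
    return msg
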