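"""Questionnaire flow: skip graphs, structural missingness, right-censoring.

Survey interviews do not ask every question of every participant: an answer
can direct the interview to a later question, so everything in between is
never asked and is released as Missing — indistinguishable, in the raw
data, from a question that was asked but not answered.  This module builds
the directed flow structure from the codebook's Skip to Item column,
identifies which variables can be skipped, classifies each missing cell as
structurally skipped versus item nonresponse, and implements the
right-censoring transform (e.g. age started smoking: participants who never
smoked are censored at their current age rather than dropped).

"Skipped" means strictly between the edge's source and target in document
order — the target itself is the next question asked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codebook_parser import CodebookDoc
from .metadata_model import END_OF_SECTION
from .translator import RawTable, code_key


@dataclass(frozen=True)
class SkipEdge:
    source: str
    code: str          # triggering answer, as the codebook spells it
    target: str        # variable name or END_OF_SECTION


@dataclass
class SkipGraph:
    question_order: list[str]
    edges: list[SkipEdge] = field(default_factory=list)
    #: skip targets that are backward or point outside this doc; recorded,
    #: never turned into edges.
    anomalies: list[str] = field(default_factory=list)

    def index(self, variable: str) -> int:
        return self.question_order.index(variable)

    def span(self, edge: SkipEdge) -> list[str]:
        """Variables skipped when this edge fires: strictly after the source
        and strictly before the target (everything after, for end-of-section
        targets)."""
        i = self.index(edge.source)
        if edge.target == END_OF_SECTION:
            return self.question_order[i + 1:]
        j = self.index(edge.target)
        return self.question_order[i + 1: j]


@dataclass
class SkipInfo:
    variable: str
    skippable: bool
    skipped_by: list[tuple[str, frozenset[str]]] = field(default_factory=list)


def build_skip_graph(doc: CodebookDoc) -> SkipGraph:
    """One edge per codebook row with a skip target.

    A target that is not in the doc (and is not the end-of-section sentinel)
    or that points backward breaks the forward-flow assumption: it is
    recorded as an anomaly and no edge is added.
    """
    order = doc.variable_names()
    pos = {v: i for i, v in enumerate(order)}
    graph = SkipGraph(question_order=order)
    for var, entries in doc.variables:
        for e in entries:
            target = e.skip_to_item
            if not target:
                continue
            if target == END_OF_SECTION:
                graph.edges.append(SkipEdge(var.variable, e.code_or_value, target))
                continue
            if target not in pos:
                graph.anomalies.append(
                    f"{var.variable}[{e.code_or_value}] -> {target}: target not in this "
                    "table (cross-section skip)"
                )
                continue
            if pos[target] <= pos[var.variable]:
                graph.anomalies.append(
                    f"{var.variable}[{e.code_or_value}] -> {target}: backward skip"
                )
                continue
            graph.edges.append(SkipEdge(var.variable, e.code_or_value, target))
    return graph


def _reachable_questions(doc: CodebookDoc, graph: SkipGraph) -> set[int]:
    """Positions an interview can actually reach.

    From a reachable question, each answer code leads either to the next
    question or along its jump edge; a question is reachable when some
    answer path arrives there.  Needed because an edge whose source can
    never be asked can never fire.
    """
    order = graph.question_order
    pos = {v: i for i, v in enumerate(order)}
    jump = {(e.source, e.code): e.target for e in graph.edges}
    codes = {v.variable: [e.code_or_value for e in entries
                          if e.code_or_value != "."]
             for v, entries in doc.variables}
    reachable: set[int] = set()
    frontier = [0] if order else []
    while frontier:
        i = frontier.pop()
        if i in reachable or i >= len(order):
            continue
        reachable.add(i)
        var = order[i]
        nexts: set[int] = set()
        if not codes.get(var):
            nexts.add(i + 1)
        for c in codes.get(var, []):
            target = jump.get((var, c))
            if target is None:
                nexts.add(i + 1)
            elif target != END_OF_SECTION:
                nexts.add(pos[target])
        frontier.extend(n for n in nexts if n not in reachable)
    return reachable


def get_skip_info(doc: CodebookDoc) -> list[SkipInfo]:
    """Which variables may never be asked, and which answers cause that.

    A variable V is skippable iff some edge whose source question is
    actually reachable jumps from before V to after V in document order;
    ``skipped_by`` aggregates, per upstream variable, the set of answer
    codes triggering such a jump.  Because jumps are forward-only, this is
    exactly equivalent to "some answer vector leaves V unasked" under
    :func:`simulate_administration`.
    """
    graph = build_skip_graph(doc)
    order = graph.question_order
    pos = {v: i for i, v in enumerate(order)}
    reachable = _reachable_questions(doc, graph)
    out = []
    for v in order:
        triggers: dict[str, set[str]] = {}
        for e in graph.edges:
            if pos[e.source] not in reachable:
                continue
            end = len(order) if e.target == END_OF_SECTION else pos[e.target]
            if pos[e.source] < pos[v] < end:
                triggers.setdefault(e.source, set()).add(e.code)
        out.append(
            SkipInfo(
                variable=v,
                skippable=bool(triggers),
                skipped_by=[(u, frozenset(cs)) for u, cs in sorted(triggers.items())],
            )
        )
    return out


def simulate_administration(graph: SkipGraph, answers: dict[str, str]) -> set[str]:
    """Brute-force walk of the interview under a given answer vector.

    Starts at the first question; whenever the answer at an asked question
    triggers an edge, the walk jumps to the edge's target.  Questions are
    consulted lazily — an answer is required only for questions actually
    asked.  Returns the set of asked variables.
    """
    order = graph.question_order
    pos = {v: i for i, v in enumerate(order)}
    jump = {(e.source, e.code): e.target for e in graph.edges}
    asked: set[str] = set()
    i = 0
    while i < len(order):
        var = order[i]
        asked.add(var)
        if var not in answers:
            raise KeyError(f"no answer provided for asked variable {var!r}")
        code = code_key(answers[var])
        target = jump.get((var, code))
        if target is None:
            i += 1
        elif target == END_OF_SECTION:
            break
        else:
            i = pos[target]
    return asked


OBSERVED = "observed"
STRUCTURALLY_SKIPPED = "structurally_skipped"
ITEM_NONRESPONSE = "item_nonresponse"


def classify_missing(raw: RawTable, doc: CodebookDoc) -> pd.DataFrame:
    """Classify every cell of a raw table by missingness mechanism.

    Returns a frame indexed by SEQN over the doc's variables with values
    ``observed`` / ``structurally_skipped`` / ``item_nonresponse``.  A
    missing cell is structurally skipped iff some answered upstream value of
    that respondent triggers an edge jumping past the variable.  When the
    upstream trigger answer is itself missing the downstream cell stays
    item_nonresponse (the conservative reading).
    """
    graph = build_skip_graph(doc)
    order = [v for v in graph.question_order if v in raw.data.columns and v != "SEQN"]
    pos = {v: i for i, v in enumerate(graph.question_order)}
    norder = len(graph.question_order)
    data = raw.data.set_index("SEQN")[order] if order else raw.data.set_index("SEQN")
    result = pd.DataFrame(index=data.index, columns=order, dtype=object)
    for seqn, row in data.iterrows():
        answered = {v: code_key(row[v]) for v in order if code_key(row[v]) is not None}
        # edges fired by this respondent's observed answers
        fired = [
            e for e in graph.edges
            if answered.get(e.source) is not None and answered[e.source] == code_key(e.code)
        ]
        for v in order:
            if code_key(row[v]) is not None:
                result.at[seqn, v] = OBSERVED
                continue
            skipped = any(
                pos[e.source] < pos[v] < (norder if e.target == END_OF_SECTION else pos[e.target])
                for e in fired
            )
            result.at[seqn, v] = STRUCTURALLY_SKIPPED if skipped else ITEM_NONRESPONSE
    return result


@dataclass
class CensoredColumn:
    """(value, event) pairs ready for a survival-style analysis.

    event 1 = observed, 0 = right-censored at the censor source's value,
    NaN = still missing (item nonresponse, or censor source unavailable).
    """

    values: pd.Series
    event: pd.Series
    warnings: list[str] = field(default_factory=list)


def right_censor(
    raw: RawTable,
    variable: str,
    trigger: tuple[str, set[str]],
    censor_source: str,
) -> CensoredColumn:
    """Turn skip-induced missingness into right-censored observations.

    Respondents whose ``trigger`` answer caused ``variable`` to be skipped
    get the value of ``censor_source`` (typically current age) with event 0;
    observed values pass through with event 1; other missing cells stay
    missing.  Row count is preserved and observed values are never changed.
    """
    for col in (variable, trigger[0], censor_source):
        if col not in raw.data.columns:
            raise KeyError(f"{raw.table_name}: column {col!r} not present")
    trig_var, trig_codes = trigger
    trig_keys = {code_key(c) for c in trig_codes}
    values = raw.data[variable].astype(float).copy()
    event = pd.Series(np.nan, index=raw.data.index)
    warnings: list[str] = []
    for i in raw.data.index:
        v = raw.data.at[i, variable]
        if code_key(v) is not None:
            event.at[i] = 1.0
            continue
        if code_key(raw.data.at[i, trig_var]) in trig_keys:
            cens = raw.data.at[i, censor_source]
            if code_key(cens) is None:
                warnings.append(
                    f"SEQN row {i}: triggered but {censor_source} is missing; left as missing"
                )
                continue
            values.at[i] = float(cens)
            event.at[i] = 0.0
    return CensoredColumn(values=values, event=event, warnings=warnings)
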