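import itertools

import numpy as np
import pandas as pd
import pytest

import nhaneskit as nk
from nhaneskit.metadata_model import END_OF_SECTION
from nhaneskit.skiplogic import (
    ITEM_NONRESPONSE,
    OBSERVED,
    STRUCTURALLY_SKIPPED,
    build_skip_graph,
    classify_missing,
    get_skip_info,
    right_censor,
    simulate_administration,
)
from conftest import doc_from_shorthand


class TestBuildSkipGraph:
    def test_one_edge_per_skip_row(self, fig2_doc):
        graph = build_skip_graph(fig2_doc)
        assert {(e.source, e.code, e.target) for e in graph.edges} == {
            ("SMQ020", "2", "SMD070"), ("SMQ020", "7", "SMD070"),
        }

    def test_skipped_question_lies_between_source_and_target(self, fig2_doc):
        graph = build_skip_graph(fig2_doc)
        edge = next(e for e in graph.edges if e.code == "2")
        assert graph.span(edge) == ["SMD030"]

    def test_no_skip_column_no_edges(self):
        doc = doc_from_shorthand("X", [("A", [("1", "Yes", None)]),
                                       ("B", [("1", "Yes", None)])])
        assert build_skip_graph(doc).edges == []

    def test_end_sentinel_span_covers_all_later_questions(self):
        doc = doc_from_shorthand("X", [
            ("V1", [("1", "Yes", None), ("2", "No", END_OF_SECTION)]),
            ("V2", [("1", "Yes", None)]),
            ("V3", [("1", "Yes", None)]),
            ("V4", [("1", "Yes", None)]),
            ("V5", [("1", "Yes", None)]),
        ])
        graph = build_skip_graph(doc)
        (edge,) = graph.edges
        assert graph.span(edge) == ["V2", "V3", "V4", "V5"]

    def test_backward_and_unknown_targets_are_anomalies_not_edges(self):
        doc = doc_from_shorthand("X", [
            ("A", [("1", "Yes", "NOT_HERE")]),
            ("B", [("1", "Yes", "A")]),
        ])
        graph = build_skip_graph(doc)
        assert graph.edges == []
        assert len(graph.anomalies) == 2
        assert any("cross-section" in a for a in graph.anomalies)
        assert any("backward" in a for a in graph.anomalies)


class TestGetSkipInfo:
    def test_gated_question_is_skippable_by_the_gate(self, fig2_doc):
        info = {i.variable: i for i in get_skip_info(fig2_doc)}
        assert info["SMD030"].skippable
        assert ("SMQ020", frozenset({"2", "7"})) in info["SMD030"].skipped_by

    def test_first_question_never_skippable(self, fig2_doc):
        info = {i.variable: i for i in get_skip_info(fig2_doc)}
        assert not info["SMQ020"].skippable

    def test_jump_target_itself_is_asked(self, fig2_doc):
        info = {i.variable: i for i in get_skip_info(fig2_doc)}
        assert not info["SMD070"].skippable

    def test_skippable_iff_skipped_by_nonempty(self, fig2_doc):
        for i in get_skip_info(fig2_doc):
            assert i.skippable == bool(i.skipped_by)


class TestSimulateAdministration:
    def test_gate_open_asks_downstream(self, fig2_doc):
        graph = build_skip_graph(fig2_doc)
        asked = simulate_administration(graph, {"SMQ020": "1", "SMD030": "1",
                                                "SMD070": "1"})
        assert asked == {"SMQ020", "SMD030", "SMD070"}

    def test_gate_closed_skips_downstream(self, fig2_doc):
        graph = build_skip_graph(fig2_doc)
        asked = simulate_administration(graph, {"SMQ020": "2", "SMD070": "1"})
        assert "SMD030" not in asked and "SMD070" in asked

    def test_no_edges_asks_everything(self):
        doc = doc_from_shorthand("X", [("A", [("1", "y", None)]),
                                       ("B", [("1", "y", None)])])
        graph = build_skip_graph(doc)
        assert simulate_administration(graph, {"A": "1", "B": "1"}) == {"A", "B"}

    def test_missing_answer_for_asked_question_errors(self, fig2_doc):
        graph = build_skip_graph(fig2_doc)
        with pytest.raises(KeyError, match="SMD030"):
            simulate_administration(graph, {"SMQ020": "1"})


def _exhaustive_skippable(doc):
    """Brute-force oracle: a variable is skippable iff it is not asked under
    some exhaustively enumerated answer vector."""
    graph = build_skip_graph(doc)
    codes = {v.variable: [e.code_or_value for e in entries
                          if e.code_or_value != "."]
             for v, entries in doc.variables}
    never_asked = set()
    for combo in itertools.product(*codes.values()):
        answers = dict(zip(codes.keys(), combo))
        asked = simulate_administration(graph, answers)
        never_asked |= set(graph.question_order) - asked
    return never_asked


CHAINED_DOCS = [
    doc_from_shorthand("CHAIN6", [
        ("Q1", [("1", "a", None), ("2", "b", "Q4")]),
        ("Q2", [("1", "a", None), ("2", "b", "Q5")]),
        ("Q3", [("1", "a", None)]),
        ("Q4", [("1", "a", None), ("2", "b", END_OF_SECTION)]),
        ("Q5", [("1", "a", None)]),
        ("Q6", [("1", "a", None)]),
    ]),
    doc_from_shorthand("OVERLAP", [
        ("A", [("1", "a", None), ("2", "b", "D")]),
        ("B", [("1", "a", None), ("2", "b", "E")]),
        ("C", [("1", "a", None)]),
        ("D", [("1", "a", None)]),
        ("E", [("1", "a", None)]),
    ]),
    doc_from_shorthand("ALLSKIP", [
        ("G", [("1", "a", END_OF_SECTION), ("2", "b", None), ("3", "c", "T")]),
        ("H", [("1", "a", None)]),
        ("T", [("1", "a", None)]),
    ]),
]


@pytest.mark.parametrize("doc", CHAINED_DOCS, ids=lambda d: d.table_name)
def test_skip_info_matches_exhaustive_simulation(doc):
    oracle = _exhaustive_skippable(doc)
    reported = {i.variable for i in get_skip_info(doc) if i.skippable}
    assert reported == oracle


def test_skip_info_matches_simulation_on_randomized_docs():
    """Property over random forward-skip questionnaires (seeded)."""
    rng = np.random.default_rng(42)
    for _ in range(25):
        n = int(rng.integers(3, 8))
        names = [f"Q{i}" for i in range(n)]
        blocks = []
        for i, name in enumerate(names):
            rows = []
            for code in range(1, int(rng.integers(2, 4)) + 1):
                target = None
                if i < n - 1 and rng.random() < 0.4:
                    j = int(rng.integers(i + 1, n + 1))
                    target = END_OF_SECTION if j == n else names[j]
                rows.append((str(code), f"lvl{code}", target))
            blocks.append((name, rows))
        doc = doc_from_shorthand("RND", blocks)
        assert {i.variable for i in get_skip_info(doc) if i.skippable} == \
            _exhaustive_skippable(doc)


class TestClassifyMissing:
    def _raw(self):
        return nk.RawTable("SMOKE", pd.DataFrame({
            "SEQN": [1, 2, 3, 4],
            "SMQ020": [2.0, 1.0, 1.0, np.nan],
            "SMD030": [np.nan, np.nan, 1.0, np.nan],
            "SMD070": [1.0, 2.0, 1.0, 1.0],
        }))

    def test_gate_closed_missing_is_structural(self, fig2_doc):
        classes = classify_missing(self._raw(), fig2_doc)
        assert classes.at[1, "SMD030"] == STRUCTURALLY_SKIPPED

    def test_gate_open_missing_is_item_nonresponse(self, fig2_doc):
        classes = classify_missing(self._raw(), fig2_doc)
        assert classes.at[2, "SMD030"] == ITEM_NONRESPONSE

    def test_fully_observed_row_all_observed(self, fig2_doc):
        classes = classify_missing(self._raw(), fig2_doc)
        assert (classes.loc[3] == OBSERVED).all()

    def test_missing_trigger_answer_is_conservative(self, fig2_doc):
        classes = classify_missing(self._raw(), fig2_doc)
        assert classes.at[4, "SMD030"] == ITEM_NONRESPONSE

    def test_every_missing_cell_classified_exactly_once(self, fig2_doc):
        raw = self._raw()
        classes = classify_missing(raw, fig2_doc)
        values = raw.data.set_index("SEQN")[classes.columns]
        assert ((classes == OBSERVED) == values.notna()).all().all()

    def test_structural_cells_agree_with_administration_simulation(
            self, clean_fixture, clean_store, smq_doc):
        """Fixture-wide consistency: a cell is structurally skipped iff the
        interview walk over that respondent's observed answers never asks it."""
        raw = nk.RawTable("SMQ", clean_store.read_table("raw", "SMQ"))
        graph = build_skip_graph(smq_doc)
        classes = classify_missing(raw, smq_doc)
        data = raw.data.set_index("SEQN")
        for seqn, row in data.iterrows():
            answers = {v: row[v] for v in graph.question_order
                       if pd.notna(row[v])}
            try:
                asked = simulate_administration(graph, answers)
            except KeyError:
                continue  # item nonresponse on an asked gate: walk undefined
            for v in graph.question_order:
                if classes.at[seqn, v] == STRUCTURALLY_SKIPPED:
                    assert v not in asked


class TestRightCensor:
    def _raw(self):
        return nk.RawTable("SMOKE", pd.DataFrame({
            "SEQN": [1, 2, 3, 4],
            "RIDAGEYR": [45.0, 60.0, 30.0, np.nan],
            "SMQ020": [2.0, 1.0, 1.0, 2.0],
            "SMD030": [np.nan, 18.0, np.nan, np.nan],
        }))

    def _censored(self):
        return right_censor(self._raw(), "SMD030",
                            trigger=("SMQ020", {"2"}), censor_source="RIDAGEYR")

    def test_triggered_missing_censored_at_age(self):
        out = self._censored()
        assert out.values.iloc[0] == 45.0 and out.event.iloc[0] == 0.0

    def test_observed_value_passes_through_as_event(self):
        out = self._censored()
        assert out.values.iloc[1] == 18.0 and out.event.iloc[1] == 1.0

    def test_item_nonresponse_stays_missing(self):
        out = self._censored()
        assert np.isnan(out.values.iloc[2]) and np.isnan(out.event.iloc[2])

    def test_missing_censor_source_warns_and_stays_missing(self):
        out = self._censored()
        assert np.isnan(out.values.iloc[3]) and out.warnings

    def test_row_count_and_observed_values_preserved(self):
        raw = self._raw()
        out = self._censored()
        assert len(out.values) == len(raw.data)
        observed = raw.data["SMD030"].notna()
        assert (out.values[observed] == raw.data.loc[observed, "SMD030"]).all()

    def test_missing_column_errors(self):
        with pytest.raises(KeyError):
            right_censor(self._raw(), "NOPE", ("SMQ020", {"2"}), "RIDAGEYR")
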