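import pytest

import nhaneskit as nk
from nhaneskit.metadata_model import (
    CodebookEntry,
    QuestionnaireDescription,
    QuestionnaireVariable,
    UseConstraint,
)
from nhaneskit.qc import CheckId, Severity, normalize_level


def meta_store(descs, variables, codebook):
    store = nk.SnapshotStore()
    store.write_metadata(descs, variables, codebook)
    return store


def desc(name, begin=1999, end=2000):
    return QuestionnaireDescription(
        table_name=name, description=name, begin_year=begin, end_year=end,
        data_group="G", use_constraints=UseConstraint.PUBLIC,
        doc_file="d", data_file="f", date_published="")


def qv(table, var="V", label="Label", text="Some text", target=("Everyone",)):
    return QuestionnaireVariable(variable=var, table_name=table, sas_label=label,
                                 english_text=text, target=target)


def cbe(table, code, description, var="V"):
    return CodebookEntry(variable=var, table_name=table, code_or_value=code,
                         value_description=description)


class TestQcVar:
    def test_label_change_partitions_tables(self):
        store = meta_store(
            [desc("T1"), desc("T2", 2001, 2002), desc("T3", 2003, 2004)],
            [qv("T1", label="Old label"), qv("T2", label="Old label"),
             qv("T3", label="New label")],
            [],
        )
        findings = nk.qc_var(store, "V")
        (f,) = [x for x in findings if x.check_id is CheckId.LABEL_MISMATCH]
        assert dict(f.variants) == {"Old label": ["T1", "T2"],
                                    "New label": ["T3"]}

    def test_identical_everywhere_no_findings(self):
        store = meta_store([desc("T1"), desc("T2", 2001, 2002)],
                           [qv("T1"), qv("T2")], [])
        assert nk.qc_var(store, "V") == []

    def test_target_and_description_checks_fire_separately(self):
        store = meta_store(
            [desc("T1"), desc("T2", 2001, 2002)],
            [qv("T1"), qv("T2", text="Other text", target=("Adults",))],
            [],
        )
        ids = {f.check_id for f in nk.qc_var(store, "V")}
        assert ids == {CheckId.DESCRIPTION_MISMATCH, CheckId.TARGET_MISMATCH}

    def test_two_tables_in_one_cycle(self):
        store = meta_store([desc("A"), desc("B")], [qv("A"), qv("B")], [])
        findings = [f for f in nk.qc_var(store, "V")
                    if f.check_id is CheckId.MULTI_TABLE_IN_CYCLE]
        assert len(findings) == 1
        assert findings[0].tables == ["A", "B"]

    def test_unknown_variable_warns_empty(self):
        store = meta_store([desc("T1")], [qv("T1")], [])
        warnings = []
        assert nk.qc_var(store, "NOPE", warnings=warnings) == []
        assert warnings

    def test_scope_never_reports_outside_tables(self):
        store = meta_store(
            [desc("T1"), desc("T2", 2001, 2002), desc("T3", 2003, 2004)],
            [qv("T1", label="A"), qv("T2", label="A"), qv("T3", label="B")],
            [],
        )
        for f in nk.qc_var(store, "V", scope={"T1", "T2"}):
            assert set(f.tables) <= {"T1", "T2"}
        assert nk.qc_var(store, "V", scope={"T1", "T2"}) == []


class TestQcLevels:
    def test_case_variant_partition_matches_table2_structure(self, tmp_path):
        """Six early tables spell a grade one way, four later ones another."""
        spec = nk.default_spec(
            seed=11,
            cycles=tuple((1999 + 2 * i, 2000 + 2 * i) for i in range(10)),
            tables=(nk.default_spec().tables[0],),  # education family only
            population=None,
        )
        spec = nk.inject(spec, nk.Injection("level_variant", "DMDEDUC3",
                                            {"level": "10th Grade",
                                             "n_affected": 4}))
        fx = nk.make_snapshot(spec, tmp_path)
        store = nk.load_fixture_snapshot(fx)
        findings = [f for f in nk.qc_levels(store, "DMDEDUC3")
                    if f.check_id is CheckId.LEVEL_VARIANT]
        assert len(findings) == 1
        sizes = sorted(len(ts) for _, ts in findings[0].variants)
        assert sizes == [4, 6]
        variant_map = dict(findings[0].variants)
        assert set(variant_map["10th Grade"]) == set(fx.table_names[:6])
        assert set(variant_map["10th grade"]) == set(fx.table_names[6:])

    def test_byte_identical_levels_no_findings(self, clean_store):
        assert nk.qc_levels(clean_store, "DMDEDUC3") == []

    def test_genuinely_different_levels_are_info_not_variant(self):
        store = meta_store(
            [desc("T1"), desc("T2", 2001, 2002)],
            [qv("T1"), qv("T2")],
            [cbe("T1", "1", "Ninth grade"), cbe("T2", "1", "9th grade")],
        )
        findings = nk.qc_levels(store, "V")
        assert all(f.check_id is not CheckId.LEVEL_VARIANT for f in findings)
        (f,) = findings
        assert f.check_id is CheckId.DESCRIPTION_MISMATCH
        assert f.severity is Severity.INFO

    @pytest.mark.parametrize(
        "a, b, same",
        [
            ("10th Grade", "10th grade", True),
            ("10th  grade", "10th grade", True),
            ("10th grade.", "10th grade", True),
            ("Ninth grade", "9th grade", False),
        ],
    )
    def test_normalization_rules(self, a, b, same):
        assert (normalize_level(a) == normalize_level(b)) is same


class TestQcUnits:
    def test_unit_token_change_detected(self):
        store = meta_store(
            [desc("T1"), desc("T2", 2001, 2002)],
            [qv("T1", label="Cadmium (nmol/L)"), qv("T2", label="Cadmium (ug/L)")],
            [],
        )
        (f,) = nk.qc_units(store, "V")
        assert f.check_id is CheckId.UNIT_CHANGE

    def test_identical_labels_and_ranges_clean(self):
        store = meta_store(
            [desc("T1"), desc("T2", 2001, 2002)],
            [qv("T1", label="Cadmium (ug/L)"), qv("T2", label="Cadmium (ug/L)")],
            [cbe("T1", "0 to 5", "Range of Values"),
             cbe("T2", "0 to 5", "Range of Values")],
        )
        assert nk.qc_units(store, "V") == []

    def test_range_midpoint_shift_fires_without_token_change(self):
        store = meta_store(
            [desc("T1"), desc("T2", 2001, 2002)],
            [qv("T1", label="Cadmium (ug/L)"), qv("T2", label="Cadmium (ug/L)")],
            [cbe("T1", "0 to 5", "Range of Values"),
             cbe("T2", "0 to 500", "Range of Values")],
        )
        (f,) = nk.qc_units(store, "V")
        assert f.check_id is CheckId.UNIT_CHANGE
        assert "100x" in f.detail


class TestQcNameReuse:
    def _store(self, text2):
        return meta_store(
            [desc("T1"), desc("T2", 2001, 2002)],
            [qv("T1", text="Hematocrit (%)"), qv("T2", text=text2)],
            [],
        )

    def test_disjoint_descriptions_flagged_as_error(self):
        (f,) = nk.qc_name_reuse(
            self._store("Hexachlorobenzene concentration in serum"), "V")
        assert f.check_id is CheckId.NAME_REUSE
        assert f.severity is Severity.ERROR
        assert len(f.variants) == 2

    def test_identical_descriptions_clean(self):
        assert nk.qc_name_reuse(self._store("Hematocrit (%)"), "V") == []

    def test_paraphrase_above_threshold_not_flagged(self):
        # 3 shared tokens of 5 -> Jaccard 0.6 >= 0.2
        store = meta_store(
            [desc("T1"), desc("T2", 2001, 2002)],
            [qv("T1", text="hematocrit percent blood sample"),
             qv("T2", text="hematocrit percent blood draw volume")],
            [],
        )
        assert nk.qc_name_reuse(store, "V") == []


class TestQcPresenceMatrix:
    def _glyphosate_store(self):
        tables = ["SSGLYP_H", "SSGLYP_I", "SSGLYP_J"]
        weights = ["WTSSCH2Y", "WTSSGL2Y", "WTSSBJ2Y"]
        variables = []
        for t, w in zip(tables, weights):
            variables.append(qv(t, var="SSGLYP", text="Urine glyphosate"))
            variables.append(qv(t, var=w, text="Subsample weight"))
        descs = [desc(t, 2013 + 2 * i, 2014 + 2 * i)
                 for i, t in enumerate(tables)]
        return meta_store(descs, variables, []), tables, weights

    def test_each_weight_absent_from_exactly_the_other_two(self):
        store, tables, weights = self._glyphosate_store()
        matrix, findings = nk.qc_presence_matrix(store, tables)
        assert {f.variable for f in findings} == set(weights)
        for f in findings:
            absent = dict(f.variants)["absent"]
            present = dict(f.variants)["present"]
            assert len(absent) == 2 and len(present) == 1

    def test_matrix_shape_and_shared_variable(self):
        store, tables, weights = self._glyphosate_store()
        matrix, _ = nk.qc_presence_matrix(store, tables)
        assert matrix.shape == (4, 3)
        assert matrix.loc["SSGLYP"].all()

    def test_identical_variable_sets_no_findings(self, clean_store):
        _, findings = nk.qc_presence_matrix(clean_store,
                                            ["EDU", "EDU_B", "EDU_C"])
        assert findings == []

    def test_one_shared_one_unique_over_two_tables(self):
        store = meta_store(
            [desc("A"), desc("B", 2001, 2002)],
            [qv("A", var="SHARED"), qv("B", var="SHARED"), qv("B", var="ONLYB")],
            [],
        )
        _, findings = nk.qc_presence_matrix(store, ["A", "B"])
        assert len(findings) == 1 and findings[0].variable == "ONLYB"

    def test_fewer_than_two_tables_rejected(self, clean_store):
        with pytest.raises(ValueError):
            nk.qc_presence_matrix(clean_store, ["EDU"])


def test_clean_snapshot_has_zero_findings_for_other_seeds(tmp_path):
    """No-injection snapshots are QC-silent regardless of seed."""
    for seed in (101, 202):
        fx = nk.make_snapshot(nk.default_spec(seed=seed, population=None),
                              tmp_path / str(seed))
        store = nk.load_fixture_snapshot(fx)
        assert nk.qc_all(store) == []


def test_findings_render_to_tsv_and_html():
    store = meta_store(
        [desc("T1"), desc("T2", 2001, 2002)],
        [qv("T1", label="A"), qv("T2", label="B")],
        [],
    )
    findings = nk.qc_var(store, "V")
    from nhaneskit.qc import findings_to_html, findings_to_tsv
    tsv = findings_to_tsv(findings)
    assert "label_mismatch" in tsv and tsv.count("\n") == 2
    assert "<table" in findings_to_html(findings)
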