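import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nhaneskit as nk
from nhaneskit.survey_est import (
    EmptyDomainError,
    LonelyPsuError,
    PooledAnalysisWarning,
    SurveySpecError,
    bootstrap_se,
    cycle_series,
    estimate,
    linearized_variance,
    pooled_analysis_guard,
    weighted_mean,
)


def design(w, s, p, y, d=None):
    d = [True] * len(w) if d is None else d
    return nk.SurveyDesign(np.asarray(w, float), np.asarray(s), np.asarray(p),
                           np.asarray(y, float), np.asarray(d))


class TestWeightedMean:
    def test_equal_weights_reduce_to_arithmetic_mean(self):
        assert weighted_mean(design([1, 1, 1], [1] * 3, [1, 2, 1], [1, 2, 3])) == 2.0

    def test_hand_weighted_example(self):
        # (1*0 + 3*4) / 4 = 3
        assert weighted_mean(design([1, 3], [1, 1], [1, 2], [0, 4])) == 3.0

    def test_constant_values_for_any_weights(self):
        assert weighted_mean(design([5, 1, 9], [1] * 3, [1, 2, 1], [7, 7, 7])) == 7.0

    def test_empty_domain_errors(self):
        with pytest.raises(EmptyDomainError):
            weighted_mean(design([1, 1], [1, 1], [1, 2], [1, 2], [False, False]))


class TestLinearizedVariance:
    def test_equal_psu_totals_give_zero_se(self):
        # identical PSU compositions -> no between-PSU variation
        se, df = linearized_variance(
            design([1, 1, 1, 1], [1, 1, 1, 1], [1, 1, 2, 2], [3, 5, 3, 5]))
        assert se == pytest.approx(0.0)
        assert df == 1

    def test_hand_computed_single_stratum_two_psus(self):
        """Six respondents, worked by hand:

        mean = 28/8 = 3.5; residual totals per PSU are -0.75 and +0.75,
        so Var = 2/1 * (0.75^2 + 0.75^2) = 2.25 and se = 1.5 with df 1.
        """
        d = design([1, 2, 1, 1, 2, 1], [1] * 6, [1, 1, 1, 2, 2, 2],
                   [1, 2, 3, 4, 5, 6])
        assert weighted_mean(d) == pytest.approx(3.5)
        se, df = linearized_variance(d)
        assert se == pytest.approx(1.5)
        assert df == 1

    def test_lonely_psu_fail_names_stratum(self):
        d = design([1, 1, 1], [1, 2, 2], [1, 1, 2], [1, 2, 3])
        with pytest.raises(LonelyPsuError) as exc:
            linearized_variance(d)
        assert 1 in exc.value.strata

    def test_lonely_psu_center_policy_is_finite(self):
        d = design([1, 1, 1], [1, 2, 2], [1, 1, 2], [1, 2, 3])
        se, df = linearized_variance(d, lonely_psu="center")
        assert np.isfinite(se) and df == 1

    def test_out_of_domain_psu_still_counts_in_df(self):
        # second stratum has no domain members but keeps its design role
        d = design([1, 1, 1, 1], [1, 1, 2, 2], [1, 2, 1, 2], [1, 2, 0, 0],
                   [True, True, False, False])
        _, df = linearized_variance(d)
        assert df == 4 - 2

    @given(st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_weight_rescaling(self, scale):
        rng = np.random.default_rng(5)
        w = rng.lognormal(0, 0.4, 24)
        s = np.repeat([1, 2, 3], 8)
        p = np.tile(np.repeat([1, 2], 4), 3)
        y = rng.normal(10, 2, 24)
        d1 = design(w, s, p, y)
        d2 = design(w * scale, s, p, y)
        assert weighted_mean(d1) == pytest.approx(weighted_mean(d2))
        assert linearized_variance(d1)[0] == \
            pytest.approx(linearized_variance(d2)[0])


class TestEstimate:
    def test_zero_se_degenerate_interval(self):
        d = design([1, 1, 1, 1], [1] * 4, [1, 1, 2, 2], [3, 5, 3, 5])
        e = estimate(d)
        assert e.ci_low == e.mean == e.ci_high == 4.0

    def test_hand_interval_with_tabulated_t(self):
        d = design([1, 2, 1, 1, 2, 1], [1] * 6, [1, 1, 1, 2, 2, 2],
                   [1, 2, 3, 4, 5, 6])
        e = estimate(d, level=0.95)
        t1 = 12.7062  # t_{0.975, df=1}
        assert e.ci_low == pytest.approx(3.5 - t1 * 1.5, rel=1e-4)
        assert e.ci_high == pytest.approx(3.5 + t1 * 1.5, rel=1e-4)

    def test_wider_level_wider_interval(self):
        rng = np.random.default_rng(6)
        d = design(rng.lognormal(0, 0.3, 40), np.repeat([1, 2], 20),
                   np.tile(np.repeat([1, 2], 10), 2), rng.normal(0, 1, 40))
        widths = [estimate(d, level=lv).ci_high - estimate(d, level=lv).ci_low
                  for lv in (0.5, 0.8, 0.95, 0.99)]
        assert widths == sorted(widths)

    def test_nonpositive_df_errors(self):
        d = design([1, 1], [1, 2], [1, 1], [1, 2])
        with pytest.raises(ValueError, match="degrees of freedom"):
            estimate(d, lonely_psu="center")


def _random_design(rng):
    n_strata = int(rng.integers(3, 7))
    npsu = int(rng.integers(2, 5))
    nper = int(rng.integers(6, 14))
    n = n_strata * npsu * nper
    s = np.repeat(np.arange(n_strata), npsu * nper)
    p = np.tile(np.repeat(np.arange(npsu), nper), n_strata)
    w = rng.lognormal(0, 0.5, n) * 100
    y = 25 + rng.normal(0, 1, n_strata * npsu).repeat(nper) + rng.normal(0, 4, n)
    d = rng.random(n) < 0.7
    return design(w, s, p, y, d)


def test_linearized_se_matches_psu_bootstrap():
    """Independent variance route: Rao-Wu resampling of PSUs within strata
    reproduces the linearized SE within a few percent."""
    rng = np.random.default_rng(2024)
    for _ in range(6):
        d = _random_design(rng)
        se, _ = linearized_variance(d)
        bse = bootstrap_se(d, n_reps=10_000, seed=int(rng.integers(2**31)))
        assert bse == pytest.approx(se, rel=0.05)


@pytest.fixture(scope="module")
def drift_store(tmp_path_factory):
    spec = nk.default_spec(
        seed=40, tables=(),
        population=nk.PopulationSpec(cycle_drift=3.0),
    )
    fx = nk.make_snapshot(spec, tmp_path_factory.mktemp("drift"))
    return nk.load_fixture_snapshot(fx), fx.ground_truth


class TestCycleSeries:
    def test_programmed_drift_recovered(self, drift_store):
        store, truth = drift_store
        series = cycle_series(
            store, value="BMXBMI", value_family="BMX",
            domain_spec="40 <= RIDAGEYR <= 59", weight="WTMEC2YR",
            strata="SDMVSTRA", psu="SDMVPSU", demo_family="DEMO",
        )
        means = [e.mean for _, e in series]
        assert len(means) == 3
        assert means == sorted(means)  # drift of 3 per cycle dominates noise
        for (cycle, est) in series:
            true_mean = truth["population"]["true_domain_means"][
                f"{cycle[0]}-{cycle[1]}"]
            assert abs(est.mean - true_mean) < 4 * est.se

    def test_single_cycle_equals_direct_estimate(self, tmp_path):
        spec = nk.default_spec(seed=41, tables=(), cycles=((1999, 2000),))
        fx = nk.make_snapshot(spec, tmp_path)
        store = nk.load_fixture_snapshot(fx)
        ((cycle, est),) = cycle_series(
            store, value="BMXBMI", value_family="BMX",
            domain_spec="40 <= RIDAGEYR <= 59", weight="WTMEC2YR",
            strata="SDMVSTRA", psu="SDMVPSU", demo_family="DEMO",
        )
        df = store.read_table("raw", "DEMO").merge(
            store.read_table("raw", "BMX"), on="SEQN")
        mask = ((df.RIDAGEYR >= 40) & (df.RIDAGEYR <= 59)).to_numpy()
        direct = estimate(design(df.WTMEC2YR, df.SDMVSTRA, df.SDMVPSU,
                                 df.BMXBMI, mask))
        assert est == direct

    def test_renamed_weight_variable_needs_explicit_mapping(self, tmp_path):
        spec = nk.default_spec(seed=42, tables=())
        spec = nk.inject(spec, nk.Injection("presence_gap", "WTMEC2YR"))
        fx = nk.make_snapshot(spec, tmp_path)
        store = nk.load_fixture_snapshot(fx)
        kwargs = dict(
            store=store, value="BMXBMI", value_family="BMX",
            domain_spec="40 <= RIDAGEYR <= 59", strata="SDMVSTRA",
            psu="SDMVPSU", demo_family="DEMO",
        )
        with pytest.raises(SurveySpecError, match="weight"):
            cycle_series(weight="WTMEC2YR", **kwargs)
        renamed = fx.ground_truth["injections"][0]["renamed"]
        mapping = {}
        for d in nk.metadata_tab(store, include_restricted=True):
            if d.table_name in renamed:
                mapping[d.cycle] = renamed[d.table_name]
        series = cycle_series(weight=mapping, **kwargs)
        assert len(series) == 3

    def test_missing_design_column_names_cycle_and_column(self, tmp_path):
        spec = nk.default_spec(seed=43, tables=(), cycles=((1999, 2000),))
        fx = nk.make_snapshot(spec, tmp_path)
        store = nk.load_fixture_snapshot(fx)
        with pytest.raises(SurveySpecError, match=r"1999.*NOPE"):
            cycle_series(store, value="BMXBMI", value_family="BMX",
                         domain_spec="RIDAGEYR >= 0", weight="NOPE",
                         strata="SDMVSTRA", psu="SDMVPSU", demo_family="DEMO")


class TestPooledAnalysisGuard:
    def test_multi_cycle_request_warns_and_computes_nothing(self):
        with pytest.warns(PooledAnalysisWarning, match="reference population"):
            msg = pooled_analysis_guard([(1999, 2000), (2001, 2002)])
        assert msg is not None and "No pooled estimate" in msg

    def test_acknowledge_still_warns(self):
        with pytest.warns(PooledAnalysisWarning):
            msg = pooled_analysis_guard([(1999, 2000), (2001, 2002)],
                                        acknowledge=True)
        assert "acknowledged" in msg

    def test_single_cycle_silent(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error")
            assert pooled_analysis_guard([(1999, 2000)]) is None
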