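import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tlagseq.synthetic_trials import ScenarioConfig, generate_trial
from tlagseq.trial_data import (
    FullTrialData,
    StepFunctionPaths,
    TrialDataError,
    build_interim_dataset,
    fit_censoring_km,
    martingale_integral,
    read_path_csv,
    read_subject_csv,
    write_path_csv,
    write_subject_csv,
)


class TestInterimConstruction:
    def test_censored_subject_has_outcome_hidden(self):
        # E=100, T=90, t=150 -> C=50 < T, so U=50, Delta=0, outcome masked
        full = FullTrialData(
            entry_time=[100.0, 0.0, 10.0],
            arm=[0, 1, 0],
            lag_time=[90.0, 90.0, 30.0],
            outcome=[3.0, 2.0, 6.0],
            max_followup=90.0,
        )
        it = build_interim_dataset(full, 150.0)
        assert it.censoring_time[0] == 50.0
        assert it.observed_time[0] == 50.0
        assert it.ascertained[0] == 0
        assert np.isnan(it.outcome[0])
        # subject followed past TF is ascertained with U = T
        assert it.ascertained[1] == 1 and it.observed_time[1] == 90.0
        assert it.treated_fraction == pytest.approx(1 / 3)

    def test_full_followup_reproduces_full_data(self):
        cfg = ScenarioConfig.ordinal(beta=0.3)
        full = generate_trial(cfg, 5)
        it = build_interim_dataset(full, full.entry_time.max() + full.max_followup + 1)
        assert it.n_enrolled == full.n_subjects
        assert np.all(it.ascertained == 1)
        np.testing.assert_array_equal(it.observed_time, full.lag_time)
        np.testing.assert_array_equal(it.outcome, full.outcome)

    def test_scenario1_final_analysis_counts(self):
        full = generate_trial(ScenarioConfig.ordinal(), 3)
        it = build_interim_dataset(full, 330.0)
        assert it.n_enrolled == 602
        assert it.n_fully_followed == 602

    def test_analysis_too_early_errors(self):
        full = FullTrialData([0.0, 50.0], [0, 1], [10.0, 10.0], [1.0, 0.0], 10.0)
        with pytest.raises(TrialDataError, match="positive"):
            build_interim_dataset(full, 0.0)
        with pytest.raises(TrialDataError, match="no subjects"):
            build_interim_dataset(FullTrialData([5.0, 6.0], [0, 1], [1.0, 1.0],
                                                [0.0, 1.0], 10.0), 1.0)
        with pytest.raises(TrialDataError, match="arm"):
            build_interim_dataset(full, 20.0)  # arm 1 not yet enrolled

    def test_warns_when_nobody_fully_followed(self):
        full = FullTrialData([0.0, 1.0], [0, 1], [50.0, 50.0], [1.0, 0.0], 50.0)
        with pytest.warns(UserWarning, match="maximum follow-up"):
            build_interim_dataset(full, 30.0)


class TestCensoringKM:
    def test_no_censoring_gives_unit_survival(self, ordinal_snapshot):
        cfg, full, _, _ = ordinal_snapshot
        it = build_interim_dataset(full, 330.0)
        cm = fit_censoring_km(it, arm_specific=True)
        for a in (0, 1):
            assert cm.jump_times(a).size == 0
            u = np.linspace(0, 90, 7)
            np.testing.assert_allclose(cm.survival(u, a), 1.0)
            np.testing.assert_allclose(cm.cum_hazard(u, a), 0.0)

    def test_hand_product_limit_values(self, four_point_fixture):
        _, it = four_point_fixture
        cm = fit_censoring_km(it, arm_specific=True)
        # jumps at 20 and 40; risk set {20,30,40} at the event at 20
        np.testing.assert_array_equal(cm.jump_times(0), [20.0, 40.0])
        assert cm.survival(20.0, 0) == pytest.approx(1.0)       # pr{C >= u} convention
        assert cm.survival(30.0, 0) == pytest.approx(2 / 3)
        assert cm.survival(40.0, 0) == pytest.approx(2 / 3)
        assert cm.cum_hazard(30.0, 0) == pytest.approx(0.4055, abs=1e-4)

    def test_survival_nonincreasing_piecewise(self, ordinal_snapshot):
        _, _, it, cm = ordinal_snapshot
        for a in (0, 1):
            u = np.linspace(0, it.observed_time.max(), 200)
            s = cm.survival(u, a)
            assert s[0] == 1.0
            assert np.all(np.diff(s) <= 1e-12)
            np.testing.assert_allclose(cm.cum_hazard(u, a), -np.log(s))

    def test_inverse_weight_conservation(self, ordinal_snapshot):
        # sum of Delta/K over an arm approximates the arm size (exact here
        # because the largest observation in each arm is ascertained)
        _, _, it, cm = ordinal_snapshot
        for a in (0, 1):
            m = (it.arm == a) & (it.ascertained == 1)
            w = 1.0 / cm.survival(it.observed_time[m], a)
            assert abs(w.sum() / (it.arm == a).sum() - 1.0) < 0.15


class TestMartingaleIntegral:
    def test_no_censoring_gives_zero(self, ordinal_snapshot):
        cfg, full, _, _ = ordinal_snapshot
        it = build_interim_dataset(full, 330.0)
        cm = fit_censoring_km(it, arm_specific=True)
        for i in (0, 10, 300):
            assert martingale_integral(i, it, cm, lambda u: np.ones_like(u)) == 0.0

    def test_hand_values_on_fixture(self, four_point_fixture):
        _, it = four_point_fixture
        cm = fit_censoring_km(it, arm_specific=True)
        h = lambda u: np.full_like(u, 2.5)
        # censored at 20: dN term minus the Nelson-Aalen increment 1/3 at 20
        assert martingale_integral(1, it, cm, h) == pytest.approx(2.5 * (1 - 1 / 3))
        # ascertained at 10, before the first jump: empty sum
        assert martingale_integral(0, it, cm, h) == 0.0
        # ascertained at 30: compensator over the jump at 20 only
        assert martingale_integral(2, it, cm, h) == pytest.approx(-2.5 / 3)

    def test_arm_sum_vanishes(self, four_point_fixture, ordinal_snapshot):
        # martingale property: sum over an arm with integrand 1 is exactly 0
        _, it = four_point_fixture
        cm = fit_censoring_km(it, arm_specific=True)
        one = lambda u: np.ones_like(u)
        total = sum(martingale_integral(i, it, cm, one)
                    for i in np.flatnonzero(it.arm == 0))
        assert abs(total) <= 1e-8
        _, _, it2, cm2 = ordinal_snapshot
        for a in (0, 1):
            total = sum(martingale_integral(i, it2, cm2, one)
                        for i in np.flatnonzero(it2.arm == a))
            assert abs(total) <= 1e-8

    def test_vector_integrand(self, four_point_fixture):
        _, it = four_point_fixture
        cm = fit_censoring_km(it, arm_specific=True)
        g = lambda u: np.column_stack([np.ones_like(u), u])
        out = martingale_integral(1, it, cm, g)
        np.testing.assert_allclose(out, [2 / 3, 20.0 * 2 / 3])


class TestStepFunctionPaths:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        times=st.lists(st.floats(0.1, 100), min_size=0, max_size=5, unique=True),
        query=st.floats(0, 120),
    )
    def test_matches_naive_lookup(self, times, query):
        t = np.concatenate([[0.0], np.sort(times)])
        v = np.arange(len(t), dtype=float)[:, None]
        paths = StepFunctionPaths.from_ragged([(t, v)])
        got = paths.evaluate([0], [query])[0, 0, 0]
        expected = v[np.flatnonzero(t <= query)[-1], 0]
        assert got == expected

    def test_truncation_drops_later_changes(self):
        t = np.array([0.0, 5.0, 10.0])
        v = np.array([[0.0], [1.0], [2.0]])
        paths = StepFunctionPaths.from_ragged([(t, v)])
        trunc = paths.truncated(np.array([0]), np.array([7.0]))
        assert trunc.evaluate([0], [20.0])[0, 0, 0] == 1.0  # change at 10 removed


class TestCsvRoundTrip:
    def test_subject_and_path_round_trip(self, tmp_path):
        full = generate_trial(ScenarioConfig.ordinal(beta=0.2).with_n_max(40), 8)
        s, p = tmp_path / "subj.csv", tmp_path / "paths.csv"
        write_subject_csv(full, s)
        write_path_csv(full, p)
        back = read_subject_csv(s, max_followup=90.0)
        back.covariate_paths = read_path_csv(p, back.n_subjects)
        np.testing.assert_allclose(back.entry_time, full.entry_time)
        np.testing.assert_allclose(back.outcome, full.outcome)
        np.testing.assert_allclose(back.baseline_covariates, full.baseline_covariates)
        u = np.array([10.0, 45.0, 80.0])
        np.testing.assert_allclose(
            back.covariate_paths.evaluate(np.arange(40), u),
            full.covariate_paths.evaluate(np.arange(40), u),
        )
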