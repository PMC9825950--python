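import numpy as np
import pytest

from tlagseq.estimators import (
    BasisSpec,
    build_augmentation_covariates,
    build_dependent_variable,
    fit_aipwcc,
    fit_ipwcc,
    fit_tf_only,
    wald_statistic,
)
from tlagseq.outcome_models import OutcomeModelSpec
from tlagseq.synthetic_trials import (
    ScenarioConfig,
    default_basis,
    default_model_spec,
    generate_trial,
)
from tlagseq.trial_data import build_interim_dataset, fit_censoring_km, martingale_integral


class TestTfOnly:
    def test_reduces_to_full_data_fit_at_final_time(self, ordinal_final_snapshot):
        cfg, full, it, cm = ordinal_final_snapshot
        spec = default_model_spec(cfg)
        res = fit_tf_only(it, spec)
        assert res.n_fully_followed == full.n_subjects
        ipw = fit_ipwcc(it, spec, cm)  # no censoring: same solver path
        assert res.beta_hat == ipw.beta_hat

    def test_continuous_outcome_is_difference_of_arm_means(self):
        cfg = ScenarioConfig.continuous()
        full = generate_trial(cfg, 21)
        it = build_interim_dataset(full, 130.0)
        res = fit_tf_only(it, OutcomeModelSpec("difference_of_means"))
        mask = it.censoring_time >= it.max_followup
        y, a = it.outcome[mask], it.arm[mask]
        assert res.beta_hat == pytest.approx(y[a == 1].mean() - y[a == 0].mean())


class TestIpwcc:
    def test_no_censoring_equals_unweighted_fit(self, ordinal_final_snapshot):
        cfg, full, it, cm = ordinal_final_snapshot
        spec = default_model_spec(cfg)
        ipw = fit_ipwcc(it, spec, cm)
        tf = fit_tf_only(it, spec)
        assert ipw.beta_hat == tf.beta_hat
        np.testing.assert_array_equal(ipw.weights, 1.0)

    def test_binary_equals_km_ratio_oracle(self):
        from lifelines import KaplanMeierFitter

        cfg = ScenarioConfig.binary(np.log(1.5))
        full = generate_trial(cfg, 31)
        it = build_interim_dataset(full, 195.0)
        cm = fit_censoring_km(it, arm_specific=True)
        res = fit_ipwcc(it, default_model_spec(cfg), cm)
        p = []
        for a in (0, 1):
            m = it.arm == a
            deaths = (np.nan_to_num(it.outcome[m]) == 1) & (it.ascertained[m] == 1)
            km = KaplanMeierFitter().fit(it.observed_time[m], event_observed=deaths)
            p.append(1.0 - km.predict(cfg.max_followup))
        assert res.beta_hat == pytest.approx(np.log(p[1] / p[0]), abs=1e-10)

    def test_dependent_variable_mean_zero(self, ordinal_snapshot):
        cfg, _, it, cm = ordinal_snapshot
        res = fit_ipwcc(it, default_model_spec(cfg), cm)
        assert abs(res.dependent_variable.sum()) <= 1e-8 * it.n_enrolled

    def test_dependent_variable_matches_subjectwise_oracle(self, four_point_fixture):
        # brute-force mu-hat ratio + per-subject martingale integral
        _, it = four_point_fixture
        cm = fit_censoring_km(it, arm_specific=True)
        spec = OutcomeModelSpec("difference_of_means")
        res = fit_ipwcc(it, spec, cm)
        m, w = res.m_values, res.weights
        wm = np.where(it.ascertained == 1, np.nan_to_num(m) * w, 0.0)

        def q_factory(a):
            def q(u_arr):
                out = []
                for u in np.atleast_1d(u_arr):
                    at_risk = (it.observed_time >= u) & (it.arm == a)
                    out.append(wm[at_risk].sum() / at_risk.sum())
                return np.array(out)
            return q

        for i in range(it.n_enrolled):
            a = int(it.arm[i])
            expected = wm[i] + martingale_integral(i, it, cm, q_factory(a))
            assert res.dependent_variable[i] == pytest.approx(expected, abs=1e-12)

    def test_fully_ascertained_dependent_variable_is_m(self, ordinal_final_snapshot):
        cfg, _, it, cm = ordinal_final_snapshot
        res = fit_ipwcc(it, default_model_spec(cfg), cm)
        np.testing.assert_allclose(res.dependent_variable, res.m_values)


class TestAugmentation:
    def test_baseline_column_is_centered_covariate(self, ordinal_snapshot):
        cfg, _, it, cm = ordinal_snapshot
        basis = BasisSpec(["const", 0], [])
        M = build_augmentation_covariates(it, basis, cm)
        pi = it.treated_fraction
        np.testing.assert_allclose(M[:, 0], it.arm - pi)
        np.testing.assert_allclose(M[:, 1], (it.arm - pi) * it.baseline_covariates[:, 0])

    def test_no_censoring_martingale_columns_vanish(self, ordinal_final_snapshot):
        cfg, _, it, cm = ordinal_final_snapshot
        basis = default_basis(cfg)
        M = build_augmentation_covariates(it, basis, cm)
        np.testing.assert_allclose(M[:, basis.n_f:], 0.0)

    def test_martingale_columns_centered_identity(self, ordinal_snapshot):
        # the compensator part cancels exactly by at-risk centering, so the
        # column sum over an arm equals the sum of (h - mu) at its own
        # censoring events; check against a brute-force evaluation
        cfg, _, it, cm = ordinal_snapshot
        basis = default_basis(cfg)
        M = build_augmentation_covariates(it, basis, cm)
        U, delta = it.observed_time, it.ascertained
        for a in (0, 1):
            jumps = cm.jump_times(a)
            sub = np.flatnonzero(it.arm == a)
            L = it.covariate_paths.evaluate(sub, jumps)
            H_list = basis.eval_h(jumps, it.baseline_covariates[sub], L)
            for ell, H in enumerate(H_list):
                at_risk = U[sub][:, None] >= jumps[None, :]
                mu = (H * at_risk).sum(axis=0) / at_risk.sum(axis=0)
                expected = 0.0
                for k, i in enumerate(sub):
                    if delta[i] == 0:
                        j = np.searchsorted(jumps, U[i], side="right") - 1
                        expected += H[k, j] - mu[j]
                col = M[:, basis.n_f + a * basis.n_h + ell]
                assert col[sub].sum() == pytest.approx(expected, abs=1e-8)
                assert np.all(col[it.arm != a] == 0.0)

    def test_martingale_columns_mean_zero_across_replicates(self):
        # unbiasedness of the augmentation columns: averaged over trials the
        # per-arm column mean is zero within Monte Carlo error
        cfg = ScenarioConfig.ordinal(beta=0.0)
        basis = default_basis(cfg)
        means = []
        for r in range(40):
            full = generate_trial(cfg.with_n_max(200), 5000 + r)
            it = build_interim_dataset(full, 150.0)
            cm = fit_censoring_km(it, arm_specific=True)
            M = build_augmentation_covariates(it, basis, cm)
            means.append(M[:, basis.n_f:].mean(axis=0))
        means = np.array(means)
        se = means.std(axis=0, ddof=1) / np.sqrt(len(means))
        assert np.all(np.abs(means.mean(axis=0)) <= 4 * np.maximum(se, 1e-12))


class TestAipwcc:
    def test_constant_basis_only_reproduces_step1(self, ordinal_snapshot):
        # f = {1} alone carries no covariate information: (A - pi) has exact
        # sample mean zero, so the one-step update leaves beta unchanged
        cfg, _, it, cm = ordinal_snapshot
        res = fit_aipwcc(it, default_model_spec(cfg), cm, BasisSpec(["const"], []))
        step1 = fit_ipwcc(it, default_model_spec(cfg), cm)
        assert abs(res.beta_hat - step1.beta_hat) <= res.se / 100

    def test_aipw1_equals_aipw2_at_final_analysis(self, ordinal_final_snapshot):
        cfg, _, it, cm = ordinal_final_snapshot
        spec = default_model_spec(cfg)
        with pytest.warns(UserWarning, match="rank deficient"):
            a2 = fit_aipwcc(it, spec, cm, default_basis(cfg, include_h=True))
        a1 = fit_aipwcc(it, spec, cm, default_basis(cfg, include_h=False))
        assert a1.beta_hat == pytest.approx(a2.beta_hat, abs=1e-12)
        assert a1.se == pytest.approx(a2.se, abs=1e-12)

    def test_augmentation_reduces_residual_variance(self, ordinal_snapshot):
        cfg, _, it, cm = ordinal_snapshot
        spec = default_model_spec(cfg)
        step1 = fit_ipwcc(it, spec, cm)
        a1 = fit_aipwcc(it, spec, cm, default_basis(cfg, include_h=False), step1=step1)
        a2 = fit_aipwcc(it, spec, cm, default_basis(cfg, include_h=True), step1=step1)
        assert a2.se <= a1.se <= step1.se

    def test_wald_statistic(self, ordinal_snapshot):
        cfg, _, it, cm = ordinal_snapshot
        res = fit_ipwcc(it, default_model_spec(cfg), cm)
        assert wald_statistic(res) == res.beta_hat / res.se
        # printed trajectory value: estimate 0.730, SE 0.292, statistic 2.496
        assert 0.730 / 0.292 == pytest.approx(2.496, abs=5e-3)
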