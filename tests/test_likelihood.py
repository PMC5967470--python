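"""Likelihood arithmetic, constraint expansion, fitting, model comparison."""

import math

import numpy as np
import pytest

from sfsdfe import (
    FitResult,
    ModelSpec,
    OptimizerOptions,
    PolarisedSFS,
    PolarisedSFSSet,
    RatioConstraint,
    SampleFrame,
    SFSValidationError,
    SiteClassParams,
    TypeModel,
    aic_compare,
    apply_constraints,
    correct_sfs_snp,
    fit_model,
    indel_log_likelihood,
    joint_log_likelihood,
    likelihood_ratio_test,
    poisson_log_likelihood,
    uncorrected_sfs_discrete,
)
from sfsdfe.likelihood import expected_spectra

from conftest import make_set, make_sfs


def snp_expected(mtheta, gamma, eps, frame):
    raw = uncorrected_sfs_discrete(
        SiteClassParams(theta=mtheta / frame.m, gamma=gamma, epsilon=eps), frame
    )
    return correct_sfs_snp([(raw, eps)])


class TestPoissonLogLik:
    def test_direct_arithmetic(self):
        frame = SampleFrame(n=3, m=100.0)
        expected = snp_expected(2.0, 0.0, 0.0, frame)  # psi = (2, 1)
        observed = make_sfs(3, 100.0, [3, 0])
        # -(2+1) + 3*ln 2
        assert poisson_log_likelihood(expected, observed) == pytest.approx(-3 + 3 * math.log(2))

    def test_all_zero_counts(self):
        frame = SampleFrame(n=3, m=100.0)
        expected = snp_expected(1.0, 0.0, 0.0, frame)  # psi = (1, 0.5)
        assert poisson_log_likelihood(expected, make_sfs(3, 100.0, [0, 0])) == pytest.approx(-1.5)

    def test_observed_equals_expected_maximises(self):
        frame = SampleFrame(n=10, m=1e4)
        expected = snp_expected(50.0, -3.0, 0.05, frame)
        observed = PolarisedSFS(frame=frame, variant_type="snp", counts=expected.values)
        best = poisson_log_likelihood(expected, observed)
        for factor in (0.9, 1.1):
            from dataclasses import replace

            perturbed = replace(expected, values=factor * expected.values)
            assert poisson_log_likelihood(perturbed, observed) < best

    def test_zero_psi_with_positive_count_is_minus_inf(self):
        frame = SampleFrame(n=3, m=100.0)
        expected = snp_expected(0.0, 0.0, 0.0, frame)
        assert poisson_log_likelihood(expected, make_sfs(3, 100.0, [1, 0])) == -math.inf

    def test_frame_mismatch(self):
        expected = snp_expected(1.0, 0.0, 0.0, SampleFrame(n=3, m=100.0))
        with pytest.raises(SFSValidationError):
            poisson_log_likelihood(expected, make_sfs(3, 200.0, [1, 0]))


class TestJointLogLik:
    def test_indel_is_sum_of_types(self):
        frame = SampleFrame(n=10, m=1e4)
        pi = snp_expected(10.0, -2.0, 0.0, frame)
        pd = snp_expected(20.0, -8.0, 0.0, frame)
        xi = make_sfs(10, 1e4, np.arange(9), vtype="ins")
        xd = make_sfs(10, 1e4, np.arange(9)[::-1], vtype="del")
        assert indel_log_likelihood(pi, pd, xi, xd) == pytest.approx(
            poisson_log_likelihood(pi, xi) + poisson_log_likelihood(pd, xd)
        )

    def test_empty_spectrum_contributes_minus_psi_total(self):
        frame = SampleFrame(n=10, m=1e4)
        pi = snp_expected(10.0, 0.0, 0.0, frame)
        xi = make_sfs(10, 1e4, np.zeros(9), vtype="ins")
        assert poisson_log_likelihood(pi, xi) == pytest.approx(-pi.total)

    def test_region_additivity_and_missing_key(self, snp_c2_spec, snp_c2_truth):
        spec = ModelSpec(
            types={"snp": TypeModel("discrete", 1)}, neutral_types=("snp",), demography=True
        )
        n = 10
        params = {
            "snp.class1.theta": 1e-3, "snp.class1.gamma": -4.0, "snp.class1.epsilon": 0.05,
            "snp.neutral.theta": 2e-3, "snp.neutral.epsilon": 0.02,
            **{f"r.{i}": 1.3 for i in range(2, n)},
        }
        rng = np.random.default_rng(0)
        sel = make_sfs(n, 1e5, rng.integers(0, 40, n - 1))
        neu = make_sfs(n, 5e4, rng.integers(0, 40, n - 1), region="neutral")
        data = make_set(sel, neu)
        ll = joint_log_likelihood(spec, params, data)
        # additivity: regional likelihoods computed independently
        psi = expected_spectra(
            spec, params, {"selected": sel.frame, "neutral": neu.frame}
        )
        from sfsdfe.likelihood import _poisson_terms

        manual = _poisson_terms(psi[("selected", "snp")], sel.counts) + _poisson_terms(
            psi[("neutral", "snp")], neu.counts
        )
        assert ll == pytest.approx(manual, rel=1e-12)
        with pytest.raises(SFSValidationError):
            joint_log_likelihood(spec, params, make_set(sel))

    def test_unit_r_equals_no_demography(self):
        n = 10
        spec_demo = ModelSpec(
            types={"snp": TypeModel("discrete", 1)}, neutral_types=("snp",), demography=True
        )
        spec_plain = ModelSpec(
            types={"snp": TypeModel("discrete", 1)}, neutral_types=("snp",)
        )
        params = {
            "snp.class1.theta": 1e-3, "snp.class1.gamma": -4.0, "snp.class1.epsilon": 0.05,
            "snp.neutral.theta": 2e-3, "snp.neutral.epsilon": 0.02,
        }
        rng = np.random.default_rng(1)
        data = make_set(
            make_sfs(n, 1e5, rng.integers(0, 40, n - 1)),
            make_sfs(n, 5e4, rng.integers(0, 40, n - 1), region="neutral"),
        )
        with_r = joint_log_likelihood(
            spec_demo, {**params, **{f"r.{i}": 1.0 for i in range(2, n)}}, data
        )
        without = joint_log_likelihood(spec_plain, params, data)
        assert with_r == without

    def test_class_label_permutation_invariance(self, snp_c2_spec, snp_c2_truth, frame50):
        rng = np.random.default_rng(2)
        data = make_set(make_sfs(50, 1e6, rng.integers(0, 100, 49)))
        swapped = {
            "snp.class1.theta": snp_c2_truth["snp.class2.theta"],
            "snp.class1.gamma": snp_c2_truth["snp.class2.gamma"],
            "snp.class1.epsilon": snp_c2_truth["snp.class2.epsilon"],
            "snp.class2.theta": snp_c2_truth["snp.class1.theta"],
            "snp.class2.gamma": snp_c2_truth["snp.class1.gamma"],
            "snp.class2.epsilon": snp_c2_truth["snp.class1.epsilon"],
        }
        assert joint_log_likelihood(snp_c2_spec, snp_c2_truth, data) == pytest.approx(
            joint_log_likelihood(snp_c2_spec, swapped, data), rel=1e-12
        )


class TestConstraints:
    def test_shared_epsilon_expansion(self):
        spec = ModelSpec(types={"snp": TypeModel("discrete", 2, "shared")})
        assert spec.free_param_count() == 5
        full = apply_constraints([1e-3, -5.0, 0.07, 2e-3, -20.0], spec, n=10)
        assert full["snp.class1.epsilon"] == full["snp.class2.epsilon"] == 0.07

    def test_ratio_derivation(self):
        spec = ModelSpec(
            types={"ins": TypeModel("discrete", 1), "del": TypeModel("discrete", 1)},
            ratio_constraints=(RatioConstraint("del.class1.theta", ("ins.class1.theta",), 5.0),),
        )
        full = apply_constraints([2e-4, -1.0, 0.0, -2.0, 0.0], spec, n=10)
        assert full["del.class1.theta"] == pytest.approx(1e-3)

    def test_zero_epsilon_fixed(self):
        spec = ModelSpec(types={"snp": TypeModel("discrete", 2, "zero")})
        full = apply_constraints([1e-3, -5.0, 2e-3, -20.0], spec, n=10)
        assert full["snp.class1.epsilon"] == 0.0 and full["snp.class2.epsilon"] == 0.0

    def test_constraint_cycle_rejected(self):
        spec = ModelSpec(
            types={"ins": TypeModel("discrete", 1), "del": TypeModel("discrete", 1)},
            ratio_constraints=(
                RatioConstraint("del.class1.theta", ("ins.class1.theta",), 5.0),
                RatioConstraint("ins.class1.theta", ("del.class1.theta",), 0.2),
            ),
        )
        with pytest.raises(SFSValidationError):
            spec.free_param_count()


class TestFitModel:
    def test_noise_free_recovery(self, snp_c2_spec, snp_c2_truth, frame50):
        psi = expected_spectra(snp_c2_spec, snp_c2_truth, {"selected": frame50})
        data = PolarisedSFSSet(
            entries={
                ("selected", "snp"): PolarisedSFS(
                    frame=frame50, variant_type="snp", counts=psi[("selected", "snp")]
                )
            }
        )
        fit = fit_model(snp_c2_spec, data, OptimizerOptions(n_starts=4, seed=11))
        for pid, true in snp_c2_truth.items():
            assert fit.params[pid] == pytest.approx(true, rel=1e-3), pid

    def test_deterministic_given_seed(self, snp_c2_spec, snp_c2_truth, frame50):
        from sfsdfe.simulate import simulate_sfs

        data = simulate_sfs(snp_c2_spec, snp_c2_truth, {"selected": frame50}, 99)
        opts = OptimizerOptions(n_starts=3, seed=5)
        a = fit_model(snp_c2_spec, data, opts)
        b = fit_model(snp_c2_spec, data, OptimizerOptions(n_starts=3, seed=5))
        assert a.params == b.params and a.loglik == b.loglik

    def test_classes_sorted_by_gamma_descending(self, snp_c2_spec, snp_c2_truth, frame50):
        from sfsdfe.simulate import simulate_sfs

        data = simulate_sfs(snp_c2_spec, snp_c2_truth, {"selected": frame50}, 21)
        fit = fit_model(snp_c2_spec, data, OptimizerOptions(n_starts=3, seed=1))
        assert fit.params["snp.class1.gamma"] > fit.params["snp.class2.gamma"]

    def test_constrained_fit_never_beats_unconstrained(self, frame50):
        from sfsdfe.simulate import simulate_sfs

        free = ModelSpec(
            types={"ins": TypeModel("discrete", 1), "del": TypeModel("discrete", 1)}
        )
        tied = ModelSpec(
            types={"ins": TypeModel("discrete", 1), "del": TypeModel("discrete", 1)},
            ratio_constraints=(RatioConstraint("del.class1.theta", ("ins.class1.theta",), 5.0),),
        )
        truth = {
            "ins.class1.theta": 5e-4, "ins.class1.gamma": -5.0, "ins.class1.epsilon": 0.02,
            "del.class1.theta": 1e-3, "del.class1.gamma": -15.0, "del.class1.epsilon": 0.02,
        }
        data = simulate_sfs(free, truth, {"selected": frame50}, 13)
        fit_free = fit_model(free, data, OptimizerOptions(n_starts=3, seed=2))
        fit_tied = fit_model(tied, data, OptimizerOptions(n_starts=3, seed=2))
        assert fit_tied.k == fit_free.k - 1
        assert fit_tied.loglik <= fit_free.loglik + 1e-6
        assert fit_tied.params["del.class1.theta"] == pytest.approx(
            5.0 * fit_tied.params["ins.class1.theta"]
        )


def _fake_fit(k, loglik):
    spec = ModelSpec(types={"snp": TypeModel("discrete", 1)})
    return FitResult(
        spec=spec, params={}, loglik=loglik, k=k, n_starts=1, converged=True
    )


class TestModelComparison:
    def test_lrt_reference_quantile(self):
        full, red = _fake_fit(4, -10.0), _fake_fit(3, -10.0 - 3.841 / 2)
        stat, df, p = likelihood_ratio_test(full, red)
        assert stat == pytest.approx(3.841)
        assert df == 1
        assert p == pytest.approx(0.05, abs=5e-4)

    def test_identical_fits(self):
        stat, df, p = likelihood_ratio_test(_fake_fit(4, -10.0), _fake_fit(2, -10.0))
        assert stat == 0.0 and df == 2 and p == 1.0

    def test_class_count_reduction_df(self):
        full = _fake_fit(6, -5.0)  # C = 2, free epsilon
        reduced = _fake_fit(3, -9.0)  # C = 1
        _, df, _ = likelihood_ratio_test(full, reduced)
        assert df == 3

    def test_reduced_better_warns(self):
        with pytest.warns(RuntimeWarning):
            likelihood_ratio_test(_fake_fit(4, -12.0), _fake_fit(3, -10.0))

    def test_not_nested_rejected(self):
        with pytest.raises(SFSValidationError):
            likelihood_ratio_test(_fake_fit(3, -10.0), _fake_fit(3, -11.0))

    def test_aic_values_and_ranking(self):
        table = aic_compare([_fake_fit(2, -10.0)])
        assert table["aic"].iloc[0] == pytest.approx(24.0)
        table = aic_compare([_fake_fit(5, -10.0), _fake_fit(6, -10.0)])
        assert table["k"].iloc[0] == 5 and table["delta_aic"].iloc[1] == pytest.approx(2.0)
        shifted = aic_compare([_fake_fit(5, 90.0), _fake_fit(6, 90.0)])
        assert list(shifted["k"]) == list(table["k"])

    def test_empty_list_rejected(self):
        with pytest.raises(SFSValidationError):
            aic_compare([])
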