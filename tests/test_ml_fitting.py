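"""Covariance-ML fit function, multi-group estimation and inference."""

import numpy as np
import pytest

from adoptsem import (
    CovarianceBlock,
    GroupData,
    ModelParams,
    ModelSpec,
    fit_model,
    lrt,
    ml_fit_function,
    sample_covariance,
    simulate_dataset,
    wald_tests,
)
from adoptsem.ml_fitting import FitResult
from adoptsem.power_analysis import population_groups

from conftest import draw_params


def _fit_result(estimates, ses, fitval=0.0, free=None):
    free = tuple(free or estimates)
    return FitResult(
        estimates=estimates, standard_errors=ses, minus2ll_fit=fitval,
        df_model=1, converged=True, n_restarts_used=0, group_fits={},
        free_params=free, fixed_params={}, n_total=100,
    )


class TestMlFitFunction:
    def test_zero_iff_equal(self):
        s = np.array([[1.0, 0.3], [0.3, 2.0]])
        assert ml_fit_function(s, s, 100) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        # Sigma=I2, S=diag(2,1), n=1 -> ln1 + 3 - ln2 - 2 = 1 - ln2
        v = ml_fit_function(np.eye(2), np.diag([2.0, 1.0]), 1)
        assert v == pytest.approx(1.0 - np.log(2.0), rel=1e-12)

    def test_linear_in_n(self):
        sigma, s = np.eye(2), np.diag([2.0, 1.0])
        assert ml_fit_function(sigma, s, 200) == pytest.approx(
            2 * ml_fit_function(sigma, s, 100)
        )

    def test_rejects_non_pd(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            ml_fit_function(bad, np.eye(2), 10)
        with pytest.raises(ValueError, match="sample"):
            ml_fit_function(np.eye(2), bad, 10)

    def test_label_mismatch(self):
        a = CovarianceBlock(("x", "y"), np.eye(2))
        b = CovarianceBlock(("y", "x"), np.eye(2))
        with pytest.raises(ValueError, match="labels"):
            ml_fit_function(a, b, 10)


def test_self_consistency_perfect_fit(theta_star, ukb_sizes):
    """Fitting the full model to its own population covariances recovers the
    generating values with (near) zero misfit, from cold starts."""
    groups = population_groups(theta_star, ukb_sizes)
    fit = fit_model(groups, ModelSpec.full(), seed=0)
    assert fit.converged
    assert fit.minus2ll_fit == pytest.approx(0.0, abs=1e-8)
    for name, est in fit.estimates.items():
        assert est == pytest.approx(getattr(theta_star, name), abs=1e-6)


def test_reduced_model_misfit_positive(theta_star, ukb_sizes):
    groups = population_groups(theta_star, ukb_sizes)
    spec = ModelSpec.full().reduced(["gamma_m"])
    fit = fit_model(groups, spec, seed=0, compute_se=False)
    assert fit.minus2ll_fit > 1.0


def test_recovery_at_many_random_points(ukb_sizes):
    """Population-covariance fits recover >= 20 random interior points."""
    rng = np.random.default_rng(11)
    for _ in range(20):
        theta = draw_params(rng)
        groups = population_groups(theta, ukb_sizes)
        fit = fit_model(groups, ModelSpec.full(), seed=0, compute_se=False)
        assert fit.converged
        assert fit.minus2ll_fit == pytest.approx(0.0, abs=1e-6)
        errs = [abs(v - getattr(theta, k)) for k, v in fit.estimates.items()]
        assert max(errs) < 1e-4


def test_parameter_recovery_from_simulated_data(ukb_sizes):
    theta = ModelParams(gamma_m=0.1, beta_m=0.1, beta_p=0.1, beta_o=0.1,
                        rho=0.0, phi=1.0, eps1_sq=1.0, eps2_sq=1.0)
    sim = simulate_dataset(theta, ukb_sizes, seed=123)
    groups = [GroupData(g.label, sample_covariance(g)) for g in sim]
    fit = fit_model(groups, ModelSpec.full(), seed=0)
    assert fit.converged and fit.standard_errors is not None
    for name, est in fit.estimates.items():
        se = fit.standard_errors[name]
        assert abs(est - getattr(theta, name)) < 4 * se


def test_objective_invariant_to_group_order(theta_star, ukb_sizes):
    groups = population_groups(theta_star, ukb_sizes)
    # perturb one sample matrix so the objective is nonzero
    groups[0].cov.matrix = groups[0].cov.matrix + 0.02 * np.eye(4)
    spec = ModelSpec(free_params=(), fixed_params=theta_star.as_dict())
    v1 = fit_model(groups, spec).minus2ll_fit
    v2 = fit_model(list(reversed(groups)), spec).minus2ll_fit
    assert v1 == pytest.approx(v2, rel=1e-12)
    assert v1 > 0


def test_model_spec_validation():
    with pytest.raises(ValueError, match="free and fixed|both free"):
        ModelSpec(free_params=("phi",), fixed_params={"phi": 1.0})
    with pytest.raises(ValueError, match="missing"):
        ModelSpec(free_params=("phi",), fixed_params={})
    spec = ModelSpec.full()
    red = spec.reduced(["gamma_m"])
    assert "gamma_m" not in red.free_params
    assert red.fixed_params["gamma_m"] == 0.0
    with pytest.raises(ValueError, match="not free"):
        spec.reduced(["r"])


def test_group_data_validation():
    block = CovarianceBlock(("Zo", "Y"), np.eye(2), n=10)
    assert GroupData("G4", block).structure == "G4"
    with pytest.raises(ValueError, match="roster"):
        GroupData("G1", block)
    with pytest.raises(ValueError, match="n="):
        GroupData("G4", CovarianceBlock(("Zo", "Y"), np.eye(2), n=2))


class TestWald:
    def test_null_estimate(self):
        fit = _fit_result({"gamma_m": 0.0}, {"gamma_m": 1.0})
        t = wald_tests(fit)["gamma_m"]
        assert t["z"] == 0.0 and t["p"] == pytest.approx(1.0)

    def test_normal_quantile(self):
        fit = _fit_result({"gamma_m": 1.96}, {"gamma_m": 1.0})
        assert wald_tests(fit)["gamma_m"]["p"] == pytest.approx(0.05, abs=1e-3)

    def test_table_style_values(self):
        fit = _fit_result({"gamma_m": 0.035}, {"gamma_m": 0.013})
        t = wald_tests(fit)["gamma_m"]
        assert t["z"] == pytest.approx(2.69, abs=0.01)
        assert t["p"] == pytest.approx(0.0072, abs=5e-4)

    def test_missing_se_flagged(self):
        fit = _fit_result({"gamma_m": 0.1}, {})
        assert wald_tests(fit)["gamma_m"]["p"] is None


class TestLrt:
    def test_identical_models(self):
        full = _fit_result({"a": 1.0, "b": 2.0}, None, fitval=3.0, free=("gamma_m", "beta_m"))
        red = _fit_result({"a": 1.0}, None, fitval=3.0, free=("gamma_m", "beta_m"))
        chi2, df, p = lrt(full, red)
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_df_counts_constraints(self):
        full = _fit_result({}, None, fitval=0.0, free=tuple("abcdefgh"))
        red = _fit_result({}, None, fitval=3.841, free=tuple("bcdefgh"))
        chi2, df, p = lrt(full, red)
        assert df == 1
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_requires_nesting(self):
        full = _fit_result({}, None, free=("gamma_m",))
        red = _fit_result({}, None, free=("beta_m",))
        with pytest.raises(ValueError, match="nest"):
            lrt(full, red)

    def test_negative_chi2_rejected(self):
        full = _fit_result({}, None, fitval=5.0, free=("a", "b"))
        red = _fit_result({}, None, fitval=1.0, free=("a",))
        with pytest.raises(ValueError, match="negative"):
            lrt(full, red)
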