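"""Engine-level tests: compilation, implied moments, ML and FIML fitting,
fit indices, standardization, nested comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcskit.lcs_models import (
    LcsModelOptions,
    build_bivariate_lcs,
    start_values_from_moments,
    theta_from_labels,
)
from lcskit.sem_core import (
    AllMissingError,
    DuplicateEdgeError,
    EmptyModelError,
    FitOptions,
    MomentsError,
    NotNestedError,
    RawDataset,
    SampleMoments,
    SingularModelError,
    StructuralModelSpec,
    UnknownVariableError,
    compile_model,
    compare_nested,
    fit_fiml,
    fit_indices,
    fit_ml_moments,
    fixed,
    free,
    implied_moments,
    fit_ml_moments as _fit_ml,
    saturated_moments_spec,
    standardize_solution,
)
from lcskit.synthetic_data import inject_missingness, recovery_parameters, simulate_lcs

FF = [f"FF_T{t}" for t in range(1, 5)]
EP = [f"EP_T{t}" for t in range(1, 5)]


# ---------------------------------------------------------------------------
# compilation

def test_compile_minimal_model_counts_two_parameters():
    spec = StructuralModelSpec(
        observed_names=["x"],
        variance_edges=[("x", "x", free("v", 1.0))],
        mean_terms=[("x", free("m"))],
    )
    model = compile_model(spec)
    assert model.theta_dimension == 2
    assert set(model.theta_labels) == {"v", "m"}


def test_shared_label_counts_once_and_maps_both_cells():
    spec = StructuralModelSpec(
        observed_names=["a", "b", "c"],
        directed_edges=[("a", "b", free("beta_x")), ("a", "c", free("beta_x"))],
        variance_edges=[(v, v, free(f"v_{v}", 1.0)) for v in "abc"],
    )
    model = compile_model(spec)
    assert model.theta_dimension == 4  # beta_x counted once
    assert len(model.parameter_index["beta_x"]) == 2


def test_bivariate_lcs_theta_dimension_matches_label_enumeration(bivariate_model):
    # enumeration oracle: walk the raw spec object and count distinct labels
    spec = build_bivariate_lcs(4)
    labels = set()
    for *_, ref in spec.directed_edges + spec.variance_edges:
        if hasattr(ref, "label"):
            labels.add(ref.label)
    for _, ref in spec.mean_terms:
        if hasattr(ref, "label"):
            labels.add(ref.label)
    assert bivariate_model.theta_dimension == len(labels) == 24


@pytest.mark.parametrize(
    "mutator, err",
    [
        (lambda s: s.directed_edges.append(("f", "x1", fixed(1.0))), DuplicateEdgeError),
        (lambda s: s.directed_edges.append(("f", "nope", free("b"))), UnknownVariableError),
        (lambda s: s.variance_edges.append(("x1", "x1", free("dup"))), DuplicateEdgeError),
    ],
)
def test_compile_spec_errors(mutator, err):
    spec = StructuralModelSpec(
        observed_names=["x1", "x2"],
        latent_names=["f"],
        directed_edges=[("f", "x1", fixed(1.0)), ("f", "x2", free("l2", 1.0))],
        variance_edges=[("x1", "x1", free("t1", 1.0)), ("x2", "x2", free("t2", 1.0)),
                        ("f", "f", free("psi", 1.0))],
    )
    mutator(spec)
    with pytest.raises(err):
        compile_model(spec)


def test_empty_model_is_an_error():
    with pytest.raises(EmptyModelError):
        compile_model(StructuralModelSpec(observed_names=["x"]))


@given(st.lists(st.floats(-3, 3), min_size=24, max_size=24))
@settings(max_examples=25, deadline=None)
def test_theta_write_read_roundtrip(bivariate_model, values):
    """Writing a parameter vector then reading cells reproduces it exactly."""
    theta = np.asarray(values)
    A, S, M = bivariate_model.matrices(theta)
    assert np.array_equal(bivariate_model.read_theta(A, S, M), theta)


# ---------------------------------------------------------------------------
# implied moments

def test_implied_moments_no_paths_is_diagonal():
    spec = StructuralModelSpec(
        observed_names=["a", "b"],
        variance_edges=[("a", "a", free("va", 2.0)), ("b", "b", free("vb", 3.0))],
        mean_terms=[("a", fixed(1.0)), ("b", fixed(-1.0))],
    )
    model = compile_model(spec)
    mu, Sigma = implied_moments(model, np.array([2.0, 3.0]))
    assert np.allclose(mu, [1.0, -1.0])
    assert np.allclose(Sigma, np.diag([2.0, 3.0]))


def test_implied_moments_regression_hand_algebra():
    # x -> y with path b: Var(y) = b^2 s + psi, Cov(x, y) = b s
    spec = StructuralModelSpec(
        observed_names=["x", "y"],
        directed_edges=[("x", "y", free("b", 0.5))],
        variance_edges=[("x", "x", free("s", 2.0)), ("y", "y", free("psi", 1.0))],
    )
    model = compile_model(spec)
    b, s, psi = 0.7, 2.5, 1.3
    theta = theta_from_labels(model, {"b": b, "s": s, "psi": psi})
    _, Sigma = implied_moments(model, theta)
    i, j = model.observed_names.index("x"), model.observed_names.index("y")
    assert Sigma[j, j] == pytest.approx(b * b * s + psi, abs=1e-12)
    assert Sigma[i, j] == pytest.approx(b * s, abs=1e-12)


def test_implied_moments_singular_loop_raises():
    spec = StructuralModelSpec(
        observed_names=["x", "y"],
        directed_edges=[("x", "y", fixed(1.0)), ("y", "x", fixed(1.0))],
        variance_edges=[("x", "x", free("v", 1.0))],
    )
    with pytest.raises(SingularModelError):
        model = compile_model(spec)
        implied_moments(model, np.array([1.0]))


# ---------------------------------------------------------------------------
# ML fitting to moments

def test_saturated_fit_is_exact(exact_moments):
    model = compile_model(saturated_moments_spec(exact_moments.variable_names))
    fit = fit_ml_moments(model, exact_moments)
    assert fit.converged
    assert fit.discrepancy_value == pytest.approx(0.0, abs=1e-10)
    assert fit.chi_square == pytest.approx(0.0, abs=1e-6)
    assert fit.df == 0
    # round-trip: implied moments reproduce the input
    mu, Sigma = implied_moments(model, fit.theta)
    assert np.allclose(mu, exact_moments.mean_vector, atol=1e-8)
    assert np.allclose(Sigma, exact_moments.covariance_matrix, atol=1e-8)


def test_two_variable_regression_closed_form():
    rng = np.random.default_rng(7)
    x = rng.normal(2.0, 1.5, 600)
    y = 1.2 + 0.8 * x + rng.normal(0, 0.9, 600)
    X = np.c_[x, y]
    mean = X.mean(axis=0)
    cov = np.cov(X.T, ddof=0)
    moments = SampleMoments(["x", "y"], mean, cov, 600)
    spec = StructuralModelSpec(
        observed_names=["x", "y"],
        directed_edges=[("x", "y", free("slope", 0.0))],
        variance_edges=[("x", "x", free("vx", 1.0)), ("y", "y", free("psi", 1.0))],
        mean_terms=[("x", free("mx")), ("y", free("intercept"))],
    )
    fit = fit_ml_moments(compile_model(spec), moments)
    slope = cov[0, 1] / cov[0, 0]
    assert fit.estimate("slope").value == pytest.approx(slope, abs=1e-6)
    assert fit.estimate("intercept").value == pytest.approx(mean[1] - slope * mean[0], abs=1e-6)


def test_lcs_self_consistency_recovery(bivariate_model, theta_star, exact_moments):
    """Fitting to exactly model-implied moments returns theta*."""
    sv = start_values_from_moments(exact_moments, FF, EP)
    fit = fit_ml_moments(bivariate_model, exact_moments,
                         FitOptions(start_overrides=sv, compute_se=False))
    assert fit.converged
    assert fit.discrepancy_value < 1e-8
    assert np.abs(fit.theta - theta_star).max() < 1e-4


def test_too_many_parameters_rejected():
    spec = saturated_moments_spec(["a", "b"])
    spec.latent_names.append("f")
    spec.directed_edges.append(("f", "a", fixed(1.0)))
    spec.variance_edges.append(("f", "f", free("psi", 1.0)))
    model = compile_model(spec)
    moments = SampleMoments(["a", "b"], np.zeros(2), np.eye(2), 50)
    with pytest.raises(Exception):
        fit_ml_moments(model, moments)


def test_equality_constraint_never_decreases_discrepancy(exact_moments):
    """Adding a binding constraint cannot improve the fit (nested pair,
    freer model warm-started from the constrained solution)."""
    free_opts = LcsModelOptions(include_phi=False)
    constrained = LcsModelOptions(include_phi=False, include_change_coupling=False)
    sv = start_values_from_moments(exact_moments, FF, EP)
    f_con = fit_ml_moments(compile_model(build_bivariate_lcs(4, constrained)),
                           exact_moments, FitOptions(start_overrides=sv, compute_se=False))
    warm = dict(f_con.theta_dict(), xi_xy=0.0, xi_yx=0.0)
    f_free = fit_ml_moments(compile_model(build_bivariate_lcs(4, free_opts)),
                            exact_moments, FitOptions(start_overrides=warm, compute_se=False))
    assert f_con.discrepancy_value >= f_free.discrepancy_value - 1e-10
    comp = compare_nested(f_con, f_free)
    assert comp.delta_df == 2  # xi_xy, xi_yx removed


# ---------------------------------------------------------------------------
# FIML

def test_fiml_equals_moments_ml_on_complete_data(bivariate_model):
    data = simulate_lcs(recovery_parameters(), 400, seed=5)
    moments = SampleMoments.from_data(data.frame, bivariate_model.observed_names, ddof=0)
    sv = start_values_from_moments(moments, FF, EP)
    opts = FitOptions(start_overrides=sv, compute_se=False)
    f_mom = fit_ml_moments(bivariate_model, moments, opts)
    f_fiml = fit_fiml(bivariate_model, data, opts)
    assert abs(f_mom.minus_two_log_likelihood - f_fiml.minus_two_log_likelihood) < 1e-6
    assert np.abs(f_mom.theta - f_fiml.theta).max() < 1e-4


def test_fiml_mcar_recovery_within_three_se(bivariate_model):
    params = recovery_parameters()
    data = inject_missingness(simulate_lcs(params, 5000, seed=6), "MCAR", 0.2, seed=7)
    mom = SampleMoments.from_data(
        data.frame[bivariate_model.observed_names].dropna(), bivariate_model.observed_names)
    sv = start_values_from_moments(mom, FF, EP)
    fit = fit_fiml(bivariate_model, data, FitOptions(start_overrides=sv))
    assert fit.converged
    true = params.label_values()
    for label, value in true.items():
        est = fit.estimate(label)
        assert est.se > 0
        assert abs(est.value - value) < 3 * est.se, label


def test_fiml_all_missing_variable_errors(bivariate_model):
    data = simulate_lcs(recovery_parameters(), 40, seed=8)
    data.frame["FF_T2"] = np.nan
    with pytest.raises(AllMissingError):
        fit_fiml(bivariate_model, data)


# ---------------------------------------------------------------------------
# fit indices

def test_perfect_fit_limits():
    idx = fit_indices(chi_square=5.0, df=10, baseline_chi_square=500.0,
                      baseline_df=28, n=468)
    assert idx.rmsea == 0.0
    assert idx.cfi == 1.0


def test_rmsea_from_printed_chi_square_ratio():
    # chi2/df = 3.11 at n = 468: rmsea = sqrt(2.11 / 467)
    chi2, df, n = 3.11 * 20, 20, 468
    idx = fit_indices(chi2, df, 800.0, 28, n)
    assert idx.rmsea == pytest.approx(math.sqrt(2.11 / 467), abs=1e-10)
    assert idx.rmsea == pytest.approx(0.0672, abs=5e-4)


def test_zero_df_reports_not_applicable_without_division_errors():
    idx = fit_indices(0.0, 0, 100.0, 28, 468)
    assert not idx.applicable
    assert math.isnan(idx.cfi) and math.isnan(idx.rmsea)


def test_degenerate_baseline_clamps_cfi():
    idx = fit_indices(30.0, 20, 30.0, 20, 468)
    assert 0.0 <= idx.cfi <= 1.0
    assert 0.0 <= idx.tli <= 1.0


def test_rmsea_interval_brackets_point_estimate():
    idx = fit_indices(62.2, 20, 800.0, 28, 468)
    lo, hi = idx.rmsea_ci
    assert 0.0 <= lo <= idx.rmsea <= hi


# ---------------------------------------------------------------------------
# standardization / nested comparison

def _simple_regression_fit():
    rng = np.random.default_rng(11)
    x = rng.normal(0, 2.0, 500)
    y = 0.6 * x + rng.normal(0, 1.0, 500)
    cov = np.cov(np.c_[x, y].T, ddof=0)
    moments = SampleMoments(["x", "y"], np.r_[x.mean(), y.mean()], cov, 500)
    spec = StructuralModelSpec(
        observed_names=["x", "y"],
        directed_edges=[("x", "y", free("slope"))],
        variance_edges=[("x", "x", free("vx", 1.0)), ("y", "y", free("psi", 1.0))],
        mean_terms=[("x", free("mx")), ("y", free("my"))],
    )
    model = compile_model(spec)
    fit = fit_ml_moments(model, moments)
    return model, fit, cov


def test_standardized_slope_equals_model_implied_correlation():
    model, fit, cov = _simple_regression_fit()
    standardize_solution(fit, model)
    r = cov[0, 1] / math.sqrt(cov[0, 0] * cov[1, 1])
    assert fit.estimate("slope").standardized_value == pytest.approx(r, abs=1e-6)


def test_unit_variance_standardization_is_identity():
    spec = StructuralModelSpec(
        observed_names=["x", "y"],
        directed_edges=[("x", "y", free("b"))],
        variance_edges=[("x", "x", fixed(1.0)), ("y", "y", free("psi", 1.0))],
        mean_terms=[("x", free("mx")), ("y", free("my"))],
    )
    model = compile_model(spec)
    moments = SampleMoments(["x", "y"], np.zeros(2),
                            np.array([[1.0, 0.6], [0.6, 1.0]]), 200)
    fit = fit_ml_moments(model, moments)
    standardize_solution(fit, model)
    b = fit.estimate("b")
    # psi fitted so Var(y) = 1: standardized equals unstandardized
    assert b.standardized_value == pytest.approx(b.value, abs=1e-6)


def test_standardized_exogenous_latent_variances_are_one(
        bivariate_model, exact_moments):
    sv = start_values_from_moments(exact_moments, FF, EP)
    fit = fit_ml_moments(bivariate_model, exact_moments,
                         FitOptions(start_overrides=sv, compute_se=False))
    standardize_solution(fit, bivariate_model)
    for label in ("var_ix", "var_sx", "var_iy", "var_sy"):
        assert fit.estimate(label).standardized_value == pytest.approx(1.0, abs=1e-8)


def test_compare_nested_identical_and_error(exact_moments):
    names = exact_moments.variable_names[:3]
    spec = StructuralModelSpec(
        observed_names=names,
        variance_edges=[(v, v, free(f"v_{v}", 1.0)) for v in names],
        mean_terms=[(v, free(f"m_{v}")) for v in names],
    )
    model = compile_model(spec)
    fit = fit_ml_moments(model, exact_moments.subset(names))
    assert fit.df == 3
    comp = compare_nested(fit, fit)
    assert (comp.delta_chi_square, comp.delta_df, comp.delta_cfi) == (0.0, 0, 0.0)
    import copy
    fit_big_df = copy.copy(fit)
    fit_big_df.df += 3
    with pytest.raises(NotNestedError):
        compare_nested(fit, fit_big_df)


# ---------------------------------------------------------------------------
# moments container

def test_moments_validation_errors():
    with pytest.raises(MomentsError):
        SampleMoments(["a", "b"], np.zeros(2), np.array([[1.0, 0.5], [0.2, 1.0]]), 10)
    with pytest.raises(MomentsError):
        SampleMoments(["a", "b"], np.zeros(2),
                      np.array([[1.0, 2.0], [2.0, 1.0]]), 10)  # eigenvalue -1


def test_correlation_repair_rule():
    # barely indefinite: repaired by eigenvalue clipping
    R = np.array([[1.0, 0.7, 0.7], [0.7, 1.0, 0.7], [0.7, 0.7, 1.0]])
    ev, V = np.linalg.eigh(R)
    ev[0] = -5e-9
    R_bad = (V * ev) @ V.T
    d = np.sqrt(np.diag(R_bad))
    R_bad = R_bad / np.outer(d, d)
    mom = SampleMoments.from_sd_corr(["a", "b", "c"], [0, 0, 0], [1, 1, 1], R_bad, 100)
    assert np.linalg.eigvalsh(mom.covariance_matrix).min() > 0
    # clearly indefinite: error
    R_bad2 = R.copy()
    R_bad2[0, 1] = R_bad2[1, 0] = -1.5
    with pytest.raises(MomentsError):
        SampleMoments.from_sd_corr(["a", "b", "c"], [0, 0, 0], [1, 1, 1], R_bad2, 100)


def test_raw_dataset_unknown_column_errors():
    import pandas as pd
    with pytest.raises(UnknownVariableError):
        RawDataset(frame=pd.DataFrame({"a": [1.0]}), variable_names=["a", "b"])
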