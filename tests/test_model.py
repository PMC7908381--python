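"""Conditional-logistic distributed-lag core: likelihood, fitting, ORs."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lagcrossover import (ConditionalLogisticDLM, SeparationError,
                          bic_select, conditional_loglik, extrapolate_lag_or,
                          fit, lag_specific_or, make_lag_basis,
                          simulate_matched_sets)
from conftest import brute_force_clogit_loglik


def random_instance(rng, n_strata=40, L=6, n_cov=0, m=3):
    X = rng.normal(25.0, 8.0, size=(n_strata * m, L + 1 + n_cov))
    y = np.zeros(n_strata * m)
    y[::m] = 1.0
    groups = np.repeat(np.arange(n_strata), m)
    return X, y, groups


# -- basis ----------------------------------------------------------------

def test_lag_basis_matrices():
    linear = make_lag_basis("linear", 6)
    assert np.array_equal(linear.C[4], [1.0, 4.0])
    log_linear = make_lag_basis("log_linear", 6)
    assert np.array_equal(log_linear.C[0], [1.0, 0.0])
    assert np.allclose(log_linear.C[3], [1.0, math.log(4.0)])
    unconstrained = make_lag_basis("unconstrained", 2)
    assert np.array_equal(unconstrained.C, np.eye(3))
    with pytest.raises(ValueError):
        make_lag_basis("cubic", 6)


# -- likelihood -----------------------------------------------------------

def test_loglik_at_zero_is_minus_log_set_sizes():
    rng = np.random.default_rng(0)
    X, y, g = random_instance(rng, n_strata=25, m=4)
    basis = make_lag_basis("linear", 6)
    res = conditional_loglik(np.zeros(2), X, y, g, basis)
    assert res["value"] == pytest.approx(-25 * math.log(4), rel=1e-12)
    assert res["value"] <= 0


def test_loglik_matches_brute_force_oracle():
    rng = np.random.default_rng(1)
    X, y, g = random_instance(rng, n_strata=15)
    basis = make_lag_basis("log_linear", 6)
    theta = np.array([0.01, -0.02])
    mine = conditional_loglik(theta, X, y, g, basis)["value"]
    Z = X @ basis.C
    oracle = brute_force_clogit_loglik(theta, Z, y, g)
    assert mine == pytest.approx(oracle, rel=1e-10)


@pytest.mark.parametrize("kind,n_cov", [("linear", 0), ("log_linear", 0),
                                        ("unconstrained", 0), ("linear", 3)])
def test_gradient_and_hessian_match_finite_differences(kind, n_cov):
    rng = np.random.default_rng(7)
    X, y, g = random_instance(rng, n_strata=30, n_cov=n_cov)
    X[:, :7] = rng.normal(25, 8, size=(X.shape[0], 7))
    basis = make_lag_basis(kind, 6)
    theta = rng.normal(0, 0.01, basis.q)
    gamma = rng.normal(0, 0.05, n_cov) if n_cov else None
    res = conditional_loglik(theta, X, y, g, basis, covariate_coefs=gamma)
    params = theta if gamma is None else np.concatenate([theta, gamma])

    def value_at(p):
        th, ga = p[:basis.q], (p[basis.q:] if n_cov else None)
        return conditional_loglik(th, X, y, g, basis,
                                  covariate_coefs=ga)["value"]

    h = 1e-5
    k = len(params)
    num_grad = np.empty(k)
    num_hess = np.empty((k, k))
    for i in range(k):
        ei = np.zeros(k); ei[i] = h
        num_grad[i] = (value_at(params + ei) - value_at(params - ei)) / (2 * h)
        for j in range(k):
            ej = np.zeros(k); ej[j] = h
            num_hess[i, j] = (
                value_at(params + ei + ej) - value_at(params + ei - ej)
                - value_at(params - ei + ej) + value_at(params - ei - ej)
            ) / (4 * h * h)
    assert np.allclose(res["gradient"], num_grad, rtol=1e-6, atol=1e-6)
    assert np.allclose(res["hessian"], num_hess, rtol=1e-4, atol=1e-3)


def test_stratum_constant_shift_leaves_likelihood_unchanged():
    """Self-matching cancels any within-stratum constant exposure shift."""
    rng = np.random.default_rng(3)
    X, y, g = random_instance(rng, n_strata=20)
    basis = make_lag_basis("linear", 6)
    theta = np.array([0.02, -0.005])
    base = conditional_loglik(theta, X, y, g, basis)["value"]
    shifts = rng.normal(0, 30, 20)
    X_shifted = X + shifts[g][:, None]
    shifted = conditional_loglik(theta, X_shifted, y, g, basis)["value"]
    assert shifted == pytest.approx(base, abs=1e-9)


def test_hessian_is_negative_semidefinite_everywhere_tested():
    rng = np.random.default_rng(5)
    X, y, g = random_instance(rng, n_strata=25)
    basis = make_lag_basis("linear", 6)
    for _ in range(10):
        theta = rng.normal(0, 0.02, 2)
        H = conditional_loglik(theta, X, y, g, basis)["hessian"]
        assert np.all(np.linalg.eigvalsh(H) <= 1e-8)


# -- fitting --------------------------------------------------------------

def test_fit_symmetric_two_strata_mle_is_zero():
    """1:1 strata with exposure differences +d and -d maximise at 0."""
    d = 5.0
    X = np.array([[30.0], [30.0 - d], [30.0], [30.0 + d]])
    y = np.array([1.0, 0.0, 1.0, 0.0])
    g = np.array([0, 0, 1, 1])
    est = ConditionalLogisticDLM(basis="unconstrained", max_lag=0)
    est.fit(X, y, groups=g)
    assert est.theta_[0] == pytest.approx(0.0, abs=1e-10)


def test_collapsed_design_equivalence(matched_sets):
    """Constrained fit == unconstrained fit on pre-collapsed C'x."""
    X, y, g, _ = matched_sets
    constrained = fit((X, y, g), basis="linear")
    Z = X @ make_lag_basis("linear", 6).C
    collapsed = ConditionalLogisticDLM(basis="unconstrained", max_lag=1)
    collapsed.fit(Z, y, groups=g)
    assert collapsed.loglik_ == pytest.approx(constrained.loglik, abs=1e-6)
    assert np.allclose(collapsed.theta_, constrained.theta, atol=1e-6)


def test_newton_reaches_same_optimum_from_random_starts(matched_sets):
    X, y, g, _ = matched_sets
    reference = fit((X, y, g), basis="linear").theta
    rng = np.random.default_rng(17)
    from lagcrossover.model import _group_slices, _newton, make_lag_basis
    basis = make_lag_basis("linear", 6)
    V = X @ basis.C
    starts = _group_slices(g)
    counts = np.diff(np.r_[starts, len(V)])
    for _ in range(5):
        theta0 = rng.normal(0, 0.05, 2)
        params, *_ = _newton(V, y, starts, counts, tol=1e-9, max_iter=100,
                             separation_norm=50.0, start_params=theta0)
        assert np.linalg.norm(params - reference) < 1e-6


def test_fit_matches_statsmodels_conditional_logit(matched_sets):
    """Independent cross-check against statsmodels' ConditionalLogit."""
    statsmodels = pytest.importorskip("statsmodels.api")
    from statsmodels.discrete.conditional_models import ConditionalLogit
    X, y, g, _ = matched_sets
    Z = X @ make_lag_basis("linear", 6).C
    ours = ConditionalLogisticDLM(basis="unconstrained", max_lag=1)
    ours.fit(Z, y, groups=g)
    theirs = ConditionalLogit(y, Z, groups=g).fit(disp=False)
    assert np.allclose(ours.theta_, theirs.params, atol=1e-5)
    assert ours.loglik_ == pytest.approx(theirs.llf, rel=1e-6)
    se_ours = np.sqrt(np.diag(ours.covariance_))
    assert np.allclose(se_ours, theirs.bse, rtol=1e-3)


def test_separation_raises():
    # case day always has the larger exposure: likelihood runs to infinity
    n = 30
    X = np.zeros((2 * n, 1))
    X[::2, 0] = 25.1
    X[1::2, 0] = 25.0
    y = np.tile([1.0, 0.0], n)
    g = np.repeat(np.arange(n), 2)
    est = ConditionalLogisticDLM(basis="unconstrained", max_lag=0)
    with pytest.raises(SeparationError):
        est.fit(X, y, groups=g)


def test_fit_input_validation():
    est = ConditionalLogisticDLM()
    X = np.zeros((4, 7)); y = np.array([1, 0, 1, 0]); g = np.array([0, 0, 1, 1])
    with pytest.raises(ValueError, match="groups"):
        est.fit(X, y)
    with pytest.raises(ValueError, match="exactly one case"):
        est.fit(X, np.array([1, 1, 1, 0]), groups=g)
    with pytest.raises(ValueError, match="control"):
        est.fit(X[:3], np.array([1.0, 0.0, 1.0]), groups=np.array([0, 0, 1]))


def test_sklearn_param_interface():
    est = ConditionalLogisticDLM(basis="log_linear", max_lag=4)
    params = est.get_params()
    assert params["basis"] == "log_linear" and params["max_lag"] == 4
    est.set_params(basis="linear")
    assert est.basis == "linear"
    from sklearn.base import clone
    assert clone(est).get_params() == est.get_params()


# -- BIC selection --------------------------------------------------------

def test_bic_definition_and_tie_break(matched_sets):
    X, y, g, _ = matched_sets
    best, table = bic_select((X, y, g))
    row = table.set_index("basis").loc[best.basis.kind]
    assert best.bic == pytest.approx(
        -2 * best.loglik + best.k * math.log(best.n_strata))
    assert best.bic == table["bic"].min()
    # declared candidate order is preserved in the table: linear first
    assert list(table["basis"]) == ["linear", "log_linear"]


def test_bic_prefers_linear_when_truth_is_linear():
    rng = np.random.default_rng(23)
    wins = 0
    n_rep = 30
    for _ in range(n_rep):
        X, y, g, _ = simulate_matched_sets(2000, 0.024, -0.006, rng)
        best, _ = bic_select((X, y, g))
        wins += best.basis.kind == "linear"
    assert wins > n_rep // 2  # clear majority


def test_bic_penalises_irrelevant_covariates():
    rng = np.random.default_rng(29)
    diffs = []
    for _ in range(20):
        X, y, g, _ = simulate_matched_sets(400, 0.0, 0.0, rng)
        W = rng.normal(size=(len(y), 2))
        unadjusted = fit((X, y, g), basis="linear")
        adjusted = fit((np.hstack([X, W]), y, g), basis="linear",
                       adjust=True)
        diffs.append(adjusted.bic - unadjusted.bic)
    assert np.mean(diffs) > 0  # on average the penalty dominates


# -- lag-specific odds ratios ---------------------------------------------

def test_lag_or_degenerate_zero_fit():
    basis = make_lag_basis("linear", 6)
    from lagcrossover.model import DlmFit
    res = DlmFit(basis=basis, theta=np.zeros(2), covariance=np.zeros((2, 2)),
                 loglik=0.0, n_strata=10, bic=0.0)
    est = lag_specific_or(res, 3)
    assert est.or_per_10 == est.ci_low == est.ci_high == 1.0
    with pytest.raises(ValueError):
        lag_specific_or(res, 7)


def test_linear_basis_or_is_geometric_in_lag(matched_sets):
    X, y, g, _ = matched_sets
    res = fit((X, y, g), basis="linear")
    or0 = res.lag_or(0).or_per_10
    or1 = res.lag_or(1).or_per_10
    for l in range(7):
        assert res.lag_or(l).or_per_10 == pytest.approx(
            or0 * (or1 / or0) ** l, rel=1e-12)


def test_delta_method_se_matches_bootstrap(matched_sets):
    """Nonparametric stratum bootstrap reproduces the Wald se within 15%."""
    X, y, g, _ = matched_sets
    n_strata = len(np.unique(g))
    m = len(y) // n_strata
    res = fit((X, y, g), basis="linear")
    se_delta = res.lag_or(0).se_log_or
    rng = np.random.default_rng(31)
    Xb = X.reshape(n_strata, m, -1)
    yb = y.reshape(n_strata, m)
    boot = []
    for _ in range(400):
        idx = rng.integers(0, n_strata, n_strata)
        rep = fit((Xb[idx].reshape(-1, X.shape[1]), yb[idx].ravel(),
                   np.repeat(np.arange(n_strata), m)), basis="linear")
        boot.append(10.0 * rep.basis.C[0] @ rep.theta)
    se_boot = np.std(boot, ddof=1)
    assert abs(se_boot - se_delta) / se_delta < 0.15


@pytest.mark.parametrize("or0,or1,l,expected", [
    (1.137, 1.099, 6, 0.927),   # particulate, coarse grid, full period
    (1.137, 1.099, 2, 1.062),
    (1.365, 1.255, 6, 0.825),   # particulate, fine grid
    (1.477, 1.313, 6, 0.729),   # nitrogen dioxide, fine grid
])
def test_extrapolate_lag_or_published_consistency(or0, or1, l, expected):
    assert extrapolate_lag_or(or0, or1, l) == pytest.approx(expected,
                                                            abs=5e-4)


@given(st.floats(0.5, 2.0), st.integers(0, 10))
def test_extrapolate_flat_response_is_identity(x, l):
    assert extrapolate_lag_or(x, x, l) == pytest.approx(x, rel=1e-12)


def test_extrapolate_rejects_bad_inputs():
    with pytest.raises(ValueError):
        extrapolate_lag_or(-1.0, 1.1, 2)
    with pytest.raises(ValueError):
        extrapolate_lag_or(1.1, 1.0, -1)
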