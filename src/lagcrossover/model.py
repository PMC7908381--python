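"""Conditional logistic regression with constrained distributed lags.

The exposure effect over lags 0..L is parameterised through a lag basis:
per-lag log-odds coefficients are beta = C @ theta with C either the
identity (unconstrained), columns (1, l) (linear in the lag) or columns
(1, ln(l+1)) (linear in the lag logarithm).  The matched-set conditional
likelihood is maximised by Newton–Raphson with analytic gradient and
Hessian; lag structures are compared by BIC; lag-specific odds ratios per
10 µg/m³ come with delta-method Wald intervals.

Internally all coefficients are per 1 µg/m³; the reporting scale (per
10 µg/m³) enters only in :func:`lag_specific_or`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import norm
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "LagBasis", "make_lag_basis", "DlmFit", "LagOrEstimate",
    "ConditionalLogisticDLM", "ConvergenceError", "SeparationError",
    "conditional_loglik", "fit", "bic_select", "lag_specific_or",
    "extrapolate_lag_or",
]

Z95 = norm.ppf(0.975)  # ≈ 1.959964; the Wald 95% quantile


class ConvergenceError(RuntimeError):
    """Newton–Raphson failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_params: np.ndarray,
                 n_iter: int, grad_norm: float):
        super().__init__(message)
        self.last_params = last_params
        self.n_iter = n_iter
        self.grad_norm = grad_norm


class SeparationError(RuntimeError):
    """The likelihood is maximised at infinity (separated data)."""


# ---------------------------------------------------------------------------
# lag basis
# ---------------------------------------------------------------------------

@dataclass
class LagBasis:
    """Transform from basis coefficients theta to per-lag coefficients.

    ``beta = C @ theta`` with C of shape (L+1, q).
    """

    kind: str
    L: int
    C: np.ndarray

    @property
    def q(self) -> int:
        return self.C.shape[1]


def make_lag_basis(kind: str, L: int = 6) -> LagBasis:
    """Build the constraint matrix for one of the three lag structures.

    The log-lag basis uses ln(l + 1) so the lag-0 column is well defined.
    """
    if L < 0:
        raise ValueError("L must be >= 0")
    lags = np.arange(L + 1, dtype=float)
    if kind == "unconstrained":
        C = np.eye(L + 1)
    elif kind == "linear":
        C = np.column_stack([np.ones(L + 1), lags])
    elif kind == "log_linear":
        C = np.column_stack([np.ones(L + 1), np.log(lags + 1.0)])
    else:
        raise ValueError(f"unknown lag basis kind {kind!r}")
    return LagBasis(kind=kind, L=L, C=C)


# ---------------------------------------------------------------------------
# conditional likelihood
# ---------------------------------------------------------------------------

def _group_slices(groups: np.ndarray) -> np.ndarray:
    """Start offsets of each contiguous group block (groups must be sorted)."""
    groups = np.asarray(groups)
    if groups.ndim != 1:
        raise ValueError("groups must be 1-D")
    if np.any(np.diff(groups) < 0):
        order_ok = False
    else:
        order_ok = True
    if not order_ok:
        raise ValueError("rows must be sorted by stratum")
    return np.flatnonzero(np.r_[True, np.diff(groups) != 0])


def _loglik_parts(params: np.ndarray, V: np.ndarray, y: np.ndarray,
                  starts: np.ndarray, counts: np.ndarray,
                  ) -> tuple[float, np.ndarray, np.ndarray]:
    """Value, gradient and Hessian of the matched-set log-likelihood.

    value = sum_i [eta_case,i - log sum_{j in i} exp(eta_j)];
    gradient = sum_i [v_case - sum_j p_j v_j];
    Hessian = -sum_i [sum_j p_j v_j v_j' - (sum_j p_j v_j)(...)'] with p the
    within-stratum softmax — exact analytic derivatives.
    """
    eta = V @ params
    # per-group logsumexp via reduceat on shifted exponentials
    gmax = np.maximum.reduceat(eta, starts)
    eta_shift = eta - np.repeat(gmax, counts)
    w = np.exp(eta_shift)
    denom = np.add.reduceat(w, starts)
    value = float(np.sum(eta[y == 1] - (np.log(denom) + gmax)))

    p = w / np.repeat(denom, counts)
    pv = V * p[:, None]
    mean_v = np.add.reduceat(pv, starts, axis=0)       # (n_strata, k)
    grad = V[y == 1].sum(axis=0) - mean_v.sum(axis=0)
    # sum_j p_j v_j v_j'  -  sum_i mean_i mean_i'
    hess = -(V.T @ pv - mean_v.T @ mean_v)
    return value, grad, hess


def conditional_loglik(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                       groups: np.ndarray, basis: LagBasis,
                       covariate_coefs: np.ndarray | None = None,
                       ) -> dict:
    """Conditional log-likelihood with exact gradient and Hessian.

    ``X`` holds the lag-0..L exposure columns first, then any covariate
    columns; derivatives are with respect to the stacked parameter
    ``(theta, covariate_coefs)``.
    """
    X = np.asarray(X, dtype=float)
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    n_lag = basis.L + 1
    Z = X[:, :n_lag] @ basis.C
    if covariate_coefs is None:
        V = Z
        params = theta
    else:
        covariate_coefs = np.atleast_1d(np.asarray(covariate_coefs,
                                                   dtype=float))
        V = np.hstack([Z, X[:, n_lag:]])
        params = np.concatenate([theta, covariate_coefs])
    starts = _group_slices(np.asarray(groups))
    counts = np.diff(np.r_[starts, len(V)])
    if np.any(counts < 2):
        raise ValueError("every stratum needs at least one control day")
    value, grad, hess = _loglik_parts(params, V, y, starts, counts)
    return {"value": value, "gradient": grad, "hessian": hess}


def _newton(V: np.ndarray, y: np.ndarray, starts: np.ndarray,
            counts: np.ndarray, tol: float, max_iter: int,
            separation_norm: float, start_params: np.ndarray | None = None,
            ) -> tuple[np.ndarray, np.ndarray, float, int, float]:
    """Maximise the matched-set likelihood; returns (params, cov, ll, it, g)."""
    k = V.shape[1]
    params = np.zeros(k) if start_params is None else start_params.copy()
    value, grad, hess = _loglik_parts(params, V, y, starts, counts)
    for it in range(1, max_iter + 1):
        gnorm = float(np.max(np.abs(grad)))
        if gnorm < tol:
            cov = _safe_inverse(-hess)
            return params, cov, value, it - 1, gnorm
        try:
            step = linalg.solve(-hess, grad, assume_a="pos")
        except linalg.LinAlgError:
            step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        # step halving: never accept a decrease in the log-likelihood
        scale = 1.0
        for _ in range(40):
            candidate = params + scale * step
            new_value, new_grad, new_hess = _loglik_parts(
                candidate, V, y, starts, counts)
            if new_value >= value - 1e-12:
                break
            scale *= 0.5
        params, value, grad, hess = candidate, new_value, new_grad, new_hess
        if np.linalg.norm(params) > separation_norm:
            raise SeparationError(
                "parameter norm exceeds the separation threshold; the "
                "matched sets are (quasi-)separated")
    gnorm = float(np.max(np.abs(grad)))
    if gnorm < tol:
        cov = _safe_inverse(-hess)
        return params, cov, value, max_iter, gnorm
    raise ConvergenceError(
        f"Newton–Raphson did not converge in {max_iter} iterations "
        f"(gradient max-norm {gnorm:.3g})", params, max_iter, gnorm)


def _safe_inverse(info: np.ndarray) -> np.ndarray:
    try:
        cov = linalg.inv(info)
    except linalg.LinAlgError:
        cov = linalg.pinvh(info)
    return 0.5 * (cov + cov.T)


# ---------------------------------------------------------------------------
# fit containers
# ---------------------------------------------------------------------------

@dataclass
class LagOrEstimate:
    """Odds ratio for a concentration increase at one lag, with Wald CI."""

    lag: int
    or_per_10: float
    ci_low: float
    ci_high: float
    se_log_or: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.or_per_10 <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


@dataclass
class DlmFit:
    """Fitted constrained distributed-lag conditional-logistic model."""

    basis: LagBasis
    theta: np.ndarray
    covariance: np.ndarray  # of (theta, covariate_coefs) jointly
    loglik: float
    n_strata: int
    bic: float
    covariate_coefs: np.ndarray | None = None
    n_iter: int = 0
    grad_norm: float = math.nan
    adjusted: bool = False

    @property
    def k(self) -> int:
        extra = 0 if self.covariate_coefs is None else len(self.covariate_coefs)
        return len(self.theta) + extra

    @property
    def cov_theta(self) -> np.ndarray:
        q = len(self.theta)
        return self.covariance[:q, :q]

    def beta_lags(self) -> np.ndarray:
        """Per-lag log-OR coefficients (per µg/m³)."""
        return self.basis.C @ self.theta

    def lag_or(self, l: int, delta: float = 10.0) -> LagOrEstimate:
        return lag_specific_or(self, l, delta=delta)

    def or_table(self, delta: float = 10.0) -> pd.DataFrame:
        rows = [self.lag_or(l, delta=delta) for l in range(self.basis.L + 1)]
        return pd.DataFrame({
            "lag": [r.lag for r in rows],
            "or": [r.or_per_10 for r in rows],
            "ci_low": [r.ci_low for r in rows],
            "ci_high": [r.ci_high for r in rows],
            "se_log_or": [r.se_log_or for r in rows],
        })

    def to_dict(self) -> dict:
        return {
            "basis": self.basis.kind, "max_lag": self.basis.L,
            "theta": self.theta.tolist(),
            "covariate_coefs": (None if self.covariate_coefs is None
                                else self.covariate_coefs.tolist()),
            "covariance": self.covariance.tolist(),
            "loglik": self.loglik, "bic": self.bic,
            "n_strata": self.n_strata, "k": self.k,
            "n_iter": self.n_iter, "grad_norm": self.grad_norm,
            "adjusted": self.adjusted,
        }


# ---------------------------------------------------------------------------
# sklearn estimator
# ---------------------------------------------------------------------------

class ConditionalLogisticDLM(BaseEstimator):
    """Conditional logistic regression with a constrained distributed lag.

    Parameters
    ----------
    basis : {"linear", "log_linear", "unconstrained"}
        Lag-constraint family: per-lag coefficients linear in the lag,
        linear in ln(lag + 1), or free.
    max_lag : int
        Longest lag L; X must carry L+1 lag columns first.
    n_covariates : int
        Number of trailing covariate columns in X (0 = unadjusted).
    tol : float
        Convergence tolerance on the gradient max-norm.
    max_iter : int
        Newton iteration cap.
    separation_norm : float
        Declare separation when the parameter norm (per µg/m³ scale)
        exceeds this.

    Attributes
    ----------
    theta_ : basis coefficients (per µg/m³)
    gamma_ : covariate coefficients, empty when unadjusted
    beta_lags_ : per-lag log-OR coefficients C @ theta
    covariance_ : joint covariance of (theta, gamma)
    loglik_, bic_, n_strata_, n_iter_, grad_norm_, converged_

    Examples
    --------
    >>> est = ConditionalLogisticDLM(basis="linear", max_lag=6)
    >>> est.fit(X, y, groups=g).lag_or(0).or_per_10  # doctest: +SKIP
    """

    def __init__(self, basis: str = "linear", max_lag: int = 6,
                 n_covariates: int = 0, tol: float = 1e-8,
                 max_iter: int = 50, separation_norm: float = 50.0):
        self.basis = basis
        self.max_lag = max_lag
        self.n_covariates = n_covariates
        self.tol = tol
        self.max_iter = max_iter
        self.separation_norm = separation_norm

    def fit(self, X, y, groups=None):
        if groups is None:
            raise ValueError("groups (stratum labels) are required")
        X = check_array(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        groups = np.asarray(groups).ravel()
        if not (len(X) == len(y) == len(groups)):
            raise ValueError("X, y and groups must have equal length")
        n_lag = self.max_lag + 1
        if X.shape[1] != n_lag + self.n_covariates:
            raise ValueError(
                f"X must have {n_lag} lag columns plus "
                f"{self.n_covariates} covariate columns")
        # sort rows by stratum; order within a stratum is irrelevant
        order = np.argsort(groups, kind="stable")
        X, y, groups = X[order], y[order], groups[order]
        starts = _group_slices(groups)
        counts = np.diff(np.r_[starts, len(X)])
        if np.any(counts < 2):
            raise ValueError("every stratum needs at least one control day")
        cases = np.add.reduceat(y, starts)
        if not np.allclose(cases, 1.0):
            raise ValueError("every stratum must contain exactly one case day")

        lag_basis = make_lag_basis(self.basis, self.max_lag)
        V = X[:, :n_lag] @ lag_basis.C
        if self.n_covariates:
            V = np.hstack([V, X[:, n_lag:]])
        params, cov, loglik, n_iter, gnorm = _newton(
            V, y, starts, counts, self.tol, self.max_iter,
            self.separation_norm)

        q = lag_basis.q
        self.lag_basis_ = lag_basis
        self.theta_ = params[:q]
        self.gamma_ = params[q:]
        self.beta_lags_ = lag_basis.C @ self.theta_
        self.covariance_ = cov
        self.loglik_ = loglik
        self.n_strata_ = int(len(starts))
        self.bic_ = -2.0 * loglik + len(params) * math.log(self.n_strata_)
        self.n_iter_ = n_iter
        self.grad_norm_ = gnorm
        self.converged_ = True
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        """Linear predictor eta for each row of X."""
        check_is_fitted(self, "theta_")
        X = check_array(X, dtype=float)
        n_lag = self.max_lag + 1
        eta = X[:, :n_lag] @ self.beta_lags_
        if self.n_covariates:
            eta = eta + X[:, n_lag:] @ self.gamma_
        return eta

    def predict_proba(self, X, groups):
        """Within-stratum case probabilities (softmax of the predictor)."""
        eta = self.decision_function(X)
        groups = np.asarray(groups).ravel()
        order = np.argsort(groups, kind="stable")
        starts = _group_slices(groups[order])
        counts = np.diff(np.r_[starts, len(eta)])
        es = eta[order]
        es = es - np.repeat(np.maximum.reduceat(es, starts), counts)
        w = np.exp(es)
        p_sorted = w / np.repeat(np.add.reduceat(w, starts), counts)
        p = np.empty_like(p_sorted)
        p[order] = p_sorted
        return p

    def score(self, X, y, groups=None):
        """Conditional log-likelihood of (X, y) under the fitted model."""
        check_is_fitted(self, "theta_")
        res = conditional_loglik(
            self.theta_, X, y, groups, self.lag_basis_,
            covariate_coefs=self.gamma_ if self.n_covariates else None)
        return res["value"]

    def lag_or(self, l: int, delta: float = 10.0) -> LagOrEstimate:
        check_is_fitted(self, "theta_")
        return lag_specific_or(self._as_fit(), l, delta=delta)

    def _as_fit(self) -> DlmFit:
        check_is_fitted(self, "theta_")
        return DlmFit(
            basis=self.lag_basis_, theta=self.theta_,
            covariance=self.covariance_, loglik=self.loglik_,
            n_strata=self.n_strata_, bic=self.bic_,
            covariate_coefs=self.gamma_ if self.n_covariates else None,
            n_iter=self.n_iter_, grad_norm=self.grad_norm_,
            adjusted=bool(self.n_covariates))


# ---------------------------------------------------------------------------
# module-level operation surface (thin wrappers over the estimator)
# ---------------------------------------------------------------------------

def _resolve_arrays(strata, adjust: bool):
    """Accept either a list of strata or a prepared (X, y, groups) tuple."""
    if isinstance(strata, tuple) and len(strata) == 3:
        return strata
    from .crossover import strata_to_arrays
    return strata_to_arrays(strata, with_covariates=adjust)


def fit(strata, basis: str = "linear", adjust: bool = False,
        max_lag: int = 6, **newton_kwargs) -> DlmFit:
    """Fit one constrained distributed-lag model on matched strata.

    ``strata`` may be a list of ``CaseCrossoverStratum`` or an
    ``(X, y, groups)`` tuple; ``adjust`` appends the calendar covariates.
    """
    X, y, groups = _resolve_arrays(strata, adjust)
    n_cov = X.shape[1] - (max_lag + 1)
    est = ConditionalLogisticDLM(basis=basis, max_lag=max_lag,
                                 n_covariates=n_cov, **newton_kwargs)
    est.fit(X, y, groups=groups)
    return est._as_fit()


def bic_select(strata, candidate_kinds=("linear", "log_linear"),
               adjust_options=(False,), max_lag: int = 6,
               ) -> tuple[DlmFit, pd.DataFrame]:
    """Fit all candidate lag structures and keep the lowest-BIC model.

    Ties go to the earliest candidate in the declared order.  Returns the
    winning fit plus a comparison table (kind, adjusted, loglik, k, BIC).
    """
    rows, fits = [], []
    errors = []
    for adjust in adjust_options:
        if isinstance(strata, tuple):
            arrays = strata
        else:
            from .crossover import strata_to_arrays
            arrays = strata_to_arrays(strata, with_covariates=adjust)
        for kind in candidate_kinds:
            try:
                res = fit(arrays, basis=kind, adjust=adjust, max_lag=max_lag)
            except (ConvergenceError, SeparationError) as err:
                errors.append((kind, adjust, err))
                continue
            fits.append(res)
            rows.append({"basis": kind, "adjusted": adjust,
                         "loglik": res.loglik, "k": res.k, "bic": res.bic})
    if not fits:
        raise errors[0][2] if errors else ValueError("no candidates fit")
    table = pd.DataFrame(rows)
    best = fits[int(np.argmin([f.bic for f in fits]))]
    return best, table


def lag_specific_or(fit_result: DlmFit, l: int,
                    delta: float = 10.0) -> LagOrEstimate:
    """Delta-method OR and 95% CI for a ``delta`` µg/m³ increase at lag l.

    log OR = delta * c_l' theta, se = delta * sqrt(c_l' V c_l) with c_l the
    lag-l row of the constraint matrix.
    """
    if not 0 <= l <= fit_result.basis.L:
        raise ValueError(f"lag {l} outside 0..{fit_result.basis.L}")
    c = fit_result.basis.C[l]
    log_or = delta * float(c @ fit_result.theta)
    se = delta * float(np.sqrt(c @ fit_result.cov_theta @ c))
    return LagOrEstimate(
        lag=l, or_per_10=math.exp(log_or),
        ci_low=math.exp(log_or - Z95 * se),
        ci_high=math.exp(log_or + Z95 * se),
        se_log_or=se)


def extrapolate_lag_or(or0: float, or1: float, l: int) -> float:
    """Lag-l OR implied by a linear-in-lag structure through lags 0 and 1.

    Under a linear lag function the log-OR is affine in the lag, so
    OR_l = exp(ln OR_0 + l (ln OR_1 − ln OR_0)).
    """
    if or0 <= 0 or or1 <= 0:
        raise ValueError("odds ratios must be positive")
    if l < 0 or int(l) != l:
        raise ValueError("lag must be a non-negative integer")
    return math.exp(math.log(or0) + l * (math.log(or1) - math.log(or0)))
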