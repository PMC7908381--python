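"""Effect modification: stratified fits and the interaction LRT.

A binary subject attribute (area, age class, gender, ...) is constant
within a matched stratum, so its main effect is absorbed by the matching
and cannot be estimated; what can be tested is whether the distributed-lag
exposure effect differs between levels.  The full model adds two
interaction terms — one shifting the intercept of the linear lag function,
one shifting its slope — and is compared to the reduced (no-interaction)
model by a df-2 likelihood-ratio test.

For a binary modifier with no shared covariates, the full interaction
model is an exact reparameterisation of two independent per-level fits, so
its log-likelihood equals their sum — used as the module's oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .crossover import CaseCrossoverStratum, strata_to_arrays
from .model import (ConditionalLogisticDLM, DlmFit, _group_slices,
                    _newton, make_lag_basis)

__all__ = ["LrtResult", "InteractionFit", "fit_stratified",
           "fit_interaction", "lrt", "modifier_levels"]


@dataclass
class LrtResult:
    """Likelihood-ratio test of nested conditional-logistic models."""

    loglik_full: float
    loglik_reduced: float
    statistic: float
    df: int
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass
class InteractionFit:
    """Joint fit with lag-function interactions for one binary modifier.

    ``theta`` is the level-0 (intercept, slope); ``delta`` the level-1
    shifts of the same two parameters.
    """

    modifier: str
    theta: np.ndarray
    delta: np.ndarray
    covariance: np.ndarray  # 4x4, order (theta, delta)
    loglik: float
    n_strata: int
    reduced: DlmFit


def modifier_levels(strata: list[CaseCrossoverStratum], cohort,
                    modifier: str) -> np.ndarray:
    """Per-stratum modifier level, from the subjects' attributes.

    ``cohort`` is a list of Subject or a DataFrame with a subject_id column;
    area and age-class strings are coerced to {0, 1}.
    """
    if isinstance(cohort, pd.DataFrame):
        table = cohort.set_index("subject_id")[modifier]
    else:
        table = pd.Series({s.subject_id: getattr(s, modifier)
                           for s in cohort})
    if table.dtype == object:
        mapping = {"urban": 1, "suburban": 0}
        table = table.map(lambda v: mapping.get(v, v))
    values = []
    for s in strata:
        if s.subject_id not in table.index or pd.isna(table[s.subject_id]):
            values.append(np.nan)
        else:
            values.append(float(table[s.subject_id]))
    return np.asarray(values)


def _split_by_level(strata, levels):
    out: dict[float, list] = {}
    for s, m in zip(strata, levels):
        if not np.isnan(m):
            out.setdefault(m, []).append(s)
    return out


def fit_stratified(strata: list[CaseCrossoverStratum], cohort,
                   modifier: str, basis: str = "linear",
                   max_lag: int = 6) -> dict:
    """Independent distributed-lag fits per modifier level.

    Levels with no strata, or where the fit fails, map to None
    (reported as not estimable rather than raised).
    """
    from .model import ConvergenceError, SeparationError, fit as fit_dlm

    levels = modifier_levels(strata, cohort, modifier)
    by_level = _split_by_level(strata, levels)
    results: dict = {}
    for level in sorted(by_level):
        try:
            results[level] = fit_dlm(by_level[level], basis=basis,
                                     max_lag=max_lag)
        except (ConvergenceError, SeparationError, ValueError):
            results[level] = None
    return results


def stratified_log_or_table(fits: dict, delta: float = 10.0) -> pd.DataFrame:
    """Per-level lag-specific log-ORs with Wald CIs, long format."""
    rows = []
    for level, fit_res in fits.items():
        if fit_res is None:
            continue
        for l in range(fit_res.basis.L + 1):
            est = fit_res.lag_or(l, delta=delta)
            rows.append({
                "level": level, "lag": l,
                "log_or": math.log(est.or_per_10),
                "ci_low": math.log(est.ci_low),
                "ci_high": math.log(est.ci_high),
            })
    return pd.DataFrame(rows)


def fit_interaction(strata: list[CaseCrossoverStratum], cohort,
                    modifier: str, max_lag: int = 6,
                    tol: float = 1e-8, max_iter: int = 50,
                    separation_norm: float = 50.0,
                    ) -> InteractionFit:
    """Full (interaction) and reduced model for one binary modifier.

    The linear predictor of the full model is z'theta + m (z'delta) with
    z = C'x the collapsed linear-lag covariates and m the stratum's
    modifier level; the reduced model sets delta = 0.  Strata whose
    subject lacks the modifier are dropped with a logged count.
    """
    import logging
    logger = logging.getLogger(__name__)

    levels = modifier_levels(strata, cohort, modifier)
    keep = ~np.isnan(levels)
    if not keep.all():
        logger.warning("dropping %d strata with missing modifier %r",
                       int((~keep).sum()), modifier)
    kept = [s for s, ok in zip(strata, keep) if ok]
    levels = levels[keep]
    if not kept:
        raise ValueError("no strata with a known modifier level")
    unique = np.unique(levels)
    if len(unique) > 2 or not np.isin(unique, (0.0, 1.0)).all():
        raise ValueError("the interaction test requires a binary modifier")

    X, y, groups = strata_to_arrays(kept)
    basis = make_lag_basis("linear", max_lag)
    Z = X[:, :max_lag + 1] @ basis.C                      # (n_days, 2)
    m_rows = np.repeat(levels, [s.n_days for s in kept])
    V_full = np.hstack([Z, m_rows[:, None] * Z])          # (n_days, 4)

    starts = _group_slices(groups)
    counts = np.diff(np.r_[starts, len(V_full)])
    params, cov, loglik, n_iter, gnorm = _newton(
        V_full, y, starts, counts, tol, max_iter, separation_norm)

    est = ConditionalLogisticDLM(basis="linear", max_lag=max_lag,
                                 tol=tol, max_iter=max_iter,
                                 separation_norm=separation_norm)
    est.fit(X, y, groups=groups)
    reduced = est._as_fit()

    return InteractionFit(
        modifier=modifier, theta=params[:2], delta=params[2:],
        covariance=cov, loglik=loglik, n_strata=len(kept), reduced=reduced)


def lrt(full, reduced, df: int = 2, tol: float = 1e-6) -> LrtResult:
    """Likelihood-ratio test of the reduced model nested in the full one.

    Accepts fit objects with a ``loglik`` attribute or plain floats.
    A materially negative statistic signals a convergence problem and
    raises rather than reporting a p-value.
    """
    ll_full = getattr(full, "loglik", full)
    ll_reduced = getattr(reduced, "loglik", reduced)
    statistic = 2.0 * (ll_full - ll_reduced)
    if statistic < -tol:
        raise RuntimeError(
            f"negative LRT statistic ({statistic:.3g}): the full model fit "
            "is worse than the reduced one — check convergence")
    statistic = max(statistic, 0.0)
    return LrtResult(
        loglik_full=float(ll_full), loglik_reduced=float(ll_reduced),
        statistic=float(statistic), df=df,
        p_value=float(chi2.sf(statistic, df)) if statistic > 0 else 1.0)
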