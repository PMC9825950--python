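"""Interim treatment-effect estimators for time-lagged outcomes.

Four estimators of the treatment effect beta at an interim analysis time t:

* ``tf_only``: the full-data analysis restricted to subjects enrolled for at
  least the maximum follow-up period (C(t) >= TF), discarding everyone else;
* ``ipw`` (IPWCC): all complete cases, weighted by the inverse estimated
  probability of remaining uncensored at their ascertainment time,
  Delta(t) / K_t{U(t), A};
* ``aipw1``: IPWCC plus a mean-zero augmentation built from baseline
  covariates, (A - pi_t) f(X);
* ``aipw2``: aipw1 plus censoring-martingale integrals of time-dependent
  covariate functions h{u, X, L(u)}.

The augmented estimators are computed by a two-step algorithm: step 1 solves
the inverse-weighted estimating equation for (alpha, beta_init) and forms the
per-subject influence values m_i; step 2 regresses a "dependent variable"
Yhat_i (the inverse-weighted influence contribution plus its censoring
martingale correction) on the augmentation covariates by ordinary least
squares and applies the one-step update
beta(t) = beta_init(t) - mean(Pred_i), with
SE = sqrt(sum_i (Yhat_i - Pred_i)^2) / n(t).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .outcome_models import (
    OutcomeModelSpec,
    EstimationError,
    estimate_G_row,
    influence_values,
    solve_weighted_equation,
)
from .trial_data import CensoringModel, InterimDataset, TrialDataError

__all__ = [
    "BasisSpec",
    "EstimatorResult",
    "fit_tf_only",
    "fit_ipwcc",
    "fit_aipwcc",
    "build_dependent_variable",
    "build_augmentation_covariates",
    "wald_statistic",
]


class BasisSpec:
    """Basis functions approximating the optimal augmentation terms.

    ``f_basis`` lists M+1 baseline functions of X with f0 constant 1;
    entries are "const", an integer column index of X, or a callable
    ``f(X) -> (n,)``.  ``h_basis`` lists L functions of (u, X, L(u));
    entries are ("x", j) for the j-th baseline column (constant in u),
    ("l", j) for the j-th time-dependent covariate evaluated along the path,
    or a callable ``h(u_grid, X_sub, L_vals) -> (n_sub, len(u_grid))`` with
    ``L_vals`` of shape (n_sub, len(u_grid), q).  ``include_h=False`` gives
    the baseline-only AIPW1 estimator.
    """

    def __init__(self, f_basis=("const",), h_basis=(), include_h=None):
        f_basis = list(f_basis)
        if not f_basis or f_basis[0] != "const":
            raise ValueError("f_basis must start with the constant function 'const'")
        self.f_basis = f_basis
        self.h_basis = list(h_basis)
        self.include_h = bool(self.h_basis) if include_h is None else include_h

    @classmethod
    def default(cls, n_baseline: int, n_path: int, include_h: bool = True) -> "BasisSpec":
        """f = {1} plus the columns of X; h = columns of X plus columns of L(u)."""
        f = ["const"] + list(range(n_baseline))
        h = [("x", j) for j in range(n_baseline)] + [("l", j) for j in range(n_path)]
        return cls(f, h, include_h=include_h and bool(h))

    @property
    def n_f(self) -> int:
        return len(self.f_basis)

    @property
    def n_h(self) -> int:
        return len(self.h_basis)

    def eval_f(self, X: np.ndarray) -> np.ndarray:
        n = X.shape[0]
        cols = []
        for entry in self.f_basis:
            if entry == "const":
                cols.append(np.ones(n))
            elif isinstance(entry, int):
                cols.append(X[:, entry])
            else:
                cols.append(np.asarray(entry(X), dtype=float))
        F = np.column_stack(cols)
        if not np.all(np.isfinite(F)):
            raise ValueError("f basis produced non-finite values")
        return F

    def eval_h(self, u_grid: np.ndarray, X_sub: np.ndarray, L_vals: np.ndarray) -> list[np.ndarray]:
        out = []
        n_sub, J = X_sub.shape[0], len(u_grid)
        for entry in self.h_basis:
            if isinstance(entry, tuple) and entry[0] == "x":
                H = np.broadcast_to(X_sub[:, entry[1]][:, None], (n_sub, J)).copy()
            elif isinstance(entry, tuple) and entry[0] == "l":
                H = L_vals[:, :, entry[1]]
            else:
                H = np.asarray(entry(u_grid, X_sub, L_vals), dtype=float)
            if not np.all(np.isfinite(H)):
                raise ValueError("h basis produced non-finite values")
            out.append(H)
        return out


@dataclass
class EstimatorResult:
    """Estimate, uncertainty, and per-subject components at one analysis time."""

    estimator_kind: str
    beta_hat: float
    se: float
    alpha_hat: np.ndarray
    n_enrolled: int
    n_fully_followed: int
    analysis_time: float
    spec: OutcomeModelSpec
    G_row: np.ndarray | None = None
    m_values: np.ndarray | None = field(default=None, repr=False)   # NaN if censored
    weights: np.ndarray | None = field(default=None, repr=False)    # Delta / K
    dependent_variable: np.ndarray | None = field(default=None, repr=False)
    predicted: np.ndarray | None = field(default=None, repr=False)
    psi_hat: np.ndarray | None = None
    ess: float | None = None
    information_fraction: float | None = None

    def __post_init__(self):
        if not (self.se > 0):
            raise EstimationError("standard error must be positive")

    @property
    def theta_hat(self) -> np.ndarray:
        return np.concatenate([self.alpha_hat, [self.beta_hat]])

    @property
    def wald(self) -> float:
        return self.beta_hat / self.se

    def to_report(self) -> dict:
        return {
            "estimator": self.estimator_kind,
            "analysis_time": self.analysis_time,
            "beta_hat": self.beta_hat,
            "se": self.se,
            "wald": self.wald,
            "n_enrolled": self.n_enrolled,
            "n_fully_followed": self.n_fully_followed,
            "ess": self.ess,
            "information_fraction": self.information_fraction,
        }


def wald_statistic(result: EstimatorResult) -> float:
    """T(t) = beta_hat(t) / SE{beta_hat(t)}."""
    return result.wald


def fit_tf_only(interim: InterimDataset, spec: OutcomeModelSpec) -> EstimatorResult:
    """Unweighted full-data fit on subjects followed for at least TF.

    The SE comes from the sample variance of the estimated influence values
    over those subjects divided by nA(t).
    """
    mask = interim.censoring_time >= interim.max_followup
    nA = int(mask.sum())
    Y, A, X = interim.outcome[mask], interim.arm[mask], interim.baseline_covariates[mask]
    if not (np.sum(A == 0) >= 2 and np.sum(A == 1) >= 2):
        raise TrialDataError("fewer than two fully-followed subjects in an arm")
    w = np.ones(nA)
    theta = solve_weighted_equation(spec, Y, A, X, w)
    G = estimate_G_row(spec, Y, A, X, theta, w, n_norm=nA)
    m = influence_values(spec, Y, A, X, theta, G)
    m_full = np.full(interim.n_enrolled, np.nan)
    m_full[mask] = m
    se = float(np.sqrt(np.sum(m ** 2)) / nA)
    return EstimatorResult(
        estimator_kind="tf_only",
        beta_hat=float(theta[-1]),
        se=se,
        alpha_hat=theta[:-1],
        n_enrolled=interim.n_enrolled,
        n_fully_followed=nA,
        analysis_time=interim.analysis_time,
        spec=spec,
        G_row=G,
        m_values=m_full,
    )


def _ipw_weights(interim: InterimDataset, cm: CensoringModel) -> np.ndarray:
    """Delta_i / K_t{U_i, A_i}; zero for censored subjects."""
    w = np.zeros(interim.n_enrolled)
    cc = interim.ascertained == 1
    for a in ([0, 1] if cm.arm_specific else [None]):
        sel = cc if a is None else (cc & (interim.arm == a))
        if sel.any():
            w[sel] = 1.0 / cm.survival(interim.observed_time[sel], a)
    return w


def fit_ipwcc(interim: InterimDataset, spec: OutcomeModelSpec, cm: CensoringModel) -> EstimatorResult:
    """Step 1: the inverse-probability-weighted complete-case estimator."""
    n = interim.n_enrolled
    w = _ipw_weights(interim, cm)
    cc = interim.ascertained == 1
    theta = solve_weighted_equation(
        spec, interim.outcome[cc], interim.arm[cc], interim.baseline_covariates[cc], w[cc]
    )
    G = estimate_G_row(
        spec, interim.outcome[cc], interim.arm[cc], interim.baseline_covariates[cc],
        theta, w[cc], n_norm=n,
    )
    m = np.full(n, np.nan)
    m[cc] = influence_values(
        spec, interim.outcome[cc], interim.arm[cc], interim.baseline_covariates[cc], theta, G
    )
    y_dep = build_dependent_variable(interim, cm, m, w)
    se = float(np.sqrt(np.sum(y_dep ** 2)) / n)
    return EstimatorResult(
        estimator_kind="ipw",
        beta_hat=float(theta[-1]),
        se=se,
        alpha_hat=theta[:-1],
        n_enrolled=n,
        n_fully_followed=interim.n_fully_followed,
        analysis_time=interim.analysis_time,
        spec=spec,
        G_row=G,
        m_values=m,
        weights=w,
        dependent_variable=y_dep,
    )


def _arm_groups(interim: InterimDataset, cm: CensoringModel):
    """(arm label for cm, boolean mask over enrolled) pairs covering everyone."""
    if cm.arm_specific:
        return [(0, interim.arm == 0), (1, interim.arm == 1)]
    return [(None, np.ones(interim.n_enrolled, dtype=bool))]


def build_dependent_variable(
    interim: InterimDataset, cm: CensoringModel, m_values: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Yhat_i(t): inverse-weighted influence value plus its martingale correction.

    Yhat_i = Delta_i m_i / K(U_i, A_i)
             + integral of dM_i(u, A_i) * q(u, A_i),
    where q(u, a) is the at-risk average, within arm a, of the inverse-weighted
    influence values Delta_k m_k / K(U_k, a) — the empirical version of
    mu(m, u, a) / K(u, a).
    """
    n = interim.n_enrolled
    term1 = np.where(interim.ascertained == 1, np.nan_to_num(m_values) * weights, 0.0)
    out = term1.copy()
    U = interim.observed_time
    delta = interim.ascertained
    for a, mask in _arm_groups(interim, cm):
        jumps = cm.jump_times(a)
        if jumps.size == 0:
            continue
        dL = cm.hazard_increments(a)
        sub = np.flatnonzero(mask)
        U_g, d_g = U[sub], delta[sub]
        wm = term1[sub]
        order = np.argsort(U_g, kind="stable")
        U_sorted = U_g[order]
        wm_sorted = wm[order]
        suffix = np.concatenate([np.cumsum(wm_sorted[::-1])[::-1], [0.0]])
        start = np.searchsorted(U_sorted, jumps, side="left")
        n_risk = U_g.size - start
        q = suffix[start] / n_risk
        cums = np.concatenate([[0.0], np.cumsum(dL * q)])
        pos = np.searchsorted(jumps, U_g, side="right")
        comp = cums[pos]
        own = np.where(d_g == 0, q[np.maximum(pos - 1, 0)], 0.0)
        out[sub] += own - comp
    return out


def build_augmentation_covariates(
    interim: InterimDataset, basis: BasisSpec, cm: CensoringModel
) -> np.ndarray:
    """The M+1+2L step-2 regression covariates.

    Columns 0..M are (A_i - pi_t) f_m(X_i).  For each arm a and each h basis
    function, a further column holds, for subjects with A_i = a, the censoring
    martingale integral of h - mu_hat(h, u, a), where mu_hat is the at-risk
    average of h within arm a; it is zero for the other arm.  Centering by the
    at-risk average makes the compensator contribution of each column sum to
    zero exactly within the arm.
    """
    n = interim.n_enrolled
    pi_t = interim.treated_fraction
    F = basis.eval_f(interim.baseline_covariates)
    cols = [ (interim.arm - pi_t)[:, None] * F ]
    if basis.n_h:
        U, delta = interim.observed_time, interim.ascertained
        for a in (0, 1):
            arm_mask = interim.arm == a
            cm_arm = a if cm.arm_specific else None
            jumps = cm.jump_times(cm_arm)
            block = np.zeros((n, basis.n_h))
            if jumps.size and arm_mask.any():
                dL = cm.hazard_increments(cm_arm)
                sub = np.flatnonzero(arm_mask)
                U_g, d_g = U[sub], delta[sub]
                at_risk = U_g[:, None] >= jumps[None, :]
                n_risk = at_risk.sum(axis=0)
                L_vals = interim.covariate_paths.evaluate(sub, jumps)
                H_list = basis.eval_h(jumps, interim.baseline_covariates[sub], L_vals)
                pos = np.searchsorted(jumps, U_g, side="right")
                own_idx = np.maximum(pos - 1, 0)
                rows = np.arange(sub.size)
                for ell, H in enumerate(H_list):
                    with np.errstate(invalid="ignore"):
                        mu = np.where(n_risk > 0, (H * at_risk).sum(axis=0) / np.maximum(n_risk, 1), 0.0)
                    Hc = H - mu[None, :]
                    cums = np.concatenate(
                        [np.zeros((sub.size, 1)), np.cumsum(dL[None, :] * Hc, axis=1)], axis=1
                    )
                    comp = cums[rows, pos]
                    own = np.where(d_g == 0, Hc[rows, own_idx], 0.0)
                    block[sub, ell] = own - comp
            cols.append(block)
    return np.concatenate(cols, axis=1)


def fit_aipwcc(
    interim: InterimDataset,
    spec: OutcomeModelSpec,
    cm: CensoringModel,
    basis: BasisSpec,
    step1: EstimatorResult | None = None,
) -> EstimatorResult:
    """Step 2: augmentation by least squares and the one-step update.

    With ``basis.include_h`` false this is AIPW1 (baseline covariates only);
    otherwise AIPW2.  Augmentation coefficients come from an ordinary least
    squares regression of Yhat_i on the covariate columns (no extra intercept:
    the f0 column plays that role).
    """
    if step1 is None:
        step1 = fit_ipwcc(interim, spec, cm)
    n = interim.n_enrolled
    y = step1.dependent_variable
    Xmat = build_augmentation_covariates(interim, basis, cm)
    if not basis.include_h:
        Xmat = Xmat[:, : basis.n_f]
    coef, _, rank, _ = np.linalg.lstsq(Xmat, y, rcond=None)
    if rank < Xmat.shape[1]:
        warnings.warn(
            f"augmentation covariates are rank deficient ({rank}/{Xmat.shape[1]}); "
            "redundant columns effectively dropped",
            UserWarning,
            stacklevel=2,
        )
    pred = Xmat @ coef
    beta = float(step1.beta_hat - pred.mean())
    se = float(np.sqrt(np.sum((y - pred) ** 2)) / n)
    return EstimatorResult(
        estimator_kind="aipw2" if basis.include_h else "aipw1",
        beta_hat=beta,
        se=se,
        alpha_hat=step1.alpha_hat,
        n_enrolled=n,
        n_fully_followed=interim.n_fully_followed,
        analysis_time=interim.analysis_time,
        spec=spec,
        G_row=step1.G_row,
        m_values=step1.m_values,
        weights=step1.weights,
        dependent_variable=y,
        predicted=pred,
        psi_hat=coef[: basis.n_f],
    )
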