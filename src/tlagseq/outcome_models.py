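"""Full-data treatment-effect models and their estimating-function machinery.

Three models for the marginal effect of a binary treatment A on outcome Y:

* ``difference_of_means``: E(Y | A = a) = alpha + beta a, beta the mean
  difference;
* ``log_relative_risk``:  E(Y | A = a) = exp(alpha + beta a), beta the log
  risk ratio for a binary outcome;
* ``proportional_odds``:  logit pr(Y <= j | A = a) = alpha_j + beta a for
  ordinal Y in 1..c, beta the log odds ratio.  Note the cumulative-indicator
  parameterization: beta > 0 shifts mass toward LOWER categories under
  treatment, the opposite sign of some software.

Each model contributes a p-vector estimating function M(Y, A; theta) with
mean zero at the truth; the last parameter is always beta.  The influence
function of the solver's beta is m = G M, where G is the last row of the
inverse of -E[dM/dtheta].  For the ordinal model we use the
"working independence" weighting by default, under which M collapses
algebraically to -(r_1, ..., r_{c-1}, A * sum_j r_j) with
r_j = I(Y <= j) - expit(alpha_j + beta A); the full multinomial covariance
(the ML score) is available via ``full_covariance=True`` and is used in tests
as an oracle cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "OutcomeModelSpec",
    "InfluenceEstimate",
    "EstimationError",
    "estimating_function",
    "average_jacobian",
    "estimate_G_row",
    "solve_weighted_equation",
    "influence_values",
]

MODEL_KINDS = ("difference_of_means", "log_relative_risk", "proportional_odds")


class EstimationError(RuntimeError):
    """Raised when an estimating equation cannot be solved on the given data."""


@dataclass(frozen=True)
class OutcomeModelSpec:
    """Model choice plus dimensions; ``param_dim`` counts (alpha, beta)."""

    model_kind: str
    n_categories: int = 2
    full_covariance: bool = False

    def __post_init__(self):
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.model_kind == "proportional_odds" and self.n_categories < 2:
            raise ValueError("proportional_odds requires n_categories >= 2")

    @property
    def param_dim(self) -> int:
        if self.model_kind == "proportional_odds":
            return self.n_categories
        return 2

    def check_outcome(self, Y: np.ndarray) -> None:
        if not np.all(np.isfinite(Y)):
            raise EstimationError("non-finite outcome values")
        if self.model_kind == "log_relative_risk" and np.any(Y < 0):
            raise EstimationError("log_relative_risk requires nonnegative outcomes")
        if self.model_kind == "proportional_odds":
            c = self.n_categories
            if np.any((Y < 1) | (Y > c)) or np.any(Y != np.round(Y)):
                raise EstimationError(f"ordinal outcomes must be integers in 1..{c}")


@dataclass
class InfluenceEstimate:
    """Estimated G row (last row of the inverted derivative matrix) and the
    per-subject influence values m_i = G . M_i it generates."""

    G_row: np.ndarray
    m_values: np.ndarray


def _check_theta(spec: OutcomeModelSpec, theta: np.ndarray) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (spec.param_dim,) or not np.all(np.isfinite(theta)):
        raise EstimationError("parameters must be a finite vector of length param_dim")
    return theta


def _cum_residuals(spec, Y, A, theta):
    """r_ij = I(Y_i <= j) - expit(alpha_j + beta A_i), plus p*q weights."""
    c = spec.n_categories
    alpha, beta = theta[: c - 1], theta[c - 1]
    eta = alpha[None, :] + beta * A[:, None]
    p = expit(eta)
    r = (Y[:, None] <= np.arange(1, c)[None, :]).astype(float) - p
    return r, p * (1.0 - p)


def estimating_function(spec: OutcomeModelSpec, Y, A, X, theta) -> np.ndarray:
    """Per-subject estimating-function values, an (n, p) array.

    X is accepted for interface uniformity; the marginal models do not use it.
    """
    theta = _check_theta(spec, theta)
    Y = np.asarray(Y, dtype=float)
    A = np.asarray(A, dtype=float)
    spec.check_outcome(Y)
    if spec.model_kind == "difference_of_means":
        resid = Y - theta[0] - theta[1] * A
        return np.column_stack([resid, A * resid])
    if spec.model_kind == "log_relative_risk":
        resid = Y - np.exp(theta[0] + theta[1] * A)
        return np.column_stack([resid, A * resid])
    r, pq = _cum_residuals(spec, Y, A, theta)
    if not spec.full_covariance:
        # D^T V_ind^{-1} r with V_ind = diag(pq): collapses to -(r, A sum r)
        return -np.column_stack([r, A * r.sum(axis=1)])
    return _ml_score(spec, r, pq, A, theta)


def _ml_score(spec, r, pq, A, theta):
    """D^T V^{-1} r with the full multinomial covariance of the cumulative
    indicators: V_jk = p_min(j,k) (1 - p_max(j,k))."""
    c = spec.n_categories
    alpha, beta = theta[: c - 1], theta[c - 1]
    out = np.empty((len(A), c))
    for a in (0.0, 1.0):
        sel = A == a
        if not sel.any():
            continue
        p = expit(alpha + beta * a)
        V = np.minimum.outer(p, p) * (1.0 - np.maximum.outer(p, p))
        D = np.zeros((c - 1, c))
        D[:, : c - 1] = -np.diag(p * (1.0 - p))
        D[:, c - 1] = -p * (1.0 - p) * a
        out[sel] = r[sel] @ np.linalg.solve(V, D)  # (D^T V^{-1} r_i)^T rowwise
    return out


def _jacobian_terms(spec, Y, A, theta):
    """Per-subject Jacobian dM_i/dtheta summarized for weighted averaging.

    Returns a callable contribution such that sum_i w_i dM_i/dtheta can be
    formed without materializing (n, p, p).
    """
    A = np.asarray(A, dtype=float)
    if spec.model_kind in ("difference_of_means", "log_relative_risk"):
        if spec.model_kind == "difference_of_means":
            scale = np.ones_like(A)
        else:
            scale = np.exp(theta[0] + theta[1] * A)

        def weighted_sum(w):
            # dM_i/dtheta = -scale_i * outer((1, A_i), (1, A_i))
            s = w * scale
            s00, s01, s11 = s.sum(), (s * A).sum(), (s * A * A).sum()
            return -np.array([[s00, s01], [s01, s11]])

        return weighted_sum

    c = spec.n_categories
    _, pq = _cum_residuals(spec, Y, A, theta)

    def weighted_sum(w):
        # M = -(r, A sum r); dM_j/dalpha_k = delta_jk pq_j, dM_j/dbeta = pq_j A,
        # dM_c/dalpha_k = A pq_k, dM_c/dbeta = A^2 sum_j pq_j
        J = np.zeros((c, c))
        wpq = (w[:, None] * pq)
        J[: c - 1, : c - 1] = np.diag(wpq.sum(axis=0))
        col = (wpq * A[:, None]).sum(axis=0)
        J[: c - 1, c - 1] = col
        J[c - 1, : c - 1] = col
        J[c - 1, c - 1] = (wpq.sum(axis=1) * A * A).sum()
        return J

    return weighted_sum


def average_jacobian(spec, Y, A, X, theta, weights, n_norm, numeric=False) -> np.ndarray:
    """(1/n_norm) * sum_i w_i dM_i/dtheta, analytic unless ``numeric``.

    The numeric path uses central differences with step 1e-6 * max(1, |theta|)
    and exists to cross-check the closed forms.
    """
    theta = _check_theta(spec, theta)
    w = np.asarray(weights, dtype=float)
    if not numeric and not spec.full_covariance:
        return _jacobian_terms(spec, np.asarray(Y, float), A, theta)(w) / n_norm
    p = spec.param_dim
    J = np.empty((p, p))
    for k in range(p):
        h = 1e-6 * max(1.0, abs(theta[k]))
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h
        tm[k] -= h
        Fp = (w[:, None] * estimating_function(spec, Y, A, X, tp)).sum(axis=0)
        Fm = (w[:, None] * estimating_function(spec, Y, A, X, tm)).sum(axis=0)
        J[:, k] = (Fp - Fm) / (2 * h)
    return J / n_norm


def estimate_G_row(spec, Y, A, X, theta, weights, n_norm, numeric=False) -> np.ndarray:
    """Last row of the inverse of the negated weighted-average Jacobian."""
    J = average_jacobian(spec, Y, A, X, theta, weights, n_norm, numeric=numeric)
    negJ = -J
    p = spec.param_dim
    try:
        cond = np.linalg.cond(negJ)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError
        G = np.linalg.solve(negJ.T, np.eye(p)[:, -1])
    except np.linalg.LinAlgError:
        _, _, vt = np.linalg.svd(negJ)
        raise EstimationError(
            "singular derivative matrix; deficient direction ~ "
            + np.array2string(vt[-1], precision=3)
        )
    return G


def influence_values(spec, Y, A, X, theta, G_row) -> np.ndarray:
    """m_i = G . M_i for each subject."""
    return estimating_function(spec, Y, A, X, theta) @ np.asarray(G_row, dtype=float)


def _initial_theta(spec, Y, A, w):
    if spec.model_kind == "difference_of_means":
        m0 = np.average(Y[A == 0], weights=w[A == 0])
        return np.array([m0, 0.0])
    if spec.model_kind == "log_relative_risk":
        m0 = np.average(Y[A == 0], weights=w[A == 0])
        if m0 <= 0:
            raise EstimationError("control-arm weighted mean outcome is zero; "
                                  "log relative risk undefined (separation)")
        return np.array([np.log(m0), 0.0])
    c = spec.n_categories
    cum = np.array([np.average(Y <= j, weights=w) for j in range(1, c)])
    if np.any(cum <= 0) or np.any(cum >= 1):
        raise EstimationError(
            "a cumulative category probability is degenerate at this analysis "
            "time (separation); consider a later analysis"
        )
    return np.concatenate([logit(np.maximum.accumulate(cum)), [0.0]])


def solve_weighted_equation(spec, Y, A, X, weights, init=None, tol_scale=None,
                            max_iter=100) -> np.ndarray:
    """Root of sum_i w_i M(Y_i, A_i; theta) = 0, jointly in (alpha, beta).

    Newton iteration with the analytic Jacobian and step halving; closed-form
    shortcuts for the two 2-parameter models.  Convergence requires
    ||equation||_inf <= 1e-9 * max(1, n).
    """
    Y = np.asarray(Y, dtype=float)
    A = np.asarray(A, dtype=float)
    w = np.asarray(weights, dtype=float)
    spec.check_outcome(Y)
    if np.any(w < 0):
        raise EstimationError("weights must be nonnegative")
    act = w > 0
    if not (np.any(act & (A == 0)) and np.any(act & (A == 1))):
        raise EstimationError("both arms must be represented with positive weight")
    tol = (tol_scale if tol_scale is not None else 1e-9) * max(1.0, len(Y))

    if spec.model_kind in ("difference_of_means", "log_relative_risk"):
        m0 = np.average(Y[A == 0], weights=w[A == 0])
        m1 = np.average(Y[A == 1], weights=w[A == 1])
        if spec.model_kind == "difference_of_means":
            return np.array([m0, m1 - m0])
        if m0 <= 0 or m1 <= 0:
            raise EstimationError("a treatment-arm weighted mean outcome is zero; "
                                  "log relative risk undefined (separation)")
        return np.array([np.log(m0), np.log(m1) - np.log(m0)])

    theta = np.asarray(init, dtype=float) if init is not None else _initial_theta(spec, Y, A, w)
    jac = None
    for _ in range(max_iter):
        F = (w[:, None] * estimating_function(spec, Y, A, X, theta)).sum(axis=0)
        fn = np.max(np.abs(F))
        if fn <= tol:
            return theta
        jac = average_jacobian(spec, Y, A, X, theta, w, n_norm=1.0,
                               numeric=spec.full_covariance)
        try:
            step = np.linalg.solve(jac, -F)
        except np.linalg.LinAlgError:
            raise EstimationError("singular Jacobian during Newton iteration")
        # step halving on the equation norm
        lam = 1.0
        for _ in range(30):
            cand = theta + lam * step
            try:
                Fc = (w[:, None] * estimating_function(spec, Y, A, X, cand)).sum(axis=0)
            except EstimationError:
                Fc = np.array([np.inf])
            if np.all(np.isfinite(Fc)) and np.max(np.abs(Fc)) < fn:
                theta = cand
                break
            lam *= 0.5
        else:
            raise EstimationError("Newton step failed to reduce the equation norm")
    raise EstimationError(f"no convergence in {max_iter} Newton iterations")
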