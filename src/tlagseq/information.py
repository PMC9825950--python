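"""Information accounting: influence variances, effective sample size,
proportion of information, and the maximum-information target.

Monitoring boundaries need the fraction of the trial's total statistical
information available at each look.  Two conventions are supported:

* ``information_based``: Inf(t) = SE{beta(t)}^-2 relative to a prespecified
  maximum information MI = {(z_{alpha/2} + z_gamma) / beta_A}^2 * IF;
* ``fixed_sample``: relative to a fixed maximum sample size n_max.  For the
  TF-only estimator the fraction is nA(t) / n_max.  For the weighted
  estimators it is n_ESS(t) / n_max, where the effective sample size
  n_ESS(t) = var_hat{m} / SE{beta(t)}^2 is the number of fully-followed
  subjects a complete-data analysis would need to match the interim
  estimator's precision.  By construction both fractions reach 1 at the
  final analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .estimators import BasisSpec, EstimatorResult, _ipw_weights
from .outcome_models import influence_values
from .trial_data import CensoringModel, InterimDataset

__all__ = [
    "InformationState",
    "influence_variance_ipw",
    "influence_variance_aipw",
    "effective_sample_size",
    "information_fraction",
    "max_information",
    "attach_information",
]


@dataclass
class InformationState:
    """Information summary for one analysis."""

    analysis_time: float
    information: float        # SE^-2
    ess: float
    fraction: float
    mode: str                 # fixed_sample | information_based
    n_max: int | None = None
    max_information: float | None = None


def _final_m(interim: InterimDataset, result: EstimatorResult) -> np.ndarray:
    """Influence values at (alpha_hat, beta_hat(t)) using the step-1 G row."""
    cc = interim.ascertained == 1
    m = np.full(interim.n_enrolled, np.nan)
    m[cc] = influence_values(
        result.spec, interim.outcome[cc], interim.arm[cc],
        interim.baseline_covariates[cc], result.theta_hat, result.G_row,
    )
    return m


def influence_variance_ipw(
    interim: InterimDataset, result: EstimatorResult, cm: CensoringModel
) -> float:
    """n(t)^-1 sum_i Delta_i m_i^2 / K{U_i, A_i} at the final estimates."""
    w = result.weights if result.weights is not None else _ipw_weights(interim, cm)
    m = _final_m(interim, result)
    return float(np.nansum(np.nan_to_num(m) ** 2 * w) / interim.n_enrolled)


def influence_variance_aipw(
    interim: InterimDataset, result: EstimatorResult, cm: CensoringModel, basis: BasisSpec
) -> float:
    """Inverse-weighted variance of m - Pred*, with Pred* = (A - pi_t) sum psi_m f_m(X).

    The psi coefficients come from a weighted least squares regression of the
    influence values on the baseline covariate columns with weights
    Delta / K; the same baseline-only form is used for both AIPW1 and AIPW2.
    """
    w = result.weights if result.weights is not None else _ipw_weights(interim, cm)
    m = _final_m(interim, result)
    pi_t = interim.treated_fraction
    F = basis.eval_f(interim.baseline_covariates)
    Xmat = (interim.arm - pi_t)[:, None] * F
    cc = interim.ascertained == 1
    sw = np.sqrt(w[cc])
    coef, _, rank, _ = np.linalg.lstsq(Xmat[cc] * sw[:, None], m[cc] * sw, rcond=None)
    if rank < Xmat.shape[1]:
        warnings.warn("baseline augmentation columns are rank deficient", UserWarning,
                      stacklevel=2)
    pred_star = Xmat @ coef
    resid = np.nan_to_num(m) - pred_star
    return float(np.sum(resid[cc] ** 2 * w[cc]) / interim.n_enrolled)


def effective_sample_size(var_m: float, se: float) -> float:
    """n_ESS = var_hat{m} / SE^2."""
    if not (var_m > 0 and se > 0):
        raise ValueError("variance and SE must be positive")
    return var_m / se ** 2


def information_fraction(
    *,
    mode: str = "fixed_sample",
    estimator_kind: str = "ipw",
    n_max: int | None = None,
    ess: float | None = None,
    n_fully_followed: int | None = None,
    information: float | None = None,
    max_information: float | None = None,
) -> float:
    """Proportion of total information at an analysis; clipped to <= 1 with a warning."""
    if mode == "fixed_sample":
        if n_max is None:
            raise ValueError("fixed_sample mode needs n_max")
        if estimator_kind == "tf_only":
            if n_fully_followed is None:
                raise ValueError("tf_only fraction needs n_fully_followed")
            frac = n_fully_followed / n_max
        else:
            if ess is None:
                raise ValueError("weighted-estimator fraction needs ess")
            frac = ess / n_max
    elif mode == "information_based":
        if information is None or max_information is None:
            raise ValueError("information_based mode needs information and max_information")
        frac = information / max_information
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if frac > 1.0:
        warnings.warn(
            f"information fraction {frac:.4f} exceeds 1; clipping (estimator noise)",
            UserWarning,
            stacklevel=2,
        )
        frac = 1.0
    if frac <= 0:
        raise ValueError("information fraction must be positive")
    return float(frac)


def max_information(alpha: float, power_complement: float, beta_A: float,
                    inflation: float = 1.0) -> float:
    """MI = {(z_{alpha/2} + z_gamma) / beta_A}^2 * IF.

    ``alpha`` is the two-sided significance level and ``power_complement`` is
    gamma = 1 - power; ``inflation`` accounts for the power cost of repeated
    testing (about 1.03 for O'Brien-Fleming boundaries).
    """
    if not (0 < alpha < 1 and 0 < power_complement < 1):
        raise ValueError("alpha and power_complement must lie in (0, 1)")
    if beta_A == 0:
        raise ValueError("beta_A must be nonzero")
    if inflation < 1:
        raise ValueError("inflation factor must be >= 1")
    z_a = norm.ppf(1 - alpha / 2)
    z_g = norm.ppf(1 - power_complement)
    return float(((z_a + z_g) / beta_A) ** 2 * inflation)


def attach_information(
    interim: InterimDataset,
    result: EstimatorResult,
    cm: CensoringModel | None,
    basis: BasisSpec | None,
    n_max: int,
) -> EstimatorResult:
    """Fill the ESS and fixed-sample information fraction on a result in place.

    At the final analysis (every planned subject enrolled and fully followed)
    the fraction is pinned to exactly 1: the influence values entering the
    ESS numerator are re-evaluated at the updated beta, so the estimated
    ratio can sit a fraction of a percent off n purely through that
    re-evaluation.
    """
    final = (result.n_fully_followed == result.n_enrolled == n_max)
    if result.estimator_kind == "tf_only":
        result.ess = float(result.n_fully_followed)
        result.information_fraction = information_fraction(
            mode="fixed_sample", estimator_kind="tf_only", n_max=n_max,
            n_fully_followed=result.n_fully_followed,
        )
        return result
    if result.estimator_kind == "ipw":
        var_m = influence_variance_ipw(interim, result, cm)
    else:
        var_m = influence_variance_aipw(interim, result, cm, basis)
    result.ess = effective_sample_size(var_m, result.se)
    if final:
        result.information_fraction = 1.0
    else:
        result.information_fraction = information_fraction(
            mode="fixed_sample", estimator_kind=result.estimator_kind,
            n_max=n_max, ess=result.ess,
        )
    return result
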