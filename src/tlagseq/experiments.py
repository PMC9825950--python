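"""Monte Carlo experiments: estimator performance across interim looks and
operating characteristics of the monitored trial.

``run_replicate`` simulates one trial and analyzes it at every planned look
with the requested estimators; ``run_monte_carlo`` aggregates replicates into
the usual performance summaries (mean, SD, average SE, MSE ratio relative to
the TF-only estimator, between-look covariance of the estimates) and, for
each spending-function type, the sequential operating characteristics
(rejection proportion, expected enrolled sample size and stopping time when
monitoring stops the trial at the first boundary crossing).

Boundaries are recomputed per replicate from that replicate's realized
information-fraction path, as a spending approach permits; fractions are
nudged onto a strictly increasing grid (epsilon = 1e-6) when estimator noise
makes them locally flat.  Replicates are independent units keyed by
(master seed, replicate index), so results do not depend on execution order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

from .boundaries import SpendingPlan, compute_boundaries
from .estimators import fit_aipwcc, fit_ipwcc, fit_tf_only
from .information import attach_information
from .outcome_models import EstimationError
from .synthetic_trials import (
    ScenarioConfig,
    default_basis,
    default_model_spec,
    generate_trial,
)
from .trial_data import TrialDataError, build_interim_dataset, fit_censoring_km

__all__ = [
    "ESTIMATOR_NAMES",
    "MCResultTable",
    "run_replicate",
    "run_monte_carlo",
    "independent_increments_check",
    "monotone_fractions",
]

ESTIMATOR_NAMES = ("tf_only", "ipw", "aipw1", "aipw2")
_EPS = 1e-6


def replicate_seed(master_seed: int, rep: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master_seed) % (2 ** 31), rep])


def run_replicate(config: ScenarioConfig, seed, estimators=ESTIMATOR_NAMES,
                  basis=None) -> dict:
    """Analyze one simulated trial at every planned look.

    Returns per-estimator dicts of arrays indexed by look:
    ``beta``, ``se``, ``frac``, ``n_enrolled``, ``n_fully_followed``.
    """
    spec = default_model_spec(config)
    basis2 = basis if basis is not None else default_basis(config, include_h=True)
    basis1 = default_basis(config, include_h=False) if basis is None else basis
    full = generate_trial(config, seed)
    times = config.all_times
    K = len(times)
    out = {
        est: {k: np.full(K, np.nan) for k in ("beta", "se", "frac")} for est in estimators
    }
    n_enr = np.zeros(K, dtype=int)
    n_followed = np.zeros(K, dtype=int)
    needs_weighted = any(e != "tf_only" for e in estimators)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for j, t in enumerate(times):
            interim = build_interim_dataset(full, t)
            n_enr[j] = interim.n_enrolled
            n_followed[j] = interim.n_fully_followed
            cm = fit_censoring_km(interim, arm_specific=True) if needs_weighted else None
            step1 = None
            for est in estimators:
                if est == "tf_only":
                    res = fit_tf_only(interim, spec)
                    res = attach_information(interim, res, None, None, config.n_max)
                else:
                    if step1 is None:
                        step1 = fit_ipwcc(interim, spec, cm)
                        step1 = attach_information(interim, step1, cm, None, config.n_max)
                    if est == "ipw":
                        res = step1
                    else:
                        b = basis1 if est == "aipw1" else basis2
                        res = fit_aipwcc(interim, spec, cm, b, step1=step1)
                        res = attach_information(interim, res, cm, b, config.n_max)
                out[est]["beta"][j] = res.beta_hat
                out[est]["se"][j] = res.se
                out[est]["frac"][j] = res.information_fraction
    for est in estimators:
        out[est]["n_enrolled"] = n_enr
        out[est]["n_fully_followed"] = n_followed
    return out


def monotone_fractions(frac: np.ndarray) -> np.ndarray:
    """Clip to (0, 1] and enforce strict increase by epsilon nudges."""
    f = np.clip(np.asarray(frac, dtype=float), _EPS, 1.0).copy()
    for j in range(1, len(f)):          # forward: push up
        f[j] = max(f[j], f[j - 1] + _EPS)
    f[-1] = min(f[-1], 1.0)
    for j in range(len(f) - 2, -1, -1):  # backward: keep below the next look
        f[j] = min(f[j], f[j + 1] - _EPS)
    return f


@dataclass
class MCResultTable:
    """Aggregated Monte Carlo results for one scenario."""

    config: ScenarioConfig
    n_reps: int
    estimates: dict = field(repr=False)          # est -> (n_reps, K) betas
    ses: dict = field(repr=False)                # est -> (n_reps, K)
    fractions: dict = field(repr=False)
    n_enrolled: np.ndarray = field(repr=False)   # (n_reps, K)
    performance: pd.DataFrame = None             # per (estimator, look)
    monitoring: pd.DataFrame = None              # per (estimator, boundary kind)
    covariances: dict = None                     # est -> (K, K)
    n_failures: int = 0

    def covariance(self, est: str) -> np.ndarray:
        return self.covariances[est]


def run_monte_carlo(config: ScenarioConfig, n_reps: int, seed: int,
                    estimators=ESTIMATOR_NAMES,
                    boundary_kinds=("obrien_fleming", "pocock"),
                    monitor_estimators=None,
                    alpha: float = 0.025, n_grid: int = 400,
                    true_beta: float | None = None) -> MCResultTable:
    """Replicated simulation of a monitored trial.

    ``true_beta`` (defaults to the config's generative effect) centers the
    MSEs.  Rejection uses one-sided monitoring in the direction of the
    configured alternative.  ``monitor_estimators`` restricts which
    estimators are run through the boundary machinery (default: all fitted).
    """
    if n_reps < 2:
        raise ValueError("n_reps must be at least 2")
    monitored = tuple(monitor_estimators) if monitor_estimators is not None else tuple(estimators)
    times = config.all_times
    K = len(times)
    beta0 = config.beta if true_beta is None else true_beta
    est_names = tuple(estimators)
    betas = {e: np.full((n_reps, K), np.nan) for e in est_names}
    ses = {e: np.full((n_reps, K), np.nan) for e in est_names}
    fracs = {e: np.full((n_reps, K), np.nan) for e in est_names}
    n_enr = np.zeros((n_reps, K), dtype=int)
    stops = {(e, bk): np.zeros((n_reps, 3)) for e in monitored for bk in boundary_kinds}
    failures = 0
    ok = np.ones(n_reps, dtype=bool)
    for r in range(n_reps):
        try:
            rep = run_replicate(config, replicate_seed(seed, r), estimators=est_names)
        except (EstimationError, TrialDataError) as exc:
            logger.warning("replicate %d failed and was skipped: %s", r, exc)
            failures += 1
            ok[r] = False
            continue
        n_enr[r] = rep[est_names[0]]["n_enrolled"]
        for e in est_names:
            betas[e][r] = rep[e]["beta"]
            ses[e][r] = rep[e]["se"]
            fracs[e][r] = monotone_fractions(rep[e]["frac"])
            if e not in monitored:
                continue
            wald = rep[e]["beta"] / rep[e]["se"]
            for bk in boundary_kinds:
                plan = SpendingPlan(alpha, "one_sided", bk)
                b = compute_boundaries(plan, fracs[e][r], n_grid=n_grid).boundaries
                if config.alternative == "lower":
                    crossed = wald <= -b
                else:
                    crossed = wald >= b
                idx = np.flatnonzero(crossed)
                if idx.size:
                    stage = idx[0]
                    stops[(e, bk)][r] = (1.0, n_enr[r][stage], times[stage])
                else:
                    stops[(e, bk)][r] = (0.0, n_enr[r][-1], times[-1])
        if failures and failures * 50 > n_reps:
            raise EstimationError(f"excessive replicate failure rate: {failures}/{r + 1}")
    sel = np.flatnonzero(ok)
    perf_rows = []
    mse = {e: np.mean((betas[e][sel] - beta0) ** 2, axis=0) for e in est_names}
    for e in est_names:
        for j, t in enumerate(times):
            perf_rows.append({
                "estimator": e,
                "analysis_time": t,
                "mc_mean": float(np.mean(betas[e][sel, j])),
                "mc_sd": float(np.std(betas[e][sel, j], ddof=1)),
                "ave_se": float(np.mean(ses[e][sel, j])),
                "mse": float(mse[e][j]),
                "mse_ratio_vs_tf": float(mse["tf_only"][j] / mse[e][j])
                if "tf_only" in mse else np.nan,
            })
    mon_rows = []
    for (e, bk), arr in stops.items():
        a = arr[sel]
        mon_rows.append({
            "estimator": e,
            "boundary": bk,
            "reject_prop": float(np.mean(a[:, 0])),
            "ess_mean": float(np.mean(a[:, 1])),
            "ess_sd": float(np.std(a[:, 1], ddof=1)),
            "stop_time_mean": float(np.mean(a[:, 2])),
            "stop_time_sd": float(np.std(a[:, 2], ddof=1)),
        })
    covs = {e: np.cov(betas[e][sel].T) for e in est_names}
    return MCResultTable(
        config=config, n_reps=int(sel.size),
        estimates={e: betas[e][sel] for e in est_names},
        ses={e: ses[e][sel] for e in est_names},
        fractions={e: fracs[e][sel] for e in est_names},
        n_enrolled=n_enr[sel],
        performance=pd.DataFrame(perf_rows),
        monitoring=pd.DataFrame(mon_rows),
        covariances=covs,
        n_failures=failures,
    )


def independent_increments_check(cov: np.ndarray) -> float:
    """Max relative deviation of cov{beta(s), beta(t)} from var{beta(t)}, s < t.

    Zero for an exact independent-increments covariance; large for, e.g.,
    estimates independent across looks.
    """
    cov = np.asarray(cov, dtype=float)
    K = cov.shape[0]
    dev = 0.0
    for t in range(1, K):
        for s in range(t):
            dev = max(dev, abs(cov[s, t] - cov[t, t]) / cov[t, t])
    return float(dev)
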