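"""Alpha-spending stopping boundaries under independent increments.

Boundaries follow the Lan-DeMets error-spending approach: a nondecreasing
function alpha*(s) with alpha*(0) = 0 and alpha*(1) = alpha allocates the
type-I error across looks at arbitrary information fractions.  Two spending
shapes are provided:

* O'Brien-Fleming type: alpha*(s) = 2{1 - Phi(z_{alpha/2} / sqrt(s))},
  very conservative early;
* Pocock type: alpha*(s) = alpha * ln(1 + (e - 1) s), near-flat boundaries.

Sequential Wald statistics with the independent-increments property satisfy
cov(Z_i, Z_j) = sqrt(p_i / p_j) for p_i <= p_j, so on the score scale
S_j = Z_j sqrt(p_j) the increments are independent Gaussians.  Boundaries are
found by the standard subdensity-propagation recursion: the density of the
score restricted to the continuation region is carried forward on a numerical
grid (trapezoidal integration), and each stage's boundary is solved so the
newly crossed probability equals that stage's incremental spend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr
from scipy.stats import norm

_SQRT2PI = np.sqrt(2.0 * np.pi)


def _phi(x):
    return np.exp(-0.5 * x * x) / _SQRT2PI

__all__ = [
    "SpendingPlan",
    "BoundaryResult",
    "MonitoringResult",
    "spending_value",
    "compute_boundaries",
    "sequential_power",
    "monitor",
]

_MIN_SPEND = 1e-12
_GRID_HALFWIDTH = 8.5  # standard deviations retained around the score mean


@dataclass(frozen=True)
class SpendingPlan:
    alpha_total: float = 0.025
    sides: str = "one_sided"          # one_sided | two_sided
    spending_kind: str = "obrien_fleming"  # obrien_fleming | pocock

    def __post_init__(self):
        if not 0 < self.alpha_total < 1:
            raise ValueError("alpha_total must lie in (0, 1)")
        if self.sides not in ("one_sided", "two_sided"):
            raise ValueError("sides must be one_sided or two_sided")
        if self.spending_kind not in ("obrien_fleming", "pocock"):
            raise ValueError("spending_kind must be obrien_fleming or pocock")

    @property
    def per_side_alpha(self) -> float:
        return self.alpha_total / (2.0 if self.sides == "two_sided" else 1.0)


def _per_side_spend(plan: SpendingPlan, s: np.ndarray) -> np.ndarray:
    a = plan.per_side_alpha
    s = np.asarray(s, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("information fraction must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        if plan.spending_kind == "obrien_fleming":
            z = norm.ppf(1 - a / 2)
            out = 2.0 * (1.0 - norm.cdf(np.where(s > 0, z / np.sqrt(np.maximum(s, 1e-300)), np.inf)))
        else:
            out = a * np.log1p((np.e - 1.0) * s)
    return np.where(s <= 0, 0.0, out)


def spending_value(plan: SpendingPlan, s) -> float | np.ndarray:
    """Cumulative alpha spent (both sides combined) at information fraction s."""
    mult = 2.0 if plan.sides == "two_sided" else 1.0
    out = mult * _per_side_spend(plan, s)
    return float(out) if np.ndim(s) == 0 else out


@dataclass
class BoundaryResult:
    fractions: np.ndarray
    boundaries: np.ndarray
    incremental_spend: np.ndarray      # per side
    cumulative_spend: np.ndarray       # per side
    crossing_probs: np.ndarray         # under the requested drift, both sides
    drift: float
    plan: SpendingPlan


def _check_fractions(fractions: np.ndarray) -> np.ndarray:
    f = np.asarray(fractions, dtype=float)
    if f.ndim != 1 or f.size == 0:
        raise ValueError("fractions must be a nonempty 1-d sequence")
    if np.any(f <= 0) or np.any(f > 1):
        raise ValueError("fractions must lie in (0, 1]")
    if np.any(np.diff(f) <= 0):
        raise ValueError("fractions must be strictly increasing")
    return f


def _recursion(fractions, drift, sides, n_grid, spends=None, boundaries=None):
    """Propagate the score-scale subdensity across stages.

    Either ``spends`` (per-side incremental spend; boundaries are solved) or
    ``boundaries`` (crossing probabilities are accumulated) must be given.
    Returns (boundaries, per-stage crossing probabilities).
    """
    f = _check_fractions(fractions)
    K = f.size
    two = sides == "two_sided"
    out_b = np.empty(K)
    out_p = np.empty(K)
    grid = None
    dens = None
    prev_I = 0.0
    for j in range(K):
        I_j = f[j]
        dI = I_j - prev_I
        sd = np.sqrt(dI)
        mu = drift * dI

        def crossing(b):
            hi = b * np.sqrt(I_j)
            if grid is None:
                p = ndtr((mu - hi) / sd)
                if two:
                    p += ndtr((-hi - mu) / sd)
                return p
            up = ndtr((grid + mu - hi) / sd)
            if two:
                up += ndtr((-hi - grid - mu) / sd)
            return np.trapezoid(dens * up, grid)

        if boundaries is not None:
            b_j = float(boundaries[j])
            out_p[j] = crossing(b_j) if np.isfinite(b_j) else 0.0
        else:
            target = spends[j] * (2.0 if two else 1.0)
            if target < _MIN_SPEND:
                b_j = np.inf
                out_p[j] = 0.0
            else:
                b_j = brentq(lambda b: crossing(b) - target, -10.0, 12.0,
                             xtol=1e-6, rtol=1e-12)
                out_p[j] = target
        out_b[j] = b_j

        if j < K - 1:
            # continuation-region grid at stage j
            center = drift * I_j
            hw = _GRID_HALFWIDTH * np.sqrt(I_j)
            hi_lim = b_j * np.sqrt(I_j) if np.isfinite(b_j) else center + hw
            lo_lim = max(-b_j * np.sqrt(I_j), center - hw) if (two and np.isfinite(b_j)) else center - hw
            hi_lim = min(hi_lim, center + hw)
            new_grid = np.linspace(lo_lim, hi_lim, n_grid)
            if grid is None:
                new_dens = _phi((new_grid - mu) / sd) / sd
            else:
                kern = _phi((new_grid[:, None] - grid[None, :] - mu) / sd) / sd
                new_dens = np.trapezoid(kern * dens[None, :], grid, axis=1)
            grid, dens = new_grid, new_dens
        prev_I = I_j
    return out_b, out_p


def compute_boundaries(plan: SpendingPlan, fractions, drift: float = 0.0,
                       n_grid: int = 4000) -> BoundaryResult:
    """Spending boundaries b_j at the given information fractions.

    ``drift`` is the mean of the z statistic at full information (E[Z_j] =
    drift * sqrt(p_j)); boundaries themselves are computed under the null, and
    ``crossing_probs`` reports per-stage crossing probabilities under the
    drift.  Stages whose incremental spend falls below 1e-12 receive an
    infinite sentinel boundary (no stopping possible there).
    """
    f = _check_fractions(fractions)
    cum = _per_side_spend(plan, f)
    spends = np.diff(np.concatenate([[0.0], cum]))
    b, _ = _recursion(f, 0.0, plan.sides, n_grid, spends=spends)
    if drift == 0.0:
        probs = np.where(np.isfinite(b), spends * (2.0 if plan.sides == "two_sided" else 1.0), 0.0)
    else:
        _, probs = _recursion(f, drift, plan.sides, n_grid, boundaries=b)
    return BoundaryResult(
        fractions=f, boundaries=b, incremental_spend=spends,
        cumulative_spend=cum, crossing_probs=probs, drift=drift, plan=plan,
    )


def sequential_power(boundaries, fractions, drift: float, sides: str = "one_sided",
                     n_grid: int = 4000) -> float:
    """Total probability of ever crossing the given boundaries under ``drift``."""
    b = np.asarray(boundaries, dtype=float)
    f = _check_fractions(fractions)
    if b.shape != f.shape:
        raise ValueError("boundaries and fractions must have matching lengths")
    _, probs = _recursion(f, drift, sides, n_grid, boundaries=b)
    return float(probs.sum())


@dataclass
class MonitoringResult:
    stopped: bool
    stage: int | None                  # 1-based stage of first crossing
    statistics: np.ndarray
    fractions: np.ndarray
    boundaries: np.ndarray
    plan: SpendingPlan
    direction: str


def monitor(statistics, fractions, plan: SpendingPlan, direction: str = "upper",
            n_grid: int = 4000) -> MonitoringResult:
    """First look, if any, at which the Wald statistic crosses its boundary.

    ``direction`` is 'upper' (stop when T_j >= b_j), 'lower' (T_j <= -b_j),
    or 'two_sided' (|T_j| >= b_j; requires a two-sided plan).  Because the
    spending boundary at look j depends only on fractions up to j, computing
    the whole path at once agrees with recomputing at each successive look.
    """
    stats = np.asarray(statistics, dtype=float)
    res = compute_boundaries(plan, fractions, n_grid=n_grid)
    b = res.boundaries
    if direction == "upper":
        crossed = stats >= b
    elif direction == "lower":
        crossed = stats <= -b
    elif direction == "two_sided":
        crossed = np.abs(stats) >= b
    else:
        raise ValueError("direction must be upper, lower, or two_sided")
    idx = np.flatnonzero(crossed)
    stage = int(idx[0]) + 1 if idx.size else None
    return MonitoringResult(
        stopped=stage is not None, stage=stage, statistics=stats,
        fractions=res.fractions, boundaries=b, plan=plan, direction=direction,
    )
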