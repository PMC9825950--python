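"""Trial data containers, interim snapshots, and censoring primitives.

A two-arm trial with a time-lagged outcome is described per subject by a
calendar entry time E, a treatment arm A in {0, 1}, baseline covariates X, a
lag time T in (0, TF] on the subject-time scale at which the outcome Y becomes
known, the outcome itself, and an optional piecewise-constant path of
time-dependent covariates L(u) observed up to T.  TF (``max_followup``) is the
subject time by which the outcome is known with certainty for everyone.

At an interim analysis at calendar time t, a subject enrolled at E <= t has
been followed for C(t) = t - E time units; the outcome is ascertained
(Delta(t) = 1) if T <= C(t) and censored otherwise, with observed time
U(t) = min{T, C(t)}.  The censoring distribution K_t(u) = pr{C(t) >= u} is
estimated by a Kaplan-Meier fit to {U(t), 1 - Delta(t)}, overall or separately
by arm, and drives the inverse-probability weights and censoring-martingale
integrals used by every interim estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StepFunctionPaths",
    "FullTrialData",
    "InterimDataset",
    "CensoringModel",
    "TrialDataError",
    "build_interim_dataset",
    "fit_censoring_km",
    "martingale_integral",
    "read_subject_csv",
    "write_subject_csv",
    "read_path_csv",
    "write_path_csv",
]


class TrialDataError(ValueError):
    """Raised for structurally invalid trial data or infeasible analyses."""


class StepFunctionPaths:
    """Right-continuous step-function covariate paths for all subjects.

    Stored densely: ``times`` is (n, kmax) with np.inf padding and first
    column 0.0; ``values`` is (n, kmax, q).  The value at subject time u is
    the one attached to the last change time <= u (right-continuous,
    last-value-carried-forward).
    """

    def __init__(self, times: np.ndarray, values: np.ndarray):
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        if times.ndim != 2 or values.ndim != 3 or values.shape[:2] != times.shape:
            raise TrialDataError("times must be (n, k); values must be (n, k, q)")
        if times.shape[1] == 0 or not np.all(times[:, 0] == 0.0):
            raise TrialDataError("each path must start with a change time at 0")
        finite = np.isfinite(times)
        with np.errstate(invalid="ignore"):
            d = np.diff(times, axis=1)
        if np.any(d[finite[:, 1:]] <= 0):
            raise TrialDataError("change times must be strictly increasing")
        self.times = times
        self.values = values

    @classmethod
    def empty(cls, n: int) -> "StepFunctionPaths":
        return cls(np.zeros((n, 1)), np.zeros((n, 1, 0)))

    @classmethod
    def from_ragged(cls, subjects: list[tuple[np.ndarray, np.ndarray]]) -> "StepFunctionPaths":
        """Build from per-subject (times, values) pairs of possibly different lengths."""
        n = len(subjects)
        kmax = max(len(t) for t, _ in subjects)
        q = np.asarray(subjects[0][1]).shape[1] if n else 0
        times = np.full((n, kmax), np.inf)
        values = np.zeros((n, kmax, q))
        for i, (t, v) in enumerate(subjects):
            t = np.asarray(t, dtype=float)
            v = np.asarray(v, dtype=float).reshape(len(t), q)
            times[i, : len(t)] = t
            values[i, : len(t)] = v
            if len(t) < kmax:  # pad with the last value so any index is safe
                values[i, len(t):] = v[-1]
        return cls(times, values)

    @property
    def n_subjects(self) -> int:
        return self.times.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[2]

    def evaluate(self, idx: np.ndarray, u_grid: np.ndarray) -> np.ndarray:
        """Path values for subjects ``idx`` at each time in ``u_grid``.

        Returns an array of shape (len(idx), len(u_grid), q).
        """
        idx = np.atleast_1d(np.asarray(idx))
        u = np.atleast_1d(np.asarray(u_grid, dtype=float))
        if self.n_features == 0:
            return np.zeros((len(idx), len(u), 0))
        t = self.times[idx]                                        # (m, k)
        pos = (t[:, None, :] <= u[None, :, None]).sum(axis=2) - 1  # (m, J)
        pos = np.clip(pos, 0, None)
        rows = np.arange(len(idx))[:, None]
        return self.values[idx][rows, pos]                         # (m, J, q)

    def truncated(self, idx: np.ndarray, u_max: np.ndarray) -> "StepFunctionPaths":
        """Copy of the paths for ``idx`` with change times after ``u_max`` removed."""
        times = self.times[idx].copy()
        values = self.values[idx].copy()
        drop = times > np.asarray(u_max, dtype=float)[:, None]
        times[drop] = np.inf
        return StepFunctionPaths(times, values)


@dataclass
class FullTrialData:
    """Per-subject data that would be available at the final analysis.

    ``outcome`` is continuous, {0,1} binary, or ordinal coded 1..c.
    """

    entry_time: np.ndarray
    arm: np.ndarray
    lag_time: np.ndarray
    outcome: np.ndarray
    max_followup: float
    baseline_covariates: np.ndarray | None = None
    covariate_paths: StepFunctionPaths | None = None

    def __post_init__(self):
        self.entry_time = np.asarray(self.entry_time, dtype=float)
        self.arm = np.asarray(self.arm, dtype=int)
        self.lag_time = np.asarray(self.lag_time, dtype=float)
        self.outcome = np.asarray(self.outcome, dtype=float)
        n = len(self.entry_time)
        if self.baseline_covariates is None:
            self.baseline_covariates = np.zeros((n, 0))
        self.baseline_covariates = np.asarray(self.baseline_covariates, dtype=float)
        if self.baseline_covariates.ndim == 1:
            self.baseline_covariates = self.baseline_covariates[:, None]
        if self.covariate_paths is None:
            self.covariate_paths = StepFunctionPaths.empty(n)
        if not np.all(np.isin(self.arm, [0, 1])):
            raise TrialDataError("arm must be coded 0/1")
        if np.any(self.entry_time < 0):
            raise TrialDataError("entry times must be nonnegative calendar times")
        if np.any(self.lag_time <= 0) or np.any(self.lag_time > self.max_followup + 1e-9):
            raise TrialDataError("lag times must lie in (0, max_followup]")
        for arr in (self.arm, self.lag_time, self.outcome):
            if len(arr) != n:
                raise TrialDataError("per-subject arrays must have equal length")

    @property
    def n_subjects(self) -> int:
        return len(self.entry_time)


@dataclass
class InterimDataset:
    """The observed data O(t) at an interim analysis at calendar time t."""

    analysis_time: float
    max_followup: float
    subject_index: np.ndarray        # indices into the originating FullTrialData
    entry_time: np.ndarray
    arm: np.ndarray
    baseline_covariates: np.ndarray
    censoring_time: np.ndarray       # C_i(t) = t - E_i
    observed_time: np.ndarray        # U_i(t) = min{T_i, C_i(t)}
    ascertained: np.ndarray          # Delta_i(t)
    outcome: np.ndarray              # NaN where Delta_i(t) = 0
    covariate_paths: StepFunctionPaths = field(repr=False, default=None)

    @property
    def n_enrolled(self) -> int:
        return len(self.entry_time)

    @property
    def n_fully_followed(self) -> int:
        """nA(t): number of subjects with C_i(t) >= TF (outcome certain)."""
        return int(np.sum(self.censoring_time >= self.max_followup))

    @property
    def treated_fraction(self) -> float:
        return float(np.mean(self.arm))


def build_interim_dataset(full: FullTrialData, t: float) -> InterimDataset:
    """Snapshot the full data at calendar time ``t`` (the observed data O(t))."""
    if t <= 0:
        raise TrialDataError("analysis time must be positive")
    enrolled = np.flatnonzero(full.entry_time <= t)
    if enrolled.size == 0:
        raise TrialDataError("analysis too early: no subjects enrolled by t")
    arm = full.arm[enrolled]
    if not (np.any(arm == 0) and np.any(arm == 1)):
        raise TrialDataError("analysis too early: an arm has no enrolled subjects")
    C = t - full.entry_time[enrolled]
    T = full.lag_time[enrolled]
    U = np.minimum(T, C)
    delta = (T <= C).astype(int)
    outcome = np.where(delta == 1, full.outcome[enrolled], np.nan)
    if not np.any(C >= full.max_followup):
        warnings.warn(
            "no subject has been followed for the maximum follow-up period; "
            "interim estimators require pr{C(t) > TF} > 0",
            UserWarning,
            stacklevel=2,
        )
    return InterimDataset(
        analysis_time=float(t),
        max_followup=full.max_followup,
        subject_index=enrolled,
        entry_time=full.entry_time[enrolled],
        arm=arm,
        baseline_covariates=full.baseline_covariates[enrolled],
        censoring_time=C,
        observed_time=U,
        ascertained=delta,
        outcome=outcome,
        covariate_paths=full.covariate_paths.truncated(enrolled, U),
    )


class CensoringModel:
    """Kaplan-Meier fit of the censoring distribution K_t(u) = pr{C(t) >= u}.

    Censoring events are observations with Delta(t) = 0.  Survival is
    evaluated left-continuously: K(u) multiplies factors at jump times
    strictly below u, matching the ">= u" definition, so a complete case
    observed exactly at a censoring time keeps a weight from strictly earlier
    jumps only.  Ties between an ascertainment and a censoring event at the
    same time treat the ascertainment as occurring first (the complete case
    stays in the censoring risk set).

    ``cum_hazard`` returns -log K(u), the paper-level cumulative hazard.  The
    martingale compensator uses Nelson-Aalen increments d_j / Y_j, which make
    the counting-process identities exact in finite samples (the sum of
    dM over an at-risk set vanishes at every jump).
    """

    def __init__(self, arm_specific: bool, groups: dict):
        self.arm_specific = arm_specific
        self._groups = groups  # key: arm label or "pooled"

    def _group(self, arm: int | None):
        if self.arm_specific:
            if arm is None:
                raise TrialDataError("arm must be given for an arm-specific model")
            return self._groups[int(arm)]
        return self._groups["pooled"]

    def jump_times(self, arm: int | None = None) -> np.ndarray:
        return self._group(arm)["jumps"]

    def hazard_increments(self, arm: int | None = None) -> np.ndarray:
        """Nelson-Aalen increments d_j / Y_j at the censoring jump times."""
        return self._group(arm)["dL"]

    def at_risk(self, u, arm: int | None = None) -> np.ndarray:
        g = self._group(arm)
        u = np.atleast_1d(np.asarray(u, dtype=float))
        return (g["U_sorted"][None, :] >= u[:, None]).sum(axis=1)

    def survival(self, u, arm: int | None = None) -> np.ndarray:
        """K_t(u) = pr{C(t) >= u}; piecewise constant, left-continuous."""
        g = self._group(arm)
        u = np.asarray(u, dtype=float)
        pos = np.searchsorted(g["jumps"], np.atleast_1d(u), side="left")
        out = g["surv_after"][pos]
        return out if np.ndim(u) else float(out[0])

    def cum_hazard(self, u, arm: int | None = None) -> np.ndarray:
        """Lambda_c(u) = -log K_t(u), exactly, at any query point."""
        s = self.survival(u, arm)
        with np.errstate(divide="ignore"):
            return -np.log(s)


def fit_censoring_km(data: InterimDataset, arm_specific: bool = True) -> CensoringModel:
    """Product-limit estimate of the censoring distribution at analysis time t."""
    if data.n_enrolled == 0:
        raise TrialDataError("empty interim dataset")
    groups: dict = {}
    if arm_specific:
        keys = [0, 1]
        masks = [data.arm == 0, data.arm == 1]
        if not all(m.any() for m in masks):
            raise TrialDataError("arm-specific censoring fit requires both arms nonempty")
    else:
        keys = ["pooled"]
        masks = [np.ones(data.n_enrolled, dtype=bool)]
    for key, mask in zip(keys, masks):
        U = data.observed_time[mask]
        delta = data.ascertained[mask]
        cens = U[delta == 0]
        jumps, d = np.unique(cens, return_counts=True)
        U_sorted = np.sort(U)
        # risk set Y(u) = #{U_k >= u}; ascertainment-first tie convention keeps
        # complete cases with U == u at risk for the censoring event at u
        Y = U.size - np.searchsorted(U_sorted, jumps, side="left")
        factors = 1.0 - d / Y
        surv_after = np.concatenate([[1.0], np.cumprod(factors)])  # K(u+) after each jump
        dL = d / Y
        groups[key] = {
            "jumps": jumps,
            "d": d,
            "Y": Y,
            "dL": dL,
            "surv_after": surv_after,
            "U_sorted": U_sorted,
        }
    cm = CensoringModel(arm_specific, groups)
    # weights must exist for every complete case
    cc = data.ascertained == 1
    if cc.any():
        k = np.empty(data.n_enrolled)
        for a in ([0, 1] if arm_specific else [None]):
            sel = cc if a is None else (cc & (data.arm == a))
            if sel.any():
                k[sel] = cm.survival(data.observed_time[sel], a)
        if np.any(k[cc] <= 0):
            raise TrialDataError(
                "estimated censoring survival is zero at an ascertained time; "
                "weights are undefined (analysis too early)"
            )
    return cm


def martingale_integral(subject: int, data: InterimDataset, cm: CensoringModel, integrand) -> np.ndarray:
    """Integral of ``integrand`` against the subject's censoring martingale.

    dM_i(u) = dN_i(u) - dLambda(u) Y_i(u), so the integral is
    (1 - Delta_i) g(U_i) minus the sum of dLambda(u_j) g(u_j) over censoring
    jump times u_j <= U_i in the subject's arm (or pooled).  ``integrand``
    maps an array of times to an array of values (scalar or vector per time).
    """
    arm = int(data.arm[subject]) if cm.arm_specific else None
    U_i = data.observed_time[subject]
    jumps = cm.jump_times(arm)
    dL = cm.hazard_increments(arm)
    sel = jumps <= U_i
    total = 0.0
    if sel.any():
        g = np.asarray(integrand(jumps[sel]), dtype=float)
        total = np.tensordot(dL[sel], g, axes=(0, 0))
    if data.ascertained[subject] == 0:
        gU = np.asarray(integrand(np.array([U_i])), dtype=float)[0]
        return gU - total
    return np.asarray(-total, dtype=float) if np.ndim(total) else float(-total)


# ---------------------------------------------------------------------------
# delimited-text interfaces

def write_subject_csv(full: FullTrialData, path) -> None:
    n = full.n_subjects
    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "entry_time": full.entry_time,
            "arm": full.arm,
            "lag_time": full.lag_time,
            "outcome": full.outcome,
        }
    )
    for j in range(full.baseline_covariates.shape[1]):
        df[f"x{j + 1}"] = full.baseline_covariates[:, j]
    df.to_csv(path, index=False)


def read_subject_csv(path, max_followup: float) -> FullTrialData:
    df = pd.read_csv(path)
    xcols = [c for c in df.columns if c.startswith("x")]
    return FullTrialData(
        entry_time=df["entry_time"].to_numpy(),
        arm=df["arm"].to_numpy(),
        lag_time=df["lag_time"].to_numpy(),
        outcome=df["outcome"].to_numpy(),
        max_followup=max_followup,
        baseline_covariates=df[xcols].to_numpy() if xcols else None,
    )


def write_path_csv(full: FullTrialData, path) -> None:
    p = full.covariate_paths
    rows = []
    for i in range(p.n_subjects):
        fin = np.isfinite(p.times[i])
        for k in np.flatnonzero(fin):
            rows.append([i, p.times[i, k], *p.values[i, k]])
    cols = ["id", "time"] + [f"l{j + 1}" for j in range(p.n_features)]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_path_csv(path, n_subjects: int) -> StepFunctionPaths:
    df = pd.read_csv(path)
    lcols = [c for c in df.columns if c.startswith("l")]
    subjects = []
    grouped = dict(tuple(df.groupby("id")))
    for i in range(n_subjects):
        if i in grouped:
            g = grouped[i].sort_values("time")
            subjects.append((g["time"].to_numpy(), g[lcols].to_numpy()))
        else:
            subjects.append((np.array([0.0]), np.zeros((1, len(lcols)))))
    return StepFunctionPaths.from_ragged(subjects)
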