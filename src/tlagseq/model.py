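"""Model/Results interface for a single interim analysis and the
group-sequential design wrapper.

``InterimAnalysis`` is constructed from trial data and an analysis time and
exposes ``fit(method=...)`` returning an ``InterimAnalysisResults`` that
carries the estimate, its standard error, the Wald statistic, the effective
sample size and information fraction, and a ``summary()`` table.

``GroupSequentialDesign`` wraps a spending plan: it computes stopping
boundaries for a path of information fractions and applies the monitoring
decision to a sequence of results.
"""

from __future__ import annotations

import json

import numpy as np

from .boundaries import MonitoringResult, SpendingPlan, compute_boundaries, monitor
from .estimators import BasisSpec, EstimatorResult, fit_aipwcc, fit_ipwcc, fit_tf_only
from .information import attach_information
from .outcome_models import OutcomeModelSpec
from .trial_data import (
    FullTrialData,
    build_interim_dataset,
    fit_censoring_km,
    read_path_csv,
    read_subject_csv,
)

__all__ = ["InterimAnalysis", "InterimAnalysisResults", "GroupSequentialDesign"]

_METHODS = ("tf_only", "ipw", "aipw1", "aipw2")


class InterimAnalysis:
    """One interim analysis of a two-arm trial with a time-lagged outcome.

    Parameters
    ----------
    data : FullTrialData
        Subject-level data (only subjects enrolled by ``analysis_time``
        contribute; later entries are ignored, so passing the eventual full
        data is safe).
    analysis_time : float
        Calendar time of the analysis.
    model : str
        'difference_of_means', 'log_relative_risk', or 'proportional_odds'.
    n_categories : int, optional
        Number of ordinal categories; inferred from the observed outcomes if
        omitted.
    basis : BasisSpec, optional
        Augmentation basis; defaults to {1, X columns} for f and
        {X columns, L columns} for h.
    n_max : int, optional
        Planned maximum sample size, used for the fixed-sample information
        fraction; defaults to the number of subjects in ``data``.
    """

    def __init__(self, data: FullTrialData, analysis_time: float, model: str,
                 n_categories: int | None = None, basis: BasisSpec | None = None,
                 arm_specific_censoring: bool = True, n_max: int | None = None):
        self.data = data
        self.analysis_time = float(analysis_time)
        if model == "proportional_odds" and n_categories is None:
            n_categories = int(np.nanmax(data.outcome))
        self.spec = OutcomeModelSpec(model, n_categories or 2)
        if basis is None:
            basis = BasisSpec.default(
                data.baseline_covariates.shape[1], data.covariate_paths.n_features
            )
        self.basis = basis
        self.n_max = int(n_max) if n_max is not None else data.n_subjects
        self.interim = build_interim_dataset(data, self.analysis_time)
        self._arm_specific = arm_specific_censoring
        self._cm = None

    @classmethod
    def from_csv(cls, subject_csv, analysis_time, model, max_followup,
                 path_csv=None, **kwargs) -> "InterimAnalysis":
        data = read_subject_csv(subject_csv, max_followup)
        if path_csv is not None:
            data.covariate_paths = read_path_csv(path_csv, data.n_subjects)
        return cls(data, analysis_time, model, **kwargs)

    @property
    def censoring_model(self):
        if self._cm is None:
            self._cm = fit_censoring_km(self.interim, self._arm_specific)
        return self._cm

    def fit(self, method: str = "aipw2") -> "InterimAnalysisResults":
        if method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        if method == "tf_only":
            res = fit_tf_only(self.interim, self.spec)
            res = attach_information(self.interim, res, None, None, self.n_max)
        else:
            cm = self.censoring_model
            step1 = fit_ipwcc(self.interim, self.spec, cm)
            if method == "ipw":
                res = attach_information(self.interim, step1, cm, None, self.n_max)
            else:
                basis = self.basis if method == "aipw2" else BasisSpec(
                    self.basis.f_basis, include_h=False
                )
                res = fit_aipwcc(self.interim, self.spec, cm, basis, step1=step1)
                res = attach_information(self.interim, res, cm, basis, self.n_max)
        return InterimAnalysisResults(self, res)


class InterimAnalysisResults:
    """Estimates and diagnostics from one interim analysis fit."""

    def __init__(self, model: InterimAnalysis, result: EstimatorResult):
        self.model = model
        self._result = result

    @property
    def beta(self) -> float:
        return self._result.beta_hat

    params = beta

    @property
    def bse(self) -> float:
        return self._result.se

    @property
    def wald(self) -> float:
        return self._result.wald

    @property
    def alpha(self) -> np.ndarray:
        return self._result.alpha_hat

    @property
    def ess(self) -> float:
        return self._result.ess

    @property
    def information_fraction(self) -> float:
        return self._result.information_fraction

    @property
    def n_enrolled(self) -> int:
        return self._result.n_enrolled

    @property
    def n_fully_followed(self) -> int:
        return self._result.n_fully_followed

    @property
    def estimator_kind(self) -> str:
        return self._result.estimator_kind

    def to_dict(self) -> dict:
        return self._result.to_report()

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    def summary(self) -> str:
        r = self._result
        lines = [
            "Interim treatment-effect analysis",
            "=" * 46,
            f"estimator            {r.estimator_kind}",
            f"model                {r.spec.model_kind}",
            f"analysis time        {r.analysis_time:g}",
            f"n enrolled           {r.n_enrolled}",
            f"n fully followed     {r.n_fully_followed}",
            "-" * 46,
            f"beta                 {r.beta_hat: .4f}",
            f"SE                   {r.se: .4f}",
            f"Wald statistic       {r.wald: .4f}",
        ]
        if r.ess is not None:
            lines.append(f"effective n          {r.ess: .1f}")
        if r.information_fraction is not None:
            lines.append(f"information fraction {r.information_fraction: .3f}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def __repr__(self):
        return (f"<InterimAnalysisResults {self.estimator_kind} "
                f"beta={self.beta:.4f} se={self.bse:.4f}>")


class GroupSequentialDesign:
    """Spending-function design: boundaries and the stop/continue decision."""

    def __init__(self, alpha: float = 0.025, sides: str = "one_sided",
                 spending: str = "obrien_fleming", direction: str = "upper",
                 n_grid: int = 4000):
        self.plan = SpendingPlan(alpha, sides, spending)
        self.direction = direction
        self.n_grid = n_grid

    def boundaries(self, fractions) -> np.ndarray:
        return compute_boundaries(self.plan, fractions, n_grid=self.n_grid).boundaries

    def monitor(self, statistics, fractions) -> MonitoringResult:
        return monitor(statistics, fractions, self.plan, direction=self.direction,
                       n_grid=self.n_grid)

    def monitor_results(self, results: list[InterimAnalysisResults]) -> MonitoringResult:
        stats = [r.wald for r in results]
        fracs = [r.information_fraction for r in results]
        return self.monitor(stats, fracs)
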