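"""Synthetic two-arm trials with staggered enrollment and time-lagged outcomes.

Three generative scenarios exercise the full monitoring stack:

* ``ordinal_tesico``: a six-category ordinal outcome modeled on a COVID-19
  inpatient trial.  A latent uniform is warped in the treated arm so the
  proportional-odds model holds exactly with log odds ratio beta; categories
  come from fixed cutpoints giving control probabilities
  (0.12, 0.23, 0.17, 0.10, 0.05, 0.33).  Death (category 6, probability 0.33
  under control) is ascertained at a random death time; all other categories
  require the full 90-day follow-up.  A baseline covariate correlated with
  the latent variable and two hospital-discharge time-dependent covariates
  are provided.
* ``binary_tesico``: the same latent machinery with Y = I(death), so the
  treatment effect is a log relative risk (log(0.247/0.33) = -0.290 at
  latent odds ratio 1.5).
* ``continuous_longitudinal``: a 52-week longitudinal endpoint from a linear
  mixed model with visits at weeks (0, 4, 12, 24, 52); the outcome is the
  week-52 measurement, the baseline covariate is the week-0 measurement, and
  the time-dependent covariate is the last observed measurement.

Entry times are uniform on [0, enrollment_span].  Randomness is drawn as one
(n, k) uniform matrix per trial, one row per subject, so enlarging n_max
leaves earlier subjects' data unchanged for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logit
from scipy.stats import norm

from .estimators import BasisSpec
from .outcome_models import OutcomeModelSpec
from .trial_data import FullTrialData, StepFunctionPaths

__all__ = [
    "ScenarioConfig",
    "CUTPOINTS",
    "generate_ordinal",
    "generate_binary",
    "generate_continuous",
    "generate_trial",
    "default_model_spec",
    "default_basis",
]

CUTPOINTS = np.array([0.00, 0.12, 0.35, 0.52, 0.62, 0.67, 1.00])
_VISITS = np.array([0.0, 4.0, 12.0, 24.0, 52.0])
_INTERCEPTS = np.array([65.0, 60.0, 55.0, 49.0])
_X1_PROBS = np.array([0.4, 0.3, 0.2, 0.1])
_D_COV = np.array([[80.0, -0.5], [-0.5, 0.08]])
_SIGMA_E = 4.5


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one simulated trial."""

    scenario: str
    n_max: int
    enrollment_span: float
    max_followup: float
    beta: float                       # log OR (scenarios 1-2); mean diff (scenario 3)
    analysis_times: tuple
    final_time: float
    alternative: str = "upper"        # direction of the prespecified alternative
    xi: tuple = (-0.3, -0.3)          # scenario 3 slope pair (control, treated)

    def __post_init__(self):
        if self.analysis_times and self.analysis_times[0] < self.max_followup:
            raise ValueError("first analysis must occur at least TF after trial start")
        if self.final_time < self.enrollment_span + self.max_followup:
            raise ValueError("final analysis must allow full follow-up of the last entrant")

    @property
    def all_times(self) -> tuple:
        return tuple(self.analysis_times) + (self.final_time,)

    @classmethod
    def ordinal(cls, beta: float = 0.0, n_max: int = 602) -> "ScenarioConfig":
        return cls("ordinal_tesico", n_max, 240.0, 90.0, beta,
                   (150.0, 195.0, 240.0, 285.0), 330.0, alternative="upper")

    @classmethod
    def binary(cls, log_or: float = 0.0, n_max: int = 900) -> "ScenarioConfig":
        # the latent log odds ratio drives generation; the estimand is the
        # log relative risk of death, negative when log_or > 0
        return cls("binary_tesico", n_max, 240.0, 90.0, log_or,
                   (150.0, 195.0, 240.0, 285.0), 330.0, alternative="lower")

    @classmethod
    def continuous(cls, xi: tuple = (-0.3, -0.3), n_max: int = 300) -> "ScenarioConfig":
        beta = (xi[1] - xi[0]) * 52.0
        return cls("continuous_longitudinal", n_max, 156.0, 52.0, beta,
                   (104.0, 130.0, 156.0, 182.0), 208.0, alternative="upper", xi=tuple(xi))

    def with_n_max(self, n_max: int) -> "ScenarioConfig":
        return replace(self, n_max=n_max)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        """Build from a plain mapping (e.g. parsed YAML/JSON).

        Either give ``scenario`` plus the standard constructor arguments
        (``beta``/``log_or``/``xi``, ``n_max``), or the full field set.
        """
        d = dict(d)
        scenario = d.pop("scenario")
        shortcuts = {
            "ordinal_tesico": cls.ordinal,
            "binary_tesico": cls.binary,
            "continuous_longitudinal": cls.continuous,
        }
        if set(d) <= {"beta", "log_or", "xi", "n_max"}:
            ctor = shortcuts[scenario]
            if scenario == "continuous_longitudinal":
                args = {"xi": tuple(d.get("xi", (-0.3, -0.3)))}
            elif scenario == "binary_tesico":
                args = {"log_or": d.get("log_or", d.get("beta", 0.0))}
            else:
                args = {"beta": d.get("beta", 0.0)}
            if "n_max" in d:
                args["n_max"] = d["n_max"]
            return ctor(**args)
        d.setdefault("analysis_times", ())
        d["analysis_times"] = tuple(d["analysis_times"])
        if "xi" in d:
            d["xi"] = tuple(d["xi"])
        return cls(scenario=scenario, **d)

    @classmethod
    def from_file(cls, path) -> "ScenarioConfig":
        """Load from a YAML or JSON config file."""
        import json

        import yaml

        with open(path) as fh:
            text = fh.read()
        try:
            d = json.loads(text)
        except json.JSONDecodeError:
            d = yaml.safe_load(text)
        return cls.from_dict(d)


def _uniform_rows(seed, n, k):
    u = np.random.default_rng(seed).random((n, k))
    return np.clip(u, 1e-12, 1 - 1e-12)


def _latent(config, u_ups, A):
    """Latent Gamma with logit pr(Gamma <= u | A=1) = logit(u) + beta."""
    e = np.exp(-config.beta)
    treated = u_ups * e / (1.0 - u_ups + u_ups * e)
    return np.where(A == 1, treated, u_ups)


def _tesico_common(config, seed):
    u = _uniform_rows(seed, config.n_max, 5)
    E = config.enrollment_span * u[:, 0]
    A = (u[:, 1] < 0.5).astype(int)
    ups = u[:, 2]
    gamma = _latent(config, ups, A)
    X = 1.5 * (ups - 0.5) + norm.ppf(u[:, 3])
    TF = config.max_followup
    dead = gamma >= CUTPOINTS[5]
    death_time = np.where(A == 1, 20.0 + 30.0 * u[:, 4], 30.0 * u[:, 4])
    # hospital stay H and discharge time W; W = TF for categories 4-6
    H = TF * gamma / CUTPOINTS[3]
    W = np.where(gamma < CUTPOINTS[3], H, TF)
    times = np.column_stack([np.zeros(config.n_max), W])
    values = np.stack(
        [np.zeros((config.n_max, 2)),
         np.column_stack([np.ones(config.n_max), TF - W])], axis=1
    )
    paths = StepFunctionPaths(times, values)
    return E, A, gamma, X, dead, death_time, paths


def generate_ordinal(config: ScenarioConfig, seed) -> FullTrialData:
    E, A, gamma, X, dead, death_time, paths = _tesico_common(config, seed)
    Y = np.searchsorted(CUTPOINTS[1:-1], gamma, side="right") + 1.0
    T = np.where(dead, death_time, config.max_followup)
    return FullTrialData(E, A, T, Y, config.max_followup, X[:, None], paths)


def generate_binary(config: ScenarioConfig, seed) -> FullTrialData:
    E, A, gamma, X, dead, death_time, paths = _tesico_common(config, seed)
    Y = dead.astype(float)
    T = np.where(dead, death_time, config.max_followup)
    return FullTrialData(E, A, T, Y, config.max_followup, X[:, None], paths)


def generate_continuous(config: ScenarioConfig, seed) -> FullTrialData:
    n = config.n_max
    u = _uniform_rows(seed, n, 10)
    E = config.enrollment_span * u[:, 0]
    A = (u[:, 1] < 0.5).astype(int)
    X1 = np.searchsorted(np.cumsum(_X1_PROBS)[:-1], u[:, 2], side="right")  # 0..3
    b = norm.ppf(u[:, 3:5]) @ np.linalg.cholesky(_D_COV).T
    e = _SIGMA_E * norm.ppf(u[:, 5:10])
    slope = np.where(A == 1, config.xi[1], config.xi[0])
    Z = (_INTERCEPTS[X1][:, None]
         + (slope[:, None] + b[:, 1][:, None]) * _VISITS[None, :]
         + b[:, 0][:, None] + e)
    Y = Z[:, -1]
    T = np.full(n, config.max_followup)
    times = np.broadcast_to(_VISITS, (n, 5)).copy()
    paths = StepFunctionPaths(times, Z[:, :, None])
    return FullTrialData(E, A, T, Y, config.max_followup, Z[:, 0][:, None], paths)


_GENERATORS = {
    "ordinal_tesico": generate_ordinal,
    "binary_tesico": generate_binary,
    "continuous_longitudinal": generate_continuous,
}


def generate_trial(config: ScenarioConfig, seed) -> FullTrialData:
    return _GENERATORS[config.scenario](config, seed)


def default_model_spec(config: ScenarioConfig) -> OutcomeModelSpec:
    if config.scenario == "ordinal_tesico":
        return OutcomeModelSpec("proportional_odds", n_categories=6)
    if config.scenario == "binary_tesico":
        return OutcomeModelSpec("log_relative_risk")
    return OutcomeModelSpec("difference_of_means")


def default_basis(config: ScenarioConfig, include_h: bool = True) -> BasisSpec:
    n_l = 2 if config.scenario in ("ordinal_tesico", "binary_tesico") else 1
    return BasisSpec.default(n_baseline=1, n_path=n_l, include_h=include_h)
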