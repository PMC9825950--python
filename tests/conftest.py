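import numpy as np
import pytest

from tlagseq.synthetic_trials import ScenarioConfig, generate_trial
from tlagseq.trial_data import (
    FullTrialData,
    build_interim_dataset,
    fit_censoring_km,
)


@pytest.fixture
def four_point_fixture():
    """Hand-checkable censoring pattern in arm 0: (U, Delta) =
    (10,1), (20,0), (30,1), (40,0); arm 1 fully followed.

    Product-limit by hand (TF = 50, t = 60): censoring jumps at 20 and 40;
    risk set at 20 is {20, 30, 40} so K(u) = 2/3 for 20 < u <= 40 and
    K(20) = 1 under the pr{C >= u} convention.
    """
    # arm 0 rows: (E, T) chosen so C = t - E gives the pattern above
    entry = np.array([10.0, 40.0, 10.0, 20.0, 0.0, 5.0])
    lag = np.array([10.0, 50.0, 30.0, 50.0, 50.0, 50.0])
    arm = np.array([0, 0, 0, 0, 1, 1])
    outcome = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
    full = FullTrialData(entry, arm, lag, outcome, max_followup=50.0)
    interim = build_interim_dataset(full, 60.0)
    return full, interim


@pytest.fixture
def ordinal_snapshot():
    """A moderate scenario-1 snapshot at the first interim look."""
    cfg = ScenarioConfig.ordinal(beta=np.log(1.5))
    full = generate_trial(cfg, 12345)
    interim = build_interim_dataset(full, 150.0)
    cm = fit_censoring_km(interim, arm_specific=True)
    return cfg, full, interim, cm


@pytest.fixture
def ordinal_final_snapshot():
    """Scenario-1 data at the final look: everyone fully followed."""
    cfg = ScenarioConfig.ordinal(beta=np.log(1.5))
    full = generate_trial(cfg, 999)
    interim = build_interim_dataset(full, 330.0)
    cm = fit_censoring_km(interim, arm_specific=True)
    return cfg, full, interim, cm
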