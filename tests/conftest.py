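import warnings

import numpy as np
import pytest

from iadtmodels import GeneratorConfig, TreatmentSchedule, generate_cohort


@pytest.fixture(autouse=True)
def _quiet_runtime_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture
def three_cycle_schedule() -> TreatmentSchedule:
    """Three alternating on/off cycles, ~250/280 days, starting on-treatment."""
    return TreatmentSchedule.from_durations(
        0.0, [(250.0, 280.0), (250.0, 280.0), (250.0, 280.0)], patient_id="fx"
    )


@pytest.fixture
def step_schedule() -> TreatmentSchedule:
    """One on-interval [0, 200) followed by an off tail (an on→off step)."""
    return TreatmentSchedule(((0.0, 200.0),), t_min=0.0, t_max=400.0)


@pytest.fixture(scope="session")
def small_h10_cohort():
    """Deterministic 8-patient noisy cohort from the default generator."""
    return generate_cohort(GeneratorConfig(n_patients=8, model_id="H10",
                                           noise_sd=0.1, seed=5))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
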