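import dataclasses

import numpy as np
import pytest

from occireach import kinematics, simulate
from occireach.simulate import ArmGeometry, CohortSpec, TruncNormal


@pytest.fixture(scope="session")
def geometry():
    return ArmGeometry()


@pytest.fixture(scope="session")
def noiseless_params():
    return simulate.noiseless(simulate.paralyzed_defaults())


def make_noiseless_trial(geometry, outward=2.3, ret=2.3,
                         flex=48.9, abd=117.5, elbow=134.2, seed=0):
    params = simulate.noiseless(simulate.paralyzed_defaults())
    targets = simulate.PhaseTargets(outward, ret, flex, abd, elbow)
    return simulate.simulate_trial(geometry, params, phase_targets=targets,
                                   seed=seed)


@pytest.fixture(scope="session")
def noiseless_trial(geometry):
    return make_noiseless_trial(geometry)


@pytest.fixture(scope="session")
def noiseless_config():
    return kinematics.ExtractionConfig.for_noiseless()


@pytest.fixture(scope="session")
def small_cohort():
    """4 participants x 2 sides x 2 trials, default noise/sway."""
    return simulate.generate_cohort(
        CohortSpec(n_participants=4, trials_per_side=2, seed=11))


@pytest.fixture(scope="session")
def default_cohort_features():
    """Features of one full default cohort (10 x 2 x 5, study conditions)."""
    cohort = simulate.generate_cohort(CohortSpec(seed=2024))
    return kinematics.extract_cohort_features(cohort)


def constant_duration_params(duration: float):
    base = simulate.noiseless(simulate.paralyzed_defaults())
    tn = TruncNormal(duration, 0.0, duration, duration)
    return dataclasses.replace(base, motor_time=tn, return_motor_time=tn)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
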