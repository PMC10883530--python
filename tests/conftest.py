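import numpy as np
import pytest

from abclook import (
    FixedSchedule,
    GaussianKernelMixture,
    Population,
    SchedulerConfig,
    get_problem,
)
from abclook.core import Particle


@pytest.fixture
def gauss_problem():
    return get_problem("gauss")


@pytest.fixture
def t1_problem():
    return get_problem("t1")


@pytest.fixture
def t2_problem():
    return get_problem("t2")


def make_particle(
    theta,
    generation=1,
    proposal_id="prior",
    launch_index=0,
    start=0.0,
    end=1.0,
    weight=1.0,
    distance=0.0,
    combined=None,
):
    """Hand-built particle for unit tests."""
    p = Particle(
        theta=np.atleast_1d(np.asarray(theta, dtype=float)),
        generation=generation,
        proposal_id=proposal_id,
        launch_index=launch_index,
        start_time=start,
        end_time=end,
        distance=distance,
        weight=weight,
    )
    p.normalized_weight = weight
    p.combined_weight = weight if combined is None else combined
    return p


def make_population(thetas, weights, generation=1, epsilon=1.0):
    """Population with given thetas and combined weights (normalized)."""
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    particles = [
        make_particle(
            th, generation=generation, launch_index=i, weight=w, combined=w
        )
        for i, (th, w) in enumerate(zip(thetas, weights))
    ]
    return Population(particles=particles, epsilon=epsilon, generation=generation)


@pytest.fixture
def make_pop():
    return make_population


@pytest.fixture
def make_part():
    return make_particle
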