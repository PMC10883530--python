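"""Domain types shared by all modules.

The central objects are :class:`Problem` (a likelihood-free inference task:
prior, stochastic simulator, distance, observed data), :class:`Particle`
(one parameter draw with its simulation metadata) and :class:`Population`
(the weighted set of accepted particles for one generation).

Simulators return, alongside the data, a *declared* simulation duration in
simulated seconds.  The simulated scheduler backend advances a virtual clock
by these declared durations; real wall-clock time is never consulted, which
makes every run bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Callable, Optional, TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .proposals import Proposal

__all__ = [
    "Problem",
    "Particle",
    "Population",
    "RNGStream",
    "as_parameter_vector",
    "evaluate_acceptance",
]


def as_parameter_vector(values: Any) -> np.ndarray:
    """Coerce ``values`` to a finite 1-d float array (a parameter vector)."""
    theta = np.atleast_1d(np.asarray(values, dtype=float))
    if theta.ndim != 1:
        raise ValueError(f"parameter vector must be 1-d, got shape {theta.shape}")
    if not np.all(np.isfinite(theta)):
        raise ValueError(f"parameter vector has non-finite entries: {theta}")
    return theta


@dataclass
class Problem:
    """A likelihood-free inference problem.

    Parameters
    ----------
    name
        Identifier used in configs and output metadata.
    prior
        A proposal-like object with ``sample(rng)`` and ``density(theta)``;
        the density must be strictly positive wherever ``sample`` can draw.
    simulator
        Callable ``(theta, rng) -> (data, duration_seconds)``.  The duration
        is the declared simulation time in simulated seconds (``>= 0``) and
        is consumed by the simulated worker pool, never slept.
    distance
        Callable ``(data, observed) -> float >= 0``.  Symmetry is not
        required, only nonnegativity.
    observed
        The observed data ``y_obs`` (assumed already summarized).
    n_theta
        Dimension of the parameter vector.
    """

    name: str
    prior: "Proposal"
    simulator: Callable[[np.ndarray, np.random.Generator], tuple]
    distance: Callable[[Any, Any], float]
    observed: Any
    n_theta: int


@dataclass
class Particle:
    """One parameter draw with simulation and scheduling metadata."""

    theta: np.ndarray
    generation: int
    proposal_id: str
    launch_index: int
    start_time: float
    end_time: float
    duration: float = 0.0
    data: Any = None
    distance: Optional[float] = None
    weight: float = 0.0  # raw (non-normalized) importance weight pi/g
    accepted: Optional[bool] = None
    # filled in when the generation's population is finalized
    normalized_weight: float = np.nan
    combined_weight: float = np.nan

    def __post_init__(self) -> None:
        if self.end_time < self.start_time:
            raise ValueError("particle end_time < start_time")


@dataclass
class Population:
    """Weighted set of N accepted particles for one generation."""

    particles: list
    epsilon: float
    generation: int
    betas: dict = field(default_factory=dict)  # proposal_id -> beta_k
    ess: dict = field(default_factory=dict)  # proposal_id -> subpopulation ESS

    def __post_init__(self) -> None:
        if not self.particles:
            raise ValueError("population must contain at least one particle")
        gens = {p.generation for p in self.particles}
        if gens != {self.generation}:
            raise ValueError(f"mixed generations in population: {gens}")

    def __len__(self) -> int:
        return len(self.particles)

    @property
    def thetas(self) -> np.ndarray:
        return np.array([p.theta for p in self.particles])

    @property
    def raw_weights(self) -> np.ndarray:
        return np.array([p.weight for p in self.particles])

    @property
    def combined_weights(self) -> np.ndarray:
        return np.array([p.combined_weight for p in self.particles])

    @property
    def distances(self) -> np.ndarray:
        return np.array([p.distance for p in self.particles])

    @property
    def subpopulation_ids(self) -> list:
        seen: list = []
        for p in self.particles:
            if p.proposal_id not in seen:
                seen.append(p.proposal_id)
        return seen

    @property
    def n_tilde(self) -> int:
        """Number of particles that originate from a preliminary proposal."""
        return sum(1 for p in self.particles if p.proposal_id.startswith("prelim"))

    def mean(self) -> np.ndarray:
        """Combined-weight posterior mean of the parameter vector."""
        return self.combined_weights @ self.thetas


class RNGStream:
    """Named, counter-based random substreams for one run.

    Every statistical draw in a run is keyed by ``(seed, stream, generation,
    launch_index)`` through :class:`numpy.random.SeedSequence`, so that the
    randomness consumed by a sampling attempt depends only on its generation
    and per-generation launch index — never on how the scheduler interleaved
    it with other work.  Identical seed + config on the simulated backend
    therefore yields bit-identical results.
    """

    _STREAMS = {"task": 0, "pilot": 1, "data": 2}

    def __init__(self, seed: int):
        self.seed = int(seed)

    def _rng(self, stream: str, *key: int) -> np.random.Generator:
        entropy = (self.seed, self._STREAMS[stream]) + tuple(int(k) for k in key)
        return np.random.default_rng(np.random.SeedSequence(entropy))

    def task(self, generation: int, launch_index: int) -> np.random.Generator:
        """RNG for one sampling attempt (parameter draw + simulation)."""
        return self._rng("task", generation, launch_index)

    def pilot(self, index: int) -> np.random.Generator:
        """RNG for one pilot (calibration) prior draw."""
        return self._rng("pilot", index)


def evaluate_acceptance(particle: Particle, epsilon: float, problem: Problem) -> bool:
    """Decide acceptance of a particle: ``distance <= epsilon``.

    Computes (if necessary) and records the distance on the particle.  A
    non-finite distance signals a pathological simulation and is rejected
    with a warning.  Acceptance depends only on ``(distance, epsilon)``,
    never on timestamps.
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    if particle.distance is None:
        if particle.data is None:
            raise ValueError("particle has no simulated data")
        particle.distance = float(problem.distance(particle.data, problem.observed))
    d = particle.distance
    if not np.isfinite(d):
        warnings.warn(
            f"non-finite distance {d!r} for particle in generation "
            f"{particle.generation}; rejecting",
            RuntimeWarning,
            stacklevel=2,
        )
        particle.accepted = False
        return False
    particle.accepted = bool(d <= epsilon)
    return particle.accepted
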