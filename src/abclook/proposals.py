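"""Proposal distributions for ABC-SMC.

A generation-``t`` proposal ``g_t`` is built from the previous weighted
population as a Gaussian kernel mixture: pick an accepted particle with
probability proportional to its weight, then perturb it with a shared
covariance ``Sigma_{t-1}`` derived from the weighted sample covariance of
that population (scaled, by default, by a factor 2 — the classic adaptive
choice).  The mixture density is available in closed form, which is what
makes exact importance weights ``pi/g_t`` possible.

Under look-ahead scheduling a *preliminary* proposal ``g~_t`` is needed
before generation ``t-1`` has fully completed: either a kernel mixture over
the first N acceptances (``prel`` mode, fast but potentially biased toward
quick-simulating parameters) or simply the previous generation's proposal
``g_{t-1}`` reused unchanged (``past`` mode, bias-free by induction).

A Gaussian kernel mixture has full support, so the domination condition
``g~_t >> pi`` holds for any prior.  Conversely a perturbed particle may
fall outside the prior's support; such draws are kept and receive prior
density 0, hence importance weight 0 — rejection happens at weighting, not
at sampling, keeping the proposal density exact.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import linalg, stats

from .core import Population, as_parameter_vector

__all__ = [
    "Proposal",
    "UniformBoxPrior",
    "GaussianPrior",
    "GaussianKernelMixture",
    "KernelConfig",
    "weighted_mean_cov",
    "build_proposal",
    "build_preliminary_proposal",
]


class Proposal(ABC):
    """A sampleable, density-evaluable distribution over parameters."""

    source: str = "kernel_mixture"
    built_from_generation: Optional[int] = None

    @abstractmethod
    def sample(self, rng: np.random.Generator) -> np.ndarray:
        ...

    @abstractmethod
    def density(self, theta) -> float:
        ...


class UniformBoxPrior(Proposal):
    """Independent uniform prior on the box ``[low_j, high_j]``."""

    source = "prior"

    def __init__(self, low, high):
        self.low = as_parameter_vector(low)
        self.high = as_parameter_vector(high)
        if self.low.shape != self.high.shape or np.any(self.low >= self.high):
            raise ValueError("invalid box bounds")
        self._dens = float(1.0 / np.prod(self.high - self.low))

    @property
    def dim(self) -> int:
        return self.low.size

    def sample(self, rng):
        return rng.uniform(self.low, self.high)

    def density(self, theta) -> float:
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        inside = np.all((theta >= self.low) & (theta <= self.high))
        return self._dens if inside else 0.0


class GaussianPrior(Proposal):
    """Independent Gaussian prior ``N(mean_j, sd_j^2)`` per component."""

    source = "prior"

    def __init__(self, mean, sd):
        self.mean = as_parameter_vector(mean)
        self.sd = as_parameter_vector(sd)
        if np.any(self.sd <= 0):
            raise ValueError("prior sd must be positive")

    @property
    def dim(self) -> int:
        return self.mean.size

    def sample(self, rng):
        return self.mean + self.sd * rng.standard_normal(self.mean.size)

    def density(self, theta) -> float:
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        z = (theta - self.mean) / self.sd
        log_d = -0.5 * float(z @ z) - np.sum(np.log(self.sd)) \
            - 0.5 * theta.size * np.log(2 * np.pi)
        return float(np.exp(log_d))


@dataclass
class KernelConfig:
    """Configuration of the Gaussian perturbation kernel.

    ``scale_factor`` multiplies the weighted sample covariance (default 2.0).
    ``jitter_rel`` adds ``jitter_rel * trace(Sigma)/d`` to the diagonal;
    ``covariance_floor`` is an absolute diagonal floor that keeps degenerate
    populations (e.g. a single particle) usable.
    """

    scale_factor: float = 2.0
    jitter_rel: float = 1e-10
    covariance_floor: float = 1e-12


def weighted_mean_cov(thetas: np.ndarray, weights: np.ndarray):
    """Weighted mean and plain weighted second moment about it.

    Weights are self-normalized internally; no small-sample unbiasedness
    correction is applied.
    """
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must not be all zero")
    w = w / total
    mu = w @ thetas
    diff = thetas - mu
    cov = (diff * w[:, None]).T @ diff
    return mu, cov


class GaussianKernelMixture(Proposal):
    """Mixture of Gaussians with shared covariance (closed-form density)."""

    source = "kernel_mixture"

    def __init__(self, means, weights, cov, built_from_generation=None):
        self.means = np.atleast_2d(np.asarray(means, dtype=float))
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("mixture weights must be nonnegative, not all zero")
        self.weights = w / w.sum()
        d = self.means.shape[1]
        self.cov = np.atleast_2d(np.asarray(cov, dtype=float))
        if self.cov.shape != (d, d):
            raise ValueError("covariance shape mismatch")
        try:
            self._chol = linalg.cholesky(self.cov, lower=True)
        except linalg.LinAlgError as err:
            raise ValueError("singular kernel covariance") from err
        self._log_norm = -0.5 * d * np.log(2 * np.pi) - np.sum(
            np.log(np.diag(self._chol))
        )
        self.built_from_generation = built_from_generation

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def sample(self, rng):
        idx = rng.choice(self.means.shape[0], p=self.weights)
        return self.means[idx] + self._chol @ rng.standard_normal(self.dim)

    def log_density(self, theta) -> float:
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        diff = theta[None, :] - self.means  # (N, d)
        z = linalg.solve_triangular(self._chol, diff.T, lower=True)  # (d, N)
        log_comp = self._log_norm - 0.5 * np.sum(z * z, axis=0)
        # weight-zero components contribute nothing
        mask = self.weights > 0
        from scipy.special import logsumexp

        return float(
            logsumexp(log_comp[mask], b=self.weights[mask])
        )

    def density(self, theta) -> float:
        return float(np.exp(self.log_density(theta)))


def kernel_covariance(pop: Population, cfg: KernelConfig) -> np.ndarray:
    """Scaled weighted sample covariance with jitter/floor regularization."""
    _, cov = weighted_mean_cov(pop.thetas, pop.combined_weights)
    d = cov.shape[0]
    cov = cfg.scale_factor * cov
    jitter = cfg.jitter_rel * np.trace(cov) / d + cfg.covariance_floor
    return cov + jitter * np.eye(d)


def build_proposal(pop: Population, cfg: Optional[KernelConfig] = None) -> Proposal:
    """Kernel-mixture proposal ``g_t`` from the weighted population ``P_{t-1}``."""
    cfg = cfg or KernelConfig()
    weights = pop.combined_weights
    if weights.sum() <= 0:
        raise ValueError("population weights are all zero")
    return GaussianKernelMixture(
        pop.thetas, weights, kernel_covariance(pop, cfg),
        built_from_generation=pop.generation,
    )


def build_preliminary_proposal(
    mode: str,
    preliminary_pop: Optional[Population] = None,
    previous_proposal: Optional[Proposal] = None,
    cfg: Optional[KernelConfig] = None,
) -> Proposal:
    """Preliminary proposal ``g~_t`` for look-ahead sampling.

    ``mode="prel"`` builds a kernel mixture from the preliminary population
    (the first N acceptances of generation ``t-1``).  ``mode="past"``
    returns ``previous_proposal`` — the exact object used as ``g_{t-1}`` —
    so ``g~_t = g_{t-1}`` holds by construction (for ``t = 2`` this is the
    prior).
    """
    if mode == "prel":
        if preliminary_pop is None:
            raise ValueError("prel mode requires the preliminary population")
        return build_proposal(preliminary_pop, cfg)
    if mode == "past":
        if previous_proposal is None:
            raise ValueError("past mode requires the previous proposal")
        return previous_proposal
    raise ValueError(f"unknown preliminary-proposal mode {mode!r}")
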