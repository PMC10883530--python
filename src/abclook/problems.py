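"""Built-in synthetic inference problems.

* ``t1`` — a bimodal 1-d model ``y = theta^2 + noise`` with observed value
  ``y_obs = 1`` (posterior modes near ``theta = +/-1``), in which the
  positive mode is given artificially long, log-normally distributed
  simulation times while the negative mode simulates in a short constant
  time.  Because run-time depends only on ``sign(theta)``, T1 isolates
  run-time bias: a scheduler that lets simulation time leak into acceptance
  will over-represent the fast (negative) mode.

* ``t2`` — a two-parameter conversion reaction ``x1 <-> x2`` with rates
  ``(k1, k2)``, solved in closed form (``x1 + x2 = 1`` is conserved), both
  species observed on a fixed time grid under multiplicative log-normal
  noise.  Simulated durations are log-normal sleep times *independent* of
  the parameters, with configurable log-scale variance — the workhorse for
  wall-time and N-tilde/N experiments under run-time heterogeneity.

* ``gauss`` — a conjugate-style toy (``theta ~ N(0, tau^2)``,
  ``y ~ N(theta, 1)``, distance ``|y - y_obs|``) whose uniform-kernel ABC
  posterior is available by quadrature, serving as an independent
  correctness oracle for the samplers.

All durations are declared simulated seconds, never slept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import integrate, stats

from .core import Problem, as_parameter_vector
from .proposals import GaussianPrior, UniformBoxPrior

__all__ = [
    "T1Config",
    "T2Config",
    "GaussToyConfig",
    "make_t1",
    "make_t2",
    "make_gauss",
    "get_problem",
    "simulate",
    "oracle_posterior_mean",
    "default_fixed_epsilons",
    "PROBLEMS",
]


# --------------------------------------------------------------------------
# T1: bimodal, run-time-skewed


@dataclass
class T1Config:
    """Bimodal toy: prior U[-bound, bound], y = theta^2 + N(0, noise_sd^2).

    Simulated duration: ``exp(N(slow_log_mean, slow_log_var))`` seconds if
    ``theta > 0`` (the artificially slow mode), else ``fast_duration``.
    """

    bound: float = 2.0
    noise_sd: float = 0.1
    y_obs: float = 1.0
    slow_log_mean: float = 1.0
    slow_log_var: float = 2.0
    fast_duration: float = 0.1


def make_t1(cfg: Optional[T1Config] = None) -> Problem:
    cfg = cfg or T1Config()
    sd_log = np.sqrt(cfg.slow_log_var)

    def simulator(theta, rng):
        th = float(np.atleast_1d(theta)[0])
        y = th * th + cfg.noise_sd * rng.standard_normal()
        if th > 0:
            duration = float(np.exp(cfg.slow_log_mean + sd_log * rng.standard_normal()))
        else:
            duration = cfg.fast_duration
        return y, duration

    problem = Problem(
        name="t1",
        prior=UniformBoxPrior([-cfg.bound], [cfg.bound]),
        simulator=simulator,
        distance=lambda y, y_obs: abs(float(y) - float(y_obs)),
        observed=cfg.y_obs,
        n_theta=1,
    )
    problem.config = cfg
    return problem


# --------------------------------------------------------------------------
# T2: conversion reaction ODE


@dataclass
class T2Config:
    """Conversion reaction x1 <-> x2 with rates (k1, k2), x1(0)=1, x2(0)=0.

    Closed form: ``x2(t) = k1/(k1+k2) * (1 - exp(-(k1+k2) t))`` and
    ``x1 = 1 - x2``.  Both species are observed on ``n_times`` points of
    ``[0, t_max]`` under multiplicative log-normal noise
    ``y = x * exp(noise_sd * xi)``.  The declared duration is a parameter-
    independent log-normal sleep time ``exp(N(sleep_log_mean,
    sleep_log_var))``; ``sleep_log_var`` is the run-time-heterogeneity dial.
    """

    k1: float = 0.06
    k2: float = 0.08
    t_max: float = 30.0
    n_times: int = 10
    noise_sd: float = 0.02
    sleep_log_mean: float = 0.0
    sleep_log_var: float = 1.0
    prior_high: float = 0.5
    data_seed: int = 0


def _t2_trajectory(k1: float, k2: float, times: np.ndarray) -> np.ndarray:
    """Noise-free (x1, x2) stacked as a length-2*len(times) vector.

    Total in (k1, k2): the closed form is evaluated even for negative rates
    (such draws can arise from the perturbation kernel; they lie outside the
    prior's support, carry importance weight 0, and their typically huge
    distances reject them anyway).  The exponent is clipped to keep the
    evaluation finite.
    """
    s = k1 + k2
    if s == 0.0:
        x2 = np.zeros_like(times)
    else:
        x2 = k1 / s * (1.0 - np.exp(np.clip(-s * times, None, 500.0)))
    return np.concatenate([1.0 - x2, x2])


def make_t2(cfg: Optional[T2Config] = None) -> Problem:
    cfg = cfg or T2Config()
    times = np.linspace(0.0, cfg.t_max, cfg.n_times)
    sd_sleep = np.sqrt(cfg.sleep_log_var)

    def simulator(theta, rng):
        k1, k2 = as_parameter_vector(theta)
        traj = _t2_trajectory(k1, k2, times)
        y = traj * np.exp(cfg.noise_sd * rng.standard_normal(traj.size))
        duration = float(np.exp(cfg.sleep_log_mean + sd_sleep * rng.standard_normal()))
        return y, duration

    # observed data: one noisy draw at the true rates, fixed by data_seed
    data_rng = np.random.default_rng(np.random.SeedSequence((cfg.data_seed, 7919)))
    y_obs, _ = simulator([cfg.k1, cfg.k2], data_rng)

    problem = Problem(
        name="t2",
        prior=UniformBoxPrior([0.0, 0.0], [cfg.prior_high, cfg.prior_high]),
        simulator=simulator,
        distance=lambda y, y_ref: float(np.linalg.norm(np.asarray(y) - np.asarray(y_ref))),
        observed=y_obs,
        n_theta=2,
    )
    problem.config = cfg
    problem.times = times
    return problem


# --------------------------------------------------------------------------
# Gaussian toy with quadrature oracle


@dataclass
class GaussToyConfig:
    """theta ~ N(0, tau^2), y ~ N(theta, 1), distance |y - y_obs|."""

    tau: float = 1.0
    y_obs: float = 1.0
    sleep_log_mean: float = 0.0
    sleep_log_var: float = 1.0


def make_gauss(cfg: Optional[GaussToyConfig] = None) -> Problem:
    cfg = cfg or GaussToyConfig()
    sd_sleep = np.sqrt(cfg.sleep_log_var)

    def simulator(theta, rng):
        th = float(np.atleast_1d(theta)[0])
        y = th + rng.standard_normal()
        duration = float(np.exp(cfg.sleep_log_mean + sd_sleep * rng.standard_normal()))
        return y, duration

    problem = Problem(
        name="gauss",
        prior=GaussianPrior([0.0], [cfg.tau]),
        simulator=simulator,
        distance=lambda y, y_obs: abs(float(y) - float(y_obs)),
        observed=cfg.y_obs,
        n_theta=1,
    )
    problem.config = cfg  # used by the oracle
    return problem


def oracle_posterior_mean(problem: Problem, epsilon: float) -> float:
    """Quadrature mean of the uniform-kernel ABC posterior of the toy.

    The ABC posterior density is proportional to
    ``pi(theta) * [Phi(y_obs + eps - theta) - Phi(y_obs - eps - theta)]``;
    mean and normalization are computed by adaptive quadrature (relative
    error well below 1e-8).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    cfg: GaussToyConfig = problem.config
    tau, y_obs = cfg.tau, cfg.y_obs

    def unnorm(th):
        return stats.norm.pdf(th, 0.0, tau) * (
            stats.norm.cdf(y_obs + epsilon - th) - stats.norm.cdf(y_obs - epsilon - th)
        )

    lo, hi = -12.0 * tau - abs(y_obs), 12.0 * tau + abs(y_obs)
    z, _ = integrate.quad(unnorm, lo, hi, epsabs=1e-14, epsrel=1e-12, limit=200)
    m, _ = integrate.quad(
        lambda th: th * unnorm(th), lo, hi, epsabs=1e-14, epsrel=1e-12, limit=200
    )
    return m / z


# --------------------------------------------------------------------------
# registry & helpers

PROBLEMS = {"t1": (make_t1, T1Config), "t2": (make_t2, T2Config), "gauss": (make_gauss, GaussToyConfig)}

# Pre-defined threshold ladders used when cross-strategy comparability
# matters: a geometric descent over 8 generations from the median
# prior-predictive distance down to the noise floor (the median
# self-distance of repeated simulations at the data-generating parameters
# — the smallest threshold worth targeting).  For the Gaussian toy, whose
# noise scale equals the prior scale, the ladder instead descends to a
# quarter of the prior-predictive median.
_DEFAULT_EPS = {
    "t1": [0.863, 0.6, 0.417, 0.289, 0.201, 0.14, 0.097, 0.067],
    "t2": [0.86, 0.6, 0.418, 0.292, 0.203, 0.142, 0.099, 0.069],
    "gauss": [1.234, 1.008, 0.824, 0.673, 0.55, 0.449, 0.367, 0.3],
}


def default_fixed_epsilons(problem_id: str, n_generations: int = 8) -> list:
    """The problem's pre-defined threshold ladder (first ``n_generations``)."""
    values = _DEFAULT_EPS[problem_id]
    if not 1 <= n_generations <= len(values):
        raise ValueError(f"n_generations must be in [1, {len(values)}]")
    return values[:n_generations]


def get_problem(problem_id: str, **params) -> Problem:
    """Build a registered problem by id ('t1', 't2', 'gauss')."""
    try:
        factory, cfg_cls = PROBLEMS[problem_id]
    except KeyError:
        raise ValueError(
            f"unknown problem {problem_id!r}; available: {sorted(PROBLEMS)}"
        ) from None
    return factory(cfg_cls(**params)) if params else factory()


def simulate(problem: Problem, theta, rng) -> tuple:
    """One model simulation: returns ``(data, duration_seconds)``."""
    theta = as_parameter_vector(theta)
    if problem.prior.density(theta) <= 0:
        raise ValueError("theta outside prior support")
    data, duration = problem.simulator(theta, rng)
    if duration < 0:
        raise ValueError("declared duration must be nonnegative")
    return data, duration
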