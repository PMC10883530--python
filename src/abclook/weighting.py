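"""Importance weights, effective sample size, and multi-proposal combination.

In ABC-SMC, a particle drawn from proposal ``g`` carries the non-normalized
importance weight ``w(theta) = pi(theta) / g(theta)`` (the Radon-Nikodym
derivative of the prior w.r.t. the proposal).  Under look-ahead scheduling a
generation may contain particles from several proposals (the preliminary
proposal and the final one).  Because each subpopulation's weight function
has its own unknown normalization constant, raw weights are *not* comparable
across subpopulations: each subpopulation is self-normalized separately and
the subpopulation estimators are mixed with coefficients ``beta_k``.

The default mixing rule maximizes the overall effective sample size

    ESS(w) = (sum_i w_i)^2 / sum_i w_i^2,

whose solution is ``beta_k proportional to ESS_k``.  The alternative rule
``beta_k proportional to N_k`` (subpopulation sizes) is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SubpopulationWeights",
    "CombinedPopulationEstimate",
    "importance_weight",
    "effective_sample_size",
    "optimal_beta",
    "combine_subpopulations",
    "weighted_expectation",
]


def importance_weight(theta, prior, proposal) -> float:
    """Non-normalized importance weight ``pi(theta) / g(theta)``.

    Raises
    ------
    ValueError
        If ``g(theta) == 0`` while ``pi(theta) > 0`` — the proposal does not
        dominate the prior, violating the support condition the unbiasedness
        argument rests on.
    """
    p = float(prior.density(theta))
    g = float(proposal.density(theta))
    if p < 0 or g < 0:
        raise ValueError("negative density encountered")
    if p == 0.0:
        return 0.0
    if g == 0.0:
        raise ValueError(
            "proposal density is 0 where the prior is positive: "
            "the proposal must dominate the prior"
        )
    return p / g


def effective_sample_size(weights) -> float:
    """ESS of a nonnegative weight vector: ``(sum w)^2 / sum w^2``.

    Invariant to positive rescaling of all weights.  Returns 0.0 for an
    empty or all-zero vector (by convention: no usable particles).
    """
    w = np.asarray(weights, dtype=float)
    if w.size and np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    s = w.sum()
    if w.size == 0 or s == 0.0:
        return 0.0
    return float(s * s / np.sum(w * w))


@dataclass
class SubpopulationWeights:
    """Weights of the particles that share one proposal distribution."""

    proposal_id: str
    raw: np.ndarray
    normalized: np.ndarray
    ess: float

    @classmethod
    def from_raw(cls, proposal_id: str, raw) -> "SubpopulationWeights":
        raw = np.asarray(raw, dtype=float)
        if raw.size and np.any(raw < 0):
            raise ValueError("weights must be nonnegative")
        total = raw.sum()
        if raw.size == 0 or total == 0.0:
            # empty / fully-rejected subpopulation: ESS 0, no contribution
            return cls(proposal_id, raw, np.zeros_like(raw), 0.0)
        if not np.isfinite(total):
            raise ValueError(f"non-finite total weight in subpopulation {proposal_id}")
        return cls(proposal_id, raw, raw / total, effective_sample_size(raw))

    def __len__(self) -> int:
        return self.raw.size


def optimal_beta(ess_list) -> np.ndarray:
    """ESS-proportional mixing coefficients ``beta_k = ESS_k / sum_j ESS_j``.

    This is the maximizer of the combined effective sample size of the
    mixed estimator over the simplex of mixing coefficients; for two
    subpopulations it reduces to ``ESS_1 / (ESS_1 + ESS_2)``.
    """
    ess = np.asarray(ess_list, dtype=float)
    if ess.size < 1:
        raise ValueError("need at least one subpopulation")
    if np.any(ess < 0):
        raise ValueError("ESS values must be nonnegative")
    total = ess.sum()
    if total == 0.0:
        raise ValueError("all subpopulations have zero ESS: no usable particles")
    return ess / total


@dataclass
class CombinedPopulationEstimate:
    """Per-subpopulation weights plus the mixed, normalized effective weights."""

    subpopulations: list
    betas: np.ndarray
    combined: np.ndarray  # concatenated in subpopulation order, sums to 1

    @property
    def ess(self) -> float:
        return effective_sample_size(self.combined)


def combine_subpopulations(
    subs: Sequence[SubpopulationWeights], rule: str = "ess"
) -> CombinedPopulationEstimate:
    """Mix disjoint self-normalized subpopulations into one estimator.

    The combined effective weight of particle ``i`` of subpopulation ``k``
    is ``beta_k * W_k^i``.  With a single (nonempty) subpopulation this
    reduces exactly to the ordinary self-normalized estimator.

    Parameters
    ----------
    rule
        ``"ess"`` (default): ``beta_k`` proportional to subpopulation ESS;
        ``"count"``: proportional to subpopulation size (the N-tilde/N rule).
    """
    subs = list(subs)
    if rule == "ess":
        betas = optimal_beta([s.ess for s in subs])
    elif rule == "count":
        sizes = np.array(
            [len(s) if s.ess > 0 else 0 for s in subs], dtype=float
        )
        if sizes.sum() == 0:
            raise ValueError("all subpopulations have zero ESS: no usable particles")
        betas = sizes / sizes.sum()
    else:
        raise ValueError(f"unknown beta rule {rule!r}")
    combined = np.concatenate(
        [b * s.normalized for b, s in zip(betas, subs)]
        or [np.empty(0)]
    )
    return CombinedPopulationEstimate(subpopulations=subs, betas=betas, combined=combined)


def weighted_expectation(
    estimate: CombinedPopulationEstimate, thetas, f: Callable
) -> float:
    """Self-normalized estimate ``sum_i c_i f(theta_i)`` over all particles.

    ``thetas`` are concatenated in the same subpopulation order as
    ``estimate.combined``.
    """
    values = np.array([float(f(t)) for t in thetas])
    if values.shape[0] != estimate.combined.shape[0]:
        raise ValueError("thetas and combined weights disagree in length")
    return float(estimate.combined @ values)
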