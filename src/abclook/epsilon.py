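"""Acceptance-threshold schedules: fixed lists and quantile-adaptive.

A fixed schedule pins the (strictly decreasing) thresholds in advance —
the setting used for cross-strategy comparability, since every scheduler
then targets exactly the same sequence of distributions.  The adaptive
schedule takes ``eps_t`` as a quantile (default: median, linear-interpolated)
of the previous generation's accepted distances, with ``eps_1`` calibrated
as the same quantile of distances from a pilot prior sample.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .core import Population

__all__ = [
    "ScheduleExhausted",
    "EpsilonSchedule",
    "FixedSchedule",
    "QuantileSchedule",
    "next_epsilon",
]


class ScheduleExhausted(Exception):
    """A fixed schedule has no further threshold: the run terminates."""


class EpsilonSchedule:
    adaptive: bool = False

    def __init__(self) -> None:
        self.history: list = []

    @property
    def n_generations(self) -> Optional[int]:
        return None

    def initial(self, pilot_distances=None) -> float:
        raise NotImplementedError

    def next(self, prev_distances) -> float:
        raise NotImplementedError

    def _record(self, eps: float) -> float:
        if eps <= 0:
            raise ValueError(f"epsilon must be positive, got {eps}")
        if self.history and eps >= self.history[-1]:
            raise ValueError("epsilon schedule must be strictly decreasing")
        self.history.append(float(eps))
        return float(eps)


class FixedSchedule(EpsilonSchedule):
    """Pre-defined strictly decreasing thresholds ``[eps_1, ..., eps_nt]``."""

    adaptive = False

    def __init__(self, values: Sequence[float]):
        super().__init__()
        values = [float(v) for v in values]
        if not values:
            raise ValueError("fixed schedule needs at least one value")
        if any(b >= a for a, b in zip(values, values[1:])):
            raise ValueError("fixed schedule must be strictly decreasing")
        if values[-1] <= 0:
            raise ValueError("thresholds must be positive")
        self.values = values

    @property
    def n_generations(self) -> int:
        return len(self.values)

    def peek(self, t: int) -> float:
        """Threshold of generation ``t`` (1-based) without consuming it."""
        if t > len(self.values):
            raise ScheduleExhausted(f"no threshold for generation {t}")
        return self.values[t - 1]

    def initial(self, pilot_distances=None) -> float:
        return self._record(self.values[0])

    def next(self, prev_distances) -> float:
        t = len(self.history) + 1
        if t > len(self.values):
            raise ScheduleExhausted(f"fixed schedule exhausted after {t - 1} generations")
        return self._record(self.values[t - 1])


class QuantileSchedule(EpsilonSchedule):
    """``eps_t`` = q-quantile of the previous generation's accepted distances.

    Linear-interpolated (type-7) quantile, ``q`` default 0.5.  ``eps_1`` is
    the q-quantile of a pilot prior sample's distances.  If the candidate is
    not strictly below ``eps_{t-1}`` (degenerate distances), it is shrunk to
    ``0.99 * eps_{t-1}``.
    """

    adaptive = True

    def __init__(self, q: float = 0.5, eps_min: float = 0.0):
        super().__init__()
        if not 0.0 < q < 1.0:
            raise ValueError("quantile q must lie in (0, 1)")
        self.q = float(q)
        self.eps_min = float(eps_min)

    def estimate(self, distances) -> float:
        return float(np.quantile(np.asarray(distances, dtype=float), self.q))

    def initial(self, pilot_distances=None) -> float:
        if pilot_distances is None:
            raise ValueError("quantile schedule needs pilot distances for eps_1")
        return self._record(self.estimate(pilot_distances))

    def next(self, prev_distances) -> float:
        if prev_distances is None or len(prev_distances) == 0:
            raise ValueError("quantile schedule needs the previous distances")
        eps = self.estimate(prev_distances)
        if self.history and eps >= self.history[-1]:
            eps = 0.99 * self.history[-1]  # guard: enforce strict decrease
        return self._record(eps)


def next_epsilon(schedule: EpsilonSchedule, previous_population: Optional[Population]) -> float:
    """Advance the schedule given the previous population (None before t=1)."""
    if previous_population is None:
        if schedule.adaptive:
            raise ValueError("adaptive eps_1 requires pilot distances; use initial()")
        return schedule.initial()
    return schedule.next(previous_population.distances)
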