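"""Parallelization strategies for ABC-SMC on a simulated worker pool.

Three strategies are implemented against a discrete-event simulation of a
pool of ``W`` workers (a priority queue of task finish times driving a
virtual clock):

* **STAT** (static): each generation defines exactly ``N`` tasks, each
  "sample until one particle is accepted"; tasks queue when ``N > W`` and
  at most ``N`` workers are ever busy.
* **DYN** (dynamic): all ``W`` workers sample back-to-back until ``N``
  particles have been accepted; all in-flight simulations then run to
  completion, and of the ``>= N`` acceptances only the ``N`` that *started*
  earliest form the population.  Selecting by start rather than finish
  order is what removes run-time bias: whether a particle is kept never
  depends on how long its simulation took.
* **LA** (look-ahead): as DYN, but once the ``N``-th acceptance of
  generation ``t-1`` arrives, freed workers immediately begin sampling for
  generation ``t`` from a *preliminary* proposal ``g~_t`` — built either
  from the first ``N`` acceptances (``la_prel``) or by reusing ``g_{t-1}``
  (``la_past``).  When the stragglers of ``t-1`` finish, the real
  population ``P_{t-1}`` is finalized, the final proposal ``g_t`` is built,
  and all workers switch to it.  Preliminary particles that pass the
  generation-``t`` acceptance criterion enter the candidate pool with
  weights ``pi/g~_t`` and compete under the same first-started rule.

Preliminary launches are capped at ``prelim_cap_factor * N`` per generation
and are suppressed when a termination predictor concludes that no further
generation will run.  The number of preliminary launches deliberately does
not depend on preliminary acceptance outcomes, so that worker-side
("pre-defined") and deferred ("delayed") acceptance evaluation produce
identical schedules and hence identical populations for a fixed threshold
schedule.

All durations are the simulators' declared simulated seconds; nothing is
ever slept, and identical seeds give bit-identical runs.
"""

from __future__ import annotations

import dataclasses
import heapq
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import Particle, Population, Problem, RNGStream, evaluate_acceptance
from .epsilon import EpsilonSchedule, FixedSchedule, QuantileSchedule, ScheduleExhausted
from .proposals import KernelConfig, Proposal, build_preliminary_proposal, build_proposal
from .weighting import (
    SubpopulationWeights,
    combine_subpopulations,
    effective_sample_size,
    importance_weight,
)

__all__ = [
    "SchedulerConfig",
    "StoppingRules",
    "WorkerEvent",
    "GenerationStats",
    "RunResult",
    "run",
    "run_static",
    "run_dynamic",
    "run_lookahead",
    "select_first_started",
    "predict_termination",
]

STRATEGIES = ("stat", "dyn", "la_prel", "la_past")


@dataclass
class SchedulerConfig:
    """Strategy and worker-pool configuration.

    ``delayed_evaluation=None`` resolves automatically: acceptance of
    preliminary samples is deferred to the main loop exactly when the
    threshold schedule is adaptive (so one common criterion is applied
    across all particles of a generation); with a pre-defined schedule it
    is checked on the workers.  ``selection_rule`` exists to demonstrate
    run-time bias: ``"first_finished"`` is a deliberately wrong selector
    for validation experiments only.
    """

    strategy: str = "dyn"
    n_workers: int = 1
    population_size: int = 100
    prelim_cap_factor: float = 10.0
    prelim_cap_basis: str = "population"
    delayed_evaluation: Optional[bool] = None
    max_generations: Optional[int] = None
    termination_prediction: bool = True
    post_processing_time: float = 0.0
    max_simulations_per_generation: int = 1_000_000
    beta_rule: str = "ess"
    selection_rule: str = "first_started"
    record_events: bool = True
    kernel: KernelConfig = field(default_factory=KernelConfig)

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.n_workers < 1 or self.population_size < 1:
            raise ValueError("need n_workers >= 1 and population_size >= 1")
        if self.selection_rule not in ("first_started", "first_finished"):
            raise ValueError(f"unknown selection rule {self.selection_rule!r}")
        if self.prelim_cap_basis not in ("population", "evaluations"):
            raise ValueError(f"unknown cap basis {self.prelim_cap_basis!r}")


@dataclass
class StoppingRules:
    max_generations: Optional[int] = None
    eps_min: float = 0.0


# WorkerEvent kinds: task_start, task_finish, idle_start, idle_end, switch_proposal
@dataclass(frozen=True)
class WorkerEvent:
    worker_id: int
    kind: str
    sim_time: float
    generation: int
    proposal_id: str


@dataclass
class GenerationStats:
    """Per-generation ledger summary."""

    generation: int
    epsilon: float
    n_launched: int
    n_prelim_launched: int
    n_accepted_total: int  # all acceptances, incl. discarded beyond first-started N
    n_tilde: int  # selected particles that came from the preliminary proposal
    n_tilde_frac: float
    ess: float  # ESS of the combined weights
    betas: dict
    finalize_time: float


@dataclass
class RunResult:
    strategy: str
    seed: int
    n_workers: int
    population_size: int
    populations: list
    generation_stats: list
    wall_time: float
    busy_time: float
    idle_fraction: float
    n_simulations: int
    n_pilot_simulations: int = 0
    events: Optional[list] = None

    @property
    def epsilons(self) -> list:
        return [g.epsilon for g in self.generation_stats]

    @property
    def final_population(self) -> Population:
        return self.populations[-1]

    def posterior_mean(self) -> np.ndarray:
        return self.final_population.mean()


def select_first_started(accepted, n: int):
    """The ``n`` accepted particles with smallest ``(start_time, launch_index)``.

    Deterministic: ties on start time break by per-generation launch
    sequence number.
    """
    if len(accepted) < n:
        raise ValueError(f"only {len(accepted)} accepted particles, need {n}")
    return sorted(accepted, key=lambda p: (p.start_time, p.launch_index))[:n]


def _select_first_finished(accepted, n: int):
    # deliberately biased selector (validation of run-time-bias correction)
    if len(accepted) < n:
        raise ValueError(f"only {len(accepted)} accepted particles, need {n}")
    return sorted(accepted, key=lambda p: (p.end_time, p.launch_index))[:n]


def predict_termination(
    generation: int,
    next_epsilon_estimate: Optional[float],
    rules: StoppingRules,
) -> bool:
    """Will the run stop after the current generation?

    True — and preliminary sampling is suppressed — if the current
    generation is the last one allowed, or if the running estimate of the
    next threshold has already reached the target ``eps_min``.
    """
    if rules.max_generations is not None and generation >= rules.max_generations:
        return True
    if (
        next_epsilon_estimate is not None
        and rules.eps_min > 0
        and next_epsilon_estimate <= rules.eps_min
    ):
        return True
    return False


# --------------------------------------------------------------------------
# shared helpers


class _Recorder:
    def __init__(self, enabled: bool):
        self.events: Optional[list] = [] if enabled else None

    def add(self, worker, kind, time, gen, pid):
        if self.events is not None:
            self.events.append(WorkerEvent(worker, kind, time, gen, pid))


def _resolve_stopping(cfg: SchedulerConfig, schedule: EpsilonSchedule) -> StoppingRules:
    n_t = cfg.max_generations
    if schedule.n_generations is not None:
        n_t = min(n_t, schedule.n_generations) if n_t else schedule.n_generations
    eps_min = getattr(schedule, "eps_min", 0.0)
    if n_t is None and eps_min <= 0:
        raise ValueError(
            "no stopping rule: set max_generations or a positive eps_min"
        )
    return StoppingRules(max_generations=n_t, eps_min=eps_min)


def _initial_epsilon(
    problem: Problem, schedule: EpsilonSchedule, rngs: RNGStream, n_pilot: int
):
    """eps_1; adaptive schedules calibrate on a pilot prior sample."""
    if not schedule.adaptive:
        return schedule.initial(), 0
    dists = np.empty(n_pilot)
    for i in range(n_pilot):
        rng = rngs.pilot(i)
        theta = problem.prior.sample(rng)
        data, _ = problem.simulator(theta, rng)
        dists[i] = problem.distance(data, problem.observed)
    return schedule.initial(dists), n_pilot


def _make_population(
    selected, eps: float, t: int, beta_rule: str
) -> Population:
    """Group selected particles by proposal, normalize, mix, and annotate."""
    order = []
    groups: dict = {}
    for p in selected:
        groups.setdefault(p.proposal_id, []).append(p)
        if p.proposal_id not in order:
            order.append(p.proposal_id)
    # preliminary subpopulation first (fixed, deterministic order)
    order.sort(key=lambda pid: (not pid.startswith("prelim"), pid))
    subs = [
        SubpopulationWeights.from_raw(pid, [p.weight for p in groups[pid]])
        for pid in order
    ]
    est = combine_subpopulations(subs, rule=beta_rule)
    offset = 0
    betas, ess = {}, {}
    for sub, beta in zip(est.subpopulations, est.betas):
        for p, nw, cw in zip(
            groups[sub.proposal_id],
            sub.normalized,
            est.combined[offset : offset + len(sub)],
        ):
            p.normalized_weight = float(nw)
            p.combined_weight = float(cw)
        offset += len(sub)
        betas[sub.proposal_id] = float(beta)
        ess[sub.proposal_id] = float(sub.ess)
    pop = Population(particles=list(selected), epsilon=eps, generation=t,
                     betas=betas, ess=ess)
    return pop


def _stats_for(pop: Population, st, t, eps, finalize_time) -> GenerationStats:
    n = len(pop)
    return GenerationStats(
        generation=t,
        epsilon=eps,
        n_launched=st["launched"],
        n_prelim_launched=st["prelim_launched"],
        n_accepted_total=st["accepted_total"],
        n_tilde=pop.n_tilde,
        n_tilde_frac=pop.n_tilde / n,
        ess=effective_sample_size(pop.combined_weights),
        betas=dict(pop.betas),
        finalize_time=finalize_time,
    )


# --------------------------------------------------------------------------
# STAT


def run_static(
    problem: Problem,
    cfg: SchedulerConfig,
    schedule: EpsilonSchedule,
    seed: int,
) -> RunResult:
    """Static scheduling: N sample-until-accepted tasks per generation."""
    if cfg.strategy != "stat":
        raise ValueError("run_static requires strategy='stat'")
    W, N = cfg.n_workers, cfg.population_size
    rngs = RNGStream(seed)
    rec = _Recorder(cfg.record_events)
    rules = _resolve_stopping(cfg, schedule)
    eps, n_pilot = _initial_epsilon(problem, schedule, rngs, N)

    populations, gen_stats = [], []
    proposal: Proposal = problem.prior
    pid = "prior"
    gen_start = 0.0
    busy = 0.0
    n_sims = 0
    t = 1
    while True:
        avail = [(gen_start, w) for w in range(W)]
        heapq.heapify(avail)
        particles = []
        launch_counter = 0
        gen_end = gen_start
        for _ in range(N):
            free_t, w = heapq.heappop(avail)
            cur = free_t
            while True:
                if launch_counter >= cfg.max_simulations_per_generation:
                    raise RuntimeError(
                        f"generation {t}: exceeded "
                        f"{cfg.max_simulations_per_generation} simulations; "
                        f"epsilon={eps} may be unreachable"
                    )
                rng = rngs.task(t, launch_counter)
                theta = proposal.sample(rng)
                data, dur = problem.simulator(theta, rng)
                n_sims += 1
                p = Particle(
                    theta=theta, generation=t, proposal_id=pid,
                    launch_index=launch_counter, start_time=cur,
                    end_time=cur + dur, duration=dur, data=data,
                )
                launch_counter += 1
                rec.add(w, "task_start", cur, t, pid)
                rec.add(w, "task_finish", cur + dur, t, pid)
                busy += dur
                cur += dur
                if evaluate_acceptance(p, eps, problem):
                    p.weight = importance_weight(p.theta, problem.prior, proposal)
                    particles.append(p)
                    break
            gen_end = max(gen_end, cur)
            heapq.heappush(avail, (cur, w))
        pop = _make_population(particles, eps, t, cfg.beta_rule)
        populations.append(pop)
        gen_stats.append(
            _stats_for(
                pop,
                {"launched": launch_counter, "prelim_launched": 0,
                 "accepted_total": N},
                t, eps, gen_end,
            )
        )
        if rules.max_generations is not None and t >= rules.max_generations:
            break
        try:
            eps = schedule.next(pop.distances)
        except ScheduleExhausted:
            break
        proposal = build_proposal(pop, cfg.kernel)
        pid = "final"
        gen_start = gen_end + cfg.post_processing_time
        t += 1

    wall = gen_stats[-1].finalize_time
    idle = 1.0 - busy / (W * wall) if wall > 0 else 0.0
    return RunResult(
        strategy="stat", seed=seed, n_workers=W, population_size=N,
        populations=populations, generation_stats=gen_stats,
        wall_time=wall, busy_time=busy, idle_fraction=idle,
        n_simulations=n_sims, n_pilot_simulations=n_pilot,
        events=rec.events,
    )


# --------------------------------------------------------------------------
# rolling engine: DYN and LA


class _GenState:
    __slots__ = (
        "eps", "proposal", "proposal_pid", "prelim_proposal", "accepted",
        "pending", "inflight", "launch_counter", "prelim_launched",
    )

    def __init__(self):
        self.eps: Optional[float] = None
        self.proposal: Optional[Proposal] = None
        self.proposal_pid = "final"
        self.prelim_proposal: Optional[Proposal] = None
        self.accepted: list = []
        self.pending: list = []
        self.inflight = 0
        self.launch_counter = 0
        self.prelim_launched = 0


def _preliminary_population(accepted, n: int, t: int) -> Population:
    """P-hat: the first ``n`` particles accepted (in acceptance order).

    Built on particle copies so premature weight annotations never touch
    the particles competing for the real population.
    """
    chosen = [dataclasses.replace(p) for p in accepted[:n]]
    total = sum(p.weight for p in chosen)
    if total <= 0:
        raise ValueError("preliminary population has zero total weight")
    for p in chosen:
        p.normalized_weight = p.weight / total
        p.combined_weight = p.weight / total
    return Population(particles=chosen, epsilon=np.inf, generation=t)


def _run_rolling(
    problem: Problem,
    cfg: SchedulerConfig,
    schedule: EpsilonSchedule,
    seed: int,
) -> RunResult:
    la = cfg.strategy in ("la_prel", "la_past")
    W, N = cfg.n_workers, cfg.population_size
    if cfg.delayed_evaluation is None:
        delayed = schedule.adaptive
    else:
        delayed = cfg.delayed_evaluation
        if schedule.adaptive and not delayed:
            raise ValueError(
                "worker-side acceptance needs a pre-defined threshold schedule"
            )
    rngs = RNGStream(seed)
    rec = _Recorder(cfg.record_events)
    rules = _resolve_stopping(cfg, schedule)

    gens: dict = {1: _GenState()}
    eps1, n_pilot = _initial_epsilon(problem, schedule, rngs, N)
    gens[1].eps = eps1
    gens[1].proposal = problem.prior
    gens[1].proposal_pid = "prior"

    populations: list = []
    gen_stats: list = []
    heap: list = []  # (finish_time, seq, worker, particle, proposal)
    seq = 0
    idle_since: dict = {}
    busy = 0.0
    n_sims = 0

    def gen_state(t: int) -> _GenState:
        if t not in gens:
            gens[t] = _GenState()
        return gens[t]

    def launch(worker: int, now: float, t: int, proposal: Proposal, pid: str):
        nonlocal seq, busy, n_sims
        st = gen_state(t)
        if st.launch_counter >= cfg.max_simulations_per_generation:
            raise RuntimeError(
                f"generation {t}: exceeded "
                f"{cfg.max_simulations_per_generation} simulations; "
                f"epsilon may be unreachable"
            )
        rng = rngs.task(t, st.launch_counter)
        theta = proposal.sample(rng)
        data, dur = problem.simulator(theta, rng)
        n_sims += 1
        p = Particle(
            theta=theta, generation=t, proposal_id=pid,
            launch_index=st.launch_counter, start_time=now,
            end_time=now + dur, duration=dur, data=data,
        )
        st.launch_counter += 1
        st.inflight += 1
        busy += dur
        rec.add(worker, "task_start", now, t, pid)
        heapq.heappush(heap, (now + dur, seq, worker, p, proposal))
        seq += 1

    active = 1
    running = True
    wall = 0.0

    def next_eps_estimate(t: int) -> Optional[float]:
        if isinstance(schedule, FixedSchedule):
            try:
                return schedule.peek(t + 1)
            except ScheduleExhausted:
                return None
        if isinstance(schedule, QuantileSchedule):
            st = gens[t]
            if st.accepted:
                return schedule.estimate([p.distance for p in st.accepted])
        return None

    def prelim_cap(t: int) -> int:
        # cap on preliminary launches for generation t+1: either a multiple
        # of the population size, or of the (running) number of evaluations
        # in the current generation t
        if cfg.prelim_cap_basis == "population":
            return int(round(cfg.prelim_cap_factor * N))
        return int(round(cfg.prelim_cap_factor * gens[t].launch_counter))

    def prelim_wanted(now: float) -> Optional[Proposal]:
        """g~ for generation active+1, or None if suppressed/capped."""
        t = active
        if isinstance(schedule, FixedSchedule) and t + 1 > schedule.n_generations:
            return None
        est = next_eps_estimate(t) if cfg.termination_prediction else None
        if cfg.termination_prediction and predict_termination(t, est, rules):
            return None
        stn = gen_state(t + 1)
        if stn.prelim_launched >= prelim_cap(t):
            return None
        if stn.prelim_proposal is None:
            st = gens[t]
            if cfg.strategy == "la_past":
                stn.prelim_proposal = build_preliminary_proposal(
                    "past", previous_proposal=st.proposal
                )
            else:
                p_hat = _preliminary_population(st.accepted, N, t)
                stn.prelim_proposal = build_preliminary_proposal(
                    "prel", preliminary_pop=p_hat, cfg=cfg.kernel
                )
        return stn.prelim_proposal

    def decide(worker: int, now: float):
        st = gens[active]
        if len(st.accepted) < N:
            launch(worker, now, active, st.proposal, st.proposal_pid)
            return
        if la:
            prop = prelim_wanted(now)
            if prop is not None:
                stn = gen_state(active + 1)
                stn.prelim_launched += 1
                launch(worker, now, active + 1, prop, "prelim")
                return
        if worker not in idle_since:
            idle_since[worker] = now
            rec.add(worker, "idle_start", now, active, "")

    def accept_particle(p: Particle, proposal: Proposal, eps: float, st: _GenState):
        if evaluate_acceptance(p, eps, problem):
            p.weight = importance_weight(p.theta, problem.prior, proposal)
            st.accepted.append(p)

    def finalize(now: float) -> bool:
        """Close the active generation; returns False when the run ends."""
        nonlocal active, wall
        st = gens[active]
        if cfg.selection_rule == "first_finished":
            selected = _select_first_finished(st.accepted, N)
        else:
            selected = select_first_started(st.accepted, N)
        pop = _make_population(selected, st.eps, active, cfg.beta_rule)
        populations.append(pop)
        gen_stats.append(
            _stats_for(
                pop,
                {"launched": st.launch_counter,
                 "prelim_launched": st.prelim_launched,
                 "accepted_total": len(st.accepted)},
                active, st.eps, now,
            )
        )
        if rules.max_generations is not None and active >= rules.max_generations:
            wall = now
            return False
        try:
            eps_next = schedule.next(pop.distances)
        except ScheduleExhausted:
            wall = now
            return False
        nxt = gen_state(active + 1)
        nxt.eps = eps_next
        nxt.proposal = build_proposal(pop, cfg.kernel)
        nxt.proposal_pid = "final"
        for p, prop in nxt.pending:  # delayed evaluation of preliminary samples
            accept_particle(p, prop, eps_next, nxt)
        nxt.pending = []
        active += 1
        wake = now + cfg.post_processing_time
        for w in sorted(idle_since):
            rec.add(w, "idle_end", wake, active, "")
            rec.add(w, "switch_proposal", wake, active, "final")
        woken = sorted(idle_since)
        idle_since.clear()
        for w in woken:
            decide(w, wake)
        return True

    # generation 1 starts on all workers at time 0
    for w in range(W):
        decide(w, 0.0)

    while heap and running:
        now, _, worker, p, proposal = heapq.heappop(heap)
        t = p.generation
        st = gens[t]
        st.inflight -= 1
        rec.add(worker, "task_finish", now, t, p.proposal_id)
        if t == active:
            accept_particle(p, proposal, st.eps, st)
        else:  # preliminary sample for generation active+1
            p.distance = float(problem.distance(p.data, problem.observed))
            if delayed:
                st.pending.append((p, proposal))
            else:
                accept_particle(p, proposal, schedule.peek(t), st)
        wake_now = now
        while (
            running
            and gens[active].inflight == 0
            and len(gens[active].accepted) >= N
        ):
            running = finalize(now)
            wake_now = now + cfg.post_processing_time
        if running:
            decide(worker, wake_now)

    if running:  # pool drained without hitting a stopping rule
        raise RuntimeError("worker pool drained before any stopping rule fired")

    # abandoned in-flight preliminary work does not count past the end
    for end, _, _, p, _ in heap:
        busy -= min(p.duration, max(0.0, end - wall))
    for w, since in idle_since.items():
        rec.add(w, "idle_end", wall, active, "")

    idle = 1.0 - busy / (W * wall) if wall > 0 else 0.0
    return RunResult(
        strategy=cfg.strategy, seed=seed, n_workers=W, population_size=N,
        populations=populations, generation_stats=gen_stats,
        wall_time=wall, busy_time=busy, idle_fraction=idle,
        n_simulations=n_sims, n_pilot_simulations=n_pilot,
        events=rec.events,
    )


def run_dynamic(problem, cfg, schedule, seed) -> RunResult:
    """Dynamic scheduling (continuous sampling, first-started selection)."""
    if cfg.strategy != "dyn":
        raise ValueError("run_dynamic requires strategy='dyn'")
    return _run_rolling(problem, cfg, schedule, seed)


def run_lookahead(problem, cfg, schedule, seed) -> RunResult:
    """Look-ahead scheduling (preemptive sampling of the next generation)."""
    if cfg.strategy not in ("la_prel", "la_past"):
        raise ValueError("run_lookahead requires strategy 'la_prel' or 'la_past'")
    return _run_rolling(problem, cfg, schedule, seed)


def run(problem: Problem, cfg: SchedulerConfig, schedule: EpsilonSchedule, seed: int) -> RunResult:
    """Run one ABC-SMC inference with the configured strategy."""
    if cfg.strategy == "stat":
        return run_static(problem, cfg, schedule, seed)
    if cfg.strategy == "dyn":
        return run_dynamic(problem, cfg, schedule, seed)
    return run_lookahead(problem, cfg, schedule, seed)
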