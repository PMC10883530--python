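"""Scheduling semantics: hand-traced timelines, selection, reductions."""

import numpy as np
import pytest

from abclook import (
    FixedSchedule,
    QuantileSchedule,
    SchedulerConfig,
    StoppingRules,
    get_problem,
    predict_termination,
    run,
    select_first_started,
)
from abclook.core import Problem
from abclook.io import populations_frame
from abclook.proposals import UniformBoxPrior


def scripted_problem(durations, distance_value=0.0):
    """Problem whose simulator pops declared durations in call order.

    Every simulation yields the same distance (default 0: always accepted),
    making scheduling timelines exactly hand-traceable.
    """
    queue = list(durations)

    def simulator(theta, rng):
        if not queue:
            raise AssertionError("scripted duration list exhausted")
        return 0.0, queue.pop(0)

    return Problem(
        name="scripted",
        prior=UniformBoxPrior([-1.0], [1.0]),
        simulator=simulator,
        distance=lambda y, y_obs: distance_value,
        observed=0.0,
        n_theta=1,
    )


def cfg_for(strategy, W, N, **kw):
    return SchedulerConfig(
        strategy=strategy, n_workers=W, population_size=N, **kw
    )


class TestStatic:
    def test_five_tasks_on_eight_workers(self):
        # unit durations, every draw accepted: wall-time 1.0, 3 workers idle
        prob = scripted_problem([1.0] * 5)
        r = run(prob, cfg_for("stat", 8, 5), FixedSchedule([1.0]), seed=0)
        assert r.wall_time == 1.0
        assert r.busy_time == 5.0
        assert r.idle_fraction == pytest.approx(3.0 / 8.0)

    def test_two_tasks_two_workers(self):
        prob = scripted_problem([3.0, 5.0])
        r = run(prob, cfg_for("stat", 2, 2), FixedSchedule([1.0]), seed=0)
        assert r.wall_time == 5.0

    def test_single_worker_queues_tasks(self):
        prob = scripted_problem([1.0, 1.0, 1.0])
        r = run(prob, cfg_for("stat", 1, 3), FixedSchedule([1.0]), seed=0)
        assert r.wall_time == 3.0
        assert r.idle_fraction == 0.0

    def test_minimal_single_task(self):
        # N=1: a single worker samples until one acceptance
        prob = scripted_problem([2.0, 2.0, 2.0], distance_value=0.0)
        r = run(prob, cfg_for("stat", 4, 1), FixedSchedule([1.0]), seed=0)
        assert len(r.final_population) == 1
        assert r.wall_time == 2.0

    def test_unreachable_epsilon_aborts(self):
        prob = scripted_problem([1.0] * 100, distance_value=2.0)
        cfg = cfg_for("stat", 1, 1, max_simulations_per_generation=50)
        with pytest.raises(RuntimeError, match="unreachable"):
            run(prob, cfg, FixedSchedule([1.0]), seed=0)


class TestDynamic:
    def test_hand_trace_first_started_selection(self):
        # launch order durations [3,5,1]: acceptances at t=3,4; wait till 5;
        # keep the two that started at t=0; worker 0 idle on [4,5]
        prob = scripted_problem([3.0, 5.0, 1.0])
        r = run(prob, cfg_for("dyn", 2, 2), FixedSchedule([1.0]), seed=0)
        assert r.wall_time == 5.0
        starts = sorted(p.start_time for p in r.final_population.particles)
        assert starts == [0.0, 0.0]
        assert r.generation_stats[0].n_accepted_total == 3
        assert r.busy_time == 9.0
        assert r.idle_fraction == pytest.approx(1.0 - 9.0 / 10.0)

    def test_no_surplus_matches_static_selection(self):
        # W=N, distinct durations, all accepted: same thetas as STAT
        durs = [3.0, 1.0, 2.0]
        r_dyn = run(
            scripted_problem(list(durs) + [5.0, 5.0]),
            cfg_for("dyn", 3, 3), FixedSchedule([1.0]), seed=7,
        )
        r_stat = run(
            scripted_problem(durs),
            cfg_for("stat", 3, 3), FixedSchedule([1.0]), seed=7,
        )
        assert np.array_equal(
            np.sort(r_dyn.final_population.thetas, axis=0),
            np.sort(r_stat.final_population.thetas, axis=0),
        )

    def test_tie_break_by_launch_index(self):
        prob = scripted_problem([1.0, 1.0, 1.0, 1.0, 1.0])
        r = run(prob, cfg_for("dyn", 4, 2), FixedSchedule([1.0]), seed=0)
        idx = sorted(p.launch_index for p in r.final_population.particles)
        assert idx == [0, 1]  # all start at 0; keep lowest launch indices


class TestSelectFirstStarted:
    def _mk(self, make_part, starts):
        return [
            make_part([0.0], launch_index=i, start=s, end=s + 1.0)
            for i, s in enumerate(starts)
        ]

    def test_earliest_starts_kept(self, make_part):
        sel = select_first_started(self._mk(make_part, [0.0, 0.0, 3.0]), 2)
        assert [p.start_time for p in sel] == [0.0, 0.0]

    def test_identity_when_n_equals_len(self, make_part):
        parts = self._mk(make_part, [2.0, 1.0])
        assert set(map(id, select_first_started(parts, 2))) == set(map(id, parts))

    def test_all_ties_by_launch_index(self, make_part):
        sel = select_first_started(self._mk(make_part, [1.0] * 4), 2)
        assert [p.launch_index for p in sel] == [0, 1]

    def test_too_few_raises(self, make_part):
        with pytest.raises(ValueError):
            select_first_started(self._mk(make_part, [0.0]), 2)


class TestLookahead:
    def test_hand_trace_prelim_fills_idle_tail(self):
        # gen-1 durations [2,9] on W=2, N=1: after the acceptance at t=2,
        # worker 0 runs preliminary generation-2 tasks during [2,9]
        prob = scripted_problem([2.0, 9.0] + [1.0] * 7)
        r = run(
            prob, cfg_for("la_past", 2, 1), FixedSchedule([1.0, 0.5]), seed=0
        )
        assert r.wall_time == 9.0
        g1, g2 = r.generation_stats
        assert g1.finalize_time == 9.0
        # gen-1 population is the first-started task
        assert r.populations[0].particles[0].start_time == 0.0
        assert r.populations[0].particles[0].launch_index == 0
        # seven preliminary launches fit into the idle window [2, 9]
        assert g2.n_prelim_launched == 7
        assert g2.n_tilde == 1 and g2.n_tilde_frac == 1.0
        assert r.populations[1].particles[0].start_time == 2.0
        # la_past at t=2: preliminary proposal is the prior -> unit weights
        assert r.populations[1].raw_weights == pytest.approx([1.0])

    def test_same_scenario_under_dyn_idles_instead(self):
        prob = scripted_problem([2.0, 9.0, 1.0, 1.0])
        r = run(prob, cfg_for("dyn", 2, 1), FixedSchedule([1.0, 0.5]),
                seed=0)  # gen 2 then runs two more tasks
        # worker 0 is idle during [2, 9] in generation 1
        idle = [e for e in r.events if e.kind == "idle_start"]
        assert idle and idle[0].worker_id == 0 and idle[0].sim_time == 2.0

    def test_prelim_cap_limits_launches(self):
        prob = scripted_problem([2.0, 9.0] + [1.0] * 20)
        r = run(
            prob,
            cfg_for("la_past", 2, 1, prelim_cap_factor=3.0),
            FixedSchedule([1.0, 0.5]),
            seed=0,
        )
        assert r.generation_stats[1].n_prelim_launched == 3

    def test_evaluation_based_cap_allows_more_prelim_work(self, gauss_problem):
        # the evaluation-proportional cap scales with rejections, so it is
        # never tighter than the population-proportional one
        vals = [2.0, 1.2, 0.8]
        runs = {
            basis: run(
                gauss_problem,
                cfg_for("la_past", 12, 10, prelim_cap_basis=basis),
                FixedSchedule(list(vals)),
                seed=4,
            )
            for basis in ("population", "evaluations")
        }
        pop_prelim = sum(
            g.n_prelim_launched for g in runs["population"].generation_stats
        )
        eval_prelim = sum(
            g.n_prelim_launched for g in runs["evaluations"].generation_stats
        )
        assert eval_prelim >= pop_prelim > 0

    def test_cap_zero_reduces_exactly_to_dyn(self, gauss_problem):
        vals = [2.0, 1.2, 0.8]
        r_la = run(
            gauss_problem,
            cfg_for("la_past", 6, 20, prelim_cap_factor=0.0),
            FixedSchedule(list(vals)),
            seed=11,
        )
        r_dyn = run(
            gauss_problem, cfg_for("dyn", 6, 20), FixedSchedule(list(vals)),
            seed=11,
        )
        fa = populations_frame(r_la)
        fb = populations_frame(r_dyn)
        assert fa.equals(fb)
        assert r_la.wall_time == r_dyn.wall_time

    def test_no_prelim_on_last_generation(self, gauss_problem):
        # termination prediction suppresses preliminary sampling for a
        # generation that will never run
        r = run(
            gauss_problem, cfg_for("la_past", 6, 15),
            FixedSchedule([2.0, 1.2]), seed=3,
        )
        assert r.generation_stats[-1].generation == 2
        total_prelim_beyond = sum(
            1 for pop in r.populations for p in pop.particles
            if p.generation > 2
        )
        assert total_prelim_beyond == 0

    def test_delayed_equals_worker_side_evaluation(self, gauss_problem):
        vals = [2.0, 1.2, 0.8]
        frames = []
        for delayed in (False, True):
            r = run(
                gauss_problem,
                cfg_for("la_prel", 8, 25, delayed_evaluation=delayed),
                FixedSchedule(list(vals)),
                seed=5,
            )
            frames.append(populations_frame(r))
        assert frames[0].equals(frames[1])

    def test_adaptive_schedule_forbids_worker_side_evaluation(self, gauss_problem):
        cfg = cfg_for("la_past", 4, 10, delayed_evaluation=False, max_generations=3)
        with pytest.raises(ValueError, match="pre-defined"):
            run(gauss_problem, cfg, QuantileSchedule(q=0.5), seed=0)

    def test_n_tilde_fraction_bounded(self, gauss_problem):
        r = run(
            gauss_problem, cfg_for("la_prel", 16, 30, max_generations=4),
            QuantileSchedule(q=0.5), seed=9,
        )
        for g in r.generation_stats:
            assert 0.0 <= g.n_tilde_frac <= 1.0
        assert [g.epsilon for g in r.generation_stats] == sorted(
            (g.epsilon for g in r.generation_stats), reverse=True
        )


class TestPredictTermination:
    def test_last_generation(self):
        rules = StoppingRules(max_generations=8)
        assert predict_termination(8, None, rules) is True
        assert predict_termination(9, None, rules) is True

    def test_not_last_with_fixed_schedule(self):
        rules = StoppingRules(max_generations=8, eps_min=0.0)
        assert predict_termination(3, 0.5, rules) is False

    def test_quantile_estimate_below_target(self):
        rules = StoppingRules(max_generations=None, eps_min=0.2)
        assert predict_termination(3, 0.15, rules) is True
        assert predict_termination(3, 0.25, rules) is False


class TestTimelineAccounting:
    def test_single_worker_sequential(self):
        prob = scripted_problem([1.0, 1.0, 1.0])
        r = run(prob, cfg_for("stat", 1, 3), FixedSchedule([1.0]), seed=0)
        assert r.wall_time == 3.0 and r.idle_fraction == 0.0

    def test_two_workers_parallel(self):
        prob = scripted_problem([1.0, 1.0])
        r = run(prob, cfg_for("stat", 2, 2), FixedSchedule([1.0]), seed=0)
        assert r.wall_time == 1.0 and r.idle_fraction == 0.0

    def test_events_cover_busy_time(self, gauss_problem):
        from abclook.io import occupancy_intervals

        r = run(
            gauss_problem, cfg_for("dyn", 4, 10), FixedSchedule([2.0, 1.2]),
            seed=2,
        )
        occ = occupancy_intervals(r)
        total = (occ.end - occ.start).sum()
        assert total == pytest.approx(r.busy_time)

    def test_post_processing_delay_shifts_generations(self):
        prob = scripted_problem([1.0, 1.0, 1.0, 1.0])
        r = run(
            prob,
            cfg_for("stat", 2, 2, post_processing_time=2.5),
            FixedSchedule([1.0, 0.5]),
            seed=0,
        )
        assert r.generation_stats[0].finalize_time == 1.0
        assert r.generation_stats[1].finalize_time == 4.5
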