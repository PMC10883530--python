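"""Run configuration, result persistence, diagnostics, replicate sweeps.

Results are plain text: one directory per run with ``populations.csv``
(one row per accepted particle), ``events.csv`` (worker timeline),
``summary.json`` (wall-time, idle fraction, per-generation thresholds and
N-tilde/N) and ``config.yaml``.  Floats go through Python's ``repr`` so
CSV/JSON round-trips are lossless, and identical seed + config produce
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .epsilon import EpsilonSchedule, FixedSchedule, QuantileSchedule
from .problems import get_problem
from .proposals import KernelConfig
from .schedulers import RunResult, SchedulerConfig, run

__all__ = [
    "RunConfig",
    "populations_frame",
    "events_frame",
    "summary_dict",
    "save_run",
    "load_populations",
    "load_summary",
    "run_experiment",
    "diagnostics_report",
    "posterior_summary",
]


@dataclass
class RunConfig:
    """Fully serializable description of one experiment."""

    problem: str = "gauss"
    problem_params: dict = field(default_factory=dict)
    strategy: str = "dyn"
    n_workers: int = 4
    population_size: int = 100
    epsilon: dict = field(default_factory=lambda: {"kind": "quantile", "q": 0.5})
    kernel: dict = field(default_factory=dict)
    seed: int = 0
    replicates: int = 1
    prelim_cap_factor: float = 10.0
    prelim_cap_basis: str = "population"
    delayed_evaluation: Optional[bool] = None
    max_generations: Optional[int] = 8
    termination_prediction: bool = True
    post_processing_time: float = 0.0
    beta_rule: str = "ess"
    record_events: bool = True

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=repr)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    # -- construction ------------------------------------------------------

    def build_problem(self):
        return get_problem(self.problem, **self.problem_params)

    def make_schedule(self) -> EpsilonSchedule:
        """A fresh (stateful) schedule; call once per run."""
        opts = dict(self.epsilon)
        kind = opts.pop("kind", "quantile")
        if kind == "fixed":
            return FixedSchedule(opts["values"])
        if kind == "quantile":
            return QuantileSchedule(**opts)
        raise ValueError(f"unknown epsilon schedule kind {kind!r}")

    def scheduler_config(self, strategy: Optional[str] = None) -> SchedulerConfig:
        return SchedulerConfig(
            strategy=strategy or self.strategy,
            n_workers=self.n_workers,
            population_size=self.population_size,
            prelim_cap_factor=self.prelim_cap_factor,
            prelim_cap_basis=self.prelim_cap_basis,
            delayed_evaluation=self.delayed_evaluation,
            max_generations=self.max_generations,
            termination_prediction=self.termination_prediction,
            post_processing_time=self.post_processing_time,
            beta_rule=self.beta_rule,
            record_events=self.record_events,
            kernel=KernelConfig(**self.kernel),
        )

    def execute(self, strategy: Optional[str] = None, seed: Optional[int] = None) -> RunResult:
        return run(
            self.build_problem(),
            self.scheduler_config(strategy),
            self.make_schedule(),
            self.seed if seed is None else seed,
        )


# --------------------------------------------------------------------------
# frames and persistence


def populations_frame(result: RunResult) -> pd.DataFrame:
    rows = []
    for pop in result.populations:
        for i, p in enumerate(pop.particles):
            row = {"generation": pop.generation, "particle": i,
                   "proposal_id": p.proposal_id}
            for j, v in enumerate(p.theta):
                row[f"theta_{j}"] = v
            row.update(
                distance=p.distance,
                raw_weight=p.weight,
                normalized_weight=p.normalized_weight,
                combined_weight=p.combined_weight,
                start_time=p.start_time,
                end_time=p.end_time,
            )
            rows.append(row)
    return pd.DataFrame(rows)


def events_frame(result: RunResult) -> pd.DataFrame:
    if result.events is None:
        return pd.DataFrame(
            columns=["worker_id", "kind", "sim_time", "generation", "proposal_id"]
        )
    return pd.DataFrame([dataclasses.asdict(e) for e in result.events])


def summary_dict(result: RunResult, config: Optional[RunConfig] = None) -> dict:
    return {
        "strategy": result.strategy,
        "seed": result.seed,
        "n_workers": result.n_workers,
        "population_size": result.population_size,
        "wall_time": result.wall_time,
        "busy_time": result.busy_time,
        "idle_fraction": result.idle_fraction,
        "n_simulations": result.n_simulations,
        "n_pilot_simulations": result.n_pilot_simulations,
        "config_hash": config.config_hash() if config else None,
        "generations": [
            {
                "generation": g.generation,
                "epsilon": g.epsilon,
                "n_launched": g.n_launched,
                "n_prelim_launched": g.n_prelim_launched,
                "n_accepted_total": g.n_accepted_total,
                "n_tilde": g.n_tilde,
                "n_tilde_frac": g.n_tilde_frac,
                "ess": g.ess,
                "betas": g.betas,
                "finalize_time": g.finalize_time,
            }
            for g in result.generation_stats
        ],
    }


def save_run(result: RunResult, out_dir, config: Optional[RunConfig] = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    populations_frame(result).to_csv(out / "populations.csv", index=False)
    events_frame(result).to_csv(out / "events.csv", index=False)
    (out / "summary.json").write_text(
        json.dumps(summary_dict(result, config), indent=2, sort_keys=True) + "\n"
    )
    if config is not None:
        config.to_yaml(out / "config.yaml")
    return out


def load_populations(run_dir) -> pd.DataFrame:
    return pd.read_csv(
        Path(run_dir) / "populations.csv", float_precision="round_trip"
    )


def load_summary(run_dir) -> dict:
    return json.loads((Path(run_dir) / "summary.json").read_text())


# --------------------------------------------------------------------------
# experiment driver


def run_experiment(
    config: RunConfig,
    out_dir,
    strategies: Optional[list] = None,
    force: bool = False,
) -> pd.DataFrame:
    """Replicate sweep over strategies with matched seeds.

    Replicate ``k`` uses seed ``config.seed + k`` for *every* strategy, so
    cross-strategy comparisons are matched-seed.  Writes one run directory
    per (strategy, replicate) plus an ``aggregate.csv``; returns the
    per-run aggregate table (with speed-up ``1 - wall/wall_dyn`` when a
    ``dyn`` reference is part of the sweep).
    """
    strategies = list(strategies) if strategies is not None else [config.strategy]
    if not strategies:
        raise ValueError("strategy list must not be empty")
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} exists; use force=True")
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for strategy in strategies:
        for k in range(config.replicates):
            seed = config.seed + k
            result = config.execute(strategy=strategy, seed=seed)
            save_run(result, out / strategy / f"rep{k}", config)
            row = {
                "strategy": strategy,
                "replicate": k,
                "seed": seed,
                "wall_time": result.wall_time,
                "idle_fraction": result.idle_fraction,
                "n_simulations": result.n_simulations,
                "final_epsilon": result.epsilons[-1],
                "final_ess": result.generation_stats[-1].ess,
                "final_n_tilde_frac": result.generation_stats[-1].n_tilde_frac,
            }
            for j, m in enumerate(result.posterior_mean()):
                row[f"posterior_mean_{j}"] = m
            rows.append(row)
    table = pd.DataFrame(rows)
    if "dyn" in strategies:
        ref = table[table.strategy == "dyn"].set_index("replicate")["wall_time"]
        table["speedup_vs_dyn"] = 1.0 - table["wall_time"] / table["replicate"].map(ref)
    table.to_csv(out / "aggregate.csv", index=False)
    return table


# --------------------------------------------------------------------------
# diagnostics


def posterior_summary(result: RunResult) -> pd.DataFrame:
    """Weighted posterior mean/sd per parameter and generation, plus ESS."""
    rows = []
    for pop, g in zip(result.populations, result.generation_stats):
        w = pop.combined_weights
        thetas = pop.thetas
        mu = w @ thetas
        var = w @ (thetas - mu) ** 2
        row = {"generation": pop.generation, "epsilon": pop.epsilon,
               "ess": g.ess, "n_tilde_frac": g.n_tilde_frac}
        for j in range(thetas.shape[1]):
            row[f"mean_{j}"] = mu[j]
            row[f"sd_{j}"] = np.sqrt(var[j])
        rows.append(row)
    return pd.DataFrame(rows)


def occupancy_intervals(result: RunResult) -> pd.DataFrame:
    """Busy intervals per worker, reconstructed from the event stream."""
    if result.events is None:
        raise ValueError("run was executed with record_events=False")
    open_tasks: dict = {}
    rows = []
    for e in result.events:
        if e.kind == "task_start":
            open_tasks[e.worker_id] = e
        elif e.kind == "task_finish":
            start = open_tasks.pop(e.worker_id, None)
            if start is not None:
                rows.append(
                    {"worker_id": e.worker_id, "start": start.sim_time,
                     "end": e.sim_time, "generation": e.generation,
                     "proposal_id": start.proposal_id}
                )
    return pd.DataFrame(rows)


def diagnostics_report(result: RunResult, plot_path=None) -> dict:
    """Summary tables (and optionally a worker-occupancy plot).

    Returns a dict with the posterior summary and, when events were
    recorded, the per-worker occupancy intervals.
    """
    report = {"posterior": posterior_summary(result)}
    if result.events is not None:
        occ = occupancy_intervals(result)
        report["occupancy"] = occ
        if plot_path is not None:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(9, 4))
            gens = sorted({g.generation for g in result.generation_stats})
            cmap = plt.get_cmap("tab10")
            for _, r in occ.iterrows():
                ax.barh(
                    r.worker_id, r.end - r.start, left=r.start, height=0.8,
                    color=cmap(int(r.generation) % 10),
                    alpha=0.5 if r.proposal_id == "prelim" else 0.9,
                    linewidth=0,
                )
            ax.set_xlabel("simulated time [s]")
            ax.set_ylabel("worker")
            ax.set_title(f"{result.strategy}: worker occupancy")
            fig.tight_layout()
            fig.savefig(plot_path, dpi=120)
            plt.close(fig)
    return report
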