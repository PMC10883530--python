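# abclook

Approximate Bayesian computation (ABC) fits mechanistic models whose
likelihood is intractable by accepting parameters θ whose simulated data
lie within a distance ε of the observations; combined with a sequential
Monte Carlo scheme (ABC-SMC) it refines the approximation over generations
t = 1, …, n_t with decreasing thresholds ε_t, reweighting particles drawn
from a kernel-mixture proposal g_t by w_t(θ) = π(θ)/g_t(θ).  On parallel
hardware the question is *scheduling*: how to keep W workers busy while a
generation needs exactly N accepted particles.

`abclook` implements and compares three strategies on a deterministic
discrete-event simulation of a worker pool:

* **STAT** — static: N sample-until-accepted tasks per generation;
* **DYN** — dynamic: all workers sample continuously until N acceptances,
  then of the Ñ_all ≥ N accepted particles only the N that *started*
  earliest are kept (this removes run-time bias exactly);
* **LA** — look-ahead: once the N-th acceptance of generation t−1 arrives,
  freed workers immediately sample generation-t candidates from a
  *preliminary* proposal g̃_t — built from the first N acceptances
  (**LA Prel**) or by reusing g_{t−1} (**LA Past**) — so that no worker
  idles during the straggler phase.

A generation sampled by LA contains Ñ particles from g̃_t (weights π/g̃_t)
and N−Ñ from g_t (weights π/g_t).  Each subpopulation is self-normalized
separately and mixed with coefficients β_k ∝ ESS_k, the choice that
maximizes the combined effective sample size ESS(w) = (Σw)²/Σw².

Because simulators *declare* their run-time in simulated seconds (nothing
ever sleeps) and every random draw is keyed by (seed, generation, launch
index), runs are bit-reproducible, wall-time and idle-time are exact, and
scheduling semantics are testable at desk scale.  Built-in problems: a
bimodal run-time-skewed toy (`t1`), a conversion-reaction ODE model with
log-normal sleep times (`t2`), and a Gaussian toy with a quadrature oracle
(`gauss`).

## Worked example

Run look-ahead scheduling on the conversion-reaction problem with N = 64
particles on W = 128 simulated workers, then inspect the result:

```sh
$ abclook run --problem t2 --strategy la_past --n 64 --workers 128 \
      --seed 7 --out results/demo
la_past: 8 generations, wall-time 128.886s, idle fraction 0.538, final eps 0.1443

$ abclook report --run-dir results/demo
{
  "busy_time": 7627.844956665894,
  "config_hash": "cab4adb66e478939",
  "idle_fraction": 0.5376333522011929,
  "n_pilot_simulations": 64,
  "n_simulations": 4568,
  "n_workers": 128,
  "population_size": 64,
  "seed": 7,
  "strategy": "la_past",
  "wall_time": 128.88589392780602
}
gen 1: eps=0.8936 ess=64.0 n_tilde/N=0.000 launched=246
gen 2: eps=0.5557 ess=64.0 n_tilde/N=1.000 launched=640
gen 3: eps=0.3942 ess=35.8 n_tilde/N=1.000 launched=640
gen 4: eps=0.3569 ess=59.7 n_tilde/N=0.297 launched=415
gen 5: eps=0.3077 ess=63.2 n_tilde/N=1.000 launched=640
gen 6: eps=0.2523 ess=63.5 n_tilde/N=0.609 launched=566
gen 7: eps=0.206 ess=63.5 n_tilde/N=1.000 launched=640
gen 8: eps=0.1443 ess=63.0 n_tilde/N=0.953 launched=781
```

Reading the output: with the default adaptive schedule, ε₁ is calibrated
as the median distance of a 64-draw pilot prior sample (hence the 64
pilot simulations) and each later ε_t is the median of the previous
generation's accepted distances, reaching 0.144 after 8 generations.  The
run took 128.9 simulated seconds of wall-time with 53.8 % of worker time
idle — W/N = 2 leaves many workers waiting even under look-ahead once the
preliminary-launch cap (10·N = 640) is hit.  `n_tilde/N` is the fraction
of each final population that originated from the preliminary proposal:
several generations here were filled entirely by look-ahead samples
(fraction 1.000) before the previous generation had even finished.  `ess`
is the effective sample size of the combined weights (out of N = 64).
The weighted posterior mean of the final population sits near the true
rates (k1, k2) = (0.06, 0.08) used to generate the data:

```sh
$ python -c "
from abclook.io import load_populations
df = load_populations('results/demo')
final = df[df.generation == 8]
print((final[['theta_0','theta_1']].mul(final.combined_weight, axis=0)).sum())"
theta_0    0.063698
theta_1    0.087581
dtype: float64
```

Matched-seed sweeps over strategies (`abclook sweep`) write an
`aggregate.csv` with per-replicate wall-times and the speed-up
1 − wall(LA)/wall(DYN).

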