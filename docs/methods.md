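# Methods

## Problem setting

`abclook` implements likelihood-free Bayesian inference by approximate
Bayesian computation with a sequential Monte Carlo scheme (ABC-SMC).  A
*problem* consists of a prior π(θ), a stochastic simulator y ∼ π(y|θ), a
distance d(y, y_obs) ≥ 0 and observed (already summarized) data y_obs.
Classical ABC draws θ from the prior, simulates y, and accepts θ when
d(y, y_obs) ≤ ε (closed threshold, `≤`).  The accepted particles sample

    π_ABC,ε(θ | y_obs) ∝ ∫ 1[d(y, y_obs) ≤ ε] π(y|θ) dy · π(θ),

which converges to the posterior as ε → 0.  ABC-SMC refines this over
generations t = 1, …, n_t with strictly decreasing thresholds ε_t.  In
generation 1 particles come from the prior (g_1 = π, all weights 1); later
generations draw from a proposal g_t built on the previous weighted
population and carry importance weights w_t(θ) = π(θ)/g_t(θ).  Posterior
expectations use the self-normalized estimator Σ_i W_t^i f(θ_t^i) with
W_t^i = w_t^i / Σ_j w_t^j.

## Proposals

g_t is a Gaussian kernel mixture over P_{t−1}: select an accepted particle
with probability proportional to its (combined, see below) weight and
perturb it with a shared covariance Σ_{t−1}.  Σ_{t−1} is the *plain
weighted second moment* of P_{t−1} about its weighted mean (no small-sample
correction), multiplied by a scale factor (default **2.0**, the classic
adaptive choice), plus a relative diagonal jitter (1e-10·trace/d) and an
absolute floor (default 1e-12) so that degenerate populations — down to a
single particle — remain usable.  The mixture density is available in
closed form, so the importance weights are exact.  Gaussian mixtures have
full support, hence the domination condition g_t ≫ π holds for every prior.
Conversely, a perturbed draw may leave the prior's support; such particles
are *kept*, receive prior density 0 and therefore weight 0 — rejection
happens at weighting, not at sampling, which keeps the proposal density
exact.  (This is why the built-in conversion-reaction model evaluates its
closed-form trajectory for any rates: out-of-support draws must still be
simulable.)

## Scheduling strategies

Sampling is executed against a pool of W workers.  Three strategies:

* **STAT** — N tasks per generation, each "sample until one acceptance";
  tasks queue when N > W, and at most N workers are ever used.
* **DYN** — all W workers sample back-to-back until N particles are
  accepted; every in-flight simulation then runs to completion, and of the
  Ñ_all ≥ N acceptances only the N that *started* earliest (ties broken by
  launch sequence number) form the population.  Because launch times are
  nondecreasing in launch index, this selection equals "the first N
  acceptances in draw order", which is independent of all simulation
  durations — the run-time-bias correction is exact by construction.
* **LA** (look-ahead) — as DYN, but when the N-th acceptance of generation
  t−1 arrives and workers begin to idle, a preliminary proposal g̃_t is
  built and freed workers immediately sample generation-t candidates from
  it.  Two variants: **LA Prel** builds g̃_t from the first N acceptances
  of generation t−1 (a set biased toward fast-simulating parameters —
  deliberately so, to expose the phenomenon), while **LA Past** reuses the
  previous proposal object, g̃_t = g_{t−1} (the prior when t = 2), which is
  bias-free by induction.  When the stragglers of t−1 finish, P_{t−1} is
  finalized, g_t is built, and all workers switch to it.  Preliminary
  particles accepted under the generation-t criterion enter the candidate
  pool with weights π/g̃_t and compete under the same first-started rule,
  yielding a population with Ñ preliminary-origin and N−Ñ final-origin
  members.

Preliminary launches are capped at `prelim_cap_factor · N` per generation
(default **10**); alternatively the cap basis can be switched to the
running number of evaluations in the current generation
(`prelim_cap_basis="evaluations"`), which scales the allowance with the
rejection rate.  Note a structural consequence of the default
population-proportional cap: when the cap, rather than the look-ahead
time window, limits preliminary launches (small N relative to W),
preliminary supply grows proportionally to N and the fraction Ñ/N of
preliminary-origin particles becomes roughly constant in N; Ñ/N only
starts to fall with N once the window binds.  The number of preliminary launches deliberately does not
depend on preliminary acceptance outcomes: workers that would launch past
the cap idle instead.  This makes worker-side ("pre-defined") and deferred
("delayed") acceptance evaluation produce *identical* event timelines, so
for a fixed threshold schedule the two modes give byte-identical
populations — a property the test suite asserts.  Delayed evaluation is
selected automatically when any acceptance component is adaptive (e.g. a
quantile threshold), so that one common criterion is applied across all
particles of a generation.

A termination predictor suppresses preliminary sampling when no further
generation will run: when the current generation is the last allowed, or
when the running quantile estimate of the next threshold already
undershoots the configured ε_min.

Generations may cascade: if preliminary sampling alone supplies N
acceptances, the next generation is complete the moment it becomes active,
and look-ahead for the following generation starts immediately.  Under
high acceptance rates whole generations can thus be sampled entirely from
the preliminary proposal (Ñ = N).

## Multi-proposal weighting

Within a generation, raw weights from different proposals have different
unknown normalization constants and are not comparable.  Each
subpopulation (preliminary vs final origin) is therefore self-normalized
separately and the subpopulation estimators are mixed:

    E[f] ≈ Σ_k β_k Σ_i W_k^i f(θ_k^i),   Σ_k β_k = 1.

The default rule maximizes the combined effective sample size
ESS(w) = (Σw)²/Σw², with solution **β_k ∝ ESS_k** (for two subpopulations,
β = ESS̃ / (ESS̃ + ESS)); the size-proportional rule β_k = N_k/N is
available as `beta_rule="count"`.  The K-subpopulation form β_k ∝ ESS_k is
the natural extension of the two-proposal solution and is implemented as
such.  An empty or fully-zero-weight subpopulation has ESS 0 and drops out
gracefully; with a single subpopulation the combination reduces exactly to
the ordinary self-normalized estimator.  The combined weights β_k·W_k^i
are used for posterior summaries *and* for building the next proposal.

## Simulated worker pool

The backend is a discrete-event simulation: a priority queue of task
finish times drives a virtual clock; simulators *declare* their duration
in simulated seconds (never slept).  Determinism is guaranteed by keying
every statistical draw with (seed, generation, per-generation launch
index) through `numpy.random.SeedSequence`, so scheduler interleaving
cannot perturb statistical draws; ties in the event queue break by a
global launch sequence number.  Identical seed + config yield
byte-identical output files.  Wall-time is the finalization time of the
last generation; worker busy time is clipped to that horizon (preliminary
work abandoned at termination does not count), and the idle fraction is
1 − busy/(W·wall).  Post-processing time between generations is a
configurable constant (default 0).  An optional real multi-process backend
was considered and deliberately omitted: every property of interest is a
function of the event timeline, which the simulated pool reproduces
exactly.

## Threshold schedules

Fixed schedules are strictly decreasing lists — the setting used whenever
strategies are compared, since all schedulers then target identical
distributions.  The adaptive schedule takes ε_t as the q-quantile (default
0.5, linear-interpolated type-7) of the previous generation's accepted
distances, with ε_1 calibrated as the same quantile of a pilot prior
sample of size N (drawn outside the simulated clock, from a dedicated RNG
stream).  A guard shrinks a non-decreasing candidate to 0.99·ε_{t−1}.

## Built-in problems and what they emulate

* **t1** — bimodal y = θ² + N(0, ς²), ς = 0.1, prior U[−2, 2], y_obs = 1,
  distance |y − y_obs|; posterior modes at θ ≈ ±1.  Durations depend only
  on sign(θ): log-normal exp(N(1, 2)) seconds for θ > 0, constant 0.1 s
  otherwise.  The (μ, σ²) of the slow mode are exposed as configuration;
  the defaults make the slow mode's median run-time (e¹ ≈ 2.7 s) more than
  an order of magnitude longer than the fast mode's 0.1 s, enough for the
  preliminary-bias phenomenon to be unmistakable at small N.
* **t2** — conversion reaction x1 ↔ x2 with rates (k1, k2), x1(0) = 1,
  solved in closed form (x1 + x2 = 1 conserved); both species observed on
  10 time points of [0, 30] under multiplicative log-normal noise
  (sd 0.02); true rates (0.06, 0.08), prior U[0, 0.5]²; distance Euclidean
  over the stacked trajectory; observed data is one noisy draw at the true
  rates from a fixed data seed.  Durations are parameter-independent
  log-normal sleep times exp(N(0, σ²)) with σ² = 1 by default (the
  run-time-heterogeneity dial, 1–4 in the experiments).
* **gauss** — θ ~ N(0, τ²), y ~ N(θ, 1), distance |y − y_obs|, defaults
  τ = 1, y_obs = 1.  Its uniform-kernel ABC posterior is computed by
  adaptive quadrature (relative error ≪ 1e-8) and serves as the
  independent correctness oracle; a 10⁷-draw vectorized rejection sampler
  cross-checks the quadrature in the tests.

Default pre-defined threshold ladders descend geometrically over 8
generations from the median prior-predictive distance down to the noise
floor (the median self-distance of repeated simulations at the true
parameters — the smallest threshold worth targeting); the Gaussian toy,
whose noise scale equals its prior scale, descends to a quarter of the
prior-predictive median instead.

What the synthetic problems do *not* emulate: real simulator cost (all
closed-form), network/transport latency, heterogeneous or failing
workers, multi-dimensional summary-statistic selection, and the
applications' high-dimensional parameter spaces.  Passing tests therefore
demonstrate the scheduling and weighting semantics and their statistical
consequences, not performance on any particular real model.

## Experiment sizes

Desk-scale study conditions used by the tests and the acceptance script:
the oracle comparison uses N = 500, W = 50, 10 replicates per strategy;
the bias experiments use N = 100, W = 100 (run-time bias) and N = 20,
W = 200 with a short high-acceptance ladder [1.0, 0.7, 0.5] (preliminary
bias), 10 replicates each; wall-time ordering uses N = 32 with
W ∈ {32, 128, 256} and 20 matched-seed replicates; the Ñ/N trend uses
W = 256 with N ∈ {64, 256, 1024} and 8 replicates.  Replicate counts are
the package's own choice for stable means at interactive run times.

## Known limitations

* The preliminary proposal for LA Prel is built once per generation (at
  the N-th acceptance) and not refreshed as further stragglers finish.
* Accepted-but-discarded particles (beyond the first-started N) are
  dropped, not recycled.
* Only one generation of look-ahead is active at a time; with extremely
  high acceptance rates deeper pipelining could in principle help.
* The ESS-optimal β targets effective sample size, not estimator variance
  for a specific f.
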