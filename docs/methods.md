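# Methods

This document records the modeling assumptions, default parameters, and
numerical choices behind `ufba`, in the order the pipeline applies them.

## 1. Time-course ingestion and imputation

Input is a long table `metabolite_id, compartment, time, replicate,
concentration`. Times must be non-negative and unique per
(metabolite, replicate); concentrations must be finite or missing.
Supported time units are hours (`h`, the internal unit) and days
(`day`, converted ×24).

Missing values are imputed with k-nearest-neighbour imputation over
metabolite profiles (scikit-learn `KNNImputer`, `weights="distance"`,
nan-Euclidean metric, default `k = 5`). Distance weighting keeps the
estimate local when coverage is uneven; `k = 5` is a conventional
compromise between bias (large k) and variance (small k) for the
5–50-metabolite panels the package targets. A profile that is entirely
missing cannot be imputed and is rejected.

Pool measurements that aggregate several model species (e.g. a combined
hexose-phosphate peak) can be divided with `apply_pool_splits` using
fixed fractions that must sum to 1.

## 2. Metabolic state discretization

Concentration dynamics are modeled as piecewise linear in time: within
one *metabolic state* every metabolite changes at a constant rate.
Windows are found on the first principal component of the z-scored
concentration matrix with an exact dynamic program minimizing total SSE
of per-segment line fits (each segment ≥ 3 time points).

The number of segments, unless pinned with `n_states`, is chosen by a
scree-style elbow rule: an extra segment is accepted only if it

* at least halves the remaining SSE (`SSE(k+1) ≤ 0.5 · SSE(k)`), **and**
* explains at least 10% of the total PC1 variance (`SSE(k) − SSE(k+1) ≥ 0.1 · SST`).

The two conditions play different roles. The halving condition rejects
incremental noise-chasing splits; the absolute condition stops the count
from growing on flat, noise-dominated courses where tiny SSEs can still
be "halved". Both thresholds were fixed a priori; noiseless two-state
courses are split exactly and flat courses always yield one state.
Discretization is invariant to translating the time axis.

## 3. Rate estimation

Within each window, each metabolite's rate is the ordinary
least-squares slope of concentration against time over all replicates,
with a two-sided t confidence interval at level `1 − alpha`
(default `alpha = 0.05`, i.e. 95% CI):

```
[b1, b2] = slope ± t_{1−alpha/2, n−2} · SE(slope)
```

A rate is *significant* when its CI excludes zero; only significant
rates constrain the model (a CI that straddles zero carries no usable
direction). Noiseless data yields a degenerate CI equal to the slope.
On simulated noisy windows the empirical coverage of the 95% CI is
0.948 (1000 windows, n = 10), consistent with nominal.

## 4. Unsteady model construction

For each state window:

* every significant rate `[b1, b2]` of metabolite `i` adds a pseudo-reaction
  `ACC_i: i →` (stoichiometry −1) with bounds `[b1, b2]`, so the net
  production `(S v)_i` is forced into the measured interval;
* all exchange reactions are removed — the system is closed, and traffic
  across the boundary appears only through measured extracellular
  accumulation terms;
* optional growth bounds pin the objective reaction to an observed rate
  interval, and declared *reserve* metabolites receive unbounded
  reservoir reactions (`RESERVE_i`, ±1000).

The matched **FBA control** applies only the extracellular rates as
integrated exchange constraints, keeps intracellular nodes at steady
state, and grants every *unmeasured* extracellular metabolite a
secretion-only efflux `EFFLUX_i ∈ [0, 1000]` — the conventional
"products may leave" assumption. On data generated at steady state the
two formulations are equivalent: their FVA envelopes agree to < 1e-6 and
their sampled flux distributions are statistically indistinguishable.

## 5. Node relaxation

Partial metabolome coverage generally makes the closed system
infeasible: unmeasured pools must be allowed to change. Candidate sinks
`RELAX_UP_i : i →` and `RELAX_DOWN_i : → i` (each `[0, 1000]`) are added
at every unmeasured node (skipping measured nodes, reserves and free
effluxes), with deviation `d_i` = total sink usage at node `i`. Five
formulations choose which nodes to open:

| case | objective | class |
|---|---|---|
| 1 | number of relaxed nodes | MILP |
| 2 | `Σ d_i` | LP |
| 3 | `Σ d_i + Σ v_j` | LP |
| 4 | `Σ d_i²` | QP |
| 5 | `Σ d_i² + Σ v_j²` | QP |

Case 1 is the default: it asks the minimal *biological* question (how
many pools must really be off steady state) and its answer is exactly
verifiable — on 50 random networks the MILP reproduces the minimum
cardinality and only truly optimal supports of an exhaustive
subset-feasibility search (agreement 50/50).

Alternative optima are enumerated with integer cuts (up to `iterations`,
default 100, with a `time_limit` of 45 s and relative `gap_tol` 1e-6 per
solve); each node's selection frequency `f_i` across optima is recorded.
The LP/QP cases add `LP_BINARY_EPS = 1e-4` times the indicator sum to
break ties toward sparse supports without perturbing the magnitude
objective materially.

**Finalization** re-solves a weighted cardinality problem with cost
`1 − f_i + FINAL_EPS` (`FINAL_EPS = 1e-3`), preferring nodes that were
selected often; the strictly positive floor keeps every node's cost
positive so the solution stays minimal. With `exo_preference` the cost of
extracellular nodes is halved — when an intracellular and an
extracellular relaxation explain the data equally well, unmeasured
secretion is the more parsimonious biology.

**Magnitude fixing**: with the final support fixed, the total deviation
is minimized to get per-node minimal magnitudes `d_i*`, and each retained
sink is capped at `[0, scale · d_i*]`. The default `scale = 1.5` grants
50% headroom over the bare minimum. Sampled flux rankings are
insensitive to this choice once it clears the minimum (Spearman ≥ 0.95
between scales 1.5, 5 and 10 over three generator seeds) whereas pinning
capacity at `scale = 1.0` measurably distorts them (Spearman ≤ 0.98
against 1.5, strictly below the headroom-group agreement) — the bare
minimum leaves no slack for routes that trade off against the relaxed
node.

QP subproblems are solved with OSQP (`polishing=True` for high-accuracy
active sets, `eps_abs = eps_rel = 1e-9`).

Infeasibility that survives all candidate relaxations raises
`InfeasibleDataError`: the measured rates are inconsistent with the
stoichiometry itself (wrong signs, wrong network), not with coverage.

## 6. Flux analysis

* **FVA** per reaction at `fraction_of_optimum = 0`, via `cobra`.
* **Sampling** uses artificial centering hit-and-run (ACHR) in nullspace
  coordinates: directions are drawn in `null(S)` (so `S v = 0` is
  maintained exactly, to ~1e-15), the chain is warm-started from FVA
  vertices, and convergence is monitored with the mixed fraction — the
  proportion of first-half/second-half sample pairs on the same side of
  the per-reaction median, 0.5 for a mixed chain. Sampling rounds double
  the thinning (initial 100, max 4 rounds) until the mixed fraction is
  ≤ 0.54. Polytopes with an infinite bound are rejected. On polytopes
  with closed-form moments, sample means fall within 3 standard errors
  of exact values, with SEs computed by batch means (30 batches) to
  account for chain autocorrelation.
* **Comparison** of two sampled models (e.g. uFBA vs FBA control) uses
  per-reaction distribution overlap on shared, loop-free reactions; a
  reaction differs significantly when the overlap is < 5%. Internal
  thermodynamically infeasible loops (fluxes possible in a closed model)
  are detected and excluded first.
* **Essentiality** disables each gene in turn (evaluating gene rules),
  re-maximizes growth, and calls a gene essential if the optimum drops
  below 1% of the reference growth. On an unsteady model the screen runs
  on a copy with forced accumulation bounds widened to include zero and
  efflux opened, so "no growth" remains expressible after a lethal
  knockout.

## 7. Synthetic data generator

The generator produces closed-loop test beds: a toy network, one or more
true flux states, piecewise-linear noiseless concentration trajectories
(`C(t) = C0 + (S v) · Δt`, accumulated across states), multiplicative
Gaussian replicate noise (relative SD `noise_sd`, default 5%, 5
replicates, 10 time points per state), optional uniform missingness
(never erasing a whole profile), and a restriction to a declared
*measured* subset — partial coverage is the default condition.

It emulates: well-replicated batch fermentations with distinct metabolic
phases, drained intracellular pools, overflow byproduct routes, and
cofactor stores that rescue growth. It does **not** emulate: kinetics
within a state (rates are piecewise constant by construction),
measurement drift or batch effects, compartment volume changes, or
degradation of metabolites outside the network.

Named motifs: `pool_depletion` (intracellular malate pool drives MDH
backwards; includes a capacity-limited overflow route whose activity
depends on downstream sink headroom), `cofactor_rescue` (a measured
depleting cofactor pool rescues a biosynthesis gene that the
steady-state control calls essential; unmeasured, the rescue disappears),
`twin_pathway` (two symmetric outlets — the relaxation has exactly two
alternative optima), `negative_control` (true steady state),
`chain_two_state` (one known internal state boundary).
`make_random_instance` builds random irreversible networks (≤ 20
reactions, ≤ 12 unmeasured metabolites) around a strictly positive flux
vector for relaxation stress tests with exhaustively verifiable answers.

## 8. Reproducibility

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; child seeds are spawned as
`default_rng([seed, salt])` so adding a new analysis never shifts the
streams of existing ones. CLI artifacts are stamped with the package
version and a 12-hex-digit SHA-256 hash of the effective configuration
(excluding the output directory, which is a location rather than a
parameter); the event log contains no timestamps. Identical inputs and
seeds therefore reproduce every artifact bit for bit.
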