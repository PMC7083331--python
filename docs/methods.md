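# Methods

## Model family

All models are absorbing continuous-time Markov chains over cell states.
A cell starts in the first (epithelial) state and is driven irreversibly —
optionally with a backward rate — toward the absorbing mesenchymal state M.
Time is measured in days throughout; all rates are 1/day.

**Arrhenius rates.** Each transition step crosses an energy barrier δE
(units of k_B·T) at rate k = k0·e^(−δE). The total barrier ΔE from E to M
divides evenly over the steps of a path: a chain with N_int intermediates
has per-step rate k0·e^(−ΔE/(N_int+1)). The attempt rate k0 defaults to
1/day; when a calibration (k_fit, N_fit) is supplied, k0 = k_fit·e^(ΔE/(N_fit+1)),
which makes the N_fit-intermediate chain reproduce the fitted step rate
exactly at every ΔE. The shipped default calibration, k_fit = 3.4261/day at
N_fit = 9, is the best-fit step rate of the MCF10A TGF-β induction time
course that motivates the model family.

**Topologies.**

* *Chain*: E → I₁ → … → I_N → M, uniform rate. Occupancy of the n-th
  microstate is the Poisson-weighted term e^(−kt)(kt)^(n−1)/(n−1)!; the
  arrival time at M is Erlang(N_int+1, k), MFAT = (N_int+1)/k.
* *Parallel*: the initial state feeds N_pth disjoint chains; the N_int
  intermediates split as evenly as possible (sizes ascending; only the
  multiset matters for every computed quantity — the ordering is a
  formatting convention, and is tested as such). Path i runs at
  k_i = k0·e^(−ΔE/(N_i+1)); the initial exit is aggregate, k_A = Σk_i. The
  division of ΔE within each path mirrors the chain rule per path; since
  each path realizes the full E→M transition, each divides the same total
  barrier over its own steps. MFAT = (1 + ΣN_i)/k_A by first-step
  analysis: Exp(k_A) to leave E, then N_i further steps at k_i with
  probability k_i/k_A, giving 1/k_A + Σᵢ (k_i/k_A)(N_i/k_i).
* *Layered*: N_ly sequential layers, remainder states assigned to the
  earliest layers (so N_L1 = ⌈N_int/N_ly⌉). Every state advances at the
  same k = k0·e^(−ΔE/(N_ly+1)); the initial state fans out at N_L1·k.
  MFAT = (N_ly + 1/N_L1)/k. Only layer-aggregate occupancy is computed
  analytically — the closed forms depend on the wiring solely through
  (N_L1, N_ly, k); the stochastic simulator wires explicit states (state j
  of a layer feeds state min(j, next-width−1) of the next).
* *Stabilized chain*: one intermediate S exits at k2 < k1 (barrier ratio
  m ≥ 1). Two bookkeeping cases: **constant total** (regular steps
  k1 = k0·e^(−ΔE/(N+m)), stabilized step k2 = k0·e^(−ΔE·m/(N+m)); barriers
  still sum to ΔE) and **varying total** (k1 keeps the uniform-chain
  value, k2 = k0·e^(−ΔE·m/(N+1)); the path barrier grows to
  ΔE + (m−1)ΔE/(N+1)). Mean dwelling time in S is 1/k2;
  MFAT to M is N_int/k1 + 1/k2.

**Two MFAT-to-the-stabilized-state conventions.** Arrival at S requires S
rate-k1 steps — an Erlang(S, k1) time with mean S/k1, which the stochastic
simulator confirms and which is the default. An alternative (S+1)/k1
convention, counting states rather than steps, circulates in the
literature of this model family; it is exposed via `convention="offset"`
rather than silently chosen.

**Parallel MFAT closed form.** A published form of the parallel MFAT,
(Σk_i + N_i·k_A)/k_A², is dimensionally coherent only if N_i denotes the
*total* intermediate count, in which case it reduces algebraically to
(1 + ΣN_i)/k_A (because Σk_i = k_A). The implementation uses the
first-step-analysis form; the literal per-path reading is exposed as
`mfat_printed` and differs (e.g. 1.0 vs the correct 1.5 days for two
single-state paths at unit rates, confirmed by Monte Carlo).

## Numerics

* **Chain occupancies** are evaluated in log space
  (xlogy − gammaln), and the absorbed mass via the regularized lower
  incomplete gamma, so kt ≫ 700 stays finite.
* **Branched occupancies**: the textbook alternating truncated-exponential
  sums cancel catastrophically for large (k_A − k_i)t. They are evaluated
  in the equivalent all-positive form
  pref·(bt)^n/n!·e^(−bt)·₁F₁(1; n+1; −(a−b)t) (Kummer transform of the
  confluent hypergeometric), log-space prefactor. The chain limit a = b is
  the removable value ₁F₁(·;·;0) = 1, so no special-casing is needed.
* **Stabilized occupancies**: states after S are a signed difference of
  two positive terms, each computed in log space with the regularized
  incomplete gamma (a leading-order series substitutes where the gamma
  underflows). Below a relative rate gap |k1−k2|/k1 < 1e-9 the uniform
  chain is used outright (the m → 1 limit; continuity verified against
  the matrix-exponential oracle).
* **Three-state model**: the removable k1 = k2 singularity switches to the
  confluent limit p_P = k1·t·e^(−k1·t) below the same relative gap.
* **Reversible chains** are solved by uniformization: e^(At) as a
  Poisson-weighted power series of P = I + A/q, truncated when the
  accumulated Poisson mass exceeds 1 − 1e-12 and renormalized onto the
  simplex. Every iterate is a probability vector, so the series cannot
  lose positivity. The backward rate acts on all interior states; the last
  column of the generator is zero (M absorbing, also in the reversible
  model).
* **FAT quadrature** uses adaptive Gauss–Kronrod on density callables over
  [0, ~50–80 mean lifetimes] (tail mass < 1e-9); grid-sampled densities are
  mass-checked by Simpson's rule at tolerance 1e-6.
* **Tie-breaks**: fitting grid ties (within 1e-10 RMSE) resolve toward
  smaller N_E + N_P, then smaller N_E (parsimony). The Gillespie
  transition choice uses strict-left/inclusive-right on the cumulative
  propensity (a measure-zero convention).

## Stochastic simulator

Exact SSA per cell: waiting time Exp(total propensity), transition by the
cumulative-propensity rule, until absorption or the horizon T_max
(recommended ≈ 50× the analytic MFAT, making censoring negligible;
censored cells are excluded from FAT statistics and counted). Cell i draws
from the substream seeded by (seed, i), so ensembles are reproducible and
enlarging n_cells never reshuffles existing trajectories.

## Fitting procedure

Inputs are macrostate percent curves (columns time, frac_E, frac_P,
frac_M; rows summing to 100). For each (N_E, N_P) on the grid (defaults
N_E ∈ 1..10, N_P ∈ 0..10; N_P = 0 is the two-macrostate model), the first
N_E microstates map to E, the next N_P to P, the absorbing state to M, and
the step rate is optimized by bounded log-scale scalar minimization
(bounds 1e-3..1e3/day, xatol 1e-10) of the pooled RMSE — equal weights
over all three macrostates and all time points, no interpolation (the
model is evaluated exactly at the data's times). The reversible variant
optimizes (k1, k_−1) by bounded Nelder–Mead from three log-space starts.
Rates pinned at a search bound flag the result as a boundary solution
(e.g. degenerate all-epithelial input drives k to the lower bound).

The search bounds and the pooled-equal-weight RMSE are package choices:
the convention for pooling the three curves is not uniquely determined by
the problem, and reported RMSEs are comparable only under the same
convention.

## Synthetic data generator

Emulates a TGF-β induction assay read out at the population level:
defaults are the truth (N_E = 5, N_P = 5, k = 3.4261/day), nine daily
samples over days 0–8, and 10⁴ cells scored per time point — the regime of
the motivating MCF10A fit; the true sampling days and depths of that
experiment are not published, so these are stated assumptions (recorded in
the file header of written tables). Noise is multinomial per time point
(not independent binomials), so fractions sum to 100 exactly; day 0 is
exactly (100, 0, 0). A `source="gillespie"` mode draws the fractions from
a simulated ensemble instead of the exact probabilities.

What passing the recovery tests shows: the fitting procedure is consistent
under its own sampling assumptions at realistic depth. What it does not
show: robustness to classifier error in macrostate calls, batch effects,
non-multinomial overdispersion, or misspecified topologies — real data
carry all of these.

## Problem sizes

Test and acceptance runs use 10⁴-cell ensembles, 20-seed recovery studies,
oracle checks on ≤ 10-state systems, and 100–300-point sweep grids — sizes
at which the Monte Carlo standard errors are a few percent of the checked
quantities and the whole suite completes in well under a minute of compute
per component; all are parameters, not limits.

## Known limitations and open edges

* The small-barrier (ΔE ≤ 1) stabilized sweeps show essentially no
  dependence of MFAT on the barrier ratio m: the m-derivative vanishes at
  m = 1 and the spread over m ∈ [1, 8] is below 1% in both barrier cases,
  calibrated or not. A qualitative reversal of the m-dependence in this
  regime has been described for this model family; it does not emerge from
  these closed forms, and the package documents the flatness instead of
  asserting either direction.
* Parallel paths of unequal length each divide the full ΔE over their own
  steps; this is the natural reading of the even-division rule per path,
  but other apportionments (e.g. proportional to path length) are
  conceivable and would change k_i.
* Mixed topologies (layered segments inside parallel paths), multiple
  simultaneously stabilized states, and backward flow out of M are out of
  scope.
* The Gillespie simulator is exact but per-cell Python; it is comfortable
  at 10⁴–10⁵ cells on small networks and is not tuned for much larger
  ensembles (tau-leaping is deliberately not implemented).
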