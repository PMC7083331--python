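# emtkinetics

Multi-state continuous-time Markov models of the epithelial-to-mesenchymal
transition (EMT): analytic first-arrival-time kinetics for chain, parallel,
layered and stabilized-state topologies under an Arrhenius energy-barrier
rate model, an exact Gillespie single-cell simulator, and hidden-microstate
model fitting for population time courses.

## The problem

During EMT, epithelial cells pass through one or more partial (hybrid)
phenotypes before reaching the mesenchymal state. Population measurements
only resolve three observable **macrostates** — epithelial (E), partial EMT
(P) and mesenchymal (M) — yet their kinetics are distinctly
non-exponential: cells linger in E and P far longer than a three-state
Markov chain allows. The resolution is hidden **microstates**: each
macrostate contains several unobserved substates, so the waiting time to
leave a macrostate is Erlang-like rather than exponential, and EMT at the
macrostate level is a non-Markov process.

This package is for systems biologists who want to (a) fit hidden-state
counts and transition rates to macrostate fraction time courses, and
(b) explore how the *architecture* of the transition network — the number
of intermediate states, parallel routes, layers, or a kinetically trapped
("stabilized") intermediate — shapes the speed of EMT.

## The model

A cell crosses a total energy barrier ΔE (units of k_B·T) from E to M.
With N_int intermediate states the barrier divides evenly over the
N_int + 1 steps, giving the Arrhenius step rate

    k = k0 · exp(−ΔE / (N_int + 1)),

with attempt rate k0 (1/day) anchored to data through the calibration
k_fit = k0·exp(−ΔE/(N_fit+1)) (best fit to an MCF10A TGF-β induction time
course: k_fit = 3.4261/day at N_fit = 9). The first arrival time (FAT) at
M is then Erlang(N_int+1, k) with mean

    MFAT = (N_int + 1) / (k0 · e^{−ΔE/(N_int+1)}),

which trades path length against per-step barrier height and is minimized
near N_int + 1 ≈ ΔE: adding intermediate states *accelerates* EMT whenever
the total barrier is steep enough. Parallel paths (path i with N_i
intermediates at rate k_i, aggregate exit k_A = Σk_i, MFAT = (1+ΣN_i)/k_A)
and layered arrangements (N_ly layers, N_L1-wide first layer,
MFAT = (N_ly + 1/N_L1)/k) generalize the chain as hypoexponential
phase-type processes. A stabilized intermediate with an m-fold exit
barrier exits at k2 < k1 and traps cells with mean dwelling time
D_S = 1/k2, delaying arrival at M (MFAT = N_int/k1 + 1/k2).

Fitting inverts this picture: given percent-of-cells-in-E/P/M curves, a
grid search over (N_E, N_P) hidden-state counts with a rate optimized per
cell, scored by pooled RMSE, recovers the hidden architecture.

## Worked example

```python
import numpy as np
from emtkinetics import (CalibrationSpec, EnergyConfig, TopologySpec,
                         calibrate_k0, step_rates, fat_mfat_chain, mfat_surface,
                         GeneratorSpec, generate_timecourse, fit_irreversible)

cal = CalibrationSpec(k_fit=3.4261, N_fit=9)
k0 = calibrate_k0(10.0, cal)                  # attempt rate at barrier 10
k = step_rates(EnergyConfig(10.0, k0), TopologySpec("chain", 9)).step_rates[0]
print(f"k0 at dE=10: {k0:.4f} /day")
print(f"per-step rate: {k:.4f} /day")
print(f"MFAT: {fat_mfat_chain(k, 9).mfat:.4f} days")
_, argmin = mfat_surface([10.0], np.arange(0, 101), cal)
print(f"optimal N_int at dE=10: {int(argmin['argmin_N_int'].iloc[0])}")

data = generate_timecourse(GeneratorSpec(seed=1))   # synthetic 10^4-cell assay
res = fit_irreversible(data)
print(f"fit: N_E={res.N_E}, N_P={res.N_P}, k={res.rates['k']:.4f} /day, "
      f"RMSE={res.rmse:.3f}%")
```

Output:

```
k0 at dE=10: 9.3131 /day
per-step rate: 3.4261 /day
MFAT: 2.9188 days
optimal N_int at dE=10: 9
fit: N_E=5, N_P=5, k=3.4421 /day, RMSE=0.143%
```

Reading: with the attempt rate calibrated so that a 9-intermediate chain
under barrier 10 runs at the fitted step rate 3.4261/day, the mean time to
complete EMT is 2.92 days, and 9 intermediates is in fact the optimal
chain length at that barrier. The grid fit applied to a synthetic
10⁴-cell daily time course generated from the (N_E = 5, N_P = 5) truth
recovers the hidden-state counts exactly and the rate to 0.5%, with a
residual RMSE of 0.14 percentage points (pure multinomial sampling noise).

The fitters are scikit-learn estimators (`IrreversibleChainEMT`,
`ReversibleChainEMT`) with `fit(X, y)` / `predict(X)` /
`get_params`, so they compose with sklearn model-selection tooling;
`fit_irreversible` / `fit_reversible` are convenience wrappers.

A CLI mirrors the computational experiments
(`emtkin chain-mfat|parallel|layered|compare|stabilized|fit|simulate|synth
--config cfg.yaml --out outdir`), writing delimited tables plus a
reproducibility manifest per run.

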