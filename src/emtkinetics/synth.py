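"""Synthetic population time courses with the statistical structure the
fitting procedure assumes.

The generator emulates a TGF-beta induction experiment read out daily at
the population level: all cells epithelial at day 0, monotone conversion
through partial EMT into the mesenchymal state, and multinomial counting
noise from scoring a finite number of cells per time point. Defaults mirror
the regime of the MCF10A best fit: truth (N_E = 5, N_P = 5, k = 3.4261/day),
nine daily samples over days 0-8, 10^4 cells scored per time point.

What it does *not* emulate: marker-intensity distributions, batch effects,
or cell-cell interactions — fractions are drawn i.i.d. per time point from
the exact (or simulated) macrostate probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chain import (
    ReversibleParams,
    chain_macrostate_map,
    erlang_occupancy,
    reversible_occupancy,
)
from .config import EnergyConfig, TopologySpec
from .gillespie import SimConfig, build_transition_system, simulate_cells, summarize_ensemble
from .rates import step_rates
from .results import MACROSTATES, TimecourseData

__all__ = ["GeneratorSpec", "generate_timecourse", "write_timecourse", "read_timecourse"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Ground truth and sampling design of a synthetic time course.

    ``rates`` is ``{"k": ...}`` (irreversible) or ``{"k_fwd": ..., "k_bwd": ...}``
    (reversible). ``n_cells = None`` gives noiseless fractions; otherwise each
    time point is an independent multinomial draw of ``n_cells`` cells.
    ``source = "gillespie"`` replaces the analytic probabilities with an
    empirical ensemble of simulated single cells.
    """

    N_E: int = 5
    N_P: int = 5
    rates: dict = field(default_factory=lambda: {"k": 3.4261})
    reversible: bool = False
    times: tuple[float, ...] = tuple(float(d) for d in range(9))
    n_cells: int | None = 10_000
    seed: int = 0
    source: str = "analytic"

    def __post_init__(self) -> None:
        if self.times[0] != 0:
            raise ValueError("sampling times must start at day 0")
        if self.n_cells is not None and self.n_cells < 1:
            raise ValueError("n_cells must be >= 1 when noise is enabled")
        if self.source not in ("analytic", "gillespie"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.N_E < 1 or self.N_P < 0:
            raise ValueError("need N_E >= 1 and N_P >= 0")


def _analytic_macro_probs(spec: GeneratorSpec, t: np.ndarray) -> np.ndarray:
    n_int = spec.N_E + spec.N_P - 1
    macro = chain_macrostate_map(n_int, N_E=spec.N_E)
    if spec.reversible:
        occ = reversible_occupancy(
            ReversibleParams(spec.rates["k_fwd"], spec.rates["k_bwd"]),
            n_int + 2,
            t,
            macrostate_map=macro,
        )
    else:
        occ = erlang_occupancy(spec.rates["k"], n_int, t, macrostate_map=macro)
    return occ.macrostate_fractions(percent=False)[["frac_E", "frac_P", "frac_M"]].to_numpy()


def _gillespie_macro_probs(spec: GeneratorSpec, t: np.ndarray) -> np.ndarray:
    if spec.reversible:
        raise NotImplementedError("gillespie source supports the irreversible chain")
    n_int = spec.N_E + spec.N_P - 1
    k = spec.rates["k"]
    topo = TopologySpec(variant="chain", N_int=n_int)
    energy = EnergyConfig(delta_E=0.0, k0=k)  # uniform rate k on every step
    sys = build_transition_system(topo, step_rates(energy, topo))
    n_cells = spec.n_cells or 10_000
    cfg = SimConfig(n_cells=n_cells, T_max=max(50 * (n_int + 1) / k, float(t[-1]) + 1), seed=spec.seed)
    summ = summarize_ensemble(simulate_cells(sys, cfg), t, n_states=sys.n_states)
    macro = chain_macrostate_map(n_int, N_E=spec.N_E)
    out = np.column_stack(
        [summ.fractions[:, macro == m].sum(axis=1) for m in MACROSTATES]
    )
    return out


def generate_timecourse(spec: GeneratorSpec) -> TimecourseData:
    """Generate a macrostate percent time course from a ground-truth model.

    Analytic source: exact chain macrostate probabilities, optionally
    multinomially sampled at ``n_cells`` per time point (so fractions always
    sum to 100). Gillespie source: empirical fractions of a simulated
    ensemble (already finite-sample). Deterministic under a fixed seed; the
    day-0 row is exactly (100, 0, 0).
    """
    t = np.asarray(spec.times, dtype=float)
    if spec.source == "analytic":
        probs = _analytic_macro_probs(spec, t)
        if spec.n_cells is None:
            fractions = 100.0 * probs
        else:
            rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 2**20]))
            counts = np.empty_like(probs)
            for i in range(t.size):
                p = np.clip(probs[i], 0, None)
                p = p / p.sum()
                counts[i] = rng.multinomial(spec.n_cells, p)
            fractions = 100.0 * counts / spec.n_cells
    else:
        fractions = 100.0 * _gillespie_macro_probs(spec, t)
    # the initial condition is exact by construction
    fractions[0] = (100.0, 0.0, 0.0)
    return TimecourseData(times=t, fractions=fractions, n_cells=spec.n_cells)


def write_timecourse(data: TimecourseData, path, spec: GeneratorSpec | None = None) -> None:
    """Write the delimited time-course format (metadata as '#' comments)."""
    with open(path, "w") as fh:
        if spec is not None:
            fh.write(f"# generator: N_E={spec.N_E} N_P={spec.N_P} rates={spec.rates} "
                     f"reversible={spec.reversible}\n")
            fh.write(f"# sampling: n_cells={spec.n_cells} seed={spec.seed} source={spec.source}\n")
            fh.write("# note: synthetic data; sampling days and depths are assumptions\n")
        data.to_frame().to_csv(fh, index=False)


def read_timecourse(path) -> TimecourseData:
    """Read the delimited format written by :func:`write_timecourse`."""
    df = pd.read_csv(path, comment="#")
    required = ["time", "frac_E", "frac_P", "frac_M"]
    if list(df.columns[:4]) != required:
        raise ValueError(f"expected header {required}, got {list(df.columns)}")
    return TimecourseData(
        times=df["time"].to_numpy(),
        fractions=df[["frac_E", "frac_P", "frac_M"]].to_numpy(),
    )
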