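"""Chain kinetics with one stabilized intermediate state.

A stabilized intermediate (index ``S`` among the ``N_int`` intermediates)
has an ``m``-fold larger exit barrier than the regular steps, so cells exit
it at ``k2 < k1`` and are trapped in that partial-EMT phenotype. Two barrier
bookkeeping cases exist (see :class:`~emtkinetics.config.StabilizedSpec`):
the total barrier either stays fixed (regular steps get easier) or grows.

Occupancies are pure phase-type expressions. With arrival into state ``n``
a convolution of ``Exp``/``Erlang`` stages, they evaluate stably as

* ``n < S``:  Poisson term ``(k1 t)^n e^{-k1 t} / n!``
* ``n = S``:  ``(k1/(k1-k2))^S e^{-k2 t} P(S, (k1-k2) t)``
* ``n > S``:  ``k2/(k1-k2) [ (k1/(k1-k2))^{n-1} e^{-k2 t} P(n-1, (k1-k2)t)
  - e^{-k1 t} (k1 t)^{n-1}/(n-1)! ]``

with ``P`` the regularized lower incomplete gamma; prefactors are taken in
log space so near-degenerate ``k1 - k2`` cannot overflow. Below a relative
rate gap of 1e-9 the uniform-chain (``m = 1``) solution is used outright.

Headline scalar summaries: the mean dwelling time in the stabilized state is
``D_S = 1/k2``; the mean first arrival at M is ``N_int/k1 + 1/k2``; the mean
first arrival at the stabilized state itself is the Erlang(S, k1) mean
``S/k1`` (an alternative ``(S+1)/k1`` indexing convention, counting the
epithelial exit as step one of S+1, is exposed via ``convention="offset"``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from ._util import default_time_grid
from .chain import chain_macrostate_map, erlang_occupancy, fat_mfat_chain
from .config import CalibrationSpec, EnergyConfig, StabilizedSpec, TopologySpec
from .rates import calibrate_k0, step_rates
from .results import FATSummary, OccupancyGrid

__all__ = [
    "StabilizedChain",
    "stabilized_chain",
    "stabilized_occupancy",
    "stabilized_fat",
    "mfat_to_mesenchymal",
    "mfat_to_stabilized",
    "mean_dwelling_time",
    "stabilized_sweep",
]

_UNIFORM_RTOL = 1e-9


@dataclass(frozen=True)
class StabilizedChain:
    """A chain of ``N_int`` intermediates with one slow exit at index ``S``."""

    N_int: int
    S: int
    k1: float
    k2: float
    case: str = "constant_total"
    m: float | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.S <= self.N_int):
            raise ValueError(f"need 1 <= S <= N_int, got S={self.S}, N_int={self.N_int}")
        if not (self.k1 > 0 and self.k2 > 0):
            raise ValueError("rates must be > 0")
        if self.k2 > self.k1 * (1 + 1e-12):
            raise ValueError("a stabilized state requires k2 <= k1")

    @property
    def is_uniform(self) -> bool:
        return abs(self.k1 - self.k2) / self.k1 < _UNIFORM_RTOL


def stabilized_chain(energy: EnergyConfig, N_int: int, stab: StabilizedSpec) -> StabilizedChain:
    """Build the (k1, k2) chain implied by an energy config and barrier ratio."""
    topo = TopologySpec(variant="chain", N_int=N_int)
    ra = step_rates(energy, topo, stab)
    k2 = ra.step_rates[stab.S]
    k1 = ra.step_rates[0]
    return StabilizedChain(N_int=N_int, S=stab.S, k1=k1, k2=k2, case=stab.case, m=stab.m)


def _log_gammainc(a: float, x: np.ndarray) -> np.ndarray:
    """log of the regularized lower incomplete gamma, underflow-safe."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        val = special.gammainc(a, x)
        out = np.log(val)
    # leading-order series where the direct value underflows
    tiny = (val == 0.0) & (x > 0)
    if np.any(tiny):
        xt = x[tiny]
        out[tiny] = a * np.log(xt) - xt - special.gammaln(a + 1.0)
    out = np.where(x <= 0, -np.inf, out)
    return out


def _occupancy_matrix(chain: StabilizedChain, t: np.ndarray) -> np.ndarray:
    """(T, N_int + 2) occupancy: E, intermediates 1..N_int, M."""
    N, S, k1, k2 = chain.N_int, chain.S, chain.k1, chain.k2
    t = np.asarray(t, dtype=float)
    cols = [np.exp(-k1 * t)]
    # pre-stabilized: uniform-k1 Poisson terms
    for n in range(1, S):
        logp = special.xlogy(n, k1 * t) - k1 * t - special.gammaln(n + 1.0)
        cols.append(np.exp(logp))
    ct = (k1 - k2) * t
    log_ratio = math.log(k1) - math.log(k1 - k2)
    # stabilized state S
    log_pS = S * log_ratio - k2 * t + _log_gammainc(S, ct)
    cols.append(np.exp(log_pS))
    # post-stabilized states
    log_pref = math.log(k2) - math.log(k1 - k2)
    for n in range(S + 1, N + 1):
        log_t1 = log_pref + (n - 1) * log_ratio - k2 * t + _log_gammainc(n - 1.0, ct)
        log_t2 = log_pref + special.xlogy(n - 1, k1 * t) - k1 * t - special.gammaln(float(n))
        cols.append(np.exp(log_t1) - np.exp(log_t2))
    probs = np.column_stack(cols)
    p_M = 1.0 - probs.sum(axis=1)
    return np.column_stack([probs, np.clip(p_M, 0.0, 1.0)])


def stabilized_occupancy(chain: StabilizedChain, times, macrostate_map=None) -> OccupancyGrid:
    """Closed-form occupancy of the stabilized chain on a time grid."""
    t = np.asarray(times, dtype=float)
    if chain.is_uniform:
        return erlang_occupancy(chain.k1, chain.N_int, t, macrostate_map=macrostate_map)
    probs = _occupancy_matrix(chain, t)
    if macrostate_map is None:
        macrostate_map = chain_macrostate_map(chain.N_int, N_E=1)
    names = ("E",) + tuple(f"I{i}" for i in range(1, chain.N_int + 1)) + ("M",)
    return OccupancyGrid(
        times=t, probs=probs, macrostate_map=np.asarray(macrostate_map), state_names=names
    )


def _fat_density_fn(chain: StabilizedChain):
    exit_rate = chain.k2 if chain.S == chain.N_int else chain.k1

    def density(t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        probs = _occupancy_matrix(chain, t)
        return exit_rate * probs[:, chain.N_int]  # last intermediate column

    return density


def stabilized_fat(chain: StabilizedChain, times=None) -> FATSummary:
    """FAT density to M (exit flux of the last intermediate) and its mean."""
    if chain.is_uniform:
        return fat_mfat_chain(chain.k1, chain.N_int, times)
    mfat = mfat_to_mesenchymal(chain)
    if times is None:
        times = default_time_grid(mfat)
    t = np.asarray(times, dtype=float)
    return FATSummary(times=t, density=_fat_density_fn(chain)(t), mfat=mfat)


def mfat_to_mesenchymal(chain: StabilizedChain) -> float:
    """Mean first arrival at M: N_int steps at k1 plus the one slow k2 exit."""
    return chain.N_int / chain.k1 + 1.0 / chain.k2


def mfat_to_stabilized(chain: StabilizedChain, convention: str = "erlang") -> float:
    """Mean first arrival at the stabilized state.

    Arrival at state S requires S rate-k1 steps, an Erlang(S, k1) time with
    mean ``S/k1`` (``convention="erlang"``, default). The alternative
    ``(S+1)/k1`` counts states rather than steps (``convention="offset"``);
    both are exposed because the two indexing conventions circulate, and the
    stochastic simulator in the test suite arbitrates for the default.
    """
    if convention == "erlang":
        return chain.S / chain.k1
    if convention == "offset":
        return (chain.S + 1) / chain.k1
    raise ValueError(f"unknown convention {convention!r}")


def mean_dwelling_time(chain: StabilizedChain) -> float:
    """Mean sojourn in the stabilized state: D_S = 1/k2 exactly."""
    if not (chain.k2 > 0):
        raise ValueError("k2 must be > 0")
    return 1.0 / chain.k2


def stabilized_sweep(
    N_int: int,
    S: int,
    m_grid,
    delta_E_grid,
    case: str = "constant_total",
    cal: CalibrationSpec | None = None,
    k0: float = 1.0,
) -> pd.DataFrame:
    """Dwelling time and MFAT-to-M over a (m, delta_E) grid.

    If ``cal`` is given the attempt rate is re-calibrated per barrier value,
    otherwise the fixed ``k0`` is used. Columns: m, delta_E, dwell_time,
    mfat_m.
    """
    ms = np.atleast_1d(np.asarray(m_grid, dtype=float))
    dEs = np.atleast_1d(np.asarray(delta_E_grid, dtype=float))
    if ms.size == 0 or dEs.size == 0:
        raise ValueError("grids must be nonempty")
    rows = []
    for m in ms:
        for dE in dEs:
            k0_eff = calibrate_k0(float(dE), cal) if cal is not None else k0
            energy = EnergyConfig(delta_E=float(dE), k0=k0_eff)
            chain = stabilized_chain(energy, N_int, StabilizedSpec(S=S, m=float(m), case=case))
            rows.append((float(m), float(dE), mean_dwelling_time(chain), mfat_to_mesenchymal(chain)))
    return pd.DataFrame(rows, columns=["m", "delta_E", "dwell_time", "mfat_m"])
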