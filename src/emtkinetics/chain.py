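"""Linear-chain kinetics: closed-form occupancies and first-arrival times.

The irreversible chain E -> I_1 -> ... -> I_N -> M with a uniform step rate
``k`` is a pure-birth process: the occupancy of the n-th microstate is the
Poisson-weighted term ``p_n(t) = e^{-kt} (kt)^{n-1} / (n-1)!`` and the
arrival time at M is Erlang(N_int + 1, k) with mean ``(N_int + 1) / k``.
Because the Arrhenius step rate is ``k0 * exp(-dE/(N_int+1))``, the mean
first arrival time (MFAT)

    MFAT(dE, N_int) = (N_int + 1) / (k0 * exp(-dE/(N_int+1)))

trades a longer path against lower per-step barriers, and has an interior
minimum in N_int whenever the total barrier is steep enough (near
``N_int + 1 = dE`` in the continuous relaxation).

A reversible variant (forward ``k1``, backward ``k_-1``, absorbing M) is
solved numerically by uniformization of the tridiagonal generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from ._util import default_time_grid
from .config import CalibrationSpec
from .rates import calibrate_k0
from .results import FATSummary, OccupancyGrid

__all__ = [
    "ThreeStateParams",
    "ReversibleParams",
    "three_state_occupancy",
    "erlang_occupancy",
    "reversible_occupancy",
    "reversible_generator",
    "uniformized_expm",
    "fat_mfat_chain",
    "chain_fat_density",
    "mfat_surface",
    "chain_macrostate_map",
]

# relative rate difference below which the k1 = k2 confluent limit is used
_CONFLUENT_RTOL = 1e-9


@dataclass(frozen=True)
class ThreeStateParams:
    """Rates of the minimal E -> P -> M model (1/day each)."""

    k1: float
    k2: float

    def __post_init__(self) -> None:
        if not (self.k1 > 0 and self.k2 > 0):
            raise ValueError("three-state rates must be > 0")


@dataclass(frozen=True)
class ReversibleParams:
    """Forward/backward step rates of the reversible chain (1/day, >= 0)."""

    k_fwd: float
    k_bwd: float

    def __post_init__(self) -> None:
        if self.k_fwd < 0 or self.k_bwd < 0:
            raise ValueError("reversible rates must be >= 0")


def chain_macrostate_map(N_int: int, N_E: int = 1) -> np.ndarray:
    """Macrostate labels for a chain with ``N_int + 1`` microstates plus M.

    The first ``N_E`` microstates report as epithelial, the remaining
    ``N_int + 1 - N_E`` as partial EMT, the absorbing state as mesenchymal.
    """
    n_micro = N_int + 1
    if not (1 <= N_E <= n_micro):
        raise ValueError(f"need 1 <= N_E <= {n_micro}, got {N_E}")
    return np.array(["E"] * N_E + ["P"] * (n_micro - N_E) + ["M"])


def three_state_occupancy(params: ThreeStateParams, times) -> OccupancyGrid:
    """Closed-form occupancy of the E -> P -> M model.

    p_E = e^{-k1 t};  p_P = k1/(k2-k1) (e^{-k1 t} - e^{-k2 t});
    p_M = 1 - k2/(k2-k1) e^{-k1 t} + k1/(k2-k1) e^{-k2 t}.

    The removable k1 = k2 singularity is handled by the confluent limit
    p_P = k1 t e^{-k1 t}.
    """
    t = np.asarray(times, dtype=float)
    k1, k2 = params.k1, params.k2
    p_E = np.exp(-k1 * t)
    if abs(k1 - k2) / k1 < _CONFLUENT_RTOL:
        p_P = k1 * t * np.exp(-k1 * t)
    else:
        p_P = k1 / (k2 - k1) * (np.exp(-k1 * t) - np.exp(-k2 * t))
    p_M = 1.0 - p_E - p_P
    probs = np.column_stack([p_E, p_P, p_M])
    return OccupancyGrid(
        times=t,
        probs=probs,
        macrostate_map=np.array(["E", "P", "M"]),
        state_names=("E", "P", "M"),
    )


def _poisson_pmf(n: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """exp(n log mu - mu - log n!) evaluated in log space; finite for mu >> 1."""
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = special.xlogy(n, mu) - mu - special.gammaln(n + 1.0)
    out = np.exp(logp)
    # xlogy(0, 0) = 0 so mu = 0 rows are already correct
    return np.where(np.isfinite(out), out, 0.0)


def erlang_occupancy(k: float, N_int: int, times, macrostate_map=None) -> OccupancyGrid:
    """Occupancy of the uniform irreversible chain with ``N_int`` intermediates.

    Microstate n (1-based, n = 1 is the starting epithelial microstate) has
    ``p_n(t) = e^{-kt}(kt)^{n-1}/(n-1)!``; the absorbing state has
    ``p_M(t) = P(N_int + 1, kt)`` (regularized lower incomplete gamma), which
    equals ``1 - sum_n p_n`` but stays accurate at large ``kt``.
    """
    if not k > 0:
        raise ValueError(f"step rate must be > 0, got {k}")
    if N_int < 0:
        raise ValueError(f"N_int must be >= 0, got {N_int}")
    t = np.asarray(times, dtype=float)
    mu = k * t[:, None]
    n = np.arange(N_int + 1, dtype=float)[None, :]  # n - 1 in the formula
    probs_micro = _poisson_pmf(n, mu)
    p_M = special.gammainc(N_int + 1.0, k * t)
    probs = np.column_stack([probs_micro, p_M])
    if macrostate_map is None:
        macrostate_map = chain_macrostate_map(N_int, N_E=1)
    names = tuple(f"I{i}" for i in range(N_int + 1))[1:]
    return OccupancyGrid(
        times=t,
        probs=probs,
        macrostate_map=np.asarray(macrostate_map),
        state_names=("E",) + names + ("M",),
    )


def reversible_generator(params: ReversibleParams, N_states: int) -> np.ndarray:
    """Tridiagonal generator of the reversible chain with absorbing last state.

    Columns are source states: forward rate ``k_fwd`` out of every
    non-absorbing state, backward rate ``k_bwd`` out of every interior state
    (the first state has nothing behind it; the absorbing state has no
    outgoing flow at all, so its column is zero).
    """
    if N_states < 2:
        raise ValueError("need at least 2 states")
    kf, kb = params.k_fwd, params.k_bwd
    A = np.zeros((N_states, N_states))
    for j in range(N_states - 1):
        A[j, j] -= kf
        A[j + 1, j] += kf
        if j >= 1:
            A[j, j] -= kb
            A[j - 1, j] += kb
    return A


def uniformized_expm(A: np.ndarray, p0: np.ndarray, t: float, tol: float = 1e-12) -> np.ndarray:
    """Action of exp(A t) on p0 for a generator A, by uniformization.

    Writes exp(At) = sum_m Poisson(m; qt) P^m with P = I + A/q and
    q >= max |diag A|; every iterate is a probability vector, so the series
    is unconditionally stable. Truncated when the accumulated Poisson mass
    exceeds 1 - tol.
    """
    q = float(np.max(-np.diag(A)))
    if q <= 0 or t == 0:
        return p0.copy()
    P = np.eye(A.shape[0]) + A / q
    mu = q * t
    # log-space Poisson weights to survive large q t
    out = np.zeros_like(p0, dtype=float)
    v = p0.astype(float).copy()
    log_w = -mu  # log Poisson(0; mu)
    acc = 0.0
    m = 0
    max_terms = int(mu + 12.0 * math.sqrt(mu + 1.0) + 50)
    while acc < 1.0 - tol and m <= max_terms:
        w = math.exp(log_w)
        out += w * v
        acc += w
        m += 1
        log_w += math.log(mu) - math.log(m)
        v = P @ v
    # renormalize the truncated series onto the simplex
    s = out.sum()
    if s > 0:
        out /= s
    return out


def reversible_occupancy(
    params: ReversibleParams, N_states: int, times, macrostate_map=None
) -> OccupancyGrid:
    """Occupancy of the reversible chain (absorbing M), by uniformization.

    With ``k_bwd = 0`` this reduces to :func:`erlang_occupancy` with
    ``N_int = N_states - 2``.
    """
    t = np.asarray(times, dtype=float)
    A = reversible_generator(params, N_states)
    p0 = np.zeros(N_states)
    p0[0] = 1.0
    probs = np.empty((t.size, N_states))
    for i, ti in enumerate(t):
        pi = uniformized_expm(A, p0, float(ti))
        if not np.all(np.isfinite(pi)):
            raise FloatingPointError(f"uniformization failed at t={ti}")
        probs[i] = pi
    if macrostate_map is None:
        macrostate_map = chain_macrostate_map(N_states - 2, N_E=1)
    return OccupancyGrid(times=t, probs=probs, macrostate_map=np.asarray(macrostate_map))


def chain_fat_density(k: float, N_int: int):
    """Callable Erlang(N_int + 1, k) density f_M(t) = k^{N+1} t^N e^{-kt} / N!."""
    if not k > 0:
        raise ValueError(f"step rate must be > 0, got {k}")
    shape = N_int + 1

    def density(t):
        t = np.asarray(t, dtype=float)
        with np.errstate(divide="ignore"):
            logf = (
                shape * math.log(k)
                + special.xlogy(shape - 1, t)
                - k * t
                - special.gammaln(shape)
            )
        return np.exp(logf)

    return density


def fat_mfat_chain(k: float, N_int: int, times=None) -> FATSummary:
    """First-arrival-time density and mean for the uniform chain.

    The density is Erlang(N_int + 1, k); MFAT = (N_int + 1) / k.
    """
    mfat = (N_int + 1) / k
    if times is None:
        times = default_time_grid(mfat)
    t = np.asarray(times, dtype=float)
    return FATSummary(times=t, density=chain_fat_density(k, N_int)(t), mfat=mfat)


def mfat_surface(
    delta_E_grid, N_int_grid, cal: CalibrationSpec = CalibrationSpec()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """MFAT over a (delta_E, N_int) grid, with the per-barrier optimal chain size.

    For each barrier the attempt rate is re-calibrated through ``cal`` and

        MFAT = (N_int + 1) / (k0(dE) * exp(-dE / (N_int + 1))).

    Returns ``(surface, argmin)``: the long-format surface table and, per
    delta_E, the integer ``N_int`` minimizing MFAT with the minimum value.
    """
    dEs = np.atleast_1d(np.asarray(delta_E_grid, dtype=float))
    Ns = np.atleast_1d(np.asarray(N_int_grid, dtype=int))
    if dEs.size == 0 or Ns.size == 0:
        raise ValueError("grids must be nonempty")
    rows = []
    argmin_rows = []
    for dE in dEs:
        k0 = calibrate_k0(float(dE), cal)
        mfats = (Ns + 1) / (k0 * np.exp(-dE / (Ns + 1)))
        for N, m in zip(Ns, mfats):
            rows.append((dE, int(N), float(m)))
        i_best = int(np.argmin(mfats))
        argmin_rows.append((dE, int(Ns[i_best]), float(mfats[i_best])))
    surface = pd.DataFrame(rows, columns=["delta_E", "N_int", "mfat"])
    argmin = pd.DataFrame(argmin_rows, columns=["delta_E", "argmin_N_int", "mfat_min"])
    return surface, argmin
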