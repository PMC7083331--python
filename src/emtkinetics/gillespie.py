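"""Exact stochastic simulation of single-cell state transitions.

The transition network is held as a :class:`TransitionSystem` — explicit
per-transition source/target indicator rows and rates (the S/P/K triple of
the master-equation bookkeeping). Each cell is an independent continuous-
time Markov jump process started in the first state: waiting times are
exponential in the total outgoing propensity and the transition is chosen
by the cumulative-propensity rule, until absorption or the time horizon.

Per-cell random substreams are derived from ``(seed, cell_index)`` so that
ensembles are reproducible and growing ``n_cells`` never reshuffles the
trajectories already drawn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RateAssignment, StabilizedSpec, TopologySpec
from .rates import split_layers, split_paths

__all__ = [
    "TransitionSystem",
    "SimConfig",
    "CellTrajectory",
    "EnsembleSummary",
    "build_transition_system",
    "simulate_cells",
    "summarize_ensemble",
]


@dataclass(frozen=True)
class TransitionSystem:
    """Explicit transition list of an absorbing Markov jump process.

    ``sources[i]`` / ``targets[i]`` are state indices (0-based; 0 is the
    initial epithelial state, ``n_states - 1`` the absorbing mesenchymal
    state), ``rates[i]`` the transition rate in 1/day.
    """

    sources: np.ndarray
    targets: np.ndarray
    rates: np.ndarray
    n_states: int
    state_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "sources", np.asarray(self.sources, dtype=int))
        object.__setattr__(self, "targets", np.asarray(self.targets, dtype=int))
        object.__setattr__(self, "rates", np.asarray(self.rates, dtype=float))
        if not (self.sources.shape == self.targets.shape == self.rates.shape):
            raise ValueError("sources, targets, rates must have equal length")
        if np.any(self.rates <= 0):
            raise ValueError("all transition rates must be > 0")
        if np.any((self.sources < 0) | (self.sources >= self.n_states)):
            raise ValueError("source index out of range")
        if np.any((self.targets < 0) | (self.targets >= self.n_states)):
            raise ValueError("target index out of range")
        if np.any(self.sources == self.n_states - 1):
            raise ValueError("the absorbing state must have no outgoing transitions")
        # reachability: every non-initial state must be reachable from state 0
        reach = {0}
        frontier = [0]
        adj: dict[int, list[int]] = {}
        for s, tgt in zip(self.sources, self.targets):
            adj.setdefault(int(s), []).append(int(tgt))
        while frontier:
            s = frontier.pop()
            for tgt in adj.get(s, ()):
                if tgt not in reach:
                    reach.add(tgt)
                    frontier.append(tgt)
        if len(reach) != self.n_states:
            raise ValueError("transition system is disconnected")

    @property
    def n_transitions(self) -> int:
        return self.sources.size

    def indicator_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """One-hot (n_transitions, n_states) source and target matrices."""
        S = np.zeros((self.n_transitions, self.n_states))
        P = np.zeros_like(S)
        S[np.arange(self.n_transitions), self.sources] = 1.0
        P[np.arange(self.n_transitions), self.targets] = 1.0
        return S, P

    def generator(self) -> np.ndarray:
        """Column-stochastic generator A with dp/dt = A p."""
        A = np.zeros((self.n_states, self.n_states))
        for s, tgt, k in zip(self.sources, self.targets, self.rates):
            A[s, s] -= k
            A[tgt, s] += k
        return A


@dataclass(frozen=True)
class SimConfig:
    """Ensemble size, horizon and seed for a stochastic run."""

    n_cells: int
    T_max: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not (self.T_max > 0):
            raise ValueError("T_max must be > 0")


@dataclass
class CellTrajectory:
    """Event times and visited states of one simulated cell.

    ``states[0]`` is the initial state at ``times[0] = 0``; subsequent
    entries record each jump. ``absorbed`` is False for cells censored at
    the horizon.
    """

    times: np.ndarray
    states: np.ndarray
    absorbed: bool

    def state_at(self, t: float) -> int:
        idx = int(np.searchsorted(self.times, t, side="right") - 1)
        return int(self.states[idx])


@dataclass
class EnsembleSummary:
    """Occupancy fractions, FAT samples and per-state dwell times of an ensemble."""

    times: np.ndarray
    fractions: np.ndarray  # (T, n_states)
    fat_samples: np.ndarray  # absorbed cells only
    n_censored: int
    dwell_samples: dict[int, np.ndarray] = field(default_factory=dict)

    def to_frame(self, state_names=None) -> pd.DataFrame:
        names = state_names or [f"s{i}" for i in range(self.fractions.shape[1])]
        df = pd.DataFrame(self.fractions, columns=list(names))
        df.insert(0, "time", self.times)
        return df


def build_transition_system(
    topo: TopologySpec,
    rates: RateAssignment,
    stab: StabilizedSpec | None = None,
) -> TransitionSystem:
    """Wire a chain / parallel / layered topology into an explicit system.

    Chain: states E, I1..I_N, M with the ``N_int + 1`` sequential steps taken
    directly from ``rates.step_rates`` (which already encode any stabilized
    state). Parallel: E fans out into each path's first intermediate at that
    path's rate. Layered: E fans out to each first-layer state at the common
    step rate (aggregate exit ``N_L1 * k``); state j of a layer feeds state
    ``min(j, next_size - 1)`` of the next layer; the last layer exits to M.
    """
    if topo.variant == "chain":
        n = topo.N_int + 2
        srcs = list(range(n - 1))
        tgts = list(range(1, n))
        ks = list(rates.step_rates)
        if len(ks) != n - 1:
            raise ValueError("rate list does not match chain length")
        names = ["E"] + [f"I{i}" for i in range(1, topo.N_int + 1)] + ["M"]
        return TransitionSystem(
            sources=np.array(srcs), targets=np.array(tgts), rates=np.array(ks),
            n_states=n, state_names=tuple(names),
        )

    if topo.variant == "parallel":
        sizes = split_paths(topo.N_int, topo.N_pth)
        if len(rates.step_rates) != len(sizes):
            raise ValueError("parallel rate list must hold one per-path rate")
        srcs, tgts, ks, names = [], [], [], ["E"]
        offset = 1
        absorbing = topo.N_int + 1
        for p, (n_i, k_i) in enumerate(zip(sizes, rates.step_rates)):
            states = list(range(offset, offset + n_i))
            names += [f"P{p + 1}_I{j + 1}" for j in range(n_i)]
            srcs.append(0); tgts.append(states[0]); ks.append(k_i)
            for a, b in zip(states[:-1], states[1:]):
                srcs.append(a); tgts.append(b); ks.append(k_i)
            srcs.append(states[-1]); tgts.append(absorbing); ks.append(k_i)
            offset += n_i
        names.append("M")
        return TransitionSystem(
            sources=np.array(srcs), targets=np.array(tgts), rates=np.array(ks),
            n_states=absorbing + 1, state_names=tuple(names),
        )

    # layered
    sizes, _ = split_layers(topo.N_int, topo.N_ly)
    k = rates.step_rates[0]
    srcs, tgts, ks, names = [], [], [], ["E"]
    layer_states: list[list[int]] = []
    offset = 1
    for ly, n_l in enumerate(sizes):
        layer_states.append(list(range(offset, offset + n_l)))
        names += [f"L{ly + 1}_I{j + 1}" for j in range(n_l)]
        offset += n_l
    absorbing = offset
    names.append("M")
    for s in layer_states[0]:
        srcs.append(0); tgts.append(s); ks.append(k)
    for cur, nxt in zip(layer_states[:-1], layer_states[1:]):
        for j, s in enumerate(cur):
            srcs.append(s); tgts.append(nxt[min(j, len(nxt) - 1)]); ks.append(k)
    for s in layer_states[-1]:
        srcs.append(s); tgts.append(absorbing); ks.append(k)
    return TransitionSystem(
        sources=np.array(srcs), targets=np.array(tgts), rates=np.array(ks),
        n_states=absorbing + 1, state_names=tuple(names),
    )


def _simulate_one(sys: TransitionSystem, T_max: float, rng: np.random.Generator) -> CellTrajectory:
    absorbing = sys.n_states - 1
    # per-state outgoing transition index lists and propensity tables
    state = 0
    t = 0.0
    times = [0.0]
    states = [0]
    while state != absorbing:
        mask = sys.sources == state
        a = sys.rates[mask]
        a0 = a.sum()
        if a0 <= 0:
            raise RuntimeError(f"zero total propensity in non-absorbing state {state}")
        rn1, rn2 = rng.random(2)
        dt = math.log(1.0 / rn1) / a0
        if t + dt > T_max:
            return CellTrajectory(np.array(times), np.array(states), absorbed=False)
        # cumulative-propensity choice: strict left, inclusive right
        cum = np.cumsum(a)
        r = int(np.searchsorted(cum, rn2 * a0, side="left"))
        r = min(r, a.size - 1)
        state = int(sys.targets[mask][r])
        t += dt
        times.append(t)
        states.append(state)
    return CellTrajectory(np.array(times), np.array(states), absorbed=True)


def simulate_cells(sys: TransitionSystem, cfg: SimConfig) -> list[CellTrajectory]:
    """Simulate ``cfg.n_cells`` independent cells, each from state 0.

    Deterministic for a fixed seed; cell i uses the substream seeded by
    ``(cfg.seed, i)``.
    """
    out = []
    for i in range(cfg.n_cells):
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), i]))
        out.append(_simulate_one(sys, cfg.T_max, rng))
    return out


def summarize_ensemble(
    trajectories: list[CellTrajectory], time_grid, n_states: int | None = None
) -> EnsembleSummary:
    """Aggregate trajectories: occupancy fractions, FAT and dwell-time samples.

    States are piecewise constant between events; the FAT of a cell is its
    first entry time into the absorbing (last) state. Censored cells carry
    no FAT sample and are counted in ``n_censored``.
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    if n_states is None:
        n_states = max(int(tr.states.max()) for tr in trajectories) + 1
    grid = np.asarray(time_grid, dtype=float)
    counts = np.zeros((grid.size, n_states))
    fat = []
    dwell: dict[int, list[float]] = {}
    n_censored = 0
    for tr in trajectories:
        idx = np.searchsorted(tr.times, grid, side="right") - 1
        occ_states = tr.states[idx]
        counts[np.arange(grid.size), occ_states] += 1.0
        if tr.absorbed:
            fat.append(tr.times[-1])
        else:
            n_censored += 1
        durations = np.diff(tr.times)
        for s, d in zip(tr.states[:-1], durations):
            dwell.setdefault(int(s), []).append(float(d))
    fractions = counts / len(trajectories)
    return EnsembleSummary(
        times=grid,
        fractions=fractions,
        fat_samples=np.array(fat),
        n_censored=n_censored,
        dwell_samples={s: np.array(v) for s, v in dwell.items()},
    )


def trajectories_to_frame(trajectories: list[CellTrajectory]) -> pd.DataFrame:
    """Long-format (cell_id, time, state) export of an ensemble."""
    rows = []
    for i, tr in enumerate(trajectories):
        for t, s in zip(tr.times, tr.states):
            rows.append((i, float(t), int(s)))
    return pd.DataFrame(rows, columns=["cell_id", "time", "state"])
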