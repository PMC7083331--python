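"""Result containers: state occupancy grids, first-arrival-time summaries,
macrostate time courses and fit results.

These are light, validated wrappers over numpy arrays with pandas export;
all solvers and the simulator return them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["OccupancyGrid", "FATSummary", "TimecourseData", "FitResult", "MACROSTATES"]

MACROSTATES = ("E", "P", "M")


@dataclass
class OccupancyGrid:
    """Per-state occupancy probabilities on a time grid.

    Attributes
    ----------
    times : (T,) array
        Time points, days, >= 0.
    probs : (T, n_states) array
        Probability of a cell being in each microstate at each time. Rows
        sum to 1. State order: initial E microstate(s) first, then
        intermediates, absorbing M last.
    macrostate_map : (n_states,) array of {"E","P","M"}
        Which observable macrostate each microstate reports to.
    state_names : tuple of str
        Column labels for export.
    """

    times: np.ndarray
    probs: np.ndarray
    macrostate_map: np.ndarray
    state_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.probs = np.atleast_2d(np.asarray(self.probs, dtype=float))
        self.macrostate_map = np.asarray(self.macrostate_map)
        if self.probs.shape != (self.times.size, self.macrostate_map.size):
            raise ValueError(
                f"probs shape {self.probs.shape} inconsistent with "
                f"{self.times.size} times x {self.macrostate_map.size} states"
            )
        if not self.state_names:
            self.state_names = tuple(f"s{i}" for i in range(self.probs.shape[1]))
        bad = set(np.unique(self.macrostate_map)) - set(MACROSTATES)
        if bad:
            raise ValueError(f"macrostate labels must be in {MACROSTATES}, got {bad}")

    @property
    def n_states(self) -> int:
        return self.probs.shape[1]

    def macrostate_fractions(self, percent: bool = True) -> pd.DataFrame:
        """Aggregate microstate occupancy to E/P/M fractions (percent by default)."""
        scale = 100.0 if percent else 1.0
        data = {
            f"frac_{m}": scale * self.probs[:, self.macrostate_map == m].sum(axis=1)
            for m in MACROSTATES
        }
        return pd.DataFrame({"time": self.times, **data})

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probs, columns=list(self.state_names))
        df.insert(0, "time", self.times)
        return df

    def validate(self, atol: float = 1e-8) -> None:
        """Check probability bounds and per-row conservation."""
        if np.any(self.probs < -atol) or np.any(self.probs > 1 + atol):
            raise ValueError("occupancy probabilities outside [0, 1]")
        rows = self.probs.sum(axis=1)
        if np.max(np.abs(rows - 1.0)) > atol:
            raise ValueError(f"occupancy rows do not sum to 1 (max err {np.max(np.abs(rows-1)):.2e})")


@dataclass
class FATSummary:
    """First-arrival-time density to the absorbing mesenchymal state.

    ``density`` holds f_M(t) = d p_M / dt on ``times`` (1/day); ``mfat`` is
    the mean first arrival time in days.
    """

    times: np.ndarray
    density: np.ndarray
    mfat: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.times.shape != self.density.shape:
            raise ValueError("times and density must have the same shape")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "density": self.density})

    def validate(self, mass_tol: float = 1e-6) -> None:
        from scipy.integrate import simpson

        if np.any(self.density < -1e-12):
            raise ValueError("FAT density must be non-negative")
        mass = simpson(self.density, x=self.times)
        if abs(mass - 1.0) > mass_tol:
            raise ValueError(f"FAT density mass {mass:.8f} != 1")
        if not (self.mfat > 0):
            raise ValueError("MFAT must be positive")


@dataclass
class TimecourseData:
    """Observed (or synthetic) macrostate fractions over time, percent scale.

    ``fractions`` has columns (E, P, M) in percent, rows matching ``times``
    (days, strictly increasing). ``n_cells`` records the sampling depth when
    the fractions come from counting a finite population.
    """

    times: np.ndarray
    fractions: np.ndarray
    n_cells: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fractions = np.atleast_2d(np.asarray(self.fractions, dtype=float))
        if self.fractions.shape != (self.times.size, 3):
            raise ValueError("fractions must be (n_times, 3): E, P, M percent columns")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        sums = self.fractions.sum(axis=1)
        if np.max(np.abs(sums - 100.0)) > 0.5:
            raise ValueError("per-time fractions must sum to 100 (within 0.5)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "frac_E": self.fractions[:, 0],
                "frac_P": self.fractions[:, 1],
                "frac_M": self.fractions[:, 2],
            }
        )


@dataclass
class FitResult:
    """Outcome of the hidden-microstate grid fit.

    ``score_grid`` is a DataFrame with one row per (N_E, N_P) grid cell and
    its optimized rate(s) and RMSE; the reported (``N_E``, ``N_P``) attain
    the grid minimum (ties broken toward smaller N_E + N_P, then smaller
    N_E). ``boundary`` flags a fitted rate pinned at a search bound.
    """

    N_E: int
    N_P: int
    rates: dict[str, float]
    rmse: float
    score_grid: pd.DataFrame
    boundary: bool = False

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")
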