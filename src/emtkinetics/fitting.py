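"""Hidden-microstate model fitting for macrostate time courses.

Population EMT data report only the percent of cells in the three
observable macrostates (E, partial, M) over time, yet their kinetics are
non-exponential — the signature of hidden microstates. The fit searches a
grid of hidden-state counts (``N_E`` epithelial, ``N_P`` partial
microstates, absorbing M), optimizing the step rate(s) at every grid cell
and scoring by the RMSE between modeled and observed percent curves pooled
over all three macrostates and all time points. The reported cell is the
grid minimum (ties broken toward parsimony: smaller ``N_E + N_P``, then
smaller ``N_E``).

Two model families are available as scikit-learn style estimators:

* :class:`IrreversibleChainEMT` — uniform forward rate ``k`` (one scalar
  per grid cell, bounded log-scale minimization);
* :class:`ReversibleChainEMT` — forward ``k1`` and backward ``k_-1``
  (two-parameter multi-start minimization; the backward rate nested at zero
  recovers the irreversible fit).

``X`` is the vector of sampling times in days, ``y`` the (n_times, 3) array
of E/P/M percentages. Fitted attributes: ``n_e_``, ``n_p_``, ``rates_``,
``rmse_``, ``score_grid_``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .chain import (
    ReversibleParams,
    chain_macrostate_map,
    erlang_occupancy,
    reversible_occupancy,
)
from .results import FitResult, OccupancyGrid, TimecourseData

__all__ = [
    "rmse_score",
    "fit_irreversible",
    "fit_reversible",
    "IrreversibleChainEMT",
    "ReversibleChainEMT",
]

_TIE_TOL = 1e-10


def rmse_score(model: OccupancyGrid, data: TimecourseData) -> float:
    """Pooled RMSE (percent) between modeled and observed macrostate curves.

    The model must be evaluated exactly at the data's time points; no
    interpolation is performed. Deviations are pooled over all three
    macrostates and all time points with equal weight.
    """
    if model.times.shape != data.times.shape or np.max(np.abs(model.times - data.times)) > 1e-9:
        raise ValueError("model must be evaluated at the data's time points")
    model_pct = model.macrostate_fractions(percent=True)[["frac_E", "frac_P", "frac_M"]].to_numpy()
    resid = model_pct - data.fractions
    return float(np.sqrt(np.mean(resid**2)))


def _macro_percent_irreversible(times: np.ndarray, n_e: int, n_p: int, k: float) -> np.ndarray:
    """(T, 3) percent curves of the chain with n_e + n_p microstates before M."""
    n_int = n_e + n_p - 1
    occ = erlang_occupancy(k, n_int, times, macrostate_map=chain_macrostate_map(n_int, N_E=n_e))
    return occ.macrostate_fractions(percent=True)[["frac_E", "frac_P", "frac_M"]].to_numpy()


def _macro_percent_reversible(
    times: np.ndarray, n_e: int, n_p: int, k_fwd: float, k_bwd: float
) -> np.ndarray:
    n_states = n_e + n_p + 1
    occ = reversible_occupancy(
        ReversibleParams(k_fwd=k_fwd, k_bwd=k_bwd),
        n_states,
        times,
        macrostate_map=chain_macrostate_map(n_states - 2, N_E=n_e),
    )
    return occ.macrostate_fractions(percent=True)[["frac_E", "frac_P", "frac_M"]].to_numpy()


def _pooled_rmse(model_pct: np.ndarray, target_pct: np.ndarray) -> float:
    return float(np.sqrt(np.mean((model_pct - target_pct) ** 2)))


def _select_best(grid: pd.DataFrame) -> pd.Series:
    """Grid argmin with parsimony tie-breaking."""
    best = grid["rmse"].min()
    tied = grid[grid["rmse"] <= best + _TIE_TOL].copy()
    tied["complexity"] = tied["N_E"] + tied["N_P"]
    tied = tied.sort_values(["complexity", "N_E"], kind="stable")
    return tied.iloc[0]


class _ChainEMTBase(BaseEstimator, RegressorMixin):
    def _validate_Xy(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError("X must be a 1-d array of times (or column vector)")
        y = np.asarray(y, dtype=float)
        if y.shape != (X.size, 3):
            raise ValueError("y must be (n_times, 3) percent fractions for E, P, M")
        if np.any(np.diff(X) <= 0):
            raise ValueError("times must be strictly increasing")
        return X, y

    def predict(self, X):
        """Macrostate percent curves of the fitted model at times ``X``."""
        check_is_fitted(self, "rmse_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        return self._predict_times(X)

    def fit_timecourse(self, data: TimecourseData) -> FitResult:
        """Fit a :class:`TimecourseData` and return a :class:`FitResult`."""
        self.fit(data.times, data.fractions)
        return FitResult(
            N_E=self.n_e_,
            N_P=self.n_p_,
            rates=dict(self.rates_),
            rmse=self.rmse_,
            score_grid=self.score_grid_,
            boundary=self.boundary_,
        )


class IrreversibleChainEMT(_ChainEMTBase):
    """Grid fit of the irreversible uniform-rate hidden-microstate chain.

    Parameters
    ----------
    n_e_range, n_p_range : iterable of int
        Hidden-state counts to try (defaults 1..10 and 0..10; ``n_p = 0``
        is the two-macrostate model without a partial state).
    k_bounds : (float, float)
        Search bounds for the step rate, 1/day; optimized on a log scale.
    """

    def __init__(self, n_e_range=range(1, 11), n_p_range=range(0, 11), k_bounds=(1e-3, 1e3)):
        self.n_e_range = n_e_range
        self.n_p_range = n_p_range
        self.k_bounds = k_bounds

    def fit(self, X, y):
        X, y = self._validate_Xy(X, y)
        lo, hi = self.k_bounds
        if not (0 < lo < hi):
            raise ValueError("k_bounds must satisfy 0 < lo < hi")
        log_lo, log_hi = np.log(lo), np.log(hi)
        rows = []
        for n_e in self.n_e_range:
            for n_p in self.n_p_range:
                def neg(log_k, n_e=n_e, n_p=n_p):
                    return _pooled_rmse(
                        _macro_percent_irreversible(X, n_e, n_p, float(np.exp(log_k))), y
                    )

                res = optimize.minimize_scalar(
                    neg, bounds=(log_lo, log_hi), method="bounded",
                    options={"xatol": 1e-10},
                )
                k_hat = float(np.exp(res.x))
                at_bound = min(res.x - log_lo, log_hi - res.x) < 1e-6
                rows.append((int(n_e), int(n_p), k_hat, float(res.fun), at_bound, res.success))
        grid = pd.DataFrame(rows, columns=["N_E", "N_P", "k", "rmse", "boundary", "converged"])
        best = _select_best(grid)
        self.n_e_ = int(best["N_E"])
        self.n_p_ = int(best["N_P"])
        self.rates_ = {"k": float(best["k"])}
        self.rmse_ = float(best["rmse"])
        self.boundary_ = bool(best["boundary"])
        self.score_grid_ = grid.drop(columns=["complexity"], errors="ignore")
        return self

    def _predict_times(self, times):
        return _macro_percent_irreversible(times, self.n_e_, self.n_p_, self.rates_["k"])


class ReversibleChainEMT(_ChainEMTBase):
    """Grid fit of the reversible hidden-microstate chain (absorbing M).

    Two free rates per grid cell (forward ``k1``, backward ``k_-1``),
    optimized on a log scale with multiple starts. Setting
    ``k_bwd_bounds = (0, 0)`` pins the backward rate to zero, which nests
    the irreversible model.
    """

    def __init__(
        self,
        n_e_range=range(1, 11),
        n_p_range=range(0, 11),
        k_fwd_bounds=(1e-3, 1e3),
        k_bwd_bounds=(1e-6, 1e3),
        n_starts=3,
    ):
        self.n_e_range = n_e_range
        self.n_p_range = n_p_range
        self.k_fwd_bounds = k_fwd_bounds
        self.k_bwd_bounds = k_bwd_bounds
        self.n_starts = n_starts

    def fit(self, X, y):
        X, y = self._validate_Xy(X, y)
        f_lo, f_hi = self.k_fwd_bounds
        b_lo, b_hi = self.k_bwd_bounds
        fixed_zero_bwd = b_lo == 0 and b_hi == 0
        rows = []
        for n_e in self.n_e_range:
            for n_p in self.n_p_range:
                if fixed_zero_bwd:
                    def neg1(log_k, n_e=n_e, n_p=n_p):
                        return _pooled_rmse(
                            _macro_percent_reversible(X, n_e, n_p, float(np.exp(log_k)), 0.0), y
                        )

                    res = optimize.minimize_scalar(
                        neg1, bounds=(np.log(f_lo), np.log(f_hi)), method="bounded",
                        options={"xatol": 1e-10},
                    )
                    kf, kb, fun, ok = float(np.exp(res.x)), 0.0, float(res.fun), res.success
                    at_bound = min(res.x - np.log(f_lo), np.log(f_hi) - res.x) < 1e-6
                else:
                    def neg2(lp, n_e=n_e, n_p=n_p):
                        return _pooled_rmse(
                            _macro_percent_reversible(
                                X, n_e, n_p, float(np.exp(lp[0])), float(np.exp(lp[1]))
                            ),
                            y,
                        )

                    bounds = [
                        (np.log(f_lo), np.log(f_hi)),
                        (np.log(max(b_lo, 1e-8)), np.log(b_hi)),
                    ]
                    starts = [
                        (np.log(1.0), np.log(0.1)),
                        (np.log(3.4), np.log(0.5)),
                        (np.log(0.3), np.log(0.01)),
                    ][: self.n_starts]
                    best_local = None
                    for x0 in starts:
                        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
                        r = optimize.minimize(
                            neg2, x0, method="Nelder-Mead", bounds=bounds,
                            options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 400},
                        )
                        if best_local is None or r.fun < best_local.fun:
                            best_local = r
                    res = best_local
                    kf, kb = float(np.exp(res.x[0])), float(np.exp(res.x[1]))
                    fun, ok = float(res.fun), bool(res.success)
                    at_bound = (
                        min(res.x[0] - bounds[0][0], bounds[0][1] - res.x[0]) < 1e-6
                        or bounds[1][1] - res.x[1] < 1e-6
                    )
                rows.append((int(n_e), int(n_p), kf, kb, fun, at_bound, ok))
        grid = pd.DataFrame(
            rows, columns=["N_E", "N_P", "k_fwd", "k_bwd", "rmse", "boundary", "converged"]
        )
        best = _select_best(grid)
        self.n_e_ = int(best["N_E"])
        self.n_p_ = int(best["N_P"])
        self.rates_ = {"k_fwd": float(best["k_fwd"]), "k_bwd": float(best["k_bwd"])}
        self.rmse_ = float(best["rmse"])
        self.boundary_ = bool(best["boundary"])
        self.score_grid_ = grid.drop(columns=["complexity"], errors="ignore")
        return self

    def _predict_times(self, times):
        return _macro_percent_reversible(
            times, self.n_e_, self.n_p_, self.rates_["k_fwd"], self.rates_["k_bwd"]
        )


def fit_irreversible(
    data: TimecourseData,
    n_e_range=range(1, 11),
    n_p_range=range(0, 11),
    k_bounds=(1e-3, 1e3),
) -> FitResult:
    """Fit the irreversible hidden-microstate chain to a time course."""
    est = IrreversibleChainEMT(n_e_range=n_e_range, n_p_range=n_p_range, k_bounds=k_bounds)
    return est.fit_timecourse(data)


def fit_reversible(
    data: TimecourseData,
    n_e_range=range(1, 11),
    n_p_range=range(0, 11),
    k_fwd_bounds=(1e-3, 1e3),
    k_bwd_bounds=(1e-6, 1e3),
) -> FitResult:
    """Fit the reversible hidden-microstate chain to a time course."""
    est = ReversibleChainEMT(
        n_e_range=n_e_range,
        n_p_range=n_p_range,
        k_fwd_bounds=k_fwd_bounds,
        k_bwd_bounds=k_bwd_bounds,
    )
    return est.fit_timecourse(data)
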