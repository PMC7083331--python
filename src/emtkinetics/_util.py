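"""Shared numerical helpers: default time grids and FAT quadrature."""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy import integrate

__all__ = ["default_time_grid", "mfat_from_density", "density_mass"]


def default_time_grid(mfat: float, n_points: int = 2001) -> np.ndarray:
    """Linear grid covering [0, max(50 * MFAT, 10)] days.

    Fifty mean first-arrival times leaves < 1e-9 of any phase-type density
    mass beyond the grid for the chain sizes used here.
    """
    t_max = max(50.0 * mfat, 10.0)
    return np.linspace(0.0, t_max, n_points)


def mfat_from_density(density: Callable[[np.ndarray], np.ndarray], t_upper: float) -> float:
    """Mean of a FAT density by adaptive quadrature of t * f(t) on [0, t_upper]."""
    val, _ = integrate.quad(
        lambda t: t * np.asarray(density(t)).ravel()[0], 0.0, t_upper, limit=400
    )
    return val


def density_mass(density: Callable[[np.ndarray], np.ndarray], t_upper: float) -> float:
    """Total mass of a FAT density by adaptive quadrature (should be ~1)."""
    val, _ = integrate.quad(lambda t: np.asarray(density(t)).ravel()[0], 0.0, t_upper, limit=400)
    return val
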