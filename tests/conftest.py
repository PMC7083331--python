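"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's closed-form code paths:
occupancies are checked against dense matrix exponentials of explicitly
assembled generators (scipy.linalg.expm), and means against adaptive
quadrature or Monte Carlo.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import binom


def chain_generator(rates: list[float]) -> np.ndarray:
    """Dense generator of a sequential chain with the given step rates."""
    n = len(rates) + 1
    A = np.zeros((n, n))
    for i, k in enumerate(rates):
        A[i, i] -= k
        A[i + 1, i] += k
    return A


def expm_occupancy(A: np.ndarray, times) -> np.ndarray:
    """Occupancy rows p(t) = expm(A t) e0 — the numeric oracle."""
    p0 = np.zeros(A.shape[0])
    p0[0] = 1.0
    return np.array([expm(A * float(t)) @ p0 for t in np.atleast_1d(times)])


def multinomial_counts_ok(counts: np.ndarray, probs: np.ndarray, n: int, alpha: float) -> bool:
    """Simultaneous (Bonferroni) exact binomial check of per-state counts."""
    m = counts.size
    level = 1.0 - alpha / m
    for c, p in zip(counts, probs):
        lo, hi = binom.interval(level, n, min(max(p, 0.0), 1.0))
        if not (lo <= c <= hi):
            return False
    return True


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
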