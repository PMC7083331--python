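"""Arrhenius rate assignment over chain / parallel / layered topologies.

Every transition step crosses an energy barrier; with the total barrier
``delta_E`` divided evenly over the steps of a path, a chain with ``N_int``
intermediates has per-step rate ``k = k0 * exp(-delta_E / (N_int + 1))``.
The attempt rate ``k0`` can be anchored to data through
:func:`calibrate_k0`, which inverts the calibration identity
``k_fit = k0 * exp(-delta_E / (N_fit + 1))``.
"""

from __future__ import annotations

import math

from .config import (
    CalibrationSpec,
    EnergyConfig,
    RateAssignment,
    StabilizedSpec,
    TopologySpec,
)

__all__ = ["calibrate_k0", "step_rates", "split_paths", "split_layers", "chain_step_rate"]


def calibrate_k0(delta_E: float, cal: CalibrationSpec = CalibrationSpec()) -> float:
    """Attempt rate ``k0`` consistent with a fitted step rate at a given barrier.

    Solves ``k_fit = k0 * exp(-delta_E / (N_fit + 1))`` for ``k0``, so that a
    uniform chain with ``N_fit`` intermediates under barrier ``delta_E``
    reproduces the fitted per-step rate exactly.

    Parameters
    ----------
    delta_E : float
        Total energy barrier, kB*T units, >= 0.
    cal : CalibrationSpec
        Fitted rate and chain size; defaults to the MCF10A best fit
        (k_fit = 3.4261/day at N_fit = 9).

    Returns
    -------
    float
        k0 in 1/day.
    """
    if not (delta_E >= 0):
        raise ValueError(f"delta_E must be >= 0, got {delta_E}")
    return cal.k_fit * math.exp(delta_E / (cal.N_fit + 1))


def chain_step_rate(energy: EnergyConfig, N_int: int) -> float:
    """Uniform per-step rate of a chain with ``N_int`` intermediates."""
    return energy.k0 * math.exp(-energy.delta_E / (N_int + 1))


def split_paths(N_int: int, N_pth: int) -> list[int]:
    """Split ``N_int`` intermediates as evenly as possible over ``N_pth`` paths.

    Sizes differ by at most one and are returned ascending (e.g. 9 states on
    2 paths -> ``[4, 5]``). Every path must get at least one intermediate.
    """
    if N_pth < 1:
        raise ValueError(f"N_pth must be >= 1, got {N_pth}")
    if N_pth > N_int:
        raise ValueError(
            f"cannot split {N_int} intermediates over {N_pth} paths: a path would be empty"
        )
    base, extra = divmod(N_int, N_pth)
    return [base] * (N_pth - extra) + [base + 1] * extra


def split_layers(N_int: int, N_ly: int) -> tuple[list[int], int]:
    """Split ``N_int`` intermediates over ``N_ly`` layers, remainder to the earliest.

    Returns ``(sizes, N_L1)`` with ``N_L1 = ceil(N_int / N_ly)`` the width of
    the first layer (e.g. 15 states on 4 layers -> ``[4, 4, 4, 3]``).
    """
    if N_ly < 1:
        raise ValueError(f"N_ly must be >= 1, got {N_ly}")
    if N_ly > N_int:
        raise ValueError(
            f"cannot split {N_int} intermediates over {N_ly} layers: a layer would be empty"
        )
    base, extra = divmod(N_int, N_ly)
    sizes = [base + 1] * extra + [base] * (N_ly - extra)
    return sizes, sizes[0]


def step_rates(
    energy: EnergyConfig,
    topo: TopologySpec,
    stab: StabilizedSpec | None = None,
) -> RateAssignment:
    """Assign per-edge rates from the even-barrier-division rule.

    * chain, no stabilization: every one of the ``N_int + 1`` steps gets
      ``k0 * exp(-dE / (N_int + 1))``.
    * chain with a stabilized state (barrier ratio ``m``): the stabilized
      exit step gets ``k2``, the rest ``k1``, per the two barrier cases of
      :class:`~emtkinetics.config.StabilizedSpec`.
    * parallel: path i with ``N_i`` intermediates divides ``dE`` over its own
      ``N_i + 1`` steps, so ``k_i = k0 * exp(-dE / (N_i + 1))``; the aggregate
      initial exit rate is ``k_A = sum k_i``.
    * layered: every step crosses ``dE / (N_ly + 1)``, so all rates equal
      ``k = k0 * exp(-dE / (N_ly + 1))`` and ``k_A = N_L1 * k``.
    """
    if stab is not None and topo.variant != "chain":
        raise ValueError("a stabilized state is only valid on a chain topology")

    dE, k0 = energy.delta_E, energy.k0

    if topo.variant == "chain":
        if stab is None:
            k = chain_step_rate(energy, topo.N_int)
            rates = (k,) * (topo.N_int + 1)
            return RateAssignment(step_rates=rates, k_A=rates[0])
        if stab.S > topo.N_int:
            raise ValueError(f"S={stab.S} exceeds N_int={topo.N_int}")
        if stab.case == "constant_total":
            k1 = k0 * math.exp(-dE / (topo.N_int + stab.m))
            k2 = k0 * math.exp(-dE * stab.m / (topo.N_int + stab.m))
        else:  # varying_total
            k1 = k0 * math.exp(-dE / (topo.N_int + 1))
            k2 = k0 * math.exp(-dE * stab.m / (topo.N_int + 1))
        # step index S (0-based: step 0 is E -> I1) is the exit from I_S
        rates = tuple(k2 if i == stab.S else k1 for i in range(topo.N_int + 1))
        return RateAssignment(step_rates=rates, k_A=rates[0])

    if topo.variant == "parallel":
        sizes = split_paths(topo.N_int, topo.N_pth)
        per_path = tuple(k0 * math.exp(-dE / (n + 1)) for n in sizes)
        return RateAssignment(step_rates=per_path, k_A=sum(per_path))

    # layered
    sizes, N_L1 = split_layers(topo.N_int, topo.N_ly)
    k = k0 * math.exp(-dE / (topo.N_ly + 1))
    return RateAssignment(step_rates=(k,) * (topo.N_ly + 1), k_A=N_L1 * k)
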