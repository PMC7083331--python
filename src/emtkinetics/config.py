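"""Declarative specifications of the energy-barrier rate model and state-graph shape.

The transition network between the epithelial (E) and mesenchymal (M)
phenotypes is described by three orthogonal pieces:

* :class:`EnergyConfig` — the Arrhenius rate model ``k = k0 * exp(-dE)`` with
  the total barrier ``delta_E`` in units of kB*T and the attempt rate ``k0``
  in 1/day.
* :class:`TopologySpec` — how the ``N_int`` intermediate states are wired:
  a single chain, ``N_pth`` parallel paths, or ``N_ly`` sequential layers.
* :class:`StabilizedSpec` — optionally, one chain intermediate whose exit
  barrier is ``m``-fold the regular step barrier (a deeper well that traps
  cells in a partial-EMT phenotype).

All specs are frozen dataclasses validated on construction, and can be read
from a YAML scenario file via :func:`load_scenario` (unknown keys rejected).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Literal

import yaml

__all__ = [
    "EnergyConfig",
    "CalibrationSpec",
    "TopologySpec",
    "StabilizedSpec",
    "RateAssignment",
    "ScenarioConfig",
    "load_scenario",
]


@dataclass(frozen=True)
class EnergyConfig:
    """Arrhenius energy-barrier rate model.

    Parameters
    ----------
    delta_E : float
        Total energy barrier from E to M, in units of kB*T. Must be >= 0.
        Zero is allowed (all rates collapse to ``k0``).
    k0 : float
        Pre-exponential attempt rate, 1/day. Must be > 0. Defaults to 1/day
        when no calibration against data is supplied.
    """

    delta_E: float
    k0: float = 1.0

    def __post_init__(self) -> None:
        if not (self.delta_E >= 0):
            raise ValueError(f"delta_E must be >= 0, got {self.delta_E}")
        if not (self.k0 > 0):
            raise ValueError(f"k0 must be > 0, got {self.k0}")


@dataclass(frozen=True)
class CalibrationSpec:
    """Anchor for the attempt rate: a fitted per-step rate at a known chain size.

    ``k_fit`` is the uniform step rate obtained by fitting a chain with
    ``N_fit`` intermediates to population data; the best fit to the MCF10A
    TGF-beta time course gives ``k_fit = 3.4261``/day at ``N_fit = 9``.
    Given a barrier ``delta_E``, the attempt rate follows from
    ``k_fit = k0 * exp(-delta_E / (N_fit + 1))``.
    """

    k_fit: float = 3.4261
    N_fit: int = 9

    def __post_init__(self) -> None:
        if not (self.k_fit > 0):
            raise ValueError(f"k_fit must be > 0, got {self.k_fit}")
        if self.N_fit < 0 or int(self.N_fit) != self.N_fit:
            raise ValueError(f"N_fit must be a non-negative integer, got {self.N_fit}")


@dataclass(frozen=True)
class TopologySpec:
    """Shape of the intermediate-state graph.

    variant ``"chain"``: E -> I1 -> ... -> I_{N_int} -> M.
    variant ``"parallel"``: ``N_pth`` disjoint chains between E and M, with
    the ``N_int`` intermediates split as evenly as possible across paths.
    variant ``"layered"``: ``N_ly`` sequential layers, the intermediates split
    as evenly as possible with remainders assigned to the earliest layers.

    The chain is the degenerate ``N_pth = 1`` / single-state-per-layer case.
    """

    variant: Literal["chain", "parallel", "layered"]
    N_int: int
    N_pth: int | None = None
    N_ly: int | None = None

    def __post_init__(self) -> None:
        if self.variant not in ("chain", "parallel", "layered"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.N_int < 0 or int(self.N_int) != self.N_int:
            raise ValueError(f"N_int must be a non-negative integer, got {self.N_int}")
        if self.variant == "parallel":
            if self.N_pth is None:
                raise ValueError("parallel topology requires N_pth")
            if self.N_ly is not None:
                raise ValueError("N_ly is only valid for the layered variant")
            if not (1 <= self.N_pth <= max(self.N_int, 1)):
                raise ValueError(
                    f"need 1 <= N_pth <= N_int, got N_pth={self.N_pth}, N_int={self.N_int}"
                )
        elif self.variant == "layered":
            if self.N_ly is None:
                raise ValueError("layered topology requires N_ly")
            if self.N_pth is not None:
                raise ValueError("N_pth is only valid for the parallel variant")
            if not (1 <= self.N_ly <= max(self.N_int, 1)):
                raise ValueError(
                    f"need 1 <= N_ly <= N_int, got N_ly={self.N_ly}, N_int={self.N_int}"
                )
        else:
            if self.N_pth is not None or self.N_ly is not None:
                raise ValueError("chain topology takes neither N_pth nor N_ly")


@dataclass(frozen=True)
class StabilizedSpec:
    """One stabilized intermediate on a chain.

    ``S`` is the 1-based index of the stabilized intermediate (1 <= S <=
    N_int); its exit barrier is ``m`` times the regular step barrier
    (``m >= 1``; ``m = 1`` recovers the uniform chain).

    ``case`` selects how the total barrier responds:

    * ``"constant_total"`` — regular barriers shrink so the total stays
      ``delta_E``: regular steps ``k1 = k0*exp(-dE/(N_int+m))``, stabilized
      step ``k2 = k0*exp(-dE*m/(N_int+m))``.
    * ``"varying_total"`` — regular steps keep the uniform-chain barrier,
      the stabilized step deepens: ``k1 = k0*exp(-dE/(N_int+1))``,
      ``k2 = k0*exp(-dE*m/(N_int+1))``.
    """

    S: int
    m: float
    case: Literal["constant_total", "varying_total"] = "constant_total"

    def __post_init__(self) -> None:
        if self.S < 1 or int(self.S) != self.S:
            raise ValueError(f"S must be a positive integer, got {self.S}")
        if not (self.m >= 1):
            raise ValueError(
                f"barrier ratio m must be >= 1 (m < 1 would not stabilize), got {self.m}"
            )
        if self.case not in ("constant_total", "varying_total"):
            raise ValueError(f"unknown case {self.case!r}")


@dataclass(frozen=True)
class RateAssignment:
    """Per-edge rates produced from (EnergyConfig, TopologySpec[, StabilizedSpec]).

    ``step_rates`` is keyed to the topology's edges:

    * chain — ``N_int + 1`` sequential step rates;
    * parallel — one per-step rate per path (each path is internally uniform);
    * layered — the single shared step rate, repeated ``N_ly + 1`` times
      (entry into layer 1, N_ly - 1 inter-layer steps, exit to M).

    ``k_A`` is the aggregate exit rate from the initial state (equals the
    first step rate for a chain).
    """

    step_rates: tuple[float, ...]
    k_A: float

    def __post_init__(self) -> None:
        if any(not (r > 0) for r in self.step_rates):
            raise ValueError("all step rates must be > 0")
        if not (self.k_A > 0):
            raise ValueError("k_A must be > 0")


_SCENARIO_KEYS = {
    "delta_E",
    "k0",
    "calibration",
    "variant",
    "N_int",
    "N_pth",
    "N_ly",
    "stabilized",
}


@dataclass(frozen=True)
class ScenarioConfig:
    """A fully parsed scenario: energy model + topology + optional stabilization."""

    energy: EnergyConfig
    topology: TopologySpec
    stabilized: StabilizedSpec | None = None
    calibration: CalibrationSpec | None = None

    def __post_init__(self) -> None:
        if self.stabilized is not None and self.topology.variant != "chain":
            raise ValueError("a stabilized state is only valid on a chain topology")
        if self.stabilized is not None and self.stabilized.S > self.topology.N_int:
            raise ValueError(
                f"stabilized index S={self.stabilized.S} exceeds N_int={self.topology.N_int}"
            )


def _reject_unknown(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")


def scenario_from_dict(raw: dict) -> ScenarioConfig:
    """Build a :class:`ScenarioConfig` from a plain mapping, rejecting unknown keys."""
    if not isinstance(raw, dict):
        raise ValueError("scenario config must be a mapping")
    _reject_unknown(raw, _SCENARIO_KEYS, "scenario")

    calibration = None
    if "calibration" in raw:
        cal_raw = raw["calibration"]
        _reject_unknown(cal_raw, {"k_fit", "N_fit"}, "calibration")
        calibration = CalibrationSpec(**cal_raw)

    delta_E = float(raw.get("delta_E", 0.0))
    if calibration is not None:
        if "k0" in raw:
            raise ValueError("give either k0 or calibration, not both")
        # local import to avoid a config <-> rates cycle at module load
        from .rates import calibrate_k0

        k0 = calibrate_k0(delta_E, calibration)
    else:
        k0 = float(raw.get("k0", 1.0))
    energy = EnergyConfig(delta_E=delta_E, k0=k0)

    topology = TopologySpec(
        variant=raw.get("variant", "chain"),
        N_int=int(raw.get("N_int", 0)),
        N_pth=raw.get("N_pth"),
        N_ly=raw.get("N_ly"),
    )

    stabilized = None
    if "stabilized" in raw and raw["stabilized"] is not None:
        stab_raw = raw["stabilized"]
        _reject_unknown(stab_raw, {"S", "m", "case"}, "stabilized")
        stabilized = StabilizedSpec(**stab_raw)

    return ScenarioConfig(
        energy=energy, topology=topology, stabilized=stabilized, calibration=calibration
    )


def load_scenario(path) -> ScenarioConfig:
    """Parse a YAML scenario file (strict: unknown keys are an error)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return scenario_from_dict(raw if raw is not None else {})
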