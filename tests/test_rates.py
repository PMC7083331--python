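"""Rate assignment, calibration and topology splitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emtkinetics import (
    CalibrationSpec,
    EnergyConfig,
    StabilizedSpec,
    TopologySpec,
    calibrate_k0,
    split_layers,
    split_paths,
    step_rates,
)
from emtkinetics.config import scenario_from_dict
from emtkinetics.rates import chain_step_rate

CAL = CalibrationSpec(k_fit=3.4261, N_fit=9)


@pytest.mark.parametrize(
    "delta_E, expected",
    [
        (0.0, 3.4261),  # exp(0) = 1
        (10.0, 3.4261 * math.e),  # one e-fold over the 10 steps
        (5.0, 3.4261 * math.exp(0.5)),
    ],
)
def test_calibrate_k0_examples(delta_E, expected):
    assert calibrate_k0(delta_E, CAL) == pytest.approx(expected, rel=1e-12)


def test_calibrate_k0_roundtrip_identity():
    """Calibration composed with the chain rate formula is the identity on k_fit."""
    for dE in (0.0, 1.0, 4.2, 10.0, 25.0):
        k0 = calibrate_k0(dE, CAL)
        k = chain_step_rate(EnergyConfig(delta_E=dE, k0=k0), CAL.N_fit)
        assert abs(k - CAL.k_fit) / CAL.k_fit < 1e-12


def test_calibrate_k0_rejects_negative_barrier():
    with pytest.raises(ValueError):
        calibrate_k0(-1.0, CAL)


class TestStepRates:
    def test_chain_zero_barrier_gives_k0(self):
        ra = step_rates(EnergyConfig(0.0, 1.0), TopologySpec("chain", 3))
        assert ra.step_rates == (1.0,) * 4

    def test_calibrated_chain_recovers_fitted_rate(self):
        e = EnergyConfig(10.0, calibrate_k0(10.0, CAL))
        ra = step_rates(e, TopologySpec("chain", 9))
        assert all(k == pytest.approx(3.4261, rel=1e-12) for k in ra.step_rates)

    def test_stabilized_constant_total_rates(self):
        # regular barrier dE/(N+m), stabilized barrier m*dE/(N+m)
        ra = step_rates(
            EnergyConfig(10.0, 1.0),
            TopologySpec("chain", 9),
            StabilizedSpec(S=6, m=6.0, case="constant_total"),
        )
        assert ra.step_rates[0] == pytest.approx(math.exp(-10 / 15), rel=1e-12)
        assert ra.step_rates[6] == pytest.approx(math.exp(-4.0), rel=1e-12)
        # barrier bookkeeping: 9 regular steps + one stabilized step sum to dE
        barriers = [-math.log(k) for k in ra.step_rates]
        assert sum(barriers) == pytest.approx(10.0, abs=1e-12)

    def test_stabilized_varying_total_path_barrier(self):
        N, m, dE = 9, 4.0, 8.0
        ra = step_rates(
            EnergyConfig(dE, 1.0),
            TopologySpec("chain", N),
            StabilizedSpec(S=3, m=m, case="varying_total"),
        )
        barriers = [-math.log(k) for k in ra.step_rates]
        assert sum(barriers) == pytest.approx(dE + (m - 1) * dE / (N + 1), abs=1e-12)

    def test_parallel_per_path_rates_and_aggregate(self):
        ra = step_rates(EnergyConfig(6.0, 2.0), TopologySpec("parallel", 9, N_pth=2))
        k4 = 2.0 * math.exp(-6.0 / 5)
        k5 = 2.0 * math.exp(-6.0 / 6)
        assert ra.step_rates == pytest.approx((k4, k5), rel=1e-12)
        assert ra.k_A == pytest.approx(k4 + k5, rel=1e-12)

    def test_layered_rates(self):
        ra = step_rates(EnergyConfig(5.0, 1.0), TopologySpec("layered", 9, N_ly=3))
        k = math.exp(-5.0 / 4)
        assert all(r == pytest.approx(k, rel=1e-12) for r in ra.step_rates)
        assert ra.k_A == pytest.approx(3 * k, rel=1e-12)  # N_L1 = 3

    def test_stabilized_requires_chain(self):
        with pytest.raises(ValueError):
            step_rates(
                EnergyConfig(1.0, 1.0),
                TopologySpec("parallel", 4, N_pth=2),
                StabilizedSpec(S=1, m=2.0),
            )

    def test_substabilizing_ratio_rejected(self):
        with pytest.raises(ValueError):
            StabilizedSpec(S=1, m=0.5)

    def test_deterministic(self):
        args = (EnergyConfig(7.3, 1.1), TopologySpec("parallel", 7, N_pth=3))
        assert step_rates(*args) == step_rates(*args)


@pytest.mark.parametrize(
    "n_int, n_pth, expected",
    [(9, 2, [4, 5]), (9, 1, [9]), (10, 4, [2, 2, 3, 3]), (9, 9, [1] * 9)],
)
def test_split_paths(n_int, n_pth, expected):
    assert split_paths(n_int, n_pth) == expected


@pytest.mark.parametrize(
    "n_int, n_ly, sizes, n_l1",
    [(9, 3, [3, 3, 3], 3), (15, 4, [4, 4, 4, 3], 4), (9, 9, [1] * 9, 1)],
)
def test_split_layers(n_int, n_ly, sizes, n_l1):
    got_sizes, got_n_l1 = split_layers(n_int, n_ly)
    assert got_sizes == sizes
    assert got_n_l1 == n_l1
    assert got_n_l1 == math.ceil(n_int / n_ly)


@pytest.mark.parametrize("fn", [split_paths, split_layers])
def test_split_rejects_empty_branches(fn):
    with pytest.raises(ValueError):
        fn(3, 4)


@given(n_int=st.integers(1, 60), n_branch=st.integers(1, 60))
@settings(derandomize=True, max_examples=120, deadline=None)
def test_split_invariants(n_int, n_branch):
    """Sizes sum to N_int, differ by at most one, and obey the stated ordering."""
    if n_branch > n_int:
        return
    sizes = split_paths(n_int, n_branch)
    assert sum(sizes) == n_int and max(sizes) - min(sizes) <= 1
    assert sizes == sorted(sizes)
    lsizes, n_l1 = split_layers(n_int, n_branch)
    assert sum(lsizes) == n_int and max(lsizes) - min(lsizes) <= 1
    assert lsizes == sorted(lsizes, reverse=True) and n_l1 == lsizes[0]


@given(
    delta_E=st.floats(0.0, 30.0),
    n_int=st.integers(1, 12),
    s=st.integers(1, 12),
    m=st.floats(1.0, 8.0),
    case=st.sampled_from(["constant_total", "varying_total"]),
)
@settings(derandomize=True, max_examples=150, deadline=None)
def test_barrier_sum_invariant(delta_E, n_int, s, m, case):
    """Per-step barriers -ln(rate/k0) along the path sum to the stated total."""
    if s > n_int:
        return
    ra = step_rates(
        EnergyConfig(delta_E, 1.0),
        TopologySpec("chain", n_int),
        StabilizedSpec(S=s, m=m, case=case),
    )
    total = sum(-math.log(k) for k in ra.step_rates)
    if case == "constant_total":
        assert abs(total - delta_E) < 1e-10
    else:
        assert abs(total - (delta_E + (m - 1) * delta_E / (n_int + 1))) < 1e-10


class TestScenarioConfig:
    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown key"):
            scenario_from_dict({"delta_E": 1.0, "bogus": 2})

    def test_calibration_and_k0_exclusive(self):
        with pytest.raises(ValueError):
            scenario_from_dict(
                {"delta_E": 1.0, "k0": 2.0, "calibration": {"k_fit": 3.4, "N_fit": 9}}
            )

    def test_full_scenario_parses(self):
        sc = scenario_from_dict(
            {
                "delta_E": 10.0,
                "calibration": {"k_fit": 3.4261, "N_fit": 9},
                "variant": "chain",
                "N_int": 9,
                "stabilized": {"S": 6, "m": 6, "case": "constant_total"},
            }
        )
        assert sc.energy.k0 == pytest.approx(3.4261 * math.e, rel=1e-12)
        assert sc.stabilized.S == 6

    def test_stabilized_on_parallel_rejected(self):
        with pytest.raises(ValueError):
            scenario_from_dict(
                {
                    "delta_E": 1.0,
                    "variant": "parallel",
                    "N_int": 4,
                    "N_pth": 2,
                    "stabilized": {"S": 1, "m": 2},
                }
            )
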