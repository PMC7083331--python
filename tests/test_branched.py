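"""Parallel and layered kinetics vs ODE and Monte Carlo oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emtkinetics import (
    EnergyConfig,
    TopologySpec,
    compare_topologies,
    fat_mfat_chain,
    layered_kinetics,
    layered_mfat,
    parallel_kinetics,
    parallel_mfat,
    split_layers,
    split_paths,
    step_rates,
)
from emtkinetics._util import mfat_from_density
from emtkinetics.gillespie import SimConfig, build_transition_system, simulate_cells

from conftest import expm_occupancy

TIMES = np.array([0.0, 0.2, 1.0, 3.0, 8.0])


class TestParallel:
    def test_single_path_reduces_to_chain(self):
        energy = EnergyConfig(4.0, 1.0)
        sol = parallel_kinetics([9], energy, times=TIMES)
        k = step_rates(energy, TopologySpec("chain", 9)).step_rates[0]
        chain = fat_mfat_chain(k, 9, TIMES)
        assert sol.mfat == pytest.approx(chain.mfat, rel=1e-12)
        np.testing.assert_allclose(sol.fat.density, chain.density, atol=1e-9)

    def test_two_single_state_paths_hand_solution(self):
        # 1/k_A to leave E (k_A = 2) plus one unit-rate step: 0.5 + 1 = 1.5
        sol = parallel_kinetics([1, 1], EnergyConfig(0.0, 1.0))
        assert sol.mfat == pytest.approx(1.5, rel=1e-12)

    def test_two_single_state_paths_monte_carlo(self, rng):
        """First-step analysis vs direct Monte Carlo of the jump process."""
        n = 100_000
        t_exit = rng.exponential(1 / 2.0, n)  # leave E at rate 2
        t_step = rng.exponential(1.0, n)  # one intermediate step either path
        emp = (t_exit + t_step).mean()
        se = (t_exit + t_step).std() / np.sqrt(n)
        assert abs(parallel_kinetics([1, 1], EnergyConfig(0.0, 1.0)).mfat - emp) < 3 * se

    def test_printed_form_discrepancy_documented(self):
        """The literal per-path reading of the textbook MFAT differs (1.0 vs 1.5)."""
        sol = parallel_kinetics([1, 1], EnergyConfig(0.0, 1.0))
        assert sol.mfat_printed == pytest.approx(1.0, rel=1e-12)
        assert sol.mfat != sol.mfat_printed

    @pytest.mark.parametrize("delta_E", [1.0, 6.0, 12.0])
    def test_fat_normalized(self, delta_E):
        sol = parallel_kinetics([4, 5], EnergyConfig(delta_E, 1.0))
        sol.fat.validate(mass_tol=1e-6)

    def test_occupancy_matches_expm_oracle(self):
        energy = EnergyConfig(6.0, 1.0)
        topo = TopologySpec("parallel", 9, N_pth=2)
        sys = build_transition_system(topo, step_rates(energy, topo))
        oracle = expm_occupancy(sys.generator(), TIMES)
        sol = parallel_kinetics([4, 5], energy, times=TIMES)
        np.testing.assert_allclose(sol.occupancy.probs, oracle, atol=1e-9)

    def test_mfat_closed_form_matches_quadrature(self):
        sol = parallel_kinetics([2, 3, 4], EnergyConfig(5.0, 1.0))
        quad = mfat_from_density(sol.fat_density, 60 * sol.mfat)
        assert quad == pytest.approx(sol.mfat, rel=1e-6)

    def test_occupancy_stable_at_large_rate_separation(self):
        """No catastrophic cancellation for widely separated k_i, k_A."""
        sol = parallel_kinetics([1, 8], EnergyConfig(24.0, 50.0), times=np.linspace(0, 400, 50))
        assert np.all(np.isfinite(sol.occupancy.probs))
        sol.occupancy.validate(atol=1e-7)


class TestLayered:
    def test_single_wide_layer_hand_solution(self):
        # exit E at 3k then three layer steps... N_ly=3, N_L1=3, k=1: 3 + 1/3
        sol = layered_kinetics(9, 3, EnergyConfig(0.0, 1.0))
        assert sol.mfat == pytest.approx(3 + 1 / 3, rel=1e-12)

    def test_one_state_layers_reduce_to_chain(self):
        energy = EnergyConfig(4.0, 1.0)
        sol = layered_kinetics(9, 9, energy, times=TIMES)  # N_L1 = 1
        k = step_rates(energy, TopologySpec("layered", 9, N_ly=9)).step_rates[0]
        chain = fat_mfat_chain(k, 9, TIMES)
        assert sol.mfat == pytest.approx(chain.mfat, rel=1e-12)
        np.testing.assert_allclose(sol.fat.density, chain.density, atol=1e-9)

    def test_layer_aggregate_matches_expm_oracle(self):
        energy = EnergyConfig(5.0, 1.0)
        topo = TopologySpec("layered", 9, N_ly=3)
        sys = build_transition_system(topo, step_rates(energy, topo))
        p = expm_occupancy(sys.generator(), TIMES)
        sizes, _ = split_layers(9, 3)
        agg = [p[:, 0]]
        off = 1
        for s in sizes:
            agg.append(p[:, off : off + s].sum(axis=1))
            off += s
        agg.append(p[:, -1])
        sol = layered_kinetics(9, 3, energy, times=TIMES)
        np.testing.assert_allclose(sol.occupancy.probs, np.column_stack(agg), atol=1e-9)

    def test_mfat_matches_quadrature(self):
        sol = layered_kinetics(15, 4, EnergyConfig(5.0, 1.0))
        quad = mfat_from_density(sol.fat_density, 60 * sol.mfat)
        assert quad == pytest.approx(sol.mfat, rel=1e-6)

    def test_conservation(self):
        sol = layered_kinetics(9, 3, EnergyConfig(5.0, 1.0), times=np.linspace(0, 30, 40))
        sol.occupancy.validate(atol=1e-7)

    def test_gillespie_mfat_agreement(self):
        """Empirical MFAT of the wired layered system within 3 SE of closed form."""
        energy = EnergyConfig(2.0, 1.0)
        topo = TopologySpec("layered", 9, N_ly=3)
        sys = build_transition_system(topo, step_rates(energy, topo))
        trs = simulate_cells(sys, SimConfig(n_cells=4000, T_max=500.0, seed=11))
        fat = np.array([t.times[-1] for t in trs if t.absorbed])
        assert fat.size == 4000
        se = fat.std() / np.sqrt(fat.size)
        assert abs(fat.mean() - layered_mfat(9, 3, energy)) < 3 * se


@given(
    n_int=st.integers(2, 6),
    n_branch=st.integers(2, 4),
    delta_E=st.floats(0.0, 10.0),
    t=st.floats(0.01, 20.0),
)
@settings(derandomize=True, max_examples=60, deadline=None)
def test_branched_occupancy_property(n_int, n_branch, delta_E, t):
    """Hypoexponential closed forms equal the master-equation solution."""
    if n_branch > n_int:
        return
    energy = EnergyConfig(delta_E, 1.0)
    topo = TopologySpec("parallel", n_int, N_pth=n_branch)
    sys = build_transition_system(topo, step_rates(energy, topo))
    oracle = expm_occupancy(sys.generator(), [t])[0]
    sol = parallel_kinetics(split_paths(n_int, n_branch), energy, times=[t])
    np.testing.assert_allclose(sol.occupancy.probs[0], oracle, atol=1e-7)


class TestCompare:
    def test_single_crossing_for_fifteen_states_four_branches(self):
        table, brackets = compare_topologies(15, 4, np.linspace(0.5, 30.0, 60))
        assert len(brackets) == 1
        lo, _ = brackets[0]
        # parallel faster below the crossing, slower above
        below = table[table["delta_E"] < lo]["diff"]
        above = table[table["delta_E"] > brackets[0][1]]["diff"]
        assert np.all(below < 0) and np.all(above > 0)

    def test_degenerate_equality_at_zero_barrier(self):
        # [1,1]-parallel and 2-wide single layer coincide at dE = 0
        energy = EnergyConfig(0.0, 1.0)
        assert parallel_mfat([1, 1], energy) == pytest.approx(
            layered_mfat(2, 1, energy), rel=1e-12
        )

    def test_curves_increasing_in_barrier(self):
        table, _ = compare_topologies(15, 4, np.linspace(0.0, 20.0, 30))
        assert np.all(np.diff(table["mfat_parallel"]) > 0)
        assert np.all(np.diff(table["mfat_layered"]) > 0)
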