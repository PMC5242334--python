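"""Multicanonical energy: DOS estimation, interpolation contract, updates,
flatness arithmetic."""

import numpy as np
import pytest

from vmcmd import (
    Conformation,
    Ensemble,
    MulticanonicalPotential,
    emc_value_and_derivative,
    estimate_initial_emc,
    flatness_metric,
    harmonic_potential,
    multicanonical_force,
    update_emc,
)
from vmcmd.constants import R_GAS
from vmcmd.errors import CoverageGapError, InsufficientSamplingError, InvalidParameterError
from vmcmd.mcenergy import flatness_from_counts


def _energy_ensemble(energies, kind="multicanonical", dim=1):
    """Minimal ensemble carrying just an energy series."""
    energies = np.asarray(energies, dtype=float)
    n = len(energies)
    return Ensemble(
        np.zeros((n, dim)), energies, np.full(n, -1), np.zeros(n, int),
        np.arange(n), model_name="synthetic", sampling_kind=kind,
    )


class TestInterpolationContract:
    def test_grid_nodes_reproduced_exactly(self, rng):
        grid = np.linspace(0.0, 10.0, 50)
        vals = np.sin(grid) + 0.3 * grid
        pot = MulticanonicalPotential(grid, vals, 300.0, (280.0, 600.0))
        np.testing.assert_array_equal(pot.value(grid), vals)

    def test_linear_extrapolation_with_boundary_slope(self):
        grid = np.linspace(1.0, 5.0, 30)
        pot = MulticanonicalPotential(grid, grid**2, 300.0, (280.0, 600.0))
        hi_slope = pot.derivative(5.0)
        assert pot.value(6.5) == pytest.approx(pot.value(5.0) + 1.5 * hi_slope)
        lo_slope = pot.derivative(1.0)
        assert pot.value(0.0) == pytest.approx(pot.value(1.0) - 1.0 * lo_slope)
        # the slope itself is constant outside the grid
        assert pot.derivative(100.0) == pytest.approx(hi_slope)

    def test_identity_table_has_unit_slope(self):
        pot = MulticanonicalPotential.identity(0.0, 10.0, 300.0)
        v, s = emc_value_and_derivative(pot, 3.7)
        assert v == pytest.approx(3.7)
        assert s == pytest.approx(1.0)
        np.testing.assert_allclose(pot.derivative(np.linspace(0, 10, 17)), 1.0)


class TestMulticanonicalForce:
    def test_identity_table_gives_canonical_force(self):
        m = harmonic_potential(3, 2.0)
        pot = MulticanonicalPotential.identity(0.0, 50.0, 300.0)
        x = Conformation(np.array([1.0, -2.0, 0.5]))
        np.testing.assert_allclose(multicanonical_force(pot, m, x), -m.gradient(x.coordinates))

    def test_flat_table_gives_zero_force(self):
        m = harmonic_potential(2, 1.0)
        grid = np.linspace(0.0, 50.0, 40)
        pot = MulticanonicalPotential(grid, np.zeros(40), 300.0, (280.0, 600.0))
        np.testing.assert_allclose(
            multicanonical_force(pot, m, Conformation(np.array([2.0, 1.0]))), 0.0, atol=1e-12
        )

    def test_chain_rule_matches_finite_differences(self, rng):
        """f = -dE_mc/dE * grad E agrees with numerical differentiation of
        the composite map x -> E_mc(E(x))."""
        m = harmonic_potential(2, 1.0)
        grid = np.linspace(0.05, 30.0, 200)
        pot = MulticanonicalPotential(grid, R_GAS * 300 * np.log(grid), 300.0, (280, 600))
        for _ in range(10):
            x = rng.normal(scale=2.0, size=2)
            f = multicanonical_force(pot, m, Conformation(x))
            h = 1e-6
            fd = np.empty(2)
            for i in range(2):
                xp, xm = x.copy(), x.copy()
                xp[i] += h
                xm[i] -= h
                fd[i] = -(pot.value(m.energy(xp)) - pot.value(m.energy(xm))) / (2 * h)
            np.testing.assert_allclose(f, fd, rtol=1e-5, atol=1e-9)


class TestEstimateInitialEmc:
    def test_single_temperature_is_a_coverage_gap(self):
        ens = _energy_ensemble(np.linspace(1, 2, 100), kind="canonical")
        with pytest.raises(CoverageGapError):
            estimate_initial_emc([(300.0, ens)], T_sim=300.0)

    def test_disjoint_histograms_name_the_gap(self):
        lo = _energy_ensemble(np.linspace(0, 1, 200), kind="canonical")
        hi = _energy_ensemble(np.linspace(10, 11, 200), kind="canonical")
        with pytest.raises(CoverageGapError) as e:
            estimate_initial_emc(
                [(300.0, lo), (400.0, hi)], T_sim=300.0,
                grid_spec=(0.0, 11.0, 110), min_count=1,
            )
        assert e.value.gap is not None
        g0, g1 = e.value.gap
        assert 0.5 < g0 < g1 < 10.5

    def test_equal_temperature_runs_pool_like_one(self):
        rng = np.random.default_rng(0)
        e1 = rng.gamma(3.0, 0.6, size=4000)
        e2 = rng.gamma(3.0, 0.6, size=4000)
        e3 = rng.gamma(3.0, 0.9, size=4000)
        spec = (0.05, 8.0, 80)
        split = estimate_initial_emc(
            [(300.0, _energy_ensemble(e1)), (300.0, _energy_ensemble(e2)),
             (450.0, _energy_ensemble(e3))],
            T_sim=300.0, grid_spec=spec,
        )
        pooled = estimate_initial_emc(
            [(300.0, _energy_ensemble(np.concatenate([e1, e2]))),
             (450.0, _energy_ensemble(e3))],
            T_sim=300.0, grid_spec=spec,
        )
        np.testing.assert_array_equal(split.emc_values, pooled.emc_values)

    def test_exact_histograms_recover_analytic_dos(self):
        """Deterministic quadrature histograms (no sampling noise) recover
        ln n up to an affine map to better than 1% of its range."""
        d = 6
        edges = np.linspace(0.05, 12.0, 161)
        centers = 0.5 * (edges[:-1] + edges[1:])
        runs = []
        for T in (280.0, 400.0, 600.0):
            beta = 1.0 / (R_GAS * T)
            pdf = centers ** (d / 2 - 1) * np.exp(-beta * centers)
            counts = np.round(4e5 * pdf / pdf.sum()).astype(int)
            energies = np.repeat(centers, counts)
            runs.append((T, _energy_ensemble(energies, kind="canonical")))
        pot = estimate_initial_emc(runs, T_sim=300.0, grid_spec=(0.05, 12.0, 160),
                                   smoothing_knots=10)
        inner = (pot.energy_grid > 0.4) & (pot.energy_grid < 10.0)
        est = pot.emc_values[inner]
        exact = R_GAS * 300.0 * (d / 2 - 1) * np.log(pot.energy_grid[inner])
        A = np.column_stack([np.ones(inner.sum()), pot.energy_grid[inner]])
        resid = est - exact - A @ np.linalg.lstsq(A, est - exact, rcond=None)[0]
        assert np.max(np.abs(resid)) < 0.01 * (exact.max() - exact.min())


class TestUpdateEmc:
    def _flat_vmc_pot(self):
        grid = np.linspace(0.0, 10.0, 80)
        return MulticanonicalPotential(grid, 0.1 * grid**1.5, 300.0, (280, 600))

    def test_flat_histogram_is_a_fixed_point(self):
        pot = self._flat_vmc_pot()
        energies = np.tile(np.linspace(0.05, 9.95, 80), 50)
        new = update_emc(pot, _energy_ensemble(energies))
        diff = new.emc_values - pot.emc_values
        assert np.max(np.abs(diff)) < 1e-6
        assert new.iteration == pot.iteration + 1

    def test_overpopulated_region_is_raised(self):
        pot = self._flat_vmc_pot()
        base = np.tile(np.linspace(0.05, 9.95, 80), 40)
        bump = np.random.default_rng(1).normal(5.0, 0.4, size=1200)
        energies = np.concatenate([base, bump[(bump > 0) & (bump < 10)]])
        new = update_emc(pot, _energy_ensemble(energies))
        delta = new.emc_values - pot.emc_values
        mid = np.argmin(np.abs(pot.energy_grid - 5.0))
        edge = np.argmin(np.abs(pot.energy_grid - 1.0))
        assert delta[mid] > delta[edge]

    def test_insufficient_coverage_lists_empty_bins(self):
        pot = self._flat_vmc_pot()
        energies = np.linspace(4.0, 5.0, 500)  # covers a sliver of the grid
        with pytest.raises(InsufficientSamplingError) as e:
            update_emc(pot, _energy_ensemble(energies))
        assert len(e.value.empty_bins) > 0


class TestFlatness:
    def test_equal_counts_are_perfectly_flat(self):
        assert flatness_from_counts([7, 7, 7, 7]) == 0.0

    def test_two_bin_arithmetic(self):
        assert flatness_from_counts([2, 1]) == pytest.approx(1.0 / 3.0)

    def test_edge_bins_excluded_when_requested(self):
        # interior bins are equal; edges differ wildly
        assert flatness_from_counts([100, 5, 5, 5, 0], exclude_edges=True) == 0.0

    def test_empty_window_raises(self):
        ens = _energy_ensemble(np.linspace(0, 1, 50))
        with pytest.raises(InsufficientSamplingError):
            flatness_metric(ens, (5.0, 6.0))
        with pytest.raises(InvalidParameterError):
            flatness_metric(ens, (1.0, 1.0))

    def test_uniform_energies_are_flat(self):
        ens = _energy_ensemble(np.tile(np.linspace(0.0, 1.0, 200), 10))
        assert flatness_metric(ens, (0.0, 1.0)) < 0.05
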