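"""Virtual-state ladder, transition rule, V-McMD runs and the iteration
protocol."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from vmcmd import (
    Ensemble,
    MulticanonicalPotential,
    build_ladder,
    harmonic_potential,
    iterate_vmcmd,
    transition_acceptance,
    ttp_run,
    virtual_transition,
    vmcmd_run,
)
from vmcmd.constants import R_GAS
from vmcmd.errors import InvalidParameterError, InvalidStateError
from vmcmd.mcenergy import flatness_metric
from vmcmd.vsampler import VirtualStateLadder


def _analytic_harmonic_pot(lo=0.2, hi=10.6, n=150):
    grid = np.linspace(lo, hi, n)
    return MulticanonicalPotential(grid, R_GAS * 300 * 2 * np.log(grid), 300.0, (280.0, 600.0))


class TestLadderConstruction:
    def test_three_zone_worked_example(self):
        lad = build_ladder(0.0, 100.0, 3, overlap_fraction=0.25)
        np.testing.assert_allclose(lad.zones, [[0, 40], [30, 70], [60, 100]], atol=1e-9)
        # adjacent overlap nonempty, next-nearest empty
        assert lad.zones[1, 0] < lad.zones[0, 1]
        assert lad.zones[2, 0] >= lad.zones[0, 1]

    def test_single_zone_ladder(self):
        lad = build_ladder(-2.0, 7.0, 1)
        np.testing.assert_allclose(lad.zones, [[-2.0, 7.0]])

    @pytest.mark.parametrize("frac", [0.5, 0.6, 0.0, -0.1])
    def test_bad_overlap_fraction_rejected(self, frac):
        with pytest.raises(InvalidParameterError):
            build_ladder(0.0, 100.0, 3, overlap_fraction=frac)

    def test_invalid_explicit_zones_rejected(self):
        with pytest.raises(InvalidParameterError):
            VirtualStateLadder([[0, 40], [50, 70]])  # no adjacent overlap
        with pytest.raises(InvalidParameterError):
            VirtualStateLadder([[0, 40], [30, 70], [35, 100]])  # 0 and 2 overlap

    @given(
        e_low=st.floats(-50, 50),
        span=st.floats(1.0, 500.0),
        n_vs=st.integers(1, 10),
        frac=st.floats(0.01, 0.49),
    )
    def test_ladder_invariants_hold_for_random_parameters(self, e_low, span, n_vs, frac):
        lad = build_ladder(e_low, e_low + span, n_vs, overlap_fraction=frac)
        z = lad.zones
        assert np.all(np.diff(z[:, 0]) > 0) or n_vs == 1
        assert np.all(np.diff(z[:, 1]) > 0) or n_vs == 1
        if n_vs >= 2:
            assert np.all(z[1:, 0] < z[:-1, 1])  # adjacent overlap
        if n_vs >= 3:
            assert np.all(z[2:, 0] >= z[:-2, 1])  # next-nearest disjoint
        assert lad.coverage == (pytest.approx(e_low), pytest.approx(e_low + span))


class TestTransitionRule:
    def test_acceptance_truth_table_over_random_probes(self, rng):
        """Acceptance is exactly 1 when the energy lies inside the proposed
        zone and exactly 0 otherwise (10^4 randomized probes)."""
        for _ in range(10):
            lo = rng.uniform(-20, 0)
            lad = build_ladder(lo, lo + rng.uniform(10, 200), rng.integers(2, 8),
                              overlap_fraction=rng.uniform(0.05, 0.45))
            span = lad.coverage[1] - lad.coverage[0]
            for _ in range(1000):
                j = int(rng.integers(0, lad.n_vs))
                E = rng.uniform(lad.coverage[0] - 0.2 * span, lad.coverage[1] + 0.2 * span)
                expected = 1.0 if lad.zones[j, 0] <= E <= lad.zones[j, 1] else 0.0
                assert transition_acceptance(E, j, lad) == expected

    def test_worked_zone_example(self):
        lad = VirtualStateLadder([[0, 40], [30, 70], [60, 100]])
        # energy 35 lies in the overlap of the first two zones
        assert transition_acceptance(35.0, 1, lad) == 1.0
        assert transition_acceptance(10.0, 1, lad) == 0.0
        # reversibility: both directions across an overlap are unit moves
        assert transition_acceptance(65.0, 2, lad) == 1.0
        assert transition_acceptance(65.0, 1, lad) == 1.0

    def test_virtual_transition_moves_only_into_containing_zones(self, rng):
        lad = VirtualStateLadder([[0, 40], [30, 70], [60, 100]])
        # E=35: from state 0 only staying or moving to state 1 is possible
        outcomes = {virtual_transition(35.0, 0, lad, rng) for _ in range(200)}
        assert outcomes == {0, 1}
        # E=10 is only in zone 0: from state 1 every proposal is rejected...
        assert all(virtual_transition(50.0, 1, lad, rng) == 1 for _ in range(100))
        # ...but E=10 from state 0 cannot leave either
        assert all(virtual_transition(10.0, 0, lad, rng) == 0 for _ in range(100))

    def test_out_of_range_state_raises(self, rng):
        lad = build_ladder(0.0, 10.0, 3)
        with pytest.raises(InvalidStateError):
            virtual_transition(5.0, 7, lad, rng)


class TestVmcmdRuns:
    def test_ttp_single_run_equals_vmcmd_run(self):
        m = harmonic_potential(6, 1.0)
        pot = _analytic_harmonic_pot()
        lad = build_ladder(0.2, 10.6, 4)
        start = m.conformation(np.full(6, np.sqrt(2 * 2.0 / 6)))
        solo = vmcmd_run(m, pot, lad, 3000, seed=5, start=start, record_every=10)
        pooled = ttp_run(m, pot, lad, 1, 3000, [start], seed_base=5, record_every=10)
        np.testing.assert_array_equal(solo.coordinates, pooled.coordinates)
        np.testing.assert_array_equal(solo.virtual_states, pooled.virtual_states)
        np.testing.assert_array_equal(solo.energies, pooled.energies)

    def test_rerun_is_bit_identical(self):
        m = harmonic_potential(6, 1.0)
        pot = _analytic_harmonic_pot()
        lad = build_ladder(0.2, 10.6, 4)
        start = m.conformation(np.full(6, np.sqrt(2 * 2.0 / 6)))
        a = vmcmd_run(m, pot, lad, 2000, seed=9, start=start)
        b = vmcmd_run(m, pot, lad, 2000, seed=9, start=start)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)

    def test_merge_order_does_not_change_pooled_statistics(self):
        m = harmonic_potential(6, 1.0)
        pot = _analytic_harmonic_pot()
        lad = build_ladder(0.2, 10.6, 4)
        start = m.conformation(np.full(6, np.sqrt(2 * 2.0 / 6)))
        runs = [
            vmcmd_run(m, pot, lad, 2000, seed=7, start=start, run_id=r)
            for r in range(3)
        ]
        bins = np.linspace(0.2, 10.6, 30)
        h_fwd = np.histogram(Ensemble.concatenate(runs).energies, bins=bins)[0]
        h_rev = np.histogram(Ensemble.concatenate(runs[::-1]).energies, bins=bins)[0]
        np.testing.assert_array_equal(h_fwd, h_rev)

    def test_duplicate_seeds_rejected(self):
        m = harmonic_potential(6, 1.0)
        pot = _analytic_harmonic_pot()
        lad = build_ladder(0.2, 10.6, 4)
        start = m.conformation(np.full(6, np.sqrt(2 * 2.0 / 6)))
        with pytest.raises(InvalidParameterError):
            ttp_run(m, pot, lad, 2, 100, [start, start], seeds=[5, 5])

    def test_single_zone_run_is_plain_multicanonical(self):
        """With one virtual state the sampler reduces to plain flat-histogram
        dynamics: the energy histogram under the analytic weight is flat."""
        m = harmonic_potential(6, 1.0)
        pot = _analytic_harmonic_pot()
        lad = build_ladder(0.2, 10.6, 1)
        starts = [m.conformation(np.full(6, np.sqrt(2 * 2.0 / 6))) for _ in range(8)]
        ens = ttp_run(m, pot, lad, 8, 30000, starts, seed_base=11,
                      record_every=20, burn_in=6000)
        assert flatness_metric(ens, (1.67, 3.58)) < 0.15
        assert set(np.unique(ens.virtual_states)) == {0}


class TestIterateProtocol:
    def test_infinite_target_runs_exactly_one_cycle(self):
        m = harmonic_potential(2, 1.0)
        _, ens = iterate_vmcmd(
            m, schedule=(2000, 2000, 2000), flatness_target=np.inf, seed=1,
            n_runs=2, seed_steps=5000, seed_burn_in=1000, grid_bins=60,
        )
        assert ens.metadata["iterations_run"] == 1
        assert ens.metadata["converged"]

    def test_identical_seeds_identical_ensembles(self):
        m = harmonic_potential(2, 1.0)
        kw = dict(schedule=(2000, 2000), flatness_target=0.0, seed=3, n_runs=2,
                  seed_steps=5000, seed_burn_in=1000, grid_bins=60)
        _, a = iterate_vmcmd(m, **kw)
        _, b = iterate_vmcmd(m, **kw)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)
        np.testing.assert_array_equal(a.energies, b.energies)
        assert not a.metadata["converged"]  # unreachable target is flagged, not raised

    def test_empty_schedule_rejected(self):
        with pytest.raises(InvalidParameterError):
            iterate_vmcmd(harmonic_potential(2, 1.0), schedule=())


class TestConvergedBenchmark:
    """Properties of the converged harmonic benchmark ensemble."""

    def test_every_state_visited_with_round_trips(self, harmonic_bench):
        ens = harmonic_bench["ensemble"]
        n_vs = harmonic_bench["ladder"].n_vs
        assert set(np.unique(ens.virtual_states)) == set(range(n_vs))
        trips = 0
        for r in np.unique(ens.run_ids):
            seq = ens.virtual_states[ens.run_ids == r]
            phase = 0  # 0: waiting for bottom, 1: climbing to top, 2: returning
            for s in seq:
                if phase == 0 and s == 0:
                    phase = 1
                elif phase == 1 and s == n_vs - 1:
                    phase = 2
                elif phase == 2 and s == 0:
                    trips += 1
                    phase = 1
        assert trips >= 5

    def test_zone_violations_are_rare(self, harmonic_bench):
        assert harmonic_bench["violation_fraction"] < 0.01
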