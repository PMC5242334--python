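"""Reweighting, distance-PCA, PMF surfaces, basins and scalar descriptors."""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, strategies as st

from vmcmd import (
    Conformation,
    Ensemble,
    MulticanonicalPotential,
    canonical_expectation,
    canonical_weights,
    compute_fel,
    conformational_sigma,
    contribution_ratio,
    distance_features,
    feature_matrix,
    find_basins,
    fit_pca,
    generate_fixture_conformations,
    merge_state_distributions,
    project,
    radius_of_gyration,
)
from vmcmd.analysis import FELGrid, PCAModel
from vmcmd.constants import R_GAS
from vmcmd.errors import (
    CoverageGapError,
    DegenerateInputError,
    InvalidParameterError,
    InvalidSelectionError,
    TemperatureRangeError,
)
from vmcmd.vsampler import VirtualStateLadder


def _flat_pot(lo=0.0, hi=10.0):
    grid = np.linspace(lo, hi, 50)
    return MulticanonicalPotential(grid, np.zeros(50), 300.0, (280.0, 600.0))


def _ens(energies, states=None, runs=None, kind="multicanonical", dim=1):
    energies = np.asarray(energies, float)
    n = len(energies)
    return Ensemble(
        np.zeros((n, dim)), energies,
        np.full(n, -1) if states is None else np.asarray(states),
        np.zeros(n, int) if runs is None else np.asarray(runs),
        np.arange(n), model_name="synthetic", sampling_kind=kind,
    )


class TestCanonicalWeights:
    def test_single_energy_gives_uniform_weights(self):
        cw = canonical_weights(_ens([2.0] * 10), _flat_pot(), 300.0)
        np.testing.assert_allclose(cw.weights, 0.1)
        assert cw.effective_sample_size == pytest.approx(10.0)
        assert abs(cw.weights.sum() - 1.0) < 1e-12

    def test_flat_emc_weight_ratio_is_boltzmann(self):
        """With E_mc constant the weight ratio of two snapshots is
        exp(-(E1 - E2)/R_gas T)."""
        for T in (300.0, 450.0):
            cw = canonical_weights(_ens([1.0, 2.5]), _flat_pot(), T)
            ratio = cw.weights[0] / cw.weights[1]
            assert ratio == pytest.approx(np.exp((2.5 - 1.0) / (R_GAS * T)))

    def test_temperature_outside_design_range_refused(self):
        for T in (100.0, 700.0):
            with pytest.raises(TemperatureRangeError):
                canonical_weights(_ens([1.0, 2.0]), _flat_pot(), T)


class TestMergeStateDistributions:
    def _vmc_ens(self, e0, e1, zones=((0.0, 40.0), (30.0, 70.0))):
        energies = np.concatenate([e0, e1])
        states = np.concatenate([np.zeros(len(e0), int), np.ones(len(e1), int)])
        ens = _ens(energies, states=states, kind="v-mcmd")
        ens.metadata["ladder_zones"] = [list(z) for z in zones]
        ens.metadata["confinement_strength"] = 25.0
        ens.metadata["T_sim"] = 300.0
        return ens, VirtualStateLadder(np.array(zones))

    def test_consistent_flat_inputs_merge_flat(self):
        e0 = np.tile(np.linspace(0.5, 39.5, 79), 40)
        e1 = np.tile(np.linspace(30.5, 69.5, 79), 40)
        ens, lad = self._vmc_ens(e0, e1)
        md = merge_state_distributions(ens, lad, 35)
        occ = md.density[md.density > 0]
        assert occ.std() / occ.mean() < 0.1

    def test_scale_invariance_of_one_input(self):
        e0 = np.tile(np.linspace(0.5, 39.5, 79), 10)
        e1 = np.tile(np.linspace(30.5, 69.5, 79), 10)
        ens_a, lad = self._vmc_ens(e0, e1)
        ens_b, _ = self._vmc_ens(e0, np.tile(e1, 7))  # 7x the counts in state 1
        da = merge_state_distributions(ens_a, lad, 35).density
        db = merge_state_distributions(ens_b, lad, 35).density
        np.testing.assert_allclose(da, db, atol=1e-9)

    def test_empty_overlap_is_a_coverage_gap(self):
        ens, lad = self._vmc_ens(
            np.linspace(1, 25, 300), np.linspace(45, 69, 300)
        )
        with pytest.raises(CoverageGapError):
            merge_state_distributions(ens, lad, 35)


class TestCanonicalExpectation:
    def test_constant_observable_has_zero_error(self):
        ens = _ens(np.linspace(0, 5, 40), runs=np.repeat(np.arange(4), 10))
        cw = canonical_weights(ens, _flat_pot(), 300.0)
        mean, se = canonical_expectation(ens, cw, lambda s: 3.14)
        assert mean == pytest.approx(3.14)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_uniform_weights_give_plain_mean(self):
        vals = np.arange(20.0)
        ens = _ens(np.full(20, 2.0), runs=np.repeat(np.arange(4), 5))
        mean, _ = canonical_expectation(ens, np.full(20, 0.05), vals)
        assert mean == pytest.approx(vals.mean())

    def test_misaligned_weights_rejected(self):
        ens = _ens([1.0, 2.0])
        with pytest.raises(InvalidParameterError):
            canonical_expectation(ens, np.array([1.0]), lambda s: 0.0)


class TestDistanceFeatures:
    def test_seventeen_sites_give_136_pairs(self):
        conf = generate_fixture_conformations("helix", 17, 1)[0]
        assert distance_features(conf).n_pair == 136

    def test_two_sites(self):
        conf = Conformation(np.array([0, 0, 0, 3, 4, 0.0]), site_count=2)
        df = distance_features(conf)
        assert df.n_pair == 1
        assert df.values[0] == pytest.approx(5.0)

    def test_collinear_equally_spaced_sites(self):
        s = 2.5
        pts = np.array([[0, 0, i * s] for i in range(4)], float)
        df = distance_features(Conformation(pts.ravel(), site_count=4))
        assert sorted(df.values) == pytest.approx([s, s, s, 2 * s, 2 * s, 3 * s])

    @given(n=st.integers(2, 64))
    def test_pair_count_law(self, n):
        conf = Conformation(np.arange(3 * n, dtype=float), site_count=n)
        assert distance_features(conf).n_pair == n * (n - 1) // 2

    def test_single_site_selection_rejected(self):
        conf = generate_fixture_conformations("helix", 5, 1)[0]
        with pytest.raises(InvalidSelectionError):
            distance_features(conf, sites=[2])


class TestPCA:
    def test_rank_one_data(self, rng):
        t = rng.normal(size=50)
        X = np.outer(t, np.array([1.0, 2.0, -1.0])) + 5.0
        model = fit_pca(X)
        assert model.eigenvalues[1] == pytest.approx(0.0, abs=1e-10)
        assert contribution_ratio(model, 0) == pytest.approx(1.0)

    def test_matches_dense_eigensolver(self, rng):
        """Weighted PCA agrees with an independently computed covariance
        eigendecomposition to 1e-8, up to eigenvector sign."""
        X = rng.normal(size=(60, 12)) @ rng.normal(size=(12, 12))
        w = rng.uniform(0.5, 2.0, size=60)
        w /= w.sum()
        model = fit_pca(X, w)
        cov = np.cov(X.T, aweights=w, ddof=0)
        evals, evecs = scipy.linalg.eigh(cov)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        np.testing.assert_allclose(model.eigenvalues, evals, atol=1e-8)
        for k in range(12):
            dot = abs(np.dot(model.components[k], evecs[:, k]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_orthonormal_components_and_ratio_normalization(self, rng):
        model = fit_pca(rng.normal(size=(80, 7)))
        gram = model.components @ model.components.T
        np.testing.assert_allclose(gram, np.eye(7), atol=1e-10)
        total = sum(contribution_ratio(model, i) for i in range(7))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_isotropic_cloud_has_near_equal_eigenvalues(self, rng):
        model = fit_pca(rng.normal(size=(4000, 5)))
        assert model.eigenvalues[0] / model.eigenvalues[-1] < 1.3

    def test_contribution_ratio_arithmetic(self):
        model = PCAModel(np.zeros(2), np.eye(2), np.array([3.0, 1.0]), 4.0)
        assert contribution_ratio(model, 0) == pytest.approx(0.75)
        with pytest.raises(DegenerateInputError):
            contribution_ratio(PCAModel(np.zeros(2), np.eye(2), np.zeros(2), 0.0), 0)

    def test_degenerate_input(self):
        with pytest.raises(DegenerateInputError):
            fit_pca(np.ones((1, 4)))


class TestProjection:
    def test_scalar_product_semantics(self):
        comps = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        model = PCAModel(np.zeros(3), comps, np.array([2.0, 1.0]), 3.0)
        np.testing.assert_allclose(project(model, np.array([0.0, 0.0, 4.0])), [0.0, 0.0])
        np.testing.assert_allclose(project(model, np.array([1.0, 0.0, 0.0])), [1.0, 0.0])

    def test_dimension_mismatch(self):
        model = PCAModel(np.zeros(3), np.eye(3), np.ones(3), 3.0)
        with pytest.raises(InvalidParameterError):
            project(model, np.ones(5))

    def test_projected_variance_recovers_eigenvalues(self, rng):
        X = rng.normal(size=(500, 6)) * np.array([3.0, 2.0, 1.0, 0.5, 0.3, 0.1])
        model = fit_pca(X)
        P = project(model, X)
        for k in range(2):
            assert P[:, k].var() == pytest.approx(model.eigenvalues[k], rel=1e-8)


class TestFEL:
    def test_uniform_probability_is_flat_zero(self, rng):
        pts = rng.uniform(0, 1, size=(4000, 2))
        surf = compute_fel(pts, None, 300.0, (np.array([0, 0.5, 1.0]), np.array([0, 0.5, 1.0])))
        # four equal cells: all pmf values ~0 after zeroing the minimum
        assert np.nanmax(surf.pmf) < 0.05

    def test_two_cell_closed_form(self):
        pts = np.array([[0.25, 0.5], [0.75, 0.5]])
        w = np.array([0.8, 0.2])
        grid = (np.array([0.0, 0.5, 1.0]), np.array([0.0, 1.0]))
        surf = compute_fel(pts, w, 300.0, grid)
        dF = surf.pmf[1, 0] - surf.pmf[0, 0]
        assert dF == pytest.approx(R_GAS * 300.0 * np.log(4.0), abs=1e-12)
        assert surf.pmf[0, 0] == 0.0  # occupied minimum pinned at exactly zero

    def test_weight_scale_invariance(self):
        pts = np.array([[0.25, 0.5], [0.75, 0.5]])
        grid = (np.array([0.0, 0.5, 1.0]), np.array([0.0, 1.0]))
        a = compute_fel(pts, np.array([0.8, 0.2]), 300.0, grid)
        b = compute_fel(pts, np.array([0.4, 0.1]), 300.0, grid)
        np.testing.assert_array_equal(a.pmf, b.pmf)

    def test_empty_cells_are_nan_not_zero(self, rng):
        pts = rng.normal(size=(50, 2))
        surf = compute_fel(pts, None, 300.0, 20)
        assert np.isnan(surf.pmf[~surf.occupied]).all()
        assert np.nanmin(surf.pmf) == 0.0

    def test_explicit_grid_must_cover_points(self):
        pts = np.array([[0.0, 0.0], [5.0, 5.0]])
        grid = (np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        with pytest.raises(InvalidParameterError):
            compute_fel(pts, None, 300.0, grid)


def _grid_from_pmf(pmf):
    nx, ny = pmf.shape
    prob = np.where(np.isfinite(pmf), np.exp(-pmf), 0.0)
    return FELGrid(
        np.arange(nx + 1.0), np.arange(ny + 1.0), prob / prob.sum(), pmf, 300.0
    )


class TestBasins:
    def test_single_minimum_surface(self):
        x, y = np.meshgrid(np.linspace(-1, 1, 15), np.linspace(-1, 1, 15), indexing="ij")
        labels = find_basins(_grid_from_pmf(x**2 + y**2), 0.0)
        assert labels.max() == 0
        assert (labels >= 0).all()

    def test_two_minima_merge_below_cutoff(self):
        x = np.linspace(-1.5, 1.5, 31)
        pmf1d = (x**2 - 1.0) ** 2 * 2.0 + 0.25 * x  # two wells, barrier ~2
        pmf = np.tile(pmf1d[:, None], (1, 5))
        pmf -= pmf.min()
        assert find_basins(_grid_from_pmf(pmf), 1.0).max() + 1 == 2
        assert find_basins(_grid_from_pmf(pmf), 3.0).max() + 1 == 1

    def test_labels_invariant_under_global_shift(self):
        x = np.linspace(-1.5, 1.5, 31)
        pmf = np.tile(((x**2 - 1.0) ** 2 * 2.0 + 0.25 * x)[:, None], (1, 5))
        a = find_basins(_grid_from_pmf(pmf - pmf.min()), 0.5)
        b = find_basins(_grid_from_pmf(pmf - pmf.min() + 7.0), 0.5)
        np.testing.assert_array_equal(a, b)


class TestSigmaAndRg:
    def test_identical_conformations_have_zero_sigma(self):
        X = np.tile(np.arange(6.0), (5, 1))
        with pytest.warns(UserWarning):
            assert conformational_sigma(X[:1]) == 0.0
        assert conformational_sigma(X) == pytest.approx(0.0, abs=1e-12)

    def test_sigma_squared_equals_eigenvalue_sum(self, rng):
        confs = generate_fixture_conformations("random", 9, 40, noise=0.8, seed=3)
        X = feature_matrix(confs)
        w = rng.uniform(0.1, 1.0, size=40)
        model = fit_pca(X, w)
        sigma = conformational_sigma(X, w)
        assert sigma**2 == pytest.approx(model.eigenvalues.sum(), rel=1e-8)

    def test_sigma_is_homogeneous_in_scale(self):
        confs = generate_fixture_conformations("random", 7, 30, noise=0.5, seed=4)
        X = feature_matrix(confs)
        assert conformational_sigma(2.0 * X) == pytest.approx(2.0 * conformational_sigma(X))

    def test_rg_single_site_is_zero(self):
        assert radius_of_gyration(Conformation(np.zeros(3), site_count=1)) == 0.0

    def test_rg_two_sites_is_half_the_separation(self):
        conf = Conformation(np.array([0, 0, 0, 0, 0, 6.0]), site_count=2)
        assert radius_of_gyration(conf) == pytest.approx(3.0)

    def test_helix_more_compact_than_extended(self):
        helix = generate_fixture_conformations("helix", 17, 1)[0]
        ext = generate_fixture_conformations("extended", 17, 1)[0]
        assert radius_of_gyration(helix) < radius_of_gyration(ext)

    def test_label_based_selection(self):
        labels = ("H", "P", "H", "P")
        pts = np.array([[0, 0, 0], [10, 0, 0], [0, 0, 2], [10, 0, 2]], float)
        conf = Conformation(pts.ravel(), site_count=4, labels=labels)
        rg_h = radius_of_gyration(conf, ["H"])
        assert rg_h == pytest.approx(1.0)  # two H sites 2 A apart
        with pytest.raises(InvalidSelectionError):
            radius_of_gyration(conf, [])
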