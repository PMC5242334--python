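"""Reweighting of flat-histogram ensembles and free-energy-landscape
analytics.

A converged V-McMD ensemble covers a wide band of energies with a flat
histogram. Each snapshot of energy E is mapped back to the canonical
ensemble at temperature T by the weight

    w(E)  propto  exp[ E_mc(E) / (R_gas T_sim) - E / (R_gas T) ]

(the density of states reconstructed from E_mc times the Boltzmann factor,
divided by the flat sampling density). Ensembles sampled with a virtual
system additionally carry a zone-multiplicity factor m(E) -- energies in a
zone overlap are visited by two states -- which the weights divide out.

Conformations are featurized as the vector of pairwise site distances; the
eigensystem of the (weighted) distance covariance gives principal axes, and
the potential of mean force over the first two axes,
F = -R_gas T ln P(x_PC1, x_PC2) zeroed at its minimum, is the free-energy
landscape. Contribution ratios, the conformational spread sigma and radii
of gyration quantify the same ensembles scalar-wise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from scipy.special import logsumexp

from .constants import R_GAS
from .ensemble import Ensemble, Snapshot
from .errors import (
    CoverageGapError,
    DegenerateInputError,
    InvalidParameterError,
    InvalidSelectionError,
    TemperatureRangeError,
)
from .mcenergy import MulticanonicalPotential
from .models import Conformation

__all__ = [
    "CanonicalWeights",
    "DistanceFeatures",
    "PCAModel",
    "FELGrid",
    "MergedDistribution",
    "canonical_weights",
    "merge_state_distributions",
    "canonical_expectation",
    "distance_features",
    "feature_matrix",
    "fit_pca",
    "contribution_ratio",
    "project",
    "compute_fel",
    "find_basins",
    "conformational_sigma",
    "radius_of_gyration",
    "block_standard_error",
]


# ---------------------------------------------------------------------------
# canonical reweighting
# ---------------------------------------------------------------------------

@dataclass
class CanonicalWeights:
    """Per-snapshot canonical weights at temperature T (normalized to 1)."""

    weights: np.ndarray
    T: float
    effective_sample_size: float


def _multiplicity(ensemble: Ensemble):
    """Soft zone-multiplicity of each snapshot energy.

    The joint stationary density of the zone-confined sampler is
    pi(r, v) ~ exp[-(E_mc + wall_v)/R T_sim], so the energy marginal picks
    up the factor m(E) = sum_v exp(-wall_v(E)/R T_sim): exactly 2 inside
    zone overlaps, 1 in zone interiors, with soft wall shoulders in
    between. Canonical weights divide this factor out.
    """
    if ensemble.sampling_kind == "v-mcmd" and "ladder_zones" in ensemble.metadata:
        from .vsampler import soft_multiplicity

        return soft_multiplicity(
            ensemble.energies,
            ensemble.metadata["ladder_zones"],
            float(ensemble.metadata.get("confinement_strength", 25.0)),
            float(ensemble.metadata.get("T_sim", 300.0)),
            ensemble.metadata.get("wall_cap"),
        )
    return np.ones(len(ensemble))


def canonical_weights(
    ensemble: Ensemble, mcpot: MulticanonicalPotential, T: float
) -> CanonicalWeights:
    """Snapshot weights restoring the canonical distribution at T.

    T must lie inside the multicanonical design range [T_low, T_high]; the
    flat histogram carries no information outside it and extrapolation is
    refused.
    """
    lo, hi = mcpot.T_range
    if not lo <= T <= hi:
        raise TemperatureRangeError(
            f"T={T:g} K outside the multicanonical design range [{lo:g}, {hi:g}] K"
        )
    E = ensemble.energies
    logw = mcpot.value(E) / (R_GAS * mcpot.T_sim) - E / (R_GAS * T)
    logw = logw - np.log(_multiplicity(ensemble))
    logw -= logsumexp(logw)
    w = np.exp(logw)
    w /= w.sum()  # exact normalization after the stabilized pass
    ess = 1.0 / np.sum(w * w)
    return CanonicalWeights(weights=w, T=float(T), effective_sample_size=float(ess))


@dataclass
class MergedDistribution:
    """1-D energy distribution assembled from per-virtual-state histograms."""

    edges: np.ndarray
    density: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def merge_state_distributions(
    ensemble: Ensemble, ladder, bins=50, wall_trim: float | None = None
) -> MergedDistribution:
    """Integrate per-virtual-state energy histograms into one P_mc(E).

    Each state's histogram is rescaled by least squares against the running
    merged estimate inside the pairwise overlap windows, then combined as a
    count-weighted average and normalized. For a converged run the output is
    flat. Adjacent states must share at least one jointly occupied bin.

    Bins within ``wall_trim`` of a state's own zone boundaries are excluded
    from that state's histogram: the confinement wall suppresses them, and
    mixing wall-distorted with undistorted counts would dent the merged
    distribution at every zone edge. The default trim is twice the thermal
    width of the wall.
    """
    if isinstance(bins, (int, np.integer)):
        lo, hi = (ladder.coverage if ladder is not None
                  else (ensemble.energies.min(), ensemble.energies.max()))
        edges = np.linspace(lo, hi, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    nb = len(edges) - 1
    centers_all = 0.5 * (edges[:-1] + edges[1:])
    if wall_trim is None and ladder is not None:
        T_sim = float(ensemble.metadata.get("T_sim", 300.0))
        wall_trim = 2.0 * np.sqrt(R_GAS * T_sim / (2.0 * ladder.confinement_strength))
        if ladder.n_vs > 1:
            # never trim away more than a third of the narrowest overlap
            min_overlap = float(np.min(ladder.zones[:-1, 1] - ladder.zones[1:, 0]))
            wall_trim = min(wall_trim, min_overlap / 3.0)

    states = sorted(int(s) for s in np.unique(ensemble.virtual_states) if s >= 0)
    if not states:
        raise InvalidParameterError("ensemble has no virtual-state labels to merge")
    hists = {}
    for s in states:
        h = np.histogram(ensemble.energies[ensemble.virtual_states == s], bins=edges)[0]
        h = h.astype(float)
        if ladder is not None and wall_trim and s < ladder.n_vs:
            zlo, zhi = ladder.zones[s]
            # interior zone edges only: the outermost ladder boundaries have
            # no neighbouring state to supply undistorted counts
            if s > 0:
                h[centers_all < zlo + wall_trim] = 0.0
            if s < ladder.n_vs - 1:
                h[centers_all > zhi - wall_trim] = 0.0
        if h.sum() > 0:
            hists[s] = h
    merged = np.zeros(nb)
    weight = np.zeros(nb)
    for s in sorted(hists):
        # normalized shape: the merge must not depend on how many counts a
        # state happens to carry, only on the shape of its distribution
        h = hists[s] / hists[s].sum()
        if weight.sum() == 0:
            merged, weight = h.copy(), h.copy()
            continue
        ov = (h > 0) & (weight > 0)
        if not np.any(ov):
            raise CoverageGapError(
                message=f"state {s} histogram shares no occupied bin with the merged estimate"
            )
        scale = np.sum(h[ov] * merged[ov]) / np.sum(h[ov] * h[ov])
        hs = scale * h
        tot = weight + h
        occ = tot > 0
        merged[occ] = (merged[occ] * weight[occ] + hs[occ] * h[occ]) / tot[occ]
        weight = tot
    width = np.diff(edges)
    norm = np.sum(merged * width)
    if norm <= 0:
        raise InvalidParameterError("merged distribution has no mass")
    return MergedDistribution(edges=edges, density=merged / norm)


def block_standard_error(values, n_blocks: int = 20) -> float:
    """Standard error of the mean from contiguous block averages (accounts
    for serial correlation within a single trajectory)."""
    values = np.asarray(values, dtype=float)
    n_blocks = min(n_blocks, len(values))
    if n_blocks < 2:
        return 0.0
    blocks = np.array_split(values, n_blocks)
    means = np.array([b.mean() for b in blocks])
    return float(means.std(ddof=1) / np.sqrt(n_blocks))


def canonical_expectation(
    ensemble: Ensemble,
    weights: CanonicalWeights | np.ndarray,
    observable,
    n_boot: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """Weighted ensemble average with a block-bootstrap standard error.

    ``observable`` is either a callable Snapshot -> scalar or a precomputed
    per-snapshot array. Bootstrap blocks are whole runs (run_id); a
    single-run ensemble falls back to 20 contiguous blocks.
    """
    w = weights.weights if isinstance(weights, CanonicalWeights) else np.asarray(weights, float)
    if len(w) != len(ensemble):
        raise InvalidParameterError("weights not aligned with ensemble")
    if callable(observable):
        obs = np.array([float(observable(s)) for s in ensemble])
    else:
        obs = np.asarray(observable, dtype=float)
        if len(obs) != len(ensemble):
            raise InvalidParameterError("observable array not aligned with ensemble")
    mean = float(np.sum(w * obs) / np.sum(w))

    runs = np.unique(ensemble.run_ids)
    if len(runs) > 1:
        groups = [np.flatnonzero(ensemble.run_ids == r) for r in runs]
    else:
        groups = [g for g in np.array_split(np.arange(len(ensemble)), 20) if len(g)]
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.integers(0, len(groups), size=len(groups))
        idx = np.concatenate([groups[p] for p in pick])
        wb = w[idx]
        boots[b] = np.sum(wb * obs[idx]) / np.sum(wb)
    return mean, float(boots.std(ddof=1))


# ---------------------------------------------------------------------------
# distance features and PCA
# ---------------------------------------------------------------------------

@dataclass
class DistanceFeatures:
    """All pairwise site distances of one conformation, in lexicographic
    (i, j), i < j order."""

    values: np.ndarray
    pair_index: list[tuple[int, int]]

    @property
    def n_pair(self) -> int:
        return len(self.values)


def _resolve_sites(conformation: Conformation, sites) -> np.ndarray:
    n = conformation.site_count
    if n is None:
        # abstract models: treat each coordinate triple as a site if possible
        if conformation.dimension % 3 == 0:
            n = conformation.dimension // 3
        else:
            raise InvalidSelectionError("conformation has no 3-D site layout")
    if sites is None:
        return np.arange(n)
    sites = list(sites)
    if sites and isinstance(sites[0], str):
        if conformation.labels is None:
            raise InvalidSelectionError("conformation carries no labels to select by")
        wanted = set(sites)
        idx = np.array([i for i, l in enumerate(conformation.labels) if l in wanted], int)
    else:
        idx = np.asarray(sites)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        idx = idx.astype(int)
    if idx.size and (idx.min() < 0 or idx.max() >= n):
        raise InvalidSelectionError(f"site index out of range for {n} sites")
    return idx


def distance_features(conformation: Conformation, sites=None) -> DistanceFeatures:
    """Pairwise distances q = [q_1 ... q_Npair] of the selected sites,
    Npair = N(N-1)/2."""
    idx = _resolve_sites(conformation, sites)
    if len(idx) < 2:
        raise InvalidSelectionError("distance features need at least 2 sites")
    pts = conformation.coordinates.reshape(-1, 3)[idx]
    ii, jj = np.triu_indices(len(idx), k=1)
    pairs = [(int(idx[a]), int(idx[b])) for a, b in zip(ii, jj)]
    return DistanceFeatures(values=pdist(pts), pair_index=pairs)


def feature_matrix(source, sites=None) -> np.ndarray:
    """(n_snapshots, n_pair) distance-feature matrix for an Ensemble or a
    list of Conformations (vectorized)."""
    if isinstance(source, Ensemble):
        coords = source.coordinates
    else:
        coords = np.stack([c.coordinates for c in source])
    if coords.shape[1] % 3 != 0:
        raise InvalidSelectionError("coordinates are not 3-D site layouts")
    pts = coords.reshape(len(coords), -1, 3)
    if sites is not None:
        ref = (source.snapshot(0).conformation if isinstance(source, Ensemble) else source[0])
        idx = _resolve_sites(ref, sites)
        pts = pts[:, idx, :]
    if pts.shape[1] < 2:
        raise InvalidSelectionError("distance features need at least 2 sites")
    ii, jj = np.triu_indices(pts.shape[1], k=1)
    return np.linalg.norm(pts[:, jj, :] - pts[:, ii, :], axis=-1)


@dataclass
class PCAModel:
    """Eigensystem of the (weighted) distance covariance.

    ``components[i]`` is the i-th orthonormal eigenvector; eigenvalues are
    sorted in descending order. ``total_variance`` equals the covariance
    trace (= sum of eigenvalues).
    """

    mean_vector: np.ndarray
    components: np.ndarray       # (k, p)
    eigenvalues: np.ndarray      # (k,) descending
    total_variance: float

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def _as_matrix(feature_sets) -> np.ndarray:
    if isinstance(feature_sets, np.ndarray):
        return np.atleast_2d(feature_sets)
    return np.stack([
        fs.values if isinstance(fs, DistanceFeatures) else np.asarray(fs, float)
        for fs in feature_sets
    ])


def _normalized_weights(n, weights) -> np.ndarray:
    if weights is None:
        return np.full(n, 1.0 / n)
    w = weights.weights if isinstance(weights, CanonicalWeights) else np.asarray(weights, float)
    if len(w) != n:
        raise InvalidParameterError("weights not aligned with feature sets")
    return w / w.sum()


def _weighted_covariance(X: np.ndarray, w: np.ndarray):
    mean = w @ X
    Xc = X - mean
    cov = (Xc * w[:, None]).T @ Xc
    return mean, cov


def fit_pca(feature_sets, weights=None) -> PCAModel:
    """Diagonalize the weighted variance-covariance matrix
    A_ij = <q_i q_j> - <q_i><q_j> of the distance features."""
    X = _as_matrix(feature_sets)
    if X.shape[0] < 2:
        raise DegenerateInputError("PCA needs at least 2 feature sets")
    w = _normalized_weights(X.shape[0], weights)
    mean, cov = _weighted_covariance(X, w)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    return PCAModel(
        mean_vector=mean,
        components=evecs.T,
        eigenvalues=evals,
        total_variance=float(np.trace(cov)),
    )


def contribution_ratio(model: PCAModel, i: int) -> float:
    """rc_i = lambda_i / sum_j lambda_j (0-based component index)."""
    if not 0 <= i < model.n_components:
        raise InvalidParameterError(f"component index {i} out of range")
    total = model.eigenvalues.sum()
    if total <= 0:
        raise DegenerateInputError("total variance is zero")
    return float(model.eigenvalues[i] / total)


def project(model: PCAModel, q) -> np.ndarray:
    """Raw scalar products of the feature vector(s) with the first two
    principal axes (no mean subtraction; an external reference conformation
    can be placed on the same landscape this way)."""
    if isinstance(q, DistanceFeatures):
        q = q.values
    q = np.asarray(q, dtype=float)
    single = q.ndim == 1
    q2 = np.atleast_2d(q)
    if q2.shape[1] != model.components.shape[1]:
        raise InvalidParameterError(
            f"feature dimension {q2.shape[1]} does not match PCA dimension "
            f"{model.components.shape[1]}"
        )
    out = q2 @ model.components[:2].T
    return out[0] if single else out


# ---------------------------------------------------------------------------
# free-energy landscape
# ---------------------------------------------------------------------------

@dataclass
class FELGrid:
    """2-D potential of mean force over the first two principal axes.

    ``pmf`` is -R_gas T ln(probability), shifted so the occupied minimum is
    exactly 0.0 kcal/mol; empty cells are NaN (unreachable), never 0.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    probability: np.ndarray
    pmf: np.ndarray
    T: float

    @property
    def occupied(self) -> np.ndarray:
        return np.isfinite(self.pmf)

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])


def _weighted_percentile(x, w, q):
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    cw /= cw[-1]
    return np.interp(np.asarray(q) / 100.0, cw, x[order])


def _auto_edges(vals, w, n_cells):
    lo, hi = _weighted_percentile(vals, w, [1.0, 99.0])
    if hi <= lo:
        lo, hi = vals.min(), vals.max()
    if hi <= lo:  # all points identical along this axis
        lo, hi = lo - 0.5, hi + 0.5
    pad = 0.05 * (hi - lo)
    return np.linspace(lo - pad, hi + pad, n_cells + 1)


def compute_fel(projections, weights, T: float, grid_spec=None) -> FELGrid:
    """Weighted 2-D histogram over (x_PC1, x_PC2) mapped to a PMF surface.

    ``grid_spec`` is a cell count per axis (default 60) or an explicit pair
    of edge arrays; the default grid spans the weighted 1st-99th percentile
    extent per axis padded by 5%, so stray outliers cannot stretch it (their
    weight is dropped and the histogram renormalized).
    """
    P = np.asarray(projections, dtype=float)
    if P.ndim != 2 or P.shape[1] != 2:
        raise InvalidParameterError("projections must be an (n, 2) array")
    w = _normalized_weights(P.shape[0], weights)
    if grid_spec is None or isinstance(grid_spec, (int, np.integer)):
        n_cells = 60 if grid_spec is None else int(grid_spec)
        xe = _auto_edges(P[:, 0], w, n_cells)
        ye = _auto_edges(P[:, 1], w, n_cells)
    else:
        xe, ye = (np.asarray(e, dtype=float) for e in grid_spec)
        if (P[:, 0].min() < xe[0] or P[:, 0].max() > xe[-1]
                or P[:, 1].min() < ye[0] or P[:, 1].max() > ye[-1]):
            raise InvalidParameterError("explicit grid does not cover all projections")
    H = np.histogram2d(P[:, 0], P[:, 1], bins=(xe, ye), weights=w)[0]
    total = H.sum()
    if total <= 0:
        raise InvalidParameterError("no probability mass inside the grid")
    prob = H / total
    pmf = np.full_like(prob, np.nan)
    occ = prob > 0
    pmf[occ] = -R_GAS * T * np.log(prob[occ])
    pmf[occ] -= pmf[occ].min()
    return FELGrid(x_edges=xe, y_edges=ye, probability=prob, pmf=pmf, T=float(T))


_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def find_basins(grid: FELGrid, barrier_cutoff: float = 0.0) -> np.ndarray:
    """Watershed labelling of the PMF surface.

    Each occupied cell descends to the local minimum reachable by steepest
    descent over the 8-neighbourhood (ties break toward the lower flat cell
    index); basins separated by a barrier below ``barrier_cutoff`` (saddle
    height above the shallower minimum) are merged. Labels are consecutive
    integers ordered by basin depth (0 = global minimum); unreachable cells
    get -1. Invariant under a global PMF shift.
    """
    pmf = grid.pmf
    nx, ny = pmf.shape
    occ = np.isfinite(pmf)
    sink = {}

    def descend(cell):
        path = []
        while cell not in sink:
            path.append(cell)
            i, j = cell
            best, best_val = None, pmf[i, j]
            for di, dj in _NEIGHBOURS:
                a, b = i + di, j + dj
                if 0 <= a < nx and 0 <= b < ny and occ[a, b]:
                    v = pmf[a, b]
                    if v < best_val or (v == best_val and best is not None
                                        and a * ny + b < best[0] * ny + best[1]):
                        best, best_val = (a, b), v
            if best is None:  # local minimum
                sink[cell] = cell
                break
            cell = best
        root = sink[cell]
        for c in path:
            sink[c] = root
        return root

    cells = [(i, j) for i in range(nx) for j in range(ny) if occ[i, j]]
    for c in cells:
        descend(c)

    minima = sorted({sink[c] for c in cells}, key=lambda c: (pmf[c], c))
    parent = {m: m for m in minima}

    def find(m):
        while parent[m] != m:
            parent[m] = parent[parent[m]]
            m = parent[m]
        return m

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra == rb:
            return
        # keep the deeper minimum as representative
        if (pmf[rb], rb) < (pmf[ra], ra):
            ra, rb = rb, ra
        parent[rb] = ra

    while True:
        saddles = {}
        for (i, j) in cells:
            la = find(sink[(i, j)])
            for di, dj in _NEIGHBOURS:
                a, b = i + di, j + dj
                if 0 <= a < nx and 0 <= b < ny and occ[a, b]:
                    lb = find(sink[(a, b)])
                    if la is not lb and la != lb:
                        key = (la, lb) if (pmf[la], la) <= (pmf[lb], lb) else (lb, la)
                        s = max(pmf[i, j], pmf[a, b])
                        if key not in saddles or s < saddles[key]:
                            saddles[key] = s
        merged = False
        best_pair, best_barrier = None, np.inf
        for (la, lb), s in saddles.items():
            barrier = s - max(pmf[la], pmf[lb])
            if barrier < barrier_cutoff and barrier < best_barrier:
                best_pair, best_barrier = (la, lb), barrier
        if best_pair is not None:
            union(*best_pair)
            merged = True
        if not merged:
            break

    roots = sorted({find(m) for m in minima}, key=lambda c: (pmf[c], c))
    index = {r: k for k, r in enumerate(roots)}
    labels = np.full(pmf.shape, -1, dtype=int)
    for c in cells:
        labels[c] = index[find(sink[c])]
    return labels


# ---------------------------------------------------------------------------
# scalar ensemble descriptors
# ---------------------------------------------------------------------------

def conformational_sigma(feature_sets, weights=None) -> float:
    """sigma = sqrt(sum_i Var(q_i)): square root of the covariance trace of
    the distance features -- the overall conformational spread in Angstrom.
    Equals sqrt(sum of PCA eigenvalues) for matching weights."""
    X = _as_matrix(feature_sets)
    if X.shape[0] < 2:
        warnings.warn("conformational sigma of a single sample is 0 by definition")
        return 0.0
    w = _normalized_weights(X.shape[0], weights)
    _, cov = _weighted_covariance(X, w)
    return float(np.sqrt(max(np.trace(cov), 0.0)))


def radius_of_gyration(conformation: Conformation, selection=None) -> float:
    """Root-mean-square distance of the selected sites from their centroid.

    ``selection`` may be site indices, a boolean mask, or label strings
    (e.g. to restrict to hydrophobic sites); default is all sites.
    """
    idx = _resolve_sites(conformation, selection)
    if len(idx) < 1:
        raise InvalidSelectionError("radius of gyration needs at least one site")
    pts = conformation.coordinates.reshape(-1, 3)[idx]
    centroid = pts.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1))))


def rg_observable(selection=None):
    """Snapshot -> Rg callable for use with :func:`canonical_expectation`."""

    def obs(s: Snapshot) -> float:
        return radius_of_gyration(s.conformation, selection)

    return obs
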