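"""Density-of-states estimation and the multicanonical energy E_mc(E).

The multicanonical trick replaces the physical potential energy E with
``E_mc(E) = R_gas * T_sim * ln n(E)`` (n = density of states), so that
sampling at the fixed simulation temperature T_sim produces a flat energy
histogram over the covered range: the sampler then behaves like a canonical
ensemble over a whole band of effective temperatures at once. The force is
obtained by the chain rule, ``f = -(dE_mc/dE) grad E``, which is why the
tabulated E_mc must carry a continuous first derivative.

n(E) is unknown a priori. It is bootstrapped from canonical runs at several
temperatures spanning [T_low, T_high]: each run contributes
``ln n(E) = ln h_T(E) + E/(R_gas T)`` up to a per-temperature constant, the
constants are fixed by least squares in the histogram overlap windows, and
the stitched curve is smoothed. Subsequent sampling under the current E_mc
refines it iteratively: ``E_mc' = E_mc + R_gas T_sim ln P_obs(E)``, which
has the flat histogram as its fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline, make_lsq_spline

from .constants import R_GAS
from .ensemble import Ensemble
from .errors import (
    CoverageGapError,
    InsufficientSamplingError,
    IntegrationFailureError,
    InvalidParameterError,
)
from .models import Conformation, PotentialModel

__all__ = [
    "MulticanonicalPotential",
    "estimate_initial_emc",
    "emc_value_and_derivative",
    "multicanonical_force",
    "update_emc",
    "flatness_metric",
    "flatness_from_counts",
]

DEFAULT_GRID_BINS = 200


@dataclass
class MulticanonicalPotential:
    """Tabulated-and-smoothed E_mc(E) on an ascending energy grid.

    The interpolant is a natural cubic spline through ``emc_values`` (so the
    tabulated values are reproduced exactly at the grid nodes) with linear
    extrapolation at the boundary slope outside ``[E_low, E_high]`` --
    equivalent to canonical tails at effective boundary temperatures, which
    prevents runaway forces when a walker leaves the covered range.
    """

    energy_grid: np.ndarray
    emc_values: np.ndarray
    T_sim: float
    T_range: tuple[float, float]
    iteration: int = 0
    _spline: CubicSpline | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.energy_grid = np.asarray(self.energy_grid, dtype=float)
        self.emc_values = np.asarray(self.emc_values, dtype=float)
        if self.energy_grid.ndim != 1 or len(self.energy_grid) < 4:
            raise InvalidParameterError("energy grid needs at least 4 ascending nodes")
        if np.any(np.diff(self.energy_grid) <= 0):
            raise InvalidParameterError("energy grid must be strictly ascending")
        if self.emc_values.shape != self.energy_grid.shape:
            raise InvalidParameterError("emc_values must match the energy grid")

    @property
    def coverage(self) -> tuple[float, float]:
        return float(self.energy_grid[0]), float(self.energy_grid[-1])

    def _ensure_spline(self) -> CubicSpline:
        if self._spline is None:
            self._spline = CubicSpline(self.energy_grid, self.emc_values, bc_type="natural")
        return self._spline

    def value(self, E):
        sp = self._ensure_spline()
        E = np.asarray(E, dtype=float)
        lo, hi = self.coverage
        inside = sp(np.clip(E, lo, hi))
        out = inside + np.where(E > hi, (E - hi) * sp(hi, 1), 0.0) + np.where(
            E < lo, (E - lo) * sp(lo, 1), 0.0
        )
        return float(out) if out.ndim == 0 else out

    def derivative(self, E):
        sp = self._ensure_spline()
        E = np.asarray(E, dtype=float)
        lo, hi = self.coverage
        out = sp(np.clip(E, lo, hi), 1)
        return float(out) if out.ndim == 0 else out

    def slope_table(self, n: int = 4096) -> tuple[np.ndarray, np.ndarray]:
        """Dense (E, dE_mc/dE) lookup used by the sampler's inner loop.

        ``np.interp`` against this table clamps to the boundary slopes,
        matching the linear-extrapolation contract.
        """
        lo, hi = self.coverage
        Es = np.linspace(lo, hi, n)
        return Es, self.derivative(Es)

    def anchored(self, at: float | None = None) -> "MulticanonicalPotential":
        """Shift so that E_mc(anchor) = 0; anchor defaults to the grid midpoint."""
        if at is None:
            at = self.energy_grid[len(self.energy_grid) // 2]
        return replace(self, emc_values=self.emc_values - self.value(at), _spline=None)

    @classmethod
    def identity(cls, E_low: float, E_high: float, T_sim: float,
                 T_range: tuple[float, float] | None = None,
                 n: int = DEFAULT_GRID_BINS) -> "MulticanonicalPotential":
        """E_mc(E) = E: the canonical limit (slope 1 everywhere)."""
        grid = np.linspace(E_low, E_high, n)
        return cls(grid, grid.copy(), T_sim, T_range or (T_sim, T_sim))


def emc_value_and_derivative(mcpot: MulticanonicalPotential, E):
    """(E_mc, slope) at energy E; the slope multiplies the physical force."""
    return mcpot.value(E), mcpot.derivative(E)


def multicanonical_force(
    mcpot: MulticanonicalPotential, model: PotentialModel, conformation: Conformation
) -> np.ndarray:
    """f = -(dE_mc/dE at E(x)) * grad E(x), chain rule through the interpolant."""
    e, g = model.energy_and_gradient(conformation.coordinates)
    if not np.isfinite(e) or not np.all(np.isfinite(g)):
        raise IntegrationFailureError(0, "non-finite model energy/gradient")
    return -mcpot.derivative(e) * g


def _smooth_fit(x, y, w, n_knots: int):
    """Weighted least-squares cubic B-spline with ``n_knots`` interior knots
    placed at weight quantiles (equal statistical mass per knot interval).

    Histogram noise along a trajectory is serially correlated, which makes
    automatic smoothing selectors (e.g. GCV) systematically under-smooth; a
    fixed, physically motivated knot budget is the robust choice here. The
    curves being fitted -- ln n(E) and flatness corrections to it -- vary on
    the scale of a whole canonical energy band, so a handful of knots spans
    their true resolution.
    """
    n_knots = max(1, int(n_knots))
    cw = np.cumsum(w)
    cw = cw / cw[-1]
    qs = np.linspace(0.0, 1.0, n_knots + 2)[1:-1]
    knots = np.interp(qs, cw, x)
    # keep knots strictly interior and distinct
    knots = np.unique(np.clip(knots, x[0] + 1e-12, x[-1] - 1e-12))
    t = np.r_[(x[0],) * 4, knots, (x[-1],) * 4]
    return make_lsq_spline(x, y, t, w=w, k=3)


def _parse_grid_spec(grid_spec, energies):
    if grid_spec is None:
        grid_spec = DEFAULT_GRID_BINS
    if isinstance(grid_spec, (int, np.integer)):
        return float(energies.min()), float(energies.max()), int(grid_spec)
    lo, hi, n = grid_spec
    return float(lo), float(hi), int(n)


def estimate_initial_emc(
    runs: list[tuple[float, Ensemble]],
    T_sim: float,
    grid_spec=None,
    min_overlap_bins: int = 2,
    smoothing_knots: int | None = None,
    trim_quantile: float = 0.002,
    min_count: int = 8,
) -> MulticanonicalPotential:
    """Stitch multi-temperature canonical histograms into an initial E_mc.

    Runs at equal temperatures are pooled. Adjacent temperatures must have
    overlapping energy histograms; a missing overlap raises
    :class:`CoverageGapError` naming the gap interval. The stitched
    ln n(E) curve is smoothed by a least-squares spline with (by default)
    two interior knots per temperature segment -- each canonical histogram
    constrains the curve over roughly its own width.

    The covered range is the pooled-sample quantile band
    [trim_quantile, 1 - trim_quantile]: the extreme histogram tails carry a
    handful of counts each, and a spline fitted through them produces
    unreliable boundary slopes that destabilize the zone-confined sampler.
    Bins with fewer than ``min_count`` counts are likewise excluded from the
    fit: E[ln h] underestimates ln(lambda) for small Poisson counts, which
    would systematically flatten the estimated density of states in the
    tails.
    """
    if not runs:
        raise InvalidParameterError("no canonical runs supplied")
    by_T: dict[float, list[np.ndarray]] = {}
    for T, ens in runs:
        by_T.setdefault(float(T), []).append(np.asarray(ens.energies, float))
    temps = sorted(by_T)
    if len(temps) < 2:
        raise CoverageGapError(
            message="density-of-states estimation needs canonical runs at >= 2 temperatures"
        )
    all_e = np.concatenate([e for lst in by_T.values() for e in lst])
    if grid_spec is None or isinstance(grid_spec, (int, np.integer)):
        qlo, qhi = np.quantile(all_e, [trim_quantile, 1.0 - trim_quantile])
        nb = int(grid_spec) if grid_spec is not None else DEFAULT_GRID_BINS
        lo, hi = float(qlo), float(qhi)
    else:
        lo, hi, nb = _parse_grid_spec(grid_spec, all_e)
    edges = np.linspace(lo, hi, nb + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    acc_val = np.zeros(nb)
    acc_w = np.zeros(nb)
    t_range = (temps[0], temps[-1])
    for idx, T in enumerate(temps):
        counts = np.histogram(np.concatenate(by_T[T]), bins=edges)[0].astype(float)
        occ = counts >= max(min_count, 1)
        lnn = np.full(nb, np.nan)
        lnn[occ] = np.log(counts[occ]) + centers[occ] / (R_GAS * T)
        if idx == 0:
            acc_val[occ] = lnn[occ]
            acc_w[occ] = counts[occ]
            continue
        overlap = occ & (acc_w > 0)
        if overlap.sum() < min_overlap_bins:
            prev_hi = centers[acc_w > 0].max()
            new_lo = centers[occ].min() if occ.any() else hi
            raise CoverageGapError(gap=(min(prev_hi, new_lo), max(prev_hi, new_lo)))
        w_ov = 1.0 / (1.0 / counts[overlap] + 1.0 / acc_w[overlap])
        offset = np.average(acc_val[overlap] - lnn[overlap], weights=w_ov)
        lnn = lnn + offset
        tot = acc_w + np.where(occ, counts, 0.0)
        new_val = np.where(
            occ & (acc_w > 0),
            (acc_val * acc_w + np.where(occ, lnn * counts, 0.0)) / np.maximum(tot, 1e-300),
            np.where(occ, lnn, acc_val),
        )
        acc_val, acc_w = new_val, tot

    occ = acc_w > 0
    x, y, w = centers[occ], R_GAS * T_sim * acc_val[occ], acc_w[occ]
    if smoothing_knots is None:
        smoothing_knots = max(4, 2 * len(temps))
    sp = _smooth_fit(x, y, w, smoothing_knots)
    grid = np.linspace(x.min(), x.max(), nb)
    pot = MulticanonicalPotential(grid, sp(grid), T_sim, t_range, iteration=0)
    return pot.anchored()


def _merged_or_raw_density(ensemble: Ensemble, edges: np.ndarray, ladder=None):
    """Histogram density of an ensemble.

    For v-mcmd ensembles the per-virtual-state distributions are integrated
    into one P_mc(E) by weighting each snapshot with the inverse of the
    known zone multiplicity m(E) (see
    :func:`vmcmd.vsampler.soft_multiplicity`); the raw pooled histogram
    would carry the m(E) modulation even for a perfectly converged E_mc.
    Canonical and plain multicanonical ensembles use the raw histogram.
    """
    counts = np.histogram(ensemble.energies, bins=edges)[0]
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    if ensemble.sampling_kind == "v-mcmd" and np.any(ensemble.virtual_states >= 0):
        from .vsampler import soft_multiplicity  # local import: avoids cycle

        if ladder is not None:
            zones, c = ladder.zones, ladder.confinement_strength
        else:
            zones = ensemble.metadata.get("ladder_zones")
            if zones is None:
                raise InvalidParameterError(
                    "v-mcmd ensemble carries no ladder zones; pass ladder explicitly"
                )
            c = float(ensemble.metadata.get("confinement_strength", 25.0))
        T_sim = float(ensemble.metadata.get("T_sim", 300.0))
        minv = 1.0 / soft_multiplicity(
            ensemble.energies, zones, c, T_sim, ensemble.metadata.get("wall_cap")
        )
        dens = np.histogram(ensemble.energies, bins=edges, weights=minv)[0]
        total = max(dens.sum(), 1e-300)
        return dens / (total * width), counts, centers
    total = max(counts.sum(), 1)
    return counts / (total * width), counts, centers


def _ladder_from_metadata(ensemble: Ensemble):
    from .vsampler import VirtualStateLadder

    zones = ensemble.metadata.get("ladder_zones")
    if zones is None:
        raise InvalidParameterError(
            "v-mcmd ensemble carries no ladder zones in its metadata; pass ladder explicitly"
        )
    return VirtualStateLadder(np.asarray(zones, float))


def update_emc(
    mcpot: MulticanonicalPotential,
    ensemble: Ensemble,
    smoothing_spec: int | None = None,
    ladder=None,
    min_coverage: float = 0.8,
) -> MulticanonicalPotential:
    """One refinement cycle: E_mc' = E_mc + R_gas T_sim ln P_obs, smoothed.

    P_obs is the observed energy density under the current E_mc (per-state
    merged for v-mcmd ensembles). The update is anchored so that E_mc at the
    grid midpoint is unchanged between iterations, keeping successive
    snapshot weights comparable. ``smoothing_spec`` is the interior-knot
    count of the least-squares smoothing spline (default 8).
    """
    grid = mcpot.energy_grid
    nb = len(grid)
    edges = np.linspace(grid[0], grid[-1], nb + 1)
    density, counts, centers = _merged_or_raw_density(ensemble, edges, ladder)
    occ = density > 0
    if occ.sum() < min_coverage * nb:
        raise InsufficientSamplingError(empty_bins=list(centers[~occ]))

    delta = np.full(nb, np.nan)
    delta[occ] = R_GAS * mcpot.T_sim * np.log(density[occ])
    # fill empty interior bins by linear interpolation across neighbours
    delta = np.interp(centers, centers[occ], delta[occ])
    w = np.maximum(counts.astype(float), 1.0)
    sp = _smooth_fit(centers, delta, w, 8 if smoothing_spec is None else smoothing_spec)
    new_vals = mcpot.value(grid) + sp(grid)
    out = MulticanonicalPotential(
        grid, new_vals, mcpot.T_sim, mcpot.T_range, iteration=mcpot.iteration + 1
    )
    mid = grid[nb // 2]
    shift = out.value(mid) - mcpot.value(mid)
    return replace(out, emc_values=out.emc_values - shift, _spline=None)


def flatness_from_counts(counts, exclude_edges: bool = False) -> float:
    """Relative standard deviation (std/mean) of histogram counts.

    0 means perfectly flat. With ``exclude_edges`` the outermost bin at each
    edge is dropped first (when more than two bins remain to judge).
    """
    counts = np.asarray(counts, dtype=float)
    if exclude_edges and len(counts) > 2:
        counts = counts[1:-1]
    if counts.size == 0 or counts.sum() == 0:
        raise InsufficientSamplingError(message="no counts in the requested window")
    mean = counts.mean()
    return float(counts.std() / mean)


def flatness_metric(
    ensemble: Ensemble,
    E_window: tuple[float, float],
    n_bins: int = 20,
    ladder=None,
) -> float:
    """Flat-histogram convergence measure over an energy window.

    For v-mcmd ensembles the per-virtual-state distributions are first
    merged (least-squares matching in zone overlaps), because the raw pooled
    histogram carries the zone-multiplicity modulation even for a perfectly
    converged E_mc. Interior bins only: the outermost bin at each window
    edge is excluded.
    """
    lo, hi = E_window
    if not hi > lo:
        raise InvalidParameterError("empty energy window")
    edges = np.linspace(lo, hi, n_bins + 1)
    in_win = (ensemble.energies >= lo) & (ensemble.energies <= hi)
    if not np.any(in_win):
        raise InsufficientSamplingError(message="no samples in the requested window")
    if ensemble.sampling_kind == "v-mcmd" and np.any(ensemble.virtual_states >= 0):
        density, _, _ = _merged_or_raw_density(ensemble, edges, ladder)
        return flatness_from_counts(density, exclude_edges=True)
    counts = np.histogram(ensemble.energies, bins=edges)[0]
    return flatness_from_counts(counts, exclude_edges=True)
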