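"""Analytically tractable potential models and geometric fixtures.

Every downstream stage of the sampler/analysis pipeline is exercised on the
models defined here, because each has a ground-truth oracle:

* :func:`harmonic_potential` -- d-dimensional harmonic well. Its density of
  states is known in closed form, n(E) proportional to E**(d/2 - 1), so the
  multicanonical energy and its slope are analytic.
* :func:`double_well_potential` -- 1-D quartic double well (optionally with
  extra harmonic dimensions). Basin partition functions are computable by
  numerical quadrature, giving an exact basin free-energy difference.
* :func:`cg_peptide_potential` -- a coarse-grained chain of 3-D sites with
  bonds, angles, a helix-biasing torsion term and soft-core pairwise
  contacts; a desk-scale stand-in for a short disordered peptide with at
  least two metastable conformational families.

Potentials evaluate on batches: ``energy`` maps an array of shape
``(..., dim)`` to ``(...,)`` and ``gradient`` preserves the trailing
coordinate axis. Energies are in kcal/mol, coordinates in Angstrom for chain
models and reduced units for the abstract models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import quad

from .constants import R_GAS
from .errors import IncompatibleModelError, InvalidParameterError

__all__ = [
    "Conformation",
    "PotentialModel",
    "harmonic_potential",
    "double_well_potential",
    "cg_peptide_potential",
    "mix_potentials",
    "generate_fixture_conformations",
    "finite_difference_gradient",
    "harmonic_mean_energy",
    "harmonic_log_dos",
    "double_well_basin_delta_f",
    "double_well_basin_occupancy",
]

#: default spacing between consecutive chain sites (Angstrom); roughly the
#: Calpha-Calpha virtual bond length of a polypeptide.
CHAIN_SPACING = 3.8


@dataclass
class Conformation:
    """A single configuration of a model system.

    ``coordinates`` is the flat vector of scalar coordinates; for chain
    models it is the concatenation of ``site_count`` xyz triples.
    """

    coordinates: np.ndarray
    site_count: int | None = None
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float).ravel()
        if self.site_count is not None and 3 * self.site_count != self.coordinates.size:
            raise InvalidParameterError(
                f"site_count {self.site_count} inconsistent with "
                f"{self.coordinates.size} coordinates"
            )

    @property
    def dimension(self) -> int:
        return self.coordinates.size

    def sites(self) -> np.ndarray:
        """Coordinates reshaped to (n_sites, 3). Chain models only."""
        if self.site_count is None:
            raise InvalidParameterError("conformation has no site layout")
        return self.coordinates.reshape(self.site_count, 3)

    def copy(self) -> "Conformation":
        return Conformation(self.coordinates.copy(), self.site_count, self.labels)


@dataclass
class PotentialModel:
    """Energy/gradient contract for a configurable model system.

    ``mass`` is a single effective mass shared by all coordinates; toy-model
    masses carry no physical meaning and are chosen so that the stiffest
    vibrational mode satisfies omega * default_dt <~ 0.1 even after the
    multicanonical slope rescales the force, which keeps the discretization
    bias of the samplers below sampling noise.
    """

    name: str
    dimension: int
    _energy: Callable[[np.ndarray], np.ndarray]
    _gradient: Callable[[np.ndarray], np.ndarray]
    n_sites: int | None = None
    mass: float = 100.0
    default_dt: float = 1.0
    default_friction: float = 0.1
    #: largest total force multiplier (multicanonical slope + wall) the
    #: model integrates stably at its default time step; anharmonic chain
    #: models with steep contact cores tolerate far less than quadratic toys
    force_scale_limit: float = 25.0
    parameters: dict = field(default_factory=dict)
    start_coordinates: np.ndarray | None = None
    _energy_and_gradient: Callable[[np.ndarray], tuple] | None = None

    def energy(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 1
        e = self._energy(np.atleast_2d(x))
        return float(e[0]) if scalar else e.reshape(x.shape[:-1])

    def gradient(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        g = self._gradient(np.atleast_2d(x))
        return g.reshape(x.shape)

    def energy_and_gradient(self, x):
        x = np.asarray(x, dtype=float)
        x2 = np.atleast_2d(x)
        if self._energy_and_gradient is not None:
            e, g = self._energy_and_gradient(x2)
        else:
            e, g = self._energy(x2), self._gradient(x2)
        if x.ndim == 1:
            return float(e[0]), g.reshape(x.shape)
        return e.reshape(x.shape[:-1]), g.reshape(x.shape)

    def default_start(self) -> Conformation:
        if self.start_coordinates is not None:
            return Conformation(self.start_coordinates.copy(), self.n_sites)
        return Conformation(np.zeros(self.dimension), self.n_sites)

    def conformation(self, coordinates) -> Conformation:
        c = Conformation(np.asarray(coordinates, dtype=float), self.n_sites)
        if c.dimension != self.dimension:
            raise InvalidParameterError(
                f"coordinate vector of length {c.dimension} for model of dimension {self.dimension}"
            )
        return c


# ---------------------------------------------------------------------------
# abstract oracle models
# ---------------------------------------------------------------------------

def harmonic_potential(d: int, k: float) -> PotentialModel:
    """Isotropic d-dimensional harmonic well, E = (k/2) sum x_i**2.

    The density of states n(E) ~ E**(d/2 - 1) is analytic, making this the
    benchmark for density-of-states estimation and flat-histogram sampling.
    """
    if not isinstance(d, (int, np.integer)) or d < 1:
        raise InvalidParameterError(f"dimension must be a positive integer, got {d!r}")
    if k <= 0:
        raise InvalidParameterError(f"spring constant must be positive, got {k!r}")

    def energy(x):
        return 0.5 * k * np.sum(x * x, axis=-1)

    def gradient(x):
        return k * x

    def both(x):
        return energy(x), gradient(x)

    return PotentialModel(
        name=f"harmonic-{d}d",
        dimension=int(d),
        _energy=energy,
        _gradient=gradient,
        _energy_and_gradient=both,
        mass=400.0 * k,  # omega = sqrt(k/m) = 0.05 per reduced time unit
        default_dt=1.0,
        parameters={"d": int(d), "k": float(k), "dos_exponent": d / 2.0 - 1.0},
    )


def harmonic_mean_energy(d: int, T: float) -> float:
    """Canonical mean potential energy of the d-D harmonic well (equipartition)."""
    return 0.5 * d * R_GAS * T


def harmonic_log_dos(E, d: int):
    """ln n(E) of the d-D harmonic well up to an additive constant."""
    return (d / 2.0 - 1.0) * np.log(E)


def double_well_potential(
    barrier_height: float,
    well_separation: float,
    asymmetry: float = 0.0,
    extra_dims: int = 0,
    extra_k: float = 1.0,
) -> PotentialModel:
    """1-D quartic double well plus independent harmonic extra dimensions.

    E(x0) = B ((x0/a)**2 - 1)**2 + asymmetry * x0 / (2 a), a = separation/2.
    Minima near x0 = +-a; with positive asymmetry the +a basin lies higher
    by ~asymmetry. Basin statistics are separable from the extra dimensions,
    so the quadrature oracle over x0 alone is exact.
    """
    if barrier_height <= 0:
        raise InvalidParameterError("barrier_height must be positive")
    if well_separation <= 0:
        raise InvalidParameterError("well_separation must be positive")
    if extra_dims < 0:
        raise InvalidParameterError("extra_dims must be nonnegative")
    a = well_separation / 2.0
    B = float(barrier_height)
    dim = 1 + int(extra_dims)

    def energy(x):
        x0 = x[..., 0]
        e = B * ((x0 / a) ** 2 - 1.0) ** 2 + asymmetry * x0 / (2 * a)
        if dim > 1:
            e = e + 0.5 * extra_k * np.sum(x[..., 1:] ** 2, axis=-1)
        return e

    def gradient(x):
        g = np.empty_like(x)
        x0 = x[..., 0]
        g[..., 0] = 4.0 * B * x0 * ((x0 / a) ** 2 - 1.0) / a**2 + asymmetry / (2 * a)
        if dim > 1:
            g[..., 1:] = extra_k * x[..., 1:]
        return g

    def both(x):
        return energy(x), gradient(x)

    stiffness = max(8.0 * B / a**2, extra_k)
    start = np.zeros(dim)
    start[0] = -a  # lower basin for positive asymmetry
    return PotentialModel(
        name="double-well",
        dimension=dim,
        _energy=energy,
        _gradient=gradient,
        _energy_and_gradient=both,
        mass=400.0 * stiffness,
        default_dt=1.0,
        parameters={
            "barrier_height": B,
            "well_separation": float(well_separation),
            "asymmetry": float(asymmetry),
            "extra_dims": int(extra_dims),
            "extra_k": float(extra_k),
            "a": a,
        },
        start_coordinates=start,
    )


def _double_well_marginal(model: PotentialModel):
    p = model.parameters
    a, B, asym = p["a"], p["barrier_height"], p["asymmetry"]

    def e1d(x0):
        return B * ((x0 / a) ** 2 - 1.0) ** 2 + asym * x0 / (2 * a)

    return e1d, a


def double_well_basin_occupancy(model: PotentialModel, T: float) -> float:
    """Quadrature oracle: canonical probability of the x0 > 0 basin.

    Exact for any number of extra harmonic dimensions (they factorize).
    """
    e1d, a = _double_well_marginal(model)
    beta = 1.0 / (R_GAS * T)
    lim = max(6.0 * a, 10.0)
    zp = quad(lambda x: np.exp(-beta * e1d(x)), 0.0, lim, limit=200)[0]
    zm = quad(lambda x: np.exp(-beta * e1d(x)), -lim, 0.0, limit=200)[0]
    return zp / (zp + zm)


def double_well_basin_delta_f(model: PotentialModel, T: float) -> float:
    """Quadrature oracle: F(+basin) - F(-basin) in kcal/mol at temperature T."""
    p = double_well_basin_occupancy(model, T)
    return -R_GAS * T * np.log(p / (1.0 - p))


# ---------------------------------------------------------------------------
# coarse-grained peptide chain
# ---------------------------------------------------------------------------

def _chain_pairs(n_sites: int, min_sep: int = 3):
    ii, jj = np.triu_indices(n_sites, k=min_sep)
    return ii, jj


def cg_peptide_potential(
    n_sites: int,
    bond_k: float = 100.0,
    angle_k: float = 5.0,
    torsion_amp: float = 1.0,
    contact_eps: float = 1.0,
    contact_sigma: float = 4.5,
    bond_r0: float = CHAIN_SPACING,
    angle_theta0: float = np.deg2rad(110.0),
    torsion_phi0: float = np.deg2rad(50.0),
    core_softening: float = 1.5,
) -> PotentialModel:
    """Coarse-grained peptide chain: one site per residue.

    Terms: harmonic bonds 0.5*k_b*(r - r0)**2, harmonic angles
    0.5*k_a*(theta - theta0)**2, torsions amp*(1 - cos(phi - phi0)) biasing
    helix-like dihedrals, and soft-core Lennard-Jones contacts between sites
    at least three bonds apart. The soft core (r**2 -> r**2 + delta**2 inside
    the LJ kernel) keeps the energy finite for any finite input, which the
    flat-histogram samplers rely on at their high-energy edge.

    With the defaults the chain has (at least) two metastable conformational
    families: a compact helix-like state favoured by the torsion and contact
    terms, and looser extended/hairpin-like states favoured entropically.
    """
    if n_sites < 4:
        raise InvalidParameterError("a chain needs at least 4 sites")
    for nm, v in [("bond_k", bond_k), ("contact_sigma", contact_sigma)]:
        if v <= 0:
            raise InvalidParameterError(f"{nm} must be positive")
    n = int(n_sites)
    ii, jj = _chain_pairs(n)
    # incidence matrix scattering per-pair forces back onto sites
    inc = np.zeros((n, len(ii)))
    inc[jj, np.arange(len(ii))] += 1.0
    inc[ii, np.arange(len(ii))] -= 1.0
    sig2 = contact_sigma**2
    delta2 = core_softening**2

    def _terms(x, with_grad):
        """x: (B, n, 3). Returns (E, grad or None)."""
        B_ = x.shape[0]
        e = np.zeros(B_)
        g = np.zeros_like(x) if with_grad else None

        # bonds
        b = x[:, 1:, :] - x[:, :-1, :]
        r = np.linalg.norm(b, axis=-1)
        dr = r - bond_r0
        e += 0.5 * bond_k * np.sum(dr * dr, axis=-1)
        if with_grad:
            coef = (bond_k * dr / np.maximum(r, 1e-12))[..., None] * b
            g[:, 1:, :] += coef
            g[:, :-1, :] -= coef

        # angles over triplets (i-1, i, i+1)
        if angle_k != 0.0 and n >= 3:
            u = x[:, :-2, :] - x[:, 1:-1, :]
            v = x[:, 2:, :] - x[:, 1:-1, :]
            nu = np.maximum(np.linalg.norm(u, axis=-1), 1e-12)
            nv = np.maximum(np.linalg.norm(v, axis=-1), 1e-12)
            uh = u / nu[..., None]
            vh = v / nv[..., None]
            c = np.clip(np.sum(uh * vh, axis=-1), -1.0, 1.0)
            th = np.arccos(c)
            dth = th - angle_theta0
            e += 0.5 * angle_k * np.sum(dth * dth, axis=-1)
            if with_grad:
                s = np.maximum(np.sqrt(1.0 - c * c), 1e-8)
                pref = (angle_k * dth / s)[..., None]
                dthdu = pref * (c[..., None] * uh - vh) / nu[..., None]
                dthdv = pref * (c[..., None] * vh - uh) / nv[..., None]
                g[:, :-2, :] += dthdu
                g[:, 2:, :] += dthdv
                g[:, 1:-1, :] -= dthdu + dthdv
        # torsions over quadruples
        if torsion_amp != 0.0 and n >= 4:
            b1 = x[:, 1:-2, :] - x[:, :-3, :]
            b2 = x[:, 2:-1, :] - x[:, 1:-2, :]
            b3 = x[:, 3:, :] - x[:, 2:-1, :]
            m = np.cross(b1, b2)
            nn = np.cross(b2, b3)
            nb2 = np.maximum(np.linalg.norm(b2, axis=-1), 1e-12)
            y = np.sum(b1 * nn, axis=-1) * nb2
            xx = np.sum(m * nn, axis=-1)
            phi = np.arctan2(y, xx)
            e += torsion_amp * np.sum(1.0 - np.cos(phi - torsion_phi0), axis=-1)
            if with_grad:
                m2 = np.maximum(np.sum(m * m, axis=-1), 1e-12)
                n2 = np.maximum(np.sum(nn * nn, axis=-1), 1e-12)
                dedphi = torsion_amp * np.sin(phi - torsion_phi0)
                f1 = (-(nb2 / m2))[..., None] * m          # dphi/dr1
                f4 = ((nb2 / n2))[..., None] * nn          # dphi/dr4
                sb = (np.sum(b1 * b2, axis=-1) / nb2**2)[..., None]
                tb = (np.sum(b3 * b2, axis=-1) / nb2**2)[..., None]
                f2 = -(1.0 + sb) * f1 + tb * f4
                f3 = sb * f1 - (1.0 + tb) * f4
                w = dedphi[..., None]
                g[:, :-3, :] += w * f1
                g[:, 1:-2, :] += w * f2
                g[:, 2:-1, :] += w * f3
                g[:, 3:, :] += w * f4

        # soft-core LJ contacts
        if contact_eps != 0.0 and len(ii) > 0:
            d = x[:, jj, :] - x[:, ii, :]
            r2 = np.sum(d * d, axis=-1)
            rho = sig2 / (r2 + delta2)
            r3 = rho**3
            e += 4.0 * contact_eps * np.sum(r3 * r3 - r3, axis=-1)
            if with_grad:
                # dE/d(r2) = 4 eps (6 rho^5 - 3 rho^2) * (-rho^2 / sig2)
                dedr2 = -4.0 * contact_eps * (6.0 * r3 * r3 - 3.0 * r3) * rho / sig2
                pair_f = (2.0 * dedr2)[..., None] * d
                g += np.einsum("np,bpc->bnc", inc, pair_f)
        return e, g

    def energy(xflat):
        x = xflat.reshape(xflat.shape[0], n, 3)
        return _terms(x, False)[0]

    def gradient(xflat):
        x = xflat.reshape(xflat.shape[0], n, 3)
        return _terms(x, True)[1].reshape(xflat.shape)

    def both(xflat):
        x = xflat.reshape(xflat.shape[0], n, 3)
        e, g = _terms(x, True)
        return e, g.reshape(xflat.shape)

    start = _helix_coordinates(n)
    return PotentialModel(
        name=f"cg-peptide-{n}",
        dimension=3 * n,
        _energy=energy,
        _gradient=gradient,
        _energy_and_gradient=both,
        n_sites=n,
        mass=2.0e4,  # omega(bond) ~ 0.07 / fs at the default 2 fs step
        default_dt=2.0,
        default_friction=1.0e-3,  # 1 / ps
        force_scale_limit=10.0,
        parameters={
            "n_sites": n,
            "bond_k": float(bond_k),
            "angle_k": float(angle_k),
            "torsion_amp": float(torsion_amp),
            "contact_eps": float(contact_eps),
            "contact_sigma": float(contact_sigma),
            "bond_r0": float(bond_r0),
            "angle_theta0": float(angle_theta0),
            "torsion_phi0": float(torsion_phi0),
            "core_softening": float(core_softening),
        },
        start_coordinates=start.ravel(),
    )


def mix_potentials(model_a: PotentialModel, model_b: PotentialModel, omega: float) -> PotentialModel:
    """Convex combination E = (1 - omega) * E_a + omega * E_b.

    The same mixing rule a hybrid force field uses to interpolate between two
    parameterizations with a single weight omega in [0, 1].
    """
    if not (0.0 <= omega <= 1.0):
        raise InvalidParameterError(f"mixing weight must lie in [0, 1], got {omega!r}")
    if model_a.dimension != model_b.dimension:
        raise IncompatibleModelError(
            f"cannot mix models of dimension {model_a.dimension} and {model_b.dimension}"
        )
    wa, wb = 1.0 - omega, omega

    def energy(x):
        return wa * model_a._energy(x) + wb * model_b._energy(x)

    def gradient(x):
        return wa * model_a._gradient(x) + wb * model_b._gradient(x)

    def both(x):
        ea, ga = model_a.energy_and_gradient(x)
        eb, gb = model_b.energy_and_gradient(x)
        return wa * ea + wb * eb, wa * ga + wb * gb

    return PotentialModel(
        name=f"mix({model_a.name},{model_b.name},{omega:g})",
        dimension=model_a.dimension,
        _energy=energy,
        _gradient=gradient,
        _energy_and_gradient=both,
        n_sites=model_a.n_sites,
        mass=wa * model_a.mass + wb * model_b.mass,
        default_dt=min(model_a.default_dt, model_b.default_dt),
        default_friction=model_a.default_friction,
        force_scale_limit=min(model_a.force_scale_limit, model_b.force_scale_limit),
        parameters={"omega": float(omega)},
        start_coordinates=model_a.start_coordinates,
    )


# ---------------------------------------------------------------------------
# geometric fixtures
# ---------------------------------------------------------------------------

def _helix_coordinates(n_sites: int, radius: float = 2.3, rise: float = 1.5,
                       turn_deg: float = 100.0) -> np.ndarray:
    """Sites on an ideal alpha-helix-like curve (consecutive spacing ~3.8 A)."""
    t = np.arange(n_sites)
    ang = np.deg2rad(turn_deg) * t
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), rise * t])


def _extended_coordinates(n_sites: int, spacing: float = CHAIN_SPACING) -> np.ndarray:
    t = np.arange(n_sites)
    return np.column_stack([np.zeros(n_sites), np.zeros(n_sites), spacing * t])


def _hairpin_coordinates(n_sites: int, spacing: float = CHAIN_SPACING,
                         strand_gap: float = 4.8) -> np.ndarray:
    n1 = n_sites // 2 + n_sites % 2
    n2 = n_sites - n1
    first = np.column_stack([np.zeros(n1), np.zeros(n1), spacing * np.arange(n1)])
    ztop = spacing * (n1 - 1)
    second = np.column_stack(
        [np.full(n2, strand_gap), np.zeros(n2), ztop - spacing * np.arange(n2)]
    )
    return np.vstack([first, second])


def _random_chain_coordinates(n_sites: int, rng: np.random.Generator,
                              spacing: float = CHAIN_SPACING) -> np.ndarray:
    steps = rng.normal(size=(n_sites - 1, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    pos = np.vstack([np.zeros(3), np.cumsum(spacing * steps, axis=0)])
    return pos


_FIXTURE_BUILDERS = {
    "helix": lambda n, rng: _helix_coordinates(n),
    "extended": lambda n, rng: _extended_coordinates(n),
    "hairpin": lambda n, rng: _hairpin_coordinates(n),
    "random": _random_chain_coordinates,
}


def generate_fixture_conformations(
    kind: str,
    n_sites: int,
    count: int,
    noise: float = 0.0,
    seed: int = 0,
    labels: Sequence[str] | None = None,
) -> list[Conformation]:
    """Deterministic chain-geometry fixtures for the analysis pipeline.

    ``kind`` is one of helix / extended / hairpin / random; Gaussian site
    jitter of scale ``noise`` (Angstrom) is applied on top of the ideal
    geometry. Identical (kind, n_sites, count, noise, seed) always produce
    identical coordinates.
    """
    if kind not in _FIXTURE_BUILDERS:
        raise InvalidParameterError(
            f"unknown fixture kind {kind!r}; expected one of {sorted(_FIXTURE_BUILDERS)}"
        )
    if n_sites < 2:
        raise InvalidParameterError("n_sites must be >= 2")
    if count < 1:
        raise InvalidParameterError("count must be >= 1")
    if noise < 0:
        raise InvalidParameterError("noise must be nonnegative")
    lab = tuple(labels) if labels is not None else None
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(count):
        base = _FIXTURE_BUILDERS[kind](n_sites, rng)
        if noise > 0:
            base = base + rng.normal(scale=noise, size=base.shape)
        out.append(Conformation(base.ravel(), site_count=n_sites, labels=lab))
    return out


# ---------------------------------------------------------------------------
# numerics helpers
# ---------------------------------------------------------------------------

def finite_difference_gradient(fn: Callable, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central finite-difference gradient of a scalar function of a vector."""
    x = np.asarray(x, dtype=float)
    g = np.empty_like(x)
    for i in range(x.size):
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (fn(xp) - fn(xm)) / (2 * h)
    return g
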