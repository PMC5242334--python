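"""The V-McMD core: virtual-state ladder, zone-confined multicanonical
dynamics, Metropolis inter-state transitions, and the iteration protocol.

A discrete *virtual system* is coupled to the physical one: virtual state i
confines the potential energy to a zone Z_i = [E_min_i, E_max_i]. Adjacent
zones overlap (so states can exchange) while next-nearest zones are
disjoint. Every ``N_int`` MD steps a Metropolis move proposes a hop to a
neighbouring state, accepted with probability 1 exactly when the current
energy lies inside the proposed zone, and 0 otherwise -- the molecular
configuration is never altered by the hop. Restricting each walker to a
narrow energy band at a time makes the per-state flat histogram much easier
to converge than one global flat histogram, while the union of states still
covers the whole design range.

Zone confinement uses a differentiable half-harmonic wall in energy space:
outside the active zone an extra term ``c (E - boundary)**2`` is added to
the multicanonical energy, so walls integrate cleanly with the thermostat.

Trivial trajectory parallelization (TTP) runs many independently seeded
walkers under the same weights and pools their snapshots as one ensemble.
"""

from __future__ import annotations

import numpy as np

from .constants import R_GAS
from .ensemble import Ensemble
from .errors import (
    InsufficientSamplingError,
    InvalidParameterError,
    InvalidStartError,
    InvalidStateError,
)
from .integrate import _dynamics, rng_streams
from .mcenergy import (
    MulticanonicalPotential,
    estimate_initial_emc,
    flatness_metric,
    update_emc,
)
from .models import Conformation, PotentialModel
from .integrate import canonical_runs

__all__ = [
    "VirtualStateLadder",
    "build_ladder",
    "transition_acceptance",
    "virtual_transition",
    "vmcmd_run",
    "ttp_run",
    "iterate_vmcmd",
    "wall_tolerance",
]


class VirtualStateLadder:
    """Ordered overlapping energy zones with a confinement wall strength.

    Invariants (checked on construction): zones ascend in both edges,
    adjacent zones overlap, next-nearest zones are disjoint.
    """

    def __init__(self, zones, confinement_strength: float = 25.0):
        zones = np.atleast_2d(np.asarray(zones, dtype=float))
        if zones.shape[1] != 2:
            raise InvalidParameterError("zones must be an (n, 2) array of [E_min, E_max]")
        if np.any(zones[:, 1] <= zones[:, 0]):
            raise InvalidParameterError("each zone needs E_min < E_max")
        if np.any(np.diff(zones[:, 0]) <= 0) or np.any(np.diff(zones[:, 1]) <= 0):
            raise InvalidParameterError("zones must strictly ascend")
        if np.any(zones[1:, 0] >= zones[:-1, 1]):
            raise InvalidParameterError("adjacent zones must overlap")
        if zones.shape[0] >= 3 and np.any(zones[2:, 0] < zones[:-2, 1]):
            raise InvalidParameterError("next-nearest zones must not overlap")
        if confinement_strength <= 0:
            raise InvalidParameterError("confinement_strength must be positive")
        self.zones = zones
        self.confinement_strength = float(confinement_strength)

    @property
    def n_vs(self) -> int:
        return len(self.zones)

    @property
    def coverage(self) -> tuple[float, float]:
        return float(self.zones[0, 0]), float(self.zones[-1, 1])

    def contains(self, E, i) -> np.ndarray | bool:
        """Whether energy E lies inside zone i (vectorized in both)."""
        zi = self.zones[np.asarray(i, dtype=int)]
        return (np.asarray(E) >= zi[..., 0]) & (np.asarray(E) <= zi[..., 1])

    def states_containing(self, E: float) -> list[int]:
        E = float(E)
        return [i for i in range(self.n_vs)
                if self.zones[i, 0] <= E <= self.zones[i, 1]]

    def state_of(self, E: float) -> int:
        """Lowest-index zone containing E (ties go to the lower index)."""
        c = self.states_containing(E)
        if not c:
            raise InvalidStateError(f"energy {E:g} lies in no zone of the ladder")
        return c[0]

    def multiplicity(self, E) -> np.ndarray:
        """Number of zones containing each energy (1 or 2 inside coverage)."""
        E = np.asarray(E, dtype=float)
        m = (
            (E[..., None] >= self.zones[:, 0]) & (E[..., None] <= self.zones[:, 1])
        ).sum(axis=-1)
        return np.maximum(m, 1)

    def __repr__(self):
        return f"VirtualStateLadder(n_vs={self.n_vs}, coverage={self.coverage})"


def build_ladder(
    E_low: float,
    E_high: float,
    n_vs: int,
    overlap_fraction: float = 0.25,
    confinement_strength: float = 25.0,
) -> VirtualStateLadder:
    """Equal-width zones tiling [E_low, E_high] with a fixed pairwise overlap.

    With stride s = w (1 - f), overlap fraction f < 0.5 guarantees that
    next-nearest zones are disjoint; f >= 0.5 is rejected.
    """
    if not E_low < E_high:
        raise InvalidParameterError("need E_low < E_high")
    if n_vs < 1:
        raise InvalidParameterError("n_vs must be >= 1")
    if n_vs == 1:
        return VirtualStateLadder([[E_low, E_high]], confinement_strength)
    if not 0.0 < overlap_fraction < 0.5:
        raise InvalidParameterError(
            f"overlap_fraction must lie in (0, 0.5); got {overlap_fraction!r} "
            "(>= 0.5 would make next-nearest zones overlap)"
        )
    span = E_high - E_low
    width = span / (1.0 + (n_vs - 1) * (1.0 - overlap_fraction))
    stride = width * (1.0 - overlap_fraction)
    lows = E_low + stride * np.arange(n_vs)
    zones = np.column_stack([lows, lows + width])
    zones[-1, 1] = E_high  # exact upper edge despite roundoff
    return VirtualStateLadder(zones, confinement_strength)


def soft_multiplicity(E, zones, confinement_strength: float, T_sim: float,
                      wall_cap: float | None = None) -> np.ndarray:
    """m(E) = sum_v exp(-wall_v(E) / R_gas T_sim).

    The energy marginal of the zone-confined sampler carries this factor:
    exactly 2 inside zone overlaps, 1 in zone interiors, soft shoulders
    across the wall bands. Dividing a pooled histogram by it recovers the
    single flat distribution the per-virtual-state pieces integrate into.
    """
    E = np.asarray(E, dtype=float)
    zones = np.asarray(zones, dtype=float)
    c = float(confinement_strength)
    cap = WALL_CAP if wall_cap is None else float(wall_cap)
    over = np.abs(
        np.maximum(E[..., None] - zones[:, 1], 0.0)
        + np.minimum(E[..., None] - zones[:, 0], 0.0)
    )
    wall = np.where(
        over <= cap,
        c * over**2,
        c * cap**2 + 2.0 * c * cap * (over - cap),
    )
    return np.maximum(np.exp(-wall / (R_GAS * T_sim)).sum(axis=-1), 1e-12)


def wall_tolerance(ladder: VirtualStateLadder, T_sim: float,
                   wall_cap: float | None = None) -> float:
    """Thermal width of the confinement wall at T_sim.

    The overshoot at which the wall energy reaches 12 R_gas T (exceedance
    probability ~e**-12 per snapshot), accounting for the harmonic-to-linear
    transition at WALL_CAP. Snapshots beyond this are genuine violations,
    not thermal wall shoulders."""
    c = ladder.confinement_strength
    cap = WALL_CAP if wall_cap is None else float(wall_cap)
    target = 12.0 * R_GAS * T_sim
    if c * cap**2 >= target:
        return float(np.sqrt(target / c))
    return float(cap + (target - c * cap**2) / (2.0 * c * cap))


def transition_acceptance(E_R: float, j: int, ladder: VirtualStateLadder) -> float:
    """Metropolis acceptance of a hop into state j at energy E_R: exactly 1
    when E_R lies inside Z_j, else 0."""
    if not 0 <= j < ladder.n_vs:
        return 0.0
    return 1.0 if ladder.contains(E_R, j) else 0.0


def virtual_transition(E_R: float, i: int, ladder: VirtualStateLadder, rng) -> int:
    """One virtual-state move. Proposes i-1 or i+1 with probability 1/2 each
    (an out-of-ladder proposal is rejected, keeping the proposal kernel
    symmetric); accepts iff the proposed zone contains E_R. Coordinates are
    untouched by construction -- only the state index can change.
    """
    if not 0 <= i < ladder.n_vs:
        raise InvalidStateError(f"state index {i} outside ladder of {ladder.n_vs} states")
    step = 1 if rng.uniform() < 0.5 else -1
    j = i + step
    if 0 <= j < ladder.n_vs and transition_acceptance(E_R, j, ladder) == 1.0:
        return j
    return i


def _wall_energy(E, zone_lo, zone_hi, c, cap):
    over = np.abs(np.maximum(E - zone_hi, 0.0) + np.minimum(E - zone_lo, 0.0))
    return np.where(
        over <= cap, c * over**2, c * cap**2 + 2.0 * c * cap * (over - cap)
    )


def _transition_batch(E, states, ladder: VirtualStateLadder, streams,
                      wall_cap: float, T_sim: float) -> np.ndarray:
    """One batched virtual-state move under the soft-wall-consistent
    acceptance min(1, exp(-(wall_new - wall_old)/R T_sim)).

    Inside zone overlaps both walls vanish and the move is accepted
    unconditionally -- the textbook hard-wall transition rule (see
    :func:`virtual_transition`) -- while hops deep into a foreign zone are
    rejected. Keeping the acceptance consistent with the differentiable
    walls preserves detailed balance of the joint (configuration, state)
    chain, so the stationary energy marginal is exactly
    n(E) exp(-E_mc/R T_sim) m(E) with the soft multiplicity m.
    """
    u = np.array([s["mc"].uniform() for s in streams])
    u2 = np.array([s["mc"].uniform() for s in streams])
    prop = states + np.where(u < 0.5, 1, -1)
    valid = (prop >= 0) & (prop < ladder.n_vs)
    pc = np.clip(prop, 0, ladder.n_vs - 1)
    c = ladder.confinement_strength
    w_old = _wall_energy(E, ladder.zones[states, 0], ladder.zones[states, 1], c, wall_cap)
    w_new = _wall_energy(E, ladder.zones[pc, 0], ladder.zones[pc, 1], c, wall_cap)
    accept = valid & (u2 < np.exp(-np.maximum(w_new - w_old, 0.0) / (R_GAS * T_sim)))
    return np.where(accept, prop, states)


#: overshoot width (kcal/mol) beyond which the confinement wall switches
#: from harmonic to linear. An unbounded harmonic wall in energy space is
#: nonlinearly unstable at fixed time step (stiffness grows with overshoot),
#: so the restoring slope saturates at 2 c WALL_CAP (or lower, when the
#: model cannot integrate that force scale stably).
WALL_CAP = 0.3


def _effective_wall_cap(model: PotentialModel, ladder: VirtualStateLadder) -> float:
    """Wall overshoot width at which the restoring slope saturates, limited
    so that slope + wall never exceed the model's stable force scale."""
    c = ladder.confinement_strength
    return float(min(WALL_CAP, 0.2 * model.force_scale_limit / c))


def _make_scaler(mcpot: MulticanonicalPotential, ladder: VirtualStateLadder,
                 limit: float, wall_cap: float):
    tab_e, tab_s = mcpot.slope_table()
    c = ladder.confinement_strength
    zones = ladder.zones
    slope_hi = 0.6 * limit

    def scaler(E, states):
        slope = np.clip(np.interp(E, tab_e, tab_s), -2.0, slope_hi)
        lo = zones[states, 0]
        hi = zones[states, 1]
        over = np.maximum(E - hi, 0.0) + np.minimum(E - lo, 0.0)
        wall = 2.0 * c * np.clip(over, -wall_cap, wall_cap)
        return slope + wall

    return scaler


def _assign_start_states(energies, ladder: VirtualStateLadder, tol: float) -> np.ndarray:
    """Round-robin state assignment restricted to zones containing each
    start energy (the two spec'd rules reconciled; ties to the lower index)."""
    out = np.empty(len(energies), dtype=int)
    for r, E in enumerate(energies):
        cands = ladder.states_containing(E)
        if not cands:
            # within wall tolerance of an edge zone is still a legal start
            if abs(E - ladder.coverage[0]) <= tol:
                cands = [0]
            elif abs(E - ladder.coverage[1]) <= tol:
                cands = [ladder.n_vs - 1]
            else:
                raise InvalidStartError(
                    f"start energy {E:g} lies outside every ladder zone"
                )
        target = r % ladder.n_vs
        out[r] = min(cands, key=lambda s: (abs(s - target), s))
    return out


def _vmcmd_batch(
    model, mcpot, ladder, n_steps, N_int, dt, T_sim, seed_base, starts, start_states,
    record_every, thermostat, friction, run_ids=None, seeds=None, burn_in=0,
):
    B = starts.shape[0]
    if run_ids is None:
        run_ids = list(range(B))
    if seeds is None:
        seeds = [seed_base] * B
    if len(set(zip(seeds, run_ids))) < B:
        raise InvalidParameterError("duplicate (seed, run_id) pairs across runs")
    streams = [rng_streams(s, r) for s, r in zip(seeds, run_ids)]
    wall_cap = _effective_wall_cap(model, ladder)
    scaler = _make_scaler(mcpot, ladder, model.force_scale_limit, wall_cap)

    def hook(E, states, strs):
        return _transition_batch(E, states, ladder, strs, wall_cap, T_sim)

    res = _dynamics(
        model, starts, np.full(B, T_sim), n_steps, dt, streams,
        thermostat=thermostat, friction=friction, record_every=record_every,
        burn_in=burn_in, scaler=scaler, transition_hook=hook, N_int=N_int,
        states=np.asarray(start_states, dtype=int),
    )
    n_rec = res["coordinates"].shape[0]
    meta = {
        "ladder_zones": ladder.zones.tolist(),
        "confinement_strength": ladder.confinement_strength,
        "wall_cap": wall_cap,
        "N_int": int(N_int),
        "T_sim": float(T_sim),
        "dt": float(dt),
        "seeds": [int(s) for s in seeds],
        "record_every": int(record_every),
        "final_coordinates": res["final_coordinates"].tolist(),
        "final_states": res["final_states"].tolist(),
        "iteration": int(mcpot.iteration),
    }
    coords = res["coordinates"].transpose(1, 0, 2).reshape(B * n_rec, -1)
    return Ensemble(
        coords,
        res["energies"].T.ravel(),
        res["states"].T.ravel(),
        np.repeat(np.asarray(run_ids, dtype=int), n_rec),
        np.tile(res["steps"], B),
        model_name=model.name,
        temperature_range=mcpot.T_range,
        sampling_kind="v-mcmd",
        n_sites=model.n_sites,
        metadata=meta,
    )


def vmcmd_run(
    model: PotentialModel,
    mcpot: MulticanonicalPotential,
    ladder: VirtualStateLadder,
    n_steps: int,
    N_int: int = 10,
    dt: float | None = None,
    T_sim: float = 300.0,
    seed: int = 0,
    start: Conformation | None = None,
    start_state: int | None = None,
    record_every: int = 10,
    thermostat: str = "langevin",
    friction: float | None = None,
    burn_in: int = 0,
    run_id: int = 0,
) -> Ensemble:
    """Single V-McMD trajectory.

    Dynamics follow the multicanonical force plus the half-harmonic energy
    wall of the current zone; a virtual-state transition is attempted every
    ``N_int`` steps. Every recorded snapshot stores (E_R, virtual state).
    Deterministic given ``seed``.
    """
    if N_int < 1:
        raise InvalidParameterError("N_int must be >= 1")
    if dt is None:
        dt = model.default_dt
    start = start or model.default_start()
    E0 = model.energy(start.coordinates)
    tol = wall_tolerance(ladder, T_sim, _effective_wall_cap(model, ladder))
    if start_state is None:
        start_state = int(_assign_start_states([E0], ladder, tol)[0])
    if not 0 <= start_state < ladder.n_vs:
        raise InvalidStateError(f"start_state {start_state} outside ladder")
    lo, hi = ladder.zones[start_state]
    if not (lo - tol <= E0 <= hi + tol):
        raise InvalidStartError(
            f"start energy {E0:g} outside zone {start_state} [{lo:g}, {hi:g}]"
        )
    return _vmcmd_batch(
        model, mcpot, ladder, n_steps, N_int, dt, T_sim, seed,
        start.coordinates[None, :], np.array([start_state]),
        record_every, thermostat, friction, run_ids=[run_id], burn_in=burn_in,
    )


def ttp_run(
    model: PotentialModel,
    mcpot: MulticanonicalPotential,
    ladder: VirtualStateLadder,
    n_runs: int,
    n_steps: int,
    starts: list[Conformation],
    seed_base: int = 0,
    seeds=None,
    start_states=None,
    N_int: int = 10,
    dt: float | None = None,
    T_sim: float = 300.0,
    record_every: int = 10,
    thermostat: str = "langevin",
    friction: float | None = None,
    burn_in: int = 0,
) -> Ensemble:
    """Trivial trajectory parallelization: ``n_runs`` independently seeded
    V-McMD walkers under the same weights, pooled into one ensemble.

    Walker r uses the stream keyed by (seed_base, r) (or by
    (seeds[r], r) when an explicit seed list is given -- duplicates are
    rejected), so pooled statistics do not depend on execution or merge
    order; initial virtual states are spread round-robin across the zones
    compatible with each start energy.
    """
    if n_runs < 1:
        raise InvalidParameterError("n_runs must be >= 1")
    if seeds is not None:
        seeds = [int(x) for x in seeds]
        if len(seeds) != n_runs:
            raise InvalidParameterError("need one seed per run")
        if len(set(seeds)) < n_runs:
            raise InvalidParameterError("duplicate seeds across runs")
    if len(starts) != n_runs:
        raise InvalidParameterError(f"need one start per run ({n_runs}), got {len(starts)}")
    if N_int < 1:
        raise InvalidParameterError("N_int must be >= 1")
    if dt is None:
        dt = model.default_dt
    xs = np.stack([s.coordinates for s in starts])
    E0 = model.energy(xs)
    tol = wall_tolerance(ladder, T_sim, _effective_wall_cap(model, ladder))
    if start_states is None:
        start_states = _assign_start_states(E0, ladder, tol)
    else:
        start_states = np.asarray(start_states, dtype=int)
        for E, st in zip(E0, start_states):
            lo, hi = ladder.zones[st]
            if not (lo - tol <= E <= hi + tol):
                raise InvalidStartError(f"start energy {E:g} outside zone {st}")
    return _vmcmd_batch(
        model, mcpot, ladder, n_steps, N_int, dt, T_sim, seed_base, xs,
        start_states, record_every, thermostat, friction, burn_in=burn_in,
        seeds=seeds,
    )


def per_state_flatness(ensemble: Ensemble, ladder: VirtualStateLadder,
                       n_bins: int = 15) -> list[float]:
    """In-zone flatness (relative std of interior-bin counts) of each
    virtual state's energy histogram -- the per-state convergence measure.
    States with no in-zone samples report inf."""
    out = []
    for s in range(ladder.n_vs):
        lo, hi = ladder.zones[s]
        sel = (ensemble.virtual_states == s) & (ensemble.energies >= lo) & (ensemble.energies <= hi)
        counts = np.histogram(ensemble.energies[sel], bins=np.linspace(lo, hi, n_bins + 1))[0]
        if counts.sum() == 0:
            out.append(float("inf"))
        else:
            from .mcenergy import flatness_from_counts

            out.append(float(flatness_from_counts(counts, exclude_edges=True)))
    return out


def _phase_seed(seed: int, phase: int) -> int:
    return (int(seed) * 1000003 + phase) % (2**31 - 1)


def iterate_vmcmd(
    model: PotentialModel,
    ladder: VirtualStateLadder | None = None,
    schedule=(20000, 20000, 20000, 40000),
    flatness_target: float = 0.1,
    T_sim: float = 300.0,
    seed: int = 0,
    *,
    per_state_target: float | None = None,
    min_cycles: int = 1,
    n_runs: int = 16,
    N_int: int = 10,
    dt: float | None = None,
    record_every: int = 20,
    thermostat: str = "langevin",
    friction: float | None = None,
    seed_temps=(280.0, 370.0, 470.0, 600.0),
    seed_steps: int = 60000,
    seed_burn_in: int | None = None,
    grid_bins: int = 120,
    n_vs: int = 4,
    overlap_fraction: float = 0.25,
    confinement_strength: float = 25.0,
    window: tuple[float, float] | None = None,
    smoothing_spec: int | None = None,
    smoothing_knots: int | None = None,
) -> tuple[MulticanonicalPotential, Ensemble]:
    """Full V-McMD protocol on one model.

    1. Canonical runs at ``seed_temps`` (spanning the design temperature
       range) estimate the density of states and hence the initial E_mc.
    2. Start conformations are drawn from the hot/warm canonical snapshots
       (the randomization role of the high-temperature preparation run).
    3. Alternating TTP production / E_mc-update cycles follow ``schedule``;
       each cycle chains the final snapshot of every walker into the next.
       Iteration stops once the merged energy histogram over ``window`` is
       flat to ``flatness_target`` (relative std of counts) -- and, when
       ``per_state_target`` is set, every virtual state's in-zone histogram
       is flat to that level -- or the schedule is exhausted; in the latter
       case the result is flagged ``converged: False`` in the ensemble
       metadata, not raised. Convergence is not tested before ``min_cycles``
       cycles have run (a protocol may insist on its full production cycle).

    Returns the final multicanonical potential and the production ensemble.
    """
    if not schedule:
        raise InvalidParameterError("schedule must contain at least one cycle length")
    if dt is None:
        dt = model.default_dt
    seed_temps = sorted(float(t) for t in seed_temps)
    if seed_burn_in is None:
        seed_burn_in = seed_steps // 5

    seeds_runs = canonical_runs(
        model, seed_temps, seed_steps, dt=dt, seed=_phase_seed(seed, 0),
        thermostat=thermostat, friction=friction, record_every=record_every,
        burn_in=seed_burn_in,
    )
    mcpot = estimate_initial_emc(
        seeds_runs, T_sim, grid_spec=grid_bins, smoothing_knots=smoothing_knots
    )
    if window is None:
        window = (
            float(np.mean(seeds_runs[0][1].energies)),
            float(np.mean(seeds_runs[-1][1].energies)),
        )
    if ladder is None:
        lo, hi = mcpot.coverage
        ladder = build_ladder(lo, hi, n_vs, overlap_fraction, confinement_strength)

    # start pool: decorrelated snapshots of the seed runs, hottest first,
    # restricted to energies inside the ladder
    lo, hi = ladder.coverage
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(_phase_seed(seed, 1))))
    starts = []
    for r in range(n_runs):
        _, ens = seeds_runs[-(1 + r % len(seeds_runs))]
        ok = np.flatnonzero((ens.energies >= lo) & (ens.energies <= hi))
        if len(ok) == 0:
            raise InvalidStartError("no canonical seed snapshot lies inside the ladder")
        starts.append(model.conformation(ens.coordinates[rng.choice(ok)]))

    history = []
    state_history = []
    start_states = None
    converged = False
    ensemble = None
    for it, steps in enumerate(schedule):
        ensemble = ttp_run(
            model, mcpot, ladder, n_runs, int(steps), starts,
            seed_base=_phase_seed(seed, 10 + it), start_states=start_states,
            N_int=N_int, dt=dt, T_sim=T_sim, record_every=record_every,
            thermostat=thermostat, friction=friction, burn_in=int(steps) // 5,
        )
        flat = flatness_metric(ensemble, window, ladder=ladder)
        history.append(float(flat))
        state_flat = per_state_flatness(ensemble, ladder)
        state_history.append(state_flat)
        if (
            it + 1 >= min_cycles
            and flat <= flatness_target
            and (per_state_target is None or max(state_flat) <= per_state_target)
        ):
            converged = True
            break
        if it < len(schedule) - 1:
            try:
                # partial coverage is tolerated inside the iteration: an
                # early cycle that only explored part of the ladder still
                # carries the information needed to push E_mc the right way
                mcpot = update_emc(
                    mcpot, ensemble, smoothing_spec, ladder=ladder, min_coverage=0.25
                )
            except InsufficientSamplingError:
                pass
            starts = [model.conformation(c) for c in ensemble.metadata["final_coordinates"]]
            start_states = np.asarray(ensemble.metadata["final_states"], dtype=int)
            # a walker that ended in a wall excursion restarts in the zone
            # that actually contains its energy; one that ended on a
            # transient spike beyond the ladder restarts from its own run's
            # most recent in-ladder snapshot
            E_fin = model.energy(np.stack([c.coordinates for c in starts]))
            tol = wall_tolerance(ladder, T_sim, _effective_wall_cap(model, ladder))
            glo, ghi = ladder.coverage
            for r, (E, st) in enumerate(zip(E_fin, start_states)):
                zlo, zhi = ladder.zones[st]
                if zlo - tol <= E <= zhi + tol:
                    continue
                cands = ladder.states_containing(E)
                if cands:
                    start_states[r] = min(cands, key=lambda c: abs(c - st))
                    continue
                if glo - tol <= E <= ghi + tol:
                    start_states[r] = 0 if E < glo else ladder.n_vs - 1
                    continue
                run_sel = np.flatnonzero(
                    (ensemble.run_ids == r)
                    & (ensemble.energies >= glo)
                    & (ensemble.energies <= ghi)
                )
                if len(run_sel) == 0:
                    run_sel = np.flatnonzero(
                        (ensemble.energies >= glo) & (ensemble.energies <= ghi)
                    )
                idx = run_sel[-1]
                starts[r] = model.conformation(ensemble.coordinates[idx])
                start_states[r] = ladder.state_of(float(ensemble.energies[idx]))

    ensemble.metadata.update(
        {
            "converged": converged,
            "flatness_history": history,
            "per_state_flatness_history": state_history,
            "iterations_run": len(history),
            "flatness_target": float(flatness_target),
            "window": [float(window[0]), float(window[1])],
            "seed": int(seed),
            "seed_temps": list(seed_temps),
        }
    )
    return mcpot, ensemble
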