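"""Canonical (fixed-temperature) dynamics.

These integrators seed the density-of-states estimate, randomize start
conformations at high temperature, and (through the scaled-force hook) drive
the multicanonical/V-McMD core in :mod:`vmcmd.vsampler`.

Two thermostats are provided:

* ``langevin`` (default) -- BAOAB splitting. Robust and ergodic on stiff,
  low-dimensional toy systems.
* ``velocity-scaling`` -- velocity Verlet with stochastic global velocity
  rescaling of the kinetic energy (canonical sampling through a rescaling
  move with time constant ``scaling_time``).

Randomness is counter-based and keyed by ``(seed, run_id)``: each walker
owns three independent Philox streams (velocity init, thermal noise, Monte
Carlo), so pooled multi-run statistics are independent of merge order and a
batch of walkers reproduces the corresponding single runs bit for bit.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .constants import R_GAS
from .ensemble import Ensemble
from .errors import IntegrationFailureError, InvalidParameterError
from .models import Conformation, PotentialModel

__all__ = ["canonical_run", "canonical_runs", "randomize_conformation", "rng_streams"]

_CHUNK = 512


def rng_streams(seed: int, run_id: int) -> dict:
    """Three independent Philox generators for one walker."""
    ss = np.random.SeedSequence([int(seed), int(run_id)])
    init, noise, mc = [np.random.Generator(np.random.Philox(c)) for c in ss.spawn(3)]
    return {"init": init, "noise": noise, "mc": mc}


def _dynamics(
    model: PotentialModel,
    starts: np.ndarray,            # (B, dim)
    temps: np.ndarray,             # (B,)
    n_steps: int,
    dt: float,
    streams: list[dict],
    thermostat: str = "langevin",
    friction: float | None = None,
    scaling_time: float | None = None,
    record_every: int = 10,
    burn_in: int = 0,
    scaler: Callable[[np.ndarray, np.ndarray | None], np.ndarray] | None = None,
    transition_hook: Callable[[np.ndarray, np.ndarray, list], np.ndarray] | None = None,
    N_int: int | None = None,
    states: np.ndarray | None = None,
):
    """Batched thermostatted dynamics; the workhorse behind all samplers.

    ``scaler(E, states)`` returns the unitless multiplier applied to the
    physical gradient (multicanonical slope plus confinement-wall term);
    ``transition_hook`` is invoked every ``N_int`` steps with the current
    energies and virtual states. Returns recorded arrays plus final state.
    """
    if n_steps < 0:
        raise InvalidParameterError("n_steps must be nonnegative")
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    if thermostat not in ("langevin", "velocity-scaling"):
        raise InvalidParameterError(f"unknown thermostat {thermostat!r}")
    B, dim = starts.shape
    m = model.mass
    temps = np.asarray(temps, dtype=float)
    if friction is None:
        friction = model.default_friction
    if scaling_time is None:
        scaling_time = 100.0 * dt

    x = starts.astype(float).copy()
    kT = R_GAS * temps
    v = np.sqrt(kT / m)[:, None] * np.stack(
        [s["init"].standard_normal(dim) for s in streams]
    )
    if states is not None:
        states = states.astype(int).copy()

    e, g = model.energy_and_gradient(x)
    if not np.all(np.isfinite(e)) or not np.all(np.isfinite(g)):
        raise IntegrationFailureError(0, "non-finite energy/force at the start conformation")
    mult = scaler(e, states) if scaler is not None else None
    f = -g if mult is None else -mult[:, None] * g

    c1 = np.exp(-friction * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * kT / m)  # (B,)
    csc = np.exp(-dt / scaling_time)

    total = burn_in + n_steps
    n_rec = n_steps // record_every if record_every > 0 else 0
    rec_x = np.empty((n_rec, B, dim))
    rec_e = np.empty((n_rec, B))
    rec_s = np.empty((n_rec, B), dtype=int) if states is not None else None
    rec_steps = np.empty(n_rec, dtype=int)
    ri = 0

    step = 0
    err_state = np.errstate(over="ignore", invalid="ignore")  # divergence is
    # detected and reported via IntegrationFailureError, not warnings
    err_state.__enter__()
    while step < total:
        chunk = min(_CHUNK, total - step)
        noise = np.stack(
            [s["noise"].standard_normal((chunk, dim)) for s in streams], axis=1
        )  # (chunk, B, dim)
        if thermostat == "velocity-scaling":
            r1 = np.stack([s["noise"].standard_normal(chunk) for s in streams], axis=1)
            if dim > 1:
                chi = np.stack(
                    [2.0 * s["noise"].standard_gamma((dim - 1) / 2.0, chunk) for s in streams],
                    axis=1,
                )
            else:
                chi = np.zeros((chunk, B))
        for j in range(chunk):
            step += 1
            if thermostat == "langevin":
                v += (0.5 * dt / m) * f
                x += 0.5 * dt * v
                v = c1 * v + c2[:, None] * noise[j]
                x += 0.5 * dt * v
                e, g = model.energy_and_gradient(x)
                mult = scaler(e, states) if scaler is not None else None
                f = -g if mult is None else -mult[:, None] * g
                v += (0.5 * dt / m) * f
            else:
                v += (0.5 * dt / m) * f
                x += dt * v
                e, g = model.energy_and_gradient(x)
                mult = scaler(e, states) if scaler is not None else None
                f = -g if mult is None else -mult[:, None] * g
                v += (0.5 * dt / m) * f
                K = 0.5 * m * np.sum(v * v, axis=-1)
                K = np.maximum(K, 1e-300)
                kbar = 0.5 * dim * kT
                a2 = (
                    csc
                    + (1.0 - csc) * (r1[j] ** 2 + chi[j]) * kbar / (dim * K)
                    + 2.0 * r1[j] * np.sqrt(csc * (1.0 - csc) * kbar / (dim * K))
                )
                v *= np.sqrt(np.maximum(a2, 0.0))[:, None]
            if not np.all(np.isfinite(e)):
                err_state.__exit__(None, None, None)
                raise IntegrationFailureError(step)
            if transition_hook is not None and N_int and step % N_int == 0:
                states = transition_hook(e, states, streams)
            rec_step = step - burn_in
            if rec_step > 0 and record_every > 0 and rec_step % record_every == 0:
                rec_x[ri] = x
                rec_e[ri] = e
                if rec_s is not None:
                    rec_s[ri] = states
                rec_steps[ri] = rec_step
                ri += 1
    err_state.__exit__(None, None, None)
    return {
        "coordinates": rec_x[:ri],
        "energies": rec_e[:ri],
        "states": rec_s[:ri] if rec_s is not None else None,
        "steps": rec_steps[:ri],
        "final_coordinates": x,
        "final_states": states,
    }


def _walker_ensemble(model, res, b, run_id, T, kind, metadata) -> Ensemble:
    n = res["coordinates"].shape[0]
    vs = res["states"][:, b] if res["states"] is not None else np.full(n, -1, dtype=int)
    return Ensemble(
        res["coordinates"][:, b, :],
        res["energies"][:, b],
        vs,
        np.full(n, run_id, dtype=int),
        res["steps"],
        model_name=model.name,
        temperature_range=(T, T),
        sampling_kind=kind,
        n_sites=model.n_sites,
        metadata=metadata,
    )


def canonical_run(
    model: PotentialModel,
    T: float,
    n_steps: int,
    dt: float | None = None,
    seed: int = 0,
    thermostat: str = "langevin",
    record_every: int = 10,
    start: Conformation | None = None,
    friction: float | None = None,
    scaling_time: float | None = None,
    burn_in: int = 0,
    run_id: int = 0,
) -> Ensemble:
    """Fixed-temperature run whose energy histogram converges to the
    canonical distribution of ``model`` at ``T``. Deterministic given seed.
    """
    if T <= 0:
        raise InvalidParameterError("temperature must be positive")
    if n_steps < 1:
        raise InvalidParameterError("n_steps must be >= 1")
    if dt is None:
        dt = model.default_dt
    c0 = (start or model.default_start()).coordinates
    if c0.size != model.dimension:
        raise InvalidParameterError("start conformation has wrong dimension")
    res = _dynamics(
        model, c0[None, :], np.array([T]), n_steps, dt,
        [rng_streams(seed, run_id)], thermostat=thermostat, friction=friction,
        scaling_time=scaling_time, record_every=record_every, burn_in=burn_in,
    )
    meta = {
        "seed": int(seed), "dt": dt, "thermostat": thermostat,
        "record_every": record_every, "burn_in": burn_in, "T": T,
    }
    return _walker_ensemble(model, res, 0, run_id, T, "canonical", meta)


def canonical_runs(
    model: PotentialModel,
    temps: Sequence[float],
    n_steps: int,
    dt: float | None = None,
    seed: int = 0,
    thermostat: str = "langevin",
    record_every: int = 10,
    start: Conformation | None = None,
    friction: float | None = None,
    scaling_time: float | None = None,
    burn_in: int = 0,
) -> list[tuple[float, Ensemble]]:
    """One canonical run per temperature, integrated as a batch.

    Walker ``j`` uses the stream keyed by ``(seed, j)``; the result is
    identical to ``canonical_run(model, temps[j], ..., run_id=j)``.
    """
    temps = list(temps)
    if any(T <= 0 for T in temps):
        raise InvalidParameterError("temperatures must be positive")
    if dt is None:
        dt = model.default_dt
    c0 = (start or model.default_start()).coordinates
    starts = np.tile(c0, (len(temps), 1))
    streams = [rng_streams(seed, j) for j in range(len(temps))]
    res = _dynamics(
        model, starts, np.array(temps, float), n_steps, dt, streams,
        thermostat=thermostat, friction=friction, scaling_time=scaling_time,
        record_every=record_every, burn_in=burn_in,
    )
    out = []
    for j, T in enumerate(temps):
        meta = {"seed": int(seed), "dt": dt, "thermostat": thermostat,
                "record_every": record_every, "burn_in": burn_in, "T": T}
        out.append((T, _walker_ensemble(model, res, j, j, T, "canonical", meta)))
    return out


def randomize_conformation(
    model: PotentialModel,
    T_high: float,
    n_steps: int,
    seed: int = 0,
    start: Conformation | None = None,
    dt: float | None = None,
    friction: float | None = None,
    run_id: int = 0,
) -> Conformation:
    """Final conformation of a high-temperature canonical run.

    The standard preparation step before flat-histogram sampling: a long hot
    run decorrelates the chain from its initial (e.g. helical) geometry.
    ``n_steps=0`` returns ``start`` unchanged.
    """
    start = start or model.default_start()
    if n_steps == 0:
        return start.copy()
    if dt is None:
        dt = model.default_dt
    res = _dynamics(
        model, start.coordinates[None, :], np.array([T_high]), n_steps, dt,
        [rng_streams(seed, run_id)], friction=friction, record_every=0,
    )
    return model.conformation(res["final_coordinates"][0])
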