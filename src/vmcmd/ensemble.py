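"""Snapshot/Ensemble containers shared by the samplers and the analysis stage.

An :class:`Ensemble` stores snapshots column-wise in numpy arrays (one row
per snapshot) for speed; :class:`Snapshot` is a lightweight row view. A
virtual-state index of -1 means "no virtual system attached" (canonical and
plain multicanonical runs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .errors import InvalidParameterError
from .models import Conformation

SAMPLING_KINDS = ("canonical", "multicanonical", "v-mcmd")


@dataclass
class Snapshot:
    """One recorded state: coordinates, potential energy, bookkeeping."""

    conformation: Conformation
    potential_energy: float
    virtual_state: int | None
    run_id: int
    step: int


@dataclass
class Ensemble:
    """Ordered collection of snapshots with provenance metadata.

    metadata keys written by the samplers include seeds, N_int, iteration
    index, the ladder zones (for v-mcmd runs) and per-iteration flatness.
    """

    coordinates: np.ndarray          # (n, dim)
    energies: np.ndarray             # (n,)
    virtual_states: np.ndarray       # (n,) int, -1 = none
    run_ids: np.ndarray              # (n,) int
    steps: np.ndarray                # (n,) int
    model_name: str = ""
    temperature_range: tuple[float, float] = (0.0, 0.0)
    sampling_kind: str = "canonical"
    n_sites: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, dtype=float))
        if self.coordinates.size == 0:
            self.coordinates = self.coordinates.reshape(0, self.coordinates.shape[-1] if self.coordinates.ndim > 1 else 0)
        self.energies = np.asarray(self.energies, dtype=float).ravel()
        self.virtual_states = np.asarray(self.virtual_states, dtype=int).ravel()
        self.run_ids = np.asarray(self.run_ids, dtype=int).ravel()
        self.steps = np.asarray(self.steps, dtype=int).ravel()
        n = len(self.energies)
        for nm, arr in [("coordinates", self.coordinates), ("virtual_states", self.virtual_states),
                        ("run_ids", self.run_ids), ("steps", self.steps)]:
            if len(arr) != n:
                raise InvalidParameterError(f"{nm} length {len(arr)} != {n} snapshots")
        if self.sampling_kind not in SAMPLING_KINDS:
            raise InvalidParameterError(f"unknown sampling kind {self.sampling_kind!r}")

    def __len__(self) -> int:
        return len(self.energies)

    @property
    def dimension(self) -> int:
        return self.coordinates.shape[1]

    def snapshot(self, i: int) -> Snapshot:
        vs = int(self.virtual_states[i])
        return Snapshot(
            conformation=Conformation(self.coordinates[i].copy(), self.n_sites),
            potential_energy=float(self.energies[i]),
            virtual_state=None if vs < 0 else vs,
            run_id=int(self.run_ids[i]),
            step=int(self.steps[i]),
        )

    def __iter__(self) -> Iterator[Snapshot]:
        for i in range(len(self)):
            yield self.snapshot(i)

    def select(self, mask) -> "Ensemble":
        mask = np.asarray(mask)
        return Ensemble(
            self.coordinates[mask],
            self.energies[mask],
            self.virtual_states[mask],
            self.run_ids[mask],
            self.steps[mask],
            model_name=self.model_name,
            temperature_range=self.temperature_range,
            sampling_kind=self.sampling_kind,
            n_sites=self.n_sites,
            metadata=dict(self.metadata),
        )

    @classmethod
    def concatenate(cls, parts: list["Ensemble"]) -> "Ensemble":
        if not parts:
            raise InvalidParameterError("cannot concatenate an empty list of ensembles")
        names = {p.model_name for p in parts}
        if len(names) > 1:
            raise InvalidParameterError(f"ensembles reference different models: {sorted(names)}")
        first = parts[0]
        meta = dict(first.metadata)
        return cls(
            np.vstack([p.coordinates for p in parts]),
            np.concatenate([p.energies for p in parts]),
            np.concatenate([p.virtual_states for p in parts]),
            np.concatenate([p.run_ids for p in parts]),
            np.concatenate([p.steps for p in parts]),
            model_name=first.model_name,
            temperature_range=first.temperature_range,
            sampling_kind=first.sampling_kind,
            n_sites=first.n_sites,
            metadata=meta,
        )
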