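"""Plain-text serialization: ensembles, multicanonical potentials and
coordinate files.

All formats are versioned, self-describing columnar text. Floats are
written with 17 significant digits, so write -> read round-trips are
bit-exact for double precision. Each file carries the number of records in
its header; a truncated file is detected and rejected rather than returned
partially.

Coordinate dialects:

* ``columnar`` -- whitespace-separated ``frame site x y z`` rows (full
  precision).
* ``minimal-pdb`` -- one CA pseudo-atom per site in fixed-column PDB
  layout (coordinates limited to 3 decimals by the format); multi-frame
  files use MODEL/ENDMDL. Only record name, serial and x/y/z are consumed
  on read; residue numbering in files is 1-based, internal site indices are
  0-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .ensemble import Ensemble
from .errors import FormatError, InvalidParameterError
from .mcenergy import MulticanonicalPotential
from .models import Conformation

__all__ = [
    "write_ensemble",
    "read_ensemble",
    "write_mcpot",
    "read_mcpot",
    "write_conformations",
    "import_coordinates",
]

_ENS_MAGIC = "# vmcmd-ensemble v1"
_POT_MAGIC = "# vmcmd-mcpot v1"
_FMT = "%.17g"


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_ensemble(ensemble: Ensemble, path) -> None:
    """Serialize an ensemble losslessly to columnar text."""
    path = Path(path)
    head = {
        "model_name": ensemble.model_name,
        "temperature_range": list(ensemble.temperature_range),
        "sampling_kind": ensemble.sampling_kind,
        "n_sites": ensemble.n_sites,
        "n_snapshots": len(ensemble),
        "dimension": int(ensemble.dimension),
        "metadata": _jsonable(ensemble.metadata),
    }
    with path.open("w") as fh:
        fh.write(_ENS_MAGIC + "\n")
        fh.write("# meta " + json.dumps(head) + "\n")
        fh.write("# columns: run_id step virtual_state energy x...\n")
        for i in range(len(ensemble)):
            coords = " ".join(_FMT % c for c in ensemble.coordinates[i])
            fh.write(
                f"{ensemble.run_ids[i]} {ensemble.steps[i]} {ensemble.virtual_states[i]} "
                + (_FMT % ensemble.energies[i]) + " " + coords + "\n"
            )


def read_ensemble(path) -> Ensemble:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != _ENS_MAGIC:
        raise FormatError(f"{path}: not a vmcmd ensemble file")
    head = None
    rows = []
    for ln, line in enumerate(lines[1:], start=2):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            if s.startswith("# meta "):
                try:
                    head = json.loads(s[len("# meta "):])
                except json.JSONDecodeError as e:
                    raise FormatError(f"{path}:{ln}: bad metadata header: {e}") from e
            continue
        rows.append((ln, s.split()))
    if head is None:
        raise FormatError(f"{path}: missing metadata header")
    dim = int(head["dimension"])
    n = int(head["n_snapshots"])
    if len(rows) != n:
        raise FormatError(
            f"{path}: expected {n} records, found {len(rows)} (truncated or corrupt file)"
        )
    run_ids = np.empty(n, int)
    steps = np.empty(n, int)
    vs = np.empty(n, int)
    energies = np.empty(n)
    coords = np.empty((n, dim))
    for k, (ln, parts) in enumerate(rows):
        if len(parts) != 4 + dim:
            raise FormatError(f"{path}:{ln}: expected {4 + dim} fields, got {len(parts)}")
        try:
            run_ids[k] = int(parts[0])
            steps[k] = int(parts[1])
            vs[k] = int(parts[2])
            energies[k] = float(parts[3])
            coords[k] = [float(p) for p in parts[4:]]
        except ValueError as e:
            raise FormatError(f"{path}:{ln}: unparsable record: {e}") from e
    return Ensemble(
        coords.reshape(n, dim), energies, vs, run_ids, steps,
        model_name=head["model_name"],
        temperature_range=tuple(head["temperature_range"]),
        sampling_kind=head["sampling_kind"],
        n_sites=head["n_sites"],
        metadata=head.get("metadata", {}),
    )


def write_mcpot(mcpot: MulticanonicalPotential, path) -> None:
    """Columnar (E, E_mc, dE_mc/dE) table plus a metadata header.

    The derivative column is informational; the grid and values alone
    reconstruct the potential bit-exactly on read.
    """
    path = Path(path)
    head = {
        "T_sim": mcpot.T_sim,
        "T_range": list(mcpot.T_range),
        "iteration": mcpot.iteration,
        "n": len(mcpot.energy_grid),
    }
    deriv = mcpot.derivative(mcpot.energy_grid)
    with path.open("w") as fh:
        fh.write(_POT_MAGIC + "\n")
        fh.write("# meta " + json.dumps(head) + "\n")
        fh.write("# columns: energy emc demc_de\n")
        for e, v, d in zip(mcpot.energy_grid, mcpot.emc_values, deriv):
            fh.write((_FMT % e) + " " + (_FMT % v) + " " + (_FMT % d) + "\n")


def read_mcpot(path) -> MulticanonicalPotential:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != _POT_MAGIC:
        raise FormatError(f"{path}: not a vmcmd multicanonical-potential file")
    head = None
    rows = []
    for ln, line in enumerate(lines[1:], start=2):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            if s.startswith("# meta "):
                head = json.loads(s[len("# meta "):])
            continue
        parts = s.split()
        if len(parts) != 3:
            raise FormatError(f"{path}:{ln}: expected 3 fields, got {len(parts)}")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError as e:
            raise FormatError(f"{path}:{ln}: unparsable record: {e}") from e
    if head is None:
        raise FormatError(f"{path}: missing metadata header")
    if len(rows) != int(head["n"]):
        raise FormatError(f"{path}: expected {head['n']} grid rows, found {len(rows)}")
    grid = np.array([r[0] for r in rows])
    vals = np.array([r[1] for r in rows])
    return MulticanonicalPotential(
        grid, vals, float(head["T_sim"]), tuple(head["T_range"]),
        iteration=int(head["iteration"]),
    )


# ---------------------------------------------------------------------------
# coordinate files
# ---------------------------------------------------------------------------

def write_conformations(conformations: list[Conformation], path, dialect: str = "columnar") -> None:
    path = Path(path)
    if dialect == "columnar":
        with path.open("w") as fh:
            fh.write("# frame site x y z\n")
            for f, conf in enumerate(conformations):
                for s, (x, y, z) in enumerate(conf.sites()):
                    fh.write(f"{f} {s} " + " ".join(_FMT % v for v in (x, y, z)) + "\n")
    elif dialect == "minimal-pdb":
        with path.open("w") as fh:
            multi = len(conformations) > 1
            for f, conf in enumerate(conformations):
                if multi:
                    fh.write(f"MODEL     {f + 1:4d}\n")
                for s, (x, y, z) in enumerate(conf.sites()):
                    fh.write(
                        f"ATOM  {s + 1:5d}  CA  GLY A{s + 1:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
                    )
                if multi:
                    fh.write("ENDMDL\n")
            fh.write("END\n")
    else:
        raise InvalidParameterError(f"unknown coordinate dialect {dialect!r}")


def _finish_frame(frames, current, path):
    if current:
        if frames and len(current) != len(frames[0]):
            raise FormatError(
                f"{path}: frame {len(frames)} has {len(current)} sites, "
                f"frame 0 has {len(frames[0])}"
            )
        frames.append(current)


def import_coordinates(path, dialect: str = "columnar") -> list[Conformation]:
    """Parse external site coordinates into conformations (0-based sites,
    file order preserved)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[list] = []
    if dialect == "columnar":
        by_frame: dict[int, list] = {}
        for ln, line in enumerate(lines, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) != 5:
                raise FormatError(f"{path}:{ln}: expected 'frame site x y z', got {len(parts)} fields")
            try:
                f = int(parts[0])
                xyz = [float(p) for p in parts[2:5]]
            except ValueError as e:
                raise FormatError(f"{path}:{ln}: unparsable record: {e}") from e
            by_frame.setdefault(f, []).append(xyz)
        counts = {len(v) for v in by_frame.values()}
        if len(counts) > 1:
            raise FormatError(f"{path}: frames have mixed site counts {sorted(counts)}")
        frames = [by_frame[k] for k in sorted(by_frame)]
    elif dialect == "minimal-pdb":
        current: list = []
        for ln, line in enumerate(lines, start=1):
            rec = line[:6].strip()
            if rec in ("MODEL",):
                _finish_frame(frames, current, path)
                current = []
            elif rec in ("ATOM", "HETATM"):
                try:
                    xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                except ValueError as e:
                    raise FormatError(f"{path}:{ln}: unparsable ATOM record: {e}") from e
                current.append(xyz)
            elif rec == "ENDMDL":
                _finish_frame(frames, current, path)
                current = []
        _finish_frame(frames, current, path)
    else:
        raise InvalidParameterError(f"unknown coordinate dialect {dialect!r}")
    if not frames:
        raise FormatError(f"{path}: no coordinate frames found")
    return [
        Conformation(np.asarray(f, float).ravel(), site_count=len(f)) for f in frames
    ]
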