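"""Trajectory and series I/O.

Multi-model PDB is the canonical interchange format (via biotite); XYZ is
supported for lightweight viewers (via MDAnalysis).  Neither format carries
frame times or hydrogen-bond role flags, so both travel in JSON sidecars
(``<file>.times.json`` and ``<file>.topology.json``) that the readers pick up
automatically when present.  An ``internal-csv`` dialect keeps everything in
two plain-text files and round-trips losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TrajectoryFormatError
from .topology import Topology
from .trajectory import ScalarSeries, Trajectory

__all__ = [
    "read_trajectory", "write_trajectory",
    "write_scalar_series", "read_scalar_series",
]

_FORMATS = ("pdb-multimodel", "xyz", "internal-csv")


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    return (path.with_suffix(path.suffix + ".times.json"),
            path.with_suffix(path.suffix + ".topology.json"))


def _times_for(path: Path, n_frames: int, dt: float) -> np.ndarray:
    times_path, _ = _sidecar_paths(path)
    if times_path.exists():
        times = np.asarray(json.loads(times_path.read_text())["times_ns"],
                           dtype=np.float64)
        if len(times) != n_frames:
            raise TrajectoryFormatError(
                f"sidecar {times_path.name} lists {len(times)} times for "
                f"{n_frames} frames")
        return times
    return dt * np.arange(n_frames)


def _topology_for(path: Path, fallback: Topology) -> Topology:
    _, top_path = _sidecar_paths(path)
    if top_path.exists():
        top = Topology.read_json(top_path)
        if top.n_atoms != fallback.n_atoms:
            raise TrajectoryFormatError(
                f"sidecar {top_path.name} describes {top.n_atoms} atoms, "
                f"file has {fallback.n_atoms}")
        return top
    return fallback


# -- PDB ----------------------------------------------------------------------

def _check_pdb_models(path: Path) -> None:
    """Pre-scan model blocks so format errors can name the offending frame."""
    counts: list[int] = []
    current: int | None = None
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                current = 0
            elif rec in ("ATOM", "HETATM"):
                if current is None:       # PDB without MODEL records: 1 frame
                    current = 0
                    counts.append(0)
                    counts[-1] += 1
                    current = None
                else:
                    current += 1
            elif rec == "ENDMDL":
                counts.append(current or 0)
                current = None
    if current is not None and current > 0:
        counts.append(current)
    if counts and any(c != counts[0] for c in counts):
        bad = next(i for i, c in enumerate(counts) if c != counts[0])
        raise TrajectoryFormatError(
            f"inconsistent atom count across models: frame {bad + 1} has "
            f"{counts[bad]} atoms, frame 1 has {counts[0]}")


def _read_pdb(path: Path, dt: float) -> Trajectory:
    import biotite.structure.io.pdb as pdb

    _check_pdb_models(path)
    try:
        pdb_file = pdb.PDBFile.read(str(path))
        stack = pdb_file.get_structure(model=None, extra_fields=["charge"])
    except TrajectoryFormatError:
        raise
    except Exception as exc:  # biotite raises various parse errors
        raise TrajectoryFormatError(f"cannot parse PDB {path}: {exc}") from exc
    coords = np.asarray(stack.coord, dtype=np.float64)
    n_atoms = coords.shape[1]
    elements = [str(e).capitalize() for e in stack.element]
    fallback = Topology.from_atoms([
        {"name": str(stack.atom_name[i]),
         "element": elements[i],
         "res_id": int(stack.res_id[i]),
         "res_name": str(stack.res_name[i]),
         "chain_id": str(stack.chain_id[i]) or "A",
         "charge": int(stack.charge[i]),
         "hydrogen": elements[i] == "H"}
        for i in range(n_atoms)])
    topology = _topology_for(path, fallback)
    times = _times_for(path, coords.shape[0], dt)
    return Trajectory(coords=coords, times=times, topology=topology)


def _write_pdb(traj: Trajectory, path: Path) -> None:
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    top = traj.topology
    stack = struc.AtomArrayStack(traj.n_frames, traj.n_atoms)
    stack.coord = np.asarray(traj.coords, dtype=np.float32)
    stack.chain_id = np.array([str(c) for c in top.chain_ids])
    stack.res_id = top.res_ids.copy()
    stack.res_name = np.array([str(r) for r in top.res_names])
    stack.atom_name = np.array([str(n) for n in top.names])
    stack.element = np.array([str(e).upper() for e in top.elements])
    stack.set_annotation("charge", top.charges.astype(int))
    stack.set_annotation("hetero", np.zeros(traj.n_atoms, dtype=bool))
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


# -- XYZ ----------------------------------------------------------------------

def _read_xyz(path: Path, dt: float) -> Trajectory:
    import warnings

    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format="XYZ")
            names = [str(n) for n in u.atoms.names]
            coords = np.array([u.atoms.positions.copy()
                               for _ in u.trajectory], dtype=np.float64)
    except TrajectoryFormatError:
        raise
    except Exception as exc:
        raise TrajectoryFormatError(f"cannot parse XYZ {path}: {exc}") from exc
    fallback = Topology.from_atoms([
        {"name": f"{n}{i}", "element": n, "hydrogen": n == "H"}
        for i, n in enumerate(names)])
    topology = _topology_for(path, fallback)
    times = _times_for(path, coords.shape[0], dt)
    return Trajectory(coords=coords, times=times, topology=topology)


def _write_xyz(traj: Trajectory, path: Path) -> None:
    # XYZ is element + 3 coordinates per line; elements come from the topology
    symbols = [str(e) for e in traj.topology.elements]
    with open(path, "w") as fh:
        for i in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"frame {i} t={traj.times[i]:.6f} ns\n")
            for sym, (x, y, z) in zip(symbols, traj.coords[i]):
                fh.write(f"{sym:<3s} {x:15.8f} {y:15.8f} {z:15.8f}\n")


# -- internal CSV -------------------------------------------------------------

def _read_internal(path: Path, dt: float) -> Trajectory:
    _, top_path = _sidecar_paths(path)
    if not top_path.exists():
        raise TrajectoryFormatError(
            f"internal-csv trajectory {path} requires sidecar {top_path.name}")
    topology = Topology.read_json(top_path)
    df = pd.read_csv(path)
    required = {"frame", "atom", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise TrajectoryFormatError(
            f"internal-csv needs columns {sorted(required)}")
    n_frames = int(df["frame"].max()) + 1
    counts = df.groupby("frame").size()
    if not (counts == topology.n_atoms).all():
        bad = int(counts[counts != topology.n_atoms].index[0])
        raise TrajectoryFormatError(
            f"inconsistent atom count at frame {bad + 1}")
    coords = (df.sort_values(["frame", "atom"])[["x", "y", "z"]]
              .to_numpy().reshape(n_frames, topology.n_atoms, 3))
    times = _times_for(path, n_frames, dt)
    return Trajectory(coords=coords, times=times, topology=topology)


def _write_internal(traj: Trajectory, path: Path) -> None:
    n_f, n_a, _ = traj.coords.shape
    df = pd.DataFrame({
        "frame": np.repeat(np.arange(n_f), n_a),
        "atom": np.tile(np.arange(n_a), n_f),
        "x": traj.coords[:, :, 0].ravel(),
        "y": traj.coords[:, :, 1].ravel(),
        "z": traj.coords[:, :, 2].ravel(),
    })
    df.to_csv(path, index=False, float_format="%.8f")


# -- public API ---------------------------------------------------------------

def read_trajectory(path, format: str = "pdb-multimodel",
                    dt: float = 0.1) -> Trajectory:
    """Read a trajectory in one of the supported dialects.

    Frame times come from a ``.times.json`` sidecar when present, otherwise
    they are synthesized as ``0, dt, 2 dt, ...`` (``dt`` in ns).  A
    ``.topology.json`` sidecar restores charges and hydrogen-bond role flags
    that the structural formats cannot carry.
    """
    path = Path(path)
    if not path.exists():
        raise TrajectoryFormatError(f"no such file: {path}")
    if format == "pdb-multimodel":
        return _read_pdb(path, dt)
    if format == "xyz":
        return _read_xyz(path, dt)
    if format == "internal-csv":
        return _read_internal(path, dt)
    raise TrajectoryFormatError(
        f"unknown trajectory format {format!r}; expected one of {_FORMATS}")


def write_trajectory(traj: Trajectory, path, format: str = "pdb-multimodel",
                     sidecars: bool = True) -> None:
    """Write a trajectory plus (by default) its times/topology sidecars."""
    path = Path(path)
    if format == "pdb-multimodel":
        _write_pdb(traj, path)
    elif format == "xyz":
        _write_xyz(traj, path)
    elif format == "internal-csv":
        _write_internal(traj, path)
        sidecars = True  # topology sidecar is mandatory for this dialect
    else:
        raise TrajectoryFormatError(
            f"unknown trajectory format {format!r}; expected one of {_FORMATS}")
    if sidecars:
        times_path, top_path = _sidecar_paths(path)
        times_path.write_text(json.dumps({"times_ns": traj.times.tolist()}))
        traj.topology.write_json(top_path)


def write_scalar_series(series: ScalarSeries, path) -> None:
    """Two-column CSV: time_ns, value (header records the unit)."""
    pd.DataFrame({"time_ns": series.times,
                  f"value_{series.unit or 'unitless'}": series.values}
                 ).to_csv(path, index=False)


def read_scalar_series(path) -> ScalarSeries:
    df = pd.read_csv(path)
    value_col = [c for c in df.columns if c.startswith("value")][0]
    unit = value_col.split("_", 1)[1] if "_" in value_col else ""
    return ScalarSeries(times=df["time_ns"].to_numpy(),
                        values=df[value_col].to_numpy(),
                        unit="" if unit == "unitless" else unit)
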