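"""File formats: LAMMPS-style dump, XYZ, LAMMPS data, config files, manifests.

Coordinates are stored unwrapped in memory and wrapped into the box on
export; dumps carry no image flags, so readers can optionally restore
unwrapped chains with a bond-continuity heuristic.  x is always the slab
normal (the long axis).  Positions round-trip at 6 decimals (nm).
"""

from __future__ import annotations

import configparser
import hashlib
import json
import time as _time
import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .model import ForceField, PolymerSpec, SystemConfiguration
from .simulate import SimulationConfig, StageSchedule, Trajectory

__all__ = [
    "DumpFormatError",
    "write_dump",
    "read_dump",
    "write_xyz",
    "read_xyz",
    "write_lammps_data",
    "write_config",
    "read_config",
    "manifest_append",
    "file_sha256",
]


class DumpFormatError(ValueError):
    """Malformed trajectory file; message carries the offending line."""


_TYPE_NAMES = {0: "A", 1: "B"}


def _wrap(frames: np.ndarray, box: np.ndarray) -> np.ndarray:
    return frames - box * np.floor(frames / box)


def write_dump(path, traj: Trajectory) -> None:
    """LAMMPS-style text dump (ITEM: TIMESTEP / TIME / NUMBER OF ATOMS /
    BOX BOUNDS / ATOMS id type x y z), wrapped coordinates, 6 decimals."""
    box = traj.box
    wrapped = _wrap(traj.frames, box)
    with open(path, "w") as fh:
        for k in range(traj.n_frames):
            fh.write("ITEM: TIMESTEP\n")
            fh.write(f"{k}\n")
            fh.write("ITEM: TIME\n")
            fh.write(f"{traj.times[k]:.6f}\n")
            fh.write("ITEM: NUMBER OF ATOMS\n")
            fh.write(f"{traj.n_beads}\n")
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for ax in range(3):
                fh.write(f"0.000000 {box[ax]:.6f}\n")
            fh.write("ITEM: ATOMS id type x y z\n")
            for i in range(traj.n_beads):
                t = int(traj.types[i]) + 1
                x, y, z = wrapped[k, i]
                fh.write(f"{i + 1} {t} {x:.6f} {y:.6f} {z:.6f}\n")


def _unwrap_frames(frames, box, bonds):
    """Bond-continuity unwrap: walk each bond, shift by box multiples so
    every bond is minimum-image short."""
    out = frames.copy()
    for k in range(out.shape[0]):
        for i, j in bonds:
            d = out[k, j] - out[k, i]
            out[k, j] -= box * np.round(d / box)
    return out


def read_dump(
    path,
    bonds: Optional[np.ndarray] = None,
    chain_id: Optional[np.ndarray] = None,
    unwrap: bool = False,
) -> Trajectory:
    """Read a dump written by :func:`write_dump` (or LAMMPS with the same
    ATOMS columns).  With ``unwrap=True`` and known bonds, chains are
    unwrapped by bond continuity (no image flags in the format; a warning
    is emitted)."""
    frames, times, boxes, types_per_frame = [], [], [], []
    with open(path) as fh:
        lines = fh.readlines()
    ln = 0
    n_lines = len(lines)

    def need(n):
        if ln + n > n_lines:
            raise DumpFormatError(f"truncated dump file at line {n_lines}")

    while ln < n_lines:
        if lines[ln].strip() == "":
            ln += 1
            continue
        if not lines[ln].startswith("ITEM: TIMESTEP"):
            raise DumpFormatError(f"expected 'ITEM: TIMESTEP' at line {ln + 1}")
        need(2)
        step = int(lines[ln + 1])
        ln += 2
        t = float(step)
        if ln < n_lines and lines[ln].startswith("ITEM: TIME"):
            need(2)
            t = float(lines[ln + 1])
            ln += 2
        need(1)
        if not lines[ln].startswith("ITEM: NUMBER OF ATOMS"):
            raise DumpFormatError(f"expected 'ITEM: NUMBER OF ATOMS' at line {ln + 1}")
        need(2)
        n_atoms = int(lines[ln + 1])
        ln += 2
        need(1)
        if not lines[ln].startswith("ITEM: BOX BOUNDS"):
            raise DumpFormatError(f"expected 'ITEM: BOX BOUNDS' at line {ln + 1}")
        need(4)
        box = np.empty(3)
        for ax in range(3):
            lo, hi = (float(v) for v in lines[ln + 1 + ax].split()[:2])
            box[ax] = hi - lo
        ln += 4
        need(1)
        if not lines[ln].startswith("ITEM: ATOMS"):
            raise DumpFormatError(f"expected 'ITEM: ATOMS' at line {ln + 1}")
        cols = lines[ln].split()[2:]
        try:
            ix = [cols.index(c) for c in ("id", "type", "x", "y", "z")]
        except ValueError as exc:
            raise DumpFormatError(
                f"ATOMS header at line {ln + 1} missing column: {exc}"
            ) from exc
        ln += 1
        need(n_atoms)
        pos = np.empty((n_atoms, 3))
        typ = np.empty(n_atoms, dtype=np.int8)
        for i in range(n_atoms):
            parts = lines[ln + i].split()
            if len(parts) < len(cols):
                raise DumpFormatError(f"short atom record at line {ln + i + 1}")
            aid = int(parts[ix[0]]) - 1
            typ[aid] = int(parts[ix[1]]) - 1
            pos[aid] = [float(parts[ix[2]]), float(parts[ix[3]]),
                        float(parts[ix[4]])]
        ln += n_atoms
        frames.append(pos)
        times.append(t)
        boxes.append(box)
        types_per_frame.append(typ)

    if not frames:
        raise DumpFormatError("empty dump file")
    if any(len(f) != len(frames[0]) for f in frames):
        raise DumpFormatError("inconsistent atom counts across frames")
    frames = np.asarray(frames)
    box = boxes[0]
    types = types_per_frame[0]
    if bonds is None:
        bonds = np.empty((0, 2), dtype=np.int64)
    if chain_id is None:
        chain_id = np.zeros(frames.shape[1], dtype=np.int64)
    if unwrap and len(bonds):
        warnings.warn("dump has no image flags; unwrapping by bond "
                      "continuity", stacklevel=2)
        frames = _unwrap_frames(frames, box, bonds)
    times = np.asarray(times, dtype=float)
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        times = np.arange(1, len(times) + 1, dtype=float)
    return Trajectory(frames=frames, times=times, box=box, types=types,
                      bonds=np.asarray(bonds, dtype=np.int64),
                      chain_id=np.asarray(chain_id, dtype=np.int64))


def write_xyz(path, traj: Trajectory) -> None:
    """Plain XYZ (element = sticker type), wrapped, with time and box in
    the comment line."""
    wrapped = _wrap(traj.frames, traj.box)
    with open(path, "w") as fh:
        for k in range(traj.n_frames):
            fh.write(f"{traj.n_beads}\n")
            fh.write(
                f"time={traj.times[k]:.6f} box="
                f"{traj.box[0]:.6f},{traj.box[1]:.6f},{traj.box[2]:.6f}\n"
            )
            for i in range(traj.n_beads):
                name = _TYPE_NAMES[int(traj.types[i])]
                x, y, z = wrapped[k, i]
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path) -> Trajectory:
    frames, times, types = [], [], None
    box = None
    with open(path) as fh:
        lines = fh.readlines()
    ln = 0
    while ln < len(lines):
        if lines[ln].strip() == "":
            ln += 1
            continue
        try:
            n = int(lines[ln])
        except ValueError as exc:
            raise DumpFormatError(f"bad atom count at line {ln + 1}") from exc
        if ln + 1 + n >= len(lines) + 1:
            raise DumpFormatError(f"truncated xyz at line {len(lines)}")
        comment = lines[ln + 1]
        t = float(len(times) + 1)
        for tok in comment.split():
            if tok.startswith("time="):
                t = float(tok[5:])
            if tok.startswith("box="):
                box = np.array([float(v) for v in tok[4:].split(",")])
        pos = np.empty((n, 3))
        typ = np.empty(n, dtype=np.int8)
        for i in range(n):
            parts = lines[ln + 2 + i].split()
            typ[i] = 0 if parts[0] == "A" else 1
            pos[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(pos)
        times.append(t)
        types = typ
        ln += 2 + n
    if box is None:
        box = np.array([1.0, 1.0, 1.0])
    n_beads = frames[0].shape[0]
    return Trajectory(frames=np.asarray(frames), times=np.asarray(times),
                      box=box, types=types,
                      bonds=np.empty((0, 2), dtype=np.int64),
                      chain_id=np.zeros(n_beads, dtype=np.int64))


def write_lammps_data(path, config: SystemConfiguration, ff: ForceField,
                      title: str = "sticker-spacer slab system") -> None:
    """LAMMPS data file (atom_style bond) for cross-validation runs."""
    pos = _wrap(config.positions[None, :, :], config.box)[0]
    n = config.n_beads
    nb = len(config.bonds)
    with open(path, "w") as fh:
        fh.write(f"# {title}\n\n")
        fh.write(f"{n} atoms\n{nb} bonds\n\n")
        fh.write("2 atom types\n1 bond types\n\n")
        for ax, name in enumerate(("x", "y", "z")):
            fh.write(f"0.0 {config.box[ax]:.6f} {name}lo {name}hi\n")
        fh.write("\nMasses\n\n1 1.0\n2 1.0\n\nAtoms\n\n")
        for i in range(n):
            fh.write(
                f"{i + 1} {int(config.chain_id[i]) + 1} "
                f"{int(config.types[i]) + 1} "
                f"{pos[i, 0]:.6f} {pos[i, 1]:.6f} {pos[i, 2]:.6f}\n"
            )
        fh.write("\nBonds\n\n")
        for b, (i, j) in enumerate(config.bonds):
            fh.write(f"{b + 1} 1 {i + 1} {j + 1}\n")


_CONFIG_SCHEMA = {
    "polymer": {"ell", "n_monomers", "n_polymers"},
    "box": {"lx", "ly", "lz"},
    "forcefield": {"k", "r0", "u0", "eps", "d", "t0"},
    "run": {"temperature_k", "confine_steps", "ramp_steps",
            "equilibrate_steps", "production_steps", "sample_every",
            "seed", "budget", "slab_half_width"},
    "analysis": {"bin_width", "rel_tol", "finite_size_factor"},
}


def write_config(path, spec: PolymerSpec, ff: ForceField,
                 sim: SimulationConfig, analysis: Optional[dict] = None) -> None:
    cp = configparser.ConfigParser()
    cp["polymer"] = {
        "ell": str(spec.block_length),
        "n_monomers": str(spec.n_monomers),
        "n_polymers": str(sim.n_polymers),
    }
    cp["box"] = {"lx": str(sim.box[0]), "ly": str(sim.box[1]),
                 "lz": str(sim.box[2])}
    cp["forcefield"] = {"k": str(ff.k_bond), "r0": str(ff.r0_bond),
                        "u0": str(ff.u0), "eps": str(ff.epsilon),
                        "d": str(ff.d_bead), "t0": str(ff.t0)}
    sched = sim.schedule
    cp["run"] = {
        "temperature_k": str(sim.temperature),
        "confine_steps": str(sched.confine_steps),
        "ramp_steps": str(sched.ramp_steps),
        "equilibrate_steps": str(sched.equilibrate_steps),
        "production_steps": str(sched.production_steps),
        "sample_every": str(sched.sample_every),
        "seed": str(sim.seed),
        "budget": str(sim.budget),
        "slab_half_width": str(sim.slab_half_width),
    }
    analysis = analysis or {"bin_width": 1.0, "rel_tol": 0.10,
                            "finite_size_factor": 0.05}
    cp["analysis"] = {k: str(v) for k, v in analysis.items()}
    with open(path, "w") as fh:
        cp.write(fh)


def read_config(path):
    """Parse a config file; unknown sections or keys are rejected."""
    cp = configparser.ConfigParser()
    if not cp.read(path):
        raise FileNotFoundError(path)
    for section in cp.sections():
        if section not in _CONFIG_SCHEMA:
            raise ValueError(f"unknown config section [{section}]")
        for key in cp[section]:
            if key not in _CONFIG_SCHEMA[section]:
                raise ValueError(f"unknown key '{key}' in section [{section}]")
    p = cp["polymer"]
    spec = PolymerSpec(block_length=int(p["ell"]),
                       n_monomers=int(p["n_monomers"]))
    f = cp["forcefield"]
    ff = ForceField(k_bond=float(f["k"]), r0_bond=float(f["r0"]),
                    u0=float(f["u0"]), epsilon=float(f["eps"]),
                    d_bead=float(f["d"]), t0=float(f["t0"]))
    b = cp["box"]
    r = cp["run"]
    sim = SimulationConfig(
        n_polymers=int(p["n_polymers"]),
        box=(float(b["lx"]), float(b["ly"]), float(b["lz"])),
        temperature=float(r["temperature_k"]),
        seed=int(r["seed"]),
        slab_half_width=float(r.get("slab_half_width", "40")),
        budget=float(r.get("budget", "1")),
        schedule=StageSchedule(
            confine_steps=int(r["confine_steps"]),
            ramp_steps=int(r["ramp_steps"]),
            equilibrate_steps=int(r["equilibrate_steps"]),
            production_steps=int(r["production_steps"]),
            sample_every=int(r["sample_every"]),
        ),
    )
    a = cp["analysis"] if "analysis" in cp else {}
    analysis = {
        "bin_width": float(a.get("bin_width", 1.0)),
        "rel_tol": float(a.get("rel_tol", 0.10)),
        "finite_size_factor": float(a.get("finite_size_factor", 0.05)),
    }
    return spec, ff, sim, analysis


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def manifest_append(path, stage: str, inputs: Sequence[str],
                    outputs: Sequence[str], seed: Optional[int] = None,
                    extra: Optional[dict] = None) -> None:
    """Append one provenance entry to a JSON-lines run manifest."""
    from . import __version__

    entry = {
        "stage": stage,
        "inputs": [str(p) for p in inputs],
        "outputs": {
            str(p): (file_sha256(p) if Path(p).is_file() else None)
            for p in outputs
        },
        "seed": seed,
        "version": __version__,
        "walltime": _time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if extra:
        entry.update(extra)
    with open(path, "a") as fh:
        fh.write(json.dumps(entry) + "\n")
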