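"""Langevin dynamics in a fixed periodic box with the slab protocol.

The integrator is BAOAB splitting at temperature T with friction set by the
velocity relaxation time tau_v (default 1 ns): zeta = m/tau_v, timestep
tau_v/100.  The bead mass is 1 internal unit (kBT0 ns^2/nm^2); equilibrium
observables do not depend on it, only the kinetic timescale does.

The equilibration protocol mirrors the slab workflow: chains are grown in a
confined slab, relaxed with the A-B attraction off, the attraction depth is
ramped linearly from 0 to U0, and the system then equilibrates unconfined.
Stage lengths scale with a ``budget`` factor (budget 1 is the reference
1e6 / 1e6 / 1e7 step schedule; production 5e7 with pressure samples every
1e5 steps).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from . import _kernels
from .model import (
    BondExtensionError,
    ForceField,
    OverlapError,
    PolymerSpec,
    SystemConfiguration,
    evaluate_forces,
)
from .units import thermal_energy

__all__ = [
    "StageSchedule",
    "SimulationConfig",
    "Trajectory",
    "PressureSample",
    "SimResult",
    "init_slab",
    "run_langevin",
    "equilibrate_protocol",
    "pressure_tensor",
    "scaled_down_preset",
]


@dataclass(frozen=True)
class StageSchedule:
    """Step counts per protocol stage, at budget factor 1."""

    confine_steps: int = 1_000_000
    ramp_steps: int = 1_000_000
    equilibrate_steps: int = 10_000_000
    production_steps: int = 50_000_000
    sample_every: int = 100_000

    def scaled(self, budget: float) -> "StageSchedule":
        def s(x):
            return max(1, int(round(x * budget)))

        return StageSchedule(
            confine_steps=s(self.confine_steps),
            ramp_steps=s(self.ramp_steps),
            equilibrate_steps=s(self.equilibrate_steps),
            production_steps=s(self.production_steps),
            sample_every=max(1, min(s(self.sample_every), s(self.production_steps))),
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Run geometry, thermostat and schedule.

    ``temperature`` in K; ``box`` in nm; ``tau_v`` is the velocity
    relaxation time in ns and fixes both the timestep (tau_v/100) and the
    friction (m/tau_v).
    """

    n_polymers: int = 625
    box: Tuple[float, float, float] = (250.0, 30.0, 30.0)
    temperature: float = 260.0
    tau_v: float = 1.0
    seed: int = 0
    slab_half_width: float = 40.0
    schedule: StageSchedule = field(default_factory=StageSchedule)
    budget: float = 1.0
    exclude_bonded: bool = False
    mass: float = 1.0

    @property
    def timestep(self) -> float:
        return self.tau_v / 100.0

    @property
    def friction(self) -> float:
        return 1.0 / self.tau_v

    def kT(self, ff: ForceField) -> float:
        return thermal_energy(self.temperature, ff.t0)


def scaled_down_preset(temperature: float = 240.0, seed: int = 0) -> Tuple[PolymerSpec, SimulationConfig]:
    """Small system that phase-separates at low T in minutes: 64 chains of
    length 12 (ell=3) in an 80 x 15 x 15 nm box, budget factor 0.02."""
    spec = PolymerSpec(block_length=3, n_monomers=12)
    sim = SimulationConfig(
        n_polymers=64,
        box=(80.0, 15.0, 15.0),
        temperature=temperature,
        seed=seed,
        slab_half_width=12.0,
        budget=0.02,
    )
    return spec, sim


@dataclass
class Trajectory:
    """Sampled frames: positions (F, N, 3) nm, times ns, plus topology."""

    frames: np.ndarray
    times: np.ndarray
    box: np.ndarray
    types: np.ndarray
    bonds: np.ndarray
    chain_id: np.ndarray

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, n_beads, 3)")
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time stamps must increase monotonically")
        self.box = np.asarray(self.box, dtype=np.float64)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_beads(self) -> int:
        return self.frames.shape[1]

    def frame_config(self, k: int) -> SystemConfiguration:
        return SystemConfiguration(
            positions=self.frames[k],
            box=self.box,
            types=self.types,
            bonds=self.bonds,
            chain_id=self.chain_id,
        )


@dataclass(frozen=True)
class PressureSample:
    """Diagonal pressure-tensor entries at one instant, kBT0/nm^3."""

    time: float
    px: float
    py: float
    pz: float


@dataclass
class SimResult:
    trajectory: Optional[Trajectory]
    pressure: pd.DataFrame  # columns time_ns, px, py, pz, potential
    config: SystemConfiguration
    velocities: np.ndarray
    steps_run: int


def _chain_topology(spec: PolymerSpec, n_polymers: int):
    n = spec.n_monomers
    types = np.tile(spec.type_codes, n_polymers)
    chain_id = np.repeat(np.arange(n_polymers, dtype=np.int64), n)
    bonds = []
    for c in range(n_polymers):
        base = c * n
        for i in range(n - 1):
            bonds.append((base + i, base + i + 1))
    bonds = np.asarray(bonds, dtype=np.int64).reshape(-1, 2)
    return types, chain_id, bonds


def init_slab(
    spec: PolymerSpec,
    sim: SimulationConfig,
    ff: Optional[ForceField] = None,
    rng: Optional[np.random.Generator] = None,
) -> SystemConfiguration:
    """Grow chains as random walks confined to the central slab and relax
    same-type overlaps by capped steepest descent (attraction off).

    Raises ``ValueError`` if the slab does not fit the box, or if a valid
    placement cannot be found at the requested density.
    """
    ff = ff or ForceField()
    rng = rng or np.random.default_rng(sim.seed)
    box = np.asarray(sim.box, dtype=float)
    half = sim.slab_half_width
    if half > box[0] / 2:
        raise ValueError("slab half-width exceeds half the box length")
    cx = box[0] / 2
    lo, hi = cx - half, cx + half

    types, chain_id, bonds = _chain_topology(spec, sim.n_polymers)
    n_beads = len(types)
    slab_vol = 2 * half * box[1] * box[2]
    if n_beads * (ff.d_bead ** 3) > 0.6 * slab_vol:
        raise ValueError("bead density too high to place chains in the slab")

    pos = np.empty((n_beads, 3))
    step = 0.9 * ff.d_bead
    for c in range(sim.n_polymers):
        base = c * spec.n_monomers
        pos[base, 0] = rng.uniform(lo, hi)
        pos[base, 1] = rng.uniform(0, box[1])
        pos[base, 2] = rng.uniform(0, box[2])
        for i in range(1, spec.n_monomers):
            v = rng.normal(size=3)
            v *= step / np.linalg.norm(v)
            p = pos[base + i - 1] + v
            # reflect back into the slab on x
            if p[0] > hi:
                p[0] = 2 * hi - p[0]
            elif p[0] < lo:
                p[0] = 2 * lo - p[0]
            pos[base + i] = p

    config = SystemConfiguration(
        positions=pos, box=box, types=types, bonds=bonds, chain_id=chain_id
    )
    # capped steepest descent on the repulsive + bond landscape
    for _ in range(200):
        res = evaluate_forces(config, ff, u0_scale=0.0,
                              exclude_bonded=sim.exclude_bonded)
        fmax = np.abs(res.forces).max()
        if fmax < 20.0:
            break
        disp = res.forces * (0.05 / max(fmax, 1e-12))
        config.positions += disp
        np.clip(config.positions[:, 0], lo, hi, out=config.positions[:, 0])
    config.validate_bonds(ff)
    d = config.positions[bonds[:, 0]] - config.positions[bonds[:, 1]]
    d -= box * np.round(d / box)
    if len(bonds) and np.sqrt((d ** 2).sum(axis=1)).max() >= 0.5 * ff.r0_bond:
        raise ValueError("initial bond longer than R0/2 after placement")
    return config


def _noise_chunk_steps(n_beads: int) -> int:
    # keep per-chunk Gaussian noise buffers around 25 MB
    return max(256, int(1_000_000 / max(1, n_beads)))


def run_langevin(
    config: SystemConfiguration,
    ff: ForceField,
    sim: SimulationConfig,
    n_steps: int,
    u0_scale: float = 1.0,
    sample_every: Optional[int] = None,
    thermostat: bool = True,
    walls: Optional[Tuple[float, float]] = None,
    rng: Optional[np.random.Generator] = None,
    velocities: Optional[np.ndarray] = None,
    collect_frames: bool = True,
    time_origin: float = 0.0,
) -> SimResult:
    """Integrate ``n_steps`` BAOAB steps; emit frames and pressure samples
    every ``sample_every`` steps (default: the schedule's stride).

    ``u0_scale`` in [0, 1] scales only the attraction depth.  ``walls``
    adds reflective x-walls (slab confinement).  A bond-divergence aborts
    with the last valid state and raises ``BondExtensionError``.
    """
    if sample_every is None:
        sample_every = min(sim.schedule.scaled(sim.budget).sample_every, n_steps)
    rng = rng or np.random.default_rng(sim.seed)
    kT = sim.kT(ff)
    m = sim.mass
    pos = np.ascontiguousarray(config.positions, dtype=np.float64).copy()
    if velocities is None:
        velocities = rng.normal(scale=np.sqrt(kT / m), size=pos.shape)
    vel = np.ascontiguousarray(velocities, dtype=np.float64).copy()
    box = config.box.astype(np.float64)
    n_beads = pos.shape[0]

    forces = np.zeros_like(pos)
    virial = np.zeros(3)
    pe, status = _kernels.compute_forces(
        pos, box, config.types, config.bonds, config.chain_id, forces, virial,
        ff.k_bond, ff.r0_bond, ff.u0 * u0_scale, ff.d_bead, ff.epsilon,
        1 if sim.exclude_bonded else 0,
    )
    if status != 0:
        raise (BondExtensionError if status == 1 else OverlapError)(
            "invalid initial configuration"
        )

    max_samples = n_steps // sample_every
    frames = np.empty((max_samples if collect_frames else max_samples, n_beads, 3))
    press = np.empty((max_samples, 3))
    pes = np.empty(max_samples)

    use_walls = 1 if walls is not None else 0
    wall_lo, wall_hi = walls if walls is not None else (0.0, 0.0)
    chunk = _noise_chunk_steps(n_beads)
    pair_cap = 64 * n_beads
    count = 0
    done = 0
    status = 0
    while done < n_steps:
        nst = min(chunk, n_steps - done)
        if thermostat:
            noise = rng.standard_normal((nst, n_beads, 3))
        else:
            noise = np.zeros((nst, n_beads, 3))
        while noise.shape[0] > 0:
            count, steps_done, status, pe = _kernels.baoab_chunk(
                pos, vel, forces, virial, box, config.types, config.bonds,
                config.chain_id, m, kT, sim.friction, sim.timestep,
                ff.u0 * u0_scale, ff.k_bond, ff.r0_bond, ff.d_bead,
                ff.epsilon, 1 if sim.exclude_bonded else 0,
                1 if thermostat else 0, use_walls, wall_lo, wall_hi,
                noise, done, sample_every, frames, press, pes, count,
                pair_cap,
            )
            done += steps_done
            if status == 3:
                # pair list overflowed; enlarge and resume mid-chunk
                pair_cap *= 2
                noise = noise[steps_done:]
                status = 0
                continue
            break
        if status != 0:
            break

    times = time_origin + sim.timestep * sample_every * np.arange(1, count + 1)
    pressure = pd.DataFrame(
        {
            "time_ns": times,
            "px": press[:count, 0],
            "py": press[:count, 1],
            "pz": press[:count, 2],
            "potential": pes[:count],
        }
    )
    out_config = SystemConfiguration(
        positions=pos, box=box, types=config.types, bonds=config.bonds,
        chain_id=config.chain_id,
    )
    traj = None
    if collect_frames and count > 0:
        traj = Trajectory(
            frames=frames[:count].copy(), times=times, box=box,
            types=config.types, bonds=config.bonds, chain_id=config.chain_id,
        )
    result = SimResult(
        trajectory=traj, pressure=pressure, config=out_config,
        velocities=vel, steps_run=done,
    )
    if status == 1:
        raise BondExtensionError(
            f"bond diverged at step {done}; last valid state attached"
        ) from None
    if status == 2:
        raise OverlapError(f"singular overlap at step {done}")
    return result


def equilibrate_protocol(
    spec: PolymerSpec,
    ff: ForceField,
    sim: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    ramp_stages: int = 20,
):
    """Three-stage slab equilibration; returns (configuration, report).

    (i) confined relaxation with the attraction off, (ii) linear ramp of the
    attraction depth 0 -> U0 (piecewise over ``ramp_stages`` sub-stages),
    (iii) unconfined equilibration.  Stage lengths come from
    ``sim.schedule`` scaled by ``sim.budget``.
    """
    rng = rng or np.random.default_rng(sim.seed)
    sched = sim.schedule.scaled(sim.budget)
    box = np.asarray(sim.box, dtype=float)
    cx = box[0] / 2
    walls = (cx - sim.slab_half_width, cx + sim.slab_half_width)

    config = init_slab(spec, sim, ff, rng)
    report = {"stages": [], "potential": [], "slab_fraction": []}

    def slab_fraction(cfg):
        x = cfg.positions[:, 0] - box[0] * np.floor(cfg.positions[:, 0] / box[0])
        return float(np.mean(np.abs(x - cx) <= sim.slab_half_width))

    # (i) confined, U0 = 0
    res = run_langevin(
        config, ff, sim, n_steps=sched.confine_steps, u0_scale=0.0,
        sample_every=max(1, sched.confine_steps // 10),
        walls=walls, rng=rng, collect_frames=False,
    )
    config, vel = res.config, res.velocities
    report["stages"].append(("confine", sched.confine_steps))
    report["potential"].append(res.pressure["potential"].tolist())
    report["slab_fraction"].append(slab_fraction(config))

    # (ii) linear ramp of the attraction, still confined
    per = max(1, sched.ramp_steps // ramp_stages)
    for k in range(ramp_stages):
        scale = (k + 1) / ramp_stages
        res = run_langevin(
            config, ff, sim, n_steps=per, u0_scale=scale,
            sample_every=per, walls=walls, rng=rng,
            velocities=vel, collect_frames=False,
        )
        config, vel = res.config, res.velocities
    report["stages"].append(("ramp", per * ramp_stages))
    report["slab_fraction"].append(slab_fraction(config))

    # (iii) unconfined equilibration at full U0
    res = run_langevin(
        config, ff, sim, n_steps=sched.equilibrate_steps, u0_scale=1.0,
        sample_every=max(1, sched.equilibrate_steps // 20),
        rng=rng, velocities=vel, collect_frames=False,
    )
    config, vel = res.config, res.velocities
    report["stages"].append(("equilibrate", sched.equilibrate_steps))
    report["potential"].append(res.pressure["potential"].tolist())
    report["slab_fraction"].append(slab_fraction(config))
    report["velocities"] = vel
    return config, report


def pressure_tensor(
    config: SystemConfiguration,
    velocities: np.ndarray,
    ff: ForceField,
    sim: SimulationConfig,
    u0_scale: float = 1.0,
    time: float = 0.0,
) -> PressureSample:
    """Instantaneous p_j = (sum_i m v_ij^2 + virial_j) / V, kBT0/nm^3."""
    res = evaluate_forces(config, ff, u0_scale=u0_scale,
                          exclude_bonded=sim.exclude_bonded)
    vol = float(np.prod(config.box))
    kin = sim.mass * (np.asarray(velocities) ** 2).sum(axis=0)
    p = (kin + res.virial) / vol
    return PressureSample(time=time, px=float(p[0]), py=float(p[1]), pz=float(p[2]))
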