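"""Integrator, thermostat and protocol tests (equipartition, Boltzmann
sampling, energy conservation, determinism)."""

import numpy as np
import pytest
from scipy import stats

from stickerslab.model import (
    BondExtensionError,
    ForceField,
    PolymerSpec,
    SystemConfiguration,
    bond_energy,
    evaluate_forces,
)
from stickerslab.simulate import (
    SimulationConfig,
    StageSchedule,
    equilibrate_protocol,
    init_slab,
    pressure_tensor,
    run_langevin,
    scaled_down_preset,
)


def free_bead_config(box=10.0):
    return SystemConfiguration(
        positions=np.array([[box / 2, box / 2, box / 2]]),
        box=np.array([box] * 3),
        types=np.array([0], dtype=np.int8),
        bonds=np.empty((0, 2), dtype=np.int64),
        chain_id=np.array([0]),
    )


def dimer_config(sep=0.5, box=20.0, same_type=False):
    return SystemConfiguration(
        positions=np.array([[box / 2, box / 2, box / 2],
                            [box / 2 + sep, box / 2, box / 2]]),
        box=np.array([box] * 3),
        types=np.array([0, 0 if same_type else 1], dtype=np.int8),
        bonds=np.array([[0, 1]]),
        chain_id=np.array([0, 0]),
    )


def bond_boltzmann_quadrature(ff, kT, moment="energy"):
    """3-D Boltzmann average over the bond potential by quadrature."""
    r = np.linspace(1e-9, ff.r0_bond * (1 - 1e-9), 200_001)
    u = bond_energy(r, ff)
    w = r ** 2 * np.exp(-u / kT)
    z = np.trapezoid(w, r)
    if moment == "energy":
        return float(np.trapezoid(u * w, r) / z)
    return r, w / z  # pdf support and density


class TestInitSlab:
    def test_slab_geometry_and_bonds(self, ff):
        spec = PolymerSpec(block_length=3, n_monomers=12)
        sim = SimulationConfig(n_polymers=20, box=(80.0, 15.0, 15.0),
                               temperature=260.0, slab_half_width=12.0, seed=4)
        cfg = init_slab(spec, sim, ff)
        x = cfg.positions[:, 0]
        assert np.all(np.abs(x - 40.0) <= 12.0 + 1e-9)
        d = cfg.positions[cfg.bonds[:, 0]] - cfg.positions[cfg.bonds[:, 1]]
        d -= cfg.box * np.round(d / cfg.box)
        assert np.sqrt((d ** 2).sum(axis=1)).max() < 0.5 * ff.r0_bond

    def test_single_polymer(self, ff):
        spec = PolymerSpec(block_length=2, n_monomers=4)
        sim = SimulationConfig(n_polymers=1, box=(40.0, 10.0, 10.0),
                               temperature=300.0, slab_half_width=10.0)
        cfg = init_slab(spec, sim, ff)
        assert cfg.n_beads == 4

    def test_impossible_geometry(self, ff):
        spec = PolymerSpec(block_length=2, n_monomers=4)
        sim = SimulationConfig(n_polymers=1, box=(40.0, 10.0, 10.0),
                               temperature=300.0, slab_half_width=30.0)
        with pytest.raises(ValueError, match="half-width"):
            init_slab(spec, sim, ff)


class TestLangevin:
    def test_equipartition_free_bead(self, ff):
        """Velocity variance per axis approaches kBT/m (3 SEM)."""
        sim = SimulationConfig(n_polymers=1, box=(10.0, 10.0, 10.0),
                               temperature=260.0, seed=7)
        res = run_langevin(free_bead_config(), ff, sim, n_steps=300_000,
                           sample_every=100)
        # ideal gas: p_j V = m <v_j^2>, so each pressure column samples v_j^2
        v2 = res.pressure[["px", "py", "pz"]].to_numpy() * 1000.0
        kT = sim.kT(ff)
        est = v2.mean()
        sem = v2.mean(axis=1).std(ddof=1) / np.sqrt(len(v2))
        assert abs(est - kT) < 3 * max(sem, 1e-4)

    def test_kinetic_temperature_within_2pct(self, ff):
        """Thermostat holds the kinetic temperature to 2% (dilute gas,
        300 velocity DOF, ~500 near-independent samples)."""
        rng = np.random.default_rng(8)
        n = 100
        box = 50.0
        cfg = SystemConfiguration(
            positions=rng.uniform(0, box, size=(n, 3)),
            box=np.array([box] * 3),
            types=np.zeros(n, dtype=np.int8),
            bonds=np.empty((0, 2), dtype=np.int64),
            chain_id=np.arange(n),
        )
        sim = SimulationConfig(n_polymers=n, box=(box, box, box),
                               temperature=230.0, seed=8)
        res = run_langevin(cfg, ff, sim, n_steps=100_000, sample_every=200,
                           u0_scale=0.0)
        # dilute gas: virial negligible, p_j V / N ~ m <v_j^2>
        p = res.pressure[["px", "py", "pz"]].to_numpy()
        kT_est = p.mean() * box ** 3 / n
        assert kT_est == pytest.approx(sim.kT(ff), rel=0.02)

    def test_dimer_mean_bond_energy_matches_quadrature(self, ff):
        sim = SimulationConfig(n_polymers=1, box=(20.0, 20.0, 20.0),
                               temperature=300.0, seed=10)
        res = run_langevin(dimer_config(), ff, sim, n_steps=400_000,
                           sample_every=50, u0_scale=0.0)
        frames = res.trajectory.frames
        r = np.linalg.norm(frames[:, 0] - frames[:, 1], axis=1)
        u = bond_energy(r, ff)
        burn = len(u) // 10
        u = u[burn:]
        # block SEM over 20 blocks
        blocks = np.array([b.mean() for b in np.array_split(u, 20)])
        sem = blocks.std(ddof=1) / np.sqrt(len(blocks))
        expected = bond_boltzmann_quadrature(ff, sim.kT(ff))
        assert abs(u.mean() - expected) < 3 * sem

    def test_dimer_bond_length_distribution_ks(self, ff):
        """Sampled bond lengths match the Boltzmann weight of the bond
        potential (KS test, alpha = 0.01, n = 2000 pre-registered)."""
        sim = SimulationConfig(n_polymers=1, box=(20.0, 20.0, 20.0),
                               temperature=300.0, seed=11)
        res = run_langevin(dimer_config(), ff, sim, n_steps=1_000_000,
                           sample_every=500, u0_scale=0.0)
        frames = res.trajectory.frames
        r = np.linalg.norm(frames[:, 0] - frames[:, 1], axis=1)
        support, pdf = bond_boltzmann_quadrature(ff, sim.kT(ff), moment="pdf")
        cdf_grid = np.cumsum(pdf) * (support[1] - support[0])
        cdf_grid /= cdf_grid[-1]

        def cdf(x):
            return np.interp(x, support, cdf_grid)

        stat = stats.ks_1samp(r, cdf)
        assert len(r) == 2000
        assert stat.pvalue > 0.01

    def test_no_attraction_slab_melts(self, ff):
        """With U0 = 0 a dense slab spreads toward a uniform profile."""
        spec = PolymerSpec(block_length=3, n_monomers=12)
        sim = SimulationConfig(n_polymers=24, box=(60.0, 12.0, 12.0),
                               temperature=300.0, slab_half_width=8.0, seed=12)
        cfg = init_slab(spec, sim, ff)
        res = run_langevin(cfg, ff, sim, n_steps=60_000, sample_every=60_000,
                           u0_scale=0.0)
        x = res.config.positions[:, 0]
        x -= 60.0 * np.floor(x / 60.0)
        assert np.std(x) > 10.0  # far beyond the initial +-8 nm slab

    def test_energy_conservation_without_thermostat(self, ff):
        """NVE mode: relative energy drift < 1e-4 per 1e4 steps."""
        sim = SimulationConfig(n_polymers=1, box=(20.0, 20.0, 20.0),
                               temperature=300.0, seed=13)
        cfg = dimer_config(sep=1.5)
        rng = np.random.default_rng(13)
        vel = rng.normal(scale=np.sqrt(sim.kT(ff)), size=(2, 3))

        def total_energy(c, v):
            return evaluate_forces(c, ff).potential + 0.5 * (v ** 2).sum()

        e0 = total_energy(cfg, vel)
        res = run_langevin(cfg, ff, sim, n_steps=10_000, sample_every=10_000,
                           thermostat=False, velocities=vel)
        e1 = total_energy(res.config, res.velocities)
        assert abs(e1 - e0) / abs(e0) < 1e-4

    def test_bitwise_reproducibility(self, ff):
        spec = PolymerSpec(block_length=2, n_monomers=8)
        sim = SimulationConfig(n_polymers=6, box=(30.0, 10.0, 10.0),
                               temperature=260.0, slab_half_width=10.0,
                               seed=21)
        runs = []
        for _ in range(2):
            cfg = init_slab(spec, sim, ff, rng=np.random.default_rng(sim.seed))
            res = run_langevin(cfg, ff, sim, n_steps=5_000, sample_every=500,
                               rng=np.random.default_rng(sim.seed))
            runs.append(res)
        assert np.array_equal(runs[0].trajectory.frames,
                              runs[1].trajectory.frames)
        assert runs[0].pressure.equals(runs[1].pressure)

    def test_bond_divergence_raises(self, ff):
        cfg = dimer_config(sep=4.999)
        sim = SimulationConfig(n_polymers=1, box=(20.0, 20.0, 20.0),
                               temperature=300.0, seed=1)
        rng = np.random.default_rng(1)
        vel = rng.normal(scale=40.0, size=(2, 3))  # absurd kick
        with pytest.raises(BondExtensionError):
            run_langevin(cfg, ff, sim, n_steps=1000, sample_every=100,
                         velocities=vel)


class TestPressure:
    def test_ideal_gas_kinetic_only(self, ff):
        cfg = free_bead_config(box=10.0)
        sim = SimulationConfig(n_polymers=1, box=(10.0, 10.0, 10.0),
                               temperature=300.0)
        vel = np.array([[0.3, -0.5, 0.7]])
        s = pressure_tensor(cfg, vel, ff, sim)
        vol = 1000.0
        assert s.px == pytest.approx(0.3 ** 2 / vol, rel=1e-12)
        assert s.py == pytest.approx(0.5 ** 2 / vol, rel=1e-12)
        assert s.pz == pytest.approx(0.7 ** 2 / vol, rel=1e-12)


class TestProtocol:
    def test_schedule_budget_scaling(self):
        sched = StageSchedule()
        s = sched.scaled(0.01)
        assert (s.confine_steps, s.ramp_steps, s.equilibrate_steps) == \
            (10_000, 10_000, 100_000)
        assert s.production_steps == 500_000
        s1 = sched.scaled(1.0)
        assert (s1.confine_steps, s1.ramp_steps, s1.equilibrate_steps) == \
            (1_000_000, 1_000_000, 10_000_000)

    def test_protocol_forms_slab_at_low_temperature(self, ff):
        """After the ramp + equilibration a cold small system keeps a dense
        slab spanning the box cross-section."""
        spec, sim = scaled_down_preset(temperature=210.0, seed=5)
        from dataclasses import replace
        sim = replace(sim, n_polymers=32, box=(60.0, 12.0, 12.0),
                      slab_half_width=10.0, budget=0.004)
        cfg, report = equilibrate_protocol(spec, ff, sim)
        assert [s[0] for s in report["stages"]] == \
            ["confine", "ramp", "equilibrate"]
        # most beads stay in a slab-like dense region
        x = cfg.positions[:, 0]
        x -= 60.0 * np.floor(x / 60.0)
        theta = 2 * np.pi * x / 60.0
        center = np.angle(np.exp(1j * theta).mean()) * 60.0 / (2 * np.pi) % 60.0
        dist = np.abs(x - center)
        dist = np.minimum(dist, 60.0 - dist)
        assert np.mean(dist < 15.0) > 0.8
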