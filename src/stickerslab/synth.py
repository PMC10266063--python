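"""Synthetic observables with known ground truth.

Each generator is the exact inverse model of one analysis stage, so the
whole analysis chain is testable in seconds without molecular dynamics:

* :func:`gen_tanh_profile`        -> ``interface.fit_tanh``
* :func:`gen_powerlaw_gamma`      -> ``scaling.fit_power_law``
* :func:`gen_pressure_series`     -> ``interface.kirkwood_buff_gamma``
* :func:`gen_oz_field`            -> ``interface.oz_xi_from_field``
* :func:`gen_toy_trajectory`      -> ``interface.radius_of_gyration``

All randomness goes through ``numpy.random.default_rng(seed)`` (PCG64, a
fixed algorithm): identical seeds give identical output on any platform.
Ground truth is returned alongside every output.  Default noise levels
mirror the scatter of slab-simulation observables (SEM of a few percent
from five independent repeats).
"""

from __future__ import annotations

import warnings
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .interface import DensityProfile
from .simulate import Trajectory

__all__ = [
    "gen_tanh_profile",
    "gen_powerlaw_gamma",
    "gen_pressure_series",
    "gen_oz_field",
    "gen_toy_trajectory",
]


def gen_tanh_profile(
    c1: float = 0.1,
    c2: float = 5.0,
    x0: float = 60.0,
    width: float = 8.0,
    lx: float = 120.0,
    bin_width: float = 0.5,
    noise: float = 0.0,
    noise_kind: str = "multiplicative",
    two_interface: bool = False,
    slab_half: Optional[float] = None,
    seed: int = 0,
) -> Tuple[DensityProfile, dict]:
    """Tanh-shaped 1-D density profile plus ground truth.

    Single-interface mode evaluates
    c(x) = (c1+c2)/2 + (c2-c1)/2 tanh(2(x-x0)/L) on the bin centers;
    two-interface mode builds a slab centered at Lx/2 with interfaces at
    Lx/2 -+ slab_half.  Noise is Gaussian, multiplicative (fractional) or
    additive (absolute).
    """
    if not (c2 > c1 >= 0):
        raise ValueError("need c2 > c1 >= 0")
    if width <= 0 or width >= lx / 4:
        if width >= lx / 4:
            warnings.warn("interface width >= Lx/4: profile has no plateaus",
                          stacklevel=2)
        if width <= 0:
            raise ValueError("width must be positive")
    rng = np.random.default_rng(seed)
    nbins = max(1, int(round(lx / bin_width)))
    bw = lx / nbins
    x = (np.arange(nbins) + 0.5) * bw
    if two_interface:
        half = slab_half if slab_half is not None else lx / 6.0
        xl, xr = lx / 2.0 - half, lx / 2.0 + half
        f = 0.5 * (np.tanh(2 * (x - xl) / width) - np.tanh(2 * (x - xr) / width))
        c = c1 + (c2 - c1) * f
        truth_x0 = (xl, xr)
    else:
        c = 0.5 * (c1 + c2) + 0.5 * (c2 - c1) * np.tanh(2 * (x - x0) / width)
        truth_x0 = x0
    if noise > 0:
        eta = rng.standard_normal(nbins)
        if noise_kind == "multiplicative":
            c = c * (1.0 + noise * eta)
        elif noise_kind == "additive":
            c = c + noise * eta
        else:
            raise ValueError("noise_kind must be multiplicative or additive")
        c = np.maximum(c, 0.0)
    profile = DensityProfile(bin_centers=x, concentration=c, bin_width=bw,
                             lx=lx, n_frames=1, cross_area=1.0)
    truth = {"c1": c1, "c2": c2, "x0": truth_x0, "width": width,
             "xi": width / 4.0, "noise": noise, "noise_kind": noise_kind,
             "two_interface": two_interface}
    return profile, truth


def gen_powerlaw_gamma(
    tc: float = 320.0,
    gamma0: float = 0.4,
    mu: float = 1.26,
    t_grid: Optional[np.ndarray] = None,
    noise: float = 0.05,
    n_repeats: int = 5,
    seed: int = 0,
    crossover_tau: Optional[float] = None,
    deviation: float = 0.3,
) -> Tuple[pd.DataFrame, dict]:
    """gamma(T) table obeying gamma = gamma0 tau^mu, with pseudo-repeats.

    Each of ``n_repeats`` pseudo-repeats gets multiplicative Gaussian noise;
    the table reports their mean and SEM per temperature, mirroring a
    five-repeat slab campaign.  Above ``crossover_tau`` (if set) the true
    curve deviates from the power law by the given fraction, emulating the
    end of the critical regime.
    """
    if t_grid is None:
        t_grid = np.arange(230.0, 305.0, 10.0)
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(t_grid >= tc):
        raise ValueError("all temperatures must lie below Tc")
    rng = np.random.default_rng(seed)
    tau = 1.0 - t_grid / tc
    g_true = gamma0 * tau ** mu
    if crossover_tau is not None:
        g_true = np.where(tau > crossover_tau, g_true * (1.0 + deviation), g_true)
    reps = g_true[None, :] * (
        1.0 + noise * rng.standard_normal((n_repeats, len(t_grid)))
    )
    gamma = reps.mean(axis=0)
    sem = (reps.std(axis=0, ddof=1) / np.sqrt(n_repeats)
           if n_repeats > 1 else np.zeros(len(t_grid)))
    if noise == 0:
        gamma = g_true.copy()
        sem = np.zeros(len(t_grid))
    table = pd.DataFrame({"T": t_grid, "gamma": gamma, "sigma": sem})
    truth = {"tc": tc, "gamma0": gamma0, "mu": mu, "noise": noise,
             "n_repeats": n_repeats, "crossover_tau": crossover_tau,
             "deviation": deviation, "gamma_true": g_true}
    return table, truth


def gen_pressure_series(
    mean_anisotropy: float = 1e-3,
    ac_time: float = 5.0,
    sigma: float = 2e-3,
    n: int = 500,
    lx: float = 250.0,
    p_iso: float = 0.1,
    dt_sample: float = 1.0,
    seed: int = 0,
) -> Tuple[pd.DataFrame, dict]:
    """AR(1) pressure-tensor anisotropy series with analytic gamma truth.

    px - (py+pz)/2 follows a stationary AR(1) process with the prescribed
    mean, marginal standard deviation ``sigma`` and autocorrelation time
    ``ac_time`` (in sample strides); py = pz = ``p_iso``.  The analytic
    truth is gamma = (Lx/2) * mean and the AR(1) standard error of the mean
    sem = (Lx/2) * sigma * sqrt((1+phi)/((1-phi) n)).
    """
    if n <= 10 * ac_time:
        raise ValueError("need n > 10 * autocorrelation time")
    rng = np.random.default_rng(seed)
    phi = np.exp(-1.0 / ac_time) if ac_time > 0 else 0.0
    a = np.empty(n)
    if sigma > 0:
        a[0] = rng.normal(0.0, sigma)
        innov = rng.normal(0.0, sigma * np.sqrt(1.0 - phi ** 2), size=n - 1)
        for i in range(1, n):
            a[i] = phi * a[i - 1] + innov[i - 1]
    else:
        a[:] = 0.0
    a += mean_anisotropy
    df = pd.DataFrame({
        "time_ns": dt_sample * np.arange(1, n + 1),
        "px": p_iso + a,
        "py": np.full(n, p_iso),
        "pz": np.full(n, p_iso),
    })
    sem_analytic = (lx / 2.0) * sigma * np.sqrt((1 + phi) / ((1 - phi) * n)) \
        if sigma > 0 and phi < 1 else 0.0
    truth = {"gamma": (lx / 2.0) * mean_anisotropy, "lx": lx, "phi": phi,
             "sigma": sigma, "sem_analytic": sem_analytic,
             "mean_anisotropy": mean_anisotropy}
    return df, truth


def gen_oz_field(
    xi: float = 3.0,
    shape: Tuple[int, int, int] = (32, 32, 32),
    spacing: float = 1.0,
    s0: float = 1.0,
    seed: int = 0,
) -> Tuple[np.ndarray, dict]:
    """Gaussian random field with Ornstein-Zernike spectrum S0/(1+k^2 xi^2).

    ``xi = 0`` gives white noise.  The field is real with zero mean.
    """
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(shape)
    wk = np.fft.fftn(white)
    kgrids = np.meshgrid(
        *[2 * np.pi * np.fft.fftfreq(nn, d=spacing) for nn in shape],
        indexing="ij",
    )
    k2 = sum(k ** 2 for k in kgrids)
    amp = np.sqrt(s0 / (1.0 + k2 * xi ** 2))
    field = np.real(np.fft.ifftn(wk * amp))
    field -= field.mean()
    truth = {"xi": xi, "s0": s0, "spacing": spacing}
    return field, truth


def gen_toy_trajectory(
    kind: str = "rod",
    n_beads: int = 24,
    spacing: float = 1.0,
    n_frames: int = 3,
    box: Tuple[float, float, float] = (250.0, 30.0, 30.0),
    block_length: int = 3,
    wrap: bool = False,
    seed: int = 0,
) -> Tuple[Trajectory, dict]:
    """Single-chain trajectory fixtures with closed-form radius of gyration.

    ``rod``: beads evenly spaced along x; Rg^2 = spacing^2 (N^2 - 1)/12.
    ``globule``: all beads coincident; Rg = 0.  With ``wrap=True`` the rod
    is placed across the periodic x-boundary to exercise unwrapping.
    """
    box = np.asarray(box, dtype=float)
    if kind == "rod":
        x = spacing * np.arange(n_beads, dtype=float)
        pos = np.zeros((n_beads, 3))
        pos[:, 0] = x
        if wrap:
            pos[:, 0] += box[0] - spacing * n_beads / 2.0
            pos[:, 0] -= box[0] * np.floor(pos[:, 0] / box[0])
        else:
            pos += box / 4.0
        rg_true = spacing * np.sqrt((n_beads ** 2 - 1) / 12.0)
    elif kind == "globule":
        pos = np.full((n_beads, 3), box / 2.0)
        rg_true = 0.0
    else:
        raise ValueError("kind must be 'rod' or 'globule'")
    types = np.array(
        [0 if (i // block_length) % 2 == 0 else 1 for i in range(n_beads)],
        dtype=np.int8,
    )
    bonds = np.column_stack([np.arange(n_beads - 1), np.arange(1, n_beads)])
    frames = np.repeat(pos[None, :, :], n_frames, axis=0)
    traj = Trajectory(
        frames=frames,
        times=np.arange(1, n_frames + 1, dtype=float),
        box=box,
        types=types,
        bonds=bonds.astype(np.int64),
        chain_id=np.zeros(n_beads, dtype=np.int64),
    )
    return traj, {"rg": rg_true, "kind": kind, "n_beads": n_beads,
                  "spacing": spacing}
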