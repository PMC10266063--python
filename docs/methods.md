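# Methods

## Model

Polymers are linear chains of spherical beads of diameter d = 1 nm, each
bead an associative sticker of type A or B. A chain is a periodic repeat of
`ell` A stickers followed by `ell` B stickers; the degree of polymerization
N is restricted to multiples of `2*ell` so A and B are always present in
equal numbers. Three interactions act (internal units: length nm, energy
kBT0 with T0 = 300 K, time ns):

* **Bond** between consecutive beads:
  `U_b(r) = -(K R0^2 / 2) ln(1 - r^2/R0^2)`, K = 0.56 kBT0/nm², R0 = 5 nm.
  The bond is finitely extensible; a separation reaching R0 aborts the run
  with a diagnostic (it indicates a too-large timestep or a bad start).
* **Heterotypic attraction** (A-B only):
  `U_a(r) = -(U0/2)(1 + cos(pi r / d))` for r < d, zero beyond; U0 = 8 kBT0.
  A-B pairs have *no* excluded volume and may overlap completely, which
  makes each sticker-sticker association effectively one-to-one and
  saturating.
* **Homotypic repulsion** (A-A and B-B): the WCA-truncated Lennard-Jones
  `U_r(r) = 4 eps [(d/r)^12 - (d/r)^6 + 1/4]` for r < 2^(1/6) d, eps = 1 kBT0.

All parameters are fixed in absolute units. Thermal energy in internal
units is T/T0, so attraction measured in kBT weakens as T rises and the
system phase-separates on cooling (UCST). The "kBT" in the bond stiffness
is read as kBT0 for the same reason: a temperature-independent spring.

Nonbonded terms are *not* excluded between bonded neighbors by default
(same-type bonded neighbors need their excluded volume to keep the chain
from collapsing onto itself); `exclude_bonded` switches this off for
sensitivity checks.

## Dynamics

Langevin dynamics with the BAOAB splitting, chosen for its configurational
accuracy at large timestep. The velocity relaxation time tau_v = 1 ns sets
both the friction (zeta = m/tau_v) and the timestep (tau_v/100 = 0.01 ns).
The relation tau_v = m D / kBT with D = kBT/zeta fixes only the ratio
m/zeta, so the bead mass is set to 1 internal mass unit
(kBT0 ns²/nm²); equilibrium averages are independent of this choice, only
the kinetic timescale depends on it. Velocities are initialized from the
Maxwell-Boltzmann distribution at the run temperature. With the thermostat
disabled the integrator reduces to velocity Verlet; an energy-drift test
guards the implementation.

Pair interactions use a Verlet neighbor list (skin 0.3 nm) rebuilt through
a cell grid whenever any bead has moved more than 0.4 x skin since the
last build (the conventional half-skin criterion, tightened slightly to
absorb intra-step drift because the check runs at step boundaries). The
list radius covers both cutoffs, so forces are exact.

## Slab protocol

Chains are grown as random walks confined to a central slab (reflective
x-walls at +-half-width, default 40 nm), relaxed by capped steepest descent
with the attraction off, then equilibrated in three stages: (i) confined
relaxation at U0 = 0, (ii) a piecewise-linear ramp of the attraction depth
from 0 to U0, (iii) unconfined equilibration. The reference schedule is
1e6 / 1e6 / 1e7 steps with 5e7 production steps and pressure samples every
1e5 steps; every stage scales by a single `budget` factor so the same
protocol runs at desk scale. The scaled-down preset (64 chains of length
12, ell = 3, in an 80 x 15 x 15 nm box, budget 0.02) phase-separates at low
temperature in minutes on one core.

## Observables

* **Surface tension (mechanical route).** gamma = (Lx/2) <px - (py+pz)/2>
  from the diagonal pressure tensor p_j = (sum_i m v_ij^2 + sum_pairs
  r_j F_j)/V; the factor 1/2 accounts for the two interfaces of the slab.
  For a stable slab with normal along x the volume-averaged anisotropy is
  positive, giving gamma > 0 directly. SEM comes from independent repeats
  when available, otherwise from block averaging (10 blocks) within a
  series to respect autocorrelation.
* **Density profile and interface width.** Bead positions are binned along
  x (default bin 1 nm, the bead diameter) after recentering each frame on
  the circular mean of the bead x-coordinates, which keeps a drifting slab
  sharp and conserves bead count exactly. Each of the two interfaces is
  fitted independently to c(x) = (c1+c2)/2 + (c2-c1)/2 tanh(2(x-x0)/L) and
  the widths averaged; parameter errors come from the fit covariance.
* **Correlation length.** xi = L/4, from matching the tanh profile's
  far-field exponential decay, exp(4(x-x0)/L) on the dilute side, to the
  Ornstein-Zernike form exp(-|x|/xi). The identity is verified numerically
  by fitting the tail of a noiseless profile (relative error < 1e-3 with a
  fit window 2L-3.5L from the midpoint). A second, independent estimate
  fits the Ornstein-Zernike Lorentzian S0/(1 + k^2 xi^2) (plus a flat
  shot-noise offset) to the radially averaged fluctuation spectrum of
  density in the slab interior, with k-shells weighted by mode count; a
  flat spectrum is reported as xi = 0 via an AIC comparison against the
  offset-only model. There is no single canonical
  estimator for bulk density-fluctuation correlation lengths; this
  spectral route is one defensible choice and is labeled as such.
* **Radius of gyration.** Per chain and frame after bond-continuity
  unwrapping; SEM over chains x time blocks.

## Critical-scaling inference

Near the UCST the system is in the 3-D Ising class: gamma = gamma0 tau^mu
and xi = xi0 tau^-nu with tau = 1 - T/Tc, mu = 1.26, nu = mu/(d-1) = 0.63.
Fits hold the exponents fixed and extract only (Tc, amplitude) by weighted
least squares (weights 1/SEM^2; zero-SEM points get the median weight; a
coarse scan over Tc seeds a bounded Levenberg-Marquardt refinement).
SEM-weighting is a genuine design choice for such fits; weighted fits are
the package default and the `sigma=None` path gives the unweighted
variant. Confidence intervals use Student-t quantiles with n-2 degrees of
freedom, appropriate for the small point counts involved.

State points whose implied correlation length exceeds 5% of Lx are excluded
(finite-size filter). When widths are measured the filter uses xi = L/4;
otherwise the fit-implied xi (through the universal ratio) is used and
filter + fit are iterated to a stable retained set.

Two-scale-factor universality fixes R- = gamma xi^(d-1) / (kB Tc) = 0.1024,
so with L = 4 xi: gamma = 16 R- kB Tc / L^2 = 1.6384 kB Tc / L^2 ~ 1.64 kB
Tc / L^2. Because mu = 2 nu, the value of gamma predicted at the reference
temperature is independent of tau_ref — the whole gamma(T) curve follows
from Tc and a single interface-width measurement. `validate_prediction`
compares the predicted curve against directly measured gamma(T) and flags
consistency when at least 80% of points sit within 2 SEM.

The extent of the critical regime is operationalized as tau* — the largest
tau such that every retained point at smaller tau deviates from tau^mu by
at most rel_tol = 0.10 after scaling by gamma0. The underlying visual
criterion is qualitative, so rel_tol is exposed and a 0.05-0.20
sensitivity sweep is cheap to run.

## Synthetic-data generators

Each generator inverts exactly one analysis stage so zero-noise round
trips are exact: tanh profiles (single- or two-interface) with additive or
multiplicative Gaussian noise; gamma(T) tables from the power law with
five pseudo-repeats (multiplicative 5% noise per repeat, matching
few-percent SEMs; an optional crossover imposes a fractional deviation
above a chosen tau to emulate the end of the critical regime); AR(1)
pressure-anisotropy series with prescribed mean, variance and
autocorrelation time (analytic standard error available in closed form);
Gaussian random fields with an imposed Ornstein-Zernike spectrum; and
rigid-rod / coincident-bead chain fixtures with closed-form Rg. All
randomness flows through `numpy.random.default_rng` (PCG64), so a seed
pins output across platforms. What the generators deliberately do *not*
emulate: capillary-wave broadening of profiles, correlated noise across
temperatures, and any coupling between gamma and L errors — passing
recovery tests therefore validates the estimators' statistics, not the
physics of a real trajectory, which is what the scaled-down MD tests are
for.

## Problem sizes used by the test suite

Exact identities run on fine-grained synthetic profiles (1600 bins).
Statistical oracles use 1e5-1e6 step runs of 1-100 beads and 200-300
Monte-Carlo fit replicates. The end-to-end critical-regime study runs 64
chains of length 12 at six temperatures (190-240 K) with a 1e4/1e4/1e5
step protocol and 3 x 1e5 production steps per temperature — the package's
desk-scale configuration. At this size the Kirkwood-Buff anisotropy of a
768-bead slab carries per-point SEMs comparable to gamma itself, so the
collapse criterion has limited statistical power compared to the
full-scale default configuration (625 chains of 24 beads — 15,000 beads —
with 5e7 production steps and five repeats per temperature, a cluster-scale
campaign); the study code is identical at every scale and the temperature
set was chosen from a coarse phase-envelope scan of the preset system.

## Known limitations

* The mechanical gamma estimate converges slowly in small boxes; treat
  scaled-down gamma(T) fits as demonstrations of the pipeline, not
  measurements.
* Very cold systems (strong bonds, tau > ~0.4) equilibrate slowly; the
  dense-phase density can still be drifting after the scaled-down
  protocol.
* No capillary-wave deconvolution is applied to interface widths (the bulk
  spectral estimate is the cross-check); no barostat, electrostatics,
  explicit spacers, or added nonspecific attraction variants.
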