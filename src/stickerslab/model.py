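"""Polymer definitions and interaction potentials.

The model is a two-component associative ("sticker-spacer") polymer: linear
chains of 1-nm beads, each bead an associative sticker of type A or B.
Chains are periodic blocks of ``ell`` consecutive A stickers followed by
``ell`` consecutive B stickers, so the degree of polymerization must be a
multiple of ``2*ell`` (equal A:B stoichiometry).

Three interactions act between beads, all in internal units (energy kBT0,
length nm):

* a stretchable bond between consecutive beads,
  ``U_b(r) = -K R0^2/2 * log(1 - r^2/R0^2)``,
* a short-ranged saturating attraction between unlike stickers,
  ``U_a(r) = -U0/2 * (1 + cos(pi r / d))`` for ``r < d``,
* a purely repulsive (WCA) excluded volume between like stickers,
  ``U_r(r) = 4 eps [(d/r)^12 - (d/r)^6 + 1/4]`` for ``r < 2^(1/6) d``.

Unlike stickers have no excluded volume and may overlap; this is what makes
the A-B association one-to-one and saturating at modest dense-phase volume
fractions.  All parameters are fixed in absolute units, so attraction
measured in thermal units weakens as T rises and the system shows a UCST.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import T0_DEFAULT

__all__ = [
    "PolymerSpec",
    "ForceField",
    "SystemConfiguration",
    "ForceResult",
    "BondExtensionError",
    "OverlapError",
    "build_sequence",
    "bond_energy",
    "bond_force",
    "attraction_energy",
    "attraction_force",
    "repulsion_energy",
    "repulsion_force",
    "evaluate_forces",
]


class BondExtensionError(ValueError):
    """A bond reached or exceeded its maximum extension R0."""


class OverlapError(ValueError):
    """Two mutually repulsive beads coincide (singular WCA core)."""


@dataclass(frozen=True)
class PolymerSpec:
    """A periodic A^ell B^ell block polymer.

    Attributes
    ----------
    block_length : int
        Number of consecutive same-type stickers per block (``ell``).
    n_monomers : int
        Degree of polymerization N; must be a multiple of ``2*ell``.
    sequence : tuple of str
        Explicit sticker types, e.g. ``('A','A','B','B',...)``.
    """

    block_length: int
    n_monomers: int
    sequence: tuple = field(default=())

    def __post_init__(self):
        ell, n = self.block_length, self.n_monomers
        if ell < 1 or n < 1:
            raise ValueError("block_length and n_monomers must be positive")
        if n % (2 * ell) != 0:
            raise ValueError(
                f"degree of polymerization N={n} must be an integer multiple "
                f"of 2*ell={2 * ell} to keep equal A:B stoichiometry"
            )
        expected = tuple(
            ("A" if (i // ell) % 2 == 0 else "B") for i in range(n)
        )
        if self.sequence == ():
            object.__setattr__(self, "sequence", expected)
        elif tuple(self.sequence) != expected:
            raise ValueError("sequence is not the periodic A^ell B^ell repeat")

    @property
    def type_codes(self) -> np.ndarray:
        """Sticker types as an int8 array (A=0, B=1)."""
        return np.array([0 if s == "A" else 1 for s in self.sequence], dtype=np.int8)


def build_sequence(block_length: int, n_monomers: int) -> PolymerSpec:
    """Build the periodic A^ell B^ell sequence of length ``n_monomers``.

    Raises ``ValueError`` if ``n_monomers`` is not a multiple of
    ``2*block_length`` (stoichiometry violation).
    """
    return PolymerSpec(block_length=block_length, n_monomers=n_monomers)


@dataclass(frozen=True)
class ForceField:
    """Interaction parameters, in kBT0 / nm at reference temperature ``t0``.

    Defaults: K = 0.56 kBT0/nm^2, R0 = 5 nm, U0 = 8 kBT0, bead diameter
    d = 1 nm, eps = 1 kBT0, T0 = 300 K.
    """

    k_bond: float = 0.56
    r0_bond: float = 5.0
    u0: float = 8.0
    d_bead: float = 1.0
    epsilon: float = 1.0
    t0: float = T0_DEFAULT

    def __post_init__(self):
        for name in ("k_bond", "r0_bond", "u0", "d_bead", "epsilon", "t0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def attraction_cutoff(self) -> float:
        return self.d_bead

    @property
    def repulsion_cutoff(self) -> float:
        return 2.0 ** (1.0 / 6.0) * self.d_bead


@dataclass
class SystemConfiguration:
    """Bead positions plus topology in a periodic box.

    positions are nm, unwrapped (minimum image applied when measuring);
    ``types`` is A=0/B=1 per bead; ``bonds`` lists bonded index pairs
    (consecutive beads within one chain); ``chain_id`` maps bead -> chain.
    """

    positions: np.ndarray
    box: np.ndarray
    types: np.ndarray
    bonds: np.ndarray
    chain_id: np.ndarray

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)
        self.types = np.ascontiguousarray(self.types, dtype=np.int8)
        self.bonds = np.ascontiguousarray(
            np.asarray(self.bonds, dtype=np.int64).reshape(-1, 2)
        )
        self.chain_id = np.ascontiguousarray(self.chain_id, dtype=np.int64)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def n_chains(self) -> int:
        return int(self.chain_id.max()) + 1 if self.n_beads else 0

    def chains(self):
        """Yield per-chain bead index arrays (beads are chain-contiguous)."""
        for c in range(self.n_chains):
            yield np.flatnonzero(self.chain_id == c)

    def validate_bonds(self, ff: ForceField) -> None:
        """Raise if any bond extension reaches R0 (minimum image)."""
        if len(self.bonds) == 0:
            return
        d = self.positions[self.bonds[:, 0]] - self.positions[self.bonds[:, 1]]
        d -= self.box * np.round(d / self.box)
        r = np.sqrt((d ** 2).sum(axis=1))
        if np.any(r >= ff.r0_bond):
            worst = int(np.argmax(r))
            raise BondExtensionError(
                f"bond {self.bonds[worst]} extended to r={r[worst]:.3f} nm "
                f">= R0={ff.r0_bond} nm"
            )


# ---------------------------------------------------------------------------
# pair potentials (vectorized reference implementations; the MD kernels in
# _kernels.py duplicate these in scalar numba form)
# ---------------------------------------------------------------------------

def bond_energy(r, ff: ForceField):
    """Stretchable-bond energy -K R0^2/2 * log(1 - r^2/R0^2), kBT0.

    Diverges as r -> R0; r >= R0 raises ``BondExtensionError``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("separation must be nonnegative")
    if np.any(r >= ff.r0_bond):
        raise BondExtensionError(
            "bond separation >= R0 (diverging bond; timestep too large or bad "
            "initial configuration)"
        )
    x = (r / ff.r0_bond) ** 2
    out = -0.5 * ff.k_bond * ff.r0_bond ** 2 * np.log1p(-x)
    return out if out.shape else float(out)


def bond_force(r, ff: ForceField):
    """Magnitude dU_b/dr = K r / (1 - r^2/R0^2) (restoring, along the bond)."""
    r = np.asarray(r, dtype=float)
    if np.any(r >= ff.r0_bond):
        raise BondExtensionError("bond separation >= R0")
    out = ff.k_bond * r / (1.0 - (r / ff.r0_bond) ** 2)
    return out if out.shape else float(out)


def attraction_energy(r, ff: ForceField, u0_scale: float = 1.0):
    """A-B attraction -U0/2 (1 + cos(pi r/d)) for r < d, else 0 (kBT0)."""
    r = np.asarray(r, dtype=float)
    u0 = ff.u0 * u0_scale
    out = np.where(
        r < ff.d_bead,
        -0.5 * u0 * (1.0 + np.cos(np.pi * np.minimum(r, ff.d_bead) / ff.d_bead)),
        0.0,
    )
    return out if out.shape else float(out)


def attraction_force(r, ff: ForceField, u0_scale: float = 1.0):
    """Magnitude dU_a/dr = (U0 pi / 2d) sin(pi r/d) inside the cutoff."""
    r = np.asarray(r, dtype=float)
    u0 = ff.u0 * u0_scale
    out = np.where(
        r < ff.d_bead,
        0.5 * u0 * np.pi / ff.d_bead * np.sin(np.pi * r / ff.d_bead),
        0.0,
    )
    return out if out.shape else float(out)


def repulsion_energy(r, ff: ForceField):
    """Same-type WCA repulsion, zero beyond 2^(1/6) d; r=0 is singular."""
    r = np.asarray(r, dtype=float)
    if np.any(r == 0):
        raise OverlapError("coincident same-type beads (singular repulsion)")
    s6 = np.where(r < ff.repulsion_cutoff, (ff.d_bead / r) ** 6, 0.0)
    out = np.where(
        r < ff.repulsion_cutoff,
        4.0 * ff.epsilon * (s6 ** 2 - s6 + 0.25),
        0.0,
    )
    return out if out.shape else float(out)


def repulsion_force(r, ff: ForceField):
    """Magnitude dU_r/dr for the WCA term (negative: repulsive, -dU/dr > 0)."""
    r = np.asarray(r, dtype=float)
    if np.any(r == 0):
        raise OverlapError("coincident same-type beads")
    s6 = np.where(r < ff.repulsion_cutoff, (ff.d_bead / r) ** 6, 0.0)
    out = np.where(
        r < ff.repulsion_cutoff,
        4.0 * ff.epsilon * (-12.0 * s6 ** 2 + 6.0 * s6) / r,
        0.0,
    )
    return out if out.shape else float(out)


@dataclass
class ForceResult:
    forces: np.ndarray       # (N,3), kBT0/nm
    potential: float         # kBT0
    virial: np.ndarray       # (3,), sum over pairs of r_j F_j, kBT0


def evaluate_forces(
    config: SystemConfiguration,
    ff: ForceField,
    u0_scale: float = 1.0,
    exclude_bonded: bool = False,
) -> ForceResult:
    """Forces, total potential energy and per-axis virial sums.

    Forces are exact negative gradients of the summed bond + attraction +
    repulsion terms under the minimum-image convention.  ``exclude_bonded``
    suppresses the nonbonded terms between bonded neighbors (off by default:
    same-type bonded neighbors keep their excluded volume).

    The per-axis virial ``sum_pairs r_j F_j`` supplies the configurational
    part of the diagonal pressure tensor.
    """
    from . import _kernels

    pos = np.ascontiguousarray(config.positions, dtype=np.float64)
    forces = np.zeros_like(pos)
    virial = np.zeros(3)
    pe, status = _kernels.compute_forces(
        pos,
        config.box.astype(np.float64),
        config.types,
        config.bonds,
        config.chain_id,
        forces,
        virial,
        ff.k_bond,
        ff.r0_bond,
        ff.u0 * u0_scale,
        ff.d_bead,
        ff.epsilon,
        1 if exclude_bonded else 0,
    )
    if status == 1:
        raise BondExtensionError("bond extension reached R0 during evaluation")
    if status == 2:
        raise OverlapError("coincident same-type beads during evaluation")
    return ForceResult(forces=forces, potential=pe, virial=virial)
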