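"""Periodic boxes, minimum-image displacements and slit electrostatics.

Two geometries are supported:

* :class:`BulkBox` — a cubic box of side L, periodic in x, y and z.  Pair
  interactions use full cubic minimum-image (MI) truncation: each pair
  interacts through its single nearest periodic image, with no spherical
  cutoff.

* :class:`SlitBox` — an L x L x H parallelepiped, periodic in x and y,
  bounded by impenetrable charged hard walls at z = +/-H/2.  Long-ranged
  lateral interactions use the charged-sheet method: the out-of-cell
  lateral periodic images of each ion are replaced by an infinite uniform
  sheet of charge at that ion's height, minus the central L x L square
  patch (whose charge is represented by the explicit minimum-image point
  charge).

The sheet/patch terms are far-field and use the bulk permittivity eps_b;
the dielectric ramp applies only to the direct minimum-image ion--ion term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import BJERRUM_PREFACTOR_AK
from .model import HARD_CORE_ENERGY

__all__ = [
    "BulkBox",
    "SlitBox",
    "min_image_disp",
    "square_patch_potential",
    "sheet_correction",
    "wall_energy",
]


@dataclass(frozen=True)
class BulkBox:
    """Cubic box of side ``L`` (angstrom), periodic in x, y, z."""

    L: float

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError(f"box side must be positive, got {self.L}")

    @property
    def volume(self) -> float:
        return self.L**3

    @property
    def periodic(self) -> tuple[bool, bool, bool]:
        return (True, True, True)


@dataclass(frozen=True)
class SlitBox:
    """Slit geometry: lateral side ``L`` (periodic in x, y), width ``H``.

    Hard walls sit at z = +/-H/2 and carry a uniform surface charge density
    ``sigma`` (e0/A^2, signed).  Ion *centers* are restricted to
    |z| <= (H - d)/2, i.e. hard spheres touch the walls at half-diameter.
    Electroneutrality requires sum(z_i) + 2*sigma*L^2 = 0.
    """

    L: float
    H: float
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.L <= 0 or self.H <= 0:
            raise ValueError("slit dimensions must be positive")

    @property
    def periodic(self) -> tuple[bool, bool, bool]:
        return (True, True, False)

    def accessible_volume(self, d: float) -> float:
        """Volume accessible to ion centers, L^2 * (H - d)."""
        return self.L**2 * (self.H - d)

    def wall_charge_per_cell(self) -> float:
        """Charge (e0) carried by each wall within one L x L cell."""
        return self.sigma * self.L**2

    @classmethod
    def from_inverse_sigma(cls, L: float, H: float, sigma_inv_A2_per_e: float) -> "SlitBox":
        """Build a slit with the surface charge given as inverse area per charge.

        A value of 70 means one *negative* elementary charge per 70 A^2
        (sigma = -1/70 e0/A^2), matching the usual convention for negatively
        charged surfaces.
        """
        return cls(L=L, H=H, sigma=-1.0 / sigma_inv_A2_per_e)


def min_image_disp(r_i, r_j, box) -> np.ndarray:
    """Minimum-image displacement vector r_j - r_i.

    Wraps along every periodic axis of ``box`` (x, y, z for :class:`BulkBox`;
    x, y only for :class:`SlitBox`, whose z component is returned unwrapped).
    At a displacement of exactly L/2 the positive image is chosen.
    """
    d = np.asarray(r_j, dtype=float) - np.asarray(r_i, dtype=float)
    L = box.L
    for ax, per in enumerate(box.periodic):
        if per:
            # round-half-to-even would make the L/2 tie-break seed-dependent;
            # floor form maps exactly +/-L/2 -> +L/2 deterministically
            d[..., ax] -= L * np.floor(d[..., ax] / L + 0.5)
            d[..., ax] = np.where(d[..., ax] == -L / 2.0, L / 2.0, d[..., ax])
    return d


def square_patch_potential(dx: float, dy: float, dz: float, L: float) -> float:
    """Electrostatic potential of a uniform unit-charge square sheet.

    The sheet has side ``L``, lies in a z-plane centred at lateral offset
    (dx, dy) and height dz from the field point, and carries total charge 1
    (surface density 1/L^2).  Returned in units where a point charge has
    potential 1/r (multiply by l_B*q to get k_BT).

    Uses the closed-form antiderivative
    F(u, v) = u*ln(v + r) + v*ln(u + r) - h*atan(u*v/(h*r)).
    """
    if L <= 0:
        raise ValueError("patch side must be positive")
    h = abs(float(dz))
    u1, u2 = dx - L / 2.0, dx + L / 2.0
    v1, v2 = dy - L / 2.0, dy + L / 2.0

    def F(u: float, v: float) -> float:
        r = math.sqrt(u * u + v * v + h * h)
        term = 0.0
        if v + r > 0.0:
            term += u * math.log(v + r)
        if u + r > 0.0:
            term += v * math.log(u + r)
        if h > 0.0:
            term -= h * math.atan2(u * v, h * r)
        return term

    val = F(u2, v2) - F(u1, v2) - F(u2, v1) + F(u1, v1)
    return val / (L * L)


def infinite_sheet_potential(dz: float, L: float) -> float:
    """Potential of an infinite sheet of surface density 1/L^2: -2*pi*|dz|/L^2.

    The (divergent) additive constant is dropped; it is configuration
    independent for fixed particle charges and cancels exactly against the
    per-ion self-sheet terms for an electroneutral system.
    """
    return -2.0 * math.pi * abs(dz) / (L * L)


def sheet_correction(
    z_i: float,
    z_j: float,
    q_i: float,
    q_j: float,
    L: float,
    eps_b: float,
    T: float = 298.0,
    dx: float = 0.0,
    dy: float = 0.0,
) -> float:
    """Charged-sheet long-range correction for one slit ion pair, in k_BT.

    Replaces the out-of-cell lateral periodic images of ion i (as seen by
    ion j) by an infinite uniform sheet of density q_i/L^2 at height z_i,
    minus the central L x L square patch centred on the minimum-image
    position of i (that image is already counted as an explicit point
    charge).  (dx, dy) is the lateral minimum-image displacement between
    the pair; far-field terms use the bulk permittivity ``eps_b``.
    """
    if L <= 0:
        raise ValueError("lateral box side must be positive")
    if q_i == 0.0 or q_j == 0.0:
        return 0.0
    dz = z_j - z_i
    lb = BJERRUM_PREFACTOR_AK / (eps_b * T)
    phi = infinite_sheet_potential(dz, L) - square_patch_potential(dx, dy, dz, L)
    return q_i * q_j * lb * phi


def self_sheet_energy(q: float, L: float, eps_b: float, T: float = 298.0) -> float:
    """Interaction of a slit ion with its own out-of-cell lateral images.

    Half the sheet-minus-patch potential at zero offset times q^2; a
    configuration-independent constant, included so that total energies
    match explicit image summation for electroneutral systems.
    """
    lb = BJERRUM_PREFACTOR_AK / (eps_b * T)
    phi = infinite_sheet_potential(0.0, L) - square_patch_potential(0.0, 0.0, 0.0, L)
    return 0.5 * q * q * lb * phi


def wall_energy(z: float, q: float, slit: SlitBox, d: float = 3.0) -> float:
    """Position-dependent wall energy for an ion at height ``z``, in k_BT.

    Outside the accessible range |z| <= (H - d)/2 the hard-wall sentinel is
    returned.  Inside, the electric fields of the two equally charged
    infinite planes cancel, so the position-dependent term is identically
    zero; electroneutrality (the extra counterions) carries the physics.
    """
    if abs(z) > (slit.H - d) / 2.0:
        return HARD_CORE_ENERGY
    return 0.0
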