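"""Ion species, the local dielectric saturation model and reference lengths.

The electrolyte is a restricted primitive model (RPM): charged hard spheres
of common diameter ``d`` in a dielectric continuum.  The modification
implemented here lets the relative permittivity depend on the ion--ion
separation ``r``: near contact the solvent is dielectrically saturated and
the permittivity takes a reduced *contact* value ``eps_c``; beyond a solvent
layer of thickness ``Delta`` it recovers the *bulk* value ``eps_b``.  The
permittivity ramps linearly between the two:

    eps_r(r) = eps_c                                    r <= d
    eps_r(r) = eps_c + (eps_b - eps_c) * (r - d)/Delta  d < r < d + Delta
    eps_r(r) = eps_b                                    r >= d + Delta

and the pair interaction (in units of k_B*T) is

    beta*u_ij(r) = z_i * z_j * l_B(eps_r(r), T) / r     for r >= d,

with a hard-core sentinel (+inf) for r < d.  Setting ``eps_c == eps_b``
recovers the uniform-permittivity RPM exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import BJERRUM_PREFACTOR_AK, molar_to_density

__all__ = [
    "IonSpecies",
    "DielectricRampModel",
    "ThermoState",
    "epsilon_r",
    "bjerrum_length",
    "pair_energy",
    "debye_length",
    "HARD_CORE_ENERGY",
]

#: Sentinel pair energy (k_BT) signalling a hard-core or hard-wall overlap.
#: exp(-inf) == 0.0, so Metropolis acceptance handles overlaps uniformly;
#: the MC kernels additionally short-circuit on overlap so inf never enters
#: energy differences.
HARD_CORE_ENERGY = math.inf


@dataclass(frozen=True)
class IonSpecies:
    """A hard-sphere ionic species.

    Parameters
    ----------
    valence : int
        Charge in units of the elementary charge (e.g. +1 for Na+).
    diameter : float
        Hard-sphere diameter d in angstrom.
    """

    valence: int
    diameter: float = 3.0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"diameter must be positive, got {self.diameter}")


@dataclass(frozen=True)
class DielectricRampModel:
    """Distance-dependent permittivity: linear ramp from contact to bulk.

    Parameters
    ----------
    eps_c : float
        Contact (saturated) relative permittivity, reached at r = d.
    eps_b : float
        Bulk solvent relative permittivity, reached at r = d + delta.
    delta : float
        Thickness of the solvent layer over which the ramp rises (angstrom).
    d : float
        Ion hard-sphere (contact) diameter in angstrom.
    """

    eps_c: float = 23.0
    eps_b: float = 78.3
    delta: float = 3.0
    d: float = 3.0

    def __post_init__(self) -> None:
        if not (1.0 <= self.eps_c <= self.eps_b):
            raise ValueError(
                f"require 1 <= eps_c <= eps_b, got eps_c={self.eps_c}, eps_b={self.eps_b}"
            )
        if self.delta <= 0:
            raise ValueError(f"delta must be positive, got {self.delta}")
        if self.d <= 0:
            raise ValueError(f"d must be positive, got {self.d}")

    @classmethod
    def uniform(cls, eps: float, d: float = 3.0, delta: float = 3.0) -> "DielectricRampModel":
        """A uniform-permittivity comparison model (eps_c == eps_b == eps)."""
        return cls(eps_c=eps, eps_b=eps, delta=delta, d=d)

    @property
    def is_uniform(self) -> bool:
        return self.eps_c == self.eps_b

    def epsilon_r(self, r):
        return epsilon_r(r, self)


@dataclass(frozen=True)
class ThermoState:
    """Thermodynamic state: temperature and (optionally) salt concentration.

    ``concentration`` is the molar concentration of the 1:1 salt (mol/L);
    ``density`` is the corresponding per-species number density in ions/A^3.
    """

    T: float = 298.0
    concentration: float | None = None

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"temperature must be positive, got {self.T}")
        if self.concentration is not None and self.concentration < 0:
            raise ValueError("concentration must be nonnegative")

    @property
    def beta(self) -> float:
        """1/(k_B T) in 1/J."""
        from .constants import BOLTZMANN

        return 1.0 / (BOLTZMANN * self.T)

    @property
    def density(self) -> float | None:
        if self.concentration is None:
            return None
        return molar_to_density(self.concentration)


def epsilon_r(r, model: DielectricRampModel):
    """Relative permittivity at ion--ion separation ``r`` (angstrom).

    Vectorised over ``r``.  Values below contact (r < d) return ``eps_c``:
    they are unreachable under the hard core but must not error.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("separation r must be nonnegative")
    t = np.clip((r - model.d) / model.delta, 0.0, 1.0)
    out = model.eps_c + (model.eps_b - model.eps_c) * t
    if out.ndim == 0:
        return float(out)
    return out


def bjerrum_length(eps: float, T: float) -> float:
    """Bjerrum length l_B = e0^2 / (4 pi eps0 eps k_B T), in angstrom.

    The separation at which two unit charges in a medium of relative
    permittivity ``eps`` interact with thermal energy k_B*T.
    """
    if eps < 1.0:
        raise ValueError(f"relative permittivity must be >= 1, got {eps}")
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    return BJERRUM_PREFACTOR_AK / (eps * T)


def pair_energy(r, z_i: int, z_j: int, model: DielectricRampModel, T: float = 298.0):
    """Pair interaction in k_BT units: beta*u = z_i z_j l_B(eps_r(r), T) / r.

    Returns the hard-core sentinel (+inf) for r < d.  Vectorised over ``r``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("separation r must be nonnegative")
    eps = np.asarray(epsilon_r(r, model))
    with np.errstate(divide="ignore"):
        u = z_i * z_j * (BJERRUM_PREFACTOR_AK / T) / (eps * r)
    u = np.where(r < model.d, HARD_CORE_ENERGY, u)
    if u.ndim == 0:
        return float(u)
    return u


def debye_length(c: float, eps: float = 78.3, T: float = 298.0) -> float:
    """Debye screening length of a 1:1 salt, in angstrom.

    lambda_D = (8 pi l_B n)^(-1/2) with ``n`` the number density of *each*
    ionic species; proportional to c^(-1/2).

    Parameters
    ----------
    c : float
        Salt concentration in mol/L.
    eps, T : float
        Relative permittivity and temperature used for the Bjerrum length.
    """
    if c <= 0:
        raise ValueError(f"concentration must be positive, got {c}")
    n = molar_to_density(c)
    lb = bjerrum_length(eps, T)
    return 1.0 / math.sqrt(8.0 * math.pi * lb * n)
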