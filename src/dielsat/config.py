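"""Run configuration: YAML dialect, schema validation, state construction.

A run configuration has five blocks plus a seed::

    model:       {d: 3.0, delta: 3.0, eps_c: 23.0, eps_b: 78.3, uniform: false}
    thermo:      {T: 298.0, concentration: 1.0}        # or n_plus/n_minus
    geometry:    {type: bulk, L: 80.0}                 # or slit: L, H,
                                                       #   sigma_inv_A2_per_e
    schedule:    {equilibration: 20000, production: 100000, stride: 100, ...}
    observables: {rdf_bin: 0.1, cluster_delta: 3.5, zbin: 0.5}
    seed: 7

Unknown keys anywhere are rejected with field-level messages.  Molarity and
explicit counts are mutually exclusive.  The surface charge is entered the
way experimentalists quote it, as inverse area per elementary charge
(70 means one negative charge per 70 A^2, i.e. sigma = -1/70 e0/A^2); it is
then adjusted minimally so the integer counterion excess neutralises the
walls exactly.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .constants import MOLAR_TO_PER_A3
from .engine import MCState, MoveSchedule, initialize_configuration
from .geometry import BulkBox, SlitBox
from .model import DielectricRampModel

__all__ = ["RunConfig", "parse_config", "ConfigError"]


class ConfigError(ValueError):
    """A configuration file failed schema validation."""


_MODEL_KEYS = {"d", "delta", "eps_c", "eps_b", "uniform"}
_THERMO_KEYS = {"T", "concentration", "n_plus", "n_minus"}
_GEOMETRY_KEYS = {"type", "L", "H", "sigma_inv_A2_per_e"}
_SCHEDULE_KEYS = {
    "max_step", "cluster_fraction", "cluster_step", "cluster_delta",
    "equilibration", "production", "stride", "tune",
}
_OBSERVABLE_KEYS = {"rdf_bin", "cluster_delta", "zbin", "fit_window"}
_TOP_KEYS = {"model", "thermo", "geometry", "schedule", "observables", "seed"}


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in '{where}' "
            f"(allowed: {sorted(allowed)})"
        )


@dataclass
class RunConfig:
    """A validated run configuration with defaults resolved."""

    model: dict = field(default_factory=dict)
    thermo: dict = field(default_factory=dict)
    geometry: dict = field(default_factory=dict)
    schedule: dict = field(default_factory=dict)
    observables: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        _check_keys(self.model, _MODEL_KEYS, "model")
        _check_keys(self.thermo, _THERMO_KEYS, "thermo")
        _check_keys(self.geometry, _GEOMETRY_KEYS, "geometry")
        _check_keys(self.schedule, _SCHEDULE_KEYS, "schedule")
        _check_keys(self.observables, _OBSERVABLE_KEYS, "observables")
        # defaults
        self.model = {"d": 3.0, "delta": 3.0, "eps_c": 23.0, "eps_b": 78.3,
                      "uniform": False, **self.model}
        self.thermo = {"T": 298.0, **self.thermo}
        self.geometry = {"type": "bulk", **self.geometry}
        self.observables = {"rdf_bin": 0.1,
                            "cluster_delta": self.model["d"] + 0.5,
                            "zbin": 0.5, **self.observables}
        self.schedule = {"cluster_delta": self.model["d"] + 0.5,
                         **self.schedule}
        # validation
        if self.model["eps_c"] > self.model["eps_b"]:
            raise ConfigError(
                f"model.eps_c ({self.model['eps_c']}) must not exceed "
                f"model.eps_b ({self.model['eps_b']})"
            )
        if self.thermo.get("T", 298.0) <= 0:
            raise ConfigError("thermo.T must be positive")
        has_conc = self.thermo.get("concentration") is not None
        has_counts = (self.thermo.get("n_plus") is not None
                      or self.thermo.get("n_minus") is not None)
        if has_conc and has_counts:
            raise ConfigError(
                "thermo.concentration and thermo.n_plus/n_minus are "
                "mutually exclusive"
            )
        if not has_conc and not has_counts:
            raise ConfigError(
                "thermo needs either 'concentration' (mol/L) or explicit "
                "'n_plus'/'n_minus' counts"
            )
        gtype = self.geometry.get("type")
        if gtype not in ("bulk", "slit"):
            raise ConfigError(f"geometry.type must be 'bulk' or 'slit', got {gtype!r}")
        if "L" not in self.geometry:
            raise ConfigError("geometry.L (angstrom) is required")
        if gtype == "slit" and "H" not in self.geometry:
            raise ConfigError("geometry.H (angstrom) is required for slit runs")

    # ---- construction helpers -------------------------------------------
    def build_model(self) -> DielectricRampModel:
        m = self.model
        if m["uniform"]:
            return DielectricRampModel.uniform(m["eps_c"], d=m["d"], delta=m["delta"])
        return DielectricRampModel(eps_c=m["eps_c"], eps_b=m["eps_b"],
                                   delta=m["delta"], d=m["d"])

    def build_geometry(self):
        g = self.geometry
        if g["type"] == "bulk":
            return BulkBox(L=float(g["L"]))
        sigma_inv = g.get("sigma_inv_A2_per_e")
        slit = SlitBox(L=float(g["L"]), H=float(g["H"]),
                       sigma=(-1.0 / sigma_inv) if sigma_inv else 0.0)
        return slit

    def resolve_counts(self) -> tuple[int, int]:
        """Ion counts from concentration (or the explicit counts).

        Bulk: N = round(c * L^3) per species.  Slit: the anion count comes
        from the accessible volume L^2 (H - d); the cation count adds the
        integer counterion excess closest to neutralising 2|sigma|L^2.
        """
        t = self.thermo
        if t.get("n_plus") is not None:
            return int(t["n_plus"]), int(t.get("n_minus", t["n_plus"]))
        c = float(t["concentration"])
        n_each = c * MOLAR_TO_PER_A3
        geom = self.build_geometry()
        if isinstance(geom, BulkBox):
            n = round(n_each * geom.volume)
            return n, n
        d = self.model["d"]
        n_minus = round(n_each * geom.accessible_volume(d))
        excess = round(2.0 * abs(geom.wall_charge_per_cell()))
        return n_minus + excess, n_minus

    def build_state(self, seed: int | None = None) -> MCState:
        """Overlap-free initial state; slit wall charge adjusted to exactly
        neutralise the integer counterion excess."""
        seed = self.seed if seed is None else seed
        n_plus, n_minus = self.resolve_counts()
        geom = self.build_geometry()
        if isinstance(geom, SlitBox):
            excess = n_plus - n_minus
            geom = SlitBox(L=geom.L, H=geom.H,
                           sigma=-excess / (2.0 * geom.L**2))
        return initialize_configuration(
            n_plus, n_minus, geom, seed,
            model=self.build_model(), T=float(self.thermo["T"]),
        )

    def build_schedule(self) -> MoveSchedule:
        return MoveSchedule(**self.schedule)

    # ---- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        _check_keys(data, _TOP_KEYS, "top level")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def parse_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration; defaults applied."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    return RunConfig.from_dict(data)
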