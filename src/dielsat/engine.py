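"""Canonical Metropolis Monte Carlo engine.

Moves: single-particle displacements and rigid cluster translations.  A
cluster is the connected component of the seed ion under a minimum-image
distance criterion ``cluster_delta``; a translated cluster that would gain
any new member is rejected outright, which preserves detailed balance for
rigid translations (the reverse move selects the identical member set with
the identical probability).

All randomness flows from a single master ``numpy.random.Generator``; the
compiled sweep kernel is re-seeded from it at every block boundary, so a
run is fully reproducible from its seed and checkpoint/resume is bitwise
identical to an uninterrupted run.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .constants import BJERRUM_PREFACTOR_AK
from .geometry import BulkBox, SlitBox
from .model import DielectricRampModel

__all__ = [
    "MCState",
    "MoveSchedule",
    "EnergyDriftError",
    "OverpackedError",
    "initialize_configuration",
    "displace_move",
    "cluster_move",
    "run",
    "save_checkpoint",
    "load_checkpoint",
]

_SEED_MAX = 2**31 - 1

_DUMMY_RTAB = np.zeros((1, 1, 2))
_RTAB_CACHE: dict = {}

#: residual-table resolution and image-shell count (see _kernels docstring)
_RTAB_NDX = 25
_RTAB_NDZ = 49
_RTAB_SHELLS = 80


def residual_table_for(slit: SlitBox, d: float) -> np.ndarray:
    """Cached lattice-discreteness residual table for a slit geometry."""
    zspan = slit.H - d
    key = (round(slit.L, 9), round(zspan, 9))
    tab = _RTAB_CACHE.get(key)
    if tab is None:
        tab = _kernels.build_residual_table(slit.L, zspan, _RTAB_NDX,
                                            _RTAB_NDZ, _RTAB_SHELLS)
        _RTAB_CACHE[key] = tab
    return tab


class EnergyDriftError(RuntimeError):
    """Running energy diverged from full recomputation beyond tolerance."""


class OverpackedError(RuntimeError):
    """Random insertion could not place all ions within the attempt budget."""


@dataclass
class MoveSchedule:
    """Move sizes and sweep counts for one MC run.

    Attributes
    ----------
    max_step : float
        Maximum single-particle displacement per axis (angstrom).  Tuned
        toward 30--50% acceptance during equilibration (if ``tune``) and
        then frozen for production; adapting during production would
        violate detailed balance.
    cluster_fraction : float
        Probability that an attempt is a cluster move (default 10%).
    cluster_step : float
        Maximum rigid cluster translation per axis (angstrom).
    cluster_delta : float
        Connectivity distance for cluster moves (angstrom); defaults to the
        analysis criterion d + 0.5.
    equilibration, production : int
        Sweep counts (one sweep = N attempted moves).
    stride : int
        Sampling stride in sweeps; observers fire every ``stride``
        production sweeps.
    """

    max_step: float = 3.0
    cluster_fraction: float = 0.1
    cluster_step: float = 5.0
    cluster_delta: float = 3.5
    equilibration: int = 20_000
    production: int = 100_000
    stride: int = 100
    tune: bool = True
    tune_every: int = 500
    reconcile_every: int = 5_000
    drift_tol_per_ion: float = 1.0e-6

    def __post_init__(self) -> None:
        if not (0.0 <= self.cluster_fraction <= 1.0):
            raise ValueError("cluster_fraction must be in [0, 1]")
        if self.max_step <= 0 or self.cluster_step <= 0:
            raise ValueError("move sizes must be positive")


@dataclass
class MCState:
    """The evolving MC configuration.

    ``positions`` are kept wrapped into [0, L) along periodic axes; the slit
    z coordinate is stored unwrapped in [-(H-d)/2, (H-d)/2].
    """

    positions: np.ndarray
    valences: np.ndarray
    geometry: BulkBox | SlitBox
    model: DielectricRampModel
    T: float = 298.0
    energy: float = 0.0
    rng: np.random.Generator = field(default_factory=lambda: np.random.default_rng(0))
    sweep: int = 0
    stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.valences = np.ascontiguousarray(self.valences, dtype=np.float64)
        if self.positions.shape != (self.valences.size, 3):
            raise ValueError("positions must be (N, 3) matching valences")

    # ---- kernel plumbing -------------------------------------------------
    @property
    def n_ions(self) -> int:
        return self.valences.size

    @property
    def is_slit(self) -> bool:
        return isinstance(self.geometry, SlitBox)

    def kernel_params(self) -> tuple:
        m = self.model
        lB1 = BJERRUM_PREFACTOR_AK / self.T
        if self.is_slit:
            zmax = (self.geometry.H - m.d) / 2.0
            return (1.0, self.geometry.L, zmax, m.d, m.eps_c, m.eps_b,
                    m.delta, lB1, lB1 / m.eps_b)
        return (0.0, self.geometry.L, 0.0, m.d, m.eps_c, m.eps_b,
                m.delta, lB1, lB1 / m.eps_b)

    @property
    def rtab(self) -> np.ndarray:
        """Lattice-discreteness residual table (slit); dummy for bulk."""
        if not self.is_slit:
            return _DUMMY_RTAB
        return residual_table_for(self.geometry, self.model.d)

    # ---- energies --------------------------------------------------------
    def total_energy(self) -> float:
        """Full O(N^2) recomputation of the configurational energy (k_BT)."""
        if self.n_ions == 0:
            return 0.0
        e = _kernels.total_energy(self.positions, self.valences,
                                  self.kernel_params(), self.rtab)
        if e == -1.0e300:
            raise RuntimeError("hard-core overlap in configuration")
        return float(e)

    def particle_energy(self, i: int) -> float:
        """Interaction energy of ion ``i`` with all others (k_BT)."""
        if not 0 <= i < self.n_ions:
            raise IndexError(f"ion index {i} out of range")
        if self.n_ions == 1:
            return 0.0
        e = _kernels.particle_energy(self.positions, self.valences, i,
                                     self.kernel_params(), self.rtab)
        if e == -1.0e300:
            return math.inf
        return float(e)

    def reconcile_energy(self, tol_per_ion: float = 1.0e-6) -> float:
        """Check the running energy against full recomputation.

        Returns the drift; raises :class:`EnergyDriftError` beyond
        ``tol_per_ion * N`` and refreshes the running energy otherwise.
        """
        full = self.total_energy()
        drift = abs(self.energy - full)
        if drift > tol_per_ion * max(self.n_ions, 1):
            raise EnergyDriftError(
                f"running energy drifted by {drift:.3e} k_BT "
                f"(tolerance {tol_per_ion * max(self.n_ions, 1):.3e})"
            )
        self.energy = full
        return drift

    def copy(self) -> "MCState":
        new = MCState(
            positions=self.positions.copy(),
            valences=self.valences.copy(),
            geometry=self.geometry,
            model=self.model,
            T=self.T,
            energy=self.energy,
            rng=np.random.default_rng(),
            sweep=self.sweep,
            stats=dict(self.stats),
        )
        new.rng.bit_generator.state = self.rng.bit_generator.state
        return new


def initialize_configuration(
    n_plus: int,
    n_minus: int,
    geometry: BulkBox | SlitBox,
    seed: int,
    model: DielectricRampModel | None = None,
    T: float = 298.0,
    max_attempts_per_ion: int = 10_000,
) -> MCState:
    """Seeded random insertion of an overlap-free initial configuration.

    Deterministic given (counts, geometry, seed).  Raises
    :class:`OverpackedError` if the attempt budget is exhausted.
    """
    if n_plus < 0 or n_minus < 0:
        raise ValueError("ion counts must be nonnegative")
    model = model or DielectricRampModel()
    rng = np.random.default_rng(seed)
    n = n_plus + n_minus
    valences = np.concatenate([np.ones(n_plus), -np.ones(n_minus)])
    positions = np.empty((n, 3))
    d2 = model.d**2
    L = geometry.L
    slit = isinstance(geometry, SlitBox)
    if slit:
        zmax = (geometry.H - model.d) / 2.0
        if zmax <= 0:
            raise ValueError("slit too narrow for the ion diameter")
    budget = max_attempts_per_ion * max(n, 1)
    placed = 0
    attempts = 0
    while placed < n:
        if attempts >= budget:
            raise OverpackedError(
                f"placed {placed}/{n} ions in {attempts} attempts; "
                "box appears overpacked"
            )
        attempts += 1
        p = rng.random(3) * L
        if slit:
            p[2] = (rng.random() * 2.0 - 1.0) * zmax
        ok = True
        for k in range(placed):
            dx = p[0] - positions[k, 0]
            dy = p[1] - positions[k, 1]
            dz = p[2] - positions[k, 2]
            dx -= L * round(dx / L)
            dy -= L * round(dy / L)
            if not slit:
                dz -= L * round(dz / L)
            if dx * dx + dy * dy + dz * dz < d2:
                ok = False
                break
        if ok:
            positions[placed] = p
            placed += 1
    state = MCState(
        positions=positions,
        valences=valences,
        geometry=geometry,
        model=model,
        T=T,
        rng=np.random.default_rng(seed + 1),
    )
    state.energy = state.total_energy() if n else 0.0
    return state


# ---------------------------------------------------------------------------
# Single-move operations (convenience / testing surface; `run` uses the
# compiled block kernel with identical semantics)
# ---------------------------------------------------------------------------

def displace_move(state: MCState, rng: np.random.Generator | None = None,
                  max_step: float = 3.0) -> bool:
    """One Metropolis single-particle displacement attempt. Returns accepted?"""
    rng = rng if rng is not None else state.rng
    n = state.n_ions
    if n < 1:
        raise ValueError("no ions to move")
    params = state.kernel_params()
    i = int(rng.integers(n))
    trial = state.positions[i] + (rng.random(3) - 0.5) * 2.0 * max_step
    L = state.geometry.L
    trial[0] %= L
    trial[1] %= L
    if state.is_slit:
        if abs(trial[2]) > params[2]:
            return False
    else:
        trial[2] %= L
    e_new = _kernels._trial_particle_energy(state.positions, state.valences,
                                            i, trial[0], trial[1], trial[2],
                                            params, state.rtab)
    if e_new == -1.0e300:
        return False
    e_old = _kernels.particle_energy(state.positions, state.valences, i,
                                     params, state.rtab)
    du = e_new - e_old
    if du <= 0.0 or rng.random() < math.exp(-du):
        state.positions[i] = trial
        state.energy += du
        return True
    return False


def build_cluster(state: MCState, seed_ion: int, delta_mv: float) -> np.ndarray:
    """Indices of the connected component of ``seed_ion`` under ``delta_mv``."""
    n = state.n_ions
    members = np.empty(n, dtype=np.int64)
    flag = np.zeros(n, dtype=np.int8)
    stack = np.empty(n, dtype=np.int64)
    nm = _kernels._build_cluster(state.positions, state.kernel_params(),
                                 seed_ion, delta_mv, members, flag, stack)
    return np.sort(members[:nm])


def cluster_move(state: MCState, rng: np.random.Generator | None = None,
                 schedule: MoveSchedule | None = None) -> bool:
    """One rigid cluster-translation attempt. Returns accepted?

    The cluster is grown from a uniformly chosen seed ion; the move is
    rejected outright if the translated cluster would gain any new member
    (detailed-balance merge guard), on any hard overlap, or by Metropolis
    on the external energy change.
    """
    rng = rng if rng is not None else state.rng
    schedule = schedule or MoveSchedule()
    n = state.n_ions
    if n < 1:
        raise ValueError("no ions to move")
    params = state.kernel_params()
    L = state.geometry.L
    s = int(rng.integers(n))
    members = build_cluster(state, s, schedule.cluster_delta)
    member_set = np.zeros(n, dtype=bool)
    member_set[members] = True
    shift = (rng.random(3) - 0.5) * 2.0 * schedule.cluster_step
    newpos = state.positions[members] + shift
    newpos[:, 0] %= L
    newpos[:, 1] %= L
    if state.is_slit:
        if np.any(np.abs(newpos[:, 2]) > params[2]):
            return False
    else:
        newpos[:, 2] %= L
    outside = np.where(~member_set)[0]
    d2 = schedule.cluster_delta**2
    du = 0.0
    for k, i in enumerate(members):
        for j in outside:
            e_new = _kernels._pair_terms(
                newpos[k, 0], newpos[k, 1], newpos[k, 2], state.valences[i],
                state.positions[j, 0], state.positions[j, 1],
                state.positions[j, 2], state.valences[j], params, state.rtab)
            if e_new == -1.0e300:
                return False
            dx = _kernels._mi(state.positions[j, 0] - newpos[k, 0], L)
            dy = _kernels._mi(state.positions[j, 1] - newpos[k, 1], L)
            dz = state.positions[j, 2] - newpos[k, 2]
            if not state.is_slit:
                dz = _kernels._mi(dz, L)
            if dx * dx + dy * dy + dz * dz <= d2:
                return False  # merge guard
            e_old = _kernels._pair_terms(
                state.positions[i, 0], state.positions[i, 1],
                state.positions[i, 2], state.valences[i],
                state.positions[j, 0], state.positions[j, 1],
                state.positions[j, 2], state.valences[j], params, state.rtab)
            du += e_new - e_old
    if du <= 0.0 or rng.random() < math.exp(-du):
        state.positions[members] = newpos
        state.energy += du
        return True
    return False


# ---------------------------------------------------------------------------
# Run driver
# ---------------------------------------------------------------------------

def _run_block(state: MCState, schedule: MoveSchedule, nsweeps: int) -> dict:
    seed = int(state.rng.integers(_SEED_MAX))
    energy, da, dacc, ca, cacc = _kernels.run_block(
        state.positions, state.valences, state.kernel_params(), state.rtab,
        nsweeps, schedule.max_step, schedule.cluster_fraction,
        schedule.cluster_step, schedule.cluster_delta, seed, state.energy,
    )
    state.energy = float(energy)
    state.sweep += nsweeps
    return {"disp_att": int(da), "disp_acc": int(dacc),
            "cl_att": int(ca), "cl_acc": int(cacc)}


def run(
    state: MCState,
    schedule: MoveSchedule,
    observers: tuple = (),
    checkpoint_path=None,
    checkpoint_every: int | None = None,
    skip_equilibration: bool | None = None,
) -> dict:
    """Equilibrate then produce, firing ``observers`` every sampling stride.

    Observers are objects with an ``update(state)`` method.  The running
    energy is reconciled against full recomputation every
    ``schedule.reconcile_every`` sweeps; drift beyond tolerance raises
    :class:`EnergyDriftError`.  Fully reproducible given the state's RNG
    seed; checkpoints written at sampling-block boundaries allow bitwise
    identical resumption.
    """
    if state.n_ions == 0:
        return {"acceptance": {}, "sweeps": 0,
                "disp_att": 0, "disp_acc": 0, "cl_att": 0, "cl_acc": 0}
    stats = {"disp_att": 0, "disp_acc": 0, "cl_att": 0, "cl_acc": 0}
    if skip_equilibration is None:
        skip_equilibration = state.sweep > 0

    # ---- equilibration with optional step-size tuning
    if not skip_equilibration and schedule.equilibration > 0:
        done = 0
        while done < schedule.equilibration:
            block = min(schedule.tune_every, schedule.equilibration - done)
            b = _run_block(state, schedule, block)
            done += block
            if schedule.tune and b["disp_att"] > 0:
                acc = b["disp_acc"] / b["disp_att"]
                if acc < 0.30:
                    schedule.max_step = max(schedule.max_step * 0.8, 0.05)
                elif acc > 0.50:
                    schedule.max_step = min(schedule.max_step * 1.25,
                                            state.geometry.L / 2.0)
        state.reconcile_energy(schedule.drift_tol_per_ion)
        state.sweep = 0  # production sweep counter starts at zero

    # ---- production
    produced = state.sweep
    since_reconcile = 0
    while produced < schedule.production:
        block = min(schedule.stride, schedule.production - produced)
        b = _run_block(state, schedule, block)
        produced = state.sweep
        since_reconcile += block
        for k in stats:
            stats[k] += b[k]
        for obs in observers:
            obs.update(state)
        if since_reconcile >= schedule.reconcile_every:
            state.reconcile_energy(schedule.drift_tol_per_ion)
            since_reconcile = 0
        if checkpoint_path is not None and checkpoint_every is not None:
            if produced % checkpoint_every == 0:
                save_checkpoint(state, schedule, checkpoint_path)
    state.stats = stats
    out = {"sweeps": produced, "acceptance": {}}
    if stats["disp_att"]:
        out["acceptance"]["displacement"] = stats["disp_acc"] / stats["disp_att"]
    if stats["cl_att"]:
        out["acceptance"]["cluster"] = stats["cl_acc"] / stats["cl_att"]
    out.update(stats)
    return out


# ---------------------------------------------------------------------------
# Checkpoints (plain JSON; positions at full precision via float hex)
# ---------------------------------------------------------------------------

def _geometry_to_dict(g) -> dict:
    if isinstance(g, SlitBox):
        return {"type": "slit", "L": g.L, "H": g.H, "sigma": g.sigma}
    return {"type": "bulk", "L": g.L}


def _geometry_from_dict(d: dict):
    if d["type"] == "slit":
        return SlitBox(L=d["L"], H=d["H"], sigma=d["sigma"])
    return BulkBox(L=d["L"])


def save_checkpoint(state: MCState, schedule: MoveSchedule, path) -> None:
    payload = {
        "positions": [[v.hex() for v in row] for row in state.positions.tolist()],
        "valences": state.valences.tolist(),
        "energy": state.energy.hex() if isinstance(state.energy, float) else float(state.energy).hex(),
        "sweep": state.sweep,
        "T": state.T,
        "geometry": _geometry_to_dict(state.geometry),
        "model": dataclasses.asdict(state.model),
        "rng_state": state.rng.bit_generator.state,
        "schedule": dataclasses.asdict(schedule),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path) -> tuple[MCState, MoveSchedule]:
    with open(path) as fh:
        payload = json.load(fh)
    positions = np.array(
        [[float.fromhex(v) for v in row] for row in payload["positions"]]
    )
    rng = np.random.default_rng()
    rng.bit_generator.state = payload["rng_state"]
    state = MCState(
        positions=positions,
        valences=np.array(payload["valences"]),
        geometry=_geometry_from_dict(payload["geometry"]),
        model=DielectricRampModel(**payload["model"]),
        T=payload["T"],
        energy=float.fromhex(payload["energy"]),
        rng=rng,
        sweep=payload["sweep"],
    )
    schedule = MoveSchedule(**payload["schedule"])
    return state, schedule
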