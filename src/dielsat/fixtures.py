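"""Deterministic micro-configurations and synthetic curves for testing.

Every fixture is reproducible bit-for-bit from (name, parameters, seed) and
carries expected-value metadata computed by the plain brute-force reference
implementations (:mod:`dielsat.reference`), never by the compiled engine
kernels and never copied in by hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import reference
from .engine import MCState, initialize_configuration
from .geometry import BulkBox, SlitBox
from .model import DielectricRampModel

__all__ = ["FixtureSpec", "make_fixture", "write_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = (
    "unlike_pair",
    "four_ion_square",
    "chain_of_three",
    "two_pairs",
    "ion_gas",
    "yukawa_curve",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Name + parameters + seed identifying one reproducible fixture."""

    name: str
    params: dict = field(default_factory=dict)
    seed: int = 1234

    def __post_init__(self) -> None:
        if self.name not in FIXTURE_NAMES:
            raise ValueError(f"unknown fixture {self.name!r}; "
                             f"choose from {FIXTURE_NAMES}")


def make_fixture(spec: FixtureSpec | str, **params):
    """Build a fixture; returns (payload, metadata).

    The payload is an :class:`MCState` for configuration fixtures and a
    dict of arrays for the synthetic-curve fixture.  Metadata holds the
    hand-checkable expected values (computed by the reference oracles).
    """
    if isinstance(spec, str):
        spec = FixtureSpec(name=spec, params=params)
    p = dict(spec.params)
    model = DielectricRampModel(**p.pop("model", {}))
    T = p.pop("T", 298.0)

    if spec.name == "unlike_pair":
        r = p.pop("r", 3.0)
        L = p.pop("L", 60.0)
        box = BulkBox(L=L)
        positions = np.array([[L / 2, L / 2, L / 2],
                              [L / 2 + r, L / 2, L / 2]])
        valences = np.array([1.0, -1.0])
        state = MCState(positions=positions, valences=valences,
                        geometry=box, model=model, T=T)
        state.energy = state.total_energy()
        meta = {
            "r": r,
            "expected_pair_energy": reference.ramp_beta_u(r, 1, -1, model, T),
        }
        return state, meta

    if spec.name == "four_ion_square":
        a = p.pop("side", 4.0)
        L = p.pop("L", 40.0)
        box = BulkBox(L=L)
        c = L / 2
        positions = np.array([
            [c, c, c], [c + a, c, c], [c + a, c + a, c], [c, c + a, c],
        ])
        valences = np.array([1.0, -1.0, 1.0, -1.0])  # alternating corners
        state = MCState(positions=positions, valences=valences,
                        geometry=box, model=model, T=T)
        state.energy = state.total_energy()
        meta = {
            "side": a,
            "expected_total_energy": reference.total_energy_bulk(
                positions, valences, box, model, T),
        }
        return state, meta

    if spec.name == "chain_of_three":
        gap = p.pop("gap", 3.2)
        L = p.pop("L", 50.0)
        box = BulkBox(L=L)
        c = L / 2
        positions = np.array([[c, c, c], [c + gap, c, c], [c + 2 * gap, c, c]])
        valences = np.array([1.0, -1.0, 1.0])
        state = MCState(positions=positions, valences=valences,
                        geometry=box, model=model, T=T)
        state.energy = state.total_energy()
        delta = p.pop("delta", model.d + 0.5)
        labels = reference.cluster_labels_bfs(positions, box, delta)
        meta = {"delta": delta,
                "expected_cluster_sizes": np.bincount(labels).tolist()}
        return state, meta

    if spec.name == "two_pairs":
        r = p.pop("r", 3.1)
        sep = p.pop("separation", 20.0)
        L = p.pop("L", 60.0)
        box = BulkBox(L=L)
        c = L / 2
        positions = np.array([
            [c, c, c], [c + r, c, c],
            [c, c, c + sep], [c + r, c, c + sep],
        ])
        valences = np.array([1.0, -1.0, 1.0, -1.0])
        state = MCState(positions=positions, valences=valences,
                        geometry=box, model=model, T=T)
        state.energy = state.total_energy()
        delta = p.pop("delta", model.d + 0.5)
        labels = reference.cluster_labels_bfs(positions, box, delta)
        sizes = np.bincount(labels)
        # P_ion(s) = (ions sitting in clusters of size s) / N
        meta = {"delta": delta,
                "expected_p_ion": {int(s): float(np.sum(sizes[sizes == s])
                                                 / len(positions))
                                   for s in np.unique(sizes)}}
        return state, meta

    if spec.name == "ion_gas":
        n_pairs = p.pop("n_pairs", 100)
        concentration = p.pop("concentration", 0.5)
        from .constants import MOLAR_TO_PER_A3

        L = p.pop("L", None)
        if L is None:
            L = (n_pairs / (concentration * MOLAR_TO_PER_A3)) ** (1.0 / 3.0)
        state = initialize_configuration(n_pairs, n_pairs, BulkBox(L=L),
                                         spec.seed, model=model, T=T)
        meta = {"L": L, "concentration": concentration, "n_pairs": n_pairs}
        return state, meta

    if spec.name == "yukawa_curve":
        lam = p.pop("lam", 5.0)
        amplitude = p.pop("amplitude", 3.0)
        noise = p.pop("noise", 0.0)
        r = np.asarray(p.pop("r", np.arange(2.0, 30.0, 0.25)), dtype=float)
        h = amplitude * np.exp(-r / lam) / r
        if noise > 0.0:
            rng = np.random.default_rng(spec.seed)
            h = h * (1.0 + noise * rng.standard_normal(len(r)))
        meta = {"lam": lam, "amplitude": amplitude, "noise": noise}
        return {"r": r, "h": h}, meta

    raise AssertionError("unreachable")


def write_fixture(spec: FixtureSpec, directory) -> Path:
    """Serialise a configuration fixture as XYZ + JSON sidecar metadata."""
    import json

    from .io import write_xyz

    payload, meta = make_fixture(spec)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = directory / spec.name
    if isinstance(payload, MCState):
        write_xyz(base.with_suffix(".xyz"), payload.positions,
                  payload.valences, comment=spec.name)
    else:
        np.savetxt(base.with_suffix(".tsv"),
                   np.column_stack([payload["r"], payload["h"]]),
                   delimiter="\t", header="r\th", comments="")
    with open(base.with_suffix(".json"), "w") as fh:
        json.dump({"name": spec.name, "seed": spec.seed,
                   "params": {k: v for k, v in spec.params.items()
                              if k != "model"}, "expected": meta}, fh,
                  indent=2, default=float)
    return base
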