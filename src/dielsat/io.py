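"""Readers and writers: TSV observable tables, XYZ snapshots, manifests.

All observable tables are tab-separated with ``#``-prefixed header lines
carrying the resolved run parameters and seed, so any table can be
regenerated from its own metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_table",
    "read_table",
    "write_xyz",
    "read_xyz",
    "write_manifest",
    "save_trajectory",
    "load_trajectory",
]


def save_trajectory(path, recorder, model, T: float) -> None:
    """Store sampled frames as a compressed npz with geometry/model metadata."""
    from .geometry import SlitBox

    geom = recorder.geometry
    if isinstance(geom, SlitBox):
        gmeta = json.dumps({"type": "slit", "L": geom.L, "H": geom.H,
                            "sigma": geom.sigma})
    else:
        gmeta = json.dumps({"type": "bulk", "L": geom.L})
    mmeta = json.dumps({"eps_c": model.eps_c, "eps_b": model.eps_b,
                        "delta": model.delta, "d": model.d, "T": T})
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path,
        positions=np.asarray(recorder.positions),
        valences=recorder.valences,
        geometry=gmeta,
        model=mmeta,
    )


def load_trajectory(path):
    """Load a trajectory npz; returns (FrameRecorder, model, T)."""
    from .geometry import BulkBox, SlitBox
    from .model import DielectricRampModel
    from .observables import FrameRecorder

    data = np.load(path, allow_pickle=False)
    gmeta = json.loads(str(data["geometry"]))
    mmeta = json.loads(str(data["model"]))
    rec = FrameRecorder()
    rec.valences = data["valences"]
    if gmeta["type"] == "slit":
        rec.geometry = SlitBox(L=gmeta["L"], H=gmeta["H"], sigma=gmeta["sigma"])
    else:
        rec.geometry = BulkBox(L=gmeta["L"])
    rec.positions = list(data["positions"])
    T = mmeta.pop("T")
    return rec, DielectricRampModel(**mmeta), T


def write_table(path, df: pd.DataFrame, metadata: dict | None = None) -> None:
    """Write a TSV table with ``#`` metadata header lines at full precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key} = {json.dumps(value)}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_table(path) -> tuple[pd.DataFrame, dict]:
    """Read a TSV table written by :func:`write_table`; returns (df, metadata)."""
    metadata = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            body_start = i + 1
            key, _, value = line[1:].partition("=")
            try:
                metadata[key.strip()] = json.loads(value.strip())
            except json.JSONDecodeError:
                metadata[key.strip()] = value.strip()
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t")
    return df, metadata


def write_xyz(path, positions: np.ndarray, valences: np.ndarray,
              comment: str = "") -> None:
    """XYZ snapshot with element tags CAT (cations) / ANI (anions)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"{len(positions)}\n{comment}\n")
        for p, v in zip(positions, valences):
            tag = "CAT" if v > 0 else "ANI"
            fh.write(f"{tag} {p[0]:.10f} {p[1]:.10f} {p[2]:.10f}\n")


def read_xyz(path) -> tuple[np.ndarray, np.ndarray, str]:
    """Read an XYZ snapshot; returns (positions, valences, comment)."""
    with open(path) as fh:
        n = int(fh.readline())
        comment = fh.readline().rstrip("\n")
        positions = np.empty((n, 3))
        valences = np.empty(n)
        for i in range(n):
            tag, x, y, z = fh.readline().split()
            positions[i] = (float(x), float(y), float(z))
            valences[i] = 1.0 if tag == "CAT" else -1.0
    return positions, valences, comment


def write_manifest(path, config: dict, seed: int, extra: dict | None = None) -> None:
    """Run manifest: resolved config, seed, package version, extras."""
    from . import __version__

    payload = {"config": config, "seed": seed, "version": __version__}
    payload.update(extra or {})
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
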