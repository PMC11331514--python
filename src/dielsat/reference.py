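"""Slow, transparent reference implementations used as oracles.

Everything here is written as plainly as possible (explicit loops over
pairs, direct image summation, dense-graph BFS) and deliberately shares no
code with the compiled kernels, so the two paths can be compared in tests
and fixture metadata can be generated independently of the engine.
"""

from __future__ import annotations

import math

import numpy as np

from .constants import BJERRUM_PREFACTOR_AK
from .geometry import BulkBox, SlitBox
from .model import DielectricRampModel


def ramp_epsilon(r: float, model: DielectricRampModel) -> float:
    if r <= model.d:
        return model.eps_c
    if r >= model.d + model.delta:
        return model.eps_b
    return model.eps_c + (model.eps_b - model.eps_c) * (r - model.d) / model.delta


def ramp_beta_u(r: float, zi: float, zj: float, model: DielectricRampModel,
                T: float = 298.0) -> float:
    if r < model.d:
        return math.inf
    lb1 = BJERRUM_PREFACTOR_AK / T
    return zi * zj * lb1 / (ramp_epsilon(r, model) * r)


def total_energy_bulk(pos: np.ndarray, q: np.ndarray, box: BulkBox,
                      model: DielectricRampModel, T: float = 298.0) -> float:
    """Direct O(N^2) minimum-image total energy for a bulk configuration."""
    n = len(pos)
    L = box.L
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            d = pos[j] - pos[i]
            d -= L * np.round(d / L)
            total += ramp_beta_u(float(np.linalg.norm(d)), q[i], q[j], model, T)
    return total


def _slit_energy_window(pos, q, slit, model, T, n_shells) -> float:
    """Slit total energy with lateral images summed over a finite square
    window of ``n_shells`` shells ((2M+1)^2 - 1 images per pair)."""
    n = len(pos)
    L = slit.L
    lb_b = BJERRUM_PREFACTOR_AK / (model.eps_b * T)
    ns = np.arange(-n_shells, n_shells + 1) * L
    sx, sy = np.meshgrid(ns, ns, indexing="ij")
    keep = ~((sx == 0.0) & (sy == 0.0))
    sx, sy = sx[keep], sy[keep]
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            d = pos[j] - pos[i]
            dx = d[0] - L * round(d[0] / L)
            dy = d[1] - L * round(d[1] / L)
            dz = d[2]
            # direct minimum-image term with the ramp potential
            r_mi = math.sqrt(dx * dx + dy * dy + dz * dz)
            total += ramp_beta_u(r_mi, q[i], q[j], model, T)
            # all other lateral images at eps_b
            r = np.sqrt((dx + sx) ** 2 + (dy + sy) ** 2 + dz * dz)
            total += q[i] * q[j] * lb_b * float(np.sum(1.0 / r))
    # each ion with its own lateral images (self-image term)
    r_self = float(np.sum(1.0 / np.sqrt(sx**2 + sy**2)))
    for i in range(n):
        total += 0.5 * q[i] * q[i] * lb_b * r_self
    return total


def total_energy_slit_images(
    pos: np.ndarray,
    q: np.ndarray,
    slit: SlitBox,
    model: DielectricRampModel,
    T: float = 298.0,
    n_shells: int = 150,
) -> float:
    """Slit total energy by explicit lateral periodic image summation.

    The direct (minimum-image) term of each pair uses the dielectric ramp;
    every other lateral image, including each ion's own images, uses the
    bulk permittivity.  For an electroneutral ion set the square-window
    sum converges like 1/M (residual dipole--dipole interactions between
    the neutral cell and its far copies), so the window limit is removed
    by Richardson extrapolation in 1/M between ``n_shells`` and
    ``2 * n_shells`` (>= 9e4 images per pair at the default).
    """
    m1, m2 = n_shells, 2 * n_shells
    e1 = _slit_energy_window(pos, q, slit, model, T, m1)
    e2 = _slit_energy_window(pos, q, slit, model, T, m2)
    return (m2 * e2 - m1 * e1) / (m2 - m1)


def two_ion_distance_pdf(r_grid: np.ndarray, model: DielectricRampModel,
                         T: float = 298.0) -> np.ndarray:
    """Normalised Boltzmann pair-distance density for one +/- pair.

    p(r) ~ r^2 exp(-beta*u(r)) on the (spherically symmetric) range
    r < L/2; normalised over ``r_grid`` by the trapezoid rule.  Serves as
    the quadrature oracle for the 2-ion sampling test.
    """
    w = np.array([
        0.0 if r < model.d else r * r * math.exp(-ramp_beta_u(r, 1, -1, model, T))
        for r in r_grid
    ])
    norm = np.trapezoid(w, r_grid)
    return w / norm


def cluster_labels_bfs(pos: np.ndarray, box, delta: float) -> np.ndarray:
    """Connected-component labels by BFS on the dense adjacency matrix."""
    n = len(pos)
    L = box.L
    periodic = box.periodic
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            d = pos[j] - pos[i]
            for ax in range(3):
                if periodic[ax]:
                    d[ax] -= L * round(d[ax] / L)
            if float(np.dot(d, d)) <= delta * delta:
                adj[i, j] = adj[j, i] = True
    labels = -np.ones(n, dtype=int)
    current = 0
    for start in range(n):
        if labels[start] >= 0:
            continue
        queue = [start]
        labels[start] = current
        while queue:
            i = queue.pop(0)
            for j in range(n):
                if adj[i, j] and labels[j] < 0:
                    labels[j] = current
                    queue.append(j)
        current += 1
    return labels
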