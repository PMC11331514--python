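"""Screening-length estimation by ghost test-charge-pair insertion.

A +q/-q ghost pair at separation r is inserted at random positions and
orientations into stored equilibrium frames; the insertion free energy

    w(r) = -ln < exp(-beta * dU) >

(dU = interaction of both ghosts with the medium plus the constant
ghost-ghost term) measures the potential of mean force between the test
charges.  In a screening medium with a Yukawa-form charge--charge
correlation the r-dependent part follows

    w(r) ~= -A * exp(-r/lambda) / r,        A > 0,

so lambda is the effective electrostatic screening length; in the dilute
(Debye--Hueckel) limit lambda -> lambda_D.  The r-independent solvation
part of w is removed by referencing to the largest sampled separation.
Ghost charges interact with medium ions through the same dielectric ramp
potential as real ions and carry the same hard core.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from . import _kernels
from .engine import _DUMMY_RTAB
from .model import DielectricRampModel, pair_energy
from .observables import FrameRecorder, ScreeningEstimate

__all__ = [
    "WidomSettings",
    "WidomTable",
    "pair_insertion_free_energy",
    "effective_screening_length",
]

_SEED_MAX = 2**31 - 1


@dataclass(frozen=True)
class WidomSettings:
    """Settings for ghost-pair insertions.

    ``separations`` must lie inside (d, L/2); ``insertions`` is the number
    of ghost-pair placements per frame and separation.
    """

    separations: tuple
    insertions: int = 500
    test_charge: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.insertions < 1:
            raise ValueError("need at least one insertion per frame")
        if len(self.separations) < 1:
            raise ValueError("need at least one separation")


@dataclass
class WidomTable:
    """w(r_k) table with per-frame averages kept for bootstrap resampling."""

    separations: np.ndarray
    w: np.ndarray  # referenced free energies, k_BT
    w_raw: np.ndarray  # unreferenced, k_BT
    reference_separation: float
    frame_means: np.ndarray  # (n_frames, n_sep) per-frame <exp(-beta dU)>
    pair_term: np.ndarray  # constant ghost-ghost beta*u at each separation

    @classmethod
    def from_w(cls, separations, w) -> "WidomTable":
        """Build a table from an externally computed (e.g. synthetic) w(r).

        The last separation becomes the reference point.
        """
        separations = np.asarray(separations, dtype=float)
        w = np.asarray(w, dtype=float)
        return cls(
            separations=separations,
            w=w - w[-1],
            w_raw=w,
            reference_separation=float(separations[-1]),
            frame_means=np.empty((0, len(separations))),
            pair_term=np.zeros(len(separations)),
        )


def pair_insertion_free_energy(
    frames,
    settings: WidomSettings,
    model: DielectricRampModel | None = None,
    T: float = 298.0,
) -> WidomTable:
    """Ghost-pair insertion free energies w(r_k) over a bulk trajectory.

    ``frames`` is a :class:`FrameRecorder` (or any object with
    ``positions`` (list of (N,3) arrays), ``valences`` and ``geometry``).
    Insertions are ghosts: stored configurations are never perturbed.
    Returns w(r_k) referenced to the largest separation, isolating the
    r-dependent part.
    """
    if isinstance(frames, FrameRecorder) and len(frames) == 0:
        raise ValueError("no frames recorded")
    geometry = frames.geometry
    valences = frames.valences
    positions = frames.positions
    model = model or DielectricRampModel()
    L = geometry.L
    seps = np.asarray(sorted(settings.separations), dtype=float)
    if np.any(seps <= model.d) or np.any(seps > L / 2.0):
        raise ValueError("separations must lie in (d, L/2]")
    from .constants import BJERRUM_PREFACTOR_AK

    lB1 = BJERRUM_PREFACTOR_AK / T
    params = (0.0, L, 0.0, model.d, model.eps_c, model.eps_b, model.delta,
              lB1, lB1 / model.eps_b)
    rng = np.random.default_rng(settings.seed)
    q = settings.test_charge
    # constant ghost-ghost term (+q/-q at fixed separation, ramp potential)
    pair_term = np.array(
        [q * q * pair_energy(r, 1, -1, model, T) for r in seps]
    )
    n_frames = len(positions)
    frame_means = np.empty((n_frames, len(seps)))
    vals = np.ascontiguousarray(valences, dtype=np.float64)
    for fi, pos in enumerate(positions):
        pos = np.ascontiguousarray(pos, dtype=np.float64)
        seed = int(rng.integers(_SEED_MAX))
        if q == 0.0:
            frame_means[fi, :] = 1.0
            continue
        frame_means[fi, :] = _kernels.widom_pair_frame_multi(
            pos, vals, params, _DUMMY_RTAB, seps, settings.insertions, q,
            seed,
        )
    mean_b = frame_means.mean(axis=0)
    if np.any(mean_b <= 0.0):
        raise RuntimeError(
            "all ghost insertions overlapped at some separation; "
            "system too dense for this insertion count"
        )
    w_raw = -np.log(mean_b) + pair_term
    w = w_raw - w_raw[-1]
    return WidomTable(
        separations=seps,
        w=w,
        w_raw=w_raw,
        reference_separation=float(seps[-1]),
        frame_means=frame_means,
        pair_term=pair_term,
    )


def _yukawa_diff(r, a, lam, r_ref):
    return -a * (np.exp(-r / lam) / r - np.exp(-r_ref / lam) / r_ref)


def effective_screening_length(
    table: WidomTable,
    n_bootstrap: int = 200,
    seed: int = 0,
    lam0: float | None = None,
) -> ScreeningEstimate:
    """Fit w(r) = -A exp(-r/lambda)/r (referenced) and return lambda.

    Uses nonlinear least squares on the reference-subtracted two-term form;
    uncertainty from a bootstrap over frames.  Non-monotone |w| (the
    oscillatory regime) is fitted anyway but flagged ``"oscillatory"``,
    mirroring the method's ability to extract an *effective* screening
    length beyond the strict Yukawa regime.  A vanishing or exactly
    Coulombic w (a zero-ion medium leaves no decay to fit) is flagged
    ``"no-screening"`` with lambda = inf.
    """
    r = table.separations
    if len(r) < 4:
        raise ValueError("need >= 4 separations to fit")
    w = table.w[:-1]  # last point is the reference (identically 0)
    rr = r[:-1]
    r_ref = table.reference_separation
    if np.max(np.abs(w)) < 1.0e-12:
        return ScreeningEstimate(
            lam=math.inf, amplitude=0.0, window=(float(r[0]), float(r_ref)),
            method="widom-pair", quality="no-screening",
        )
    # unscreened (pure Coulomb) limit: w is an exact multiple of
    # -(1/r - 1/r_ref), i.e. lambda -> inf; flag instead of fitting
    basis = -(1.0 / rr - 1.0 / r_ref)
    a_c = float(np.dot(basis, w) / np.dot(basis, basis))
    res_c = float(np.linalg.norm(w - a_c * basis) / np.linalg.norm(w))
    if res_c < 1.0e-8:
        return ScreeningEstimate(
            lam=math.inf, amplitude=a_c, window=(float(r[0]), float(r_ref)),
            method="widom-pair", quality="no-screening",
        )
    quality = "ok"
    mags = np.abs(w)
    if np.any(np.diff(mags) > 1e-15):  # |w| should decay toward the reference
        quality = "oscillatory"
    if lam0 is None:
        lam0 = max((rr[-1] - rr[0]) / max(math.log(mags[0] / max(mags[-1], 1e-300)), 1.0), 0.5)
    lam_hi = 10.0 * r_ref
    lam0 = min(max(lam0, 0.2), lam_hi * 0.9)
    a0 = min(abs(w[0]) * rr[0] * math.exp(rr[0] / lam0), 1e3)
    # per-separation uncertainties (bootstrap over frames) weight the fit;
    # without them the near-zero far points dominate the residuals
    sigma = None
    nf = table.frame_means.shape[0]
    if nf > 1:
        rng_s = np.random.default_rng(seed + 1)
        ws = []
        for _ in range(100):
            idx = rng_s.integers(nf, size=nf)
            mb = table.frame_means[idx].mean(axis=0)
            if np.any(mb <= 0):
                continue
            wb = -np.log(mb) + table.pair_term
            ws.append((wb - wb[-1])[:-1])
        if len(ws) >= 20:
            sigma = np.std(np.asarray(ws), axis=0, ddof=1)
            sigma = np.clip(sigma, max(np.max(sigma) * 1e-3, 1e-12), None)

    def fit_once(wv):
        popt, _ = curve_fit(
            lambda x, a, lam: _yukawa_diff(x, a, lam, r_ref),
            rr, wv, p0=(a0, lam0), sigma=sigma, maxfev=20_000,
            bounds=([0.0, 0.1], [np.inf, lam_hi]),
        )
        return popt

    try:
        a_fit, lam_fit = fit_once(w)
    except RuntimeError:
        return ScreeningEstimate(
            lam=math.nan, amplitude=math.nan,
            window=(float(r[0]), float(r_ref)),
            method="widom-pair", quality="fit-failed",
        )
    # bootstrap over frames
    stderr = math.nan
    if n_bootstrap > 0 and table.frame_means.shape[0] > 1:
        rng = np.random.default_rng(seed)
        nf = table.frame_means.shape[0]
        lams = []
        for _ in range(n_bootstrap):
            idx = rng.integers(nf, size=nf)
            mb = table.frame_means[idx].mean(axis=0)
            if np.any(mb <= 0):
                continue
            wb = -np.log(mb) + table.pair_term
            wb = wb - wb[-1]
            try:
                _, lam_b = fit_once(wb[:-1])
            except RuntimeError:
                continue
            if lam_b > 0:
                lams.append(lam_b)
        if len(lams) >= 10:
            stderr = float(np.std(lams, ddof=1))
    return ScreeningEstimate(
        lam=float(abs(lam_fit)),
        amplitude=float(a_fit),
        window=(float(r[0]), float(r_ref)),
        method="widom-pair",
        stderr=stderr,
        quality=quality,
    )
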