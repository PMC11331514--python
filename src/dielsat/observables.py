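"""Structural observables: RDFs, cluster statistics, tail fits, profiles.

Species-resolved radial distribution functions are pooled over the
symmetry-equivalent channels, as usual for a symmetric 1:1 electrolyte:
``g_pp`` holds the like-charge pool (g++ + g--)/2 and ``g_pm`` the
unlike-charge pool (g+- + g-+)/2.  The density--density and charge--charge
combinations are then

    g_nn = (g_pp + g_pm)/2        g_cc = (g_pm - g_pp)/2

which are algebraically identical to the four-term definitions.  The
longer-ranged of h_nn and h_cc controls surface--surface interactions at
large separation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .constants import MOLAR_TO_PER_A3
from .engine import MCState
from .geometry import BulkBox, SlitBox

__all__ = [
    "RDFSet",
    "ClusterPartition",
    "ClusterSizeDistribution",
    "DensityProfile",
    "ScreeningEstimate",
    "FitNotApplicableError",
    "accumulate_rdf",
    "derive_gnn_gcc",
    "cluster_decomposition",
    "cluster_size_distribution",
    "yukawa_tail_fit",
    "phase_separation_diagnostic",
    "density_profiles",
    "midplane_concentration",
    "charge_neutrality_integral",
    "RDFObserver",
    "ClusterObserver",
    "ProfileObserver",
    "FrameRecorder",
]


class FitNotApplicableError(RuntimeError):
    """The correlation tail is oscillatory/sign-changing over the fit window."""


# ---------------------------------------------------------------------------
# Pair distances
# ---------------------------------------------------------------------------

def _mi_distances(pos_a: np.ndarray, pos_b: np.ndarray | None, box) -> np.ndarray:
    """All minimum-image pair distances between two position sets.

    With ``pos_b`` None, returns the N*(N-1)/2 intra-set distances.
    """
    L = box.L
    if pos_b is None:
        n = len(pos_a)
        iu = np.triu_indices(n, k=1)
        d = pos_a[iu[0]] - pos_a[iu[1]]
    else:
        d = pos_a[:, None, :] - pos_b[None, :, :]
        d = d.reshape(-1, 3)
    for ax, per in enumerate(box.periodic):
        if per:
            d[:, ax] -= L * np.round(d[:, ax] / L)
    return np.sqrt(np.einsum("ij,ij->i", d, d))


# ---------------------------------------------------------------------------
# Radial distribution functions
# ---------------------------------------------------------------------------

@dataclass
class RDFSet:
    """Binned, pooled pair correlations for a bulk frame stream."""

    bin_edges: np.ndarray
    counts_pp: np.ndarray = None
    counts_pm: np.ndarray = None
    frames: int = 0
    n_plus: int = 0
    n_minus: int = 0
    volume: float = 0.0

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        nb = len(self.bin_edges) - 1
        if nb < 1 or np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be increasing with >= 1 bin")
        if self.counts_pp is None:
            self.counts_pp = np.zeros(nb)
        if self.counts_pm is None:
            self.counts_pm = np.zeros(nb)

    @classmethod
    def for_box(cls, box: BulkBox, bin_width: float = 0.1) -> "RDFSet":
        """Bins of ``bin_width`` from 0 to L/2 (the reliable MI range)."""
        edges = np.arange(0.0, box.L / 2.0 + bin_width / 2.0, bin_width)
        return cls(bin_edges=edges)

    @property
    def r(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def _shell_volumes(self) -> np.ndarray:
        return 4.0 / 3.0 * np.pi * np.diff(self.bin_edges**3)

    def accumulate(self, state: MCState) -> None:
        if state.n_ions == 0:
            raise ValueError("cannot accumulate an empty frame")
        plus = state.positions[state.valences > 0]
        minus = state.positions[state.valences < 0]
        if self.frames == 0:
            self.n_plus, self.n_minus = len(plus), len(minus)
            self.volume = state.geometry.volume
        box = state.geometry
        like = np.concatenate([
            _mi_distances(plus, None, box), _mi_distances(minus, None, box)
        ])
        unlike = _mi_distances(plus, minus, box)
        self.counts_pp += np.histogram(like, bins=self.bin_edges)[0]
        self.counts_pm += np.histogram(unlike, bins=self.bin_edges)[0]
        self.frames += 1

    def _normalize(self, counts: np.ndarray, n_pairs: float) -> np.ndarray:
        if self.frames == 0 or n_pairs == 0:
            return np.zeros_like(counts, dtype=float)
        expected = n_pairs * self._shell_volumes() / self.volume
        return counts / (self.frames * expected)

    @property
    def g_pp(self) -> np.ndarray:
        """Pooled like-charge RDF, (g++ + g--)/2."""
        n_pairs = (self.n_plus * (self.n_plus - 1) / 2
                   + self.n_minus * (self.n_minus - 1) / 2)
        return self._normalize(self.counts_pp, n_pairs)

    @property
    def g_pm(self) -> np.ndarray:
        """Pooled unlike-charge RDF, (g+- + g-+)/2."""
        return self._normalize(self.counts_pm, self.n_plus * self.n_minus)

    @property
    def g_nn(self) -> np.ndarray:
        return derive_gnn_gcc(self)[0]

    @property
    def g_cc(self) -> np.ndarray:
        return derive_gnn_gcc(self)[1]


def accumulate_rdf(frame: MCState, rdf: RDFSet) -> RDFSet:
    """Accumulate one frame into ``rdf`` (shell-normalised MI histogram)."""
    rdf.accumulate(frame)
    return rdf


def derive_gnn_gcc(rdf_or_pp, g_pm: np.ndarray | None = None):
    """Density--density and charge--charge combinations from pooled RDFs.

    Accepts either an :class:`RDFSet` or two pooled arrays (g_pp, g_pm).
    """
    if g_pm is None:
        g_pp, g_pm = rdf_or_pp.g_pp, rdf_or_pp.g_pm
    else:
        g_pp = np.asarray(rdf_or_pp, dtype=float)
        g_pm = np.asarray(g_pm, dtype=float)
    if g_pp.shape != g_pm.shape:
        raise ValueError("mismatched bins between g_pp and g_pm")
    return (g_pp + g_pm) / 2.0, (g_pm - g_pp) / 2.0


# ---------------------------------------------------------------------------
# Cluster analysis
# ---------------------------------------------------------------------------

@dataclass
class ClusterPartition:
    """Partition of ions into connected clusters under distance ``delta``."""

    labels: np.ndarray
    delta: float

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    @property
    def sizes(self) -> np.ndarray:
        """Size of each cluster, indexed by label."""
        return np.bincount(self.labels, minlength=self.n_clusters)

    def size_of_ion(self) -> np.ndarray:
        """For each ion, the size of the cluster it belongs to."""
        return self.sizes[self.labels]


def cluster_decomposition(frame: MCState, delta: float) -> ClusterPartition:
    """Connected components under minimum-image pair distance <= delta.

    Neighbour pairs come from a periodic KD-tree (bulk) or a direct pair
    scan (slit); components from a union-find style graph pass.  Clusters
    may wrap the box and are counted by total membership.
    """
    pos = frame.positions
    n = len(pos)
    if n == 0:
        return ClusterPartition(labels=np.zeros(0, dtype=int), delta=delta)
    box = frame.geometry
    L = box.L
    if isinstance(box, BulkBox):
        tree = cKDTree(np.mod(pos, L), boxsize=L)
        pairs = tree.query_pairs(delta, output_type="ndarray")
    else:
        iu = np.triu_indices(n, k=1)
        d = pos[iu[0]] - pos[iu[1]]
        d[:, 0] -= L * np.round(d[:, 0] / L)
        d[:, 1] -= L * np.round(d[:, 1] / L)
        keep = np.einsum("ij,ij->i", d, d) <= delta * delta
        pairs = np.column_stack([iu[0][keep], iu[1][keep]])
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(adj, directed=False)
    return ClusterPartition(labels=labels, delta=delta)


@dataclass
class ClusterSizeDistribution:
    """P_ion(N_c): probability that an ion sits in a cluster of size N_c."""

    sizes: np.ndarray  # N_c values with nonzero probability, ascending
    p_ion: np.ndarray

    def mean_cluster_size(self) -> float:
        """Ion-weighted mean cluster size, sum N_c * P_ion(N_c)."""
        return float(np.sum(self.sizes * self.p_ion))

    def probability(self, n_c: int) -> float:
        idx = np.where(self.sizes == n_c)[0]
        return float(self.p_ion[idx[0]]) if idx.size else 0.0


def cluster_size_distribution(partitions) -> ClusterSizeDistribution:
    """Average P_ion(N_c) over a sequence of :class:`ClusterPartition`."""
    partitions = list(partitions)
    if not partitions:
        raise ValueError("need at least one partition")
    max_size = max(int(p.sizes.max()) for p in partitions)
    ion_counts = np.zeros(max_size + 1)
    n_ions_total = 0
    for p in partitions:
        sizes = p.sizes
        for s in sizes:
            ion_counts[s] += s  # s ions sit in this cluster of size s
        n_ions_total += p.labels.size
    p_ion = ion_counts / n_ions_total
    support = np.nonzero(p_ion)[0]
    return ClusterSizeDistribution(sizes=support, p_ion=p_ion[support])


# ---------------------------------------------------------------------------
# Tail fits and phase diagnostics
# ---------------------------------------------------------------------------

@dataclass
class ScreeningEstimate:
    """A fitted Yukawa decay length lambda with amplitude and diagnostics."""

    lam: float
    amplitude: float
    window: tuple
    method: str = "rdf-fit"
    stderr: float = float("nan")
    gof: float = float("nan")
    quality: str = "ok"


def yukawa_tail_fit(
    r: np.ndarray,
    h: np.ndarray,
    window: tuple,
    weights: np.ndarray | None = None,
    method: str = "rdf-fit",
) -> ScreeningEstimate:
    """Fit h(r) ~ A*exp(-r/lambda)/r over ``window`` by weighted least squares.

    Linearises to ln(r*|h|) = ln A - r/lambda.  The sign of h must be
    consistent over the window; sign changes (the oscillatory regime) raise
    :class:`FitNotApplicableError`.
    """
    r = np.asarray(r, dtype=float)
    h = np.asarray(h, dtype=float)
    lo, hi = window
    mask = (r >= lo) & (r <= hi) & (h != 0.0)
    if mask.sum() < 3:
        raise FitNotApplicableError("fewer than 3 usable points in fit window")
    rw, hw = r[mask], h[mask]
    signs = np.sign(hw)
    if not (np.all(signs > 0) or np.all(signs < 0)):
        raise FitNotApplicableError("sign change inside fit window (oscillatory)")
    y = np.log(rw * np.abs(hw))
    if weights is None:
        w = np.ones_like(y)
    else:
        w = np.asarray(weights, dtype=float)[mask]
    X = np.column_stack([np.ones_like(rw), -rw])
    sw = np.sqrt(w)
    coef, res, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    ln_a, inv_lam = coef
    if inv_lam <= 0:
        raise FitNotApplicableError("non-decaying tail (fitted lambda <= 0)")
    lam = 1.0 / inv_lam
    fitted = X @ coef
    ss_res = float(np.sum(w * (y - fitted) ** 2))
    ss_tot = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
    gof = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    # delta-method stderr of lambda from the slope variance
    dof = max(len(y) - 2, 1)
    s2 = ss_res / dof
    cov = s2 * np.linalg.inv((X * w[:, None]).T @ X)
    stderr = math.sqrt(cov[1, 1]) * lam**2
    return ScreeningEstimate(
        lam=lam,
        amplitude=float(signs[0] * math.exp(ln_a)),
        window=(float(lo), float(hi)),
        method=method,
        stderr=stderr,
        gof=gof,
    )


def phase_separation_diagnostic(
    r: np.ndarray,
    g_pp: np.ndarray,
    window: tuple | None = None,
    slope_threshold: float = 0.05,
    mean_threshold: float = 0.02,
) -> dict:
    """Classify a bulk run as phase separated from the tail of g++(r).

    A pronounced long-ranged slope in the g++ tail signals separation into
    a condensed and a dilute phase.  Linear regression over the tail window
    (default [max(r)/2, max(r)]); classified "separated" when
    |slope| * window_length > ``slope_threshold`` and the tail mean deviates
    from 1 by more than ``mean_threshold``.
    """
    r = np.asarray(r, dtype=float)
    g_pp = np.asarray(g_pp, dtype=float)
    if window is None:
        window = (r.max() / 2.0, r.max())
    lo, hi = window
    mask = (r >= lo) & (r <= hi)
    if mask.sum() < 3:
        raise ValueError("tail window contains fewer than 3 bins")
    rw, gw = r[mask], g_pp[mask]
    slope, intercept = np.polyfit(rw, gw, 1)
    tail_mean = float(gw.mean())
    excess = abs(slope) * (hi - lo)
    separated = (excess > slope_threshold) and (abs(tail_mean - 1.0) > mean_threshold)
    return {
        "classification": "separated" if separated else "homogeneous",
        "slope": float(slope),
        "tail_mean": tail_mean,
        "slope_excess": float(excess),
        "window": (float(lo), float(hi)),
    }


# ---------------------------------------------------------------------------
# Slit density profiles
# ---------------------------------------------------------------------------

@dataclass
class DensityProfile:
    """z-resolved ion concentrations in a slit, in mol/L."""

    z: np.ndarray
    n_plus: np.ndarray
    n_minus: np.ndarray
    bin_width: float
    frames: int
    L: float

    @property
    def delta_n(self) -> np.ndarray:
        """Charge-density contrast n+(z) - n-(z), mol/L."""
        return self.n_plus - self.n_minus

    def total_count(self) -> float:
        """Ion count implied by integrating both profiles (consistency check)."""
        slab = self.L**2 * self.bin_width
        return float(np.sum(self.n_plus + self.n_minus) * MOLAR_TO_PER_A3 * slab)

    def symmetrized(self) -> "DensityProfile":
        """Average the profile with its mirror image about z = 0."""
        return DensityProfile(
            z=self.z,
            n_plus=0.5 * (self.n_plus + self.n_plus[::-1]),
            n_minus=0.5 * (self.n_minus + self.n_minus[::-1]),
            bin_width=self.bin_width,
            frames=self.frames,
            L=self.L,
        )


def density_profiles(frames, bin_width: float = 0.5,
                     symmetrize: bool = False) -> DensityProfile:
    """Histogram n+(z), n-(z) from slit frames, normalised to mol/L.

    ``frames`` is an iterable of slit :class:`MCState` snapshots (or a
    :class:`FrameRecorder`).  Bins span the full wall-to-wall width H.
    """
    if isinstance(frames, FrameRecorder):
        geometry = frames.geometry
        valences = frames.valences
        frame_pos = frames.positions
    else:
        frames = list(frames)
        if not frames:
            raise ValueError("no frames")
        geometry = frames[0].geometry
        valences = frames[0].valences
        frame_pos = [f.positions for f in frames]
    if not isinstance(geometry, SlitBox):
        raise ValueError("density profiles require slit geometry")
    H, L = geometry.H, geometry.L
    nbins = max(int(round(H / bin_width)), 1)
    edges = np.linspace(-H / 2.0, H / 2.0, nbins + 1)
    hist_p = np.zeros(nbins)
    hist_m = np.zeros(nbins)
    nframes = 0
    for pos in frame_pos:
        z = pos[:, 2]
        hist_p += np.histogram(z[valences > 0], bins=edges)[0]
        hist_m += np.histogram(z[valences < 0], bins=edges)[0]
        nframes += 1
    dz = edges[1] - edges[0]
    slab = L * L * dz
    conv = 1.0 / (MOLAR_TO_PER_A3 * slab * nframes)
    prof = DensityProfile(
        z=0.5 * (edges[:-1] + edges[1:]),
        n_plus=hist_p * conv,
        n_minus=hist_m * conv,
        bin_width=dz,
        frames=nframes,
        L=L,
    )
    return prof.symmetrized() if symmetrize else prof


def midplane_concentration(profile: DensityProfile, width: float = 5.0) -> float:
    """Mean salt concentration (n+ + n-)/2 over the central |z| <= width/2.

    Reports the effective bulk concentration of a slit run from midplane
    values.
    """
    mask = np.abs(profile.z) <= width / 2.0
    if not mask.any():
        raise ValueError("width selects no bins")
    return float(np.mean((profile.n_plus[mask] + profile.n_minus[mask]) / 2.0))


# ---------------------------------------------------------------------------
# Electroneutrality moment
# ---------------------------------------------------------------------------

def charge_neutrality_integral(rdf: RDFSet, density: float,
                               baseline_correct: bool = True) -> float:
    """Zeroth charge moment 8*pi*n * integral r^2 g_cc(r) dr (e0 units).

    ``density`` is the per-species number density in ions/A^3.  Local
    electroneutrality requires the counter-charge around an ion to cancel
    its own charge, so the integral approaches 1 for a homogeneous bulk
    phase.  In a canonical (fixed-N) simulation g_cc carries an O(1/N)
    offset at large r which the r^2 weight amplifies; with
    ``baseline_correct`` the mean of g_cc over the outer 30% of the range
    is subtracted before integrating.
    """
    r = rdf.r
    g_cc = rdf.g_cc.copy()
    if baseline_correct:
        tail = r > 0.7 * r.max()
        if tail.any():
            g_cc = g_cc - g_cc[tail].mean()
    return float(8.0 * np.pi * density * np.trapezoid(r**2 * g_cc, r))


# ---------------------------------------------------------------------------
# Observers for engine.run
# ---------------------------------------------------------------------------

class RDFObserver:
    """Accumulates an :class:`RDFSet` every sampling stride."""

    def __init__(self, box: BulkBox, bin_width: float = 0.1):
        self.rdf = RDFSet.for_box(box, bin_width)

    def update(self, state: MCState) -> None:
        self.rdf.accumulate(state)


class ClusterObserver:
    """Accumulates cluster partitions under criterion ``delta``."""

    def __init__(self, delta: float = 3.5):
        self.delta = delta
        self.partitions: list[ClusterPartition] = []

    def update(self, state: MCState) -> None:
        self.partitions.append(cluster_decomposition(state, self.delta))

    def distribution(self) -> ClusterSizeDistribution:
        return cluster_size_distribution(self.partitions)


class FrameRecorder:
    """Stores position snapshots (copies) for post-hoc analysis."""

    def __init__(self):
        self.positions: list[np.ndarray] = []
        self.valences: np.ndarray | None = None
        self.geometry = None

    def update(self, state: MCState) -> None:
        if self.valences is None:
            self.valences = state.valences.copy()
            self.geometry = state.geometry
        self.positions.append(state.positions.copy())

    def __len__(self) -> int:
        return len(self.positions)


class ProfileObserver:
    """Accumulates slit z-histograms; ``profile()`` returns mol/L profiles."""

    def __init__(self, slit: SlitBox, bin_width: float = 0.5):
        self.slit = slit
        nbins = max(int(round(slit.H / bin_width)), 1)
        self.edges = np.linspace(-slit.H / 2.0, slit.H / 2.0, nbins + 1)
        self.hist_p = np.zeros(nbins)
        self.hist_m = np.zeros(nbins)
        self.frames = 0

    def update(self, state: MCState) -> None:
        z = state.positions[:, 2]
        v = state.valences
        self.hist_p += np.histogram(z[v > 0], bins=self.edges)[0]
        self.hist_m += np.histogram(z[v < 0], bins=self.edges)[0]
        self.frames += 1

    def profile(self, symmetrize: bool = False) -> DensityProfile:
        dz = self.edges[1] - self.edges[0]
        conv = 1.0 / (MOLAR_TO_PER_A3 * self.slit.L**2 * dz * max(self.frames, 1))
        prof = DensityProfile(
            z=0.5 * (self.edges[:-1] + self.edges[1:]),
            n_plus=self.hist_p * conv,
            n_minus=self.hist_m * conv,
            bin_width=dz,
            frames=self.frames,
            L=self.slit.L,
        )
        return prof.symmetrized() if symmetrize else prof
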