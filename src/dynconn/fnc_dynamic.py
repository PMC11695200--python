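"""Dynamic functional network connectivity (dFNC).

Sliding-window tapered correlations, k-means decomposition of the pooled
windowed connectivity into recurring brain states, per-subject temporal
state metrics (fraction time, mean dwell time, number of transitions), and
across-window connectivity variability.

The window is a rectangle of ``width`` TRs convolved with a Gaussian taper
(sigma in TR units) and advanced in steps of ``step`` TRs; correlations
inside a window use taper-weighted moments. The default clustering metric is
city-block (the convention of the GIFT dFNC toolbox, where centroids are
coordinate-wise medians); squared Euclidean is available by flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .fnc_static import fisher_z, pair_indices, vectorize_matrix

logger = logging.getLogger(__name__)

KMEANS_MAX_ITER = 500


# ---------------------------------------------------------------------------
# Window construction
# ---------------------------------------------------------------------------

def build_taper(width: int, gaussian_sigma: float) -> np.ndarray:
    """Tapered window weights: rectangle of ones convolved with a Gaussian.

    The Gaussian kernel is evaluated on integer offsets, truncated at
    +/- 3 sigma and renormalized; the central ``width`` samples of the full
    convolution are kept and normalized to sum to one. As sigma -> 0 the
    kernel collapses to a delta and the taper becomes uniform.
    """
    if width < 2:
        raise ValueError(f"window width must be >= 2, got {width}")
    if gaussian_sigma <= 0:
        raise ValueError(f"gaussian_sigma must be > 0, got {gaussian_sigma}")
    radius = max(1, int(math.ceil(3.0 * gaussian_sigma)))
    offsets = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-0.5 * (offsets / gaussian_sigma) ** 2)
    kernel /= kernel.sum()
    full = np.convolve(np.ones(width), kernel, mode="full")
    # full has length width + 2*radius; central `width` samples start at radius
    taper = full[radius:radius + width]
    taper = taper / taper.sum()
    return taper


@dataclass
class WindowSpec:
    """Sliding-window parameters (TR units)."""

    width: int = 20
    step: int = 1
    gaussian_sigma: float = 3.0
    taper: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.step < 1:
            raise ValueError(f"step must be >= 1, got {self.step}")
        if self.taper is None:
            self.taper = build_taper(self.width, self.gaussian_sigma)
        self.taper = np.asarray(self.taper, dtype=float)
        if self.taper.shape != (self.width,):
            raise ValueError("taper length must equal window width")
        if np.any(self.taper <= 0):
            raise ValueError("taper weights must be strictly positive")
        if not np.allclose(self.taper, self.taper[::-1]):
            raise ValueError("taper must be symmetric about the window center")
        if not np.isclose(self.taper.sum(), 1.0):
            raise ValueError("taper must sum to 1")


def n_windows(n_timepoints: int, spec: WindowSpec) -> int:
    """Number of windows: floor((T - width)/step) + 1."""
    if n_timepoints < spec.width:
        raise ValueError(
            f"series length {n_timepoints} shorter than window {spec.width}"
        )
    return (n_timepoints - spec.width) // spec.step + 1


def _weighted_corr(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted Pearson correlation of the columns of ``x`` (weights sum 1).

    Pairs involving a channel with zero weighted variance get correlation 0
    (degenerate-window policy; a warning is logged by the caller).
    """
    mu = w @ x
    xc = x - mu
    cov = (xc * w[:, None]).T @ xc
    var = np.diag(cov).copy()
    # numerically-constant channels: variance at rounding-error level
    bad = var <= 1e-20 * (1.0 + mu**2)
    sd = np.sqrt(np.where(bad, 1.0, var))
    r = cov / np.outer(sd, sd)
    if bad.any():
        r[bad, :] = 0.0
        r[:, bad] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0), bad.any()


@dataclass
class DFNCArray:
    """Per-subject stack of windowed Fisher-z matrices ``(W, C, C)``."""

    z_windows: np.ndarray
    window_starts: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.z_windows.shape[0]

    def pair_matrix(self) -> np.ndarray:
        """Windows-by-pairs view (strict lower triangle, row-major)."""
        rows, cols = pair_indices(self.z_windows.shape[1])
        return self.z_windows[:, rows, cols]

    def r_windows(self) -> np.ndarray:
        """Windowed correlation coefficients recovered from z-values."""
        r = np.tanh(self.z_windows)
        # the diagonal carries no information; keep it at r = 1
        for w in r:
            np.fill_diagonal(w, 1.0)
        return r


def windowed_fnc(ts: np.ndarray, spec: WindowSpec) -> DFNCArray:
    """Sliding tapered-window Fisher-z connectivity of a ``(T, C)`` series."""
    ts = np.asarray(ts, dtype=float)
    t, c = ts.shape
    w = n_windows(t, spec)
    starts = np.arange(w) * spec.step
    z = np.empty((w, c, c))
    any_degenerate = False
    for k, s0 in enumerate(starts):
        r, degenerate = _weighted_corr(ts[s0:s0 + spec.width], spec.taper)
        any_degenerate = any_degenerate or degenerate
        zk = fisher_z(r)
        np.fill_diagonal(zk, 0.0)
        z[k] = zk
    if any_degenerate:
        logger.warning(
            "constant channel inside at least one window; affected pair "
            "correlations set to 0"
        )
    return DFNCArray(z_windows=z, window_starts=starts)


def dfnc(panel, spec: WindowSpec = None) -> list:
    """Windowed FNC for every subject of a panel (panel order preserved)."""
    spec = spec or WindowSpec()
    panel.validate()
    return [windowed_fnc(s.data, spec) for s in panel.subjects]


# ---------------------------------------------------------------------------
# k-means state decomposition
# ---------------------------------------------------------------------------

@dataclass
class StateModel:
    """k-means decomposition of pooled windowed connectivity.

    ``labels`` are 1-based state indices over the pooled window rows,
    renumbered in descending order of pooled occupancy so that state 1 is
    the most frequent.
    """

    k: int
    centroids: np.ndarray
    labels: np.ndarray
    inertia: float
    distance_metric: str
    seed: int


def _centroid_update(x, labels, k, metric, current):
    # empty clusters were re-seeded during assignment; keep centroid if any slip
    reducer = np.median if metric == "cityblock" else np.mean
    centroids = current.copy()
    for c in range(k):
        members = labels == c
        if members.any():
            centroids[c] = reducer(x[members], axis=0)
    return centroids


def _kmeans_once(x, k, metric, rng, max_iter):
    n = x.shape[0]
    centroids = x[rng.choice(n, size=k, replace=False)].copy()
    labels = None
    for _ in range(max_iter):
        d = cdist(x, centroids, metric=metric)
        new_labels = d.argmin(axis=1)
        # repair empty clusters by re-seeding at the worst-fit point
        for c in range(k):
            if not (new_labels == c).any():
                far = int(np.argmax(d[np.arange(n), new_labels]))
                centroids[c] = x[far]
                new_labels[far] = c
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        centroids = _centroid_update(x, labels, k, metric, centroids)
    d = cdist(x, centroids, metric=metric)
    inertia = float(d[np.arange(n), labels].sum())
    return centroids, labels, inertia


def cluster_states(
    windows: np.ndarray,
    k: int = 6,
    distance: str = "cityblock",
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = KMEANS_MAX_ITER,
) -> StateModel:
    """Best-of-restarts Lloyd k-means on pooled windows-by-pairs data.

    ``distance`` is ``"cityblock"`` (median centroids) or ``"sqeuclidean"``
    (mean centroids). Deterministic given ``seed``. States are relabeled in
    descending order of occupancy (1 = most frequent).
    """
    x = np.asarray(windows, dtype=float)
    if x.ndim != 2:
        raise ValueError("windows must be a 2-D (windows x pairs) array")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if x.shape[0] < k:
        raise ValueError(f"{x.shape[0]} windows cannot support k={k} states")
    if distance not in ("cityblock", "sqeuclidean"):
        raise ValueError(f"unknown distance metric {distance!r}")
    master = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        rng = np.random.default_rng(master.integers(2**31))
        result = _kmeans_once(x, k, distance, rng, max_iter)
        if best is None or result[2] < best[2]:
            best = result
    centroids, labels, inertia = best
    # canonical state order: descending pooled occupancy, ties by old index
    counts = np.bincount(labels, minlength=k)
    order = np.argsort(-counts, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return StateModel(
        k=k,
        centroids=centroids[order],
        labels=remap[labels] + 1,
        inertia=inertia,
        distance_metric=distance,
        seed=seed,
    )


def split_labels(labels: np.ndarray, windows_per_subject) -> list:
    """Split pooled state labels back into per-subject sequences."""
    bounds = np.cumsum(windows_per_subject)
    if bounds[-1] != len(labels):
        raise ValueError("window counts do not sum to the pooled label length")
    return np.split(np.asarray(labels), bounds[:-1])


# ---------------------------------------------------------------------------
# Temporal state metrics and variability
# ---------------------------------------------------------------------------

@dataclass
class StateMetrics:
    """Per-subject temporal properties of the state sequence.

    ``mean_dwell_time`` is NaN for states the subject never visits.
    """

    fraction_time: np.ndarray
    mean_dwell_time: np.ndarray
    n_transitions: int


def run_lengths(labels: np.ndarray):
    """Maximal constant runs of a label sequence as (label, length) pairs."""
    labels = np.asarray(labels)
    change = np.flatnonzero(labels[1:] != labels[:-1])
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [len(labels)]))
    return [(int(labels[s]), int(e - s)) for s, e in zip(starts, ends)]


def state_metrics(labels: np.ndarray, k: int) -> StateMetrics:
    """Fraction time, mean dwell time (windows) and transition count."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty state label sequence")
    if labels.min() < 1 or labels.max() > k:
        raise ValueError(f"labels must lie in [1..{k}]")
    w = labels.size
    fraction = np.bincount(labels, minlength=k + 1)[1:] / w
    dwell = np.full(k, np.nan)
    runs = run_lengths(labels)
    for s in range(1, k + 1):
        lengths = [length for lab, length in runs if lab == s]
        if lengths:
            dwell[s - 1] = float(np.mean(lengths))
    transitions = int(np.sum(labels[1:] != labels[:-1]))
    return StateMetrics(fraction, dwell, transitions)


def dfnc_variability(array: DFNCArray) -> np.ndarray:
    """Across-window SD (ddof=1) of the windowed correlation per pair.

    The SD is taken on correlation coefficients r (not their z-transforms);
    returns a symmetric ``(C, C)`` matrix with zero diagonal.
    """
    if array.n_windows < 2:
        raise ValueError("variability needs at least 2 windows")
    r = array.r_windows()
    sd = r.std(axis=0, ddof=1)
    sd = (sd + sd.T) / 2.0
    np.fill_diagonal(sd, 0.0)
    return sd


def variability_pairs(array: DFNCArray) -> np.ndarray:
    """Pair-vectorized variability (strict lower triangle)."""
    return vectorize_matrix(dfnc_variability(array))
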