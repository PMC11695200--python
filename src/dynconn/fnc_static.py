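"""Static functional network connectivity (sFNC).

Per-subject connectivity is the Pearson correlation between channel time
courses (ICA component or atlas-node signals), Fisher z-transformed so that
group statistics operate on an approximately variance-stabilized scale.
This module also defines the in-memory cohort container
(:class:`TimeSeriesPanel`) shared by every downstream stage, and fixes the
pair-vectorization convention (row-major strict lower triangle) used
throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

#: Canonical resting-state network names used for channel grouping.
NETWORKS = ("DMN", "CEN", "SN", "AUN", "VN", "SMN")

#: Clipping distance from |r| = 1 applied before the Fisher transform.
FISHER_EPS = 1e-7


@dataclass
class Subject:
    """One subject's channel time courses plus group label and covariates.

    ``data`` is a ``(T, C)`` float array (rows = time points); ``covariates``
    maps covariate names (``age``, ``gender``, ``education``, ``mean_fd`` and
    optional clinical scores) to scalars.
    """

    subject_id: str
    data: np.ndarray
    group: str
    covariates: dict = field(default_factory=dict)


@dataclass
class TimeSeriesPanel:
    """Ordered collection of subjects sharing channel layout and sampling.

    ``channel_networks`` assigns each channel to a functional network (one of
    :data:`NETWORKS`) or an atlas region group, used for network-level
    summaries.
    """

    subjects: list
    channel_labels: list
    channel_networks: list
    tr_seconds: float = 2.0

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    def validate(self) -> None:
        c = self.n_channels
        if len(self.channel_networks) != c:
            raise ValueError(
                f"channel_networks has {len(self.channel_networks)} entries "
                f"for {c} channels"
            )
        for s in self.subjects:
            if s.data.ndim != 2 or s.data.shape[1] != c:
                raise ValueError(
                    f"subject {s.subject_id}: data shape {s.data.shape} "
                    f"does not match {c} channels"
                )
            if s.data.shape[0] < 2:
                raise ValueError(f"subject {s.subject_id}: fewer than 2 time points")
            if not np.all(np.isfinite(s.data)):
                raise ValueError(f"subject {s.subject_id}: non-finite values")
            var = s.data.var(axis=0)
            if np.any(var == 0):
                ch = self.channel_labels[int(np.argmin(var))]
                raise ValueError(
                    f"subject {s.subject_id}: channel {ch!r} has zero variance"
                )

    def groups(self) -> list:
        seen = []
        for s in self.subjects:
            if s.group not in seen:
                seen.append(s.group)
        return seen


# ---------------------------------------------------------------------------
# Pair vectorization: row-major strict lower triangle, fixed package-wide.
# ---------------------------------------------------------------------------

def pair_indices(n_channels: int):
    """Row/column indices of the strict lower triangle in row-major order."""
    return np.tril_indices(n_channels, k=-1)


def pair_labels(channel_labels) -> list:
    rows, cols = pair_indices(len(channel_labels))
    return [f"{channel_labels[i]}--{channel_labels[j]}" for i, j in zip(rows, cols)]


def vectorize_matrix(mat: np.ndarray) -> np.ndarray:
    """Extract the strict lower triangle of a square matrix as a vector."""
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {mat.shape}")
    return mat[pair_indices(mat.shape[0])]


def matrix_from_pairs(vec: np.ndarray, n_channels: int) -> np.ndarray:
    """Rebuild a symmetric zero-diagonal matrix from a pair vector."""
    vec = np.asarray(vec, dtype=float)
    expected = n_channels * (n_channels - 1) // 2
    if vec.shape != (expected,):
        raise ValueError(f"expected {expected} pairs, got {vec.shape}")
    mat = np.zeros((n_channels, n_channels))
    rows, cols = pair_indices(n_channels)
    mat[rows, cols] = vec
    mat[cols, rows] = vec
    return mat


# ---------------------------------------------------------------------------
# Correlation and Fisher transform
# ---------------------------------------------------------------------------

def pearson_matrix(ts: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of the columns of a ``(T, C)`` array.

    Raises if any column is constant (the correlation is undefined there);
    the offending channel index is named in the error.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError(f"expected a 2-D time-by-channel array, got {ts.ndim}-D")
    t, _ = ts.shape
    if t < 3:
        raise ValueError(f"need at least 3 time points, got {t}")
    sd = ts.std(axis=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"constant channel(s) at column index {bad.tolist()}")
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def fisher_z(r, eps: float = FISHER_EPS):
    """Fisher z-transform ``atanh(r)`` with |r| clipped to ``1 - eps``.

    Works element-wise on arrays; odd and strictly increasing on (-1, 1).
    """
    r = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite correlation input to fisher_z")
    z = np.arctanh(np.clip(r, -1.0 + eps, 1.0 - eps))
    return z if z.ndim else float(z)


def sfnc(panel: TimeSeriesPanel, detrend: bool = False) -> list:
    """Per-subject static FNC: Fisher-z correlation matrices, zero diagonal.

    ``detrend`` removes a linear trend from each channel before correlating
    (off by default). Returns one ``(C, C)`` z-matrix per subject, in panel
    order.
    """
    panel.validate()
    out = []
    for s in panel.subjects:
        data = signal.detrend(s.data, axis=0) if detrend else s.data
        z = fisher_z(pearson_matrix(data))
        np.fill_diagonal(z, 0.0)
        out.append(z)
    return out
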