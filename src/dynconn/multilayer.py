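"""Multilayer modularity over time-ordered connectivity layers and
per-node network switching rates.

The quality function is the standard multilayer modularity with uniform
ordinal interlayer coupling:

    Q = (1/2mu) sum_{ijlr} [ (A_ijl - gamma k_il k_jl / 2m_l) delta_lr
                             + delta_ij omega 1{|l-r|=1} ] delta(g_il, g_jr)

where ``A_ijl`` is the weight of edge (i, j) in layer l, ``k_il`` the
strength of node i in layer l, ``m_l`` the total edge weight of layer l,
``gamma`` the resolution, ``omega`` the coupling between the same node in
adjacent layers, and ``mu`` the total edge weight plus total ordinal
coupling. Optimization uses an iterative ordinal Louvain scheme: greedy
moves over (node, layer) units with coupling-aware gains, followed by
aggregation and moves on the aggregated quality matrix, iterated to a local
optimum; the best of ``n_repeats`` randomized restarts is kept.

A node's switching rate is the fraction of adjacent-layer transitions at
which its community label changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_GAIN_TOL = 1e-12


@dataclass
class LayeredNetwork:
    """Time-ordered stack of symmetric nonnegative weight matrices."""

    layers: np.ndarray  # (L, N, N)
    node_labels: list = None
    node_networks: list = None

    def __post_init__(self):
        self.layers = np.asarray(self.layers, dtype=float)
        if self.layers.ndim != 3 or self.layers.shape[1] != self.layers.shape[2]:
            raise ValueError(
                f"layers must be (L, N, N), got shape {self.layers.shape}"
            )
        if np.any(self.layers < 0):
            raise ValueError("layer weights must be nonnegative")
        if not np.allclose(self.layers, np.swapaxes(self.layers, 1, 2)):
            raise ValueError("every layer must be symmetric")
        if np.any(np.abs(np.diagonal(self.layers, axis1=1, axis2=2)) > 0):
            raise ValueError("layers must have zero diagonal")
        if self.node_labels is None:
            self.node_labels = [f"node{i + 1:03d}" for i in range(self.n_nodes)]

    @property
    def n_layers(self) -> int:
        return self.layers.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.layers.shape[1]


@dataclass
class MultilayerParams:
    """Resolution, ordinal coupling, restarts and seed."""

    gamma: float = 1.1
    omega: float = 0.5
    n_repeats: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class Partition:
    """Node-by-layer community labels (1-based) and their quality."""

    labels: np.ndarray  # (N, L) int
    quality: float


def layered_from_windows(r_windows: np.ndarray, negative: str = "zero",
                         node_labels=None, node_networks=None) -> LayeredNetwork:
    """Build a layered network from windowed correlation matrices.

    Negative correlations are set to 0 by default (the quality function
    assumes nonnegative weights); ``negative="abs"`` takes magnitudes.
    """
    if negative not in ("zero", "abs"):
        raise ValueError(f"unknown negative-weight policy {negative!r}")
    w = np.abs(r_windows) if negative == "abs" else np.clip(r_windows, 0.0, None)
    w = w.copy()
    for layer in w:
        np.fill_diagonal(layer, 0.0)
    return LayeredNetwork(w, node_labels=node_labels, node_networks=node_networks)


# ---------------------------------------------------------------------------
# Quality function
# ---------------------------------------------------------------------------

def _modularity_blocks(net: LayeredNetwork, gamma: float) -> list:
    """Per-layer quality blocks ``B_l = A_l - gamma k k^T / 2m_l``.

    A layer with zero total weight contributes no null-model term.
    """
    blocks = []
    for idx, a in enumerate(net.layers):
        two_m = a.sum()
        if two_m == 0:
            logger.warning("layer %d has zero total weight; null term set to 0", idx)
            blocks.append(a.copy())
        else:
            k = a.sum(axis=1)
            blocks.append(a - gamma * np.outer(k, k) / two_m)
    return blocks


def _total_coupling_norm(net: LayeredNetwork, omega: float) -> float:
    """2*mu: total (doubled) edge weight plus total (doubled) coupling."""
    return float(net.layers.sum()) + 2.0 * omega * net.n_nodes * (net.n_layers - 1)


def multilayer_modularity(partition, net: LayeredNetwork,
                          params: MultilayerParams) -> float:
    """Evaluate Q for a node-by-layer partition."""
    labels = partition.labels if isinstance(partition, Partition) else partition
    labels = np.asarray(labels)
    if labels.shape != (net.n_nodes, net.n_layers):
        raise ValueError(
            f"partition shape {labels.shape} does not cover the network "
            f"({net.n_nodes} nodes x {net.n_layers} layers)"
        )
    blocks = _modularity_blocks(net, params.gamma)
    total = 0.0
    for l, b in enumerate(blocks):
        same = labels[:, l][:, None] == labels[:, l][None, :]
        total += b[same].sum()
    if net.n_layers > 1:
        coupl = (labels[:, 1:] == labels[:, :-1]).sum()
        total += 2.0 * params.omega * coupl
    two_mu = _total_coupling_norm(net, params.omega)
    if two_mu == 0:
        return 0.0
    return float(total / two_mu)


def modularity_q(adjacency: np.ndarray, labels: np.ndarray,
                 gamma: float = 1.0) -> float:
    """Single-layer Newman-Girvan modularity (with resolution gamma)."""
    net = LayeredNetwork(np.asarray(adjacency, dtype=float)[None])
    return multilayer_modularity(np.asarray(labels)[:, None], net,
                                 MultilayerParams(gamma=gamma, omega=0.0))


# ---------------------------------------------------------------------------
# Iterative ordinal Louvain
# ---------------------------------------------------------------------------

def _structured_moves(g, blocks, omega, rng):
    """Greedy unit moves on the (node, layer) representation.

    ``g`` is the (N, L) label array, modified in place. Returns True if any
    move was made.
    """
    n, L = g.shape
    size = n * L
    improved = False
    while True:
        moved = 0
        for unit in rng.permutation(size):
            i, l = divmod(int(unit), L)
            cur = g[i, l]
            b_row = blocks[l][i]
            s = np.bincount(g[:, l], weights=b_row, minlength=size)
            candidates = set(np.unique(g[:, l]).tolist())
            adj = []
            if l > 0:
                adj.append(g[i, l - 1])
                candidates.add(g[i, l - 1])
            if l < L - 1:
                adj.append(g[i, l + 1])
                candidates.add(g[i, l + 1])
            base = s[cur] - b_row[i] + omega * sum(1 for a in adj if a == cur)
            best_c, best_gain = cur, 0.0
            for c in candidates:
                if c == cur:
                    continue
                gain = s[c] + omega * sum(1 for a in adj if a == c) - base
                if gain > best_gain + _GAIN_TOL:
                    best_gain, best_c = gain, c
            if best_c != cur:
                g[i, l] = best_c
                moved += 1
        if moved == 0:
            break
        improved = True
    return improved


def _aggregate(g, blocks, omega):
    """Collapse communities: dense quality matrix between communities."""
    comms, compressed = np.unique(g, return_inverse=True)
    compressed = compressed.reshape(g.shape)
    k = len(comms)
    n, L = g.shape
    b_agg = np.zeros((k, k))
    for l in range(L):
        s = np.zeros((n, k))
        s[np.arange(n), compressed[:, l]] = 1.0
        b_agg += s.T @ blocks[l] @ s
    for l in range(L - 1):
        np.add.at(b_agg, (compressed[:, l], compressed[:, l + 1]), omega)
        np.add.at(b_agg, (compressed[:, l + 1], compressed[:, l]), omega)
    return compressed, b_agg


def _dense_moves(b_agg, rng):
    """Greedy Louvain moves on an aggregated quality matrix."""
    k = b_agg.shape[0]
    h = np.arange(k)
    improved = False
    while True:
        moved = 0
        for u in rng.permutation(k):
            cur = h[u]
            s = np.bincount(h, weights=b_agg[u], minlength=k)
            base = s[cur] - b_agg[u, u]
            occupied = np.unique(h)
            gains = s[occupied] - base
            gains[occupied == cur] = 0.0
            best = int(np.argmax(gains))
            if gains[best] > _GAIN_TOL:
                h[u] = occupied[best]
                moved += 1
        if moved == 0:
            break
        improved = True
    return h, improved


def _louvain_once(net, params, rng, max_outer=100):
    blocks = _modularity_blocks(net, params.gamma)
    n, L = net.n_nodes, net.n_layers
    g = np.arange(n * L).reshape(n, L)
    for _ in range(max_outer):
        moved_units = _structured_moves(g, blocks, params.omega, rng)
        compressed, b_agg = _aggregate(g, blocks, params.omega)
        h, merged = _dense_moves(b_agg, rng)
        g = h[compressed]
        if not (moved_units or merged):
            break
    return g


def canonicalize_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel communities 1, 2, ... in order of first occurrence
    (row-major over the node-by-layer array)."""
    flat = np.asarray(labels).ravel()
    _, first = np.unique(flat, return_index=True)
    order = flat[np.sort(first)]
    remap = {old: new + 1 for new, old in enumerate(order)}
    return np.vectorize(remap.__getitem__)(labels)


def louvain_multilayer(net: LayeredNetwork, params: MultilayerParams) -> Partition:
    """Best-of-restarts iterative ordinal Louvain optimization."""
    master = np.random.default_rng(params.seed)
    best_labels, best_q = None, -np.inf
    for _ in range(params.n_repeats):
        rng = np.random.default_rng(master.integers(2**31))
        g = _louvain_once(net, params, rng)
        q = multilayer_modularity(g, net, params)
        if q > best_q:
            best_q, best_labels = q, g
    labels = canonicalize_labels(best_labels)
    return Partition(labels=labels, quality=best_q)


# ---------------------------------------------------------------------------
# Switching rates
# ---------------------------------------------------------------------------

@dataclass
class SwitchingRates:
    """Per-node switching rates with optional network-level means."""

    node_rates: np.ndarray
    network_rates: dict = field(default_factory=dict)
    node_sd: np.ndarray = None


def switching_rate(partition, node_networks=None) -> SwitchingRates:
    """Fraction of adjacent-layer transitions at which a node changes
    community; optional mean per network group."""
    labels = partition.labels if isinstance(partition, Partition) else partition
    labels = np.asarray(labels)
    if labels.ndim != 2 or labels.shape[1] < 2:
        raise ValueError("switching rate needs at least 2 layers")
    changes = (labels[:, 1:] != labels[:, :-1]).sum(axis=1)
    rates = changes / (labels.shape[1] - 1)
    network_rates = {}
    if node_networks is not None:
        for name in dict.fromkeys(node_networks):
            members = [i for i, n in enumerate(node_networks) if n == name]
            network_rates[name] = float(rates[members].mean())
    return SwitchingRates(node_rates=rates, network_rates=network_rates)


def consensus_switching(net: LayeredNetwork, params: MultilayerParams,
                        node_networks=None) -> SwitchingRates:
    """Mean per-node switching rate over independent optimizer runs.

    Runs the optimizer ``params.n_repeats`` times with distinct seeds (one
    run each, not best-of) and averages the node rates; the across-run SD is
    reported alongside.
    """
    master = np.random.default_rng(params.seed)
    single = MultilayerParams(gamma=params.gamma, omega=params.omega,
                              n_repeats=1, seed=0)
    all_rates = []
    for _ in range(params.n_repeats):
        single.seed = int(master.integers(2**31))
        part = louvain_multilayer(net, single)
        all_rates.append(switching_rate(part).node_rates)
    all_rates = np.asarray(all_rates)
    mean_rates = all_rates.mean(axis=0)
    network_rates = {}
    if node_networks is not None:
        for name in dict.fromkeys(node_networks):
            members = [i for i, n in enumerate(node_networks) if n == name]
            network_rates[name] = float(mean_rates[members].mean())
    return SwitchingRates(
        node_rates=mean_rates,
        network_rates=network_rates,
        node_sd=all_rates.std(axis=0, ddof=0),
    )
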