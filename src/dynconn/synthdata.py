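"""Synthetic resting-state cohorts and planted-truth layered networks.

The generator emulates the statistical structure the downstream analysis
assumes, without simulating raw BOLD volumes: each subject's channel time
courses follow a hidden-Markov model over covariance "states" (zero-mean
multivariate normal emissions whose covariance is set by the active state),
group differences enter as Fisher-z shifts on selected channel pairs, and
demographic covariates are drawn from distributions matching a typical
age-related hearing-loss cohort (two groups of 66 and 54, ages 50-80,
~11 years of education, mean framewise displacement around 0.23 mm).

For the multilayer stage, :func:`make_layered_network` plants a per-layer
stochastic block model in which designated "switcher" nodes change module
at configured layers, giving a known ground-truth switching pattern.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fnc_static import NETWORKS, Subject, TimeSeriesPanel, fisher_z

#: Default channel -> network map for the 13-component layout.
DEFAULT_COMPONENT_NETWORKS = (
    "CEN", "CEN", "CEN",
    "DMN", "DMN",
    "AUN", "AUN",
    "SN",
    "VN", "VN", "VN",
    "SMN", "SMN",
)

PD_EIGEN_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class CovariateModel:
    """Sampling distributions for subject covariates.

    Defaults mirror the margins of a mild age-related hearing-loss cohort:
    age ~ N(58.6, 6.7) truncated to [50, 80] years, education ~ N(10.9, 1.7)
    years, gender ~ Bernoulli(0.525) (coded 1 = female), mean framewise
    displacement ~ N(0.23, 0.07) mm truncated at 0.
    """

    age_mean: float = 58.6
    age_sd: float = 6.7
    age_range: tuple = (50.0, 80.0)
    education_mean: float = 10.9
    education_sd: float = 1.7
    gender_p: float = 0.525
    mean_fd_mean: float = 0.23
    mean_fd_sd: float = 0.07

    def sample(self, rng: np.random.Generator) -> dict:
        lo, hi = self.age_range
        age = float(np.clip(rng.normal(self.age_mean, self.age_sd), lo, hi))
        return {
            "age": age,
            "gender": int(rng.random() < self.gender_p),
            "education": float(rng.normal(self.education_mean, self.education_sd)),
            "mean_fd": float(max(0.0, rng.normal(self.mean_fd_mean, self.mean_fd_sd))),
        }


@dataclass
class GroupEffect:
    """A Fisher-z connectivity shift on one channel pair in one group."""

    pair: tuple
    shifts: dict  # group label -> z shift


@dataclass
class SimConfig:
    """Full specification of a synthetic cohort.

    ``n_per_group`` maps group labels to sizes (default 66 patients / 54
    controls); ``transition_matrix`` is the row-stochastic Markov kernel over
    the covariance states; ``state_covariances`` holds one symmetric
    positive-definite ``(C, C)`` matrix per state.
    """

    n_per_group: dict = None
    n_timepoints: int = 234
    tr_seconds: float = 2.0
    n_components: int = 13
    n_nodes: int = 90
    n_states: int = 6
    transition_matrix: np.ndarray = None
    state_covariances: np.ndarray = None
    group_effects: list = field(default_factory=list)
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group is None:
            self.n_per_group = {"patient": 66, "control": 54}
        if any(n < 1 for n in self.n_per_group.values()):
            raise ValueError("group sizes must be >= 1")
        if self.n_timepoints < 1 or self.n_states < 1:
            raise ValueError("n_timepoints and n_states must be >= 1")
        if self.transition_matrix is None:
            self.transition_matrix = sticky_transition_matrix(self.n_states)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        validate_transition_matrix(self.transition_matrix)
        if self.transition_matrix.shape[0] != self.n_states:
            raise ValueError("transition_matrix size must equal n_states")
        if self.state_covariances is None:
            self.state_covariances = default_state_covariances(
                self.n_components, self.n_states, seed=self.seed
            )
        self.state_covariances = np.asarray(self.state_covariances, dtype=float)
        expected = (self.n_states, self.n_components, self.n_components)
        if self.state_covariances.shape != expected:
            raise ValueError(
                f"state_covariances shape {self.state_covariances.shape} "
                f"!= {expected}"
            )
        for s, cov in enumerate(self.state_covariances):
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValueError(f"state {s + 1} covariance is not symmetric")
            if np.linalg.eigvalsh(cov).min() <= 0:
                raise ValueError(f"state {s + 1} covariance is not positive definite")


@dataclass
class SimulationTruth:
    """Planted ground truth recorded alongside a synthetic dataset."""

    state_sequences: list = None
    stationary_distribution: np.ndarray = None
    planted_partitions: np.ndarray = None
    switcher_nodes: list = None


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def validate_transition_matrix(p: np.ndarray) -> None:
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError(f"transition matrix must be square, got shape {p.shape}")
    if np.any(p < 0):
        raise ValueError("transition matrix entries must be >= 0")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("transition matrix rows must sum to 1")


def sticky_transition_matrix(k: int, stay: float = 0.95) -> np.ndarray:
    """Uniform sticky Markov kernel: stay with probability ``stay``.

    The default dwell of 1/(1-stay) = 20 TRs (40 s at TR = 2 s) matches the
    dwell-time scale commonly reported for resting-state connectivity states.
    """
    if k == 1:
        return np.ones((1, 1))
    p = np.full((k, k), (1.0 - stay) / (k - 1))
    np.fill_diagonal(p, stay)
    return p


def stationary_distribution(p: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    validate_transition_matrix(p)
    vals, vecs = np.linalg.eig(p.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def sample_state_sequence(
    transition_matrix: np.ndarray, length: int, seed
) -> np.ndarray:
    """Markov-chain realization with 1-based labels.

    The initial state is drawn from the stationary distribution; ``seed``
    may be an int or a :class:`numpy.random.Generator`.
    """
    p = np.asarray(transition_matrix, dtype=float)
    validate_transition_matrix(p)
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = p.shape[0]
    pi = stationary_distribution(p)
    seq = np.empty(length, dtype=int)
    state = rng.choice(k, p=pi)
    seq[0] = state
    cum = p.cumsum(axis=1)
    draws = rng.random(length - 1)
    for t in range(1, length):
        state = int(np.searchsorted(cum[state], draws[t - 1], side="right"))
        state = min(state, k - 1)
        seq[t] = state
    return seq + 1


def default_state_covariances(
    n_channels: int, n_states: int, strength: float = 0.8, seed: int = 0
) -> np.ndarray:
    """Well-separated state correlation matrices from random sign factors.

    State ``s`` has correlation ``+/- strength`` between channels i, j with
    sign ``u_i u_j`` for a random sign vector ``u`` (a rank-one factor model
    ``I + lambda u u^T`` rescaled to unit diagonal, which is positive
    definite for any lambda > 0). Distinct sign patterns give states that
    differ by large Fisher-z distances on roughly half of all pairs.
    """
    if not 0 < strength < 1:
        raise ValueError("strength must be in (0, 1)")
    rng = np.random.default_rng(seed)
    lam = strength / (1.0 - strength)
    covs = np.empty((n_states, n_channels, n_channels))
    seen = set()
    for s in range(n_states):
        while True:
            u = rng.choice([-1.0, 1.0], size=n_channels)
            key = tuple(u * u[0])  # u and -u give the same correlation pattern
            if key not in seen:
                seen.add(key)
                break
        cov = np.eye(n_channels) + lam * np.outer(u, u)
        d = 1.0 / np.sqrt(np.diag(cov))
        covs[s] = cov * np.outer(d, d)
    return covs


def nearest_positive_definite(mat: np.ndarray, floor: float = PD_EIGEN_FLOOR):
    """Project a symmetric matrix to the PD cone by eigenvalue clipping."""
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() > floor:
        return sym
    vals = np.clip(vals, floor, None)
    return (vecs * vals) @ vecs.T


def apply_group_effects(
    covariances: np.ndarray, effects: list, group: str
) -> np.ndarray:
    """Return state covariances with the group's Fisher-z pair shifts applied.

    The shifted correlation is ``tanh(atanh(r) + dz)``; the resulting matrix
    is projected back to the nearest positive-definite matrix (eigenvalue
    floor 1e-6) and rescaled to unit diagonal.
    """
    out = covariances.copy()
    for effect in effects:
        dz = effect.shifts.get(group, 0.0)
        if dz == 0.0:
            continue
        i, j = effect.pair
        for s in range(out.shape[0]):
            cov = out[s]
            scale = np.sqrt(cov[i, i] * cov[j, j])
            r_new = np.tanh(fisher_z(cov[i, j] / scale) + dz)
            if not np.isfinite(r_new) or abs(r_new) >= 1.0:
                raise ValueError(
                    f"group effect on pair {effect.pair} with shift {dz} "
                    f"yields invalid correlation {r_new}"
                )
            cov[i, j] = cov[j, i] = r_new * scale
            fixed = nearest_positive_definite(cov)
            d = np.sqrt(np.diag(cov) / np.diag(fixed))
            out[s] = fixed * np.outer(d, d)
            if np.linalg.eigvalsh(out[s]).min() <= 0:
                raise ValueError(
                    f"group effect on pair {effect.pair} with shift {dz} "
                    "produces a non-positive-definite covariance"
                )
    return out


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _emit_series(seq, chols, n_channels, rng):
    data = np.empty((len(seq), n_channels))
    noise = rng.standard_normal((len(seq), n_channels))
    for t, state in enumerate(seq):
        data[t] = chols[state - 1] @ noise[t]
    return data


def make_cohort(config: SimConfig):
    """Generate a synthetic cohort and its ground truth.

    Each subject gets an independent pseudorandom stream derived from
    ``(config.seed, subject_index)``, so cohorts are reproducible and stable
    under subject reordering. Returns ``(TimeSeriesPanel, SimulationTruth)``.
    """
    c = config.n_components
    if c == 13:
        networks = list(DEFAULT_COMPONENT_NETWORKS)
        labels = [f"IC{k + 1:02d}_{networks[k]}" for k in range(c)]
    else:
        networks = [NETWORKS[k % len(NETWORKS)] for k in range(c)]
        labels = [f"ch{k + 1:02d}_{networks[k]}" for k in range(c)]

    group_chols = {}
    for group in config.n_per_group:
        covs = apply_group_effects(
            config.state_covariances, config.group_effects, group
        )
        group_chols[group] = [np.linalg.cholesky(cov) for cov in covs]

    subjects, sequences = [], []
    index = 0
    for group, n in config.n_per_group.items():
        for _ in range(n):
            rng = np.random.default_rng([config.seed, index])
            seq = sample_state_sequence(
                config.transition_matrix, config.n_timepoints, rng
            )
            data = _emit_series(seq, group_chols[group], c, rng)
            covariates = config.covariate_model.sample(rng)
            subjects.append(
                Subject(f"sub-{index + 1:04d}", data, group, covariates)
            )
            sequences.append(seq)
            index += 1

    panel = TimeSeriesPanel(subjects, labels, networks, config.tr_seconds)
    truth = SimulationTruth(
        state_sequences=sequences,
        stationary_distribution=stationary_distribution(config.transition_matrix),
    )
    return panel, truth


def window_state_labels(sequence: np.ndarray, width: int, taper: np.ndarray,
                        step: int = 1) -> np.ndarray:
    """True per-window state: the state carrying the most taper weight."""
    sequence = np.asarray(sequence)
    w = (len(sequence) - width) // step + 1
    k = int(sequence.max())
    out = np.empty(w, dtype=int)
    for idx in range(w):
        chunk = sequence[idx * step:idx * step + width]
        weight = np.bincount(chunk, weights=taper, minlength=k + 1)
        out[idx] = int(np.argmax(weight))
    return out


# ---------------------------------------------------------------------------
# Planted layered networks
# ---------------------------------------------------------------------------

def make_layered_network(
    n_nodes: int,
    n_layers: int,
    module_spec,
    switcher_nodes,
    switch_layers,
    p_in: float,
    p_out: float,
    seed: int = 0,
):
    """Per-layer stochastic block model with planted community switches.

    ``module_spec`` assigns each node a base module label. Non-switcher
    nodes keep their module across all layers; each node in
    ``switcher_nodes`` moves to the next module (cyclically) at every layer
    in ``switch_layers`` (1-based, must lie in [2..n_layers]). Edges within
    a module appear with probability ``p_in``, between modules with
    ``p_out``; weights are binary. Returns a ``(layers, truth)`` pair where
    ``layers`` is an ``(L, N, N)`` stack and ``truth`` records the planted
    node-by-layer partition.
    """
    if not 0 <= p_out < p_in <= 1:
        raise ValueError(
            f"need p_in > p_out with both in [0, 1]; got p_in={p_in}, p_out={p_out}"
        )
    base = np.asarray(module_spec, dtype=int)
    if base.shape != (n_nodes,):
        raise ValueError("module_spec must assign one module per node")
    switch_layers = sorted(set(switch_layers))
    if any(l < 2 or l > n_layers for l in switch_layers):
        raise ValueError("switch_layers must lie in [2..n_layers]")
    switchers = sorted(set(switcher_nodes))
    n_modules = int(base.max()) + 1

    partitions = np.empty((n_nodes, n_layers), dtype=int)
    current = base.copy()
    for layer in range(n_layers):
        if (layer + 1) in switch_layers:
            for node in switchers:
                current[node] = (current[node] + 1) % n_modules
        partitions[:, layer] = current

    rng = np.random.default_rng(seed)
    layers = np.zeros((n_layers, n_nodes, n_nodes))
    iu, ju = np.triu_indices(n_nodes, k=1)
    for layer in range(n_layers):
        same = partitions[iu, layer] == partitions[ju, layer]
        prob = np.where(same, p_in, p_out)
        edges = (rng.random(len(iu)) < prob).astype(float)
        layers[layer][iu, ju] = edges
        layers[layer][ju, iu] = edges
    truth = SimulationTruth(
        planted_partitions=partitions, switcher_nodes=switchers
    )
    return layers, truth


# ---------------------------------------------------------------------------
# On-disk format (TSV matrices + manifest TSV + truth JSON)
# ---------------------------------------------------------------------------

def write_cohort(panel: TimeSeriesPanel, truth: SimulationTruth, outdir) -> Path:
    """Write per-subject TSVs, a manifest TSV and a truth JSON; returns the
    manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = "\t".join(panel.channel_labels)
    manifest_rows = []
    for s in panel.subjects:
        fname = f"{s.subject_id}.tsv"
        np.savetxt(outdir / fname, s.data, delimiter="\t", header=header,
                   comments="")
        manifest_rows.append(
            [s.subject_id, s.group,
             f"{s.covariates['age']:.3f}", str(s.covariates["gender"]),
             f"{s.covariates['education']:.3f}",
             f"{s.covariates['mean_fd']:.4f}", fname]
        )
    manifest = outdir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("subject_id\tgroup\tage\tgender\teducation\tmean_fd\tfile\n")
        for row in manifest_rows:
            fh.write("\t".join(row) + "\n")
    meta = {
        "tr_seconds": panel.tr_seconds,
        "channel_networks": list(panel.channel_networks),
        "stationary_distribution":
            None if truth.stationary_distribution is None
            else truth.stationary_distribution.tolist(),
        "state_sequences":
            None if truth.state_sequences is None
            else [seq.tolist() for seq in truth.state_sequences],
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(meta, fh)
    return manifest
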