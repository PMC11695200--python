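"""Planted-truth recovery experiments and calibration benchmarks.

These routines exercise the full pipeline against the synthetic generator's
ground truth: brain-state recovery from sliding-window connectivity,
switching-rate recovery on planted layered networks, optimizer optimality on
exhaustively enumerable instances, limit behaviors of the multilayer
quality, and the statistical calibration of the inference layer. They are
used by the test suite and the reproduction script; each takes an explicit
seed and returns plain numbers.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score, confusion_matrix

from . import fnc_dynamic, fnc_static, multilayer, stats, synthdata, topology


# ---------------------------------------------------------------------------
# Brain-state recovery
# ---------------------------------------------------------------------------

def well_separated_state_config(seed: int, n_per_group=(10, 10),
                                n_timepoints: int = 234) -> synthdata.SimConfig:
    """Cohort whose six covariance states are strongly separated.

    Rank-one sign-factor states with correlation magnitude 0.9 and a sticky
    chain (stay probability 0.99, mean dwell 100 TRs): in windows-by-pairs
    Fisher-z space the minimum centroid separation is about five times the
    within-state dispersion, the regime in which window labels are well
    defined.
    """
    covs = synthdata.default_state_covariances(13, 6, strength=0.9, seed=seed)
    return synthdata.SimConfig(
        n_per_group={"patient": n_per_group[0], "control": n_per_group[1]},
        n_timepoints=n_timepoints,
        transition_matrix=synthdata.sticky_transition_matrix(6, stay=0.99),
        state_covariances=covs,
        seed=seed,
    )


def state_recovery_experiment(seed: int, n_per_group=(10, 10)):
    """Recover planted states end to end; returns a result dict.

    Windows are labeled with the true state carrying the most taper weight;
    recovered states are matched one-to-one to true states by maximum
    confusion-matrix overlap before comparing fraction times.
    """
    config = well_separated_state_config(seed, n_per_group)
    panel, truth = synthdata.make_cohort(config)
    spec = fnc_dynamic.WindowSpec()
    arrays = fnc_dynamic.dfnc(panel, spec)
    pooled = np.vstack([a.pair_matrix() for a in arrays])
    true_windows = np.concatenate([
        synthdata.window_state_labels(seq, spec.width, spec.taper)
        for seq in truth.state_sequences
    ])
    model = fnc_dynamic.cluster_states(pooled, k=6, seed=seed, n_restarts=20)
    ari = adjusted_rand_score(true_windows, model.labels)

    cm = confusion_matrix(true_windows, model.labels, labels=range(1, 7))
    rows, cols = linear_sum_assignment(-cm)
    remap = {cols[i] + 1: rows[i] + 1 for i in range(6)}
    counts = [a.n_windows for a in arrays]
    per_subject_err = []
    rec_ft_sum = np.zeros(6)
    true_ft_sum = np.zeros(6)
    for rec, tru in zip(fnc_dynamic.split_labels(model.labels, counts),
                        fnc_dynamic.split_labels(true_windows, counts)):
        mapped = np.array([remap[lab] for lab in rec])
        ft_rec = np.bincount(mapped, minlength=7)[1:] / len(rec)
        ft_true = np.bincount(tru, minlength=7)[1:] / len(tru)
        per_subject_err.append(np.abs(ft_rec - ft_true).max())
        rec_ft_sum += ft_rec
        true_ft_sum += ft_true
    n_subj = len(counts)
    return {
        "ari": float(ari),
        "mean_ft_error": float(np.mean(per_subject_err)),
        "max_ft_error": float(np.max(per_subject_err)),
        "cohort_ft_error": float(
            np.abs(rec_ft_sum / n_subj - true_ft_sum / n_subj).max()
        ),
        "n_windows": int(sum(counts)),
    }


# ---------------------------------------------------------------------------
# Switching-rate recovery
# ---------------------------------------------------------------------------

def switching_recovery_experiment(seed: int, n_nodes: int = 20,
                                  n_layers: int = 10, n_switchers: int = 4,
                                  p_in: float = 0.9, p_out: float = 0.05,
                                  n_repeats: int = 10):
    """Planted-switcher recovery; returns (switcher mean, non-switcher mean)."""
    half = n_nodes // 2
    layers, truth = synthdata.make_layered_network(
        n_nodes, n_layers, [0] * half + [1] * (n_nodes - half),
        list(range(n_switchers)), [n_layers // 2 + 1], p_in, p_out, seed=seed,
    )
    net = multilayer.LayeredNetwork(layers)
    params = multilayer.MultilayerParams(n_repeats=n_repeats, seed=seed)
    rates = multilayer.consensus_switching(net, params)
    switchers = rates.node_rates[truth.switcher_nodes].mean()
    others = np.delete(rates.node_rates, truth.switcher_nodes).mean()
    return float(switchers), float(others)


# ---------------------------------------------------------------------------
# Oracle comparisons
# ---------------------------------------------------------------------------

def efficiency_vs_networkx(seed: int, n_graphs: int = 50,
                           max_nodes: int = 12) -> float:
    """Max |difference| of both efficiencies vs networkx on random graphs."""
    import networkx as nx

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_graphs):
        n = int(rng.integers(4, max_nodes + 1))
        a = np.triu(rng.random((n, n)) < rng.uniform(0.15, 0.7), 1)
        adj = a | a.T
        g = nx.from_numpy_array(adj.astype(int))
        worst = max(
            worst,
            abs(topology.global_efficiency(adj) - nx.global_efficiency(g)),
            abs(topology.local_efficiency(adj) - nx.local_efficiency(g)),
        )
    return float(worst)


def _set_partitions(n):
    """All set partitions of range(n) as label arrays."""
    if n == 0:
        yield np.empty(0, dtype=int)
        return
    labels = np.zeros(n, dtype=int)

    def rec(i, n_used):
        if i == n:
            yield labels.copy()
            return
        for c in range(n_used + 1):
            labels[i] = c
            yield from rec(i + 1, max(n_used, c + 1))

    yield from rec(1, 1)


def louvain_exhaustive_experiment(seed: int, n_instances: int = 30,
                                  n_nodes: int = 4, n_layers: int = 2):
    """Fraction of random instances where the optimizer attains the
    exhaustive-search optimum over all node-layer partitions."""
    parts = [p.reshape(n_nodes, n_layers)
             for p in _set_partitions(n_nodes * n_layers)]
    rng = np.random.default_rng(seed)
    hits = 0
    for instance in range(n_instances):
        layers = np.zeros((n_layers, n_nodes, n_nodes))
        for l in range(n_layers):
            w = np.triu((rng.random((n_nodes, n_nodes)) < 0.6)
                        * rng.random((n_nodes, n_nodes)), 1)
            layers[l] = w + w.T
        net = multilayer.LayeredNetwork(layers)
        params = multilayer.MultilayerParams(
            gamma=1.0, omega=0.5, n_repeats=10, seed=int(rng.integers(2**31))
        )
        found = multilayer.louvain_multilayer(net, params).quality
        best = max(multilayer.multilayer_modularity(p, net, params)
                   for p in parts)
        hits += found >= best - 1e-10
    return hits / n_instances


# ---------------------------------------------------------------------------
# Limit behaviors
# ---------------------------------------------------------------------------

def omega_decoupling_error(seed: int) -> float:
    """|Q_multi(omega=0) - weighted sum of per-layer Q| on a random instance."""
    rng = np.random.default_rng(seed)
    layers = np.zeros((3, 6, 6))
    for l in range(3):
        w = np.triu(rng.random((6, 6)), 1)
        layers[l] = w + w.T
    net = multilayer.LayeredNetwork(layers)
    labels = rng.integers(1, 4, size=(6, 3))
    params = multilayer.MultilayerParams(gamma=1.0, omega=0.0)
    q_multi = multilayer.multilayer_modularity(labels, net, params)
    q_layers = sum(
        multilayer.modularity_q(layers[l], labels[:, l]) * layers[l].sum()
        for l in range(3)
    ) / layers.sum()
    return float(abs(q_multi - q_layers))


def high_omega_max_switching(seed: int, n_seeds: int = 10,
                             omega: float = 1e3) -> float:
    """Maximum observed switching rate under overwhelming coupling."""
    worst = 0.0
    for offset in range(n_seeds):
        rng = np.random.default_rng(seed + offset)
        layers = np.zeros((4, 8, 8))
        for l in range(4):
            w = np.triu(rng.random((8, 8)) * (rng.random((8, 8)) < 0.5), 1)
            layers[l] = w + w.T
        net = multilayer.LayeredNetwork(layers)
        part = multilayer.louvain_multilayer(
            net, multilayer.MultilayerParams(omega=omega, n_repeats=3,
                                             seed=seed + offset)
        )
        worst = max(worst,
                    multilayer.switching_rate(part).node_rates.max())
    return float(worst)


def taper_uniform_deviation(width: int = 20) -> float:
    """Max |taper - 1/width| in the sigma -> 0 limit."""
    taper = fnc_dynamic.build_taper(width, 1e-6)
    return float(np.abs(taper - 1.0 / width).max())


# ---------------------------------------------------------------------------
# Inference calibration
# ---------------------------------------------------------------------------

def glm_type1_experiment(seed: int, n_repeats: int = 200,
                         n_per_group: int = 60, n_features: int = 10,
                         alpha: float = 0.05) -> float:
    """Empirical type-I error of the covariate-adjusted GLM under the null."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    group = np.r_[np.ones(n_per_group), np.zeros(n_per_group)]
    rejections = 0
    for _ in range(n_repeats):
        covs = np.column_stack([
            rng.normal(58, 7, n), rng.integers(0, 2, n), rng.normal(11, 2, n)
        ])
        y = rng.normal(size=(n, n_features))
        _, _, _, p = stats.glm_group_test(y, group, covs)
        rejections += int((p < alpha).sum())
    return rejections / (n_repeats * n_features)


def bh_agreement_experiment(seed: int, n_vectors: int = 1000) -> float:
    """Fraction of random p-vectors where the BH mask matches the literal
    step-up definition."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_vectors):
        p = rng.random(int(rng.integers(1, 60)))
        _, mask = stats.bh_fdr(p, 0.05)
        m = len(p)
        order = np.argsort(p)
        cutoff = -1
        for i in range(m):
            if p[order[i]] <= (i + 1) * 0.05 / m:
                cutoff = i
        ref = np.zeros(m, dtype=bool)
        if cutoff >= 0:
            ref[order[:cutoff + 1]] = True
        agree += int(np.array_equal(mask, ref))
    return agree / n_vectors


def effect_detection_experiment(seed: int, n_repeats: int = 20,
                                n_per_group: int = 30, shift: float = 0.3,
                                pair=(4, 3)) -> float:
    """Power of the sFNC GLM + BH pipeline against an injected z-shift.

    Each repeat simulates a single-state cohort with a Fisher-z shift on one
    channel pair in the patient group, runs the full static-FNC contrast
    with covariate adjustment and FDR, and checks whether the shifted pair
    is flagged. Returns the detection rate.
    """
    import pandas as pd

    detected = 0
    for rep in range(n_repeats):
        covs = synthdata.default_state_covariances(13, 1, strength=0.3,
                                                   seed=seed + rep)
        config = synthdata.SimConfig(
            n_per_group={"patient": n_per_group, "control": n_per_group},
            n_timepoints=234, n_states=1, transition_matrix=np.ones((1, 1)),
            state_covariances=covs,
            group_effects=[synthdata.GroupEffect(pair=pair,
                                                 shifts={"patient": shift})],
            seed=seed + 1000 + rep,
        )
        panel, _ = synthdata.make_cohort(config)
        z = fnc_static.sfnc(panel)
        features = pd.DataFrame(
            np.array([fnc_static.vectorize_matrix(m) for m in z]),
            columns=fnc_static.pair_labels(panel.channel_labels),
        )
        group = np.array([1.0 if s.group == "patient" else 0.0
                          for s in panel.subjects])
        cov = np.column_stack([
            [s.covariates[k] for s in panel.subjects]
            for k in ("age", "gender", "education")
        ])
        table = stats.glm_table(features, group, cov)
        rows, cols = fnc_static.pair_indices(13)
        idx = next(k for k, (i, j) in enumerate(zip(rows, cols))
                   if (i, j) == pair)
        detected += bool(table.sig.iloc[idx])
    return detected / n_repeats
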