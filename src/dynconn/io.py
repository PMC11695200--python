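"""Formats, configuration and the pipeline driver.

Cohorts are exchanged as plain delimited matrices (one TSV per subject,
rows = time points, header row = channel labels) plus a manifest TSV with
group and covariates — the natural post-ICA interchange. All result tables
are CSV with a sidecar ``.schema.json`` declaring the column layout, and
every run directory carries a ``run_info.json`` stamped with the config
hash and seed so runs are reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fnc_dynamic, fnc_static, multilayer, stats, topology
from .fnc_static import NETWORKS, Subject, TimeSeriesPanel

logger = logging.getLogger(__name__)

ALL_STAGES = ("sfnc", "dfnc", "topology", "multilayer", "stats")

#: Frozen default profile: the analysis parameters of the study design
#: (20-TR Gaussian-tapered windows, six states, gamma 1.1 / omega 0.5,
#: BH-FDR at q < 0.05).
PAPER2025 = {
    "window": {"width": 20, "sigma": 3.0, "step": 1},
    "states": {"k": 6, "metric": "cityblock", "restarts": 20},
    "topology": {"sparsity_min": 0.10, "sparsity_max": 0.34,
                 "sparsity_step": 0.01, "edge_ranking": "signed"},
    "multilayer": {"gamma": 1.1, "omega": 0.5, "repeats": 20},
    "stats": {"fdr_q": 0.05},
}


@dataclass
class RunConfig:
    """Flattened pipeline configuration with study-profile defaults."""

    window_width: int = 20
    window_sigma: float = 3.0
    window_step: int = 1
    states_k: int = 6
    states_metric: str = "cityblock"
    states_restarts: int = 20
    topology_sparsity_min: float = 0.10
    topology_sparsity_max: float = 0.34
    topology_sparsity_step: float = 0.01
    topology_edge_ranking: str = "signed"
    multilayer_gamma: float = 1.1
    multilayer_omega: float = 0.5
    multilayer_repeats: int = 20
    stats_fdr_q: float = 0.05

    def __post_init__(self):
        if self.window_width < 2 or self.window_step < 1:
            raise ValueError("window width must be >= 2 and step >= 1")
        if self.states_k < 2:
            raise ValueError("states_k must be >= 2")
        if not 0 < self.topology_sparsity_min <= self.topology_sparsity_max <= 1:
            raise ValueError("sparsity range must satisfy 0 < min <= max <= 1")
        if not 0 < self.stats_fdr_q < 1:
            raise ValueError("stats_fdr_q must be in (0, 1)")

    @classmethod
    def from_dict(cls, nested: dict) -> "RunConfig":
        kwargs = {}
        for section, entries in nested.items():
            if section not in PAPER2025:
                raise ValueError(f"unknown config section {section!r}")
            for key, value in entries.items():
                flat = f"{section}_{key}" if f"{section}_{key}" in cls.__dataclass_fields__ \
                    else f"{section}_{'sigma' if key == 'sigma' else key}"
                if flat not in cls.__dataclass_fields__:
                    raise ValueError(f"unknown config key {section}.{key}")
                kwargs[flat] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            nested = yaml.safe_load(fh) or {}
        return cls.from_dict(nested)

    def window_spec(self) -> fnc_dynamic.WindowSpec:
        return fnc_dynamic.WindowSpec(
            width=self.window_width, step=self.window_step,
            gaussian_sigma=self.window_sigma,
        )

    def sparsity_grid(self) -> np.ndarray:
        return np.round(
            np.arange(self.topology_sparsity_min,
                      self.topology_sparsity_max + self.topology_sparsity_step / 2,
                      self.topology_sparsity_step),
            6,
        )

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Panel IO
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ("subject_id", "group", "age", "gender", "education",
                    "mean_fd", "file")


def read_panel(manifest_path) -> TimeSeriesPanel:
    """Load a cohort from a manifest TSV and its per-subject matrices.

    Validates dimensions subject by subject; any mismatch, missing file or
    non-finite value is reported with the subject id.
    """
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path, sep="\t")
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"manifest is missing columns {missing_cols}")
    if table["subject_id"].duplicated().any():
        dup = table.loc[table["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids in manifest: {dup}")
    extra = [c for c in table.columns if c not in MANIFEST_COLUMNS]

    root = manifest_path.parent
    subjects = []
    labels = None
    errors = []
    for row in table.itertuples(index=False):
        fpath = root / row.file
        if not fpath.exists():
            errors.append(f"{row.subject_id}: missing file {fpath}")
            continue
        frame = pd.read_csv(fpath, sep="\t")
        data = frame.to_numpy(dtype=float)
        if labels is None:
            labels = list(frame.columns)
        elif list(frame.columns) != labels:
            errors.append(
                f"{row.subject_id}: {data.shape[1]} channels, expected "
                f"{len(labels)}"
            )
            continue
        if not np.all(np.isfinite(data)):
            errors.append(f"{row.subject_id}: non-finite values in {fpath.name}")
            continue
        covariates = {c: getattr(row, c) for c in
                      ("age", "gender", "education", "mean_fd")}
        for c in extra:
            covariates[c] = getattr(row, c)
        subjects.append(Subject(str(row.subject_id), data, str(row.group),
                                covariates))
    if errors:
        raise ValueError("panel validation failed:\n" + "\n".join(errors))

    meta_path = root / "truth.json"
    tr = 2.0
    networks = None
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
        tr = float(meta.get("tr_seconds", tr))
        networks = meta.get("channel_networks")
    if networks is None:
        networks = [lab.split("_")[-1] if lab.split("_")[-1] in NETWORKS
                    else "NODE" for lab in labels]
    panel = TimeSeriesPanel(subjects, labels, list(networks), tr)
    panel.validate()
    return panel


def _write_table(frame: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    schema = {"columns": [{"name": c, "dtype": str(frame[c].dtype)}
                          for c in frame.columns]}
    with open(path.with_suffix(path.suffix + ".schema.json"), "w") as fh:
        json.dump(schema, fh, indent=1)


def validate_outputs(outdir) -> list:
    """Check every CSV in a results directory against its schema sidecar.

    Returns a list of problems (empty when everything validates).
    """
    problems = []
    for csv_path in sorted(Path(outdir).rglob("*.csv")):
        schema_path = csv_path.with_suffix(".csv.schema.json")
        if not schema_path.exists():
            problems.append(f"{csv_path}: missing schema sidecar")
            continue
        with open(schema_path) as fh:
            schema = json.load(fh)
        frame = pd.read_csv(csv_path)
        declared = [c["name"] for c in schema["columns"]]
        if list(frame.columns) != declared:
            problems.append(
                f"{csv_path}: columns {list(frame.columns)} != declared {declared}"
            )
    return problems


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

def _pair_long_table(matrices, panel, value_name):
    rows_i, cols_j = fnc_static.pair_indices(panel.n_channels)
    records = []
    for subject, mat in zip(panel.subjects, matrices):
        vals = mat[rows_i, cols_j]
        for i, j, v in zip(rows_i, cols_j, vals):
            records.append((subject.subject_id, panel.channel_labels[i],
                            panel.channel_labels[j], v))
    return pd.DataFrame(records, columns=["subject_id", "channel_i",
                                          "channel_j", value_name])


def _covariate_matrix(panel, names):
    return np.column_stack(
        [[float(s.covariates[n]) for s in panel.subjects] for n in names]
    )


def _group_vector(panel):
    groups = panel.groups()
    if len(groups) != 2:
        raise ValueError(f"group contrasts need exactly 2 groups, got {groups}")
    return np.array([1.0 if s.group == groups[0] else 0.0
                     for s in panel.subjects]), groups


def run_pipeline(manifest, outdir, config: RunConfig = None, seed: int = 0,
                 stages=None, panel: TimeSeriesPanel = None) -> Path:
    """Execute the analysis stages and write the results directory.

    ``stages`` selects a subset of :data:`ALL_STAGES`; prerequisites of a
    requested stage are computed in memory but only requested stages write
    output. Identical inputs, config and seed give identical result files.
    """
    config = config or RunConfig()
    stages = set(ALL_STAGES if stages is None else stages)
    unknown = stages - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if panel is None:
        panel = read_panel(manifest)
    subject_ids = [s.subject_id for s in panel.subjects]
    t0 = time.time()
    logger.info("pipeline start: %d subjects, stages=%s, config=%s, seed=%d",
                len(subject_ids), sorted(stages), config.hash(), seed)

    need_dfnc = stages & {"dfnc", "topology", "multilayer", "stats"}
    spec = config.window_spec()

    feature_tables = {}  # family name -> (DataFrame, fdr flag)

    z_static = None
    if stages & {"sfnc", "stats"}:
        z_static = fnc_static.sfnc(panel)
    if "sfnc" in stages:
        for s, z in zip(panel.subjects, z_static):
            path = outdir / "sfnc" / f"zmatrix_{s.subject_id}.tsv"
            path.parent.mkdir(parents=True, exist_ok=True)
            np.savetxt(path, z, delimiter="\t",
                       header="\t".join(panel.channel_labels), comments="")
        _write_table(_pair_long_table(z_static, panel, "z"),
                     outdir / "sfnc" / "sfnc_pairs.csv")
        logger.info("stage sfnc done (%.1fs)", time.time() - t0)

    dfnc_arrays = None
    state_labels = None
    metrics = None
    if need_dfnc:
        dfnc_arrays = fnc_dynamic.dfnc(panel, spec)
    if stages & {"dfnc", "stats"}:
        pooled = np.vstack([a.pair_matrix() for a in dfnc_arrays])
        model = fnc_dynamic.cluster_states(
            pooled, k=config.states_k, distance=config.states_metric,
            n_restarts=config.states_restarts, seed=seed,
        )
        counts = [a.n_windows for a in dfnc_arrays]
        state_labels = fnc_dynamic.split_labels(model.labels, counts)
        metrics = [fnc_dynamic.state_metrics(lab, config.states_k)
                   for lab in state_labels]
        variability = [fnc_dynamic.dfnc_variability(a) for a in dfnc_arrays]
        k = config.states_k
        metric_frame = pd.DataFrame({
            "subject_id": subject_ids,
            **{f"FT_{s + 1}": [m.fraction_time[s] for m in metrics]
               for s in range(k)},
            **{f"MDT_{s + 1}": [m.mean_dwell_time[s] for m in metrics]
               for s in range(k)},
            "NT": [m.n_transitions for m in metrics],
        })
        if "dfnc" in stages:
            assign = pd.DataFrame(
                [(sid, w, int(lab)) for sid, labs in zip(subject_ids, state_labels)
                 for w, lab in enumerate(labs)],
                columns=["subject_id", "window", "state"],
            )
            _write_table(assign, outdir / "dfnc" / "assignments.csv")
            _write_table(metric_frame, outdir / "dfnc" / "state_metrics.csv")
            for s in range(k):
                np.savetxt(
                    outdir / "dfnc" / f"centroid_state{s + 1}.tsv",
                    fnc_static.matrix_from_pairs(model.centroids[s],
                                                 panel.n_channels),
                    delimiter="\t",
                )
            _write_table(_pair_long_table(variability, panel, "sd"),
                         outdir / "dfnc" / "variability.csv")
            logger.info("stage dfnc done (%.1fs)", time.time() - t0)
        if "stats" in stages:
            pair_names = fnc_static.pair_labels(panel.channel_labels)
            feature_tables["sfnc"] = (
                pd.DataFrame(np.array([fnc_static.vectorize_matrix(z)
                                       for z in z_static]),
                             columns=pair_names, index=subject_ids),
                True,
            )
            feature_tables["state_metrics"] = (
                metric_frame.drop(columns="subject_id").set_axis(subject_ids),
                False,  # temporal state properties are reported uncorrected
            )
            feature_tables["variability"] = (
                pd.DataFrame(np.array([fnc_static.vectorize_matrix(v)
                                       for v in variability]),
                             columns=pair_names, index=subject_ids),
                True,
            )

    if stages & {"topology", "stats"}:
        flex = [
            topology.efficiency_flexibility(
                a.r_windows(), config.sparsity_grid(),
                ranking=config.topology_edge_ranking,
            )
            for a in dfnc_arrays
        ]
        flex_frame = pd.DataFrame({
            "subject_id": subject_ids,
            "eglob_flex": [f.eglob_flex for f in flex],
            "eloc_flex": [f.eloc_flex for f in flex],
        })
        if "topology" in stages:
            _write_table(flex_frame, outdir / "topology" / "flexibility.csv")
            logger.info("stage topology done (%.1fs)", time.time() - t0)
        if "stats" in stages:
            feature_tables["flexibility"] = (
                flex_frame.drop(columns="subject_id").set_axis(subject_ids),
                True,
            )

    if "multilayer" in stages:
        params_rng = np.random.default_rng([seed, 7])
        node_rows, net_rows = [], []
        rate_matrix = []
        for s, a in zip(panel.subjects, dfnc_arrays):
            params = multilayer.MultilayerParams(
                gamma=config.multilayer_gamma, omega=config.multilayer_omega,
                n_repeats=config.multilayer_repeats,
                seed=int(params_rng.integers(2**31)),
            )
            net = multilayer.layered_from_windows(
                a.r_windows(), node_labels=panel.channel_labels,
                node_networks=panel.channel_networks,
            )
            rates = multilayer.consensus_switching(net, params,
                                                   panel.channel_networks)
            rate_matrix.append(rates.node_rates)
            for node, (rate, sd) in enumerate(zip(rates.node_rates,
                                                  rates.node_sd)):
                node_rows.append((s.subject_id, panel.channel_labels[node],
                                  rate, sd))
            for name, rate in rates.network_rates.items():
                net_rows.append((s.subject_id, name, rate))
        _write_table(pd.DataFrame(node_rows, columns=["subject_id", "node",
                                                      "rate", "run_sd"]),
                     outdir / "multilayer" / "switching_nodes.csv")
        _write_table(pd.DataFrame(net_rows, columns=["subject_id", "network",
                                                     "rate"]),
                     outdir / "multilayer" / "switching_networks.csv")
        logger.info("stage multilayer done (%.1fs)", time.time() - t0)
        if "stats" in stages:
            feature_tables["switching"] = (
                pd.DataFrame(np.array(rate_matrix),
                             columns=panel.channel_labels, index=subject_ids),
                True,
            )

    if "stats" in stages:
        group, group_names = _group_vector(panel)
        covs = _covariate_matrix(panel, ["age", "gender", "education"])
        covs_fd = _covariate_matrix(panel, ["age", "gender", "education",
                                            "mean_fd"])
        for family, (frame, use_fdr) in feature_tables.items():
            table = stats.glm_table(frame, group, covs, fdr=use_fdr,
                                    q_threshold=config.stats_fdr_q)
            _write_table(table, outdir / "stats" / f"{family}_glm.csv")
            validated = stats.glm_table(frame, group, covs_fd, fdr=use_fdr,
                                        q_threshold=config.stats_fdr_q)
            _write_table(validated, outdir / "stats" / f"{family}_glm_fd.csv")
        logger.info("stage stats done (%.1fs); contrast %s vs %s",
                    time.time() - t0, group_names[0], group_names[1])

    info = {
        "config": asdict(config),
        "config_hash": config.hash(),
        "seed": seed,
        "stages": sorted(stages),
        "n_subjects": len(subject_ids),
        "wall_seconds": round(time.time() - t0, 2),
    }
    with open(outdir / "run_info.json", "w") as fh:
        json.dump(info, fh, indent=1)
    return outdir
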