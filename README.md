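# dynconn

Static and dynamic functional network connectivity analysis for
resting-state fMRI cohorts — the post-ICA stage of a connectomics study:
given per-subject component or atlas-node time courses and a subject
manifest, the package computes group contrasts on static connectivity,
sliding-window dynamic connectivity and its brain-state decomposition,
windowed graph-efficiency flexibility, and multilayer-network switching
rates, with covariate-adjusted inference throughout. A synthetic-cohort
generator with planted ground truth makes every stage testable without any
imaging data.

It is aimed at researchers studying network reorganization in clinical
populations (the built-in defaults mirror a mild age-related hearing-loss
cohort: 66 patients vs 54 controls, 234 volumes at TR = 2 s, 13 ICA
components in six networks — DMN, CEN, SN, AUN, VN, SMN).

## Methods at a glance

* **sFNC** — per subject, Pearson correlations between channel time
  courses, Fisher z-transformed: `z_ij = atanh(r_ij)`.
* **dFNC** — tapered sliding windows (rectangle of 20 TRs convolved with a
  Gaussian, σ = 3 TRs, step 1 TR); taper-weighted correlations per window;
  the pooled windows-by-pairs matrix is clustered by k-means (k = 6,
  city-block distance, best of 20 restarts) into recurring connectivity
  states. Per subject: fraction time, mean dwell time, number of
  transitions, and dFNC variability (across-window SD of each pair's
  windowed *r*).
* **Dynamic topology** — each windowed matrix is binarized over a sparsity
  grid (10–34 %); global efficiency `E_glob = mean_{i≠j} 1/d_ij` and local
  efficiency (neighborhood `E_glob`) are integrated over the grid (AUC) and
  their across-window SD is the subject's flexibility.
* **Multilayer switching** — time-ordered layers with ordinal interlayer
  coupling; multilayer modularity
  `Q = (1/2μ) Σ_{ijlr} [(A_ijl − γ k_il k_jl / 2m_l) δ_lr + δ_ij ω 1{|l−r|=1}] δ(g_il, g_jr)`
  with γ = 1.1, ω = 0.5, optimized by an iterative ordinal Louvain scheme;
  a node's switching rate is the fraction of adjacent-layer transitions at
  which its community changes.
* **Inference** — every feature family is contrasted between groups with an
  OLS GLM (`y ~ 1 + group + age + gender + education`), Benjamini–Hochberg
  FDR at q < 0.05 (temporal state properties are reported uncorrected, per
  convention), a parallel head-motion validation rerun with mean framewise
  displacement added to the covariates, partial correlations with clinical
  traits, and within-patient subgroup contrasts (MoCA ≥ 26, age ≥ 60).

## Worked example

Simulate a cohort with a planted Fisher-z shift of 0.5 on the DMN pair
(IC05, IC04) in the patient group, then run the full pipeline:

```python
import numpy as np, pandas as pd
import dynconn as dc

config = dc.SimConfig(
    n_per_group={"patient": 30, "control": 30},
    n_timepoints=234,
    group_effects=[dc.GroupEffect(pair=(4, 3), shifts={"patient": 0.5})],
    seed=42,
)
panel, truth = dc.make_cohort(config)
manifest = dc.write_cohort(panel, truth, "demo_cohort")
outdir = dc.run_pipeline(
    manifest, "demo_results",
    dc.RunConfig(states_restarts=10, multilayer_repeats=5), seed=42,
)

glm = pd.read_csv(outdir / "stats" / "sfnc_glm.csv")
print(glm.sort_values("q").head(3).to_string(index=False))
metrics = pd.read_csv(outdir / "dfnc" / "state_metrics.csv")
print("mean fraction time per state:",
      np.round(metrics[[f"FT_{s}" for s in range(1, 7)]].mean().to_numpy(), 3))
print("mean transitions:", round(metrics["NT"].mean(), 1))
```

which prints

```
           feature      beta         t  df        p        q   sig
IC05_DMN--IC04_DMN  0.236871  2.713972  55 0.008861 0.691178 False
IC02_CEN--IC01_CEN -0.024768 -0.287546  55 0.774775 0.959256 False
IC04_DMN--IC01_CEN -0.005801 -0.365970  55 0.715791 0.959256 False
mean fraction time per state: [0.21  0.178 0.176 0.162 0.141 0.133]
mean transitions: 7.7
```

The planted DMN pair ranks first among all 78 pairs (raw p = 0.009,
positive sign matching the injected shift); at 30 subjects per group the
0.24 observed z-difference — the planted shift diluted by state-mixture
averaging — does not survive FDR across 78 comparisons, which is the
expected power at this sample size. The fraction-time row shows the six
recovered states ordered by pooled occupancy, and patients and controls
average 7.7 state transitions over the 215 windows.

The same pipeline is available from the shell:

```sh
dynconn simulate --out demo_cohort --seed 42 --n-patients 30 --n-controls 30
dynconn run-all --manifest demo_cohort/manifest.tsv --out demo_results --seed 42
```

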