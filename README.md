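# connectodiff

Group-level comparison of weighted structural connectomes — the kind of
analysis used to ask whether the cortical network of a patient group
(e.g. first-episode vs chronic psychosis) differs from healthy controls
in anatomy (which connections are weaker?) or topology (is the hub
hierarchy rearranged?).

A connectome here is a symmetric weighted adjacency matrix per subject
and weight kind — diffusion scalars (FA, MD, RD, AD) or the
log-transformed SIFT2-weighted streamline count — over a fixed atlas
parcellation. The package provides, as a library plus a thin
`connectodiff` CLI:

- **Graph metrics** — nodal strength `s_i = Σ_j w_ij`, weighted
  betweenness and mean shortest-path length (edge length `1/w`), Onnela
  clustering, global efficiency, and the global network average
  `⟨s⟩ = 2 Σ_{i<j} w_ij / N`.
- **Composite hubness** — per subject, each of the four nodal metrics
  is rank-scored to `[0, 1]` via `(rank − 1)/(N − 1)` (degree and
  betweenness ascending, path length and clustering descending) and
  averaged; hubs score near 1.
- **Rank similarity** — Kendall's tau-b between subjects' hubness
  vectors; within- vs between-group mean tau compared by permuting
  subject labels (add-one p-values).
- **Network-based statistic (NBS)** — edgewise GLM with nuisance
  covariates (age, sex, site), one-sided components of edges with
  `t ≥ 3`, and family-wise error control from the permutation null of
  the maximum component extent (Freedman–Lane when nuisance covariates
  are present). Significant edges are classified intra- vs
  interhemispheric.
- **Hub vulnerability** — for each hubness threshold `k` on a grid, the
  proportion of disrupted edges touching the band `k ± 0.05` (or the
  above/below-`k` subgraph) is compared to randomly selected node sets
  of equal size; the 2.5–97.5 null percentiles form the envelope.
- **Scalar statistics** — chi-square with the clipped Yates continuity
  correction for 2×2 demographics tables, pooled/Welch two-sample t
  (raw data or `(mean, sd, n)` summaries), one-way ANOVA with Tukey HSD.
- **Synthetic cohorts** — a generator that plants known group
  differences (global, fixed edge cluster, hub-targeted,
  interhemispheric, per-subject idiosyncratic) in hub-structured,
  log-normally noisy connectomes, so every inferential claim can be
  checked against ground truth.

## Worked example

```python
from connectodiff import (AnalysisConfig, DisruptionSpec, SimulationSpec,
                          make_design, nbs, simulate_cohort)

cohort = simulate_cohort(SimulationSpec(
    n_nodes=50, groups=(("HC", 20), ("PATIENT", 20)),
    disruption=DisruptionSpec(mode="EDGE_SET", effect_size=0.5,
                              n_target_edges=10),
    rng_seed=21))
design = make_design(cohort.matrices, cohort.manifest,
                     contrast=("HC", "PATIENT"),
                     covariates=("age", "sex"), tail="lower")
result = nbs(design, AnalysisConfig(n_perm_nbs=2000, rng_seed=21), seed=21)
for extent, p in zip(result.extents, result.p_values):
    print(extent, p)
```

prints

```
10 0.0005
1 0.5467
```

— the planted 10-edge cluster comes back as a single suprathreshold
component whose extent no permutation matched (p = 1/2001), while a
stray single-edge exceedance is correctly non-significant. On this run
all 10 planted edges are recovered. The `examples/` directory has one
short script per capability (simulation, metrics, hubness + rank
similarity, NBS, hub vulnerability, scalar stats), each printing the
numbers it computes and what they mean.

The CLI mirrors the library:
`connectodiff simulate|validate|metrics|hubness|nbs|ranksim|hubvuln|groupstats|demographics|run`,
with `connectodiff run --config cfg.yaml --spec sim.yaml --out results/`
executing every stage and writing a run manifest with per-stage output
hashes (re-running the same config and seed reproduces identical
hashes).

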