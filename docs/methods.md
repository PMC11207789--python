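# Methods

## Data model

A subject's structural connectome is a symmetric, nonnegative,
zero-diagonal `N × N` matrix over a fixed parcellation, one matrix per
weight kind: FA (unitless, in `[0, 1]`), MD/RD/AD (diffusivities,
mm²/s), or the natural log of the SIFT2-weighted streamline count.
Zero entries denote absent connections: they are excluded from
edge-level statistics but contribute 0 to nodal strength, matching
streamline-count semantics where no streamline means no connection.
Matrices are validated on load (symmetry within 1e-9, finiteness,
nonnegativity, unique node ids) and stored as TSV with node ids as the
first row and column. The cohort manifest carries group labels and
covariates; missing covariates are excluded listwise per analysis, not
imputed.

All randomness flows from a single seed through named substreams per
stage, so permutation results are bit-reproducible.

## Graph metrics

- **Strength** (weighted degree): `s_i = Σ_j w_ij`. The *global network
  average* is the mean strength, `2 Σ_{i<j} w_ij / N`.
- **Shortest paths** use edge length `1/w`: a stronger connection is
  topologically closer. This is the streamline-count convention from
  the weighted graph-metric literature; it is logged per run and the
  choice matters only through ranks for hubness.
- **Nodal path length**: mean distance to reachable nodes; disconnected
  pairs are omitted from the mean (and contribute 0 to efficiency).
  Synthetic graphs are connected by construction, so this is a
  degenerate-input convention rather than a modeling decision.
- **Betweenness**: weighted Brandes betweenness, endpoints excluded,
  ties split fractionally, unnormalized (rank-based hubness makes
  normalization irrelevant). Computed with igraph's C implementation;
  the test suite checks it against exhaustive shortest-path enumeration
  on small graphs.
- **Global efficiency**: mean of `1/d_ij` over ordered pairs, 0 for
  disconnected pairs.
- **Clustering**: Onnela geometric-mean form on weights normalized by
  the matrix maximum, `C_i = Σ_{j,h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3} /
  (k_i(k_i−1))` with binary degree `k_i`, and `C_i = 0` for `k_i < 2`.
  The weighted-metric literature admits more than one clustering and
  path-length variant; the chosen forms are the ones stated here and
  alternative direction/variant choices are exposed as arguments where
  they affect results (`composite_hubness(directions=...)`).

## Composite hubness

Per subject, each metric vector is rank-scored to `[0, 1]` as
`(rank − 1)/(N − 1)` with average ranks for ties. A "position divided
by count" convention differs only by an affine factor and yields
identical ranks and taus; the `(rank − 1)/(N − 1)` form is used because
it places the lowest node at exactly 0 and the highest at exactly 1.
Directions: degree and betweenness ascending, path length and
clustering descending — integrative hubs are strong, much-traversed,
close to everything, and locally sparse. The composite is the
arithmetic mean of the four scores, computed independently per subject;
group-level hubness is the nodewise mean over a group's subjects.

## Rank similarity

Similarity between two subjects' hubness vectors is Kendall's tau-b
(tie-corrected, since average-rank ties occur). For a two-group
contrast we report mean within-group tau per group and mean
between-group tau. Inference permutes subject labels (group sizes
fixed), recomputing the statistics from the precomputed pairwise tau
matrix; p-values are two-sided with the add-one rule
`p = (1 + #{|null| ≥ |obs|})/(n_perm + 1)`, so `p ≥ 1/(n_perm+1)` and
exact validity holds. The test statistic for the main contrast is the
difference of within-group means; between-vs-within contrasts are
reported per group the same way. (Which functional the original
analysis permuted is not derivable from its description; the mean
difference is the natural choice.)

## Network-based statistic

Edges present in ≥ 90% of subjects (configurable) form the analysis
mask. Each masked edge's weight is regressed by OLS on
`[1, predictor, nuisance]`, where the predictor is a group indicator or
a continuous clinical score (PANSS subscores; duration of untreated
psychosis is log-transformed first, with subjects lacking a valid value
excluded listwise). The edgewise t is signed so the hypothesized
direction (patients lower FA / log-streamline count, higher MD/RD/AD)
is positive, and only positive exceedances of the T = 3.0 threshold
form components — a one-sided test by construction. Components are
connected sets of suprathreshold edges sharing nodes; the cluster
statistic is the extent (edge count).

FWER control: the predictor is permuted — Freedman–Lane residual
permutation of the reduced (nuisance-only) model when nuisance
covariates are present, plain label permutation otherwise (both
available via `permute_scheme`) — and the null distribution is the
maximum component extent per permutation. Component
`p = (1 + #{null max ≥ extent})/(n_perm + 1)`. With two groups and no
nuisance the edgewise t equals the classical pooled two-sample t to
1e-10, which the tests assert.

## Hub vulnerability

Given a disrupted edge set (typically NBS-significant edges) and a
group-level hubness ranking (the control group's mean composite, or
rank-scored degree), for each `k` on the grid 0.10, 0.15, …, 0.90:

- **band statistic**: select nodes with hubness in `k ± r` (`r = 0.05`;
  the band is read as the symmetric window around `k`) and compute the
  fraction of disrupted edges with ≥ 1 endpoint in the selection;
- **threshold variants**: select all nodes above (or below) `k` and
  count only edges with both endpoints inside the subgraph.

The observed proportion is compared to uniformly random node sets of
the same cardinality (10 000 for the band, 1000 for the threshold
variants by default); the 2.5th–97.5th percentiles form the 95%
envelope. Empty selections yield a missing point and a log warning.
The denominator is the total number of disrupted edges; an alternative
reading for the threshold variant — proportion over the selected
subgraph's own edges — is available via
`denominator="subgraph_edges"`.

A property worth knowing: the random-node-set null does not condition
on degree. In a hub-structured graph, a high-hubness band touches more
of the *existing* edges than a typical random set, so even disruption
drawn uniformly from existing edges drifts above the envelope at high
`k`. The envelope is exactly calibrated against disruption that is
unrelated to the topology (uniform over node pairs), which is what the
calibration study in `validation.py` uses; detection of hub-targeted
disruption should therefore be read against that baseline. This is a
property of the published procedure itself, not of this
implementation.

## Scalar statistics

2×2 contingency tables use Pearson chi-square with the *clipped* Yates
continuity correction — each term `(max(0, |O−E| − 0.5))²/E` — which is
required to give exactly 0 when every observed count is within 0.5 of
expectation (as the published FEP-vs-chronic sex table prints);
larger tables are uncorrected, `df = (R−1)(C−1)`. Two-sample t-tests
default to pooled variance (`df = n₁+n₂−2`, matching the published
degrees of freedom) and accept `(mean, sd, n)` summaries, so printed
table rows can be re-tested directly. Three-group comparisons use
one-way ANOVA with Tukey HSD pairwise p-values from the studentized
range distribution. Global network averages dispatch to t-test (2
groups) or ANOVA+Tukey (≥ 3), two-tailed.

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes,
not anatomy:

- latent node propensities `s_i = 1 + Pareto(2.5)` give expected edge
  weight `∝ (s_i s_j)^hub_exponent` (default 1.0) — a heavy-tailed hub
  hierarchy;
- the densest `base_density` (default 0.3) fraction of pairs forms the
  shared topology, patched to connectivity by joining components via
  their best-scoring crossing pair; all subjects share one topology;
- subject noise is log-normal multiplicative with `σ = 0.3` (default),
  mean-corrected, consistent with log-streamline weights being roughly
  additive-Gaussian after the log;
- hemispheres split the nodes half/half, so interhemispheric edges are
  those crossing the split; lobes cycle through a fixed list;
- group disruption multiplies targeted edge means by `effect_size` in
  the affected (non-reference) groups. Modes: GLOBAL (all edges),
  EDGE_SET (a connected cluster grown by BFS from a random seed edge —
  connected because cluster recovery is what the extent statistic is
  for), HUB_TARGETED (edges incident to nodes above the propensity
  `hub_quantile`), INTERHEMISPHERIC (crossing edges), IDIOSYNCRATIC
  (per-subject random subsets multiplied by `exp(±effect_size)` with
  random sign, leaving the group geometric mean unchanged);
- manifests draw age ~ N(25, 4) clipped to [18, 45] and sex M/F with
  p = 0.6/0.4, one site;
- DTI-kind matrices are monotone rescalings of the same latent
  structure (FA squashed into (0, 1); AD ≥ MD ≥ RD in expectation), so
  rank-based analyses are identical across kinds and only scales
  differ.

What it does *not* emulate: spatial embedding, distance-dependent
connectivity, atlas-specific community structure, measurement artifacts
correlated with motion or site, or realistic covariate-connectivity
confounding. Passing operating-characteristic tests on these cohorts
shows the inference machinery is calibrated and sensitive under its own
assumptions; it does not certify effect sizes or power on real MRI
cohorts.

## Validation studies and problem sizes

`connectodiff.validation` packages the simulation studies:

- NBS family-wise error under the global null: 50-node cohorts, 20
  subjects per group, 1000 permutations, 200 replicates — the rejection
  rate should lie in the n=200 binomial 95% CI around 0.05.
- NBS recovery: a planted connected 10-edge cluster at effect 0.5
  (weights scaled to half) detected with ≥ 8/10 edges recovered.
- Hub-vulnerability coverage and detection at the full 246-node atlas
  scale with 1000 node-set nulls: coverage of the envelope against
  topology-unrelated disruption, and detection (exceedance at some
  k ≥ 0.8) of disruption targeted at top-decile hubs, where the band
  grid's upper reach (0.90 + 0.05) covers about half the targeted hub
  nodes — detection leans on that overlap, which is why band analyses
  need node counts large enough for bands to hold several nodes.
- Tau rank-similarity type-I error (30-node, 2×8 cohorts, 200
  replicates) and power against strong idiosyncratic rewiring (50-node
  cohorts, 30% of edges per subject scaled by `e^{±1.5}`).

Replicate and permutation counts in the tests and the acceptance script
are the package's own precision/runtime trade-off; all of them are
arguments.

## Numerical conventions

- Permutation p-values always include the observed statistic (add-one
  rule); they are never 0 and floor at `1/(n_perm+1)`.
- Matrices are symmetrized by averaging only below the 1e-9 tolerance;
  larger asymmetry is an error, not a repair.
- Ties in rank scores use average ranks; tau is the tie-corrected
  tau-b.
- `extract_components` uses union-find over suprathreshold edges;
  lowering the threshold can only grow extents (asserted as a property
  test).
- Degenerate inputs: empty suprathreshold sets give an empty component
  list; zero disrupted edges give a zero curve flagged in the log;
  constant vectors are rejected where a rank correlation would be
  undefined.

## Known limitations

- The edgewise GLM is OLS with homoscedastic errors per edge; no
  exchangeability blocks, sign-flipping, or TFCE-style statistics.
- The hub-vulnerability null is degree-blind (see above); a
  degree-preserving null would be a different procedure.
- No rich-club, modularity, or small-worldness metrics; no
  intensity-based cluster statistics; no imaging formats or
  tractogram handling — inputs are matrices, full stop.
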