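"""Synthetic cohorts of weighted connectomes with planted group differences.

The generator emulates the statistical structure the downstream analysis
assumes: a shared edge topology across subjects, heavy-tailed weighted
degree (a hub hierarchy), log-normal multiplicative subject variation,
hemisphere labels for intra/inter edge classification, and configurable
group-level disruption. Expected edge weight is (s_i * s_j)**hub_exponent
for latent node propensities s with a power-law tail; the densest
``base_density`` fraction of node pairs (plus a connectivity patch-up)
forms the common topology.

Disruption modes (applied multiplicatively to affected groups' means):

- GLOBAL: every edge scaled by ``effect_size``.
- EDGE_SET: a connected edge cluster (grown by BFS from a random seed
  edge) of ``round(target_fraction * n_edges)`` edges.
- HUB_TARGETED: random subset of edges incident to nodes above the
  ``hub_quantile`` of latent propensity.
- INTERHEMISPHERIC: random subset of hemisphere-crossing edges.
- IDIOSYNCRATIC: no group-mean shift; per-subject random perturbations
  via :func:`plant_idiosyncrasy`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (
    CohortManifest,
    ConnectomeMatrix,
    NodeTable,
    ValidationError,
    WeightKind,
)


class DisruptionMode(str, enum.Enum):
    NONE = "NONE"
    GLOBAL = "GLOBAL"
    EDGE_SET = "EDGE_SET"
    HUB_TARGETED = "HUB_TARGETED"
    INTERHEMISPHERIC = "INTERHEMISPHERIC"
    IDIOSYNCRATIC = "IDIOSYNCRATIC"


@dataclass
class DisruptionSpec:
    """What to plant, where, and how strongly.

    ``effect_size`` is a multiplicative factor on targeted edge means
    (1.0 = none; 0.7 = 30% reduction). ``affected_groups`` defaults to
    every group except the first listed (the reference/control group).
    """

    mode: DisruptionMode = DisruptionMode.NONE
    effect_size: float = 1.0
    target_fraction: float = 0.1
    hub_quantile: float = 0.9
    n_target_edges: int | None = None  # overrides target_fraction if set
    affected_groups: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.mode = DisruptionMode(self.mode)
        if not np.isfinite(self.effect_size):
            raise ValidationError("effect_size must be finite")
        if not 0 <= self.target_fraction <= 1:
            raise ValidationError("target_fraction must be in [0, 1]")


@dataclass
class SimulationSpec:
    """Cohort-level generator settings.

    Defaults emulate an atlas-scale parcellation (246 nodes), moderate
    density, a clear hub hierarchy, and ~30% log-normal subject noise.
    """

    n_nodes: int = 246
    groups: tuple[tuple[str, int], ...] = (("HC", 20), ("PATIENT", 20))
    base_density: float = 0.3
    hub_exponent: float = 1.0
    subject_noise_sigma: float = 0.3
    weight_kind: WeightKind = WeightKind.LOG_SIFT2
    disruption: DisruptionSpec = field(default_factory=DisruptionSpec)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.weight_kind = WeightKind(self.weight_kind)
        if self.n_nodes < 10:
            raise ValidationError("n_nodes must be >= 10")
        if not 0 < self.base_density <= 1:
            raise ValidationError("base_density must be in (0, 1]")
        for label, n in self.groups:
            if n < 2:
                raise ValidationError(f"group {label!r} needs >= 2 subjects")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    disrupted_edges: list[tuple[str, str]]
    latent_propensity: np.ndarray  # per node, drives expected strength
    hub_nodes: list[str]  # above hub_quantile when HUB_TARGETED, else top decile


@dataclass
class SyntheticCohort:
    matrices: dict[str, ConnectomeMatrix]
    node_table: NodeTable
    manifest: CohortManifest
    truth: GroundTruth
    #: per-edge mean weights and the common topology, kept for planting
    mean_weights: np.ndarray
    edge_index: np.ndarray  # (E, 2) upper-triangle node indices


def _build_topology(score: np.ndarray, density: float, rng: np.random.Generator) -> np.ndarray:
    """Select the densest ``density`` fraction of pairs, then patch
    connectivity by adding the best edge between components."""
    n = score.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    n_edges = max(n - 1, int(round(density * iu.size)))
    order = np.argsort(score[iu, ju])[::-1]
    adj = np.zeros((n, n), dtype=bool)
    take = order[:n_edges]
    adj[iu[take], ju[take]] = True
    adj |= adj.T
    # union-find patch-up: connect remaining components via their
    # highest-score crossing pair
    parent = np.arange(n)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in zip(*np.nonzero(np.triu(adj, 1))):
        parent[find(int(a))] = find(int(b))
    roots = {find(i) for i in range(n)}
    while len(roots) > 1:
        comps = {}
        for i in range(n):
            comps.setdefault(find(i), []).append(i)
        groups_list = list(comps.values())
        a_nodes = np.array(groups_list[0])
        best = (-np.inf, None)
        for other in groups_list[1:]:
            b_nodes = np.array(other)
            sub = score[np.ix_(a_nodes, b_nodes)]
            k = np.unravel_index(np.argmax(sub), sub.shape)
            if sub[k] > best[0]:
                best = (sub[k], (int(a_nodes[k[0]]), int(b_nodes[k[1]])))
        a, b = best[1]
        adj[a, b] = adj[b, a] = True
        parent[find(a)] = find(b)
        roots = {find(i) for i in range(n)}
    return adj


def _select_targets(
    spec: SimulationSpec,
    edge_index: np.ndarray,
    propensity: np.ndarray,
    hemisphere: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Indices into ``edge_index`` of the edges whose group mean shifts."""
    d = spec.disruption
    n_edges = edge_index.shape[0]
    if d.n_target_edges is not None:
        n_target = d.n_target_edges
    else:
        n_target = int(round(d.target_fraction * n_edges))
    if d.mode is DisruptionMode.GLOBAL:
        return np.arange(n_edges)
    if d.mode is DisruptionMode.EDGE_SET:
        return _grow_edge_cluster(edge_index, n_target, rng)
    if d.mode is DisruptionMode.HUB_TARGETED:
        cut = np.quantile(propensity, d.hub_quantile)
        hub = propensity >= cut
        cand = np.nonzero(hub[edge_index[:, 0]] | hub[edge_index[:, 1]])[0]
    elif d.mode is DisruptionMode.INTERHEMISPHERIC:
        cand = np.nonzero(
            hemisphere[edge_index[:, 0]] != hemisphere[edge_index[:, 1]]
        )[0]
    else:  # NONE, IDIOSYNCRATIC
        return np.empty(0, dtype=int)
    if n_target > cand.size:
        raise ValidationError(
            f"target_fraction asks for {n_target} edges but only {cand.size} candidates"
        )
    return rng.choice(cand, size=n_target, replace=False)


def _grow_edge_cluster(
    edge_index: np.ndarray, n_target: int, rng: np.random.Generator
) -> np.ndarray:
    """Grow a connected cluster of edges by BFS from a random seed edge."""
    n_edges = edge_index.shape[0]
    if n_target > n_edges:
        raise ValidationError(f"cannot plant {n_target} edges in a {n_edges}-edge graph")
    if n_target == 0:
        return np.empty(0, dtype=int)
    incident: dict[int, list[int]] = {}
    for e, (a, b) in enumerate(edge_index):
        incident.setdefault(int(a), []).append(e)
        incident.setdefault(int(b), []).append(e)
    seed = int(rng.integers(n_edges))
    chosen = [seed]
    chosen_set = {seed}
    frontier = list(edge_index[seed])
    while len(chosen) < n_target:
        cand = [
            e
            for node in frontier
            for e in incident.get(int(node), [])
            if e not in chosen_set
        ]
        if not cand:  # component exhausted; jump to a fresh seed edge
            rest = [e for e in range(n_edges) if e not in chosen_set]
            cand = [int(rng.choice(rest))]
        e = int(rng.choice(np.unique(cand)))
        chosen.append(e)
        chosen_set.add(e)
        frontier.extend(edge_index[e])
    return np.array(sorted(chosen), dtype=int)


# rough anatomical groupings for generated node metadata
_LOBES = ("frontal", "parietal", "temporal", "occipital", "insula", "subcortical")


def _make_node_table(n_nodes: int, rng: np.random.Generator) -> NodeTable:
    """Half/half hemisphere split; lobes cycle through a fixed list."""
    hemi = np.array(["L"] * (n_nodes // 2) + ["R"] * (n_nodes - n_nodes // 2))
    lobes = [_LOBES[i % len(_LOBES)] for i in range(n_nodes)]
    ids = [f"n{i:03d}" for i in range(n_nodes)]
    return NodeTable(
        pd.DataFrame(
            {
                "node_id": ids,
                "name": [f"region_{i:03d}_{h}" for i, h in enumerate(hemi)],
                "hemisphere": hemi,
                "lobe": lobes,
            }
        )
    )


def _make_manifest(spec: SimulationSpec, rng: np.random.Generator) -> CohortManifest:
    rows = []
    for label, n in spec.groups:
        for i in range(n):
            rows.append(
                {
                    "subject_id": f"{label}_{i:03d}",
                    "group": label,
                    "age": float(np.clip(rng.normal(25.0, 4.0), 18, 45).round(1)),
                    "sex": "M" if rng.random() < 0.6 else "F",
                    "site": "SIM",
                }
            )
    return CohortManifest(pd.DataFrame(rows))


def simulate_cohort(spec: SimulationSpec) -> SyntheticCohort:
    """Generate a cohort with identical topology across subjects and the
    planted group difference described by ``spec.disruption``.

    Same seed => byte-identical output. Ground truth (disrupted edge
    list, latent propensities, hub nodes) is returned for recovery
    tests.
    """
    root = np.random.SeedSequence(spec.rng_seed)
    keys = ("structure", "targets", "manifest", "noise")
    streams = dict(zip(keys, (np.random.default_rng(s) for s in root.spawn(len(keys)))))

    n = spec.n_nodes
    rng = streams["structure"]
    propensity = 1.0 + rng.pareto(2.5, size=n)
    score = np.power(np.outer(propensity, propensity), spec.hub_exponent)
    np.fill_diagonal(score, 0.0)
    adj = _build_topology(score, spec.base_density, rng)
    iu, ju = np.nonzero(np.triu(adj, 1))
    edge_index = np.column_stack([iu, ju])

    mean_w = score[iu, ju]
    mean_w = mean_w / mean_w.mean()  # unit mean edge weight

    node_table = _make_node_table(n, streams["structure"])
    hemisphere = node_table.hemisphere_vector()
    manifest = _make_manifest(spec, streams["manifest"])

    targets = _select_targets(spec, edge_index, propensity, hemisphere, streams["targets"])
    d = spec.disruption
    affected = (
        set(d.affected_groups)
        if d.affected_groups is not None
        else {label for label, _ in spec.groups[1:]}
    )

    node_ids = node_table.node_ids
    sigma = spec.subject_noise_sigma
    noise_rng = streams["noise"]
    matrices: dict[str, ConnectomeMatrix] = {}
    for _, row in manifest.table.iterrows():
        mu = mean_w.copy()
        if row["group"] in affected and targets.size:
            mu[targets] = mu[targets] * d.effect_size
        z = noise_rng.normal(size=mean_w.size)
        w_edges = mu * np.exp(sigma * z - sigma**2 / 2.0)
        w = np.zeros((n, n))
        w[iu, ju] = w_edges
        w = w + w.T
        matrices[row["subject_id"]] = ConnectomeMatrix(
            row["subject_id"], spec.weight_kind, w, node_ids
        )

    cut = np.quantile(propensity, d.hub_quantile if d.mode is DisruptionMode.HUB_TARGETED else 0.9)
    truth = GroundTruth(
        disrupted_edges=[(node_ids[a], node_ids[b]) for a, b in edge_index[targets]],
        latent_propensity=propensity,
        hub_nodes=[node_ids[i] for i in np.nonzero(propensity >= cut)[0]],
    )
    return SyntheticCohort(matrices, node_table, manifest, truth, mean_w, edge_index)


def plant_idiosyncrasy(
    cohort: SyntheticCohort,
    per_subject_fraction: float,
    effect_size: float,
    groups: tuple[str, ...] | None = None,
    seed: int = 0,
) -> SyntheticCohort:
    """Perturb an independent random edge subset per subject.

    Each selected edge is multiplied by exp(+-effect_size) with random
    sign, so the group geometric mean is unchanged in expectation while
    within-group similarity of hub rankings drops. ``groups`` restricts
    the perturbation to listed groups (default: all).
    """
    if not 0 <= per_subject_fraction <= 1:
        raise ValidationError("per_subject_fraction must be in [0, 1]")
    if per_subject_fraction == 0 or effect_size == 0:
        return cohort
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x1D10)))
    iu = cohort.edge_index[:, 0]
    ju = cohort.edge_index[:, 1]
    n_pick = int(round(per_subject_fraction * cohort.edge_index.shape[0]))
    groupset = set(groups) if groups is not None else None
    new_matrices = {}
    group_of = dict(zip(cohort.manifest.subject_ids, cohort.manifest.table["group"]))
    for sid, m in cohort.matrices.items():
        if groupset is not None and group_of[sid] not in groupset:
            new_matrices[sid] = m
            continue
        pick = rng.choice(cohort.edge_index.shape[0], size=n_pick, replace=False)
        sign = rng.choice([-1.0, 1.0], size=n_pick)
        w = m.weights.copy()
        factor = np.exp(sign * effect_size)
        w[iu[pick], ju[pick]] *= factor
        w[ju[pick], iu[pick]] = w[iu[pick], ju[pick]]
        new_matrices[sid] = ConnectomeMatrix(sid, m.weight_kind, w, m.node_ids)
    return replace(cohort, matrices=new_matrices)


#: target expectation scales per weight kind (FA unitless; diffusivities mm^2/s)
_KIND_SCALE = {
    WeightKind.FA: ("unit_interval", 0.45),
    WeightKind.MD: ("linear", 0.8e-3),
    WeightKind.AD: ("linear", 1.2e-3),
    WeightKind.RD: ("linear", 0.6e-3),
    WeightKind.LOG_SIFT2: ("identity", 1.0),
}


def rescale_to_kind(m: ConnectomeMatrix, kind: WeightKind | str) -> ConnectomeMatrix:
    """Monotonically rescale a generated matrix to a weight kind's range.

    FA maps to (0, 1) via w/(w + median); MD/RD/AD are linear rescales
    to typical diffusivity magnitudes with AD >= MD >= RD on expectation.
    Monotone maps preserve ranks, so hubness and rank-based analyses
    are unchanged; only scales differ.
    """
    kind = WeightKind(kind)
    how, scale = _KIND_SCALE[kind]
    w = m.weights.copy()
    nz = w > 0
    if how == "identity":
        out = w
    elif how == "unit_interval":
        med = np.median(w[nz]) if nz.any() else 1.0
        out = np.where(nz, 2 * scale * w / (w + med), 0.0)
    else:
        mean = w[nz].mean() if nz.any() else 1.0
        out = np.where(nz, w * (scale / mean), 0.0)
    return ConnectomeMatrix(m.subject_id, kind, out, m.node_ids)
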