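"""Edgewise GLM and the extent-based network-based statistic (NBS).

Edges present in at least ``edge_mask_fraction`` of subjects form the
analysis mask. Each masked edge's weight is regressed on the predictor
of interest (a group indicator or a continuous clinical score) plus
nuisance covariates (age, sex, optionally site). Edgewise t statistics
are signed so the hypothesized direction is positive, and one-sided
components are formed from edges with t >= t_threshold. Family-wise
error over components is controlled by permutation: the null
distribution is the maximum component extent (edge count) per
permutation, using Freedman-Lane residual permutation when nuisance
covariates are present and plain label permutation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    AnalysisConfig,
    CohortManifest,
    ConnectomeMatrix,
    NodeTable,
    ValidationError,
)


@dataclass
class EdgewiseDesign:
    """Aligned response/predictor matrices for the edgewise GLM."""

    Y: np.ndarray  # n_subjects x n_edges
    predictor: np.ndarray  # n_subjects
    nuisance: np.ndarray  # n_subjects x q (may be empty)
    edge_index: np.ndarray  # n_edges x 2 node indices (upper triangle)
    node_ids: list[str]
    subject_ids: list[str]
    tail: str = "higher"  # hypothesized sign of the predictor effect
    permute_scheme: str = "auto"  # auto | freedman_lane | labels

    def __post_init__(self) -> None:
        n = self.Y.shape[0]
        if self.predictor.shape != (n,):
            raise ValidationError("predictor misaligned with response rows")
        if self.nuisance.ndim != 2 or self.nuisance.shape[0] != n:
            raise ValidationError("nuisance misaligned with response rows")
        if self.tail not in ("lower", "higher"):
            raise ValidationError("tail must be 'lower' or 'higher'")
        q = self.nuisance.shape[1]
        if n <= q + 2:
            raise ValidationError(f"{n} subjects cannot support {q} nuisance covariates")
        X = np.column_stack([np.ones(n), self.predictor, self.nuisance])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValidationError("design matrix is rank deficient")


@dataclass
class NbsResult:
    t_stats: np.ndarray  # signed t per masked edge
    edge_index: np.ndarray
    node_ids: list[str]
    components: list[np.ndarray]  # edge-index arrays, sorted by extent desc
    extents: list[int]
    p_values: list[float]
    null_max_extent: np.ndarray
    t_threshold: float
    alpha: float
    n_perm: int

    def significant_edges(self) -> list[tuple[str, str]]:
        """Node-id pairs of every edge in a component with p <= alpha."""
        out: list[tuple[str, str]] = []
        for comp, p in zip(self.components, self.p_values):
            if p <= self.alpha:
                out.extend(
                    (self.node_ids[a], self.node_ids[b])
                    for a, b in self.edge_index[comp]
                )
        return out


def common_edge_mask(
    matrices: list[ConnectomeMatrix], fraction: float = 0.9
) -> np.ndarray:
    """(E, 2) upper-triangle indices of edges nonzero in >= ``fraction``
    of subjects."""
    if not matrices:
        raise ValidationError("no matrices")
    n = matrices[0].n_nodes
    present = np.zeros((n, n))
    for m in matrices:
        present += m.weights > 0
    iu, ju = np.triu_indices(n, k=1)
    keep = present[iu, ju] >= fraction * len(matrices)
    return np.column_stack([iu[keep], ju[keep]])


def make_design(
    matrices: dict[str, ConnectomeMatrix],
    manifest: CohortManifest,
    contrast: tuple[str, str] | None = None,
    score: str | None = None,
    covariates: tuple[str, ...] = ("age", "sex"),
    tail: str = "higher",
    edge_mask_fraction: float = 0.9,
    log_transform_score: bool = False,
) -> EdgewiseDesign:
    """Assemble an EdgewiseDesign for a group contrast or a continuous
    clinical-score regression.

    For a contrast (A, B) the predictor is the group-B indicator, so
    ``tail='lower'`` hypothesizes lower weights in B (e.g. patients
    lower FA). For ``score`` regressions the predictor is the named
    manifest column (optionally log-transformed, as for duration of
    untreated psychosis); subjects missing the score or any covariate
    are excluded listwise.
    """
    if (contrast is None) == (score is None):
        raise ValidationError("specify exactly one of contrast or score")
    t = manifest.table.set_index("subject_id")
    if contrast is not None:
        ga, gb = contrast
        sids = [s for s in manifest.subject_ids if t.loc[s, "group"] in (ga, gb)]
        pred = pd.Series(
            [1.0 if t.loc[s, "group"] == gb else 0.0 for s in sids], index=sids
        )
    else:
        if score not in t.columns:
            raise ValidationError(f"score column {score!r} missing from manifest")
        pred = pd.to_numeric(t[score], errors="coerce")
        sids = list(pred.dropna().index)
        pred = pred.loc[sids]
        if log_transform_score:
            if (pred <= 0).any():
                raise ValidationError("log transform requires positive scores")
            pred = np.log(pred)

    cov_cols = []
    for c in covariates:
        if c not in t.columns:
            raise ValidationError(f"covariate {c!r} missing from manifest")
        col = t[c]
        if c == "sex":
            col = col.map({"M": 0.0, "F": 1.0})
        elif col.dtype == object:
            col = pd.Series(pd.factorize(col)[0], index=col.index, dtype=float)
        cov_cols.append(pd.to_numeric(col, errors="coerce"))
    if cov_cols:
        cov = pd.concat(cov_cols, axis=1).loc[sids]
        complete = cov.notna().all(axis=1)
        sids = [s for s, ok in zip(sids, complete) if ok]
        Z = cov.loc[sids].to_numpy(dtype=float)
        # drop constant nuisance columns (e.g. single-site cohorts)
        Z = Z[:, Z.std(axis=0) > 0]
    else:
        Z = np.empty((len(sids), 0))

    mats = [matrices[s] for s in sids]
    edge_index = common_edge_mask(mats, edge_mask_fraction)
    Y = np.stack([m.weights[edge_index[:, 0], edge_index[:, 1]] for m in mats])
    return EdgewiseDesign(
        Y=Y,
        predictor=pred.loc[sids].to_numpy(dtype=float),
        nuisance=Z,
        edge_index=edge_index,
        node_ids=mats[0].node_ids,
        subject_ids=sids,
        tail=tail,
    )


def _t_for_predictor(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """t statistic of column 1 of X, per column of Y (OLS)."""
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    pinv = xtx_inv @ X.T
    B = pinv @ Y
    resid = Y - X @ B
    dof = n - p
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    se = np.sqrt(np.maximum(sigma2, 0.0) * xtx_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, B[1] / se, 0.0)
    return t


def edgewise_glm(design: EdgewiseDesign) -> np.ndarray:
    """Signed edgewise t: OLS of each edge weight on [1, predictor,
    nuisance]; positive t = evidence in the hypothesized direction.

    With two groups and no nuisance this equals the classical pooled
    two-sample t (up to the tail sign convention).
    """
    X = np.column_stack(
        [np.ones(design.Y.shape[0]), design.predictor, design.nuisance]
    )
    t = _t_for_predictor(X, design.Y)
    return -t if design.tail == "lower" else t


def extract_components(
    t_stats: np.ndarray,
    t_threshold: float,
    edge_index: np.ndarray,
    n_nodes: int,
) -> tuple[list[np.ndarray], list[int]]:
    """Connected components (via shared nodes) of edges with
    t >= threshold; extent = edge count. Sorted by extent descending."""
    supra = np.nonzero(t_stats >= t_threshold)[0]
    if supra.size == 0:
        return [], []
    parent = np.arange(n_nodes)

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for e in supra:
        a, b = edge_index[e]
        parent[find(int(a))] = find(int(b))
    comp_edges: dict[int, list[int]] = {}
    for e in supra:
        comp_edges.setdefault(find(int(edge_index[e, 0])), []).append(int(e))
    comps = sorted(comp_edges.values(), key=len, reverse=True)
    return [np.array(c) for c in comps], [len(c) for c in comps]


def _null_max_extents(
    design: EdgewiseDesign,
    t_threshold: float,
    n_perm: int,
    rng: np.random.Generator,
    n_nodes: int,
) -> np.ndarray:
    n = design.Y.shape[0]
    has_nuisance = design.nuisance.shape[1] > 0
    scheme = design.permute_scheme
    if scheme == "auto":
        scheme = "freedman_lane" if has_nuisance else "labels"
    sign = -1.0 if design.tail == "lower" else 1.0
    X_full = np.column_stack([np.ones(n), design.predictor, design.nuisance])

    null = np.zeros(n_perm, dtype=int)
    if scheme == "freedman_lane":
        # permute reduced-model residuals, keep nuisance fit in place
        Z = np.column_stack([np.ones(n), design.nuisance])
        fitted = Z @ (np.linalg.pinv(Z) @ design.Y)
        resid = design.Y - fitted
        for i in range(n_perm):
            Y_star = fitted + resid[rng.permutation(n)]
            t = sign * _t_for_predictor(X_full, Y_star)
            _, extents = extract_components(t, t_threshold, design.edge_index, n_nodes)
            null[i] = max(extents, default=0)
    elif scheme == "labels":
        for i in range(n_perm):
            Xp = X_full.copy()
            Xp[:, 1] = design.predictor[rng.permutation(n)]
            t = sign * _t_for_predictor(Xp, design.Y)
            _, extents = extract_components(t, t_threshold, design.edge_index, n_nodes)
            null[i] = max(extents, default=0)
    else:
        raise ValidationError(f"unknown permutation scheme {scheme!r}")
    return null


def nbs(
    design: EdgewiseDesign,
    config: AnalysisConfig | None = None,
    seed: int | None = None,
) -> NbsResult:
    """Extent-based NBS with permutation FWER control.

    Component p = (1 + #{null max extent >= observed extent}) /
    (n_perm + 1); the observed statistic is included in the null
    (add-one rule), so p is never 0.
    """
    config = config or AnalysisConfig()
    if 1.0 / (config.n_perm_nbs + 1) > config.alpha:
        import warnings

        warnings.warn(
            f"n_perm={config.n_perm_nbs} cannot reach alpha={config.alpha}",
            stacklevel=2,
        )
    n_nodes = len(design.node_ids)
    t_obs = edgewise_glm(design)
    components, extents = extract_components(
        t_obs, config.t_threshold, design.edge_index, n_nodes
    )
    rng = np.random.default_rng(
        np.random.SeedSequence((seed if seed is not None else config.rng_seed, 0x0B5))
    )
    null = _null_max_extents(design, config.t_threshold, config.n_perm_nbs, rng, n_nodes)
    p_values = [
        float((1 + int((null >= ext).sum())) / (config.n_perm_nbs + 1))
        for ext in extents
    ]
    return NbsResult(
        t_stats=t_obs,
        edge_index=design.edge_index,
        node_ids=design.node_ids,
        components=components,
        extents=extents,
        p_values=p_values,
        null_max_extent=null,
        t_threshold=config.t_threshold,
        alpha=config.alpha,
        n_perm=config.n_perm_nbs,
    )


def classify_edges(
    edges: list[tuple[str, str]], node_table: NodeTable
) -> dict[str, object]:
    """Partition edges by endpoint hemispheres and count per-node
    incidences. Per-node counts sum to 2x the number of edges."""
    hemi = node_table.table.set_index("node_id")["hemisphere"]
    intra = inter = 0
    per_node: dict[str, int] = {}
    for a, b in edges:
        for node in (a, b):
            if node not in hemi.index:
                raise ValidationError(f"node {node!r} missing hemisphere")
            per_node[node] = per_node.get(node, 0) + 1
        if hemi[a] == hemi[b]:
            intra += 1
        else:
            inter += 1
    return {
        "intrahemispheric": intra,
        "interhemispheric": inter,
        "per_node_counts": per_node,
    }
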