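"""Composite hubness scoring and rank-similarity permutation inference.

A node's hubness is the average of four rank scores computed per
subject: weighted degree and betweenness contribute ascending (higher =
more hub-like), path length and clustering descending (central,
integrative nodes have short paths and low local clustering). Each rank
score is (rank - 1)/(N - 1) with average ranks for ties, so every
metric contributes on [0, 1] and the composite lies in [0, 1].

Rank similarity between subjects' hubness vectors is Kendall's tau-b;
group differences in within-group mean tau are tested by permuting
subject labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import CohortManifest, ValidationError

#: metric -> direction in which larger values mean more hub-like
HUB_DIRECTIONS = {
    "degree": "ascending",
    "betweenness": "ascending",
    "path_length": "descending",
    "clustering": "descending",
}


@dataclass
class HubnessProfile:
    """Per-subject rank scores per metric and their composite."""

    subject_id: str
    metric_scores: dict[str, np.ndarray]
    composite: np.ndarray


@dataclass
class TauSummary:
    """Rank-similarity summary for one two-group contrast."""

    groups: tuple[str, str]
    subject_ids: list[str]
    tau_matrix: np.ndarray  # S x S, unit diagonal
    within_mean: dict[str, float]
    between_mean: float
    p_within_difference: float
    p_between_vs_within: dict[str, float]
    n_perm: int


def rank_score(values: np.ndarray, direction: str = "ascending") -> np.ndarray:
    """Rank-based score on [0, 1]: (rank - 1)/(N - 1), average ranks
    for ties; 'descending' ranks the negated values."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValidationError("rank_score needs a 1-d vector of length >= 2")
    if not np.all(np.isfinite(values)):
        raise ValidationError("rank_score requires finite values")
    if direction not in ("ascending", "descending"):
        raise ValidationError(f"unknown direction {direction!r}")
    v = values if direction == "ascending" else -values
    ranks = stats.rankdata(v, method="average")
    return (ranks - 1.0) / (values.size - 1.0)


def composite_hubness(
    subject_id: str,
    metrics: dict[str, np.ndarray],
    directions: dict[str, str] | None = None,
) -> HubnessProfile:
    """Average the four per-metric rank scores into one hubness vector.

    Computed independently per subject; no cross-subject pooling.
    """
    directions = directions or HUB_DIRECTIONS
    missing = [k for k in directions if k not in metrics]
    if missing:
        raise ValidationError(f"missing metrics {missing}")
    scores = {k: rank_score(metrics[k], d) for k, d in directions.items()}
    composite = np.mean([scores[k] for k in directions], axis=0)
    return HubnessProfile(subject_id, scores, composite)


def group_mean_hubness(
    profiles: dict[str, HubnessProfile], manifest: CohortManifest, group: str
) -> np.ndarray:
    """Nodewise mean composite hubness over a group's subjects."""
    sids = [s for s in manifest.subjects_in(group) if s in profiles]
    if not sids:
        raise ValidationError(f"no hubness profiles for group {group!r}")
    return np.mean([profiles[s].composite for s in sids], axis=0)


def kendall_tau(a: np.ndarray, b: np.ndarray) -> float:
    """Kendall's tau-b between two score vectors (tie-corrected)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValidationError("kendall_tau needs two equal-length vectors, n >= 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValidationError("kendall_tau undefined for a constant vector")
    return float(stats.kendalltau(a, b).statistic)


def pairwise_tau_matrix(profiles: list[HubnessProfile]) -> np.ndarray:
    """Symmetric S x S matrix of pairwise tau-b with unit diagonal."""
    S = len(profiles)
    tau = np.eye(S)
    for i in range(S):
        for j in range(i + 1, S):
            tau[i, j] = tau[j, i] = kendall_tau(
                profiles[i].composite, profiles[j].composite
            )
    return tau


def _group_tau_means(
    tau: np.ndarray, labels: np.ndarray, ga: str, gb: str
) -> tuple[float, float, float]:
    """(within-A mean, within-B mean, between mean) from a tau matrix."""
    ia = np.nonzero(labels == ga)[0]
    ib = np.nonzero(labels == gb)[0]
    wa = tau[np.ix_(ia, ia)][np.triu_indices(ia.size, k=1)].mean()
    wb = tau[np.ix_(ib, ib)][np.triu_indices(ib.size, k=1)].mean()
    bt = tau[np.ix_(ia, ib)].mean()
    return float(wa), float(wb), float(bt)


def tau_similarity_test(
    profiles: dict[str, HubnessProfile],
    manifest: CohortManifest,
    contrast: tuple[str, str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> TauSummary:
    """Within/between-group rank-similarity with permutation inference.

    Observed statistics: mean pairwise tau within each group, and the
    between-group mean. The null redistributes subjects across the two
    group labels (sizes fixed); two-sided add-one p-values are reported
    for the within-group difference (wA - wB) and for each group's
    between-vs-within contrast. p is never 0; its floor is 1/(n_perm+1).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    ga, gb = contrast
    sids = [s for g in contrast for s in manifest.subjects_in(g) if s in profiles]
    labels = np.array(
        [manifest.table.set_index("subject_id")["group"].loc[s] for s in sids]
    )
    for g in contrast:
        if (labels == g).sum() < 2:
            raise ValidationError(f"group {g!r} needs >= 2 subjects with profiles")
    tau = pairwise_tau_matrix([profiles[s] for s in sids])

    wa, wb, bt = _group_tau_means(tau, labels, ga, gb)
    obs_diff = wa - wb
    obs_bw = {ga: bt - wa, gb: bt - wb}

    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x7A0)))
    exceed_diff = 0
    exceed_bw = {ga: 0, gb: 0}
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        pwa, pwb, pbt = _group_tau_means(tau, perm, ga, gb)
        if abs(pwa - pwb) >= abs(obs_diff):
            exceed_diff += 1
        if abs(pbt - pwa) >= abs(obs_bw[ga]):
            exceed_bw[ga] += 1
        if abs(pbt - pwb) >= abs(obs_bw[gb]):
            exceed_bw[gb] += 1
    denom = n_perm + 1
    return TauSummary(
        groups=(ga, gb),
        subject_ids=sids,
        tau_matrix=tau,
        within_mean={ga: wa, gb: wb},
        between_mean=bt,
        p_within_difference=(1 + exceed_diff) / denom,
        p_between_vs_within={g: (1 + exceed_bw[g]) / denom for g in contrast},
        n_perm=n_perm,
    )
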