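"""Hub-vulnerability analysis: do disrupted edges preferentially attach
to nodes of a given hubness?

For each threshold k on a grid inside (0, 1), a node set is selected
from a group-level hubness ranking — either the band k +- r (kernel
radius r, default 0.05) or all nodes above/below k (threshold variants)
— and the proportion of disrupted edges touching that set is compared
to randomly selected node sets of equal size. The null envelope is the
2.5th-97.5th percentile of the random-set proportions.

The band statistic counts edges with at least one endpoint in the set
(INCIDENT); the threshold-subgraph variants count edges with both
endpoints inside (INDUCED), since only edges within the subgraph are
evaluated there. The denominator is the total number of disrupted
edges; passing ``denominator='subgraph_edges'`` (with ``all_edges``)
switches to the alternative reading where the threshold-variant
proportion is taken over the edges of the selected subgraph.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np

from .containers import AnalysisConfig, ValidationError

log = logging.getLogger("connectodiff")


class BandStatistic(str, enum.Enum):
    BAND = "BAND"
    THRESHOLD_ABOVE = "THRESHOLD_ABOVE"
    THRESHOLD_BELOW = "THRESHOLD_BELOW"


@dataclass
class BandCurve:
    """Observed disruption proportion over the k grid with its null."""

    k_grid: np.ndarray
    statistic: BandStatistic
    observed: np.ndarray  # NaN where the selection was empty
    null_mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    set_sizes: np.ndarray
    n_null: int

    def exceedances(self) -> np.ndarray:
        """Boolean per k: observed above the 95% null envelope."""
        with np.errstate(invalid="ignore"):
            return self.observed > self.ci_high


def band_select(hubness: np.ndarray, k: float, r: float) -> np.ndarray:
    """Boolean mask of nodes with hubness in [k - r, k + r]."""
    hubness = np.asarray(hubness, dtype=float)
    if hubness.min() < 0 or hubness.max() > 1:
        raise ValidationError("hubness scores must lie in [0, 1]")
    if not 0 < r < 0.5:
        raise ValidationError("kernel radius must be in (0, 0.5)")
    return (hubness >= k - r) & (hubness <= k + r)


def threshold_select(hubness: np.ndarray, k: float, above: bool) -> np.ndarray:
    hubness = np.asarray(hubness, dtype=float)
    return hubness >= k if above else hubness <= k


def disruption_proportion(
    disrupted: np.ndarray, selected: np.ndarray, mode: str = "incident"
) -> float:
    """Fraction of disrupted edges touching the selected node set.

    ``incident``: >= 1 endpoint selected (band analysis);
    ``induced``: both endpoints selected (threshold-subgraph analysis).
    Zero disrupted edges => 0.
    """
    if disrupted.size == 0:
        return 0.0
    a = selected[disrupted[:, 0]]
    b = selected[disrupted[:, 1]]
    if mode == "incident":
        hit = a | b
    elif mode == "induced":
        hit = a & b
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return float(hit.mean())


def _null_proportions(
    disrupted: np.ndarray,
    n_nodes: int,
    set_size: int,
    mode: str,
    n_null: int,
    rng: np.random.Generator,
    all_edges: np.ndarray | None = None,
) -> np.ndarray:
    """Proportions for ``n_null`` uniformly random node sets of the
    same cardinality (vectorized over draws). With ``all_edges`` the
    denominator is each random set's induced-subgraph edge count."""
    if disrupted.size == 0:
        return np.zeros(n_null)
    member = np.zeros((n_null, n_nodes), dtype=bool)
    for i in range(n_null):
        member[i, rng.choice(n_nodes, size=set_size, replace=False)] = True
    a = member[:, disrupted[:, 0]]
    b = member[:, disrupted[:, 1]]
    hit = ((a | b) if mode == "incident" else (a & b)).sum(axis=1).astype(float)
    if all_edges is None:
        return hit / disrupted.shape[0]
    denom = (member[:, all_edges[:, 0]] & member[:, all_edges[:, 1]]).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, hit / denom, np.nan)


def vulnerability_curve(
    hubness: np.ndarray,
    disrupted_edges: np.ndarray,
    statistic: BandStatistic | str = BandStatistic.BAND,
    config: AnalysisConfig | None = None,
    seed: int | None = None,
    denominator: str = "all_disrupted",
    all_edges: np.ndarray | None = None,
) -> BandCurve:
    """Observed vs null disruption proportion across the hubness grid.

    ``hubness`` is a group-level per-node score in [0, 1] (composite
    hubness or rank-scored degree). ``disrupted_edges`` is an (m, 2)
    array of node indices (e.g. NBS-significant edges). The null uses
    ``config.n_null_nodesets`` random sets for the band statistic and
    ``config.n_null_subgraphs`` for the threshold variants. Empty
    selections yield NaN at that k and are logged.
    """
    config = config or AnalysisConfig()
    statistic = BandStatistic(statistic)
    hubness = np.asarray(hubness, dtype=float)
    disrupted = np.asarray(disrupted_edges, dtype=int).reshape(-1, 2)
    n_nodes = hubness.size
    if disrupted.size and disrupted.max() >= n_nodes:
        raise ValidationError("disrupted edge index out of range")
    if denominator not in ("all_disrupted", "subgraph_edges"):
        raise ValidationError(f"unknown denominator {denominator!r}")
    if denominator == "subgraph_edges" and all_edges is None:
        raise ValidationError("denominator='subgraph_edges' requires all_edges")
    all_edges_arr = (
        np.asarray(all_edges, dtype=int).reshape(-1, 2)
        if denominator == "subgraph_edges"
        else None
    )

    if statistic is BandStatistic.BAND:
        mode, n_null = "incident", config.n_null_nodesets
    else:
        mode, n_null = "induced", config.n_null_subgraphs

    rng = np.random.default_rng(
        np.random.SeedSequence((seed if seed is not None else config.rng_seed, 0xBA7D))
    )
    k_grid = np.asarray(config.k_grid, dtype=float)
    observed = np.full(k_grid.size, np.nan)
    null_mean = np.full(k_grid.size, np.nan)
    ci_low = np.full(k_grid.size, np.nan)
    ci_high = np.full(k_grid.size, np.nan)
    sizes = np.zeros(k_grid.size, dtype=int)

    if disrupted.shape[0] == 0:
        log.warning("vulnerability_curve: zero disrupted edges; degenerate curve")

    for idx, k in enumerate(k_grid):
        if statistic is BandStatistic.BAND:
            sel = band_select(hubness, k, config.kernel_radius)
        else:
            sel = threshold_select(
                hubness, k, above=statistic is BandStatistic.THRESHOLD_ABOVE
            )
        size = int(sel.sum())
        sizes[idx] = size
        if size == 0:
            log.warning("vulnerability_curve: empty selection at k=%.2f", k)
            continue
        obs = disruption_proportion(disrupted, sel, mode)
        if all_edges_arr is not None:
            n_sub = int((sel[all_edges_arr[:, 0]] & sel[all_edges_arr[:, 1]]).sum())
            obs = (
                obs * disrupted.shape[0] / n_sub if n_sub and disrupted.size else np.nan
            )
        null = _null_proportions(
            disrupted, n_nodes, size, mode, n_null, rng, all_edges_arr
        )
        null = null[np.isfinite(null)]
        if null.size == 0:
            continue
        observed[idx] = obs
        null_mean[idx] = float(null.mean())
        ci_low[idx], ci_high[idx] = np.percentile(null, [2.5, 97.5])

    return BandCurve(
        k_grid=k_grid,
        statistic=statistic,
        observed=observed,
        null_mean=null_mean,
        ci_low=ci_low,
        ci_high=ci_high,
        set_sizes=sizes,
        n_null=n_null,
    )
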