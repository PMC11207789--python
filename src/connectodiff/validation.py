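"""Simulation studies that validate the inferential machinery against
the synthetic generator's ground truth.

Each study generates fresh cohorts per replicate, runs the relevant
analysis, and returns aggregate operating characteristics: family-wise
error and recovery for the network-based statistic, envelope coverage
and detection for the hub-vulnerability analysis, and type-I error and
power for the rank-similarity permutation test.

Study conditions are the module defaults below; replicate and
permutation counts are arguments so callers can trade precision for
runtime.
"""

from __future__ import annotations

import numpy as np

from .containers import AnalysisConfig
from .hubness import composite_hubness, group_mean_hubness, tau_similarity_test
from .metrics import node_metrics
from .nbs import make_design, nbs
from .simulate import (
    DisruptionSpec,
    SimulationSpec,
    plant_idiosyncrasy,
    simulate_cohort,
)
from .vulnerability import BandStatistic, vulnerability_curve


def _seed_stream(seed: int, tag: int, n: int) -> list[int]:
    """Deterministic per-replicate seeds below 2**31."""
    ss = np.random.SeedSequence((seed, tag))
    return [int(s) for s in ss.generate_state(n) >> 1]


def nbs_fwer_calibration(
    n_replicates: int = 200,
    n_perm: int = 1000,
    n_nodes: int = 50,
    n_per_group: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Family-wise rejection rate of NBS under the global null.

    Two exchangeable groups (no planted difference); a replicate counts
    as a rejection if any component reaches p <= alpha. Should sit near
    alpha.
    """
    cfg = AnalysisConfig(n_perm_nbs=n_perm, alpha=alpha)
    rejections = 0
    for rep_seed in _seed_stream(seed, 0xF3E, n_replicates):
        cohort = simulate_cohort(
            SimulationSpec(
                n_nodes=n_nodes,
                groups=(("HC", n_per_group), ("PATIENT", n_per_group)),
                rng_seed=rep_seed,
            )
        )
        design = make_design(
            cohort.matrices,
            cohort.manifest,
            contrast=("HC", "PATIENT"),
            covariates=(),
            tail="lower",
        )
        result = nbs(design, cfg, seed=rep_seed)
        if any(p <= alpha for p in result.p_values):
            rejections += 1
    return rejections / n_replicates


def nbs_cluster_recovery(
    n_replicates: int = 50,
    n_perm: int = 1000,
    n_nodes: int = 50,
    n_per_group: int = 20,
    cluster_size: int = 10,
    effect_size: float = 0.5,
    min_recovered: int = 8,
    seed: int = 0,
) -> float:
    """Fraction of replicates where a planted connected edge cluster is
    detected (component p <= .05) with >= ``min_recovered`` of its
    edges inside significant components."""
    cfg = AnalysisConfig(n_perm_nbs=n_perm)
    hits = 0
    for rep_seed in _seed_stream(seed, 0x2EC, n_replicates):
        cohort = simulate_cohort(
            SimulationSpec(
                n_nodes=n_nodes,
                groups=(("HC", n_per_group), ("PATIENT", n_per_group)),
                disruption=DisruptionSpec(
                    mode="EDGE_SET", effect_size=effect_size, n_target_edges=cluster_size
                ),
                rng_seed=rep_seed,
            )
        )
        design = make_design(
            cohort.matrices,
            cohort.manifest,
            contrast=("HC", "PATIENT"),
            covariates=(),
            tail="lower",
        )
        result = nbs(design, cfg, seed=rep_seed)
        sig = {tuple(sorted(e)) for e in result.significant_edges()}
        truth = {tuple(sorted(e)) for e in cohort.truth.disrupted_edges}
        if (
            result.p_values
            and min(result.p_values) <= cfg.alpha
            and len(sig & truth) >= min_recovered
        ):
            hits += 1
    return hits / n_replicates


def _control_hubness(cohort, group: str = "HC") -> np.ndarray:
    profiles = {
        sid: composite_hubness(sid, node_metrics(cohort.matrices[sid]))
        for sid in cohort.manifest.subjects_in(group)
    }
    return group_mean_hubness(profiles, cohort.manifest, group)


def vulnerability_envelope_coverage(
    n_replicates: int = 50,
    n_nodes: int = 246,
    n_per_group: int = 8,
    n_disrupted: int = 100,
    n_null: int = 1000,
    seed: int = 0,
) -> float:
    """Mean fraction of grid points where a hubness-unrelated disrupted
    set stays inside the 95% null envelope.

    The disrupted set is drawn uniformly over node pairs, which makes
    the observed selection exchangeable with the random-node-set null;
    expected coverage is ~95% per point.
    """
    cfg = AnalysisConfig(n_null_nodesets=n_null)
    coverages = []
    for rep_seed in _seed_stream(seed, 0xC0B, n_replicates):
        cohort = simulate_cohort(
            SimulationSpec(
                n_nodes=n_nodes,
                groups=(("HC", n_per_group), ("PATIENT", n_per_group)),
                rng_seed=rep_seed,
            )
        )
        rng = np.random.default_rng(np.random.SeedSequence((rep_seed, 0xD15)))
        iu, ju = np.triu_indices(n_nodes, 1)
        pick = rng.choice(iu.size, size=n_disrupted, replace=False)
        disrupted = np.column_stack([iu[pick], ju[pick]])
        hub = _control_hubness(cohort)
        curve = vulnerability_curve(
            hub, disrupted, BandStatistic.BAND, cfg, seed=rep_seed
        )
        ok = np.isfinite(curve.observed)
        inside = (curve.observed[ok] >= curve.ci_low[ok]) & (
            curve.observed[ok] <= curve.ci_high[ok]
        )
        coverages.append(float(inside.mean()))
    return float(np.mean(coverages))


def vulnerability_hub_detection(
    n_replicates: int = 50,
    n_nodes: int = 246,
    n_per_group: int = 8,
    target_fraction: float = 0.1,
    effect_size: float = 0.5,
    hub_quantile: float = 0.9,
    n_null: int = 1000,
    k_detect: float = 0.8,
    seed: int = 0,
) -> float:
    """Fraction of replicates where hub-targeted disruption pushes the
    observed proportion above the null envelope at some k >= k_detect."""
    cfg = AnalysisConfig(n_null_nodesets=n_null)
    detected = 0
    for rep_seed in _seed_stream(seed, 0x47B, n_replicates):
        cohort = simulate_cohort(
            SimulationSpec(
                n_nodes=n_nodes,
                groups=(("HC", n_per_group), ("PATIENT", n_per_group)),
                disruption=DisruptionSpec(
                    mode="HUB_TARGETED",
                    effect_size=effect_size,
                    target_fraction=target_fraction,
                    hub_quantile=hub_quantile,
                ),
                rng_seed=rep_seed,
            )
        )
        pos = {nid: i for i, nid in enumerate(cohort.node_table.node_ids)}
        disrupted = np.array(
            [[pos[a], pos[b]] for a, b in cohort.truth.disrupted_edges]
        )
        hub = _control_hubness(cohort)
        curve = vulnerability_curve(
            hub, disrupted, BandStatistic.BAND, cfg, seed=rep_seed
        )
        if np.any(curve.exceedances()[curve.k_grid >= k_detect]):
            detected += 1
    return detected / n_replicates


def tau_type1_error(
    n_replicates: int = 200,
    n_perm: int = 500,
    n_nodes: int = 30,
    n_per_group: int = 8,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate of the within-group tau-difference test under
    exchangeable groups; should sit near alpha."""
    rejections = 0
    for rep_seed in _seed_stream(seed, 0x791, n_replicates):
        cohort = simulate_cohort(
            SimulationSpec(
                n_nodes=n_nodes,
                groups=(("HC", n_per_group), ("PATIENT", n_per_group)),
                rng_seed=rep_seed,
            )
        )
        profiles = {
            sid: composite_hubness(sid, node_metrics(m))
            for sid, m in cohort.matrices.items()
        }
        res = tau_similarity_test(
            profiles, cohort.manifest, ("HC", "PATIENT"), n_perm=n_perm, seed=rep_seed
        )
        if res.p_within_difference <= alpha:
            rejections += 1
    return rejections / n_replicates


def tau_idiosyncrasy_power(
    n_replicates: int = 50,
    n_perm: int = 500,
    n_nodes: int = 50,
    n_per_group: int = 8,
    per_subject_fraction: float = 0.3,
    effect_size: float = 1.5,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Power against per-subject idiosyncratic rewiring in one group.

    Returns the detection rate (reduced within-group tau in the
    perturbed group with p <= alpha) and the fraction of replicates
    with the within-group tau reduction in the expected direction.
    """
    detected = 0
    direction = 0
    for rep_seed in _seed_stream(seed, 0x1D2, n_replicates):
        cohort = simulate_cohort(
            SimulationSpec(
                n_nodes=n_nodes,
                groups=(("HC", n_per_group), ("PATIENT", n_per_group)),
                rng_seed=rep_seed,
            )
        )
        cohort = plant_idiosyncrasy(
            cohort, per_subject_fraction, effect_size, groups=("PATIENT",), seed=rep_seed
        )
        profiles = {
            sid: composite_hubness(sid, node_metrics(m))
            for sid, m in cohort.matrices.items()
        }
        res = tau_similarity_test(
            profiles, cohort.manifest, ("HC", "PATIENT"), n_perm=n_perm, seed=rep_seed
        )
        lower = res.within_mean["PATIENT"] < res.within_mean["HC"]
        direction += lower
        if lower and res.p_within_difference <= alpha:
            detected += 1
    return {
        "power": detected / n_replicates,
        "direction_rate": direction / n_replicates,
    }
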