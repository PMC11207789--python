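"""End-to-end orchestration: simulate (or load) -> metrics -> hubness ->
NBS -> hub vulnerability -> rank similarity -> group stats, with a run
manifest recording the config snapshot, per-stage output hashes, and
the seed registry. Re-running with the same config and seed reproduces
identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import AnalysisConfig, ValidationError
from .hubness import composite_hubness, group_mean_hubness, tau_similarity_test
from .io import (
    load_cohort_matrices,
    read_manifest,
    read_node_table,
    write_config,
    write_connectome,
    write_manifest,
    write_node_table,
)
from .metrics import global_metrics, node_metrics
from .nbs import classify_edges, make_design, nbs
from .group_stats import global_average_comparison
from .simulate import SimulationSpec, simulate_cohort
from .vulnerability import BandStatistic, vulnerability_curve

log = logging.getLogger("connectodiff")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(
    config: AnalysisConfig,
    out_dir: str | Path,
    sim_spec: SimulationSpec | None = None,
    data_dir: str | Path | None = None,
    contrast: tuple[str, str] | None = None,
) -> dict:
    """Run every stage in dependency order and write a consolidated
    report. Returns the run manifest (also written as run_manifest.json).

    Inputs come either from ``sim_spec`` (synthetic cohort) or from
    ``data_dir`` containing manifest.tsv, nodes.tsv and per-subject
    matrix TSVs. ``contrast`` defaults to (first group, second group).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}
    seed = config.rng_seed

    def record(stage: str, files: list[Path], **extra) -> None:
        stages[stage] = {
            "outputs": {f.name: _sha256(f) for f in files},
            **extra,
        }

    # --- inputs -----------------------------------------------------
    try:
        if sim_spec is not None:
            cohort = simulate_cohort(sim_spec)
            matrices, node_table, manifest = (
                cohort.matrices,
                cohort.node_table,
                cohort.manifest,
            )
            sim_dir = out / "cohort"
            sim_dir.mkdir(exist_ok=True)
            for sid, m in matrices.items():
                write_connectome(m, sim_dir / f"{sid}.tsv")
            write_manifest(manifest, out / "manifest.tsv")
            write_node_table(node_table, out / "nodes.tsv")
            truth_path = out / "ground_truth.json"
            truth_path.write_text(
                json.dumps(
                    {
                        "disrupted_edges": cohort.truth.disrupted_edges,
                        "hub_nodes": cohort.truth.hub_nodes,
                    },
                    default=_json_default,
                )
            )
            record(
                "simulate",
                [out / "manifest.tsv", out / "nodes.tsv", truth_path],
                n_subjects=len(matrices),
            )
        elif data_dir is not None:
            data_dir = Path(data_dir)
            manifest = read_manifest(data_dir / "manifest.tsv")
            node_table = read_node_table(data_dir / "nodes.tsv")
            matrices = load_cohort_matrices(
                data_dir / "cohort", manifest, config_weight_kind(config)
            )
            cohort = None
            record("load", [], n_subjects=len(matrices))
        else:
            raise ValidationError("provide sim_spec or data_dir")
    except ValidationError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError("inputs", exc) from exc

    groups = manifest.groups
    contrast = contrast or (groups[0], groups[1])

    # --- graph metrics ----------------------------------------------
    try:
        nodal = {sid: node_metrics(m) for sid, m in matrices.items()}
        glob = {sid: global_metrics(m) for sid, m in matrices.items()}
        rows = [
            {"subject_id": sid, "metric": met, "node": node, "value": val}
            for sid, mm in nodal.items()
            for met, vec in mm.items()
            for node, val in zip(matrices[sid].node_ids, vec)
        ]
        metrics_path = out / "node_metrics.tsv"
        pd.DataFrame(rows).to_csv(metrics_path, sep="\t", index=False)
        glob_path = out / "global_metrics.tsv"
        pd.DataFrame(
            [{"subject_id": s, **g} for s, g in glob.items()]
        ).to_csv(glob_path, sep="\t", index=False)
        record("metrics", [metrics_path, glob_path])
    except Exception as exc:
        raise StageError("metrics", exc) from exc

    # --- hubness -----------------------------------------------------
    try:
        profiles = {sid: composite_hubness(sid, mm) for sid, mm in nodal.items()}
        hub_path = out / "hubness.tsv"
        pd.DataFrame(
            {sid: p.composite for sid, p in profiles.items()},
            index=next(iter(matrices.values())).node_ids,
        ).rename_axis("node_id").to_csv(hub_path, sep="\t")
        record("hubness", [hub_path])
    except Exception as exc:
        raise StageError("hubness", exc) from exc

    # --- NBS ---------------------------------------------------------
    try:
        wk = next(iter(matrices.values())).weight_kind.value
        design = make_design(
            matrices,
            manifest,
            contrast=contrast,
            covariates=("age", "sex"),
            tail=config.tail.get(wk, "lower"),
            edge_mask_fraction=config.edge_mask_fraction,
        )
        result = nbs(design, config, seed=seed)
        sig_edges = result.significant_edges()
        edge_class = classify_edges(sig_edges, node_table)
        nbs_path = out / "nbs.json"
        nbs_path.write_text(
            json.dumps(
                {
                    "contrast": list(contrast),
                    "extents": result.extents,
                    "p_values": result.p_values,
                    "n_significant_edges": len(sig_edges),
                    "intrahemispheric": edge_class["intrahemispheric"],
                    "interhemispheric": edge_class["interhemispheric"],
                },
                default=_json_default,
            )
        )
        sig_path = out / "nbs_significant_edges.tsv"
        pd.DataFrame(sig_edges, columns=["node_i", "node_j"]).to_csv(
            sig_path, sep="\t", index=False
        )
        record("nbs", [nbs_path, sig_path], n_components=len(result.extents))
    except Exception as exc:
        raise StageError("nbs", exc) from exc

    # --- hub vulnerability -------------------------------------------
    try:
        ref_hub = group_mean_hubness(profiles, manifest, contrast[0])
        node_pos = {nid: i for i, nid in enumerate(design.node_ids)}
        dis = np.array(
            [[node_pos[a], node_pos[b]] for a, b in sig_edges], dtype=int
        ).reshape(-1, 2)
        curve = vulnerability_curve(
            ref_hub, dis, BandStatistic.BAND, config, seed=seed
        )
        vuln_path = out / "hub_vulnerability.tsv"
        pd.DataFrame(
            {
                "k": curve.k_grid,
                "observed": curve.observed,
                "null_mean": curve.null_mean,
                "ci_low": curve.ci_low,
                "ci_high": curve.ci_high,
                "set_size": curve.set_sizes,
            }
        ).to_csv(vuln_path, sep="\t", index=False)
        record("hubvuln", [vuln_path], n_disrupted_edges=int(dis.shape[0]))
    except Exception as exc:
        raise StageError("hubvuln", exc) from exc

    # --- rank similarity ---------------------------------------------
    try:
        tau = tau_similarity_test(
            profiles, manifest, contrast, n_perm=config.n_perm_tau, seed=seed
        )
        tau_path = out / "rank_similarity.json"
        tau_path.write_text(
            json.dumps(
                {
                    "within_mean": tau.within_mean,
                    "between_mean": tau.between_mean,
                    "p_within_difference": tau.p_within_difference,
                    "p_between_vs_within": tau.p_between_vs_within,
                    "n_perm": tau.n_perm,
                },
                default=_json_default,
            )
        )
        record("ranksim", [tau_path])
    except Exception as exc:
        raise StageError("ranksim", exc) from exc

    # --- group stats --------------------------------------------------
    try:
        cmp_res = global_average_comparison(matrices, manifest)
        stats_path = out / "group_stats.json"
        stats_path.write_text(
            json.dumps(
                {
                    "test": cmp_res.test,
                    "statistic": cmp_res.statistic,
                    "df": cmp_res.df,
                    "p": cmp_res.p,
                    "pairwise_p": {f"{a}|{b}": p for (a, b), p in cmp_res.pairwise_p.items()},
                },
                default=_json_default,
            )
        )
        record("groupstats", [stats_path])
    except Exception as exc:
        raise StageError("groupstats", exc) from exc

    cfg_path = out / "config.yaml"
    write_config(config, cfg_path)
    run_manifest = {
        "version": __version__,
        "seed": seed,
        "config": cfg_path.name,
        "config_hash": _sha256(cfg_path),
        "contrast": list(contrast),
        "stages": stages,
    }
    (out / "run_manifest.json").write_text(
        json.dumps(run_manifest, indent=2, default=_json_default)
    )
    return run_manifest


def config_weight_kind(config: AnalysisConfig) -> str:
    """Weight kind to load when reading data from disk (first tail key)."""
    return next(iter(config.tail))
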