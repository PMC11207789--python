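"""TSV/YAML input-output and cohort filtering.

Matrix dialect: TSV with node ids as the first row and first column.
Manifests and node tables are plain TSV with one header row. All
readers validate on load and raise :class:`ValidationError` on
malformed input.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import (
    AnalysisConfig,
    CohortManifest,
    ConnectomeMatrix,
    NodeTable,
    ValidationError,
    WeightKind,
)

log = logging.getLogger("connectodiff")


def read_connectome(path: str | Path, weight_kind: WeightKind | str) -> ConnectomeMatrix:
    """Read one subject's connectome from a TSV with id header row/column.

    The subject id is taken from the file stem. Symmetry within 1e-9 is
    required; the matrix is symmetrized by averaging residual rounding.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValidationError(f"{path}: non-square matrix {df.shape}")
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if row_ids != col_ids:
        raise ValidationError(f"{path}: row and column node ids disagree")
    w = df.to_numpy(dtype=float)
    if np.isnan(w).any():
        raise ValidationError(f"{path}: NaN entries")
    return ConnectomeMatrix(path.stem, WeightKind(weight_kind), w, row_ids)


def write_connectome(m: ConnectomeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(m.weights, index=m.node_ids, columns=m.node_ids)
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_node_table(path: str | Path) -> NodeTable:
    return NodeTable(pd.read_csv(path, sep="\t", dtype={"node_id": str}))


def write_node_table(nt: NodeTable, path: str | Path) -> None:
    nt.table.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> CohortManifest:
    """Read the cohort manifest. Optional covariates absent from the
    file are left out entirely; empty cells become NaN (missing), never
    zero."""
    return CohortManifest(pd.read_csv(path, sep="\t", dtype={"subject_id": str}))


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    manifest.table.to_csv(path, sep="\t", index=False)


def read_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from YAML or JSON."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) if path.suffix in {".yaml", ".yml"} else json.load(fh)
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys {sorted(unknown)}")
    if "k_grid" in raw:
        raw["k_grid"] = tuple(raw["k_grid"])
    return AnalysisConfig(**raw)


def write_config(config: AnalysisConfig, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    d["k_grid"] = [float(k) for k in config.k_grid]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def filter_cohort(
    manifest: CohortManifest,
    groups: list[str] | None = None,
    age_min: float | None = None,
    age_max: float | None = None,
) -> CohortManifest:
    """Declarative cohort filter: group membership and/or age bounds.

    Used e.g. to form an age-matched subset by applying the same age
    cutoff to each group. Logs per-group counts before and after.
    Raises if a requested group is absent or a referenced group ends
    up empty.
    """
    t = manifest.table
    keep = pd.Series(True, index=t.index)
    if groups is not None:
        present = set(t["group"])
        absent = [g for g in groups if g not in present]
        if absent:
            raise ValidationError(f"groups not in manifest: {absent}")
        keep &= t["group"].isin(groups)
    if age_min is not None:
        keep &= t["age"] >= age_min
    if age_max is not None:
        keep &= t["age"] <= age_max
    out = t.loc[keep]
    before = t["group"].value_counts().to_dict()
    after = out["group"].value_counts().to_dict()
    log.info("filter_cohort: group sizes %s -> %s", before, after)
    for g in groups or []:
        if after.get(g, 0) == 0:
            raise ValidationError(f"filter leaves group {g!r} empty")
    return CohortManifest(out.reset_index(drop=True))


def load_cohort_matrices(
    directory: str | Path,
    manifest: CohortManifest,
    weight_kind: WeightKind | str,
) -> dict[str, ConnectomeMatrix]:
    """Load ``<subject_id>.tsv`` for every manifest subject, checking
    node-id consistency across the cohort."""
    directory = Path(directory)
    out: dict[str, ConnectomeMatrix] = {}
    node_ids: list[str] | None = None
    for sid in manifest.subject_ids:
        m = read_connectome(directory / f"{sid}.tsv", weight_kind)
        m.subject_id = sid
        if node_ids is None:
            node_ids = m.node_ids
        elif m.node_ids != node_ids:
            raise ValidationError(f"subject {sid}: node ids differ from cohort")
        out[sid] = m
    return out
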