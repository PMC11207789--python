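"""Core data containers for weighted structural-connectome analysis.

A connectome here is a symmetric, nonnegative, zero-diagonal weighted
adjacency matrix over a fixed node set (an atlas parcellation). One
matrix exists per subject per weight kind: DTI scalars (FA, MD, RD, AD)
or the log-transformed SIFT2-weighted streamline count.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SYMMETRY_TOL = 1e-9


class WeightKind(str, enum.Enum):
    """Edge-weight semantics of a connectome matrix.

    FA is unitless in [0, 1]; MD/RD/AD are diffusivities in mm^2/s;
    LOG_SIFT2 is the natural log of the SIFT2-weighted streamline count.
    """

    FA = "FA"
    MD = "MD"
    RD = "RD"
    AD = "AD"
    LOG_SIFT2 = "LOG_SIFT2"


class Group(str, enum.Enum):
    """Recognised cohort group labels."""

    HC = "HC"
    FEP = "FEP"
    CHRONIC = "CHRONIC"
    EP = "EP"
    PATIENT = "PATIENT"


#: Group labels accepted in manifests (synthetic cohorts may add A/B style
#: labels; validation only requires consistency, but these are canonical).
CANONICAL_GROUPS = frozenset(g.value for g in Group)


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass
class ConnectomeMatrix:
    """One subject's symmetric weighted adjacency for one weight kind.

    Invariants (enforced on construction): square, symmetric within
    1e-9, zero diagonal, all entries finite and >= 0, unique node ids.
    Zero entries denote absent edges.
    """

    subject_id: str
    weight_kind: WeightKind
    weights: np.ndarray
    node_ids: list[str]

    def __post_init__(self) -> None:
        self.weight_kind = WeightKind(self.weight_kind)
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError(f"matrix must be square, got shape {w.shape}")
        n = w.shape[0]
        if len(self.node_ids) != n:
            raise ValidationError(
                f"{len(self.node_ids)} node ids for a {n}x{n} matrix"
            )
        if len(set(self.node_ids)) != n:
            raise ValidationError("duplicate node ids")
        if not np.all(np.isfinite(w)):
            raise ValidationError("non-finite weight")
        if np.any(w < 0):
            raise ValidationError("negative weight")
        asym = np.max(np.abs(w - w.T)) if n else 0.0
        if asym > SYMMETRY_TOL:
            raise ValidationError(f"asymmetry {asym:g} exceeds {SYMMETRY_TOL:g}")
        w = (w + w.T) / 2.0  # symmetrize residual rounding
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def copy(self) -> "ConnectomeMatrix":
        return ConnectomeMatrix(
            self.subject_id, self.weight_kind, self.weights.copy(), list(self.node_ids)
        )


@dataclass
class NodeTable:
    """Node metadata: id, name, hemisphere (L/R) and lobe per node.

    Hemisphere is required for every node so edges can be classified
    as intra- vs interhemispheric.
    """

    table: pd.DataFrame

    REQUIRED = ("node_id", "name", "hemisphere", "lobe")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"node table missing columns {missing}")
        ids = self.table["node_id"].astype(str)
        if ids.duplicated().any():
            raise ValidationError("duplicate node ids in node table")
        bad = ~self.table["hemisphere"].isin(["L", "R"])
        if bad.any():
            raise ValidationError(
                f"hemisphere must be L or R for all nodes; offending rows {list(self.table.index[bad])}"
            )
        self.table = self.table.assign(node_id=ids).reset_index(drop=True)

    @property
    def node_ids(self) -> list[str]:
        return list(self.table["node_id"])

    def hemisphere_vector(self, node_ids: list[str] | None = None) -> np.ndarray:
        """Hemisphere label per node, ordered as ``node_ids``."""
        hemi = self.table.set_index("node_id")["hemisphere"]
        order = node_ids if node_ids is not None else self.node_ids
        try:
            return hemi.loc[order].to_numpy()
        except KeyError as exc:
            raise ValidationError(f"node missing from node table: {exc}") from exc


@dataclass
class CohortManifest:
    """Subject-level table: group membership plus covariates.

    Required columns: subject_id, group, age, sex. Optional covariates
    (site, smoker, cannabis, PANSS subscores, dup_weeks) may be missing
    (NaN); analyses exclude subjects listwise per analysis.
    """

    table: pd.DataFrame

    REQUIRED = ("subject_id", "group", "age", "sex")
    OPTIONAL = (
        "site",
        "smoker",
        "cannabis",
        "panss_positive",
        "panss_negative",
        "panss_general",
        "panss_total",
        "dup_weeks",
    )

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise ValidationError(f"manifest missing columns {missing}")
        if t["subject_id"].duplicated().any():
            dups = t.loc[t["subject_id"].duplicated(), "subject_id"].tolist()
            raise ValidationError(f"duplicate subject ids {dups}")
        age = pd.to_numeric(t["age"], errors="coerce")
        if age.isna().any():
            raise ValidationError("unparsable age")
        bad_sex = ~t["sex"].isin(["M", "F"])
        if bad_sex.any():
            raise ValidationError("sex must be M or F")
        self.table = t.assign(
            subject_id=t["subject_id"].astype(str),
            group=t["group"].astype(str),
            age=age.astype(float),
        ).reset_index(drop=True)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.table["subject_id"])

    @property
    def groups(self) -> list[str]:
        """Group labels in first-appearance order."""
        return list(dict.fromkeys(self.table["group"]))

    def group_sizes(self) -> dict[str, int]:
        return self.table["group"].value_counts().to_dict()

    def subjects_in(self, group: str) -> list[str]:
        sel = self.table["group"] == group
        if not sel.any():
            raise ValidationError(f"group {group!r} not present in manifest")
        return list(self.table.loc[sel, "subject_id"])

    def covariate(self, name: str) -> pd.Series:
        """Covariate indexed by subject_id; missing values are NaN."""
        if name not in self.table.columns:
            return pd.Series(np.nan, index=self.subject_ids, name=name)
        return self.table.set_index("subject_id")[name]


@dataclass
class AnalysisConfig:
    """Tunable parameters of the full analysis.

    Defaults follow the published analysis: edgewise T threshold 3.0
    with 10 000 permutations and alpha 0.05 for the network-based
    statistic; hubness-band kernel radius 0.05 over k in (0.1, 0.9);
    10 000 random node sets for the band null and 1000 random subgraphs
    for the threshold variant; 10 000 permutations for the rank
    similarity test.
    """

    t_threshold: float = 3.0
    n_perm_nbs: int = 10_000
    alpha: float = 0.05
    kernel_radius: float = 0.05
    k_grid: tuple[float, ...] = tuple(np.round(np.arange(0.10, 0.901, 0.05), 2))
    n_null_nodesets: int = 10_000
    n_null_subgraphs: int = 1_000
    n_perm_tau: int = 10_000
    rng_seed: int = 0
    edge_mask_fraction: float = 0.9
    #: hypothesised patient-vs-control direction per weight kind
    tail: dict = field(
        default_factory=lambda: {
            "FA": "lower",
            "MD": "higher",
            "RD": "higher",
            "AD": "higher",
            "LOG_SIFT2": "lower",
        }
    )

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.t_threshold <= 0:
            raise ValidationError("t_threshold must be > 0")
        for name in ("n_perm_nbs", "n_null_nodesets", "n_null_subgraphs", "n_perm_tau"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if not all(0 < k < 1 for k in self.k_grid):
            raise ValidationError("k_grid values must lie strictly inside (0, 1)")
        if not 0 < self.kernel_radius < 0.5:
            raise ValidationError("kernel_radius must be in (0, 0.5)")
        if not 0 < self.edge_mask_fraction <= 1:
            raise ValidationError("edge_mask_fraction must be in (0, 1]")
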