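"""Scalar statistics layer: contingency tests for demographics tables
and global network-average comparisons.

Chi-square tests on 2x2 tables use the clipped Yates continuity
correction (each cell term (max(0, |O-E| - 0.5))^2 / E, so the
statistic is exactly 0 when every observed count is within 0.5 of
expectation); larger tables are uncorrected Pearson. Two-sample t-tests
default to pooled variance and accept either raw vectors or
(mean, sd, n) summaries. Three-group comparisons use one-way ANOVA with
Tukey HSD post hoc pairwise tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    CohortManifest,
    ConnectomeMatrix,
    ValidationError,
)
from .metrics import global_network_average


@dataclass
class GroupComparisonResult:
    test: str  # ANOVA_TUKEY | T_TEST | CHI_SQUARE
    statistic: float
    df: float | tuple
    p: float
    pairwise_p: dict[tuple[str, str], float] = field(default_factory=dict)


def chi_square(
    table: np.ndarray, correction: str = "auto"
) -> GroupComparisonResult:
    """Pearson chi-square on an RxC contingency table.

    ``auto`` applies the clipped Yates correction for 2x2 tables only;
    ``yates_clipped`` forces it (2x2 only); ``none`` disables it.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValidationError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise ValidationError("negative counts")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValidationError("zero margin in contingency table")
    correction = correction.lower()
    if correction not in ("auto", "none", "yates_clipped"):
        raise ValidationError(f"unknown correction {correction!r}")
    is_2x2 = obs.shape == (2, 2)
    if correction == "yates_clipped" and not is_2x2:
        raise ValidationError("Yates correction applies to 2x2 tables only")
    use_correction = (correction == "auto" and is_2x2) or correction == "yates_clipped"
    # scipy's 2x2 continuity correction is the clipped form
    res = stats.chi2_contingency(obs, correction=use_correction)
    return GroupComparisonResult(
        test="CHI_SQUARE",
        statistic=float(res.statistic),
        df=float(res.dof),
        p=float(res.pvalue),
    )


def two_sample_t(
    a: np.ndarray | tuple[float, float, int],
    b: np.ndarray | tuple[float, float, int],
    variance: str = "pooled",
) -> GroupComparisonResult:
    """Two-sided two-sample t-test from raw samples or (mean, sd, n)
    summaries. Pooled df = n1 + n2 - 2; Welch uses Satterthwaite df."""
    def summarize(x):
        if isinstance(x, tuple):
            m, s, n = x
            return float(m), float(s), int(n)
        x = np.asarray(x, dtype=float)
        return float(x.mean()), float(x.std(ddof=1)), x.size

    m1, s1, n1 = summarize(a)
    m2, s2, n2 = summarize(b)
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs n >= 2")
    if variance == "pooled":
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
        if sp2 == 0:
            raise ValidationError("zero pooled variance")
        t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    elif variance == "welch":
        v1, v2 = s1**2 / n1, s2**2 / n2
        if v1 + v2 == 0:
            raise ValidationError("zero variance")
        t = (m1 - m2) / np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        raise ValidationError(f"unknown variance option {variance!r}")
    p = 2 * stats.t.sf(abs(t), df)
    return GroupComparisonResult(
        test="T_TEST", statistic=float(t), df=float(df), p=float(p)
    )


def anova_tukey(groups: dict[str, np.ndarray]) -> GroupComparisonResult:
    """One-way ANOVA F with Tukey HSD pairwise p-values (studentized
    range distribution, family-wise 0.05 convention)."""
    labels = list(groups)
    samples = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(samples) < 2 or any(s.size < 2 for s in samples):
        raise ValidationError("ANOVA needs >= 2 groups with n >= 2 each")
    if np.ptp(np.concatenate(samples)) == 0:
        # identical constant data: F = 0, all pairwise p = 1
        pair_p = {
            (labels[i], labels[j]): 1.0
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        }
        return GroupComparisonResult(
            "ANOVA_TUKEY", 0.0, (len(labels) - 1, sum(s.size for s in samples) - len(labels)), 1.0, pair_p
        )
    f_res = stats.f_oneway(*samples)
    tukey = stats.tukey_hsd(*samples)
    pair_p = {
        (labels[i], labels[j]): float(tukey.pvalue[i, j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    }
    df = (len(labels) - 1, sum(s.size for s in samples) - len(labels))
    return GroupComparisonResult(
        test="ANOVA_TUKEY",
        statistic=float(f_res.statistic),
        df=df,
        p=float(f_res.pvalue),
        pairwise_p=pair_p,
    )


def demographics_table(manifest: CohortManifest) -> pd.DataFrame:
    """Demographics summary in the style of a cohort table.

    One row per covariate: per-group mean (sd) for numeric columns or
    category counts for sex/boolean columns, plus the pairwise test for
    every group pair — pooled t for numeric covariates, chi-square
    (clipped Yates on 2x2) for categorical ones. Subjects missing a
    covariate are dropped listwise for that row only.
    """
    t = manifest.table
    groups = manifest.groups
    pairs = [
        (groups[i], groups[j])
        for i in range(len(groups))
        for j in range(i + 1, len(groups))
    ]
    skip = {"subject_id", "group", "site"}
    rows = []
    for col in t.columns:
        if col in skip:
            continue
        series = t[col]
        is_cat = col == "sex" or series.dtype == bool or series.dtype == object
        row: dict[str, object] = {"covariate": col}
        for g in groups:
            vals = series[t["group"] == g].dropna()
            if is_cat:
                counts = vals.value_counts()
                row[g] = "/".join(f"{counts.get(k, 0)}" for k in sorted(counts.index))
            else:
                v = pd.to_numeric(vals, errors="coerce").dropna()
                row[g] = f"{v.mean():.2f} ({v.std(ddof=1):.2f})" if len(v) > 1 else "N/A"
        for ga, gb in pairs:
            label = f"{ga} vs {gb}"
            a = series[t["group"] == ga].dropna()
            b = series[t["group"] == gb].dropna()
            try:
                if is_cat:
                    cats = sorted(set(a) | set(b))
                    table = [
                        [int((a == c).sum()) for c in cats],
                        [int((b == c).sum()) for c in cats],
                    ]
                    res = chi_square(table)
                    row[label] = f"chi2({res.df:.0f})={res.statistic:.3g}, p={res.p:.3g}"
                else:
                    av = pd.to_numeric(a, errors="coerce").dropna().to_numpy()
                    bv = pd.to_numeric(b, errors="coerce").dropna().to_numpy()
                    if len(av) < 2 or len(bv) < 2:
                        row[label] = "N/A"
                        continue
                    res = two_sample_t(av, bv)
                    row[label] = f"t({res.df:.0f})={res.statistic:.3g}, p={res.p:.3g}"
            except ValidationError:
                row[label] = "N/A"
        rows.append(row)
    return pd.DataFrame(rows)


def global_average_comparison(
    matrices: dict[str, ConnectomeMatrix],
    manifest: CohortManifest,
    groups: list[str] | None = None,
) -> GroupComparisonResult:
    """Compare per-subject global network averages across groups.

    Two groups dispatch to a two-tailed pooled t-test; three or more to
    one-way ANOVA with Tukey HSD (both two-tailed).
    """
    groups = groups or manifest.groups
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    samples = {
        g: np.array(
            [
                global_network_average(matrices[s])
                for s in manifest.subjects_in(g)
                if s in matrices
            ]
        )
        for g in groups
    }
    for g, v in samples.items():
        if v.size < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 subjects with matrices")
    if len(groups) == 2:
        a, b = (samples[g] for g in groups)
        if np.ptp(np.concatenate([a, b])) == 0:
            return GroupComparisonResult("T_TEST", 0.0, a.size + b.size - 2, 1.0)
        return two_sample_t(a, b, variance="pooled")
    return anova_tukey(samples)
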