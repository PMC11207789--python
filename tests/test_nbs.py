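"""Edgewise GLM and network-based statistic."""

import numpy as np
import pytest
from scipy import stats

from connectodiff import (
    AnalysisConfig,
    DisruptionSpec,
    SimulationSpec,
    ValidationError,
    classify_edges,
    common_edge_mask,
    edgewise_glm,
    extract_components,
    make_design,
    nbs,
    simulate_cohort,
)
from connectodiff.nbs import EdgewiseDesign


def null_design(seed=0, n=20, n_edges=30, nuisance=0, tail="higher"):
    rng = np.random.default_rng(seed)
    edge_index = np.column_stack(np.triu_indices(9, k=1))[:n_edges]
    return EdgewiseDesign(
        Y=rng.normal(size=(n, n_edges)),
        predictor=np.repeat([0.0, 1.0], n // 2),
        nuisance=rng.normal(size=(n, nuisance)),
        edge_index=edge_index,
        node_ids=[f"n{i}" for i in range(9)],
        subject_ids=[f"s{i}" for i in range(n)],
        tail=tail,
    )


class TestEdgewiseGlm:
    def test_equals_pooled_two_sample_t_without_nuisance(self):
        d = null_design(seed=1)
        t_glm = edgewise_glm(d)
        a = d.Y[d.predictor == 1]
        b = d.Y[d.predictor == 0]
        t_classic = stats.ttest_ind(a, b, equal_var=True).statistic
        assert np.abs(t_glm - t_classic).max() < 1e-10

    def test_tail_lower_flips_sign(self):
        d_hi = null_design(seed=2, tail="higher")
        d_lo = null_design(seed=2, tail="lower")
        assert edgewise_glm(d_lo) == pytest.approx(-edgewise_glm(d_hi))

    def test_six_subject_normal_equations_oracle(self):
        """Hand-solved least squares on 6 subjects, 1 edge, 1 covariate."""
        y = np.array([1.0, 2.0, 1.5, 3.0, 2.5, 3.5])
        g = np.array([0.0, 0, 0, 1, 1, 1])
        z = np.array([0.1, -0.2, 0.0, 0.3, -0.1, 0.2])
        X = np.column_stack([np.ones(6), g, z])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        sigma2 = resid @ resid / (6 - 3)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        expected_t = beta[1] / se

        d = EdgewiseDesign(
            Y=y[:, None],
            predictor=g,
            nuisance=z[:, None],
            edge_index=np.array([[0, 1]]),
            node_ids=["a", "b"],
            subject_ids=[f"s{i}" for i in range(6)],
            tail="higher",
        )
        assert edgewise_glm(d)[0] == pytest.approx(expected_t, abs=1e-12)

    def test_null_t_follows_student_t(self):
        """Predictor independent of response: pooled edgewise t values
        follow Student's t with n - 2 df (KS calibration check)."""
        ts = np.concatenate(
            [edgewise_glm(null_design(seed=seed, n=40)) for seed in range(40)]
        )
        ks = stats.kstest(ts, stats.t(df=38).cdf)
        assert ks.pvalue > 0.01
        # extreme edges (|t| >= 3) occur at roughly the nominal rate
        assert np.mean(np.abs(ts) >= 3.0) < 0.02

    def test_rank_deficient_design_rejected(self):
        d = null_design(seed=3)
        with pytest.raises(ValidationError, match="rank"):
            EdgewiseDesign(
                Y=d.Y,
                predictor=d.predictor,
                nuisance=d.predictor[:, None],  # collinear with predictor
                edge_index=d.edge_index,
                node_ids=d.node_ids,
                subject_ids=d.subject_ids,
            )


class TestExtractComponents:
    def test_empty_when_nothing_suprathreshold(self):
        edges = np.array([[0, 1], [1, 2]])
        comps, extents = extract_components(np.array([1.0, 2.0]), 3.0, edges, 3)
        assert comps == [] and extents == []

    def test_two_disjoint_edges_two_components(self):
        edges = np.array([[0, 1], [2, 3]])
        comps, extents = extract_components(np.array([5.0, 5.0]), 3.0, edges, 4)
        assert extents == [1, 1]

    def test_shared_node_merges(self):
        edges = np.array([[0, 1], [1, 2], [3, 4]])
        comps, extents = extract_components(np.array([4.0, 4.0, 4.0]), 3.0, edges, 5)
        assert extents == [2, 1]

    def test_lowering_threshold_never_shrinks_extent(self):
        rng = np.random.default_rng(7)
        edges = np.column_stack(np.triu_indices(12, k=1))
        t = rng.normal(size=edges.shape[0]) * 2
        prev_max = 0
        for thr in (3.0, 2.0, 1.0, 0.5):
            _, extents = extract_components(t, thr, edges, 12)
            cur = max(extents, default=0)
            assert cur >= prev_max
            prev_max = cur


class TestNbs:
    def _planted_cohort(self, seed, effect=0.5):
        spec = SimulationSpec(
            n_nodes=50,
            groups=(("HC", 20), ("PATIENT", 20)),
            base_density=0.3,
            disruption=DisruptionSpec(
                mode="EDGE_SET", effect_size=effect, n_target_edges=10
            ),
            rng_seed=seed,
        )
        return simulate_cohort(spec)

    def test_detects_planted_cluster(self):
        c = self._planted_cohort(seed=21)
        design = make_design(
            c.matrices, c.manifest, contrast=("HC", "PATIENT"), covariates=(),
            tail="lower",
        )
        res = nbs(design, AnalysisConfig(n_perm_nbs=500, rng_seed=21), seed=21)
        assert res.p_values and min(res.p_values) <= 0.05
        sig = set(map(tuple, res.significant_edges()))
        truth = {tuple(sorted(e)) for e in c.truth.disrupted_edges}
        sig = {tuple(sorted(e)) for e in sig}
        assert len(sig & truth) >= 8

    def test_determinism(self):
        c = self._planted_cohort(seed=22)
        design = make_design(
            c.matrices, c.manifest, contrast=("HC", "PATIENT"), covariates=(),
            tail="lower",
        )
        cfg = AnalysisConfig(n_perm_nbs=200, rng_seed=5)
        r1 = nbs(design, cfg, seed=5)
        r2 = nbs(design, cfg, seed=5)
        assert r1.p_values == r2.p_values
        assert np.array_equal(r1.null_max_extent, r2.null_max_extent)

    def test_p_floor_and_warning_for_tiny_nperm(self):
        c = self._planted_cohort(seed=23)
        design = make_design(
            c.matrices, c.manifest, contrast=("HC", "PATIENT"), covariates=(),
            tail="lower",
        )
        with pytest.warns(UserWarning, match="cannot reach"):
            res = nbs(design, AnalysisConfig(n_perm_nbs=10, rng_seed=1), seed=1)
        assert all(p >= 1 / 11 for p in res.p_values)

    def test_freedman_lane_with_covariates_runs_and_detects(self):
        c = self._planted_cohort(seed=24)
        design = make_design(
            c.matrices, c.manifest, contrast=("HC", "PATIENT"),
            covariates=("age", "sex"), tail="lower",
        )
        assert design.nuisance.shape[1] >= 1
        res = nbs(design, AnalysisConfig(n_perm_nbs=300, rng_seed=2), seed=2)
        assert res.p_values and min(res.p_values) <= 0.05

    def test_observed_extent_never_beaten_gives_p_one(self):
        # constant-ish tiny effect: every permutation >= observed extent 0 case
        rng = np.random.default_rng(30)
        d = null_design(seed=30, n=20)
        res = nbs(d, AnalysisConfig(n_perm_nbs=100, rng_seed=3), seed=3)
        for p, ext in zip(res.p_values, res.extents):
            exceed = (res.null_max_extent >= ext).mean()
            assert p == pytest.approx((1 + exceed * 100) / 101)


class TestDesignBuilding:
    def test_edge_mask_fraction(self, small_manifest):
        from conftest import make_matrix

        rng = np.random.default_rng(4)
        mats = {}
        for i, sid in enumerate(small_manifest.subject_ids):
            w = np.zeros((4, 4))
            w[0, 1] = w[1, 0] = 1.0  # edge in all subjects
            if i < 2:
                w[2, 3] = w[3, 2] = 1.0  # edge in only 2/5 subjects
            mats[sid] = make_matrix(w, sid)
        mask = common_edge_mask(list(mats.values()), fraction=0.9)
        assert [tuple(e) for e in mask] == [(0, 1)]
        mask_loose = common_edge_mask(list(mats.values()), fraction=0.3)
        assert len(mask_loose) == 2

    def test_score_regression_excludes_missing_listwise(self, small_manifest):
        from conftest import make_matrix

        rng = np.random.default_rng(5)
        mats = {}
        for sid in small_manifest.subject_ids:
            w = rng.random((4, 4))
            w = np.triu(w, 1) + np.triu(w, 1).T
            mats[sid] = make_matrix(w, sid)
        d = make_design(
            mats, small_manifest, score="dup_weeks", covariates=(),
            log_transform_score=True, tail="lower",
        )
        assert "s1" not in d.subject_ids  # missing dup_weeks
        assert len(d.subject_ids) == 4

    def test_contrast_and_score_mutually_exclusive(self, small_manifest):
        with pytest.raises(ValidationError):
            make_design({}, small_manifest, contrast=("A", "B"), score="dup_weeks")


class TestClassifyEdges:
    def test_within_left_block_counts_zero_inter(self, node_table_lr):
        res = classify_edges([("a", "b")], node_table_lr)
        assert res["interhemispheric"] == 0
        assert res["intrahemispheric"] == 1

    def test_handshake_identity(self, node_table_lr):
        edges = [("a", "b"), ("a", "c"), ("c", "d"), ("b", "d")]
        res = classify_edges(edges, node_table_lr)
        assert sum(res["per_node_counts"].values()) == 2 * len(edges)

    def test_missing_hemisphere_rejected(self, node_table_lr):
        with pytest.raises(ValidationError, match="hemisphere"):
            classify_edges([("a", "zzz")], node_table_lr)
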