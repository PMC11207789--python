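"""Scalar statistics layer: chi-square, t-tests, ANOVA + Tukey."""

import numpy as np
import pytest

from connectodiff import (
    SimulationSpec,
    ValidationError,
    anova_tukey,
    chi_square,
    global_average_comparison,
    simulate_cohort,
    two_sample_t,
)


class TestChiSquare:
    def test_balanced_table_is_exactly_zero(self):
        res = chi_square([[10, 10], [10, 10]])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_clipping_zeroes_near_expected_tables(self):
        """Clipped Yates: every |O-E| <= 0.5 table scores exactly 0."""
        res = chi_square([[48, 10], [14, 3]])
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_transposition_invariance(self):
        t = np.array([[24, 13], [48, 10]])
        assert chi_square(t).statistic == pytest.approx(chi_square(t.T).statistic)

    def test_never_negative(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            t = rng.integers(1, 50, size=(2, 2))
            assert chi_square(t).statistic >= 0.0

    def test_2x3_without_correction(self):
        res = chi_square([[34, 0, 3], [50, 1, 7]], correction="none")
        assert res.df == 2
        # independent Pearson evaluation
        obs = np.array([[34, 0, 3], [50, 1, 7]], float)
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        assert res.statistic == pytest.approx(((obs - exp) ** 2 / exp).sum())

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError, match="margin"):
            chi_square([[0, 0], [5, 3]])

    def test_yates_forced_on_non2x2_rejected(self):
        with pytest.raises(ValidationError):
            chi_square([[1, 2, 3], [4, 5, 6]], correction="yates_clipped")


class TestTwoSampleT:
    def test_identical_groups_t_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        res = two_sample_t(a, a.copy())
        assert res.statistic == 0.0 and res.p == pytest.approx(1.0)

    def test_summary_path_equals_raw_path(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 30), rng.normal(0.4, 1.3, 25)
        raw = two_sample_t(a, b)
        summ = two_sample_t(
            (a.mean(), a.std(ddof=1), a.size), (b.mean(), b.std(ddof=1), b.size)
        )
        assert raw.statistic == pytest.approx(summ.statistic, abs=1e-12)
        assert raw.df == summ.df

    def test_pooled_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=12), rng.normal(size=9)
        res = two_sample_t(a, b, variance="pooled")
        sp2 = ((11 * a.var(ddof=1)) + (8 * b.var(ddof=1))) / 19
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 12 + 1 / 9))
        assert res.statistic == pytest.approx(t, abs=1e-12)
        assert res.df == 19

    def test_welch_df_below_pooled_for_unequal_variances(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 0.1, 20), rng.normal(0, 3.0, 20)
        assert two_sample_t(a, b, "welch").df < two_sample_t(a, b, "pooled").df

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValidationError):
            two_sample_t(np.ones(3), np.ones(4))


class TestAnovaTukey:
    def test_three_identical_groups(self):
        g = np.array([1.0, 2.0, 3.0])
        res = anova_tukey({"a": g, "b": g.copy(), "c": g.copy()})
        assert res.statistic == pytest.approx(0.0)
        assert all(p == pytest.approx(1.0) for p in res.pairwise_p.values())

    def test_f_matches_hand_computed_sums_of_squares(self):
        groups = {
            "a": np.array([1.0, 2.0, 3.0]),
            "b": np.array([2.0, 3.0, 4.0]),
            "c": np.array([6.0, 7.0, 8.0]),
        }
        allv = np.concatenate(list(groups.values()))
        grand = allv.mean()
        ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
        ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
        f = (ss_between / 2) / (ss_within / 6)
        res = anova_tukey(groups)
        assert res.statistic == pytest.approx(f, abs=1e-12)
        assert res.df == (2, 6)

    def test_shifted_group_flagged_by_tukey(self):
        rng = np.random.default_rng(4)
        groups = {
            "a": rng.normal(0, 1, 30),
            "b": rng.normal(0, 1, 30),
            "c": rng.normal(2.5, 1, 30),
        }
        res = anova_tukey(groups)
        assert res.pairwise_p[("a", "c")] < 0.01
        assert res.pairwise_p[("b", "c")] < 0.01
        assert res.pairwise_p[("a", "b")] > 0.05

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValidationError):
            anova_tukey({"a": np.array([1.0]), "b": np.array([1.0, 2.0])})


class TestDemographicsTable:
    def test_summaries_and_pairwise_tests(self):
        import pandas as pd
        from connectodiff import CohortManifest, demographics_table

        man = CohortManifest(
            pd.DataFrame(
                {
                    "subject_id": [f"s{i}" for i in range(12)],
                    "group": ["HC"] * 6 + ["FEP"] * 6,
                    "age": [20, 22, 24, 26, 28, 30, 21, 23, 25, 27, 29, 31],
                    "sex": ["M", "F"] * 6,
                    "dup_weeks": [np.nan] * 6 + [10, 12, 8, 20, 15, 11.0],
                }
            )
        )
        table = demographics_table(man)
        assert set(table["covariate"]) == {"age", "sex", "dup_weeks"}
        age_row = table.set_index("covariate").loc["age"]
        assert age_row["HC"].startswith("25.00")
        assert "t(10)" in age_row["HC vs FEP"]
        sex_row = table.set_index("covariate").loc["sex"]
        assert "chi2(1)" in sex_row["HC vs FEP"]
        # dup_weeks entirely missing in HC: no test possible
        dup_row = table.set_index("covariate").loc["dup_weeks"]
        assert dup_row["HC vs FEP"] == "N/A"


class TestGlobalAverageComparison:
    def test_two_identical_groups_t_zero(self):
        spec = SimulationSpec(
            n_nodes=20, groups=(("A", 4), ("B", 4)), rng_seed=0
        )
        c = simulate_cohort(spec)
        # clone group A matrices into B so samples are identical
        a_subj = c.manifest.subjects_in("A")
        b_subj = c.manifest.subjects_in("B")
        mats = dict(c.matrices)
        for a, b in zip(a_subj, b_subj):
            m = mats[a]
            mats[b] = type(m)(b, m.weight_kind, m.weights.copy(), m.node_ids)
        res = global_average_comparison(mats, c.manifest)
        assert res.statistic == pytest.approx(0.0)

    def test_three_groups_dispatch_to_anova(self):
        spec = SimulationSpec(
            n_nodes=20, groups=(("A", 4), ("B", 4), ("C", 4)), rng_seed=1
        )
        c = simulate_cohort(spec)
        res = global_average_comparison(c.matrices, c.manifest)
        assert res.test == "ANOVA_TUKEY"
        assert set(res.pairwise_p) == {("A", "B"), ("A", "C"), ("B", "C")}

    def test_strong_global_disruption_detected(self):
        from connectodiff import DisruptionSpec

        spec = SimulationSpec(
            n_nodes=30,
            groups=(("A", 10), ("B", 10)),
            disruption=DisruptionSpec(mode="GLOBAL", effect_size=0.6),
            rng_seed=2,
        )
        c = simulate_cohort(spec)
        res = global_average_comparison(c.matrices, c.manifest)
        assert res.test == "T_TEST" and res.p < 0.01
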