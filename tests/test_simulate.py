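"""Synthetic cohort generator: determinism, planted effects, invariants."""

import numpy as np
import pytest

from connectodiff import (
    DisruptionMode,
    DisruptionSpec,
    SimulationSpec,
    ValidationError,
    WeightKind,
    plant_idiosyncrasy,
    rescale_to_kind,
    simulate_cohort,
)


def small_spec(**kw):
    defaults = dict(
        n_nodes=24, groups=(("HC", 4), ("PATIENT", 4)), base_density=0.3, rng_seed=0
    )
    defaults.update(kw)
    return SimulationSpec(**defaults)


class TestGenerator:
    def test_same_seed_byte_identical(self):
        c1 = simulate_cohort(small_spec(rng_seed=3))
        c2 = simulate_cohort(small_spec(rng_seed=3))
        for sid in c1.matrices:
            assert np.array_equal(c1.matrices[sid].weights, c2.matrices[sid].weights)
        assert c1.manifest.table.equals(c2.manifest.table)

    def test_different_seed_differs(self):
        c1 = simulate_cohort(small_spec(rng_seed=3))
        c2 = simulate_cohort(small_spec(rng_seed=4))
        sid = next(iter(c1.matrices))
        assert not np.array_equal(c1.matrices[sid].weights, c2.matrices[sid].weights)

    def test_identical_topology_across_subjects(self):
        c = simulate_cohort(small_spec(rng_seed=1))
        masks = [m.weights > 0 for m in c.matrices.values()]
        for mask in masks[1:]:
            assert np.array_equal(mask, masks[0])

    def test_topology_connected(self):
        from scipy.sparse.csgraph import connected_components
        from scipy.sparse import csr_array

        c = simulate_cohort(small_spec(base_density=0.1, rng_seed=2))
        m = next(iter(c.matrices.values()))
        n_comp, _ = connected_components(csr_array(m.weights > 0))
        assert n_comp == 1

    def test_global_disruption_shifts_mean_ratio(self):
        c = simulate_cohort(
            small_spec(
                n_nodes=40,
                groups=(("HC", 15), ("PATIENT", 15)),
                disruption=DisruptionSpec(mode="GLOBAL", effect_size=0.9),
                rng_seed=5,
            )
        )
        hc = np.mean(
            [c.matrices[s].weights.mean() for s in c.manifest.subjects_in("HC")]
        )
        pat = np.mean(
            [c.matrices[s].weights.mean() for s in c.manifest.subjects_in("PATIENT")]
        )
        assert pat / hc == pytest.approx(0.9, abs=0.04)

    def test_hub_targeted_edges_touch_top_decile(self):
        c = simulate_cohort(
            small_spec(
                n_nodes=50,
                groups=(("HC", 2), ("PATIENT", 2)),
                disruption=DisruptionSpec(
                    mode="HUB_TARGETED", effect_size=0.5, target_fraction=0.1,
                    hub_quantile=0.9,
                ),
                rng_seed=6,
            )
        )
        hubs = set(c.truth.hub_nodes)
        assert c.truth.disrupted_edges  # something was planted
        assert all(a in hubs or b in hubs for a, b in c.truth.disrupted_edges)

    def test_edge_set_cluster_is_connected(self):
        c = simulate_cohort(
            small_spec(
                disruption=DisruptionSpec(
                    mode="EDGE_SET", effect_size=0.5, n_target_edges=8
                ),
                rng_seed=7,
            )
        )
        edges = c.truth.disrupted_edges
        assert len(edges) == 8
        nodes = {n for e in edges for n in e}
        # BFS over the planted edges only
        adj = {n: set() for n in nodes}
        for a, b in edges:
            adj[a].add(b)
            adj[b].add(a)
        seen, stack = set(), [next(iter(nodes))]
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            stack.extend(adj[x] - seen)
        assert seen == nodes

    def test_interhemispheric_targets_cross(self):
        c = simulate_cohort(
            small_spec(
                disruption=DisruptionSpec(
                    mode="INTERHEMISPHERIC", effect_size=0.6, target_fraction=0.3
                ),
                rng_seed=8,
            )
        )
        hemi = c.node_table.table.set_index("node_id")["hemisphere"]
        assert all(hemi[a] != hemi[b] for a, b in c.truth.disrupted_edges)

    def test_degenerate_group_size_rejected(self):
        with pytest.raises(ValidationError):
            small_spec(groups=(("HC", 1), ("P", 4)))

    def test_overfull_target_fraction_rejected(self):
        with pytest.raises(ValidationError):
            simulate_cohort(
                small_spec(
                    disruption=DisruptionSpec(
                        mode="INTERHEMISPHERIC", effect_size=0.5, target_fraction=1.0
                    ),
                    rng_seed=9,
                )
            )


class TestExchangeability:
    def test_null_cohort_type1_error_near_nominal(self):
        """With no planted disruption the groups are exchangeable: a
        two-sample t on per-subject mean edge weight rejects at ~5%
        (binomial 95% CI for 100 replicates)."""
        from scipy import stats

        rejections = 0
        for rep in range(100):
            c = simulate_cohort(
                small_spec(n_nodes=20, groups=(("A", 5), ("B", 5)), rng_seed=70_000 + rep)
            )
            a = [c.matrices[s].weights.mean() for s in c.manifest.subjects_in("A")]
            b = [c.matrices[s].weights.mean() for s in c.manifest.subjects_in("B")]
            if stats.ttest_ind(a, b).pvalue <= 0.05:
                rejections += 1
        assert 1 <= rejections <= 11


class TestIdiosyncrasy:
    def test_fraction_zero_is_identity(self):
        c = simulate_cohort(small_spec(rng_seed=10))
        c2 = plant_idiosyncrasy(c, 0.0, 1.0, seed=1)
        assert c2 is c

    def test_group_mean_approximately_preserved(self):
        c = simulate_cohort(
            small_spec(n_nodes=40, groups=(("HC", 12), ("P", 12)), rng_seed=11)
        )
        before = np.mean([m.weights.mean() for m in c.matrices.values()])
        c2 = plant_idiosyncrasy(c, 0.3, 0.8, seed=2)
        after = np.mean([m.weights.mean() for m in c2.matrices.values()])
        assert after == pytest.approx(before, rel=0.15)

    def test_only_listed_groups_touched(self):
        c = simulate_cohort(small_spec(rng_seed=12))
        c2 = plant_idiosyncrasy(c, 0.3, 1.0, groups=("PATIENT",), seed=3)
        for sid in c.manifest.subjects_in("HC"):
            assert np.array_equal(c.matrices[sid].weights, c2.matrices[sid].weights)
        changed = [
            not np.array_equal(c.matrices[s].weights, c2.matrices[s].weights)
            for s in c.manifest.subjects_in("PATIENT")
        ]
        assert all(changed)


class TestWeightKinds:
    def test_fa_rescale_in_unit_interval(self):
        c = simulate_cohort(small_spec(rng_seed=13))
        m = rescale_to_kind(next(iter(c.matrices.values())), WeightKind.FA)
        nz = m.weights[m.weights > 0]
        assert nz.min() > 0 and nz.max() < 1

    def test_dti_expected_ordering(self):
        c = simulate_cohort(small_spec(rng_seed=14))
        base = next(iter(c.matrices.values()))
        means = {}
        for kind in (WeightKind.AD, WeightKind.MD, WeightKind.RD):
            w = rescale_to_kind(base, kind).weights
            means[kind] = w[w > 0].mean()
        assert means[WeightKind.AD] > means[WeightKind.MD] > means[WeightKind.RD]

    def test_rescale_is_monotone(self):
        c = simulate_cohort(small_spec(rng_seed=15))
        base = next(iter(c.matrices.values()))
        fa = rescale_to_kind(base, WeightKind.FA)
        iu, ju = np.nonzero(np.triu(base.weights, 1))
        order = np.argsort(base.weights[iu, ju])
        rescaled = fa.weights[iu, ju][order]
        assert np.all(np.diff(rescaled) >= 0)
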