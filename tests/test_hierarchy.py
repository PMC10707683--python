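import numpy as np
import pytest

from netmod import (NodeAttributes, TwoStepConfig, WMMConfig,
                    community_distance, distance_matrix,
                    generate_hierarchical_fixture, nmi, permutation_test,
                    post_subdivision_distance, two_step_wmm)
from netmod.hierarchy import _null_distances


class TestDistances:
    def test_3_4_5(self):
        attrs = NodeAttributes(["a", "b"], [[0, 0, 0], [3, 4, 0]])
        D = distance_matrix(attrs)
        assert D[0, 1] == 5 and D[1, 0] == 5
        assert np.all(np.diag(D) == 0)

    def test_identical_coordinates(self):
        attrs = NodeAttributes(list("abc"), np.ones((3, 2)))
        assert np.all(distance_matrix(attrs) == 0)

    def test_one_dimensional(self):
        attrs = NodeAttributes(list("abc"), [[0.0], [1.0], [3.0]])
        D = distance_matrix(attrs)
        assert np.array_equal(D, [[0, 1, 3], [1, 0, 2], [3, 2, 0]])

    def test_singleton_community_distance_zero(self):
        D = np.array([[0.0, 5.0], [5.0, 0.0]])
        assert community_distance([0], D) == 0.0

    def test_pair_mean_includes_diagonal(self):
        # (0 + 5 + 5 + 0) / 4
        D = np.array([[0.0, 5.0], [5.0, 0.0]])
        assert community_distance([0, 1], D) == 2.5

    def test_three_node_printed_formula(self):
        # nodes at 0, 1, 3 on a line: sum of distances 2*(1+3+2) = 12 over 9
        attrs = NodeAttributes(list("abc"), [[0.0], [1.0], [3.0]])
        D = distance_matrix(attrs)
        assert np.isclose(community_distance([0, 1, 2], D), 12 / 9)

    def test_post_subdivision_identity_when_one_group(self):
        attrs = NodeAttributes(list("abc"), [[0.0], [1.0], [3.0]])
        D = distance_matrix(attrs)
        assert post_subdivision_distance([1, 1, 1], D) == \
            community_distance([0, 1, 2], D)

    def test_post_subdivision_unweighted_mean(self):
        # split {0,1} and {3}: mean(0.5, 0) = 0.25
        attrs = NodeAttributes(list("abc"), [[0.0], [1.0], [3.0]])
        D = distance_matrix(attrs)
        assert np.isclose(post_subdivision_distance([1, 1, 2], D), 0.25)

    def test_all_singletons_zero(self):
        attrs = NodeAttributes(list("abc"), [[0.0], [1.0], [3.0]])
        D = distance_matrix(attrs)
        assert post_subdivision_distance([1, 2, 3], D) == 0.0


class TestPermutationTest:
    def test_clear_split_accepted(self, rng):
        # two tight clusters far apart
        pts = np.vstack([rng.normal(0, 0.1, (15, 3)),
                         rng.normal(50, 0.1, (15, 3))])
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        labels = np.repeat([1, 2], 15)
        rec = permutation_test(labels, D, d_before=float(D.mean()),
                               T=2000, alpha=0.05, seed=0)
        assert rec.accepted
        assert rec.d_after < rec.null_quantile

    def test_random_split_rejected(self, rng):
        pts = rng.standard_normal((30, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        labels = rng.integers(1, 4, 30)
        while len(np.unique(labels)) < 2:
            labels = rng.integers(1, 4, 30)
        rec = permutation_test(labels, D, d_before=float(D.mean()),
                               T=1000, alpha=0.05, seed=1)
        assert not rec.accepted

    def test_type_one_error_controlled(self):
        # unstructured attributes: acceptance rate stays near alpha
        reps, alpha = 200, 0.05
        master = np.random.default_rng(42)
        accepted = 0
        for r in range(reps):
            pts = master.standard_normal((24, 3))
            D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            labels = master.integers(1, 4, 24)
            while len(np.unique(labels)) < 2:
                labels = master.integers(1, 4, 24)
            rec = permutation_test(labels, D, d_before=float(D.mean()),
                                   T=400, alpha=alpha, seed=r)
            accepted += rec.accepted
        bound = alpha + 3 * np.sqrt(alpha * (1 - alpha) / reps)
        assert accepted / reps <= bound

    def test_null_preserves_group_sizes(self, rng):
        pts = rng.standard_normal((12, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        labels = np.array([1] * 8 + [2] * 4)
        null = _null_distances(labels, D, 50, np.random.default_rng(0))
        assert null.shape == (50,)
        # null of a singleton-free split is strictly positive
        assert np.all(null > 0)

    def test_null_matches_direct_recomputation(self, rng):
        # oracle: same shuffles recomputed with a plain python loop
        pts = rng.standard_normal((10, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        labels = np.array([1, 1, 1, 1, 2, 2, 2, 3, 3, 3])
        vec = _null_distances(labels, D, 20, np.random.default_rng(7))
        rng2 = np.random.default_rng(7)
        n = len(labels)
        groups = [np.nonzero(labels == g)[0] for g in np.unique(labels)]
        perms = np.argsort(rng2.random((20, n)), axis=1)
        for t in range(20):
            ds = []
            for pos in groups:
                idx = perms[t, pos]
                ds.append(D[np.ix_(idx, idx)].mean())
            assert np.isclose(vec[t], np.mean(ds))

    def test_requires_two_groups(self):
        D = np.zeros((3, 3))
        with pytest.raises(ValueError, match="2 sub"):
            permutation_test([1, 1, 1], D, 0.0, T=100)

    def test_quantile_undefined(self):
        D = np.zeros((4, 4))
        with pytest.raises(ValueError, match="quantile"):
            permutation_test([1, 1, 2, 2], D, 0.0, T=10, alpha=0.001)


def small_wmm(seed=0):
    return WMMConfig(pool_size=10, n_selected=5, n_selections=5, seed=seed)


class TestTwoStep:
    def test_recovers_planted_hierarchy(self):
        net, attrs, l1, l2 = generate_hierarchical_fixture(seed=1)
        cfg = TwoStepConfig(n_permutations=500,
                            wmm_config=small_wmm(seed=1))
        hier = two_step_wmm(net, attrs, cfg)
        assert nmi(hier.level1, l1) == 1.0
        assert nmi(hier.level2, l2) == 1.0
        assert hier.refines()

    def test_level2_refines_level1(self):
        net, attrs, _, _ = generate_hierarchical_fixture(
            n_super=3, n_sub_per_super=2, sub_size=12, seed=5)
        cfg = TwoStepConfig(n_permutations=300, wmm_config=small_wmm(seed=5))
        hier = two_step_wmm(net, attrs, cfg)
        assert hier.refines()
        # provenance maps every level-2 label to its parent level-1 label
        for nid in net.node_ids:
            assert (hier.provenance[hier.level2.label_of(nid)]
                    == hier.level1.label_of(nid))

    def test_no_spatial_signal_keeps_level1(self, rng):
        # sep = 0: sub-blocks share one center, so subdivision should be
        # rejected and level 2 ~= level 1
        net, attrs, l1, _ = generate_hierarchical_fixture(
            spatial_sep=0.0, sigma=1.0, seed=3)
        cfg = TwoStepConfig(n_permutations=500, alpha=0.05,
                            wmm_config=small_wmm(seed=3))
        hier = two_step_wmm(net, attrs, cfg)
        rejected = [r for r in hier.test_results.values() if not r.accepted]
        assert len(rejected) >= 1  # most/all tests reject without signal

    def test_small_community_passed_through(self):
        net, attrs, _, _ = generate_hierarchical_fixture(
            n_super=2, n_sub_per_super=2, sub_size=25, seed=2)
        cfg = TwoStepConfig(n_permutations=300, min_subdivide_size=200,
                            wmm_config=small_wmm(seed=2))
        hier = two_step_wmm(net, attrs, cfg)
        # nothing is large enough to subdivide
        assert all(r.reason == "below min_subdivide_size"
                   for r in hier.test_results.values())
        assert hier.level2.equivalent(hier.level1)

    def test_all_rejected_means_level2_equals_level1(self):
        net, attrs, _, _ = generate_hierarchical_fixture(
            spatial_sep=0.0, sigma=1.0, seed=11)
        cfg = TwoStepConfig(n_permutations=400, alpha=0.01,
                            wmm_config=small_wmm(seed=11))
        hier = two_step_wmm(net, attrs, cfg)
        if all(not r.accepted for r in hier.test_results.values()):
            assert hier.level2.equivalent(hier.level1)

    def test_acceptance_monotone_in_separation(self):
        # acceptance probability should not decrease as the spatial
        # separation of sub-clusters grows
        rates = []
        for sep in (0.0, 2.0, 8.0):
            accepted = total = 0
            for r in range(8):
                net, attrs, _, _ = generate_hierarchical_fixture(
                    n_super=2, n_sub_per_super=2, sub_size=20,
                    spatial_sep=sep, sigma=1.0, seed=100 + r)
                cfg = TwoStepConfig(n_permutations=300,
                                    wmm_config=small_wmm(seed=r))
                hier = two_step_wmm(net, attrs, cfg)
                for rec in hier.test_results.values():
                    if rec.reason == "tested":
                        total += 1
                        accepted += rec.accepted
            rates.append(accepted / max(total, 1))
        assert rates[0] <= rates[1] + 0.15
        assert rates[1] <= rates[2] + 0.15
        assert rates[2] >= 0.8

    def test_attribute_mismatch_raises(self):
        net, attrs, _, _ = generate_hierarchical_fixture(seed=0)
        short = NodeAttributes(net.node_ids[:10], attrs.values[:10])
        with pytest.raises(ValueError, match="cover"):
            two_step_wmm(net, short, TwoStepConfig(wmm_config=small_wmm()))

    def test_deterministic(self):
        net, attrs, _, _ = generate_hierarchical_fixture(seed=9)
        cfg = TwoStepConfig(n_permutations=200, wmm_config=small_wmm(seed=9))
        a = two_step_wmm(net, attrs, cfg)
        b = two_step_wmm(net, attrs, cfg)
        assert a.level2 == b.level2

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TwoStepConfig(alpha=1.5)
        with pytest.raises(ValueError):
            TwoStepConfig(n_permutations=0)
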