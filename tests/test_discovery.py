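"""Two-stage discovery pipeline: stages, weights, merging, profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import distress_patterns as dp
from distress_patterns.scales import ITEM_COLUMNS
from distress_patterns.discovery import (
    NOISE, HDBSCANParams, UMAPParams, PatternAssignment, SymptomClusterMap,
    ItemWeights, embed_items, cluster_items, compute_item_weights, reweight,
    cluster_patients, merge_small_clusters, build_profiles, scaled_min_pts,
)


def _items_frame(array):
    return pd.DataFrame(np.asarray(array, dtype=int), columns=ITEM_COLUMNS)


class TestEmbedItems:
    def test_shape_contract(self, small_cohort):
        emb = embed_items(small_cohort.items)
        assert emb.shape == (16, 2)
        assert list(emb.index) == ITEM_COLUMNS

    def test_duplicate_columns_coincide(self, small_cohort, rng):
        items = small_cohort.items.copy()
        items["gad7"] = items["phq1"]  # exact duplicate column
        emb = embed_items(items)
        from scipy.spatial.distance import pdist
        dup = np.linalg.norm(emb.loc["gad7"] - emb.loc["phq1"])
        assert dup < 0.3 * np.median(pdist(emb.to_numpy()))

    def test_constant_item_rejected_by_name(self, small_cohort):
        items = small_cohort.items.copy()
        items["phq9"] = 0
        with pytest.raises(ValueError, match="phq9"):
            embed_items(items)


class TestClusterItems:
    def test_two_perfect_blocks_recovered(self, rng):
        # two blocks of 8 strongly correlated items; a descending loading
        # ladder gives each block one hub item every member is closest to
        f = rng.standard_normal((800, 2))
        loadings = np.linspace(0.95, 0.60, 8)
        cols = []
        for j in range(16):
            block, l = j // 8, loadings[j % 8]
            latent = l * f[:, block] + np.sqrt(1 - l**2) * rng.standard_normal(800)
            cols.append(1.5 + 0.9 * latent)
        items = _items_frame(np.clip(np.round(np.column_stack(cols)), 0, 3))
        cm = cluster_items(embed_items(items))
        assert cm.n_clusters == 2
        assert sorted(cm.sizes.tolist()) == [8, 8]
        # the partition splits exactly along the construction
        first_block = set(ITEM_COLUMNS[:8])
        lbl = cm.assignments
        assert len({lbl[i] for i in first_block}) == 1
        assert len({lbl[i] for i in ITEM_COLUMNS[8:]}) == 1

    def test_planted_four_blocks_recovered(self, small_cohort):
        from distress_patterns.cohort import ITEM_BLOCKS
        cm = cluster_items(embed_items(small_cohort.items))
        assert cm.n_clusters == 4
        for items_in_block in ITEM_BLOCKS.values():
            assert len({cm.assignments[i] for i in items_in_block}) == 1

    def test_within_block_distances_smaller(self, small_cohort):
        from distress_patterns.cohort import ITEM_BLOCKS
        emb = embed_items(small_cohort.items)
        block_of = {i: b for b, items in enumerate(ITEM_BLOCKS.values()) for i in items}
        within, between = [], []
        names = list(emb.index)
        for i in range(16):
            for j in range(i + 1, 16):
                d = np.linalg.norm(emb.iloc[i] - emb.iloc[j])
                (within if block_of[names[i]] == block_of[names[j]] else between).append(d)
        assert np.mean(within) < np.mean(between)


class TestWeights:
    @pytest.mark.parametrize("sizes, expected", [
        ({0: 7, 1: 4, 2: 3, 3: 2}, {0: 1 / 7, 1: 1 / 4, 2: 1 / 3, 3: 1 / 2}),
        ({0: 16}, {0: 1 / 16}),
        ({k: 1 for k in range(16)}, {k: 1.0 for k in range(16)}),
    ])
    def test_weight_rule(self, sizes, expected):
        labels = [k for k, s in sizes.items() for _ in range(s)]
        cm = SymptomClusterMap(pd.Series(labels, index=ITEM_COLUMNS[:len(labels)]))
        w = compute_item_weights(cm).weights
        for item, lbl in cm.assignments.items():
            assert w[item] == pytest.approx(expected[lbl])
        sums = w.groupby(cm.assignments).sum()
        assert np.allclose(sums, 1.0, atol=1e-12)

    @given(st.lists(st.integers(0, 5), min_size=16, max_size=16))
    @settings(max_examples=60, deadline=None)
    def test_cluster_weight_mass_always_one(self, raw_labels):
        # relabel to contiguous ids
        uniq = {v: i for i, v in enumerate(dict.fromkeys(raw_labels))}
        cm = SymptomClusterMap(pd.Series([uniq[v] for v in raw_labels],
                                         index=ITEM_COLUMNS))
        w = compute_item_weights(cm).weights
        sums = w.groupby(cm.assignments).sum()
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_reweight_identity_scaling_inverse(self, small_cohort):
        items = small_cohort.items
        ones = ItemWeights(pd.Series(1.0, index=ITEM_COLUMNS))
        pd.testing.assert_frame_equal(reweight(items, ones), items.astype(float))
        half = pd.Series(1.0, index=ITEM_COLUMNS); half["phq1"] = 0.5
        halved = reweight(items, ItemWeights(half))
        assert (halved["phq1"] * 2 == items["phq1"]).all()
        inv = ItemWeights(1.0 / half)
        pd.testing.assert_frame_equal(reweight(halved, inv), items.astype(float))

    def test_missing_weight_rejected(self, small_cohort):
        partial = ItemWeights(pd.Series(1.0, index=ITEM_COLUMNS[:-1]))
        with pytest.raises(ValueError, match="gad7"):
            reweight(small_cohort.items, partial)


class TestClusterPatients:
    def test_too_small_cohort_rejected_with_hint(self, small_cohort):
        few = small_cohort.items.iloc[:50]
        with pytest.raises(ValueError, match="auto_scale"):
            cluster_patients(few.astype(float))

    def test_same_seed_identical_assignment(self, small_cohort):
        weighted = small_cohort.items.astype(float) * 0.25
        params = HDBSCANParams(min_pts=scaled_min_pts(len(weighted)))
        a, _ = cluster_patients(weighted, hdbscan_params=params)
        b, _ = cluster_patients(weighted, hdbscan_params=params)
        pd.testing.assert_series_equal(a.labels, b.labels)


def _assignment(sizes, centers, noise=0, rng=None):
    rng = rng or np.random.default_rng(0)
    pts, labels = [], []
    for k, (n, c) in enumerate(zip(sizes, centers)):
        pts.append(c + 0.1 * rng.standard_normal((n, 2)))
        labels += [k] * n
    if noise:
        pts.append(rng.uniform(50, 60, (noise, 2)))
        labels += [NOISE] * noise
    pts = np.vstack(pts)
    idx = pd.RangeIndex(len(pts))
    return PatternAssignment(pd.Series(labels, index=idx),
                             pd.DataFrame(pts, index=idx, columns=["umap1", "umap2"]))


class TestMergeSmallClusters:
    def test_single_possible_partner(self):
        a = _assignment([5000, 150], [np.zeros(2), np.array([5.0, 0])])
        merged = merge_small_clusters(a, min_size=200)
        assert merged.sizes.tolist() == [5150]

    def test_no_op_when_all_large(self):
        a = _assignment([500, 300], [np.zeros(2), np.array([5.0, 0])])
        merged = merge_small_clusters(a, min_size=200)
        np.testing.assert_array_equal(merged.labels.to_numpy(),
                                      a.labels.to_numpy())

    def test_nearest_centroid_rule(self):
        # the 150-cluster centroid is nearer the 300-cluster
        a = _assignment([500, 300, 150],
                        [np.zeros(2), np.array([10.0, 0]), np.array([12.0, 0])])
        merged = merge_small_clusters(a, min_size=200)
        assert sorted(merged.sizes.tolist()) == [450, 500]

    def test_noise_untouched(self):
        a = _assignment([500, 150], [np.zeros(2), np.array([5.0, 0])], noise=30)
        merged = merge_small_clusters(a, min_size=200)
        assert int((merged.labels == NOISE).sum()) == 30

    @given(st.lists(st.integers(20, 400), min_size=1, max_size=6),
           st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_termination_and_growth(self, sizes, seed):
        rng = np.random.default_rng(seed)
        centers = [rng.uniform(-20, 20, 2) for _ in sizes]
        a = _assignment(sizes, centers, rng=rng)
        merged = merge_small_clusters(a, min_size=150)
        out_sizes = merged.sizes
        assert len(out_sizes) <= len(sizes)
        # every surviving cluster is at least as big as any input cluster it
        # absorbed; total non-noise count conserved
        assert out_sizes.sum() == sum(sizes)
        if len(out_sizes) > 1:
            assert out_sizes.min() >= 150


class TestProfiles:
    def test_all_zero_pattern_named_normal(self):
        items = _items_frame(np.zeros((120, 16)))
        items.iloc[60:, :3] = 3  # a second, clearly elevated pattern
        a = _assignment([60, 60], [np.zeros(2), np.array([8.0, 0])])
        a.labels.index = items.index
        a.embedding.index = items.index
        profiles = build_profiles(a, items)
        by_name = {p.name: p for p in profiles}
        assert dp.NORMAL_PATTERN in by_name
        assert (by_name[dp.NORMAL_PATTERN].item_means == 0).all()

    def test_profile_means_bounded_by_member_scores(self, small_discovery, small_cohort):
        for p in small_discovery.profiles:
            members = small_cohort.items.loc[
                small_discovery.assignment.labels == p.pattern]
            assert (p.item_means >= members.min(axis=0) - 1e-12).all()
            assert (p.item_means <= members.max(axis=0) + 1e-12).all()

    def test_planted_nervousness_named_by_gad_items(self, small_discovery, small_cohort):
        truth = small_cohort.truth
        lab = small_discovery.assignment.labels
        nerv_cluster = lab[(truth == "nervousness") & (lab != NOISE)].mode()[0]
        name = small_discovery.pattern_names()[nerv_cluster]
        assert "gad1" in name and "gad2" in name


class TestRunDiscovery:
    def test_end_to_end_recovery_small(self, small_discovery, small_cohort):
        from sklearn.metrics import adjusted_rand_score
        res = small_discovery
        assert res.symptom_clusters.n_clusters == 4
        lab = res.assignment.labels.to_numpy()
        tr = small_cohort.truth.to_numpy()
        keep = (lab != NOISE) & (tr != dp.OUTLIER_LABEL)
        assert adjusted_rand_score(tr[keep], lab[keep]) > 0.7

    def test_label_permutation_leaves_profiles_invariant(self, small_discovery, small_cohort):
        res = small_discovery
        perm = {k: (k + 1) % res.n_patterns for k in range(res.n_patterns)}
        relabelled = PatternAssignment(
            res.assignment.labels.map(lambda v: perm.get(v, NOISE)),
            res.assignment.embedding)
        orig = {tuple(np.round(p.item_means, 10)) for p in res.profiles}
        new = {tuple(np.round(p.item_means, 10))
               for p in build_profiles(relabelled, small_cohort.items)}
        assert orig == new

    def test_determinism_byte_identical_labels(self, small_cohort, small_discovery):
        cfg = dp.DiscoveryConfig(auto_scale=True)
        again = dp.run_discovery(small_cohort.items, cfg)
        pd.testing.assert_series_equal(again.assignment.labels,
                                       small_discovery.assignment.labels)

    def test_stage_errors_are_labelled(self):
        bad = _items_frame(np.zeros((200, 16)))  # constant items
        with pytest.raises(RuntimeError, match="embed_items"):
            dp.run_discovery(bad, dp.DiscoveryConfig(auto_scale=True))


def test_hdbscan_stage_deterministic_over_min_pts_grid(small_discovery):
    """Density clustering of a fixed embedding is reproducible at every
    density setting (the labelling, including which points are noise, is a
    pure function of the inputs)."""
    from distress_patterns.discovery import _run_hdbscan
    emb = small_discovery.assignment.embedding.to_numpy()
    for mp in (5, 10, 20, 40):
        _, a = _run_hdbscan(emb, HDBSCANParams(min_pts=mp))
        _, b = _run_hdbscan(emb, HDBSCANParams(min_pts=mp))
        np.testing.assert_array_equal(a, b)
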