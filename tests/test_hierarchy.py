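"""Dendrogram construction, cuts, and nested label hierarchies.

The naive O(n^3) agglomeration oracle used here recomputes cluster
distances from scratch at every merge (no Lance-Williams recursion), so it
is an independent check on the linkage behind build_dendrogram.
"""

import itertools

import numpy as np
import pytest

from stlseg.feature_analysis import ObservationMatrix
from stlseg.hierarchy import (
    Dendrogram,
    LabelHierarchy,
    Partition,
    Stage,
    build_dendrogram,
    build_label_hierarchy,
    cut_at_height,
    cuts_by_greatest_links,
    cuts_by_target_counts,
    load_dendrogram,
    remap_mask,
    save_dendrogram,
)


# ---------------------------------------------------------------------------
# Naive agglomeration oracle
# ---------------------------------------------------------------------------

def cluster_distance(a, b, X, method):
    pd = [float(np.linalg.norm(X[i] - X[j])) for i in a for j in b]
    if method == "single":
        return min(pd)
    if method == "complete":
        return max(pd)
    if method == "average":
        return sum(pd) / len(pd)
    if method == "ward":
        ca, cb = X[list(a)].mean(axis=0), X[list(b)].mean(axis=0)
        na, nb = len(a), len(b)
        return float(np.sqrt(2.0 * na * nb / (na + nb)) *
                     np.linalg.norm(ca - cb))
    raise ValueError(method)


def naive_agglomerate(X, method):
    """Merge the closest pair repeatedly; returns (heights, partitions).

    ``partitions[k]`` is the set of frozenset clusters after k merges.
    """
    clusters = [frozenset([i]) for i in range(len(X))]
    heights = []
    partitions = [set(clusters)]
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            d = cluster_distance(clusters[i], clusters[j], X, method)
            if best is None or d < best[0]:
                best = (d, i, j)
        d, i, j = best
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
        heights.append(d)
        partitions.append(set(clusters))
    return heights, partitions


def partitions_from_dendrogram(dend):
    """Cluster sets after each merge, replayed from the linkage rows."""
    n = dend.n_leaves
    nodes = {i: frozenset([i]) for i in range(n)}
    partitions = [set(nodes.values())]
    active = set(nodes.values())
    for j, (a, b, h, sz) in enumerate(dend.links):
        merged = nodes[int(a)] | nodes[int(b)]
        nodes[n + j] = merged
        active -= {nodes[int(a)], nodes[int(b)]}
        active.add(merged)
        partitions.append(set(active))
    return partitions


def obs_from(X):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return ObservationMatrix(rows=X, class_order=list(range(1, len(X) + 1)))


LINE = obs_from([0.0, 1.0, 2.0, 10.0, 11.0])


# ---------------------------------------------------------------------------
# build_dendrogram
# ---------------------------------------------------------------------------

class TestBuildDendrogram:
    def test_two_observations_single_link(self):
        dend = build_dendrogram(obs_from([[0.0], [3.0]]), linkage="single")
        assert dend.n_leaves == 2
        assert dend.heights[0] == pytest.approx(3.0)

    def test_line_fixture_final_single_linkage_height(self):
        dend = build_dendrogram(LINE, linkage="single")
        assert dend.heights[-1] == pytest.approx(8.0)

    def test_n_minus_one_links(self):
        rng = np.random.default_rng(0)
        obs = obs_from(rng.normal(size=(65, 4)))
        dend = build_dendrogram(obs)
        assert dend.links.shape == (64, 4)

    @pytest.mark.parametrize("method", ["single", "complete", "average", "ward"])
    def test_matches_naive_oracle(self, method):
        rng = np.random.default_rng(11)
        for _ in range(10):
            X = rng.normal(size=(rng.integers(3, 9), 3))
            dend = build_dendrogram(obs_from(X), linkage=method)
            oracle_heights, oracle_parts = naive_agglomerate(X, method)
            np.testing.assert_allclose(dend.heights, oracle_heights, rtol=1e-9)
            ours = partitions_from_dendrogram(dend)
            assert ours == oracle_parts

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            build_dendrogram(obs_from([[1.0]]))

    def test_ward_requires_euclidean(self):
        with pytest.raises(ValueError):
            build_dendrogram(LINE, linkage="ward", metric="cityblock")


# ---------------------------------------------------------------------------
# cuts
# ---------------------------------------------------------------------------

class TestCutAtHeight:
    def test_below_all_links_gives_singletons(self):
        dend = build_dendrogram(LINE, linkage="single")
        part = cut_at_height(dend, 0.5)
        assert part.n_clusters == 5

    def test_above_all_links_gives_one_cluster(self):
        dend = build_dendrogram(LINE, linkage="single")
        assert cut_at_height(dend, 100.0).n_clusters == 1

    def test_line_fixture_mid_cut(self):
        dend = build_dendrogram(LINE, linkage="single")
        part = cut_at_height(dend, 1.5)
        groups = {frozenset(v) for v in part.clusters().values()}
        assert groups == {frozenset({1, 2, 3}), frozenset({4, 5})}

    def test_cluster_count_formula(self):
        rng = np.random.default_rng(5)
        dend = build_dendrogram(obs_from(rng.normal(size=(12, 2))))
        for h in rng.uniform(0, dend.heights[-1] * 1.1, size=20):
            part = cut_at_height(dend, float(h))
            assert part.n_clusters == 1 + int((dend.heights > h).sum())

    def test_refinement_of_decreasing_heights(self):
        rng = np.random.default_rng(9)
        dend = build_dendrogram(obs_from(rng.normal(size=(10, 3))))
        h1, h2 = 0.8 * dend.heights[-1], 0.3 * dend.heights[-1]
        coarse, fine = cut_at_height(dend, h1), cut_at_height(dend, h2)
        for cluster in fine.clusters().values():
            assert len({coarse.assignment[c] for c in cluster}) == 1


class TestCutsByGreatestLinks:
    def test_k1_is_two_cluster_split(self):
        dend = build_dendrogram(LINE, linkage="single")
        (part,) = cuts_by_greatest_links(dend, 1)
        assert part.n_clusters == 2

    def test_line_fixture_k2_sizes(self):
        # single-linkage heights are [1, 1, 1, 8]: the second distinct
        # height is 1, and severing its tied links together yields all
        # five singletons
        dend = build_dendrogram(LINE, linkage="single")
        parts = cuts_by_greatest_links(dend, 2)
        assert [p.n_clusters for p in parts] == [2, 5]

    def test_distinct_heights_give_k_plus_one_clusters(self):
        # without ties the k-th cut has exactly k+1 clusters
        obs = obs_from([0.0, 1.0, 3.0, 10.0, 30.0])
        dend = build_dendrogram(obs, linkage="single")
        parts = cuts_by_greatest_links(dend, 3)
        assert [p.n_clusters for p in parts] == [2, 3, 4]

    def test_tied_heights_severed_together(self):
        # manual dendrogram: two merges at height 1.0, root at 2.0
        links = np.array([[0, 1, 1.0, 2], [2, 3, 1.0, 2], [4, 5, 2.0, 4]])
        dend = Dendrogram(n_leaves=4, links=links, leaf_labels=[1, 2, 3, 4])
        parts = cuts_by_greatest_links(dend, 2)
        assert [p.n_clusters for p in parts] == [2, 4]

    def test_out_of_range_k_rejected(self):
        dend = build_dendrogram(LINE, linkage="single")
        for k in (0, 5):
            with pytest.raises(ValueError):
                cuts_by_greatest_links(dend, k)

    def test_target_counts_selection(self):
        dend = build_dendrogram(LINE, linkage="single")
        parts = cuts_by_target_counts(dend, [2, 3])
        # the tied height-1 links sever together, so the coarsest cut with
        # >= 3 clusters already has 5
        assert [p.n_clusters for p in parts] == [2, 5]
        with pytest.raises(ValueError):
            cuts_by_target_counts(dend, [3, 2])


# ---------------------------------------------------------------------------
# label hierarchies
# ---------------------------------------------------------------------------

class TestLabelHierarchy:
    def test_single_partition_over_four_classes(self):
        part = Partition(assignment={1: 1, 2: 1, 3: 2, 4: 2}, n_clusters=2,
                         cut_height=1.0)
        lh = build_label_hierarchy([part], [1, 2, 3, 4])
        assert lh.stage_class_counts() == [3, 5]
        assert lh.stages[-1].remap == {1: 1, 2: 2, 3: 3, 4: 4}

    def test_remap_composition_is_nested(self):
        rng = np.random.default_rng(3)
        dend = build_dendrogram(obs_from(rng.normal(size=(9, 3))))
        parts = cuts_by_greatest_links(dend, 3)
        lh = build_label_hierarchy(parts, list(range(1, 10)))
        for coarse, fine in zip(lh.stages, lh.stages[1:]):
            fine_to_coarse = {}
            for cls in fine.remap:
                key = fine.remap[cls]
                fine_to_coarse.setdefault(key, coarse.remap[cls])
                assert fine_to_coarse[key] == coarse.remap[cls]

    def test_non_nested_partitions_rejected(self):
        # coarse groups {1,2}{3}; "finer" groups {1,3}{2} cut across them
        coarse = Partition(assignment={1: 1, 2: 1, 3: 2}, n_clusters=2,
                           cut_height=2.0)
        crossing = Partition(assignment={1: 1, 2: 2, 3: 1}, n_clusters=2,
                             cut_height=1.0)
        with pytest.raises(ValueError, match="not nested"):
            build_label_hierarchy([coarse, crossing], [1, 2, 3])

    def test_json_round_trip(self, tmp_path):
        part = Partition(assignment={1: 1, 2: 1, 3: 2, 4: 2}, n_clusters=2,
                         cut_height=1.0)
        lh = build_label_hierarchy([part], [1, 2, 3, 4])
        path = lh.to_json(tmp_path / "h.json")
        loaded = LabelHierarchy.from_json(path)
        assert loaded.stage_class_counts() == lh.stage_class_counts()
        assert [s.remap for s in loaded] == [s.remap for s in lh]


class TestRemapMask:
    def test_identity_stage(self):
        mask = np.array([[0, 5], [9, 5]])
        stage = Stage(C=10, remap={5: 5, 9: 9})
        np.testing.assert_array_equal(remap_mask(mask, stage), mask)

    def test_cluster_collapse(self):
        mask = np.array([[0, 5], [9, 5]])
        stage = Stage(C=2, remap={5: 1, 9: 1})
        np.testing.assert_array_equal(remap_mask(mask, stage),
                                      np.array([[0, 1], [1, 1]]))

    def test_background_only_mask_unchanged(self):
        mask = np.zeros((3, 3), dtype=int)
        stage = Stage(C=2, remap={5: 1})
        np.testing.assert_array_equal(remap_mask(mask, stage), mask)

    def test_unknown_label_rejected(self):
        mask = np.array([[7]])
        with pytest.raises(KeyError, match="7"):
            remap_mask(mask, Stage(C=2, remap={5: 1}))


class TestDendrogramPersistence:
    def test_csv_round_trip(self, tmp_path):
        dend = build_dendrogram(LINE, linkage="average")
        path = save_dendrogram(dend, tmp_path / "linkage.csv")
        loaded = load_dendrogram(path)
        assert loaded.n_leaves == dend.n_leaves
        assert loaded.leaf_labels == dend.leaf_labels
        np.testing.assert_allclose(loaded.links, dend.links)
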