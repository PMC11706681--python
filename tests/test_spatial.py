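"""Geometry-derived epsilon, DBSCAN semantics and cluster summaries."""

import numpy as np
import pytest

from rootmitosis import (
    ARABIDOPSIS_CELL,
    ClusterParams,
    cell_diameter,
    cluster_count_size_distribution,
    dbscan,
    epsilon_from_diameter,
    pairwise_centre_distances,
    summarize_clusters,
)
from rootmitosis.spatial import cluster_table
from rootmitosis.synthetic import SynthConfig, simulate_positions_with_truth
from rootmitosis import simulate_table, intact_defaults, regenerating_defaults


def _components_oracle(points, eps):
    """Union-find connected components of the eps-neighbourhood graph;
    isolated vertices are noise (-1).  Exact DBSCAN for min_samples=2."""
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    linked = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(points[i] - points[j]) <= eps:
                linked[i] = linked[j] = True
                parent[find(i)] = find(j)
    labels = np.full(n, -1)
    next_label = 0
    seen = {}
    for i in range(n):
        if not linked[i]:
            continue
        root = find(i)
        if root not in seen:
            seen[root] = next_label
            next_label += 1
        labels[i] = seen[root]
    return labels


class TestGeometry:
    def test_cell_diameter_matches_printed_value(self):
        d = cell_diameter(6, 4, 4)
        assert d == pytest.approx(np.sqrt(68))
        assert abs(d - 8.24) < 0.01

    @pytest.mark.parametrize("edges,expected", [((1, 0, 0), 1.0), ((3, 4, 12), 13.0)])
    def test_cell_diameter_euclidean(self, edges, expected):
        assert cell_diameter(*edges) == pytest.approx(expected)

    def test_negative_edge_rejected(self):
        with pytest.raises(ValueError):
            cell_diameter(-1, 2, 3)

    def test_epsilon_three_diameters(self):
        assert epsilon_from_diameter(8.24, 3) == pytest.approx(24.72)
        assert epsilon_from_diameter(5.0, 1) == 5.0
        assert epsilon_from_diameter(ARABIDOPSIS_CELL.diameter, 3) == pytest.approx(
            3 * np.sqrt(68)
        )

    def test_epsilon_invalid_inputs(self):
        with pytest.raises(ValueError):
            epsilon_from_diameter(0.0, 3)
        with pytest.raises(ValueError):
            epsilon_from_diameter(8.24, 0)


class TestDbscan:
    params = ClusterParams(24.72, 2)

    def test_close_pair_forms_one_cluster(self):
        pts = np.array([[0, 0, 0], [10, 0, 0]], dtype=float)
        lab = dbscan(pts, self.params)
        assert list(lab.labels) == [0, 0]
        assert lab.n_clusters == 1

    def test_isolated_point_is_noise(self):
        pts = np.array([[0, 0, 0], [100, 0, 0]], dtype=float)
        assert list(dbscan(pts, self.params).labels) == [-1, -1]

    def test_empty_input_is_empty_labeling(self):
        lab = dbscan(np.empty((0, 3)), self.params)
        assert lab.labels.size == 0 and lab.n_clusters == 0

    def test_matches_component_oracle_on_random_frames(self, rng):
        for _ in range(30):
            pts = rng.uniform(0, 200, size=(rng.integers(2, 40), 3))
            ours = dbscan(pts, self.params).labels
            oracle = _components_oracle(pts, 24.72)
            assert (ours == -1).tolist() == (oracle == -1).tolist()
            # identical partitions up to label names
            pairs = {(a, b) for a, b in zip(ours, oracle) if a >= 0}
            assert len({a for a, _ in pairs}) == len(pairs) == len({b for _, b in pairs})

    def test_partition_invariant_under_permutation(self, rng):
        pts = rng.uniform(0, 150, size=(25, 3))
        base = dbscan(pts, self.params).labels
        for _ in range(5):
            perm = rng.permutation(len(pts))
            permuted = dbscan(pts[perm], self.params).labels
            # compare partitions as sets of frozensets of original indices
            def groups(labels, index):
                out = {}
                for lab, idx in zip(labels, index):
                    if lab >= 0:
                        out.setdefault(lab, set()).add(idx)
                return {frozenset(v) for v in out.values()}
            assert groups(base, np.arange(len(pts))) == groups(permuted, perm)

    def test_partition_invariant_under_rigid_motion(self, rng):
        pts = rng.uniform(0, 150, size=(30, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = pts @ q.T + np.array([17.0, -4.0, 220.0])
        a = dbscan(pts, self.params).labels
        b = dbscan(moved, self.params).labels
        assert list(a) == list(b)

    def test_growing_epsilon_only_merges(self, rng):
        for _ in range(100):
            pts = rng.uniform(0, 150, size=(20, 3))
            small = dbscan(pts, ClusterParams(12.0, 2)).labels
            big = dbscan(pts, ClusterParams(24.0, 2)).labels
            for c in set(small[small >= 0]):
                members = np.flatnonzero(small == c)
                assert len(set(big[members])) == 1  # never split
                assert np.all(big[members] >= 0)

    def test_matches_sklearn_reference(self, rng):
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        for min_samples in (2, 3):
            for _ in range(10):
                pts = rng.uniform(0, 120, size=(40, 3))
                ours = dbscan(pts, ClusterParams(24.72, min_samples)).labels
                ref = sklearn_cluster.DBSCAN(eps=24.72, min_samples=min_samples).fit(pts).labels_
                assert (ours == -1).tolist() == (ref == -1).tolist()
                pairs = {(a, b) for a, b in zip(ours, ref) if a >= 0}
                assert len({a for a, _ in pairs}) == len(pairs) == len({b for _, b in pairs})


class TestSummaries:
    def test_pair_centre_is_midpoint(self):
        pts = np.array([[0, 0, 0], [10, 0, 0]], dtype=float)
        s = summarize_clusters(dbscan(pts, ClusterParams(24.72, 2)), pts)
        assert s.n_clusters == 1 and list(s.sizes) == [2]
        assert np.allclose(s.centres[0], [5, 0, 0])

    def test_all_noise_summary_is_empty(self):
        pts = np.array([[0, 0, 0], [500, 0, 0]], dtype=float)
        s = summarize_clusters(dbscan(pts, ClusterParams(24.72, 2)), pts)
        assert s.n_clusters == 0 and s.sizes.size == 0
        assert pairwise_centre_distances(s).size == 0

    def test_centres_recover_thomas_parents(self):
        # sparse regime: matched cluster centres land near true parents
        errs = []
        for seed in range(20):
            cfg = SynthConfig(seed=seed, domain_um=(400.0, 400.0, 400.0),
                              cluster_sigma_um=2.0, events_per_cluster_mean=3.0)
            pos, truth = simulate_positions_with_truth(60, cfg)
            lab = dbscan(pos, ClusterParams(24.72, 2))
            s = summarize_clusters(lab, pos)
            for c in s.centres:
                d = np.linalg.norm(truth.parent_centres - c, axis=1).min()
                errs.append(d)
        assert np.mean(errs) < 2 * 2.0  # ~ sigma-scale accuracy

    def test_count_size_distribution_expands_frames(self):
        pts = np.array([[0, 0, 0], [5, 0, 0], [100, 0, 0], [104, 0, 0], [108, 0, 0]], float)
        lab = dbscan(pts, ClusterParams(24.72, 2), frame_index=0)
        s = summarize_clusters(lab, pts)
        dist = cluster_count_size_distribution([s])
        rows = {(r.n_clusters, r.size): r.frequency for r in dist.itertuples()}
        assert rows == {(2, 2): 1, (2, 3): 1}

    def test_count_size_distribution_conserves_events(self):
        t = simulate_table(intact_defaults(4), regenerating_defaults(4), 2)
        labels_df, summaries = cluster_table(t, ClusterParams(24.72, 2))
        dist = cluster_count_size_distribution(summaries)
        assert (dist["size"] * dist["frequency"]).sum() == (labels_df["label"] >= 0).sum()

    def test_three_centre_distances_match_enumeration(self):
        centres = np.array([[0, 0, 0], [3, 4, 0], [0, 0, 10]], dtype=float)
        from rootmitosis.spatial import ClusterSummary
        s = ClusterSummary(0, 3, np.array([2, 2, 2]), centres)
        got = sorted(pairwise_centre_distances(s))
        brute = sorted(
            np.linalg.norm(centres[i] - centres[j])
            for i in range(3) for j in range(i + 1, 3)
        )
        assert np.allclose(got, brute)

    def test_two_centres_single_distance(self):
        from rootmitosis.spatial import ClusterSummary
        s = ClusterSummary(0, 2, np.array([2, 2]), np.array([[0, 0, 0], [3, 4, 0]], float))
        assert pairwise_centre_distances(s).tolist() == [5.0]


def test_cluster_table_is_per_frame_and_per_root(tiny_table):
    labels_df, summaries = cluster_table(tiny_table, ClusterParams(24.72, 2))
    # intact_1 frame 0 has two events 10*sqrt(1) apart -> one cluster;
    # every other frame holds a single (noise) event
    by_frame = {(s.root_id, s.frame_index): s.n_clusters for s in summaries}
    assert by_frame[("intact_1", 0)] == 1
    assert by_frame[("intact_1", 2)] == 0
    assert (labels_df.groupby(["root_id", "frame_index"])["label"].max() >= 0).sum() == 1
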