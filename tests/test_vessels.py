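import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesselfish import (
    BinMatrix,
    VesselCluster,
    VesselParams,
    bh_adjust,
    classify_caliber,
    cluster_vessels,
    compare_calibers,
    compare_groups,
    vessel_gene_stats,
)


def grid_bm(bin_coords, counts=None, genes=("G",)):
    """BinMatrix from (i, j) lattice indices at pitch 50."""
    coords = np.array(bin_coords, dtype=float)
    n = len(coords)
    if counts is None:
        counts = np.ones((n, len(genes)), dtype=int)
    return BinMatrix(
        (coords[:, 0] + 0.5) * 50.0,
        (coords[:, 1] + 0.5) * 50.0,
        list(genes),
        counts,
        pitch=50.0,
    )


def exact_ranksum_p(a, b):
    """Full enumeration of all C(n+m, n) rank assignments (tie-free)."""
    pooled = sorted(a) + sorted(b)
    n, m = len(a), len(b)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    w_obs = sum(ranks[v] for v in a)
    mean_w = n * (n + m + 1) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(1, n + m + 1), n):
        w = sum(combo)
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / total


def bh_oracle(p):
    """Closed-form step-up: adj_i = min_{j >= i} m * p_(j) / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum.accumulate((m * p[order] / (np.arange(m) + 1))[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


class TestClusterVessels:
    def test_six_contiguous_bins_form_one_retained_cluster(self):
        bm = grid_bm([(i, 0) for i in range(6)])
        clusters = cluster_vessels(bm)
        assert len(clusters) == 1
        assert clusters[0].n_bins == 6

    def test_four_bin_cluster_removed(self):
        bm = grid_bm([(i, 0) for i in range(4)])
        assert cluster_vessels(bm) == []

    def test_two_blobs_match_connected_components_oracle(self, rng):
        import networkx as nx

        blob_a = [(i, j) for i in range(3) for j in range(2)]
        blob_b = [(i + 10, j) for i in range(2) for j in range(3)]
        coords = blob_a + blob_b
        bm = grid_bm(coords)
        clusters = cluster_vessels(bm)

        g = nx.Graph()
        g.add_nodes_from(range(len(coords)))
        for p, q in itertools.combinations(range(len(coords)), 2):
            d = 50.0 * math.hypot(
                coords[p][0] - coords[q][0], coords[p][1] - coords[q][1]
            )
            if d <= 75.0:
                g.add_edge(p, q)
        oracle = {
            frozenset(c) for c in nx.connected_components(g) if len(c) >= 5
        }
        got = {frozenset(map(int, c.bin_indices)) for c in clusters}
        assert got == oracle

    def test_empty_input_gives_empty_list(self):
        bm = grid_bm([(0, 0)]).select(np.zeros(1, dtype=bool))
        assert cluster_vessels(bm) == []

    def test_diagonal_bins_join_within_linkage_cut(self):
        # 8-neighborhood: diagonal lattice distance = sqrt(2)*pitch < 1.5*pitch
        bm = grid_bm([(0, 0), (1, 1), (2, 2), (3, 3), (4, 4)])
        clusters = cluster_vessels(bm)
        assert len(clusters) == 1


class TestCaliber:
    @pytest.mark.parametrize("n_bins,expected", [(31, "larger"), (30, "smaller"), (5, "smaller")])
    def test_threshold_boundaries(self, n_bins, expected):
        assert classify_caliber(n_bins) == expected

    def test_caliber_is_function_of_bin_count_only(self):
        a = VesselCluster(0, np.arange(31), "artery", classify_caliber(31))
        b = VesselCluster(1, np.arange(100, 131), "vein", classify_caliber(31))
        assert a.caliber == b.caliber == "larger"


class TestVesselGeneStats:
    def test_hand_computed_pct_and_mean(self):
        bm = grid_bm([(0, 0), (1, 0), (2, 0)], counts=np.array([[0], [2], [4]]))
        cluster = VesselCluster(0, np.arange(3), "artery", "smaller")
        pct, mean = vessel_gene_stats(cluster, bm, "G")
        assert pct == pytest.approx(100 * 2 / 3)
        assert mean == pytest.approx(3.0)

    def test_all_zero_counts_flagged_undefined_mean(self):
        bm = grid_bm([(0, 0), (1, 0)], counts=np.zeros((2, 1), dtype=int))
        cluster = VesselCluster(0, np.arange(2), "artery", "smaller")
        pct, mean = vessel_gene_stats(cluster, bm, "G")
        assert pct == 0.0 and math.isnan(mean)

    def test_uniform_counts(self):
        bm = grid_bm([(0, 0), (1, 0)], counts=np.full((2, 1), 7))
        cluster = VesselCluster(0, np.arange(2), "artery", "smaller")
        pct, mean = vessel_gene_stats(cluster, bm, "G")
        assert pct == 100.0 and mean == 7.0

    def test_unknown_gene_rejected(self):
        bm = grid_bm([(0, 0), (1, 0)])
        cluster = VesselCluster(0, np.arange(2), "artery", "smaller")
        with pytest.raises(KeyError):
            vessel_gene_stats(cluster, bm, "NOPE")


class TestRankSum:
    def test_identical_groups_give_p_one(self):
        cmp = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert cmp.p_value == pytest.approx(1.0)

    def test_textbook_example_exact_p(self):
        cmp = compare_groups([1, 2, 3], [4, 5, 6])
        assert cmp.p_value == pytest.approx(0.1)

    def test_exact_p_matches_enumeration_for_all_small_tie_free_samples(self, rng):
        for n, m in [(2, 3), (3, 3), (4, 2), (4, 4), (5, 3), (6, 6)]:
            vals = rng.permutation(np.arange(1.0, n + m + 1))
            a, b = vals[:n], vals[n:]
            cmp = compare_groups(a, b)
            assert cmp.p_value == pytest.approx(exact_ranksum_p(list(a), list(b)))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0])

    def test_tied_large_samples_use_corrected_normal(self, rng):
        a = rng.integers(0, 4, size=30).astype(float)
        b = rng.integers(0, 4, size=30).astype(float) + 1
        cmp = compare_groups(a, b)
        assert 0 <= cmp.p_value <= 1


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_stepup_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_closed_form_oracle_on_random_vectors(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, size=rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), bh_oracle(p))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_adjusted_at_least_raw(self, p):
        adj = bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-12).all()
        assert (adj <= 1.0).all()


class TestCompareCalibersNull:
    def test_null_simulation_controls_false_discoveries(self):
        """Both caliber groups drawn from one distribution: BH discovery
        rate stays within 0.05 + 3 Monte-Carlo sd over 200 genes."""
        rng = np.random.default_rng(7)
        n_genes = 200
        p_values = []
        for _ in range(n_genes):
            a = rng.normal(50, 10, size=12)
            b = rng.normal(50, 10, size=12)
            p_values.append(compare_groups(a, b).p_value)
        frac = (bh_adjust(p_values) < 0.05).mean()
        assert frac <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_genes)


def test_compare_calibers_detects_planted_rate_difference(rng):
    """Six vessels per caliber with per-bin rates 0.6 vs 0.2 separate."""
    coords, counts, clusters = [], [], []
    idx = 0
    genes = ["SULF1", "VWF"]
    for v in range(12):
        large = v < 6
        n_bins = 36 if large else 20
        rate = 0.6 if large else 0.2
        members = []
        for b in range(n_bins):
            coords.append((b, 3 * v))
            counts.append([int(rng.uniform() < rate), 2])
            members.append(idx)
            idx += 1
        clusters.append(
            VesselCluster(v, np.array(members), "artery", "larger" if large else "smaller")
        )
    bm = grid_bm(coords, counts=np.array(counts), genes=genes)
    df = compare_calibers(clusters, bm, genes)
    row = df[(df.gene == "SULF1") & (df.metric == "pct_expressing")].iloc[0]
    assert row.p_adj < 0.05
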