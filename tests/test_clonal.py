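"""Change-point features, dissimilarity, permutation FDR and clone calls."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from scnpipe import clonal
from scnpipe.clonal import (ChangePoint, IncidenceTables, build_incidence,
                            changepoints_from_cn, cluster_tree, detect_clones,
                            detect_subclones, minimal_stabbing, null_distribution,
                            pair_dissimilarity, pair_fdr)
from scnpipe.stats import fisher_exact_greater, log_dissimilarity


class TestChangepointsFromCN:
    def test_gain_and_loss_positions(self):
        cps = changepoints_from_cn([2, 2, 3, 3, 1, 1], ["chr1"] * 6)
        assert [(cp.sign, cp.lo <= 2 <= cp.hi) for cp in cps][0] == (1, True)
        assert [cp.sign for cp in cps] == [1, -1]
        assert cps[0].lo <= 2 <= cps[0].hi
        assert cps[1].lo <= 4 <= cps[1].hi

    def test_chromosome_boundary_not_a_changepoint(self):
        cps = changepoints_from_cn([2, 2, 3, 3], ["chr1", "chr1", "chr2", "chr2"])
        assert cps == []

    def test_intervals_clipped_to_chromosome(self):
        cps = changepoints_from_cn([2, 3, 3, 3], ["chr1"] * 4, halfwidth=5)
        assert cps[0].lo == 0 and cps[0].hi == 3

    def test_count_matches_scan_oracle(self, rng):
        cn = rng.integers(1, 5, 200)
        chrom = np.repeat(["chr1", "chr2", "chr3"], [80, 60, 60])
        cps = changepoints_from_cn(cn, chrom)
        expected = sum(1 for i in range(1, 200)
                       if chrom[i] == chrom[i - 1] and cn[i] != cn[i - 1])
        assert len(cps) == expected


def brute_force_min_stabbing(intervals):
    """Oracle: smallest subset of candidate points covering all intervals."""
    if not intervals:
        return 0
    candidates = sorted({p for lo, hi in intervals for p in (lo, hi)})
    for size in range(1, len(candidates) + 1):
        for subset in itertools.combinations(candidates, size):
            if all(any(lo <= p <= hi for p in subset) for lo, hi in intervals):
                return size
    raise AssertionError("unreachable")


class TestMinimalStabbing:
    def test_single_interval(self):
        assert minimal_stabbing([(1, 3)]) == [3]

    def test_three_intervals(self):
        assert minimal_stabbing([(1, 3), (2, 5), (6, 8)]) == [3, 8]
        assert brute_force_min_stabbing([(1, 3), (2, 5), (6, 8)]) == 2

    def test_empty_input(self):
        assert minimal_stabbing([]) == []

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError, match="invalid interval"):
            minimal_stabbing([(5, 2)])

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 40), st.integers(0, 8)),
                    min_size=1, max_size=8))
    def test_property_covers_with_minimal_cardinality(self, raw):
        intervals = [(lo, lo + length) for lo, length in raw]
        points = minimal_stabbing(intervals)
        assert all(any(lo <= p <= hi for p in points) for lo, hi in intervals)
        assert len(points) == brute_force_min_stabbing(intervals)
        assert points == sorted(points)

    def test_greedy_is_minimal_on_random_instances(self, rng):
        for _ in range(200):
            k = int(rng.integers(1, 9))
            los = rng.integers(0, 25, k)
            lens = rng.integers(0, 6, k)
            intervals = list(zip(los.tolist(), (los + lens).tolist()))
            points = minimal_stabbing(intervals)
            assert all(any(lo <= p <= hi for p in points) for lo, hi in intervals)
            assert len(points) == brute_force_min_stabbing(intervals)


class TestBuildIncidence:
    def test_shared_and_private_changepoint(self):
        # two cells share a gain interval, a third has a distinct one
        cps = [ChangePoint("a", 10, 14, 1), ChangePoint("b", 11, 15, 1),
               ChangePoint("c", 40, 44, 1)]
        tables = build_incidence(cps, ["a", "b", "c"])
        assert tables.pos.shape == (2, 3)
        shared = tables.pos[tables.pos.sum(axis=1) == 2]
        np.testing.assert_array_equal(shared, [[1, 1, 0]])

    def test_single_cell_single_cp(self):
        tables = build_incidence([ChangePoint("a", 5, 9, -1)], ["a"])
        np.testing.assert_array_equal(tables.neg, [[1]])
        assert tables.pos.shape == (0, 1)

    def test_zero_cp_cell_gets_zero_column(self):
        cps = [ChangePoint("a", 5, 9, 1)]
        tables = build_incidence(cps, ["a", "b"])
        assert tables.pos[:, 1].sum() == 0

    def test_matches_containment_oracle(self, rng):
        cells = [f"c{i}" for i in range(12)]
        cps = []
        for cell in cells:
            for _ in range(rng.integers(0, 6)):
                lo = int(rng.integers(0, 100))
                hi = lo + int(rng.integers(0, 5))
                cps.append(ChangePoint(cell, lo, hi, int(rng.choice([1, -1]))))
        tables = build_incidence(cps, cells)
        for mat, points, sign in ((tables.pos, tables.pos_points, 1),
                                  (tables.neg, tables.neg_points, -1)):
            for fi, point in enumerate(points):
                for cj, cell in enumerate(cells):
                    expected = any(cp.lo <= point <= cp.hi for cp in cps
                                   if cp.cell_id == cell and cp.sign == sign)
                    assert mat[fi, cj] == expected
            # every interval contains at least one stabbing point of its sign
            for cp in cps:
                if cp.sign == sign:
                    assert any(cp.lo <= p <= cp.hi for p in points)
            assert (mat.sum(axis=1) >= 1).all()


def _tables(pos, neg, cells=None):
    pos = np.asarray(pos, dtype=np.uint8).reshape(-1, len(cells))
    neg = np.asarray(neg, dtype=np.uint8).reshape(-1, len(cells))
    return IncidenceTables(cells=list(cells), pos_points=np.arange(pos.shape[0]),
                           neg_points=np.arange(neg.shape[0]), pos=pos, neg=neg)


class TestPairDissimilarity:
    def test_identical_pair_more_similar_than_differing_pair(self, rng):
        pos = np.zeros((10, 3), dtype=np.uint8)
        pos[:5, 0] = pos[:5, 1] = 1  # a, b identical; 5 features absent in both
        pos[:4, 2] = 1
        pos[9, 2] = 1
        d = pair_dissimilarity(_tables(pos, np.zeros((0, 3)), cells="abc"))
        assert d[0, 1] < d[0, 2]
        assert d[0, 1] < d[1, 2]

    def test_symmetry_and_diagonal(self, rng):
        pos = (rng.random((20, 6)) < 0.4).astype(np.uint8)
        neg = (rng.random((15, 6)) < 0.4).astype(np.uint8)
        d = pair_dissimilarity(_tables(pos, neg, cells="abcdef"))
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0)
        assert (d <= 0).all()

    def test_relabeling_permutes_matrix(self, rng):
        pos = (rng.random((20, 5)) < 0.4).astype(np.uint8)
        neg = (rng.random((20, 5)) < 0.4).astype(np.uint8)
        d = pair_dissimilarity(_tables(pos, neg, cells="abcde"))
        perm = [2, 0, 4, 1, 3]
        d2 = pair_dissimilarity(_tables(pos[:, perm], neg[:, perm], cells="abcde"))
        np.testing.assert_allclose(d2, d[np.ix_(perm, perm)])

    def test_matches_direct_fisher_combination(self, rng):
        pos = (rng.random((12, 4)) < 0.5).astype(np.uint8)
        neg = (rng.random((9, 4)) < 0.5).astype(np.uint8)
        d = pair_dissimilarity(_tables(pos, neg, cells="abcd"))
        for i, j in itertools.combinations(range(4), 2):
            ps = []
            for mat in (pos, neg):
                both = int(mat[:, i] @ mat[:, j])
                na, nb = int(mat[:, i].sum()), int(mat[:, j].sum())
                ps.append(fisher_exact_greater(both, na - both, nb - both,
                                               mat.shape[0] - na - nb + both))
            assert d[i, j] == pytest.approx(log_dissimilarity(ps[0], ps[1]), abs=1e-9)

    def test_empty_sign_contributes_p_one(self):
        pos = np.array([[1, 1], [1, 1], [0, 1]], dtype=np.uint8)
        d_both = pair_dissimilarity(_tables(pos, np.zeros((0, 2)), cells="ab"))
        p_pos = fisher_exact_greater(2, 0, 1, 0)
        assert d_both[0, 1] == pytest.approx(log_dissimilarity(p_pos, 1.0), abs=1e-9)

    def test_null_pvalues_near_uniform(self, rng):
        # independent random columns: per-sign Fisher p-values ~ U(0,1)
        mat = (rng.random((1000, 1000)) < 0.3).astype(np.int64)
        ps = []
        for i in range(0, 1000, 2):
            a, b = mat[:, i], mat[:, i + 1]
            both = int(a @ b)
            ps.append(fisher_exact_greater(both, a.sum() - both, b.sum() - both,
                                           1000 - a.sum() - b.sum() + both))
        assert kstest(ps, "uniform").pvalue > 0.01


class TestClusterTree:
    def test_two_cells_merge_at_their_dissimilarity(self):
        d = np.array([[0.0, -5.0], [-5.0, 0.0]])
        z = cluster_tree(d)
        assert z.shape == (1, 4)
        assert z[0, 2] == pytest.approx(-5.0)

    def test_closest_pair_merges_first(self):
        d = np.array([[0, -9, -2], [-9, 0, -2], [-2, -2, 0]], dtype=float)
        z = cluster_tree(d)
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}

    def test_matches_naive_average_linkage(self, rng):
        n = 8
        d = -rng.uniform(0, 50, (n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        z = cluster_tree(d, "average")
        # naive agglomerative average-linkage oracle
        clusters = {i: [i] for i in range(n)}
        dist = {frozenset((i, j)): d[i, j] for i in range(n) for j in range(i)}
        heights = []
        next_id = n
        while len(clusters) > 1:
            pair = min(dist, key=lambda k: dist[k])
            heights.append(dist[pair])
            a, b = tuple(pair)
            merged = clusters.pop(a) + clusters.pop(b)
            for c in list(clusters):
                dist[frozenset((next_id, c))] = np.mean(
                    [d[x, y] for x in merged for y in clusters[c]])
            dist = {k: v for k, v in dist.items() if a not in k and b not in k}
            clusters[next_id] = merged
            next_id += 1
        np.testing.assert_allclose(np.sort(z[:, 2]), np.sort(heights), atol=1e-9)

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError):
            cluster_tree(np.zeros((1, 1)))

    def test_unknown_linkage_rejected(self):
        with pytest.raises(ValueError):
            cluster_tree(np.zeros((3, 3)), "median")


class TestNullDistribution:
    def test_all_zero_tables_give_zero_dissimilarity(self):
        t = _tables(np.zeros((0, 4)), np.zeros((0, 4)), cells="abcd")
        null = null_distribution(t, n_perm=5, rng=np.random.default_rng(0))
        np.testing.assert_allclose(null, 0.0, atol=1e-12)

    def test_row_sums_preserved(self, rng):
        mat = (rng.random((30, 10)) < 0.3).astype(np.uint8)
        shuffled = clonal._row_shuffled(mat.copy(), rng)
        np.testing.assert_array_equal(shuffled.sum(axis=1), mat.sum(axis=1))

    def test_reproducible_with_fixed_seed(self, rng):
        t = _tables((rng.random((20, 8)) < 0.4).astype(np.uint8),
                    (rng.random((20, 8)) < 0.4).astype(np.uint8), cells="abcdefgh")
        a = null_distribution(t, n_perm=10, rng=np.random.default_rng(7))
        b = null_distribution(t, n_perm=10, rng=np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)


class TestPairFDR:
    def test_observed_below_all_null_gets_zero(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = -50.0
        d[0, 2] = d[2, 0] = -1.0
        d[1, 2] = d[2, 1] = -1.0
        fdr = pair_fdr(d, null_sample=np.array([-10.0, -5.0, -1.0, 0.0]))
        assert fdr[0, 1] == 0.0

    def test_observed_equal_null_calibrates_to_one(self, rng):
        vals = -rng.uniform(0, 10, 45)
        d = np.zeros((10, 10))
        iu = np.triu_indices(10, 1)
        d[iu] = vals
        d[(iu[1], iu[0])] = vals
        fdr = pair_fdr(d, null_sample=np.repeat(vals, 20))
        assert fdr[np.triu_indices(10, 1)].min() >= 0.9

    def test_planted_pairs_detected(self, rng):
        # 10 planted cell pairs sharing 30 features among 40 noise cells
        n_features, n_cells = 120, 60
        mat = (rng.random((n_features, n_cells)) < 0.08).astype(np.uint8)
        for k in range(10):
            rows = rng.choice(n_features, 30, replace=False)
            mat[rows, 2 * k] = 1
            mat[rows, 2 * k + 1] = 1
        t = _tables(mat[:60], mat[60:], cells=[f"c{i}" for i in range(n_cells)])
        d = pair_dissimilarity(t)
        null = null_distribution(t, n_perm=40, rng=rng)
        fdr = pair_fdr(d, null)
        planted = [fdr[2 * k, 2 * k + 1] for k in range(10)]
        assert sum(f < 0.05 for f in planted) >= 9  # >= 90% power
        assert (fdr <= 1.0).all()


def _clone_tables(rng, n_cells=30, clone=range(10), n_features=40, shared=12):
    """Random sparse tables with one planted clone sharing `shared` features."""
    pos = (rng.random((n_features, n_cells)) < 0.05).astype(np.uint8)
    neg = (rng.random((n_features, n_cells)) < 0.05).astype(np.uint8)
    rows = rng.choice(n_features, shared, replace=False)
    for mat, rr in ((pos, rows[: shared // 2]), (neg, rows[shared // 2 :])):
        for c in clone:
            mat[rr, c] = 1
    return _tables(pos, neg, cells=[f"c{i:02d}" for i in range(n_cells)])


class TestDetectClones:
    def _run(self, tables, rng, **kw):
        d = pair_dissimilarity(tables)
        z = cluster_tree(d)
        null = null_distribution(tables, n_perm=50, rng=rng)
        fdr = pair_fdr(d, null)
        return detect_clones(z, fdr, tables, **kw), z, fdr

    def test_planted_clone_recovered_exactly(self, rng):
        tables = _clone_tables(rng)
        clones, _, _ = self._run(tables, rng)
        hard = [c for c in clones if c.kind == "hard"]
        assert len(hard) == 1
        assert set(hard[0].cells) == {f"c{i:02d}" for i in range(10)}

    def test_two_disjoint_clones(self, rng):
        n_cells = 100
        pos = np.zeros((70, n_cells), dtype=np.uint8)
        neg = np.zeros((70, n_cells), dtype=np.uint8)
        pos[:15, :20] = 1   # clone 1: 30 features over pos+neg
        neg[:15, :20] = 1
        pos[15:30, 20:40] = 1  # clone 2, disjoint features
        neg[15:30, 20:40] = 1
        # sprinkle rare noise so remaining rows are not empty
        noise = (rng.random((70, n_cells)) < 0.02).astype(np.uint8)
        tables = _tables(pos | noise, neg | noise,
                         cells=[f"c{i:03d}" for i in range(n_cells)])
        clones, _, _ = self._run(tables, rng)
        hard = sorted([c for c in clones if c.kind == "hard"],
                      key=lambda c: min(c.cells))
        assert len(hard) == 2
        assert set(hard[0].cells) == {f"c{i:03d}" for i in range(20)}
        assert set(hard[1].cells) == {f"c{i:03d}" for i in range(20, 40)}

    def test_feature_sharing_gate(self, rng):
        # cohesive branch sharing only 2 features is not a clone at nshare_min=3
        tables = _clone_tables(rng, shared=2)
        clones, z, fdr = self._run(tables, rng, nshare_min=3)
        assert [c for c in clones if c.kind == "hard"] == []

    def test_no_structure_no_clones(self, rng):
        pos = (rng.random((30, 20)) < 0.1).astype(np.uint8)
        neg = (rng.random((30, 20)) < 0.1).astype(np.uint8)
        tables = _tables(pos, neg, cells=[f"c{i:02d}" for i in range(20)])
        clones, _, _ = self._run(tables, rng)
        assert [c for c in clones if c.kind == "hard"] == []


class TestDetectSubclones:
    def test_split_clone_recovered(self):
        # one clone of 24 cells whose halves differ by 10 private features each
        # (5 per sign, the way a private CNV event leaves one CP of each sign)
        rng = np.random.default_rng(0)
        n_cells, n_features = 40, 80
        pos = (rng.random((n_features, n_cells)) < 0.02).astype(np.uint8)
        neg = (rng.random((n_features, n_cells)) < 0.02).astype(np.uint8)
        pos[:10, :24] = 1
        neg[:10, :24] = 1  # 20 clone-wide features
        pos[10:15, :12] = 1    # subclone A private
        neg[10:15, :12] = 1
        pos[15:20, 12:24] = 1  # subclone B private
        neg[15:20, 12:24] = 1
        tables = _tables(pos, neg, cells=[f"c{i:02d}" for i in range(n_cells)])
        clone = clonal.Clone(clone_id="C1", kind="hard",
                             cells=[f"c{i:02d}" for i in range(24)], node=-1)
        subs = detect_subclones(clone, tables, rng=rng)
        assert len(subs) == 2
        sets = sorted((set(s.cells) for s in subs), key=min)
        assert sets[0] == {f"c{i:02d}" for i in range(12)}
        assert sets[1] == {f"c{i:02d}" for i in range(12, 24)}

    def test_identical_cells_no_subclones(self):
        pos = np.zeros((10, 30), dtype=np.uint8)
        pos[:, :12] = 1
        pos[5:, :] = 0
        tables = _tables(pos, np.zeros((0, 30)), cells=[f"c{i:02d}" for i in range(30)])
        clone = clonal.Clone(clone_id="C1", kind="hard",
                             cells=[f"c{i:02d}" for i in range(12)], node=-1)
        assert detect_subclones(clone, tables, rng=np.random.default_rng(0)) == []

    def test_invariant_to_all_ones_rows(self, rng):
        tables = _clone_tables(rng, n_cells=30, clone=range(12), shared=10)
        clone = clonal.Clone(clone_id="C1", kind="hard",
                             cells=[f"c{i:02d}" for i in range(12)], node=-1)
        subs_a = detect_subclones(clone, tables, rng=np.random.default_rng(3))
        ones = np.ones((4, 30), dtype=np.uint8)
        padded = _tables(np.vstack([tables.pos, ones]),
                         np.vstack([tables.neg, ones]), cells=tables.cells)
        subs_b = detect_subclones(clone, padded, rng=np.random.default_rng(3))
        assert [set(s.cells) for s in subs_a] == [set(s.cells) for s in subs_b]

    def test_too_small_clone_skipped(self, rng):
        tables = _clone_tables(rng)
        clone = clonal.Clone(clone_id="C1", kind="hard",
                             cells=[f"c{i:02d}" for i in range(5)], node=-1)
        assert detect_subclones(clone, tables, rng=rng, min_clone_size=3) == []
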