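import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirbic.core import (
    Bicluster,
    PbeConfig,
    bimax_seeds,
    extend_seed,
    meet_min_distance,
    merge_biclusters,
    run_pbe,
)


def brute_force_maximal_bicliques(M, min_rows, min_cols):
    """Exhaustive column-subset oracle for inclusion-maximal all-1 submatrices.

    For every non-empty column subset C, take the rows covering C and close
    the pair; closed patterns meeting both size minima are exactly the
    inclusion-maximal all-1 submatrices of that size.
    """
    M = np.asarray(M, dtype=bool)
    n_rows, n_cols = M.shape
    found = set()
    for mask in range(1, 1 << n_cols):
        cols = [j for j in range(n_cols) if mask >> j & 1]
        rows = [i for i in range(n_rows) if M[i, cols].all()]
        if len(rows) < min_rows:
            continue
        closed_cols = [j for j in range(n_cols) if M[np.ix_(rows, [j])].all()]
        if len(closed_cols) < min_cols:
            continue
        found.add((tuple(rows), tuple(closed_cols)))
    return found


class TestBimaxSeeds:
    @pytest.mark.parametrize(
        "shape,density,min_rows,min_cols,seed",
        [
            ((6, 6), 0.5, 1, 1, 0),
            ((8, 8), 0.6, 2, 2, 1),
            ((10, 8), 0.4, 2, 3, 2),
            ((12, 12), 0.55, 2, 2, 3),
            ((12, 10), 0.7, 3, 3, 4),
        ],
    )
    def test_uncapped_enumeration_matches_oracle(
        self, shape, density, min_rows, min_cols, seed
    ):
        rng = np.random.default_rng(seed)
        M = rng.random(shape) < density
        expected = brute_force_maximal_bicliques(M, min_rows, min_cols)
        got = {
            (b.rows, b.cols)
            for b in bimax_seeds(M, min_rows, min_cols, max_seeds=None)
        }
        assert got == expected

    def test_all_ones_matrix_yields_whole_matrix(self):
        M = np.ones((12, 12), dtype=int)
        seeds = bimax_seeds(M, 10, 10, max_seeds=None)
        assert len(seeds) == 1
        assert seeds[0].rows == tuple(range(12))
        assert seeds[0].cols == tuple(range(12))

    def test_planted_block_recovered(self):
        M = np.zeros((30, 25), dtype=int)
        rows, cols = list(range(5, 15)), list(range(8, 18))
        M[np.ix_(rows, cols)] = 1
        for cap in (None, 5):
            seeds = bimax_seeds(M, 10, 10, max_seeds=cap)
            assert len(seeds) == 1
            assert seeds[0].rows == tuple(rows)
            assert seeds[0].cols == tuple(cols)

    def test_capped_seeds_are_maximal_all_one_and_not_nested(self, tiny_profile):
        seeds = bimax_seeds(tiny_profile.matrix, 10, 10, max_seeds=10)
        assert seeds
        M = tiny_profile.matrix
        for s in seeds:
            assert s.density == 1.0
            sub = M[np.ix_(list(s.rows), list(s.cols))]
            assert sub.all()
            # inclusion-maximality: no row or column can be added
            other_rows = np.setdiff1d(np.arange(M.shape[0]), s.rows)
            assert not M[np.ix_(other_rows, list(s.cols))].all(axis=1).any()
            other_cols = np.setdiff1d(np.arange(M.shape[1]), s.cols)
            assert not M[np.ix_(list(s.rows), other_cols)].all(axis=0).any()
        for a in seeds:
            for b in seeds:
                if a is not b:
                    assert not (
                        set(a.rows) <= set(b.rows) and set(a.cols) <= set(b.cols)
                    )

    def test_cap_is_a_prefix_of_larger_cap(self, tiny_profile):
        s5 = bimax_seeds(tiny_profile.matrix, 10, 10, max_seeds=5)
        s10 = bimax_seeds(tiny_profile.matrix, 10, 10, max_seeds=10)
        assert [(b.rows, b.cols) for b in s5] == [
            (b.rows, b.cols) for b in s10[: len(s5)]
        ]

    def test_no_qualifying_seed_gives_empty_list(self):
        M = np.zeros((20, 20), dtype=int)
        assert bimax_seeds(M, 10, 10, max_seeds=20) == []


class TestExtendSeed:
    def test_all_ones_profile_extends_to_full_matrix(self):
        M = np.ones((15, 12), dtype=int)
        seed = Bicluster(rows=tuple(range(10)), cols=tuple(range(10)))
        ext = extend_seed(seed, M, PbeConfig())
        assert ext.rows == tuple(range(15))
        assert ext.cols == tuple(range(12))
        assert ext.stage == "extended"
        assert ext.density == 1.0

    def test_isolated_seed_returned_unchanged(self):
        M = np.zeros((30, 30), dtype=int)
        M[np.ix_(range(10), range(10))] = 1
        seed = Bicluster(rows=tuple(range(10)), cols=tuple(range(10)))
        ext = extend_seed(seed, M, PbeConfig())
        assert ext.rows == seed.rows and ext.cols == seed.cols

    def test_noisy_planted_block_recovery(self):
        rng = np.random.default_rng(11)
        M = (rng.random((200, 100)) < 0.20).astype(int)
        rows = rng.choice(200, 40, replace=False)
        cols = rng.choice(100, 40, replace=False)
        block = np.ones((40, 40), dtype=int)
        flip = rng.choice(1600, size=32, replace=False)  # 2% zeros
        block.flat[flip] = 0
        M[np.ix_(rows, cols)] = block
        # deterministic interior all-1 10x10 seed
        clean_rows = [int(r) for i, r in enumerate(rows)
                      if block[i].sum() == 40][:10]
        clean_cols = [int(c) for j, c in enumerate(cols)
                      if block[:, j].sum() == 40][:10]
        assert len(clean_rows) == 10 and len(clean_cols) == 10
        seed = Bicluster(rows=tuple(clean_rows), cols=tuple(clean_cols))
        ext = extend_seed(seed, M, PbeConfig())
        row_recall = len(set(ext.rows) & set(rows.tolist())) / 40
        col_recall = len(set(ext.cols) & set(cols.tolist())) / 40
        assert row_recall >= 0.95 and col_recall >= 0.95
        # exit contract: every row/column has zero fraction <= 0.10
        sub = M[np.ix_(list(ext.rows), list(ext.cols))]
        assert (1 - sub.mean(axis=1)).max() <= 0.10 + 1e-9
        assert (1 - sub.mean(axis=0)).max() <= 0.10 + 1e-9

    def test_extension_is_deterministic(self, tiny_profile):
        M = tiny_profile.matrix
        seeds = bimax_seeds(M, 10, 10, max_seeds=5)
        first = [extend_seed(s, M, PbeConfig()) for s in seeds]
        second = [extend_seed(s, M, PbeConfig()) for s in seeds]
        assert [(b.rows, b.cols) for b in first] == [
            (b.rows, b.cols) for b in second
        ]

    def test_dense_seed_survives_first_threshold(self):
        # a density-1.0 seed is a fixed point of removal at t = 0.01
        M = np.zeros((40, 40), dtype=int)
        M[np.ix_(range(12), range(12))] = 1
        seed = Bicluster(rows=tuple(range(12)), cols=tuple(range(12)))
        ext = extend_seed(seed, M, PbeConfig())
        assert set(seed.rows) <= set(ext.rows)
        assert set(seed.cols) <= set(ext.cols)


def _bicluster(rows, cols):
    return Bicluster(rows=tuple(rows), cols=tuple(cols),
                     stage="extended", density=0.95)


class TestMeetMinDistance:
    def test_identical_biclusters_have_distance_zero(self):
        a = _bicluster(range(4), range(5))
        assert meet_min_distance(a, a) == 0.0

    def test_row_disjoint_pairs_have_distance_one(self):
        a = _bicluster(range(4), range(5))
        b = _bicluster(range(10, 14), range(5))
        assert meet_min_distance(a, b) == 1.0

    def test_hand_computed_half_overlap(self):
        # |A| = 4*5 = 20, |B| = 2*10 = 20, shared 2 rows x 5 cols = 10 cells
        a = _bicluster(range(4), range(5))
        b = _bicluster(range(2), range(10))
        assert meet_min_distance(a, b) == pytest.approx(0.5)

    @given(
        ra=st.sets(st.integers(0, 12), min_size=1),
        ca=st.sets(st.integers(0, 12), min_size=1),
        rb=st.sets(st.integers(0, 12), min_size=1),
        cb=st.sets(st.integers(0, 12), min_size=1),
    )
    @settings(max_examples=120, deadline=None)
    def test_symmetry_and_range(self, ra, ca, rb, cb):
        a, b = _bicluster(ra, ca), _bicluster(rb, cb)
        d = meet_min_distance(a, b)
        assert d == meet_min_distance(b, a)
        assert 0.0 <= d <= 1.0


class TestMergeBiclusters:
    def _block_profile(self):
        M = np.zeros((40, 40), dtype=int)
        M[np.ix_(range(15), range(15))] = 1
        M[np.ix_(range(25, 40), range(25, 40))] = 1
        return M

    def test_single_bicluster_passes_through(self):
        M = self._block_profile()
        b = _bicluster(range(15), range(15))
        merged = merge_biclusters([b], M, PbeConfig())
        assert len(merged) == 1
        assert merged[0].stage == "merged"

    def test_identical_biclusters_collapse(self):
        M = self._block_profile()
        b = _bicluster(range(15), range(15))
        merged = merge_biclusters([b, _bicluster(range(15), range(15))], M,
                                  PbeConfig())
        assert len(merged) == 1

    def test_distant_biclusters_stay_separate(self):
        M = self._block_profile()
        a = _bicluster(range(15), range(15))
        b = _bicluster(range(25, 40), range(25, 40))
        assert meet_min_distance(a, b) == 1.0
        merged = merge_biclusters([a, b], M, PbeConfig())
        assert len(merged) == 2

    def test_trimming_removes_noisy_union_parts(self):
        # two overlapping biclusters whose union spans zero cells
        M = np.zeros((30, 30), dtype=int)
        M[np.ix_(range(12), range(12))] = 1
        M[np.ix_(range(10, 22), range(10, 22))] = 1
        a = _bicluster(range(12), range(12))
        b = _bicluster(range(10, 22), range(10, 22))
        merged = merge_biclusters([a, b], M, PbeConfig())
        for m in merged:
            sub = M[np.ix_(list(m.rows), list(m.cols))]
            assert (1 - sub.mean(axis=1)).max() <= 0.10 + 1e-9
            assert (1 - sub.mean(axis=0)).max() <= 0.10 + 1e-9


class TestRunPbe:
    def test_all_zero_profile_gives_no_biclusters(self):
        assert run_pbe(np.zeros((50, 30), dtype=int)) == []

    def test_single_all_one_block_profile(self):
        M = np.ones((20, 20), dtype=int)
        out = run_pbe(M)
        assert len(out) == 1
        assert out[0].rows == tuple(range(20))
        assert out[0].cols == tuple(range(20))

    def test_planted_biclusters_recovered(self, tiny_profile):
        out = run_pbe(tiny_profile.matrix)
        assert out
        for rows, cols in tiny_profile.planted:
            planted_cells = len(rows) * len(cols)
            best = max(
                len(set(b.rows) & set(rows)) * len(set(b.cols) & set(cols))
                for b in out
            )
            assert best >= 0.8 * planted_cells

    def test_outputs_sorted_and_trimmed(self, tiny_profile):
        out = run_pbe(tiny_profile.matrix)
        sizes = [b.n_cells for b in out]
        assert sizes == sorted(sizes, reverse=True)
        M = tiny_profile.matrix
        for b in out:
            sub = M[np.ix_(list(b.rows), list(b.cols))]
            assert (1 - sub.mean(axis=1)).max() <= 0.10 + 1e-9
            assert (1 - sub.mean(axis=0)).max() <= 0.10 + 1e-9

    def test_pipeline_is_deterministic(self, tiny_profile):
        a = run_pbe(tiny_profile.matrix)
        b = run_pbe(tiny_profile.matrix)
        assert [(x.rows, x.cols, x.density) for x in a] == [
            (x.rows, x.cols, x.density) for x in b
        ]
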