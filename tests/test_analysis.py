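"""Embedded-space distances, theta overlap, coverage, correlations."""

import dataclasses
import itertools

import numpy as np
import pytest
from scipy import stats

from hcase.analysis import (
    EmbeddingVector,
    chebyshev_distance,
    coverage_matrix,
    distance_correlation,
    embedding_vector,
    rank_distance,
    theta_overlap,
)
from hcase.embedding import EmbeddedCompound
from hcase.hilbert import GridPoint, hilbert_coords


def stub(cid, b, x, y, z=3, checksum="cs"):
    return EmbeddedCompound(
        compound_id=cid,
        bms_smiles="c1ccccc1",
        nearest_rank=1,
        d_sk_nearest=0.0,
        b=b,
        point=GridPoint(x, y),
        z=z,
        space_checksum=checksum,
    )


class TestDistances:
    def test_rank_distance_absolute_difference(self):
        a, b = stub("a", 5, 0, 0), stub("b", 2, 1, 1)
        assert rank_distance(a, b) == 3
        assert rank_distance(b, a) == 3
        assert rank_distance(a, a) == 0

    def test_rank_distance_refuses_mixed_spaces(self):
        a = stub("a", 5, 0, 0, checksum="s1")
        b = stub("b", 2, 1, 1, checksum="s2")
        with pytest.raises(ValueError):
            rank_distance(a, b)

    def test_chebyshev_values(self):
        assert chebyshev_distance(GridPoint(0, 0), GridPoint(3, 1)) == 3
        assert chebyshev_distance(GridPoint(2, 2), GridPoint(2, 2)) == 0

    def test_chebyshev_metric_axioms_on_8x8_grid(self):
        grid = [GridPoint(x, y) for x in range(8) for y in range(8)]
        for p, q in itertools.combinations(grid, 2):
            d = chebyshev_distance(p, q)
            assert d > 0
            assert d == chebyshev_distance(q, p)
        rng = np.random.default_rng(0)
        idx = rng.integers(0, len(grid), size=(3000, 3))
        for i, j, k in idx:
            p, q, r = grid[i], grid[j], grid[k]
            assert chebyshev_distance(p, r) <= chebyshev_distance(
                p, q
            ) + chebyshev_distance(q, r)


class TestEmbeddingVector:
    def test_empty_embedding_is_all_zero(self):
        v = embedding_vector([], z=2)
        assert v.counts.sum() == 0 and len(v.counts) == 16

    def test_counts_accumulate_per_bin(self):
        emb = [stub(f"c{i}", 7, 0, 0, z=2) for i in range(3)]
        v = embedding_vector(emb, z=2)
        assert v.counts[7] == 3 and v.counts.sum() == 3

    def test_total_conserved_on_fixture(self, embedded):
        v = embedding_vector(embedded, z=4)
        assert v.counts.sum() == len(embedded)

    def test_z_mismatch_rejected(self):
        with pytest.raises(ValueError):
            embedding_vector([stub("a", 0, 0, 0, z=3)], z=2)


def vec(counts, z=1, checksum="cs"):
    return EmbeddingVector(counts=np.asarray(counts), z=z, space_checksum=checksum)


class TestTheta:
    def test_identity(self):
        a = vec([1, 2, 0, 3])
        assert theta_overlap(a, a) == 1.0

    def test_disjoint_supports(self):
        assert theta_overlap(vec([2, 0, 1, 0]), vec([0, 3, 0, 4])) == 0.0

    def test_worked_value_one_third(self):
        a = vec([1, 1, 0, 0])
        b = vec([1, 0, 1, 0])
        assert theta_overlap(a, b) == pytest.approx(1 / 3)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a = vec(rng.integers(0, 5, size=4))
            b = vec(rng.integers(0, 5, size=4))
            if a.counts.sum() == 0 and b.counts.sum() == 0:
                continue
            t = theta_overlap(a, b)
            assert 0.0 <= t <= 1.0
            assert t == pytest.approx(theta_overlap(b, a))

    def test_all_zero_pair_is_an_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            theta_overlap(vec([0, 0, 0, 0]), vec([0, 0, 0, 0]))

    def test_cross_resolution_refused(self):
        with pytest.raises(ValueError):
            theta_overlap(vec([1, 0, 0, 0], z=1), vec([1] + [0] * 15, z=2))

    def test_cross_space_refused(self):
        with pytest.raises(ValueError):
            theta_overlap(vec([1, 0, 0, 0], checksum="a"), vec([1, 0, 0, 0], checksum="b"))


class TestDistanceCorrelation:
    def test_perfect_monotone_layout(self):
        # bins on the x-axis: d_C == d_r exactly
        emb = [stub(f"c{i}", i, i, 0) for i in range(6)]
        assert distance_correlation(emb) == pytest.approx(1.0)

    def test_matches_brute_force_all_pairs(self, embedded):
        subset = embedded[:50]
        d_r, d_c = [], []
        for a, b in itertools.combinations(subset, 2):
            d_r.append(rank_distance(a, b))
            d_c.append(chebyshev_distance(a.point, b.point))
        expected = stats.pearsonr(d_r, d_c).statistic
        assert distance_correlation(subset) == pytest.approx(expected)
        expected_k = stats.kendalltau(d_r, d_c).statistic
        assert distance_correlation(subset, method="kendall") == pytest.approx(
            expected_k
        )

    def test_duplicates_shift_correlation_only_marginally(self, embedded):
        """Duplicating every compound adds zero-distance pairs and
        reweights cross pairs, so the value moves slightly, not freely."""
        dup = list(embedded) + [
            dataclasses.replace(e, compound_id=e.compound_id + "-dup")
            for e in embedded
        ]
        assert distance_correlation(dup) == pytest.approx(
            distance_correlation(embedded), abs=0.05
        )

    def test_subset_protocol_nonoverlapping_and_seeded(self, embedded):
        mean_a, std_a = distance_correlation(
            embedded, subset_size=12, n_subsets=3, seed=9
        )
        mean_b, std_b = distance_correlation(
            embedded, subset_size=12, n_subsets=3, seed=9
        )
        assert (mean_a, std_a) == (mean_b, std_b)
        assert -1.0 <= mean_a <= 1.0 and std_a >= 0.0
        with pytest.raises(ValueError):
            distance_correlation(embedded, subset_size=30, n_subsets=2)

    def test_constant_distance_is_undefined(self):
        emb = [stub(f"c{i}", 4, 2, 2) for i in range(4)]
        with pytest.raises(ValueError, match="constant"):
            distance_correlation(emb)


class TestCoverageMatrix:
    def test_counts_conserved_and_binarized_support(self, embedded):
        mat = coverage_matrix(embedded, z=4)
        assert mat.sum() == len(embedded)
        binary = coverage_matrix(embedded, z=4, binarize=True)
        assert set(np.unique(binary)) <= {0, 1}
        occupied = {(e.point.x, e.point.y) for e in embedded}
        assert binary.sum() == len(occupied)

    def test_support_matches_embedding_vector(self, embedded):
        binary = coverage_matrix(embedded, z=4, binarize=True)
        v = embedding_vector(embedded, z=4)
        assert binary.sum() == np.count_nonzero(v.counts)

    def test_cell_indexing_row_is_y(self):
        emb = [stub("a", 0, 3, 1, z=2)]
        mat = coverage_matrix(emb, z=2)
        assert mat[1, 3] == 1 and mat.sum() == 1
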