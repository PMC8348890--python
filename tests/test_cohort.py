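"""Cohort layer: level vectors, correlation matrix, CSA detection."""

import numpy as np
import pytest

from anis.cohort import (
    CohortMatrix,
    LevelVectors,
    build_level_vectors,
    correlation_matrix,
    detect_csa,
    stability_scan,
    threshold_mask,
)
from anis.entropy import EntropyCurves
from anis.fixtures import planted_cohort


def _curves_from_sprime(idx, sprime):
    sprime = np.asarray(sprime, dtype=float)
    s_dev = np.concatenate([[0.0], np.cumsum(sprime)])
    m = sprime.size + 1
    return EntropyCurves(
        y_levels=np.arange(1, m + 1),
        S=s_dev.copy(),
        n=np.ones(m, dtype=int),
        S_dev=s_dev,
        S_prime=sprime,
        provenance={"id": f"p{idx}"},
    )


class TestLevelVectors:
    def test_shapes_and_membership(self):
        cohort = [_curves_from_sprime(i, np.arange(9, dtype=float) + i)
                  for i in range(3)]
        vectors = build_level_vectors(cohort, min_proteins=3)
        assert vectors.levels.tolist() == list(range(1, 10))
        for y in vectors.levels:
            assert vectors.vectors[int(y)].size == 3
            assert vectors.members[int(y)].tolist() == [0, 1, 2]

    def test_mixed_lengths_mask(self):
        cohort = [
            _curves_from_sprime(0, np.ones(10)),
            _curves_from_sprime(1, np.ones(5)),
        ]
        vectors = build_level_vectors(cohort, min_proteins=1)
        assert vectors.members[3].tolist() == [0, 1]
        assert vectors.members[8].tolist() == [0]

    def test_entries_match_curves(self, rng):
        cohort = [_curves_from_sprime(i, rng.normal(size=12)) for i in range(8)]
        vectors = build_level_vectors(cohort, min_proteins=8)
        for i, curves in enumerate(cohort):
            for li, y in enumerate(curves.prime_levels):
                v = vectors.vectors[int(y)]
                m = vectors.members[int(y)].tolist()
                assert v[m.index(i)] == curves.S_prime[li]

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_level_vectors([])

    def test_min_proteins_unmet_rejected(self):
        cohort = [_curves_from_sprime(0, np.ones(5))]
        with pytest.raises(ValueError, match="at least"):
            build_level_vectors(cohort, min_proteins=2)


class TestCorrelationMatrix:
    def test_identical_vectors_give_one(self):
        cohort = [_curves_from_sprime(i, [float(i + 1)] * 6) for i in range(12)]
        vectors = build_level_vectors(cohort, min_proteins=12)
        matrix = correlation_matrix(vectors, min_pair=12)
        np.testing.assert_array_equal(matrix.r, np.ones_like(matrix.r))

    def test_orthogonal_vectors_give_zero(self):
        vectors = LevelVectors(
            levels=np.array([1, 2]),
            vectors={1: np.array([1.0, 0.0]), 2: np.array([0.0, 1.0])},
            members={1: np.array([0, 1]), 2: np.array([0, 1])},
        )
        matrix = correlation_matrix(vectors, min_pair=2)
        assert matrix.r[0, 1] == 0.0
        assert matrix.r[0, 0] == matrix.r[1, 1] == 1.0

    def test_matches_textbook_cosine(self, rng):
        data = rng.normal(size=(4, 5))  # 4 proteins, 5 levels
        cohort = [_curves_from_sprime(i, data[i]) for i in range(4)]
        vectors = build_level_vectors(cohort, min_proteins=4)
        matrix = correlation_matrix(vectors, min_pair=4)
        for a in range(5):
            for b in range(5):
                va, vb = data[:, a], data[:, b]
                expected = (va @ vb) / np.sqrt((va @ va) * (vb @ vb))
                if a == b:
                    expected = 1.0
                assert matrix.r[a, b] == pytest.approx(expected, abs=1e-12)

    def test_symmetry_and_bounds(self, rng):
        cohort = [_curves_from_sprime(i, rng.normal(size=15)) for i in range(30)]
        matrix = correlation_matrix(build_level_vectors(cohort))
        np.testing.assert_allclose(matrix.r, matrix.r.T, atol=1e-12)
        assert np.nanmax(np.abs(matrix.r)) <= 1.0

    def test_pairwise_complete_intersection(self):
        # protein 1 is absent from high levels; shared subset drives r
        cohort = [
            _curves_from_sprime(0, [1.0, 2.0, 3.0, 4.0]),
            _curves_from_sprime(1, [1.0, 2.0]),
            _curves_from_sprime(2, [2.0, 4.0, 6.0, 8.0]),
        ]
        vectors = build_level_vectors(cohort, min_proteins=2)
        matrix = correlation_matrix(vectors, min_pair=2)
        assert matrix.pair_counts[0, 3].item() == 2  # levels 1 and 4
        # V_1 over {0,1,2} vs V_4 over {0,2}: intersection {0,2} is
        # proportional ([1,2] vs [4,8]) so r = 1
        assert matrix.r[0, 3] == pytest.approx(1.0, abs=1e-12)

    def test_zero_norm_vector_masked(self):
        cohort = [_curves_from_sprime(i, [0.0, 1.0]) for i in range(10)]
        vectors = build_level_vectors(cohort, min_proteins=10)
        matrix = correlation_matrix(vectors, min_pair=10)
        assert np.isnan(matrix.r[0, 0]) and np.isnan(matrix.r[0, 1])
        assert matrix.r[1, 1] == 1.0


class TestThresholdMask:
    def _matrix(self):
        r = np.array([[1.0, 0.8, 0.2], [0.8, 1.0, 0.5], [0.2, 0.5, 1.0]])
        return CohortMatrix(levels=np.arange(1, 4), r=r,
                            pair_counts=np.full((3, 3), 10))

    def test_strict_exceedance(self):
        mask = threshold_mask(self._matrix(), 0.5)
        expected = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]])
        np.testing.assert_array_equal(mask, expected)

    def test_just_below_max_selects_argmax_pair(self):
        mask = threshold_mask(self._matrix(), 0.79)
        assert mask.sum() == 3 + 2  # diagonal plus the symmetric 0.8 pair

    def test_high_threshold_identity(self):
        np.testing.assert_array_equal(
            threshold_mask(self._matrix(), 0.999), np.eye(3, dtype=int)
        )

    def test_monotone_in_threshold(self, rng):
        r = rng.uniform(0, 1, size=(8, 8))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        matrix = CohortMatrix(levels=np.arange(8), r=r,
                              pair_counts=np.full((8, 8), 10))
        m_lo = threshold_mask(matrix, 0.3)
        m_hi = threshold_mask(matrix, 0.7)
        assert np.all(m_hi <= m_lo)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            threshold_mask(self._matrix(), 1.5)
        with pytest.raises(ValueError):
            threshold_mask(self._matrix(), 0.0)


def _csa_oracle(mask):
    """Exhaustive re-derivation: from each uncovered start, the largest
    all-ones square is found by scanning every candidate from scratch."""
    m = mask.shape[0]
    blocks = []
    a = 0
    while a < m:
        best = a
        for b in range(a, m):
            if np.all(mask[a : b + 1, a : b + 1] == 1):
                best = b
            else:
                break
        blocks.append((a + 1, best + 1))
        a = best + 1
    return blocks


class TestDetectCsa:
    def test_identity_mask_singletons(self):
        blocks = detect_csa(np.eye(6, dtype=int))
        assert [(b.y_start, b.y_end) for b in blocks] == [(i, i) for i in range(1, 7)]

    def test_all_ones_single_block(self):
        blocks = detect_csa(np.ones((5, 5), dtype=int))
        assert [(b.y_start, b.y_end) for b in blocks] == [(1, 5)]

    def test_matches_bruteforce_on_random_masks(self, rng):
        for _ in range(200):
            m = 20
            upper = rng.random((m, m)) < 0.45
            mask = np.triu(upper, 1)
            mask = (mask | mask.T).astype(int)
            np.fill_diagonal(mask, 1)
            got = [(b.y_start, b.y_end) for b in detect_csa(mask)]
            assert got == _csa_oracle(mask)

    def test_nonsymmetric_rejected(self):
        mask = np.eye(3, dtype=int)
        mask[0, 1] = 1
        with pytest.raises(ValueError, match="symmetric"):
            detect_csa(mask)

    def test_blocks_disjoint_and_cover_diagonal(self, rng):
        m = 15
        upper = rng.random((m, m)) < 0.5
        mask = np.triu(upper, 1)
        mask = (mask | mask.T).astype(int)
        np.fill_diagonal(mask, 1)
        blocks = detect_csa(mask)
        covered = [y for b in blocks for y in range(b.y_start, b.y_end + 1)]
        assert covered == list(range(1, m + 1))


class TestStabilityScan:
    def test_constant_structure_stabilizes_second_threshold(self):
        r = np.eye(4)
        matrix = CohortMatrix(levels=np.arange(1, 5), r=r,
                              pair_counts=np.full((4, 4), 10))
        result = stability_scan(matrix, [0.9, 0.5, 0.1])
        assert result.stable and result.threshold == 0.5
        assert [(b.y_start, b.y_end) for b in result.blocks] == [
            (1, 1), (2, 2), (3, 3), (4, 4)]

    def test_recovers_planted_blocks(self, rng):
        m = 12
        r = np.full((m, m), 0.05)
        r[:6, :6] = 0.8
        r[6:, 6:] = 0.8
        r += rng.normal(scale=0.01, size=(m, m))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        matrix = CohortMatrix(levels=np.arange(1, m + 1), r=r,
                              pair_counts=np.full((m, m), 10))
        result = stability_scan(matrix, [0.7, 0.5, 0.3])
        assert result.stable
        assert [(b.y_start, b.y_end) for b in result.blocks] == [(1, 6), (7, 12)]

    def test_short_schedule_rejected(self):
        matrix = CohortMatrix(levels=np.arange(2), r=np.eye(2),
                              pair_counts=np.full((2, 2), 10))
        with pytest.raises(ValueError):
            stability_scan(matrix, [0.5])

    def test_nondecreasing_schedule_rejected(self):
        matrix = CohortMatrix(levels=np.arange(2), r=np.eye(2),
                              pair_counts=np.full((2, 2), 10))
        with pytest.raises(ValueError, match="decreasing"):
            stability_scan(matrix, [0.5, 0.5])


class TestPlantedCohortEndToEnd:
    def test_zero_noise_exact_blocks(self):
        bands = [(4, 8), (16, 22)]
        curves = planted_cohort(3, 50, bands, noise=0.0)
        matrix = correlation_matrix(build_level_vectors(curves))
        lv = matrix.levels.tolist()
        in1 = [lv.index(y) for y in range(4, 9)]
        in2 = [lv.index(y) for y in range(16, 23)]
        assert matrix.r[np.ix_(in1, in1)].min() == 1.0
        assert np.abs(matrix.r[np.ix_(in1, in2)]).max() < 1e-12

    def test_noisy_recovery_of_both_bands(self):
        bands = [(4, 8), (16, 22)]
        curves = planted_cohort(11, 200, bands, noise=0.1)
        matrix = correlation_matrix(build_level_vectors(curves))
        result = stability_scan(matrix)
        assert result.stable
        for lo, hi in bands:
            assert any(
                b.overlaps(lo, hi) and b.y_end > b.y_start for b in result.blocks
            )
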