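"""CNV score, Moran's I, patch co-localization and cluster separation."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from merlin import synthetic
from merlin.spatial import (
    Contingency2x2,
    cnv_score,
    cnv_scores,
    fisher_exact_2x2,
    morans_i,
    multiscale_cooccurrence,
    patch_cooccurrence,
    rook_weights,
    separation_indices,
)


def fisher_greater_oracle(a, b, c, d):
    """Exact upper-tail hypergeometric p by rational enumeration."""
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = comb(n, c1)
    hi = min(r1, c1)
    p = sum(Fraction(comb(r1, x) * comb(n - r1, c1 - x), denom) for x in range(a, hi + 1))
    return float(p)


class TestCnvScore:
    def test_neutral_matrix_scores_zero(self):
        assert cnv_score([1.0, 1.0, 1.0]) == 0.0

    def test_hand_case(self):
        assert cnv_score([0.5, 1.0, 1.5, 1.05]) == pytest.approx(0.5)

    def test_boundaries_count_as_inside(self):
        # the window uses strict inequalities: 0.9 and 1.1 are neutral
        assert cnv_score([0.9, 1.1]) == 0.0
        assert cnv_score([0.9 - 1e-9, 1.1 + 1e-9]) == 1.0

    def test_invariant_to_gene_order(self):
        rng = np.random.default_rng(0)
        x = rng.normal(1.0, 0.2, size=200)
        assert cnv_score(x) == cnv_score(np.sort(x))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cnv_score([])

    def test_matrix_scores_match_planted_fraction(self):
        mat, _ = synthetic.simulate_cnv_matrix(
            3, 200, noise_sd=0.0, planted_segments=[((1,), 0, 80, -0.4)]
        )
        scores = cnv_scores(mat)
        assert scores.tolist() == [0.0, 0.4, 0.0]


class TestMoransI:
    def test_checkerboard_is_minus_one(self):
        grid, _ = synthetic.simulate_spatial_field(4, 4, "checkerboard")
        i, _ = morans_i(grid.ravel(), rook_weights(4, 4))
        assert i == pytest.approx(-1.0, abs=1e-12)

    def test_iid_fields_average_to_null_expectation(self):
        w = rook_weights(10, 10)
        rng = np.random.default_rng(1)
        vals = [morans_i(rng.normal(size=100), w)[0] for _ in range(200)]
        assert np.mean(vals) == pytest.approx(-1 / 99, abs=0.015)

    def test_contiguous_block_positive(self):
        grid, _ = synthetic.simulate_spatial_field(8, 8, "clustered")
        assert morans_i(grid.ravel(), rook_weights(8, 8))[0] > 0

    def test_invariant_to_constant_shift(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=36)
        w = rook_weights(6, 6)
        assert morans_i(z, w)[0] == pytest.approx(morans_i(z + 100.0, w)[0])

    def test_permutation_p_small_for_structured_field(self):
        grid, _ = synthetic.simulate_spatial_field(8, 8, "checkerboard")
        _, p = morans_i(grid.ravel(), rook_weights(8, 8), n_perm=199, seed=0)
        assert p is not None and p < 0.05

    def test_constant_field_rejected(self):
        with pytest.raises(ValueError):
            morans_i(np.ones(9), rook_weights(3, 3))


class TestPatchCooccurrence:
    def test_identical_half_coverage_masks(self):
        # 8 of 16 patches positive in both channels
        m = np.zeros((40, 40), dtype=int)
        for i in range(4):
            for j in range(4):
                if (i + j) % 2 == 0:
                    m[i * 10 : (i + 1) * 10, j * 10 : (j + 1) * 10] = 1
        table, p = patch_cooccurrence(m, m, k=4)
        assert table == Contingency2x2(8, 0, 0, 8)
        assert p == pytest.approx(1 / 12870, rel=1e-12)

    def test_one_channel_everywhere(self):
        a = np.ones((20, 20), dtype=int)
        b = np.zeros((20, 20), dtype=int)
        table, p = patch_cooccurrence(a, b, k=4)
        assert table == Contingency2x2(0, 16, 0, 0)
        assert p == 1.0

    def test_patch_counts_sum_to_k_squared(self):
        rng = np.random.default_rng(3)
        a = (rng.random((37, 53)) < 0.2).astype(int)
        b = (rng.random((37, 53)) < 0.2).astype(int)
        for k in (4, 6, 8, 10):
            table, _ = patch_cooccurrence(a, b, k)
            assert sum(table) == k * k

    def test_multiscale_readout_covers_requested_grids(self):
        a, b, _ = synthetic.simulate_mask_pair((80, 80), "identical", seed=4)
        res = multiscale_cooccurrence(a, b)
        assert res["k"].tolist() == [4, 6, 8, 10]
        assert (res["p"] <= 1.0).all()

    def test_identical_masks_at_least_as_enriched_as_independent(self):
        worse = 0
        trials = 40
        for s in range(trials):
            ai, bi, _ = synthetic.simulate_mask_pair((100, 100), "identical", seed=s)
            an, bn, _ = synthetic.simulate_mask_pair((100, 100), "independent", seed=1000 + s)
            _, p_same = patch_cooccurrence(ai, bi, k=6)
            _, p_indep = patch_cooccurrence(an, bn, k=6)
            worse += p_same > p_indep
        assert worse <= trials * 0.05

    def test_oversized_grid_rejected(self):
        with pytest.raises(ValueError):
            patch_cooccurrence(np.zeros((3, 3), int), np.zeros((3, 3), int), k=4)


class TestFisherExact:
    def test_point_mass_case(self):
        assert fisher_exact_2x2((8, 0, 0, 8)) == pytest.approx(1 / 12870, rel=1e-12)

    def test_degenerate_margin(self):
        assert fisher_exact_2x2((0, 0, 0, 9)) == 1.0

    def test_matches_enumeration_oracle_on_sampled_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 10, size=4)
            assert fisher_exact_2x2((a, b, c, d)) == pytest.approx(
                fisher_greater_oracle(a, b, c, d), abs=1e-12
            )

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2((-1, 0, 0, 0))


class TestSeparationIndices:
    def test_hand_evaluated_two_cluster_case(self):
        # clusters {(0,0),(0,1)} and {(10,10),(10,11)}:
        # between-SS = 200, within-SS = 1, CH = (200/1)/(1/2) = 400
        pts = np.array([[0, 0], [0, 1], [10, 10], [10, 11]], float)
        ch, sil = separation_indices(pts, [0, 0, 1, 1])
        assert ch == pytest.approx(400.0)
        assert sil > 0.9

    def test_random_labels_on_one_blob_score_low(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(100, 2))
        labels = rng.integers(0, 2, size=100)
        _, sil = separation_indices(pts, labels)
        assert abs(sil) < 0.15

    def test_single_label_rejected(self):
        with pytest.raises(ValueError):
            separation_indices(np.zeros((4, 2)), [0, 0, 0, 0])
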