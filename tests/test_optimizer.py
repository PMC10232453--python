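"""Grid-search calibration of the VCI contribution weight."""

import numpy as np
import pytest
from scipy import stats

from vhiopt import (
    candidate_grid, compute_vhi, compute_vhi_opt, correlation_profile,
    dominance_summary, optimize_contribution, pearson, select_a_opt,
)
from vhiopt.optimizer import ContributionMap

from conftest import make_cube


def brute_force_a_opt(vci, tci, ref, candidates):
    """Independent oracle: recompute VHI(a) and its Pearson correlation for
    every candidate with scipy, then take the argmax (first on ties)."""
    best = (None, -np.inf)
    for a in candidates:
        vhi = a * vci + (1 - a) * tci
        r = stats.pearsonr(vhi, ref).statistic
        if r > best[1]:
            best = (a, r)
    return best


class TestCandidateGrid:
    def test_default_grid_is_the_49_point_grid(self):
        grid = candidate_grid()
        assert len(grid) == 49
        assert grid[0] == pytest.approx(0.02)
        assert grid[-1] == pytest.approx(0.98)
        assert np.all(np.diff(grid) > 0)
        np.testing.assert_allclose(np.diff(grid), 0.02)
        assert 0.5 in grid  # 25 * 0.02: a balanced optimum is representable

    def test_other_steps(self):
        assert len(candidate_grid(0.1)) == 9
        with pytest.raises(ValueError):
            candidate_grid(0.0)


class TestPearson:
    def test_self_correlation(self, rng):
        x = rng.uniform(size=10)
        assert pearson(x, x) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # direct evaluation of the product-moment formula on (1,2,3),(1,2,4)
        assert pearson([1, 2, 3], [1, 2, 4]) == pytest.approx(0.981981, abs=1e-5)

    def test_matches_scipy_on_random_pairs(self, rng):
        for _ in range(20):
            x = rng.normal(size=15)
            y = rng.normal(size=15)
            assert pearson(x, y) == pytest.approx(stats.pearsonr(x, y).statistic, abs=1e-12)

    def test_undefined_cases_flagged_not_raised(self):
        assert np.isnan(pearson([1, 2], [3, 4]))          # too short
        assert np.isnan(pearson([1, 1, 1], [1, 2, 3]))    # constant
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([1.0, np.nan, 3.0, 4.0, 5.0])
        # pairwise filtering leaves 3 pairs
        assert pearson(x, y) == pytest.approx(1.0)


class TestCorrelationProfile:
    def test_ref_equal_vci_maximal_at_high_weight(self, rng):
        vci = rng.normal(50, 10, size=41)
        tci = rng.normal(50, 10, size=41)
        prof = correlation_profile(vci, tci, ref=vci)
        assert len(prof) == 49
        a, _ = select_a_opt(prof)
        assert a == pytest.approx(0.98)

    def test_ref_equal_tci_maximal_at_low_weight(self, rng):
        vci = rng.normal(50, 10, size=41)
        tci = rng.normal(50, 10, size=41)
        a, _ = select_a_opt(correlation_profile(vci, tci, ref=tci))
        assert a == pytest.approx(0.02)

    def test_identical_inputs_give_constant_profile(self, rng):
        v = rng.normal(50, 10, size=41)
        ref = rng.normal(size=41)
        prof = correlation_profile(v, v, ref)
        np.testing.assert_allclose(prof, prof[0], atol=1e-12)

    def test_short_overlap_flags_all_entries(self, rng):
        v = rng.normal(size=41)
        t = rng.normal(size=41)
        ref = np.full(41, np.nan)
        ref[:5] = rng.normal(size=5)
        prof = correlation_profile(v, t, ref, min_overlap=10)
        assert np.all(np.isnan(prof))


class TestSelectAOpt:
    def test_unique_maximum(self):
        cands = candidate_grid()
        prof = -np.abs(cands - 0.30)
        a, r = select_a_opt(prof, cands)
        assert a == pytest.approx(0.30)
        assert r == pytest.approx(0.0)

    def test_tie_breaks_to_smallest_candidate(self):
        cands = candidate_grid()
        assert select_a_opt(np.zeros(49), cands)[0] == pytest.approx(0.02)
        prof = np.zeros(49)
        prof[[23, 24]] = 0.7  # exact tie at 0.48 and 0.50
        assert select_a_opt(prof, cands)[0] == pytest.approx(0.48)

    def test_all_undefined_gives_invalid(self):
        a, r = select_a_opt(np.full(49, np.nan))
        assert np.isnan(a) and np.isnan(r)


class TestOptimizeContribution:
    def test_matches_brute_force_oracle(self, rng):
        """On random pixels, the vectorized grid search equals a from-scratch
        scipy recomputation of all 49 candidate correlations."""
        cands = candidate_grid()
        n = 41
        for _ in range(200):
            vci = rng.uniform(0, 100, size=n)
            tci = rng.uniform(0, 100, size=n)
            ref = rng.normal(size=n)
            a, r = select_a_opt(correlation_profile(vci, tci, ref), cands)
            a_bf, r_bf = brute_force_a_opt(vci, tci, ref, cands)
            assert a == pytest.approx(a_bf)
            assert r == pytest.approx(r_bf, abs=1e-12)

    def test_four_pixel_scene(self, rng):
        vci = rng.normal(50, 10, size=(41, 2, 2))
        tci = rng.normal(50, 10, size=(41, 2, 2))
        ref = np.empty_like(vci)
        ref[:, 0, :] = vci[:, 0, :]   # top row follows VCI
        ref[:, 1, :] = tci[:, 1, :]   # bottom row follows TCI
        cmap = optimize_contribution(make_cube(vci), make_cube(tci), make_cube(ref))
        np.testing.assert_allclose(cmap.a_opt, [[0.98, 0.98], [0.02, 0.02]])
        assert cmap.valid.all()
        assert np.all(cmap.n_used == 41)

    def test_all_invalid_reference_gives_invalid_map(self, rng):
        vci = make_cube(rng.uniform(0, 100, (41, 2, 2)))
        tci = make_cube(rng.uniform(0, 100, (41, 2, 2)))
        ref = make_cube(np.zeros((41, 2, 2)), valid=np.zeros((41, 2, 2), bool))
        cmap = optimize_contribution(vci, tci, ref)
        assert not cmap.valid.any()

    def test_noiseless_mixture_recovers_true_weight(self, rng):
        """Closed-form oracle: with ref an exact mixture of orthogonal
        equal-variance components, r(a) is the cosine between the weight
        directions (a, 1-a) and (a_true, 1-a_true); the 49-point argmax is
        the argmax of that closed form, within one grid step of a_true."""
        n = 41
        cands = candidate_grid()
        for a_true in (0.17, 0.3, 0.55, 0.834):
            v = rng.normal(size=n)
            t = rng.normal(size=n)
            v = (v - v.mean()) / v.std()
            t = t - t.mean()
            t -= (t @ v) / (v @ v) * v  # exactly orthogonal components
            t /= t.std()
            ref = a_true * v + (1 - a_true) * t
            a, _ = select_a_opt(correlation_profile(v, t, ref))
            closed_form = (cands * a_true + (1 - cands) * (1 - a_true)) / np.sqrt(
                (cands**2 + (1 - cands) ** 2) * (a_true**2 + (1 - a_true) ** 2)
            )
            assert a == pytest.approx(cands[np.argmax(closed_form)])
            assert abs(a - a_true) <= 0.02 + 1e-12

    def test_scale_invariance_of_reference(self, rng):
        vci = make_cube(rng.uniform(0, 100, (41, 2, 2)))
        tci = make_cube(rng.uniform(0, 100, (41, 2, 2)))
        ref_vals = rng.normal(size=(41, 2, 2))
        cm1 = optimize_contribution(vci, tci, make_cube(ref_vals))
        cm2 = optimize_contribution(vci, tci, make_cube(3.7 * ref_vals + 11.0))
        np.testing.assert_array_equal(cm1.a_opt, cm2.a_opt)
        np.testing.assert_allclose(cm1.r_max, cm2.r_max, atol=1e-12)

    def test_r_max_dominates_baseline_weight(self, rng):
        """VHI_opt correlates with the reference at least as well as the
        equal-weight VHI at every valid pixel (in-sample dominance)."""
        vci = make_cube(rng.uniform(0, 100, (41, 4, 4)))
        tci = make_cube(rng.uniform(0, 100, (41, 4, 4)))
        ref = make_cube(rng.normal(size=(41, 4, 4)))
        cmap = optimize_contribution(vci, tci, ref)
        vhi_half = compute_vhi(vci, tci, 0.5)
        for i in range(4):
            for j in range(4):
                r_half = pearson(vhi_half.values[:, i, j], ref.values[:, i, j])
                assert cmap.r_max[i, j] >= r_half - 1e-12

    def test_grid_mismatch_rejected(self, rng):
        from vhiopt import GridSpec
        vci = make_cube(rng.uniform(size=(41, 2, 2)))
        tci = make_cube(rng.uniform(size=(41, 2, 2)))
        ref = make_cube(rng.uniform(size=(41, 2, 2)), grid=GridSpec(2, 2, 9.0, 2.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="grid"):
            optimize_contribution(vci, tci, ref)


class TestVhiOpt:
    def test_uniform_half_weight_reproduces_original_vhi(self, rng):
        vci = make_cube(rng.uniform(0, 100, (3, 2, 2)))
        tci = make_cube(rng.uniform(0, 100, (3, 2, 2)))
        cmap = ContributionMap(
            vci.grid, np.full((2, 2), 0.5), np.zeros((2, 2)),
            np.full((2, 2), 3), np.ones((2, 2), bool),
        )
        out = compute_vhi_opt(vci, tci, cmap)
        np.testing.assert_allclose(out.values, compute_vhi(vci, tci, 0.5).values)

    def test_single_pixel_arithmetic(self):
        vci = make_cube(np.array([[[70.0]]]))
        tci = make_cube(np.array([[[30.0]]]))
        cmap = ContributionMap(
            vci.grid, np.array([[0.2]]), np.zeros((1, 1)),
            np.array([[3]]), np.ones((1, 1), bool),
        )
        assert compute_vhi_opt(vci, tci, cmap).values[0, 0, 0] == pytest.approx(38.0)

    def test_high_weight_tracks_vci(self, rng):
        vci = make_cube(rng.uniform(0, 100, (3, 1, 1)))
        tci = make_cube(rng.uniform(0, 100, (3, 1, 1)))
        cmap = ContributionMap(
            vci.grid, np.array([[0.98]]), np.zeros((1, 1)),
            np.array([[3]]), np.ones((1, 1), bool),
        )
        out = compute_vhi_opt(vci, tci, cmap)
        gap = np.abs(vci.values - tci.values)
        assert np.all(np.abs(out.values - vci.values) <= 0.02 * gap + 1e-12)

    def test_invalid_weights_propagate(self, rng):
        vci = make_cube(rng.uniform(0, 100, (3, 1, 2)))
        tci = make_cube(rng.uniform(0, 100, (3, 1, 2)))
        a = np.array([[0.3, np.nan]])
        cmap = ContributionMap(vci.grid, a, np.zeros((1, 2)),
                               np.array([[3, 0]]), np.isfinite(a))
        out = compute_vhi_opt(vci, tci, cmap)
        assert out.valid[:, 0, 0].all()
        assert not out.valid[:, 0, 1].any()


class TestDominance:
    def test_split_scene(self):
        grid_a = np.array([[0.98, 0.98], [0.02, 0.02]])
        cmap = ContributionMap(
            make_cube(np.zeros((1, 2, 2))).grid, grid_a, np.zeros((2, 2)),
            np.full((2, 2), 41), np.ones((2, 2), bool),
        )
        assert dominance_summary(cmap) == (0.5, 0.5)

    def test_fractions_sum_to_at_most_one(self, rng):
        cands = candidate_grid()
        a = rng.choice(cands, size=(5, 5))
        cmap = ContributionMap(
            make_cube(np.zeros((1, 5, 5))).grid, a, np.zeros((5, 5)),
            np.full((5, 5), 41), np.ones((5, 5), bool),
        )
        f_tci, f_vci = dominance_summary(cmap)
        balanced = float((a == 0.5).mean())
        assert f_tci + f_vci == pytest.approx(1.0 - balanced)

    def test_all_tci_dominated(self):
        a = np.full((2, 2), 0.02)
        cmap = ContributionMap(
            make_cube(np.zeros((1, 2, 2))).grid, a, np.zeros((2, 2)),
            np.full((2, 2), 41), np.ones((2, 2), bool),
        )
        assert dominance_summary(cmap) == (1.0, 0.0)

    def test_no_valid_pixels_rejected(self):
        cmap = ContributionMap(
            make_cube(np.zeros((1, 2, 2))).grid, np.full((2, 2), np.nan),
            np.full((2, 2), np.nan), np.zeros((2, 2), int), np.zeros((2, 2), bool),
        )
        with pytest.raises(ValueError):
            dominance_summary(cmap)
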