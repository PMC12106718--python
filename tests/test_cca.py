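"""CCA fitting, family-blocked permutation inference and regression controls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from physiocca import (FrameSeries, InvalidArgumentError, align_signs,
                       backproject_weights, compare_modes, fit_cca,
                       permutation_test_modes, regress_out_map,
                       regress_out_series)
from physiocca.families import BlockPermuter


class TestFitCCA:
    def test_one_dimensional_blocks_reduce_to_pearson(self, rng):
        x = rng.standard_normal(100)
        y = 0.4 * x + rng.standard_normal(100)
        mode = fit_cca(x[:, None], y[:, None])[0]
        assert abs(mode.canonical_r - abs(np.corrcoef(x, y)[0, 1])) < 1e-12

    def test_linearly_equivalent_blocks_correlate_perfectly(self, rng):
        X = rng.standard_normal((50, 4))
        A = rng.standard_normal((4, 4)) + 4 * np.eye(4)
        modes = fit_cca(X, X @ A)
        assert np.allclose([m.canonical_r for m in modes], 1.0, atol=1e-9)

    def test_invariance_under_invertible_transforms(self, rng):
        X = rng.standard_normal((80, 4))
        Y = X @ rng.standard_normal((4, 3)) + rng.standard_normal((80, 3))
        base = [m.canonical_r for m in fit_cca(X, Y)]
        A = rng.standard_normal((4, 4)) + 3 * np.eye(4)
        B = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        moved = [m.canonical_r for m in fit_cca(X @ A, Y @ B)]
        assert np.allclose(base, moved, atol=1e-8)

    def test_scores_correlate_at_canonical_r(self, rng):
        X = rng.standard_normal((60, 3))
        Y = 0.5 * X + rng.standard_normal((60, 3))
        for m in fit_cca(X, Y):
            r = np.corrcoef(m.brain_scores, m.behavior_scores)[0, 1]
            assert abs(r - m.canonical_r) < 1e-9

    def test_modes_ordered_by_decreasing_r(self, rng):
        X = rng.standard_normal((60, 5))
        Y = rng.standard_normal((60, 5))
        rs = [m.canonical_r for m in fit_cca(X, Y)]
        assert rs == sorted(rs, reverse=True)

    def test_matches_sklearn_cross_check(self, rng):
        sklearn_cca = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.standard_normal((120, 4))
        Y = 0.5 * X @ rng.standard_normal((4, 3)) + rng.standard_normal((120, 3))
        ours = fit_cca(X, Y)[0]
        ref = sklearn_cca.CCA(n_components=1, max_iter=2000).fit(X, Y)
        u, v = ref.transform(X, Y)
        r_ref = abs(np.corrcoef(u[:, 0], v[:, 0])[0, 1])
        assert abs(ours.canonical_r - r_ref) < 1e-6

    def test_rank_deficient_block_rejected(self, rng):
        X = rng.standard_normal((40, 3))
        X = np.column_stack([X, X[:, 0]])
        with pytest.raises(InvalidArgumentError, match="rank deficient"):
            fit_cca(X, rng.standard_normal((40, 2)))


class TestBlockPermuter:
    def test_families_move_as_units(self, rng):
        fam = np.array([0, 0, 1, 1, 2, 3, 4])  # two pairs, three singletons
        perm = BlockPermuter(fam)
        for _ in range(20):
            p = perm.permutation(rng)
            assert sorted(p) == list(range(7))
            # pair members stay adjacent and in order
            for lo in (0, 2):
                assert p[lo + 1] == p[lo] + 1
                assert fam[p[lo]] == fam[p[lo + 1]]
            # pairs land on pair slots, singletons on singleton slots
            assert set(p[:4]) == {0, 1, 2, 3}

    def test_singleton_families_reach_all_positions(self, rng):
        perm = BlockPermuter(np.arange(6))
        hits = np.zeros((6, 6), dtype=int)
        for _ in range(300):
            p = perm.permutation(rng)
            hits[np.arange(6), p] += 1
        assert (hits > 0).all()

    def test_unmatched_sizes_warn_and_fall_back(self, rng):
        with pytest.warns(UserWarning, match="unrestricted"):
            BlockPermuter(np.array([0, 0, 1, 1, 1]))


class TestPermutationTestModes:
    def test_add_one_floor_for_dominant_mode(self, rng):
        z = rng.standard_normal(80)
        X = np.column_stack([z, rng.standard_normal(80)])
        Y = np.column_stack([z + 0.01 * rng.standard_normal(80),
                             rng.standard_normal(80)])
        p = permutation_test_modes(X, Y, None, n_perm=99, seed=0)
        assert np.isclose(p[0], 1 / 100)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(500):
            X = rng.standard_normal((60, 3))
            Y = rng.standard_normal((60, 3))
            ps.append(permutation_test_modes(X, Y, None, n_perm=200,
                                             seed=int(rng.integers(2**31)))[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_planted_mode_detected(self, rng):
        z = rng.standard_normal(300)
        X = np.column_stack([z + 0.7 * rng.standard_normal(300),
                             rng.standard_normal(300)])
        Y = np.column_stack([z + 0.7 * rng.standard_normal(300),
                             rng.standard_normal(300)])
        p = permutation_test_modes(X, Y, None, n_perm=500, seed=4)
        assert p[0] < 0.01


class TestBackProjection:
    def test_variable_identical_to_score_is_significant(self, rng):
        z = rng.standard_normal(100)
        X = np.column_stack([z, rng.standard_normal(100)])
        Y = z[:, None] + 0.1 * rng.standard_normal((100, 1))
        mode = fit_cca(X, Y)[0]
        originals = pd.DataFrame({"self": mode.behavior_scores,
                                  "noise": rng.standard_normal(100)})
        bp = backproject_weights(mode, originals, n_perm=500, alpha=0.01, seed=0)
        assert np.isclose(abs(bp.full_weights[0]), 1.0)
        assert bp.significant[0] and not bp.significant[1]

    def test_fwer_controls_pure_noise(self):
        rng = np.random.default_rng(21)
        false_pos = 0
        for rep in range(10):
            z = rng.standard_normal(80)
            mode = fit_cca(z[:, None], (z + rng.standard_normal(80))[:, None])[0]
            noise = pd.DataFrame(rng.standard_normal((80, 50)))
            bp = backproject_weights(mode, noise, n_perm=500, alpha=0.001,
                                     seed=rep)
            false_pos += bp.significant.sum()
        assert false_pos <= 1

    def test_constant_variable_excluded(self, rng):
        z = rng.standard_normal(50)
        mode = fit_cca(z[:, None], (z + rng.standard_normal(50))[:, None])[0]
        originals = pd.DataFrame({"flat": np.ones(50), "ok": rng.standard_normal(50)})
        bp = backproject_weights(mode, originals, n_perm=100, seed=0)
        assert bp.excluded == ["flat"]
        assert np.isnan(bp.full_weights[0])


class TestAlignSigns:
    def _mode_and_bp(self, rng):
        z = rng.standard_normal(60)
        X = z[:, None]
        Y = (z + 0.3 * rng.standard_normal(60))[:, None]
        mode = fit_cca(X, Y)[0]
        originals = pd.DataFrame({"anchor": -mode.behavior_scores
                                  + 0.1 * rng.standard_normal(60)})
        bp = backproject_weights(mode, originals, n_perm=100, seed=0)
        return mode, bp

    def test_correct_anchor_is_identity(self, rng):
        mode, bp = self._mode_and_bp(rng)
        aligned, abp = align_signs(mode, bp, "anchor", desired_sign=-1)
        assert np.allclose(aligned.behavior_scores, mode.behavior_scores)
        assert aligned.sign_state == "aligned"

    def test_flip_negates_everything_and_keeps_r(self, rng):
        mode, bp = self._mode_and_bp(rng)
        flipped, fbp = align_signs(mode, bp, "anchor", desired_sign=+1)
        assert np.allclose(flipped.behavior_scores, -mode.behavior_scores)
        assert np.allclose(flipped.brain_weights, -mode.brain_weights)
        assert np.allclose(fbp.full_weights, -bp.full_weights)
        assert flipped.canonical_r == mode.canonical_r

    def test_double_application_is_involution(self, rng):
        mode, bp = self._mode_and_bp(rng)
        once, obp = align_signs(mode, bp, "anchor", desired_sign=+1)
        twice, tbp = align_signs(once, obp, "anchor", desired_sign=-1)
        assert np.allclose(twice.behavior_scores, mode.behavior_scores)

    def test_missing_anchor_warns(self, rng):
        mode, bp = self._mode_and_bp(rng)
        with pytest.warns(UserWarning, match="anchor"):
            align_signs(mode, bp, "not_there")


class TestCompareModes:
    def _pair(self, rng):
        z = rng.standard_normal(60)
        X = np.column_stack([z, rng.standard_normal(60)])
        Y = np.column_stack([z + 0.3 * rng.standard_normal(60),
                             rng.standard_normal(60)])
        mode = fit_cca(X, Y)[0]
        ob = pd.DataFrame(rng.standard_normal((60, 5)))
        ot = pd.DataFrame(rng.standard_normal((60, 7)))
        bpb = backproject_weights(mode, ob, side="behavior", n_perm=50, seed=0)
        bpt = backproject_weights(mode, ot, side="brain", n_perm=50, seed=0)
        return mode, bpb, bpt

    def test_self_similarity_is_one(self, rng):
        mode, bpb, bpt = self._pair(rng)
        sim = compare_modes(mode, bpb, bpt, mode, bpb, bpt)
        assert np.allclose([sim.r_behavior_scores, sim.r_topography_scores,
                            sim.r_behavior_weights, sim.r_topography_weights], 1.0)

    def test_sign_flip_gives_minus_one(self, rng):
        from dataclasses import replace
        mode, bpb, bpt = self._pair(rng)
        neg = replace(mode, brain_scores=-mode.brain_scores,
                      behavior_scores=-mode.behavior_scores)
        nbpb = replace(bpb, full_weights=-bpb.full_weights)
        nbpt = replace(bpt, full_weights=-bpt.full_weights)
        sim = compare_modes(mode, bpb, bpt, neg, nbpb, nbpt)
        assert np.allclose([sim.r_behavior_scores, sim.r_topography_scores,
                            sim.r_behavior_weights, sim.r_topography_weights], -1.0)

    def test_mismatched_spaces_rejected(self, rng):
        mode, bpb, bpt = self._pair(rng)
        with pytest.raises(InvalidArgumentError):
            compare_modes(mode, bpb, bpt, mode, bpt, bpb)


class TestRegressOut:
    def test_map_regressor_equal_to_target_vanishes(self, rng):
        T = rng.standard_normal((5, 30))
        assert np.abs(regress_out_map(T, T)).max() < 1e-10

    def test_map_mixture_recovers_second_component(self, rng):
        reg = rng.standard_normal((8, 40))
        other = rng.standard_normal((8, 40))
        resid = regress_out_map(0.6 * reg + other, reg)
        for i in range(8):
            assert np.corrcoef(resid[i], other[i])[0, 1] > 0.95

    def test_series_self_regression_vanishes(self, rng):
        x = FrameSeries(rng.standard_normal(200), 0.72)
        resid, sl = regress_out_series(x, [x])
        assert np.abs(resid.values).max() < 1e-10
        assert sl == slice(0, 200)

    def test_white_noise_regressor_removes_little_variance(self, rng):
        drops = []
        for _ in range(20):
            y = rng.standard_normal(1200)
            r = rng.standard_normal(1200)
            resid, _ = regress_out_series(FrameSeries(y, 0.72),
                                          [FrameSeries(r, 0.72)])
            drops.append(1 - resid.values.var() / y.var())
        assert np.mean(drops) < 0.01

    def test_lagged_flipped_regressor_alignment(self, rng):
        n, lag = 300, 7
        base = rng.standard_normal(n + lag)
        target = FrameSeries(-base[:n], 0.72)          # contains -reg(t - lag)
        reg = FrameSeries(base[lag:], 0.72)
        resid, sl = regress_out_series(target, [reg], lags=[lag], flips=[True])
        assert sl == slice(lag, n)
        assert np.abs(resid.values).max() < 1e-10

    def test_collinear_regressors_rejected(self, rng):
        y = FrameSeries(rng.standard_normal(100), 0.72)
        r = rng.standard_normal(100)
        with pytest.raises(InvalidArgumentError, match="collinear"):
            regress_out_series(y, [r, 2 * r])
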