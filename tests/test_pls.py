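"""Unit and oracle tests for the mean-centered and behavioural PLS core."""

import itertools

import numpy as np
import pandas as pd
import pytest

from oscpls.pls import (
    behavioural_pls,
    bootstrap_saliences,
    crossblock_pct,
    mean_centered_pls,
    permutation_test,
)

from conftest import make_task_matrix

INV_SQRT2 = 1.0 / np.sqrt(2.0)


class TestMeanCenteredPLS:
    def test_hand_computable_symmetric_case(self):
        # cell means [[1,0],[0,1]] -> centered [[.5,-.5],[-.5,.5]]: one LV,
        # sigma 1, both saliences proportional to [1,-1]/sqrt(2)
        X = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        data = make_task_matrix(X, n_conditions=2)
        res = mean_centered_pls(data)
        assert res.singular_values[0] == pytest.approx(1.0, abs=1e-12)
        assert res.singular_values[1] == pytest.approx(0.0, abs=1e-12)
        assert res.brain_saliences[:, 0] == pytest.approx([INV_SQRT2, -INV_SQRT2])
        assert res.design_saliences[:, 0] == pytest.approx([INV_SQRT2, -INV_SQRT2])
        assert res.crossblock_pct[0] == pytest.approx(100.0)

    def test_identical_cell_means_degenerate(self, rng):
        row = rng.standard_normal(5)
        X = np.tile(row, (8, 1))
        data = make_task_matrix(X, n_groups=2, n_conditions=2)
        res = mean_centered_pls(data)
        assert res.degenerate
        assert np.all(res.singular_values < 1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_svd_reconstruction_and_eigensolver_oracle(self, seed):
        # independent oracle: eigendecomposition of Mc^T Mc gives the brain
        # saliences up to sign; U S V^T reconstructs the centered cell means
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((8, 6))
        data = make_task_matrix(X, n_groups=2, n_conditions=2)
        res = mean_centered_pls(data)

        M = np.vstack([X[idx].mean(axis=0) for idx in data.cell_index()])
        Mc = M - M.mean(axis=0)
        recon = res.design_saliences @ np.diag(res.singular_values) @ res.brain_saliences.T
        assert np.max(np.abs(recon - Mc)) < 1e-10

        evals, evecs = np.linalg.eigh(Mc.T @ Mc)
        order = np.argsort(evals)[::-1]
        for i in range(len(res.singular_values)):
            # compare sigma^2 with the eigenvalue: the sqrt of a zero
            # eigenvalue is dominated by floating-point noise
            assert res.singular_values[i] ** 2 == pytest.approx(
                max(evals[order[i]], 0.0), abs=1e-10
            )
            if res.singular_values[i] > 1e-8:
                v_oracle = evecs[:, order[i]]
                dot = abs(float(v_oracle @ res.brain_saliences[:, i]))
                assert dot == pytest.approx(1.0, abs=1e-10)

    def test_salience_orthonormality(self, rng):
        X = rng.standard_normal((12, 7))
        data = make_task_matrix(X, n_groups=2, n_conditions=3)
        res = mean_centered_pls(data)
        k = res.brain_saliences.shape[1]
        assert res.brain_saliences.T @ res.brain_saliences == pytest.approx(np.eye(k), abs=1e-10)
        assert res.design_saliences.T @ res.design_saliences == pytest.approx(np.eye(k), abs=1e-10)

    def test_brain_score_cell_means_match_design_pattern(self, rng):
        # mean brain score per cell equals U * S for the corresponding LV
        X = rng.standard_normal((12, 5))
        data = make_task_matrix(X, n_groups=2, n_conditions=2)
        res = mean_centered_pls(data)
        expected = res.design_saliences @ np.diag(res.singular_values)
        for i, idx in enumerate(data.cell_index()):
            assert res.brain_scores[idx].mean(axis=0) == pytest.approx(expected[i], abs=1e-10)

    def test_sign_convention_largest_brain_element_positive(self, rng):
        X = rng.standard_normal((8, 6))
        data = make_task_matrix(X, n_groups=2, n_conditions=2)
        res = mean_centered_pls(data)
        for i in range(res.n_lv):
            if res.singular_values[i] > 1e-10:
                j = np.argmax(np.abs(res.brain_saliences[:, i]))
                assert res.brain_saliences[j, i] > 0


class TestCrossblockPct:
    def test_single_value(self):
        assert crossblock_pct(np.array([5.0])) == pytest.approx([100.0])

    def test_three_four(self):
        assert crossblock_pct(np.array([3.0, 4.0])) == pytest.approx([36.0, 64.0])

    def test_equal_values(self):
        assert crossblock_pct(np.ones(3)) == pytest.approx([100 / 3] * 3)

    def test_sums_to_100(self, rng):
        s = np.sort(np.abs(rng.standard_normal(6)))[::-1]
        assert crossblock_pct(s).sum() == pytest.approx(100.0, abs=1e-9)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            crossblock_pct(np.zeros(3))


class TestPermutation:
    def test_monte_carlo_matches_exhaustive_enumeration(self):
        # 3 subjects x 2 conditions: all 720 row orderings enumerable.
        rng = np.random.default_rng(7)
        X = rng.standard_normal((6, 4))
        data = make_task_matrix(X, n_conditions=2)

        # independent exhaustive oracle over all 6! row orderings
        exceed = np.zeros(2)
        count = 720
        M0 = np.vstack([X[:3].mean(axis=0), X[3:].mean(axis=0)])
        s_obs = np.linalg.svd(M0 - M0.mean(axis=0), compute_uv=False)
        for perm in itertools.permutations(range(6)):
            Xp = X[list(perm)]
            M = np.vstack([Xp[:3].mean(axis=0), Xp[3:].mean(axis=0)])
            s = np.linalg.svd(M - M.mean(axis=0), compute_uv=False)
            exceed += s >= s_obs
        p_exact = exceed / count

        n_perm = 800
        p_mc = permutation_test(data, n_perm=n_perm, seed=11)
        # only LV1 is meaningful: a centered 2-cell matrix has rank 1, so the
        # second singular value is floating-point noise on both sides
        tol = 4.0 * np.sqrt(p_exact[0] * (1 - p_exact[0]) / n_perm) + 1.0 / n_perm
        assert abs(p_mc[0] - p_exact[0]) <= tol

    def test_noise_free_planted_effect_gives_p_zero(self):
        # a maximal observed sigma can only be matched by a permutation that
        # reproduces the original partition of rows into cells; at 10
        # subjects per condition such draws are measure-zero in practice
        rng = np.random.default_rng(0)
        X = rng.normal(0.0, 1e-6, size=(20, 4))
        X[10:, 0] += 10.0  # condition effect, essentially noise-free
        data = make_task_matrix(X, n_conditions=2)
        p = permutation_test(data, n_perm=200, seed=3)
        assert p[0] == 0.0

    def test_within_group_scheme_preserves_group_labels(self, rng):
        X = rng.standard_normal((12, 4))
        # group main effect, huge: within-group reassignment can never move it
        X[6:] += 50.0
        data = make_task_matrix(X, n_groups=2, n_conditions=2)
        p_within = permutation_test(data, n_perm=100, seed=5, scheme="within_group")
        p_cells = permutation_test(data, n_perm=100, seed=5, scheme="cells")
        # under within-group reassignment the group LV is always reproduced,
        # so its singular value is never smaller than observed
        assert p_within[0] > 0.9
        assert p_cells[0] == 0.0

    def test_smoothing_counting_rule(self, rng):
        X = rng.standard_normal((6, 3))
        data = make_task_matrix(X, n_conditions=2)
        p_plain = permutation_test(data, n_perm=50, seed=1, smoothing=False)
        p_smooth = permutation_test(data, n_perm=50, seed=1, smoothing=True)
        assert np.all(p_smooth == (p_plain * 50 + 1) / 51)


class TestBootstrap:
    def test_identical_subjects_zero_se_flagged(self):
        X = np.tile(np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]), (4, 1))
        # rows: 4 subjects x 2 conditions, every subject identical
        X = np.vstack([np.tile([1.0, 2.0, 3.0], (4, 1)), np.tile([4.0, 5.0, 6.0], (4, 1))])
        data = make_task_matrix(X, n_conditions=2)
        boot = bootstrap_saliences(data, n_boot=20, seed=0)
        assert np.all(boot.se < 1e-12)
        assert boot.degenerate

    def test_two_draw_ci_is_min_max(self, rng):
        X = rng.standard_normal((8, 4)) + np.repeat([[0.0], [2.0]], 4, axis=0) @ np.ones((1, 4))
        data = make_task_matrix(X, n_conditions=2)
        base = mean_centered_pls(data)
        boot = bootstrap_saliences(data, n_boot=2, seed=9, base=base)
        k = int(np.sum(base.singular_values > 1e-12))
        # with exactly two aligned draws the percentile rule returns min/max
        assert np.all(boot.ci_lo[:, :k] <= boot.ci_hi[:, :k])
        se_from_two = boot.se[:, :k]
        # SE of two draws is |a-b|/sqrt(2); CI width is |a-b|
        width = boot.ci_hi[:, :k] - boot.ci_lo[:, :k]
        assert width == pytest.approx(se_from_two * np.sqrt(2.0), abs=1e-12)

    def test_planted_effect_reliable_null_channels_mostly_not(self):
        # one channel carries a 5-SD condition effect; the rest are noise
        n_rel_planted = 0
        fp = 0
        n_null_total = 0
        reps = 30
        for rep in range(reps):
            rng = np.random.default_rng(100 + rep)
            X = rng.standard_normal((24, 10))
            X[12:, 0] += 5.0
            data = make_task_matrix(X, n_conditions=2)
            boot = bootstrap_saliences(data, n_boot=150, seed=rep)
            n_rel_planted += int(boot.reliable[0, 0])
            fp += int(boot.reliable[1:, 0].sum())
            n_null_total += 9
        assert n_rel_planted >= int(0.9 * reps)
        # false-positive rate over null channels near the nominal 5%
        assert fp / n_null_total < 0.15


class TestBehaviouralPLS:
    def test_single_group_single_measure_closed_form(self, rng):
        # R is 1 x p: sigma = ||r||_2 and the brain salience is r / ||r||
        n, p = 20, 5
        X = rng.standard_normal((n, p))
        b = rng.standard_normal((n, 1))
        res = behavioural_pls(X, ["g"] * n, b, measures=["m"], n_perm=0, n_boot=0)
        r = np.array(
            [np.corrcoef(b[:, 0], X[:, j])[0, 1] for j in range(p)]
        )
        assert res.singular_values[0] == pytest.approx(np.linalg.norm(r), abs=1e-10)
        v = res.brain_saliences[:, 0]
        sign = np.sign(v @ (r / np.linalg.norm(r)))
        assert v == pytest.approx(sign * r / np.linalg.norm(r), abs=1e-10)

    def test_measure_equal_to_one_brain_column_dominates(self, rng):
        n, p = 200, 6
        X = rng.standard_normal((n, p))
        b = X[:, [2]].copy()
        res = behavioural_pls(X, ["g"] * n, b, measures=["m"], n_perm=0, n_boot=0)
        v = np.abs(res.brain_saliences[:, 0])
        assert np.argmax(v) == 2
        # correlation entry for the matching column approaches 1
        r2 = np.corrcoef(b[:, 0], X[:, 2])[0, 1]
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert v[2] > 2 * np.max(np.delete(v, 2))

    def test_zero_variance_measure_rejected(self, rng):
        X = rng.standard_normal((10, 4))
        b = np.ones((10, 1))
        with pytest.raises(ValueError, match="zero-variance"):
            behavioural_pls(X, ["g"] * 10, b, measures=["m"], n_perm=0, n_boot=0)

    def test_planted_group_specific_coupling_recovered(self):
        # coupling between one measure and 4 of 12 brain columns in group A
        # only; salience signs should match and reliability be asymmetric
        rng = np.random.default_rng(42)
        n = 40  # per group; generous so the check is about correctness
        u_a = rng.standard_normal(n)
        X_a = rng.standard_normal((n, 12))
        X_a[:, :4] += 1.5 * u_a[:, None]
        b_a = u_a + 0.3 * rng.standard_normal(n)
        X_b = rng.standard_normal((n, 12))
        b_b = rng.standard_normal(n)
        X = np.vstack([X_a, X_b])
        b = np.concatenate([b_a, b_b])[:, None]
        groups = ["A"] * n + ["B"] * n
        res = behavioural_pls(
            X, groups, b, measures=["m"], groups=("A", "B"), n_perm=200, n_boot=300, seed=1
        )
        v = res.brain_saliences[:, 0]
        planted_sign = np.sign(res.behaviour_saliences[0, 0])
        assert np.mean(np.sign(v[:4]) == planted_sign) >= 0.9
        assert res.perm_p[0] <= 0.05
        rel = res.score_corr_reliable[:, 0, 0]
        assert rel[0] and not rel[1]
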