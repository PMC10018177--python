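import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from effdyn import dea


def ratio_ccr_oracle(x, y):
    """Closed form for 1 input / 1 output: θ_i = (y_i/x_i) / max_j (y_j/x_j)."""
    r = np.asarray(y, float) / np.asarray(x, float)
    return r / r.max()


class TestCCR:
    def test_single_dmu_is_self_efficient(self):
        res = dea.solve_ccr([[3.0]], [[2.0]])
        assert res.theta[0] == pytest.approx(1.0)
        assert res.lambdas[0, 0] == pytest.approx(1.0)

    def test_ratio_oracle_example(self):
        res = dea.solve_ccr([[2.0, 4.0, 8.0]], [[1.0, 1.0, 1.0]])
        np.testing.assert_allclose(res.theta, [1.0, 0.5, 0.25], atol=1e-7)

    def test_doubled_inputs_halve_theta(self):
        X = np.array([[2.0, 4.0], [3.0, 6.0]])
        Y = np.array([[5.0, 5.0]])
        res = dea.solve_ccr(X, Y)
        assert res.theta[1] == pytest.approx(res.theta[0] / 2, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_problems_match_ratio_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 11)
        x = rng.uniform(1, 10, n)
        y = rng.uniform(1, 10, n)
        res = dea.solve_ccr(x[None, :], y[None, :])
        np.testing.assert_allclose(res.theta, ratio_ccr_oracle(x, y), atol=1e-7)

    def test_units_invariance(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(1, 10, (3, 6))
        Y = rng.uniform(1, 10, (2, 6))
        base = dea.solve_ccr(X, Y).theta
        X2, Y2 = X.copy(), Y.copy()
        X2[1] *= 1000.0
        Y2[0] *= 0.001
        scaled = dea.solve_ccr(X2, Y2).theta
        np.testing.assert_allclose(scaled, base, atol=1e-7)

    def test_dominated_dmu_changes_no_other_score(self):
        rng = np.random.default_rng(11)
        X = rng.uniform(1, 10, (2, 5))
        Y = rng.uniform(1, 10, (2, 5))
        base = dea.solve_ccr(X, Y).theta
        X_aug = np.column_stack([X, X[:, 0] * 2])  # dominated copy of DMU 0
        Y_aug = np.column_stack([Y, Y[:, 0] * 0.5])
        aug = dea.solve_ccr(X_aug, Y_aug).theta
        np.testing.assert_allclose(aug[:5], base, atol=1e-7)


class TestBCC:
    def test_convex_hull_oracle(self):
        X = np.array([[2.0, 4.0, 8.0]])
        Y = np.array([[1.0, 2.0, 3.0]])
        np.testing.assert_allclose(dea.solve_bcc(X, Y).theta, [1, 1, 1], atol=1e-7)
        np.testing.assert_allclose(dea.solve_ccr(X, Y).theta, [1, 1, 0.75], atol=1e-7)

    @pytest.mark.parametrize("seed", range(5))
    def test_bcc_at_least_ccr(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.uniform(1, 10, (2, 7))
        Y = rng.uniform(1, 10, (2, 7))
        te = dea.solve_ccr(X, Y).theta
        pte = dea.solve_bcc(X, Y).theta
        assert (pte >= te - 1e-7).all()

    def test_min_input_dmu_is_bcc_efficient(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(2, 10, (2, 6))
        X[:, 0] = 1.0  # strictly smallest in every input
        Y = rng.uniform(1, 10, (1, 6))
        assert dea.solve_bcc(X, Y).theta[0] == pytest.approx(1.0, abs=1e-7)


class TestScaleEfficiencyAndRTS:
    def test_se_identity_and_division(self):
        np.testing.assert_allclose(
            dea.compute_scale_efficiency([1.0, 0.5], [1.0, 1.0]), [1.0, 0.5]
        )
        assert dea.compute_scale_efficiency([0.7], [0.7])[0] == pytest.approx(1.0)

    def test_se_matches_printed_table_row(self):
        se = dea.compute_scale_efficiency([0.923478], [0.941243])
        assert se[0] == pytest.approx(0.981125, abs=1e-5)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(Exception, match="length"):
            dea.compute_scale_efficiency([1.0, 0.5], [1.0])

    def test_rts_labels_from_lambda_sums(self):
        res = dea.solve_ccr([[2.0, 4.0, 8.0]], [[1.0, 2.0, 3.0]])
        assert res.rts == ["CRS", "CRS", "DRS"]

    def test_tiny_dmu_below_mps_is_irs(self):
        res = dea.solve_ccr([[2.0, 1.0]], [[1.0, 0.4]])
        assert res.rts == ["CRS", "IRS"]
        assert res.lambdas[1].sum() == pytest.approx(0.4, abs=1e-7)


class TestSBM:
    def test_efficient_dmu_scores_one(self):
        res = dea.solve_sbm([[1.0, 2.0]], [[1.0, 1.0]])
        assert res.rho[0] == pytest.approx(1.0, abs=1e-9)

    def test_slack_example(self):
        res = dea.solve_sbm([[1.0, 2.0]], [[1.0, 1.0]])
        assert res.rho[1] == pytest.approx(0.5, abs=1e-9)
        # the slack projection lands on the frontier ray y/x = 1 (slacks may
        # split between sides across alternate optima; the target is unique)
        x_proj = 2.0 - res.input_slacks[1, 0]
        y_proj = 1.0 + res.output_slacks[1, 0]
        assert y_proj / x_proj == pytest.approx(1.0, abs=1e-7)

    @pytest.mark.parametrize("seed", range(5))
    def test_sbm_below_ccr(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.uniform(1, 10, (2, 6))
        Y = rng.uniform(1, 10, (2, 6))
        rho = dea.solve_sbm(X, Y).rho
        theta = dea.solve_ccr(X, Y).theta
        assert (rho <= theta + 1e-7).all()

    def test_zero_input_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            dea.solve_sbm([[0.0, 2.0]], [[1.0, 1.0]])


def super_sbm_1d_brute(x, y, o, grid=200001):
    """1-input/1-output brute force: δ = min over λ of max(xλ/x0, 1) / min(yλ/y0, 1)."""
    xs = np.delete(x, o)
    ys = np.delete(y, o)
    lam = np.linspace(1e-6, 10, grid)[:, None]
    xbar = np.maximum((lam * xs).sum(axis=1), x[o])
    ybar = np.minimum((lam * ys).sum(axis=1), y[o])
    ok = ybar > 0
    return (xbar[ok] / x[o] / (ybar[ok] / y[o])).min()


class TestSuperSBM:
    def test_worked_example_against_brute_force(self):
        x = np.array([1.0, 2.0])
        y = np.array([1.0, 1.0])
        res = dea.solve_super_sbm(x[None, :], y[None, :])
        brute = super_sbm_1d_brute(x, y, 0)
        assert res.rho[0] == pytest.approx(2.0, abs=1e-6)
        assert res.rho[0] == pytest.approx(brute, abs=1e-4)

    def test_inefficient_dmu_keeps_sbm_score(self):
        res = dea.solve_super_sbm([[1.0, 2.0]], [[1.0, 1.0]])
        assert res.rho[1] == pytest.approx(0.5, abs=1e-9)

    def test_scores_above_one_only_for_efficient(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(1, 10, (2, 6))
        Y = rng.uniform(1, 10, (2, 6))
        sbm = dea.solve_sbm(X, Y)
        sup = dea.solve_super_sbm(X, Y)
        eff = sbm.rho >= 1 - 1e-6
        assert (sup.rho[eff] >= 1 - 1e-9).all()
        np.testing.assert_allclose(sup.rho[~eff], sbm.rho[~eff])

    def test_single_dmu_gets_inf_sentinel(self):
        res = dea.solve_super_sbm([[2.0]], [[1.0]])
        assert np.isinf(res.rho[0])


class TestRanking:
    def test_descending_with_stable_ties(self):
        np.testing.assert_array_equal(
            dea.rank_by_super_sbm([1.0, 1.0, 0.5]), [1, 2, 3]
        )

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.1, 10.0, allow_nan=False), min_size=2,
                    max_size=12),
           st.randoms(use_true_random=False))
    def test_score_to_rank_mapping_is_permutation_invariant(self, scores, rnd):
        """Shuffling the score vector permutes ranks consistently: each
        score keeps the same rank up to stable resolution of exact ties."""
        scores = np.asarray(scores)
        ranks = dea.rank_by_super_sbm(scores)
        assert sorted(ranks) == list(range(1, len(scores) + 1))
        idx = list(range(len(scores)))
        rnd.shuffle(idx)
        shuffled_ranks = dea.rank_by_super_sbm(scores[idx])
        if len(set(scores.tolist())) == len(scores):  # no ties: exact match
            np.testing.assert_array_equal(shuffled_ranks, ranks[idx])
        else:  # ties: the multiset of (score, rank) pairs is preserved
            assert sorted(zip(scores[idx], shuffled_ranks)) == \
                sorted(zip(scores, ranks))

    def test_rank_is_permutation(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(size=12)
        ranks = dea.rank_by_super_sbm(s)
        assert sorted(ranks) == list(range(1, 13))
        assert (np.argsort(ranks) == np.argsort(-s, kind="stable")).all()


class TestPerYear:
    def test_counts_on_tiny_panel(self, tiny_panel):
        counts = dea.count_efficient_per_year(tiny_panel)
        assert set(counts["year"]) == {2019, 2020}
        # every unit has distinct input mix; BCC count >= CCR count
        assert (counts["PTE"] >= counts["TE"]).all()

    def test_all_on_one_ray_all_efficient(self, tiny_schema):
        rows = []
        for i, unit in enumerate(["A", "B", "C"]):
            scale = i + 1.0
            for year in (2019, 2020):
                rows += [(unit, year, "staff", scale), (unit, year, "beds", scale),
                         (unit, year, "residents", 2 * scale)]
        from effdyn.panel import PanelDataset
        panel = PanelDataset(
            pd.DataFrame(rows, columns=["unit", "year", "variable", "value"]),
            tiny_schema,
        )
        counts = dea.count_efficient_per_year(panel)
        assert (counts["TE"] == 3).all()

    def test_solve_year_table_shape(self, tiny_panel):
        tab = dea.solve_year(tiny_panel, 2019)
        assert list(tab.columns) == ["unit", "year", "TE", "PTE", "SE", "RTS",
                                     "SBM", "rank"]
        np.testing.assert_allclose(tab["SE"], tab["TE"] / tab["PTE"], atol=1e-9)
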