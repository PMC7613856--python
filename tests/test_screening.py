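import numpy as np
import pytest
import statsmodels.api as sm

from ridgescreen import (
    ConfigurationError,
    CorrelationStructure,
    EffectSpec,
    SimulationConfig,
    generate_trial,
    ridge_screen,
    univariate_screen,
)
from ridgescreen.screening import _ridge_path, default_lambda_grid

from conftest import make_trial


class TestUnivariateScreen:
    def test_exact_linear_relation_floors_p(self):
        rng = np.random.default_rng(0)
        x1 = rng.standard_normal(50)
        x2 = rng.standard_normal(50)
        data = make_trial(2.0 * x1, (np.arange(50) % 2), np.column_stack([x1, x2]))
        res = univariate_screen(data)
        assert res.scores[0] < 1e-30
        assert res.ranking[0] == 1

    def test_matches_statsmodels_oracle(self, small_trial):
        res = univariate_screen(small_trial)
        for j in (0, 3, 11):
            fit = sm.OLS(
                small_trial.outcome, sm.add_constant(small_trial.biomarkers[:, j])
            ).fit()
            assert res.scores[j] == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_matches_normal_equations_slope(self, small_trial):
        # [DERIVED] independent two-column least-squares solve
        y = small_trial.outcome
        for j in (0, 5):
            a = np.column_stack([np.ones(small_trial.n), small_trial.biomarkers[:, j]])
            slope = np.linalg.solve(a.T @ a, a.T @ y)[1]
            fit = sm.OLS(y, a).fit()
            assert fit.params[1] == pytest.approx(slope, abs=1e-10)

    def test_null_calibration(self):
        # [DERIVED] size of the t-test under its null, 2000 tests total
        rng = np.random.default_rng(11)
        rejections, total = 0, 0
        for _ in range(5):
            y = rng.standard_normal(40)
            x = rng.standard_normal((40, 400))
            data = make_trial(y, (np.arange(40) % 2), x)
            res = univariate_screen(data)
            rejections += (res.scores < 0.05).sum()
            total += 400
        rate = rejections / total
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / total)

    def test_constant_column_warns_and_ranks_last(self):
        rng = np.random.default_rng(1)
        x = np.column_stack([rng.standard_normal(30), np.full(30, 2.0)])
        data = make_trial(rng.standard_normal(30), np.arange(30) % 2, x)
        with pytest.warns(UserWarning, match="constant"):
            res = univariate_screen(data)
        assert res.scores[1] == 1.0
        assert res.ranking[-1] == 2

    def test_needs_three_observations(self):
        data = make_trial([1.0, 2.0], [0, 1], [[0.1], [0.2]])
        with pytest.raises(ConfigurationError):
            univariate_screen(data)


def _centered_design(data):
    yc = data.outcome - data.outcome.mean()
    tc = data.treatment - data.treatment.mean()
    xs = (data.biomarkers - data.biomarkers.mean(axis=0)) / data.biomarkers.std(axis=0)
    return np.column_stack([tc, xs]), yc


class TestRidgeScreen:
    def test_lambda_zero_equals_ols(self, small_trial):
        res = ridge_screen(small_trial, lambda_grid=np.array([0.0]))
        d, yc = _centered_design(small_trial)
        ols = np.linalg.lstsq(d, yc, rcond=None)[0]
        np.testing.assert_allclose(res.scores, ols[1:], atol=1e-8)

    def test_fixed_lambda_matches_direct_solve(self, small_trial):
        # closed-form (D'D + lam I)^{-1} D'y under the sum-of-squares loss
        lam = 37.5
        res = ridge_screen(small_trial, lambda_grid=np.array([lam]))
        d, yc = _centered_design(small_trial)
        direct = np.linalg.solve(d.T @ d + lam * np.eye(d.shape[1]), d.T @ yc)
        np.testing.assert_allclose(res.scores, direct[1:], atol=1e-8)
        assert res.lambda_ == lam

    def test_orthonormal_design_shrinkage(self):
        # [DERIVED] with biomarker columns orthogonal (X'X = nI) and
        # orthogonal to the centered treatment, each ridge coefficient is
        # the OLS coefficient shrunk by n/(n + lambda)
        rng = np.random.default_rng(8)
        n, m = 64, 6
        t = np.repeat([0.0, 1.0], n // 2)
        tc = t - 0.5
        basis = np.column_stack([np.ones(n), tc, rng.standard_normal((n, m))])
        q, _ = np.linalg.qr(basis)
        x = q[:, 2:] * np.sqrt(n)  # mean 0, sd 1, mutually orthogonal
        y = rng.standard_normal(n)
        data = make_trial(y, t, x)
        lam = 12.0
        res = ridge_screen(data, lambda_grid=np.array([lam]))
        d, yc = _centered_design(data)
        ols = np.linalg.lstsq(d, yc, rcond=None)[0]
        np.testing.assert_allclose(res.scores, ols[1:] * n / (n + lam), atol=1e-8)

    def test_cv_selects_sensible_lambda_and_is_deterministic(self, small_trial):
        a = ridge_screen(small_trial, cv_seed=3)
        b = ridge_screen(small_trial, cv_seed=3)
        assert a.lambda_ == b.lambda_
        np.testing.assert_array_equal(a.ranking, b.ranking)
        grid = default_lambda_grid(*_centered_design(small_trial))
        assert grid.min() <= a.lambda_ <= grid.max()

    def test_column_order_invariance(self, small_trial):
        res = ridge_screen(small_trial, cv_seed=5)
        perm = np.random.default_rng(2).permutation(small_trial.m)
        permuted = small_trial.subset_biomarkers(perm)
        res_p = ridge_screen(permuted, cv_seed=5)
        np.testing.assert_allclose(res_p.scores, res.scores[perm], atol=1e-10)
        # ranking maps through the permutation
        inv = np.empty_like(perm)
        inv[perm] = np.arange(small_trial.m)
        np.testing.assert_array_equal(res_p.rank_of(), res.rank_of()[perm])

    def test_solution_norm_monotone_in_lambda(self, small_trial):
        d, yc = _centered_design(small_trial)
        lambdas = np.geomspace(1e-2, 1e4, 25)[::-1]
        coefs = _ridge_path(d.T @ d, d.T @ yc, lambdas)
        norms = np.linalg.norm(coefs, axis=0)  # ascending lambda order is reversed
        assert np.all(np.diff(norms) >= -1e-10)

    def test_treatment_not_in_ranking(self, small_trial):
        res = ridge_screen(small_trial, cv_seed=0)
        assert res.scores.shape == (small_trial.m,)
        assert sorted(res.ranking) == list(range(1, small_trial.m + 1))

    def test_to_frame_serialization(self, small_trial, tmp_path):
        res = ridge_screen(small_trial, cv_seed=1)
        frame = res.to_frame()
        assert list(frame.columns) == ["biomarker", "score", "rank", "method", "lambda"]
        path = tmp_path / "screening.tsv"
        frame.to_csv(path, sep="\t", index=False)
        assert path.read_text().startswith("biomarker\tscore")
        uni = univariate_screen(small_trial).to_frame()
        assert uni["method"].eq("univariate").all()
        assert sorted(uni["rank"]) == list(range(1, small_trial.m + 1))

    def test_empty_lambda_grid_raises(self, small_trial):
        with pytest.raises(ConfigurationError):
            ridge_screen(small_trial, lambda_grid=np.array([]))

    def test_degenerate_folds_raise(self):
        data = make_trial([1.0, 2.0, 3.0], [0, 1, 0], [[0.1], [0.2], [0.3]])
        with pytest.raises(ConfigurationError):
            ridge_screen(data, n_folds=3)

    def test_downranks_correlated_proxies(self):
        # [DERIVED] cluster mates of the interacting biomarker carry no
        # direct effect; ridge (which adjusts for X1) should rank them
        # worse than the univariate screen does, on average.
        eff = EffectSpec(
            treatment_effect=0.5,
            main={1: 1.5, 21: 1.5, 41: 1.5, 61: 1.5, 81: 1.5},
            interaction={1: 1.0},
            noise_sd=5.0,
        )
        st = CorrelationStructure(m=100, cluster_size=20, rho=0.6)
        diffs = []
        for rep in range(6):
            data = generate_trial(
                SimulationConfig(n=600, effects=eff, structure=st, seed=300 + rep)
            )
            uni = univariate_screen(data).rank_of()[1:20]
            rid = ridge_screen(data, cv_seed=rep).rank_of()[1:20]
            diffs.append((rid - uni).mean())
        assert np.mean(diffs) > 0
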