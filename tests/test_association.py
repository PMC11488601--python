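"""Ridge fits, penalty selection, cross-validated RSS and the ratio map."""

import numpy as np
import pytest

from gutbrainmap import (
    FoldAssignment,
    assemble_design,
    cv_rss,
    fit_ridge,
    rss_ratio_map,
    select_lambda,
)
from gutbrainmap.association import DEFAULT_LAMBDA_GRID, CVPlan, FoldError, RatioEngine
from gutbrainmap.preprocess import DesignMatrix, StandardizationRecord
from gutbrainmap.synthetic import SyntheticScenario, generate_abundances, generate_covariates

from _oracles import naive_cv_rss, naive_ridge


def _design(n=40, p=8, seed=0):
    sc = SyntheticScenario(n_subjects=n, n_families=p, seed=seed)
    return assemble_design(generate_abundances(sc), generate_covariates(sc))


class TestFolds:
    def test_balanced_deterministic_labels(self):
        f = FoldAssignment.create(43, K=10, seed=3)
        g = FoldAssignment.create(43, K=10, seed=3)
        assert np.array_equal(f.labels, g.labels)
        sizes = np.bincount(f.labels)[1:]
        assert sizes.max() - sizes.min() <= 1
        assert set(f.labels) == set(range(1, 11))

    def test_too_many_folds_rejected(self):
        with pytest.raises(FoldError):
            FoldAssignment.create(5, K=10, seed=0)


class TestFitRidge:
    def test_zero_penalty_matches_ols(self, rng):
        X = rng.normal(size=(30, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0]) + rng.normal(size=30)
        sol = fit_ridge(X, y, 0.0)
        Xd = np.column_stack([np.ones(30), X])
        beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        assert np.allclose(sol.coef, beta[1:], atol=1e-8)
        assert sol.intercept == pytest.approx(beta[0], abs=1e-8)

    def test_sklearn_cross_check(self, rng):
        sklearn = pytest.importorskip("sklearn.linear_model")
        X = rng.normal(size=(50, 5))
        y = rng.normal(size=50)
        lam = 2.5
        sol = fit_ridge(X - X.mean(0), y, lam)
        sk = sklearn.Ridge(alpha=lam, fit_intercept=True).fit(X - X.mean(0), y)
        assert np.allclose(sol.coef, sk.coef_, atol=1e-8)

    def test_infinite_penalty_shrinks_to_mean(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        sol = fit_ridge(X, y, 1e12)
        assert np.all(np.abs(sol.coef) < 1e-9)
        assert sol.intercept == pytest.approx(y.mean(), abs=1e-6)

    def test_one_dimensional_normal_equation_oracle(self):
        x = np.array([1.0, 2.0, 3.0])
        x = (x - x.mean()) / x.std(ddof=0)
        y = np.array([1.0, 2.0, 3.0])
        sol = fit_ridge(x[:, None], y, 1.0)
        # centered normal equation: (x'x + 1) beta = x'y
        expected = (x @ (y - y.mean())) / (x @ x + 1.0)
        assert sol.coef[0] == pytest.approx(expected, abs=1e-12)
        i0, c0 = naive_ridge(x[:, None], y, 1.0)
        assert sol.coef[0] == pytest.approx(c0[0], abs=1e-12)
        assert sol.intercept == pytest.approx(i0, abs=1e-12)

    def test_collinear_at_zero_penalty_warns_minimum_norm(self, rng):
        x = rng.normal(size=20)
        X = np.column_stack([x, x])
        with pytest.warns(UserWarning, match="rank-deficient"):
            sol = fit_ridge(X, 2 * x, 0.0)
        assert np.allclose(sol.coef, [1.0, 1.0], atol=1e-8)  # minimum-norm split

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            fit_ridge(np.ones((3, 1)), np.ones(3), -1.0)


class TestSelectLambda:
    def test_noiseless_signal_prefers_smallest(self, rng):
        X = rng.normal(size=(40, 3))
        y = 2.0 * X[:, 0]
        folds = FoldAssignment.create(40, K=10, seed=1)
        lam = select_lambda(X, y, folds)
        assert lam == pytest.approx(DEFAULT_LAMBDA_GRID.min())

    def test_single_element_grid(self, rng):
        X = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        folds = FoldAssignment.create(30, K=5, seed=2)
        assert select_lambda(X, y, folds, grid=np.array([7.5])) == 7.5

    def test_pure_noise_prefers_upper_half(self):
        grid = DEFAULT_LAMBDA_GRID
        upper = np.median(grid)
        hits = 0
        for i in range(100):
            r = np.random.default_rng(5000 + i)
            X = r.normal(size=(60, 5))
            y = r.normal(size=60)
            folds = FoldAssignment.create(60, K=10, seed=i)
            if select_lambda(X, y, folds, grid=grid) >= upper:
                hits += 1
        assert hits >= 80

    def test_constant_outcome_returns_largest(self, rng):
        X = rng.normal(size=(30, 3))
        folds = FoldAssignment.create(30, K=5, seed=3)
        assert select_lambda(X, np.full(30, 4.2), folds) == pytest.approx(
            DEFAULT_LAMBDA_GRID.max()
        )


class TestCvRss:
    def test_constant_outcome_gives_zero(self, rng):
        X = rng.normal(size=(30, 4))
        folds = FoldAssignment.create(30, K=10, seed=4)
        # exactly constant outcome: the training mean predicts it perfectly
        # (up to the floating-point residue of the fold means)
        assert cv_rss(X, np.full(30, 3.3), folds) == pytest.approx(0.0, abs=1e-18)

    def test_noiseless_signal_near_zero(self, rng):
        X = rng.normal(size=(40, 1))
        y = 2.0 * X[:, 0]
        folds = FoldAssignment.create(40, K=10, seed=5)
        assert cv_rss(X, y, folds) < 1e-6

    def test_matches_naive_reimplementation(self, rng):
        X = rng.normal(size=(20, 3))
        y = X[:, 0] + rng.normal(size=20)
        folds = FoldAssignment.create(20, K=10, seed=6)
        ours = cv_rss(X, y, folds)
        ref = naive_cv_rss(X, y, folds.labels, DEFAULT_LAMBDA_GRID)
        assert ours == pytest.approx(ref, rel=1e-8)

    def test_vectorized_engine_equals_per_voxel_loop(self, rng):
        X = rng.normal(size=(30, 5))
        Y = rng.normal(size=(30, 7))
        folds = FoldAssignment.create(30, K=10, seed=7)
        plan = CVPlan(X, folds)
        batch = plan.rss(Y)
        single = np.array([plan.rss(Y[:, j]) for j in range(7)])
        # chunked and per-voxel paths agree to BLAS rounding
        assert np.allclose(batch, single, rtol=1e-12, atol=0)

    def test_undersized_training_fold_rejected(self, rng):
        X = rng.normal(size=(4, 2))
        bad = FoldAssignment(K=2, labels=np.array([1, 1, 1, 1]), seed=0)
        with pytest.raises(FoldError):
            CVPlan(X, bad)


class TestRatio:
    def test_zero_family_design_gives_ratio_one(self, rng):
        cov = rng.normal(size=(30, 3))
        design = DesignMatrix(
            [f"s{i}" for i in range(30)],
            [],
            (cov - cov.mean(0)) / cov.std(0),
            StandardizationRecord(["sex", "age", "bmi"], cov.mean(0), cov.std(0)),
        )
        folds = FoldAssignment.create(30, K=10, seed=8)
        engine = RatioEngine(design, folds)
        ratio, rc, rf = engine.rss_ratio(rng.normal(size=(30, 5)))
        assert np.array_equal(rc, rf)
        assert np.all(ratio == 1.0)

    def test_invariant_to_affine_rescaling_of_outcome(self):
        design = _design(n=40, p=6, seed=9)
        folds = FoldAssignment.create(40, K=10, seed=9)
        engine = RatioEngine(design, folds)
        r = np.random.default_rng(10)
        y = r.normal(size=(40, 4))
        a, *_ = engine.rss_ratio(y)
        b, *_ = engine.rss_ratio(3.5 * y - 11.0)
        assert np.allclose(a, b, rtol=1e-10)

    def test_null_ratios_hover_near_or_below_one(self):
        design = _design(n=60, p=30, seed=11)
        folds = FoldAssignment.create(60, K=10, seed=11)
        engine = RatioEngine(design, folds)
        y = np.random.default_rng(12).normal(size=(60, 500))
        ratio, *_ = engine.rss_ratio(y)
        med = np.median(ratio)
        assert 0.9 <= med <= 1.05

    def test_map_fills_mask_and_matches_components(self, small_null_cohort):
        from gutbrainmap import MicrobiomeBrainModel

        m = MicrobiomeBrainModel.from_cohort(small_null_cohort)
        folds = FoldAssignment.create(len(m.design.subjects), K=10, seed=1)
        smap = rss_ratio_map(m.design, m.images, m.mask, folds)
        inm = m.mask.mask
        assert np.all(np.isnan(smap.ratio[~inm]))
        assert np.allclose(
            smap.ratio[inm], smap.rss_covariates[inm] / smap.rss_full[inm], rtol=1e-12
        )
        assert np.all(smap.ratio[inm] > 0)
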