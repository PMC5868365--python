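"""Metadata generation, NNLS stacking, case filtering, and the full ensemble."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dvhstack.dvh import DVHPrincipalComponents, WeightScheme, wrmse_matrix
from dvhstack.ensemble import (
    DVHStackingEnsemble,
    MetadataTable,
    build_metadata,
    case_wrmse_profile,
    compare_models,
    filter_cases,
    optimize_stack_weights,
    predict_dvh,
    train_ensemble,
)
from dvhstack.io import save_model
from dvhstack.learners import BaseLearnerSpec, default_learner_bank
from dvhstack.synthetic import CohortConfig, generate_cohort


def _stack_objective(Z, y, alpha):
    r = y - Z @ alpha
    return r @ r


class TestBuildMetadata:
    def test_loo_mean_with_intercept_only_learner(self):
        """Stepwise on pure noise with a tiny entry threshold predicts the
        training-fold mean, so each z is the mean of the other cases."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(3, 2))
        y = np.array([1.0, 4.0, 10.0])
        spec = BaseLearnerSpec("stepwise", p_enter=1e-12)
        table = build_metadata(X, y, [spec], seed=0)
        expect = np.array([(4 + 10) / 2, (1 + 10) / 2, (1 + 4) / 2])
        np.testing.assert_allclose(table.z[:, 0], expect, atol=1e-10)

    def test_interpolation_limit_near_zero_ridge(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0])  # noiseless
        spec = BaseLearnerSpec("ridge", lambda2=1e-10)
        table = build_metadata(X, y, [spec], seed=0)
        assert np.max(np.abs(table.z[:, 0] - y)) < 1e-6

    def test_matches_naive_double_loop(self):
        """The LOO table equals an independent double-loop recomputation with
        per-fold standardization and closed-form ridge/OLS models."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 3))
        y = X @ np.array([1.0, 0.5, -1.0]) + rng.normal(0, 0.2, 10)
        specs = [BaseLearnerSpec("ridge", lambda2=2.0),
                 BaseLearnerSpec("ridge", lambda2=1e-8),
                 BaseLearnerSpec("stepwise", p_enter=1e-12)]
        table = build_metadata(X, y, specs, seed=0)
        z = np.empty((10, 3))
        for n in range(10):
            tr = [i for i in range(10) if i != n]
            Xtr, ytr = X[tr], y[tr]
            mu, sd = Xtr.mean(0), Xtr.std(0, ddof=1)
            A = (Xtr - mu) / sd
            a_new = (X[n] - mu) / sd
            for k, lam in enumerate([2.0, 1e-8]):
                beta = np.linalg.solve(A.T @ A + lam * np.eye(3),
                                       A.T @ (ytr - ytr.mean()))
                z[n, k] = ytr.mean() + a_new @ beta
            z[n, 2] = ytr.mean()  # intercept-only stepwise
        np.testing.assert_allclose(table.z, z, atol=1e-8)

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            build_metadata(np.zeros((2, 2)), np.zeros(2),
                           [BaseLearnerSpec("ridge", lambda2=1.0)])


class TestStackWeights:
    def test_perfect_predictor_gets_all_weight(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=30)
        Z = np.column_stack([y, rng.normal(size=30), rng.normal(size=30)])
        alpha = optimize_stack_weights(Z, y)
        np.testing.assert_allclose(alpha, [1.0, 0.0, 0.0], atol=1e-10)
        assert _stack_objective(Z, y, alpha) == pytest.approx(0.0, abs=1e-18)

    def test_matches_grid_search_k2(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=25)
        Z = np.column_stack([0.7 * y + rng.normal(0, 0.3, 25),
                             0.4 * y + rng.normal(0, 0.5, 25)])
        alpha = optimize_stack_weights(Z, y)
        grid = np.linspace(0, 3, 200)
        objs = np.array([[_stack_objective(Z, y, np.array([a, b])) for b in grid]
                         for a in grid])
        i, j = np.unravel_index(np.argmin(objs), objs.shape)
        step = grid[1] - grid[0]
        assert abs(alpha[0] - grid[i]) <= step
        assert abs(alpha[1] - grid[j]) <= step

    def test_interior_solution_equals_unconstrained(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=40)
        Z = np.column_stack([y + rng.normal(0, 0.4, 40),
                             -y + rng.normal(0, 0.4, 40)])
        # second column anti-correlated -> constrained; build a clearly
        # positive case instead
        Z = np.column_stack([0.8 * y + rng.normal(0, 0.2, 40),
                             0.5 * y + rng.normal(0, 0.2, 40)])
        ls, *_ = np.linalg.lstsq(Z, y, rcond=None)
        if np.all(ls >= 0):
            np.testing.assert_allclose(optimize_stack_weights(Z, y), ls, atol=1e-10)

    def test_all_zero_metadata_warns(self):
        with pytest.warns(UserWarning, match="all-zero"):
            alpha = optimize_stack_weights(np.zeros((5, 3)), np.ones(5))
        np.testing.assert_array_equal(alpha, 0.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_stacking_optimality_vs_unit_vectors(self, seed):
        """NNLS optimality: the stacked objective never exceeds the
        objective of any single learner on the same metadata."""
        rng = np.random.default_rng(seed)
        n, k = 20, 5
        y = rng.normal(size=n)
        Z = np.column_stack([y * rng.uniform(0, 1.2) + rng.normal(0, 0.5, n)
                             for _ in range(k)])
        alpha = optimize_stack_weights(Z, y)
        assert np.all(alpha >= 0)
        obj = _stack_objective(Z, y, alpha)
        for j in range(k):
            e = np.zeros(k)
            e[j] = 1.0
            assert obj <= _stack_objective(Z, y, e) + 1e-9


class TestProfileAndFilter:
    def test_profile_matches_naive_loop(self, fitted_basis, rank3_curves, grid):
        rng = np.random.default_rng(6)
        truth = fitted_basis.transform(rank3_curves)
        n, k = truth.shape[0], 4
        tables = []
        for c in range(3):
            z = truth[:, [c]] + rng.normal(0, 0.05, size=(n, k))
            tables.append(MetadataTable(z, truth[:, c], tuple(f"m{i}" for i in range(k))))
        scheme = WeightScheme("linear_relative")
        prof = case_wrmse_profile(tables, fitted_basis, rank3_curves, scheme, grid)
        naive = np.empty(n)
        for i in range(n):
            errs = []
            for j in range(k):
                s = np.array([tables[c].z[i, j] for c in range(3)])
                pred = fitted_basis.inverse_transform(s[None, :])[0]
                errs.append(wrmse_matrix(rank3_curves[i][None, :], pred[None, :],
                                         grid, scheme, 70.0)[0])
            naive[i] = np.median(errs)
        np.testing.assert_allclose(prof, naive, atol=1e-12)

    def test_exact_predictions_give_zero_profile(self, fitted_basis, rank3_curves, grid):
        truth = fitted_basis.transform(rank3_curves)
        tables = [MetadataTable(np.repeat(truth[:, [c]], 3, axis=1), truth[:, c],
                                ("a", "b", "c")) for c in range(3)]
        prof = case_wrmse_profile(tables, fitted_basis, rank3_curves,
                                  WeightScheme("constant"), grid)
        assert np.max(prof) < 1e-10

    def test_median_over_learners(self):
        # directly exercise the median over per-learner errors
        assert np.median([0.1, 0.4, 0.2]) == pytest.approx(0.2)

    def test_filter_counts(self):
        prof = np.arange(50, dtype=float)
        retained, report = filter_cases(prof, 10.0)
        assert len(report) == 5 and retained.size == 45
        assert set(report["case_id"]) == {45, 46, 47, 48, 49}
        retained0, report0 = filter_cases(prof, 0.0)
        assert retained0.size == 50 and len(report0) == 0

    def test_constructed_separation_removed_exactly(self):
        rng = np.random.default_rng(7)
        prof = rng.uniform(0.01, 0.02, 100)
        bad = rng.choice(100, 10, replace=False)
        prof[bad] = prof[bad] * 10
        retained, report = filter_cases(prof, 10.0)
        assert set(report["case_id"]) == set(bad.tolist())

    def test_tie_broken_toward_lower_index(self):
        prof = np.array([1.0, 2.0, 2.0, 0.5])
        _, report = filter_cases(prof, 25.0)  # removes exactly 1
        assert list(report["case_id"]) == [1]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_filter_monotone_in_s(self, seed):
        prof = np.random.default_rng(seed).uniform(size=30)
        removed_prev: set = set()
        for s in (0, 10, 20, 40, 60):
            _, report = filter_cases(prof, s)
            removed = set(report["case_id"])
            assert removed_prev <= removed
            removed_prev = removed


@pytest.fixture(scope="module")
def tiny_noiseless():
    train = generate_cohort(CohortConfig(n_cases=40, seed=20, noise_sd=0.0))
    val = generate_cohort(CohortConfig(n_cases=25, seed=21, noise_sd=0.0))
    return train, val


class TestTrainedEnsemble:
    def test_noiseless_cohort_recovered(self, tiny_noiseless):
        train, val = tiny_noiseless
        est = DVHStackingEnsemble(s_percent=0, penalty_mode="shared",
                                  random_state=0)
        est.fit(train.features, train.curves, dose_grid=train.dose_grid)
        pred = est.predict(val.features[val.in_gamut])
        errs = wrmse_matrix(val.curves[val.in_gamut], pred, val.dose_grid,
                            WeightScheme("linear_relative"), val.prescription_dose)
        assert errs.max() < 1e-3

    def test_deterministic_serialization(self, tmp_path, tiny_noiseless):
        train, _ = tiny_noiseless
        paths = []
        for i in (1, 2):
            est = train_ensemble(train.features, train.curves,
                                 dose_grid=train.dose_grid, seed=5,
                                 penalty_mode="shared", s_percent=10.0)
            p = tmp_path / f"model{i}.json"
            save_model(p, est)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_single_learner_reduces_to_scaled_learner(self, tiny_noiseless):
        train, val = tiny_noiseless
        spec = BaseLearnerSpec("ridge", lambda2=5.0)
        est = DVHStackingEnsemble(learner_specs=[spec], s_percent=0,
                                  penalty_mode="shared", random_state=0)
        est.fit(train.features, train.curves, dose_grid=train.dose_grid)
        Xz = est.scaler_.transform(val.features)
        for c in range(3):
            alone = est.learners_[c][0].predict(Xz)
            np.testing.assert_allclose(est.predict_scores(val.features)[:, c],
                                       est.alpha_[c, 0] * alone, atol=1e-10)
            assert est.alpha_[c, 0] >= 0

    def test_over_filtering_rejected(self, tiny_noiseless):
        train, _ = tiny_noiseless
        est = DVHStackingEnsemble(s_percent=80.0, penalty_mode="shared")
        with pytest.raises(ValueError, match="retained"):
            est.fit(train.features, train.curves, dose_grid=train.dose_grid)

    def test_feature_dimension_checked(self, tiny_noiseless):
        train, val = tiny_noiseless
        est = DVHStackingEnsemble(s_percent=0, penalty_mode="shared")
        est.fit(train.features, train.curves, dose_grid=train.dose_grid)
        with pytest.raises(ValueError, match="features"):
            est.predict(val.features[:, :4])


class TestPredictDVH:
    def _manual_ensemble(self, fitted_basis, grid):
        """A hand-assembled two-learner ensemble with known coefficients."""
        from dvhstack.learners import FeatureStandardizer, PenalizedLinearModel
        est = DVHStackingEnsemble(n_components=3)
        est.basis_ = fitted_basis
        sc = FeatureStandardizer()
        sc.mean_ = np.zeros(2)
        sc.scale_ = np.ones(2)
        sc.constant_mask_ = np.zeros(2, bool)
        sc.n_features_in_ = 2
        est.scaler_ = sc
        banks, coefs = [], []
        for c in range(3):
            bank = []
            for k in range(2):
                m = PenalizedLinearModel(kind="ridge")
                m.coef_ = np.array([0.1 * (c + 1), -0.05 * (k + 1)])
                m.intercept_ = 0.02 * (c - k)
                m.n_features_in_ = 2
                bank.append(m)
            banks.append(bank)
        est.learners_ = banks
        est.alpha_ = np.array([[0.6, 0.5], [1.0, 0.0], [0.0, 0.0]])
        est.learner_names_ = ("a", "b")
        est.n_features_in_ = 2
        est.dose_grid_ = grid
        est.prescription_dose_ = 70.0
        return est

    def test_hand_computed_combination(self, fitted_basis, grid):
        est = self._manual_ensemble(fitted_basis, grid)
        x = np.array([0.3, -0.7])
        curve, scores = predict_dvh(est, x)
        expect = []
        for c in range(3):
            s = 0.0
            for k in range(2):
                m = est.learners_[c][k]
                s += est.alpha_[c, k] * (m.intercept_ + x @ m.coef_)
            expect.append(s)
        np.testing.assert_allclose(scores, expect, atol=1e-12)
        # component 3 has zero weight: prediction is pure components 1-2
        assert expect[2] == pytest.approx(0.0)

    def test_zero_alpha_decodes_mean(self, fitted_basis, grid):
        est = self._manual_ensemble(fitted_basis, grid)
        est.alpha_ = np.zeros((3, 2))
        curve, scores = predict_dvh(est, np.array([1.0, 1.0]))
        np.testing.assert_allclose(scores, 0.0, atol=1e-12)
        np.testing.assert_allclose(
            curve.volume_fraction,
            fitted_basis.inverse_transform(np.zeros((1, 3)))[0], atol=1e-12)


class TestCompareModels:
    def test_identical_models_p_one(self, rank3_curves, grid):
        preds = {"ensemble": rank3_curves.copy(), "other": rank3_curves.copy()}
        with pytest.warns(UserWarning, match="identical"):
            _, summary, tests = compare_models(preds, rank3_curves, grid,
                                               WeightScheme("constant"))
        assert tests["wilcoxon_p"].iloc[0] == 1.0
        assert tests["mean_diff"].iloc[0] == 0.0

    def test_doubled_residuals_always_worse(self, fitted_basis, rank3_curves, grid):
        rng = np.random.default_rng(8)
        resid = rng.normal(0, 0.01, rank3_curves.shape)
        good = np.clip(rank3_curves + resid, 0, 1)
        bad = np.clip(rank3_curves + 2 * resid, 0, 1)
        from dvhstack.dvh import postprocess_curves
        good, bad = postprocess_curves(good), postprocess_curves(bad)
        per_case, summary, _ = compare_models(
            {"ensemble": good, "bad": bad}, rank3_curves, grid,
            WeightScheme("constant"))
        assert np.all(per_case["bad"] >= per_case["ensemble"])
        assert summary.loc["bad", "mean_wrmse"] > summary.loc["ensemble", "mean_wrmse"]

    def test_wilcoxon_matches_direct_computation(self, fitted_basis, grid):
        """Six-case paired comparison agrees with scipy computed directly on
        the per-case wRMSE differences."""
        rng = np.random.default_rng(9)
        truth = fitted_basis.inverse_transform(
            rng.normal(0, [0.2, 0.1, 0.05], size=(6, 3)))
        a = fitted_basis.inverse_transform(
            fitted_basis.transform(truth) + rng.normal(0, 0.02, (6, 3)))
        b = fitted_basis.inverse_transform(
            fitted_basis.transform(truth) + rng.normal(0, 0.05, (6, 3)))
        scheme = WeightScheme("constant")
        per_case, _, tests = compare_models({"ensemble": a, "b": b}, truth,
                                            grid, scheme)
        d = per_case["ensemble"].to_numpy() - per_case["b"].to_numpy()
        expect = stats.wilcoxon(d, zero_method="wilcox",
                                alternative="two-sided").pvalue
        assert tests["wilcoxon_p"].iloc[0] == pytest.approx(expect, rel=1e-12)

    def test_minimum_sizes_enforced(self, rank3_curves, grid):
        with pytest.raises(ValueError):
            compare_models({"only": rank3_curves}, rank3_curves, grid,
                           WeightScheme("constant"))
        with pytest.raises(ValueError):
            compare_models({"a": rank3_curves[:3], "b": rank3_curves[:3]},
                           rank3_curves[:3], grid, WeightScheme("constant"))
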