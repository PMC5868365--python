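"""Stacked ensemble of linear DVH predictors with model-based case filtering.

The pipeline: leave-one-out metadata (every base learner predicts every
training case from a model fitted without it), non-negative least-squares
stacking weights minimizing the internal cross-validation error, and a
filtering step that drops the s% of training cases with the highest median
(over learners) out-of-fold wRMSE — the cases no linear model can predict,
i.e. the anatomical/dosimetric outliers. After filtering, metadata, weights
and learners are all regenerated on the retained cases.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .dvh import (
    DEFAULT_PRESCRIPTION_GY,
    DVHPrincipalComponents,
    WeightScheme,
    default_dose_grid,
    postprocess_curves,
    wrmse_matrix,
)
from .learners import (
    BaseLearnerSpec,
    FeatureStandardizer,
    default_learner_bank,
    make_learner,
    penalty_magnitude_grid,
    select_penalty,
)

__all__ = [
    "MetadataTable",
    "MetadataFitError",
    "DVHStackingEnsemble",
    "build_metadata",
    "optimize_stack_weights",
    "case_wrmse_profile",
    "filter_cases",
    "train_ensemble",
    "predict_dvh",
    "compare_models",
]


logger = logging.getLogger("dvhstack")


class MetadataFitError(RuntimeError):
    """An inner (case, learner) fit failed during metadata generation."""

    def __init__(self, case: int, learner: str, cause: Exception):
        self.case, self.learner = case, learner
        super().__init__(f"metadata fit failed for case {case}, learner {learner!r}: {cause}")


@dataclass
class MetadataTable:
    """Out-of-fold predictions for one PCS component.

    ``z[n, k]`` is learner k's prediction of case n from a model trained
    without case n; ``y[n]`` is the held-out truth.
    """

    z: np.ndarray
    y: np.ndarray
    learner_names: tuple[str, ...]
    case_ids: np.ndarray | None = None

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.z.ndim != 2 or self.z.shape[0] != self.y.shape[0]:
            raise ValueError("z must be (n_cases, n_learners) matching y")
        if len(self.learner_names) != self.z.shape[1]:
            raise ValueError("learner_names length must match z columns")


def _fold_seed(seed: int, *key: int) -> int:
    """A stable derived seed (< 2**31) for one fold / stage."""
    return int(np.random.SeedSequence([int(seed), *key]).generate_state(1)[0] >> 1)


def _metadata_folds(n: int, n_folds: int | None, seed: int):
    """(train, test) index pairs: leave-one-out by default, else k-fold."""
    if n_folds is None or n_folds >= n:
        idx = np.arange(n)
        return [(np.delete(idx, i), np.array([i])) for i in range(n)]
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=_fold_seed(seed, 97))
    return list(kf.split(np.empty((n, 1))))


def build_metadata(X: np.ndarray, y: np.ndarray, specs: list[BaseLearnerSpec],
                   seed: int = 0, penalty_mode: str = "per_fold",
                   n_folds: int | None = None, grid_size: int = 20,
                   cv_folds: int = 5,
                   case_ids: np.ndarray | None = None) -> MetadataTable:
    """Out-of-fold predictions of one PCS component for every base learner.

    Features are re-standardized inside every fold using that fold's
    training cases only. ``penalty_mode='per_fold'`` re-runs penalty
    cross-validation in each fold (the exact scheme); ``'shared'`` selects
    penalties once on the full set and reuses them in every fold (fast,
    approximate).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 cases for out-of-fold metadata")
    if penalty_mode not in ("per_fold", "shared"):
        raise ValueError("penalty_mode must be 'per_fold' or 'shared'")
    names = tuple(s.name for s in specs)

    shared_specs = None
    if penalty_mode == "shared":
        sc = FeatureStandardizer().fit(X)
        Xz = sc.transform(X)
        grid = penalty_magnitude_grid(Xz, y, grid_size)
        shared_specs = [
            select_penalty(Xz, y, s, grid=grid, n_folds=min(cv_folds, n),
                           seed=_fold_seed(seed, 11, k))
            for k, s in enumerate(specs)
        ]

    z = np.empty((n, len(specs)))
    folds = _metadata_folds(n, n_folds, seed)
    for f, (tr, te) in enumerate(folds):
        if f % 10 == 0:
            logger.debug("metadata fold %d/%d", f + 1, len(folds))
        sc = FeatureStandardizer().fit(X[tr])
        Xtr, Xte = sc.transform(X[tr]), sc.transform(X[te])
        ytr = y[tr]
        if penalty_mode == "per_fold":
            grid = penalty_magnitude_grid(Xtr, ytr, grid_size)
            fold_specs = [
                select_penalty(Xtr, ytr, s, grid=grid,
                               n_folds=min(cv_folds, tr.size),
                               seed=_fold_seed(seed, 13, f, k))
                for k, s in enumerate(specs)
            ]
        else:
            fold_specs = shared_specs
        for k, spec in enumerate(fold_specs):
            try:
                model = make_learner(spec).fit(Xtr, ytr)
            except Exception as exc:  # identify the failing (case, learner)
                raise MetadataFitError(int(te[0]), names[k], exc) from exc
            z[te, k] = model.predict(Xte)
    return MetadataTable(z=z, y=y.copy(), learner_names=names,
                         case_ids=None if case_ids is None else np.asarray(case_ids))


def optimize_stack_weights(Z: MetadataTable | np.ndarray,
                           y: np.ndarray | None = None) -> np.ndarray:
    """Non-negative least-squares stacking weights on the metadata.

    Solves min_alpha ||y - Z alpha||^2 s.t. alpha >= 0 exactly (Lawson-Hanson
    active set). The weights are not constrained to sum to one.
    """
    if isinstance(Z, MetadataTable):
        y = Z.y
        Z = Z.z
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.isfinite(Z).all() or not np.isfinite(y).all():
        raise ValueError("metadata must be finite")
    if np.all(Z == 0):
        warnings.warn("all-zero metadata; stacking weights set to zero", UserWarning)
        return np.zeros(Z.shape[1])
    alpha, _ = optimize.nnls(Z, y)
    return alpha


def case_wrmse_profile(tables: list[MetadataTable], basis: DVHPrincipalComponents,
                       clinical_curves: np.ndarray, scheme: WeightScheme,
                       dose_grid: np.ndarray,
                       prescription_dose: float = DEFAULT_PRESCRIPTION_GY) -> np.ndarray:
    """Per-case median (over learners) out-of-fold wRMSE of the decoded DVH.

    For each learner its out-of-fold PCS predictions (one per component) are
    decoded to a DVH and scored against the clinical curve; the per-case
    median over learners is the filtering profile.
    """
    if len(tables) != basis.components_.shape[0]:
        raise ValueError(
            f"need metadata for all {basis.components_.shape[0]} components, got {len(tables)}")
    n, k = tables[0].z.shape
    for t in tables[1:]:
        if t.z.shape != (n, k):
            raise ValueError("metadata tables disagree on case/learner counts")
    V = np.asarray(clinical_curves, dtype=float)
    errs = np.empty((n, k))
    for j in range(k):
        S = np.column_stack([t.z[:, j] for t in tables])
        pred = basis.inverse_transform(S)
        errs[:, j] = wrmse_matrix(V, pred, dose_grid, scheme, prescription_dose)
    return np.median(errs, axis=1)


def filter_cases(profile: np.ndarray, s_percent: float = 10.0,
                 case_ids: np.ndarray | None = None
                 ) -> tuple[np.ndarray, pd.DataFrame]:
    """Drop the floor(s% * N) cases with the highest profile values.

    Ties are broken by removing the lower case index first. Returns the
    retained index array (sorted) and a report of the removed cases.
    """
    profile = np.asarray(profile, dtype=float)
    if not 0 <= s_percent < 100:
        raise ValueError("s_percent must lie in [0, 100)")
    n = profile.shape[0]
    n_remove = int(np.floor(s_percent / 100.0 * n))
    # primary key: profile descending; secondary: index ascending
    order = np.lexsort((np.arange(n), -profile))
    removed = np.sort(order[:n_remove])
    retained = np.sort(order[n_remove:])
    ids = np.arange(n) if case_ids is None else np.asarray(case_ids)
    report = pd.DataFrame({"case_id": ids[removed],
                           "median_oof_wrmse": profile[removed]})
    return retained, report


class DVHStackingEnsemble(RegressorMixin, BaseEstimator):
    """Stacked nine-model DVH predictor with metadata-based case filtering.

    Fit pipeline: fit the PCA basis on all training curves -> encode DVHs to
    PCS -> build out-of-fold metadata per component -> score each case by its
    median out-of-fold wRMSE and drop the worst ``s_percent`` -> on the
    retained cases, regenerate metadata, optimize non-negative stacking
    weights per component, and refit every base learner on the full retained
    set. Prediction combines learner PCS outputs with the stacking weights
    and decodes through the basis.

    Parameters
    ----------
    learner_specs : list of BaseLearnerSpec, default the nine-model bank
        (stepwise, ridge, lasso, six elastic-net ratios).
    n_components : retained PCS per curve (default 3).
    s_percent : filtering percentage (default 10; 0 disables filtering).
    weight_scheme : WeightScheme used by the filter profile (default the
        linear 50-100 scheme).
    penalty_mode : 'per_fold' (exact, penalty CV re-run in every metadata
        fold) or 'shared' (fast, penalties selected once per training set).
    metadata_folds : None for leave-one-out (default) or an integer k-fold.
    random_state : seed driving fold shuffles and penalty CV.
    """

    def __init__(self, learner_specs: list[BaseLearnerSpec] | None = None,
                 n_components: int = 3, s_percent: float = 10.0,
                 weight_scheme: WeightScheme | None = None,
                 penalty_mode: str = "per_fold", penalty_grid_size: int = 20,
                 penalty_cv_folds: int = 5, metadata_folds: int | None = None,
                 random_state: int = 0):
        self.learner_specs = learner_specs
        self.n_components = n_components
        self.s_percent = s_percent
        self.weight_scheme = weight_scheme
        self.penalty_mode = penalty_mode
        self.penalty_grid_size = penalty_grid_size
        self.penalty_cv_folds = penalty_cv_folds
        self.metadata_folds = metadata_folds
        self.random_state = random_state

    def _specs(self) -> list[BaseLearnerSpec]:
        return list(self.learner_specs) if self.learner_specs is not None \
            else default_learner_bank()

    def _scheme(self) -> WeightScheme:
        return self.weight_scheme if self.weight_scheme is not None else WeightScheme()

    def _metadata(self, X, y, stage: int, component: int):
        return build_metadata(
            X, y, self._specs(), seed=_fold_seed(self.random_state, stage, component),
            penalty_mode=self.penalty_mode, n_folds=self.metadata_folds,
            grid_size=self.penalty_grid_size, cv_folds=self.penalty_cv_folds)

    def fit(self, X: np.ndarray, V: np.ndarray, dose_grid: np.ndarray | None = None,
            prescription_dose: float = DEFAULT_PRESCRIPTION_GY,
            case_ids: np.ndarray | None = None):
        """Fit from an (N, P) feature matrix and (N, n_bins) clinical curves."""
        X = np.asarray(X, dtype=float)
        V = np.asarray(V, dtype=float)
        if X.shape[0] != V.shape[0]:
            raise ValueError("feature and DVH matrices disagree on case count")
        n = X.shape[0]
        specs = self._specs()
        k = len(specs)
        if dose_grid is None:
            dose_grid = default_dose_grid(prescription_dose, V.shape[1])
        ids = np.arange(n) if case_ids is None else np.asarray(case_ids)

        basis = DVHPrincipalComponents(n_components=self.n_components).fit(
            V, dose_grid=dose_grid)
        Y = basis.transform(V)

        if self.s_percent > 0:
            tables = [self._metadata(X, Y[:, c], 0, c)
                      for c in range(self.n_components)]
            profile = case_wrmse_profile(tables, basis, V, self._scheme(),
                                         dose_grid, prescription_dose)
            retained, report = filter_cases(profile, self.s_percent, case_ids=ids)
        else:
            retained = np.arange(n)
            report = pd.DataFrame({"case_id": [], "median_oof_wrmse": []})
        if retained.size < k + 2:
            raise ValueError(
                f"only {retained.size} cases retained after filtering; "
                f"need at least n_learners + 2 = {k + 2}")

        Xr, Vr, Yr = X[retained], V[retained], Y[retained]
        alpha = np.empty((self.n_components, k))
        learners: list[list] = []
        scaler = FeatureStandardizer().fit(Xr)
        Xrz = scaler.transform(Xr)
        for c in range(self.n_components):
            table = self._metadata(Xr, Yr[:, c], 1, c)
            alpha[c] = optimize_stack_weights(table)
            grid = penalty_magnitude_grid(Xrz, Yr[:, c], self.penalty_grid_size)
            bank = []
            for j, spec in enumerate(specs):
                resolved = select_penalty(
                    Xrz, Yr[:, c], spec, grid=grid,
                    n_folds=min(self.penalty_cv_folds, retained.size),
                    seed=_fold_seed(self.random_state, 2, c, j))
                bank.append(make_learner(resolved).fit(Xrz, Yr[:, c]))
            learners.append(bank)

        self.basis_ = basis
        self.scaler_ = scaler
        self.alpha_ = alpha
        self.learners_ = learners
        self.learner_names_ = tuple(s.name for s in specs)
        self.retained_indices_ = retained
        self.filter_report_ = report
        self.dose_grid_ = np.asarray(dose_grid, float)
        self.prescription_dose_ = float(prescription_dose)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Ensemble-predicted PCS, one row per case."""
        check_is_fitted(self, "alpha_")
        Xz = self.scaler_.transform(X)
        S = np.empty((Xz.shape[0], self.n_components))
        for c in range(self.n_components):
            preds = np.column_stack([m.predict(Xz) for m in self.learners_[c]])
            S[:, c] = preds @ self.alpha_[c]
        return S

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted valid DVH curves, one row per case."""
        return self.basis_.inverse_transform(self.predict_scores(X))


def train_ensemble(X: np.ndarray, curves: np.ndarray,
                   dose_grid: np.ndarray | None = None,
                   prescription_dose: float = DEFAULT_PRESCRIPTION_GY,
                   seed: int = 0, **params) -> DVHStackingEnsemble:
    """Convenience wrapper: construct and fit a :class:`DVHStackingEnsemble`."""
    est = DVHStackingEnsemble(random_state=seed, **params)
    return est.fit(X, curves, dose_grid=dose_grid, prescription_dose=prescription_dose)


def predict_dvh(model: DVHStackingEnsemble, x_new: np.ndarray):
    """Predict one case; returns (DVHCurve, PCS vector)."""
    from .dvh import DVHCurve
    x_new = np.atleast_2d(np.asarray(x_new, dtype=float))
    scores = model.predict_scores(x_new)[0]
    v = model.basis_.inverse_transform(scores[None, :])[0]
    return DVHCurve(model.dose_grid_, v, model.prescription_dose_), scores


def compare_models(models: dict[str, np.ndarray], clinical_curves: np.ndarray,
                   dose_grid: np.ndarray, scheme: WeightScheme,
                   prescription_dose: float = DEFAULT_PRESCRIPTION_GY,
                   reference: str | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-model validation wRMSE plus paired tests against a reference model.

    ``models`` maps a model name to its (M, n_bins) predicted-curve matrix.
    Returns (per-case wRMSE table, summary with mean/median, paired
    two-sided Wilcoxon signed-rank and sign-test p-values reference-vs-each).
    """
    if len(models) < 2:
        raise ValueError("need at least two models to compare")
    V = np.asarray(clinical_curves, dtype=float)
    if V.shape[0] < 5:
        raise ValueError("need at least 5 validation cases")
    per_case = pd.DataFrame({
        name: wrmse_matrix(V, np.asarray(pred, float), dose_grid, scheme,
                           prescription_dose)
        for name, pred in models.items()})
    summary = pd.DataFrame({"mean_wrmse": per_case.mean(),
                            "median_wrmse": per_case.median()})
    ref = reference if reference is not None else (
        "ensemble" if "ensemble" in models else next(iter(models)))
    rows = []
    for name in per_case.columns:
        if name == ref:
            continue
        diff = per_case[ref].to_numpy() - per_case[name].to_numpy()
        if np.allclose(diff, 0):
            warnings.warn(f"identical predictions for {ref!r} and {name!r}; p set to 1",
                          UserWarning)
            p_w, p_sign = 1.0, 1.0
        else:
            p_w = float(stats.wilcoxon(diff, zero_method="wilcox",
                                       alternative="two-sided").pvalue)
            nz = diff[diff != 0]
            p_sign = float(stats.binomtest(int((nz > 0).sum()), nz.size).pvalue)
        rows.append({"model": name, "reference": ref,
                     "mean_diff": float(np.mean(diff)),
                     "wilcoxon_p": p_w, "sign_test_p": p_sign})
    return per_case, summary, pd.DataFrame(rows)
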