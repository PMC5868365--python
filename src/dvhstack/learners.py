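"""The four linear base-learner families fitting one PCS component from features.

All penalized fits minimize the literal residual-sum-of-squares objective

    ||y - X beta||^2 + lambda1 ||beta||_1 + lambda2 ||beta||_2^2

with an unpenalized intercept. Ridge (lambda1 = 0) and the l1 family
(lasso / elastic net) are solved by scikit-learn behind an exact penalty
mapping; forward stepwise selection enters the candidate with the smallest
coefficient t-test p-value and refits the selected set by OLS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, Ridge
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "BaseLearnerSpec",
    "FeatureStandardizer",
    "PenalizedLinearModel",
    "ForwardStepwiseOLS",
    "ConvergenceError",
    "default_learner_bank",
    "DEFAULT_ELASTIC_NET_RATIOS",
    "standardize_features",
    "fit_penalized",
    "fit_stepwise",
    "select_penalty",
    "make_learner",
    "null_path_bound",
    "penalty_magnitude_grid",
]

# lambda2-to-lambda1 ratios spanning lasso-like to ridge-like elastic nets
DEFAULT_ELASTIC_NET_RATIOS = (0.1, 0.3, 1.0, 3.0, 10.0, 30.0)

DEFAULT_P_ENTER = 0.05


class ConvergenceError(RuntimeError):
    def __init__(self, n_iter: int):
        self.n_iter = n_iter
        super().__init__(f"coordinate descent did not converge after {n_iter} iterations")


@dataclass(frozen=True)
class BaseLearnerSpec:
    """One base learner's family and hyperparameters.

    Exactly the fields relevant to ``kind`` are set: ``p_enter`` for
    ``stepwise``; ``lambda2`` for ``ridge``; ``lambda1`` for ``lasso``;
    ``lambda1``/``lambda2`` (or ``ratio`` = lambda2/lambda1 with the
    magnitude left for cross-validation) for ``elastic_net``. A ``None``
    penalty marks a template whose magnitude is chosen by
    :func:`select_penalty`.
    """

    kind: str
    lambda1: float | None = None
    lambda2: float | None = None
    ratio: float | None = None
    p_enter: float | None = None

    def __post_init__(self):
        kinds = ("stepwise", "ridge", "lasso", "elastic_net")
        if self.kind not in kinds:
            raise ValueError(f"unknown learner kind {self.kind!r}")
        for name in ("lambda1", "lambda2", "ratio"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.p_enter is not None and not 0 < self.p_enter < 1:
            raise ValueError("p_enter must lie in (0, 1)")

    @property
    def needs_selection(self) -> bool:
        """True for template specs whose penalty magnitude is still open."""
        if self.kind == "stepwise":
            return False
        if self.kind == "ridge":
            return self.lambda2 is None
        return self.lambda1 is None

    @property
    def name(self) -> str:
        if self.kind == "elastic_net":
            r = self.ratio
            if r is None and self.lambda1:
                r = (self.lambda2 or 0.0) / self.lambda1
            return f"elastic_net_r{r:g}" if r is not None else "elastic_net"
        return self.kind

    def with_magnitude(self, m: float) -> "BaseLearnerSpec":
        """Concrete spec with the overall penalty magnitude set to ``m``.

        For elastic net the lambda2/lambda1 ratio is held fixed while the
        magnitude scales both penalties (lambda1 = m, lambda2 = ratio * m).
        """
        if self.kind == "ridge":
            return replace(self, lambda2=m)
        if self.kind == "lasso":
            return replace(self, lambda1=m)
        if self.kind == "elastic_net":
            r = self.ratio if self.ratio is not None else (
                (self.lambda2 or 0.0) / self.lambda1 if self.lambda1 else 1.0)
            return replace(self, lambda1=m, lambda2=r * m, ratio=r)
        return self  # stepwise has no penalty magnitude


def default_learner_bank() -> list[BaseLearnerSpec]:
    """The default nine-model bank: stepwise, ridge, lasso, six elastic nets."""
    bank = [
        BaseLearnerSpec("stepwise", p_enter=DEFAULT_P_ENTER),
        BaseLearnerSpec("ridge"),
        BaseLearnerSpec("lasso"),
    ]
    bank += [BaseLearnerSpec("elastic_net", ratio=r) for r in DEFAULT_ELASTIC_NET_RATIOS]
    return bank


class FeatureStandardizer(TransformerMixin, BaseEstimator):
    """Column-wise z-scoring with the sample standard deviation (ddof=1).

    Constant columns are flagged with a warning and passed through centered
    only (their scale is left at 1).
    """

    def fit(self, X: np.ndarray, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need an (n >= 2, p) feature matrix")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        constant = sd < 1e-12
        if constant.any():
            warnings.warn(
                f"{int(constant.sum())} constant feature column(s); centered only",
                UserWarning, stacklevel=2)
        sd = np.where(constant, 1.0, sd)
        self.scale_ = sd
        self.constant_mask_ = constant
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "mean_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}")
        return (X - self.mean_) / self.scale_


def standardize_features(X: np.ndarray) -> tuple[np.ndarray, FeatureStandardizer]:
    """Z-score a training feature matrix; returns (Xz, fitted standardizer)."""
    sc = FeatureStandardizer().fit(X)
    return sc.transform(X), sc


def null_path_bound(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest lambda1 at which the lasso solution is exactly zero.

    Under the RSS-scaled objective with an unpenalized intercept, beta = 0 is
    optimal iff |2 X_j^T (y - mean(y))| <= lambda1 for every column j.
    """
    yc = y - y.mean()
    return float(np.max(np.abs(2.0 * X.T @ yc)))


def penalty_magnitude_grid(X: np.ndarray, y: np.ndarray, size: int = 20) -> np.ndarray:
    """Log-spaced penalty magnitudes from 1e-4 up to the null-path bound."""
    hi = max(null_path_bound(X, y), 2e-4)
    return np.geomspace(1e-4, hi, size)


class PenalizedLinearModel(RegressorMixin, BaseEstimator):
    """Ridge / lasso / elastic net minimizing RSS + l1 + squared-l2 penalties.

    Parameters are on the literal objective scale (penalties multiply norms
    of beta directly, not per-sample averages), so grids are comparable
    across training-set sizes. The intercept is unpenalized.
    """

    def __init__(self, kind: str = "ridge", lambda1: float = 0.0,
                 lambda2: float = 0.0, max_iter: int = 100_000, tol: float = 1e-8):
        self.kind = kind
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.kind not in ("ridge", "lasso", "elastic_net"):
            raise ValueError(f"kind must be ridge/lasso/elastic_net, got {self.kind!r}")
        l1 = float(self.lambda1 or 0.0)
        l2 = float(self.lambda2 or 0.0)
        if self.kind == "ridge" and l1 != 0.0:
            raise ValueError("ridge takes no l1 penalty")
        if self.kind == "lasso" and l2 != 0.0:
            raise ValueError("lasso takes no l2 penalty")
        n = X.shape[0]
        if l1 == 0.0:
            # closed-form family: sklearn Ridge minimizes ||y-Xb||^2 + a||b||^2
            est = Ridge(alpha=l2, fit_intercept=True).fit(X, y)
            self.n_iter_ = 0
        else:
            # sklearn ElasticNet objective x 2n:
            #   ||y-Xb||^2 + 2n*a*rho*||b||_1 + n*a*(1-rho)*||b||^2
            alpha = l1 / (2 * n) + l2 / n
            l1_ratio = (l1 / (2 * n)) / alpha
            with warnings.catch_warnings():
                warnings.simplefilter("error", ConvergenceWarning)
                try:
                    est = ElasticNet(alpha=alpha, l1_ratio=l1_ratio,
                                     fit_intercept=True, max_iter=self.max_iter,
                                     tol=self.tol).fit(X, y)
                except ConvergenceWarning as exc:
                    raise ConvergenceError(self.max_iter) from exc
            self.n_iter_ = int(est.n_iter_)
        self.coef_ = np.asarray(est.coef_, dtype=float)
        self.intercept_ = float(est.intercept_)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} features, got {X.shape[1]}")
        return self.intercept_ + X @ self.coef_


class ForwardStepwiseOLS(RegressorMixin, BaseEstimator):
    """Forward feature selection by coefficient significance, then an OLS refit.

    At each step every remaining candidate is tried in the model extended by
    that candidate; the one whose coefficient t-test p-value (equivalent to
    the partial F-test) is smallest enters if p < ``p_enter``, otherwise
    selection stops. Ties go to the lower feature index. Coefficients of
    unselected features are exactly zero.
    """

    def __init__(self, p_enter: float = DEFAULT_P_ENTER):
        self.p_enter = p_enter

    @staticmethod
    def _candidate_pvalue(A: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray] | None:
        """p-value of the last column's coefficient in the OLS fit y ~ A.

        Returns None when the design is rank-deficient or has no residual
        degrees of freedom.
        """
        n, m = A.shape
        df = n - m
        if df < 1 or np.linalg.matrix_rank(A) < m:
            return None
        beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        sigma2 = resid @ resid / df
        XtX_inv = np.linalg.pinv(A.T @ A)
        se = np.sqrt(max(sigma2 * XtX_inv[-1, -1], 0.0))
        if se == 0.0:
            # perfect fit: the coefficient is infinitely significant
            return 0.0, beta
        t = beta[-1] / se
        return float(2.0 * stats.t.sf(abs(t), df)), beta

    def fit(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if not 0 < self.p_enter < 1:
            raise ValueError("p_enter must lie in (0, 1)")
        n, p = X.shape
        selected: list[int] = []
        ones = np.ones((n, 1))
        while len(selected) < p:
            best: tuple[float, int] | None = None
            for j in range(p):
                if j in selected:
                    continue
                A = np.hstack([ones, X[:, selected + [j]]])
                res = self._candidate_pvalue(A, y)
                if res is None:
                    continue
                pval, _ = res
                if best is None or pval < best[0]:
                    best = (pval, j)
            if best is None or best[0] >= self.p_enter:
                break
            selected.append(best[1])
        self.selected_features_ = tuple(selected)
        self.coef_ = np.zeros(p)
        if selected:
            A = np.hstack([ones, X[:, selected]])
            beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
            self.intercept_ = float(beta[0])
            self.coef_[selected] = beta[1:]
        else:
            self.intercept_ = float(y.mean())
        self.n_features_in_ = p
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} features, got {X.shape[1]}")
        return self.intercept_ + X @ self.coef_


def make_learner(spec: BaseLearnerSpec):
    """Instantiate the (unfitted) estimator a concrete spec describes."""
    if spec.kind == "stepwise":
        return ForwardStepwiseOLS(p_enter=spec.p_enter if spec.p_enter is not None
                                  else DEFAULT_P_ENTER)
    l1 = spec.lambda1 or 0.0
    l2 = spec.lambda2 or 0.0
    return PenalizedLinearModel(kind=spec.kind, lambda1=l1, lambda2=l2)


def fit_penalized(X: np.ndarray, y: np.ndarray, spec: BaseLearnerSpec) -> PenalizedLinearModel:
    """Fit one penalized model from a concrete (non-template) spec."""
    if spec.kind == "stepwise":
        raise ValueError("use fit_stepwise for stepwise specs")
    if spec.kind in ("lasso", "elastic_net") and spec.lambda1 is None:
        raise ValueError("spec has no penalty magnitude; run select_penalty first")
    if spec.kind == "ridge" and spec.lambda2 is None:
        raise ValueError("spec has no penalty magnitude; run select_penalty first")
    return make_learner(spec).fit(X, y)


def fit_stepwise(X: np.ndarray, y: np.ndarray,
                 p_enter: float = DEFAULT_P_ENTER) -> ForwardStepwiseOLS:
    return ForwardStepwiseOLS(p_enter=p_enter).fit(X, y)


def select_penalty(X: np.ndarray, y: np.ndarray, spec_template: BaseLearnerSpec,
                   grid: np.ndarray | None = None, n_folds: int = 5,
                   seed: int = 0) -> BaseLearnerSpec:
    """Choose the penalty magnitude by internal k-fold cross-validation.

    Returns the grid point minimizing the mean squared out-of-fold error;
    ties are broken toward the larger penalty. Specs that are already
    concrete (stepwise, or penalties set explicitly) are returned unchanged.
    """
    if not spec_template.needs_selection:
        return spec_template
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n_folds < 2 or n_folds > n:
        raise ValueError(f"n_folds must lie in [2, {n}]")
    if grid is None:
        grid = penalty_magnitude_grid(X, y)
    grid = np.sort(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValueError("empty penalty grid")
    folds = list(KFold(n_splits=n_folds, shuffle=True, random_state=seed).split(X))
    best_m, best_mse = None, np.inf
    for m in grid:  # ascending: '<=' keeps the larger penalty on ties
        spec = spec_template.with_magnitude(float(m))
        sse, cnt = 0.0, 0
        for tr, te in folds:
            model = make_learner(spec).fit(X[tr], y[tr])
            r = y[te] - model.predict(X[te])
            sse += float(r @ r)
            cnt += te.size
        mse = sse / cnt
        if mse <= best_mse:
            best_mse, best_m = mse, float(m)
    return spec_template.with_magnitude(best_m)
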