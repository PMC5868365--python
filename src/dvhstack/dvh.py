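"""Dose-volume histogram representation, PCA compression, and weighted-RMSE scoring.

A cumulative DVH gives, for each dose level d, the fraction of an organ's
volume receiving at least d. Curves from a planning cohort are sampled on a
shared dose grid and compressed to a handful of principal-component scores
(PCS); those scores are the regression targets of knowledge-based planning.
Prediction quality is scored with a weighted RMSE whose dose-dependent
weights emphasize the clinically important part of the curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "DVHCurve",
    "WeightScheme",
    "DVHPrincipalComponents",
    "GridMismatchError",
    "InsufficientDataError",
    "MedianDoseUndefinedError",
    "default_dose_grid",
    "fit_dvh_basis",
    "encode_dvh",
    "decode_dvh",
    "postprocess_curves",
    "make_weight_vector",
    "median_dose",
    "wrmse",
]

DEFAULT_PRESCRIPTION_GY = 70.0

_MONO_TOL = 1e-9


class GridMismatchError(ValueError):
    """Dose grids of two curves (or a curve and a basis) differ."""


class InsufficientDataError(ValueError):
    """Too few curves to fit the requested number of components."""


class MedianDoseUndefinedError(ValueError):
    """The curve never crosses 50% volume, so D50 does not exist."""


def default_dose_grid(prescription_dose: float = DEFAULT_PRESCRIPTION_GY,
                      n_bins: int = 111) -> np.ndarray:
    """Uniform grid from 0 Gy to 1.1x the prescription dose."""
    return np.linspace(0.0, 1.1 * prescription_dose, n_bins)


@dataclass(frozen=True)
class DVHCurve:
    """A cumulative fractional-volume DVH on a fixed dose grid.

    Invariants enforced at construction: the grid starts at 0 Gy and is
    strictly increasing; volume fractions lie in [0, 1], are non-increasing
    with dose, and equal 1 at 0 Gy (the whole organ receives >= 0 dose).
    """

    dose_grid: np.ndarray
    volume_fraction: np.ndarray
    prescription_dose: float = DEFAULT_PRESCRIPTION_GY

    def __post_init__(self):
        d = np.asarray(self.dose_grid, dtype=float)
        v = np.asarray(self.volume_fraction, dtype=float)
        if d.ndim != 1 or v.shape != d.shape:
            raise ValueError("dose_grid and volume_fraction must be 1-D and equal length")
        if d[0] != 0.0:
            raise ValueError("dose grid must start at 0 Gy")
        if np.any(np.diff(d) <= 0):
            raise ValueError("dose grid must be strictly increasing")
        if v.min() < -_MONO_TOL or v.max() > 1 + _MONO_TOL:
            raise ValueError("volume fractions must lie in [0, 1]")
        if np.any(np.diff(v) > _MONO_TOL):
            raise ValueError("volume fractions must be non-increasing with dose")
        if abs(v[0] - 1.0) > _MONO_TOL:
            raise ValueError("volume fraction at 0 Gy must equal 1")
        object.__setattr__(self, "dose_grid", d)
        object.__setattr__(self, "volume_fraction", v)

    def same_grid(self, other: "DVHCurve") -> bool:
        return self.dose_grid.shape == other.dose_grid.shape and np.allclose(
            self.dose_grid, other.dose_grid, rtol=0, atol=1e-12)


@dataclass(frozen=True)
class WeightScheme:
    """Per-bin weighting of the wRMSE metric.

    kind:
      * ``linear_relative`` -- weights rise linearly from ``w_low`` at 0 Gy to
        ``w_high`` at the prescription dose (and stay there above it); the
        bladder/rectum scheme (50 to 100).
      * ``gaussian_median`` -- Gaussian centered at the clinical curve's
        median dose D50 with standard deviation ``sd_gy``; the parotid
        scheme (SD 2 Gy).
      * ``constant`` -- all-ones weights; wRMSE reduces to plain RMSE.
    """

    kind: str = "linear_relative"
    w_low: float = 50.0
    w_high: float = 100.0
    sd_gy: float = 2.0

    _KINDS = ("linear_relative", "gaussian_median", "constant")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown weight scheme {self.kind!r}; choose from {self._KINDS}")


def _check_grids(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape or not np.allclose(a, b, rtol=0, atol=1e-12):
        raise GridMismatchError("dose grids do not match")


def postprocess_curves(raw: np.ndarray) -> np.ndarray:
    """Project raw decoded curves onto the valid-DVH set.

    Row-wise: clip to [0, 1], enforce monotone non-increase by a running
    minimum from low to high dose, and force the 0 Gy bin to 1.
    """
    v = np.clip(np.atleast_2d(np.asarray(raw, dtype=float)), 0.0, 1.0)
    v = np.minimum.accumulate(v, axis=1)
    v[:, 0] = 1.0
    # re-run the cumulative minimum in case forcing bin 0 exposed nothing:
    # v[:,1] <= clipped v[:,0] <= 1, so monotonicity is already preserved.
    return v


class DVHPrincipalComponents(TransformerMixin, BaseEstimator):
    """PCA basis for a cohort of DVH curves on a common dose grid.

    Fits the mean curve and the top ``n_components`` orthonormal principal
    directions of the centered curve matrix. Component signs are fixed so the
    largest-magnitude entry of each component is positive, making the basis
    reproducible across linear-algebra backends.

    Attributes
    ----------
    mean_ : (n_bins,) mean fractional volume per grid point.
    components_ : (n_components, n_bins) orthonormal rows.
    explained_variance_ : per-component sample variance (ddof=1).
    dose_grid_ : the shared dose grid, stored when passed to :meth:`fit`.
    """

    def __init__(self, n_components: int = 3):
        self.n_components = n_components

    def fit(self, V: np.ndarray, y=None, dose_grid: np.ndarray | None = None):
        V = np.asarray(V, dtype=float)
        if V.ndim != 2:
            raise ValueError("expected an (n_curves, n_bins) matrix")
        n, g = V.shape
        k = self.n_components
        if not 1 <= k <= g:
            raise ValueError("n_components must be in [1, n_bins]")
        if n < k + 1:
            raise InsufficientDataError(
                f"need at least n_components + 1 = {k + 1} curves, got {n}")
        self.mean_ = V.mean(axis=0)
        centered = V - self.mean_
        # SVD of the centered matrix: right singular vectors are the PCs.
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        comps = vt[:k]
        signs = np.sign(comps[np.arange(k), np.argmax(np.abs(comps), axis=1)])
        signs[signs == 0] = 1.0
        self.components_ = comps * signs[:, None]
        self.explained_variance_ = (s[:k] ** 2) / (n - 1)
        self.dose_grid_ = None if dose_grid is None else np.asarray(dose_grid, float)
        self.n_features_in_ = g
        return self

    def transform(self, V: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "components_")
        V = np.atleast_2d(np.asarray(V, dtype=float))
        if V.shape[1] != self.mean_.shape[0]:
            raise GridMismatchError("curve length does not match the basis grid")
        return (V - self.mean_) @ self.components_.T

    def inverse_transform(self, S: np.ndarray, raw: bool = False) -> np.ndarray:
        """Decode scores to curves; unless ``raw``, project onto valid DVHs."""
        check_is_fitted(self, "components_")
        S = np.atleast_2d(np.asarray(S, dtype=float))
        if S.shape[1] != self.components_.shape[0]:
            raise ValueError("score length does not match n_components")
        curves = self.mean_ + S @ self.components_
        return curves if raw else postprocess_curves(curves)


def fit_dvh_basis(curves, n_pc: int = 3) -> DVHPrincipalComponents:
    """Fit a PCA basis to a collection of :class:`DVHCurve` on a common grid."""
    curves = list(curves)
    if not curves:
        raise InsufficientDataError("no curves given")
    grid = curves[0].dose_grid
    for c in curves[1:]:
        _check_grids(grid, c.dose_grid)
    V = np.stack([c.volume_fraction for c in curves])
    return DVHPrincipalComponents(n_components=n_pc).fit(V, dose_grid=grid)


def encode_dvh(curve: DVHCurve, basis: DVHPrincipalComponents) -> np.ndarray:
    """Project a curve onto the basis; returns its PCS vector."""
    if basis.dose_grid_ is not None:
        _check_grids(basis.dose_grid_, curve.dose_grid)
    return basis.transform(curve.volume_fraction[None, :])[0]


def decode_dvh(scores: np.ndarray, basis: DVHPrincipalComponents,
               prescription_dose: float = DEFAULT_PRESCRIPTION_GY) -> DVHCurve:
    """Reconstruct a valid DVH curve from PCS."""
    if basis.dose_grid_ is None:
        raise ValueError("basis was fitted without a dose grid; cannot build a DVHCurve")
    v = basis.inverse_transform(np.asarray(scores, float)[None, :])[0]
    return DVHCurve(basis.dose_grid_, v, prescription_dose)


def median_dose(curve: DVHCurve) -> float:
    """Dose at which the curve first crosses 50% volume (linear interpolation)."""
    v = curve.volume_fraction
    d = curve.dose_grid
    below = np.nonzero(v < 0.5)[0]
    if below.size == 0:
        raise MedianDoseUndefinedError("curve never drops below 50% volume")
    i = below[0]
    if i == 0:  # cannot happen for a valid curve (v[0] == 1) but keep safe
        return d[0]
    v0, v1 = v[i - 1], v[i]
    if v0 == 0.5:
        return float(d[i - 1])
    return float(d[i - 1] + (0.5 - v0) * (d[i] - d[i - 1]) / (v1 - v0))


def make_weight_vector(scheme: WeightScheme, truth: DVHCurve) -> np.ndarray:
    """Raw (unnormalized) per-bin weights for a given clinical truth curve."""
    d = truth.dose_grid
    if scheme.kind == "constant":
        return np.ones_like(d)
    if scheme.kind == "linear_relative":
        rx = truth.prescription_dose
        if not rx > 0:
            raise ValueError("linear_relative weighting needs a positive prescription dose")
        frac = np.minimum(d / rx, 1.0)
        return scheme.w_low + (scheme.w_high - scheme.w_low) * frac
    # gaussian_median
    d50 = median_dose(truth)
    w = np.exp(-((d - d50) ** 2) / (2.0 * scheme.sd_gy ** 2))
    return np.maximum(w, 1e-12)


def wrmse(truth: DVHCurve, prediction: DVHCurve,
          scheme: WeightScheme = WeightScheme("constant")) -> float:
    """Weighted RMSE between two DVHs on the same grid.

    Weights are normalized to sum to one, so the constant scheme is exactly
    the standard RMSE over bins.
    """
    _check_grids(truth.dose_grid, prediction.dose_grid)
    w = make_weight_vector(scheme, truth)
    wn = w / w.sum()
    r = truth.volume_fraction - prediction.volume_fraction
    return float(np.sqrt(np.sum(wn * r * r)))


def wrmse_matrix(truth: np.ndarray, prediction: np.ndarray, dose_grid: np.ndarray,
                 scheme: WeightScheme, prescription_dose: float) -> np.ndarray:
    """Vectorized per-case wRMSE between two (N, n_bins) curve matrices.

    The weight vector is built per truth curve (the gaussian scheme centers
    on each clinical curve's own median dose).
    """
    truth = np.atleast_2d(truth)
    prediction = np.atleast_2d(prediction)
    if truth.shape != prediction.shape:
        raise GridMismatchError("curve matrices must have the same shape")
    r2 = (truth - prediction) ** 2
    if scheme.kind in ("constant", "linear_relative"):
        # weights do not depend on the individual truth curve
        ref = DVHCurve(dose_grid, truth[0], prescription_dose)
        w = make_weight_vector(scheme, ref)
        return np.sqrt(r2 @ (w / w.sum()))
    out = np.empty(truth.shape[0])
    for i in range(truth.shape[0]):
        t = DVHCurve(dose_grid, truth[i], prescription_dose)
        w = make_weight_vector(scheme, t)
        out[i] = np.sqrt(r2[i] @ (w / w.sum()))
    return out
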