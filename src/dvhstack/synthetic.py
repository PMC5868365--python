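"""Synthetic planning cohorts with controlled outlier contamination.

The generator emulates the statistical structure the stacked-regression
method assumes: correlated Gaussian anatomical features, a linear
features-to-PCS mapping with additive noise, and DVH curves decoded from the
scores through a smooth ground-truth curve family. Three contamination
mechanisms mirror the clinically observed failure modes: anatomical
outliers (feature vectors far outside the normal range with a nonlinear
response departure), dosimetrically inferior plans (a systematic shift of
the first PCS toward worse sparing), and mislabeled cases (a different
coefficient matrix altogether). Scenario presets reproduce the four
robustness experiments' cohort compositions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dvh import (
    DEFAULT_PRESCRIPTION_GY,
    DVHCurve,
    default_dose_grid,
    postprocess_curves,
)

__all__ = [
    "DVHFamily",
    "CohortConfig",
    "Cohort",
    "OutlierSpec",
    "ScenarioData",
    "make_dvh_family",
    "generate_cohort",
    "inject_outliers",
    "scenario_preset",
    "SCENARIO_NAMES",
    "default_true_coefficients",
]

SCENARIO_NAMES = ("small_training", "anatomical", "dosimetric_inferior", "mislabeled")

# standard deviations of the true per-component signal B.x, in score units;
# decaying like the leading PCA modes of clinical DVH cohorts
_SIGNAL_SD = (0.25, 0.12, 0.06)

# clean-fit R^2 target on each component: noise_sd = signal_sd * sqrt(0.3/0.7)
_R2_TARGET = 0.7


@dataclass(frozen=True)
class DVHFamily:
    """Ground-truth curve family: a mean falloff plus 3 orthonormal smooth modes.

    ``score_budget`` gives, per mode, the score magnitude within which
    mean + scores . modes is guaranteed (and test-verified) to remain a
    valid DVH without projection.
    """

    dose_grid: np.ndarray
    prescription_dose: float
    mean: np.ndarray
    modes: np.ndarray  # (3, n_bins), orthonormal rows
    score_budget: np.ndarray  # (3,)

    def decode(self, scores: np.ndarray, raw: bool = False) -> np.ndarray:
        """Scores (N, 3) -> curves (N, n_bins); projected to valid unless raw."""
        S = np.atleast_2d(np.asarray(scores, dtype=float))
        curves = self.mean + S @ self.modes
        return curves if raw else postprocess_curves(curves)


def make_dvh_family(grid: np.ndarray | None = None,
                    prescription_dose: float = DEFAULT_PRESCRIPTION_GY,
                    seed: int = 0) -> DVHFamily:
    """Build the ground-truth mean curve and three orthonormal smooth modes.

    The mean is a logistic falloff rescaled to run from 1 at 0 Gy to 0 at
    the top of the grid. The modes are built from the mean's derivative the
    way cohort DVH principal components look in practice: an overall
    dose-shift mode (proportional to -dmean/dd), a slope/width mode, and a
    curvature mode, each tapered by mean*(1-mean) so they vanish where the
    curve is pinned at 1 or 0, then Gram-Schmidt orthonormalized. This
    construction leaves generous score headroom, so systematic score shifts
    (e.g. dosimetrically inferior plans) stay representable as visibly
    shifted curves rather than saturating against the [0, 1] bounds.
    """
    if grid is None:
        grid = default_dose_grid(prescription_dose)
    d = np.asarray(grid, dtype=float)
    rx = float(prescription_dose)
    rng = np.random.default_rng(seed)
    center = (0.55 + rng.uniform(-0.01, 0.01)) * rx
    width = 0.18 * rx
    raw = 1.0 / (1.0 + np.exp((d - center) / width))
    mean = (raw - raw[-1]) / (raw[0] - raw[-1])
    mean[0] = 1.0

    g = np.gradient(mean, d)
    envelope = mean * (1.0 - mean)
    u = (d - center) / width
    seeds = [-g * envelope, -g * envelope * u, -g * envelope * (u ** 2 - 1.0)]
    modes = np.empty((3, d.size))
    for j, v in enumerate(seeds):
        v = np.array(v)
        for i in range(j):  # Gram-Schmidt against earlier modes
            v = v - (v @ modes[i]) * modes[i]
        modes[j] = v / np.linalg.norm(v)
        if modes[j, np.argmax(np.abs(modes[j]))] < 0:
            modes[j] = -modes[j]
    budget = _score_budget(mean, modes)
    return DVHFamily(d, rx, mean, modes, budget)


def _score_budget(mean: np.ndarray, modes: np.ndarray,
                  margin: float = 0.97) -> np.ndarray:
    """Per-mode score bounds keeping mean + scores.modes a valid DVH.

    Worst case over sign patterns: the perturbation of the value is
    sum |s_j m_j| and of the slope sum |s_j dm_j|. The budget scales a
    reference shape (the signal SDs) by the largest factor keeping the
    worst-case curve in [0, 1] and non-increasing.
    """
    ref = np.asarray(_SIGNAL_SD[:modes.shape[0]])
    absm = np.abs(modes) * ref[:, None]
    val_pert = absm.sum(axis=0)
    dmean = np.diff(mean)
    dpert = np.abs(np.diff(modes, axis=1) * ref[:, None]).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        room_hi = np.where(val_pert > 0, (1.0 - mean) / val_pert, np.inf)
        room_lo = np.where(val_pert > 0, mean / val_pert, np.inf)
        room_slope = np.where(dpert > 0, -dmean / dpert, np.inf)
    t = margin * min(room_hi.min(), room_lo.min(), room_slope.min())
    return t * ref


def default_true_coefficients(n_features: int = 9, n_pc: int = 3) -> np.ndarray:
    """Fixed sparse-ish 3 x P coefficient pattern (unscaled)."""
    B = np.zeros((n_pc, n_features))
    patterns = [
        [1.0, -0.7, 0.5, 0.0, 0.35, 0.0, -0.25, 0.0, 0.0],
        [0.0, 0.6, 0.0, -0.8, 0.0, 0.4, 0.0, 0.0, -0.3],
        [0.5, 0.0, 0.0, 0.0, -0.6, 0.0, 0.0, 0.7, 0.0],
    ]
    for c in range(n_pc):
        row = patterns[c % 3][:n_features]
        B[c, :len(row)] = row
    return B


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Features are multivariate normal with unit variances and
    compound-symmetric correlation ``feature_correlation``; true PCS are
    ``B x`` plus Gaussian noise. ``true_coefficients`` rows are rescaled at
    construction so the signal SD per component matches the clinical-like
    defaults, and ``noise_sd`` defaults to the level giving a clean linear
    fit R^2 of about 0.7 per component.
    """

    n_cases: int = 50
    n_features: int = 9
    feature_correlation: float = 0.5
    true_coefficients: np.ndarray | None = None
    noise_sd: np.ndarray | None = None
    family: DVHFamily | None = None
    seed: int = 0

    def resolved(self) -> "CohortConfig":
        """Fill in derived defaults (B scaling, noise level, curve family)."""
        fam = self.family if self.family is not None else make_dvh_family()
        rho = self.feature_correlation
        p = self.n_features
        Sigma = np.full((p, p), rho) + (1 - rho) * np.eye(p)
        if np.linalg.eigvalsh(Sigma).min() <= 0:
            raise ValueError("feature correlation gives a non-PD covariance")
        B = (self.true_coefficients if self.true_coefficients is not None
             else default_true_coefficients(p))
        B = np.array(B, dtype=float)
        n_pc = B.shape[0]
        target = np.asarray(_SIGNAL_SD[:n_pc])
        for c in range(n_pc):
            sd = np.sqrt(B[c] @ Sigma @ B[c])
            if sd > 0:
                B[c] *= target[c] / sd
        if self.noise_sd is not None:
            noise = np.asarray(self.noise_sd, dtype=float) * np.ones(n_pc)
        else:
            noise = target * np.sqrt((1 - _R2_TARGET) / _R2_TARGET)
        if np.any(noise < 0):
            raise ValueError("noise_sd must be >= 0")
        return replace(self, true_coefficients=B, noise_sd=noise, family=fam)

    @property
    def covariance(self) -> np.ndarray:
        rho, p = self.feature_correlation, self.n_features
        return np.full((p, p), rho) + (1 - rho) * np.eye(p)


@dataclass
class Cohort:
    """A generated cohort: features, clinical curves, and ground truth."""

    features: np.ndarray  # (N, P)
    curves: np.ndarray  # (N, n_bins), valid DVHs
    true_scores: np.ndarray  # (N, n_pc) before decode projection
    labels: np.ndarray  # per-case: normal / anatomical / dosimetric_inferior / mislabeled
    in_gamut: np.ndarray  # True where decode needed no projection
    config: CohortConfig
    case_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.case_ids is None:
            self.case_ids = np.array([f"case_{i:04d}" for i in range(len(self.features))])

    @property
    def family(self) -> DVHFamily:
        return self.config.family

    @property
    def dose_grid(self) -> np.ndarray:
        return self.family.dose_grid

    @property
    def prescription_dose(self) -> float:
        return self.family.prescription_dose

    def outlier_indices(self) -> np.ndarray:
        return np.nonzero(self.labels != "normal")[0]


def _decode_with_gamut(fam: DVHFamily, scores: np.ndarray):
    raw = fam.decode(scores, raw=True)
    curves = postprocess_curves(raw)
    in_gamut = np.max(np.abs(curves - raw), axis=1) < 1e-9
    return curves, in_gamut


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a clean cohort under the configured linear model."""
    cfg = config.resolved()
    rng = np.random.default_rng(cfg.seed)
    X = rng.multivariate_normal(np.zeros(cfg.n_features), cfg.covariance,
                                size=cfg.n_cases, method="cholesky")
    B = cfg.true_coefficients
    scores = X @ B.T + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_cases, B.shape[0]))
    curves, in_gamut = _decode_with_gamut(cfg.family, scores)
    labels = np.full(cfg.n_cases, "normal", dtype=object)
    return Cohort(X, curves, scores, labels, in_gamut, cfg)


@dataclass(frozen=True)
class OutlierSpec:
    """Contamination mechanism and magnitudes.

    * ``anatomical``: features shifted by ``feature_shift_sd`` standard
      deviations along a unit direction; the response follows B x plus a
      quadratic departure ``quad_coeff * max(0, u.x - onset_sd)^2`` on the
      first PCS, active only beyond the normal feature range.
    * ``dosimetric_inferior``: first PCS shifted by
      ``offset_noise_sd * noise_sd[0]`` toward inferior sparing.
    * ``mislabeled``: response generated by an alternative coefficient
      matrix B' (default: B with its columns rolled, preserving signal
      scale under the exchangeable feature correlation).
    """

    kind: str
    n_outliers: int
    feature_shift_sd: float = 3.0
    quad_coeff: float = 0.3
    onset_sd: float = 2.0
    offset_noise_sd: float = 5.0
    alt_coefficients: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in ("anatomical", "dosimetric_inferior", "mislabeled"):
            raise ValueError(f"unknown outlier kind {self.kind!r}")
        if self.n_outliers < 0:
            raise ValueError("n_outliers must be >= 0")


def inject_outliers(cohort: Cohort, spec: OutlierSpec,
                    seed: int | None = None) -> Cohort:
    """Replace the last ``n_outliers`` cases with contaminated ones.

    Returns a new cohort whose ``labels`` mark the injected cases; the
    original is untouched.
    """
    cfg = cohort.config
    n = len(cohort.features)
    if spec.n_outliers >= n:
        raise ValueError("n_outliers must be smaller than the cohort size")
    if spec.n_outliers == 0:
        return cohort
    rng = np.random.default_rng(cfg.seed + 104729 if seed is None else seed)
    idx = np.arange(n - spec.n_outliers, n)
    m = idx.size
    B = cfg.true_coefficients
    X = cohort.features.copy()
    scores = cohort.true_scores.copy()
    noise = rng.normal(0.0, cfg.noise_sd, size=(m, B.shape[0]))

    if spec.kind == "anatomical":
        u = np.ones(cfg.n_features) / np.sqrt(cfg.n_features)
        # SD of the projection along u under the feature covariance, so the
        # shift is in standard deviations of that direction
        sd_u = float(np.sqrt(u @ cfg.covariance @ u))
        X[idx] = rng.multivariate_normal(np.zeros(cfg.n_features), cfg.covariance,
                                         size=m, method="cholesky") \
            + spec.feature_shift_sd * sd_u * u
        scores[idx] = X[idx] @ B.T + noise
        proj = (X[idx] @ u) / sd_u
        scores[idx, 0] += spec.quad_coeff * np.maximum(0.0, proj - spec.onset_sd) ** 2
    elif spec.kind == "dosimetric_inferior":
        scores[idx] = X[idx] @ B.T + noise
        scores[idx, 0] += spec.offset_noise_sd * cfg.noise_sd[0]
    else:  # mislabeled
        Balt = (np.asarray(spec.alt_coefficients, float)
                if spec.alt_coefficients is not None else np.roll(B, 3, axis=1))
        scores[idx] = X[idx] @ Balt.T + noise

    curves, in_gamut = _decode_with_gamut(cfg.family, scores)
    labels = cohort.labels.copy()
    labels[idx] = spec.kind
    return Cohort(X, curves, scores, labels, in_gamut, cfg,
                  case_ids=cohort.case_ids.copy())


@dataclass
class ScenarioData:
    """One robustness experiment: contaminated training set, clean validation."""

    name: str
    train: Cohort
    validation: Cohort
    outlier_indices: np.ndarray
    scheme_kind: str  # recommended wRMSE weighting for this disease site


_SCENARIOS = {
    # name: (n_train_normal, n_outliers, outlier_kind, n_validation, scheme)
    "small_training": (20, 0, None, 146, "linear_relative"),
    "anatomical": (40, 10, "anatomical", 111, "linear_relative"),
    "dosimetric_inferior": (40, 10, "dosimetric_inferior", 110, "linear_relative"),
    "mislabeled": (80, 10, "mislabeled", 148, "gaussian_median"),
}


def scenario_preset(name: str, seed: int = 0,
                    base_config: CohortConfig | None = None) -> ScenarioData:
    """Training/validation cohorts for one of the four robustness experiments.

    Validation cohorts are always outlier-free; training contamination
    follows the experiment design (e.g. 40 normal + 10 inferior plans).
    """
    if name not in _SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    n_norm, n_out, kind, n_val, scheme = _SCENARIOS[name]
    base = base_config if base_config is not None else CohortConfig()
    train_cfg = replace(base, n_cases=n_norm + n_out, seed=seed)
    train = generate_cohort(train_cfg)
    if n_out:
        train = inject_outliers(train, OutlierSpec(kind, n_out), seed=seed + 499979)
    val_cfg = replace(base, n_cases=n_val, seed=seed + 999983)
    validation = generate_cohort(val_cfg)
    return ScenarioData(name, train, validation, train.outlier_indices(), scheme)
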