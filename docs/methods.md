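# Methods

## Model

The package predicts an organ-at-risk cumulative DVH from P anatomical
features by regressing the curve's first n_pc = 3 principal-component scores
(PCS) on the features and decoding through the cohort PCA basis. The working
assumption is that a linear map explains the majority of training cases;
cases for which it cannot (anatomical outliers with a nonlinear response,
dosimetrically inferior or mislabeled plans) are treated as contamination to
be detected and removed, not modeled.

Nine base learners are fit per PCS component: forward stepwise selection
(entry by the smallest coefficient t-test p-value, threshold `p_enter`,
equivalent to the partial F-test; OLS refit on the selected set), ridge,
lasso, and elastic net at six lambda2/lambda1 ratios. All penalized fits
minimize the residual *sum* of squares plus `lambda1·||beta||_1 +
lambda2·||beta||_2^2` — penalties multiply the literal norms, not per-sample
averages — with an unpenalized intercept. Features are z-scored with the
sample SD (ddof = 1); the intercept treatment is then equivalent to
centering the response.

The stack is classical stacked generalization with out-of-fold metadata:
every learner predicts every training case from a model fitted without it
(leave-one-out by default, k-fold configurable), and the per-component
stacking weights solve a non-negative least-squares problem on that
metadata. NNLS guarantees, exactly and on every run, that the stacked
internal-CV squared error is no larger than any single learner's (the
single-learner solutions are feasible points). Weights are deliberately not
normalized: shrunken learners earn weights above 1, overfit ones below; the
sum typically lands between 0.5 and 1.5.

Case filtering reuses the metadata: each case is scored by the median, over
the nine learners, of the weighted RMSE between its out-of-fold decoded DVH
(all components) and its clinical curve, and the `floor(s/100·N)` worst
cases are dropped (ties resolved toward the lower case index). Metadata,
weights, and learners are then regenerated from scratch on the retained set
so removed cases cannot influence the final weights; the PCA basis is kept
from the full set, since it is a representation rather than a fit to
protect, and keeping it fixed keeps filter scores comparable.

## Parameters that matter

| parameter | default | meaning |
| --- | --- | --- |
| `n_components` | 3 | PCS retained per curve; three capture the bulk of cohort DVH variation |
| learner bank | 9 models | stepwise, ridge, lasso, elastic net at ratios 0.1/0.3/1/3/10/30 (log-spaced, lasso-like to ridge-like; the ratio values are a package choice) |
| `p_enter` | 0.05 | stepwise entry threshold (conventional significance level; a package choice) |
| penalty CV | 5-fold, 20 grid points | magnitude grid log-spaced from 1e-4 to the null-path bound `max_j |2 X_j^T (y − ȳ)|`; ties go to the larger penalty |
| `s_percent` | 10 | filtering percentage; balances robustness against discarding usable cases |
| `metadata_folds` | None (LOO) | out-of-fold scheme for the metadata |
| `penalty_mode` | `per_fold` | re-run penalty CV inside every metadata fold (exact); `shared` selects once per training set and is the labeled-approximate fast path |
| weighting | linear 50→100 over 0 Gy→prescription | bladder/rectum-style wRMSE weights; `gaussian_median` (SD 2 Gy at D50) for parotid-style scoring; `constant` ≡ RMSE |
| dose grid | 111 bins, 0 to 1.1× prescription (70 Gy) | shared cohort grid |

wRMSE normalizes raw weights to sum to one, `w''_i = w_i / Σ_j w_j`, so the
constant scheme reduces exactly to the standard RMSE; a normalization with
an extra factor N would scale the constant case by √N and break that
reduction. Decoded curves are projected onto valid DVHs by clipping to
[0, 1], a running minimum from low to high dose, and forcing bin 0 to 1 —
the minimal projection; the median dose D50 is the linearly interpolated
first downward crossing of 50% volume, and gaussian weights are floored at
1e-12 to stay positive.

## Synthetic cohorts

The generator emulates exactly the structure the method assumes: features
are multivariate normal with unit variances and compound-symmetric
correlation 0.5; true PCS are `B·x` plus independent Gaussian noise; curves
are decoded from the true scores through a smooth ground-truth family. The
family's mean is a logistic falloff (centered at 0.55× prescription, width
0.18×), and its three orthonormal modes are built from the mean's
derivative — an overall dose-shift mode, a width mode, and a curvature
mode, tapered by `mean·(1−mean)` — mirroring how cohort DVH principal
components look in practice and leaving enough score headroom (worst-case
budget ≈ 0.90/0.43/0.22) that systematic shifts such as inferior plans
remain visibly shifted curves instead of saturating against the [0, 1]
bounds. Per-component signal SDs are (0.25, 0.12, 0.06); noise SDs are set
so a clean OLS fit attains R² ≈ 0.7 per component, i.e. most but not all
variance is feature-explainable.

Contamination mechanisms: *anatomical* outliers shift the feature vector 3
standard deviations along the equi-weighted direction (SD measured along
that direction under the feature covariance) and add a quadratic response
departure active only beyond 2 SD; *dosimetric inferior* plans shift the
first PCS by 5 noise SDs; *mislabeled* cases follow an alternative
coefficient matrix (the columns of B rolled, which preserves signal scale
under the exchangeable correlation). The four scenario presets fix the
cohort compositions (train/validation): 20/146 clean, 40+10/111 anatomical,
40+10/110 inferior, 80+10/148 mislabeled; validation sets are always clean.

What the generator does **not** emulate: real anatomical feature
distributions (distance-to-target-histogram scores are neither Gaussian nor
exchangeable), organ-specific curve shapes, planner-dependent heterogeneity,
or inter-organ correlation. Passing tests therefore demonstrate the
machinery is correct and the robustness mechanisms act as designed under
the assumed model class — not clinical performance. One consequence worth
stating: under the linear generator all nine learners perform within a few
percent of each other, whereas on clinical cohorts individual families can
fail dramatically (heavily shrunk ridge on sparse feature spaces, unstable
stepwise on small cohorts), which is precisely where stacking shows its
largest clinical gains.

## Numerical choices

PCA uses the SVD of the centered curve matrix; component signs are fixed by
making each component's largest-magnitude entry positive. Ridge is solved in
closed form (scikit-learn), the l1 family by coordinate descent with
tolerance 1e-8, mapped exactly onto the literal objective scale; penalty
grids are therefore comparable across cohort sizes. NNLS uses the
Lawson–Hanson active-set algorithm (scipy). Stepwise stops when no
candidate's entry p-value clears the threshold, when the extended design
becomes rank-deficient, or when residual degrees of freedom run out;
degenerate candidates are skipped. All fold assignments and penalty CV
shuffles derive from a single integer seed through hashed seed sequences, so
a fitted and serialized model is byte-reproducible given (data, config,
seed). Stacking is solved independently per PCS component.

## Problem sizes used by the shipped checks

The test suite and acceptance script run the method at cohort sizes 20–100
with the shared-penalty fast path, a 10-point penalty grid, and 20-fold
metadata for the replicated scenario studies (20 replicates per scenario);
these are the package's chosen desk-scale study conditions. The
stacking-weight diagnostic uses 20 cohorts of 50 cases with the full
default bank on the first PCS component.

## Known limitations

- Filtering always removes `floor(s/100·N)` cases, outliers or not; on
  clean cohorts of 20 it measurably costs accuracy (the robustness/accuracy
  trade-off inherent in a fixed percentage).
- With 20% contamination the metadata itself is fit on contaminated data,
  so models absorb part of a systematic outlier shift (intercept plus
  spurious slopes along the outliers' mean feature direction); filter
  recall of strong inferior-plan outliers plateaus around 7–8 of 10 at
  40+10 cohort sizes.
- Outlier-like *new* cases are predicted without warning (case-based
  handling of out-of-distribution queries is out of scope).
- Only cumulative DVHs on a shared grid are supported; no differential
  DVHs, no grid resampling beyond what the caller does, single-organ bases.
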