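# Methods

## Problem

Blinding a clinical trial of a granulated herbal medicine requires a
placebo whose powder color is visually indistinguishable from the active
granule. Granule colors are dominated by brownish natural pigments, so
the package works with a four-pigment tinting system — caramel (brown
base), lemon yellow, carmine and indigo — dosed in mg per fixed 20.00 g
excipient batch (lactose/dextrin 4:1). The task is inverse color
formulation: given a measured mean RGB color of a powder, predict the
pigment doses that reproduce it.

## Model

The predictor is a cluster-then-regress hierarchy:

1. **Standardization.** Each RGB channel is z-scored with the training
   library's per-channel mean and *sample* standard deviation (n−1
   denominator; recorded in the model metadata). Query colors are always
   transformed with the training statistics.
2. **Clustering.** k-means (k-means++ init, 10 restarts, max 300
   iterations, tol 1e-4, seeded) partitions the standardized colors.
   The cluster count is scanned over 2–11; the within-cluster sum of
   squares (SSE) gives the elbow diagnostic (largest second difference)
   and the mean silhouette coefficient s = (b−a)/max(a,b) decides:
   chosen k = silhouette argmax, ties toward smaller k. On the bundled
   synthetic world this selects k = 2, separating a light and a dark
   color population.
3. **Per-cluster model competition.** Five regressor families — linear,
   ridge, RBF-SVR, random forest, gradient boosting — predict each of
   the four pigment doses from standardized RGB. Hyperparameters are
   grid-searched by inner 5-fold CV RMSE; each tuned family is then
   scored with repeated k-fold CV (5 folds × 3 repeats, seeded), and
   scores are macro-averaged over folds, repeats and pigments. The
   family with the smallest mean RMSE wins the cluster (ties: higher
   mean R², then the fixed order linear → ridge → SVR → forest →
   boosting) and is refitted on the whole cluster, one estimator per
   pigment. Per-pigment score breakdowns are always retained because
   indigo's near-constant doses make its R² fragile.
4. **Prediction.** A query color is standardized, routed to its nearest
   centroid (ties to the lowest index), and passed to that cluster's
   winner. Negative dose predictions are clamped to 0 and doses are
   rounded half-up to 0.01 mg, the weighing precision; the excipient is
   fixed at 20.00 g.

### Similarity evaluation

Reference/placebo pairs are graded with the CIELAB color difference
ΔE = ‖(L,a,b) − (L₀,a₀,b₀)‖₂, banded at the conventional perceptibility
thresholds (half-open intervals [0,1), [1,3), [3,6), [6,9), [9,12),
[12,∞): nearly undetectable → very small → slight → fair → clear →
different), and with the cosine similarity of the raw RGB vectors.
RGB→Lab uses sRGB companding with the D65 2° white point (scikit-image);
when measured Lab values are supplied alongside RGB they take precedence,
so evaluation does not depend on the conversion convention. The separate
"ΔE ≤ 3" count uses ≤ deliberately, distinct from the band edges.
Sensory-panel scores (0–3 identity scale, two blinded arms) are compared
with a classical paired t-test at α = 0.05; all-zero differences return
the degenerate t = 0, p = 1, while a nonzero constant difference raises.

### Channel attribution

With only three features, Shapley attributions are computed exactly by
enumerating all 2³ coalitions. The value of a coalition is
interventional: the predictor is averaged over a background sample
(capped at 200 seeded rows) with the coalition's channels pinned to the
explained color. Efficiency (φ_R+φ_G+φ_B equals prediction minus the
background mean) holds to float precision on every sample; dominance
reports give the channel with the largest mean |φ| per cluster and
pigment plus the sign of the channel/attribution correlation.

## Synthetic world

No public pigment/color library exists, so testing uses a forward
simulator: each channel is attenuated exponentially,
`channel = base · exp(−Σ_j K[c,j]·dose_j) + ε`, ε ~ N(0, 2²) channel
units, base = (253, 251, 250) (near-white excipient powder). The default
attenuation matrix K encodes the pigment hues — caramel absorbs
B > G > R, lemon yellow mainly blue, carmine mainly green, indigo mainly
red — so the attribution module's dominance findings (caramel↦R,
lemon↦B, carmine↦G, negative associations) emerge from the fitted
models rather than being wired in.

The default library design draws 323 formulations from a light and a
dark regime split on caramel (0–200 mg vs 200–800 mg, beta-shaped within
the regime), with lemon yellow up to 155 mg and carmine up to 265 mg in
the dark regime but concentrated near small doses in the light regime
(as real light placebo recipes are), and indigo zero for ~80% of samples,
otherwise ≤ 1 mg. K and the base color were calibrated once, analytically,
so the library spans roughly R 63–255, G 54–255, B 32–255 and shows a
clean two-population structure (mean silhouette ≈ 0.78 at k = 2); they
are not revisited per test.

What the generator does **not** emulate: batch-to-batch pigment
variability, non-Gaussian measurement error, camera gamma and lighting
drift, and any sharp local irregularities of real powder reflectance. A
consequence worth stating plainly: because the simulated inverse map is
smooth and the 3-channel→4-dose problem is underdetermined, smooth
low-variance regressors (RBF-SVR, linear) usually win the competition on
synthetic libraries. On real libraries tree ensembles are frequently
reported as winners; the suite therefore verifies the competition
machinery (the true min-RMSE family is selected, and a nonsmooth target
makes the random forest win) rather than asserting a particular winner
on synthetic data. A green pipeline run establishes that doses are
recoverable (held-out per-pigment R² ≥ 0.85, indigo exempt) and that
predicted formulas round-trip to within ΔE < 6 of the query color for
≥ 90% of held-out samples — not that any specific regressor family is
superior in general.

## Numerical choices

- Half-up decimal rounding for rendered ΔE/COS (4 dp) and doses (2 dp);
  full precision retained internally.
- Band boundaries 1, 3, 6, 9, 12 belong to the upper band (half-open
  partition covers every d ≥ 0 exactly once).
- Empty clusters during Lloyd iterations are handled by the underlying
  k-means implementation's relocation strategy; singleton clusters score
  silhouette 0.
- Cross-validation folds below 2×folds samples trigger automatic fold
  reduction with a warning; fewer than 4 samples is an error.
- R² is undefined (raises) for a constant target; CV folds with a
  constant target are skipped in the R² average only.
- A single run seed fans out to per-stage seeds via numpy SeedSequence,
  so simulation, fitting and query generation are independently
  reproducible; model archives embed a 20-color probe set that is
  re-predicted at load time (tolerance 1e-9) to catch corruption.
- Whiteboard calibration scales each channel by 255/whiteboard before
  ROI averaging and clips to [0, 255]; pixel membership in a circular
  ROI uses integer pixel centers with a ≤ comparison.

## Limitations

- The RGB→Lab convention of external measurement software may differ;
  supplying measured Lab sidesteps this.
- Indigo dose recovery is out of reach by construction (near-constant
  target) and is excluded from recovery claims.
- The synthetic dose design matches published marginal ranges, not any
  real library's joint distribution; conclusions about relative model
  performance do not transfer to real data.
- Container detection in images is out of scope; the circular ROI is an
  input.
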