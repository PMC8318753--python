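# Methods

This note documents the models, estimators and numerical choices behind
`svml`, and what the synthetic experiments do and do not demonstrate.

## Problem

Segmenting the lung fields in a 2D thoracic MR slice is a per-pixel binary
classification problem complicated by low boundary contrast and adhesion
between the lung and neighbouring organs. `svml` addresses it with local
texture features fed to a kernel SVM whose training set is curated by a
self-paced curriculum, followed by 2D morphological clean-up. The package
also quantifies the two MR measurements used alongside segmentation in
solitary-pulmonary-nodule work-ups: dynamic contrast-enhanced (DCE)
time–signal curves and diffusion-weighted (DWI) decays.

## Texture features (GLGCM)

For each pixel, intensity and Sobel gradient magnitude are quantized
(min–max, 1-based) into `Lg = Lv = 16` levels over the whole image, and the
joint co-occurrence counts `H(i, j)` of (gray level i, gradient level j)
are accumulated over the 5×5 window centred on the pixel
(`P = H / 25`). Two statistics summarise the window:

- small-gradient advantage `mu1 = Σ H(i,j)/j² / Σ H(i,j)` ∈ (0, 1] — large
  in smooth regions, small at texture borders;
- inverse difference moment `mu2 = −Σ P(i,j)/(1+(i−j)²)` ∈ [−1, 0) —
  magnitude large when gray and gradient levels agree. The leading minus
  sign is kept as a convention of this package's feature definition; since
  all features are z-scored before training, the sign has no effect on the
  classifier.

The per-pixel feature vector is `[i/Lg, j/Lv, mu1, mu2]`. Because both
statistics are window means of per-pixel terms (`mu1 = mean(1/j²)`,
`mu2 = −mean(1/(1+(i−j)²))`), the full feature map is computed with two
uniform filters; this is algebraically identical to the per-window
definition and is cross-checked against it in the tests.

Border handling is edge-excluding reflection (NumPy `reflect` /SciPy
`mirror`) for both the gradient operator and the windows. The gradient
operator is the 3×3 Sobel magnitude; any isotropic first-derivative stencil
would serve.

## Weighted soft-margin RBF-SVM

Training solves the kernelized dual

    min_a 1/2 ΣΣ a_i a_j y_i y_j K(x_i,x_j) − Σ a_i
    s.t.  Σ y_i a_i = 0,  0 ≤ a_i ≤ C·v_i,

with `K(x,x') = exp(−γ‖x−x'‖²)` and per-sample curriculum weights
`v_i ∈ [0,1]` entering as box caps (`v_i = 0` removes the sample). The
solver is a two-variable maximal-violating-pair working-set method
(SMO-style): at each step the most KKT-violating feasible pair is updated
in closed form; starting from `a = 0` the equality constraint is preserved
exactly. It stops when the violating-pair gap falls below `tol = 1e−3`
(iteration cap `min(max(2·10⁴, 10 n²), 5·10⁵)`); at that gap the dual
objective agrees with an independent SLSQP solution to ≲1e−5 on the toy
suites. The bias is the mean of `y_i − Σ_j a_j y_j K_ij` over free support
vectors (`0 < a_i < C·v_i`), falling back to the midpoint of the KKT bounds
when no vector is free. Features are z-scored with training statistics
stored in the model. Defaults `C = 10`, `γ = 0.5` suit the z-scored 4-D
texture features; both are exposed.

The training report includes the correct-rate discriminant weight
`w_t = 1 − Ns/n`, with the expected support-vector count estimated by the
realized count of the single trained model (no resampling): by the
leave-one-out bound `E[P(error)] ≤ E(SV)/n`, `w_t` lower-bounds the
expected correct rate of a separable machine.

Prediction is `sign(f(x))` with the tie `f(x) = 0` assigned to background,
so segmentations are deterministic.

## Self-paced curriculum

The curriculum minimizes, alternating over the model and binary weights v,

    Σ v_i L_i + η‖w‖² − λ Σ v_i,

where `L_i` is the hinge loss and `−λΣv_i` is the hard self-paced
regularizer: its v-step has the closed form `v_i = 1[L_i < λ]`, so only
samples easier than the pace λ are trained on. λ starts at `lambda0`
(default: the 60th percentile of the warm-up losses from an unweighted
fit) and grows geometrically (`growth`, default 2) each round, admitting
harder samples until all are included and v is stable, or `max_rounds`
(default 10) is reached. A round whose v would be all-zero or single-class
falls back to `v = 1` with a warning.

The "step length" η is tied to the SVM trade-off by `η = 1/(2C)`. This
particular mapping makes each retraining step an exact block-coordinate
minimization of the objective above — the weighted-SVM primal
`½‖w‖² + C Σ v_i L_i` is the objective's model block scaled by C — so the
recorded objective trace cannot increase across either half-step (v-step
exactly, model-step up to solver tolerance). `‖w‖²` is evaluated in the
RKHS as `Σ_ij a_i a_j y_i y_j K(x_i,x_j)` over support vectors.

Robustness experiment (frozen study conditions): two unit-variance
Gaussian blobs 3.0 apart, n = 100, 10% of labels flipped; curriculum
`lambda0 = 1.0, growth = 1.3, max_rounds = 3, C = 1, γ = 0.5`. The
schedule deliberately stops before λ reaches the flipped samples' losses
(≈1.9); at it the curriculum excludes ≳90% of the flipped points, keeps
≳97% of the clean ones, and does not lose held-out accuracy to the plain
SVM (paired over 20 seeds). Annealing to completion would re-admit the
outliers and reproduce the plain SVM — the degenerate large-λ equivalence
is itself a tested property.

## Segmentation pipeline

1. **Parenchyma extraction** — Otsu threshold, discard border-touching
   components, keep the two largest, fill holes. This is a deliberately
   simple, reproducible pre-extraction step.
2. **Working ROI** — the parenchyma mask dilated by `roi_margin_px`
   (default 5). The band around the parenchyma supplies the negative class
   at the lung boundary; without it the pre-extracted ROI nearly coincides
   with the target and leaves the classifier nothing to learn.
3. **Training sampling** — balanced per class, seeded; `train_fraction`
   (default 0.1) of labelled ROI pixels, capped at `max_train_per_class`
   (default 800) to bound the kernel problem regardless of how many images
   are supplied. Pixel-dense training is quadratic in the kernel matrix
   and adds nothing on these features.
4. **Classification** — per-pixel prediction inside the ROI only; outside
   is background.
5. **Post-processing** — morphological closing (disc radius 1), hole
   filling, removal of components below `min_component_px = 50` pixels.
   Post-processing never increases the component count and is idempotent
   on clean masks.

## Evaluation metrics

With A the reference mask and B the prediction: Dice `2|A∩B|/(|A|+|B|)`
(1.0 when both masks are empty; a `denominator="union"` variant is
available but exceeds [0, 1] and is off by default), `SE = |A∩B|/|B|` and
`SP = |A1∩B1|/|B1|` over the complements — under these roles SE is the
precision and SP the negative predictive value, so the standard
recall/specificity readings `|A∩B|/|A|` and `|A1∩B1|/|A1|` are reported
alongside, clearly labelled — and MSE, the mean squared pixel difference,
which for binary masks is the disagreeing-pixel fraction. Undefined
denominators are reported as missing, never as 0.

## DCE quantification and ADC

Percent enhancement is `E(t) = 100 (S(t) − S_pre)/S_pre` with `S_pre` the
mean of the pre-contrast samples. The steepest slope (SS, %/s) is the
maximum consecutive-sample slope of E — computed on relative enhancement
so the unit matches the conventional %/s reporting and is invariant to
scanner scaling. The washout ratio is `WR = 100 (E_peak − E_last)/E_peak`,
defined only for positive peak enhancement.

Curve typing follows the three-type (persistent/plateau/washout) scheme.
The relative late change is estimated from a least-squares line fitted to
E(t) from the early-phase peak (the maximum within the first half of the
acquisition) to the end: `r = 100 (E_fit(t_end) − E_fit(t_peak)) /
E_fit(t_peak)`, thresholded at ±`tol` (default 10% of peak). On noiseless
piecewise-linear curves this equals the pointwise late change exactly; the
fit (rather than two raw samples) keeps typing stable under sampling noise
— at 2%-of-baseline noise the generated type is recovered for ≥95% of
curves, whereas raw first/last-sample differences misclassify a third of
them (a rising curve's raw maximum is its own last sample). The exact
decision thresholds of the clinical three-type convention vary between
reports; ±10% is this package's documented default and is exposed as
`tol`/`--tol`.

ADC comes from the least-squares line through `(b, ln S)`; with two b
values this is exactly `ln(S1/S2)/(b2 − b1)`. The log-linear estimator is
exact on noiseless data; under additive Gaussian noise of 1% of S0 its
mean bias on the default 3-point protocol (b = 0/500/1000 s/mm²) is ≈0.1%
over 500 repeats.

## Synthetic data

No clinical images ship with the package; all experiments run on seeded
synthetic data:

- **Lung phantom** — two ellipses (semi-axes ≈ width/5 × height/3,
  mirrored about the midline) on a darker background, optional nodule
  disc; lung 200, background 50 on a 0–255 scale, Gaussian noise
  `noise_sigma = 10` by default, plus smoothed (uniform filter, width 4)
  texture of amplitude `noise_sigma/2` inside the lung only, which gives
  the GLGCM features a discriminative signal. Lungs are rendered
  *brighter* than background purely as a phantom convention (real lung MR
  is dark; contrast, not polarity, is what the classifier uses — swap the
  two intensities to invert it). Noise is Gaussian, not Rician.
- **Enhancement curves** — piecewise-linear: rise to
  `baseline·(1+peak_enhancement)` at `time_to_peak` (default 60 s), then a
  linear late phase of `late_slope_fraction` of the peak enhancement over
  the remainder (+0.3 persistent / 0 plateau / −0.4 washout by default);
  duration 180 s at Δt = 6 s, loosely mirroring a ~30-phase dynamic
  acquisition.
- **DWI decays** — `S(b) = S0 exp(−b·ADC) + noise`, default
  ADC 1.2×10⁻³ mm²/s, b = 0/500/1000 s/mm².

All generators are bit-reproducible under a fixed seed.

**What the phantom does not show.** It has none of the coil bias,
Rician noise, motion, partial-volume or anatomy-dependent intensity
structure of real thoracic MR. Passing the phantom quality gate (mean
Dice ≥ 0.85, mean SP ≥ 0.98 on 20 default-noise images; in practice the
pipeline scores ≈1.0 at `noise_sigma = 10` and ≈0.99 even at
`noise_sigma = 50`) demonstrates that the feature/classifier/morphology
chain is implemented correctly and is robust to heavy additive noise —
not that it reaches any particular accuracy on clinical images.

## Problem sizes and numerical conventions

The documented experiment sizes are: 3 training + 20 evaluation phantoms
at 128×128 for the segmentation suite; ≤1600 training pixels per model;
20 random n ≤ 30 toys for the QP comparison; 20 seeds × 100 samples for
the curriculum experiment; 200 curves and 500 DWI repeats for the
DCE/ADC recovery rates. Degenerate inputs are handled explicitly:
constant images quantize to level 1 and yield an empty parenchyma mask
with a warning; empty masks evaluate under the conventions above;
`f(x) = 0` predicts background; an empty or single-class curriculum round
falls back to full inclusion.

## Known limitations

Strictly 2D; binary lung-vs-rest segmentation (no nodule-vs-lung class);
no DICOM; no pharmacokinetic modelling; the plain (non-self-paced) SVM is
the only in-repo baseline; group statistics on SS/WR/ADC are left to
external tools (per-curve CSV/JSON output is designed to feed them).
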