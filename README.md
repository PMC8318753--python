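# svml

Lung-field segmentation for 2D thoracic MR slices with a **self-paced,
texture-feature kernel SVM**, plus the quantitative MR measurements that
accompany solitary-pulmonary-nodule imaging: DCE time–signal curve
parameters (steepest slope, washout ratio, curve type) and the apparent
diffusion coefficient (ADC) from multi-b-value DWI.

The package is aimed at medical-image-analysis researchers who want a
small, fully reproducible, dependency-light reference implementation of
this classical pipeline — every stage is exercisable on bundled synthetic
phantoms, with no clinical data required.

## Method

**Features.** Each pixel is described by its quantized gray level i and
Sobel gradient level j (16 levels each) and by two statistics of the
gray-level/gradient-level co-occurrence matrix H(i,j) in the 5×5 window
around it: the small-gradient advantage
μ₁ = Σᵢⱼ H(i,j)/j² / Σᵢⱼ H(i,j) and the inverse difference moment
μ₂ = −Σᵢⱼ P(i,j)/(1+(i−j)²), P = H/25.

**Classifier.** A weighted soft-margin RBF-kernel SVM,
f(x) = Σᵢ yᵢβᵢ exp(−γ‖x−xᵢ‖²) + c, trained by an SMO-style dual solver
under per-sample box constraints 0 ≤ αᵢ ≤ C·vᵢ. The weights v ∈ {0,1}ⁿ
follow a self-paced curriculum: minimizing
Σᵢ vᵢLᵢ + η‖w‖² − λΣᵢvᵢ alternately in the model and v admits only
samples with hinge loss below the pace λ, which grows each round — easy
pixels first, noisy outliers last (or never).

**Pipeline.** Otsu-based parenchyma pre-extraction → feature maps →
per-pixel SVM classification inside the ROI → 2D morphological
post-processing (closing, hole fill, small-component removal).
Segmentations are scored by Dice, sensitivity, specificity and MSE.

See `docs/methods.md` for assumptions, parameter defaults and numerical
details.

## Worked example

```bash
# synthetic phantoms (image.png, mask.png per directory)
for s in 0 1 2 3; do svml simulate phantom --out p$s --seed $s; done

# train on three, segment the held-out fourth
svml train --image p0/image.png --mask p0/mask.png \
           --image p1/image.png --mask p1/mask.png \
           --image p2/image.png --mask p2/mask.png \
           --out model.svml --seed 0
svml segment p3/image.png --model model.svml --out pred.png \
             --ref p3/mask.png --metrics metrics.json
```

prints

```
trained on 1600 pixels, 47 support vectors, w_t=0.971
wrote pred.png (dice=1.0000)
```

`w_t = 1 − Ns/n` is the correct-rate discriminant weight: with 47 support
vectors among 1600 training pixels, the leave-one-out bound puts the
expected error below ≈3%. The held-out phantom (two lung-field ellipses,
Gaussian noise σ=10 on a 150-unit contrast) is recovered exactly
(Dice 1.0); at σ=50 the pipeline still scores ≈0.99.

Curve and diffusion quantification:

```bash
svml simulate tic --out . --curve-type washout && svml dce curve.csv
svml simulate dwi --out . && svml adc dwi.csv
```

```json
{
  "ss_percent_per_s": 0.8333333333333334,
  "wr_percent": 40.0,
  "curve_type": "washout",
  "peak_time_s": 60.0,
  "peak_enhancement_percent": 50.0
}
{
  "adc_mm2_per_s": 0.0011999999999999992,
  "s0_fit": 999.9999999999989,
  "r_squared": 1.0
}
```

The washout phantom rises 50% above baseline over 60 s (steepest slope
50/60 ≈ 0.83 %/s) and loses 40% of its peak enhancement by the end; the
DWI decay is fit exactly (generator truth ADC = 1.2×10⁻³ mm²/s).

The same operations are available as a library: `svml.phantom`,
`svml.glgcm`, `svml.svm`, `svml.self_paced`, `svml.pipeline`,
`svml.metrics`, `svml.dce`, `svml.io`.

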