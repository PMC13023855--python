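# Methods

`cemprep` implements a deterministic, label-independent preprocessing and
masking pipeline for contrast-enhanced mammography (CEM), a leakage-safe
patient-level evaluation protocol, and the paired statistics needed to
compare two input representations of the same cohort under identical
training conditions. This note records the models, conventions and design
choices, and what the synthetic phantom experiments do and do not show.

## The enhancement chain

Every image passes through the same fixed sequence; no stage ever receives
a class label, and the only cross-image statistic is the reference CDF.

1. **Percentile windowing.** Intensities are clipped to the image's own
   empirical 5th and 99.5th percentiles (linear-interpolation definition)
   and rescaled affinely to [0, 1]. A constant image maps to zeros.
   Windowing is strictly per-image, so it introduces no cross-sample
   coupling.
2. **8-bit quantization** with the symmetric rule `v -> floor(255 v + 0.5)`,
   chosen because it is bit-exact testable.
3. **Global histogram matching.** A 256-level reference CDF is pooled over
   the whole cohort after background exclusion (default rule: windowed u8
   intensity < 2, i.e. near-black air; an alternative rule can be supplied).
   Each image's source CDF is built under the same exclusion rule and mapped
   through the monotone LUT `v -> min{u : ref_cdf[u] >= F(v)}`; excluded
   pixels pass through the same LUT with no special-casing. Note that
   matching deliberately equalizes intensity *distributions*: absolute
   amplitude information (e.g. "this image has unusually many bright
   pixels") is removed, and only the spatial arrangement of intensities
   carries signal downstream. This is the intended behavior of a global
   harmonization stage, but it matters for interpreting the phantom
   experiments (below).
4. **Local contrast mapping (LCM).** The unsharp-style high-pass
   `d = img - gaussian(img, sigma)` with reflect padding, min-max rescaled
   to [0, 1]. Default sigma is 25 px at a 512-px working width and scales
   proportionally with image width; the scale is a package default (a
   conventional unsharp radius of ~5% of the field), exposed in config.
5. **CLAHE.** Contrast-limited adaptive equalization via scikit-image.
   `clip_limit` follows the common histogram-multiple convention (default
   2.0) and is converted to scikit-image's normalized fraction by dividing
   by the 256 histogram bins. Tile grid defaults to 8x8. Tiles are clamped
   to at least 32 px per side: below that, the integer per-bin clip count
   `int(clip/256 * tile_pixels)` collapses to its floor of 1 and CLAHE
   silently degenerates to unlimited adaptive equalization, which is not
   the configured behavior. The clamp keeps the operator's effective
   strength consistent across working resolutions.
6. **BayesShrink wavelet denoising.** Two-level db1 decomposition; the
   noise scale is estimated once from the finest diagonal subband as
   `median(|HH1|)/0.6745` and reused for every detail subband; each subband
   is soft-thresholded at `T = sigma_n^2 / sigma_x` with
   `sigma_x = sqrt(max(E[c^2] - sigma_n^2, 0))`, and a subband whose energy
   does not exceed the noise floor is zeroed. Output is clipped to [0, 1].
   A cross-check test confirms close agreement with scikit-image's
   independent implementation on a piecewise-constant phantom.
7. **Resize** to the configured output grid (default 224x224) by bilinear
   interpolation without aspect preservation, once, at the end of the
   chain. Placing the single resize last minimizes resampling passes;
   masks are resized nearest-neighbour so they stay binary.

## Breast masking

Masks are computed from the **original** (unenhanced) image: Gaussian
smoothing (2 px), Otsu threshold, largest connected component adjacent to
the detected chest-wall side (the 5%-wide border band with higher mean
intensity; ties break to the left), morphological closing with a disk of
1% of the image width, hole filling, and — on MLO views — straight-line
pectoral removal. The pectoral boundary is fit through the steepest
horizontal intensity-gradient ridge in the upper chest-wall quadrant; the
triangle between the line and the corner is removed only when the fitted
line recedes toward the chest wall and the intensity step across it exceeds
0.05 on the unit scale, which makes the operation a near no-op when no
pectoral wedge is present. The resulting mask is guaranteed to be a single
8-connected, hole-free component touching the chest-wall border. Applying
a mask zeroes non-breast pixels and leaves breast pixels untouched, so the
masked and full-field representations are bitwise identical inside the
mask.

This segmenter is a deliberately compact implementation of the standard
operator classes (intensity filtering, morphology, anatomical priors); it
does not attempt dense-tissue quantification.

## Cohort handling

All partitioning is at the patient level. A patient is malignant if any of
their images is malignant. The hold-out test set draws
`round(0.15 * n_malignant)` malignant patients uniformly plus an equal
number of benign/negative patients ("balanced sampling"), making test-set
balanced accuracy symmetric. The remainder is dealt into stratified
k-folds (default 5) by shuffling each class separately and dealing
round-robin, so per-fold class counts are within 1 of perfect
stratification. Majority-class undersampling (ratio 2.0) drops whole
patients, never single images. An audit utility asserts zero patient
overlap and that the reference-CDF rule carries no partition tags.

## Training protocol and reference classifier

The training recipe: 5 head-only warm-up epochs with the backbone frozen,
then joint fine-tuning with per-group learning rates (head 1e-4, backbone
3e-5), decoupled weight decay 1e-4, cosine annealing with T_max = 20,
maximum 30 epochs, early stopping on validation loss with patience 6, and
batch size 32 with class-balanced mini-batches (the minority class is
recycled within an epoch). Augmentation is light geometric: rotation
±10°, translation ±5%, scale 0.9–1.1, shear ±8°, horizontal flip p=0.5.
The best-validation-loss weights are restored at the end.

The reference classifier is a compact numpy CNN: three 3x3
conv/leaky-ReLU/max-pool blocks (channels 4, 8, 16) and a linear head on
the flattened 8x-downsampled feature map. The conv stack is the "backbone"
parameter group and the linear layer the "head", so the full
warm-up/fine-tune protocol is exercised. Inputs are z-scored per image over
their nonzero support; for masked images this decouples the effective
tissue contrast from the mask area (including the zeroed background in the
statistics couples the two and destabilizes training). The head is
initialized to zeros so optimization starts from calibrated uniform
logits. Optimization is Adam with decoupled weight decay. Everything is
deterministic under the construction seed.

`TrainConfig.scaled_down()` provides the profile used for desk-scale
phantom experiments: 20 epochs (2 warm-up), T_max 14, patience 5, learning
rates 6e-3/2e-3. A small randomly initialized network needs substantially
larger learning rates and a shorter schedule than fine-tuning a pretrained
backbone; these values are part of the scaled study conditions.

## The representation-comparison experiment

One phantom cohort, one split plan shared by both arms. For each
representation (enhanced full-field vs. the same images with the breast
mask applied) the protocol trains one model per fold on the undersampled
union of the other folds; all seeds derive only from (experiment seed,
fold), so both arms train under identical randomness and differ only in
their input pixels. The Youden operating threshold (ties toward the lower
threshold, favoring sensitivity) is computed once per arm from the
aggregated validation predictions and applied unchanged to the hold-out
test set, whose predictions are the mean probability over the k fold
models — a deterministic reading of "the final model" that uses all folds.
Between arms, the package reports DeLong's test on the paired test-set
AUROCs, McNemar's test on matched correctness at each arm's threshold, and
exact paired Wilcoxon signed-rank tests on fold-level AUROC and balanced
accuracy. Confidence intervals are patient-level percentile bootstrap
(default B=2000; the scaled profile uses 200).

## The phantom generator

The generator emulates the nuisance structure the pipeline is meant to
control, not X-ray physics. Geometry: a half-elliptical breast (axes
randomized ~±12–15%) attached to one lateral border, with a triangular
pectoral wedge in the upper chest-wall corner on MLO views. Tissue is a
smooth Gaussian random texture (std 0.10) on a 0.45 base level, background
air at 0.03, all on a unit scale quantized to 16 bits, so tissue occupies
roughly the 20–80% band and windowing has real work to do.

Lesions: malignant patients always carry a bright Gaussian mass (default
radius 6% of the field width — the proportion of a 10–30 mm mass on a
~200 mm field — contrast 0.35) with 6–10 radial spicules of length
1.2x radius; half of benign patients carry a smooth blob at 0.6x the
malignant contrast (CEM enhancement asymmetry between malignant and benign
lesions), the rest are lesion-free. The two morphology classes are the
learnable, mask-independent signal.

Background artifacts: every image carries a label-independent bright
"view tag" in a scanner-characteristic corner, mimicking burned-in
view/laterality annotations; in addition, with probability
`min(1, artifact_rate*(1+c))` for malignant and `artifact_rate*(1-c)` for
benign images (c = `confound_strength`), 1–3 extra markers of the same
appearance are stamped at random background positions. All artifacts lie
strictly in the air background, outside both the breast and the pectoral
wedge, so masking provably removes every label-correlated background
signal. At c=1 the extra markers are exclusive to malignant images. A
per-scanner multiplicative gain (0.85–1.15) is applied before additive
Gaussian noise (sigma 0.02) and quantization.

What the phantom does **not** emulate: dual-energy recombination physics,
BI-RADS density structure, realistic lesion texture, or scatter/detector
effects. Passing phantom tests therefore demonstrates that the pipeline's
*mechanics* are correct (masking removes exactly the background, the
protocol is leakage-free, the comparison is isolated to masking) and that
the direction of the masking effect reproduces under a controlled
confound — not that the absolute performance numbers transfer to clinical
data.

### Problem sizes for the end-to-end checks

The representation comparison runs on cohorts of 200 patients (two views
each) at 64-px resolution with `confound_strength` 0.8 and
`artifact_rate` 0.3, five experiment seeds, using the scaled-down training
profile; the determinism check uses a 30-patient cohort. These sizes were
chosen so a full study executes on a single CPU core in minutes while
keeping ~40 test images in the hold-out set.

## Numerical conventions and degenerate inputs

- Percentiles: linear interpolation between order statistics.
- Constant images: windowing and LCM return zeros; CLAHE returns the input.
- Histogram-matching LUT: `searchsorted(ref_cdf, F, side="left")`, clipped
  to [0, 255]; monotone by construction.
- Youden ties break toward the lowest threshold.
- DeLong with zero variance of the difference (e.g. identical scores)
  reports z = 0, p = 1.
- McNemar switches from the exact doubled binomial tail to the
  continuity-corrected chi-square at 25 discordant pairs; zero discordance
  gives p = 1.
- Wilcoxon drops zero differences, midranks ties, and enumerates the exact
  null over sign assignments for n <= 12 (valid under ties); no nonzero
  differences gives p = 1 by convention.
- Bootstrap resamples that lose a class (metric undefined) are skipped.
- Masks resize nearest-neighbour; images bilinear.

## Known limitations

- The pectoral estimate is a straight line; curved boundaries are
  approximated.
- The reference CDF is built on the full cohort before splitting (the
  protocol's stated convention); a stricter train-only reference can be
  built by passing only training images to `build_reference_cdf`, but the
  experiment driver does not automate it.
- The numpy reference CNN is intentionally small; it exists to exercise the
  protocol and the representation contrast at desk scale, not to model the
  capacity of ImageNet-pretrained backbones. Adapters for pretrained
  architectures can be plugged in through the same interface.
- Because the phantom couples marker presence to the label i.i.d. per
  image, the marker is genuine predictive information at test time, not
  merely a spurious cue: an ideal full-field model can combine it with the
  lesion signal and weakly dominate the masked model. In practice the two
  effects of masking separate cleanly at this problem size: the
  *stability* benefit (lower and more consistent fold-level AUROC variance
  for the masked arm) reproduces across most cohort draws, while the
  hold-out AUROC *ordering* fluctuates within the sampling noise of the
  small balanced test set (~36 images) and is not reliably positive. A
  confound that genuinely fails to generalize — the mechanism usually
  invoked for real cohorts — would require a train/deployment distribution
  shift that an i.i.d. generator cannot produce.
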