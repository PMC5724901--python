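# Methods

`retinaseg` implements a supervised pixel-classification approach to
retinal blood-vessel segmentation in color fundus photographs: the image is
enhanced by a chain of contrast and matched-filter operations, every pixel
inside the field of view (FOV) is described by a 35-dimensional texture
feature vector, an AdaBoost ensemble of shallow decision trees labels each
pixel vessel/background, and the binary map is cleaned by a small-component
rule. This note records the model, its assumptions, the tunable parameters,
the numerical choices, and what the synthetic fixtures do and do not
exercise.

## Image model and conventions

All internal images are 2-D float fields on the [0, 1] scale; coordinates
are (row, col), 0-based. The working channel is the green channel of the
RGB fundus image, where vessels show the highest contrast against the
background (red saturates, blue is dim and noisy). Vessels are *dark*
curvilinear structures of roughly Gaussian cross-section, 1–8 px wide at
DRIVE-like resolutions, on a brighter, unevenly illuminated background; the
retina occupies a roughly circular FOV on a black surround. Only FOV pixels
are classified or scored.

## Enhancement chain

Stages run in the order of the worked reference chain (configurable via
`EnhanceConfig.stage_order`):

1. **3×3 median filter** — impulse-noise removal that preserves edges.
2. **FOV border smoothing** — the FOV is grown one pixel per iteration,
   each new rim pixel receiving the mean of its 8-connected in-mask
   neighbors, repeated 50 times; this removes the strong dark-to-bright
   rim transition that otherwise triggers false vessel responses. The FOV
   itself comes from thresholding CIELab luminance (D65) at 0.10 of full
   scale, keeping the largest component and filling holes.
3. **CLAHE** — contrast-limited adaptive histogram equalization
   (clip 0.01, 8×8 tiles); the clip limit bounds noise amplification.
4. **Bilateral-filter Retinex** — illumination is estimated by a 3×3
   bilateral filter (spatial spread σ_d = 0.3 px, range spread σ_r = 0.3)
   and removed as a log-difference, R = log(I+1) − log(L+1). With these
   published spreads the estimate stays close to the input, so R is a
   small signed high-pass field; it is min–max rescaled to [0, 1] over the
   FOV for the later stages. (A constant image maps to the zero field.)
5. **Morphological enhancement** — opening with a 1-px disk, then
   `clip01(opened + tophat − bottomhat)` with a 4-px disk: for dark
   vessels the bottom-hat term deepens them, raising contrast.
6. **Background subtraction** — the image is subtracted *from* its 25-px
   median-filtered version, `clip01(median(img) − img)`: the flat
   background cancels and the dark vessels, far narrower than the kernel,
   come out bright on ≈0.
7. **Final white top-hat** (4-px disk) — keeps only small bright
   structures, i.e. the vessels.

## Matched filters

**DoG / B-COSFIRE.** The bar detector combines difference-of-Gaussian
responses sampled at prototype positions S = {(ρ_i, φ_i)} along the bar
axis. The DoG kernel is G_σ − G_{0.5σ} (both unit-normalized), which is
negative at the origin and therefore responds to *dark* bars; the pipeline
feeds it the complement (1 − x) of the bright-vessel stage-7 image, which
is algebraically identical to applying the positive-center DoG to the
bright-vessel image itself. Each point's rectified DoG response field is
blurred by a Gaussian-weighted maximum (σ′ = σ0 + αρ_i, square support
|x′|,|y′| ≤ 3σ′), shifted back to the filter center (shifts rounded to
integer pixels; exact for the even ρ defaults at axis-aligned
orientations), and the shifted responses are combined by their weighted
geometric mean with ω_i = exp(−ρ_i²/2σ̂²), σ̂ = max ρ/3 — an AND-type
combination that is zero wherever any point is silent. Rotation invariance
takes the pixelwise maximum over 12 orientations θ_k = kπ/12. The
symmetric (bar) filter uses σ = 2.4, ρ = {0,2,…,10}, σ0 = 3, α = 0.6; the
asymmetric (bar-ending) filter uses σ = 2.1, ρ = {0,2,…,18}, σ0 = 1,
α = 0.1; their responses are summed. The response threshold t defaults to
0 (off): the downstream vesselness filter and classifier make hard
thresholding unnecessary. The weighted-max blur is computed exactly in the
log domain as a grayscale dilation; convolutions use reflect padding,
shifts fill with zero.

**Frangi vesselness.** Per scale σ ∈ {1, 1.1, …, 4} the Hessian is built
from σ²-normalized Gaussian derivatives; with eigenvalues ordered
|λ1| ≤ |λ2| the response is 0 where λ2 > 0 (bright ridges have λ2 < 0) and
otherwise exp(−R_b²/2α²)(1 − exp(−S²/2β²)) with R_b = |λ1|/|λ2| (blob
discrimination, α = 0.9) and S = √(λ1²+λ2²) (structureness, β = 13); the
final map is the maximum over scales. It is applied to the combined
B-COSFIRE response (normalized to [0, 1] by its FOV peak) and its output,
again peak-normalized over the FOV, is the image on which features are
computed. The per-image peak normalization is deliberate: it is what lets
a classifier trained on one image transfer to others with different
absolute contrast (an absolute-scale variant measurably hurt held-out
discrimination). Its known cost is that a vessel-free image has its noise
stretched to full scale, so a blank retina yields a small number of
ridge-like false positives rather than a strictly empty mask.

## Pixel features (35)

Each classified pixel is described by features of the 3×3 window centered
on it (edge-replicated at borders):

* **Intensity moments (4)** — raw central moments of order 1–4 divided by
  the pixel count (not standardized), per the source formulas.
* **GLCM statistics (22)** — one co-occurrence table per window, pooled
  over the four 45° angles at distance 1, counted symmetrically and
  normalized; gray levels come from equal-width quantization to Ng = 8
  bins over the FOV intensity range. Logs are natural with 0·log 0 := 0;
  degenerate tables and zero-variance marginals map to 0. Two printed
  formulas required interpretation: Sum Variance is implemented exactly as
  printed (it squares the index against the signed Sum Entropy term), and
  Difference Variance uses the difference histogram p_{x−y} (the standard
  form; a switch restores the printed p_{x+y} variant). The inverse
  difference (moment) normalized pair follows the standard Clausi
  definitions.
* **GLRLM statistics (7)** — maximal constant-level runs along the four
  directions pooled into one table; run percentage divides the total run
  count by the window pixel count (counted once). Gray-level indices are
  1-based in the i² terms.
* **Gabor (2)** — at the first wavelength of the bank (λ ∈ {4, 8}, 8
  orientations over [0, π), aspect γ = 0.5, octave bandwidth b = 1, σ from
  the standard bandwidth relation): the quadrature amplitude (phases 0 and
  π/2) averaged over orientations, and the window-local squared energy of
  the even response averaged over orientations. Gabor maps are computed
  once per image and sampled at each pixel.

The shipped feature ordering (`TABLE_RANKING`) is the incremental
combination ranking whose first ten features (Mean, Cluster Prominence,
Run-Length Non-Uniformity, Gabor Mean Amplitude, Low Gray-Level Run
Emphasis, Difference Entropy, Variance, Sum of Squares: Variance,
Correlation II, Gray-Level Non-Uniformity) gave the best overall accuracy;
the pipeline default selects exactly those ten. The source ordering lists
Difference Entropy twice and omits Difference Variance; the duplicate slot
(rank 33) carries Difference Variance so that all 35 names appear exactly
once.

## Feature selection

The optional re-ranking uses minimum-redundancy maximum-relevance (mRMR)
with the difference criterion: greedy forward selection maximizing
MI(f; label) − mean MI(f; selected), with plug-in mutual information
(natural log) over 8 equal-width bins and ties resolved by registry order.
The quotient variant (MIQ) is available via a switch.

## Classifier

Discrete binary AdaBoost over depth-3 decision trees (depth is
configurable; "tree-based" weak learners with a few levels keep hundreds
of rounds tractable while exceeding stumps). Round t fits a tree to the
current sample distribution, computes its weighted error ε_t, votes with
α_t = ½ ln((1−ε_t)/ε_t), and reweights through Z_t = 2√(ε_t(1−ε_t)) so the
distribution stays normalized and misclassified samples carry exactly half
the mass. Training stops early at ε = 0 (α capped via ε_min = 1e-10) or
ε ≥ 0.5. The initial distribution is uniform. Fitted trees are converted
to explicit node arrays immediately; prediction, JSON serialization and
reloading all use that portable representation.

A seeded 90/10 split of the training table records the holdout
error-vs-length curve and its first minimum (`validate_length`). The full
ensemble is used for inference: at the holdout sizes of the desk-scale
study (~120 samples) the misclassification curve is flat over wide ranges,
and truncating at its first minimum would collapse the margin resolution
the ROC needs, without reducing holdout error. On large validation sets
with a genuine overfitting dip, the recorded optimum is where a production
budget should be set.

Per-image training pixels are sampled uniformly without replacement inside
the FOV (⌊fraction × FOV count⌋ per image, sub-seed = run seed + image
index); the default fraction is 0.05 (the DRIVE-style split), with 0.01
the convention for datasets without a training split. Labels come from the
truth mask at the pixel, with no tolerance band.

## Postprocessing and evaluation

8-connected components smaller than 30 px are removed, unless elongated
(region eccentricity ≥ 0.85) *and* within 2 px (Chebyshev) of a surviving
component — under strict 8-connectivity a component can never touch
another, so the 2-px reattachment radius is what gives the "elongated and
connected" exemption operational meaning (thin fragments split from a
vessel by a small classifier gap are reattached; isolated blobs are
dropped). The rule is idempotent.

Sensitivity, specificity and accuracy are the usual confusion ratios over
FOV pixels only; a zero denominator flags NaN rather than raising. The ROC
sweeps the continuous ensemble margin over its unique values; AUC is the
trapezoidal area and equals the Mann–Whitney pair statistic. The binary
decision threshold on margins is 0, ties classified as vessel.

## Synthetic fixtures

The generator emulates exactly the properties the pipeline targets: dark
branching vessel trees (curvature-bounded random walks with 2 rim-rooted
trees, per-step turn jitter σ = 0.10 rad, branch probability 0.02, slow
taper) with Gaussian cross-section of width 1–4 px and hard truth disks of
the drawn width; background green level 0.55 with vessel contrast 0.25;
smooth multiplicative illumination inhomogeneity (amplitude 0.15);
additive Gaussian noise (σ = 0.02); a circular FOV (radius 0.45·min(H,W))
on a black surround. Default frame 96×96 — a deliberately scaled-down
fundus frame that keeps the full study (8 images, 4 train / 4 test, 200
boosting rounds) around a minute of CPU. The geometry was calibrated so
the vessel-pixel fraction inside the FOV stays in [0.05, 0.20] across
seeds, bracketing real vessel densities.

What the fixtures do **not** model: pathologies (exudates, hemorrhages),
the optic disc and macula, central vessel reflexes, camera vignetting
beyond a smooth field, color calibration differences, and JPEG-like
artifacts. Passing the end-to-end study therefore shows the pipeline's
machinery is correct and self-consistent at desk scale — not that the
headline accuracies on public fundus datasets are reproduced; an optional
harness (`retinaseg train/segment/eval/cross` on dataset manifests) can
consume such datasets when available.

## Numerical choices and degenerate inputs

* Reflect padding for every convolution and morphological operation;
  edge replication for median filters and feature windows; zero fill for
  B-COSFIRE shifts.
* The B-COSFIRE geometric mean treats responses ≤ 1e-200 as exact zeros
  (AND semantics survive the log-domain fast path).
* Min–max rescales guard the constant case (range < 1e-12 maps to zeros).
* Quantization and MI discretization use equal-width bins over the
  observed (FOV) range; constant columns map to bin 0.
* mRMR and boosting are deterministic given data order, bin count and
  seed; the full pipeline is a pure function of (images, config, seed) and
  the config hash is recorded in every bundle.

## Known limitations

* Single-scale bar prototypes: very wide vessels (> ~8 px at the filter's
  native scale) are attenuated by the fixed ρ sets.
* Per-image contrast normalization hallucinates a small vessel area
  (~2% of the FOV) on pathologically vessel-free images.
* The Retinex stage with the published 3×3/0.3 parameters acts as a weak
  high-pass rather than a large-scale illumination corrector; the heavy
  lifting of inhomogeneity removal falls to CLAHE and background
  subtraction.
* Pixel-independent classification ignores label correlations; the
  component-size rule is the only spatial prior applied to the decision.
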