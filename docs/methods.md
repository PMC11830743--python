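# Methods

This note documents the models, algorithms and design choices in
`gclspace`: what is simulated, what is fitted, which constants matter, and
what the synthetic world does and does not establish about real data.

## 1. The scientific setting

Glaucoma, optic neuritis (ON) and non-arteritic anterior ischemic optic
neuropathy (NAION) damage retinal ganglion cells in spatially distinct
ways, visible as thinning of the macular ganglion cell + inner plexiform
layer (GCIPL) on OCT. Healthy GCIPL is thickest in an elliptical annulus
roughly 4–6° from the fovea; glaucoma preferentially thins the inferior
half of that annulus, NAION the superior half, and ON thins it diffusely.
`gclspace` implements a booster variational autoencoder (bVAE) that
compresses a 200 × 200 px (6 × 6 mm) GCIPL thickness map into

* two **display latents** (d1, d2) that are anatomically anchored so the
  latent plane reads like a clinical chart (inferior thinning upper-left,
  normal/thickening upper-right, diffuse lower-left, superior lower-right),
* eight **booster latents** (b1…b8) that carry residual detail,
* a fovea-location estimate (f_x, f_y) and a poor-quality exclusion
  probability (f_EXC).

A display decoder reconstructs a fovea-centered crop from (d1, d2) alone
(y_D); a booster decoder, conditioned on all ten latents, adds a residual
y_B, so the full reconstruction is exactly y = y_D + y_B. The two decoders
are co-trained and share no parameters.

## 2. Synthetic GCIPL phantom

Clinical cohorts are not shipped; a seeded generator emulates the
anatomy the encoder must exploit. In elliptical-polar coordinates
(ρ, θ) about the (possibly decentered) fovea, with a 1.2 horizontal :
vertical aspect and ρ in vertical-equivalent millimetres:

    thickness(ρ, θ) = F + A · e^{−(ρ − r₀)² / 2w²} · M(θ) + ε

with floor F = 40 µm, crest eccentricity r₀ = 1.15 mm, ring width
w = 0.55 mm, and peak amplitude A = 53.3647 µm calibrated so the noise-free
normal template's six-sector annulus mean is exactly 78.68 µm (the
normative cohort summary it emulates). The angular mask is
M(θ) = 1 − severity · w(θ), where w(θ) is a raised-cosine bump over the
affected hemifield with 20° shoulders (w ≡ 1 for diffuse loss, 0 for
normal eyes); severity ∈ [0, 1] is the fraction of maximal loss in the
affected region. Noise ε is i.i.d. Gaussian (σ = 3 µm) smoothed with a
1-px Gaussian kernel, mimicking spatially correlated segmentation error;
σ is the pre-smoothing value. Values are clipped at 0; OS eyes are
mirrored horizontally at generation and re-mirrored to right-eye
orientation at load.

Artifacts: `erm_focal_thickening` adds a +30 µm Gaussian blob
(σ = 0.5 mm) in the superior-temporal quadrant (epiretinal-membrane-like);
`poor_quality` adds extra noise (doubling the pixel-noise sd) and a
rectangular dropout to 0 µm covering ≥ 15 % of pixels, and flags the scan
QC-bad.

**Cohort calibration.** Because the ring factor and the angular mask
separate over the annulus, the expected sector-mean deficit is
A·G·η·E[severity], with G the annulus mean of the ring Gaussian (0.7248
measured on the rendered grid) and η the angular mass of the bump (4/9 for
a hemifield bump, 1 for diffuse). Class severity Beta distributions
(concentration 6) were solved analytically to land 500-eye cohorts on the
emulated class summaries: glaucoma mean severity 0.7678 (85 % inferior /
15 % superior pattern), NAION 0.3868 (superior), ON 0.1911 (diffuse). The
glaucoma mean severity is high because the emulated population is a
tertiary-care cohort whose mean thickness (65.5 µm) sits 13 µm below
normal. Per-eye realism jitters: floor sd 4 µm, peak sd 2 µm, ring radius
sd 0.04 mm, ring width sd 0.03 mm, fovea decentration uniform within
±15 px (±20 px in the training pool).

Longitudinal series progress linearly: severity_k = min(1, s₀ + k·rate).
An eye is labeled `beyond_normal_range` iff its final severity exceeds
0.2 — a crisp synthetic stand-in for expert longitudinal review, not a
reconstruction of any clinical rule. NAION series may start with transient
annulus-peak inflation (×1.25) emulating disc edema before atrophy.

What the phantom does **not** model: raw B-scans and speckle, layer
segmentation, vessel shadows, demographic covariates, eye-specific annulus
shape beyond the global 1.2 aspect, and non-linear progression. Passing
tests therefore demonstrate the pipeline's correctness and its behavior
under the assumed geometry, not clinical performance.

## 3. Elliptical annulus sector grid

The Cirrus-equivalent grid: vertical inner/outer radii 0.5/2.0 mm,
horizontal 0.6/2.4 mm, six 60° wedges (SN, S, ST, IT, I, IN) of the
elliptically normalized angle (coordinates scaled by 1/h_outer, 1/v_outer,
so wedge boundaries are straight lines through the fovea). S and I are
centered on the vertical meridian; nasal/temporal is defined in right-eye
convention (nasal = +x). Pixels are assigned by center membership; the
resulting quantization error in sector means is below 0.1 µm at 0.03 mm
pitch. The annulus mean equals the pixel-count-weighted mean of the six
sector means exactly, and the unweighted mean of sector means (the
chart-style summary used throughout) differs only by pixelization because
the six wedges have equal area. Hemifield ratios r_inf, r_sup are the
pixel-weighted means of (IT, I, IN) and (ST, S, SN) divided by a
reference of 80 µm.

## 4. Booster VAE

**Architecture.** Convolutional encoder of stride-2 residual blocks
(conv3×3 → ReLU → conv3×3 + projected skip), followed by a dense trunk and
four heads: latent Gaussian parameters (means and log-variances for d and
b), fovea regression (normalized image coordinates), and an exclusion
logit. Each decoder is a dense expansion followed by nearest-neighbor-2×
upsampling residual blocks and a 3×3 output convolution. The default
configuration is 5 stages (16→256 channels) on 200 × 200 inputs with
160 × 160 crops; the reference harness uses 3 stages (4/8/16 channels,
dense 80) on 64 × 64 inputs with 48 × 48 crops — 48 is the largest
multiple of 2³ below the 0.8 crop fraction. Thickness is normalized by
150 µm and clipped to [0, 1.3]; outputs are de-normalized (and clipped at
0 only where a single map is rendered for display, so the additive
identity y = y_D + y_B is preserved exactly elsewhere).

**Losses.** With QC-good mask m over the batch:

* reconstruction: mean squared error in normalized units of (y_D, x_C)
  and (y, x_C), where x_C is the 0.8-fraction crop centered on the true
  fovea (edge-replicated at borders);
* KL of both latent groups against N(0, I), closed form
  0.5·(μ² + e^logvar − 1 − logvar);
* anatomical anchors: (d1 − t(r_inf))² + (d2 − t(r_sup))² with the affine
  map t(r) = 10·(r − 0.8), so the normative ratio (≈ 0.98) anchors near
  +1.8 and a half-thinned hemifield near −3; the anchors use the sector
  profile of the input at the true fovea;
* fovea: squared error of normalized coordinates;
* exclusion: binary cross-entropy from the logit, label 1 = poor quality.

Poor-quality samples contribute **only** the exclusion term; all other
terms are masked for them. Weights: recon 1.0 each, kl_d 10⁻³,
kl_b 10⁻⁴, anat 0.5 each, fovea 2.0, exclusion 0.1. The booster KL is
deliberately weak: the booster's attainable reconstruction gain on these
phantoms is of order 10⁻³ in normalized MSE, and any KL weight above that
scale makes "encode nothing" the optimum (posterior collapse). For the
same reason the log-variance head biases are initialized negative (−2 for
d, −4 for b): with log-variances starting at 0 the sampled latents are
unit-variance noise, the decoders learn to ignore them, and the mean paths
then receive no gradient. The fovea weight of 2 keeps the mean signed
fovea error within a pixel at canonical resolution.

**Sampling.** Reparameterized draws from both latent groups during
training; posterior means (temperature 0, fully deterministic) at
inference.

## 5. Training

Adam (lr 10⁻³), batch 64, at most 40 epochs, early stopping on the
validation total loss with patience 8 and restoration of the
best-validation weights; a non-finite loss aborts training with the best
checkpoint retained. Splits are subject-level via a salted MD5 hash of the
subject id (validation fraction 0.15), so no subject ever appears on both
sides. A single integer seed controls initialization, shuffling and
sampling; it is recorded in the checkpoint. The network runs on a small
reverse-mode autodiff engine written in numpy (tape of vector-Jacobian
products; convolution lowered to one GEMM per kernel tap), whose gradients
are verified against central finite differences to 10⁻⁴ relative error in
the test suite.

The reference harness trains on 2 000 phantoms (classes mixed, severity
near-uniform, ±20 px decentration, 8 % poor-quality, 5 % ERM) rendered at
200 × 200 and downsampled to 64 × 64. These problem sizes are the
package's standard experiment; the full 200 × 200 configuration is
supported but not exercised by the default suite.

## 6. Latent-space montage, contours, trajectories

The montage decodes one display-only tile per node of an inclusive
(d1, d2) grid, default (−5, −5)…(8, 4) at step 1 (14 × 10 tiles), rendered
on a shared 0–120 µm color scale. Normative contours use a
product-Gaussian KDE with per-dimension Scott bandwidth (floored at 10⁻³;
degenerate point sets trigger the floor with a warning); contour levels
are iso-proportion: the 0.5 contour bounds the highest-density region
containing 50 % of the probability mass, computed by thresholding the
gridded density against its sorted cumulative mass. Trajectories are
per-visit (d1, d2) polylines with inter-visit intervals annotated in
months (days / 30.44).

## 7. Classification of thinning status and cause

Feature rows take the display latents (optionally plus booster latents)
at three visits: first, last, and the visit minimizing
|gap-to-first − gap-to-last| (ties to the earlier visit); QC-failed visits
are dropped first and eyes with fewer than three usable visits are
excluded with a logged reason. XGBoost with max depth 15, learning rate
0.3 and the softprob objective (the binary task is 2-class softprob), 200
boosting rounds with early stopping on a validation fold when provided,
single-threaded for reproducibility. Evaluation splits are subject-level.
ROC/AUC are one-vs-rest; an absent class yields a NaN sentinel. The
"booster features do not hurt" property is tested by a paired bootstrap of
the per-class AUC difference. In the longitudinal cohorts ERM artifacts
are more frequent in the glaucoma class (15 % vs 2 %), so booster latents
— which absorb the artifact — carry class-relevant signal there.

## 8. Evaluation metrics

Image RMSE in µm. SSIM with an 11-px Gaussian window (σ = 1.5),
K1 = 0.01, K2 = 0.03 and a fixed dynamic range of 150 µm (not per-image),
so scores are comparable across eyes; the implementation is independent
of, and tested against, scikit-image's. Sectoral signed differences
(original − reconstruction) are aggregated per sector over a cohort.
Display-only vs full reconstruction errors are compared with a paired
one-sided Wilcoxon signed-rank test; the harness requires p < 0.01 in the
improving direction. Fovea error is reported as signed mean ± sd per axis
in canonical 200-px units. QC metrics are standard confusion-matrix rates
at a 0.5 threshold.

## 9. Numerical and degenerate-case choices

* Maps with non-finite pixels are filled nearest-neighbor at load and
  flagged QC-bad; an all-NaN map is a hard error.
* A fovea so decentered that the outer annulus ellipse leaves the image
  sets a `clipped` warning flag on the profile; an empty sector yields
  NaN, never a silent zero.
* The additive identity y = y_D + y_B is exact by construction; tests
  compare `y` against the recomputed sum bit-for-bit.
* Tie-breaks: equidistant middle visits resolve to the earlier visit;
  sector membership of boundary pixels follows the floor of the
  normalized angle.
* 16-bit TIFF export quantizes at 0.1 µm per unit; round-trips are
  bit-exact for maps already on that grid.

## 10. Known limitations

* The anatomical anchors make the latent layout largely supervised by the
  hemifield ratios; on real data, where the "true" ratio is itself noisy,
  the latent spread would be broader than the phantom results suggest.
* The harness model is small and trained at 64 × 64; reported
  reconstruction errors are not comparable to clinical-scale numbers.
* The booster's benefit depends on residual structure (per-eye geometry
  jitter, artifacts); phantoms with no unexplained structure would show no
  booster gain.
* XGBoost results use a single split and seed; no hyperparameter search
  is performed.
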