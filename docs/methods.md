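# Methods

`spectramir` implements a complete in-silico version of a multiplexed
single-molecule microRNA quantification workflow based on compact spectral
(prism-dispersed) imaging and supervised crop classification. This note
documents the models, the defaults and why they were chosen, and what the
synthetic benchmark does and does not demonstrate.

## Dispersed dual-spot PSF model

A probe carries two fluorophores separated by ~10 nm — far below the
diffraction limit — so both emitters image at the same physical position.
A pair of rotatable dispersing prisms shifts each emission wavelength along
one image axis (rows, by our convention; longer wavelengths move downward).
A dye's image is therefore the sum over its emission spectrum of isotropic
Gaussians of standard deviation σ = 1.15 px, each displaced by the
dispersion calibration d(λ); a dye *pair* produces a dual-spot PSF whose
interspot distance encodes the color combination.

Rendering steps per dye:

1. effective emission = emission spectrum × multiband filter transmission
   (shared 1 nm grid, 400–850 nm; CSV inputs are linearly resampled);
2. the reference dispersion curve is scaled by sin((180 − RPA)/2), where RPA
   is the relative prism angle (RPA = 180° cancels dispersion entirely);
3. per-wavelength Gaussians (amplitude ∝ filtered emission, truncated at
   5σ) are summed, the total intensity is normalized to 1 analytically
   (mass 2πσ² per unit-amplitude Gaussian), and the image is multiplied by
   the excitation efficiency — the excitation-spectrum value at the laser
   line; with several lasers we take the maximum single-line value, since
   the brightest line dominates a simultaneous-excitation exposure;
4. the two dye images are summed; the interspot distance is measured on the
   dispersion-axis profile by sub-pixel peak finding (log-parabolic
   three-point interpolation, exact for sampled Gaussians; plateau maxima
   are reported at the plateau centre).

The rendered patch total equals the excitation efficiency only up to
truncation at the patch edges; the anchored top blob at row 2 loses ≈1.5%
of its upper tail by construction. Axial chromatic focus effects are not
modeled.

### Fixtures

Vendor spectra are not shipped. The fixture library provides parametric
skew-normal excitation/emission shapes approximating AF405/488/568/647-class
dyes, a five-band emission filter (bands 425–455, 500–545, 580–635,
665–725, 780–840 nm with raised-cosine edges), and a monotone-cubic
dispersion calibration spanning ≈23 px across 400–850 nm at RPA 177.5°, the
default acquisition angle. The knots were placed so the default three-class
panel — miR-15b = (488, 568), miR-155 = (488, 647), miR-126 = (568, 647) —
yields interspot distances of ≈4.9, 13.3 and 8.5 px, keeping every pairwise
distance gap above 3 px (≳2.6σ), which is what makes the panel separable by
a distance-driven classifier. All fixtures are user-replaceable via
`wavelength_nm,value` CSVs.

## Synthetic scenes

Each 256×256 px field of view (FOV) carries an exact number of molecules
per class at rejection-sampled positions (margin 24 px; pairwise separation
≥ 8 px between top-blob anchors), plus spurious single-Gaussian blobs at
20% of the molecule count — stand-ins for autofluorescent debris and
nonspecific binding. Ground-truth positions are the *top*-blob centres;
rows are integers and columns half-integers so patches paste at integer
offsets without resampling.

Defaults, chosen to emulate "hundreds of molecules per FOV" at a
desk-scale image size: 250 molecules/FOV in mixtures, total molecule
brightness log-normal with median 2000 photons (σ_log = 0.3), background
20 photons/px modulated ±30% by a smooth low-order polynomial shared
across FOVs, Poisson shot noise at 1 photon/unit, and additive Gaussian
read noise of mean 0.3 and variance 4 counts². These give top-blob peak
SNR ≈ 20. Real brightness and background distributions of the instrument
are unpublished; these values are plausible, tunable, and not claimed to
match any specific hardware.

Because the background field is identical across FOVs, pixel-wise median
subtraction removes it exactly; an optional per-FOV jitter exercises the
pruning stage instead.

## Preprocessing

1. **Median background**: per-pixel median across all FOVs, subtracted.
2. **FOV pruning**: per FOV, the mean of positive residual pixels and the
   absolute mean of negative residuals are combined by their maximum; the
   FOVs are ranked and the best `ceil(keep_fraction · n)` kept
   (`keep_fraction` = 0.8, ties broken by FOV index). The quantile rule
   realizes an "about 80% kept" outcome without a hand-tuned constant, and
   one shared threshold on the max-statistic avoids a second free
   parameter.
3. **Denoising slot**: identity by default. The pipeline is designed to
   function without a denoiser; small Gaussian/median smoothers are built
   in and an external learned denoiser (e.g. a self-supervised network)
   can be registered through an array-in/array-out plugin contract.

## Detection and crops

Blobs are found per FOV by a difference-of-Gaussians band-pass (σ = 1, 2),
local maxima above a robust threshold (median + 5 × 1.4826·MAD of the
band-passed image — a reproducible statistical replacement for visually
tuned thresholds), followed by least-squares refinement of an isotropic 2-D
Gaussian in a 7×7 window. Fits narrower than 0.6 px are rejected as
single-pixel artifacts; plateau maxima (noiseless blobs centred between
pixels) are deduplicated before fitting. Localizations closer than 2 px are
merged at their mean position — single linkage iterated to a fixed point so
merging is idempotent — and the merge radius is validated against the
panel's minimum interspot distance. A 24×10 px crop is cut around *every*
surviving localization (blob at row 2, columns 4–5 straddling it; boxes
leaving the FOV are discarded). Both blobs of each molecule produce crops;
only the top crop contains the whole barcode, so at least half of all crops
are expected to be non-barcode "noise" crops.

## Classification

Crop preprocessing: subtract the median of the crop-edge pixels; discard
the crop if any of the four anchor pixels (rows 1–2 × cols 4–5, the "four
central pixels of the top blob") becomes negative; zero other negatives;
divide by k = anchor mean (making the anchor mean exactly 1; k is kept as
a feature); fold the crop onto its mirrored right half (240 → 120 values).
Preprocessing is scale-invariant by construction.

Training labels come from ground truth: a crop is labeled with a molecule's
class iff its anchor localization lies within 1 px of that molecule's
top-blob truth position; everything else is noise. This replaces the visual
tagging GUI of a real deployment with a deterministic rule.

The labeled set is augmented ×3 with weak pixel-wise Gaussian noise (SD =
5% of each crop's anchor mean). Augmentation covers all labeled crops, not
only barcode crops, keeping the size factor exact. Features are the 20
leading PCA coefficients of the 120-value half-crops plus k, jointly
standardized to zero mean and unit variance over the training set. A
4-class RBF-kernel SVM (C = 10, γ = 1/(21·Var), 5-fold Platt-style
probability calibration, seeded 90/10 stratified train/validation split)
is trained on the standardized features. `predict` is *defined* as the
argmax of the calibrated probability vector so the label and probability
interfaces can never disagree. Per-class precision–recall curves are
produced by sweeping a threshold on the class probability over [0, 1];
AUC-PR is the average precision of the ranking.

## Calibration and uncertainty

For true class i and predicted class j, the labeled subset of the 1:1:1
calibration mixture gives a 4×4 confusion matrix C_ij. Predicted counts h
relate to true counts h′ by h = Ĉh′, which holds identically only for the
generative normalization Ĉ_ij = P(pred = i | true = j) (columns index true
classes and sum to 1); that convention is adopted, with the literal
column-normalization formula available behind a flag for comparison.
Unconfusion solves Ĉh′ = h (condition number checked against 1e8; negative
components, possible under a noisy Ĉ, are clipped to zero with a warning
rather than erroring, because the downstream normalization requires
non-negative counts). Because Ĉ is column-stochastic, Σh′ = Σh.

The mixture composition is the element-wise ratio of the corrected mixture
counts to the corrected counts of the 1:1:1 reference, noise class dropped,
normalized to sum 1. Any per-class multiplicative bias shared by the two
experiments — capture efficiency, competitive binding, detection and
classifier bias — cancels exactly in this ratio; this algebraic fact is
enforced by tests.

Uncertainty: 10,000 repetitions, each drawing a *pair* of confusion
matrices whose rows are multinomial resamples of the observed rows
(per-row resampling preserves the labeled per-class totals), perturbing
both raw count vectors per class with Gaussian noise of SD = 5% of the
mean, unconfusing each vector with its own resampled matrix, and recording
the normalized composition. A 2-D Gaussian is fit to the ensemble in
isometric ternary coordinates (orthonormal basis of the sum-zero plane);
the reported composition is the ensemble mean and the per-class 95%
half-widths are 2·sd of the covariance projected onto the
centroid-to-vertex directions v_k (under which p_k = 1/3 + v_k·x, so the
projection is exact, not approximate). Degenerate repetitions (singular
resample or a non-positive reference component) are redrawn with a bounded
retry budget and counted.

## Benchmark problem sizes

The standard benchmark uses, per class, 4 training FOVs of 250 molecules
(≈1,700 labeled crops per single-species dataset after the 80% FOV
pruning; training scenes deliberately share the mixtures' molecule density
so the classifier is trained under deployment-like crowding), and two
mixtures of 25 FOVs × 250 molecules (≈5,000 molecules
and ≈9,500 crops each after pruning): a 1:1:1 calibration mixture, whose
first 4,000 crops provide the confusion matrix, and a blind 2:5:3 test
mixture. These sizes make the whole experiment run in about a minute on a
single CPU while keeping every count large enough for the multinomial
uncertainty model to be meaningful. The interval width is dominated by the
confusion-matrix sampling noise and the 5% count perturbation, not by the
total crop count: the composition estimate is invariant to rescaling
either count vector, so enlarging the mixtures shrinks only the (already
subdominant) counting contribution.

## What the synthetic benchmark shows — and what it does not

Passing tests demonstrate that the *computational* pipeline is correct and
self-consistent: detection finds the rendered blobs, the classifier
separates barcodes whose distance gaps exceed ≈3 px at SNR ≈ 20, and the
confusion-matrix/reference calibration recovers a known 2:5:3 composition
within its own confidence intervals, with worst-case 95% half-widths of a
few percentage points. The generator does not emulate axial chromatic
aberration, focal drift, photobleaching kinetics, camera gain structure,
competitive-binding chemistry, or spatially correlated noise, so passing
tests bound algorithmic — not instrumental — error. The noise-composition
of a mixture (which blob shapes populate the noise class) differs slightly
between calibration and test mixtures with different ratios; this
second-order effect is not corrected, mirroring the caveat that error
sources outside the model may persist.

## Numerical choices and degenerate inputs

- Wavelength grid 1 nm; Gaussians truncated at 5σ (speed vs fidelity).
- Interspot distance of a single-peak profile is 0 (identical dyes).
- A zero excitation efficiency renders a zero image with a warning rather
  than erroring, so panel exploration can include unexcitable dyes.
- Flat crops (anchor mean 0 after background subtraction) are rejected
  with a reason, and rejected crops are *labeled noise* at classification
  time so count vectors always cover all crops.
- Empty confusion rows/columns raise for unconfusion but are NaN-flagged
  (never silently 0) in precision/recall.
- All randomness flows through per-stage seeds derived by hashing the
  global seed with the stage name (stable across runs and platforms;
  always below 2³¹).
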