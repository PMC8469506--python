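# Methods

This note records the scientific and numerical choices behind the package:
what each component assumes, which parameters matter, what the synthetic
world does and does not emulate, and where the design was genuinely open.

## Spectral reconstruction

The conversion module maps a 3-channel endoscopic pixel to a 401-band
reflectance spectrum (380–780 nm, 1 nm). It is calibrated on a 24-patch
color target observed by both camera and spectrometer.

**Feature expansion.** The regression form is a design choice: encoded RGB is
first linearized (the standard piecewise sRGB curve by default; pure-gamma
and identity transfers are available, since endoscope transfer behavior is
rarely documented), then expanded into all monomials r^a g^b b^c with
a+b+c ≤ degree. Degree 3 (20 features) is the default — the standard
operating point for 3→N spectral super-resolution from a 24-sample target:
enough curvature to absorb mild camera nonlinearity, few enough parameters
that 24 samples still constrain the fit.

**Ridge penalty.** λ = 1e-6 by default. With 24 samples and 20 features the
normal equations are close to ill-conditioned; the tiny penalty stabilizes the
solve without visibly biasing the fit (mean patch RMSE ≈ 5×10⁻⁵ on the
synthetic target). λ = 0 falls back to the minimum-norm least-squares
solution and flags rank deficiency.

**Clipping.** Reconstructed reflectance below 0 is clipped to 0 (physical
constraint); the clipped fraction is recorded on the cube rather than
silently discarded.

**Modalities.** WLI and NBI share the machinery; each modality gets its own
fitted matrix and the modality travels as a metadata tag on matrices and
cubes.

## PCA reduction

Spectra are mean-centered but not variance-scaled: every band is a
reflectance in the same units, so correlation-based scaling would only
amplify noise in dim bands. Covariance uses 1/(n−1). The implementation sits
on scikit-learn's full-SVD PCA with one convention added: the
largest-magnitude element of each loading is made positive, so bases (and
downstream plots and fixtures) are reproducible regardless of input order or
solver sign whims. Default k = 3, with the first two scores used for
separability displays.

## Detection components

- **Matching.** Two-step rule: each ground truth first claims its argmax-IoU
  default box (ties to the lowest index), guaranteeing every lesion at least
  one positive anchor even under poor overlap; then any unclaimed default
  whose best IoU reaches the threshold (default 0.5) becomes positive for its
  argmax ground truth.
- **Loss.** Total = (L_conf + α·L_loc)/N, defined as 0 when N = 0. α is not
  standardized anywhere authoritative; the default is 1. L_conf is softmax
  cross-entropy over positives plus hard negatives mined at 3:1 (highest
  per-default confidence loss first, index tie-break); L_loc is smooth-L1 on
  offsets coded as (Δcx/w, Δcy/h, log w-ratio, log h-ratio) scaled by
  variances (0.1, 0.1, 0.2, 0.2).
- **NMS.** Greedy, per-stage, descending score with index tie-break,
  suppression at IoU ≥ 0.45. Verified against an exhaustive maximal-subset
  oracle on small instances.
- **Image-level call.** Detections below the score floor (0.5) are ignored;
  no surviving detection means a normal call; otherwise the stage of the
  highest-scoring detection wins, with score ties broken toward the more
  severe stage (the clinically conservative choice). How the original
  clinical system derived image-level stages is not documented; this rule is
  an explicit interpretation.
- **Scorer contract.** The trained VGG-16-Atrous SSD is deliberately out of
  scope (training data unavailable, GPU-scale). Anything mapping an
  image/cube to per-default confidences and offsets plugs in; the package
  ships a deterministic ground-truth stub that exercises the full
  decode→NMS→call path and can inject a seeded stage-confusion rate for
  evaluation tests. Original training hyperparameters (batch 32, lr 5e-4,
  80k steps) are retained as config defaults for provenance only.

## Evaluation conventions

Rows are predicted stage, columns true stage, order (normal, low-grade,
high-grade, invasive). Percentages are rounded half-up to integers and kappa
to two decimals — the only convention consistent with every cross-checkable
cell of the bundled reference tables. The reported F1 is the harmonic mean of
the *rounded* sensitivity/precision pair (again the only reading that
reproduces every printed F1 cell); the unrounded harmonic mean is returned
alongside. Zero-denominator metrics raise and render as NA, never as 0.

The bundled `nbi_spectrum` matrix is shipped exactly as printed in its
source even though it is internally inconsistent (it sums to 150, not the
stated 153 test images, and implies 93% accuracy rather than the stated
91%); only its normal column is used in cross-checks. The source text also
states kappa increases of "0.8 and 0.3" where its own values give 0.08 and
0.03 — an evident decimal slip, documented here rather than corrected.

## The synthetic world

The generator emulates what the clinical study measured but cannot share.

- **Reflectance family.** Every synthetic spectrum — the four tissue-stage
  means and the 24 color-target patches — is a nonnegative combination of
  three broad Gaussian bumps (centers 430/550/670 nm, σ = 65 nm), clipped to
  [0, 1]. Real reflectances are well described by low-dimensional smooth
  linear models, and a three-channel camera can pin down at most three
  spectral degrees of freedom: the rank-3 family is precisely the prior under
  which color-target calibration is well posed. This is a stated-world
  choice, not a tuned one — with a higher-dimensional family the RGB→spectrum
  problem is metameric and no regression could succeed.
- **Tissue stages.** Each stage mean activates 2–3 bumps with fixed base
  weights (healthy mucosa broad and red-tinted, advancing dysplasia darker
  with shifted balance) plus ±10% seeded jitter. Pixel spectra add a smooth
  low-frequency spatial field (amplitude 0.03 reflectance) and iid Gaussian
  band noise (σ = 0.01), clipped to [0, 1.5]. Stage means must separate by
  pairwise RMSE > 3× the noise σ or generation refuses.
- **Cameras.** WLI: broad Gaussians at 610/545/465 nm (σ 55/50/45 nm). NBI:
  narrow bands at 415 and 540 nm (σ = 12 nm, ≥90% of each channel's mass
  within a ≤60 nm window), the hemoglobin absorption bands used clinically;
  the red channel reuses 415 nm at reduced gain to give the characteristic
  false color. All parameters are fictional — no acquisition specifications
  exist for the original endoscopes. Channels integrate sensitivity ×
  reflectance, scale by exposure (0.9), clip to [0,1] and apply the sRGB
  transfer.
- **Scenes.** Elliptical lesions (rotated, fully inside the frame) on a
  normal background; the ground-truth box is the ellipse's tight axis-aligned
  bounding box. Augmentation covers flips and 90°-multiples with consistent
  box transforms.

**What a green test establishes.** The synthetic world validates the
*machinery* — calibration, reconstruction fidelity on a low-rank smooth
family, matching/loss algebra, end-to-end bookkeeping — not clinical
performance. It has no specular highlights, no illumination falloff, no
mucus/motion artifacts, no intra-stage biological variability beyond a
scalar field, and lesions are clean ellipses. The published clinical
accuracies are reproduced only from their printed confusion matrices, never
from training.

## Numerical notes

- Half-open pixel boxes, origin top-left; degenerate boxes rejected at
  construction.
- The matching, hard-negative selection and NMS all break ties by lowest
  index, making every pipeline stage deterministic for a fixed seed.
- The smooth spatial field is a 5×5 standard-normal grid upsampled by cubic
  spline and normalized to unit peak, so "amplitude" is a true maximum
  deviation.
- Scene rendering uses float32 cubes (a 128×128 scene is ~26 MB at 401
  bands).
- PCA on rank-deficient collections: eigenvalues beyond the data rank are
  reported as ≈0 rather than dropped.

## Known limitations

- The stub scorer bypasses learned confidence calibration; score values are
  saturated softmax outputs, so score-threshold behavior is not
  representative of a trained network.
- The NBI camera cannot see the 670 nm basis direction well; spectral
  reconstruction under NBI is intrinsically worse than WLI (a physical
  property of narrow-band sensing, visible in the synthetic world too).
- `augment` currently covers the flip/rotation group only; photometric
  augmentation is out of scope.
- Confidence intervals on the diagnostic metrics and localization-aware
  detection metrics (mAP) are deliberately not implemented.
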