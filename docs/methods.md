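# Methods

## Blur model

Linear motion blur is modeled as convolution with a uniform line
segment: `g = f * h + η`, where `h` carries weight `1/n` on each of its
`n` taps along the line at direction θ and `η` is additive Gaussian
sensor noise. The kernel is rasterized nearest-pixel with one tap per
step of the major axis, so the tap count is `n = round(L·max(|cosθ|,
|sinθ|))` and the segment's *physical* extent along the motion line is
L pixels regardless of direction. For axis-aligned directions this is
exactly L taps of value 1/L. The physical-length convention matters:
the frequency-domain signature of the blur — sinc nulls spaced
`d = N/L` bins apart — responds to the segment's extent, and a
convention with L taps on the diagonal (extent L√2) would make every
diagonal length estimate come out √2 too large.

Directions live on the half-turn `[0°, 180°)`, measured
counterclockwise on screen from the +x axis (image y grows downward).
`length = 1` is the identity kernel. Convolution uses reflective
padding by default (no artificial dark borders in the spectrum); a
`wrap` mode exists for exact frequency-domain equivalence in tests.

Spectra are computed as `log(|DFT|² + ε)` with DC centered, after a
separable Hann taper that suppresses the cross-shaped boundary
artifact. The floor ε is *relative*: 10⁻¹² times the spectral maximum.
A natural image's power spectrum spans far more than six decades
between DC and the mid-frequency background, so a larger floor (10⁻⁶
was tried first) clips the spectrum everywhere past the first null and
erases the very structure the length estimator fits.

## Direction estimation

The estimator accumulates the (lightly smoothed, min-shifted) log
spectrum along lines `x cosφ + y sinφ = ρ` with a Radon transform
restricted to an annulus around DC, sums the result over
`ρ ∈ [−margin, margin]` per angle (a `(2·margin+1)`-tap box filter
across offsets), and takes the argmax over a 1° angle grid; the motion
direction is the ridge angle's orthogonal. Ties take the smallest
angle.

Geometry defaults (fractions of the smaller spectrum dimension):

| parameter | default | rationale |
|---|---|---|
| outer radius | 0.49·min(H,W) | the ridge's angular width scales as d/radius, so a larger circle sharpens the angular response; 0.25 leaves multi-degree errors at short lengths |
| inner radius | 0.0625·min(H,W) | the innermost bins carry spectral noise but almost no directional contrast (the sinc is flat there) |
| ρ margin | 12 | pooling parallel offsets averages the chi-square noise of individual spectral bins; much larger margins start crossing nulls at the longest motion lengths |
| smoothing σ | 2.0 px | Gaussian smoothing of the log spectrum, same statistical-pooling rationale as the ρ summation |
| θ step | 1° | below the sub-degree mean error the estimator reaches |

These were calibrated once on the synthetic texture generator (the
per-bin log-spectrum noise of a broadband texture is the binding
constraint; real photographs behave similarly or better) and then
frozen.

## Length estimation

The spectral profile along the motion direction is fit by
`s(t) ≈ background(t) + log(sinc²(t/d) + ε)` in the least-squares
sense, scanning d on a coarse grid and refining by golden section;
the motion length is `N/d`, optionally snapped to the protocol's odd
grid {1, 3, …, 15}. Samples within 3 px of DC are excluded (DC spike).
Two background treatments:

* **log** (default): a global `c + a·log(1+|t|)` term with closed-form
  coefficients, absorbing the ~1/f radial decay of broadband spectra.
* **local**: both profile and candidate model are high-pass filtered by
  subtracting a Gaussian-smoothed copy (σ = 0.35·d), so only the
  periodic null comb is compared. This is the robust choice for
  spectra whose background is not log-linear — faces — at the price of
  discarding envelope evidence.

Two profile readers exist: `extract_profile` (bilinear samples along
the single line through DC, the textbook definition) and
`radon_profile`, which averages each ridge-parallel line over its
chord inside the circle. Because the sinc attenuation at offset ρ
along the motion direction is constant along the entire orthogonal
line, the pooled profile has the same null comb with the per-bin noise
averaged out; the prediction pipeline uses it for face images.

When the caller already knows the image is blurred (length estimation
runs downstream of the focus classifier), the feasible null spacing is
capped at N/2 (motion length ≥ 2). Without the cap, a very large d
plus the background term can imitate a smooth no-blur profile and
occasionally beats the true comb fit at the longest motion lengths.

The face pipeline additionally refines direction and length jointly:
it scans candidate angles within ±6° of the Radon estimate and keeps
the (θ, d) pair with the lowest detrended fit error. A few degrees of
direction error tilts the profile off the ridge and smears a dense
null comb (spacing N/L is only ~9 px at L = 13 on a 128 px window);
the joint scan recovers it.

## Focus score and grouping

`FS = 100·P(θ*+90°)/P(θ*)` where θ* is the argmax of the ρ-range sum.
Since θ* is the maximizer, FS ≤ 100 up to interpolation noise;
isotropic spectra give values in the 90s, blurred ones fall with
motion length. The decision threshold minimizes training
misclassifications (ties resolve to the midpoint of the optimal
threshold interval); the equal-error-rate operating point is reported
alongside.

Group assignment is total and deterministic over nine groups: focused;
{slight, blurred} × {0°, 45°, 90°, 135°}. Estimated lengths below 4.5
fold into the focused group (covering the no-blur and trivial L = 3
cases), 4.5–10 is slight, ≥ 10 blurred; directions quantize to the
nearest canonical direction modulo 180°. Focused-classified images
skip parameter estimation entirely.

## Age features and per-group models

* **MLBP**: the aligned face ROI (eye-geometry rectangle: width 2.0·D,
  top 0.6·D above the eye line, height 2.4·D, with D the inter-eye
  distance) is resized to 128×128; LBP codes with bilinear neighbor
  sampling and the ≥-comparison are histogrammed over the uniform
  partition (P(P−1)+3 bins; 59 for P = 8) in non-overlapping blocks,
  L1-normalized per block. Default levels: (R=1, P=8, 4×4 blocks) and
  (R=2, P=8, 8×8 blocks) — 4720 dimensions.
* **Gabor wrinkles**: five regions placed from the eye geometry
  (forehead, two outer eye corners, two under-eye boxes; all ratios of
  D and configurable) are filtered with even-symmetric Gabor kernels
  at 4 scales × 6 orientations (center frequencies 0.17 to 0.06
  cycles/px in half-octave steps, σ = 0.56 wavelengths ≈ one-octave
  bandwidth, truncated at 2.5σ, edge-replicated borders); the mean and
  standard deviation of each filtered region give 240 dimensions. The
  bank spans the wrinkle wavelengths of a face at a few tens of pixels
  of inter-eye distance.
* Streams are Z-score normalized (std floored at 10⁻⁸), concatenated
  MLBP-first, PCA-reduced to 10 components by default, and regressed
  with an RBF SVR whose C is picked from {1, 10, 100} by seeded 3-fold
  search (γ = "scale", ε = 1). A small fixed PCA dimension works much
  better here than a variance-fraction rule: after Z-scoring, the
  4720 MLBP histogram dimensions are dominated by per-block sampling
  noise of roughly unit variance, so high-variance directions are not
  the informative ones. Predictions clamp to the training age range.

Training simulates the blur grid (4 directions × lengths 3–15) on the
sharp training faces and trains each group on the images that truly
belong to it; prediction routes each image through focus score → blur
estimate → group → that group's model.

## Synthetic data

`make_texture`: 1/f-shaped Gaussian noise plus ~60 short anti-aliased
edge fragments at uniformly random orientations — broadband, with
localized high-frequency content, isotropic on average so sharp
textures score high on FS. `make_face`: an elliptical head with two
dark eye blobs at known coordinates and additive oriented sinusoid
bands inside the five wrinkle regions, with amplitude
`5 + 28·(age−18)/75` intensity units and frequency
`0.06 + 0.10·(age−18)/75` cycles/px, plus seeded Gaussian noise
(σ = 2 by default). Everything is a pure function of its spec.

What the fixtures do *not* emulate: real skin micro-texture,
illumination and pose variation, identity-specific facial structure,
demographic effects, detector jitter in the eye positions, and the
nonlinear ways real faces age. Passing tests therefore demonstrate
that the estimators and the grouped pipeline recover the signals the
model family defines — not field performance on photographs.

## Problem sizes and numerics

The benchmark replays use 25 textures × 28 blur variants (700 images,
256×256) for parameter recovery and classification, and 200 synthetic
faces (100 train / 100 holdout, 140×140, blurred over the full grid)
for the grouped-versus-sharp-model comparison; these sizes give stable
means while keeping a full run in minutes on one CPU. Bilinear
interpolation is used for all resampling (rotation, Radon sampling,
LBP neighbors). All argmax operations break ties toward the smaller
index. Seeds flow from explicit arguments; two runs with the same
inputs are bit-identical.

## Known limitations

* Only linear, spatially uniform motion blur; no defocus, curved or
  multi-segment paths, and no deblurring.
* Direction accuracy degrades gracefully toward L = 3, where the sinc
  ridge is wide and shallow; at L = 1 the estimators are undefined by
  design (callers guard with the focus score).
* The focus threshold is dataset-dependent: it is learned from
  training scores, not a universal constant.
* Face detection is out of scope: eye positions arrive as annotations
  (or from any external detector) in `EyeAnnotation` form.
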