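# Methods

`speckleplane` asks a concrete question from computational imaging: when an
amplitude object is hidden behind a strong glass diffuser in a coherent 4f
imaging system, should the camera's conjugate plane sit on the *object* or
on the *diffuser surface* before a neural network tries to invert the
speckle?  The package answers it entirely in silico: a scalar wave-optics
simulator stands in for the optical bench, a U-Net trained with a
correlation loss performs the inversion, and the evaluation battery
(SSIM, digit-classification accuracy, loss curves, PCC defocus sweeps)
quantifies the outcome.

## Optical model

**Geometry.** A collimated He–Ne beam (632.8 nm) optionally passes a weak
diffuser D1, travels to a transmissive SLM displaying a digit as an
amplitude mask, continues to a strong diffuser D2, and enters a two-lens 4f
relay (L1, Fourier-plane iris, L2) ending on an 8-bit camera.  The camera
is fixed at the back focal plane of L2, which the relay conjugates to the
plane at distance f1 in front of L1; the distance d between D2 and L1
therefore selects the imaged plane.  d = f1 images the D2 surface;
d = f1 − (SLM→D2 separation) images the object.  The relay inverts the
image with magnification −f2/f1.

**Propagation.** Free-space segments use the band-limited angular-spectrum
method on a square complex grid: exact transfer function
exp(i2πz·sqrt(1/λ² − f²)) with evanescent waves zeroed and, per axis, a
frequency limit 1/(λ·sqrt((2Δf·z)²+1)) that suppresses wrap-around on the
periodic grid.  Energy in propagating, in-band components is conserved to
machine precision; clipped spectral energy is logged.  The L1→iris→L2
segment is evaluated as two exact focal-plane-to-focal-plane scaled Fourier
transforms with the iris applied as a hard circular mask in physical
Fourier-plane coordinates.  This is mathematically the same mapping as
propagating through the lens phase masks, but it respects the fact that
the Fourier-plane sampling (λf1/(N·pitch)) is incommensurate with the
object-plane grid, which makes brute-force angular-spectrum propagation
through a short-focal-length lens unsound on a single fixed grid.  Thin
lens and iris are nevertheless exposed (and tested) as standalone element
operations.

**Diffusers.** Each diffuser is a thin random phase screen: a Gaussian
random field smoothed to a correlation length and scaled to a phase
standard deviation of 2π (fully developed scattering, no ballistic
residue).  The correlation length is calibrated by log-space bisection so
that the far-field intensity envelope of a plane wave through the screen
has the requested full width at half maximum ("diffusion angle").  A
single-realization far field is fully developed speckle, so the envelope
width is estimated from the axis marginals of the power spectrum (each
marginal averages a full grid dimension of speckle; for the Gaussian-like
envelopes these screens produce, the marginal FWHM equals the radial
envelope FWHM).  Angles beyond the grid's Nyquist angle asin(λ/2·pitch)
are refused with an explicit error; angles too small to realize at full
phase depth fall back to a weak screen with linearly reduced phase
standard deviation, which degenerates to a flat screen in the
no-diffuser limit.

**Camera.** Intensity |u|², averaged over camera pixel areas (integer
binning of the simulation grid), central crop, per-image normalization of
the maximum to 255, rounding to 8 bits.  Per-image normalization is the
least-assumption exposure model and makes the capture invariant to global
field scaling.  No noise is injected by default; Poisson shot noise is
available behind a config flag (`shot_noise_photons`).

**Coordinate bookkeeping.**  The 4f inversion is never silent: the
reference image for any camera-plane comparison is produced by
`truth_on_camera`, which flips the SLM pattern, squares it (the camera
measures intensity), rescales by the magnification and applies the same
binning/cropping/quantization as the camera model.  Reconstruction
targets, PCC sweeps and SSIM evaluations all use this reference.

## Presets

The **paper preset** stores the benchtop geometry: f1 = 150 mm,
f2 = 50 mm, D1→SLM 100 mm, SLM→D2 80 mm, 7.5 mm iris, 36 µm SLM pixels
(central 160×160 used), 3.75 µm camera pixels (central 256×256 used),
diffusion angles 5° and 120°.  Those angles are far beyond the Nyquist
angle of any tractable grid (0.5° at 36 µm pitch), so screen creation
refuses them: the preset documents the geometry and serves clear-system
checks rather than speckle generation.

The **desk preset** is a self-consistent scaled-down bench chosen to
preserve the physical regimes that drive the investigated effect rather
than the absolute dimensions:

| quantity | value | preserved regime |
|---|---|---|
| grid / pitch | 512 × 2 µm | strong diffuser (4°) well below Nyquist (9.1°) |
| f1 / f2 | 6 mm / 2 mm | magnification −1/3 as on the bench |
| D1→SLM / SLM→D2 | 3.0 / 2.4 mm | Fresnel number ≈ 21 for the object at D2 (near-field: the object casts an essentially geometric pattern on the diffuser, the "secondary image") |
| iris | 1.2 mm | defocus-to-depth-of-field ratio ≈ 125 between the two conjugate choices (defocus dominates, as on the bench), while the weak 1° diffuser passes the aperture and the strong 4° one is mostly clipped |
| diffusers | 1° (weak), 4° (strong) | weak-in-front / strong-behind ordering |
| camera | 6 µm pixels, 32×32 crop | digit image fills ≈ 60% of the crop |
| object | 180 SLM px (360 µm) | stroke width ≈ 2.5× the iris cutoff period |

Conjugate distances: d = 3.6 mm images the object, d = 6.0 mm images the
diffuser — the desk analogs of 70 mm and 150 mm.

## Synthetic objects

Digits 0–9 are rendered from hand-laid stroke templates (polylines and
arc samples) with anti-aliased edges, then jittered per sample with a
random affine map (rotation ≤ 15°, scale 0.8–1.2, translation ≤ 10%),
giving a ten-class recognition task with no dataset download.  An IDX
reader/writer provides compatibility with real digit files.  What the
generator does *not* emulate: the intra-class diversity of real
handwriting (strokes vary affinely, not topologically), SLM pixelation
artifacts, and partial coherence.  Passing results therefore demonstrate
the image-plane effect for digit-like amplitude objects under ideal
coherent illumination, not recognition performance on real handwriting.

## Reconstruction network and training

The U-Net encoder applies, per level, two 3×3 convolutions (ReLU after
each) and a 2×2 max-pool, doubling the channel depth per level up to 64 at
the deepest map; encoder and decoder are joined by a dense
(fully connected) bottleneck on the flattened deepest features; the
decoder mirrors the encoder with 2×2 nearest-neighbor upsampling followed
by convolutions, with concatenation skip connections at every level; a
final linear 1×1 convolution emits the single-channel reconstruction.
Nearest-neighbor-plus-convolution upsampling avoids transposed-convolution
checkerboarding.  At the paper scale (256×256 input, five levels, base 4)
the deepest tensor is 8×8×64; the desk scale (32×32, three levels,
base 16) reaches 4×4×64.

The loss is the negative Pearson correlation coefficient between
prediction and target, averaged per batch; it is scale-free, so the output
nonlinearity is linear and reconstructions are affinely rescaled to 0–255
only for metric evaluation.  Optimization uses Adam (lr 1e-3, default
moments), batch size 8, at most 30–40 epochs with early stopping on a
validation plateau (patience 8, minimum improvement 1e-3).  Training is
pure numpy (im2col convolutions over BLAS), float32, and exactly
reproducible given the config seed; every backward pass is verified
against finite differences in the test suite.  Datasets follow the
2220:560:200 train/validation/test proportions of the acquisition
protocol, scaled to the generated set (desk default: 180 objects →
134/34/12); the validation split drives the per-epoch "testing error"
curve and early stopping, the test split is reserved for final SSIM/ACC.

The convergence epoch of a run is the first epoch whose validation loss
comes within 0.02 NPCC of the run's minimum — a tolerance chosen because
the quantity is read qualitatively (epochs-scale) rather than exactly.

## Evaluation

* **SSIM** is computed globally from whole-image means, variances and
  covariance with C1 = (255·0.01)², C2 = (255·0.03)², exactly as the
  evaluation protocol defines it; the conventional sliding-window variant
  is available behind `windowed=True` for comparison.  Note the global
  form can be negative for anticorrelated pairs; it equals 1 only for
  identical images.
* **ACC** is the fraction of reconstructions whose digit is recognized by
  a small CNN (two conv blocks + dense softmax head) trained on clean
  camera-frame renderings of an independent digit set.  The classifier
  must reach ≥ 95% held-out accuracy on clean digits or it refuses to
  exist — below that, ACC would measure the classifier, not the
  reconstruction.
* **PCC** between ground truth and raw speckle, swept over d, reproduces
  the defocus-sweep analysis; the sweep is sampled at 1.2 mm steps, no
  finer than the imaging depth of field, so neighboring samples are not
  degenerate within single-realization speckle noise.

## Experiment protocol

A paired comparison generates the two arms (object-plane d and
diffuser-plane d) from identical digit objects and identical frozen
diffuser screens — the image plane is the only varying factor, asserted at
run time by a configuration digest over every other field.  Three seeds
re-draw objects, screens and network initialization.  All CSV outputs are
bitwise reproducible for fixed seeds.

Problem sizes (32×32 reconstructions, 180 objects, ≤ 30 epochs, 3 seeds,
20-object sweeps) are the package's desk-scale defaults, chosen so a full
paired study runs in minutes on a single CPU core while every qualitative
contrast of the benchtop study remains measurable.

## Known limitations

* Thin-screen diffusers: the physical elements' thickness (0.78 / 1.25 mm)
  and volumetric scattering are not modelled; the 120° glass is replaced
  by a 4° screen in a correspondingly rescaled geometry.
* Scalar, fully coherent, noise-free model: no polarization, partial
  coherence, SLM diffraction orders, lens aberrations, or camera noise.
* One screen realization per physical diffuser: train/validation/test all
  see the same diffuser (as in the lab); nothing here measures
  generalization across diffusers.
* The desk-scale effect sizes are analogs, not predictions of the
  benchtop numbers: ordering and rough magnitude transfer, absolute
  values need not.
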