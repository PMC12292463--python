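# Methods

This note documents the models and numerical choices behind `lungperf`: a
self-supervised denoising and quantification pipeline for pulmonary dynamic
contrast-enhanced (DCE) MRI perfusion images, exercised end-to-end on
synthetic lung-perfusion phantoms.

## The restoration problem

A background-subtracted peak-phase perfusion slice `y` is modelled as a clean
enhancement image `x` plus zero-mean additive noise that is spatially
correlated in-plane and has spatially varying magnitude (coil/inhomogeneity
effects). No clean reference exists — the contrast bolus cannot be imaged
twice — so the denoiser must be learned from single noisy images.

### Blind-spot network (BSN)

The denoiser is a convolutional network whose receptive field structurally
excludes the output pixel's own input value. Each of two branches starts with
a centrally masked convolution (3×3 or 5×5) followed by dilated residual
blocks (3×3 kernels at dilation 2 behind the 3×3 mask, dilation 3 behind the
5×5 mask), then the branches are concatenated and reduced by 1×1
convolutions. The exclusion is an arithmetic fact about tap offsets: after a
masked k×k first layer, every later offset is a multiple of the dilation d,
and no initial offset within the masked kernel is congruent to zero modulo d
except the (masked) centre, provided `d >= (k+1)/2`. The config validator
enforces exactly this pairing. With the identity path removed, minimising an
L1 self-reconstruction loss cannot be solved by copying the input, and the
optimum approaches the conditional median of the clean signal given the
neighbourhood.

Convolutions use zero padding. Reflective padding shifts coordinates by even
amounts, which would preserve the 3×3/dilation-2 blind spot but can alias
taps of the 5×5/dilation-3 branch back onto the centre at image borders;
zero padding keeps the blind spot exact at every pixel, a property the test
suite checks by finite differences.

### Pixel-shuffle downsampling (PD) and asymmetry

MRI noise is correlated over a few pixels, so a one-pixel blind spot is not
blind to the noise. The image is therefore subsampled into an s×s set of
replicas (pixels congruent mod s); at stride s the nearest neighbours inside
a replica are s pixels apart in the original image, beyond the noise
correlation length. Training uses a large stride; inference uses a small
stride to preserve detail, followed by T = 16 random-replacement refinement
passes: a random half of the estimate's pixels are reset to the original
noisy values, the PD→BSN→inverse path is re-run, and the pass outputs are
averaged. Each replica is processed as a separate image in the network
batch; tiling replicas into a single mosaic would place artificial
discontinuities (image-wrap seams) inside the receptive field.

Default strides are 5 (training) and 2 (inference), matching the full-scale
method. At the desk scale used by the tests (64×64 slices, roughly one sixth
of acquisition resolution) the strides scale with the geometry to 3/2 — see
"Scaled-down evaluation" below.

### Plug-and-play ADMM (PnP-BSN)

Aggressive self-supervised denoising loses fidelity. The final estimate
solves

    argmin_x 1/2 ||y − x||² + ρ/2 ||x − z||²,   z ~ D(x),

with the trained denoiser D as the prior, via scaled ADMM: initialise
`u = 0`, `z = D(y)`; then for k = 1..K

    x ← (y + ρ(z − u)) / (1 + ρ)        (exact quadratic minimiser)
    z ← D(x + u)
    u ← u + x − z

with ρ = 1 and K = 3 fixed (no convergence test). Two textual ambiguities in
this family — whether ρ multiplies `u` in the x-update, and whether D sees
`x + u` or `x` — are resolved to the standard scaled-ADMM forms above, with
the literal alternatives switchable via `PnPConfig(scaled_x_update,
z_from_shifted)` for auditability. With a linear shrinkage prior
`D(v) = αv` the iteration's fixed point has the closed form
`x* = αy / (α + ρ(1 − α))`, which the acceptance suite verifies to 1e-6.

### Training

Per-slice robust normalisation (99.9th-percentile scale) maps slices to
[0, 1]; patches are drawn uniformly, PD-split at the training stride, and the
network minimises pixel-wise L1 against the replica itself, with Adam
(learning rate 1e-3 by default, 2e-3 in the scaled runs). All randomness
flows from one integer seed; identical seeds and data give bit-identical
parameters. Divergence (non-finite loss) aborts with the epoch index.

## Phantom generator

The phantom stands in for private clinical data and states the world the
tests run in:

* **Anatomy.** A body ellipse (intensity 60) containing two lung ellipsoids
  (parenchyma 20), each with a recursive bifurcating vascular tree: trunk
  radius 5.5% of the in-plane dimension, child radius ×0.75 and length ×0.75
  per generation, ~35° branching with seeded jitter, rasterised as tubes and
  clipped to the lungs. Branch generations are labelled so tests can check
  that per-generation voxel counts decrease. Vessel calibre is deliberately
  kept wider than the PD stride, as it is at acquisition resolution; vessels
  narrower than the stride would present sub-stride delta structures outside
  the method's regime.
* **Partial volume.** The clean volume is convolved in-plane with a 2-px-FWHM
  Gaussian PSF. MR magnitude images are band-limited; razor-edged digital
  cylinders are not an achievable signal, and blind-spot prediction relies on
  the local continuity the PSF provides.
* **Dynamics.** Per-timepoint enhancement factors (default
  0, 0.15, 0.6, 1.0, 0.7, 0.4) scale an enhancement map: `vessel_contrast`
  (100) inside vessels, the parenchyma level elsewhere in the lung; an
  optional spherical lesion scales its enhancement by `1 − deficit`.
* **Noise.** White Gaussian noise smoothed in-plane with a Gaussian kernel of
  configurable FWHM (default 3 px; periodic boundaries keep the field
  stationary), rescaled to unit pointwise variance, then multiplied by
  `base_sigma` (default 4) times a radial-quadratic gain field
  (1 + 0.5 r²/r_max², emulating surface-coil inhomogeneity). Noise is
  additive and zero-mean, not Rician: the pipeline operates on
  background-subtracted magnitude differences where this is the standard
  approximation. A consequence is that the noisy series dips slightly below
  zero in air — clipping would break the zero-mean property the tests
  calibrate against.

What a green test does *not* establish: the phantom has no breathing motion,
no Rician bias, no k-space artefacts, no inter-subject anatomical
variability, and its noise correlation is exactly Gaussian; conclusions about
clinical images need clinical data.

## Fractal-dimension mapping

Perfusion texture complexity is quantified by the fractal dimension of the
intensity surface, estimated per pixel by differential box counting over a
sliding window (default 11×11, box sizes 2, 3, 4, 5, 7): for box size r the
window is partitioned into r×r columns, each column's intensity spread is
measured in units of a box height h = r·σ_window/(w·γ), and FD is the slope
of log N(r) against log(1/r), with per-pixel R² recorded. Two estimator
choices matter:

* **Spread = standard deviation, not max − min.** On lattice-sampled rough
  surfaces the sampled extremes underestimate the continuum extremes, and the
  deficit shrinks as boxes grow; the max−min spread therefore scales like
  r^(H+0.1..0.2) instead of r^H and compresses FD estimates towards 2 (on
  64² fractional Brownian surfaces with H = 0.2 the classical count
  plateaued near 2.5 against a theoretical 2.8, and no scale set repaired
  it). The standard deviation is an average, converges quickly under
  sampling, and restores recovery of 3 − H within ±0.15, while preserving
  the flat→2.0 baseline, intensity-scale invariance and the white-noise→3
  limit. γ = 8 refines the vertical quantisation so counts do not saturate
  at the smallest boxes.
* **Flat rule.** A window whose spread is at floating-point rounding level
  (std ≤ 1e-12 of the window's max magnitude) is assigned FD = 2.0 exactly —
  the flat-surface baseline — instead of a degenerate fit.

The fBm oracle surfaces used to validate the estimator are synthesised by
exact circulant embedding of Stein's compactly supported covariance (an
FFT-based method); naive power-law periodogram synthesis yields fine-scale
increments that are measurably too smooth and would corrupt the oracle.

Noise inflates apparent FD. The pipeline-level check mirrors the clinical
reading: on phantoms, the lung-mask mean FD of the noisy image exceeds that
of the denoised image, and the denoised FD is closer to the clean image's.

## Segmentation and metrics

K-means (k = 3, k-means++ with 10 restarts, seeded) clusters masked pixel
intensities into low/medium/high perfusion classes, relabelled by ascending
centroid; the result is invariant to pixel order and to affine intensity
rescaling. The conventional baseline is a normalized Gaussian filter whose σ
is tuned on matched phantom pairs by maximising mean PSNR. Objective metrics
replace the paper-style reader scores: PSNR (capped at 100 dB for identical
images), SSIM, region SNR = mean(signal)/std(background), and sharpness =
mean Sobel gradient magnitude over the top-decile gradient pixels of the
masked region (edge pixels; a region-mean would be nearly blur-invariant
because smoothing spreads rather than removes gradient mass).

## Preprocessing defaults

Baseline frames are all frames before the first whose mean exceeds 10% of the
series maximum (falling back to frame 0); subtraction clips negatives so the
non-negativity invariant survives, which also makes the operation idempotent.
The peak frame maximises masked mean enhancement (earliest on ties). MIP
slabs default to 20 slices centred on the lung-mask centroid. The lung mask
estimator smooths (σ = 1.5 in-plane), log-compresses, Otsu-thresholds,
erodes one in-plane voxel (stripping the smoothing rim), closes, keeps up to
two largest components and fills holes; on default phantoms it reaches Dice
≈ 0.91 against the generator mask.

## Scaled-down evaluation

The acceptance-grade end-to-end check trains the reduced network (32
channels, 4 dilated blocks per branch) on 72 slices drawn from three
phantoms at three enhancement phases each — echoing the multi-subject,
multi-slice corpus of the full-scale method — for 1000 Adam steps, and
evaluates 10 held-out slices of a fourth phantom. At this scale the PD
strides are 3 (train) and 2 (test): 64×64 slices carry roughly one sixth of
the linear resolution the full-scale strides were chosen for, and a stride
that subsamples below the structure scale would test a regime the method is
not defined on. Every structural element — blind-spot architecture, stride
asymmetry, T = 16 refinement, PnP fidelity — is exercised unchanged. The
margin in this world is intrinsically narrow: an oracle-tuned Gaussian
filter (σ chosen against the clean references the self-supervised method
never sees) improves mean PSNR by under a decibel.

## Known limitations

* The numpy network engine is CPU-bound and desk-scale; it is not a route to
  training at clinical resolution.
* DICOM input is not supported (no DICOM library in the runtime); convert to
  NIfTI first.
* Per-slice robust normalisation assumes slices contain anatomy; slices of
  pure noise are normalised to full scale and should be excluded from
  training corpora (the pipeline trains on the MIP slab for this reason).
* FD values at strong step edges approach 3 by construction — edges are
  maximal-roughness features on the intensity surface — so FD maps highlight
  vessel boundaries as high-complexity structures.
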