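# Methods

## Problem and scope

Ultrasound axial resolution is tied to the transducer's temporal bandwidth.
This package studies the restoration problem "given a B-mode reconstruction
from band-limited RF data, estimate the full-bandwidth reconstruction" end
to end: data synthesis, the image-formation chain, three CNN restorers, two
training losses, classical histogram baselines, and an evaluation suite of
pixel, spectral and speckle statistics. Everything is seeded and runs on a
single CPU; no scanner data, GPU or deep-learning framework is required.

## Speckle simulation

Real training data for this task are plane-wave acquisitions of gelatin
phantoms doped with silicon-carbide scatterers. We emulate them with the
standard fully-developed-speckle model: a sparse reflectivity map (each
pixel is a scatterer with probability `density`, amplitude uniform in
[-1, 1]) convolved with a separable PSF. Inclusions are axis-aligned
rectangles and circles whose scatterer amplitudes are scaled by per-region
echogenicity multipliers (defaults 0.25/2/4 relative to background,
emulating low/medium/high scatterer-concentration contrast).

The PSF is a Gabor pulse axially — a cosine at the carrier under a Gaussian
envelope — times a Gaussian lateral beam profile. Defaults: carrier
7.8 MHz, axial sampling 31.25 MHz, lateral sigma 2 px, scatterer density
0.6/px (many scatterers per resolution cell, giving Rayleigh envelope
statistics). The carrier is a configurable placeholder consistent with a
5–11 MHz linear array, not a measured value.

**Pulse vs. acquisition passband.** The acquisition passband (default
3.04 MHz, the quantity fractional bandwidths refer to) and the pulse's
-6 dB spectral width are distinct parameters. The pulse width defaults to
0.6 x the passband so that >99% of pulse energy lies inside the passband;
only then is the unfiltered image genuinely "full bandwidth", and a
brick-wall at fraction 1.0 is a near-identity (we measure a residual B-mode
RMSE of ~0.03 from the <1% Gaussian tail energy it removes). Tying the
pulse width to the passband itself would make the fraction-1.0 filter
truncate the spectrum at its -6 dB points, which contradicts the intended
degenerate behaviour.

What the simulator does not emulate: diffraction and depth-dependent beam
width, attenuation and time-gain compensation, reverberation/grating-lobe
artifacts, scan conversion, and electronic noise. Consequently, passing
tests show the pipeline recovers convolutional band-limited speckle
structure; they do not certify performance on in-vivo images.

## Image-formation chain

Band limiting is an axial zero-phase band-pass of full width
`fraction x passband`, centred on the carrier. The default realization is
an FFT brick-wall mask — it makes the fractional bandwidth exact, is
idempotent to ~1e-15 (RF kept in float64 until storage), and has no phase
delay. A forward-backward Butterworth is available as a dialect. Envelope
detection is the magnitude of the axial analytic signal; log compression is
`20 log10(env / max)` clipped to a 60 dB display range (configurable) and
mapped affinely to [0, 1]. Both members of a pair are normalized by the
full-bandwidth envelope maximum so RMSE/PSNR compare on one intensity
scale; per-pair (rather than per-dataset) normalization is a deliberate
choice recorded in the config.

## Architectures

Widths and kernels live in `ModelSpec` as data, so the exact parameter
accounting of a built model is diagnosable layer by layer. The builds
reproduce the published parameter accounting exactly (total / trainable /
non-trainable):

| model | layout | parameters |
|---|---|---|
| SRCNN | conv 9x9/128 -> 3x3/64 -> 5x5/1 | 85,889 / 85,889 / 0 |
| U-Net | depth 5, base 16 doubling to 256; two 3x3 conv+BN per block; 2x2 max-pool; upsample+3x3 conv decoder (no BN on up-convs); skip concats; 3x3 head | 2,164,433 / 2,161,489 / 2,944 |
| REDNet | frozen 32-orientation Sobel bank concat input; seven dilated 3x3 convs 14-24-42-42-42-24-14, dilations 1-2-3-4-3-2-1, dropout 0.05; input re-concat; 3x3 head; residual add | 60,760 / 60,440 / 320 |

These layouts are reconstructions: the figure-level layer widths of the
original models are not published in machine-readable form, so the
architectures were chosen to satisfy the textual description (Sobel edge
layer, dilated convolutions, dropout 0.05, batch-normalized U-Net, ReLU
outputs) *and* the exact published counts simultaneously. The U-Net's
non-trainable count pins the batch-norm placement (1,472 normalized
channels); the REDNet's 320 non-trainable parameters are exactly a frozen
3x3 conv bank of 32 kernels with biases — realized as steered Sobel kernels
cos(t)Gx + sin(t)Gy over 32 orientations. The canonical 9-5-5 / 64-32-1
SRCNN (57,281 parameters) is included as `srcnn_canonical` for reference.

All models end in a ReLU (non-negative output, replacing a sigmoid head).
The REDNet adds its prediction to the input (residual output), so a
zero-initialized head is an identity — this is also why it trains quickly
at small step counts.

Weight initialization is Glorot-uniform from the model seed (convention;
not specified by the original description). Adam uses epsilon 1e-7 and no
decay (framework defaults for an unspecified epsilon).

## Losses

PL1 is `tau * MSE`. On [0, 1] display-scaled images the raw MSE is ~1e-2
to 1e-4 and its float32 gradients underflow as training converges; tau
(default 1000, configurable) rescales the objective. Adam's normalization
makes the optimum invariant to tau, so the default is a numerical-range
choice, not a tuning parameter.

PL2 mixes a pixel term and a perceptual term 30:70 (pixel weight 0.3 —
textual order of the stated ratio; swappable in config). The pixel term
defaults to MSE with RMSE available by flag (both conventions appear in
descriptions of this loss; we default to the one that matches the stated
combination with a pretrained-feature loss). The perceptual term is the
MSE of activations from a frozen convolutional feature pyramid (three
conv-conv-pool stages, widths 8/16/32, He-initialized from a fixed seed).
A deterministic random-feature extractor is used because no pretrained
VGG-type weights ship with the environment; random convolutional features
are a standard texture-sensitive comparison basis, and user-supplied
weights can be loaded from an `.npz` — a missing file raises immediately
rather than falling back silently. The extractor takes single-channel
input directly; no channel replication is needed.

## Training protocol

64 random overlapping 128x128 patches per image (drawn once, not re-drawn
per epoch, so patch totals are fixed: 400 images -> 25,600 train patches,
135 -> 8,640 validation patches), batch 16, Adam(lr 1e-4, beta1 0.9,
beta2 0.999), up to 300 epochs with early stopping on validation loss.
Early-stop patience defaults to 20 epochs with best-weights restoration
(the stated protocol gives the criterion but not the patience). Epoch
shuffling and dropout use per-epoch seeds derived from (seed, epoch), which
makes runs reproducible and checkpoint-resumable bit-for-bit.

## Baselines

HE maps each pixel to its empirical CDF value on a 256-level quantization.
CLAHE follows the four canonical steps: non-overlapping tile partition,
histogram clipping above `clip_limit x tile_pixels` with uniform
redistribution of the excess over all bins (one pass; the per-bin remainder
is below one count), per-tile equalization, and bilinear interpolation of
the tile mappings. HE and CLAHE share one binning/CDF convention, so CLAHE
with a single tile and no clipping equals HE pixelwise — a contract the
tests assert exactly. Defaults (256 bins, 8x8 tiles, clip 0.01) are common
conventions; the baselines' parameters are otherwise unconstrained.

## Metrics and speckle statistics

RMSE is computed in float64; PSNR uses the reference image's maximum
(hence PSNR is deliberately asymmetric), with MSE = 0 reported as +inf and
excluded from aggregates with a warning. PC is the Pearson correlation of
the flattened magnitudes of the unshifted 2D DFTs (1D axial spectra
available by flag; no window by default). Aggregates are arithmetic mean
+/- sample standard deviation over test images.

Speckle size is the FWHM of the mean-subtracted linear autocorrelation
(zero-padded FFT, peak-normalized, linear interpolation between the lags
bracketing 0.5). The axis profiles use the unbiased overlap correction so a
patch smaller than its correlation support is reported as an error instead
of silently truncated. Eccentricity is sqrt(b^2 - a^2)/b with canonical
(a <= b) ordering. Envelope histograms are density-normalized on shared bin
edges; the overlap coefficient integrates the bin-wise minimum.

## Desk-scale experiment sizing

The reduced-scale recovery experiment (`usbwx.workflows`) simulates 56
phantoms of 256x256 (40 train / 6 validation / 10 held-out test) at 20%
fractional bandwidth, trains the REDNet with PL1 on 2,080 random 32x32
patches for 6 epochs, and evaluates RMSE and PC on the held-out images.
These sizes were chosen so a full run takes a few minutes on one CPU while
keeping >2,000 training patches and >=10 test images; they are two orders
of magnitude below a full-scale study (669 images of 801x401, 25,600
patches of 128x128, up to 300 epochs), so the measured improvement
(~5% RMSE, ~0.5 dB) is a direction indicator, not a performance ceiling.

## Numerical choices and degenerate inputs

- RF processing in float64 end to end; float32 only at HDF5/image
  boundaries. Metrics in float64.
- Brick-wall masks are applied symmetrically to positive and negative
  frequencies, preserving realness exactly.
- An all-zero RF image cannot be normalized and raises; a constant image
  has an undefined spectrum correlation and raises; a constant image under
  HE warns and passes through unchanged.
- Tiled inference keeps only the central region of each overlapping tile
  (margin = overlap/2 >= the receptive-field radius), which makes tiled and
  whole-image inference identical for the fully convolutional models; image
  sizes not divisible by the U-Net grid are reflect-padded and cropped.
- Patch extraction corners are uniform over valid placements; a 128x128
  image yields 64 identical corner patches by construction.

## Known limitations

- The simulator's convolutional model omits depth-dependent blur,
  attenuation and artifacts; results transfer qualitatively, not
  quantitatively, to scanner data.
- PC on log-compressed images is dominated by low-frequency amplitudes and
  sits near 1; it resolves orderings (which the tests use) better than
  absolute differences.
- The perceptual extractor is not a trained recognition network; PL2
  results should be read as "pixel + fixed random-feature loss".
- The numpy engine is single-threaded through BLAS and sized for
  patch-scale training; full 300-epoch runs at 128x128 are supported but
  slow.
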