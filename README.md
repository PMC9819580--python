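# usbwx — bandwidth expansion for ultrasound B-mode images

The axial resolution of a B-mode ultrasound image is set by the temporal
bandwidth of the transducer: a narrow passband blurs speckle along depth and
washes out fine structure, and broadband probes are expensive. `usbwx`
implements a learning-based bandwidth-expansion pipeline: convolutional
networks are trained on paired (band-limited, full-bandwidth) reconstructions
of the same field of view, and then map a narrowband image to an estimate of
its broadband counterpart.

The package provides every stage needed to study the problem without access
to a research scanner:

- **`phantom_sim`** — seeded synthetic speckle phantoms: sparse random
  scatterer fields with rectangular/circular inclusions of differing
  echogenicity, convolved with a separable point-spread function (axial Gabor
  pulse x lateral Gaussian beam).
- **`bmode`** — the image-formation chain: zero-phase fractional band-pass
  filtering of the RF data (brick-wall FFT or Butterworth), envelope
  detection via the analytic signal, log compression to a display dynamic
  range, and [0, 1] pair normalization.
- **`nets`** — three fully convolutional restoration models built on a small
  numpy network engine (`usbwx.nn`): SRCNN (85,889 parameters), a
  batch-normalized U-Net (2,164,433), and a residual encoder-decoder
  "REDNet" with a frozen Sobel edge bank and dilated convolutions (60,760,
  the lightest and strongest of the three).
- **`losses`** — PL1, a tau-scaled MSE that keeps early-training gradients
  away from float32 underflow on display-scaled images, and PL2, a 30:70
  pixel/perceptual mixture using a frozen convolutional feature extractor.
- **`training`** — 64 random overlapping 128x128 patches per image, batch
  16, Adam(1e-4, 0.9, 0.999), early stopping on validation loss.
- **`baselines`** — histogram equalization and four-step CLAHE comparators.
- **`metrics`** — RMSE, PSNR (reference-maximum convention) and the Pearson
  correlation of Fourier amplitude spectra (PC), with mean +/- std
  aggregation; error maps and amplitude spectra.
- **`speckle`** — envelope histograms and their overlap, speckle size as the
  FWHM of the autocorrelation, and resolution-ellipse eccentricity
  sqrt(b^2 - a^2)/b.

## The model in brief

A band-limited image `y_BL` is produced from full-bandwidth RF by an axial
band-pass of width `f x W` (fraction `f` of the full passband `W = 3.04 MHz`,
centred on the carrier), followed by envelope detection and log compression.
A network `g_theta` is trained to minimise

    PL1:  L = tau * mean( (g_theta(y_BL) - y_FB)^2 )          (tau = 1000)
    PL2:  L = 0.3 * pixel-term + 0.7 * perceptual-term

on patch pairs; at test time the restored image is compared to `y_FB` by
RMSE, PSNR = 10 log10(Imax^2 / MSE), and PC on amplitude spectra.

## Worked example

```python
from usbwx.workflows import RecoveryConfig, bandwidth_recovery_experiment

out = bandwidth_recovery_experiment(RecoveryConfig(seed=1))
print(f"band-limited RMSE {out['band_limited']['rmse']:.4f}  "
      f"PC {out['band_limited']['pc']:.4f}")
print(f"REDNet-PL1   RMSE {out['model']['rmse']:.4f}  "
      f"PC {out['model']['pc']:.4f}")
print(f"improvement {out['rmse_improvement_pct']:.1f}%  "
      f"PSNR gain {out['psnr_gain_db']:.2f} dB")
```

prints (seed 1, 56 simulated 256x256 phantoms, 20% bandwidth, 2080 training
patches, 6 epochs):

```
band-limited RMSE 0.1278  PC 0.9938
REDNet-PL1   RMSE 0.1208  PC 0.9947
improvement 5.5%  PSNR gain 0.49 dB
```

i.e. the trained network moves the 20%-bandwidth reconstruction toward the
full-bandwidth reference in both pixel error and recovered frequency
content. At this desk scale the improvement is a fraction of what full-scale
training on real phantom data reaches; it demonstrates the pipeline's
direction, not its ceiling.

The same stages are scriptable from the shell:

```bash
usbwx simulate --shape 801x401 --n-images 8 --seed 1 --out rf.h5
usbwx bandlimit --fraction 0.2 --dr 60 --in rf.h5 --out pairs.h5
usbwx train --model rednet --loss pl1 --pairs pairs.h5 --val pairs.h5 --out run/
usbwx enhance --method model --model rednet --weights run/weights.npz \
      --in pairs.h5 --out enhanced.h5
usbwx evaluate --pairs pairs.h5 --enhanced enhanced.h5 --out report/
usbwx speckle-report --in pairs.h5 --region 100,100,400,300 --out speckle.csv
```

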