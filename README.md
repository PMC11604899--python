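# xeosc — mapping cardiogenic ¹²⁹Xe RBC signal oscillations

Hyperpolarized ¹²⁹Xe dissolved-phase lung MRI separates xenon dissolved in
the alveolar membrane/tissue-plasma (M) from xenon bound to red blood cells
(RBC). The RBC signal is modulated at the heartbeat frequency by the
pulsatile capillary blood volume, and the *regional* amplitude and phase of
that modulation report on pulmonary microvascular function. `xeosc`
implements keyhole-reconstruction oscillation mapping for multi-echo 3D
radial dissolved-phase acquisitions, for physicists and engineers working on
gas-exchange lung MRI:

* a **digital lung phantom and forward simulator** of the acquisition
  (934 center-out radial spokes, 4 flyback echoes, 13 samples/echo, TR 15 ms,
  14-s breath hold), including the three spectral compartments, RF/T1 signal
  decay, and a voxelwise cardiac modulation
  `S(r,t) ∝ 1 + α(r)/2 · f(ωt − ϕ(r))`,
  where `α(r)` is the peak-to-peak fractional amplitude, `ω` the heartbeat
  frequency, and `ϕ(r)` the local phase lag;
* **chemical-shift separation** of gas/M/RBC in k-space by least squares over
  the echo dimension, with triple-Lorentzian calibration fitting;
* 3D radial **gridding reconstruction** (Kaiser–Bessel kernel, Beatty β, 2×
  oversampling) with **iterative sample-density compensation**
  `w ← w / (w ⊛ C)`;
* whole-lung **k0 analysis**: biexponential decay correction, 0.5–2.5 Hz
  zero-phase band-pass, peak detection, the global amplitude
  `α_k0 = 100 · (mean of detrended maxima − mean of minima)`, and heart rate;
* **Two-Key mapping**: spokes adjacent to the k0 maxima/minima (≈20% of
  projections each, keyhole radius 6 readout points) reconstruct S_high and
  S_low, and `α_2-Key = 100 · (S_high − S_low) / ((S_high + S_low)/2)`;
* **sliding-window (SW) mapping**: N keyhole reconstructions with the key
  stepped one spoke at a time over one cardiac cycle; per voxel, after
  Gaussian smoothing along the key index j,
  `α_SW = 100 · (S_max − S_min)/S_mean` and `ϕ = wrap(2π (j_max − 1)/N)`,
  which makes the amplitude phase-independent and maps the local lag;
* lung masking, the eight standard lung regions, SNR gating (Rose criterion,
  threshold 4.5), and scan-rescan repeatability metrics (bias, limits of
  agreement, % difference, 3-scan CV).

## Worked example

```python
import numpy as np
from xeosc import (SequenceParams, simulate_acquisition, add_noise,
                   run_oscillation_mapping)
from xeosc.pipeline import ReconContext, calibrate_noise_sd
from xeosc.presets import amplitude_phantom

phantom, truth = amplitude_phantom()      # α bands 10/20/40% + antiphase pocket
seq = SequenceParams()                    # 934 spokes, 4 echoes, TR 15 ms
clean = simulate_acquisition(phantom, seq)
ctx = ReconContext.for_acquisition(clean)
sd = calibrate_noise_sd(phantom, clean, target_snr=15.0, context=ctx)
scan = add_noise(clean, sd, seed=1)

result = run_oscillation_mapping(scan, context=ctx)
print(f"heart rate      {result.heart_rate:6.1f} bpm")
print(f"alpha_k0        {result.alpha_k0:6.1f} %")
print(f"alpha_2key mean {result.alpha_2key_mean:6.1f} %")
print(f"alpha_SW median {result.alpha_sw_median:6.1f} %")
m = truth["antiphase"][0] & result.mask
print(f"antiphase pocket: two-key {np.nanmedian(result.maps.alpha_2key[m]):.1f} %, "
      f"SW {np.nanmedian(result.maps.alpha_sw[m]):.1f} %")
```

prints

```
heart rate        69.8 bpm
alpha_k0          19.5 %
alpha_2key mean   17.4 %
alpha_SW median   21.8 %
antiphase pocket: two-key -4.5 %, SW 10.5 %
```

The detected heart rate matches the phantom's programmed 70 bpm; the global
and Two-Key amplitudes sit near the lung-averaged programmed amplitude; and
the pocket oscillating in antiphase with the rest of the lung shows the
characteristic *negative* Two-Key amplitude that the phase-independent SW
amplitude turns positive. `result.summary` holds the per-region table
(mean for α_2-Key, median for α_SW and ϕ) and the spatial coefficients of
variation; `result.maps` holds the voxel maps.

## Command line

```bash
xeosc simulate --preset amplitude --seed 1 --snr 15 -o scan.h5
xeosc map scan.h5 -o maps/ --method both       # alpha/phi NIfTIs + QC JSON
xeosc report maps/ --truth scan.h5 -o summary.csv
xeosc repro maps1/k0_qc.json maps2/k0_qc.json -o repro.json
```

Acquisitions live in a single HDF5 container (`/kspace`, `/trajectory`,
`/timestamps`, `/seq`, optional `/truth/*` and `/separated/*`); all volumes
are written as NIfTI-1 (RAS+, FOV-derived voxel size); configuration is YAML
(`--config`), with defaults matching the published protocol (20% bins,
keyhole radius 6, 0.5–2.5 Hz, smoothing window 10, SNR threshold 4.5).

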