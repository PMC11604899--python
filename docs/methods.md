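# Methods

## Signal model

Dissolved-phase ¹²⁹Xe acquisitions excite a narrow band centered on the
membrane (M) resonance; gaseous xenon sits ≈197 ppm upfield and RBC-bound
xenon ≈21 ppm downfield of M (17.66 Hz/ppm at 1.5 T). Each compartment c is
modelled as a decaying complex exponential with offset Δf_c and relaxation
T2*_c. A voxel's RBC density is modulated by the cardiac cycle,

    ρ_rbc(r, t) = ρ_rbc(r) · [1 + α(r)/2 · f(ωt − ϕ(r))],

with f a zero-mean periodic waveform normalized to peak-to-peak 2, so α(r)
is the peak-to-peak fractional amplitude; ω = 2π·HR/60; and ϕ(r) the local
*lag* relative to a ϕ = 0 voxel. The sign convention follows the mapping
output: positive ϕ means the local oscillation peaks later than the
whole-lung k0 oscillation. Both dissolved compartments additionally carry a
global biexponential envelope D(t) = a₁e^(−t/τ₁) + a₂e^(−t/τ₂) emulating
RF-induced depolarization and T1 relaxation of the gas reservoir that feeds
them; defaults (a₁ = a₂ = 0.5, τ₁ = 3 s, τ₂ = 40 s) halve the dissolved
signal by ≈7 s, the window used for oscillation analysis. The gas
compartment, which is barely excited by the selective pulse, is simulated
with a small constant amplitude and no envelope.

The sampled signal of spoke s (excited at t_s, after 20 dummy excitations),
echo e, readout point p is

    y(s, e, p) = Σ_c A_c e^{iθ_c} E_c(t_e) D_c(t_s) · F[ρ_c,s](k_{s,p}) + n,

with E_c(t_e) = exp((i2πΔf_c − 1/T2*_c)·t_e) the chemical evolution at the
echo time, F the exact (direct, type-3) nonuniform DFT of the voxel maps,
and n circular complex Gaussian noise. Chemical evolution *within* a
readout is neglected in both the simulator and the separation — the same
approximation the multi-echo separation makes — so the noiseless
simulate→separate round trip is exact to solver precision. The exact DFT at
this scale (32³ grid, ≤1k spokes) removes gridding error from the ground
truth; the periodic waveform is expanded in its Fourier harmonics so the
time-varying volume reduces to a few static volumes with per-spoke scalar
coefficients (a sinusoid needs one harmonic; the asymmetric "systolic"
waveform a handful).

## Trajectory

Center-out 3D radial, 13 samples per spoke spaced uniformly from k = 0 to
k_max = 1.3 × (nominal Nyquist radius). With a 40-cm FOV and 2-cm nominal
resolution the Nyquist radius is 10 cycles/FOV, so k_max = 13 cycles/FOV;
images are reconstructed to 32³. The scanner's actual spoke ordering is not
published; the default here places spokes on a uniform spherical Fibonacci
lattice traversed with a golden-ratio index stride. This gives (i) a
uniform complete set, so the full-trajectory density compensation converges
(the raw 2D-golden-means direction generator has sub-kernel-scale clusters
that stall the fixed point at a residual ≈0.07), and (ii) equidistributed
temporally contiguous runs, which is what keyhole keys need. Archimedean
(spiral) and seeded-random orderings are available for comparison.

## Reconstruction

Gridding uses a separable Kaiser–Bessel kernel, width 4 grid units on a 2×
oversampled grid, β from Beatty's formula, with deapodization by the
kernel's continuous Fourier transform and cropping to 32³. Density
compensation is the multiplicative fixed point w ← w/(w ⊛ C) with C the
*radially symmetric* autoconvolution profile of the gridding kernel —
density compensation must not depend on a pattern's orientation, and the
separable product kernel's square footprint measurably breaks the symmetry
of, e.g., a uniform ring. Exactly coincident samples (every spoke's k = 0
point) are collapsed to one node with a multiplicity and share the weight
equally. Defaults: 25 iterations, tolerance 0.05 on max|w ⊛ C − 1|;
divergence is declared after three consecutive iterations more than 50%
above the best residual seen (the fixed point of undersampled keyhole
geometries plateaus with a slow percent-level creep, which is not
divergence). On the full default trajectory the residual reaches ≈8·10⁻⁴
in 25 iterations; on a 20%-key keyhole trajectory it plateaus near 0.15,
because the ≈3.7× sampling-density step at the keyhole radius cannot be
flattened in max-norm by positive weights — the weights remain finite and
well behaved, and each key gets its own compensation (measurably lower
sliding-key artifact than scaled full-trajectory weights).

## Processing chain

1. **Separation.** Least squares over the 4 echoes (4 ≥ 3 compartments)
   using E[e, c]; the condition number of E is reported (≈3.6 at the default
   shifts/echo times; a warning is raised above 10³).
2. **k0 analysis.** Membrane k0 magnitude normalized by its mean and fit to
   a biexponential (initialization τ₁ = 2 s, τ₂ = 15 s, amplitudes 0.5;
   monoexponential fallback with a warning). RBC k0 normalized by its mean
   and divided by the fit. Band-pass 0.5–2.5 Hz, 4th-order Butterworth run
   forward-backward (zero phase, so peak timing is unbiased). Peak detection
   with prominence 0.25× the in-window SD and 0.2-s minimum separation,
   alternation enforced; the first second (~60 spokes) is excluded as
   transient, optionally also a noisy tail. α_k0 uses extrema in the
   high-SNR window up to 7 s. Heart rate comes from the mean maxima
   spacing; N = round(mean spokes per cardiac cycle).
3. **Decay correction of k-space.** The mapped oscillation is defined on the
   decay-corrected signal, so every spoke's separated k-space is divided by
   the fitted membrane envelope before keyhole reconstruction; without this
   the ≈8%-per-cardiac-cycle decay drift aliases into the sliding-window
   amplitude and phase.
4. **Keyhole assembly.** Readout points beyond the keyhole radius (default
   6, i.e. points 7–13) from every spoke, plus points 1–6 from key spokes
   only. Keys grow symmetric windows around the detected extrema until each
   holds round(20% × n_spokes) spokes; high/low keys never overlap
   (windows shrink with a warning if they collide). Assembly operates on
   the raw multi-echo data; separation commutes per point.
5. **Maps.** Two-Key: α_2-Key = 100(S_high − S_low)/((S_high + S_low)/2).
   SW: key j is key 1 stepped forward j−1 spokes, j = 1…N; per voxel the
   signal across keys is smoothed with a Gaussian-weighted moving average,
   window length 10, σ = 2 keys. The even window is realized as the average
   of its two integer placements (an 11-tap symmetric kernel with the same
   window weights), so the smoothed argmax carries no half-key bias, and
   the boundary is *circular*: the key axis spans one cardiac cycle, so
   S(j) is periodic, and a reflective boundary measurably biases j_max for
   voxels peaking near the cycle boundary. α_SW = 100(S_max − S_min)/S_mean;
   j_max ties break to the smallest key; ϕ = wrap(2π(j_max − 1)/N) ∈ (−π, π].
   ϕ/ω converts phase to delay: π at 70 bpm ≈ 429 ms.
6. **Masking and regions.** Lung mask from a 3σ noise threshold on the
   membrane image (Rayleigh-corrected background), connected components
   (up to two, a second only if ≥10% of the largest — a genuine second lung
   is comparable in size), one-voxel closing. Left/right split at the
   sagittal gap near the bounding-box middle (fallback: midline);
   upper/lower and anterior/posterior at the extent midlines; central by
   2-voxel erosion, peripheral the remainder. RBC image SNR gate at 4.5
   with a borderline flag to 5.5. Summaries: mean for α_2-Key
   (approximately normal), median for α_SW and ϕ (skewed); spatial CV per
   map, with the CV of ϕ suppressed when the phase distribution approaches
   the wrap point. Repeatability: bias, 1.96-SD limits of agreement, mean
   absolute % difference (normalized by the two-scan mean), and 3-scan CV
   (sample SD over mean, per subject, averaged).

## What the phantoms emulate — and what they do not

The synthetic phantoms reproduce the acquisition geometry and timing, the
three-compartment spectrum, realistic decay, spatially varying oscillation
amplitude and phase, and calibrated image SNR (noise SD chosen so the
decay-corrected RBC image reaches a target constructed SNR; the default
study condition is SNR 15). They are piecewise-constant ellipsoid lungs:
no respiratory or bulk motion, no B1/coil shading, no heart-rate drift or
waveform variability over the breath hold, no susceptibility effects, and
chemical shifts/T2* that match the separation model exactly. Passing tests
therefore validate the *algorithms* under the stated acquisition physics,
not robustness to those confounds; with real data the keys drift "out of
step" as the heart rate wanders, which these phantoms do not exercise
(the window-mean cycle length is used and its spread is visible in the
detected peak intervals).

## Measured accuracy limits (study-scale phantoms)

Two limits are properties of the published method at this geometry, not of
any particular implementation, and the validation suite documents them
rather than hiding them:

* **Sliding-key sampling artifact.** Reconstructing a *static* object from
  the N sliding keys gives a per-voxel (S_max − S_min)/S_mean with median
  ≈12% (p90 ≈21%): the 20% key is ≈2× angularly undersampled at the outer
  keyhole shells and each key aliases differently. The level is invariant
  to spoke ordering, DCF kernel width, and iteration count. Consequently
  α_SW has an additive floor: programmed amplitudes of 20% and 40% are
  recovered within ±10%, but a 10% region reads ≈16–18%. The same
  inflation is visible in vivo, where cohort α_SW medians run roughly twice
  α_2-Key means.
* **Phase quantization and argmax sensitivity.** The phase estimator is the
  argmax of the smoothed S(j), quantized at 2π/N ≈ 0.11 rad (N ≈ 57 at
  70 bpm). The artifact flattens the curve's peak, so per-region median
  phases carry errors of ~0.1–0.35 rad that change with the key placement
  (heart rate, noise seed), even though the *fundamental-harmonic* phase of
  the region-mean S(j) is exact to <0.001 rad. Regional phase structure
  finer than lung scale is additionally compressed toward its surroundings
  by the keyhole aliasing (≈0.3 rad for adjacent bands). Phase maps should
  be read as reliable at the half-lung scale and to roughly ±2–3 key steps.

Other numerical facts from the validation runs: separation round trip exact
to ~10⁻¹⁵; interior NRMSE of an analytic uniform sphere 4.8% (excluding a
2-voxel boundary layer — the k-space support band-limits any
reconstruction to a ≈1.7-voxel edge transition); median of the per-key
maximum density-compensation weight ≈1.6; α_SW scan-rescan % difference
≈1% versus ≈4% for α_2-Key at SNR 15, mirroring the in-vivo ordering.

## Problem sizes

All validation and acceptance computations run at full study scale — 934
spokes, 32³ matrix, N ≈ 57 keys — except the unit-test fixtures (300
spokes, 16³) and the gridding oracle (2000 spokes for full angular
sampling). The trajectory-dependent systems (kernel-autoconvolution matrix,
gridding matrix) are built once per trajectory and shared across keys and
noise realizations, which makes a full mapping run ≈2 s after setup.
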