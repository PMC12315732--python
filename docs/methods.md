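# Methods

## Signal model

The package models the magnitude MR signal of a heterogeneous voxel under
tensor-valued diffusion encoding with relaxation weighting as a finite
mixture of discrete diffusion–relaxation components,

    S(b(ω), TE, TR) = Σ_c f_c · exp(−∫ b(ω) : D_c(ω) dω)
                          · (1 − exp(−TR · R1_c)) · exp(−TE · R2_c),

where b(ω) is the tensor-valued encoding power spectral density (its
frequency integral is the conventional b-tensor), ":" the Frobenius inner
product, and each component carries nine parameters: zero-frequency axial
and radial diffusivities D∥, D⊥ (μm²/ms), orientation (θ, φ), a common
high-frequency isotropic diffusivity D0, axial and radial transition
frequencies Γ∥, Γ⊥ (rad/s), and relaxation rates R1, R2 (s⁻¹).  The
frequency profile along each tensor axis is Lorentzian,

    D_axis(ω) = D_axis(0) + (D0 − D_axis(0)) · ω² / (ω² + Γ_axis²),

which interpolates monotonically between the long-time (zero-frequency)
diffusivity and the free high-frequency limit with corner frequency Γ — the
phenomenological signature of restricted diffusion under the Gaussian phase
approximation.  Both axes share D0; non-Gaussian (microscopic-kurtosis)
effects are outside the model.

Units: b in ms/μm² and D in μm²/ms (their product is dimensionless), TE in
ms, TR in s, angular frequency internally always rad/s with Hz only at I/O
boundaries.  The Γ sampling bounds 0.01–10⁴ are interpreted in rad/s.

### Encoding spectra

Two spectral representations are supported.  Gradient waveforms g(t) are
turned into full tensor-valued densities via the dephasing vector
q(t) = γ∫g dt′ and its Fourier transform; the density is normalized so the
frequency integral reproduces the time-domain b-tensor exactly (rectangle
rule on the DFT grid, exact by discrete Parseval; irregular grids fall back
to trapezoidal quadrature).  A narrow-band shortcut places all power at the
centroid frequency ω_cent, making the attenuation integral collapse to the
closed form b·Diso(ω)·(1 + 2 b_Δ D_Δ(ω) P₂(cos ψ)) for axisymmetric
tensors, with ψ the angle between encoding and component symmetry axes.

The default protocol contains 139 measurements: b = 0 entries spanning the
TR ladder (0.62–7.6 s) and TE ladder (40–150 ms), plus linear (b_Δ = 1),
planar (−0.5), and spherical (0) b-tensors at shells b = 0.1–3 ms/μm² and
centroid frequencies 6.6–21 Hz, with the attainable frequency decreasing
with b (21 Hz up to b = 0.5, 15 Hz up to 1.5, 11 Hz at 3).  The protocol's
measurements use the narrow-band representation: the default cohort and the
closure studies then run thousands of voxel inversions, and the closed-form
attenuation keeps the design-matrix cost independent of a spectral grid.
The waveform route (cosine bursts composed per axis) produces equivalent
narrow-band spectra and is exercised by the spectrum tests; rotating a
waveform rotates its b-tensor congruently.

The length scale probed by an encoding frequency is ℓ = √(2D/ω); at the
protocol's lowest centroid frequency (6.6 Hz) with intracellular
diffusivity 3.5 μm²/ms this gives ≈13 μm, which is why the narrow
experimental window is mainly sensitive to large restrictions and the
frequency-difference maps are noisy for typical cellular scales.

## Monte Carlo inversion

Estimating the nine-parameter component distribution from 139 measurements
is severely ill-posed.  The estimator is a bootstrapped, quasi-genetic NNLS
search:

1. **Bootstrap**: each of `n_bootstrap` replicates (default 300; reduced
   counts are used in the test studies) resamples the measurements with
   replacement at full length.
2. **Candidate sampling**: components are drawn log-uniformly in the scale
   parameters (diffusivities 0.05–5 μm²/ms, Γ 0.01–10⁴ rad/s, R1 0.2–2 s⁻¹,
   R2 1–30 s⁻¹) and uniformly on the sphere in orientation.
3. **Generations** (default 20, population 200): the population holds the
   current survivors, two mutated copies of each (multiplicative log-normal,
   scale 0.2, one copy annealed by 0.9 per generation — coarse-to-fine), and
   fresh random candidates.  NNLS weights the population against the
   resampled signals; positive-weight components (above 10⁻⁴ of total
   weight) survive.  The incumbent best solution is kept whenever a
   generation fails to improve the residual, so the residual trace is
   non-increasing.
4. **Prune and polish**: the solution is pruned to the `max_components`
   (default 10) largest weights and refit; a polish phase (default 25
   passes) then applies small annealed mutations to the pruned support
   only.  Without it the accepted solution is a diffuse cloud of
   near-degenerate components whose weighted-mean anisotropy is biased
   high; the polish collapses the cloud onto the data-supported optimum and
   is what brings noiseless recovery errors from ~10% to ~1–2%.

Per-voxel random streams derive from (seed, voxel index, replicate), so
results are independent of scheduling and iteration order.

**Magnitude noise floor.**  When magnitude data has not been denoised, the
Rician floor at strong diffusion/relaxation weighting masquerades as
slowly-attenuating signal and inflates spurious anisotropic weight.  The
inversion optionally applies the second-moment correction
ŝ = √max(m² − 2σ², 0) before fitting when the noise level σ is supplied
(`noise_sigma`); the synthetic closure studies supply σ exactly (measured
reference b = 0 signal divided by the nominal SNR), and real pipelines
would estimate it from the background or from repeated b = 0 scans.

## Consolidation and projections

Bootstrap ensembles are consolidated for visualization by k-means with the
L1 metric (k-medians: L1 nearest-centroid assignment, coordinate-wise
median updates, deterministic greedy-spread initialization) on the features
(Diso(ω_ref), D_Δ²(ω_ref), θ, φ, R1, R2), each divided by its pooled
maximum.  ω_ref defaults to the lowest protocol frequency (2π·6.6 rad/s).
k defaults to the median number of positive-weight components per
bootstrap.  Each cluster becomes one component: weight-weighted mean of
every parameter, median of member weights.  Representative components are
deposited (nearest cell, edge-clipped) on 64×64 meshes — Diso and
relaxation axes logarithmic over the sampling ranges, D_Δ² linear on
[0, 1] — normalized to unit sum.  ROI-characteristic distributions sum
voxel meshes per scan, normalize per scan, then average across scans.

## Parameter maps

Scalar statistics are computed per bootstrap replicate and
median-aggregated (the paper-standard robustification of the ill-posed
fit): E[x] is the weight-weighted mean over components, with Diso and D_Δ²
evaluated at the window's low end (6.6 Hz) and relaxation rates
frequency-free (relaxation does not depend on ω in the signal equation).
Δ_ω[x] is the raw difference of E[x] between the window endpoints (21 Hz
minus 6.6 Hz values), not divided by the bandwidth.  Spectral bins in the
(Diso, D_Δ²) plane at 6.6 Hz: bin 1 (WM-like) Diso ≤ 2.5 μm²/ms and
D_Δ² > 0.25; bin 2 (GM-like) Diso ≤ 2.5 and D_Δ² ≤ 0.25; bin 3 (CSF-like)
Diso > 2.5, including D_Δ² = 0 (a perfectly isotropic fast component is the
CSF prototype).  Boundary values deliberately go to the lower-index bin.
Because medians of per-replicate fractions need not sum to one, the three
median fractions are renormalized.  Bin-resolved relaxation means are NaN
(never 0) when a bin is empty.  ROI reductions exclude voxels with
estimated CSF fraction fbin3 > 0.2 and support majority-vote (≥50%)
template ROIs across subjects and repetitions.

## Reliability statistics

ICC(A,1) — single-measurement, absolute-agreement intraclass correlation —
is computed from the two-way ANOVA mean squares as
(MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE)); the absolute-agreement
single-measure value is identical across the two-way random/mixed
conventions.  Raw (possibly negative) values are returned, with clamping at
zero for summaries, and classified poor/moderate/good/excellent at
0.5/0.75/0.9.  CV_ws = √MS_ws/|grand mean| (absolute value because several
derived maps can be negative).  Bland–Altman summaries report the mean
test–retest difference, mean ± 1.96·SD limits of agreement, and the bias as
a percentage of the grand mean.  Voxel-wise analyses smooth maps with a
mask-renormalized Gaussian kernel (σ = FWHM/2√(2 ln 2), truncated at 4σ;
out-of-mask voxels contribute nothing and constants are preserved exactly);
the default FWHM is 4 mm at 2 mm voxels.  Heavy-tailed CV_ws distributions
(max > 100%) are trimmed by iteratively dropping values in automatic
histogram bins (numpy "auto": Freedman–Diaconis with Sturges fallback)
holding under 0.1% of the current count.

## Synthetic cohort

The phantom is a labeled block volume with four regions.  Archetypes
(chosen once, inside the sampling box, to land in the intended spectral
bins):

| region | composition | key values |
|---|---|---|
| WM-like | 0.85 anisotropic restricted + 0.15 near-isotropic | D∥=1.6, D⊥=0.25, D0=1.2, Γ⊥=2π·30 rad/s, R1=0.6, R2=15 |
| GM-like | single low-anisotropy | Diso≈0.8, D_Δ²≈0.05 at 6.6 Hz, R1=0.45, R2=11 |
| CSF-like | single fast isotropic | Diso=3.0, D_Δ²≈10⁻⁴, R1=0.25, R2=2 |
| mixed | 0.6 WM + 0.4 CSF partial volume | — |

The WM radial transition frequency sits near the encoding window, so its
anisotropy falls and Diso rises with frequency (D_Δ² ≈ 0.36 at 6.6 Hz,
0.15 at 21 Hz), making the frequency-difference maps nonzero and signed.
Between-subject biological variability is a multiplicative log-normal
perturbation (σ = 0.05) of each scale parameter, drawn once per subject and
shared across sessions; session noise is Rician, with σ defined at the
reference condition b = 0, longest TR, shortest TE (default SNR 50).  The
cohort defaults to ten subjects scanned twice.  Truth maps are computed
through the same statistics code as estimated maps.

What the generator does **not** emulate: anatomy, partial-volume geometry
beyond the mixed block, motion/eddy/susceptibility artifacts, spatially
correlated noise, and registration error.  Reliability numbers from this
cohort therefore isolate estimator-plus-noise variability; in vivo values
additionally contain registration and physiological terms.

## Study sizes and numerical choices

The test studies are scaled to desk hardware: noiseless recovery uses 50
voxels × 64 bootstraps (population 100, 12 generations) and requires the
median of E[Diso], E[D_Δ²], E[R1], E[R2] within 5% of truth; the SNR-50
closure uses 4 voxels per region × 64 bootstraps (population 200, 20
generations) with the floor correction; the reliability-closure
monotonicity study uses 4 subjects × 2 sessions × 8 voxels at three noise
levels with 8 bootstraps.  The ICC calibration study uses 200 simulated
tables (n = 10, k = 2) per variance ratio.

Known limitations:

- **Bin closure near boundaries.**  Spectral-bin fractions are threshold
  integrals, so their accuracy degrades sharply when true components sit
  near a bin boundary.  At SNR 50 two phantom regions expose this: the
  restricted WM component's anisotropy at the 6.6 Hz evaluation frequency
  (D_Δ² ≈ 0.36, pulled down from its 0.41 zero-frequency value by the very
  restriction the phantom is built to exhibit) straddles the 0.25 split
  under noise, and the mixed voxel's CSF component (Diso = 3.0, ~0.08
  above the 2.5 split in log₁₀) scatters across the diffusivity boundary.
  Measured mean absolute bin-fraction errors are ≈0.07 (GM) and ≈0.04
  (CSF) but 0.09–0.12 (WM) and 0.12–0.18 (mixed) across estimator
  configurations and noise realizations.  Deeper searches, more
  bootstraps, and the floor correction do not reduce the WM/mixed errors —
  they are bias of the ill-posed fit at this noise level, not search
  variance — so the bin-closure checks for those two regions fail at the
  fixed study conditions, and the acceptance suite reports them as such.
  The corresponding in vivo observation is the poor voxel-wise
  repeatability of fbin3 in low-CSF regions.
- Frequency-difference maps Δ_ω[x] are differences of two nearly equal
  estimates and carry the worst noise amplification of all outputs; only
  their sign in strongly restricted regions is asserted.
- The quasi-genetic search is stochastic; per-voxel medians over bootstraps
  are the stable quantities, individual replicate solutions are not.
- At low SNR the Rician floor correction clips corrected signals at zero,
  which slightly biases the weakest measurements; this is preferable to the
  uncorrected floor bias.
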