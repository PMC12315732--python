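# mdmri — diffusion–relaxation correlation MD-MRI analysis

Multidimensional diffusion–relaxation MRI (MD-MRI) replaces voxel-averaged
diffusion and relaxation metrics with a nonparametric joint distribution of
frequency-dependent diffusion tensors **D**(ω) and relaxation rates R1, R2.
Each voxel's signal under tensor-valued encoding with spectral content
b(ω), echo time TE and repetition time TR is modeled as a weighted sum of
discrete components:

    S(b(ω), TE, TR) = Σ_c f_c · exp(−∫ b(ω):D_c(ω) dω)
                          · (1 − exp(−TR·R1_c)) · exp(−TE·R2_c)

with each component an axisymmetric tensor whose axial and radial
diffusivities follow Lorentzian frequency profiles
D(ω) = D(0) + (D0 − D(0))·ω²/(ω² + Γ²) — the signature of restricted
diffusion.  The distribution is estimated per voxel by Monte Carlo
inversion: random candidate components, non-negative least squares (NNLS)
weighting, quasi-genetic survivor refinement, and bootstrap replication over
resampled measurements.  The ensemble is reduced to scalar maps — E[Diso],
E[D_Δ²], E[R1], E[R2], their frequency differences Δ_ω[x], and spectral-bin
signal fractions f_bin1–3 (≈ white matter, gray matter, CSF) — whose
test–retest reliability (ICC(A,1)), repeatability (CV_ws), and bias
(Bland–Altman) the package quantifies on a synthetic test–retest phantom
cohort.

The package is aimed at researchers developing or validating quantitative
MD-MRI pipelines who need a fully synthetic, ground-truth-controlled
test bed for the estimation and reliability-analysis chain.

## Worked example

```python
import numpy as np
import mdmri

# the sparse 139-measurement protocol: b = 0.1–3 ms/um^2, linear/planar/
# spherical b-tensors, centroid frequencies 6.6–21 Hz, TR/TE ladders
protocol = mdmri.make_default_protocol(seed=0)
print(len(protocol))                                  # 139

# a white-matter-like voxel: one restricted anisotropic component
wm = mdmri.VoxelDistribution.from_components([
    mdmri.DRComponent(d_par=1.6, d_perp=0.25, theta=0.3, phi=1.1, d0=1.2,
                      gamma_par=6283.0, gamma_perp=188.5, r1=0.6, r2=15.0),
])
signal = mdmri.signal(wm, protocol)

# Monte Carlo inversion (reduced bootstrap count for the example)
cfg = mdmri.InversionConfig(n_bootstrap=16, population_size=100,
                            n_generations=12, seed=0)
result = mdmri.invert_voxel(signal, protocol, cfg)
stats = mdmri.voxel_statistics(result)
print(round(stats["e_diso"], 3), round(stats["e_ddeltasq"], 3))
# 0.733 0.365   (truth at 6.6 Hz: Diso = 0.729, D_Delta^2 = 0.356)
print([round(stats[f"fbin{j}"], 2) for j in (1, 2, 3)])
# [0.83, 0.17, 0.0]  (dominantly anisotropic, WM-like)
```

Test–retest statistics on a cohort table (subjects × sessions):

```python
table = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0]])
mdmri.icc_a1(table)     # 0.6667 — moderate reliability
mdmri.cv_ws(table)      # 0.2828 — within-subject CV of 28%
```

An end-to-end run (simulate → invert → maps → reliability → report) is
available through the CLI:

```bash
mdmri demo --out demo_run --seed 0
```

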