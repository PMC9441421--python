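# Methods

## Measurement model

The acquisition modeled here is clinical echo-planar DWI with three
motion-probing gradients applied along the **image axes** (not the magnet
frame) at a single non-zero b-value, plus a b=0 volume. Because only
b ∈ {0, b} is available per axis, diffusivity is estimated voxelwise by the
monoexponential inversion `ADC_i = ln(S0/S_i)/b`; no diffusion tensor is
fit (three axis-aligned directions cannot determine off-diagonal terms).
All diffusivities are stored in units of 10⁻³ mm²/s, so a value of 1.2
means 1.2·10⁻³ mm²/s; b is in s/mm² (default 1000).

Voxel policy: a voxel is valid only if S0 and all three DWIs are positive
there; invalid voxels carry NaN and a `False` mask entry rather than a
clamped value, because clamping would bias ROI means. Negative ADCs
(S_i > S0, a noise effect) are kept and counted (`ADCMaps.n_negative`);
zeroing them would bias means upward. Region summary SDs use the sample
estimator (n−1).

## ROIs and the index

ROIs are circles on one axial slice — the slice through the body of the
lateral ventricle — defined by center (row, col) and radius in voxels,
with inclusive boundary membership ((r−cr)² + (c−cc)² ≤ radius²) so voxel
counts are bit-exact. Config-driven geometric ROIs replace expert manual
placement; this trades anatomical fidelity for reproducibility, which is
the right trade for a tested pipeline. Default radius 2.5 voxels,
configurable; observers in practice use small ROIs of a few voxels.

The index is `mean(ADCx_proj, ADCx_assoc) / mean(ADCy_proj, ADCz_assoc)`.
Left/right hemisphere ROI means are averaged per fiber type **before** the
formula (symmetric treatment, standard ALPS practice); per-hemisphere
indices remain available via `hemisphere_indices`. Non-positive
denominators raise rather than return infinities.

The composite image maps ADC_x→red, ADC_y→green, ADC_z→blue with channel
value `clip(ADC/adc_ref, 0, 1)`, `adc_ref` = 2.0·10⁻³ mm²/s by default.
This is a fixed-reference brightness scheme, not anisotropy-weighted
eigenvector coloring (impossible without a tensor); it preserves the
axis-to-color assignment that ROI placement relies on. PNG export
quantizes with round-half-up so golden-image comparisons are bit-exact.
The ventricle-slice suggester scores each slice by the central-band count
of CSF-like voxels (mean ADC > 2.0·10⁻³ mm²/s, band = central half of rows
and columns), breaking ties toward the lowest slice; it is advisory only.

## Phantom simulator

Phantoms are axis-aligned blocks on a 64×64×32 grid (in-plane resolution
and slice thickness of the modeled scan are not fixed by the method, so
voxel units are used): a central CSF stack tapered to be widest at slice
16 (isotropic D = 3.0), mirrored projection blocks (default
D = (1.2, 0.4, 1.4)) and association blocks (D = (1.2, 1.4, 0.4)) sharing
the perivascular Dx, over an isotropic background (D = 0.8). Tensors are
diagonal by construction — a 3-axis measurement is blind to off-diagonal
terms — which is a deliberate simplification: real fibers are oblique, so
passing phantom tests demonstrates correctness of the estimator chain, not
robustness to anatomy, head rotation or partial-volume effects.

Signal: `S_i = S0 · exp(−b·D_i)` with S0 = 1000 in tissue; noise is Rician
(`|S + n₁ + i·n₂|`, n ~ N(0, σ²)), the correct magnitude-MRI model whose
small-signal upward bias is what the noise tests probe. SNR means S0/σ.
The closed-form ground-truth index `mean(Dx_proj, Dx_assoc)/mean(Dy_proj,
Dz_assoc)` is 3.0 for the default preset, 2.0 for the reduced-perivascular
preset, 1.0 for the isotropic null, and 1.5 for a "normal-range" preset
chosen to sit inside the range reported for healthy adults (~1.3–1.6).
The default preset's strong anisotropy makes closed-form checks sharp;
the normal-range preset exists for realism-flavored experiments.

All randomness flows from one integer seed through
`numpy.random.default_rng`; the four volumes draw noise in fixed order
(b0, x, y, z), so outputs are bit-reproducible.

## Cohort simulator

Ages are drawn uniformly (integer years) within each decade with counts
(24, 21, 14, 15, 19, 14, 15, 6) for the 10s…80s — n = 128, matching the
reference normal-cohort composition. The true index follows
`peak_value − curvature·(age − peak_age)²` with defaults peak 1.6 at 45
years and curvature 2·10⁻⁴ per year² (≈0.24 index units lower at the age
extremes, comparable to published normal ranges). Subject noise SD 0.1
index units; observer readings add independent N(0, 0.05²). The observer
SD was set from the attenuation identity
E[r] ≈ var_subj/(var_subj + var_obs) so that simulated inter-observer
correlation lands near the mid-0.8s typical of trained readers. The
generator omits real-data features — ROI placement variability between
observers (observer noise is additive on the index, not geometric), head
positioning, age-varying variance, scanner drift — so cohort tests verify
the statistics, not rater behavior.

## Statistics

* Inter-observer agreement: Pearson r (two observers required), CI by
  Fisher z with normal critical values; ICC(2,1) offered as a labeled
  extension for absolute agreement.
* Regressions: OLS of the across-observer mean index on age; the
  "older than 40" subgroup filter is strict (age > 40). Linear fits report
  signed r; the quadratic fit reports R = √R² and the vertex −b₁/(2b₂)
  only when the parabola opens downward. Degenerate designs (constant
  response ⇒ R² = 0/0, treated as 0; fewer than 3 distinct ages) are
  handled explicitly.
* Decade ANOVA: one-way F across decade groups (groups with <2 records are
  dropped with a log notice); post-hoc all-pairs Tukey HSD at family-wise
  0.05 — chosen as the standard symmetric all-pairs procedure. The
  `posthoc=False` path, used by large calibration simulations, computes
  the identical F and p.
* Boxplot summaries use type-7 (linear-interpolation) quantiles and the
  1.5·IQR outlier rule, fixed for reproducibility.

## Problem sizes and numerical tolerances

Noiseless phantom checks require relative error < 10⁻⁹ voxelwise ADC and
< 10⁻⁶ end-to-end index (observed ~10⁻¹⁶). Stochastic checks run at sizes
chosen to make the Monte-Carlo error small relative to the asserted bound:
50 Rician replicates for the SNR-20 bias bound (2%), 100 cohorts for
peak-age recovery (±5 years), and 1000–2000 null cohorts for ANOVA type-I
calibration (band [0.03, 0.07] around α = 0.05). Statistical routines are
verified against brute-force sum-formula oracles at 10⁻¹².

## CLI conventions

Subcommands mirror the stages (`simulate`, `adc`, `composite`, `measure`,
`cohort-stats`, `run`); every run writes a JSON manifest with parameters,
package version and SHA-256 of each artifact. Exit codes follow click:
0 success, 2 usage error, 1 runtime/data error.

## Known limitations

No DICOM ingestion, registration, eddy-current or noise-floor correction;
ROIs are planar circles, not anatomical masks; phantoms have no partial
volume, crossing fibers or susceptibility effects; cohort models have no
covariates beyond age. The headline statistics of any particular clinical
cohort depend on its raw measurements and are not reproduced here — the
package verifies the formulas, estimators and analysis structure against
ground truth it generates itself.
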