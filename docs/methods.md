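# Methods

## The measurement model

A blood-pool contrast agent (liposomal gadolinium for MRI, liposomal iodine
for CT) remains intravascular over the imaging window and does not cross the
placental barrier. Under fast exchange of water between vascular and
extravascular spaces, a tissue voxel whose volume fraction `f` is blood
changes its longitudinal relaxation rate by the same fraction of the blood's
change:

```
R1_tissue,post = R1_tissue,pre + f · ΔR1_blood
HU_tissue,post = HU_tissue,pre + f · ΔHU_blood
```

Inverting either relation with the IVC as the `f = 1` reference gives the
two FBV estimators, `ΔR1_P/ΔR1_IVC` and `ΔHU_P/ΔHU_IVC`. Linear mixing is
the unique generative model under which both ratio estimators are unbiased,
which is what makes round-trip recovery on the phantom a meaningful test:
the generator and the estimators are mutual inverses in the noiseless limit,
to machine precision.

Consequences worth noting:

- **MRI FBV is invariant to global signal scaling** (receiver gain, coil
  sensitivity, the `e^(−TE/T2)` factor), because VFA T1 estimation is itself
  scale-invariant. A gain change *between* the pre- and post-contrast scans,
  however, breaks nothing in T1 fitting but is not detectable by the
  pipeline; constancy of receiver gain is an assumption the user must
  guarantee on real data.
- **CT FBV is invariant to a common HU offset** applied to both scans, but a
  multiplicative recalibration applied to only one scan biases the ratio.
  Both behaviours are asserted in the test suite.
- Estimates are maternal-side only: the agent never reaches fetal
  circulation, so `f` is the maternal blood fraction.

## VFA T1 estimation

The spoiled-GRE steady-state signal is linearized as
`S/sin α = e^(−TR/T1) · S/tan α + M0(1 − e^(−TR/T1))` and fitted by
unweighted ordinary least squares on the per-flip-angle ROI means (pool,
then fit). No nonlinear refinement pass is applied; a weighted or
Levenberg-style refinement would be a natural extension but the linear fit
is the documented reference procedure and recovers noiseless T1 to better
than 1e−9 relative error. Flip angles are taken as nominal (no B1
correction).

Numerical choices:

- `x = S·cos α / sin α` rather than `S/tan α` so that α = 90° yields exactly
  x = 0 (cos(π/2) is not exactly zero in floating point).
- Fits with slope outside (0, 1), or T1 outside (1, 10000) ms, or a
  degenerate abscissa spread are returned as invalid results carrying a
  reason string, never exceptions; voxelwise maps encode invalid voxels as a
  −1 sentinel so a T1 map remains a single scalar field.
- An invalid IVC fit aborts the whole subject (the blood reference is
  load-bearing); an invalid placental fit yields a NaN estimate flagged
  `INVALID_FIT`.
- ROI-mean fitting is the only path feeding FBV. Voxelwise maps are for
  inspection; for a homogeneous compartment the two agree exactly, which the
  suite asserts.

The simulator applies the full signal model including `e^(−TE/T2)`
(TE = 3.5 ms; T2 defaults: 50 ms tissue, 100 ms blood) while the estimator
assumes TE ≪ T2. Because the T2 factor is flip-angle-independent it is
absorbed by scale invariance; the residual bias on fitted T1 is below 0.5 %
and is verified numerically rather than assumed.

## The digital phantom

Geometry is deliberately schematic — parametric shapes on a 3×3×2 cell
lattice with seeded jitter: ellipsoidal amniotic sacs each capped by a
discoid placenta, a ~2 mm diameter cylindrical IVC, an ellipsoidal maternal
body, air outside. ROI statistics, not anatomy, drive the analysis, so shape
realism buys nothing for these tests. Each phantom guarantees ≥ 50 voxels
per placenta and ≥ 30 IVC voxels or raises.

Defaults emulate late-gestation mice at 1 T:

| parameter | default | note |
| --- | --- | --- |
| grid | 96³ voxels at 0.5 mm isotropic | matches the GRE voxel size; CT is simulated on the same grid since ROI-mean ratios are grid-invariant under linear mixing |
| acquisition | TR 20 ms, TE 3.5 ms, α = 8/15/25/35/45° | the VFA protocol |
| placenta T1 pre (ms) | 1300 / 1240 / 1200 | E14.5 / E16.5 / E18.5 presets |
| blood T1 pre→post (ms) | 1020→690, 1150→600, 1060→480 | per-age presets; post-contrast placental T1 is *derived* from `f` via linear mixing, not set independently |
| blood fraction `f` | mean 0.47/0.50/0.52, SD 0.06/0.04/0.04 | per-age cohort statistics; each FPU draws its own `f`, clipped to [0, 1] |
| litter size | 6–10 FPUs per subject | drawn per subject unless fixed |
| M0 (a.u.) | placenta 1000, AF 900, body 800, blood 1000 | arbitrary units; only ratios across flip angles matter |
| HU | placenta 55, AF 15, body 45, blood 55→555 | soft-tissue-range baselines; +500 HU blood enhancement is typical of a nanoparticle CT agent at steady state |
| AF T1/T2 | 2500 / 200 ms | fluid-like; AF never enhances in either modality |
| noise | NONE by default; GAUSSIAN with σ = max(pre-contrast signal)/SNR, SNR 50 | SNR is a repository choice (no measured value to emulate); Rician available for magnitude-image realism studies |

Blood properties are shared across a subject's FPUs — one maternal IVC per
animal — so all of a subject's estimates divide by the same reference ΔR1.

What the phantom does **not** emulate: fetal/maternal motion, partial-volume
mixing at compartment boundaries (compartments are homogeneous), B1
inhomogeneity, CT beam hardening, contrast-agent kinetics over time (the
agent is treated as a steady-state blood pool), and intra-placental
heterogeneity. Passing round-trip tests therefore demonstrate correctness of
the estimators under the stated model, not robustness to these real-data
effects; the noise criterion probes only sensor noise.

## Statistics

- **Bland-Altman**: per-pair percent differences `100·(MRI − CT)/mean` by
  default (the pair mean is the standard denominator), limits of agreement
  at bias ± 1.96 sample SD. Differences can also be computed on the absolute
  FBV scale; the CLI emits both, percent primary, since the two conventions
  answer slightly different questions and published practice varies.
- **Wilcoxon rank-sum**: two-sided throughout. Exact null distribution when
  the pooled sample is ≤ 20 and tie-free; otherwise a normal approximation
  with midranks, tie-corrected variance and continuity correction (ties make
  the exact distribution nonstandard). The exact path is validated against
  brute-force enumeration of all rank splits. Exhaustive comparison at 8+8
  shows the approximation tracks the exact two-sided p to within 0.011
  (worst case near p ≈ 0.44). No multiple-testing correction is applied.
- Significance tiers: 3 stars for p < 0.0005, 2 for p < 0.005, 1 for
  p < 0.05, strict inequalities.
- Sample (n−1) SD everywhere; cohorts are small.
- Out-of-range FBV (outside [0, 1], possible under noise) is flagged
  `OUT_OF_RANGE` but retained — box plots and agreement analyses should see
  outliers, not a censored sample.

## Known inconsistency in cohort-level inputs

Plugging cohort-*mean* T1 values into the FBV ratio does not reproduce
cohort-mean FBV: the ratio of means is not the mean of per-FPU ratios (for
the E14.5 preset the ratio of means gives 0.76 against a cohort mean of
0.47; for E18.5, 0.487 against 0.52). The package therefore validates FBV by
per-FPU round-trip recovery — each placenta is simulated with a known `f`
and the pipeline must return it — and never by evaluating the estimator on
cohort means. The ratio-of-means value appears in the suite only as a
hand-arithmetic check of the estimator formula itself.

## Problem sizes

Unit tests run phantoms at 48³ with 2–4 FPUs: noiseless round trips are
grid-invariant, so the smaller grid checks the same property. The acceptance
script runs the default 96³ conditions with 6 FPUs per deterministic target,
and a 3-subject / 20-FPU cohort (7+7+6) at SNR 50 for the stochastic one.
Simulation-based statistical properties use 10⁴ Bland-Altman pairs and 2000
rank-sum replicates.
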