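# placfbv

Estimation of **placental fractional blood volume (FBV)** from
contrast-enhanced imaging, with a digital pregnant-mouse phantom for
validation.

Placental FBV — the fraction of placental tissue volume occupied by maternal
blood — is a marker of placental perfusion, and abnormally low values may
flag placental insufficiency and fetal growth restriction. With a blood-pool
contrast agent that stays intravascular and does not cross the placental
barrier, the contrast-induced change in a tissue's MR relaxation rate (or CT
attenuation) is proportional to the blood volume it contains, so FBV can be
read off by normalizing against a pure-blood reference vessel (the inferior
vena cava, IVC):

```
FBV_MRI = ΔR1_P / ΔR1_IVC          R1 = 1/T1,  Δ = post − pre contrast
FBV_CT  = ΔHU_P / ΔHU_IVC          HU = Hounsfield units
```

T1 is measured by the **variable flip angle (VFA)** method: spoiled
gradient-recalled-echo (GRE) images at flip angles α = 8°, 15°, 25°, 35°, 45°
with TR = 20 ms, TE = 3.5 ms. The steady-state signal

```
S(α) = M0 (1 − E1) e^(−TE/T2) sin α / (1 − E1 cos α),   E1 = e^(−TR/T1)
```

linearizes to `S/sin α = E1 · S/tan α + M0(1 − E1)`, so an ordinary
least-squares line through the per-flip-angle ROI means yields
`T1 = −TR / ln(slope)`.

The package provides:

- `core_io` — NIfTI volumes and label masks, YAML study manifests, CSV
  tables, and a `placfbv` CLI;
- `synthetic_phantom` — a multi-compartment 3D phantom (placentae, amniotic
  sacs, IVC, maternal body) with known per-placenta blood fractions, and
  forward simulation of pre/post-contrast VFA MRI series and CT pairs with
  seeded Gaussian or Rician noise;
- `vfa_t1_mapping` — the GRE signal model and the linearized VFA T1
  estimator (ROI-mean and voxelwise);
- `fbv_pipeline` — per-placenta FBV estimates and cohort summaries;
- `agreement_stats` — Bland-Altman limits of agreement and Wilcoxon
  rank-sum tests between modalities and gestational ages.

## Worked example

Simulate a two-subject cohort at gestational day E16.5 with Gaussian noise
(SNR 50) on a small 48³ grid, then run both arms of the pipeline and compare
them:

```sh
cat > cfg.yaml <<EOF
grid_shape: [48, 48, 48]
EOF
placfbv --seed 11 --out-dir sim --config cfg.yaml simulate \
    --age E16.5 --subjects 2 --noise GAUSSIAN --snr 50
placfbv --out-dir mri fbv sim/subj01_manifest.yaml sim/subj02_manifest.yaml --modality mri
placfbv --out-dir ct  fbv sim/subj01_manifest.yaml sim/subj02_manifest.yaml --modality ct
placfbv --out-dir agr agree mri/fbv_estimates.csv ct/fbv_estimates.csv
```

`mri/fbv_estimates.csv` holds one row per feto-placental unit (FPU):

```
subject,fpu,gestational_age,modality,fbv,numerator,denominator,flags
subj01,0,E16.5,MRI,0.5317296821492838,0.0004239961567445126,0.0007973904240791943,
subj01,1,E16.5,MRI,0.4446117184528406,0.0003545291267276899,0.0007973904240791943,
```

`numerator`/`denominator` are the placental and IVC ΔR1 in 1/ms (all FPUs of
a subject share the subject's IVC reference). The cohort summary

```
gestational_age,modality,n_fpu,mean_fbv,sd_fbv
E16.5,MRI,18,0.4927242182190019,0.035762938459667985
```

says the 18 simulated placentae (true fractions drawn around 0.50) came back
with mean FBV 0.493 ± 0.036 despite image noise. `agr/agreement_summary.json`
reports the cross-modality agreement, e.g. a Bland-Altman bias of −0.42 % with
limits of agreement [−6.6 %, +5.7 %] and all pairs within the limits, and a
rank-sum p-value for MRI vs CT.

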