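# lesym — voxel-based and tract-based lesion-symptom mapping

`lesym` analyses cohorts of co-registered **binary lesion maps** — white
matter lesions (WML) and small lacunar lesions (LL) on a shared template
grid — against cognitive performance, asking whether *where* a lesion sits
matters beyond *how much* lesion there is. It is aimed at researchers in
cerebral small-vessel disease and vascular cognitive impairment who have
per-patient lesion segmentations in a common space, a probabilistic white
matter tract atlas, and neuropsychological test scores.

The analysis has two stages:

1. **Voxel-based lesion-symptom mapping (VLSM).** Composite domain
   z-scores (memory, executive, speed/attention — lower-better subtests
   sign-flipped, each subtest z-scored against the sample, averaged per
   domain) are residualised on age, sex, education level and a reading
   test by OLS. At every voxel lesioned in at least `min_patients`
   (default 5) patients, a pooled-variance two-sample t-test compares
   residual scores of intact vs lesioned patients,

   t = (x̄_intact − x̄_lesioned) / (s_p · √(1/n₁ + 1/n₀)),  df = n₁ + n₀ − 2,

   so t > 0 means lesioned patients perform worse. Benjamini–Hochberg
   FDR at q = 0.05 over the eligible voxels gives the p (and equivalent
   t) threshold; surviving voxels are grouped into 3D connected
   components (26-connectivity by default).

2. **Tract-ROI analysis and the regression ladder.** Each probabilistic
   tract is thresholded at 0.1; a tract is *selected* when it contains
   more than 50 significant voxels or a single significant cluster
   overlapping it in more than 5 voxels. Per-patient regional lesion
   volumes (ml) within each tract mask then enter a fixed nested sequence
   of twelve OLS models (covariates → + total burden → + regional
   volumes), each increment tested with the partial-F statistic on ΔR²:

   F = (ΔR²/k) / ((1 − R²_ext)/df_ext).

   The coefficient of interest, B (z-units per ml of regional lesion
   volume, with t-based 95% CI), quantifies the *strategic* effect of
   lesions in that tract over and above total lesion burden.

Because no suitable patient cohort is publicly deposited, the package
ships a fully synthetic cohort generator (`lesym.simulate`) with planted,
recoverable effects: smooth thresholded Gaussian random fields for the
confluent WML pattern, sparse spheres for lacunes, and a linear latent
cognition model. Every downstream stage is validated by oracle
equivalence, calibration and parameter recovery on these cohorts (see
`docs/methods.md`).

## Worked example

```python
import lesym

sim = lesym.replicate_config(seed=1)          # 300 patients, 32x32x16 grid
cfg = lesym.PipelineConfig(mode="synthetic", sim=sim, seed=1,
                           ladder_tracts=("tract_a", "tract_b"),
                           write_volumes=False)
report = lesym.run_pipeline(cfg)
print(report.summary)
print(report.ladder.to_frame()[["r2", "delta_r2", "p_delta_r2", "B"]].round(3))
```

prints (tract summary, then an excerpt of the ladder report):

```
         n_significant  largest_cluster_overlap  selected
tract
tract_a            187                      187      True
tract_b              1                        1     False

          r2  delta_r2  p_delta_r2      B
model
1      0.292       NaN         NaN    NaN
2a     0.302     0.011       0.036 -0.301
2b     0.320     0.029       0.001 -0.062
2c     0.330     0.038       0.000    NaN
3a     0.358     0.066       0.000 -3.664
3b     0.293     0.001       0.542 -0.391
3c     0.531     0.239       0.000 -1.237
3d     0.292     0.000       0.727  0.042
4a     0.389     0.059       0.000 -4.062
4b     0.333     0.003       0.272  0.920
4c     0.538     0.208       0.000 -1.249
4d     0.336     0.006       0.095  0.206
```

Reading this: this synthetic cohort was generated with a lacunar effect
of −3.0 z/ml and a WML effect of −1.2 z/ml planted in tract A only. VLSM
lights up 187 voxels in tract A (selected by both rules) and essentially
nothing in the null tract B. In the ladder, model 1 (covariates) explains
29% of variance; adding regional LL volume in tract A on top of total
lesion burden (model 4a) raises R² by 0.059 (partial-F p < 0.001) with
B = −4.06 (95% CI −5.57 to −2.56), covering the planted −3.0 — the
strategic-location signal survives adjustment for total burden, while the
same terms for the null tract (4b/4d) stay flat.

The same analysis is scriptable from the shell:

```sh
lesym simulate --out sim/ --seed 1            # cohort NIfTIs + tables + ground truth
lesym run --seed 1 --out run/                 # full pipeline, report bundle
lesym vlsm --cohort sim/cohort/manifest.tsv --scores run/residual_scores.tsv \
      --domain executive --class wml --q 0.05 --min-patients 5 --out vlsm/
```

`lesym run` writes prevalence/t/p/significance/cluster volumes (NIfTI),
tract summary, regional volumes and the ladder report (TSV), and a
`run_manifest.json` echoing every parameter and seed; reruns with the
same config and seed are bit-identical.

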