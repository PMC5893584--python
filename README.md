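# uromet

Longitudinal analysis of urinary organic-acid profiles from crossover
intervention studies.

## The problem

Acute-intervention metabolomics studies (for example a controlled single
alcohol dose) measure a panel of urinary organic acids by GC–MS in every
participant at several hourly time points, under both a vehicle and an
active intervention, in a two-period crossover.  The resulting data are
longitudinal (5 hours), multi-subject (n = 12), two-arm, and wide
(~120 creatinine-normalized metabolite concentrations, μmol/mmol Cr).
`uromet` implements the statistical workflow such studies need,
end-to-end and reproducibly, for analysts working with this kind of
repeated-measures profiling data:

- **Preprocessing** — creatinine normalization (v / Cr), half-minimum
  imputation of non-detects, log transform with auto/Pareto scaling,
  pooled-QC and repeat-injection repeatability diagnostics.
- **Cross-sectional latent models** — PCA and two-class NIPALS PLS-DA
  (control hour vs post-intervention hour) with variable importance in
  projection, VIPⱼ = √( p · Σₐ SSYₐ (w_{ja}/‖wₐ‖)² / Σₐ SSYₐ ), so that
  mean VIP² = 1.
- **ASCA** — ANOVA-simultaneous component analysis: the centered matrix
  is partitioned into additive time- and participant-effect matrices
  plus residual (X = M_time + M_subject + E), each effect summarized by
  simultaneous component analysis with 95 % centroid ellipses, and the
  time effect tested by permuting hours within subjects.
- **Unfolded PCA** — the cases × metabolites × hours tensor is unfolded
  to cases × (metabolite·hour); per-hour *block scores* (which sum to
  each case's total score) trace a trajectory per case, with per-hour
  90 % score ellipses and bi-plot ranking of metabolites by the sum of
  squared loadings on the first two components.
- **Selection & univariate statistics** — signed fold change
  (+ratio or −1/ratio), exact Wilcoxon signed-rank p-values (full
  sign-assignment enumeration up to n = 25, mid-ranked ties), and the
  triple criterion **VIP ≥ 1.0 ∧ p ≤ 0.05 ∧ |FC| ≥ 1.5**; Spearman
  correlation matrices with fixed colour bands (|r| ≥ 0.6 high,
  0.2–0.6 moderate, < 0.2 neutral); analytic noncentral-t paired power
  with a Monte-Carlo companion.
- **Synthetic studies** — a generator that emulates the crossover design
  (subject random effects, lognormal noise, per-void creatinine,
  planted time-response shapes, the 25-injection QC/repeat batch
  layout), plus recovery scoring against the planted truth.

## Worked example

```python
from uromet import (GeneratorConfig, PipelineConfig, generate_study,
                    paired_power, run_pipeline, table1_preset)

truth = table1_preset()                      # 13 planted alcohol responses
table, truth = generate_study(GeneratorConfig(), truth, seed=17)
res = run_pipeline(PipelineConfig(outdir="results/demo", seed=17), table=table)

selected = res["biomarkers"].query("selected")
print(selected[["metabolite", "vip", "p_0_1", "fc_0_1"]]
      .round(3).to_string(index=False))
print("ASCA time-effect permutation p:", res["asca_perm"]["p_value"])
print("power (d=0.9, n=12, alpha=0.05):", round(paired_power(0.9, 12), 3))
```

prints

```
              metabolite   vip  p_0_1  fc_0_1
             lactic acid 3.243  0.000  23.926
            fumaric acid 2.990  0.000   7.831
   3-hydroxybutyric acid 2.966  0.000   4.623
              malic acid 2.841  0.000   3.076
   2-hydroxybutyric acid 2.736  0.000   5.706
           succinic acid 2.545  0.000   2.284
           hippuric acid 2.521  0.000   4.327
2-hydroxyisobutyric acid 2.275  0.001   1.915
 2-ethylhydracrylic acid 2.058  0.000   2.091
  2-hydroxyglutaric acid 1.739  0.000   2.190
   vanillylmandelic acid 1.385  0.001  -1.687

ASCA time-effect permutation p: 0.005
power (d=0.9, n=12, alpha=0.05): 0.81
```

At this study's realistic noise level the triple criterion recovers 11
of the 13 planted responses in this run (sorted by VIP; `fc_0_1` is the
signed fold change of the 1 h mean vs the 0 h control mean, so lactic
acid rises ~24-fold while vanillylmandelic acid falls).  The ASCA
permutation p of 0.005 = 1/200 is the smallest value attainable with 199
permutations, and a paired design with 12 subjects has 81 % power for a
large (d = 0.9) within-pair effect.  At low noise the selection recovers
exactly the 13 planted metabolites.

The same workflow runs from the shell:

```bash
uromet simulate --preset table1 --seed 17 --out synth/
uromet run --input synth/study.csv --out results/ --seed 17
```

writing TSV artifacts (biomarkers, ASCA effect sums of squares,
trajectories, centroids with ellipse parameters, bi-plot rankings,
correlations, QC summaries) and a markdown report with the seed and a
configuration hash.

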