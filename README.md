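# longewas

Longitudinal epigenome-wide association analysis (EWAS) of BMI change, as a
reusable, tested Python pipeline. The package is aimed at epigenetics
researchers who want to analyse — or prototype analyses of — paired-visit
blood DNA methylation cohorts where the phenotype of interest is the *change*
in body mass index over a follow-up interval, rather than BMI itself.

## What it computes

For each CpG probe, the longitudinal model regresses the change in the beta
value (methylated-signal fraction in [0, 1]) on the **BMI change degree**
ΔBMI_i = (BMI_followup − BMI_baseline) / BMI_baseline, with covariates:

```
ΔM_i = β0 + β_S·ΔBMI_i + β_age·age_i + β_ageing·IntervalYears_i + β_sex·sex_i + γ·(cell fractions)_i
```

fitted by ordinary least squares per probe (complete cases), with two-sided
t-tests and Benjamini–Hochberg FDR across probes. Around that core the
package provides:

- **synthetic cohorts** (`synthetic_cohort`): two-visit beta matrices with
  Dirichlet cell composition expressed through reference profiles, a planted
  causal CpG set, detection-p / bead-count contamination, and full ground
  truth for recovery tests;
- **QC** (`qc_preprocess`): detection-p masking (> 0.01), the bead filter
  (< 3 beads in ≥ 5% of samples), chrX/Y and SNP-probe removal, and the
  ΔM matrix;
- **cell deconvolution** (`cell_deconvolution`): simplex-constrained least
  squares of sample betas on cell-type reference profiles;
- **EWAS engines** (`longitudinal_ewas`): the Δ model (with optional
  smoking/drinking adjustment, variance moderation, inverse-normal
  phenotype transform), cross-sectional BMI models per visit, sex-stratified
  fits, effect-size concordance, and the published-CpG-list vs random-CpG
  comparison;
- **meta-analysis** (`meta_analysis`): sample-size-weighted z-score
  combination (w_k ∝ √n_k, Σw_k² = 1), Cochran's Q and I² heterogeneity,
  and discovery/replication significance calls;
- **enrichment** (`enrichment`): hypergeometric over-representation of
  annotated genes (or probes, for TFBS) against GMT gene-set collections;
- **pipeline** (`pipeline`, `cli`): one-config end-to-end runs with a fixed
  artifact layout and a machine-readable run manifest.

## Worked example

```python
from longewas import (SimulationConfig, simulate_cohort, compute_delta_matrix,
                      estimate_cell_fractions, fit_delta_ewas)

cfg = SimulationConfig(n_samples=200, n_probes=500, n_causal=3, seed=5)
baseline, followup, pheno, truth = simulate_cohort(cfg)
fracs = estimate_cell_fractions(baseline, truth.cell_reference)
res = fit_delta_ewas(compute_delta_matrix(baseline, followup), pheno, fracs)
print(res.set_index("probe_id").loc[truth.causal_probe_ids, ["effect", "se", "p_value"]])
print("true effects:", truth.true_effects.round(3).tolist())
```

prints (effects are on the beta-change-per-unit-change-degree scale):

```
              effect        se       p_value
probe_id
cg00000166  0.616657  0.020074  1.282330e-75
cg00000292  0.472942  0.020231  8.472141e-58
cg00000359  0.806708  0.021882  1.630935e-88
true effects: [0.565, 0.485, 0.771]
```

i.e. the three planted effects are recovered within ~2.5 standard errors and
are genome-wide significant at this sample size. An end-to-end run of the
bundled two-cohort configuration:

```bash
longewas run --config configs/smoke.yaml --out runs/demo
cat runs/demo/report/report.txt
```

simulates a 407-sample discovery cohort and a 126-sample replication cohort
over 5000 probes, applies QC, deconvolution, per-cohort EWAS, meta-analysis,
enrichment and the CpG-list comparison, and reports discovery-significant
probes (P < 1×10⁻⁶) with their replication directions and meta p-values.

## Layout

```
src/longewas/    library modules (core_io, synthetic_cohort, qc_preprocess,
                 cell_deconvolution, longitudinal_ewas, meta_analysis,
                 enrichment, pipeline, cli)
configs/         bundled pipeline configuration
tests/           pytest suite (unit, property and end-to-end tests)
docs/methods.md  model and design notes
```
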