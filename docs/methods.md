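# Methods and design notes

## The longitudinal model

The unit of analysis is a CpG probe's beta value b ∈ [0, 1], the fraction of
methylated signal. For subject *i* with visits roughly four years apart, the
response is the per-probe change ΔM_i = b_followup − b_baseline and the
exposure is the BMI change degree ΔBMI_i = (BMI_fu − BMI_bl)/BMI_bl — a
dimensionless relative change. The model is ordinary least squares per probe:

ΔM_i = β0 + β_S ΔBMI_i + β_age age_i + β_ageing IntervalYears_i + β_sex sex_i + γᵀ f_i

with f_i the blood leukocyte fractions (one cell type dropped, see below),
sex coded 0 = female / 1 = male, and two-sided p-values from the t
distribution on n − p degrees of freedom. A secondary model adds smoking and
drinking indicators. Missing betas are handled per probe by complete-case
analysis; probes with fewer complete cases than design columns + 2, or with a
constant response, get missing results rather than errors. FDR is
Benjamini–Hochberg across probes with finite p.

Two definitions of the change phenotype circulate for this kind of study:
relative change over baseline, and relative change additionally divided by
the follow-up interval. The cohort summary statistics (mean gain 0.76 kg/m²
on a 23.9 kg/m² baseline printing as degree 0.03) are consistent only with
the un-annualised definition, which is therefore the default; an
`annualize=True` flag divides by IntervalYears_i, and the interval otherwise
enters the model as the β_ageing covariate.

### Variance moderation

The reference engine is plain OLS. An optional moderated-variance mode
shrinks per-probe residual variances toward a pooled inverse-chi-square prior
whose scale and prior degrees of freedom are fitted by moment matching on the
log residual variances (trigamma inversion), giving moderated t-statistics on
augmented degrees of freedom. It is provided for users who expect
empirical-Bayes behaviour from microarray pipelines; all defaults and all
calibration claims in the test suite use plain OLS.

## Cell-type deconvolution

Blood methylation is a mixture over leukocyte types, and composition shifts
correlated with the phenotype confound per-probe associations. Fractions are
estimated per sample by least squares of the observed betas over a panel of
cell-type-discriminating probes on the reference mean-beta profiles, subject
to f ≥ 0 and Σf = 1. The solver appends the sum constraint as a heavily
weighted row and runs non-negative least squares (an exact active-set
method), then applies an exact Euclidean projection onto the unit simplex, so
returned fractions satisfy the constraints to machine precision — by
projection, not rescaling. On noiseless mixtures the recovery is exact; the
test suite checks max-abs error < 10⁻³ at measurement noise 10⁻⁴.

Because fractions sum to one, including all six cell types alongside an
intercept would make the design singular; the majority type (neutrophils by
default) is dropped from the regression covariates. Which visit's fractions
enter the Δ model is a genuinely open choice; the default is baseline, with
`average` and `delta` modes available.

## Meta-analysis

Per cohort, each probe's evidence is summarised as a signed z-statistic
z_k = sign(β̂_S) · Φ⁻¹(1 − p_k/2). Cohorts combine as η̂ = Σ w_k z_k with
w_k = √(n_k / Σn), so that Σ w_k² = 1 and Var(η̂) = Σ w_k² V_k = 1 for
unit-variance z-scores (unequal V_k may be supplied); the combined two-sided
p is 2Φ(−|η̂|). When a per-cohort p underflows double precision the z is
taken from the regression t-statistic directly.

Heterogeneity uses Cochran's Q = Σ w_k (y_k − ȳ)² with ȳ the weighted mean,
df = K − 1, and I² = (Q − df)/Q clipped into [0, 1] (the formula is negative
whenever Q < df). The per-study "effects" y_k are the z-statistics
themselves: published per-cohort effect magnitudes for this design are on
unlike scales across cohorts, so the z scale is the only shared one. Note
that with this Q definition I² is not invariant to rescaling the weights; the
package always evaluates it at the normalised meta weights.

Probes present in only one cohort are combined as K = 1 (the single study's
p), flagged via `n_studies`, and padded with `?` in the direction string.

## The synthetic cohort generator

The generator emulates a two-cohort, paired-visit blood methylation study:
a discovery cohort of n = 407 (baseline age 61.7 ± 7.5 y, 44% male, BMI
23.9 ± 3.0 kg/m², interval 4.1 y, change degree 0.03 ± 0.07, smoking 19%,
drinking 18%) and a replication cohort of n = 126 (age 62.4 ± 8.6, 52% male,
BMI 24.1 ± 2.5, interval 4.4 y, degree 0.02 ± 0.08, smoking 23%, drinking
9%). Both cohorts share the causal probe set, the signed true effects and
the cell reference; samples and noise are independent.

Mechanics, in order:

- **Cell composition.** Per-sample fractions over {B, CD4T, CD8T, NK, Mono,
  Neutro} are Dirichlet with mean (0.08, 0.16, 0.10, 0.06, 0.06, 0.54) and
  concentration 60. A `cell_confounding` tilt multiplies the log-fractions
  by the sample's change degree along a granulocyte-vs-lymphoid contrast,
  creating composition–phenotype correlation for confounding experiments.
- **Baseline betas.** A reference panel (60 probes by default, one
  discriminating probe per draw: ~0.85 in its marker type, ~0.15 elsewhere)
  gets mixture means Σ_c f_c·ref_{c,p}; other probes get probe-level means
  drawn U(0.1, 0.9). Betas are expit(logit(mean) + N(0, σ_logit)) with
  σ_logit = 0.3, so values live strictly inside (0, 1) with no hard clip.
- **Follow-up betas.** The change signal is composed on the beta-change
  scale — β_S·ΔBMI for causal probes, small age/sex/interval contributions
  (coefficient sds 2·10⁻⁴, 2·10⁻³, 5·10⁻⁴), an optional cell-sensitivity
  term, and N(0, noise_sd = 0.02) — and realised through the logistic link:
  followup = expit(logit(b) + δ/(b(1−b))), which equals b + δ to first
  order while staying bounded. The curvature of this link is second order
  in δ; causal probes draw their base means from U(0.35, 0.65), where the
  distortion of an injected slope is negligible relative to its standard
  error. Default true effects are N(0.5, 0.1) on the beta-change per unit
  change-degree scale — chosen for test power (the magnitude of real
  methylation–BMI-change effects is not established), giving per-probe
  signal sd ≈ 0.035 against noise sd 0.02 at n ≈ 400.
- **QC contamination.** Detection p-values are U(0, 0.005) with a configured
  fraction (0.2%) replaced by values strictly above 0.01; bead counts are
  3 + Poisson(14) with a configured fraction (0.5%) set to 1–2 beads.
- **Confounding experiments.** With the tilt active and per-probe cell
  sensitivities N(0, 0.01) — half the residual noise scale, the realistic
  regime where composition effects do not dominate measurement noise — the
  unadjusted model's null rejection rate at α = 0.05 rises severalfold while
  the fraction-adjusted model stays in the binomial calibration band. The
  adjusted model absorbs the cell term exactly because it is linear in the
  fractions.

Randomness flows from one seed through per-stage, per-cohort
`SeedSequence` spawn keys, so any stage is individually reproducible and
adding stages never reshuffles existing draws.

What the generator does **not** emulate: Infinium type-I/II probe chemistry
and its beta-value distribution shape, batch structure (normalisation and
batch correction are explicit no-op hooks), sample-level outliers,
probe–probe correlation along the genome, and composition change between
visits (fractions are held fixed per sample). Passing tests therefore show
that the statistical machinery is correct under the stated model, not that
the pipeline is robust to array artefacts those published preprocessing
methods exist to remove.

## Enrichment

Top CpGs are the probes with p below a loosened threshold (default 10⁻⁵),
best 20 by p with lexicographic tie-breaks, annotated to genes through the
manifest (multi-gene annotations split on ';'). With universe N, set size M,
marker count R and overlap k, the default p is the upper hypergeometric tail
P(X ≥ k) — the one-sided Fisher test. The literal 1 − Σ_{i=0}^{k} form
(P(X > k)) excludes the observed overlap and returns 0 at full overlap, so
it cannot be the intended test; it is available as `tail="paper_gt"`, and
the exact relation p_geq(k) = p_gt(k−1) is asserted in the suite. The
universe is a substantive choice (all genes? annotated genes? tool default?)
and is therefore required to be explicit — from the collection or an
override — rather than guessed. TFBS enrichment reuses the same machinery
with probes as the unit.

## Numerical choices and degenerate inputs

- Detection-p masking uses strict inequality (a beta at exactly p = 0.01 is
  retained); the bead filter uses ≥ 5% ("at least"). Both boundaries are
  unit-tested.
- The OLS engine groups probes by missingness pattern and factorises each
  pattern's design once (QR); rank-deficient patterns yield missing results,
  and a rank-deficient full design raises.
- BH-FDR is missing-aware: missing p-values do not count toward the number
  of tests.
- Duplicate reference cell types trigger a condition-number warning
  (> 10⁸) and a tie-broken active-set solution.
- Ties in top-CpG selection break lexicographically by probe id, making
  selection deterministic.
- Pipeline artifacts are written to an explicit run directory named by the
  caller rather than a timestamped one: reruns of the same config must be
  byte-identical, and the run manifest already records everything a
  timestamp would.

## Problem sizes

Desk-scale defaults are 5000 probes (bundled end-to-end config, study-size
cohorts of 407 and 126) and 2000–4000 probes for the calibration suites at
n = 400 — large enough for binomial rejection-rate bands of ±0.009 and KS
uniformity tests, small enough that the whole test suite and the acceptance
script each run in a couple of minutes on one CPU. All module surfaces
accept arbitrarily larger inputs.

## Known limitations

- Effects are injected and estimated on the beta-change scale; M-value
  analyses are out of scope.
- No linear mixed models, genomic-control correction, or inverse-variance
  effect-size meta-analysis (a z-based scheme cannot produce a pooled
  effect estimate).
- The deconvolution reference shipped by simulation is synthetic; no real
  EPIC blood reference is bundled.
- Live ontology/pathway queries are out of scope; enrichment runs against
  user-supplied (or seeded synthetic) collections only.
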