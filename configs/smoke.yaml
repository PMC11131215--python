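# End-to-end smoke configuration: two cohorts at their study sizes over a
# 5000-probe desk-scale universe, with a small planted causal set.
seed: 11
simulation:
  n_probes: 5000
  n_causal: 8
cohorts:
  cohort1: {}
  cohort2:
    preset: cohort2
qc:
  detection_p_threshold: 0.01
  min_beads: 3
  max_low_bead_fraction: 0.05
ewas:
  adjust_lifestyle: false
  fraction_mode: baseline
  stratified: true
  cross_sectional: true
meta:
  discovery_cohort: cohort1
  discovery_threshold: 1.0e-6
selection:
  p_threshold: 1.0e-5
  top_k: 20
enrichment:
  gmt: null
  n_synthetic_sets: 10
comparison:
  cpg_list: null
  n_random: 200
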