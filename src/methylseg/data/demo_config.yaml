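# Demonstration pipeline: five cohorts simulated against a shared WT control,
# with planted DMR classes exercising the somatic and gametic segregation
# profiles and the germ-cell propagation check.
seed: 7
thresholds:
  q_max: 0.01
  min_diff: 15.0
  min_coverage: 10
  min_sites: 4
  max_gap: 1000
simulation:
  genome:
    chromosomes: [[chr1, 1000000]]
    n_genes: 12
    islands_per_mb: 6.0
    cpg_fraction: 0.97
  design:
    WT: [WT_1, WT_2, WT_3]
    F1: [F1_1, F1_2, F1_3]
    F2: [F2_1, F2_2, F2_3]
    F3: [F3_1, F3_2, F3_3]
    F2G: [F2G_1, F2G_2, F2G_3]
    PGC: [PGC_1, PGC_2, PGC_3]
  coverage:
    mean: 30.0
    dispersion: 5.0
    overdispersion: 0.005
  classes:
    - {label: somatic_only, n_dmrs: 6, affected_groups: [F1, F2], delta: 0.30,
       n_sites: 6, hypo_fraction: 0.55}
    - {label: all_generations, n_dmrs: 6, affected_groups: [F1, F2, F3],
       delta: 0.30, n_sites: 6, hypo_fraction: 0.55}
    - {label: f2_only, n_dmrs: 6, affected_groups: [F2], delta: 0.30,
       n_sites: 6, hypo_fraction: 0.55}
    - {label: gametic, n_dmrs: 6, affected_groups: [F2, F2G], delta: 0.30,
       n_sites: 6, hypo_fraction: 0.80}
    - {label: f2g_only, n_dmrs: 4, affected_groups: [F2G], delta: 0.30,
       n_sites: 6, hypo_fraction: 0.50}
    - {label: pgc_only, n_dmrs: 6, affected_groups: [PGC], delta: 0.30,
       n_sites: 6, hypo_fraction: 0.80}
contrasts:
  control: WT
  cohorts: [F1, F2, F3, F2G, PGC]
profiles:
  somatic:
    present: [F1, F2]
    absent: [F3]
    expected_class: somatic_only
  gametic:
    present: [F2, F2G]
    absent: []
    q_max: 0.05
    overlap_test: true
    expected_class: gametic
propagation:
  pgc_cohort: PGC
  downstream: [WT, F2G]
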