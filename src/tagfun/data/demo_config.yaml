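# Demo end-to-end pipeline: simulate a two-locus case/control study, QC it,
# test association, combine the packaged locus table, run the constrained
# resampling null, and test genotype-dependent coexpression.
outdir: tagfun_demo_out
log_level: INFO
stages:
  - stage: simulate
    params:
      freq_causal: 0.25
      freq_tag: 0.25
      r2_target: 0.6
      odds_ratio: 1.5
      n_case: 200
      n_control: 800
      n_hap: 20000
      seed: 7
  - stage: qc
  - stage: assoc
  - stage: meta
  - stage: finemap-sim
    params:
      b: 500
      seed: 11
  - stage: coexpr
    params:
      r_class0: 0.24
      r_class1: 0.15
      seed: 13
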