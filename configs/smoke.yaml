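# Small end-to-end smoke configuration: simulate -> QC -> adjust -> 3-fold CV
# with two methods. Runs in well under two minutes on one CPU.
seed: 3
output_dir: genopred_out
simulate:
  enabled: true
  n: 200
  m: 500
  architecture: polygenic
  h2: 0.5
  missing_rate: 0.02
validation:
  scheme: kfold
  k: 3
gblup:
  enabled: true
en:
  enabled: true
  alpha: 0.001
  n_lambda: 20
bayesb:
  enabled: false
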