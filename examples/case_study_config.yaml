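# Full evaluation config for a two-arm surgical trial (N = 130, 1:1),
# joint selection bias + linear time trend. Run with:
#   randeval report --config examples/case_study_config.yaml
trial:
  N: 130
  alpha: 0.05
  allocation: "1:1"
procedures:
  - CR
  - RAR
  - {name: PBR, b: 2}
  - {name: PBR, b: 10}
  - {name: BSD, a: 3}
  - {name: BSD, a: 5}
  - {name: BSD, a: 10}
  - {name: MP, a: 3}
  - {name: EBC, p: 0.6667}
  - {name: CHEN, a: 2, p: 0.6667}
  - {name: UD, alpha: 0, beta: 1}
bias:
  eta: 0.09        # selection bias effect (response units)
  q: 0.5           # sign-of-imbalance guessing rule
  trend: linear
  theta: 0.26      # time trend effect (response units)
  sigma: 0.73      # residual SD
evaluation:
  r: 100000
  seed: 42
sensitivity:
  eta_values: [0.04, 0.09, 0.14]
  theta_values: [0.13, 0.26, 0.39]
  paired: true
report:
  title: Randomization procedure evaluation, two-arm surgical trial (N = 130)
  output_path: scratch/case_study_report.md
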