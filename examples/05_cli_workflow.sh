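#!/usr/bin/env bash
# End-to-end CLI workflow: simulate a cohort to disk, run the full
# estimation pipeline (duo resolution -> scoring -> MV models -> MR ->
# difference tests -> diagnostics) and print the report.
set -euo pipefail

workdir=$(mktemp -d)
cat > "$workdir/run.yaml" <<EOF
out_dir: $workdir/run
sim:
  n_trios: 1000
  n_snps: 80
  beta_m: {bw: 0.14, bmi15: 0.0}
  missing_rate: 0.05
  seed: 11
n_boot: 1000
seed: 11
mr_covariates: [pc1, pc2, pc3, pc4]
EOF

ntmr simulate --config "$workdir/run.yaml"
ntmr estimate --config "$workdir/run.yaml"
ntmr report --out "$workdir/run"
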