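#!/usr/bin/env bash
# End-to-end shell pipeline: simulate -> run -> plot.
set -euo pipefail

OUT=${1:-example_cli_output}

spatialccc simulate --out "$OUT/data" --seed 1 --n-units 80 --n-types 2 --dmax 2.5
spatialccc run \
  --expr "$OUT/data/expression.csv" \
  --coords "$OUT/data/coordinates.csv" \
  --celltypes "$OUT/data/cell_types.csv" \
  --lr-db "$OUT/data/lr_database.csv" \
  --dmax 2.5 --rho 0.5 \
  --out "$OUT/results"
spatialccc plot \
  --results "$OUT/results/results.tsv" \
  --target "LIGA→RECA" --threshold 0.1 \
  --out "$OUT/figures"

echo "pipeline complete; see $OUT/results/results.tsv and $OUT/figures/"
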