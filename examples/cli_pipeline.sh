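#!/usr/bin/env bash
# End-to-end shell workflow: simulate a study, analyse it, compare conditions.
set -euo pipefail

out=$(mktemp -d)

rootmitosis simulate --seed 1 --roots 4 --out "$out/sim"
rootmitosis analyse --events "$out/sim/events.csv" --out "$out/analysis"
rootmitosis compare "$out/sim" --out "$out/comparison"

echo
echo "bundle contents:"
ls "$out/analysis"
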