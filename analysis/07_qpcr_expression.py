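#!/usr/bin/env python
"""Relative expression from the simulated Ct table.

Normalises against beta-actin, screens replicate groups with Grubbs' test,
scales control means to 1.0, and compares groups with two-tailed t-tests.
Writes results/expression.csv and prints estimates next to the planted folds.
"""

import json
from pathlib import Path

from polymito import qpcr

DATA = Path("results/data")


def main() -> None:
    table = qpcr.read_ct_table(DATA / "ct_table.csv")
    manifest = json.loads((DATA / "qpcr_manifest.json").read_text())

    results = qpcr.relative_expression(table,
                                       reference_gene=manifest["reference_gene"])
    df = qpcr.expression_frame(results)
    df.insert(1, "true_fold", df["gene"].map(manifest["true_folds"]))
    df = df.round(4)
    df.to_csv("results/expression.csv", index=False)
    print(df.to_string(index=False))

    sig = df[(df.p_value < 0.05) & (df.true_fold < 1)]
    print(f"\n{len(sig)} of {sum(f < 1 for f in manifest['true_folds'].values())} "
          "suppressed genes detected at p < 0.05")


if __name__ == "__main__":
    main()
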