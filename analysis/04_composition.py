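#!/usr/bin/env python
"""Composition statistics: AT%, AT/GC skew per region, genome-level RSCU.

Writes results/composition.csv and results/rscu.csv.
"""

from pathlib import Path

import pandas as pd

from polymito import composition as comp
from polymito.mito_io import extract_feature, read_fasta, read_feature_table

DATA = Path("results/data")


def main() -> None:
    genome = read_fasta(DATA / "genome.fasta")[0]
    features = read_feature_table(DATA / "features.tsv")

    rows = [{
        "region": "genome", "length": len(genome),
        "at_percent": comp.at_content(genome.residues),
        "at_skew": comp.skew(genome.residues).at_skew,
        "gc_skew": comp.skew(genome.residues).gc_skew,
    }]
    for f in features:
        s = extract_feature(genome, f)
        sk = comp.skew(s)
        rows.append({"region": f.name, "length": len(s),
                     "at_percent": comp.at_content(s),
                     "at_skew": sk.at_skew, "gc_skew": sk.gc_skew})
    df = pd.DataFrame(rows).round(3)
    df.to_csv("results/composition.csv", index=False)

    cds = [extract_feature(genome, f) for f in features if f.kind == "CDS"]
    rscu = comp.rscu(cds).round(3)
    rscu.to_csv("results/rscu.csv", index=False)

    crs = df[df.region.str.startswith("CR")]
    print(df[df.region == "genome"].to_string(index=False))
    print(crs.to_string(index=False))
    top = rscu.dropna().nlargest(5, "rscu")
    print("\nmost over-represented codons:\n" + top.to_string(index=False))


if __name__ == "__main__":
    main()
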