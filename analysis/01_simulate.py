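#!/usr/bin/env python
"""Generate the synthetic study inputs (genome, Ct table, IBD set).

Writes FASTA/TSV/CSV inputs plus JSON truth manifests under results/data/.
Every later analysis script reads from there, so the whole chain is
reproducible from this one seed.
"""

import json
from pathlib import Path

from polymito import synthetic_data as synth
from polymito.mito_io import write_fasta, write_feature_table

SEED = 42
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    genome, features, manifest = synth.make_genome(seed=SEED)
    write_fasta([genome], OUT / "genome.fasta")
    write_feature_table(features, OUT / "features.tsv")
    (OUT / "genome_manifest.json").write_text(json.dumps(manifest, indent=2))
    print(f"genome: {len(genome)} nt, {len(features)} features "
          f"(ATP8 planted at {manifest['atp8']['start'] + 1}..{manifest['atp8']['end']})")

    ct, qman = synth.make_qpcr(seed=SEED)
    ct.to_csv(OUT / "ct_table.csv", index=False)
    (OUT / "qpcr_manifest.json").write_text(json.dumps(qman, indent=2))
    print(f"qPCR: {len(ct)} Ct rows, true folds {qman['true_folds']}")

    seqs, coords, iman = synth.make_ibd(seed=SEED)
    with open(OUT / "alignment.fasta", "w") as fh:
        for label, s in seqs:
            fh.write(f">{label} linear\n{s}\n")
    coords.to_csv(OUT / "coords.csv", index=False)
    (OUT / "ibd_manifest.json").write_text(json.dumps(iman, indent=2))
    print(f"IBD: {len(seqs)} demes x {iman['seq_len']} nt, slope {iman['slope']}")


if __name__ == "__main__":
    main()
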