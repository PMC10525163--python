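"""Synthetic inputs with planted, recorded ground truth.

Three generators emulate the study conditions of a ~24 kb tree-frog-type
mitogenome with a duplicated architecture:

* ``make_genome`` — a circular genome carrying three control regions that
  share a near-identical 5' block (38-bp tandem array x5 in each; a 100-bp
  array x3 only at the 3' side of CR3), two ND5 copies at configurable
  divergence, a short degenerate ATP8 (ATG...TAG) whose final four bases ATAG
  are shared with the ATP6 start, an N-terminal transmembrane stretch in the
  ATP8 peptide, and a pseudo-tRNA-Lys fragment inside the 713-nt LNCR.
* ``make_qpcr`` — Ct tables with known fold changes (default: the suppressed-
  gene regime 0.44-0.65), configurable noise and planted outliers.
* ``make_ibd`` — aligned sequences from a linear stepping-stone chain of demes
  so genetic distance grows with geographic separation at a configurable
  slope, plus deme coordinates.

Every generator is deterministic given (recipe, seed) and returns a truth
manifest sufficient to score the corresponding pipeline stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .mito_io import (
    VERTEBRATE_MITO,
    CircularSequence,
    GeneFeature,
    reverse_complement,
    translate,
)

__all__ = ["GenomeRecipe", "make_genome", "make_qpcr", "make_ibd"]

_BASES = np.array(list("ACGT"))

# Codon pools for planting the ATP8 hydropathy signature.  The transmembrane
# body draws from strongly hydrophobic residues (I/L/V); the residues
# immediately after it are arginines so the profile drops sharply, and the
# tail draws from hydrophilic residues.
_HYDROPHOBIC_CODONS = ("ATT", "ATC", "CTT", "CTA", "GTT", "GTA", "CTC", "GTC")
_ARG_CODON = "CGA"
_HYDROPHILIC_CODONS = ("GAT", "GAA", "AAT", "CAA", "AAA", "AGT", "GAC", "AAC")

_PAPER_FOLDS = {"COIII": 0.64, "ND2": 0.55, "ND4": 0.44, "ND6": 0.65, "ATP6": 1.0}


@dataclass(frozen=True)
class GenomeRecipe:
    """Parameters of the planted genome architecture (defaults = study regime)."""

    total_length: int = 24000
    at_genome: float = 0.61  # genome-wide AT fraction for neutral sequence
    at_cr: float = 0.67  # control-region AT fraction
    at_lncr: float = 0.58
    cr_block: int = 500  # shared 5' block length per CR
    cr_block_divergence: float = 0.01  # ~99% block similarity
    repeat_unit_5p: int = 38
    repeat_copies_5p: int = 5
    repeat_unit_3p: int = 100
    repeat_copies_3p: int = 3
    repeat_mutation: float = 0.02  # per-copy substitution rate
    nd5_length: int = 1779
    nd5_divergence: float = 0.015  # ~98.5% copy similarity
    atp8_length: int = 165  # nt incl. stop
    atp8_tm_aa: int = 20  # N-terminal hydrophobic stretch incl. Met
    atp8_overlap: int = 4  # shared ATAG with the ATP6 start
    lncr_length: int = 713
    pseudo_trna_identity: float = 0.76
    trna_length: int = 70


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int, at: float) -> str:
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def _mutate(rng: np.random.Generator, seq: str, divergence: float,
            exact: bool = False) -> str:
    """Substitute bases at the given per-site rate (count is exact if asked)."""
    n = len(seq)
    if exact:
        k = int(round(divergence * n))
        sites = rng.choice(n, size=k, replace=False)
    else:
        sites = np.where(rng.random(n) < divergence)[0]
    out = list(seq)
    for i in sites:
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def _skewed_codons(code=VERTEBRATE_MITO):
    """Non-stop codons with AT-skewed sampling weights (gives RSCU structure)."""
    base_w = {"A": 0.32, "T": 0.29, "C": 0.22, "G": 0.17}
    codons = sorted(code.codon_to_aa)
    w = np.array([base_w[c[0]] * base_w[c[1]] * base_w[c[2]] for c in codons])
    return codons, w / w.sum()


def _random_cds(rng: np.random.Generator, length_nt: int, code=VERTEBRATE_MITO) -> str:
    """ATG + skewed-usage codons + TAA, with no internal stop."""
    if length_nt % 3:
        raise ValueError("CDS length must be a multiple of 3")
    codons, w = _skewed_codons(code)
    n_body = length_nt // 3 - 2
    body = rng.choice(codons, size=n_body, p=w)
    return "ATG" + "".join(body) + "TAA"


def _mutate_cds(rng: np.random.Generator, cds: str, divergence: float,
                code=VERTEBRATE_MITO) -> str:
    """Substitute without creating internal stops or touching start/stop codons."""
    out = list(cds)
    n = len(cds)
    k = int(round(divergence * n))
    tries = 0
    placed = 0
    while placed < k and tries < 50 * k:
        tries += 1
        i = int(rng.integers(3, n - 3))
        old = out[i]
        new = rng.choice([b for b in "ACGT" if b != old])
        out[i] = new
        c0 = 3 * (i // 3)
        if "".join(out[c0 : c0 + 3]) in code.stop_codons:
            out[i] = old
            continue
        placed += 1
    return "".join(out)


def _repeat_array(rng: np.random.Generator, unit_len: int, copies: int,
                  mutation: float, at: float) -> tuple[str, str]:
    unit = _random_seq(rng, unit_len, at)
    parts = [_mutate(rng, unit, mutation) for _ in range(copies)]
    return unit, "".join(parts)


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

def _build_atp8_atp6(rng: np.random.Generator, recipe: GenomeRecipe,
                     atp6_length: int = 681):
    """ATP8 with planted hydropathy signature + overlapping ATP6.

    Returns (merged nt, atp8_len, atp6_len).  ATP8's last four bases are ATAG
    (TAG stop); ATP6 starts at the A of that tetranucleotide with the
    mitochondrial start codon ATA.
    """
    n_aa = recipe.atp8_length // 3 - 1  # coding residues incl. Met
    tm_extra = recipe.atp8_tm_aa - 1  # hydrophobic residues after Met
    codons = ["ATG"]  # M (KD 1.9, counts toward the TM stretch)
    codons += ["GTA", "AAA", "ACA"]  # V, K, T -> N-terminal motif MVKT
    codons += list(rng.choice(_HYDROPHOBIC_CODONS, size=tm_extra - 3))
    codons += [_ARG_CODON] * 4  # sharp hydropathy drop after the TM
    n_tail = n_aa - len(codons) - 1
    if tm_extra < 3 or n_tail < 0:
        raise ValueError(
            f"infeasible recipe: atp8_length {recipe.atp8_length} nt cannot hold a "
            f"{recipe.atp8_tm_aa}-residue TM stretch plus a hydrophilic tail"
        )
    codons += list(rng.choice(_HYDROPHILIC_CODONS, size=n_tail))
    codons += ["AAA"]  # Lys; codon ends in A so the last 4 nt read A-TAG
    atp8 = "".join(codons) + "TAG"
    assert len(atp8) == recipe.atp8_length and atp8[-4:] == "ATAG"

    # ATP6: starts on the A of ATAG (codon ATA = Met under code 2); the first
    # base after the overlap completes codon 2 as G + 2 random bases.
    codons6, w6 = _skewed_codons()
    body_len = atp6_length // 3 - 3  # minus start, codon2, stop
    codon2 = "G" + "".join(rng.choice(list("ACGT"), size=2))
    body = "".join(rng.choice(codons6, size=body_len, p=w6))
    atp6 = "ATA" + codon2 + body + "TAA"
    assert len(atp6) == atp6_length
    merged = atp8 + atp6[recipe.atp8_overlap :]
    return merged, len(atp8), len(atp6)


def _build_cr(rng, recipe, block: str, with_3p_array: bool, tail_len: int):
    """One control region from the shared block; returns (seq, repeat truths)."""
    seq = block
    truths = [
        {
            "region_offset": 0,
            "period": recipe.repeat_unit_5p,
            "copies": recipe.repeat_copies_5p,
        }
    ]
    seq += _random_seq(rng, tail_len, recipe.at_cr)
    if with_3p_array:
        _, arr = _repeat_array(
            rng, recipe.repeat_unit_3p, recipe.repeat_copies_3p,
            recipe.repeat_mutation, recipe.at_cr,
        )
        truths.append(
            {
                "region_offset": len(seq),
                "period": recipe.repeat_unit_3p,
                "copies": recipe.repeat_copies_3p,
            }
        )
        seq += arr
    return seq, truths


def make_genome(recipe: GenomeRecipe | None = None, seed: int = 0):
    """Assemble a circular synthetic mitogenome.

    Returns ``(CircularSequence, [GeneFeature], manifest)`` where the manifest
    records every planted coordinate and divergence.  Deterministic given
    (recipe, seed).
    """
    recipe = recipe or GenomeRecipe()
    rng = np.random.default_rng(seed)

    # shared CR 5' block: 38-bp array + filler up to cr_block nt
    _, array5 = _repeat_array(
        rng, recipe.repeat_unit_5p, recipe.repeat_copies_5p,
        recipe.repeat_mutation, recipe.at_cr,
    )
    filler = _random_seq(rng, recipe.cr_block - len(array5), recipe.at_cr)
    block0 = array5 + filler
    blocks = [block0] + [
        _mutate(rng, block0, recipe.cr_block_divergence, exact=True) for _ in range(2)
    ]

    trnk = _random_seq(rng, recipe.trna_length, recipe.at_genome)
    pseudo = _mutate(rng, trnk, 1 - recipe.pseudo_trna_identity, exact=True)
    lncr_pad = recipe.lncr_length - recipe.trna_length
    lncr_pre = _random_seq(rng, lncr_pad // 2, recipe.at_lncr)
    lncr_post = _random_seq(rng, lncr_pad - len(lncr_pre), recipe.at_lncr)
    lncr = lncr_pre + pseudo + lncr_post

    atp86, atp8_len, atp6_len = _build_atp8_atp6(rng, recipe)
    nd5_1 = _random_cds(rng, recipe.nd5_length)
    nd5_2 = _mutate_cds(rng, nd5_1, recipe.nd5_divergence)
    nd6 = _random_cds(rng, 519)

    def trna(rng):
        return _random_seq(rng, recipe.trna_length, recipe.at_genome)

    # (name, kind, strand, sequence-as-placed) in genome order; ATP8/ATP6 and
    # the CR/ND5 cluster are appended with explicit overlap/divergence control.
    parts: list[tuple[str, str, str, str]] = [
        ("trnF", "tRNA", "+", trna(rng)),
        ("rrnS", "rRNA", "+", _random_seq(rng, 930, recipe.at_genome)),
        ("rrnL", "rRNA", "+", _random_seq(rng, 1700, recipe.at_genome)),
        ("ND1", "CDS", "+", _random_cds(rng, 951)),
        ("ND2", "CDS", "+", _random_cds(rng, 1032)),
        ("COX1", "CDS", "+", _random_cds(rng, 1551)),
        ("COX2", "CDS", "+", _random_cds(rng, 690)),
        ("trnK", "tRNA", "+", trnk),
        ("LNCR", "LNCR", "+", lncr),
    ]
    spacered = []
    for name, kind, strand, s in parts:
        spacered.append((name, kind, strand, s))
        spacered.append((None, None, None, _random_seq(rng, int(rng.integers(5, 70)),
                                                       recipe.at_genome)))
    parts2: list[tuple[str | None, str | None, str | None, str]] = [
        ("COX3", "CDS", "+", _random_cds(rng, 783)),
        ("ND3", "CDS", "+", _random_cds(rng, 342)),
        ("ND4L", "CDS", "+", _random_cds(rng, 291)),
        ("ND4", "CDS", "+", _random_cds(rng, 1371)),
        ("ND6", "CDS", "-", reverse_complement(nd6)),
        ("Cytb", "CDS", "+", _random_cds(rng, 1141 - 1)),
    ]

    # budget the CR tails so the genome lands on total_length
    fixed = sum(len(s) for *_1, s in spacered) + len(atp86)
    fixed += sum(len(s) for *_1, s in parts2) + 5 * 30  # spacers in parts2
    fixed += 2 * recipe.nd5_length + 4 * recipe.trna_length + 3 * 20
    fixed += 3 * recipe.cr_block + recipe.repeat_copies_3p * recipe.repeat_unit_3p
    spare = max(200, recipe.total_length - fixed - 60)
    tail1 = spare // 3
    tail2 = spare // 3
    tail3 = spare - tail1 - tail2

    cr1, t1 = _build_cr(rng, recipe, blocks[0], False, tail1)
    cr2, t2 = _build_cr(rng, recipe, blocks[1], False, tail2)
    cr3, t3 = _build_cr(rng, recipe, blocks[2], True, tail3)

    layout = list(spacered)
    layout.append(("ATP8+ATP6", "CDS", "+", atp86))
    for name, kind, strand, s in parts2:
        layout.append((name, kind, strand, s))
        layout.append((None, None, None, _random_seq(rng, 30, recipe.at_genome)))
    layout += [
        ("CR1", "CR", "+", cr1),
        ("ND5_1", "CDS", "+", nd5_1),
        ("CR2", "CR", "+", cr2),
        ("ND5_2", "CDS", "+", nd5_2),
        ("CR3", "CR", "+", cr3),
        ("trnT", "tRNA", "+", trna(rng)),
        (None, None, None, _random_seq(rng, 20, recipe.at_genome)),
        ("trnL", "tRNA", "+", trna(rng)),
        (None, None, None, _random_seq(rng, 20, recipe.at_genome)),
        ("trnP", "tRNA", "+", trna(rng)),
        (None, None, None, _random_seq(rng, 20, recipe.at_genome)),
    ]

    residues = []
    features: list[GeneFeature] = []
    manifest: dict = {"seed": seed, "recipe": asdict(recipe), "repeats": []}
    pos = 0
    for name, kind, strand, s in layout:
        if name == "ATP8+ATP6":
            a8_start = pos
            features.append(GeneFeature("ATP8", pos, pos + atp8_len, "+", "CDS"))
            a6_start = pos + atp8_len - recipe.atp8_overlap
            features.append(GeneFeature("ATP6", a6_start, a6_start + atp6_len, "+", "CDS"))
            manifest["atp8"] = {
                "start": a8_start,
                "end": a8_start + atp8_len,
                "length_nt": atp8_len,
                "overlap_nt": recipe.atp8_overlap,
                "overlap_tetranucleotide": s[atp8_len - 4 : atp8_len],
                "tm_aa": [0, recipe.atp8_tm_aa],
                "peptide": translate(s[:atp8_len]),
            }
            manifest["atp6"] = {"start": a6_start, "end": a6_start + atp6_len}
        elif name is not None:
            features.append(GeneFeature(name, pos, pos + len(s), strand, kind))
        residues.append(s)
        pos += len(s)

    genome = CircularSequence("synthetic_mitogenome", "".join(residues), circular=True)

    by_name = {f.name: f for f in features}
    for cr_name, truths in (("CR1", t1), ("CR2", t2), ("CR3", t3)):
        f = by_name[cr_name]
        for t in truths:
            manifest["repeats"].append(
                {
                    "region": cr_name,
                    "start": f.start + t["region_offset"],
                    "region_offset": t["region_offset"],
                    "period": t["period"],
                    "copies": t["copies"],
                }
            )
    manifest["nd5"] = {
        "divergence": recipe.nd5_divergence,
        "copy1": [by_name["ND5_1"].start, by_name["ND5_1"].end],
        "copy2": [by_name["ND5_2"].start, by_name["ND5_2"].end],
    }
    manifest["cr_blocks"] = {
        "divergence": recipe.cr_block_divergence,
        "block_length": recipe.cr_block,
    }
    lncr_f = by_name["LNCR"]
    manifest["pseudo_trna"] = {
        "identity": recipe.pseudo_trna_identity,
        "start": lncr_f.start + len(lncr_pre),
        "end": lncr_f.start + len(lncr_pre) + recipe.trna_length,
        "trna": "trnK",
    }
    manifest["peptides"] = {
        f.name: translate(genome.fetch(f.start, f.end) if f.strand == "+"
                          else reverse_complement(genome.fetch(f.start, f.end)))
        for f in features if f.kind == "CDS" and f.name != "ATP6"
    }
    manifest["length"] = len(genome)
    return genome, features, manifest


# ---------------------------------------------------------------------------
# qPCR tables
# ---------------------------------------------------------------------------

def make_qpcr(
    genes: dict[str, float] | None = None,
    n_bio: int = 4,
    n_tech: int = 3,
    sigma_ct: float = 0.25,
    outlier_rate: float = 0.0,
    outlier_shift_sd: float = 8.0,
    reference_gene: str = "ACTIN",
    seed: int = 0,
):
    """Simulate a Ct table with known fold changes.

    ``genes`` maps gene -> true fold (stress/control); the default is the
    suppressed-gene regime {COIII 0.64, ND2 0.55, ND4 0.44, ND6 0.65, ATP6 1}.
    Ct = gene baseline + sample effect - log2(fold, stress only) + N(0, sigma).
    With probability ``outlier_rate`` per (group, gene), one biological
    sample's Ct is shifted down by ``outlier_shift_sd * sigma_ct`` (an
    expression excursion); planted outliers are listed in the manifest.

    Returns ``(DataFrame, manifest)`` in long format (sample, group, gene,
    rep, ct).
    """
    folds = dict(genes) if genes is not None else dict(_PAPER_FOLDS)
    rng = np.random.default_rng(seed)
    baselines = {g: float(rng.uniform(18, 30)) for g in [reference_gene, *folds]}
    rows = []
    planted = []
    for group in ("control", "stress"):
        sample_ids = [f"{group[0].upper()}{i + 1}" for i in range(n_bio)]
        effects = rng.normal(0.0, 0.3, size=n_bio)
        for gene in [reference_gene, *folds]:
            fold = 1.0 if gene == reference_gene else folds[gene]
            shift = -np.log2(fold) if group == "stress" and gene != reference_gene else 0.0
            out_sample = None
            if gene != reference_gene and rng.random() < outlier_rate:
                out_sample = int(rng.integers(n_bio))
                planted.append({"group": group, "gene": gene,
                                "sample": sample_ids[out_sample]})
            for b in range(n_bio):
                base = baselines[gene] + effects[b] + shift
                if b == out_sample:
                    base -= outlier_shift_sd * sigma_ct
                for t in range(n_tech):
                    rows.append(
                        {
                            "sample": sample_ids[b],
                            "group": group,
                            "gene": gene,
                            "rep": t + 1,
                            "ct": base + rng.normal(0.0, sigma_ct),
                        }
                    )
    df = pd.DataFrame(rows)
    manifest = {
        "seed": seed,
        "true_folds": folds,
        "reference_gene": reference_gene,
        "sigma_ct": sigma_ct,
        "n_bio": n_bio,
        "n_tech": n_tech,
        "outliers": planted,
    }
    return df, manifest


# ---------------------------------------------------------------------------
# isolation-by-distance sequence sets
# ---------------------------------------------------------------------------

def _mutate_biased(rng, seq_arr: np.ndarray, p: float, bias: float) -> np.ndarray:
    """Substitute with transition:transversion weighting ``bias``:1 per path."""
    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    out = seq_arr.copy()
    sites = np.where(rng.random(len(out)) < p)[0]
    for i in sites:
        b = out[i]
        if rng.random() < bias / (bias + 2):
            out[i] = transitions[b]
        else:
            tv = [x for x in "ACGT" if x != b and x != transitions[b]]
            out[i] = tv[int(rng.integers(2))]
    return out


def make_ibd(
    n_demes: int = 8,
    seq_len: int = 1000,
    mutation_rate: float = 0.002,
    transition_bias: float = 4.0,
    slope: float = 5e-5,
    spacing_km: float = 100.0,
    lat0: float = 25.0,
    lon0: float = 110.0,
    seed: int = 0,
):
    """Sequences and coordinates with a configurable isolation-by-distance signal.

    Demes sit on a line ``spacing_km`` apart.  Each deme's sequence derives
    from its neighbour with ``slope * spacing_km`` substitutions/site per step
    (the heritable, distance-proportional component) plus ``mutation_rate``
    private substitutions (noise).  ``slope=0`` gives a null scenario.

    Returns ``(list of (label, sequence), coords DataFrame, manifest)``.
    """
    if n_demes < 4:
        raise ValueError("need at least 4 demes")
    rng = np.random.default_rng(seed)
    root = rng.choice(_BASES, size=seq_len)
    chain = [root]
    for _ in range(1, n_demes):
        chain.append(_mutate_biased(rng, chain[-1], slope * spacing_km, transition_bias))
    seqs = []
    for i, anc in enumerate(chain):
        private = _mutate_biased(rng, anc, mutation_rate, transition_bias)
        seqs.append((f"deme{i + 1:02d}", "".join(private)))
    km_per_deg = 111.19
    coords = pd.DataFrame(
        {
            "label": [s[0] for s in seqs],
            "lat": [lat0 + i * spacing_km / km_per_deg for i in range(n_demes)],
            "lon": [lon0] * n_demes,
        }
    )
    manifest = {
        "seed": seed,
        "n_demes": n_demes,
        "seq_len": seq_len,
        "slope": slope,
        "spacing_km": spacing_km,
        "mutation_rate": mutation_rate,
        "transition_bias": transition_bias,
    }
    return seqs, coords, manifest
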