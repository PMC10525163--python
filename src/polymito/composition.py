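"""Nucleotide-composition statistics: AT content, AT/GC skew, and RSCU.

Skews are the strand asymmetries AT-skew = (A - T)/(A + T) and
GC-skew = (G - C)/(G + C); RSCU (relative synonymous codon usage) is the
observed count of a codon divided by the mean count within its synonymous
family, so a uniformly used family has RSCU 1 for every member.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .mito_io import VERTEBRATE_MITO, GeneticCode

__all__ = ["SkewResult", "at_content", "skew", "rscu"]


@dataclass(frozen=True)
class SkewResult:
    at_skew: float  # NaN when A + T == 0
    gc_skew: float  # NaN when G + C == 0


def _counts(seq: str) -> dict:
    seq = seq.upper()
    return {b: seq.count(b) for b in "ACGT"}


def at_content(seq: str) -> float:
    """Percent (A+T) of unambiguous bases; N is excluded from both sides.

    Returns NaN for an all-N (or empty after exclusion) sequence.
    """
    if not seq:
        raise ValueError("empty sequence")
    c = _counts(seq)
    denom = sum(c.values())
    if denom == 0:
        return math.nan
    return 100.0 * (c["A"] + c["T"]) / denom


def skew(seq: str) -> SkewResult:
    if not seq:
        raise ValueError("empty sequence")
    c = _counts(seq)
    at = (c["A"] - c["T"]) / (c["A"] + c["T"]) if c["A"] + c["T"] else math.nan
    gc = (c["G"] - c["C"]) / (c["G"] + c["C"]) if c["G"] + c["C"] else math.nan
    return SkewResult(at_skew=at, gc_skew=gc)


def rscu(
    cds_seqs: Sequence[str] | Iterable[str],
    code: GeneticCode = VERTEBRATE_MITO,
    per_gene: bool = False,
) -> pd.DataFrame:
    """Relative synonymous codon usage over one or more coding sequences.

    Counts are pooled across all supplied CDSs (genome-level RSCU); with
    ``per_gene`` a ``gene`` column indexes each input separately.  Stop codons
    are excluded.  Codons of families never observed get RSCU NaN; within any
    used family the mean RSCU is exactly 1.

    Returns a DataFrame with columns ``codon, aa, count, rscu`` (plus ``gene``
    in per-gene mode).
    """
    seqs = list(cds_seqs)
    if not seqs:
        raise ValueError("no coding sequences supplied")
    if per_gene:
        frames = []
        for i, s in enumerate(seqs):
            df = rscu([s], code=code)
            df.insert(0, "gene", i)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    counts: dict[str, int] = {c: 0 for c in code.codon_to_aa}
    for s in seqs:
        s = s.upper()
        if len(s) % 3:
            warnings.warn(
                f"CDS length {len(s)} not divisible by 3; trailing bases ignored",
                stacklevel=2,
            )
        for i in range(0, len(s) - len(s) % 3, 3):
            codon = s[i : i + 3]
            if codon in counts:  # skips stops and N-containing codons
                counts[codon] += 1

    rows = []
    for aa in sorted(set(code.codon_to_aa.values())):
        family = code.family(aa)
        fam_counts = [counts[c] for c in family]
        total = sum(fam_counts)
        mean = total / len(family)
        for codon, n in zip(family, fam_counts):
            rows.append(
                {
                    "codon": codon,
                    "aa": aa,
                    "count": n,
                    "rscu": (n / mean) if total > 0 else math.nan,
                }
            )
    return pd.DataFrame(rows).sort_values(["aa", "codon"], ignore_index=True)
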