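"""Cryptic short-ORF (ATP8) recovery.

ATP8 is the shortest, fastest-evolving vertebrate mitochondrial gene and is
routinely missed by automated annotators.  Its reliable signatures are
positional rather than homology-based: it sits immediately upstream of ATP6,
shares a 4-nt overlap with the ATP6 start (tetranucleotide ATAG, the ATP8 TAG
stop overlapping the ATP6 start codon), is ~100-250 nt long, carries a single
N-terminal transmembrane helix of about 20 residues, and shows a hydropathy
profile that is positive at the N-terminus and negative at the C-terminus.
This module turns that manual curation into an explicit, weighted score over
circular-ORF-scan candidates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .mito_io import (
    VERTEBRATE_MITO,
    CircularSequence,
    GeneFeature,
    GeneticCode,
    reverse_complement,
    translate,
)

__all__ = [
    "KYTE_DOOLITTLE",
    "OrfCandidate",
    "HydropathyProfile",
    "TmSegment",
    "RecoveryScore",
    "scan_orfs",
    "kyte_doolittle",
    "find_tm_segments",
    "profile_similarity",
    "recover_atp8",
    "pairwise_peptide_identity",
]

# Kyte & Doolittle residue hydropathy scale (range -4.5 .. 4.5).
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

STRICT_STARTS = frozenset({"ATG"})
EXTENDED_STARTS = frozenset({"ATG", "ATA", "GTG"})

# N-terminal motifs seen in Polypedates-type ATP8 (MVKT/MAKT) plus the
# canonical vertebrate MPQL.
NTERM_MOTIFS = ("MVKT", "MAKT", "MPQL")


@dataclass(frozen=True)
class OrfCandidate:
    """A scanned ORF with positional context (0-based half-open, stop included)."""

    start: int
    end: int
    strand: str
    frame: int
    nt_seq: str
    aa_seq: str
    has_canonical_start: bool
    stop_codon: str

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class HydropathyProfile:
    """Windowed-mean hydropathy values; ``values[p]`` covers residues [p, p+window)."""

    values: np.ndarray
    window: int

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class TmSegment:
    """A putative transmembrane stretch, in residue coordinates [start, end)."""

    start: int
    end: int
    mean_hydropathy: float

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RecoveryScore:
    candidate: OrfCandidate
    overlap_with_next_gene: int
    overlap_tetranucleotide: str
    n_term_motif: str
    tm_segments: tuple = field(repr=False)
    components: dict = field(repr=False)
    total: float = 0.0


def scan_orfs(
    seq: CircularSequence,
    code: GeneticCode = VERTEBRATE_MITO,
    min_aa: int = 10,
    max_aa: int | None = None,
    region: tuple[int, int] | None = None,
    extended_starts: bool = False,
    strands: str = "both",
) -> list[OrfCandidate]:
    """Scan all frames (both strands, origin-aware) for start->stop ORFs.

    ``min_aa``/``max_aa`` bound the peptide length (stop excluded).  ``region``
    restricts candidates to a forward-strand interval (end may exceed the
    sequence length to wrap the origin on circular records).  Candidates are
    returned sorted by start coordinate.
    """
    n = len(seq)
    starts = EXTENDED_STARTS if extended_starts else STRICT_STARTS
    if region is not None:
        r0, r1 = region
        if not (0 <= r0 < n) or r1 <= r0 or r1 - r0 > n:
            raise ValueError(f"region {region} outside sequence of length {n}")
        search = seq.fetch(r0, r1)
        offset = r0
        wrap = False
    else:
        search = seq.residues + (seq.residues[: min(n, 3 * ((max_aa or 200) + 1))]
                                 if seq.circular else "")
        offset = 0
        wrap = seq.circular

    found: dict[tuple, OrfCandidate] = {}
    for strand in ("+", "-"):
        if strands != "both" and strand != strands:
            continue
        s = search if strand == "+" else reverse_complement(search)
        L = len(s)
        for frame in range(3):
            # nested ORFs sharing a stop are all reported, one per start codon
            open_starts: list[int] = []
            for i in range(frame, L - 2, 3):
                codon = s[i : i + 3]
                if codon in code.stop_codons:
                    for start_pos in open_starts:
                        _maybe_add(found, s, start_pos, i + 3, strand, code,
                                   min_aa, max_aa, offset, n, L, wrap)
                    open_starts.clear()
                elif codon in starts:
                    open_starts.append(i)
    return sorted(found.values(), key=lambda c: (c.start, c.end, c.strand))


def _maybe_add(found, s, i0, i1, strand, code, min_aa, max_aa, offset, n, L, wrap):
    aa_len = (i1 - i0) // 3 - 1
    if aa_len < min_aa or (max_aa is not None and aa_len > max_aa):
        return
    nt = s[i0:i1]
    if strand == "+":
        start = offset + i0
    else:  # map back from reverse-complement coordinates
        start = offset + (L - i1)
    if wrap:
        if start >= n:  # duplicate of an unwrapped hit
            return
        end = start + (i1 - i0)
        if not (end > n and start < n) and end > n:
            return
    else:
        end = start + (i1 - i0)
    key = (start % n if wrap else start, end, strand)
    if key in found:
        return
    aa = translate(nt, code)
    found[key] = OrfCandidate(
        start=key[0],
        end=end if not wrap else key[0] + (i1 - i0),
        strand=strand,
        frame=key[0] % 3,
        nt_seq=nt,
        aa_seq=aa,
        has_canonical_start=nt[:3] == "ATG",
        stop_codon=nt[-3:],
    )


def kyte_doolittle(aa: str, window: int = 9) -> HydropathyProfile:
    """Sliding unweighted mean of Kyte-Doolittle residue values.

    The profile has ``len(aa) - window + 1`` points; unknown residues score 0
    with a warning.  ``window`` must be odd and no longer than the peptide.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(aa):
        raise ValueError(f"window {window} exceeds peptide length {len(aa)}")
    vals = np.empty(len(aa))
    for i, r in enumerate(aa):
        if r not in KYTE_DOOLITTLE:
            warnings.warn(f"unknown residue {r!r} treated as hydropathy 0", stacklevel=2)
            vals[i] = 0.0
        else:
            vals[i] = KYTE_DOOLITTLE[r]
    kernel = np.ones(window) / window
    prof = np.convolve(vals, kernel, mode="valid")
    return HydropathyProfile(values=prof, window=window)


def find_tm_segments(
    profile: HydropathyProfile, min_len: int = 18, threshold: float = 1.6
) -> list[TmSegment]:
    """Maximal runs of windows with mean hydropathy >= ``threshold``.

    A run of qualifying windows [p_first, p_last] spans residues
    [p_first, p_last + window); runs shorter than ``min_len`` residues are
    dropped.  1.6 over an 18+ residue span is the classic Kyte-Doolittle
    criterion for a membrane-spanning helix.
    """
    if len(profile) == 0:
        raise ValueError("empty profile")
    above = profile.values >= threshold
    segments: list[TmSegment] = []
    p = 0
    w = profile.window
    while p < len(above):
        if above[p]:
            q = p
            while q + 1 < len(above) and above[q + 1]:
                q += 1
            start, end = p, q + w
            if end - start >= min_len:
                segments.append(
                    TmSegment(start, end, float(profile.values[p : q + 1].mean()))
                )
            p = q + 1
        else:
            p += 1
    return segments


def profile_similarity(a: HydropathyProfile, b: HydropathyProfile) -> float:
    """Pearson correlation of two profiles after resampling to a common length.

    Both profiles are linearly resampled to the longer of the two; returns NaN
    when either profile is constant (correlation undefined).
    """
    va, vb = np.asarray(a.values, float), np.asarray(b.values, float)
    if len(va) == 0 or len(vb) == 0:
        raise ValueError("empty profile")
    m = max(len(va), len(vb))
    xa = np.interp(np.linspace(0, 1, m), np.linspace(0, 1, len(va)), va)
    xb = np.interp(np.linspace(0, 1, m), np.linspace(0, 1, len(vb)), vb)
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        return math.nan
    return float(np.corrcoef(xa, xb)[0, 1])


# ---------------------------------------------------------------------------
# Positional recovery scoring
# ---------------------------------------------------------------------------

def _peptide_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


def pairwise_peptide_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / aligned columns x 100.

    Identity-oriented scoring (match 1, mismatch 0, gap -1); gap columns count
    toward the denominator.
    """
    if not a or not b:
        raise ValueError("empty peptide")
    aln = _peptide_aligner().align(a, b)[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length


def _component_scores(
    cand: OrfCandidate,
    atp6_start: int,
    tetra: str,
    kd_window: int,
    tm_threshold: float,
    tm_min_len: int,
    length_band: tuple[int, int],
):
    aa = cand.aa_seq
    comps: dict[str, float] = {}

    overlap = max(0, cand.end - atp6_start)
    comps["overlap"] = (
        1.0 if (overlap == 4 and tetra == "ATAG")
        else max(0.0, 1.0 - abs(overlap - 4) / 10.0) * 0.5
    )

    lo, hi = length_band
    nt_len = len(cand)
    if lo <= nt_len <= hi:
        comps["length"] = 1.0
    else:
        dist = (lo - nt_len) if nt_len < lo else (nt_len - hi)
        comps["length"] = max(0.0, 1.0 - dist / 150.0)

    tm_segments: list[TmSegment] = []
    if len(aa) >= kd_window:
        prof = kyte_doolittle(aa, kd_window)
        tm_segments = find_tm_segments(prof, min_len=tm_min_len, threshold=tm_threshold)
    if any(seg.start <= 5 for seg in tm_segments):
        comps["tm"] = 1.0
    elif tm_segments:
        comps["tm"] = 0.5
    else:
        comps["tm"] = 0.0

    # N-terminal hydropathy positive, C-terminal negative (scale-normalised
    # contrast as a continuous tie-break).
    half = max(1, min(25, len(aa) // 2))
    vals = np.array([KYTE_DOOLITTLE.get(r, 0.0) for r in aa])
    nmean, cmean = float(vals[:half].mean()), float(vals[half:].mean() if len(vals) > half else 0.0)
    comps["hydro_contrast"] = 0.5 * float(nmean > 0 and cmean < 0) + 0.5 * float(
        np.clip((nmean - cmean) / 9.0, 0.0, 1.0)
    )

    head = aa[:4]
    motif = head if head in NTERM_MOTIFS else ""
    comps["motif"] = (
        1.0 if motif
        else max(sum(x == y for x, y in zip(head, m)) for m in NTERM_MOTIFS) / 4.0 * 0.5
    )
    return comps, overlap, tm_segments, motif


def recover_atp8(
    genome: CircularSequence,
    features: list[GeneFeature],
    window_nt: int = 1000,
    kd_window: int = 9,
    tm_threshold: float = 1.6,
    tm_min_len: int = 18,
    min_aa: int = 20,
    length_band: tuple[int, int] = (100, 250),
    weights: dict | None = None,
    code: GeneticCode = VERTEBRATE_MITO,
) -> list[RecoveryScore]:
    """Rank ORF candidates upstream of ATP6 as putative ATP8 genes.

    Candidates are forward-strand ORFs ending within ``window_nt`` of the
    annotated ATP6 start.  Five component scores (4-nt ATAG overlap with the
    ATP6 start, length within ``length_band``, N-terminal TM helix, N-/C-
    terminal hydropathy contrast, N-terminal motif MVKT/MAKT/MPQL) are min-max
    normalised across candidates and combined as a weighted sum (equal weights
    by default).  Returns scores sorted best-first.
    """
    atp6 = next((f for f in features if f.name.upper() in ("ATP6", "ATPASE6")), None)
    if atp6 is None:
        raise ValueError("no ATP6 feature annotated; positional recovery needs it")

    n = len(genome)
    if genome.circular:
        region_start = (atp6.start - window_nt) % n
        region_end = region_start + window_nt + 4
    else:
        region_start = max(0, atp6.start - window_nt)
        region_end = min(n, atp6.start + 4)

    cands = scan_orfs(
        genome, code=code, min_aa=min_aa,
        region=(region_start, region_end), strands="+",
    )
    # ATP6 start in the (possibly origin-unwrapped) coordinate frame of the
    # scan region, so candidate/ATP6 arithmetic stays single-interval.
    atp6_anchor = atp6.start if atp6.start >= region_start else atp6.start + n

    # Keep ORFs that terminate at or upstream of just-past the ATP6 start.
    cands = [c for c in cands if c.end <= atp6_anchor + 8]
    if not cands:
        return []

    tetra_at = genome.fetch(atp6.start, atp6.start + 4)
    raw = []
    for c in cands:
        tetra = tetra_at if c.end == atp6_anchor + 4 else ""
        comps, overlap, tms, motif = _component_scores(
            c, atp6_anchor, tetra, kd_window, tm_threshold, tm_min_len, length_band
        )
        raw.append((c, comps, overlap, tetra, tms, motif))

    # Min-max normalise each component across candidates (constant components
    # are left as-is so a lone candidate keeps its raw scores).
    keys = raw[0][1].keys()
    norm: dict[str, tuple[float, float]] = {}
    for k in keys:
        vals = [r[1][k] for r in raw]
        lo, hi = min(vals), max(vals)
        norm[k] = (lo, hi)
    weights = weights or {k: 1.0 for k in keys}
    wsum = sum(weights.values())

    scores = []
    for c, comps, overlap, tetra, tms, motif in raw:
        normed = {}
        for k, v in comps.items():
            lo, hi = norm[k]
            normed[k] = (v - lo) / (hi - lo) if hi > lo else v
        total = sum(weights.get(k, 0.0) * normed[k] for k in keys) / wsum
        scores.append(
            RecoveryScore(
                candidate=c,
                overlap_with_next_gene=max(0, c.end - atp6_anchor),
                overlap_tetranucleotide=tetra,
                n_term_motif=motif,
                tm_segments=tuple(tms),
                components=comps,
                total=total,
            )
        )
    scores.sort(key=lambda s: (-s.total, s.candidate.start))
    return scores
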