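"""Control-region and LNCR characterisation.

Duplicated mitochondrial control regions in this architecture share a
near-identical 5' block and carry tandem-repeat arrays (38-bp units at the 5'
sides of all three CRs, a 100-bp array only at the 3' side of CR3); the long
non-coding region (LNCR) harbours a degenerate tRNA-Lys remnant.  This module
detects tandem arrays with a deterministic seeded detector, measures pairwise
block/gene identities by global alignment, and reports per-region composition.

The repeat detector is intentionally simple and reproducible: candidate
periods are seeded by exact k-mer recurrence, arrays are extended copy by copy
against a majority-rule consensus, and overlapping calls are resolved by the
highest copy_number x period x identity score.  Period and copy number on
clean arrays are the contract; it does not reproduce the probabilistic model
or alignment weights of Tandem Repeats Finder.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from Bio import Align

from .composition import at_content
from .mito_io import CircularSequence, GeneFeature, extract_feature

__all__ = [
    "TandemRepeat",
    "RegionReport",
    "find_tandem_repeats",
    "pairwise_identity_nt",
    "compare_crs",
    "pseudo_trna_similarity",
]


@dataclass(frozen=True)
class TandemRepeat:
    """A tandem array: ``[start, end)`` of ``copy_number`` copies of ``period`` nt."""

    start: int
    end: int
    period: int
    copy_number: float
    consensus: str
    percent_match: float

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class RegionReport:
    name: str
    length: int
    at_percent: float
    repeats: list = field(default_factory=list)
    block_identity: dict = field(default_factory=dict)  # sibling region -> %


def _hamming_identity(a: str, b: str) -> float:
    m = min(len(a), len(b))
    if m == 0:
        return 0.0
    return 100.0 * sum(x == y for x, y in zip(a, b)) / m


def _consensus(copies: list[str]) -> str:
    """Majority-rule consensus over equal-length copies."""
    out = []
    for col in zip(*copies):
        counts = defaultdict(int)
        for b in col:
            counts[b] += 1
        out.append(max(sorted(counts), key=lambda b: counts[b]))
    return "".join(out)


def _extend_array(seq: str, pos: int, period: int, min_identity: float):
    """Grow an array around the anchor copy at ``pos``; returns (start, end, copies)."""
    n = len(seq)
    unit = seq[pos : pos + period]
    if len(unit) < period:
        return None
    copies = [unit]
    start = pos
    end = pos + period
    # extend right, full copies
    while end + period <= n:
        nxt = seq[end : end + period]
        if _hamming_identity(nxt, _consensus(copies)) >= min_identity:
            copies.append(nxt)
            end += period
        else:
            break
    # extend left, full copies
    while start - period >= 0:
        prv = seq[start - period : start]
        if _hamming_identity(prv, _consensus(copies)) >= min_identity:
            copies.insert(0, prv)
            start -= period
        else:
            break
    return start, end, copies


def _partial_tail(seq: str, end: int, consensus: str, min_identity: float) -> int:
    """Length of a trailing partial copy matching a consensus prefix."""
    best = 0
    for plen in range(len(consensus) - 1, 1, -1):
        if end + plen > len(seq):
            continue
        if _hamming_identity(seq[end : end + plen], consensus[:plen]) >= min_identity:
            best = plen
            break
    return best


def _smallest_period(copies: list[str], period: int, min_period: int,
                     min_identity: float) -> int:
    """Collapse to the smallest sub-period the array also satisfies (e.g. 38 not 76)."""
    joined = "".join(copies)
    for p in sorted(d for d in range(min_period, period) if period % d == 0):
        unit = joined[:p]
        ok = all(
            _hamming_identity(joined[i : i + p], unit) >= min_identity
            for i in range(p, len(joined) - p + 1, p)
        )
        if ok:
            return p
    return period


def find_tandem_repeats(
    seq: str,
    min_period: int = 10,
    max_period: int = 200,
    min_copies: float = 2.0,
    min_identity: float = 80.0,
    k: int = 12,
) -> list[TandemRepeat]:
    """Detect tandem-repeat arrays in ``seq``.

    Candidate periods are distances between recurrences of exact k-mers
    (k is clipped to ``min_period``); each candidate is extended greedily in
    both directions against a majority-rule consensus, a trailing partial copy
    is appended, and overlapping calls are resolved best-score-first.
    """
    seq = seq.upper()
    k = min(k, min_period)
    n = len(seq)
    if n < 2 * min_period:
        return []

    # seed: consecutive occurrences of the same k-mer at a usable distance
    occ: dict[str, int] = {}
    candidates: set[tuple[int, int]] = set()
    for i in range(n - k + 1):
        kmer = seq[i : i + k]
        if kmer in occ:
            d = i - occ[kmer]
            if min_period <= d <= max_period:
                candidates.add((occ[kmer], d))
        occ[kmer] = i

    arrays: dict[tuple[int, int], TandemRepeat] = {}
    for pos, period in sorted(candidates):
        grown = _extend_array(seq, pos, period, min_identity)
        if grown is None:
            continue
        start, end, copies = grown
        if len(copies) < 2:
            continue
        cons = _consensus(copies)
        tail = _partial_tail(seq, end, cons, min_identity)
        span = (end + tail) - start
        copy_number = round(span / period, 1)
        if copy_number < min_copies:
            continue
        p = _smallest_period(copies, period, min_period, min_identity)
        if p != period:
            sub = [c[i : i + p] for c in copies for i in range(0, period, p)]
            cons = _consensus(sub)
            period = p
            copy_number = round(span / period, 1)
            copies = sub
        ident = sum(_hamming_identity(c, cons) for c in copies) / len(copies)
        if ident < min_identity:
            continue
        key = (start, period)
        rep = TandemRepeat(start, start + span, period, copy_number, cons, round(ident, 1))
        prev = arrays.get(key)
        if prev is None or len(rep) > len(prev):
            arrays[key] = rep

    # resolve overlaps: highest copy_number * period * identity wins
    ranked = sorted(
        arrays.values(),
        key=lambda r: (-(r.copy_number * r.period * r.percent_match), r.start, r.period),
    )
    chosen: list[TandemRepeat] = []
    for rep in ranked:
        if all(rep.end <= c.start or rep.start >= c.end for c in chosen):
            chosen.append(rep)
    return sorted(chosen, key=lambda r: r.start)


# ---------------------------------------------------------------------------
# Alignment identities
# ---------------------------------------------------------------------------

def _nt_aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


def pairwise_identity_nt(a: str, b: str) -> float:
    """Global-alignment nucleotide identity (match 1, mismatch 0, gap -2/-1).

    Identity = matches / aligned columns x 100 (gap columns included).
    """
    if not a or not b:
        raise ValueError("empty sequence")
    aln = _nt_aligner("global").align(a.upper(), b.upper())[0]
    return 100.0 * aln.counts().identities / aln.length


def pseudo_trna_similarity(lncr_seq: str, trna_seq: str) -> float:
    """Identity of the best local-alignment window of a tRNA inside the LNCR.

    Local alignment with the same scoring as ``pairwise_identity_nt``;
    identity is matches over the aligned columns of the local window.
    """
    if not lncr_seq or not trna_seq:
        raise ValueError("empty sequence")
    aln = _nt_aligner("local").align(lncr_seq.upper(), trna_seq.upper())[0]
    return 100.0 * aln.counts().identities / aln.length


# ---------------------------------------------------------------------------
# Per-region reports
# ---------------------------------------------------------------------------

def compare_crs(
    genome: CircularSequence,
    features: list[GeneFeature],
    block: int = 500,
    min_period: int = 10,
    max_period: int = 200,
) -> list[RegionReport]:
    """Per-CR length, AT%, tandem repeats, and pairwise 5'-block identities.

    The 5' block of each control region is its first ``block`` nt in genome
    forward-strand order; block identities are computed between every pair of
    control regions present (a missing CR yields a report subset).
    """
    crs = [f for f in features if f.kind == "CR"]
    if len(crs) < 2:
        raise ValueError("need at least two control-region features")
    crs = sorted(crs, key=lambda f: f.start)

    seqs = {f.name: extract_feature(genome, f) for f in crs}
    reports = []
    for f in crs:
        s = seqs[f.name]
        rep = RegionReport(
            name=f.name,
            length=len(s),
            at_percent=at_content(s),
            repeats=find_tandem_repeats(s, min_period=min_period, max_period=max_period),
        )
        for g in crs:
            if g.name == f.name:
                continue
            a = s[:block]
            b = seqs[g.name][:block]
            rep.block_identity[g.name] = round(pairwise_identity_nt(a, b), 2)
        reports.append(rep)
    return reports
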