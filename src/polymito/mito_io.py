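"""Sequence/annotation I/O and circular-coordinate primitives.

Internal convention: 0-based half-open coordinates on the forward strand.
Origin-spanning features on circular sequences are encoded with ``end > len``
(single-interval algebra) rather than split parts.  All printed output is
1-based inclusive, matching the GenBank convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "ParseError",
    "CircularSequence",
    "GeneFeature",
    "GeneticCode",
    "VERTEBRATE_MITO",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
    "read_feature_table",
    "write_feature_table",
    "extract_feature",
    "translate",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = re.compile(r"^[ACGTN]+$")

FEATURE_KINDS = {"CDS", "tRNA", "rRNA", "CR", "LNCR", "repeat"}


class ParseError(ValueError):
    """Malformed input file (bad residues, bad coordinates, unknown dialect)."""


def reverse_complement(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CircularSequence:
    """A nucleotide record with topology-aware coordinate arithmetic.

    Residues are uppercase over the alphabet {A, C, G, T, N}.  ``fetch`` wraps
    across the origin when the topology is circular.
    """

    id: str
    residues: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"empty sequence for record {self.id!r}")
        if not _VALID.match(self.residues):
            bad = sorted(set(self.residues) - set("ACGTN"))
            raise ParseError(
                f"record {self.id!r} contains non-IUPAC/ambiguous characters {bad}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def fetch(self, start: int, end: int) -> str:
        """Extract ``[start, end)``; ``end`` may exceed length on circular records."""
        n = len(self.residues)
        if not 0 <= start < n:
            raise IndexError(f"start {start} outside [0, {n})")
        if end < start:
            raise IndexError(f"end {end} < start {start}")
        if end <= n:
            return self.residues[start:end]
        if not self.circular:
            raise ValueError(
                f"feature [{start}, {end}) wraps the origin but {self.id!r} is linear"
            )
        if end - start > n:
            raise IndexError(f"span {end - start} exceeds sequence length {n}")
        return self.residues[start:] + self.residues[: end - n]

    def reverse_complement(self) -> "CircularSequence":
        return CircularSequence(self.id, reverse_complement(self.residues), self.circular)


@dataclass(frozen=True)
class GeneFeature:
    """A named interval on the forward strand (0-based half-open).

    ``end > sequence length`` denotes an origin-spanning feature on a circular
    record; the extracted length is always ``end - start``.
    """

    name: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "CDS"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"bad interval [{self.start}, {self.end}) for {self.name!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneticCode:
    """A codon translation table (NCBI numbering).

    The vertebrate mitochondrial code (id 2) differs from the standard code in
    that AGA/AGG are stops, ATA encodes Met, and TGA encodes Trp.
    """

    code_id: int
    codon_to_aa: dict = field(repr=False)
    start_codons: frozenset = field(repr=False)
    stop_codons: frozenset = field(repr=False)

    @classmethod
    def from_ncbi(cls, code_id: int) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[code_id]
        mapping = dict(table.forward_table)
        return cls(
            code_id=code_id,
            codon_to_aa=mapping,
            start_codons=frozenset(table.start_codons),
            stop_codons=frozenset(table.stop_codons),
        )

    def family(self, aa: str) -> list[str]:
        """All codons translating to ``aa`` (synonymous family)."""
        return sorted(c for c, a in self.codon_to_aa.items() if a == aa)


VERTEBRATE_MITO = GeneticCode.from_ncbi(2)


def translate(
    nt: str,
    code: GeneticCode = VERTEBRATE_MITO,
    to_stop: bool = True,
    report_stop: bool = False,
):
    """Translate a nucleotide string in frame 0.

    Translation stops at the first stop codon when ``to_stop`` is set; a
    trailing partial codon is ignored; codons containing N translate to ``X``.
    With ``report_stop`` the return value is ``(peptide, stop_observed)``.
    """
    if len(nt) < 3:
        raise ValueError("need at least one full codon")
    nt = nt.upper()
    aa: list[str] = []
    stop_seen = False
    for i in range(0, len(nt) - len(nt) % 3, 3):
        codon = nt[i : i + 3]
        if codon in code.stop_codons:
            stop_seen = True
            if to_stop:
                break
            continue
        aa.append(code.codon_to_aa.get(codon, "X"))
    peptide = "".join(aa)
    return (peptide, stop_seen) if report_stop else peptide


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, circular: bool | None = None) -> list[CircularSequence]:
    """Read a (multi-)FASTA file into ``CircularSequence`` records.

    Topology is taken from ``circular`` if given, else from a ``circular`` /
    ``linear`` keyword in the header description (default circular, the normal
    case for mitogenomes).  Non-IUPAC residues raise ``ParseError`` naming the
    offending record.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        if circular is None:
            desc = rec.description.lower()
            topo = not ("linear" in desc.split())
        else:
            topo = circular
        out.append(CircularSequence(rec.id, str(rec.seq).upper(), circular=topo))
    return out


def write_fasta(seqs: Iterable[CircularSequence], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            topo = "circular" if s.circular else "linear"
            fh.write(f">{s.id} {topo}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Feature tables (tab-delimited and GenBank flat-file dialects)
# ---------------------------------------------------------------------------

_GB_LOCATION = re.compile(r"(complement\()?<?(\d+)\.\.>?(\d+)\)?")


def read_feature_table(path) -> list[GeneFeature]:
    """Read gene features from a tab-delimited table or a GenBank flat file.

    The tab dialect has columns ``name  start  end  strand  kind`` with 1-based
    inclusive coordinates on disk; the GenBank dialect is detected by a LOCUS /
    FEATURES header.  Coordinates are normalised to 0-based half-open, anchored
    on the forward strand; ``complement(..)`` features get strand '-'.
    """
    path = Path(path)
    head = path.read_text().lstrip()[:2000]
    if head.startswith("LOCUS") or head.startswith("FEATURES"):
        return _read_genbank_features(path)
    return _read_tab_features(path)


def _read_tab_features(path: Path) -> list[GeneFeature]:
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() == "name":  # header row
                continue
            if len(parts) != 5:
                raise ParseError(f"{path}:{lineno}: expected 5 tab-separated columns")
            name, start, end, strand, kind = parts
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            feats.append(GeneFeature(name, start_i - 1, end_i, strand, kind))
    if not feats:
        raise ParseError(f"{path}: no features found")
    return feats


def _read_genbank_features(path: Path) -> list[GeneFeature]:
    kind_map = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                "D-loop": "CR", "misc_feature": "LNCR", "repeat_region": "repeat"}
    feats = []
    current: tuple[str, str] | None = None  # (gb_kind, location string)
    name = None
    with open(path) as fh:
        in_features = False
        for lineno, line in enumerate(fh, 1):
            if line.startswith("FEATURES"):
                in_features = True
                continue
            if in_features and line[:1] not in (" ", "\t"):
                break  # ORIGIN or next record
            if not in_features or not line.strip():
                continue
            if len(line) > 5 and line[5] != " " and line[:5] == "     ":  # new feature
                if current is not None:
                    feats.append(_gb_feature(current, name, kind_map, path, lineno))
                cols = line.split()
                if len(cols) != 2:
                    raise ParseError(f"{path}:{lineno}: malformed feature line")
                current = (cols[0], cols[1])
                name = None
            else:
                m = re.search(r'/(?:gene|product|note)="?([^"\n]+)"?', line)
                if m and name is None:
                    name = m.group(1)
    if current is not None:
        feats.append(_gb_feature(current, name, kind_map, path, 0))
    if not feats:
        raise ParseError(f"{path}: no features found")
    return feats


def _gb_feature(current, name, kind_map, path, lineno) -> GeneFeature:
    gb_kind, loc = current
    m = _GB_LOCATION.match(loc)
    if not m:
        raise ParseError(f"{path}:{lineno}: unsupported location {loc!r}")
    strand = "-" if m.group(1) else "+"
    start, end = int(m.group(2)) - 1, int(m.group(3))
    return GeneFeature(name or gb_kind, start, end, strand, kind_map.get(gb_kind, "CDS"))


def write_feature_table(features: Iterable[GeneFeature], path) -> None:
    """Write the tab dialect (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("name\tstart\tend\tstrand\tkind\n")
        for f in features:
            fh.write(f"{f.name}\t{f.start + 1}\t{f.end}\t{f.strand}\t{f.kind}\n")


def extract_feature(seq: CircularSequence, f: GeneFeature) -> str:
    """Extract a feature's nucleotides; reverse-complemented for strand '-'."""
    nt = seq.fetch(f.start, f.end)
    return reverse_complement(nt) if f.strand == "-" else nt
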