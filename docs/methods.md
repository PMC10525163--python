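# Methods

This note documents the models, defaults, and numerical choices behind each
stage, what the synthetic generator does and does not emulate, and the known
limitations.

## Coordinates and genetic code

All internal coordinates are 0-based half-open on the forward strand; printed
output is 1-based inclusive (GenBank convention).  Origin-spanning features on
circular sequences are encoded with `end > length` so interval arithmetic
stays single-interval.  Translation uses the vertebrate mitochondrial code
(NCBI table 2: AGA/AGG are stops, ATA→M, TGA→W) via Biopython's codon tables;
codons containing N translate to `X`, and ambiguity codes other than N are
rejected at parse time because the downstream statistics (skew, K2P) are
defined over unambiguous bases, with N handled by pairwise deletion.

## ATP8 recovery

`scan_orfs` walks all three frames on both strands, extends across the origin
on circular records, and reports one candidate per start codon (nested ORFs
sharing a stop are all reported) — necessary because an incidental upstream
in-frame start would otherwise absorb the true gene.  `recover_atp8`
restricts to forward-strand ORFs ending within 1 kb upstream of the annotated
*ATP6* start and scores five components, each in [0, 1]:

* **overlap** — 1 when the ORF ends exactly 4 nt inside *ATP6* and the shared
  tetranucleotide is `ATAG`; otherwise decays with distance from 4 nt.
* **length** — 1 inside the 100–250 nt band typical of the gene, linear decay
  outside.
* **TM** — 1 for a transmembrane segment starting within the first 5
  residues, 0.5 for a TM elsewhere, 0 for none.  TM segments are maximal runs
  of Kyte–Doolittle windowed means ≥ 1.6 spanning ≥ 18 residues; a run of
  qualifying windows [p₁, p₂] spans residues [p₁, p₂ + window), so the
  reported segment is the full residue extent of the evidence.
* **hydropathy contrast** — rewards positive N-terminal and negative
  C-terminal mean hydropathy (half indicator, half scaled difference).
* **motif** — match of the first four residues against MVKT/MAKT (the
  *Polypedates*-type starts) or the canonical MPQL; partial credit for
  partial matches.

Components are min–max normalised across candidates (a constant component is
left raw, so a lone candidate keeps its scores) and combined as an
equal-weight mean; the weighting is explicit and overridable because the
underlying curation judgement is qualitative.  The Kyte–Doolittle window
defaults to 9 residues (the common ProtScale default) and is a parameter.
Peptide identity uses global alignment with match 1, mismatch 0, gap −1
(identity-oriented), identity = matches/columns.

## Tandem repeats

The detector favours determinism and testability over sensitivity: candidate
periods are the distances between successive occurrences of exact k-mers
(k = min(12, min_period)); each candidate is extended copy-by-copy in both
directions while copies stay ≥ 80% identical (Hamming) to the running
majority-rule consensus, a trailing partial copy is appended, arrays are
collapsed to the smallest sub-period they satisfy (so a 76-nt seed reports
the 38-nt unit), and overlapping calls are resolved best-first by
copy_number × period × identity.  Period and copy number on clean arrays are
the contract; the probabilistic alignment model of Tandem Repeats Finder is
deliberately not reproduced, so copy-number equality with TRF output on real
accessions is not guaranteed (period length is the robust quantity).
Nucleotide identities use global alignment (match 1, mismatch 0, gap −2
open/−1 extend); the pseudo-tRNA similarity is the identity of the best
local-alignment window of the tRNA against the LNCR under the same scoring.
On random 700-nt backgrounds this local identity stays below ~65%, well
separated from the ≈76% of a genuine degenerate copy.

## TDRL search

A TDRL event replaces a segment with 2–3 tandem copies and deletes a subset
of copied slots; deletion of every copy of a gene is an error unless loss is
explicitly enabled.  "Random loss" is generalised to an arbitrary
keep-pattern; event count is the number of duplication episodes (the second
event of the two-event scenario deletes six tRNA copies in one episode).
`explain` runs breadth-first over canonicalised label tuples (circular orders
rotated to the *Cytb* anchor).  Intermediate events are enumerated with the
keep-pattern space bounded at copies × segment-length ≤ 12 slots; the final
step of every series instead uses an exact reachability check that splits the
replaced window into the fewest chains, each an in-order subsequence of the
segment (greedy earliest-match, which is optimal).  Series of length ≤ 2 are
therefore found exactly whenever one exists within the copy bound; the
number of reported equivalent series is capped (default 50), and hitting a
state-space bound is reported as `truncated`, never silently.

## K2P / Mantel

K2P uses pairwise deletion (complete deletion available upstream by
filtering); saturated pairs (log argument ≤ 0) are NaN rather than clamped.
Geographic distances are great circles on a 6371.0-km sphere.  The Mantel
statistic is the Pearson correlation of strictly-lower-triangle entries; the
permutation p-value is (1 + #{r* ≥ r})/(1 + N) for the one-tailed "greater"
alternative (the isolation-by-distance hypothesis; two-sided available), with
N = 9999 by default and a seeded generator.  The implementation is
cross-checked against scikit-bio's Mantel test in the suite.

## qPCR

Technical replicates are collapsed by mean first; the biological replicate is
the unit of analysis (n = 4 in the emulated design).  ΔCt = Ct_gene −
Ct_reference per sample, relative level 2^−ΔCt (amplification efficiency
fixed at 2; no efficiency correction), Grubbs screening within each group
(single pass, at most one removal), control mean scaled to exactly 1.0,
Student's equal-variance two-tailed t-test by default (Welch optional), no
multiple-testing correction (per-gene p < 0.05).  The Grubbs critical value
GP(n) = ((n−1)/√n)·√(t²/(n−2+t²)) uses the one-sided upper-α/n t quantile
with n−2 df: the one-sided form reproduces the conventional printed value
GP(4) = 1.46 (two-sided would give 1.48).

## Synthetic generator

`make_genome` assembles, deterministically per (recipe, seed), a ~24 kb
circular genome (within 5% of target; CR tails absorb the length budget):
a shared 5′ CR block (500 nt) containing a 38-bp ×5 array (2% per-copy
substitution) copied into CR1/CR2/CR3 at 1% divergence; a 100-bp ×3 array
only at the 3′ side of CR3; two *ND5* copies (1779 nt) at 1.5% divergence
with substitutions placed so no internal stop arises; a 713-nt LNCR at 58% AT
holding a tRNA-Lys copy mutated to exactly 76% identity; and an *ATP8* whose
peptide is M + MVKT-motif + hydrophobic body (I/L/V codons) to residue 20,
then four arginines, then a hydrophilic tail, ending `...A-TAG` so the final
four bases `ATAG` contain both the TAG stop and the *ATP6* start.  Because
`ATAG` cannot contain `ATG` in frame, *ATP6* starts on the leading A with the
mitochondrial start codon ATA.  The four arginines pin the hydropathy
drop-off so the detected TM segment ends within 2 residues of the planted
boundary for any draw of the hydrophobic body.  Codon usage for ordinary
CDSs is sampled from AT-skewed weights (so RSCU has structure) tuned to give
≈62% AT genome-wide with CRs at 66–68% — the emulated compositional regime.
Intergenic spacers and tRNA placeholders are random sequence (5–70 nt); the
generator does not emulate real tRNA structure, replication-origin motifs,
strand-asymmetric mutation, or sequencing/assembly error, so passing tests
demonstrate correctness of the *computations*, not annotation performance on
real chromatograms.

`make_qpcr` draws Ct = gene baseline + sample effect − log2(fold, stress
only) + N(0, 0.25), 4 biological × 3 technical replicates, default folds
{0.64, 0.55, 0.44, 0.65, 1.0} (the suppressed-gene regime).  Planted outliers
shift one biological sample's Ct down by 8σ (2 cycles, a 4-fold excursion).
The floor for a *detectable* outlier at n = 4 is structural: the Grubbs
statistic is bounded by (n−1)/√n = 1.5 against GP(4) = 1.463, so small
excursions are undetectable by construction and the default is chosen to be
unambiguous.

`make_ibd` places demes 100 km apart on a meridian and evolves sequences
along the chain (5×10⁻⁵ substitutions/site/km, transition:transversion 4:1)
plus per-deme private noise (0.002/site), yielding K2P distances of roughly
0.005–0.05 across 8 demes — the emulated divergence range.  A zero slope
gives the exchangeable null used for calibration.

## Problem sizes in the test suite

The simulation-backed assertions use 100 genomes (ATP8 recall, repeat
recovery), 200 replicates (qPCR folds and outliers, TDRL oracle
consistency), and 1000 null / 100 power replicates at 999 permutations for
Mantel calibration; the full suite runs in about a minute on one CPU.

## Known limitations

* The repeat detector reports one consensus per array and can merge adjacent
  arrays whose units are rotations of each other.
* The TDRL intermediate-event enumeration bound (12 slots) means series of
  length ≥ 3 whose *intermediate* events duplicate very long segments may be
  missed; the final event of any series is checked exactly.
* Alignment-based "similarity" values depend on scoring; published figures
  produced by unspecified tools are reproducible only to within a few
  percentage points.
* Mapping of sequence records to sampling localities (for real-data IBD runs)
  must be supplied by the user.
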