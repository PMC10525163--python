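"""ORF scanning, hydropathy profiling, TM detection, and ATP8 recovery."""

import math

import numpy as np
import pytest

from polymito import orf_recovery as orf
from polymito import synthetic_data as synth
from polymito.mito_io import CircularSequence, GeneFeature, translate


class TestScanOrfs:
    def test_simple_orf(self):
        seq = CircularSequence("s", "CCC" + "ATGAAATAG" + "CCC", circular=False)
        cands = orf.scan_orfs(seq, min_aa=1, strands="+")
        assert any(c.aa_seq == "MK" and c.start == 3 and c.end == 12 for c in cands)

    def test_all_a_no_candidates_under_strict_starts(self):
        seq = CircularSequence("s", "A" * 300, circular=False)
        assert orf.scan_orfs(seq, min_aa=1) == []

    def test_reverse_strand_candidate(self):
        from polymito.mito_io import reverse_complement

        fwd = "ATGAAATAG"
        seq = CircularSequence("s", "CC" + reverse_complement(fwd) + "CC", circular=False)
        cands = orf.scan_orfs(seq, min_aa=1, strands="-")
        assert any(c.aa_seq == "MK" and c.strand == "-" for c in cands)

    def test_origin_spanning_orf_found_on_circular(self):
        core = "ATGAAAAAATAG"
        # place the ORF across the origin: last 6 nt at the end, rest at the start
        residues = core[6:] + ("C" * 60) + core[:6]
        seq = CircularSequence("s", residues, circular=True)
        cands = orf.scan_orfs(seq, min_aa=1)
        hit = [c for c in cands if c.aa_seq == "MKK"]
        assert hit and hit[0].start == 66 and hit[0].end == 78  # end > len marks wrap

    def test_region_outside_sequence_rejected(self):
        seq = CircularSequence("s", "ACGT" * 10)
        with pytest.raises(ValueError):
            orf.scan_orfs(seq, region=(50, 60))

    def test_candidates_internally_consistent(self, genome, manifest):
        a8 = manifest["atp8"]
        cands = orf.scan_orfs(genome, min_aa=20, region=(a8["start"] - 500, a8["end"]))
        assert cands
        for c in cands:
            assert (c.end - c.start) % 3 == 0
            assert translate(c.nt_seq) == c.aa_seq
            assert c.nt_seq[-3:] == c.stop_codon


class TestHydropathy:
    def test_scale_extremes(self):
        assert orf.kyte_doolittle("IIIII", 5).values == pytest.approx([4.5])
        assert orf.kyte_doolittle("RRRRR", 5).values == pytest.approx([-4.5])

    def test_windowed_means_match_hand_computation(self):
        aa = "MIKAG"  # KD: 1.9, 4.5, -3.9, 1.8, -0.4
        prof = orf.kyte_doolittle(aa, 3)
        expected = [(1.9 + 4.5 - 3.9) / 3, (4.5 - 3.9 + 1.8) / 3, (-3.9 + 1.8 - 0.4) / 3]
        assert prof.values == pytest.approx(expected)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            orf.kyte_doolittle("MIKA", 2)

    def test_unknown_residue_warns_and_scores_zero(self):
        with pytest.warns(UserWarning):
            prof = orf.kyte_doolittle("IZI", 3)
        assert prof.values == pytest.approx([3.0])


class TestTmSegments:
    def test_uniform_hydrophobic_profile_one_segment(self):
        prof = orf.HydropathyProfile(np.full(30, 4.5), window=9)
        (seg,) = orf.find_tm_segments(prof)
        assert (seg.start, seg.end) == (0, 38)  # spans every covered residue

    def test_all_zero_profile_empty(self):
        prof = orf.HydropathyProfile(np.zeros(30), window=9)
        assert orf.find_tm_segments(prof) == []

    def test_planted_tm_recovered_within_two_residues(self, manifest):
        peptide = manifest["atp8"]["peptide"]
        lo, hi = manifest["atp8"]["tm_aa"]
        prof = orf.kyte_doolittle(peptide, 9)
        segs = orf.find_tm_segments(prof)
        assert len(segs) == 1
        assert abs(segs[0].start - lo) <= 2 and abs(segs[0].end - hi) <= 2


class TestProfileSimilarity:
    def test_self_and_negation(self):
        prof = orf.kyte_doolittle("MIKAGRRLIV", 3)
        neg = orf.HydropathyProfile(-prof.values, prof.window)
        assert orf.profile_similarity(prof, prof) == pytest.approx(1.0)
        assert orf.profile_similarity(prof, neg) == pytest.approx(-1.0)

    def test_constant_profile_missing(self):
        a = orf.HydropathyProfile(np.full(5, 2.0), 9)
        b = orf.kyte_doolittle("MIKAGRRLIV", 3)
        assert math.isnan(orf.profile_similarity(a, b))

    def test_shared_tm_block_gives_positive_correlation(self):
        _, _, m1 = synth.make_genome(seed=101)
        _, _, m2 = synth.make_genome(seed=202)
        p1 = orf.kyte_doolittle(m1["atp8"]["peptide"], 9)
        p2 = orf.kyte_doolittle(m2["atp8"]["peptide"], 9)
        assert orf.profile_similarity(p1, p2) > 0.5


class TestPeptideIdentity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("MVKT", "MVKT", 100.0), ("AAAA", "CCCC", 0.0), ("MVKT", "MAKT", 75.0)],
    )
    def test_values(self, a, b, expected):
        assert orf.pairwise_peptide_identity(a, b) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            orf.pairwise_peptide_identity("", "MK")


class TestRecoverAtp8:
    def test_planted_orf_ranked_first(self, genome, features, manifest):
        scores = orf.recover_atp8(genome, features)
        best = scores[0]
        a8 = manifest["atp8"]
        assert (best.candidate.start, best.candidate.end) == (a8["start"], a8["end"])
        assert best.overlap_with_next_gene == 4
        assert best.overlap_tetranucleotide == "ATAG"
        assert best.n_term_motif == "MVKT"

    def test_requires_atp6_annotation(self, genome, features):
        rest = [f for f in features if f.name != "ATP6"]
        with pytest.raises(ValueError, match="ATP6"):
            orf.recover_atp8(genome, rest)

    def test_orf_free_window_gives_empty_result(self):
        # genome whose upstream window contains no ORF of the minimum length
        rng = np.random.default_rng(5)
        filler = "".join(
            rng.choice(list("ACGT"), size=400)
        )
        # kill every start codon in the window
        filler = filler.replace("ATG", "ACC").replace("GTG", "GCC").replace("ATA", "ACA")
        residues = filler + "ATAGGG" + "C" * 200
        seq = CircularSequence("s", residues, circular=False)
        feats = [GeneFeature("ATP6", len(filler), len(filler) + 6)]
        assert orf.recover_atp8(seq, feats, window_nt=len(filler), min_aa=30) == []

    def test_overlap_component_monotone_in_rank(self, genome, features, manifest):
        """Raising only the overlap component never lowers a candidate's rank."""
        scores = orf.recover_atp8(genome, features)
        target = scores[-1]
        base_rank = scores.index(target)
        boosted = dict(target.components)
        boosted["overlap"] = 1.0
        totals = []
        for s in scores:
            comps = dict(s.components) if s is not target else boosted
            totals.append(sum(comps.values()) / len(comps))
        new_rank = sorted(range(len(totals)), key=lambda i: -totals[i]).index(
            len(scores) - 1
        )
        assert new_rank <= base_rank
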