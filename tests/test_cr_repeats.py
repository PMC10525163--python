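"""Tandem-repeat detection, alignment identities, and CR/LNCR reports."""

import numpy as np
import pytest

from polymito import cr_repeats as cr
from polymito import synthetic_data as synth
from polymito.composition import at_content
from polymito.mito_io import extract_feature


class TestFindTandemRepeats:
    def test_partial_trailing_copy(self):
        reps = cr.find_tandem_repeats("ACGTACGTAC", min_period=4)
        assert len(reps) == 1
        r = reps[0]
        assert r.period == 4 and r.copy_number == pytest.approx(2.5)
        assert r.percent_match == pytest.approx(100.0)

    def test_exact_array_full_recovery(self):
        unit = "ACCGTTAGGCAT"
        reps = cr.find_tandem_repeats(unit * 4, min_period=10)
        assert len(reps) == 1
        r = reps[0]
        assert r.period == len(unit) and r.copy_number == pytest.approx(4.0)
        assert r.percent_match == pytest.approx(100.0)
        assert (r.start, r.end) == (0, 48)

    def test_smallest_period_reported(self):
        unit = "ACCGTTAGGCAT"
        # a 24-mer seed must still collapse onto the 12-nt unit
        reps = cr.find_tandem_repeats(unit * 6, min_period=10, max_period=40)
        assert reps[0].period == len(unit)

    def test_random_sequence_has_no_arrays(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = "".join(rng.choice(list("ACGT"), size=1000))
            assert cr.find_tandem_repeats(s, min_period=10, min_identity=80) == []

    def test_short_input_empty(self):
        assert cr.find_tandem_repeats("ACGTACG", min_period=10) == []

    def test_reported_arrays_never_overlap(self, genome, features_by_name):
        for name in ("CR1", "CR2", "CR3"):
            region = extract_feature(genome, features_by_name[name])
            reps = cr.find_tandem_repeats(region)
            for a, b in zip(reps, reps[1:]):
                assert a.end <= b.start
            for r in reps:
                assert 0 <= r.start < r.end <= len(region)
                # span consistent with period x copies to within one period
                assert abs(len(r) - r.period * r.copy_number) <= r.period

    def test_planted_arrays_recovered(self, genome, features_by_name, manifest):
        for truth in manifest["repeats"]:
            region = extract_feature(genome, features_by_name[truth["region"]])
            reps = cr.find_tandem_repeats(region)
            hit = [
                r
                for r in reps
                if abs(r.period - truth["period"]) <= 1
                and abs(r.copy_number - truth["copies"]) <= 1
                and abs(r.start - truth["region_offset"]) <= truth["period"]
            ]
            assert hit, f"array {truth} not recovered"


class TestIdentities:
    def test_identical_and_simple_mismatch(self):
        assert cr.pairwise_identity_nt("ACGTACGT", "ACGTACGT") == pytest.approx(100.0)
        assert cr.pairwise_identity_nt("AAAA", "AAAT") == pytest.approx(75.0)

    def test_nd5_copies_match_planted_divergence(self, genome, features_by_name, manifest):
        a = extract_feature(genome, features_by_name["ND5_1"])
        b = extract_feature(genome, features_by_name["ND5_2"])
        expected = 100.0 * (1 - manifest["nd5"]["divergence"])
        assert cr.pairwise_identity_nt(a, b) == pytest.approx(expected, abs=1.0)

    def test_zero_divergence_copies_identical(self):
        recipe = synth.GenomeRecipe(nd5_divergence=0.0)
        genome, features, _ = synth.make_genome(recipe, seed=3)
        by = {f.name: f for f in features}
        a = extract_feature(genome, by["ND5_1"])
        b = extract_feature(genome, by["ND5_2"])
        assert cr.pairwise_identity_nt(a, b) == pytest.approx(100.0)


class TestCompareCrs:
    def test_block_identities_match_planted_divergence(self, genome, features, manifest):
        reports = {r.name: r for r in cr.compare_crs(genome, features)}
        assert set(reports) == {"CR1", "CR2", "CR3"}
        d = manifest["cr_blocks"]["divergence"]
        # CR2/CR3 blocks are independent mutants of the CR1 block
        assert reports["CR1"].block_identity["CR2"] == pytest.approx(100 * (1 - d), abs=0.5)
        assert reports["CR1"].block_identity["CR3"] == pytest.approx(100 * (1 - d), abs=0.5)
        for rep in reports.values():
            for ident in rep.block_identity.values():
                assert ident >= 97.5

    def test_identical_blocks_give_100(self):
        recipe = synth.GenomeRecipe(cr_block_divergence=0.0)
        genome, features, _ = synth.make_genome(recipe, seed=2)
        for rep in cr.compare_crs(genome, features):
            for ident in rep.block_identity.values():
                assert ident == pytest.approx(100.0)

    def test_100bp_array_only_in_cr3(self, genome, features):
        reports = {r.name: r for r in cr.compare_crs(genome, features)}
        assert any(t.period >= 90 for t in reports["CR3"].repeats)
        for name in ("CR1", "CR2"):
            assert all(t.period < 90 for t in reports[name].repeats)

    def test_at_percent_matches_composition_module(self, genome, features, features_by_name):
        for rep in cr.compare_crs(genome, features):
            region = extract_feature(genome, features_by_name[rep.name])
            assert rep.at_percent == pytest.approx(at_content(region))

    def test_fewer_than_two_crs_rejected(self, genome, features):
        only_cr1 = [f for f in features if f.kind != "CR" or f.name == "CR1"]
        with pytest.raises(ValueError):
            cr.compare_crs(genome, only_cr1)


class TestPseudoTrna:
    def test_exact_copy_scores_100(self):
        rng = np.random.default_rng(1)
        trna = "".join(rng.choice(list("ACGT"), size=70))
        lncr = "".join(rng.choice(list("ACGT"), size=300)) + trna + "ACGT" * 20
        assert cr.pseudo_trna_similarity(lncr, trna) == pytest.approx(100.0)

    def test_random_background_below_70(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            lncr = "".join(rng.choice(list("ACGT"), size=700))
            trna = "".join(rng.choice(list("ACGT"), size=70))
            assert cr.pseudo_trna_similarity(lncr, trna) < 70.0

    def test_planted_degenerate_copy_recovered(self, genome, features_by_name, manifest):
        lncr = extract_feature(genome, features_by_name["LNCR"])
        trna = extract_feature(genome, features_by_name["trnK"])
        planted = 100.0 * manifest["pseudo_trna"]["identity"]
        assert cr.pseudo_trna_similarity(lncr, trna) == pytest.approx(planted, abs=3.0)
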