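"""Library enumeration, min-Hamming codon choice, dedup and silencing."""

import itertools

import numpy as np
import pytest

import sgescan as sg
from sgescan.library_design import (
    NoVariantError,
    UnsilenceableMotifError,
    complete_codons,
)
from sgescan.seqmodel import CODON_TO_AA, apply_edit, translate


def brute_force_library_sequences(model, region, max_del=3):
    """Independent enumerator: every edit applied naively, set of results."""
    wt = model.variable_sequence(region)
    seqs = set()
    for i, base in enumerate(wt):  # SNVs
        for alt in "ACGT":
            if alt != base:
                seqs.add(wt[:i] + alt + wt[i + 1 :])
    for codon_i, off in complete_codons(model, region):  # all codon swaps
        ref = wt[off : off + 3]
        wt_aa = CODON_TO_AA[ref]
        reachable = {
            CODON_TO_AA[ref[:i] + b + ref[i + 1 :]]
            for i in range(3)
            for b in "ACGT"
            if b != ref[i]
        }
        targets = set("ACDEFGHIKLMNPQRSTVWY*")
        if len([c for c, a in CODON_TO_AA.items() if a == wt_aa]) < 2:
            targets.discard(wt_aa)
        for target in targets - reachable:
            codons = sorted(
                c for c, a in CODON_TO_AA.items() if a == target and c != ref
            )
            if not codons:
                continue
            dmin = min(sum(x != y for x, y in zip(ref, c)) for c in codons)
            best = min(c for c in codons if sum(x != y for x, y in zip(ref, c)) == dmin)
            seqs.add(wt[:off] + best + wt[off + 3 :])
    for i in range(len(wt)):  # insertions
        for b in "ACGT":
            seqs.add(wt[:i] + b + wt[i:])
    for size in range(1, max_del + 1):  # deletions
        for i in range(len(wt) - size + 1):
            seqs.add(wt[:i] + wt[i + size :])
    seqs.discard(wt)
    seqs.discard("")
    return seqs


class TestMinHammingCodon:
    @pytest.mark.parametrize(
        "ref, target, expected",
        [
            ("CGC", "H", "CAC"),  # His codons CAC (d=1) beats CAT (d=2)
            ("CTG", "I", "ATA"),  # ties ATA/ATC/ATT at d=2, lexicographic
            ("GGA", "G", "GGC"),  # synonymous tie at d=1, lexicographic
        ],
    )
    def test_examples_match_enumeration(self, ref, target, expected):
        assert sg.min_hamming_codon(ref, target) == expected

    def test_agrees_with_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        codons = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
        for _ in range(100):
            ref = codons[rng.integers(len(codons))]
            target = "ACDEFGHIKLMNPQRSTVWY*"[rng.integers(21)]
            cands = [c for c, a in CODON_TO_AA.items() if a == target and c != ref]
            if not cands:
                with pytest.raises(NoVariantError):
                    sg.min_hamming_codon(ref, target)
                continue
            got = sg.min_hamming_codon(ref, target)
            dist = lambda c: sum(x != y for x, y in zip(ref, c))  # noqa: E731
            assert CODON_TO_AA[got] == target
            assert dist(got) == min(dist(c) for c in cands)
            assert got == min(c for c in cands if dist(c) == dist(got))

    def test_met_trp_have_no_synonym(self):
        with pytest.raises(NoVariantError):
            sg.min_hamming_codon("ATG", "M")
        with pytest.raises(NoVariantError):
            sg.min_hamming_codon("TGG", "W")


class TestEnumerators:
    def test_snv_closed_form(self):
        assert len(sg.enumerate_snvs("A")) == 3
        edits = sg.enumerate_snvs("ACG")
        assert len(edits) == 9
        assert len({apply_edit("ACG", e) for e in edits}) == 9

    def test_snvs_on_random_50mer_are_all_distinct(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=50))
        edits = sg.enumerate_snvs(seq)
        assert len(edits) == 150
        assert len({apply_edit(seq, e) for e in edits}) == 150

    def test_indel_closed_forms(self):
        seq = "ACGT"
        edits = sg.enumerate_indels(seq)
        ins = [e for e in edits if e.kind == "insertion"]
        dels = [e for e in edits if e.kind == "deletion"]
        assert len(ins) == 4 * len(seq)
        assert len(dels) == 3 * len(seq) - 3
        del_seqs = {apply_edit(seq, e) for e in dels}
        assert del_seqs == {"CGT", "AGT", "ACT", "ACG", "GT", "AT", "AC", "T", "A"}

    def test_insertion_dedup_on_homopolymer(self):
        edits = [e for e in sg.enumerate_indels("AC") if e.kind == "insertion"]
        assert len(edits) == 8
        assert len({apply_edit("AC", e) for e in edits}) == 7  # "AAC" arises twice

    def test_aa_substitution_targets_complete_per_codon(self, toy_model):
        """SNV-reachable plus multi-nt targets cover 19 missense + STOP."""
        wt = toy_model.variable_sequence(0)
        multi = sg.enumerate_aa_substitutions(toy_model, 0)
        snvs = sg.enumerate_snvs(wt)
        for codon_i, off in complete_codons(toy_model, 0):
            ref = wt[off : off + 3]
            targets = set()
            for e in snvs + multi:
                if not (off <= e.pos < off + 3 and e.kind == "substitution"):
                    continue
                seq = apply_edit(wt, e)
                new_codon = seq[off : off + 3]
                if len(seq) == len(wt) and new_codon != ref:
                    targets.add(CODON_TO_AA[new_codon])
            missense = targets - {"*", CODON_TO_AA[ref]}
            assert len(missense) == 19
            assert "*" in targets

    def test_multi_nt_edits_only_for_snv_unreachable(self, toy_model):
        wt = toy_model.variable_sequence(0)
        for e in sg.enumerate_aa_substitutions(toy_model, 0):
            assert e.kind == "substitution"
            assert sum(a != b for a, b in zip(e.ref, e.alt)) >= 2


class TestBuildLibrary:
    def test_wt_absent_and_sequences_unique(self, toy_model):
        lib = sg.build_library(toy_model)
        for region in (0, 1):
            seqs = [r.sequence for r in lib.region_records(region)]
            assert len(seqs) == len(set(seqs))
            assert lib.wt_sequences[region] not in seqs

    def test_matches_independent_bruteforce_enumerator(self, toy_model):
        lib = sg.build_library(toy_model)
        for region in (0, 1):
            expected = brute_force_library_sequences(toy_model, region)
            got = {r.sequence for r in lib.region_records(region)}
            assert got == expected

    def test_min_pairwise_hamming_is_one(self, toy_model):
        lib = sg.build_library(toy_model)
        seqs = [r.sequence for r in lib.region_records(0)]
        by_len = {}
        for s in seqs:
            by_len.setdefault(len(s), []).append(s)
        dmin = min(
            sum(x != y for x, y in zip(a, b))
            for group in by_len.values()
            for a, b in itertools.combinations(group, 2)
        )
        assert dmin == 1

    def test_class_taxonomy_present(self, minigene_library):
        nt_classes = {r.consequence.nt_class for r in minigene_library.records}
        assert {"sub1_Ts", "sub1_Tv", "sub2", "sub3", "ins", "del_if", "del_fs", "intronic"} <= nt_classes

    def test_substitution_hamming_recorded(self, toy_model):
        lib = sg.build_library(toy_model)
        for r in lib.records:
            if r.edit.kind == "substitution":
                wt = lib.wt_sequences[r.region]
                assert r.hamming_to_wt == sum(a != b for a, b in zip(wt, r.sequence))

    def test_dedup_idempotent(self, toy_model):
        a = {r.sequence for r in sg.build_library(toy_model).records}
        b = {r.sequence for r in sg.build_library(toy_model).records}
        assert a == b


class TestSilenceMotif:
    def test_absent_motif_returns_unchanged(self, toy_model):
        out = sg.silence_motif(toy_model, "GAAGAC")
        assert out.sequence == toy_model.sequence

    def test_coding_occurrence_removed_synonymously(self):
        # GAAGAC spans codons GAA|GAC (E-D); synonymous swaps can break it
        m = sg.build_transcript_model(
            "ATGGAAGACTAA", [(0, 12)], flank_len=0, constant_len=0
        )
        out = sg.silence_motif(m, "GAAGAC")
        assert "GAAGAC" not in out.sequence
        assert "GTCTTC" not in out.sequence
        assert out.protein() == m.protein()

    def test_intronic_occurrence_removed(self):
        seq = "ATG" + "GTAA" + "GAAGAC" + "CCAG" + "AAATAA"
        m = sg.build_transcript_model(seq, [(0, 3), (17, 23)], flank_len=0, constant_len=0)
        out = sg.silence_motif(m, "GAAGAC")
        assert "GAAGAC" not in out.sequence and "GTCTTC" not in out.sequence
        assert out.protein() == m.protein()
        assert out.spliced() == m.spliced()

    def test_reverse_complement_occurrence_also_removed(self):
        seq = "ATG" + "GTAA" + "GTCTTC" + "CCAG" + "AAATAA"
        m = sg.build_transcript_model(seq, [(0, 3), (17, 23)], flank_len=0, constant_len=0)
        out = sg.silence_motif(m, "GAAGAC")
        assert "GTCTTC" not in out.sequence
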