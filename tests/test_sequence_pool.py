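from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aptascreen.sequence_pool import (
    ResponseElement,
    find_inverted_repeat,
    read_fasta_pool,
    select_aptamer_like,
    transcribe_sense,
    write_fasta_pool,
)

from .conftest import random_rna_corpus
from .oracles import brute_force_inverted_repeat

dna_seq = st.text(alphabet="ACGT", min_size=1, max_size=20)


def _el(seq, ident="x"):
    return ResponseElement(id=ident, gene_name="", dna_sense=seq)


class TestTranscription:
    @pytest.mark.parametrize(
        "dna, rna",
        [
            ("GGGGTCAAGGTGACCCC", "GGGGUCAAGGUGACCCC"),  # cytochrome c oxidase ERE
            ("ACGT", "ACGU"),
            ("GAGGTCACTGAGACCAT", "GAGGUCACUGAGACCAU"),  # lipocalin-2 ERE
        ],
    )
    def test_sense_strand_to_rna_analog(self, dna, rna):
        cand = transcribe_sense(_el(dna))
        assert cand.rna == rna
        assert len(cand) == len(dna)
        assert cand.parent_id == "x"

    def test_invalid_base_rejected_with_position(self):
        with pytest.raises(ValueError, match="position 3"):
            _el("ACXT")

    @settings(max_examples=100, derandomize=True)
    @given(dna_seq)
    def test_reverse_mapping_recovers_input(self, seq):
        assert transcribe_sense(_el(seq)).rna.replace("U", "T") == seq


class TestInvertedRepeat:
    def test_perfect_palindrome_detected(self):
        dec = find_inverted_repeat("GGGGUCAAGGUGACCCC")
        assert (dec.arm_length, dec.loop_length) == (7, 3)
        assert (dec.n_wc_pairs, dec.n_mismatches) == (7, 0)
        assert dec.paired_positions[0] == (1, 17)
        assert dec.paired_positions[-1] == (7, 11)

    def test_homopolymer_has_no_repeat(self):
        assert find_inverted_repeat("AAAAAAAAAAAAAAAAA") is None

    def test_imperfect_palindrome_reports_mismatches(self):
        dec = find_inverted_repeat("GAGGUCACUGAGACCAU")
        assert dec.n_mismatches >= 1

    def test_too_short_sequence_returns_none(self):
        # needs 2*5 + 3 = 13 nt for min_arm 5
        assert find_inverted_repeat("GGGGGCCCCC", min_arm=5) is None

    def test_wobble_counted_separately(self):
        # G pairs U only as a wobble
        dec = find_inverted_repeat("GGGAAAUUU", min_arm=1, allow_wobble=True)
        assert dec.n_wobble_pairs > 0

    @pytest.mark.parametrize("arm", [3, 5, 7])
    def test_perfect_arm_scores_full_wc_regardless_of_loop(self, arm, rng):
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        for _ in range(10):
            left = "".join(rng.choice(list("ACGU"), size=arm))
            loop = "".join(rng.choice(list("ACGU"), size=3))
            seq = left + loop + "".join(comp[b] for b in reversed(left))
            dec = find_inverted_repeat(seq, min_arm=1)
            assert dec.arm_length == arm
            assert dec.n_wc_pairs == arm

    @pytest.mark.parametrize("allow_wobble", [False, True])
    def test_agrees_with_brute_force_enumeration(self, rng, allow_wobble):
        for seq in random_rna_corpus(300, rng):
            got = find_inverted_repeat(seq, min_arm=3, allow_wobble=allow_wobble)
            want = brute_force_inverted_repeat(seq, min_arm=3, allow_wobble=allow_wobble)
            if want is None:
                assert got is None, seq
            else:
                arm, n_wc, n_wob, n_mm = want
                assert got is not None, seq
                assert (got.arm_length, got.n_wc_pairs, got.n_wobble_pairs,
                        got.n_mismatches) == (arm, n_wc, n_wob, n_mm), seq


class TestSelection:
    def test_printed_pool_all_retained_under_permissive_settings(self, table1):
        result = select_aptamer_like(table1, min_arm=5, max_mismatch=3)
        assert len(result.selected) == 18
        assert [el.id for el in result.selected] == [el.id for el in table1]
        assert all(rec.passed for rec in result.records)

    def test_poly_a_pool_rejected(self):
        pool = [_el("A" * 17, f"p{i}") for i in range(3)]
        result = select_aptamer_like(pool)
        assert result.selected == ()
        assert all("matched pairs" in rec.reason or "register" in rec.reason
                   for rec in result.records)

    def test_min_arm_larger_than_palindrome_excludes(self):
        # perfect 4-arm palindrome, but 6-arm registers don't fit in 11 nt
        pool = [_el("GGCGAAACGCC", "pal")]
        result = select_aptamer_like(pool, min_arm=6, max_mismatch=0)
        assert result.selected == ()

    def test_mismatch_threshold_excludes(self, table1):
        result = select_aptamer_like(table1, min_arm=5, max_mismatch=0)
        kept = {el.id for el in result.selected}
        assert kept < {el.id for el in table1}  # strictly fewer
        for rec in result.records:
            if rec.id not in kept and rec.decomposition is not None:
                assert rec.decomposition.n_mismatches > 0

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            select_aptamer_like([])


def test_fasta_round_trip(tmp_path, table1):
    path = tmp_path / "pool.fasta"
    write_fasta_pool(table1, path)
    back = read_fasta_pool(path)
    assert [(el.id, el.dna_sense) for el in back] == [
        (el.id, el.dna_sense) for el in table1
    ]
    assert back[0].gene_name == table1[0].gene_name
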