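"""ORF prediction versus brute-force enumeration, genetic-code behaviour."""

import pytest

from isocurate.orf import (GeneticCode, OrfCall, compare_orf_lengths,
                           find_best_orf, translate_orf)

from conftest import random_seq

SENSE = "GCT"  # Ala in both codes


def brute_force_best(seq, code, min_nt):
    """Enumerate every ATG..stop span in the three forward frames."""
    candidates = []
    for frame in range(3):
        codons = [(p, seq[p:p + 3]) for p in range(frame, len(seq) - 2, 3)]
        for i, (p, codon) in enumerate(codons):
            if codon != "ATG":
                continue
            for q, stop in codons[i + 1:]:
                if code.is_stop(stop):
                    length = q + 3 - p
                    if length >= min_nt:
                        candidates.append((length, p, frame))
                    break
    if not candidates:
        return None
    length, start, frame = max(candidates,
                               key=lambda c: (c[0], -c[1], -c[2]))
    # prefer longest, then 5'-most start, then smallest frame
    best = sorted(candidates, key=lambda c: (-c[0], c[1], c[2]))[0]
    return best


class TestFindBestOrf:
    def test_exact_minimum_length_accepted(self):
        seq = "ATG" + SENSE * 48 + "TAA"
        call = find_best_orf(seq, min_nt=150)
        assert call is not None and call.nt_length == 150
        assert call.complete

    def test_below_minimum_rejected(self):
        seq = "ATG" + SENSE * 47 + "TAA"
        assert find_best_orf(seq, min_nt=150) is None

    def test_codes_disagree_on_aga(self):
        seq = "ATG" + "AGA" + SENSE * 60 + "TAA"
        standard = find_best_orf(seq, "standard", 150)
        mito = find_best_orf(seq, "vertebrate_mitochondrial", 150)
        assert standard is not None and standard.nt_length == 3 * 63
        assert mito is None  # AGA terminates a 6-nt ORF, below threshold

    def test_tga_read_through_in_mito(self):
        seq = "ATG" + "TGA" + SENSE * 55 + "TAG"
        assert find_best_orf(seq, "standard", 150) is None
        mito = find_best_orf(seq, "vertebrate_mitochondrial", 150)
        assert mito is not None and mito.nt_length == 3 * 58

    def test_n_codon_terminates_nothing(self):
        seq = "ATG" + "ANA" + SENSE * 55 + "TAA"
        call = find_best_orf(seq, min_nt=150)
        assert call is not None and call.nt_length == 3 * 58

    def test_matches_brute_force(self, rng):
        code = GeneticCode.by_name("standard")
        for _ in range(300):
            seq = random_seq(rng, int(rng.integers(30, 900)))
            got = find_best_orf(seq, code, 60)
            want = brute_force_best(seq, code, 60)
            if want is None:
                assert got is None
            else:
                length, start, frame = want
                assert (got.nt_length, got.start, got.frame) == \
                    (length, start, frame)

    def test_frameshift_destroys_call(self):
        seq = "ATG" + SENSE * 60 + "TAA"
        intact = find_best_orf(seq, min_nt=150)
        shifted = seq[:90] + "G" + seq[90:]
        broken = find_best_orf(shifted, min_nt=150)
        assert intact is not None
        assert broken is None or broken.nt_length < intact.nt_length


class TestGeneticCode:
    def test_code_tables(self):
        std = GeneticCode.by_name("standard")
        mito = GeneticCode.by_name("vertebrate_mitochondrial")
        assert std.stop_codons == {"TAA", "TAG", "TGA"}
        assert mito.stop_codons == {"TAA", "TAG", "AGA", "AGG"}
        assert mito.translate("TGA") == "W"

    def test_translation(self):
        seq = "ATGGCTTAA"
        call = OrfCall("r", 0, 0, 9, True, True)
        assert translate_orf(seq, call) == "MA"


class TestCompareOrfLengths:
    def test_identical_maps_all_same(self):
        calls = {"a": OrfCall("a", 0, 0, 150, True, True), "b": None}
        assert compare_orf_lengths(calls, dict(calls)) == \
            {"longer": 0, "same": 2, "shorter": 0}

    def test_gain_counts_longer(self):
        before = {"a": None}
        after = {"a": OrfCall("a", 0, 0, 300, True, True)}
        assert compare_orf_lengths(before, after)["longer"] == 1

    def test_mixed_enumeration(self):
        mk = lambda n: OrfCall("x", 0, 0, n, True, True)
        before = {"a": mk(150), "b": mk(150), "c": mk(153)}
        after = {"a": mk(150), "b": mk(153), "c": mk(150)}
        assert compare_orf_lengths(before, after) == \
            {"longer": 1, "same": 1, "shorter": 1}

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError):
            compare_orf_lengths({"a": None}, {"b": None})
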