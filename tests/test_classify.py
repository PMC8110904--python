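"""Structural category decisions, junction canonicality and 3' annotations."""

import numpy as np
import pytest

from isocurate.annotation import AnnotationIndex, ExonChain, GeneModel
from isocurate.classify import (classify_chain, downstream_a_fraction,
                                find_polya_signal, junction_is_canonical)
from isocurate.io import revcomp

from conftest import random_seq


@pytest.fixture(scope="module")
def mini():
    """Hand-built two-gene annotation with canonical junctions."""
    rng = np.random.default_rng(5)
    genome = list(random_seq(rng, 10_000))
    g1_exons = ((1000, 1200), (1500, 1700), (2000, 2200), (2500, 2700))
    for istart, iend in ((1200, 1500), (1700, 2000), (2200, 2500)):
        genome[istart:istart + 2] = "GT"
        genome[iend - 2:iend] = "AG"
    g2_exons = ((5000, 5200), (5500, 5700))
    genome[5200:5202] = "GT"
    genome[5498:5500] = "AG"
    genome = {"chr1": "".join(genome)}
    g1 = GeneModel("g1", "chr1", "+")
    g1.transcripts["t1"] = ExonChain("t1", "chr1", "+", g1_exons)
    g2 = GeneModel("g2", "chr1", "+")
    g2.transcripts["t2"] = ExonChain("t2", "chr1", "+", g2_exons)
    g3 = GeneModel("g3", "chr1", "+")
    g3.transcripts["t3"] = ExonChain("t3", "chr1", "+", ((7000, 7400),))
    return genome, AnnotationIndex([g1, g2, g3])


def _call(mini, exons, strand="+"):
    genome, ann = mini
    chain = ExonChain("q", "chr1", strand, tuple(exons))
    return classify_chain(chain, ann, genome)


class TestCategories:
    def test_full_splice_match(self, mini):
        call = _call(mini, [(990, 1200), (1500, 1700), (2000, 2200),
                            (2500, 2710)])
        assert call.category == "FSM"
        assert call.associated_transcript == "t1"

    def test_incomplete_splice_match_is_consecutive_suffix(self, mini):
        call = _call(mini, [(1600, 1700), (2000, 2200), (2500, 2700)])
        assert call.category == "ISM"

    def test_exon_skip_of_known_junctions_is_nic(self, mini):
        # junctions i1 and i3 both annotated; the combination is novel
        call = _call(mini, [(1000, 1200), (1500, 2200), (2500, 2700)])
        assert call.category == "NIC"

    def test_shifted_donor_is_nnc(self, mini):
        call = _call(mini, [(1000, 1204), (1500, 1700), (2000, 2200),
                            (2500, 2700)])
        assert call.category == "NNC"

    def test_mono_exon_inside_intron(self, mini):
        call = _call(mini, [(1750, 1900)])
        assert call.category == "genic_intron"
        assert call.associated_gene == "g1"

    def test_mono_exon_straddling_exon_and_intron(self, mini):
        call = _call(mini, [(1600, 1800)])
        assert call.category == "genic_genomic"

    def test_antisense_when_only_reverse_gene(self, mini):
        call = _call(mini, [(1000, 1200)], strand="-")
        assert call.category == "antisense"

    def test_intergenic_without_any_gene(self, mini):
        call = _call(mini, [(8_000, 8_100)])
        assert call.category == "intergenic"
        assert call.associated_gene is None

    def test_fusion_spans_two_loci(self, mini):
        call = _call(mini, [(2500, 2700), (5000, 5200)])
        assert call.category == "fusion"
        assert {call.associated_gene, call.associated_gene_2} == {"g1", "g2"}

    def test_mono_exon_in_mono_exon_transcript_is_fsm(self, mini):
        call = _call(mini, [(7050, 7350)])
        assert call.category == "FSM"
        assert call.associated_transcript == "t3"

    def test_exactly_one_category(self, mini, rng):
        """Random mapped chains always get exactly one known category."""
        genome, ann = mini
        for _ in range(100):
            start = int(rng.integers(0, 9_000))
            width = int(rng.integers(50, 800))
            exons = [(start, start + width)]
            if rng.random() < 0.5 and start + width + 400 < 10_000:
                exons.append((start + width + 100, start + width + 400))
            strand = "+" if rng.random() < 0.5 else "-"
            call = _call(mini, exons, strand)
            from isocurate.classify import CATEGORIES
            assert call.category in CATEGORIES


class TestJunctionCanonicality:
    def test_gt_ag_forward(self, mini):
        genome, _ = mini
        assert junction_is_canonical(genome, "chr1", (1200, 1500), "+")

    def test_reverse_strand_reads_transcript_sense(self):
        # genomic CT..AC is GT..AG on the minus strand transcript
        genome = {"c": "AAAA" + "CT" + "GGGG" + "AC" + "AAAA"}
        assert junction_is_canonical(genome, "c", (4, 12), "-")
        assert not junction_is_canonical(genome, "c", (4, 12), "+")

    def test_at_ag_not_canonical(self):
        genome = {"c": "AAAA" + "AT" + "GGGG" + "AG" + "AAAA"}
        assert not junction_is_canonical(genome, "c", (4, 12), "+")

    def test_strand_symmetry_under_revcomp(self, rng):
        """Reverse-complementing the genome and flipping the strand leaves
        canonicality unchanged."""
        for _ in range(20):
            seq = random_seq(rng, 60)
            L = len(seq)
            start, end = 10, 40
            fwd = junction_is_canonical({"c": seq}, "c", (start, end), "+")
            mirrored = junction_is_canonical(
                {"c": revcomp(seq)}, "c", (L - end, L - start), "-")
            assert fwd == mirrored


class TestDownstreamA:
    def test_pure_a_tract(self):
        genome = {"c": "G" * 50 + "A" * 20 + "G" * 30}
        assert downstream_a_fraction(genome, "c", 50, "+") == 1.0

    def test_sixteen_of_twenty_flags(self):
        genome = {"c": "G" * 50 + "A" * 16 + "C" * 4 + "G" * 30}
        assert downstream_a_fraction(genome, "c", 50, "+") == 0.80

    def test_truncation_at_contig_edge(self):
        genome = {"c": "G" * 50 + "AAAAA"}
        assert downstream_a_fraction(genome, "c", 50, "+") == 1.0

    def test_minus_strand_counts_t(self):
        genome = {"c": "T" * 20 + "G" * 50}
        assert downstream_a_fraction(genome, "c", 20, "-") == 1.0


class TestPolyASignal:
    def test_motif_found(self):
        seq = "G" * 100 + "AATAAA" + "C" * 20
        assert find_polya_signal(seq) == 100

    def test_absent_motif(self):
        assert find_polya_signal("ACGT" * 30) is None

    def test_three_prime_most_wins(self):
        seq = "G" * 60 + "AATAAA" + "G" * 10 + "ATTAAA" + "G" * 10
        assert find_polya_signal(seq) == 76

    def test_motif_outside_window_ignored(self):
        seq = "AATAAA" + "G" * 200
        assert find_polya_signal(seq, search_window=50) is None
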