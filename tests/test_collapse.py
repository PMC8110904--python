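"""Alignment-to-chain conversion, locus grouping and redundancy collapse."""

import io
import random

import pysam
import pytest

from isocurate.annotation import ExonChain
from isocurate.collapse import (chain_from_paf, chains_from_sam,
                                collapse_identity, group_and_collapse)
from isocurate.io import ReadRegistry

from conftest import random_seq

SAM_HEADER = "@SQ\tSN:chr1\tLN:100000\n"


def _sam_chain(tmp_path, cigar, pos=1, flag=0, name="r1"):
    path = tmp_path / "t.sam"
    seq_len = sum(int(n) for n, op in
                  __import__("re").findall(r"(\d+)([MIS=X])", cigar))
    seq = "A" * seq_len if seq_len else "*"
    path.write_text(SAM_HEADER +
                    f"{name}\t{flag}\tchr1\t{pos}\t60\t{cigar}\t*\t0\t0\t{seq}\t*\n")
    (chain,) = chains_from_sam(str(path))
    return chain


class TestChainFromAlignment:
    def test_spliced_cigar(self, tmp_path):
        chain = _sam_chain(tmp_path, "50M1000N50M")
        assert chain.exons == ((0, 50), (1050, 1100))
        assert chain.strand == "+"

    def test_unspliced_single_exon(self, tmp_path):
        chain = _sam_chain(tmp_path, "100M")
        assert chain.exons == ((0, 100),)
        assert chain.introns == ()

    def test_insertion_consumes_no_reference(self, tmp_path):
        chain = _sam_chain(tmp_path, "10M5I10M")
        assert chain.exons == ((0, 20),)

    def test_reverse_flag_sets_strand(self, tmp_path):
        chain = _sam_chain(tmp_path, "30M", flag=16)
        assert chain.strand == "-"

    def test_terminal_intron_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="terminal intron"):
            _sam_chain(tmp_path, "10N50M")

    def test_paf_with_cigar_tag(self):
        line = ("r1\t100\t0\t100\t+\tchr1\t100000\t0\t1100\t100\t100\t60\t"
                "cg:Z:50M1000N50M")
        chain = chain_from_paf(line)
        assert chain.exons == ((0, 50), (1050, 1100))


def _chain(name, exons, strand="+", chrom="chr1"):
    return ExonChain(name, chrom, strand, tuple(exons))


class TestGroupAndCollapse:
    def test_fuzz_5p_boundary_merges(self):
        # identical introns, 5' starts differ by 9,999: within the limit
        a = _chain("a", [(0, 20_100), (21_000, 21_300)])
        b = _chain("b", [(9_999, 20_100), (21_000, 21_300)])
        clusters = group_and_collapse([a, b], fuzz_5p=10_000, fuzz_3p=1_000)
        assert len(clusters) == 1
        assert clusters[0].representative_id == "a"  # longer member

    def test_fuzz_3p_exceeded_splits(self):
        a = _chain("a", [(0, 100), (200, 300)])
        b = _chain("b", [(0, 100), (200, 1_301)])
        clusters = group_and_collapse([a, b], fuzz_5p=10_000, fuzz_3p=1_000)
        assert len(clusters) == 2

    def test_opposite_strands_separate_loci(self):
        a = _chain("a", [(0, 100)], "+")
        b = _chain("b", [(0, 100)], "-")
        clusters = group_and_collapse([a, b])
        assert len({c.locus_id for c in clusters}) == 2

    def test_mono_exon_containment_merges(self):
        a = _chain("a", [(0, 500)])
        b = _chain("b", [(100, 400)])
        clusters = group_and_collapse([a, b])
        assert len(clusters) == 1 and clusters[0].representative_id == "a"

    def test_permutation_invariance(self, rng):
        chains = []
        for g in range(10):
            base = g * 50_000
            for v in range(3):
                chains.append(_chain(
                    f"g{g}v{v}",
                    [(base + v * 5, base + 100), (base + 200, base + 300 + v)]))
        ref = group_and_collapse(chains)
        for seed in (1, 2):
            shuffled = chains[:]
            random.Random(seed).shuffle(shuffled)
            out = group_and_collapse(shuffled)
            assert [(c.locus_id, c.representative_id, c.member_ids)
                    for c in out] == \
                   [(c.locus_id, c.representative_id, c.member_ids)
                    for c in ref]

    def test_registry_conservation(self):
        reg = ReadRegistry()
        chains = [_chain("a", [(0, 300), (400, 500)]),
                  _chain("b", [(10, 300), (400, 500)])]
        reg.add("a", "s1", 4)
        reg.add("b", "s2", 3)
        group_and_collapse(chains, registry=reg)
        assert reg.total_flnc() == 7
        assert reg["a"].contributing_samples == {"s1", "s2"}


def mismatch_tail(rep, start, length):
    """Tail bases that mismatch the representative position-wise, so the
    local alignment cannot profitably extend into them."""
    swap = {"A": "C", "C": "G", "G": "T", "T": "A"}
    return "".join(swap[b] for b in rep[start:start + length])


class TestCollapseIdentity:
    def test_exact_duplicate_joins_longer(self, rng):
        long = random_seq(rng, 500)
        clusters = collapse_identity({"long": long, "short": long[:400]})
        assert len(clusters) == 1
        assert clusters[0].representative_id == "long"

    def test_long_member_31_uncovered_founds_cluster(self, rng):
        rep = random_seq(rng, 4_100)
        # member: 4,000 nt, 31 of which cannot align
        member = rep[:3_969] + mismatch_tail(rep, 3_969, 31)
        clusters = collapse_identity({"rep": rep, "member": member})
        assert len(clusters) == 2

    def test_long_member_30_uncovered_joins(self, rng):
        rep = random_seq(rng, 4_100)
        member = rep[:3_970] + mismatch_tail(rep, 3_970, 30)
        clusters = collapse_identity({"rep": rep, "member": member})
        assert len(clusters) == 1

    def test_one_percent_rule_short_member(self, rng):
        rep = random_seq(rng, 1_500)
        # 1,000-nt member with exactly 10 unalignable bases (1.0%)
        member = rep[:990] + mismatch_tail(rep, 990, 10)
        clusters = collapse_identity({"rep": rep, "member": member})
        assert len(clusters) == 1

    def test_idempotence(self, rng):
        seqs = {f"s{i}": random_seq(rng, 300) for i in range(6)}
        first = collapse_identity(seqs)
        reps = {c.representative_id: seqs[c.representative_id] for c in first}
        second = collapse_identity(reps)
        assert {c.representative_id for c in second} == set(reps)
        assert all(len(c.member_ids) == 1 for c in second)
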