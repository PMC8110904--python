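"""Solid k-mer graph, coverage profiling, the support filter and correction."""

import numpy as np
import pytest

from isocurate.io import LongRead, revcomp
from isocurate.kmer import (INTERNAL, TERMINAL5, build_graph, canonical,
                            correct_read, coverage_profile,
                            passes_support_filter)

from conftest import random_seq


def naive_profile(seq, graph):
    """Independent oracle: test every read k-mer against the solid set."""
    covered = [False] * len(seq)
    for s in range(len(seq) - graph.k + 1):
        kmer = seq[s:s + graph.k]
        if canonical(kmer) in graph.solid:
            for i in range(s, s + graph.k):
                covered[i] = True
    return covered


class TestBuildGraph:
    def test_canonical_counting(self):
        graph = build_graph(["ACGTACGT"] * 3, 3, 3)
        assert graph.solid == {"ACG": 12, "GTA": 6}

    def test_homopolymer_counts(self):
        assert build_graph(["AAAA"] * 2, 3, 3).solid == {"AAA": 4}

    def test_no_reads_empty_graph(self):
        assert len(build_graph([], 5, 2)) == 0

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            build_graph(["ACGT"], 4, 1)

    def test_n_kmers_skipped(self):
        graph = build_graph(["AANAA" * 10], 3, 1)
        assert all("N" not in k for k in graph.solid)


class TestCoverageProfile:
    def test_fully_covered_read(self, rng):
        src = random_seq(rng, 200)
        graph = build_graph([src] * 3, 21, 3)
        profile = coverage_profile(src, graph)
        assert profile.coverage_fraction == 1.0
        assert profile.runs == ()

    def test_single_substitution_makes_internal_run(self, rng):
        src = random_seq(rng, 100)
        graph = build_graph([src] * 30, 21, 3)
        base = src[50]
        mutated = src[:50] + ("A" if base != "A" else "C") + src[51:]
        profile = coverage_profile(mutated, graph)
        assert profile.runs == ((50, 51, INTERNAL),)
        assert profile.coverage_fraction == pytest.approx(0.99)

    def test_read_shorter_than_k(self):
        graph = build_graph(["ACGTACGTACGTACGTACGTACGTT"], 21, 1)
        profile = coverage_profile("ACGTACGTAC", graph)
        assert profile.coverage_fraction == 0.0
        assert profile.runs == ((0, 10, TERMINAL5),)
        assert not passes_support_filter(profile)

    def test_agrees_with_naive_scan(self, rng):
        """Position-by-position equality with the brute-force oracle."""
        for _ in range(50):
            k = 7
            src = random_seq(rng, int(rng.integers(30, 120)))
            shorts = [src[i:i + 25] for i in range(0, max(1, len(src) - 25), 5)]
            graph = build_graph(shorts, k, 2)
            read = "".join(
                b if rng.random() > 0.05
                else rng.choice(list("ACGT")) for b in src)
            profile = coverage_profile(read, graph)
            assert profile.covered.tolist() == naive_profile(read, graph)


class TestSupportFilter:
    def _profile(self, covered):
        from isocurate.kmer import CoverageProfile, _runs_from_mask
        mask = np.array(covered, dtype=bool)
        return CoverageProfile("r", len(mask), mask, _runs_from_mask(mask),
                               float(mask.sum()) / len(mask))

    def test_full_coverage_passes(self):
        assert passes_support_filter(self._profile([True] * 100))

    def test_internal_gap_fails_even_at_99pct(self):
        covered = [True] * 100
        covered[50] = False
        assert not passes_support_filter(self._profile(covered))

    def test_terminal_within_one_percent_passes(self):
        covered = [False, False] + [True] * 298  # 2/300 = 0.67%
        assert passes_support_filter(self._profile(covered))

    def test_coverage_below_99pct_fails(self):
        covered = [False] * 4 + [True] * 296  # 98.67% covered
        assert not passes_support_filter(self._profile(covered))

    def test_combined_terminal_allowance(self):
        # 1 + 2 uncovered terminal bases on a 300-nt read: 1% combined
        covered = [False] + [True] * 296 + [False] * 3
        assert not passes_support_filter(self._profile(covered))
        covered = [False] + [True] * 297 + [False] * 2
        assert passes_support_filter(self._profile(covered))


class TestCorrectRead:
    def test_fully_covered_read_unchanged(self, rng):
        src = random_seq(rng, 150)
        graph = build_graph([src] * 3, 21, 3)
        seq, profile = correct_read(src, graph)
        assert seq == src and profile.coverage_fraction == 1.0

    def test_planted_substitution_restored(self, rng):
        src = random_seq(rng, 300)
        graph = build_graph([src] * 30, 21, 3)
        pos = 150
        wrong = "A" if src[pos] != "A" else "C"
        mutated = src[:pos] + wrong + src[pos + 1:]
        seq, profile = correct_read(mutated, graph)
        assert seq == src
        assert profile.coverage_fraction == 1.0

    def test_unbridgeable_region_is_noop(self, rng):
        src = random_seq(rng, 200)
        graph = build_graph([src[:80], src[120:]], 21, 1)
        # middle 40 bases absent from the graph: no path can bridge
        mutated = src[:100] + revcomp(src[100:110]) + src[110:]
        seq, profile = correct_read(mutated, graph)
        before = coverage_profile(mutated, graph)
        assert profile.coverage_fraction >= before.coverage_fraction

    def test_monotone_and_fixed_point(self, rng):
        for _ in range(10):
            src = random_seq(rng, 250)
            graph = build_graph([src] * 10, 21, 3)
            pos = int(rng.integers(40, 210))
            mutated = src[:pos] + ("T" if src[pos] != "T" else "G") \
                + src[pos + 1:]
            before = coverage_profile(mutated, graph).coverage_fraction
            seq1, p1 = correct_read(mutated, graph)
            assert p1.coverage_fraction >= before
            seq2, p2 = correct_read(seq1, graph)
            assert seq2 == seq1  # fixed point after one pass here
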