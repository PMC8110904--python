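"""Solid k-mer graph, long-read support profiling and hybrid correction.

Short reads are decomposed into canonical k-mers (lexicographic minimum of a
k-mer and its reverse complement); k-mers reaching the solidity threshold
form the trusted de Bruijn graph. A long-read position counts as supported
when at least one solid k-mer of the read overlaps it; the support filter
rejects any read with an internal unsupported gap, or with more than the
allowed fraction of terminal positions unsupported (99% coverage at the
default 1%). A bounded de Bruijn path search can re-spell internal weak
regions between solid anchors (a deliberately simplified hybrid corrector).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import numpy as np

from .io import LongRead, revcomp

TERMINAL5 = "terminal5"
TERMINAL3 = "terminal3"
INTERNAL = "internal"


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class KmerGraph:
    k: int
    solidity: int
    solid: dict[str, int]

    def is_solid(self, kmer: str) -> bool:
        return canonical(kmer) in self.solid

    def __len__(self) -> int:
        return len(self.solid)

    def successors(self, kmer: str) -> list[str]:
        """Solid k-mers reachable by a one-base extension (A<C<G<T order)."""
        suffix = kmer[1:]
        return [suffix + b for b in "ACGT" if self.is_solid(suffix + b)]


def build_graph(short_reads: Iterable[str], k: int, solidity: int) -> KmerGraph:
    """Count canonical k-mers over all reads and keep the solid ones.

    k must be odd (a palindromic even k-mer equals its own reverse
    complement, making canonical counting ambiguous); k-mers containing N
    are skipped.
    """
    if k < 3 or k % 2 == 0:
        raise ValueError(f"k must be odd and >= 3, got {k}")
    counts: dict[str, int] = {}
    for seq in short_reads:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            if "N" in kmer:
                continue
            key = canonical(kmer)
            counts[key] = counts.get(key, 0) + 1
    solid = {kmer: n for kmer, n in counts.items() if n >= solidity}
    return KmerGraph(k=k, solidity=solidity, solid=solid)


@dataclass
class CoverageProfile:
    read_id: str
    length: int
    covered: np.ndarray  # boolean per position
    runs: tuple[tuple[int, int, str], ...]  # maximal uncovered runs
    coverage_fraction: float

    @property
    def internal_runs(self) -> tuple[tuple[int, int, str], ...]:
        return tuple(r for r in self.runs if r[2] == INTERNAL)

    @property
    def uncovered(self) -> int:
        return self.length - int(self.covered.sum())


def _runs_from_mask(covered: np.ndarray) -> tuple[tuple[int, int, str], ...]:
    length = len(covered)
    runs = []
    i = 0
    while i < length:
        if not covered[i]:
            j = i
            while j < length and not covered[j]:
                j += 1
            if i == 0:
                kind = TERMINAL5
            elif j == length:
                kind = TERMINAL3
            else:
                kind = INTERNAL
            runs.append((i, j, kind))
            i = j
        else:
            i += 1
    return tuple(runs)


def coverage_profile(read: LongRead | str, graph: KmerGraph,
                     read_id: str = "") -> CoverageProfile:
    """Per-position support of a long read by the solid k-mer graph.

    Position i is covered iff some solid k-mer of the read overlaps i. A
    read shorter than k is fully uncovered (a single 5'-terminal run).
    """
    seq = read.sequence if isinstance(read, LongRead) else read
    rid = read.read_id if isinstance(read, LongRead) else read_id
    length = len(seq)
    covered = np.zeros(length, dtype=bool)
    k = graph.k
    for s in range(length - k + 1):
        if graph.is_solid(seq[s:s + k]):
            covered[s:s + k] = True
    runs = _runs_from_mask(covered)
    frac = float(covered.sum()) / length if length else 0.0
    return CoverageProfile(rid, length, covered, runs, frac)


def passes_support_filter(profile: CoverageProfile,
                          max_uncovered_frac: float = 0.01,
                          per_end: bool = False) -> bool:
    """True iff the read has no internal unsupported gap and the terminal
    unsupported positions stay within the allowance (combined by default)."""
    if profile.internal_runs:
        return False
    if per_end:
        limit = max_uncovered_frac * profile.length
        return all(end - start <= limit for start, end, _ in profile.runs)
    return profile.uncovered <= max_uncovered_frac * profile.length


def _bridge_paths(graph: KmerGraph, source: str, target: str,
                  min_len: int, max_len: int,
                  max_path_nodes: int) -> list[str]:
    """Enumerate de Bruijn spellings from source k-mer to target k-mer with
    total spelled length in [min_len, max_len]. Deterministic DFS, children
    in A<C<G<T order, bounded by max_path_nodes expansions."""
    results: list[str] = []
    expansions = 0
    stack: list[str] = [source]
    k = graph.k
    while stack:
        spelled = stack.pop()
        if expansions >= max_path_nodes:
            break
        expansions += 1
        if spelled.endswith(target) and min_len <= len(spelled) <= max_len:
            results.append(spelled)
        if len(spelled) >= max_len:
            continue
        tail = spelled[-k:]
        # push in reverse so A is explored first
        for nxt in reversed(graph.successors(tail)):
            stack.append(spelled + nxt[-1])
    return results


def correct_read(read: LongRead | str, graph: KmerGraph,
                 max_path_nodes: int = 20_000,
                 max_len_slack: float = 0.3,
                 read_id: str = "") -> tuple[str, CoverageProfile]:
    """Re-spell internal weak regions via bounded de Bruijn path search.

    For each internal unsupported run, the nearest flanking solid k-mers act
    as anchors; candidate paths between them (length within the slack band
    of the original span) are ranked by edit distance to the original weak
    span, ties broken by lexicographic order. A replacement is kept only if
    it strictly increases the overall coverage fraction. Anchored flanks and
    everything outside weak regions are never modified; failure to bridge is
    a silent no-op.
    """
    seq = read.sequence if isinstance(read, LongRead) else read
    rid = read.read_id if isinstance(read, LongRead) else read_id
    k = graph.k
    profile = coverage_profile(seq, graph, rid)
    if not profile.internal_runs or not graph.solid:
        return seq, profile

    offset = 0
    current = seq
    best_frac = profile.coverage_fraction
    for run_start, run_end, _kind in profile.internal_runs:
        rs, re = run_start + offset, run_end + offset
        # nearest solid anchors; maximality of the run guarantees they abut it
        left = None
        for s in range(rs - 1, -1, -1):
            if s + k <= len(current) and graph.is_solid(current[s:s + k]):
                left = s
                break
        right = None
        for s in range(re, len(current) - k + 1):
            if graph.is_solid(current[s:s + k]):
                right = s
                break
        if left is None or right is None:
            continue
        source = current[left:left + k]
        target = current[right:right + k]
        span = current[left:right + k]
        min_len = max(2 * k, int(round(len(span) * (1 - max_len_slack))))
        max_len = int(round(len(span) * (1 + max_len_slack)))
        paths = _bridge_paths(graph, source, target, min_len, max_len,
                              max_path_nodes)
        if not paths:
            continue
        paths.sort(key=lambda p: (edlib.align(p, span)["editDistance"], p))
        candidate = current[:left] + paths[0] + current[right + k:]
        cand_profile = coverage_profile(candidate, graph, rid)
        if cand_profile.coverage_fraction > best_frac:
            offset += len(paths[0]) - len(span)
            current = candidate
            best_frac = cand_profile.coverage_fraction
    final = coverage_profile(current, graph, rid)
    return current, final


def filter_reads(reads: Sequence[LongRead], graph: KmerGraph,
                 max_uncovered_frac: float = 0.01,
                 correct: bool = False,
                 per_end: bool = False,
                 ) -> tuple[list[LongRead], list[tuple[str, CoverageProfile, bool]]]:
    """Profile (optionally correct) every read and apply the support filter.

    Returns the passing reads and a QC row per input read
    ``(read_id, profile, passed)``.
    """
    kept: list[LongRead] = []
    qc: list[tuple[str, CoverageProfile, bool]] = []
    for read in reads:
        if correct:
            seq, profile = correct_read(read, graph)
            read = LongRead(read.read_id, seq, read.sample_id, read.flnc_count)
        else:
            profile = coverage_profile(read, graph)
        ok = passes_support_filter(profile, max_uncovered_frac, per_end)
        qc.append((read.read_id, profile, ok))
        if ok:
            kept.append(read)
    return kept, qc
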