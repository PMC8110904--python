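"""Locus grouping and redundancy collapse of aligned long reads.

Aligned reads are grouped into loci (connected components of same-strand
exonic overlap), reads with identical splice patterns merge into isoform
clusters (allowing generous 5' and 3' end fuzz, 10 kb / 1 kb by default,
keeping the longest member as representative), and unaligned reads are
greedily clustered by local-alignment identity with CD-Hit-style criteria:
0.99 identity, the member aligned over 99% of its length (an absolute 30 bp
uncovered cap for members above 3 kb), unrestricted representative
overhang.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pysam

from .align import ScoringScheme, local_align
from .annotation import ExonChain
from .io import ReadRegistry

_REF_CONSUMES = {0: True, 1: False, 2: True, 3: True, 4: False,
                 5: False, 6: False, 7: True, 8: True}
# op codes: 0=M 1=I 2=D 3=N 4=S 5=H 6=P 7== 8=X


def chain_from_alignment(record: pysam.AlignedSegment) -> ExonChain | None:
    """Exon chain of a spliced SAM alignment (N operations delimit introns).

    M/=/X/D advance the current exon, N closes it, I/S/H consume no
    reference. Unmapped records return None; a CIGAR starting or ending with
    N is malformed.
    """
    if record.is_unmapped or record.cigartuples is None:
        return None
    cig = record.cigartuples
    ops = [op for op, _ in cig if op not in (4, 5)]
    if ops and (ops[0] == 3 or ops[-1] == 3):
        raise ValueError(f"{record.query_name}: CIGAR has terminal intron (N)")
    exons: list[tuple[int, int]] = []
    pos = record.reference_start  # already 0-based in pysam
    exon_start = pos
    for op, length in cig:
        if op == 3:  # N: close exon, skip intron
            exons.append((exon_start, pos))
            pos += length
            exon_start = pos
        elif _REF_CONSUMES[op]:
            pos += length
    exons.append((exon_start, pos))
    strand = "-" if record.is_reverse else "+"
    return ExonChain(record.query_name, record.reference_name, strand,
                     tuple(exons))


def chains_from_sam(path: str) -> list[ExonChain]:
    chains = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for record in sam:
            chain = chain_from_alignment(record)
            if chain is not None:
                chains.append(chain)
    return chains


_CIGAR_CODE = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "H": 5, "P": 6,
               "=": 7, "X": 8}


def chain_from_paf(line: str) -> ExonChain | None:
    """Exon chain from a PAF line carrying a cg:Z: CIGAR tag."""
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 12:
        raise ValueError("PAF line has fewer than 12 columns")
    name, strand, chrom = parts[0], parts[4], parts[5]
    tstart = int(parts[7])
    cigar = None
    for tag in parts[12:]:
        if tag.startswith("cg:Z:"):
            cigar = tag[5:]
    if cigar is None:
        raise ValueError(f"{name}: PAF record lacks a cg:Z: CIGAR tag")
    import re
    cig = [(_CIGAR_CODE[m[1]], int(m[0]))
           for m in re.findall(r"(\d+)([MIDNSHP=X])", cigar)]
    ops = [op for op, _ in cig if op not in (4, 5)]
    if ops and (ops[0] == 3 or ops[-1] == 3):
        raise ValueError(f"{name}: CIGAR has terminal intron (N)")
    exons: list[tuple[int, int]] = []
    pos = tstart
    exon_start = pos
    for op, length in cig:
        if op == 3:
            exons.append((exon_start, pos))
            pos += length
            exon_start = pos
        elif _REF_CONSUMES[op]:
            pos += length
    exons.append((exon_start, pos))
    return ExonChain(name, chrom, strand, tuple(exons))


@dataclass
class IsoformCluster:
    locus_id: str
    cluster_id: str
    representative_id: str
    member_ids: tuple[str, ...]
    intron_chain: tuple[tuple[int, int], ...] = ()
    chain: ExonChain | None = None


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _member_length(chain: ExonChain,
                   seq_lengths: Mapping[str, int] | None) -> int:
    if seq_lengths is not None and chain.read_id in seq_lengths:
        return seq_lengths[chain.read_id]
    return chain.exonic_length()


def group_and_collapse(chains: Sequence[ExonChain],
                       fuzz_5p: int = 10_000,
                       fuzz_3p: int = 1_000,
                       seq_lengths: Mapping[str, int] | None = None,
                       registry: ReadRegistry | None = None,
                       strand_aware: bool = True,
                       ) -> list[IsoformCluster]:
    """Group chains into loci and merge same-splice-pattern chains.

    Loci are connected components of same-chromosome (same-strand, unless
    relaxed) exonic overlap. Within a locus, multi-exon chains with an
    identical intron chain merge when their transcription start positions
    differ by at most ``fuzz_5p`` and their transcription ends by at most
    ``fuzz_3p`` (single linkage); a mono-exon chain merges into another it
    is contained in, within the same fuzz limits. The representative is the
    member with the longest sequence (ties to the smallest id). Output
    ordering is re-derived internally, so results are invariant under input
    permutation.
    """
    chains = sorted(chains, key=lambda c: (c.chrom, c.strand, c.span, c.read_id))
    n = len(chains)
    uf = _UnionFind(n)
    # locus components via sweep over exon intervals per (chrom[, strand])
    events: dict[tuple, list[tuple[int, int, int]]] = {}
    for idx, chain in enumerate(chains):
        key = (chain.chrom, chain.strand) if strand_aware else (chain.chrom,)
        for s, e in chain.exons:
            events.setdefault(key, []).append((s, e, idx))
    for key, intervals in events.items():
        intervals.sort()
        active: list[tuple[int, int]] = []  # (end, idx)
        for s, e, idx in intervals:
            active = [(aend, aidx) for aend, aidx in active if aend > s]
            for _aend, aidx in active:
                uf.union(idx, aidx)
            active.append((e, idx))
    locus_members: dict[int, list[int]] = {}
    for idx in range(n):
        locus_members.setdefault(uf.find(idx), []).append(idx)

    clusters: list[IsoformCluster] = []
    locus_order = sorted(locus_members,
                         key=lambda r: (chains[r].chrom, chains[r].span[0],
                                        chains[r].strand))
    for locus_no, root in enumerate(locus_order):
        locus_id = f"locus_{locus_no + 1}"
        members = locus_members[root]
        sub = _UnionFind(len(members))
        local = [chains[i] for i in members]
        for a in range(len(local)):
            for b in range(a + 1, len(local)):
                ca, cb = local[a], local[b]
                if ca.strand != cb.strand:
                    continue
                if ca.n_exons > 1 and cb.n_exons > 1:
                    if ca.introns != cb.introns:
                        continue
                    if (abs(ca.tss - cb.tss) <= fuzz_5p
                            and abs(ca.tes - cb.tes) <= fuzz_3p):
                        sub.union(a, b)
                elif ca.n_exons == 1 and cb.n_exons == 1:
                    (s1, e1), (s2, e2) = ca.exons[0], cb.exons[0]
                    contained = (s1 <= s2 and e2 <= e1) or (s2 <= s1 and e1 <= e2)
                    if (contained and abs(ca.tss - cb.tss) <= fuzz_5p
                            and abs(ca.tes - cb.tes) <= fuzz_3p):
                        sub.union(a, b)
        groups: dict[int, list[int]] = {}
        for i in range(len(local)):
            groups.setdefault(sub.find(i), []).append(i)
        ordered_groups = sorted(
            groups.values(),
            key=lambda idxs: (local[idxs[0]].span, local[idxs[0]].read_id))
        for cluster_no, idxs in enumerate(ordered_groups):
            group = [local[i] for i in idxs]
            rep = sorted(group, key=lambda c: (-_member_length(c, seq_lengths),
                                               c.read_id))[0]
            member_ids = tuple(sorted(c.read_id for c in group))
            clusters.append(IsoformCluster(
                locus_id=locus_id,
                cluster_id=f"{locus_id}.{cluster_no + 1}",
                representative_id=rep.read_id,
                member_ids=member_ids,
                intron_chain=rep.introns,
                chain=rep))
            if registry is not None:
                registry.merge(rep.read_id,
                               [m for m in member_ids if m != rep.read_id])
    return clusters


def collapse_identity(seqs: Mapping[str, str] | Iterable[tuple[str, str]],
                      identity: float = 0.99,
                      min_cover: float = 0.99,
                      long_cap_len: int = 3_000,
                      long_cap_nt: int = 30,
                      scheme: ScoringScheme = ScoringScheme(),
                      registry: ReadRegistry | None = None,
                      ) -> list[IsoformCluster]:
    """Greedy identity clustering of (typically unaligned) sequences.

    Sequences are visited longest-first (ties by id). A sequence joins the
    qualifying representative of highest alignment identity — qualification
    means local-alignment identity >= ``identity`` and member uncovered
    bases <= 1% of its length (or <= ``long_cap_nt`` for members longer
    than ``long_cap_len``) — otherwise it founds a new cluster.
    Representative overhang is unrestricted.
    """
    items = sorted(dict(seqs).items(), key=lambda kv: (-len(kv[1]), kv[0]))
    reps: list[tuple[str, str]] = []  # (id, seq)
    members: dict[str, list[str]] = {}
    for seq_id, seq in items:
        best: tuple[float, int, str] | None = None  # (identity, len, rep_id)
        for rep_id, rep_seq in reps:
            aln = local_align(seq, rep_seq, scheme)
            if aln.n_columns == 0:
                continue
            uncovered = len(seq) - (aln.query_span[1] - aln.query_span[0])
            allowed = (long_cap_nt if len(seq) > long_cap_len
                       else (1.0 - min_cover) * len(seq))
            if aln.identity >= identity and uncovered <= allowed:
                key = (aln.identity, len(rep_seq), rep_id)
                if best is None or (key[0], key[1]) > (best[0], best[1]) or (
                        key[:2] == best[:2] and rep_id < best[2]):
                    best = key
        if best is None:
            reps.append((seq_id, seq))
            members[seq_id] = [seq_id]
        else:
            members[best[2]].append(seq_id)
    clusters = []
    for no, (rep_id, _seq) in enumerate(sorted(reps, key=lambda r: r[0])):
        ids = tuple(sorted(members[rep_id]))
        clusters.append(IsoformCluster(
            locus_id=f"identity_{no + 1}",
            cluster_id=f"identity_{no + 1}.1",
            representative_id=rep_id,
            member_ids=ids))
        if registry is not None:
            registry.merge(rep_id, [m for m in ids if m != rep_id])
    return clusters


def write_clusters_tsv(path: str, clusters: Sequence[IsoformCluster]) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tcluster_id\trepresentative\tmembers\n")
        for cl in sorted(clusters, key=lambda c: (c.locus_id, c.cluster_id)):
            fh.write(f"{cl.locus_id}\t{cl.cluster_id}\t{cl.representative_id}"
                     f"\t{','.join(cl.member_ids)}\n")
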