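"""Exon chains and the reference annotation index.

All internal coordinates are 0-based half-open on the genome; conversion to
and from GTF's 1-based inclusive convention happens only at the file
boundary. An :class:`ExonChain` is the strand-aware exon structure of one
read or reference transcript; an :class:`AnnotationIndex` holds the
reference gene models plus the splice-junction sets used by the structural
classifier.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable

import gffutils
from intervaltree import IntervalTree


@dataclass(frozen=True)
class ExonChain:
    """Ordered exon structure (0-based half-open genomic intervals)."""

    read_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.read_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"{self.read_id}: chain has no exons")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValueError(f"{self.read_id}: empty exon ({start}, {end})")
            if prev_end is not None and start <= prev_end:
                raise ValueError(
                    f"{self.read_id}: exons overlap or abut at {start}")
            prev_end = end

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple((self.exons[i][1], self.exons[i + 1][0])
                     for i in range(len(self.exons) - 1))

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def tss(self) -> int:
        """Genomic position of the transcription start (strand-aware)."""
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1]

    @property
    def tes(self) -> int:
        """Genomic position of the transcription end (strand-aware)."""
        return self.exons[-1][1] if self.strand == "+" else self.exons[0][0]

    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def overlaps_exonic(self, other: "ExonChain") -> bool:
        for s1, e1 in self.exons:
            for s2, e2 in other.exons:
                if s1 < e2 and s2 < e1:
                    return True
        return False


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, ExonChain] = field(default_factory=dict)

    @property
    def span(self) -> tuple[int, int]:
        starts = [c.span[0] for c in self.transcripts.values()]
        ends = [c.span[1] for c in self.transcripts.values()]
        return min(starts), max(ends)

    @property
    def junctions(self) -> frozenset[tuple[int, int]]:
        out: set[tuple[int, int]] = set()
        for chain in self.transcripts.values():
            out.update(chain.introns)
        return frozenset(out)

    def exon_tree(self) -> IntervalTree:
        tree = IntervalTree()
        for chain in self.transcripts.values():
            for s, e in chain.exons:
                tree.addi(s, e)
        return tree


class AnnotationIndex:
    """Reference gene models with interval indexes for classification."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: dict[str, GeneModel] = {}
        self.transcripts: dict[str, ExonChain] = {}
        self._gene_trees: dict[str, IntervalTree] = {}
        self._gene_exon_trees: dict[str, IntervalTree] = {}
        for gene in genes:
            if gene.gene_id in self.genes:
                raise ValueError(f"duplicate gene id {gene.gene_id!r}")
            self.genes[gene.gene_id] = gene
            for tx_id, chain in gene.transcripts.items():
                if tx_id in self.transcripts:
                    raise ValueError(f"duplicate transcript id {tx_id!r}")
                self.transcripts[tx_id] = chain
            span = gene.span
            self._gene_trees.setdefault(gene.chrom, IntervalTree()).addi(
                span[0], span[1], gene.gene_id)
            self._gene_exon_trees[gene.gene_id] = gene.exon_tree()
        self.junctions: frozenset[tuple[str, str, int, int]] = frozenset(
            (g.chrom, g.strand, s, e)
            for g in self.genes.values() for (s, e) in g.junctions)

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self._gene_trees.get(chrom)
        if tree is None:
            return []
        hits = sorted({iv.data for iv in tree.overlap(start, end)})
        return [self.genes[g] for g in hits]

    def gene_exon_tree(self, gene_id: str) -> IntervalTree:
        return self._gene_exon_trees[gene_id]

    def chroms(self) -> set[str]:
        return set(self._gene_trees)


def parse_annotation(path: str | os.PathLike,
                     genome_lengths: dict[str, int] | None = None,
                     ) -> AnnotationIndex:
    """Parse a GTF into an :class:`AnnotationIndex`.

    GTF coordinates (1-based inclusive) become 0-based half-open. Exon
    features must carry ``gene_id`` and ``transcript_id``. Exons beyond the
    contig length (when lengths are given) or overlapping within a
    transcript are rejected.
    """
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, disable_infer_genes=True,
                            disable_infer_transcripts=True)
    per_tx: dict[str, list] = {}
    tx_meta: dict[str, tuple[str, str, str]] = {}
    for exon in db.features_of_type("exon"):
        gene_id = exon.attributes["gene_id"][0]
        tx_id = exon.attributes["transcript_id"][0]
        start, end = exon.start - 1, exon.end  # to 0-based half-open
        if genome_lengths is not None:
            length = genome_lengths.get(exon.seqid)
            if length is None:
                raise ValueError(f"unknown contig {exon.seqid!r} in {path}")
            if end > length:
                raise ValueError(
                    f"exon {exon.seqid}:{exon.start}-{exon.end} exceeds "
                    f"contig length {length}")
        per_tx.setdefault(tx_id, []).append((start, end))
        tx_meta[tx_id] = (gene_id, exon.seqid, exon.strand)
    genes: dict[str, GeneModel] = {}
    for tx_id, exons in per_tx.items():
        gene_id, chrom, strand = tx_meta[tx_id]
        exons.sort()
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"transcript {tx_id!r} has overlapping exons")
        chain = ExonChain(tx_id, chrom, strand, tuple(exons))
        genes.setdefault(gene_id, GeneModel(gene_id, chrom, strand)) \
             .transcripts[tx_id] = chain
    return AnnotationIndex(genes.values())


def write_annotation(path: str | os.PathLike, index: AnnotationIndex,
                     source: str = "isocurate") -> None:
    """Write an index back to GTF (exon features only); the write->parse
    round trip preserves every exon coordinate exactly."""
    with open(path, "w") as fh:
        for gene_id in sorted(index.genes):
            gene = index.genes[gene_id]
            for tx_id in sorted(gene.transcripts):
                chain = gene.transcripts[tx_id]
                for s, e in chain.exons:
                    attrs = f'gene_id "{gene_id}"; transcript_id "{tx_id}";'
                    fh.write(f"{chain.chrom}\t{source}\texon\t{s + 1}\t{e}\t."
                             f"\t{chain.strand}\t.\t{attrs}\n")
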