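"""Structural classification of exon chains against a reference annotation.

Each chain receives exactly one of nine categories, decided in a fixed
precedence order:

1. no overlap with any gene span on either strand — ``intergenic``;
2. overlap only with opposite-strand genes — ``antisense``;
3. exonic overlap with two or more distinct same-strand genes — ``fusion``;
4. chain entirely inside one annotated intron — ``genic_intron``;
5. against the single associated gene: identical intron chain — ``FSM``;
   consecutive sub-chain of a transcript's introns — ``ISM``; all junctions
   known at the gene but the combination novel — ``NIC``; at least one
   unknown junction — ``NNC``; mono-exon chains contained in a reference
   exon associate to that transcript (FSM if it is mono-exon, ISM
   otherwise);
6. anything else overlapping exons and introns — ``genic_genomic``.

Junction canonicality (GT..AG / GC..AG / AT..AC on the transcription
strand), the downstream genomic A fraction used to flag intrapriming, and
polyA-signal motifs are annotated alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .annotation import AnnotationIndex, ExonChain, GeneModel
from .io import revcomp

CATEGORIES = ("FSM", "ISM", "NIC", "NNC", "genic_genomic", "genic_intron",
              "intergenic", "antisense", "fusion")

CANONICAL_MOTIFS = {("GT", "AG"), ("GC", "AG"), ("AT", "AC")}


@dataclass
class StructuralCall:
    read_id: str
    category: str
    associated_gene: str | None = None
    associated_gene_2: str | None = None  # second partner for fusion
    associated_transcript: str | None = None
    all_junctions_canonical: bool = True
    downstream_a_fraction: float = 0.0
    intrapriming_flag: bool = False
    polya_motif: str | None = None
    n_exons: int = 1


def _fetch(genome: Mapping[str, str], chrom: str, start: int, end: int) -> str:
    seq = genome[chrom]
    if start < 0 or end > len(seq):
        raise ValueError(f"{chrom}:{start}-{end} outside contig bounds")
    return str(seq[start:end]).upper()


def junction_is_canonical(genome: Mapping[str, str], chrom: str,
                          intron: tuple[int, int], strand: str) -> bool:
    """True iff the transcription-strand donor..acceptor dinucleotides are
    one of GT..AG, GC..AG, AT..AC."""
    start, end = intron
    if end - start < 4:
        raise ValueError(f"intron {chrom}:{start}-{end} shorter than 4 nt")
    left = _fetch(genome, chrom, start, start + 2)
    right = _fetch(genome, chrom, end - 2, end)
    if strand == "+":
        donor, acceptor = left, right
    else:
        donor, acceptor = revcomp(right), revcomp(left)
    return (donor, acceptor) in CANONICAL_MOTIFS


def downstream_a_fraction(genome: Mapping[str, str], chrom: str,
                          tx_end: int, strand: str, window: int = 20) -> float:
    """Fraction of transcription-strand A among up to ``window`` genomic
    bases immediately 3' of the mapped transcript end (the denominator is
    the number of available bases)."""
    contig_len = len(genome[chrom])
    if strand == "+":
        seq = _fetch(genome, chrom, tx_end, min(tx_end + window, contig_len))
        base = "A"
    else:
        seq = _fetch(genome, chrom, max(tx_end - window, 0), tx_end)
        base = "T"  # genomic T reads as A on the transcription strand
    if not seq:
        return 0.0
    return seq.count(base) / len(seq)


def find_polya_signal(seq3p: str, motifs: Sequence[str] = ("AATAAA", "ATTAAA"),
                      search_window: int = 50) -> int | None:
    """Position (on the given sequence) of the 3'-most occurrence of any
    motif within the last ``search_window`` bases, or None."""
    window_start = max(0, len(seq3p) - search_window)
    best = None
    for motif in motifs:
        pos = seq3p.rfind(motif)
        if pos >= window_start and (best is None or pos > best):
            best = pos
    return best


def _is_subchain(sub: tuple, full: tuple) -> bool:
    """True iff ``sub`` is a consecutive run inside ``full``."""
    n, m = len(sub), len(full)
    if n == 0 or n > m:
        return False
    return any(full[i:i + n] == sub for i in range(m - n + 1))


def _associate_gene(chain: ExonChain, candidates: list[GeneModel]) -> GeneModel:
    """Pick the gene sharing the most junctions, then most exonic overlap."""
    def score(gene: GeneModel):
        shared = len(set(chain.introns) & gene.junctions)
        tree = gene.exon_tree()
        overlap = 0
        for s, e in chain.exons:
            for iv in tree.overlap(s, e):
                overlap += min(e, iv.end) - max(s, iv.begin)
        return (shared, overlap, gene.gene_id)
    return sorted(candidates, key=score, reverse=True)[0]


def _exonic_overlap_genes(chain: ExonChain,
                          genes: list[GeneModel]) -> list[GeneModel]:
    out = []
    for gene in genes:
        tree = gene.exon_tree()
        if any(tree.overlap(s, e) for s, e in chain.exons):
            out.append(gene)
    return out


def classify_chain(chain: ExonChain, ann: AnnotationIndex,
                   genome: Mapping[str, str],
                   a_window: int = 20, a_frac: float = 0.80,
                   nic_gene_level: bool = True) -> StructuralCall:
    """Classify one exon chain; total over mapped chains (exactly one
    category always applies)."""
    if chain.chrom not in genome:
        raise ValueError(f"{chain.read_id}: contig {chain.chrom!r} missing "
                         "from the genome")
    span = chain.span
    overlapping = ann.genes_overlapping(chain.chrom, span[0], span[1])
    same = [g for g in overlapping if g.strand == chain.strand]
    opposite = [g for g in overlapping if g.strand != chain.strand]

    call = StructuralCall(chain.read_id, "", n_exons=chain.n_exons)
    if chain.introns:
        call.all_junctions_canonical = all(
            junction_is_canonical(genome, chain.chrom, intron, chain.strand)
            for intron in chain.introns)
    call.downstream_a_fraction = downstream_a_fraction(
        genome, chain.chrom, chain.tes, chain.strand, a_window)
    call.intrapriming_flag = call.downstream_a_fraction >= a_frac

    if not overlapping:
        call.category = "intergenic"
        return call
    if not same:
        call.category = "antisense"
        return call
    exonic = _exonic_overlap_genes(chain, same)
    if len(exonic) >= 2:
        exonic = sorted(exonic, key=lambda g: g.span)
        call.category = "fusion"
        call.associated_gene = exonic[0].gene_id
        call.associated_gene_2 = exonic[1].gene_id
        return call

    gene = _associate_gene(chain, exonic or same)
    call.associated_gene = gene.gene_id

    # entirely inside one annotated intron of the associated locus
    for g in same:
        for tx in g.transcripts.values():
            for istart, iend in tx.introns:
                if istart <= span[0] and span[1] <= iend:
                    call.category = "genic_intron"
                    call.associated_gene = g.gene_id
                    return call

    if chain.n_exons > 1:
        known = (gene.junctions if nic_gene_level
                 else {(s, e) for (c, st, s, e) in ann.junctions
                       if c == chain.chrom and st == chain.strand})
        introns = chain.introns
        for tx_id in sorted(gene.transcripts):
            if gene.transcripts[tx_id].introns == introns:
                call.category = "FSM"
                call.associated_transcript = tx_id
                return call
        for tx_id in sorted(gene.transcripts):
            full = gene.transcripts[tx_id].introns
            if len(introns) < len(full) and _is_subchain(introns, full):
                call.category = "ISM"
                call.associated_transcript = tx_id
                return call
        if all(j in known for j in introns):
            call.category = "NIC"
        else:
            call.category = "NNC"
        return call

    # mono-exon chain against the associated gene
    s0, e0 = chain.exons[0]
    containing_mono: list[str] = []
    containing_multi: list[str] = []
    for tx_id in sorted(gene.transcripts):
        tx = gene.transcripts[tx_id]
        for es, ee in tx.exons:
            if es <= s0 and e0 <= ee:
                (containing_mono if tx.n_exons == 1
                 else containing_multi).append(tx_id)
                break
    if containing_mono:
        call.category = "FSM"
        call.associated_transcript = containing_mono[0]
    elif containing_multi:
        call.category = "ISM"
        call.associated_transcript = containing_multi[0]
    else:
        call.category = "genic_genomic"
    return call


def classify_chains(chains: Sequence[ExonChain], ann: AnnotationIndex,
                    genome: Mapping[str, str],
                    sequences: Mapping[str, str] | None = None,
                    a_window: int = 20, a_frac: float = 0.80,
                    polya_motifs: Sequence[str] = ("AATAAA", "ATTAAA"),
                    polya_window: int = 50) -> list[StructuralCall]:
    calls = []
    for chain in sorted(chains, key=lambda c: c.read_id):
        call = classify_chain(chain, ann, genome, a_window, a_frac)
        if sequences is not None and chain.read_id in sequences:
            pos = find_polya_signal(sequences[chain.read_id], polya_motifs,
                                    polya_window)
            call.polya_motif = (None if pos is None
                                else sequences[chain.read_id][pos:pos + 6])
        calls.append(call)
    return calls
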