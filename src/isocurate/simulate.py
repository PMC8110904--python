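"""Seeded synthetic truth sets for every pipeline stage.

The generator emulates the study conditions the pipeline was designed for:
multi-isoform multi-exon genes with canonical GT..AG junctions (plus
planted alternative donors so novel-in-catalog combinations exist), planted
isoforms of all nine structural categories with labels that are verifiable
against the annotation, long reads with per-sample FLNC multiplicities
(optionally with substitution/indel/homopolymer errors), stranded paired
short reads at configurable depth, interspersed-repeat decoys, intergenic
ORF islands, and an 11-sample x 3-organ design (4 gill, 4 liver, 3
head-kidney). A single integer seed governs all randomness.

Short-read simulation adds ``solidity`` end-anchored pairs per source
transcript on top of uniform fragments; without end anchoring, uniform
fragment sampling leaves the terminal k-1 bases of every transcript without
solid k-mer support at any realistic depth, because a k-mer covering the
first base requires a read starting exactly at it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .annotation import AnnotationIndex, ExonChain, GeneModel
from .io import LongRead, ReadRegistry, revcomp

BASES = "ACGT"
STOPS_STANDARD = ("TAA", "TAG", "TGA")

# donor offsets planted into every intron (relative to the intron start, in
# the gene's transcription orientation): +3 is an annotated alternative
# donor, +6 an unannotated canonical donor, +9 an unannotated non-canonical
# donor site
ALT_DONOR_SHIFT = 3
NNC_CANONICAL_SHIFT = 6
NNC_NONCANONICAL_SHIFT = 9

DEFAULT_SAMPLE_ORGAN = {
    "GiU1": "gill", "GiU2": "gill", "GiU3": "gill", "GiU4": "gill",
    "LiU1": "liver", "LiU2": "liver", "LiU3": "liver", "LiU4": "liver",
    "HKU1": "head_kidney", "HKU2": "head_kidney", "HKU3": "head_kidney",
}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def _scrub_atg(seq: str) -> str:
    """Remove every ATG occurrence (so no ORF can start)."""
    out = list(seq)
    i = 0
    while i <= len(out) - 3:
        if out[i] == "A" and out[i + 1] == "T" and out[i + 2] == "G":
            out[i + 2] = "C"
        i += 1
    return "".join(out)


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + n_codons sense codons + TAA."""
    body = []
    while len(body) < n_codons:
        codon = _random_seq(rng, 3)
        if codon not in STOPS_STANDARD:
            body.append(codon)
    return "ATG" + "".join(body) + "TAA"


def has_complete_orf(seq: str, min_nt: int = 150,
                     stops: Sequence[str] = STOPS_STANDARD) -> bool:
    """Brute-force check: does any forward frame hold an ATG..stop span of
    at least ``min_nt`` nucleotides (stop included)? Independent of the ORF
    caller; used only to label truth."""
    seq = seq.upper()
    for frame in range(3):
        codons = [seq[p:p + 3] for p in range(frame, len(seq) - 2, 3)]
        starts: list[int] = []
        for idx, codon in enumerate(codons):
            if codon == "ATG":
                starts.append(idx)
            elif codon in stops:
                for s in starts:
                    if (idx - s + 1) * 3 >= min_nt:
                        return True
                starts = []
    return False


@dataclass
class SyntheticGene:
    gene_id: str
    symbol: str
    chrom: str
    strand: str
    offset: int          # genomic start of the gene block
    length: int          # genomic length of the gene block
    local_exons: tuple[tuple[int, int], ...]   # transcription orientation
    local_introns: tuple[tuple[int, int], ...]
    gene_seq: str        # transcription-orientation sequence of the block

    def to_genomic(self, local: tuple[int, int]) -> tuple[int, int]:
        a, b = local
        if self.strand == "+":
            return self.offset + a, self.offset + b
        return self.offset + self.length - b, self.offset + self.length - a

    def chain_from_local(self, read_id: str,
                         local_exons: Sequence[tuple[int, int]]) -> ExonChain:
        genomic = sorted(self.to_genomic(e) for e in local_exons)
        return ExonChain(read_id, self.chrom, self.strand, tuple(genomic))

    def local_subseq(self, local: tuple[int, int]) -> str:
        return self.gene_seq[local[0]:local[1]]


@dataclass
class PlantedIsoform:
    iso_id: str
    gene_id: str | None
    category: str                    # nine categories or "unmapped"
    chain: ExonChain | None
    sequence: str
    all_junctions_canonical: bool
    has_complete_cds: bool
    is_repeat_decoy: bool = False
    sample_flnc: dict[str, int] = field(default_factory=dict)
    fragment_offsets: tuple[int, ...] = ()   # extra 5'-truncated read copies

    @property
    def total_flnc(self) -> int:
        return sum(self.sample_flnc.values())

    def expected_samples(self) -> set[str]:
        return set(self.sample_flnc)


@dataclass
class TruthSet:
    seed: int
    genome: dict[str, str]
    annotation: AnnotationIndex
    genes: list[SyntheticGene]
    gene_symbols: dict[str, str]
    isoforms: list[PlantedIsoform]
    repeat_library: list[tuple[str, str]]
    sample_organ: dict[str, str]
    flnc_low: int = 2
    flnc_high: int = 5
    min_orf_nt: int = 150

    def expected_kept_ids(self) -> set[str]:
        """Isoforms satisfying the category-aware FLNC + complete-CDS rule,
        computed directly from the planted truth."""
        kept: set[str] = set()
        for iso in self.isoforms:
            if iso.is_repeat_decoy or not iso.has_complete_cds:
                continue
            total = sum(iso.sample_flnc.values())
            baseline = iso.category in ("FSM", "NIC") or (
                iso.category == "NNC" and iso.all_junctions_canonical)
            need = self.flnc_low if baseline else self.flnc_high
            if total >= need:
                kept.add(iso.iso_id)
        return kept

    def expected_organ_labels(self, min_samples: int = 3
                              ) -> dict[str, str | None]:
        """Brute-force application of the organ-specificity rule to the kept
        isoforms' planted sample sets."""
        organs = sorted(set(self.sample_organ.values()))
        labels: dict[str, str | None] = {}
        kept = self.expected_kept_ids()
        for iso in self.isoforms:
            if iso.iso_id not in kept:
                continue
            present = iso.expected_samples()
            label = None
            for organ in organs:
                inside = sum(1 for s in present
                             if self.sample_organ[s] == organ)
                outside = sum(1 for s in present
                              if self.sample_organ[s] != organ)
                if inside >= min_samples and outside == 0:
                    label = organ
            labels[iso.iso_id] = label
        return labels


def _build_gene(rng: np.random.Generator, gene_id: str, symbol: str,
                chrom: str, strand: str, offset: int, n_exons: int,
                exon_len: tuple[int, int], intron_len: tuple[int, int],
                orf_codons: tuple[int, int]) -> SyntheticGene:
    """Assemble one gene block in transcription orientation.

    The CDS lives inside exon 1 (or exon 0 of a mono-exon gene) with a 10 nt
    pad on each side; every intron is GT..AG with the planted alternative /
    novel donor motifs at fixed offsets; an extra ORF is embedded in the
    interior of the last intron (so intron-contained isoforms can code) and
    the reverse complement of an ORF in exon 0 (so antisense isoforms can).
    """
    orf = _random_orf(rng, int(rng.integers(orf_codons[0], orf_codons[1] + 1)))
    exon_seqs: list[str] = []
    cds_exon = 1 if n_exons > 1 else 0
    for i in range(n_exons):
        if i == cds_exon:
            exon_seqs.append(_random_seq(rng, 10) + orf + _random_seq(rng, 10))
        else:
            length = int(rng.integers(exon_len[0], exon_len[1] + 1))
            seq = _random_seq(rng, length)
            if i == 0 and n_exons > 1:
                inner_orf = _random_orf(
                    rng, int(rng.integers(orf_codons[0], orf_codons[1] + 1)))
                if length < len(inner_orf) + 20:
                    seq = _random_seq(rng, len(inner_orf) + 20)
                seq = seq[:10] + revcomp(inner_orf) + seq[10 + len(inner_orf):]
            exon_seqs.append(seq)
    intron_seqs: list[str] = []
    for i in range(n_exons - 1):
        length = int(rng.integers(intron_len[0], intron_len[1] + 1))
        if i == n_exons - 2:
            length = max(length, 260)
        body = list(_random_seq(rng, length))
        body[0:2] = "GT"
        body[-2:] = "AG"
        body[ALT_DONOR_SHIFT:ALT_DONOR_SHIFT + 2] = "GT"
        body[NNC_CANONICAL_SHIFT:NNC_CANONICAL_SHIFT + 2] = "GT"
        body[NNC_NONCANONICAL_SHIFT:NNC_NONCANONICAL_SHIFT + 2] = "CC"
        if i == n_exons - 2 and length >= 230:
            intron_orf = _random_orf(rng, 50)   # 156 nt, codes inside intron
            start = 40
            body[start:start + len(intron_orf)] = intron_orf
        intron_seqs.append("".join(body))
    parts: list[str] = []
    local_exons: list[tuple[int, int]] = []
    local_introns: list[tuple[int, int]] = []
    pos = 0
    for i, exon in enumerate(exon_seqs):
        parts.append(exon)
        local_exons.append((pos, pos + len(exon)))
        pos += len(exon)
        if i < len(intron_seqs):
            parts.append(intron_seqs[i])
            local_introns.append((pos, pos + len(intron_seqs[i])))
            pos += len(intron_seqs[i])
    gene_seq = "".join(parts)
    return SyntheticGene(gene_id, symbol, chrom, strand, offset, len(gene_seq),
                         tuple(local_exons), tuple(local_introns), gene_seq)


def simulate_reference(seed: int, n_genes: int = 20,
                       exons_per_gene: tuple[int, int] = (4, 6),
                       exon_len: tuple[int, int] = (130, 220),
                       intron_len: tuple[int, int] = (90, 160),
                       gap: int = 25_000,
                       orf_codons: tuple[int, int] = (55, 75),
                       paralog_every: int = 8,
                       chrom: str = "chr1",
                       ) -> tuple[dict[str, str], AnnotationIndex,
                                  list[SyntheticGene], dict[str, str]]:
    """Build a genome and multi-isoform annotation.

    Gene strands follow a + + - - pattern (so adjacent same-strand pairs
    exist for fusion placements); every ``paralog_every``-th gene shares its
    symbol with the following gene, planting a known multilocus fraction.
    Returns (genome, annotation index, gene blocks, gene_id -> symbol).
    """
    if n_genes < 1 or exons_per_gene[0] < 1:
        raise ValueError("need at least one gene with at least one exon")
    if exon_len[0] < 40 or intron_len[0] < 20:
        raise ValueError("infeasible geometry: exons/introns too short")
    rng = np.random.default_rng(seed)
    genes: list[SyntheticGene] = []
    symbols: dict[str, str] = {}
    pieces: list[str] = []
    pos = 0
    for i in range(n_genes):
        pieces.append(_random_seq(rng, gap))
        pos += gap
        gene_id = f"G{i + 1:03d}"
        if paralog_every and i % paralog_every == 1 and i >= 1:
            symbol = symbols[f"G{i:03d}"]   # share the previous gene's symbol
        else:
            symbol = f"sym{i + 1:03d}"
        symbols[gene_id] = symbol
        strand = "+" if (i % 4) in (0, 1) else "-"
        n_exons = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        gene = _build_gene(rng, gene_id, symbol, chrom, strand, pos, n_exons,
                           exon_len, intron_len, orf_codons)
        if strand == "+":
            pieces.append(gene.gene_seq)
        else:
            pieces.append(revcomp(gene.gene_seq))
        pos += gene.length
        genes.append(gene)
    pieces.append(_random_seq(rng, gap))
    pos += gap
    genome = {chrom: "".join(pieces)}

    models: list[GeneModel] = []
    for gene in genes:
        model = GeneModel(gene.gene_id, gene.chrom, gene.strand)
        m = len(gene.local_introns)
        chains: dict[str, list[tuple[int, int]]] = {
            f"{gene.gene_id}.t1": list(gene.local_exons)}
        if m >= 1:
            chains[f"{gene.gene_id}.t2"] = _shift_donor(gene.local_exons, 0,
                                                        ALT_DONOR_SHIFT)
        if m >= 2:
            chains[f"{gene.gene_id}.t3"] = _shift_donor(gene.local_exons, 1,
                                                        ALT_DONOR_SHIFT)
        for tx_id, local in chains.items():
            model.transcripts[tx_id] = gene.chain_from_local(tx_id, local)
        models.append(model)
    return genome, AnnotationIndex(models), genes, symbols


def _shift_donor(local_exons: Sequence[tuple[int, int]], intron_index: int,
                 shift: int) -> list[tuple[int, int]]:
    """Extend the donor-side exon of one intron by ``shift`` bases (local,
    transcription-orientation coordinates)."""
    exons = [list(e) for e in local_exons]
    exons[intron_index][1] += shift
    return [tuple(e) for e in exons]


def _splice_local(gene: SyntheticGene,
                  local_exons: Sequence[tuple[int, int]]) -> str:
    return "".join(gene.local_subseq(e) for e in local_exons)


# fusion sits at a position whose gene index is 0 mod 4, where the + + - -
# strand pattern guarantees the next gene shares the strand
_CYCLE = ("fusion", "ISM", "NIC", "NNC_canonical", "NNC_noncanonical",
          "genic_intron", "genic_genomic", "antisense")


def simulate_isoforms(genome: dict[str, str], genes: list[SyntheticGene],
                      ann: AnnotationIndex, seed: int,
                      categories_per_gene: Sequence[str] | None = None,
                      n_intergenic: int = 4, n_unmapped: int = 4,
                      n_decoys: int = 3,
                      repeat_library: list[tuple[str, str]] | None = None,
                      all_categories: bool = False,
                      ) -> tuple[list[PlantedIsoform], list[tuple[str, str]]]:
    """Plant isoforms with known structural labels.

    Every gene contributes an FSM copy of its primary transcript plus one
    extra category cycled from ISM/NIC/NNC(canonical|non)/genic_intron/
    genic_genomic/antisense/fusion; intergenic isoforms sit on ORF islands
    in the gaps (every other island ATG-scrubbed, hence non-coding),
    unmapped isoforms are free sequences, and repeat decoys carry an
    interspersed-repeat insertion. Infeasible category requests (e.g. a
    junction recombination on a gene without alternative donors) raise an
    error naming the gene.
    """
    rng = np.random.default_rng(seed + 1)
    if repeat_library is None:
        repeat_library = [
            (f"REP{i + 1}", _random_seq(rng, 400)) for i in range(2)]
    isoforms: list[PlantedIsoform] = []

    for i, gene in enumerate(genes):
        tx1 = f"{gene.gene_id}.t1"
        full = list(gene.local_exons)
        seq_full = _splice_local(gene, full)
        iso_id = f"{gene.gene_id}_FSM"
        isoforms.append(PlantedIsoform(
            iso_id, gene.gene_id, "FSM",
            gene.chain_from_local(iso_id, full), seq_full, True,
            has_complete_orf(seq_full)))
        if all_categories:
            wanted = [c for c in _CYCLE
                      if c != "fusion" or (i + 1 < len(genes)
                                           and genes[i + 1].strand
                                           == gene.strand)]
        elif categories_per_gene:
            wanted = [categories_per_gene[i % len(categories_per_gene)]]
        else:
            wanted = [_CYCLE[i % len(_CYCLE)]]
        for extra in wanted:
            iso = _plant_category(gene, genes, i, extra, rng)
            if iso is not None:
                isoforms.append(iso)

    # intergenic islands: midway inside a gap, >= 10 kb from any gene
    chrom = genes[0].chrom
    for j in range(n_intergenic):
        gene = genes[(j * 2 + 1) % len(genes)]
        island_start = gene.offset - 12_600
        island_len = 600
        seq = genome[chrom][island_start:island_start + island_len]
        if j % 2 == 0:
            orf = _random_orf(rng, 60)
            seq = seq[:50] + orf + seq[50 + len(orf):]
        else:
            seq = _scrub_atg(seq)
        genome[chrom] = (genome[chrom][:island_start] + seq
                         + genome[chrom][island_start + island_len:])
        iso_id = f"INTERGENIC_{j + 1}"
        chain = ExonChain(iso_id, chrom, "+",
                          ((island_start, island_start + island_len),))
        isoforms.append(PlantedIsoform(iso_id, None, "intergenic", chain, seq,
                                       True, has_complete_orf(seq)))

    for j in range(n_unmapped):
        seq = _random_seq(rng, 800)
        if j % 2 == 0:
            orf = _random_orf(rng, 60)
            seq = seq[:100] + orf + seq[100 + len(orf):]
        else:
            seq = _scrub_atg(seq)
        iso_id = f"UNMAPPED_{j + 1}"
        isoforms.append(PlantedIsoform(iso_id, None, "unmapped", None, seq,
                                       True, has_complete_orf(seq)))

    for j in range(n_decoys):
        name, entry = repeat_library[j % len(repeat_library)]
        seq = _random_seq(rng, 400) + entry[:300] + _random_seq(rng, 300)
        iso_id = f"DECOY_{j + 1}"
        isoforms.append(PlantedIsoform(iso_id, None, "unmapped", None, seq,
                                       True, has_complete_orf(seq),
                                       is_repeat_decoy=True))
    return isoforms, repeat_library


def _plant_category(gene: SyntheticGene, genes: list[SyntheticGene],
                    index: int, category: str,
                    rng: np.random.Generator) -> PlantedIsoform | None:
    m = len(gene.local_introns)
    full = list(gene.local_exons)
    iso_id = f"{gene.gene_id}_{category}"

    if category == "ISM":
        if m < 2:
            raise ValueError(f"{gene.gene_id}: ISM needs >= 3 exons")
        local = full[1:]
        seq = _splice_local(gene, local)
        return PlantedIsoform(iso_id, gene.gene_id, "ISM",
                              gene.chain_from_local(iso_id, local), seq, True,
                              has_complete_orf(seq))
    if category == "NIC":
        if m < 2:
            raise ValueError(f"{gene.gene_id}: NIC needs >= 3 exons "
                             "(two annotated alternative donors)")
        local = _shift_donor(_shift_donor(full, 0, ALT_DONOR_SHIFT), 1,
                             ALT_DONOR_SHIFT)
        seq = _splice_local(gene, local)
        return PlantedIsoform(iso_id, gene.gene_id, "NIC",
                              gene.chain_from_local(iso_id, local), seq, True,
                              has_complete_orf(seq))
    if category in ("NNC_canonical", "NNC_noncanonical"):
        if m < 1:
            raise ValueError(f"{gene.gene_id}: NNC needs a multi-exon gene")
        shift = (NNC_CANONICAL_SHIFT if category == "NNC_canonical"
                 else NNC_NONCANONICAL_SHIFT)
        local = _shift_donor(full, 0, shift)
        seq = _splice_local(gene, local)
        return PlantedIsoform(iso_id, gene.gene_id, "NNC",
                              gene.chain_from_local(iso_id, local), seq,
                              category == "NNC_canonical",
                              has_complete_orf(seq))
    if category == "genic_intron":
        if m < 1:
            raise ValueError(f"{gene.gene_id}: genic_intron needs an intron")
        istart, iend = gene.local_introns[-1]
        local = [(istart + 15, iend - 15)]
        seq = _splice_local(gene, local)
        return PlantedIsoform(iso_id, gene.gene_id, "genic_intron",
                              gene.chain_from_local(iso_id, local), seq, True,
                              has_complete_orf(seq))
    if category == "genic_genomic":
        if m < 2:
            raise ValueError(f"{gene.gene_id}: genic_genomic placement needs "
                             ">= 3 exons")
        (es, ee) = gene.local_exons[1]
        (is2, ie2) = gene.local_introns[1]
        local = [(es + 2, is2 + 60)]
        seq = _splice_local(gene, local)
        return PlantedIsoform(iso_id, gene.gene_id, "genic_genomic",
                              gene.chain_from_local(iso_id, local), seq, True,
                              has_complete_orf(seq))
    if category == "antisense":
        (es, ee) = gene.local_exons[0]
        genomic = gene.to_genomic((es + 2, ee - 2))
        strand = "-" if gene.strand == "+" else "+"
        chain = ExonChain(iso_id, gene.chrom, strand, (genomic,))
        block = gene.local_subseq((es + 2, ee - 2))
        seq = revcomp(block)   # opposite of the gene's transcription strand
        return PlantedIsoform(iso_id, gene.gene_id, "antisense", chain, seq,
                              True, has_complete_orf(seq))
    if category == "fusion":
        if index + 1 >= len(genes):
            return None
        partner = genes[index + 1]
        if partner.strand != gene.strand or len(partner.local_exons) < 1:
            return None
        cds_exon = 1 if len(gene.local_exons) > 1 else 0
        exon_a = gene.to_genomic(gene.local_exons[cds_exon])
        exon_b = partner.to_genomic(partner.local_exons[0])
        exons = tuple(sorted([exon_a, exon_b]))
        chain = ExonChain(iso_id, gene.chrom, gene.strand, exons)
        blocks = [genome_slice(gene, partner, e) for e in exons]
        genomic_seq = "".join(blocks)
        seq = genomic_seq if gene.strand == "+" else revcomp(genomic_seq)
        return PlantedIsoform(iso_id, gene.gene_id, "fusion", chain, seq, True,
                              has_complete_orf(seq))
    raise ValueError(f"{gene.gene_id}: unknown category request {category!r}")


def genome_slice(gene: SyntheticGene, partner: SyntheticGene,
                 genomic: tuple[int, int]) -> str:
    """Forward-strand genomic sequence of an interval that lies inside one
    of the two gene blocks."""
    for g in (gene, partner):
        if g.offset <= genomic[0] and genomic[1] <= g.offset + g.length:
            local = (genomic[0] - g.offset, genomic[1] - g.offset)
            if g.strand == "+":
                return g.gene_seq[local[0]:local[1]]
            flipped = (g.length - local[1], g.length - local[0])
            return revcomp(g.gene_seq[flipped[0]:flipped[1]])
    raise ValueError("interval outside both gene blocks")


def _assign_expression(isoforms: list[PlantedIsoform],
                       sample_organ: dict[str, str],
                       rng: np.random.Generator) -> None:
    """Attach per-sample FLNC counts.

    FSM isoforms alternate between broad expression (several samples across
    organs) and minimal baseline support (one sample, 2 FLNCs); a third of
    the planted isoforms are organ-specific (>= 3 samples of one organ,
    absent elsewhere); non-baseline categories alternate between >= 5 total
    FLNCs (kept) and < 5 (dropped), exercising both sides of the evidence
    rule.
    """
    samples = sorted(sample_organ)
    organs = sorted(set(sample_organ.values()))
    by_organ = {o: [s for s in samples if sample_organ[s] == o]
                for o in organs}
    specific_counter = 0
    for n, iso in enumerate(isoforms):
        baseline = iso.category in ("FSM", "NIC") or (
            iso.category == "NNC" and iso.all_junctions_canonical)
        if n % 3 == 0 and not iso.is_repeat_decoy:
            organ = organs[specific_counter % len(organs)]
            pool = by_organ[organ]
            take = min(len(pool), 3 + int(rng.integers(0, 2)))
            chosen = list(rng.choice(pool, size=take, replace=False))
            specific_counter += 1
        else:
            take = 4 + int(rng.integers(0, 4))
            chosen = list(rng.choice(samples, size=take, replace=False))
        if baseline and n % 6 == 1:
            chosen = [chosen[0]]              # minimal 2-FLNC baseline case
            iso.sample_flnc = {chosen[0]: 2}
            continue
        if not baseline and n % 2 == 0:
            # under-supported: single sample, total < flnc_high
            iso.sample_flnc = {chosen[0]: int(rng.integers(2, 5))}
            continue
        iso.sample_flnc = {s: int(rng.integers(2, 7)) for s in chosen}


@dataclass
class ReadSet:
    long_reads: list[LongRead]
    registry: ReadRegistry
    truth_sam: str                      # SAM text of true alignments
    short_pairs: list[tuple[str, str]]  # (R1, R2) sequences
    read_isoform: dict[str, str]        # read_id -> planted isoform


def _apply_long_errors(seq: str, rng: np.random.Generator, sub: float,
                       ins: float, dele: float, homopoly: float,
                       ) -> tuple[str, list[tuple[int, str]]]:
    out: list[str] = []
    events: list[tuple[int, str]] = []
    i = 0
    while i < len(seq):
        base = seq[i]
        r = rng.random()
        if r < sub:
            out.append(rng.choice([b for b in BASES if b != base]))
            events.append((i, "sub"))
        elif r < sub + dele:
            events.append((i, "del"))
        elif r < sub + dele + ins:
            out.append(base)
            out.append(rng.choice(list(BASES)))
            events.append((i, "ins"))
        elif r < sub + dele + ins + homopoly and i > 0 and seq[i - 1] == base:
            out.append(base)
            out.append(base)
            events.append((i, "homopoly"))
        else:
            out.append(base)
        i += 1
    return "".join(out), events


def simulate_reads(truth: TruthSet, seed: int,
                   depth: float = 30.0, short_read_len: int = 150,
                   fragment_len: tuple[int, int] = (250, 350),
                   short_error: float = 0.0,
                   long_sub: float = 0.0, long_ins: float = 0.0,
                   long_del: float = 0.0, long_homopoly: float = 0.0,
                   solidity_anchor: int = 3,
                   fragment_every: int = 5, fragment_offset: int = 30,
                   ) -> ReadSet:
    """Long reads (one per isoform per expressing sample), paired short
    reads over every source sequence, the registry, and a truth SAM.

    Every ``fragment_every``-th mapped multi-exon isoform also emits a
    5'-truncated fragment read (same intron chain), exercising the collapse
    step. The truth SAM carries each read's true exon chain; when long-read
    errors are enabled the SAM keeps the error-free coordinates and omits
    SEQ.
    """
    rng = np.random.default_rng(seed + 2)
    long_reads: list[LongRead] = []
    registry = ReadRegistry()
    read_isoform: dict[str, str] = {}
    sam_lines: list[str] = []
    error_free = (long_sub == long_ins == long_del == long_homopoly == 0.0)

    sources: list[tuple[str, str]] = []   # (source id, sequence) for shorts
    for n, iso in enumerate(truth.isoforms):
        sources.append((iso.iso_id, iso.sequence))
        emit_fragment = (iso.chain is not None and iso.chain.n_exons > 1
                         and n % fragment_every == 0)
        frag_seq = None
        frag_chain = None
        if emit_fragment:
            chain = iso.chain
            if chain.strand == "+":
                exons = ((chain.exons[0][0] + fragment_offset,
                          chain.exons[0][1]),) + chain.exons[1:]
                frag_seq = iso.sequence[fragment_offset:]
            else:
                exons = chain.exons[:-1] + (
                    (chain.exons[-1][0],
                     chain.exons[-1][1] - fragment_offset),)
                frag_seq = iso.sequence[fragment_offset:]
            frag_chain = ExonChain(iso.iso_id + "_frag", chain.chrom,
                                   chain.strand, exons)
            sources.append((iso.iso_id + "_frag", frag_seq))
        first = True
        for sample in sorted(iso.sample_flnc):
            flnc = iso.sample_flnc[sample]
            read_id = f"{iso.iso_id}|{sample}"
            seq = iso.sequence
            if not error_free:
                seq, _events = _apply_long_errors(
                    seq, rng, long_sub, long_ins, long_del, long_homopoly)
            long_reads.append(LongRead(read_id, seq, sample, flnc))
            registry.add(read_id, sample, flnc)
            read_isoform[read_id] = iso.iso_id
            if iso.chain is not None:
                sam_lines.append(_sam_line(read_id, iso.chain,
                                           seq if error_free else None))
            if first and emit_fragment:
                frag_id = f"{iso.iso_id}|{sample}|frag"
                long_reads.append(LongRead(frag_id, frag_seq, sample, 2))
                registry.add(frag_id, sample, 2)
                read_isoform[frag_id] = iso.iso_id
                sam_lines.append(_sam_line(frag_id, frag_chain,
                                           frag_seq if error_free else None))
                iso.sample_flnc = dict(iso.sample_flnc)
                # fragment support counts toward the isoform's total
                iso.sample_flnc[sample] = flnc + 2
                first = False

    header = "".join(f"@SQ\tSN:{c}\tLN:{len(s)}\n"
                     for c, s in sorted(truth.genome.items()))
    truth_sam = header + "".join(sam_lines)

    short_pairs: list[tuple[str, str]] = []
    for _sid, seq in sources:
        L = len(seq)
        rl = min(short_read_len, L)
        for _ in range(solidity_anchor):    # end-anchored pairs
            short_pairs.append((seq[:rl], revcomp(seq[-rl:])))
        n_frag = max(1, int(round(depth * L / (2 * rl))))
        for _ in range(n_frag):
            flen = min(L, int(rng.integers(fragment_len[0],
                                           fragment_len[1] + 1)))
            start = int(rng.integers(0, L - flen + 1))
            frag = seq[start:start + flen]
            r1, r2 = frag[:rl], revcomp(frag[-rl:])
            if short_error > 0:
                r1 = _mutate(r1, rng, short_error)
                r2 = _mutate(r2, rng, short_error)
            short_pairs.append((r1, r2))
    return ReadSet(long_reads, registry, truth_sam, short_pairs, read_isoform)


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in BASES if b != out[i]])
    return "".join(out)


def _sam_line(read_id: str, chain: ExonChain, seq: str | None) -> str:
    cigar_parts = []
    for i, (s, e) in enumerate(chain.exons):
        cigar_parts.append(f"{e - s}M")
        if i < chain.n_exons - 1:
            cigar_parts.append(f"{chain.exons[i + 1][0] - e}N")
    flag = 16 if chain.strand == "-" else 0
    if seq is None:
        sam_seq = "*"
    else:
        sam_seq = seq if chain.strand == "+" else revcomp(seq)
    return (f"{read_id}\t{flag}\t{chain.chrom}\t{chain.span[0] + 1}\t60\t"
            f"{''.join(cigar_parts)}\t*\t0\t0\t{sam_seq}\t*\n")


def make_truth_set(seed: int, n_genes: int = 20,
                   sample_organ: dict[str, str] | None = None,
                   n_intergenic: int = 4, n_unmapped: int = 4,
                   n_decoys: int = 3, **ref_kwargs) -> TruthSet:
    """One-call truth set: reference + isoforms + expression design."""
    genome, ann, genes, symbols = simulate_reference(seed, n_genes,
                                                     **ref_kwargs)
    isoforms, repeats = simulate_isoforms(genome, genes, ann, seed,
                                          n_intergenic=n_intergenic,
                                          n_unmapped=n_unmapped,
                                          n_decoys=n_decoys)
    # island edits modify the genome in place; rebuild nothing else
    sample_organ = dict(sample_organ or DEFAULT_SAMPLE_ORGAN)
    rng = np.random.default_rng(seed + 3)
    _assign_expression(isoforms, sample_organ, rng)
    return TruthSet(seed, genome, ann, genes, symbols, isoforms, repeats,
                    sample_organ)
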