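"""End-to-end orchestration: support -> screen -> collapse -> classify ->
ORF -> final filter -> organ specificity, over in-memory objects.

Each stage is the corresponding library function; this module only wires
them together and keeps the read registry consistent across collapses.
"""

from __future__ import annotations

import io as _io
import tempfile
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .align import ScoringScheme
from .annotation import AnnotationIndex, ExonChain
from .classify import StructuralCall, classify_chain, find_polya_signal
from .collapse import (IsoformCluster, chains_from_sam, collapse_identity,
                       group_and_collapse)
from .config import DEFAULT_CONFIG, PipelineConfig
from .io import LongRead, ReadRegistry
from .kmer import build_graph, filter_reads
from .mrna import TranscriptRecord, final_mrna_filter
from .organs import (PresenceMatrix, locus_organ_presence,
                     organ_specific_transcripts, partition_gene_vs_variant)
from .orf import find_best_orf
from .screen import screen_repeats


@dataclass
class PipelineResult:
    kept: list[TranscriptRecord]
    dropped: list[tuple[TranscriptRecord, str]]
    clusters: list[IsoformCluster]
    registry: ReadRegistry
    support_failed: list[str]
    repeat_flagged: list[str]
    organ_of: dict[str, str | None] = field(default_factory=dict)
    gene_specific: set[str] = field(default_factory=set)
    variant_specific: set[str] = field(default_factory=set)

    def kept_ids(self) -> set[str]:
        return {r.read_id for r in self.kept}


def run_pipeline(long_reads: Sequence[LongRead],
                 short_reads: Sequence[str],
                 chains: Sequence[ExonChain] | str,
                 annotation: AnnotationIndex,
                 genome: Mapping[str, str],
                 repeat_library: Sequence[tuple[str, str]] = (),
                 sample_organ: Mapping[str, str] | None = None,
                 gene_symbols: Mapping[str, str] | None = None,
                 cfg: PipelineConfig = DEFAULT_CONFIG,
                 correct: bool = False) -> PipelineResult:
    """Run the whole curation pipeline.

    ``chains`` may be a list of true exon chains or a path to a SAM file of
    spliced alignments; reads without a chain are treated as unmapped and
    clustered by identity instead.
    """
    registry = ReadRegistry()
    for read in long_reads:
        registry.add(read.read_id, read.sample_id, read.flnc_count)

    graph = build_graph(short_reads, cfg.k, cfg.solidity)
    supported, qc = filter_reads(long_reads, graph, cfg.max_uncovered_frac,
                                 correct=correct,
                                 per_end=cfg.terminal_allowance_per_end)
    support_failed = [rid for rid, _p, ok in qc if not ok]

    scheme = ScoringScheme(cfg.match, cfg.mismatch, cfg.gap_open,
                           cfg.gap_extend)
    kept_reads, flagged = screen_repeats(supported, list(repeat_library),
                                         scheme, cfg.sw_threshold)
    repeat_flagged = [f.read_id for f in flagged]

    if isinstance(chains, str):
        chains = chains_from_sam(chains)
    kept_ids = {r.read_id for r in kept_reads}
    chain_by_read = {c.read_id: c for c in chains if c.read_id in kept_ids}
    seqs = {r.read_id: r.sequence for r in kept_reads}
    lengths = {rid: len(s) for rid, s in seqs.items()}

    mapped = [chain_by_read[rid] for rid in sorted(chain_by_read)]
    clusters = group_and_collapse(mapped, cfg.fuzz_5p, cfg.fuzz_3p,
                                  seq_lengths=lengths, registry=registry,
                                  strand_aware=cfg.strand_aware_loci)
    unmapped = {rid: seqs[rid] for rid in sorted(kept_ids - set(chain_by_read))}
    clusters += collapse_identity(unmapped, cfg.identity_threshold,
                                  cfg.min_cover, cfg.long_cap_len,
                                  cfg.long_cap_nt, scheme, registry=registry)

    records: list[TranscriptRecord] = []
    locus_of: dict[str, str] = {}
    for cluster in clusters:
        rid = cluster.representative_id
        call: StructuralCall | None = None
        if cluster.chain is not None:
            call = classify_chain(cluster.chain, annotation, genome,
                                  cfg.a_window, cfg.a_frac)
            pos = find_polya_signal(seqs[rid], cfg.polya_motifs,
                                    cfg.polya_search_window)
            call.polya_motif = None if pos is None else seqs[rid][pos:pos + 6]
        orf = find_best_orf(seqs[rid], min_nt=cfg.min_orf_nt, read_id=rid)
        entry = registry[rid]
        symbol = None
        if call is not None and call.associated_gene and gene_symbols:
            symbol = gene_symbols.get(call.associated_gene)
        records.append(TranscriptRecord(
            read_id=rid, structural_call=call, orf_call=orf,
            flnc_count=entry.flnc_count,
            contributing_samples=set(entry.contributing_samples),
            locus_id=cluster.locus_id, gene_symbol=symbol))
        locus_of[rid] = cluster.locus_id

    kept, dropped = final_mrna_filter(records, cfg.flnc_low, cfg.flnc_high,
                                      cfg.nnc_all_junctions_canonical)

    result = PipelineResult(kept, dropped, clusters, registry,
                            support_failed, repeat_flagged)
    if sample_organ:
        contributing = {r.read_id: r.contributing_samples for r in kept}
        matrix = PresenceMatrix.from_contributing_samples(contributing,
                                                          dict(sample_organ))
        result.organ_of = organ_specific_transcripts(matrix,
                                                     cfg.organ_min_samples)
        presence = locus_organ_presence(matrix, locus_of)
        result.gene_specific, result.variant_specific = \
            partition_gene_vs_variant(result.organ_of, locus_of, presence)
    return result
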