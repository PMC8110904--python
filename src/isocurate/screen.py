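"""Repeat and contaminant screening of long reads.

A read matching any interspersed-repeat consensus with a Smith-Waterman
score at or above the threshold is removed whole (both orientations of each
library entry are searched). Contaminant screening removes reads for which
a local alignment to a contaminant reference covers enough of the read at
high enough identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .align import LocalAlignment, ScoringScheme, local_align
from .io import LongRead, revcomp


@dataclass
class ScreenResult:
    read_id: str
    best_score: float
    best_library_entry: str | None
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    flagged: bool


def _best_hit(seq: str, library: Sequence[tuple[str, str]],
              scheme: ScoringScheme,
              both_orientations: bool = True,
              ) -> tuple[float, str | None, LocalAlignment | None]:
    best_score, best_entry, best_aln = 0.0, None, None
    for name, entry in library:
        orientations = (entry, revcomp(entry)) if both_orientations else (entry,)
        for oriented in orientations:
            aln = local_align(seq, oriented, scheme)
            if aln.score > best_score:
                best_score, best_entry, best_aln = aln.score, name, aln
    return best_score, best_entry, best_aln


def screen_repeats(reads: Iterable[LongRead],
                   library: Sequence[tuple[str, str]],
                   scheme: ScoringScheme = ScoringScheme(),
                   threshold: float = 225.0,
                   ) -> tuple[list[LongRead], list[ScreenResult]]:
    """Partition reads into (kept, flagged) by best repeat-library score.

    A read is flagged iff its best local-alignment score over all library
    entries (either orientation) reaches the threshold (inclusive). An empty
    library keeps everything.
    """
    kept: list[LongRead] = []
    flagged: list[ScreenResult] = []
    for read in reads:
        score, entry, aln = _best_hit(read.sequence, library, scheme)
        if score >= threshold:
            flagged.append(ScreenResult(
                read.read_id, score, entry,
                aln.query_span if aln else (0, 0),
                aln.target_span if aln else (0, 0), True))
        else:
            kept.append(read)
    return kept, flagged


def screen_contaminants(reads: Iterable[LongRead],
                        contaminant_refs: Sequence[tuple[str, str]],
                        min_identity: float = 0.9,
                        min_cover: float = 0.5,
                        scheme: ScoringScheme = ScoringScheme(),
                        ) -> tuple[list[LongRead], list[ScreenResult]]:
    """Remove reads well-aligned to a contaminant reference.

    A read is removed iff some local alignment to a reference (either
    orientation) covers at least ``min_cover`` of the read length at
    identity at least ``min_identity``.
    """
    if not contaminant_refs:
        raise ValueError("contaminant screen requires at least one reference")
    kept: list[LongRead] = []
    removed: list[ScreenResult] = []
    for read in reads:
        hit: ScreenResult | None = None
        for name, ref in contaminant_refs:
            for oriented in (ref, revcomp(ref)):
                aln = local_align(read.sequence, oriented, scheme)
                if aln.n_columns == 0:
                    continue
                cover = (aln.query_span[1] - aln.query_span[0]) / len(read)
                if cover >= min_cover and aln.identity >= min_identity:
                    hit = ScreenResult(read.read_id, aln.score, name,
                                       aln.query_span, aln.target_span, True)
                    break
            if hit:
                break
        if hit:
            removed.append(hit)
        else:
            kept.append(read)
    return kept, removed
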