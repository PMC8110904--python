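"""Final evidence filter producing the full-length mRNA set.

A transcript is kept iff it has a complete CDS and either (a) it is
classified FSM, NIC, or NNC with all junctions canonical and has the
baseline support of at least 2 FLNCs, or (b) it is in any other structural
category (or unmapped, grouped only by identity clustering) and has at
least 5 supporting FLNCs. Dropped records carry machine-readable reasons.
The multilocus estimate reports the fraction of gene symbols whose kept
transcripts map to two or more distinct loci (a paralog signal in a
genome shaped by whole-genome duplication).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .classify import StructuralCall
from .orf import OrfCall

UNMAPPED = "unmapped"

NO_COMPLETE_CDS = "no_complete_cds"
LOW_FLNC = "low_flnc"
NONCANONICAL_LOW_FLNC = "noncanonical_low_flnc"


@dataclass
class TranscriptRecord:
    read_id: str
    structural_call: StructuralCall | None  # None marks an unmapped read
    orf_call: OrfCall | None
    flnc_count: int
    contributing_samples: set[str] = field(default_factory=set)
    locus_id: str = ""
    gene_symbol: str | None = None
    orf_evaluated: bool = True

    @property
    def category(self) -> str:
        return self.structural_call.category if self.structural_call else UNMAPPED

    @property
    def complete_cds(self) -> bool:
        return self.orf_call is not None and self.orf_call.complete


def _baseline_evidence(record: TranscriptRecord,
                       nnc_all_canonical: bool = True) -> bool:
    """True for the categories that only need the 2-FLNC baseline."""
    call = record.structural_call
    if call is None:
        return False
    if call.category in ("FSM", "NIC"):
        return True
    if call.category == "NNC":
        return call.all_junctions_canonical if nnc_all_canonical else True
    return False


def final_mrna_filter(records: Iterable[TranscriptRecord],
                      flnc_low: int = 2, flnc_high: int = 5,
                      nnc_all_canonical: bool = True,
                      ) -> tuple[list[TranscriptRecord],
                                 list[tuple[TranscriptRecord, str]]]:
    """Partition records into (kept, dropped-with-reason)."""
    kept: list[TranscriptRecord] = []
    dropped: list[tuple[TranscriptRecord, str]] = []
    for record in records:
        if not record.orf_evaluated:
            raise ValueError(f"record {record.read_id!r} lacks an ORF verdict")
        if not record.complete_cds:
            dropped.append((record, NO_COMPLETE_CDS))
            continue
        if _baseline_evidence(record, nnc_all_canonical):
            if record.flnc_count >= flnc_low:
                kept.append(record)
            else:
                dropped.append((record, LOW_FLNC))
        else:
            if record.flnc_count >= flnc_high:
                kept.append(record)
            elif (record.structural_call is not None
                  and record.structural_call.category == "NNC"):
                dropped.append((record, NONCANONICAL_LOW_FLNC))
            else:
                dropped.append((record, LOW_FLNC))
    return kept, dropped


def estimate_multilocus_genes(records: Sequence[TranscriptRecord]) -> float:
    """Fraction of gene symbols whose transcripts occupy >= 2 distinct loci.

    Records without a symbol are excluded; an empty denominator is an error.
    """
    loci_by_symbol: dict[str, set[str]] = {}
    for record in records:
        if record.gene_symbol:
            loci_by_symbol.setdefault(record.gene_symbol, set()) \
                          .add(record.locus_id)
    if not loci_by_symbol:
        raise ValueError("no records carry a gene symbol")
    multi = sum(1 for loci in loci_by_symbol.values() if len(loci) >= 2)
    return multi / len(loci_by_symbol)
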