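"""Categorisation of pairwise transcriptome comparison hits.

A query is an *identical isoform* of a subject when E-value < 1e-50,
percent identity >= 99, and either query coverage per HSP > 99% or
alignment length * 100 / subject length > 99 (one of the two sequences may
still carry the longer UTR, which the subgrouping records). Any other hit
with E-value < 1e-15 is a *significant hit*; everything else — including
queries with no hit at all — is *non-matching*. All inequalities are
applied exactly as printed, strict or non-strict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .config import DEFAULT_CONFIG, PipelineConfig
from .io import HitRecord

IDENTICAL = "identical_isoform"
SIGNIFICANT = "significant_hit"
NON_MATCHING = "non_matching"

SUBJECT_LONGER = "subject_longer"
QUERY_LONGER = "query_longer"
NEAR_EQUAL = "near_equal"
NA = "n/a"


@dataclass
class QueryVerdict:
    query_id: str
    category: str
    best_subject: str | None = None
    utr_subgroup: str = NA


def subject_coverage(hit: HitRecord) -> float:
    return hit.aln_len * 100.0 / hit.slen


def categorize_hit(hit: HitRecord,
                   cfg: PipelineConfig = DEFAULT_CONFIG) -> str:
    if (hit.evalue < cfg.identical_evalue
            and hit.pident >= cfg.identical_pident
            and (hit.qcovhsp > cfg.identical_cov
                 or subject_coverage(hit) > cfg.identical_cov)):
        return IDENTICAL
    if hit.evalue < cfg.significant_evalue:
        return SIGNIFICANT
    return NON_MATCHING


def _utr_subgroup(hit: HitRecord, cfg: PipelineConfig) -> str:
    if hit.qcovhsp < cfg.identical_cov:
        return SUBJECT_LONGER
    if subject_coverage(hit) < cfg.identical_cov:
        return QUERY_LONGER
    return NEAR_EQUAL


def categorize_queries(hits: Iterable[HitRecord],
                       query_ids: Sequence[str],
                       cfg: PipelineConfig = DEFAULT_CONFIG,
                       ) -> dict[str, QueryVerdict]:
    """One verdict per query in ``query_ids`` (hitless queries included).

    A query is identical_isoform if ANY of its hits qualifies (the best such
    hit — lowest E-value, then highest identity — is recorded); otherwise
    significant_hit if any hit passes the significance cutoff; otherwise
    non_matching. Duplicate (query, subject) rows are legal (multiple HSPs).
    """
    best_identical: dict[str, HitRecord] = {}
    best_significant: dict[str, HitRecord] = {}
    universe = set(query_ids)
    for hit in hits:
        if hit.query_id not in universe:
            raise ValueError(f"hit for unknown query {hit.query_id!r}")
        category = categorize_hit(hit, cfg)
        key = (hit.evalue, -hit.pident)
        if category == IDENTICAL:
            cur = best_identical.get(hit.query_id)
            if cur is None or key < (cur.evalue, -cur.pident):
                best_identical[hit.query_id] = hit
        elif category == SIGNIFICANT:
            cur = best_significant.get(hit.query_id)
            if cur is None or key < (cur.evalue, -cur.pident):
                best_significant[hit.query_id] = hit
    verdicts: dict[str, QueryVerdict] = {}
    for query_id in sorted(universe):
        if query_id in best_identical:
            hit = best_identical[query_id]
            verdicts[query_id] = QueryVerdict(
                query_id, IDENTICAL, hit.subject_id, _utr_subgroup(hit, cfg))
        elif query_id in best_significant:
            hit = best_significant[query_id]
            verdicts[query_id] = QueryVerdict(query_id, SIGNIFICANT,
                                              hit.subject_id)
        else:
            verdicts[query_id] = QueryVerdict(query_id, NON_MATCHING)
    return verdicts


def summarize(verdicts: dict[str, QueryVerdict]) -> dict[str, int]:
    counts = {IDENTICAL: 0, SIGNIFICANT: 0, NON_MATCHING: 0,
              SUBJECT_LONGER: 0, QUERY_LONGER: 0, NEAR_EQUAL: 0}
    for verdict in verdicts.values():
        counts[verdict.category] += 1
        if verdict.category == IDENTICAL:
            counts[verdict.utr_subgroup] += 1
    return counts
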