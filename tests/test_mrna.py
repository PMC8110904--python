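"""The category-aware FLNC evidence filter and the multilocus estimate."""

import pytest

from isocurate.classify import StructuralCall
from isocurate.mrna import (LOW_FLNC, NO_COMPLETE_CDS, NONCANONICAL_LOW_FLNC,
                            TranscriptRecord, estimate_multilocus_genes,
                            final_mrna_filter)
from isocurate.orf import OrfCall


def record(category, flnc, cds=True, canonical=True, read_id="r",
           locus="L1", symbol=None):
    call = None
    if category != "unmapped":
        call = StructuralCall(read_id, category,
                              all_junctions_canonical=canonical)
    orf = OrfCall(read_id, 0, 0, 300, True, True) if cds else None
    return TranscriptRecord(read_id, call, orf, flnc, {"s1"}, locus,
                            gene_symbol=symbol)


class TestFinalFilter:
    @pytest.mark.parametrize("category,canonical,flnc,cds,kept", [
        # baseline categories: complete CDS + >= 2 FLNC
        ("FSM", True, 2, True, True),
        ("FSM", True, 1, True, False),
        ("FSM", True, 2, False, False),
        ("NIC", True, 2, True, True),
        ("NIC", True, 4, False, False),
        ("NNC", True, 2, True, True),
        ("NNC", True, 1, True, False),
        # NNC with a non-canonical junction needs the stricter threshold
        ("NNC", False, 3, True, False),
        ("NNC", False, 5, True, True),
        # every other category needs >= 5 FLNC
        ("ISM", True, 4, True, False),
        ("ISM", True, 5, True, True),
        ("genic_intron", True, 5, True, True),
        ("genic_intron", True, 2, True, False),
        ("fusion", True, 5, True, True),
        ("antisense", True, 4, True, False),
        ("intergenic", True, 5, False, False),
        ("unmapped", True, 5, True, True),
        ("unmapped", True, 4, True, False),
    ])
    def test_rule_table(self, category, canonical, flnc, cds, kept):
        rec = record(category, flnc, cds, canonical)
        kept_list, dropped = final_mrna_filter([rec])
        assert bool(kept_list) == kept
        assert len(kept_list) + len(dropped) == 1

    def test_drop_reasons(self):
        cases = {
            NO_COMPLETE_CDS: record("FSM", 9, cds=False),
            LOW_FLNC: record("ISM", 4),
            NONCANONICAL_LOW_FLNC: record("NNC", 3, canonical=False),
        }
        for want, rec in cases.items():
            _kept, dropped = final_mrna_filter([rec])
            assert dropped[0][1] == want

    def test_partition_and_reason_coverage(self):
        records = [record("FSM", 2, read_id="a"),
                   record("ISM", 1, read_id="b"),
                   record("NNC", 2, canonical=False, read_id="c"),
                   record("unmapped", 9, read_id="d")]
        kept, dropped = final_mrna_filter(records)
        assert len(kept) + len(dropped) == len(records)
        assert all(reason for _r, reason in dropped)

    def test_monotone_in_flnc_high(self):
        records = [record("ISM", f, read_id=f"r{f}") for f in range(2, 9)]
        sizes = [len(final_mrna_filter(records, flnc_high=h)[0])
                 for h in (3, 5, 7)]
        assert sizes == sorted(sizes, reverse=True)

    def test_no_kept_record_lacks_complete_cds(self):
        records = [record(c, f, cds=(f % 2 == 0), read_id=f"{c}{f}")
                   for c in ("FSM", "ISM", "NNC") for f in range(1, 8)]
        kept, _ = final_mrna_filter(records)
        assert all(r.complete_cds for r in kept)


class TestMultilocus:
    def test_single_locus_per_symbol(self):
        records = [record("FSM", 2, read_id="a", locus="L1", symbol="g1"),
                   record("FSM", 2, read_id="b", locus="L1", symbol="g1")]
        assert estimate_multilocus_genes(records) == 0.0

    def test_half_multilocus(self):
        records = [record("FSM", 2, read_id="a", locus="L1", symbol="g1"),
                   record("FSM", 2, read_id="b", locus="L2", symbol="g2"),
                   record("FSM", 2, read_id="c", locus="L3", symbol="g2")]
        assert estimate_multilocus_genes(records) == 0.5

    def test_empty_denominator_rejected(self):
        with pytest.raises(ValueError):
            estimate_multilocus_genes([record("FSM", 2)])
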