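"""Strand-specific ORF prediction with selectable genetic codes.

Reads are already oriented 5'->3', so only the three forward frames are
scanned. An ORF runs ATG..in-frame stop (stop included); the single best
call is the longest complete ORF of at least ``min_nt`` nucleotides, ties
broken by the 5'-most start and then the smallest frame. The vertebrate
mitochondrial code differs from the standard one where it matters here:
TGA encodes Trp (never terminates) while AGA and AGG are stops.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from Bio.Data import CodonTable

STANDARD = "standard"
VERTEBRATE_MITOCHONDRIAL = "vertebrate_mitochondrial"
_NCBI_ID = {STANDARD: 1, VERTEBRATE_MITOCHONDRIAL: 2}


@dataclass(frozen=True)
class GeneticCode:
    code_id: str
    stop_codons: frozenset[str]
    start_codons: frozenset[str]
    forward_table: Mapping[str, str]

    @classmethod
    def by_name(cls, code_id: str) -> "GeneticCode":
        if code_id not in _NCBI_ID:
            raise ValueError(f"unknown genetic code {code_id!r}")
        table = CodonTable.unambiguous_dna_by_id[_NCBI_ID[code_id]]
        # ATG-only starts: the conservative common choice for both codes
        return cls(code_id, frozenset(table.stop_codons), frozenset({"ATG"}),
                   dict(table.forward_table))

    def is_stop(self, codon: str) -> bool:
        # codons containing N translate to unknown and terminate no ORF
        return codon in self.stop_codons

    def is_start(self, codon: str) -> bool:
        return codon in self.start_codons

    def translate(self, codon: str) -> str:
        if codon in self.stop_codons:
            return "*"
        return self.forward_table.get(codon, "X")


@dataclass
class OrfCall:
    read_id: str
    frame: int
    start: int
    end: int  # half-open on the read; includes the stop codon when present
    has_start: bool
    has_stop: bool

    @property
    def nt_length(self) -> int:
        return self.end - self.start

    @property
    def complete(self) -> bool:
        return self.has_start and self.has_stop


def find_best_orf(seq: str, code: GeneticCode | str = STANDARD,
                  min_nt: int = 150, read_id: str = "") -> OrfCall | None:
    """Best complete ORF over the three forward frames, or None.

    "Best" is the longest complete ORF with nt_length >= min_nt; ties go to
    the 5'-most start, then the smallest frame index.
    """
    if isinstance(code, str):
        code = GeneticCode.by_name(code)
    seq = seq.upper().replace("U", "T")
    best: OrfCall | None = None
    for frame in range(3):
        open_start: int | None = None  # 5'-most unclosed ATG in this frame
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos:pos + 3]
            if open_start is None and code.is_start(codon):
                open_start = pos
            elif open_start is not None and code.is_stop(codon):
                call = OrfCall(read_id, frame, open_start, pos + 3,
                               has_start=True, has_stop=True)
                if call.nt_length >= min_nt and (
                        best is None
                        or call.nt_length > best.nt_length
                        or (call.nt_length == best.nt_length
                            and (call.start, call.frame)
                            < (best.start, best.frame))):
                    best = call
                open_start = None
    return best


def translate_orf(seq: str, call: OrfCall,
                  code: GeneticCode | str = STANDARD) -> str:
    if isinstance(code, str):
        code = GeneticCode.by_name(code)
    sub = seq[call.start:call.end]
    aa = [code.translate(sub[i:i + 3]) for i in range(0, len(sub) - 2, 3)]
    return "".join(aa).rstrip("*")


def compare_orf_lengths(before: Mapping[str, OrfCall | None],
                        after: Mapping[str, OrfCall | None],
                        ) -> dict[str, int]:
    """Per-id comparison of ORF lengths (absent calls count as length 0).

    Returns counts {"longer", "same", "shorter"} over the shared id
    universe; mismatched universes are an error.
    """
    if set(before) != set(after):
        raise ValueError("before/after id universes differ")
    counts = {"longer": 0, "same": 0, "shorter": 0}
    for read_id in before:
        b = before[read_id].nt_length if before[read_id] else 0
        a = after[read_id].nt_length if after[read_id] else 0
        if a > b:
            counts["longer"] += 1
        elif a < b:
            counts["shorter"] += 1
        else:
            counts["same"] += 1
    return counts
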