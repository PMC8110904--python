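"""Sequence I/O, the read registry, hit-table parsing and the annotation table.

Sequences flow through Bio.SeqIO; the registry tracks, for every high-quality
long read, its sample of origin and the number of full-length non-concatemer
(FLNC) molecules that support it, so that provenance survives every collapse
step downstream.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

from Bio import SeqIO

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class LongRead:
    """An error-corrected high-quality long read.

    ``flnc_count`` is the number of FLNC molecules supporting the read's
    cluster consensus; high-quality reads require at least two.
    """

    read_id: str
    sequence: str
    sample_id: str = ""
    flnc_count: int = 2

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r} has an empty sequence")
        if self.flnc_count < 1:
            raise ValueError(f"read {self.read_id!r}: flnc_count must be positive")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class RegistryEntry:
    sample_id: str
    flnc_count: int
    contributing_samples: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.contributing_samples:
            self.contributing_samples = {self.sample_id}


class ReadRegistry:
    """read_id -> (sample of origin, FLNC support, contributing samples).

    After a collapse, a representative's entry absorbs its members: FLNC
    counts add, contributing sample sets union. Total FLNC over the registry
    is invariant under any sequence of merges.
    """

    def __init__(self) -> None:
        self._entries: dict[str, RegistryEntry] = {}

    def add(self, read_id: str, sample_id: str, flnc_count: int) -> None:
        if read_id in self._entries:
            raise ValueError(f"duplicate read id in registry: {read_id!r}")
        self._entries[read_id] = RegistryEntry(sample_id, flnc_count)

    def __contains__(self, read_id: str) -> bool:
        return read_id in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __getitem__(self, read_id: str) -> RegistryEntry:
        return self._entries[read_id]

    def ids(self) -> list[str]:
        return sorted(self._entries)

    def merge(self, representative: str, members: Iterable[str]) -> None:
        """Fold ``members`` into ``representative`` (sum counts, union samples)."""
        rep = self._entries[representative]
        for member in members:
            if member == representative:
                continue
            entry = self._entries.pop(member)
            rep.flnc_count += entry.flnc_count
            rep.contributing_samples |= entry.contributing_samples

    def total_flnc(self) -> int:
        return sum(e.flnc_count for e in self._entries.values())

    def write_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tsample_id\tflnc_count\tcontributing_samples\n")
            for read_id in sorted(self._entries):
                e = self._entries[read_id]
                samples = ",".join(sorted(e.contributing_samples))
                fh.write(f"{read_id}\t{e.sample_id}\t{e.flnc_count}\t{samples}\n")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "ReadRegistry":
        reg = cls()
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("read_id"):
                raise ValueError(f"{path}: missing registry header")
            for line in fh:
                read_id, sample_id, flnc, samples = line.rstrip("\n").split("\t")
                reg.add(read_id, sample_id, int(flnc))
                reg._entries[read_id].contributing_samples = set(samples.split(","))
        return reg


def _normalise(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_sequences(path: str | os.PathLike | IO, format: str = "fasta",
                   ) -> Iterator[tuple[str, str, list[int] | None]]:
    """Stream ``(id, sequence, qualities)`` records from a FASTA/FASTQ file.

    Sequences are upper-cased and U is mapped to T. Duplicate record ids are
    an error; an empty file yields an empty stream.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format: {format!r}")
    seen: set[str] = set()
    for n, record in enumerate(SeqIO.parse(path, format), start=1):
        if record.id in seen:
            raise ValueError(f"duplicate sequence id {record.id!r} (record {n})")
        seen.add(record.id)
        quals = record.letter_annotations.get("phred_quality")
        yield record.id, _normalise(str(record.seq)), quals


def write_fasta(path: str | os.PathLike, records: Iterable[tuple[str, str]],
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


@dataclass
class HitRecord:
    """One row of a tabular pairwise hit table (outfmt "6 std qcovhsp slen")."""

    query_id: str
    subject_id: str
    pident: float
    aln_len: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    qcovhsp: float
    slen: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.pident <= 100.0 and 0.0 <= self.qcovhsp <= 100.0):
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: "
                             "pident/qcovhsp must be percentages")
        if self.aln_len <= 0 or self.slen <= 0:
            raise ValueError("alignment and subject lengths must be positive")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")


_HIT_COLUMNS = 14


def parse_hit_table(path: str | os.PathLike | IO) -> Iterator[HitRecord]:
    """Parse a 14-column hit table: the 12 standard fields + qcovhsp + slen."""
    fh = open(path) if isinstance(path, (str, os.PathLike)) else path
    try:
        for n, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != _HIT_COLUMNS:
                raise ValueError(
                    f"row {n}: expected {_HIT_COLUMNS} columns, got {len(parts)}")
            yield HitRecord(
                query_id=parts[0], subject_id=parts[1],
                pident=float(parts[2]), aln_len=int(parts[3]),
                mismatches=int(parts[4]), gap_opens=int(parts[5]),
                qstart=int(parts[6]), qend=int(parts[7]),
                sstart=int(parts[8]), send=int(parts[9]),
                evalue=float(parts[10]), bitscore=float(parts[11]),
                qcovhsp=float(parts[12]), slen=int(parts[13]))
    finally:
        if isinstance(path, (str, os.PathLike)):
            fh.close()


ANNOTATION_COLUMNS = (
    "read_id", "category", "associated_gene", "associated_transcript",
    "n_exons", "all_junctions_canonical", "downstream_a_fraction",
    "intrapriming_flag", "polya_motif", "orf_start", "orf_end", "orf_nt_length",
    "complete_cds", "flnc_count", "contributing_samples", "locus_id",
)

_MANDATORY = ("read_id", "category", "flnc_count", "contributing_samples")


def write_annotation_table(path: str | os.PathLike, records: Iterable[dict]) -> None:
    """Write the final per-transcript annotation TSV (one row per transcript,
    sorted by read id; reruns on identical input are byte-identical)."""
    rows = []
    for rec in records:
        for key in _MANDATORY:
            if rec.get(key) in (None, ""):
                raise ValueError(
                    f"record {rec.get('read_id', '<unknown>')!r} lacks "
                    f"mandatory field {key!r}")
        samples = rec["contributing_samples"]
        if not isinstance(samples, str):
            samples = ",".join(sorted(samples))
        row = dict(rec, contributing_samples=samples)
        rows.append(tuple(str(row.get(c, "")) for c in ANNOTATION_COLUMNS))
    rows.sort(key=lambda r: r[0])
    with open(path, "w") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
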