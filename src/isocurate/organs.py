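"""Organ-specific expression detection.

Presence of a transcript in a sample is the only expression signal the
pipeline carries (the sample contributed at least one FLNC to the
transcript's cluster). A transcript is organ-specific when it is present in
at least ``min_samples`` samples of one organ and absent from every sample
of every other organ; organ-specific transcripts split into gene-level
specificity (no transcript of the locus is seen in another organ) and
splice-variant-level specificity (the locus has isoforms elsewhere).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd


@dataclass
class PresenceMatrix:
    """transcripts x samples boolean presence plus the sample -> organ map."""

    presence: pd.DataFrame  # bool, index = transcript ids, columns = samples
    sample_organ: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = set(self.presence.columns) - set(self.sample_organ)
        if missing:
            raise ValueError(f"samples without an organ: {sorted(missing)}")
        self.presence = self.presence.astype(bool)

    @classmethod
    def from_contributing_samples(
            cls, contributing: Mapping[str, set[str]],
            sample_organ: Mapping[str, str]) -> "PresenceMatrix":
        samples = sorted(sample_organ)
        data = {tx: [s in members for s in samples]
                for tx, members in contributing.items()}
        frame = pd.DataFrame.from_dict(data, orient="index", columns=samples)
        return cls(frame.sort_index(), sample_organ)

    @property
    def organs(self) -> list[str]:
        return sorted(set(self.sample_organ.values()))

    def organ_samples(self, organ: str) -> list[str]:
        return [s for s in self.presence.columns
                if self.sample_organ[s] == organ]


def organ_specific_transcripts(matrix: PresenceMatrix,
                               min_samples: int = 3,
                               ) -> dict[str, str | None]:
    """Assign each transcript its specific organ, or None.

    Transcript -> organ O iff present in >= min_samples samples of O and in
    zero samples of every other organ.
    """
    organs = matrix.organs
    if len(organs) < 2:
        raise ValueError("organ specificity needs at least two organs")
    counts = {o: matrix.presence[matrix.organ_samples(o)].sum(axis=1)
              for o in organs}
    result: dict[str, str | None] = {}
    for tx in matrix.presence.index:
        assigned = None
        for organ in organs:
            if counts[organ][tx] >= min_samples and all(
                    counts[other][tx] == 0
                    for other in organs if other != organ):
                assigned = organ
                break
        result[tx] = assigned
    return result


def locus_organ_presence(matrix: PresenceMatrix,
                         locus_of: Mapping[str, str]) -> dict[str, set[str]]:
    """locus -> set of organs where ANY of its transcripts is present."""
    out: dict[str, set[str]] = {}
    for tx in matrix.presence.index:
        locus = locus_of[tx]
        present = matrix.presence.loc[tx]
        organs = {matrix.sample_organ[s]
                  for s in matrix.presence.columns if present[s]}
        out.setdefault(locus, set()).update(organs)
    return out


def partition_gene_vs_variant(specific: Mapping[str, str | None],
                              locus_of: Mapping[str, str],
                              locus_presence: Mapping[str, set[str]],
                              ) -> tuple[set[str], set[str]]:
    """Split organ-specific transcripts into (gene_specific, variant_specific).

    A specific transcript is gene-level specific iff its locus is not
    detected in any other organ; otherwise it is a specific splice variant
    of a more broadly expressed locus. The two sets partition the specific
    transcripts.
    """
    gene_specific: set[str] = set()
    variant_specific: set[str] = set()
    for tx, organ in specific.items():
        if organ is None:
            continue
        other = locus_presence[locus_of[tx]] - {organ}
        (gene_specific if not other else variant_specific).add(tx)
    return gene_specific, variant_specific
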