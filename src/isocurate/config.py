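"""Pipeline configuration.

Every numeric threshold used anywhere in the pipeline lives here, with the
defaults the pipeline was designed around: a 21-mer de Bruijn graph at
solidity 3, a 99% coverage requirement for hybrid support, a Smith-Waterman
repeat score threshold of 225, cdna_Cupcake-style collapse fuzz of 10 kb /
1 kb, CD-Hit-style 0.99 identity with a 30 bp uncovered cap for members
longer than 3 kb, a 150 nt minimum ORF, the 2/5 FLNC evidence thresholds,
and the BLAST comparison thresholds (1e-50 / 99% / 99% and 1e-15).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


@dataclass
class PipelineConfig:
    # hybrid k-mer support
    k: int = 21
    solidity: int = 3
    max_uncovered_frac: float = 0.01
    terminal_allowance_per_end: bool = False  # combined terminal allowance by default

    # repeat / contaminant screening
    sw_threshold: float = 225.0
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    contaminant_min_identity: float = 0.9
    contaminant_min_cover: float = 0.5

    # locus grouping and collapse
    fuzz_5p: int = 10_000
    fuzz_3p: int = 1_000
    identity_threshold: float = 0.99
    min_cover: float = 0.99
    long_cap_len: int = 3_000
    long_cap_nt: int = 30
    strand_aware_loci: bool = True

    # ORF prediction
    min_orf_nt: int = 150
    orf_include_stop: bool = True

    # final mRNA evidence filter
    flnc_low: int = 2
    flnc_high: int = 5
    nnc_all_junctions_canonical: bool = True

    # transcriptome comparison
    identical_evalue: float = 1e-50
    identical_pident: float = 99.0
    identical_cov: float = 99.0
    significant_evalue: float = 1e-15

    # intrapriming / polyA
    a_window: int = 20
    a_frac: float = 0.80
    polya_motifs: tuple[str, ...] = ("AATAAA", "ATTAAA")
    polya_search_window: int = 50

    # organ specificity
    organ_min_samples: int = 3

    def __post_init__(self) -> None:
        if self.k < 3 or self.k % 2 == 0:
            raise ValueError(f"k must be odd and >= 3, got {self.k}")
        if not (0 < self.max_uncovered_frac < 1):
            raise ValueError("max_uncovered_frac must be in (0, 1)")
        for name in ("solidity", "sw_threshold", "fuzz_5p", "fuzz_3p",
                     "identity_threshold", "long_cap_nt", "long_cap_len",
                     "min_orf_nt", "flnc_low", "flnc_high",
                     "identical_evalue", "identical_pident", "identical_cov",
                     "significant_evalue", "a_window", "a_frac",
                     "organ_min_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_key_values(cls, pairs: dict[str, str]) -> "PipelineConfig":
        """Build a config from CLI-style ``key=value`` string pairs."""
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, raw in pairs.items():
            if key not in fields:
                raise KeyError(f"unknown configuration key: {key!r}")
            typ = fields[key].type
            if typ in ("int", int):
                kwargs[key] = int(raw)
            elif typ in ("float", float):
                kwargs[key] = float(raw)
            elif typ in ("bool", bool):
                kwargs[key] = raw.lower() in ("1", "true", "yes", "on")
            elif "tuple" in str(typ):
                kwargs[key] = tuple(x for x in raw.split(",") if x)
            else:
                kwargs[key] = raw
        return cls(**kwargs)


DEFAULT_CONFIG = PipelineConfig()
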