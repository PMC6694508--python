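"""Configuration for the allopolyploid small-RNA simulation."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: Illumina TruSeq small-RNA 3' adapter, the field-standard default.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclass
class SimulationConfig:
    """Parameters of the synthetic triploid-hybrid study design.

    The defaults describe one hybridization experiment: two parental genomes
    that share the A subgenome through recent common ancestry (An in parent 1,
    Ar in parent 2, separated by ``parental_divergence`` substitutions per
    site), a C subgenome private to parent 1, and a triploid F1 carrying
    An + Ar + Cn.  miRNA loci are planted with hairpin-forming precursors and
    protein-coding neighbours; sequencing libraries (3 samples x
    ``n_replicates``) draw negative-binomial expression with a configurable
    non-additive fraction, read-length mode at 24 nt, adapter read-through
    and structural ncRNA contamination.
    """

    seed: int = 0
    n_chrom_per_subgenome: int = 3
    chrom_length: int = 100_000
    n_mirna_loci: int = 50
    n_coding_genes_per_chrom: int = 40
    mature_len_range: tuple[int, int] = (20, 24)
    conserved_fraction: float = 0.8
    parental_divergence: float = 0.02
    f1_loss_fraction: float = 0.1
    f1_gain_count: int = 3
    nonadditive_fraction: float = 0.3
    nonadditive_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    mean_depth: int = 100_000
    error_rate: float = 0.001
    adapter_seq: str = DEFAULT_ADAPTER
    adapter_fraction: float = 1.0
    contaminant_fraction: float = 0.1
    background_24nt_fraction: float = 0.4
    n_replicates: int = 3
    gene_length: int = 600

    def __post_init__(self) -> None:
        self.mature_len_range = tuple(self.mature_len_range)  # type: ignore[assignment]
        for name in (
            "conserved_fraction",
            "parental_divergence",
            "f1_loss_fraction",
            "nonadditive_fraction",
            "error_rate",
            "adapter_fraction",
            "contaminant_fraction",
            "background_24nt_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        lo, hi = self.mature_len_range
        if not (18 <= lo <= hi <= 26):
            raise ValueError(f"mature_len_range {self.mature_len_range} must lie within [18, 26]")
        if self.chrom_length <= 0:
            raise ValueError("chrom_length must be positive")
        for name in ("n_chrom_per_subgenome", "n_mirna_loci", "n_coding_genes_per_chrom",
                     "mean_depth", "n_replicates", "gene_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.f1_gain_count < 0:
            raise ValueError("f1_gain_count must be non-negative")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if self.contaminant_fraction + self.background_24nt_fraction >= 1.0:
            raise ValueError("contaminant and background fractions must sum to < 1")
        if not self.adapter_seq or set(self.adapter_seq.upper()) - set("ACGT"):
            raise ValueError("adapter_seq must be a non-empty ACGT string")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["mature_len_range"] = list(self.mature_len_range)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
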