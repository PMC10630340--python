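"""Run-wide configuration: every threshold the pipeline applies, in one place.

The defaults reproduce the published workflow: exons shorter than 300 bp are
discarded, an exon with a second genomic hit above 50% identity and 30%
coverage is not single copy, orthologs must exceed 300 bp without internal
stops, alignment rows with >60% N/gaps or <30% average similarity to the rest
are culled, candidate alignments need two terminal 8-aa blocks above 50%
similarity, must exceed 300 bp after trimming and must not exceed 90% overall
identity, primer blocks are 7 or 8 aa, outer primers are sought within 450 bp
of the inner pair, and the total score weights PCR performance against locus
informativeness with PIs = 1.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass
class PipelineConfig:
    # --- module 1: exon catalogue ---
    min_exon_len_nt: int = 300
    single_copy_max_identity: float = 0.50   # fraction; second hit above BOTH -> multi-copy
    single_copy_max_coverage: float = 0.30

    # --- module 1: orthology ---
    min_ortholog_len_nt: int = 300           # strict: length must exceed this
    min_ingroup_taxa: int = 1

    # --- module 1: alignment filtering / candidate selection ---
    max_missing_fraction: float = 0.60       # row dropped if N+gap fraction strictly greater
    min_avg_similarity: float = 0.30         # row dropped while mean identity strictly lower
    terminal_block_len_aa: int = 8
    block_min_similarity: float = 0.50       # blocks need similarity strictly greater
    min_candidate_len_nt: int = 300          # trimmed alignment must be strictly longer
    max_msa_similarity: float = 0.90         # alignment dropped if mean nt identity strictly greater

    # --- module 2: primer design ---
    block_len_set_aa: tuple[int, ...] = (7, 8)
    outer_flank_nt: int = 450
    pis: float = 1.0
    max_primer_degeneracy: int = 8192
    inner_product_len_range_nt: tuple[int, int] = (300, 1200)

    # ScorePCR components (conservation / degeneracy / complexity weights and
    # the complexity penalties; the p-distance cap normalises ScoreINFOR)
    score_w_conservation: float = 1.0
    score_w_degeneracy: float = 1.0
    score_w_complexity: float = 1.0
    homopolymer_min_run: int = 5
    homopolymer_penalty: float = 0.25
    gc_range: tuple[float, float] = (0.30, 0.70)
    gc_penalty: float = 0.25
    three_prime_window_nt: int = 3
    three_prime_max_degeneracy: int = 2
    three_prime_penalty: float = 0.5
    p_distance_cap: float = 0.5

    # --- search backend ---
    nt_match_score: int = 2
    nt_mismatch_score: int = -3
    nt_open_gap_score: int = -7
    nt_extend_gap_score: int = -2
    prot_open_gap_score: int = -12
    prot_extend_gap_score: int = -1
    nt_min_hit_score: float = 60.0
    prot_min_hit_score: float = 40.0
    nt_kmer_size: int = 11
    prot_kmer_size: int = 5
    max_hits_per_subject: int = 4
    fallback_min_coverage: float = 0.5

    # --- misc ---
    genetic_code_table: int = 1
    random_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        fractions = {
            "single_copy_max_identity": self.single_copy_max_identity,
            "single_copy_max_coverage": self.single_copy_max_coverage,
            "max_missing_fraction": self.max_missing_fraction,
            "min_avg_similarity": self.min_avg_similarity,
            "block_min_similarity": self.block_min_similarity,
            "max_msa_similarity": self.max_msa_similarity,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        lengths = {
            "min_exon_len_nt": self.min_exon_len_nt,
            "min_ortholog_len_nt": self.min_ortholog_len_nt,
            "min_candidate_len_nt": self.min_candidate_len_nt,
            "terminal_block_len_aa": self.terminal_block_len_aa,
            "outer_flank_nt": self.outer_flank_nt,
            "max_primer_degeneracy": self.max_primer_degeneracy,
        }
        for name, value in lengths.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.pis < 0:
            raise ValueError(f"PIs must be >= 0, got {self.pis}")
        lo, hi = self.inner_product_len_range_nt
        if not (0 < lo <= hi):
            raise ValueError(
                f"inner_product_len_range_nt must be 0 < lo <= hi, got {(lo, hi)}"
            )
        if any(n <= 0 for n in self.block_len_set_aa):
            raise ValueError("block_len_set_aa entries must be positive")

    # --- serialisation -----------------------------------------------------

    def as_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for key, value in d.items():
            if isinstance(value, tuple):
                d[key] = list(value)
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        kwargs: dict[str, Any] = {}
        for key, value in data.items():
            if key not in known:
                raise ValueError(f"unknown configuration key: {key}")
            if isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a flat key-value YAML document; absent keys keep defaults."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must be a flat mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        """Echo the effective configuration (auditable run)."""
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def replace(self, **kwargs: Any) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)
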