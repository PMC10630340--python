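"""Ortholog harvest by mutual-best-hit search and orthologous-group assembly.

For every reference exon the exon's protein is searched against each ingroup
genome (or outgroup CDS set) in translated mode; the best hit region is
extracted, strand-resolved and frame-trimmed, and kept only if the region's
best hit back against the reference exon set is the exon it came from.
Surviving orthologs longer than 300 bp and free of internal stops are pooled
per exon into orthologous groups carrying both DNA and protein sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

from .config import PipelineConfig
from .exons import FramedExon
from .io import SeqRecord, translate
from .search import SearchParams, mutual_best_hit

logger = logging.getLogger(__name__)

Role = Literal["ingroup", "outgroup", "reference"]


@dataclass
class OrthologSeq:
    taxon: str
    role: Role
    dna: str
    protein: str
    ref_exon_id: str
    source_id: str | None = None
    source_interval: tuple[int, int] | None = None
    strand: str = "+"


@dataclass
class OrthologGroup:
    ref_exon_id: str
    members: list[OrthologSeq]

    @property
    def n_ingroup(self) -> int:
        return sum(1 for m in self.members if m.role == "ingroup")

    @property
    def n_outgroup(self) -> int:
        return sum(1 for m in self.members if m.role == "outgroup")

    def __post_init__(self) -> None:
        taxa = [m.taxon for m in self.members]
        if len(set(taxa)) != len(taxa):
            raise ValueError(f"{self.ref_exon_id}: duplicate taxa in OG")
        n_ref = sum(1 for m in self.members if m.role == "reference")
        if n_ref != 1:
            raise ValueError(f"{self.ref_exon_id}: OG needs exactly one reference member")


def extract_orthologs(
    framed_exons: Sequence[FramedExon],
    taxon: str,
    taxon_seqs: Sequence[SeqRecord],
    role: Role,
    config: PipelineConfig,
) -> list[OrthologSeq]:
    """Mutual-best-hit orthologs of the reference exons in one taxon.

    The forward search runs the exon proteins against the taxon's genome or
    CDS set (six-frame translated); the extracted hit region must point back
    to its source exon to be accepted.  Hit regions come back on codon
    boundaries of the matched frame, so downstream codon alignment is safe.
    """
    if not framed_exons or not taxon_seqs:
        return []
    params = SearchParams.from_config(config)
    protein_queries = [SeqRecord(id=e.exon_id, seq=e.protein) for e in framed_exons]
    pairs = mutual_best_hit(
        protein_queries, taxon_seqs, protein_queries, "prot_vs_dna", params
    )
    out: list[OrthologSeq] = []
    for exon_id, region in pairs:
        dna = region.seq[: len(region.seq) - len(region.seq) % 3]
        protein = translate(dna, config.genetic_code_table)
        out.append(
            OrthologSeq(
                taxon=taxon,
                role=role,
                dna=dna,
                protein=protein,
                ref_exon_id=exon_id,
                source_id=region.subject_id,
                source_interval=region.interval,
                strand=region.strand,
            )
        )
    return out


def filter_orthologs(
    seqs: Sequence[OrthologSeq],
    min_ortholog_len_nt: int,
    genetic_code_table: int = 1,
) -> list[OrthologSeq]:
    """Keep orthologs strictly longer than the cutoff and free of stops.

    Sequences are trimmed at the 3' end to a codon boundary before testing;
    a terminal stop codon is trimmed off rather than counted as internal.
    """
    out: list[OrthologSeq] = []
    for s in seqs:
        dna = s.dna[: len(s.dna) - len(s.dna) % 3]
        protein = translate(dna, genetic_code_table)
        if protein.endswith("*"):
            dna = dna[:-3]
            protein = protein[:-1]
        if "*" in protein:
            continue
        if len(dna) <= min_ortholog_len_nt:
            continue
        if dna != s.dna:
            s = OrthologSeq(
                taxon=s.taxon, role=s.role, dna=dna, protein=protein,
                ref_exon_id=s.ref_exon_id, source_id=s.source_id,
                source_interval=s.source_interval, strand=s.strand,
            )
        out.append(s)
    return out


def build_ogs(
    framed_exons: Sequence[FramedExon],
    all_orthologs: Sequence[OrthologSeq],
    config: PipelineConfig,
    reference_taxon: str = "reference",
) -> list[OrthologGroup]:
    """One orthologous group per exon with enough ingroup support.

    The reference exon is always a member; groups lacking the configured
    minimum number of ingroup orthologs are not emitted.
    """
    by_exon: dict[str, list[OrthologSeq]] = {}
    for o in all_orthologs:
        by_exon.setdefault(o.ref_exon_id, []).append(o)
    ogs: list[OrthologGroup] = []
    for exon in framed_exons:
        members = [
            OrthologSeq(
                taxon=reference_taxon,
                role="reference",
                dna=exon.dna,
                protein=exon.protein,
                ref_exon_id=exon.exon_id,
            )
        ]
        members.extend(by_exon.get(exon.exon_id, []))
        og = OrthologGroup(ref_exon_id=exon.exon_id, members=members)
        if og.n_ingroup >= config.min_ingroup_taxa:
            ogs.append(og)
    return ogs
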