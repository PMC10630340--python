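"""Reference exon catalogue: frame trimming, length filter, single-copy filter.

The reference species contributes the loci everything downstream hangs on:
each exome entry is trimmed to its correct reading frame using the proteome
as a guide (translated search), short exons are discarded, and exons with a
second genomic hit above 50% identity and 30% query coverage are rejected as
multi-copy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .config import PipelineConfig
from .io import SeqRecord, reverse_complement, translate
from .search import SearchHit, SearchParams, search

logger = logging.getLogger(__name__)


@dataclass
class FramedExon:
    """A reference exon trimmed to the correct reading frame."""

    exon_id: str
    dna: str                 # in-frame, length divisible by 3
    protein: str             # translation, no internal stop
    source_id: str           # exome record id
    source_interval: tuple[int, int]   # interval within the exome record
    strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.dna) % 3 != 0:
            raise ValueError(f"{self.exon_id}: dna length not divisible by 3")


def frame_trim_exons(
    exome: Sequence[SeqRecord],
    proteome: Sequence[SeqRecord],
    config: PipelineConfig,
) -> list[FramedExon]:
    """Trim each exon to the in-frame interval of its best proteome hit.

    Exons without a qualifying translated hit, or whose trimmed translation
    still contains an internal stop, are dropped.
    """
    if not proteome:
        raise ValueError("empty proteome: frame trimming needs a protein guide")
    if not exome:
        return []
    params = SearchParams.from_config(config)
    hits = search(exome, proteome, "dna_vs_prot", params)
    best: dict[str, SearchHit] = {}
    for h in hits:
        if h.rank == 1:
            best[h.query_id] = h
    out: list[FramedExon] = []
    for exon in exome:
        hit = best.get(exon.id)
        if hit is None:
            continue
        start, end = hit.query_interval
        dna = exon.seq[start:end]
        strand = "+"
        if hit.frame is not None and hit.frame < 0:
            dna = reverse_complement(dna)
            strand = "-"
        protein = translate(dna, config.genetic_code_table)
        if "*" in protein:
            continue
        out.append(
            FramedExon(
                exon_id=exon.id,
                dna=dna,
                protein=protein,
                source_id=exon.id,
                source_interval=(start, end),
                strand=strand,
            )
        )
    return out


def filter_long_exons(exons: Sequence[FramedExon], min_exon_len_nt: int) -> list[FramedExon]:
    """Discard exons shorter than the minimum length (default 300 bp kept)."""
    return [e for e in exons if len(e.dna) >= min_exon_len_nt]


def filter_single_copy(
    exons: Sequence[FramedExon],
    genome: Sequence[SeqRecord],
    config: PipelineConfig,
) -> list[FramedExon]:
    """Keep exons with no similar second copy in the reference genome.

    The rank-1 genomic hit is taken to be the exon's own locus; an exon is
    rejected if any further hit exceeds both the identity and the coverage
    thresholds.  An exon with no genomic hit at all suggests an input
    mismatch: it is warned about and excluded.
    """
    if not exons:
        return []
    params = SearchParams.from_config(config)
    queries = [SeqRecord(id=e.exon_id, seq=e.dna) for e in exons]
    hits = search(queries, genome, "nt_nt", params)
    by_query: dict[str, list[SearchHit]] = {e.exon_id: [] for e in exons}
    for h in hits:
        by_query[h.query_id].append(h)
    out: list[FramedExon] = []
    for exon in exons:
        exon_hits = sorted(by_query[exon.exon_id], key=lambda h: h.rank)
        if not exon_hits:
            logger.warning(
                "exon %s has no hit against its own source genome; excluded",
                exon.exon_id,
            )
            continue
        multi_copy = any(
            h.percent_identity / 100.0 > config.single_copy_max_identity
            and h.query_coverage > config.single_copy_max_coverage
            for h in exon_hits[1:]
        )
        if not multi_copy:
            out.append(exon)
    return out


def build_exon_catalog(
    exome: Sequence[SeqRecord],
    proteome: Sequence[SeqRecord],
    genome: Sequence[SeqRecord],
    config: PipelineConfig,
) -> tuple[list[FramedExon], dict[str, int]]:
    """Full step: frame trim, length filter, single-copy filter.

    Returns the surviving exons and the per-stage counts for the manifest.
    """
    framed = frame_trim_exons(exome, proteome, config)
    long_exons = filter_long_exons(framed, config.min_exon_len_nt)
    single_copy = filter_single_copy(long_exons, genome, config)
    counts = {
        "exons_in": len(exome),
        "exons_framed": len(framed),
        "exons_long": len(long_exons),
        "exons_single_copy": len(single_copy),
    }
    return single_copy, counts
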