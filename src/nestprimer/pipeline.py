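"""End-to-end orchestration: exon catalogue -> orthology -> MSAs -> primers.

Every stage writes its outputs under the run directory and contributes a
count to the run manifest; each locus that falls out of the pipeline is
recorded with a machine-readable reason, so a run can be audited (and, on
synthetic data, compared against the planted truth) locus by locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path


from . import __version__
from .config import PipelineConfig
from .exons import filter_long_exons, filter_single_copy, frame_trim_exons
from .io import SeqRecord, write_fasta
from .msa import (
    CandidateMsa,
    MsaDiscarded,
    MsaRejection,
    align_proteins,
    back_translate_alignment,
    drop_dissimilar_sequences,
    drop_gappy_sequences,
    select_candidate_msa,
    trim_to_reference,
)
from .orthology import build_ogs, extract_orthologs, filter_orthologs
from .primers import design_primers_for_candidate, emit_outputs
from .fixtures import Fixture

logger = logging.getLogger(__name__)

# manifest count keys in filter-chain order
MANIFEST_CHAIN = [
    "exons_in",
    "exons_framed",
    "exons_long",
    "exons_single_copy",
    "ogs_built",
    "msas_aligned",
    "msas_filtered",
    "candidate_msas",
    "loci_with_primers",
]


@dataclass
class PipelineInputs:
    reference_exome: list[SeqRecord]
    reference_proteome: list[SeqRecord]
    reference_genome: list[SeqRecord]
    ingroups: dict[str, list[SeqRecord]]        # taxon -> genome records
    outgroups: dict[str, list[SeqRecord]]       # taxon -> CDS records

    @classmethod
    def from_fixture(cls, fixture: Fixture) -> "PipelineInputs":
        return cls(
            reference_exome=fixture.exome,
            reference_proteome=fixture.proteome,
            reference_genome=fixture.genome,
            ingroups=fixture.ingroups,
            outgroups=fixture.outgroups,
        )


@dataclass
class RunManifest:
    config: PipelineConfig
    counts: dict[str, int]
    locus_fates: dict[str, str]     # locus -> primer_emitted | drop reason
    version: str = __version__
    seed: int = 0

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("key\tvalue\n")
            fh.write(f"version\t{self.version}\n")
            fh.write(f"seed\t{self.seed}\n")
            for key in MANIFEST_CHAIN:
                fh.write(f"{key}\t{self.counts.get(key, 0)}\n")


def run_pipeline(
    config: PipelineConfig,
    inputs: PipelineInputs,
    outdir: str | Path,
) -> RunManifest:
    """Run both modules and write all outputs under ``outdir``.

    Returns the manifest; a run that designs zero primer sets is still a
    successful run (with a warning).
    """
    if not inputs.ingroups:
        raise ValueError("at least one ingroup genome is required")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config_echo.yaml")
    counts: dict[str, int] = {}
    fates: dict[str, str] = {}
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    # --- module 1, step 1: exon catalogue ---
    framed = frame_trim_exons(inputs.reference_exome, inputs.reference_proteome, config)
    long_exons = filter_long_exons(framed, config.min_exon_len_nt)
    exons = filter_single_copy(long_exons, inputs.reference_genome, config)
    counts["exons_in"] = len(inputs.reference_exome)
    counts["exons_framed"] = len(framed)
    counts["exons_long"] = len(long_exons)
    counts["exons_single_copy"] = len(exons)
    for rec in inputs.reference_exome:
        fates[rec.id] = "dropped_no_frame"
    for e in framed:
        fates[e.exon_id] = "dropped_short"
    for e in long_exons:
        fates[e.exon_id] = "dropped_multicopy"
    for e in exons:
        fates[e.exon_id] = "dropped_no_og"
    write_fasta(
        [SeqRecord(id=e.exon_id, seq=e.dna) for e in exons],
        outdir / "framed_exons.fasta",
    )
    write_fasta(
        [SeqRecord(id=e.exon_id, seq=e.protein) for e in exons],
        outdir / "framed_exons.pep.fasta",
    )
    log(
        f"exon catalogue: {counts['exons_in']} in, {counts['exons_framed']} framed, "
        f"{counts['exons_long']} long, {counts['exons_single_copy']} single-copy"
    )

    # --- module 1, step 2: orthologs and OGs ---
    all_orthologs = []
    for taxon in sorted(inputs.ingroups):
        raw = extract_orthologs(exons, taxon, inputs.ingroups[taxon], "ingroup", config)
        kept = filter_orthologs(raw, config.min_ortholog_len_nt, config.genetic_code_table)
        log(f"orthologs {taxon}: {len(raw)} extracted, {len(kept)} retained")
        all_orthologs.extend(kept)
    for taxon in sorted(inputs.outgroups):
        raw = extract_orthologs(exons, taxon, inputs.outgroups[taxon], "outgroup", config)
        kept = filter_orthologs(raw, config.min_ortholog_len_nt, config.genetic_code_table)
        log(f"orthologs {taxon}: {len(raw)} extracted, {len(kept)} retained")
        all_orthologs.extend(kept)
    ogs = build_ogs(exons, all_orthologs, config)
    counts["ogs_built"] = len(ogs)
    og_dir = outdir / "ogs"
    og_dir.mkdir(exist_ok=True)
    for og in ogs:
        write_fasta(
            [SeqRecord(id=m.taxon, seq=m.dna) for m in og.members],
            og_dir / f"{og.ref_exon_id}.dna.fasta",
        )
        write_fasta(
            [SeqRecord(id=m.taxon, seq=m.protein) for m in og.members],
            og_dir / f"{og.ref_exon_id}.pep.fasta",
        )
    log(f"orthologous groups: {len(ogs)}")

    # --- module 1, steps 3-5: alignment, filtering, candidate selection ---
    rejections: list[tuple[str, str]] = []
    candidates: dict[str, CandidateMsa] = {}
    n_aligned = 0
    n_filtered = 0
    msa_dir = outdir / "candidate_msas"
    msa_dir.mkdir(exist_ok=True)
    for og in ogs:
        locus = og.ref_exon_id
        try:
            pmsa = align_proteins(og, config)
            cmsa = back_translate_alignment(pmsa, og, config.genetic_code_table)
            n_aligned += 1
            cmsa = trim_to_reference(cmsa)
            cmsa = drop_gappy_sequences(cmsa, config.max_missing_fraction)
            if len(cmsa.rows) >= 2:
                cmsa = drop_dissimilar_sequences(cmsa, config.min_avg_similarity)
        except MsaDiscarded as exc:
            rejections.append((locus, exc.reason))
            fates[locus] = f"dropped_{exc.reason}"
            continue
        if len(cmsa.rows) < 2:
            rejections.append((locus, "no_rows"))
            fates[locus] = "dropped_no_rows"
            continue
        n_filtered += 1
        result = select_candidate_msa(cmsa, config)
        if isinstance(result, MsaRejection):
            rejections.append((locus, result.reason))
            fates[locus] = f"dropped_{result.reason}"
            continue
        candidates[locus] = result
        fates[locus] = "candidate"
        write_fasta(
            [SeqRecord(id=t, seq=r) for t, r in result.msa.rows.items()],
            msa_dir / f"{locus}.codon.fasta",
        )
        write_fasta(
            [
                SeqRecord(id=t, seq=r)
                for t, r in result.msa.aa_rows(config.genetic_code_table).items()
            ],
            msa_dir / f"{locus}.pep.fasta",
        )
    counts["msas_aligned"] = n_aligned
    counts["msas_filtered"] = n_filtered
    counts["candidate_msas"] = len(candidates)
    with open(outdir / "msa_rejections.tsv", "w") as fh:
        fh.write("locus_id\treason\n")
        for locus, reason in rejections:
            fh.write(f"{locus}\t{reason}\n")
    log(
        f"alignments: {n_aligned} aligned, {n_filtered} past row filters, "
        f"{len(candidates)} candidates"
    )

    # --- module 2: primer design ---
    selected = {}
    for locus in sorted(candidates):
        nested = design_primers_for_candidate(candidates[locus], config)
        if nested is None:
            fates[locus] = "dropped_no_nested_pair"
            continue
        selected[locus] = nested
        fates[locus] = "primer_emitted"
    counts["loci_with_primers"] = len(selected)
    emit_outputs(selected, candidates, outdir)
    log(f"primer design: {len(selected)} loci with nested primer sets")
    if not selected:
        logger.warning("no loci yielded a nested primer set")

    manifest = RunManifest(
        config=config, counts=counts, locus_fates=fates, seed=config.random_seed
    )
    manifest.write(outdir / "manifest.tsv")
    with open(outdir / "run.log", "w") as fh:
        fh.write(f"nestprimer {__version__}\n")
        for key, value in sorted(config.as_dict().items()):
            fh.write(f"config {key} = {value}\n")
        for line in log_lines:
            fh.write(line + "\n")
    with open(outdir / "locus_fates.tsv", "w") as fh:
        fh.write("locus_id\tfate\n")
        for locus in sorted(fates):
            fh.write(f"{locus}\t{fates[locus]}\n")
    return manifest
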