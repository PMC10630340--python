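"""Synthetic reference/ingroup/outgroup inputs with known per-locus fate.

The generator plants five classes of loci and records what the pipeline
should do with each:

* qualifying loci — 400-1100 nt exons carrying four perfectly conserved
  8-codon blocks (outer/inner forward, inner/outer reverse) separated by
  regions diverging at a controlled per-site substitution rate, laid out so
  the inner product is 300-1200 nt and the outer blocks sit within the 450 bp
  flank; these must come out the far end with a nested primer set (fate
  ``primer_emitted``);
* short decoys — frame-correct exons under 300 nt (``dropped_short``);
* duplicated decoys — normal exons whose reference genome carries a second
  full-length copy at ~90% identity (``dropped_multicopy``);
* hyperconserved decoys — identical across every taxon, so the alignment
  exceeds the 90% conservation ceiling (``dropped_too_conserved``);
* hypervariable decoys — orthologs rewritten at the amino-acid level so that
  no 7/8-aa window can reach the 0.5 block-similarity threshold anywhere in
  the alignment, for any subset of rows (``dropped_too_variable_blocks``).
  Destroying only the terminal blocks would not pin the fate down — interior
  conserved windows would simply become the new terminal blocks — so the
  whole exon is made hypervariable by construction (see
  ``_hypervariable_rows``) and the no-window property is asserted at
  generation time.

Exons are embedded in genome contigs between random spacer tracts (intron /
intergenic stand-ins), on a random strand per ingroup copy; outgroups are
emitted as clean CDS records.  Substitutions are frame-preserving: a mutated
codon that would introduce a stop is resampled.  All randomness flows from a
single seed through one named stream per output, so outputs are
byte-identical across runs and independent of generation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .io import SeqRecord, reverse_complement, translate, write_fasta
from .msa import PairwiseStats

Fate = Literal[
    "primer_emitted",
    "dropped_short",
    "dropped_multicopy",
    "dropped_too_conserved",
    "dropped_too_variable_blocks",
]

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    a + b + c
    for a in _BASES for b in _BASES for c in _BASES
    if a + b + c not in _STOPS
)


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic data set."""

    n_qualifying_loci: int = 20
    n_short_exons: int = 5
    n_duplicated_exons: int = 5
    n_hyperconserved: int = 5
    n_hypervariable: int = 5
    n_ingroup_taxa: int = 6
    n_outgroup_taxa: int = 2
    core_divergence: float = 0.10        # per-site substitution prob, variable regions
    outgroup_divergence_factor: float = 1.5
    terminal_block_len_aa: int = 8
    middle_len_range_codons: tuple[int, int] = (84, 240)   # inner amplified region
    flank_len_range_codons: tuple[int, int] = (10, 50)     # between outer and inner block
    short_len_range_nt: tuple[int, int] = (150, 297)
    duplicate_divergence: float = 0.10   # the planted second copy sits at ~90% identity
    intron_len_range: tuple[int, int] = (200, 400)
    exome_junk_max_nt: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_qualifying_loci", "n_short_exons", "n_duplicated_exons",
            "n_hyperconserved", "n_hypervariable", "n_ingroup_taxa",
            "n_outgroup_taxa",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.core_divergence < 1.0:
            raise ValueError("core_divergence must be in [0, 1)")


@dataclass
class PlantedLocus:
    locus_id: str
    fate: Fate
    exon: str                        # reference exon, in frame
    ref_contig: str
    ref_exon_interval: tuple[int, int]
    ingroup_seqs: dict[str, str]     # taxon -> in-frame ortholog (reading orientation)
    outgroup_seqs: dict[str, str]


@dataclass
class FixtureTruth:
    loci: list[PlantedLocus]

    def fate_of(self, locus_id: str) -> Fate:
        for l in self.loci:
            if l.locus_id == locus_id:
                return l.fate
        raise KeyError(locus_id)

    @property
    def expected_emitted(self) -> set[str]:
        return {l.locus_id for l in self.loci if l.fate == "primer_emitted"}


@dataclass
class Fixture:
    spec: FixtureSpec
    exome: list[SeqRecord]
    proteome: list[SeqRecord]
    genome: list[SeqRecord]
    ingroups: dict[str, list[SeqRecord]]
    outgroups: dict[str, list[SeqRecord]]
    truth: FixtureTruth


def _stream(seed: int, name: str) -> np.random.Generator:
    """One named pseudo-random stream per output, derived from the run seed."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


def _random_codons(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return "".join(_SENSE_CODONS[i] for i in idx)


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _mutate_codon_region(
    rng: np.random.Generator, dna: str, rate: float, max_tries: int = 50
) -> str:
    """Per-site substitution at the given rate, resampling codons that
    become stops so the reading frame stays clean."""
    if rate <= 0:
        return dna
    out = []
    for i in range(0, len(dna), 3):
        codon = dna[i : i + 3]
        for _ in range(max_tries):
            mutated = "".join(
                _BASES[(_BASES.index(ch) + 1 + rng.integers(0, 3)) % 4]
                if rng.random() < rate else ch
                for ch in codon
            )
            if mutated not in _STOPS:
                out.append(mutated)
                break
        else:
            raise RuntimeError(
                "could not produce a stop-free mutated codon; divergence too high"
            )
    return "".join(out)


_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon in _SENSE_CODONS:
    _AA_TO_CODONS.setdefault(translate(_codon), []).append(_codon)


def _hypervariable_rows(
    rng: np.random.Generator, exon: str, taxa: list[str]
) -> dict[str, str]:
    """Orthologs in which no 7/8-aa window can reach 50% similarity.

    Two of every three codon positions are replaced, and at each replaced
    position every taxon receives its own amino acid, distinct from the
    reference's and from every other taxon's.  Any pair of rows (reference
    included) can then match at no more than 3 positions of any 7- or 8-aa
    window — at most 43% identity, deterministically, for every subset of
    rows the pipeline might retain.  The untouched anchor codons (one in
    three) keep the rows recoverable by translated local search and keep
    nucleotide identity far above the row-retention cutoff.
    """
    n_codons = len(exon) // 3
    rows = {t: [] for t in taxa}
    for i in range(n_codons):
        codon = exon[3 * i : 3 * i + 3]
        if i % 3 == 2:          # conserved anchor position
            for t in taxa:
                rows[t].append(codon)
            continue
        orig_aa = translate(codon)
        other_aas = [aa for aa in sorted(_AA_TO_CODONS) if aa != orig_aa]
        order = rng.permutation(len(other_aas))
        for k, t in enumerate(taxa):
            aa = other_aas[order[k % len(other_aas)]]
            codons = _AA_TO_CODONS[aa]
            rows[t].append(codons[rng.integers(0, len(codons))])
    return {t: "".join(chunks) for t, chunks in rows.items()}


def _max_block_similarity(rows: list[str], lengths: tuple[int, ...]) -> float:
    """Highest mean pairwise aa-window identity over all 7/8-aa windows."""
    aa_rows = [translate(r) for r in rows]
    stats = PairwiseStats(aa_rows)
    n = len(aa_rows[0])
    best = 0.0
    for length in lengths:
        for start in range(n - length + 1):
            best = max(best, stats.mean_identity(start, start + length))
    return best


def _taxon_names(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i + 1}" for i in range(n)]


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Generate all pipeline inputs plus the per-locus truth table."""
    ingroup_taxa = _taxon_names("ingroup", spec.n_ingroup_taxa)
    outgroup_taxa = _taxon_names("outgroup", spec.n_outgroup_taxa)
    block_nt = 3 * spec.terminal_block_len_aa

    loci: list[PlantedLocus] = []
    plan: list[tuple[str, Fate]] = []
    for i in range(spec.n_qualifying_loci):
        plan.append((f"locus{i + 1:03d}", "primer_emitted"))
    for i in range(spec.n_short_exons):
        plan.append((f"short{i + 1:03d}", "dropped_short"))
    for i in range(spec.n_duplicated_exons):
        plan.append((f"dup{i + 1:03d}", "dropped_multicopy"))
    for i in range(spec.n_hyperconserved):
        plan.append((f"conserved{i + 1:03d}", "dropped_too_conserved"))
    for i in range(spec.n_hypervariable):
        plan.append((f"variable{i + 1:03d}", "dropped_too_variable_blocks"))

    for locus_id, fate in plan:
        rng = _stream(spec.seed, f"locus/{locus_id}")
        # lay the exon out as segments: (codon string, is_conserved)
        if fate == "dropped_short":
            lo, hi = spec.short_len_range_nt
            n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
            segments = [(_random_codons(rng, n_codons), False)]
        elif fate in ("dropped_too_variable_blocks",):
            m_lo, m_hi = spec.middle_len_range_codons
            n_codons = int(rng.integers(m_lo + 64, m_hi + 96))
            segments = [(_random_codons(rng, n_codons), False)]
        else:
            # four conserved 8-codon blocks around variable flanks and middle:
            # outer_f | flank | inner_f | middle | inner_r | flank | outer_r
            f_lo, f_hi = spec.flank_len_range_codons
            m_lo, m_hi = spec.middle_len_range_codons
            g1 = int(rng.integers(f_lo, f_hi + 1))
            g2 = int(rng.integers(f_lo, f_hi + 1))
            mid = int(rng.integers(m_lo, m_hi + 1))
            conserved_everywhere = fate == "dropped_too_conserved"
            segments = [
                (_random_codons(rng, spec.terminal_block_len_aa), True),
                (_random_codons(rng, g1), conserved_everywhere),
                (_random_codons(rng, spec.terminal_block_len_aa), True),
                (_random_codons(rng, mid), conserved_everywhere),
                (_random_codons(rng, spec.terminal_block_len_aa), True),
                (_random_codons(rng, g2), conserved_everywhere),
                (_random_codons(rng, spec.terminal_block_len_aa), True),
            ]
        exon = "".join(seg for seg, _ in segments)

        ingroup_seqs: dict[str, str] = {}
        outgroup_seqs: dict[str, str] = {}
        if fate == "dropped_too_variable_blocks":
            all_rows = _hypervariable_rows(rng, exon, ingroup_taxa + outgroup_taxa)
            ingroup_seqs = {t: all_rows[t] for t in ingroup_taxa}
            outgroup_seqs = {t: all_rows[t] for t in outgroup_taxa}
            check = [exon] + list(all_rows.values())
            if _max_block_similarity(check, (7, 8)) > 0.5:
                raise RuntimeError(
                    f"{locus_id}: hypervariable construction left a conserved window"
                )
        else:
            for taxa, seqs, div in (
                (ingroup_taxa, ingroup_seqs, spec.core_divergence),
                (
                    outgroup_taxa,
                    outgroup_seqs,
                    min(0.95, spec.core_divergence * spec.outgroup_divergence_factor),
                ),
            ):
                for taxon in taxa:
                    seqs[taxon] = "".join(
                        seg if conserved else _mutate_codon_region(rng, seg, div)
                        for seg, conserved in segments
                    )
        loci.append(
            PlantedLocus(
                locus_id=locus_id,
                fate=fate,
                exon=exon,
                ref_contig=f"ref_contig_{locus_id}",
                ref_exon_interval=(0, 0),   # set when the genome is laid out
                ingroup_seqs=ingroup_seqs,
                outgroup_seqs=outgroup_seqs,
            )
        )

    # reference exome (with small out-of-frame junk flanks) and proteome
    exome: list[SeqRecord] = []
    proteome: list[SeqRecord] = []
    for locus in loci:
        rng = _stream(spec.seed, f"exome/{locus.locus_id}")
        left = _random_nt(rng, int(rng.integers(0, spec.exome_junk_max_nt + 1)))
        right = _random_nt(rng, int(rng.integers(0, spec.exome_junk_max_nt + 1)))
        exome.append(SeqRecord(id=locus.locus_id, seq=left + locus.exon + right))
        proteome.append(
            SeqRecord(id=f"{locus.locus_id}_prot", seq=translate(locus.exon))
        )

    # reference genome: one contig per locus, exon between spacer tracts;
    # duplicated decoys get a diverged second copy further along the contig
    genome: list[SeqRecord] = []
    for locus in loci:
        rng = _stream(spec.seed, f"genome/{locus.locus_id}")
        lo, hi = spec.intron_len_range
        left = _random_nt(rng, int(rng.integers(lo, hi + 1)))
        right = _random_nt(rng, int(rng.integers(lo, hi + 1)))
        contig = left + locus.exon + right
        locus.ref_exon_interval = (len(left), len(left) + len(locus.exon))
        if locus.fate == "dropped_multicopy":
            copy = _mutate_codon_region(rng, locus.exon, spec.duplicate_divergence)
            spacer = _random_nt(rng, int(rng.integers(lo, hi + 1)))
            contig = contig + copy + spacer
        genome.append(SeqRecord(id=locus.ref_contig, seq=contig))

    # ingroup genomes: one contig per locus and taxon, random strand
    ingroups: dict[str, list[SeqRecord]] = {}
    for taxon in ingroup_taxa:
        records = []
        for locus in loci:
            rng = _stream(spec.seed, f"ingroup/{taxon}/{locus.locus_id}")
            lo, hi = spec.intron_len_range
            left = _random_nt(rng, int(rng.integers(lo, hi + 1)))
            right = _random_nt(rng, int(rng.integers(lo, hi + 1)))
            insert = locus.ingroup_seqs[taxon]
            contig = left + insert + right
            if rng.random() < 0.5:
                contig = reverse_complement(contig)
            records.append(
                SeqRecord(id=f"{taxon}_contig_{locus.locus_id}", seq=contig)
            )
        ingroups[taxon] = records

    # outgroup CDS sets
    outgroups: dict[str, list[SeqRecord]] = {}
    for taxon in outgroup_taxa:
        outgroups[taxon] = [
            SeqRecord(id=f"{taxon}_cds_{locus.locus_id}", seq=locus.outgroup_seqs[taxon])
            for locus in loci
        ]

    return Fixture(
        spec=spec,
        exome=exome,
        proteome=proteome,
        genome=genome,
        ingroups=ingroups,
        outgroups=outgroups,
        truth=FixtureTruth(loci=loci),
    )


def write_fixture(fixture: Fixture, outdir: str | Path) -> None:
    """Write the fixture as standard FASTA files plus truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(fixture.exome, outdir / "reference_exome.fasta")
    write_fasta(fixture.proteome, outdir / "reference_proteome.fasta")
    write_fasta(fixture.genome, outdir / "reference_genome.fasta")
    for taxon, records in fixture.ingroups.items():
        write_fasta(records, outdir / f"{taxon}_genome.fasta")
    for taxon, records in fixture.outgroups.items():
        write_fasta(records, outdir / f"{taxon}_cds.fasta")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("locus_id\tfate\tref_contig\texon_start\texon_end\texon_len_nt\n")
        for locus in fixture.truth.loci:
            s, e = locus.ref_exon_interval
            fh.write(
                f"{locus.locus_id}\t{locus.fate}\t{locus.ref_contig}\t{s}\t{e}\t{len(locus.exon)}\n"
            )


@dataclass
class TruthReport:
    matches: list[tuple[str, Fate, str]]
    mismatches: list[tuple[str, Fate, str]]

    @property
    def ok(self) -> bool:
        return not self.mismatches


# which pipeline outcome(s) realise each planted fate; hypervariable loci
# surface as a no_blocks candidate rejection
_FATE_TO_OBSERVED: dict[Fate, frozenset[str]] = {
    "primer_emitted": frozenset({"primer_emitted"}),
    "dropped_short": frozenset({"dropped_short"}),
    "dropped_multicopy": frozenset({"dropped_multicopy"}),
    "dropped_too_conserved": frozenset({"dropped_too_conserved"}),
    "dropped_too_variable_blocks": frozenset({"dropped_no_blocks"}),
}


def verify_against_truth(
    observed_fates: dict[str, str], truth: FixtureTruth
) -> TruthReport:
    """Compare the pipeline's per-locus outcome with the planted fates.

    ``observed_fates`` maps locus id to the pipeline's recorded outcome
    (``primer_emitted`` or a drop reason); a missing locus is reported as
    ``absent``.
    """
    matches, mismatches = [], []
    for locus in truth.loci:
        observed = observed_fates.get(locus.locus_id, "absent")
        entry = (locus.locus_id, locus.fate, observed)
        if observed in _FATE_TO_OBSERVED[locus.fate]:
            matches.append(entry)
        else:
            mismatches.append(entry)
    return TruthReport(matches=matches, mismatches=mismatches)
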