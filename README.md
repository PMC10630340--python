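# nestprimer

Universal nested-PCR primer design for single-copy nuclear protein-coding
loci (NPCLs) from annotated genome data.

Phylogeneticists building multi-locus data sets by PCR or amplicon capture
need primers that (a) sit in regions conserved across a whole clade, (b)
amplify a single-copy locus variable enough to carry phylogenetic signal,
and (c) actually work at the bench.  Finding such loci by hand — scanning
alignments for conserved priming sites, checking copy number, balancing
degeneracy against coverage — does not scale past a handful of markers.
`nestprimer` automates the whole path: from a reference species' exome,
proteome and genome plus ingroup genomes (and optional outgroup CDS), it
discovers long single-copy exonic loci shared across the clade, builds
quality-filtered codon alignments, and designs a **nested** primer set per
locus — an outer forward/reverse pair amplifying a larger region and an
inner pair re-amplifying the target from that product, which is what makes
high-throughput PCR succeed without per-locus optimisation.

Each candidate alignment is scanned for conserved 7–8 amino-acid blocks
(mean pairwise similarity > 50%); degenerate primers are the IUPAC consensus
of the bases observed in each block column; inner pairs are filtered by
degeneracy (≤ 8192) and product length (300–1200 bp on the reference), outer
primers are sought within 450 bp of flank, and every nested set is scored by

    Totalscore = (PIs · ScorePCR + ScoreINFOR) / (1 + PIs)

where `ScorePCR ∈ [0,1]` summarises block conservation, primer degeneracy
and sequence complexity over the four primers, `ScoreINFOR ∈ [0,1]` is the
capped mean pairwise p-distance of the amplified region, and `PIs ≥ 0`
(default 1) weighs amplification reliability against informativeness.  The
highest-scoring set per locus is reported.  See `docs/methods.md` for the
full model, every threshold, and the design decisions.

## Worked example

The package ships a synthetic-data generator that plants loci with known
fates — qualifying loci, too-short exons, duplicated (multi-copy) exons,
hyperconserved and hypervariable decoys — so the whole pipeline can be run
and verified without any downloads:

```python
import tempfile
from nestprimer import FixtureSpec, PipelineConfig, generate_fixture, run_pipeline
from nestprimer.pipeline import PipelineInputs
from nestprimer.io import read_primer_table

fixture = generate_fixture(FixtureSpec(
    n_qualifying_loci=3, n_short_exons=1, n_duplicated_exons=1,
    n_hyperconserved=1, n_hypervariable=1, n_ingroup_taxa=2,
    n_outgroup_taxa=1, seed=7,
))
out = tempfile.mkdtemp()
manifest = run_pipeline(PipelineConfig(random_seed=7),
                        PipelineInputs.from_fixture(fixture), out)
print(manifest.counts)
for r in read_primer_table(f"{out}/primer_table.tsv"):
    print(r.locus_id, r.inner_forward, r.inner_product_len_ref,
          f"{r.ScorePCR:.4f}", f"{r.ScoreINFOR:.4f}", f"{r.Totalscore:.4f}")
```

prints

```
{'exons_in': 7, 'exons_framed': 7, 'exons_long': 6, 'exons_single_copy': 5,
 'ogs_built': 5, 'msas_aligned': 5, 'msas_filtered': 5, 'candidate_msas': 3,
 'loci_with_primers': 3}
locus001 AGCGTAGGCCTGGCACGCTGTCCA 366 0.9508 0.4019 0.6764
locus003 GGACAGGCTACAGTTTGGGCTTTG 759 1.0000 0.3310 0.6655
locus002 AGCACGGGCAATTTCGAAGGAATA 477 0.9896 0.3131 0.6514
```

Reading the count chain: of 7 planted exons, all 7 frame-trim cleanly, the
150–297 nt decoy falls to the 300 bp length floor (7→6), the planted 90%
duplicate falls to the single-copy rule (6→5), the hyperconserved decoy is
rejected as >90% identical and the hypervariable decoy has no conserved
primer block (5→3 candidates), and exactly the 3 qualifying loci emerge with
nested primer sets.  Per locus you see the inner forward primer (IUPAC,
5'→3'), the inner product length on the reference, and the three scores;
`Totalscore` is their PIs-weighted combination, here the plain mean.
Alongside the primer table the run directory holds the reference nucleotide
and peptide sequences of each locus' amplified region
(`reference_NPCLs.*.fasta`, the guide sequences for downstream capture-data
analysis), per-stage FASTA outputs, a rejection log, a per-locus fate table,
the effective configuration and the run manifest.

The same run from the shell:

```bash
nestprimer fixtures --outdir fx --seed 7          # write synthetic inputs
nestprimer run --reference-exome fx/reference_exome.fasta \
    --reference-pep fx/reference_proteome.fasta \
    --reference-genome fx/reference_genome.fasta \
    --ingroup fx/ingroup1_genome.fasta --ingroup fx/ingroup2_genome.fasta \
    --outgroup fx/outgroup1_cds.fasta \
    --outdir run1 --seed 7
```

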