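# Methods

`nestprimer` automates the design of universal nested-PCR primer sets for
nuclear protein-coding loci (NPCLs) from annotated genome data.  Given a
reference species (exome + proteome + genome), one or more ingroup genomes
and optional outgroup coding sequences, it (module 1) assembles quality-
filtered codon alignments of long, single-copy exonic loci shared across the
clade, and (module 2) designs a scored nested primer set — an inner
forward/reverse pair flanked by an outer forward/reverse pair — for each
suitable alignment.

## Module 1: candidate alignments

1. **Exon catalogue.** Each exome entry is searched against the proteome in
   translated mode (BLASTX-like) and trimmed to the in-frame interval of its
   best hit; exons without a qualifying hit, or whose trimmed translation
   contains a stop, are dropped.  Exons shorter than `min_exon_len_nt`
   (300 bp) are discarded.  Remaining exons are searched against the
   reference genome (BLASTN-like); the best hit is taken to be the exon's own
   locus, and the exon is rejected as multi-copy if any further hit exceeds
   **both** 50% identity and 30% query coverage.
2. **Orthology.** For each surviving exon, its protein is searched against
   every ingroup genome and outgroup CDS set in six-frame translated mode;
   the best hit region (strand- and frame-resolved, automatically on codon
   boundaries) is extracted and kept only if its best hit back against the
   reference exon set is the exon it came from (mutual best hit).  Orthologs
   must be strictly longer than 300 bp and free of internal stops (a
   terminal stop codon is trimmed, not fatal).  Exons with at least
   `min_ingroup_taxa` (1) ingroup orthologs form an orthologous group (OG)
   carrying paired DNA and protein sequences.
3. **Alignment.** OG proteins are aligned with a centre-star progressive
   aligner: all pairwise optimal global alignments (BLOSUM62, gap open −12 /
   extend −1, end gaps penalised) are computed, the row with the highest
   mean pairwise identity becomes the centre, and the other rows are merged
   under once-a-gap-always-a-gap.  The protein alignment is back-translated
   codon-by-codon (amino-acid gap → `---`), so every codon row with gaps
   removed equals its source DNA exactly.  An adapter for MAFFT is provided
   for production-scale runs; the built-in aligner is what the tests pin
   down.
4. **Row filters.** Columns outside the reference row's first/last non-gap
   codon are trimmed.  Rows whose N+gap fraction strictly exceeds 60% are
   dropped; then, iteratively, the row with the lowest mean pairwise
   nucleotide identity to the others is dropped while that mean is strictly
   below 30% (recomputed after each removal).  If the reference row itself
   is the offender the whole alignment is discarded with a logged reason.
5. **Candidate selection.** Scanning 8-aa windows from the left and the
   right, the first window on each side with block similarity strictly
   above 0.5 becomes a terminal block; the alignment is trimmed to the two
   blocks inclusive.  Alignments with no such distinct pair are rejected
   (`no_blocks`), trimmed alignments not exceeding 300 nt are rejected
   (`too_short`), and alignments whose mean pairwise nucleotide identity
   strictly exceeds 0.90 are rejected (`too_conserved`).

**Similarity, one definition everywhere.**  The identity of two gapped rows
is matches / aligned columns excluding gap–gap pairs; a gap against a
residue counts as a mismatch; `N`/`X` never match.  Block similarity is the
mean of this over all unordered row pairs within the window; alignment-level
similarity is the same at full width; p-distance is the complement.  The
implementation precomputes per-pair prefix sums so any column interval is
scored in O(pairs); results are exact integer ratios, identical to a brute-
force double loop (asserted at 1e−12 in the tests).

## Module 2: nested primer design

Every 7- or 8-aa window with block similarity strictly above 0.5 is a primer
block.  A degenerate primer is the IUPAC consensus of the bases *observed*
in each nucleotide column (gaps and N excluded; full genetic-code
back-translation is deliberately not used, keeping degeneracy minimal);
degeneracy is the product of per-column alternatives, and the reverse primer
is the reverse complement.  Inner pairs are all forward×reverse block
combinations with the forward block strictly left of (not overlapping) the
reverse block, both degeneracies ≤ `max_primer_degeneracy` (8192), and a
primer-inclusive product length on the *ungapped reference row* within
`inner_product_len_range_nt` ([300, 1200]; the ceiling reflects typical
amplicon-capture products).  Outer candidates are blocks wholly outside the
inner pair (zero-gap adjacency allowed) whose near edge is within
`outer_flank_nt` (450 bp, again on the ungapped reference row) of the inner
primer; inner pairs lacking either outer side yield no nested set.

**Scoring.**  Each primer scores
`(w_c·conservation + w_d·degeneracy_term + w_x·complexity) / (w_c+w_d+w_x)`
with unit weights, where conservation is the block similarity,
`degeneracy_term = max(0, 1 − log(deg)/log(max_deg))`, and complexity is 1
minus penalties: −0.25 if any base can run ≥5 consecutive positions in some
concrete expansion, −0.25 if the consensus GC fraction (each position
contributing |set ∩ {G,C}|/|set|) falls outside [0.30, 0.70], and −0.5 if
the degeneracy of the last 3 nt at the 3′ end exceeds 2 (floored at 0).
`ScorePCR` is the mean over the four primers.  `ScoreINFOR` is the mean
pairwise nucleotide p-distance of the region strictly between the inner
primers, divided by a 0.5 cap and clipped to 1 — 0.5 p-distance is already
near mutational saturation, so anything beyond it is "maximally
informative".  These concrete component formulas are this package's own
definitions; the combination is

    Totalscore = (PIs · ScorePCR + ScoreINFOR) / (1 + PIs),   PIs ≥ 0 (default 1),

so PIs = 1 is the arithmetic mean, PIs = 0 ranks purely by informativeness,
and large PIs ranks purely by PCR performance.  Per locus the highest
Totalscore wins; ties go to the larger inner product, then the leftmost
inner forward primer, then the lexicographically smallest concatenated
primer string.

The pipeline's per-locus selection is a vectorised equivalent of the full
enumeration: the total score is non-decreasing in each primer's own score,
so for a fixed inner pair only best-scoring outer blocks can appear in the
argmax; all score ties are materialised and pushed through the exact scoring
and tie-break path.  The exhaustive path is retained
(`design_primers_brute`) and the tests assert both select the same set.  At
PIs = 0 (where ScorePCR is ignored entirely) the exhaustive path's string
tie-break over *all* outer combinations is not fully reproduced — a
documented, deliberate corner.

## Search backend

All similarity search runs on optimal affine-gap local dynamic programming
(Biopython's C `PairwiseAligner`): nucleotide mode (+2/−3, gap −7/−2, both
strands, min score 60) and translated modes (BLOSUM62, gap −12/−1, six
frames, min score 40); `N`/`X` never match anything.  A shared-k-mer
prefilter (k = 11 nt / 5 aa) selects which query/subject pairs receive the
DP; whenever the seeded pass produces no hit covering ≥ 50% of the query,
the backend re-scans every unit exhaustively, so a divergent homolog without
a single exact shared k-mer is still found — or its absence proven rather
than assumed.  Secondary hits (needed by the single-copy rule) are recovered
by masking each hit region with a sentinel residue and re-aligning.  Hits
are ranked by score with deterministic tie-breaks (subject id, then leftmost
start), making the whole pipeline reproducible bit-for-bit; no heuristic can
change *whether* a homolog is found, only how much work finding it costs.
Raw score thresholds stand in for e-values: at desk scale there is no
database-size statistic worth modelling.

## Synthetic study conditions

The fixture generator plants five locus classes with known fates; the
default conditions are 20 qualifying loci and 5 decoys of each class across
6 ingroup and 2 outgroup taxa:

* **qualifying** — four perfectly conserved 8-codon blocks (outer/inner ×
  forward/reverse) separated by regions diverging at `core_divergence`
  (0.10 per site per ingroup taxon; outgroups ×1.5), laid out so the inner
  product falls in [300, 1200] nt and the outer blocks sit within the 450 bp
  flank.  Two terminal blocks alone would never be emitted — an inner pair
  made of them leaves no room for outer primers — hence four.
* **short** — frame-correct exons of 150–297 nt.
* **duplicated** — ordinary exons whose reference contig carries a second
  full-length copy at ~90% identity further along.
* **hyperconserved** — identical across every taxon.
* **hypervariable** — two of every three codons replaced, each taxon
  receiving its own amino acid distinct from the reference's and from every
  other taxon's.  Any row pair then matches at most 3 positions of any
  7/8-aa window (≤43% < 50%) *for every subset of rows* the row filters
  might retain, while the untouched anchor codon per triplet keeps
  translated-search recovery full-length and nucleotide identity ~0.5,
  safely above the 30% retention cutoff.  This is deterministic where a
  random scramble cannot satisfy all three constraints at once at small
  taxon counts.

Substitutions are frame-preserving (codons that would become stops are
resampled); exons are embedded in contigs between random spacer tracts of
200–400 nt, on a random strand per ingroup copy; exome entries carry 0–2 nt
of out-of-frame junk on each side to exercise frame trimming.  One named
random stream per output file hangs off the single run seed, so outputs are
byte-identical across runs and independent of generation order.

What the generator does **not** emulate: indels within coding sequence,
introns splitting an ortholog (spacers only flank it), repeats and GC skew,
sequencing error / N runs, paralogy more subtle than a 90% duplicate, and
rate heterogeneity along the exon.  Passing the planted-truth test therefore
shows the machinery implements the stated rules exactly — not that real
genomes will be as clean; on real data the MAFFT adapter and an external
BLAST front end would be the production choices.

## Numerical and interface choices

* Boundary semantics follow the printed wording literally: "shorter than
  300" drops <300, "greater than 300" keeps >300, ">60%"/">50%"/">90%"
  strict, "below 30%" strict.
* "Similarity" in the single-copy rule is read as alignment percent
  identity, "coverage" as query-side coverage; the 90% conservation cull and
  the 30% dissimilarity rule operate on nucleotide identity; dissimilar-row
  removal is iterative.  Each of these was genuinely open; one definition is
  fixed, applied everywhere, and echoed into the run config.
* Degenerate bases come from observed residues only, never from genetic-code
  expansion.
* Coordinates are 0-based half-open internally; product lengths and flank
  distances are measured on the ungapped reference row with primer
  footprints included in products.
* The run manifest records the count chain (exons in → framed → long →
  single-copy → OGs → aligned → filtered → candidates → loci with primers)
  plus a per-locus fate table; every threshold actually applied is echoed to
  `config_echo.yaml` in the output directory.
* `--threads` is accepted for interface stability; the run executes
  sequentially, so results are trivially independent of it.
* Default problem sizes used by the test suite and the acceptance script are
  the fixture defaults above (~40 loci, 9 taxa, ~50 kb per genome); a full
  run takes on the order of a minute on one CPU.

## Known limitations

* The scoring components (weights, log-degeneracy transform, complexity
  penalties, 0.5 p-distance cap) are this package's definitions of the three
  named score ingredients; alternative published weightings would reorder
  near-tied primer sets.
* The built-in star aligner is exact for pairs and adequate for the low-gap
  alignments this pipeline sees, but it is not a general MSA tool; heavily
  gapped or very deep alignments should go through the MAFFT adapter.
* Raw-score search thresholds are not e-values; on genome-scale databases an
  external search tool should replace the built-in backend (the contract is
  the `search()` signature).
* Multi-copy orthology resolution (more than "reject on a strong second
  hit") and tree-based orthology are out of scope.
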