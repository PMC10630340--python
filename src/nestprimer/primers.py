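"""Nested-PCR primer design from candidate codon alignments.

From each candidate alignment the engine enumerates every conserved 7- or
8-aa window (block similarity strictly above 0.5), builds one degenerate
forward and one degenerate reverse primer per block from the union of bases
observed in each nucleotide column, pairs forward and reverse blocks into
inner primer pairs filtered by degeneracy and product length, attaches outer
primers found within 450 bp of flank, scores every nested set for PCR
performance (block conservation, degeneracy, sequence complexity) and locus
informativeness (p-distance of the amplified region), and keeps the
highest-scoring nested set per locus:

    Totalscore = (PIs * ScorePCR + ScoreINFOR) / (1 + PIs)

Product lengths and flank distances are measured on the ungapped reference
row, with primer footprints included in products.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

from pathlib import Path
from typing import Sequence

import numpy as np

from .config import PipelineConfig
from .io import (
    PrimerTableRow,
    SeqRecord,
    translate,
    write_fasta,
    write_primer_table,
)
from .msa import GAP, CandidateMsa, PairwiseStats

logger = logging.getLogger(__name__)

IUPAC_CODES: dict[frozenset[str], str] = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}
CODE_TO_BASES: dict[str, frozenset[str]] = {v: k for k, v in IUPAC_CODES.items()}
_COMPLEMENT_BASE = {"A": "T", "C": "G", "G": "C", "T": "A"}


def complement_sets(sets: Sequence[frozenset[str]]) -> list[frozenset[str]]:
    return [frozenset(_COMPLEMENT_BASE[b] for b in s) for s in sets]


@dataclass
class PrimerBlock:
    """A conserved alignment window eligible to seed a degenerate primer."""

    aa_start: int
    len_aa: int
    block_similarity: float
    nt_unions: list[frozenset[str]]   # template strand, one set per nt column

    @property
    def nt_start(self) -> int:
        return 3 * self.aa_start

    @property
    def nt_end(self) -> int:
        return 3 * (self.aa_start + self.len_aa)

    @property
    def degeneracy(self) -> int:
        d = 1
        for s in self.nt_unions:
            d *= len(s)
        return d


@dataclass
class DegeneratePrimer:
    iupac: str                         # 5'->3' in primer orientation
    degeneracy: int
    orientation: str                   # 'forward' | 'reverse'
    block: PrimerBlock
    position_sets: list[frozenset[str]]   # 5'->3' in primer orientation

    def __post_init__(self) -> None:
        if self.degeneracy < 1:
            raise ValueError("degeneracy must be positive")


@dataclass
class InnerPair:
    forward: DegeneratePrimer
    reverse: DegeneratePrimer
    product_len_ref: int


@dataclass
class NestedPrimerSet:
    inner_f: DegeneratePrimer
    inner_r: DegeneratePrimer
    outer_f: DegeneratePrimer
    outer_r: DegeneratePrimer
    inner_product_len_ref: int
    outer_product_len_ref: int
    score_pcr: float = 0.0
    score_infor: float = 0.0
    total_score: float = 0.0


# --- block discovery -------------------------------------------------------


class _CandidateView:
    """Precomputed per-candidate arrays shared by the primer operations."""

    def __init__(self, cand: CandidateMsa, config: PipelineConfig):
        self.cand = cand
        self.config = config
        rows = list(cand.msa.rows.values())
        self.nt_stats = PairwiseStats(rows)
        aa_rows = list(cand.msa.aa_rows(config.genetic_code_table).values())
        self.aa_stats = PairwiseStats(aa_rows)
        self.n_aa = len(aa_rows[0])
        arr = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8)
        arr = arr.reshape(len(rows), -1)
        self.unions: list[frozenset[str]] = []
        for col in range(arr.shape[1]):
            bases = frozenset(
                chr(b) for b in arr[:, col] if chr(b) in "ACGT"
            )
            self.unions.append(bases)
        ref = cand.msa.rows[cand.msa.ref_taxon]
        ref_non_gap = np.frombuffer(ref.encode("ascii"), dtype=np.uint8) != ord(GAP)
        self.ref_cum = np.concatenate([[0], np.cumsum(ref_non_gap)])
        self.ref_row = ref

    def ref_len(self, start: int, end: int) -> int:
        """Ungapped reference length of alignment columns [start, end)."""
        return int(self.ref_cum[end] - self.ref_cum[start])


def find_primer_blocks(
    cand: CandidateMsa, config: PipelineConfig, view: _CandidateView | None = None
) -> list[PrimerBlock]:
    """Every 7/8-aa window whose block similarity strictly exceeds the cutoff.

    Overlapping blocks are allowed.  Windows containing a nucleotide column
    with no unambiguous base observed (all gaps/N) cannot seed a primer and
    are excluded.  Blocks are ordered by start position then length.
    """
    view = view or _CandidateView(cand, config)
    blocks: list[PrimerBlock] = []
    for start in range(view.n_aa):
        for length in sorted(config.block_len_set_aa):
            if start + length > view.n_aa:
                continue
            sim = view.aa_stats.mean_identity(start, start + length)
            if sim <= config.block_min_similarity:
                continue
            unions = view.unions[3 * start : 3 * (start + length)]
            if any(len(u) == 0 for u in unions):
                continue
            blocks.append(
                PrimerBlock(
                    aa_start=start,
                    len_aa=length,
                    block_similarity=sim,
                    nt_unions=list(unions),
                )
            )
    blocks.sort(key=lambda b: (b.aa_start, b.len_aa))
    return blocks


# --- degenerate primer construction ----------------------------------------


def build_degenerate_primer(block: PrimerBlock, orientation: str) -> DegeneratePrimer:
    """IUPAC consensus of a block; reverse is the reverse complement.

    The degeneracy is the product over positions of the number of observed
    bases.  A column with no observed base cannot be encoded: the block is
    rejected with an error.
    """
    if orientation not in ("forward", "reverse"):
        raise ValueError(f"bad orientation: {orientation}")
    for i, s in enumerate(block.nt_unions):
        if not s:
            raise ValueError(f"block at aa {block.aa_start}: empty base union at nt column {i}")
    if orientation == "forward":
        sets = list(block.nt_unions)
    else:
        sets = complement_sets(block.nt_unions)[::-1]
    iupac = "".join(IUPAC_CODES[frozenset(s)] for s in sets)
    return DegeneratePrimer(
        iupac=iupac,
        degeneracy=block.degeneracy,
        orientation=orientation,
        block=block,
        position_sets=sets,
    )


# --- pair enumeration ------------------------------------------------------


def enumerate_inner_pairs(
    blocks: Sequence[PrimerBlock],
    cand: CandidateMsa,
    config: PipelineConfig,
    view: _CandidateView | None = None,
) -> list[InnerPair]:
    """All forward/reverse block combinations passing the pair filters.

    The forward block must lie strictly left of (not overlapping) the reverse
    block; both primers must respect the degeneracy ceiling and the
    primer-inclusive product length on the ungapped reference row must fall
    within the configured range.
    """
    view = view or _CandidateView(cand, config)
    lo, hi = config.inner_product_len_range_nt
    max_deg = config.max_primer_degeneracy
    eligible = [b for b in blocks if b.degeneracy <= max_deg]
    pairs: list[InnerPair] = []
    for f in eligible:
        for r in eligible:
            if f.nt_end > r.nt_start:
                continue
            product = view.ref_len(f.nt_start, r.nt_end)
            if not (lo <= product <= hi):
                continue
            pairs.append(
                InnerPair(
                    forward=build_degenerate_primer(f, "forward"),
                    reverse=build_degenerate_primer(r, "reverse"),
                    product_len_ref=product,
                )
            )
    return pairs


def find_outer_pairs(
    inner: InnerPair,
    blocks: Sequence[PrimerBlock],
    cand: CandidateMsa,
    config: PipelineConfig,
    view: _CandidateView | None = None,
) -> list[NestedPrimerSet]:
    """Nested sets for one inner pair: outer primers within the flank window.

    An outer forward block must lie wholly 5' of the inner forward block
    (zero-gap adjacency allowed) with its 3' end within the flank distance of
    the inner primer's 5' end, measured on the ungapped reference row; the
    outer reverse rule is symmetric.  Inner pairs lacking either outer
    candidate yield nothing.
    """
    view = view or _CandidateView(cand, config)
    flank = config.outer_flank_nt
    max_deg = config.max_primer_degeneracy
    inner_f_start = inner.forward.block.nt_start
    inner_r_end = inner.reverse.block.nt_end
    fwd_candidates = [
        b for b in blocks
        if b.degeneracy <= max_deg
        and b.nt_end <= inner_f_start
        and view.ref_len(b.nt_end, inner_f_start) <= flank
    ]
    rev_candidates = [
        b for b in blocks
        if b.degeneracy <= max_deg
        and b.nt_start >= inner_r_end
        and view.ref_len(inner_r_end, b.nt_start) <= flank
    ]
    fwd_primers = [build_degenerate_primer(b, "forward") for b in fwd_candidates]
    rev_primers = [build_degenerate_primer(b, "reverse") for b in rev_candidates]
    sets: list[NestedPrimerSet] = []
    for of_block, of in zip(fwd_candidates, fwd_primers):
        for orv_block, orv in zip(rev_candidates, rev_primers):
            sets.append(
                NestedPrimerSet(
                    inner_f=inner.forward,
                    inner_r=inner.reverse,
                    outer_f=of,
                    outer_r=orv,
                    inner_product_len_ref=inner.product_len_ref,
                    outer_product_len_ref=view.ref_len(
                        of_block.nt_start, orv_block.nt_end
                    ),
                )
            )
    return sets


# --- scoring ---------------------------------------------------------------


def _primer_complexity(primer: DegeneratePrimer, config: PipelineConfig) -> float:
    """1 minus penalties for homopolymer risk, GC imbalance and 3' degeneracy."""
    sets = primer.position_sets
    penalty = 0.0
    # homopolymer: some base can appear in >= N consecutive positions of a
    # concrete expansion
    run_needed = config.homopolymer_min_run
    for base in "ACGT":
        run = 0
        found = False
        for s in sets:
            run = run + 1 if base in s else 0
            if run >= run_needed:
                found = True
                break
        if found:
            penalty += config.homopolymer_penalty
            break
    gc = float(np.mean([len(s & {"G", "C"}) / len(s) for s in sets]))
    lo, hi = config.gc_range
    if gc < lo or gc > hi:
        penalty += config.gc_penalty
    tail = sets[-config.three_prime_window_nt:]
    tail_deg = 1
    for s in tail:
        tail_deg *= len(s)
    if tail_deg > config.three_prime_max_degeneracy:
        penalty += config.three_prime_penalty
    return max(0.0, 1.0 - penalty)


def _primer_score(primer: DegeneratePrimer, config: PipelineConfig) -> float:
    conservation = primer.block.block_similarity
    max_deg = config.max_primer_degeneracy
    if max_deg > 1:
        deg_term = max(0.0, 1.0 - math.log(primer.degeneracy) / math.log(max_deg))
    else:
        deg_term = 1.0 if primer.degeneracy == 1 else 0.0
    complexity = _primer_complexity(primer, config)
    w_c = config.score_w_conservation
    w_d = config.score_w_degeneracy
    w_x = config.score_w_complexity
    return (w_c * conservation + w_d * deg_term + w_x * complexity) / (w_c + w_d + w_x)


def score_pcr(nested: NestedPrimerSet, config: PipelineConfig) -> float:
    """Mean PCR-performance score of the four primers, in [0, 1]."""
    primers = (nested.inner_f, nested.inner_r, nested.outer_f, nested.outer_r)
    return float(np.mean([_primer_score(p, config) for p in primers]))


def score_infor(
    inner: InnerPair,
    cand: CandidateMsa,
    config: PipelineConfig,
    view: _CandidateView | None = None,
) -> float:
    """Informativeness of the amplified region strictly between the inner primers.

    The mean pairwise nucleotide p-distance of the region is scaled by the
    p-distance cap (default 0.5) and clipped to 1; an empty region scores 0.
    """
    view = view or _CandidateView(cand, config)
    start = inner.forward.block.nt_end
    end = inner.reverse.block.nt_start
    if end <= start:
        return 0.0
    p_dist = view.nt_stats.mean_p_distance(start, end)
    return min(1.0, p_dist / config.p_distance_cap)


def total_score(score_pcr_value: float, score_infor_value: float, pis: float) -> float:
    """Weighted combination of PCR performance and informativeness."""
    if pis < 0:
        raise ValueError(f"PIs must be >= 0, got {pis}")
    return (pis * score_pcr_value + score_infor_value) / (1.0 + pis)


# --- per-locus selection ---------------------------------------------------


def score_nested_sets(
    sets: Sequence[NestedPrimerSet],
    cand: CandidateMsa,
    config: PipelineConfig,
    view: _CandidateView | None = None,
) -> list[NestedPrimerSet]:
    view = view or _CandidateView(cand, config)
    infor_cache: dict[tuple[int, int], float] = {}
    pcr_cache: dict[tuple[int, int, str], float] = {}

    def primer_score_cached(p: DegeneratePrimer) -> float:
        key = (p.block.aa_start, p.block.len_aa, p.orientation)
        if key not in pcr_cache:
            pcr_cache[key] = _primer_score(p, config)
        return pcr_cache[key]

    out = []
    for s in sets:
        pcr = float(
            np.mean([
                primer_score_cached(p)
                for p in (s.inner_f, s.inner_r, s.outer_f, s.outer_r)
            ])
        )
        region = (s.inner_f.block.nt_end, s.inner_r.block.nt_start)
        if region not in infor_cache:
            if region[1] <= region[0]:
                infor_cache[region] = 0.0
            else:
                infor_cache[region] = min(
                    1.0,
                    view.nt_stats.mean_p_distance(*region) / config.p_distance_cap,
                )
        infor = infor_cache[region]
        out.append(
            replace(
                s,
                score_pcr=pcr,
                score_infor=infor,
                total_score=total_score(pcr, infor, config.pis),
            )
        )
    return out


def select_best_per_msa(scored_sets: Sequence[NestedPrimerSet]) -> NestedPrimerSet:
    """Highest Totalscore; deterministic tie-break.

    Ties go to the larger inner product, then the leftmost inner forward
    primer, then the lexicographically smallest concatenated primer string.
    """
    if not scored_sets:
        raise ValueError("no scored nested sets to select from")
    return min(
        scored_sets,
        key=lambda s: (
            -s.total_score,
            -s.inner_product_len_ref,
            s.inner_f.block.nt_start,
            s.outer_f.iupac + s.inner_f.iupac + s.inner_r.iupac + s.outer_r.iupac,
        ),
    )


def design_primers_brute(
    cand: CandidateMsa, config: PipelineConfig
) -> NestedPrimerSet | None:
    """Exhaustive module-2 path: enumerate every nested combination and pick
    the best.  Reference implementation; cost grows as blocks^4."""
    view = _CandidateView(cand, config)
    blocks = find_primer_blocks(cand, config, view)
    if len(blocks) < 2:
        return None
    inner_pairs = enumerate_inner_pairs(blocks, cand, config, view)
    nested: list[NestedPrimerSet] = []
    for pair in inner_pairs:
        nested.extend(find_outer_pairs(pair, blocks, cand, config, view))
    if not nested:
        return None
    scored = score_nested_sets(nested, cand, config, view)
    return select_best_per_msa(scored)


def design_primers_for_candidate(
    cand: CandidateMsa, config: PipelineConfig
) -> NestedPrimerSet | None:
    """Best nested primer set for one candidate alignment; None if none exists.

    Selects the same set as the exhaustive enumeration but in vectorised
    time: because the total score is non-decreasing in each primer's own
    score, the optimum for a fixed inner pair always uses a best-scoring
    outer block on each side, so only those need materialising.  Pairs within
    floating-point reach of the maximum are re-scored exactly through the
    enumeration path, which also reproduces its tie-breaking.
    """
    view = _CandidateView(cand, config)
    blocks = find_primer_blocks(cand, config, view)
    eligible = [b for b in blocks if b.degeneracy <= config.max_primer_degeneracy]
    if len(eligible) < 2:
        return None
    B = len(eligible)
    starts = np.array([b.nt_start for b in eligible])
    ends = np.array([b.nt_end for b in eligible])
    s_fwd = np.empty(B)
    s_rev = np.empty(B)
    iupac_fwd: list[str] = []
    iupac_rev: list[str] = []
    for i, b in enumerate(eligible):
        pf = build_degenerate_primer(b, "forward")
        pr = build_degenerate_primer(b, "reverse")
        s_fwd[i] = _primer_score(pf, config)
        s_rev[i] = _primer_score(pr, config)
        iupac_fwd.append(pf.iupac)
        iupac_rev.append(pr.iupac)
    refcum = view.ref_cum
    flank = config.outer_flank_nt

    # per inner-forward candidate: the best-scoring allowed outer-forward
    # blocks (all score ties kept so downstream tie-breaking stays exact)
    outer_f: list[list[int]] = []
    outer_r: list[list[int]] = []
    for i in range(B):
        ok = np.nonzero(
            (ends <= starts[i]) & (refcum[starts[i]] - refcum[ends] <= flank)
        )[0]
        if ok.size:
            top = s_fwd[ok].max()
            outer_f.append([int(j) for j in ok if s_fwd[j] == top])
        else:
            outer_f.append([])
        ok = np.nonzero(
            (starts >= ends[i]) & (refcum[starts] - refcum[ends[i]] <= flank)
        )[0]
        if ok.size:
            top = s_rev[ok].max()
            outer_r.append([int(j) for j in ok if s_rev[j] == top])
        else:
            outer_r.append([])
    best_of_score = np.array([s_fwd[c[0]] if c else -np.inf for c in outer_f])
    best_or_score = np.array([s_rev[c[0]] if c else -np.inf for c in outer_r])

    lo, hi = config.inner_product_len_range_nt
    product = refcum[ends][None, :] - refcum[starts][:, None]   # [f, r]
    valid = (
        (ends[:, None] <= starts[None, :])
        & (product >= lo)
        & (product <= hi)
        & np.isfinite(best_of_score)[:, None]
        & np.isfinite(best_or_score)[None, :]
    )
    f_idx, r_idx = np.nonzero(valid)
    if f_idx.size == 0:
        return None

    match_cum, comp_cum = view.nt_stats.cumulative
    a = ends[f_idx]       # amplified region between the inner primers
    b = starts[r_idx]
    m = match_cum[:, b] - match_cum[:, a]
    c = comp_cum[:, b] - comp_cum[:, a]
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(c > 0, 1.0 - m / np.maximum(c, 1), np.nan)
        n_ok = (c > 0).sum(axis=0)
        p_dist = np.where(n_ok > 0, np.nansum(ratio, axis=0) / np.maximum(n_ok, 1), 0.0)
    infor = np.minimum(1.0, p_dist / config.p_distance_cap)
    pcr = (s_fwd[f_idx] + s_rev[r_idx] + best_of_score[f_idx] + best_or_score[r_idx]) / 4.0
    total = (config.pis * pcr + infor) / (1.0 + config.pis)

    shortlist = np.nonzero(total >= total.max() - 1e-9)[0]
    sets: list[NestedPrimerSet] = []
    for k in shortlist:
        fi, ri = int(f_idx[k]), int(r_idx[k])
        inner = InnerPair(
            forward=build_degenerate_primer(eligible[fi], "forward"),
            reverse=build_degenerate_primer(eligible[ri], "reverse"),
            product_len_ref=int(product[fi, ri]),
        )
        for of in outer_f[fi]:
            for orv in outer_r[ri]:
                sets.append(
                    NestedPrimerSet(
                        inner_f=inner.forward,
                        inner_r=inner.reverse,
                        outer_f=build_degenerate_primer(eligible[of], "forward"),
                        outer_r=build_degenerate_primer(eligible[orv], "reverse"),
                        inner_product_len_ref=inner.product_len_ref,
                        outer_product_len_ref=view.ref_len(
                            eligible[of].nt_start, eligible[orv].nt_end
                        ),
                    )
                )
    if not sets:
        return None
    scored = score_nested_sets(sets, cand, config, view)
    return select_best_per_msa(scored)


# --- output ----------------------------------------------------------------


def nested_set_to_row(
    locus_id: str, nested: NestedPrimerSet, n_taxa: int
) -> PrimerTableRow:
    return PrimerTableRow(
        locus_id=locus_id,
        outer_forward=nested.outer_f.iupac,
        inner_forward=nested.inner_f.iupac,
        inner_reverse=nested.inner_r.iupac,
        outer_reverse=nested.outer_r.iupac,
        outer_forward_degeneracy=nested.outer_f.degeneracy,
        inner_forward_degeneracy=nested.inner_f.degeneracy,
        inner_reverse_degeneracy=nested.inner_r.degeneracy,
        outer_reverse_degeneracy=nested.outer_r.degeneracy,
        inner_product_len_ref=nested.inner_product_len_ref,
        outer_product_len_ref=nested.outer_product_len_ref,
        ScorePCR=nested.score_pcr,
        ScoreINFOR=nested.score_infor,
        Totalscore=nested.total_score,
        msa_n_taxa=n_taxa,
    )


def reference_region(cand: CandidateMsa, nested: NestedPrimerSet) -> tuple[str, str]:
    """Ungapped reference DNA and peptide of the inner region (primers excluded)."""
    start = nested.inner_f.block.nt_end
    end = nested.inner_r.block.nt_start
    ref = cand.msa.rows[cand.msa.ref_taxon][start:end]
    dna = ref.replace(GAP, "")
    return dna, translate(dna)


def emit_outputs(
    selected: dict[str, NestedPrimerSet],
    candidates: dict[str, CandidateMsa],
    outdir: str | Path,
) -> None:
    """Write the primer table and the reference locus sequences."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [
        nested_set_to_row(locus, nested, candidates[locus].n_taxa)
        for locus, nested in selected.items()
    ]
    write_primer_table(rows, outdir / "primer_table.tsv")
    dna_records, pep_records = [], []
    for locus in sorted(selected):
        dna, pep = reference_region(candidates[locus], selected[locus])
        dna_records.append(SeqRecord(id=locus, seq=dna))
        pep_records.append(SeqRecord(id=locus, seq=pep))
    write_fasta(dna_records, outdir / "reference_NPCLs.dna.fasta")
    write_fasta(pep_records, outdir / "reference_NPCLs.pep.fasta")
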