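"""Protein alignment, codon back-translation, trimming and candidate selection.

One similarity definition is used throughout the pipeline: the identity of
two gapped rows is matches over aligned columns excluding gap-gap pairs,
where a gap against a residue counts as a mismatch and ambiguous residues
(N, X) never match.  Alignment-level similarity is the mean of this over all
unordered row pairs; p-distance is its complement.  ``PairwiseStats``
precomputes prefix sums so any column interval can be scored in constant
time per pair — the primer engine leans on this heavily.

The built-in multiple aligner is a centre-star progressive scheme on top of
optimal pairwise global dynamic programming (BLOSUM62, affine gaps):
the centre is the row with the highest mean pairwise identity and other rows
are merged under the once-a-gap-always-a-gap rule.  An adapter for an
external aligner (MAFFT) is provided for large production runs.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .config import PipelineConfig
from .io import translate
from .orthology import OrthologGroup

logger = logging.getLogger(__name__)

GAP = "-"
_AMBIGUOUS = frozenset("NX")

_PROTEIN_OK = set("ACDEFGHIKLMNPQRSTVWYX*")


class MsaDiscarded(Exception):
    """The whole alignment must be discarded (reason in ``.reason``)."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


# --- similarity primitives -------------------------------------------------


def pairwise_identity(a: str, b: str) -> float:
    """Identity of two equal-length gapped rows.

    Matches over columns excluding gap-gap; gap vs residue is a mismatch;
    N/X never match.  Returns 1.0 when no column is comparable.
    """
    if len(a) != len(b):
        raise ValueError("rows must have equal length")
    matches = 0
    columns = 0
    for x, y in zip(a, b):
        if x == GAP and y == GAP:
            continue
        columns += 1
        if x == y and x not in _AMBIGUOUS:
            matches += 1
    return matches / columns if columns else 1.0


class PairwiseStats:
    """Prefix-summed match/comparable counts for every unordered row pair.

    Lets interval identity and p-distance queries run in O(pairs) instead of
    O(pairs x columns); results are exact integer ratios, identical to the
    brute-force double loop.
    """

    def __init__(self, rows: Sequence[str]):
        if not rows:
            raise ValueError("need at least one row")
        n_cols = len(rows[0])
        if any(len(r) != n_cols for r in rows):
            raise ValueError("rows must have equal length")
        self.n_rows = len(rows)
        self.n_cols = n_cols
        arr = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8)
        arr = arr.reshape(self.n_rows, n_cols)
        gap = arr == ord(GAP)
        ambiguous = (arr == ord("N")) | (arr == ord("X"))
        pairs = [(i, j) for i in range(self.n_rows) for j in range(i + 1, self.n_rows)]
        self.pairs = pairs
        n_pairs = len(pairs)
        match_cum = np.zeros((n_pairs, n_cols + 1), dtype=np.int64)
        comp_cum = np.zeros((n_pairs, n_cols + 1), dtype=np.int64)
        for p, (i, j) in enumerate(pairs):
            comparable = ~(gap[i] & gap[j])
            match = (arr[i] == arr[j]) & comparable & ~ambiguous[i] & ~gap[i]
            match_cum[p, 1:] = np.cumsum(match)
            comp_cum[p, 1:] = np.cumsum(comparable)
        self._match = match_cum
        self._comp = comp_cum

    def pair_counts(self, start: int, end: int) -> tuple[np.ndarray, np.ndarray]:
        """(matches, comparable_columns) per pair on [start, end)."""
        return (
            self._match[:, end] - self._match[:, start],
            self._comp[:, end] - self._comp[:, start],
        )

    @property
    def cumulative(self) -> tuple[np.ndarray, np.ndarray]:
        """(match, comparable) prefix-sum matrices, shape (n_pairs, n_cols+1)."""
        return self._match, self._comp

    def mean_identity(self, start: int, end: int) -> float:
        """Mean over pairs of interval identity; incomparable pairs skipped."""
        m, c = self.pair_counts(start, end)
        mask = c > 0
        if not mask.any():
            return 1.0
        return float(np.mean(m[mask] / c[mask]))

    def mean_p_distance(self, start: int, end: int) -> float:
        m, c = self.pair_counts(start, end)
        mask = c > 0
        if not mask.any():
            return 0.0
        return float(np.mean(1.0 - m[mask] / c[mask]))


def mean_pairwise_identity(rows: Sequence[str]) -> float:
    """Mean pairwise identity of an alignment (>= 2 rows)."""
    if len(rows) < 2:
        raise ValueError("need >= 2 rows")
    return PairwiseStats(rows).mean_identity(0, len(rows[0]))


# --- protein MSA -----------------------------------------------------------


@dataclass
class ProteinMsa:
    rows: dict[str, str]          # taxon -> gapped aa string, insertion-ordered
    ref_taxon: str

    @property
    def n_cols(self) -> int:
        return len(next(iter(self.rows.values())))

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("protein MSA needs >= 2 rows")
        n = self.n_cols
        if any(len(r) != n for r in self.rows.values()):
            raise ValueError("protein MSA rows differ in length")


@dataclass
class CodonMsa:
    rows: dict[str, str]
    ref_taxon: str

    @property
    def n_cols(self) -> int:
        return len(next(iter(self.rows.values())))

    def aa_rows(self, table_id: int = 1) -> dict[str, str]:
        """Per-row amino-acid view: each codon column collapses to one aa."""
        out = {}
        for taxon, row in self.rows.items():
            chars = []
            for i in range(0, len(row), 3):
                codon = row[i : i + 3]
                chars.append(GAP if codon == "---" else translate(codon, table_id) or "X")
            out[taxon] = "".join(chars)
        return out


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    matrix = substitution_matrices.load("BLOSUM62")
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    return aligner


def _sanitize_for_blosum(seq: str) -> str:
    ok = set("ARNDCQEGHILKMFPSTWYVBZX*")
    return "".join(ch if ch in ok else "X" for ch in seq)


def _pairwise_global(aligner, a: str, b: str) -> tuple[str, str]:
    aln = aligner.align(_sanitize_for_blosum(a), _sanitize_for_blosum(b))[0]
    ga, gb = str(aln[0]), str(aln[1])
    # restore original residues (sanitising only affects scoring)
    out_a, out_b = [], []
    ia = ib = 0
    for ca, cb in zip(ga, gb):
        if ca == GAP:
            out_a.append(GAP)
        else:
            out_a.append(a[ia]); ia += 1
        if cb == GAP:
            out_b.append(GAP)
        else:
            out_b.append(b[ib]); ib += 1
    return "".join(out_a), "".join(out_b)


def align_proteins(og: OrthologGroup, config: PipelineConfig | None = None) -> ProteinMsa:
    """Centre-star progressive multiple alignment of an OG's proteins.

    Deterministic for fixed input: the centre is the member with the highest
    mean pairwise identity (ties to the lexicographically smallest taxon) and
    pairwise alignments against the centre are merged with the
    once-a-gap-always-a-gap rule.
    """
    members = og.members
    if len(members) < 2:
        raise ValueError(f"{og.ref_exon_id}: OG needs >= 2 members to align")
    for m in members:
        bad = set(m.protein) - _PROTEIN_OK
        if bad:
            raise ValueError(
                f"{og.ref_exon_id}/{m.taxon}: illegal amino acid {sorted(bad)[0]!r}"
            )
    aligner = _global_aligner()
    taxa = [m.taxon for m in members]
    seqs = {m.taxon: m.protein for m in members}

    # centre selection by mean pairwise identity
    idents = {t: [] for t in taxa}
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            ga, gb = _pairwise_global(aligner, seqs[taxa[i]], seqs[taxa[j]])
            ident = pairwise_identity(ga, gb)
            idents[taxa[i]].append(ident)
            idents[taxa[j]].append(ident)
    centre = min(taxa, key=lambda t: (-float(np.mean(idents[t])), t))

    centre_seq = seqs[centre]
    others = [t for t in taxa if t != centre]
    # per-other alignment expressed as (insertions before centre residue k, row chars)
    L = len(centre_seq)
    master = [0] * (L + 1)
    parsed: dict[str, tuple[list[str], list[str]]] = {}
    for t in others:
        gc, gr = _pairwise_global(aligner, centre_seq, seqs[t])
        ins: list[str] = [""] * (L + 1)   # other-row residues where centre has gaps
        aligned: list[str] = []           # other-row char per centre residue
        k = 0
        for cc, cr in zip(gc, gr):
            if cc == GAP:
                ins[k] += cr
            else:
                aligned.append(cr)
                k += 1
        parsed[t] = (ins, aligned)
        for k in range(L + 1):
            master[k] = max(master[k], len(ins[k]))

    rows: dict[str, str] = {}
    centre_row = []
    for k in range(L):
        centre_row.append(GAP * master[k] + centre_seq[k])
    centre_row.append(GAP * master[L])
    rows[centre] = "".join(centre_row)
    for t in others:
        ins, aligned = parsed[t]
        chunks = []
        for k in range(L):
            chunks.append(ins[k] + GAP * (master[k] - len(ins[k])) + aligned[k])
        chunks.append(ins[L] + GAP * (master[L] - len(ins[L])))
        rows[t] = "".join(chunks)

    ref_taxon = next(m.taxon for m in members if m.role == "reference")
    ordered = {t: rows[t] for t in taxa}
    return ProteinMsa(rows=ordered, ref_taxon=ref_taxon)


def align_proteins_mafft(og: OrthologGroup) -> ProteinMsa:
    """External-aligner adapter (MAFFT); requires ``mafft`` on PATH."""
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "og.fasta"
        with open(fasta, "w") as fh:
            for m in og.members:
                fh.write(f">{m.taxon}\n{m.protein}\n")
        result = subprocess.run(
            ["mafft", "--auto", "--quiet", str(fasta)],
            capture_output=True, text=True, check=True,
        )
    rows: dict[str, str] = {}
    taxon = None
    for line in result.stdout.splitlines():
        if line.startswith(">"):
            taxon = line[1:].strip()
            rows[taxon] = ""
        elif taxon:
            rows[taxon] += line.strip().upper()
    ref_taxon = next(m.taxon for m in og.members if m.role == "reference")
    return ProteinMsa(rows=rows, ref_taxon=ref_taxon)


# --- codon back-translation ------------------------------------------------


def back_translate_alignment(
    pmsa: ProteinMsa, og: OrthologGroup, table_id: int = 1
) -> CodonMsa:
    """Expand each aligned amino acid to its source codon; gaps become ``---``.

    Every protein row must be the exact translation of the member's DNA; a
    mismatch is an error naming the taxon and position.
    """
    dna_by_taxon = {m.taxon: m.dna for m in og.members}
    rows: dict[str, str] = {}
    for taxon, aa_row in pmsa.rows.items():
        dna = dna_by_taxon[taxon]
        expected = translate(dna, table_id)
        chunks: list[str] = []
        pos = 0
        for col, aa in enumerate(aa_row):
            if aa == GAP:
                chunks.append("---")
                continue
            if pos >= len(expected) or expected[pos] != aa:
                raise ValueError(
                    f"protein/DNA mismatch for {taxon} at alignment column {col}: "
                    f"alignment has {aa!r}, translation has "
                    f"{expected[pos] if pos < len(expected) else '<end>'!r}"
                )
            chunks.append(dna[3 * pos : 3 * pos + 3])
            pos += 1
        if pos != len(expected):
            raise ValueError(
                f"protein/DNA mismatch for {taxon}: alignment uses {pos} residues, "
                f"translation has {len(expected)}"
            )
        rows[taxon] = "".join(chunks)
    return CodonMsa(rows=rows, ref_taxon=pmsa.ref_taxon)


# --- trimming and row filters ----------------------------------------------


def trim_to_reference(cmsa: CodonMsa) -> CodonMsa:
    """Remove columns outside the reference row's first/last non-gap codon."""
    ref = cmsa.rows.get(cmsa.ref_taxon)
    if ref is None:
        raise ValueError(f"reference row {cmsa.ref_taxon!r} missing")
    codons = [ref[i : i + 3] for i in range(0, len(ref), 3)]
    non_gap = [i for i, c in enumerate(codons) if c != "---"]
    if not non_gap:
        raise ValueError("reference row is all gaps")
    start, end = 3 * non_gap[0], 3 * (non_gap[-1] + 1)
    rows = {t: r[start:end] for t, r in cmsa.rows.items()}
    return CodonMsa(rows=rows, ref_taxon=cmsa.ref_taxon)


def drop_gappy_sequences(cmsa: CodonMsa, max_missing_fraction: float) -> CodonMsa:
    """Drop rows whose N+gap fraction strictly exceeds the threshold.

    The reference row is never dropped: if it exceeds the threshold the whole
    alignment is discarded.
    """
    rows = {}
    for taxon, row in cmsa.rows.items():
        missing = sum(1 for ch in row if ch == GAP or ch == "N") / len(row)
        if missing > max_missing_fraction:
            if taxon == cmsa.ref_taxon:
                raise MsaDiscarded("reference_too_gappy")
            continue
        rows[taxon] = row
    return CodonMsa(rows=rows, ref_taxon=cmsa.ref_taxon)


def drop_dissimilar_sequences(cmsa: CodonMsa, min_avg_similarity: float) -> CodonMsa:
    """Iteratively drop the row least similar to the rest while below cutoff.

    After each removal the mean pairwise identities are recomputed.  If the
    reference row itself is the offender the alignment is discarded.
    """
    rows = dict(cmsa.rows)
    while len(rows) >= 2:
        taxa = list(rows)
        stats = PairwiseStats([rows[t] for t in taxa])
        n = len(taxa)
        sums = np.zeros(n)
        counts = np.zeros(n)
        m, c = stats.pair_counts(0, stats.n_cols)
        for p, (i, j) in enumerate(stats.pairs):
            ident = m[p] / c[p] if c[p] else 1.0
            sums[i] += ident; counts[i] += 1
            sums[j] += ident; counts[j] += 1
        means = sums / counts
        worst = int(np.lexsort((taxa, means))[0])
        if means[worst] >= min_avg_similarity:
            break
        taxon = taxa[worst]
        if taxon == cmsa.ref_taxon:
            raise MsaDiscarded("reference_dissimilar")
        del rows[taxon]
    return CodonMsa(rows=rows, ref_taxon=cmsa.ref_taxon)


# --- candidate selection ---------------------------------------------------


@dataclass
class CandidateMsa:
    """A codon alignment trimmed to its terminal conserved blocks."""

    msa: CodonMsa
    left_block_start: int     # aa column index (post-trim this is 0)
    right_block_start: int
    mean_pairwise_identity_nt: float

    @property
    def n_cols_nt(self) -> int:
        return self.msa.n_cols

    @property
    def n_taxa(self) -> int:
        return len(self.msa.rows)


@dataclass
class MsaRejection:
    reason: str               # no_blocks | too_short | too_conserved


def block_similarity(aa_stats: PairwiseStats, start: int, length: int) -> float:
    """Mean over row pairs of identity within an aa window."""
    return aa_stats.mean_identity(start, start + length)


def select_candidate_msa(
    cmsa: CodonMsa, config: PipelineConfig
) -> CandidateMsa | MsaRejection:
    """Trim to the outermost conserved terminal blocks and apply final filters.

    Scanning aa windows of the terminal block length from the left and the
    right, the first window on each side whose block similarity strictly
    exceeds the cutoff becomes a terminal block.  The alignment is trimmed to
    the two blocks inclusive and rejected if the blocks do not exist or
    coincide (``no_blocks``), if the trimmed length does not exceed the
    minimum (``too_short``), or if the trimmed alignment's mean pairwise
    nucleotide identity strictly exceeds the conservation ceiling
    (``too_conserved``).
    """
    if len(cmsa.rows) < 2:
        return MsaRejection("no_blocks")
    block_len = config.terminal_block_len_aa
    aa_rows = list(cmsa.aa_rows(config.genetic_code_table).values())
    n_aa = len(aa_rows[0])
    if n_aa < block_len:
        return MsaRejection("no_blocks")
    aa_stats = PairwiseStats(aa_rows)
    n_windows = n_aa - block_len + 1
    left = None
    for w in range(n_windows):
        if block_similarity(aa_stats, w, block_len) > config.block_min_similarity:
            left = w
            break
    right = None
    for w in range(n_windows - 1, -1, -1):
        if block_similarity(aa_stats, w, block_len) > config.block_min_similarity:
            right = w
            break
    if left is None or right is None or right <= left:
        return MsaRejection("no_blocks")
    nt_start, nt_end = 3 * left, 3 * (right + block_len)
    trimmed = CodonMsa(
        rows={t: r[nt_start:nt_end] for t, r in cmsa.rows.items()},
        ref_taxon=cmsa.ref_taxon,
    )
    if trimmed.n_cols <= config.min_candidate_len_nt:
        return MsaRejection("too_short")
    identity = mean_pairwise_identity(list(trimmed.rows.values()))
    if identity > config.max_msa_similarity:
        return MsaRejection("too_conserved")
    return CandidateMsa(
        msa=trimmed,
        left_block_start=0,
        right_block_start=right - left,
        mean_pairwise_identity_nt=identity,
    )
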