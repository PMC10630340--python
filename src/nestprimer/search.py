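"""Similarity-search backend: BLAST-like contracts on exact local alignment.

Three search modes are provided: nucleotide vs nucleotide (both strands),
protein vs DNA (six-frame translated subject, TBLASTN-like) and DNA vs
protein (six-frame translated query, BLASTX-like).  Alignment itself is
optimal affine-gap local dynamic programming (Biopython's C implementation);
a shared-k-mer prefilter decides which query/subject pairs are worth the DP
and falls back to an exhaustive scan whenever the seeded pass fails to
explain most of the query (no hit, or best coverage below a floor), so the
heuristic can never silently lose a divergent homolog.  Secondary hits
within one subject are recovered by masking previous hit regions with a
sentinel residue and re-aligning.

Hit statistics follow tabular-search conventions: percent identity is
matches over aligned columns (gap columns counted, N/X never match) and
coverage is aligned query residues over query length.  Coordinates are
0-based half-open on the forward strand of the original sequences.
"""

from __future__ import annotations


from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .config import PipelineConfig
from .io import SeqRecord, reverse_complement, translate

Mode = Literal["nt_nt", "prot_vs_dna", "dna_vs_prot"]

_MASK = "#"
_NEVER_MATCH = frozenset("NX*" + _MASK)

_NT_ALPHABET = "ACGTN" + _MASK


def _nt_matrix(match: float, mismatch: float) -> substitution_matrices.Array:
    m = substitution_matrices.Array(alphabet=_NT_ALPHABET, dims=2)
    for a in _NT_ALPHABET:
        for b in _NT_ALPHABET:
            if a == _MASK or b == _MASK:
                m[a, b] = -1000.0
            elif a == "N" or b == "N":
                m[a, b] = mismatch
            else:
                m[a, b] = match if a == b else mismatch
    return m


def _prot_matrix() -> substitution_matrices.Array:
    blosum = substitution_matrices.load("BLOSUM62")
    alphabet = str(blosum.alphabet) + _MASK
    m = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if a == _MASK or b == _MASK:
                m[a, b] = -1000.0
            else:
                m[a, b] = blosum[a, b]
    return m


@dataclass
class SearchParams:
    nt_match_score: float = 2.0
    nt_mismatch_score: float = -3.0
    nt_open_gap_score: float = -7.0
    nt_extend_gap_score: float = -2.0
    prot_open_gap_score: float = -12.0
    prot_extend_gap_score: float = -1.0
    nt_min_hit_score: float = 60.0
    prot_min_hit_score: float = 40.0
    nt_kmer_size: int = 11
    prot_kmer_size: int = 5
    max_hits_per_subject: int = 4
    fallback_min_coverage: float = 0.5
    genetic_code_table: int = 1

    @classmethod
    def from_config(cls, config: PipelineConfig) -> "SearchParams":
        return cls(
            nt_match_score=config.nt_match_score,
            nt_mismatch_score=config.nt_mismatch_score,
            nt_open_gap_score=config.nt_open_gap_score,
            nt_extend_gap_score=config.nt_extend_gap_score,
            prot_open_gap_score=config.prot_open_gap_score,
            prot_extend_gap_score=config.prot_extend_gap_score,
            nt_min_hit_score=config.nt_min_hit_score,
            prot_min_hit_score=config.prot_min_hit_score,
            nt_kmer_size=config.nt_kmer_size,
            prot_kmer_size=config.prot_kmer_size,
            max_hits_per_subject=config.max_hits_per_subject,
            fallback_min_coverage=config.fallback_min_coverage,
            genetic_code_table=config.genetic_code_table,
        )


@dataclass
class SearchHit:
    query_id: str
    subject_id: str
    percent_identity: float          # in [0, 100]
    query_coverage: float            # in [0, 1], on the query
    score: float
    query_interval: tuple[int, int]  # 0-based half-open, original query coords
    subject_interval: tuple[int, int]
    subject_strand: str              # '+' or '-'
    frame: int | None                # -3..+3 (translated modes) or None
    rank: int = 0


# --- query/subject expansion into alignable units --------------------------


@dataclass
class _Unit:
    """A single alignable string derived from a record (strand/frame variant)."""

    record: SeqRecord
    seq: str
    strand: str = "+"
    frame: int | None = None
    offset: int = 0      # frame offset into the nt sequence
    translated: bool = False

    def map_interval(self, start: int, end: int) -> tuple[int, int]:
        """Map a unit-coordinate interval back to original forward-strand coords."""
        if not self.translated:
            if self.strand == "+":
                return start, end
            n = len(self.record.seq)
            return n - end, n - start
        nt_start = self.offset + 3 * start
        nt_end = self.offset + 3 * end
        if self.strand == "+":
            return nt_start, nt_end
        n = len(self.record.seq)
        return n - nt_end, n - nt_start


def _sanitize_nt(seq: str) -> str:
    return "".join(ch if ch in "ACGT" else "N" for ch in seq)


_PROT_OK = set("ARNDCQEGHILKMFPSTWYVBZX*")


def _sanitize_prot(seq: str) -> str:
    return "".join(ch if ch in _PROT_OK else "X" for ch in seq)


def _six_frames(record: SeqRecord, table: int) -> list[_Unit]:
    units = []
    seq = _sanitize_nt(record.seq)
    rc = reverse_complement(seq)
    for strand, s in (("+", seq), ("-", rc)):
        for off in range(3):
            n_codons = (len(s) - off) // 3
            if n_codons <= 0:
                continue
            prot = _sanitize_prot(translate(s[off : off + 3 * n_codons], table))
            units.append(
                _Unit(
                    record=record,
                    seq=prot,
                    strand=strand,
                    frame=(off + 1) if strand == "+" else -(off + 1),
                    offset=off,
                    translated=True,
                )
            )
    return units


def _query_units(record: SeqRecord, mode: Mode, table: int) -> list[_Unit]:
    if mode == "dna_vs_prot":
        return _six_frames(record, table)
    if mode == "nt_nt":
        return [_Unit(record=record, seq=_sanitize_nt(record.seq))]
    return [_Unit(record=record, seq=_sanitize_prot(record.seq))]


def _subject_units(record: SeqRecord, mode: Mode, table: int) -> list[_Unit]:
    if mode == "prot_vs_dna":
        return _six_frames(record, table)
    if mode == "nt_nt":
        seq = _sanitize_nt(record.seq)
        return [
            _Unit(record=record, seq=seq, strand="+"),
            _Unit(record=record, seq=reverse_complement(seq), strand="-"),
        ]
    return [_Unit(record=record, seq=_sanitize_prot(record.seq))]


def _aligner(alphabet: Literal["nt", "prot"], params: SearchParams, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    if alphabet == "nt":
        aligner.substitution_matrix = _nt_matrix(
            params.nt_match_score, params.nt_mismatch_score
        )
        aligner.open_gap_score = params.nt_open_gap_score
        aligner.extend_gap_score = params.nt_extend_gap_score
    else:
        aligner.substitution_matrix = _prot_matrix()
        aligner.open_gap_score = params.prot_open_gap_score
        aligner.extend_gap_score = params.prot_extend_gap_score
    return aligner


def _alignment_stats(alignment) -> tuple[int, int, tuple[int, int], tuple[int, int]]:
    """(matches, columns, target_interval, query_interval) of a local alignment."""
    t_blocks, q_blocks = alignment.aligned
    if len(t_blocks) == 0:
        return 0, 0, (0, 0), (0, 0)
    target = str(alignment.target)
    query = str(alignment.query)
    matches = 0
    columns = 0
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if prev_t is not None:
            columns += (ts - prev_t) + (qs - prev_q)
        for a, b in zip(target[ts:te], query[qs:qe]):
            if a == b and a not in _NEVER_MATCH:
                matches += 1
        columns += te - ts
        prev_t, prev_q = te, qe
    t_iv = (int(t_blocks[0][0]), int(t_blocks[-1][1]))
    q_iv = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
    return matches, columns, t_iv, q_iv


def _kmers(seq: str, k: int) -> set[str]:
    if len(seq) < k:
        return set()
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def search(
    queries: Sequence[SeqRecord],
    subjects: Sequence[SeqRecord],
    mode: Mode,
    params: SearchParams | None = None,
) -> list[SearchHit]:
    """All local alignments above the score threshold, ranked per query.

    Rank 1 is the best hit for that query; ties are broken by subject id and
    then by leftmost subject start, so results are fully deterministic.
    """
    if not queries or not subjects:
        raise ValueError("queries and subjects must be non-empty")
    params = params or SearchParams()
    table = params.genetic_code_table

    alphabet: Literal["nt", "prot"] = "nt" if mode == "nt_nt" else "prot"
    min_score = params.nt_min_hit_score if alphabet == "nt" else params.prot_min_hit_score
    k = params.nt_kmer_size if alphabet == "nt" else params.prot_kmer_size
    aligner = _aligner(alphabet, params, "local")

    subject_units: list[_Unit] = []
    for s in subjects:
        subject_units.extend(_subject_units(s, mode, table))
    unit_kmers = [_kmers(u.seq, k) for u in subject_units]

    all_hits: list[SearchHit] = []
    for q in queries:
        q_units = [qu for qu in _query_units(q, mode, table) if qu.seq]
        query_nt_len = len(q.seq)
        hits: list[SearchHit] = []
        seeded: set[tuple[int, int]] = set()
        for qi, qu in enumerate(q_units):
            qk = _kmers(qu.seq, k)
            for i, sk in enumerate(unit_kmers):
                if len(subject_units[i].seq) < k or (qk & sk):
                    seeded.add((qi, i))
                    hits.extend(
                        _align_pair(
                            aligner, qu, subject_units[i], mode, min_score,
                            params.max_hits_per_subject, query_nt_len,
                        )
                    )
        best_cov = max((h.query_coverage for h in hits), default=0.0)
        if best_cov < params.fallback_min_coverage:
            # seeds explained too little of the query: exhaustive fallback so
            # divergent homologs without a useful exact shared k-mer are still
            # found (or their absence is proven, not assumed)
            for qi, qu in enumerate(q_units):
                for i, su in enumerate(subject_units):
                    if (qi, i) in seeded:
                        continue
                    hits.extend(
                        _align_pair(
                            aligner, qu, su, mode, min_score,
                            params.max_hits_per_subject, query_nt_len,
                        )
                    )
        hits.sort(key=lambda h: (-h.score, h.subject_id, h.subject_interval[0], h.subject_strand, h.frame or 0))
        for rank, h in enumerate(hits, start=1):
            h.rank = rank
        all_hits.extend(hits)
    return all_hits


def _align_pair(
    aligner: Align.PairwiseAligner,
    qu: _Unit,
    su: _Unit,
    mode: Mode,
    min_score: float,
    max_hits: int,
    query_nt_len: int,
) -> list[SearchHit]:
    hits: list[SearchHit] = []
    subject_seq = su.seq
    for _ in range(max_hits):
        if not subject_seq:
            break
        alignments = aligner.align(subject_seq, qu.seq)
        if alignments.score < min_score:
            break
        best = alignments[0]
        matches, columns, t_iv, q_iv = _alignment_stats(best)
        if columns == 0 or t_iv[1] <= t_iv[0]:
            break
        pid = 100.0 * matches / columns
        q_start, q_end = qu.map_interval(*q_iv)
        aligned_q = q_iv[1] - q_iv[0]
        if qu.translated:
            aligned_q *= 3
        coverage = aligned_q / query_nt_len
        s_start, s_end = su.map_interval(*t_iv)
        frame = qu.frame if qu.translated else su.frame
        strand = su.strand
        hits.append(
            SearchHit(
                query_id=qu.record.id,
                subject_id=su.record.id,
                percent_identity=pid,
                query_coverage=coverage,
                score=float(alignments.score),
                query_interval=(q_start, q_end),
                subject_interval=(s_start, s_end),
                subject_strand=strand,
                frame=frame,
            )
        )
        subject_seq = (
            subject_seq[: t_iv[0]] + _MASK * (t_iv[1] - t_iv[0]) + subject_seq[t_iv[1] :]
        )
    return hits


def best_hits(hits: Iterable[SearchHit]) -> dict[str, SearchHit]:
    """Rank-1 hit per query id."""
    out: dict[str, SearchHit] = {}
    for h in hits:
        if h.rank == 1:
            out[h.query_id] = h
    return out


# --- mutual best hit -------------------------------------------------------


@dataclass
class SubjectRegion:
    """A strand-resolved region of a subject record, reading-frame oriented."""

    subject_id: str
    interval: tuple[int, int]   # forward-strand coordinates
    strand: str
    frame: int | None
    seq: str                    # oriented 5'->3' in the hit's reading direction
    score: float


def extract_region(subject: SeqRecord, hit: SearchHit) -> SubjectRegion:
    start, end = hit.subject_interval
    seq = subject.seq[start:end]
    if hit.subject_strand == "-":
        seq = reverse_complement(seq)
    return SubjectRegion(
        subject_id=subject.id,
        interval=(start, end),
        strand=hit.subject_strand,
        frame=hit.frame,
        seq=seq,
        score=hit.score,
    )


_REVERSE_MODE: dict[Mode, Mode] = {
    "nt_nt": "nt_nt",
    "prot_vs_dna": "dna_vs_prot",
    "dna_vs_prot": "prot_vs_dna",
}


def mutual_best_hit(
    query_set: Sequence[SeqRecord],
    forward_db: Sequence[SeqRecord],
    reverse_db: Sequence[SeqRecord],
    mode: Mode,
    params: SearchParams | None = None,
) -> list[tuple[str, SubjectRegion]]:
    """Reciprocal rank-1 pairs between a query set and a database.

    A pair (q, region) is returned iff region is q's best hit in
    ``forward_db`` and q's record is the best hit when the extracted region
    is searched back against ``reverse_db`` (the reverse database must use
    the query set's ids).
    """
    params = params or SearchParams()
    forward = best_hits(search(query_set, forward_db, mode, params))
    if not forward:
        return []
    by_id = {s.id: s for s in forward_db}
    regions: dict[str, SubjectRegion] = {}
    region_records: list[SeqRecord] = []
    for qid, hit in forward.items():
        region = extract_region(by_id[hit.subject_id], hit)
        regions[qid] = region
        region_records.append(SeqRecord(id=f"{qid}\x1fregion", seq=region.seq))
    reverse = best_hits(
        search(region_records, reverse_db, _REVERSE_MODE[mode], params)
    )
    pairs: list[tuple[str, SubjectRegion]] = []
    for qid in sorted(regions):
        back = reverse.get(f"{qid}\x1fregion")
        if back is not None and back.subject_id == qid:
            pairs.append((qid, regions[qid]))
    return pairs
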