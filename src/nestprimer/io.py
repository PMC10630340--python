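"""FASTA and primer-table I/O plus the shared sequence utilities.

Sequence records are uppercased on input and validated against an explicit
alphabet; ``N`` (nucleotide) and ``X`` (amino acid) are legal residues but
never count as matches anywhere downstream.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

Alphabet = Literal["dna", "protein"]

# IUPAC nucleotide one-letter codes (sequence input side)
DNA_LETTERS = set("ACGTNRYSWKMBDHV")
PROTEIN_LETTERS = set("ACDEFGHIKLMNPQRSTVWYX*")

_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB"
)


@dataclass
class SeqRecord:
    """One FASTA record; ``seq`` is an uppercase residue string."""

    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _codon_map(table_id: int) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = dict(table.forward_table)
    for codon in table.stop_codons:
        mapping[codon] = "*"
    return mapping


_CODON_CACHE: dict[int, dict[str, str]] = {}


def translate(dna: str, table_id: int = 1) -> str:
    """Translate an in-frame nucleotide string; ambiguous codons give 'X'.

    Trailing nucleotides beyond the last complete codon are ignored.
    """
    if table_id not in _CODON_CACHE:
        _CODON_CACHE[table_id] = _codon_map(table_id)
    codons = _CODON_CACHE[table_id]
    out = []
    for i in range(0, len(dna) - len(dna) % 3, 3):
        out.append(codons.get(dna[i : i + 3], "X"))
    return "".join(out)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path, alphabet: Alphabet) -> list[SeqRecord]:
    """Read a (possibly gzipped) FASTA file with alphabet validation.

    Raises ``ValueError`` on a duplicate id or on an illegal residue, naming
    the offending id/position.
    """
    letters = DNA_LETTERS if alphabet == "dna" else PROTEIN_LETTERS
    records: list[SeqRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate id: {rec.id}")
            seen.add(rec.id)
            seq = str(rec.seq).upper().replace("\r", "").replace(" ", "")
            if not seq:
                raise ValueError(f"empty sequence for id: {rec.id}")
            for pos, ch in enumerate(seq):
                if ch not in letters:
                    raise ValueError(
                        f"illegal {alphabet} residue {ch!r} in {rec.id} at position {pos}"
                    )
            if alphabet == "protein" and "*" in seq[:-1]:
                pos = seq.index("*")
                raise ValueError(
                    f"internal stop '*' in {rec.id} at position {pos}"
                )
            description = rec.description
            if description.startswith(rec.id):
                description = description[len(rec.id):].strip()
            records.append(SeqRecord(id=rec.id, seq=seq, description=description))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# --- primer table ----------------------------------------------------------

PRIMER_TABLE_COLUMNS = [
    "locus_id",
    "outer_forward",
    "inner_forward",
    "inner_reverse",
    "outer_reverse",
    "outer_forward_degeneracy",
    "inner_forward_degeneracy",
    "inner_reverse_degeneracy",
    "outer_reverse_degeneracy",
    "inner_product_len_ref",
    "outer_product_len_ref",
    "ScorePCR",
    "ScoreINFOR",
    "Totalscore",
    "msa_n_taxa",
]

_FLOAT_COLUMNS = ("ScorePCR", "ScoreINFOR", "Totalscore")


@dataclass
class PrimerTableRow:
    locus_id: str
    outer_forward: str
    inner_forward: str
    inner_reverse: str
    outer_reverse: str
    outer_forward_degeneracy: int
    inner_forward_degeneracy: int
    inner_reverse_degeneracy: int
    outer_reverse_degeneracy: int
    inner_product_len_ref: int
    outer_product_len_ref: int
    ScorePCR: float
    ScoreINFOR: float
    Totalscore: float
    msa_n_taxa: int


def write_primer_table(rows: list[PrimerTableRow], path: str | Path) -> None:
    """Write the nested-PCR primer table as TSV.

    Rows are ordered by descending Totalscore, ties broken by ascending
    locus_id; floats are printed with 4 decimals.
    """
    data = [vars(r).copy() for r in rows]
    df = pd.DataFrame(data, columns=PRIMER_TABLE_COLUMNS)
    df = df.sort_values(
        ["Totalscore", "locus_id"], ascending=[False, True], kind="mergesort"
    )
    for col in _FLOAT_COLUMNS:
        df[col] = df[col].map(lambda x: f"{x:.4f}")
    df.to_csv(path, sep="\t", index=False)


def read_primer_table(path: str | Path) -> list[PrimerTableRow]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != PRIMER_TABLE_COLUMNS:
        raise ValueError(f"unexpected primer table columns in {path}")
    rows = []
    for _, rec in df.iterrows():
        rows.append(
            PrimerTableRow(
                locus_id=rec["locus_id"],
                outer_forward=rec["outer_forward"],
                inner_forward=rec["inner_forward"],
                inner_reverse=rec["inner_reverse"],
                outer_reverse=rec["outer_reverse"],
                outer_forward_degeneracy=int(rec["outer_forward_degeneracy"]),
                inner_forward_degeneracy=int(rec["inner_forward_degeneracy"]),
                inner_reverse_degeneracy=int(rec["inner_reverse_degeneracy"]),
                outer_reverse_degeneracy=int(rec["outer_reverse_degeneracy"]),
                inner_product_len_ref=int(rec["inner_product_len_ref"]),
                outer_product_len_ref=int(rec["outer_product_len_ref"]),
                ScorePCR=float(rec["ScorePCR"]),
                ScoreINFOR=float(rec["ScoreINFOR"]),
                Totalscore=float(rec["Totalscore"]),
                msa_n_taxa=int(rec["msa_n_taxa"]),
            )
        )
    return rows
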