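"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive pure Python: affine-gap dynamic
programming written from the recurrences, double-loop identity counting and
explicit IUPAC expansion.  None of it shares code with the package paths it
checks.
"""

from __future__ import annotations

import itertools

NEG = float("-inf")

# same convention as the backend: the first residue of a gap costs `open_`,
# every further residue `extend`


def sw_local_score(a: str, b: str, score_fn, open_: float, extend: float) -> float:
    """Optimal affine-gap Smith-Waterman local alignment score (Gotoh)."""
    n, m = len(a), len(b)
    best = 0.0
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in a (consumes b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in b (consumes a)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + open_, E[i][j - 1] + extend)
            F[i][j] = max(H[i - 1][j] + open_, F[i - 1][j] + extend)
            diag = H[i - 1][j - 1] + score_fn(a[i - 1], b[j - 1])
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def nw_global_score(a: str, b: str, score_fn, open_: float, extend: float) -> float:
    """Optimal affine-gap global alignment score (end gaps penalised)."""
    n, m = len(a), len(b)
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    H[0][0] = 0.0
    for j in range(1, m + 1):
        E[0][j] = open_ + extend * (j - 1)
        H[0][j] = E[0][j]
    for i in range(1, n + 1):
        F[i][0] = open_ + extend * (i - 1)
        H[i][0] = F[i][0]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + open_, E[i][j - 1] + extend)
            F[i][j] = max(H[i - 1][j] + open_, F[i - 1][j] + extend)
            H[i][j] = max(
                H[i - 1][j - 1] + score_fn(a[i - 1], b[j - 1]), E[i][j], F[i][j]
            )
    return H[n][m]


def nt_score_fn(match: float = 2.0, mismatch: float = -3.0):
    def fn(x: str, y: str) -> float:
        if x == "N" or y == "N":
            return mismatch
        return match if x == y else mismatch
    return fn


def brute_identity(a: str, b: str) -> float:
    """Row identity: matches / columns excluding gap-gap; N/X never match."""
    matches = 0
    columns = 0
    for x, y in zip(a, b):
        if x == "-" and y == "-":
            continue
        columns += 1
        if x == y and x not in "NX":
            matches += 1
    return matches / columns if columns else 1.0


def brute_mean_identity(rows: list[str]) -> float:
    pairs = [
        brute_identity(rows[i], rows[j])
        for i in range(len(rows))
        for j in range(i + 1, len(rows))
    ]
    return sum(pairs) / len(pairs)


def brute_mean_p_distance(rows: list[str], start: int, end: int) -> float:
    vals = []
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            a, b = rows[i][start:end], rows[j][start:end]
            comparable = sum(
                1 for x, y in zip(a, b) if not (x == "-" and y == "-")
            )
            if comparable == 0:
                continue
            matches = sum(
                1 for x, y in zip(a, b)
                if x == y and x != "-" and x not in "NX"
            )
            vals.append(1.0 - matches / comparable)
    return sum(vals) / len(vals) if vals else 0.0


IUPAC_EXPAND = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def enumerate_degeneracy(iupac: str) -> int:
    """Count the concrete sequences an IUPAC string encodes, by enumeration."""
    return sum(1 for _ in itertools.product(*(IUPAC_EXPAND[ch] for ch in iupac)))
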