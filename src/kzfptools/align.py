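"""Global affine-gap alignment of sequences and profiles.

The progressive multiple aligner used for per-cluster consensus building:
a guide order is derived from k-mer (k=6) profile distances by greedy
joining, and sequences are folded into a growing alignment with
profile-profile global Gotoh dynamic programming under sum-of-pairs column
scoring (average score over non-gap residue pairs; ambiguity codes score 0).

Gap cost convention: a gap of length L costs ``gap_open + (L-1)*gap_extend``
(the opening penalty covers the first gapped column).

The O(mn) Gotoh fill is JIT-compiled with numba when available; a plain
Python fallback keeps the module importable without it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .intervals import SequenceRecord

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit
except Exception:  # pragma: no cover
    def _njit(*args, **kwargs):
        def deco(f):
            return f
        return deco(*args) if args and callable(args[0]) else deco

DNA_ALPHABET = "ACGT"
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NEG = -1e30


@dataclass(frozen=True)
class AlignParams:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0
    alphabet: str = DNA_ALPHABET

    def substitution_matrix(self) -> np.ndarray:
        """(k+1)x(k+1) residue score matrix; the last row/column is the
        ambiguity code (N/X), scoring 0 against everything."""
        k = len(self.alphabet)
        s = np.full((k + 1, k + 1), self.mismatch)
        np.fill_diagonal(s, self.match)
        s[k, :] = 0.0
        s[:, k] = 0.0
        return s


@dataclass(frozen=True)
class Msa:
    """A multiple sequence alignment: equal-length gapped rows."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple((i, s) for i, s in self.rows))
        lens = {len(s) for _, s in self.rows}
        if len(lens) > 1:
            raise ValueError("MSA rows must all have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def degapped(self, row: int) -> str:
        return self.rows[row][1].replace("-", "")

    def to_fasta(self) -> str:
        from .io import serialize_fasta

        return serialize_fasta([SequenceRecord(i, s) for i, s in self.rows])


def _encode(seq: str, alphabet: str) -> np.ndarray:
    lut = np.full(128, len(alphabet), dtype=np.int64)  # unknown -> ambiguity slot
    for i, a in enumerate(alphabet):
        lut[ord(a)] = i
        lut[ord(a.lower())] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _profile_counts(rows: Sequence[str], alphabet: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-column residue counts (k+1 slots, ambiguity last) and non-gap counts."""
    k = len(alphabet)
    ncol = len(rows[0])
    counts = np.zeros((ncol, k + 1))
    for row in rows:
        for j, ch in enumerate(row):
            if ch != "-":
                counts[j, _char_slot(ch, alphabet)] += 1
    nongap = counts.sum(axis=1)
    return counts, nongap


def _char_slot(ch: str, alphabet: str) -> int:
    i = alphabet.find(ch.upper())
    return i if i >= 0 else len(alphabet)


@_njit(cache=True)
def _gotoh_fill(S, gap_open, gap_extend):  # pragma: no cover - numba kernel
    m, n = S.shape
    M = np.full((m + 1, n + 1), NEG)
    X = np.full((m + 1, n + 1), NEG)  # gap in second profile (vertical)
    Y = np.full((m + 1, n + 1), NEG)  # gap in first profile (horizontal)
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, n + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            best_prev = M[i - 1, j - 1]
            if X[i - 1, j - 1] > best_prev:
                best_prev = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > best_prev:
                best_prev = Y[i - 1, j - 1]
            M[i, j] = best_prev + S[i - 1, j - 1]
            a = M[i - 1, j] + gap_open
            b = X[i - 1, j] + gap_extend
            c = Y[i - 1, j] + gap_open
            X[i, j] = a if a >= b else b
            if c > X[i, j]:
                X[i, j] = c
            a = M[i, j - 1] + gap_open
            b = Y[i, j - 1] + gap_extend
            c = X[i, j - 1] + gap_open
            Y[i, j] = a if a >= b else b
            if c > Y[i, j]:
                Y[i, j] = c
    return M, X, Y


def _traceback(M, X, Y, gap_open, gap_extend, S):
    """Recover one optimal path; ties prefer diagonal, then vertical."""
    i, j = M.shape[0] - 1, M.shape[1] - 1
    path: list[tuple[int, int]] = []  # 1 = consume row i, 1 = consume col j
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    while i > 0 or j > 0:
        if i == 0:
            path.append((0, 1))
            j -= 1
            continue
        if j == 0:
            path.append((1, 0))
            i -= 1
            continue
        if state == 0:  # M
            path.append((1, 1))
            prev = np.array([M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]])
            state = int(np.argmax(prev))
            i, j = i - 1, j - 1
        elif state == 1:  # X: gap in second profile
            path.append((1, 0))
            opts = np.array(
                [M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend, Y[i - 1, j] + gap_open]
            )
            state = int(np.argmax(opts))
            i -= 1
        else:  # Y: gap in first profile
            path.append((0, 1))
            opts = np.array(
                [M[i, j - 1] + gap_open, X[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend]
            )
            state = int(np.argmax(opts))
            j -= 1
    path.reverse()
    return path


def align_profiles(
    rows_a: Sequence[str], rows_b: Sequence[str], params: AlignParams
) -> tuple[list[str], list[str], float]:
    """Globally align two profiles (lists of equal-length gapped rows).

    Returns the re-gapped rows of each profile plus the alignment score.
    Column scores are the mean substitution score over non-gap residue
    pairs; a column pair with no non-gap residues on one side scores 0.
    """
    sub = params.substitution_matrix()
    ca, na = _profile_counts(rows_a, params.alphabet)
    cb, nb = _profile_counts(rows_b, params.alphabet)
    denom = np.outer(na, nb)
    denom[denom == 0] = 1.0
    S = (ca @ sub @ cb.T) / denom
    M, X, Y = _gotoh_fill(S, params.gap_open, params.gap_extend)
    path = _traceback(M, X, Y, params.gap_open, params.gap_extend, S)
    score = float(max(M[-1, -1], X[-1, -1], Y[-1, -1]))
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for da, db in path:
        for r, row in enumerate(rows_a):
            out_a[r] += row[ia] if da else "-"
        for r, row in enumerate(rows_b):
            out_b[r] += row[ib] if db else "-"
        ia += da
        ib += db
    return out_a, out_b, score


def align_pair(
    a: str, b: str, params: AlignParams | None = None
) -> tuple[str, str, float]:
    """Global alignment of two plain sequences."""
    params = params or AlignParams()
    ra, rb, score = align_profiles([a], [b], params)
    return ra[0], rb[0], score


def kmer_profile_distance(a: str, b: str, k: int = 6) -> float:
    """1 − Jaccard similarity of k-mer sets (1.0 for disjoint sets)."""
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / len(ka | kb)


def guide_order(seqs: Sequence[str], k: int = 6) -> list[int]:
    """Greedy joining order from k-mer profile distances.

    Starts with the closest pair, then repeatedly appends the unplaced
    sequence nearest (single linkage) to the placed set. Ties break on the
    smallest index pair, making the order deterministic.
    """
    n = len(seqs)
    if n <= 2:
        return list(range(n))
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = kmer_profile_distance(seqs[i], seqs[j], k)
    best = min(
        ((d[i, j], i, j) for i in range(n) for j in range(i + 1, n)),
        key=lambda t: (t[0], t[1], t[2]),
    )
    order = [best[1], best[2]]
    placed = set(order)
    while len(order) < n:
        cand = min(
            (
                (min(d[i, j] for j in placed), i)
                for i in range(n)
                if i not in placed
            ),
            key=lambda t: (t[0], t[1]),
        )
        order.append(cand[1])
        placed.add(cand[1])
    return order


def progressive_align(
    seqs: Sequence[SequenceRecord],
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
    alphabet: str = DNA_ALPHABET,
) -> Msa:
    """Progressive multiple alignment in greedy k-mer guide order."""
    if not seqs:
        raise ValueError("progressive_align requires at least one sequence")
    for s in seqs:
        if not s.residues:
            raise ValueError(f"empty sequence {s.id!r}")
    if len(seqs) == 1:
        return Msa(((seqs[0].id, seqs[0].residues),))
    params = AlignParams(match, mismatch, gap_open, gap_extend, alphabet)
    order = guide_order([s.residues for s in seqs])
    ids = [seqs[i].id for i in order]
    rows_a, rows_b, _ = align_profiles(
        [seqs[order[0]].residues], [seqs[order[1]].residues], params
    )
    msa_rows = rows_a + rows_b
    ids = ids[:2]
    for idx in order[2:]:
        new_rows, old_rows, _ = align_profiles([seqs[idx].residues], msa_rows, params)
        msa_rows = old_rows + new_rows
        ids.append(seqs[idx].id)
    return Msa(tuple(zip(ids, msa_rows)))
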