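"""Multiple sequence alignment and alignment trimming.

The built-in aligner is a progressive profile aligner: a UPGMA guide tree on
k-mer distances fixes the merge order, and profiles are merged by global
affine-gap (Gotoh) dynamic programming on column-frequency profiles. It is a
deliberate simplification of consistency-based aligners such as MAFFT
L-ins-i: at gene-family scale it produces alignments good enough for
p-distance trees, and an adapter (``Alignment.from_records`` on an aligned
FASTA) lets users substitute any external tool.

Trimming implements two rules applied in a fixed order per cycle: columns
with occupancy below a threshold are removed first, then sequences covering
too little of the trimmed alignment are dropped, and the survivors are
re-aligned until a fixpoint.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

# 20 canonical residues, unknown residue, stop.
ALPHABET = "ACDEFGHIKLMNPQRSTVWYX*"
_AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}
GAP = "-"


class AlignmentError(ValueError):
    pass


def _score_matrix(name: str = "BLOSUM62", stop_penalty: float = -1000.0) -> np.ndarray:
    """Substitution scores over ALPHABET; stops score prohibitively low."""
    blosum = substitution_matrices.load(name)
    n = len(ALPHABET)
    S = np.zeros((n, n))
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            if a == "*" or b == "*":
                S[i, j] = stop_penalty if (a != b) else 1.0
            else:
                S[i, j] = blosum[a][b]
    return S


def encode(seq: str) -> np.ndarray:
    """Map a protein string to alphabet indices; rare codes become X."""
    return np.array([_AA_INDEX.get(c, _AA_INDEX["X"]) for c in seq], dtype=np.int64)


@dataclass
class Alignment:
    """An ordered multiple sequence alignment of gapped rows."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in length")
        if self.rows:
            ncol = len(self.rows[0])
            for i, r in enumerate(self.rows):
                if len(r) != ncol:
                    raise AlignmentError(
                        f"row {self.ids[i]!r} has length {len(r)}, expected {ncol}")

    @property
    def ncol(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def nrow(self) -> int:
        return len(self.rows)

    def degapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def sequences(self) -> list[tuple[str, str]]:
        """Ungapped input sequences, in row order."""
        return [(self.ids[i], self.degapped(i)) for i in range(self.nrow)]

    @classmethod
    def from_records(cls, records: list[tuple[str, str]]) -> "Alignment":
        return cls([i for i, _ in records], [s for _, s in records])


@dataclass
class MsaParams:
    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    k: int = 3
    min_occupancy: float = 0.10
    min_coverage: float = 0.50
    matrix: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.matrix is None:
            self.matrix = _score_matrix(self.matrix_name)


def kmer_distance(a: str, b: str, k: int = 3) -> float:
    """Multiset-Jaccard k-mer distance in [0, 1]; 0 iff identical multisets."""
    if len(a) < k or len(b) < k:
        raise AlignmentError(f"sequence shorter than k={k}")
    ka = Counter(a[i:i + k] for i in range(len(a) - k + 1))
    kb = Counter(b[i:i + k] for i in range(len(b) - k + 1))
    inter = sum((ka & kb).values())
    union = sum((ka | kb).values())
    return 1.0 - inter / union


def _profile(aln: Alignment) -> np.ndarray:
    """Column frequency profile (ncol, |ALPHABET|); gaps contribute nothing."""
    P = np.zeros((aln.ncol, len(ALPHABET)))
    for row in aln.rows:
        idx = np.fromiter(((_AA_INDEX.get(c, _AA_INDEX["X"]) if c != GAP else -1)
                           for c in row), dtype=np.int64, count=len(row))
        mask = idx >= 0
        P[np.nonzero(mask)[0], idx[mask]] += 1.0
    return P / max(1, aln.nrow)


_NEG = -1e30


def _gotoh_profiles(PA: np.ndarray, PB: np.ndarray, S: np.ndarray,
                    open_: float, ext: float) -> list[tuple[int, int]]:
    """Global affine alignment of two profiles; returns a column path.

    Path steps are (da, db) in {(1,1),(1,0),(0,1)}. The first gap character
    of a run costs ``open_``, each further one ``ext``.
    """
    n1, n2 = PA.shape[0], PB.shape[0]
    col = (PA @ S) @ PB.T  # (n1, n2) expected column-pair score
    M = np.full((n1 + 1, n2 + 1), _NEG)
    X = np.full((n1 + 1, n2 + 1), _NEG)  # gap columns inserted into B
    Y = np.full((n1 + 1, n2 + 1), _NEG)  # gap columns inserted into A
    M[0, 0] = 0.0
    if n1:
        X[1:, 0] = -(open_ + ext * np.arange(n1))
    if n2:
        Y[0, 1:] = -(open_ + ext * np.arange(n2))
    jj = np.arange(1, n2 + 1)
    for i in range(1, n1 + 1):
        M[i, 1:] = col[i - 1, :] + np.maximum.reduce(
            [M[i - 1, :-1], X[i - 1, :-1], Y[i - 1, :-1]])
        X[i, 1:] = np.maximum(M[i - 1, 1:] - open_, X[i - 1, 1:] - ext)
        X[i, 0] = -(open_ + ext * (i - 1))
        # Y[i,j] = max(M[i,j-1]-open, Y[i,j-1]-ext): prefix-max recurrence
        a = np.maximum(M[i, :-1] - open_, np.concatenate(([Y[i, 0]], np.full(n2 - 1, _NEG)))) \
            + ext * jj
        t = np.maximum.accumulate(a)
        Y[i, 1:] = t - ext * jj
    # traceback
    path: list[tuple[int, int]] = []
    i, j = n1, n2
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    tol = 1e-9
    while i > 0 or j > 0:
        if state == 0:  # M
            path.append((1, 1))
            prev = np.array([M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]])
            state = int(np.argmax(prev))
            i, j = i - 1, j - 1
        elif state == 1:  # X: column from A, gap in B
            path.append((1, 0))
            if i - 1 >= 0 and abs(X[i, j] - (M[i - 1, j] - open_)) < tol:
                state = 0
            i -= 1
        else:  # Y: gap in A, column from B
            path.append((0, 1))
            if j - 1 >= 0 and abs(Y[i, j] - (M[i, j - 1] - open_)) < tol:
                state = 0
            j -= 1
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    path.reverse()
    return path


def _merge(alnA: Alignment, alnB: Alignment, params: MsaParams) -> Alignment:
    path = _gotoh_profiles(_profile(alnA), _profile(alnB), params.matrix,
                           params.gap_open, params.gap_extend)
    rowsA = [[] for _ in alnA.rows]
    rowsB = [[] for _ in alnB.rows]
    ia = ib = 0
    for da, db in path:
        for r, row in zip(rowsA, alnA.rows):
            r.append(row[ia] if da else GAP)
        for r, row in zip(rowsB, alnB.rows):
            r.append(row[ib] if db else GAP)
        ia += da
        ib += db
    return Alignment(alnA.ids + alnB.ids,
                     ["".join(r) for r in rowsA] + ["".join(r) for r in rowsB])


def progressive_align(proteins: list[tuple[str, str]],
                      params: MsaParams | None = None) -> Alignment:
    """Progressive alignment guided by UPGMA on k-mer distances.

    Deterministic for a fixed input order and parameters. A single sequence
    aligns trivially to itself; an empty input is an error.
    """
    params = params or MsaParams()
    if not proteins:
        raise AlignmentError("cannot align an empty sequence set")
    if len(proteins) == 1:
        return Alignment([proteins[0][0]], [proteins[0][1]])
    n = len(proteins)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = kmer_distance(proteins[i][1], proteins[j][1],
                                              params.k)
    Z = linkage(squareform(D, checks=False), method="average")
    clusters: dict[int, Alignment] = {
        i: Alignment([proteins[i][0]], [proteins[i][1]]) for i in range(n)}
    for step, (a, b, _, _) in enumerate(Z):
        a, b = int(a), int(b)
        clusters[n + step] = _merge(clusters.pop(a), clusters.pop(b), params)
    (merged,) = clusters.values()
    # restore input row order
    order = {pid: i for i, (pid, _) in enumerate(proteins)}
    pairs = sorted(zip(merged.ids, merged.rows), key=lambda t: order[t[0]])
    return Alignment([p for p, _ in pairs], [r for _, r in pairs])


def occupancy(aln: Alignment) -> np.ndarray:
    """Per-column non-gap fraction."""
    arr = np.array([list(r) for r in aln.rows])
    return (arr != GAP).mean(axis=0)


def trim_columns(aln: Alignment, min_occupancy: float = 0.10) -> Alignment:
    """Drop columns whose occupancy is strictly below the threshold.

    Boundary columns (occupancy exactly at the threshold) are retained.
    """
    if aln.ncol == 0:
        return aln
    keep = occupancy(aln) >= min_occupancy
    rows = ["".join(np.array(list(r))[keep]) for r in aln.rows]
    return Alignment(list(aln.ids), rows)


def drop_low_coverage(aln: Alignment,
                      min_cov: float = 0.50) -> tuple[Alignment, list[str]]:
    """Drop rows covering strictly less than ``min_cov`` of the columns."""
    if aln.ncol == 0:
        return aln, []
    kept_ids, kept_rows, removed = [], [], []
    for i, row in enumerate(aln.rows):
        cov = 1.0 - row.count(GAP) / len(row)
        if cov >= min_cov:
            kept_ids.append(aln.ids[i])
            kept_rows.append(row)
        else:
            removed.append(aln.ids[i])
    if not kept_ids:
        raise AlignmentError("degenerate family: every sequence fell below "
                             "the coverage threshold")
    return Alignment(kept_ids, kept_rows), removed


def align_trim_cycle(proteins: list[tuple[str, str]],
                     params: MsaParams | None = None,
                     ) -> tuple[Alignment, list[str]]:
    """Align, trim columns, drop low-coverage rows, re-align to a fixpoint.

    Returns the converged alignment and the ids removed for low coverage.
    Each cycle either removes at least one row or terminates, so the loop
    always halts.
    """
    params = params or MsaParams()
    current = list(proteins)
    removed_all: list[str] = []
    while True:
        aln = progressive_align(current, params)
        aln = trim_columns(aln, params.min_occupancy)
        aln, removed = drop_low_coverage(aln, params.min_coverage)
        if not removed:
            return aln, removed_all
        removed_all.extend(removed)
        current = aln.sequences()
        if len(current) == 1:
            return Alignment([current[0][0]], [current[0][1]]), removed_all
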