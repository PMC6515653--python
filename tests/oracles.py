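"""Independent oracles used by the test suite.

Everything here is written from first principles (standard genetic code
table typed by hand, dynamic programs built directly from the scoring
definition) and never imports the implementation modules it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

# Standard genetic code, typed independently of any library.
STD_CODON = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _translate_codon(codon: str) -> str:
    """One codon to one residue; N resolves to X unless unambiguous."""
    if "N" not in codon:
        return STD_CODON[codon]
    options = {STD_CODON["".join(c)] for c in itertools.product(
        *[("ACGT" if b == "N" else b) for b in codon])}
    return options.pop() if len(options) == 1 else "X"


def translate_oracle(nt: str, frame: int) -> str:
    """Translation of one reading frame, written from the code table."""
    nt = nt.upper()
    if frame < 0:
        nt = "".join(_COMPLEMENT[b] for b in reversed(nt))
    off = abs(frame) - 1
    out = []
    for i in range(off, len(nt) - 2, 3):
        out.append(_translate_codon(nt[i:i + 3]))
    return "".join(out)


def batch_local_scores(Q: np.ndarray, S: np.ndarray, sub: np.ndarray,
                       gap_open: float, gap_extend: float) -> np.ndarray:
    """Affine-gap Smith-Waterman scores for a batch of int-encoded pairs.

    ``Q`` is (P, la), ``S`` is (P, lb); ``sub`` is the substitution matrix
    over the integer alphabet. The first residue of a gap run costs
    ``gap_open + gap_extend``, each further residue ``gap_extend``.
    """
    P, la = Q.shape
    lb = S.shape[1]
    first = gap_open + gap_extend
    NEG = -1e9
    M = np.full((P, la + 1, lb + 1), NEG)
    X = np.full((P, la + 1, lb + 1), NEG)
    Y = np.full((P, la + 1, lb + 1), NEG)
    best = np.zeros(P)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            prev = np.maximum.reduce([M[:, i - 1, j - 1], X[:, i - 1, j - 1],
                                      Y[:, i - 1, j - 1],
                                      np.zeros(P)])
            M[:, i, j] = sub[Q[:, i - 1], S[:, j - 1]] + prev
            X[:, i, j] = np.maximum.reduce([M[:, i - 1, j] - first,
                                            X[:, i - 1, j] - gap_extend,
                                            Y[:, i - 1, j] - first])
            Y[:, i, j] = np.maximum.reduce([M[:, i, j - 1] - first,
                                            Y[:, i, j - 1] - gap_extend,
                                            X[:, i, j - 1] - first])
            best = np.maximum(best, M[:, i, j])
    return np.maximum(best, 0.0)


def enumerate_local_score(q: str, s: str, sub: dict[tuple[str, str], float],
                          gap_open: float, gap_extend: float) -> float:
    """Literal enumeration of every gapped local alignment (tiny inputs).

    Considers every pair of non-empty substrings and every monotone edit
    path between them, scoring affine gaps directly. Exponential; use only
    for lengths of a few residues.
    """
    first = gap_open + gap_extend

    def paths(a: str, b: str):
        # yields total scores of all global alignments of a vs b
        def rec(i, j, state, acc):
            if i == len(a) and j == len(b):
                yield acc
                return
            if i < len(a) and j < len(b):
                yield from rec(i + 1, j + 1, "M", acc + sub[(a[i], b[j])])
            if i < len(a):
                cost = gap_extend if state == "X" else first
                yield from rec(i + 1, j, "X", acc - cost)
            if j < len(b):
                cost = gap_extend if state == "Y" else first
                yield from rec(i, j + 1, "Y", acc - cost)
        yield from rec(0, 0, "start", 0.0)

    best = 0.0
    for i1 in range(len(q)):
        for i2 in range(i1 + 1, len(q) + 1):
            for j1 in range(len(s)):
                for j2 in range(j1 + 1, len(s) + 1):
                    best = max(best, max(paths(q[i1:i2], s[j1:j2])))
    return best


def nj_least_squares(D: np.ndarray, tree_dists: np.ndarray) -> float:
    """Sum of squared differences between two distance matrices."""
    return float(((D - tree_dists) ** 2).sum()) / 2.0


def random_additive_tree(rng, n: int):
    """A random binary tree with positive branch lengths.

    Returns (labels, D, bipartitions): leaf labels, the additive
    leaf-to-leaf distance matrix computed by breadth-first search on the
    tree's adjacency (independent of any phylogenetics library), and the
    non-trivial bipartitions, each normalised to the side holding the
    lexicographically smallest label.
    """
    labels = [f"t{i:02d}" for i in range(n)]
    adj: dict[str, list[tuple[str, float]]] = {l: [] for l in labels}
    clusters = list(labels)
    nxt = 0

    def connect(a: str, b: str) -> None:
        w = rng.uniform(0.05, 1.0)
        adj[a].append((b, w))
        adj[b].append((a, w))

    while len(clusters) > 3:
        i, j = sorted(rng.sample(range(len(clusters)), 2), reverse=True)
        a, b = clusters.pop(i), clusters.pop(j)
        node = f"I{nxt}"
        nxt += 1
        adj[node] = []
        connect(node, a)
        connect(node, b)
        clusters.append(node)
    center = f"I{nxt}"
    adj[center] = []
    for c in clusters:
        connect(center, c)

    def bfs(src: str) -> dict[str, float]:
        dist = {src: 0.0}
        stack = [src]
        while stack:
            cur = stack.pop()
            for nb, w in adj[cur]:
                if nb not in dist:
                    dist[nb] = dist[cur] + w
                    stack.append(nb)
        return dist

    D = np.zeros((n, n))
    for i, a in enumerate(labels):
        d = bfs(a)
        for j, b in enumerate(labels):
            D[i, j] = d[b]
    # per-source summation order can differ in the last float bit
    D = (D + D.T) / 2.0

    all_leaves = frozenset(labels)
    anchor = min(all_leaves)
    bips = set()
    for node in adj:
        for nb, _ in adj[node]:
            # leaves reachable from nb without passing through node
            seen = {node, nb}
            stack = [nb]
            side = set()
            while stack:
                cur = stack.pop()
                if cur in all_leaves:
                    side.add(cur)
                for nb2, _ in adj[cur]:
                    if nb2 not in seen:
                        seen.add(nb2)
                        stack.append(nb2)
            if 1 < len(side) < n - 1:
                fs = frozenset(side)
                bips.add(fs if anchor in fs else all_leaves - fs)
    return labels, D, bips
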