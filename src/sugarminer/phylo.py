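"""Distance-based phylogenetics: p-distances, neighbor joining, bootstrap.

Distances are uncorrected p-distances computed from a protein alignment in
one of two gap modes. ``gaps_as_difference`` (the curation default) scores a
gap aligned to a residue as a mismatch and drops only gap/gap sites;
``pairwise_deletion`` restricts each pair to its shared residue columns.
Trees are classical neighbor joining with the Studier–Keppler O(n^3)
update, negative branch-length clamping, and deterministic lexicographic
tie-breaking; bootstrap supports are bipartition frequencies over
column-resampled replicate trees.

Trees are dendropy ``Tree`` objects throughout, so Newick IO, rerooting and
patristic distances come from dendropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

from .alignment import GAP, Alignment


class PhyloError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise PhyloError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise PhyloError("distance matrix is not symmetric")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


GAP_MODES = ("gaps_as_difference", "pairwise_deletion")


def p_distance_matrix(aln: Alignment,
                      gap_mode: str = "gaps_as_difference") -> DistanceMatrix:
    """Pairwise proportion of differing sites, uncorrected.

    In ``gaps_as_difference`` mode a site where exactly one row is gapped
    counts as a difference and only gap/gap sites are excluded; in
    ``pairwise_deletion`` mode any site with a gap in either row is
    excluded. A pair with zero comparable sites is an error naming the pair.
    """
    if gap_mode not in GAP_MODES:
        raise PhyloError(f"unknown gap_mode {gap_mode!r}")
    if aln.nrow < 2:
        raise PhyloError("need at least two rows for distances")
    arr = np.array([list(r) for r in aln.rows])
    isgap = arr == GAP
    n = aln.nrow
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both_gap = isgap[i] & isgap[j]
            if gap_mode == "gaps_as_difference":
                comp = ~both_gap
            else:
                comp = ~(isgap[i] | isgap[j])
            m = int(comp.sum())
            if m == 0:
                raise PhyloError(
                    f"no comparable sites between {aln.ids[i]!r} and {aln.ids[j]!r}")
            diff = int((arr[i][comp] != arr[j][comp]).sum())
            D[i, j] = D[j, i] = diff / m
    return DistanceMatrix(list(aln.ids), D)


def _min_leaf_label(node: dendropy.Node) -> str:
    return min(lf.taxon.label for lf in node.leaf_iter())


def neighbor_joining(D: DistanceMatrix,
                     clamp_negative: bool = True) -> dendropy.Tree:
    """Neighbor joining; exact on additive matrices.

    Q-matrix ties are broken toward the lexicographically smallest pair of
    cluster labels (each cluster labelled by its smallest leaf). Negative
    estimated branch lengths are clamped to zero when ``clamp_negative``.
    """
    n = len(D.ids)
    if n < 2:
        raise PhyloError("neighbor joining needs at least two taxa")
    taxa = dendropy.TaxonNamespace(D.ids)
    tree = dendropy.Tree(taxon_namespace=taxa)

    def clamp(x: float) -> float:
        return max(0.0, x) if clamp_negative else x

    nodes: dict[int, dendropy.Node] = {}
    labels: dict[int, str] = {}
    for i, name in enumerate(D.ids):
        nd = dendropy.Node(taxon=taxa.get_taxon(name))
        nodes[i] = nd
        labels[i] = name
    if n == 2:
        d = float(D.values[0, 1])
        root = dendropy.Node()
        for i in (0, 1):
            nodes[i].edge.length = clamp(d / 2.0)
            root.add_child(nodes[i])
        tree.seed_node = root
        tree.update_taxon_namespace()
        return tree

    d = D.values.astype(float).copy()
    active = list(range(n))
    next_id = n
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(np.isclose(Q, qmin, rtol=0.0, atol=1e-12))
        best = min(
            ((tuple(sorted((labels[active[a]], labels[active[b]]))), (a, b))
             for a, b in cand if a < b),
        )[1]
        ai, bi = best
        i, j = active[ai], active[bi]
        dij = sub[ai, bi]
        li = 0.5 * dij + (r[ai] - r[bi]) / (2.0 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        nodes[i].edge.length = clamp(li)
        nodes[j].edge.length = clamp(lj)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # distances from the new node to the remaining clusters
        newrow = np.zeros(d.shape[0] + 1)
        for kpos, k in enumerate(active):
            if k in (i, j):
                continue
            newrow[k] = 0.5 * (sub[ai, kpos] + sub[bi, kpos] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[next_id, :next_id + 1] = newrow
        d[:next_id + 1, next_id] = newrow
        nodes[next_id] = parent
        labels[next_id] = min(labels[i], labels[j])
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    # connect the last three clusters through one internal node
    a, b, c = active
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    root = dendropy.Node()
    nodes[a].edge.length = clamp(0.5 * (dab + dac - dbc))
    nodes[b].edge.length = clamp(0.5 * (dab + dbc - dac))
    nodes[c].edge.length = clamp(0.5 * (dac + dbc - dab))
    for k in (a, b, c):
        root.add_child(nodes[k])
    tree.seed_node = root
    tree.update_taxon_namespace()
    tree.is_rooted = False
    return tree


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as the leaf side containing the smallest taxon."""
    all_taxa = frozenset(leaf_labels(tree))
    anchor = min(all_taxa)
    out: set[frozenset[str]] = set()
    for nd in tree.preorder_internal_node_iter():
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        side = below if anchor in below else all_taxa - below
        if 1 < len(side) < len(all_taxa) - 1 or (
                1 < len(all_taxa - side) < len(all_taxa) - 1):
            out.add(side)
    return out


def bootstrap_support(aln: Alignment, n_reps: int = 1000, seed: int = 0,
                      gap_mode: str = "gaps_as_difference") -> dendropy.Tree:
    """NJ tree with bootstrap supports on internal edges.

    Supports are percentages of column-resampled replicate NJ trees that
    contain each internal bipartition of the full-alignment tree.
    """
    if n_reps < 1:
        raise PhyloError("n_reps must be at least 1")
    if aln.nrow < 4:
        raise PhyloError("bootstrap needs at least 4 rows")
    base = neighbor_joining(p_distance_matrix(aln, gap_mode))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in bipartitions(base)}
    cols = np.array([list(r) for r in aln.rows]).T  # (ncol, nrow)
    n_done = 0
    for _ in range(n_reps):
        idx = rng.integers(0, aln.ncol, size=aln.ncol)
        rep_rows = ["".join(c) for c in cols[idx].T]
        rep = Alignment(list(aln.ids), rep_rows)
        try:
            rep_tree = neighbor_joining(p_distance_matrix(rep, gap_mode))
        except PhyloError:
            continue  # a pair lost all comparable sites in this replicate
        n_done += 1
        rep_bps = bipartitions(rep_tree)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    all_taxa = frozenset(leaf_labels(base))
    anchor = min(all_taxa)
    for nd in base.preorder_internal_node_iter():
        if nd is base.seed_node:
            continue
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        side = below if anchor in below else all_taxa - below
        if side in counts and n_done:
            nd.label = f"{100.0 * counts[side] / n_done:g}"
    return base


def root_tree(tree: dendropy.Tree, outgroup_ids: list[str]) -> dendropy.Tree:
    """Root on the edge separating the outgroup from the ingroup.

    If the outgroup is not monophyletic with respect to the ingroup on the
    unrooted tree, warns and falls back to midpoint rooting.
    """
    tree = tree.clone(depth=1)
    present = set(leaf_labels(tree))
    missing = [o for o in outgroup_ids if o not in present]
    if missing:
        raise PhyloError(f"outgroup taxa absent from tree: {missing}")
    og = frozenset(outgroup_ids)
    all_taxa = frozenset(leaf_labels(tree))
    target_edge = None
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if below == og or below == all_taxa - og:
            target_edge = nd.edge
            break
    if target_edge is None:
        warnings.warn("outgroup is polyphyletic with respect to the ingroup; "
                      "falling back to midpoint rooting")
        tree.reroot_at_midpoint(update_bipartitions=False)
        tree.is_rooted = True
        return tree
    L = target_edge.length or 0.0
    tree.reroot_at_edge(target_edge, length1=L / 2.0, length2=L / 2.0,
                        update_bipartitions=False)
    tree.is_rooted = True
    return tree


def neighborhood_lengths(tree: dendropy.Tree, leaf_label: str,
                         k: int = 2) -> list[float]:
    """Terminal branch lengths of leaves within ``k`` internal nodes.

    A leaf qualifies when the tree path from the query to it passes through
    at most ``k`` internal nodes; the query's own branch is excluded.
    """
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    if leaf_label not in leaves:
        raise PhyloError(f"leaf {leaf_label!r} not in tree")
    start = leaves[leaf_label]
    # undirected adjacency
    out: list[float] = []
    seen = {start}
    frontier = [(start, 0)]
    while frontier:
        node, used = frontier.pop(0)
        neighbors = list(node.child_nodes())
        if node.parent_node is not None:
            neighbors.append(node.parent_node)
        for nb in neighbors:
            if nb in seen:
                continue
            seen.add(nb)
            if nb.is_leaf():
                if used >= 1:  # path passes >=1 internal node
                    out.append(nb.edge.length or 0.0)
                continue
            cost = used + 1  # nb is an internal node on the path
            if cost <= k:
                frontier.append((nb, cost))
    return out


def patristic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(leaf_labels(tree))
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}
    n = len(labels)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = pdm.patristic_distance(taxa[labels[i]],
                                                       taxa[labels[j]])
    return DistanceMatrix(labels, M)


def pendant_lengths(tree: dendropy.Tree) -> dict[str, float]:
    return {lf.taxon.label: (lf.edge.length or 0.0)
            for lf in tree.leaf_node_iter()}
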