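"""Iterative phylogeny-driven curation of a candidate gene family.

Each iteration removes exact-duplicate/substring sequences, re-aligns and
trims, builds a neighbor-joining phylogram on uncorrected p-distances
(gaps counted as differences), flags long-branch outliers (pendant branch
above 0.3 while every related terminal branch within two internal nodes is
under 0.1), groups putative isoforms (patristic distance under 0.01 with
compatible motif architectures, plus a short-sequence rule for truncated
copies), collapses each group to its longest member, and repeats until no
removal occurs. Every removal is ledgered with its reason, so the curated
family satisfies |input| = |representatives| + |ledger|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

from .alignment import Alignment, MsaParams, align_trim_cycle
from .phylo import (
    neighbor_joining,
    neighborhood_lengths,
    p_distance_matrix,
    patristic_distances,
    pendant_lengths,
)


class CurationError(ValueError):
    pass


@dataclass
class CurationParams:
    long_branch_threshold: float = 0.3
    related_branch_threshold: float = 0.1
    isoform_distance: float = 0.01
    short_fraction: float = 0.5
    max_iterations: int = 10
    architecture_rule: str = "prefix_or_equal"  # prefix_or_equal | exact | ignore
    neighborhood_radius: int = 2
    gap_mode: str = "gaps_as_difference"
    isoform_metric: str = "path"  # path | pendant

    def __post_init__(self) -> None:
        if not (0.0 < self.isoform_distance < self.related_branch_threshold
                < self.long_branch_threshold):
            raise CurationError(
                "thresholds must satisfy 0 < isoform < related < long_branch")


@dataclass
class LedgerEntry:
    sequence_id: str
    reason: str  # duplicate | isoform_of | long_branch_outlier | low_coverage
    target: str = ""
    iteration: int = 0


@dataclass
class CuratedFamily:
    representatives: list[tuple[str, str]]
    ledger: list[LedgerEntry]
    iterations: int
    converged: bool
    alignment: Alignment | None = None
    tree: dendropy.Tree | None = None
    snapshots: list[dendropy.Tree] = field(default_factory=list)

    @property
    def representative_ids(self) -> list[str]:
        return [i for i, _ in self.representatives]

    def removal_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.ledger:
            out[e.reason] = out.get(e.reason, 0) + 1
        return out

    def collapse_target(self, seq_id: str) -> str:
        """Follow duplicate/isoform links transitively to a representative."""
        link = {e.sequence_id: e.target for e in self.ledger
                if e.reason in ("duplicate", "isoform_of") and e.target}
        cur = seq_id
        seen = set()
        while cur in link and cur not in seen:
            seen.add(cur)
            cur = link[cur]
        return cur


def remove_redundant(proteins: list[tuple[str, str]],
                     ) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Drop sequences identical to, or exact substrings of, another.

    The longer sequence survives; on equal length the lexicographically
    smaller id survives. Returns (retained, removed-with-survivor-id).
    """
    order = sorted(proteins, key=lambda t: (-len(t[1]), t[0]))
    kept: list[tuple[str, str]] = []
    removed: list[tuple[str, str]] = []
    for pid, seq in order:
        host = next((kid for kid, kseq in kept if seq in kseq), None)
        if host is None:
            kept.append((pid, seq))
        else:
            removed.append((pid, host))
    pos = {pid: i for i, (pid, _) in enumerate(proteins)}
    kept.sort(key=lambda t: pos[t[0]])
    return kept, removed


def detect_long_branches(tree: dendropy.Tree,
                         params: CurationParams | None = None) -> list[str]:
    """Leaves on a long pendant branch inside a uniformly short neighborhood."""
    params = params or CurationParams()
    flagged = []
    pend = pendant_lengths(tree)
    for leaf, length in pend.items():
        if length <= params.long_branch_threshold:
            continue
        related = neighborhood_lengths(tree, leaf, params.neighborhood_radius)
        # neighbors that are long-branch candidates themselves do not count
        # as related context: co-occurring outliers attract one another on
        # the tree and would otherwise shield each other from the flag
        context = [r for r in related if r <= params.long_branch_threshold]
        if all(r < params.related_branch_threshold for r in context):
            flagged.append(leaf)
    return sorted(flagged)


def _arch_ok(a: tuple[str, ...], b: tuple[str, ...], rule: str) -> bool:
    if rule == "ignore":
        return True
    if rule == "exact":
        return a == b
    if rule == "prefix_or_equal":
        n = min(len(a), len(b))
        return a[:n] == b[:n]
    raise CurationError(f"unknown architecture rule {rule!r}")


def _shared_site_distance(aln: Alignment, i: int, j: int) -> float | None:
    """Pairwise-deletion p-distance between two alignment rows."""
    ri, rj = aln.rows[i], aln.rows[j]
    diff = comp = 0
    for a, b in zip(ri, rj):
        if a == "-" or b == "-":
            continue
        comp += 1
        if a != b:
            diff += 1
    return diff / comp if comp else None


def detect_isoform_groups(tree: dendropy.Tree,
                          proteins: dict[str, str],
                          architectures: dict[str, tuple[str, ...]] | None,
                          params: CurationParams | None = None,
                          alignment: Alignment | None = None,
                          ) -> list[set[str]]:
    """Connected components of the isoform graph; singletons omitted.

    Two leaves are joined when their tree distance (patristic by default,
    pendant-sum under ``isoform_metric='pendant'``) is below the isoform
    threshold and their motif architectures are compatible under the
    configured rule. Additionally, a sequence shorter than
    ``short_fraction`` of another's length whose architecture is a strict
    prefix of the other's is joined when their substitution-only distance
    over shared alignment columns stays below the isoform threshold —
    the truncated-isoform case, where gap-scored distances are dominated
    by the truncation itself.
    """
    params = params or CurationParams()
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if params.isoform_metric == "path":
        D = patristic_distances(tree)
        dist = D.get
    else:
        pend = pendant_lengths(tree)
        dist = lambda a, b: pend[a] + pend[b]  # noqa: E731

    row_of = None
    if alignment is not None:
        row_of = {pid: i for i, pid in enumerate(alignment.ids)}

    def arch(x: str) -> tuple[str, ...] | None:
        if architectures is None:
            return None
        return architectures.get(x, ())

    parent = {l: l for l in leaves}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    def shared_distance(a: str, b: str) -> float | None:
        if row_of is None or a not in row_of or b not in row_of:
            return None
        return _shared_site_distance(alignment, row_of[a], row_of[b])

    for i, a in enumerate(leaves):
        for b in leaves[i + 1:]:
            arch_pass = (architectures is None
                         or _arch_ok(arch(a), arch(b),
                                     params.architecture_rule))
            if not arch_pass:
                continue
            if dist(a, b) < params.isoform_distance:
                union(a, b)
                continue
            # substitution-only similarity over shared columns catches
            # truncated copies (whose gap-scored distance is dominated by
            # the truncation) and near-copies whose tree-path distance is
            # inflated by reconstruction noise
            la, lb = len(proteins.get(a, "")), len(proteins.get(b, ""))
            if architectures is None and la != lb:
                # without architecture evidence, only a clearly truncated
                # sequence may ride on shared-site similarity alone
                if min(la, lb) >= params.short_fraction * max(la, lb):
                    continue
            d = shared_distance(a, b)
            if d is not None and d < params.isoform_distance:
                union(a, b)
    groups: dict[str, set[str]] = {}
    for l in leaves:
        groups.setdefault(find(l), set()).add(l)
    return sorted((g for g in groups.values() if len(g) > 1),
                  key=lambda g: min(g))


def collapse_isoforms(groups: list[set[str]], proteins: dict[str, str],
                      ) -> tuple[list[str], list[LedgerEntry]]:
    """One representative per group: the longest member, ties to smaller id."""
    reps: list[str] = []
    entries: list[LedgerEntry] = []
    for g in groups:
        rep = min(g, key=lambda x: (-len(proteins[x]), x))
        reps.append(rep)
        for m in sorted(g):
            if m != rep:
                entries.append(LedgerEntry(m, "isoform_of", rep))
    return reps, entries


def curate_family(candidates: list[tuple[str, str]],
                  params: CurationParams | None = None,
                  msa_params: MsaParams | None = None,
                  architectures: dict[str, tuple[str, ...]] | None = None,
                  keep_snapshots: bool = False) -> CuratedFamily:
    """Run the full curation loop to a fixpoint.

    Rerunning on the returned representatives removes nothing. If the
    iteration cap is hit with removals still occurring, the result carries
    ``converged=False``.
    """
    params = params or CurationParams()
    msa_params = msa_params or MsaParams()
    if len(candidates) < 3:
        raise CurationError("need at least three candidate sequences")
    current = list(candidates)
    originals = dict(candidates)
    ledger: list[LedgerEntry] = []
    snapshots: list[dendropy.Tree] = []
    aln: Alignment | None = None
    tree: dendropy.Tree | None = None
    iteration = 0
    converged = False
    while iteration < params.max_iterations:
        iteration += 1
        removed_this_round = 0

        current, dup = remove_redundant(current)
        for pid, host in dup:
            ledger.append(LedgerEntry(pid, "duplicate", host, iteration))
        removed_this_round += len(dup)

        aln, low_cov = align_trim_cycle(current, msa_params)
        for pid in low_cov:
            ledger.append(LedgerEntry(pid, "low_coverage", "", iteration))
        removed_this_round += len(low_cov)
        # survivors keep their original, untrimmed sequences
        current = [(pid, originals[pid]) for pid in aln.ids]
        if len(current) < 3:
            converged = True
            break

        D = p_distance_matrix(aln, params.gap_mode)
        tree = neighbor_joining(D)
        if keep_snapshots:
            snapshots.append(tree.clone(depth=1))

        proteins = dict(current)
        groups = detect_isoform_groups(tree, proteins, architectures, params,
                                       alignment=aln)
        grouped = set().union(*groups) if groups else set()
        long_ids = [l for l in detect_long_branches(tree, params)
                    if l not in grouped]
        for pid in long_ids:
            ledger.append(LedgerEntry(pid, "long_branch_outlier", "",
                                      iteration))
        removed_this_round += len(long_ids)
        _, iso_entries = collapse_isoforms(groups, proteins)
        for e in iso_entries:
            e.iteration = iteration
            ledger.append(e)
        removed_this_round += len(iso_entries)

        drop = set(long_ids) | {e.sequence_id for e in iso_entries}
        current = [(pid, s) for pid, s in current if pid not in drop]

        if removed_this_round == 0:
            converged = True
            break
    return CuratedFamily(current, ledger, iteration, converged, aln, tree,
                         snapshots)
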