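"""Clade assignment against labeled reference anchors, and the census.

Assignment walks from each query leaf toward the root of an
outgroup-rooted tree and reports the label of the smallest enclosing clade
whose reference members are non-empty and label-pure (method
``monophyletic``); when that clade mixes labels, the nearest reference by
patristic distance decides (method ``nearest``). The census tabulates the
retained representatives per species and clade with percentages of each
family total, rounded half-up to two decimals — the convention that
reproduces every printed cell of the published family-size table.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import dendropy
import pandas as pd

from .phylo import patristic_distances


class ClassifyError(ValueError):
    pass


@dataclass
class CladeAssignment:
    sequence_id: str
    family: str
    clade: str  # clade label or "unassigned"
    method: str  # monophyletic | nearest | none
    support: float | None = None
    tied: bool = False


def assign_clades(tree: dendropy.Tree, reference_labels: dict[str, str],
                  family: str = "MST",
                  exclude: set[str] | None = None) -> dict[str, CladeAssignment]:
    """Assign every non-reference leaf to a clade.

    ``reference_labels`` maps reference leaf ids to clade labels; ids
    labeled ``outgroup`` anchor the root and never vote. ``exclude`` lists
    additional leaves (e.g. the outgroup) to skip as queries.
    """
    refs = {k: v for k, v in reference_labels.items() if v != "outgroup"}
    exclude = (exclude or set()) | set(reference_labels)
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    queries = [l for l in leaves if l not in exclude]
    if not any(r in leaves for r in refs):
        return {q: CladeAssignment(q, family, "unassigned", "none")
                for q in queries}
    D = None
    out: dict[str, CladeAssignment] = {}
    for q in sorted(queries):
        node = leaves[q].parent_node
        assigned = None
        while node is not None:
            below = {lf.taxon.label for lf in node.leaf_iter()}
            ref_labels_below = sorted({refs[r] for r in below if r in refs})
            if ref_labels_below:
                if len(ref_labels_below) == 1:
                    support = None
                    if node.label is not None:
                        try:
                            support = float(node.label)
                        except ValueError:
                            support = None
                    assigned = CladeAssignment(q, family, ref_labels_below[0],
                                               "monophyletic", support)
                break
            node = node.parent_node
        if assigned is None:
            if D is None:
                D = patristic_distances(tree)
            scored = sorted((D.get(q, r), lbl) for r, lbl in refs.items()
                            if r in leaves)
            best_d, best_lbl = scored[0]
            tied = len(scored) > 1 and abs(scored[1][0] - best_d) < 1e-12 \
                and scored[1][1] != best_lbl
            assigned = CladeAssignment(q, family, best_lbl, "nearest",
                                       tied=tied)
        out[q] = assigned
    return out


def percent_half_up(count: int, total: int) -> str:
    """Two-decimal half-up percentage string, e.g. 5/34 -> '14.71%'."""
    if total == 0:
        return "0.00%"
    pct = Decimal(count) * 100 / Decimal(total)
    return f"{pct.quantize(Decimal('0.01'), rounding=ROUND_HALF_UP)}%"


@dataclass
class CensusTable:
    """Per-species, per-clade counts and percentages (one family)."""

    family: str
    counts: pd.DataFrame  # index clade, columns species, integer counts
    percents: pd.DataFrame  # same shape, formatted strings
    totals: pd.Series  # per species, family total on tree
    unassigned: pd.Series  # per species, excluded from percent denominators
    extras: pd.Series  # per species, isoforms + outliers tally

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for clade in self.counts.index:
            row = {"clade": clade}
            for sp in self.counts.columns:
                row[f"{sp}_count"] = int(self.counts.loc[clade, sp])
                row[f"{sp}_percent"] = self.percents.loc[clade, sp]
            rows.append(row)
        total_row = {"clade": f"Total {self.family} on Tree"}
        extra_row = {"clade": "Isoforms and Outliers"}
        un_row = {"clade": "Unassigned"}
        for sp in self.counts.columns:
            total_row[f"{sp}_count"] = int(self.totals[sp])
            total_row[f"{sp}_percent"] = ""
            extra_row[f"{sp}_count"] = int(self.extras[sp])
            extra_row[f"{sp}_percent"] = ""
            un_row[f"{sp}_count"] = int(self.unassigned[sp])
            un_row[f"{sp}_percent"] = ""
        rows.extend([total_row, extra_row, un_row])
        return pd.DataFrame(rows)


def census(assignments: dict[str, CladeAssignment],
           species_of: dict[str, str],
           clade_order: list[str],
           ledger_tallies: dict[str, int] | None = None,
           family: str = "MST") -> CensusTable:
    """Build the per-species, per-clade census from assignments.

    ``ledger_tallies`` gives the per-species isoform + outlier counts from
    the curation ledger. Unassigned sequences are counted in their own row
    and excluded from the percentage denominators.
    """
    species = sorted(set(species_of[q] for q in assignments))
    counts = pd.DataFrame(0, index=list(clade_order), columns=species)
    unassigned = pd.Series(0, index=species)
    for q, a in assignments.items():
        sp = species_of[q]
        if a.clade == "unassigned":
            unassigned[sp] += 1
        elif a.clade in counts.index:
            counts.loc[a.clade, sp] += 1
        else:
            raise ClassifyError(
                f"clade {a.clade!r} not in the declared vocabulary")
    totals = counts.sum(axis=0)
    percents = pd.DataFrame("", index=counts.index, columns=species)
    for clade in counts.index:
        for sp in species:
            percents.loc[clade, sp] = percent_half_up(
                int(counts.loc[clade, sp]), int(totals[sp]))
    extras = pd.Series({sp: (ledger_tallies or {}).get(sp, 0)
                        for sp in species})
    return CensusTable(family, counts, percents, totals, unassigned, extras)


def census_from_counts(counts: dict[str, dict[str, int]],
                       clade_order: list[str],
                       family: str = "MST",
                       ledger_tallies: dict[str, int] | None = None,
                       ) -> CensusTable:
    """Census arithmetic straight from per-species, per-clade counts.

    ``counts`` maps species -> clade -> count (a printed table is a valid
    input). Percentages and totals are recomputed, never copied.
    """
    species = sorted(counts)
    table = pd.DataFrame(0, index=list(clade_order), columns=species)
    for sp, per_clade in counts.items():
        for clade, n in per_clade.items():
            if clade not in table.index:
                raise ClassifyError(f"unknown clade {clade!r}")
            table.loc[clade, sp] = int(n)
    totals = table.sum(axis=0)
    percents = pd.DataFrame("", index=table.index, columns=species)
    for clade in table.index:
        for sp in species:
            percents.loc[clade, sp] = percent_half_up(
                int(table.loc[clade, sp]), int(totals[sp]))
    extras = pd.Series({sp: (ledger_tallies or {}).get(sp, 0)
                        for sp in species})
    return CensusTable(family, table, percents, totals,
                       pd.Series(0, index=species), extras)


def collapse_display_groups(tree: dendropy.Tree, threshold: float = 0.025,
                            ) -> tuple[dendropy.Tree, dict[str, list[str]]]:
    """Collapse maximal clades whose mean branch length is under threshold.

    Each collapsed clade is replaced by a single marker leaf; the sidecar
    maps marker names to the member leaves. Idempotent: marker leaves have
    no subtree left to collapse.
    """
    tree = tree.clone(depth=1)
    sidecar: dict[str, list[str]] = {}
    counter = [0]

    def mean_branch(node: dendropy.Node) -> float:
        lens = [nd.edge.length or 0.0 for nd in node.preorder_iter()
                if nd is not node]
        return sum(lens) / len(lens) if lens else 0.0

    def visit(node: dendropy.Node) -> None:
        for child in list(node.child_nodes()):
            if child.is_leaf():
                continue
            if mean_branch(child) < threshold:
                members = sorted(lf.taxon.label for lf in child.leaf_iter())
                counter[0] += 1
                name = f"GROUP_{counter[0]}_n{len(members)}"
                sidecar[name] = members
                length = child.edge.length
                node.remove_child(child)
                taxon = dendropy.Taxon(label=name)
                tree.taxon_namespace.add_taxon(taxon)
                marker = dendropy.Node(taxon=taxon)
                marker.edge.length = length
                node.add_child(marker)
            else:
                visit(child)

    visit(tree.seed_node)
    tree.update_taxon_namespace()
    return tree, sidecar
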