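"""Motif-architecture and orthogroup association statistics.

Motif hit tables (external discovery tools plug in here; the adapter
convention records the discovery settings used in the source study —
at most 100 motifs, widths 25–250 — as metadata only) are turned into
ordered architectures per sequence, then summarised per motif against a
grouping (clade, stage of strongest expression, or species): the modal
group by raw occurrence count, its percentage of the motif's occurrences,
and whether the motif is exclusive to one group. Orthogroup memberships
are cross-tabulated against clades and against stage calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .simulate import STAGES


class AssociationError(ValueError):
    pass


def build_architectures(hits: pd.DataFrame,
                        seq_lengths: dict[str, int] | None = None,
                        ) -> dict[str, tuple[str, ...]]:
    """Ordered motif ids per sequence, sorted by start then motif id.

    With ``seq_lengths`` provided, out-of-bounds hits raise an error naming
    the sequence. Sequences present in ``seq_lengths`` but without hits get
    an empty architecture.
    """
    out: dict[str, list[tuple[int, str]]] = {}
    for _, row in hits.iterrows():
        sid = str(row["sequence_id"])
        start, stop = int(row["start"]), int(row["stop"])
        if start < 1 or stop < start:
            raise AssociationError(f"{sid}: bad hit coordinates {start}-{stop}")
        if seq_lengths is not None:
            if sid not in seq_lengths:
                raise AssociationError(f"unknown sequence id {sid!r}")
            if stop > seq_lengths[sid]:
                raise AssociationError(
                    f"{sid}: hit {row['motif_id']} ends at {stop}, beyond "
                    f"length {seq_lengths[sid]}")
        out.setdefault(sid, []).append((start, str(row["motif_id"])))
    archs = {sid: tuple(m for _, m in sorted(v)) for sid, v in out.items()}
    if seq_lengths is not None:
        for sid in seq_lengths:
            archs.setdefault(sid, ())
    return archs


def architecture_match(a: tuple[str, ...], b: tuple[str, ...],
                       rule: str = "prefix_or_equal") -> bool:
    """Compare two ordered motif lists under the given rule."""
    if rule == "exact":
        return tuple(a) == tuple(b)
    if rule == "prefix_or_equal":
        n = min(len(a), len(b))
        return tuple(a[:n]) == tuple(b[:n])
    raise AssociationError(f"unknown rule {rule!r}")


@dataclass
class AssociationRow:
    motif_id: str
    key: str  # clade | stage | species
    modal_group: str
    modal_count: int
    total_count: int
    modal_percent: float
    exclusive: bool
    tied: bool


def motif_association(hits: pd.DataFrame, grouping: dict[str, str],
                      key: str) -> pd.DataFrame:
    """Per-motif modal group, percentage and exclusivity.

    ``grouping`` maps each hit's sequence id to its group value (clade,
    stage call, or species); every hit's sequence must have one. Modal
    group is by raw occurrence count, ties broken toward the
    lexicographically smallest group id and flagged. Percentages of a
    motif's occurrences over groups sum to 100.
    """
    missing = sorted(set(hits["sequence_id"].astype(str)) - set(grouping))
    if missing:
        raise AssociationError(
            f"sequence(s) without a {key} value: {missing[:5]}")
    df = hits.copy()
    df["group"] = df["sequence_id"].astype(str).map(grouping)
    rows = []
    for motif, grp in df.groupby("motif_id"):
        counts = grp["group"].value_counts()
        total = int(counts.sum())
        top = int(counts.max())
        modal_candidates = sorted(counts[counts == top].index)
        modal = modal_candidates[0]
        rows.append(AssociationRow(
            str(motif), key, str(modal), top, total,
            100.0 * top / total, len(counts) == 1,
            len(modal_candidates) > 1).__dict__)
    return pd.DataFrame(rows).sort_values("motif_id").reset_index(drop=True)


def motif_group_percentages(hits: pd.DataFrame,
                            grouping: dict[str, str]) -> pd.DataFrame:
    """Full motif-by-group percentage table (rows sum to 100 per motif)."""
    df = hits.copy()
    df["group"] = df["sequence_id"].astype(str).map(grouping)
    tab = pd.crosstab(df["motif_id"], df["group"])
    return tab.div(tab.sum(axis=1), axis=0) * 100.0


def orthogroup_clade_crosstab(memberships: pd.DataFrame,
                              assignments: dict[str, str],
                              ) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Counts per (orthogroup, clade) plus spread flags.

    Returns the contingency table, a flags frame (per orthogroup: does it
    span several clades; per clade: how many orthogroups), and the list of
    assigned sequences with no membership.
    """
    df = memberships.copy()
    df["sequence_id"] = df["sequence_id"].astype(str)
    known = df["sequence_id"].isin(assignments)
    df = df[known]
    unmatched = sorted(set(assignments) - set(df["sequence_id"]))
    if df.empty:
        empty = pd.DataFrame()
        return empty, pd.DataFrame(columns=["kind", "id", "value"]), unmatched
    df["clade"] = df["sequence_id"].map(assignments)
    tab = pd.crosstab(df["orthogroup_id"], df["clade"])
    flags = []
    for og in tab.index:
        n_clades = int((tab.loc[og] > 0).sum())
        flags.append({"kind": "orthogroup_multi_clade", "id": str(og),
                      "value": n_clades > 1})
    for clade in tab.columns:
        n_ogs = int((tab[clade] > 0).sum())
        flags.append({"kind": "clade_multi_orthogroup", "id": str(clade),
                      "value": n_ogs})
    return tab, pd.DataFrame(flags), unmatched


def orthogroup_stage_preference(memberships: pd.DataFrame,
                                stage_calls: dict[str, str]) -> pd.DataFrame:
    """Modal strongest-stage per orthogroup.

    Members without a stage call are skipped; "none" calls do not vote.
    Ties resolve toward the earliest stage in life-cycle order and are
    flagged.
    """
    rows = []
    for og, grp in memberships.groupby("orthogroup_id"):
        stages = [stage_calls[s] for s in grp["sequence_id"].astype(str)
                  if s in stage_calls and stage_calls[s] != "none"]
        if not stages:
            rows.append({"orthogroup_id": str(og), "modal_stage": "none",
                         "n_members": len(grp), "tied": False})
            continue
        counts = pd.Series(stages).value_counts()
        top = counts.max()
        cands = sorted(counts[counts == top].index, key=STAGES.index)
        rows.append({"orthogroup_id": str(og), "modal_stage": cands[0],
                     "n_members": len(grp), "tied": len(cands) > 1})
    return pd.DataFrame(rows).sort_values("orthogroup_id").reset_index(drop=True)
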