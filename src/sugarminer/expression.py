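"""Life-cycle expression profiling: isoform-summed FPKM and stage calls.

FPKM values arrive per isoform; gene-level expression is the sum over the
gene's isoforms at each stage. A gene's stage of strongest expression is
the argmax over the stages available to its species (missing stages are
masked, never treated as zero), with ties resolved toward the earliest
stage in the fixed life-cycle order and all-zero rows called "none".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .simulate import STAGES


class ExpressionError(ValueError):
    pass


def normalize_stage(stage: str) -> str:
    """Canonical dotted stage id; hyphen/en-dash forms accepted on input."""
    s = str(stage).strip().replace("–", ".").replace("-", ".")
    if s not in STAGES:
        raise ExpressionError(f"unknown stage id {stage!r}")
    return s


@dataclass(frozen=True)
class StageSet:
    """The fixed stage order plus a per-species availability mask."""

    masks: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for sp, mask in self.masks.items():
            bad = [s for s in mask if s not in STAGES]
            if bad:
                raise ExpressionError(f"species {sp}: unknown stages {bad}")

    def stages_for(self, species: str) -> tuple[str, ...]:
        mask = self.masks[species]
        return tuple(s for s in STAGES if s in mask)


def gene_fpkm(isoform_table: pd.DataFrame,
              gene_map: dict[str, str]) -> pd.DataFrame:
    """Sum isoform FPKM to gene level, per species and stage.

    ``isoform_table`` columns: sequence_id, species, stage, fpkm.
    ``gene_map`` maps every sequence id to its gene id; an unmapped
    sequence is an error.
    """
    required = {"sequence_id", "species", "stage", "fpkm"}
    missing = required - set(isoform_table.columns)
    if missing:
        raise ExpressionError(f"missing columns: {sorted(missing)}")
    if isoform_table.empty:
        return pd.DataFrame(columns=["gene_id", "species", "stage", "fpkm"])
    unknown = sorted(set(isoform_table["sequence_id"]) - set(gene_map))
    if unknown:
        raise ExpressionError(f"isoform(s) mapped to no gene: {unknown[:5]}")
    df = isoform_table.copy()
    df["stage"] = df["stage"].map(normalize_stage)
    df["gene_id"] = df["sequence_id"].map(gene_map)
    out = (df.groupby(["gene_id", "species", "stage"], as_index=False)["fpkm"]
           .sum())
    return out


def strongest_stage(row: dict[str, float],
                    mask: tuple[str, ...]) -> str:
    """Stage of strongest expression over the available stages.

    Ties go to the earliest stage in the fixed order; an all-zero row is
    "none"; an empty mask is an error.
    """
    if not mask:
        raise ExpressionError("empty stage mask")
    avail = [s for s in STAGES if s in mask and s in row]
    if not avail:
        raise ExpressionError("row has no values on the masked stages")
    best = max(avail, key=lambda s: (row[s], -STAGES.index(s)))
    if row[best] == 0:
        return "none"
    return best


def stage_calls(gene_table: pd.DataFrame,
                stage_set: StageSet) -> pd.DataFrame:
    """Per-gene strongest-stage calls from a gene-level table."""
    rows = []
    for (gene, sp), grp in gene_table.groupby(["gene_id", "species"]):
        row = {normalize_stage(s): f
               for s, f in zip(grp["stage"], grp["fpkm"])}
        call = strongest_stage(row, stage_set.stages_for(sp))
        rows.append({"gene_id": gene, "species": sp, "stage": call})
    return pd.DataFrame(rows, columns=["gene_id", "species", "stage"])


def clade_stage_summary(assignments: dict[str, str],
                        calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clade-by-stage count matrix per species, plus the "none" tally.

    Every counted gene needs both an assignment and a stage call; entries
    sum to the number of genes with calls other than "none".
    """
    missing = sorted(set(calls["gene_id"]) - set(assignments))
    if missing:
        raise ExpressionError(f"gene(s) without clade assignment: {missing[:5]}")
    df = calls.copy()
    df["clade"] = df["gene_id"].map(assignments)
    none_df = (df[df["stage"] == "none"]
               .groupby(["species", "clade"], as_index=False)["gene_id"]
               .count().rename(columns={"gene_id": "n_none"}))
    df = df[df["stage"] != "none"]
    mat = (df.groupby(["species", "clade", "stage"], as_index=False)["gene_id"]
           .count().rename(columns={"gene_id": "n"}))
    return mat, none_df


MASK_SENTINEL = "NA"


def export_heatmap_annotations(gene_table: pd.DataFrame,
                               leaf_ids: list[str],
                               species_of: dict[str, str],
                               stage_set: StageSet,
                               sentinel: str = MASK_SENTINEL) -> pd.DataFrame:
    """One row per tree leaf, stage columns in fixed order.

    Stages outside the species mask carry the sentinel (they are absent
    phases, not zero expression — the blank-block convention of life-cycle
    heatmaps). A leaf without expression data yields a sentinel row and a
    warning.
    """
    values = {(g, normalize_stage(s)): f for g, s, f in
              zip(gene_table["gene_id"], gene_table["stage"],
                  gene_table["fpkm"])}
    have = set(gene_table["gene_id"])
    rows = []
    for leaf in leaf_ids:
        if leaf not in have:
            warnings.warn(f"leaf {leaf!r} has no expression data")
            rows.append({"id": leaf, **{s: sentinel for s in STAGES}})
            continue
        mask = stage_set.stages_for(species_of[leaf])
        row = {"id": leaf}
        for s in STAGES:
            row[s] = values.get((leaf, s), 0.0) if s in mask else sentinel
        rows.append(row)
    return pd.DataFrame(rows, columns=["id", *STAGES])
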