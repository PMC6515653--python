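"""Pipeline driver: screen -> confirm -> curate -> classify -> profile -> associate.

``run_core`` chains the stages over in-memory inputs and returns a
``RunResult`` holding every intermediate artifact plus a per-stage count
report. ``run_synthetic`` generates a synthetic bundle and feeds it through;
``run_pipeline`` does the same from files described by a ``PipelineConfig``
and writes the output bundle (census, assignments, ledger, expression and
association tables, Newick trees) under one run directory. No stage mutates
its inputs; everything is deterministic given the configuration and seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import dendropy
import pandas as pd
import yaml

from . import associations, clades, curation, expression, homology, io, simulate
from .alignment import Alignment, MsaParams, progressive_align, trim_columns
from .phylo import neighbor_joining, p_distance_matrix, root_tree
from .simulate import STAGES, SynthConfig


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    transcripts_path: str
    refs_path: str
    refs_labels_path: str
    outdir: str
    expression_path: str | None = None
    motif_hits_path: str | None = None
    orthogroups_path: str | None = None
    alignment_in: str | None = None  # adapter: externally computed alignment
    tree_in: str | None = None  # adapter: externally computed Newick tree
    family: str = "MST"
    seed: int = 0
    scoring: homology.ScoringParams = field(default_factory=homology.ScoringParams)
    curation_params: curation.CurationParams = field(
        default_factory=curation.CurationParams)
    msa_params: MsaParams = field(default_factory=MsaParams)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key, klass in (("scoring", homology.ScoringParams),
                           ("curation_params", curation.CurationParams),
                           ("msa_params", MsaParams)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**kwargs[key])
        cfg = cls(**kwargs)
        for p in (cfg.transcripts_path, cfg.refs_path, cfg.refs_labels_path):
            if not os.path.exists(p):
                raise PipelineError(f"input does not exist: {p}")
        return cfg


@dataclass
class RunResult:
    candidates: dict[str, dict]
    confirmed: dict[str, dict]
    curated: curation.CuratedFamily
    classification_tree: dendropy.Tree
    assignments: dict[str, clades.CladeAssignment]
    census: clades.CensusTable
    gene_table: pd.DataFrame
    stage_call_table: pd.DataFrame
    clade_stage: pd.DataFrame
    clade_stage_none: pd.DataFrame
    motif_assoc: dict[str, pd.DataFrame]
    og_crosstab: pd.DataFrame
    og_flags: pd.DataFrame
    og_stage_pref: pd.DataFrame
    report: dict


def _stage_masks_from_expression(expr: pd.DataFrame) -> expression.StageSet:
    masks = {}
    for sp, grp in expr.groupby("species"):
        present = {expression.normalize_stage(s) for s in grp["stage"]}
        masks[sp] = tuple(s for s in STAGES if s in present)
    return expression.StageSet(masks)


def run_core(transcripts: list[tuple[str, str]],
             refs: list[tuple[str, str]],
             ref_labels: dict[str, str],
             species_of: dict[str, str],
             expr: pd.DataFrame | None = None,
             motif_hits: pd.DataFrame | None = None,
             orthogroups: pd.DataFrame | None = None,
             decoy_db: list[tuple[str, str]] | None = None,
             family: str = "MST",
             scoring: homology.ScoringParams | None = None,
             curation_params: curation.CurationParams | None = None,
             msa_params: MsaParams | None = None,
             external_alignment: Alignment | None = None,
             external_tree: dendropy.Tree | None = None,
             ) -> RunResult:
    """Run every pipeline stage over in-memory inputs.

    ``ref_labels`` maps reference ids to clade labels, with rooting
    sequences labeled ``outgroup``. ``decoy_db`` optionally extends the
    best-hit confirmation database with non-family proteins.
    """
    scoring = scoring or homology.ScoringParams()
    curation_params = curation_params or curation.CurationParams()
    msa_params = msa_params or MsaParams()
    report: dict = {"n_transcripts": len(transcripts), "n_refs": len(refs)}

    baits = [(rid, seq) for rid, seq in refs
             if ref_labels.get(rid) != "outgroup"]
    candidates = homology.screen_transcriptome(baits, transcripts, scoring)
    report["n_candidates"] = len(candidates)

    db = list(refs) + list(decoy_db or [])
    labels = {rid: (family if ref_labels.get(rid) not in (None, "outgroup")
                    else "decoy") for rid, _ in refs}
    labels.update({did: "decoy" for did, _ in (decoy_db or [])})
    confirmed, _ = homology.best_hit_confirm(candidates, db, labels, scoring)
    report["n_confirmed"] = len(confirmed)

    archs = None
    if motif_hits is not None and not motif_hits.empty:
        archs = associations.build_architectures(motif_hits)

    # curation works on the homologous (locally aligned) region of the best
    # hit, which excludes untranslated-region junk from the frame translation
    cand_seqs = [(tid, rec["matched_region"])
                 for tid, rec in sorted(confirmed.items())]
    if len(cand_seqs) < 3:
        raise PipelineError(
            f"curation needs at least 3 confirmed candidates, got {len(cand_seqs)}")
    curated = curation.curate_family(cand_seqs, curation_params, msa_params,
                                     architectures=archs)
    report["n_representatives"] = len(curated.representatives)
    report["removals"] = curated.removal_counts()
    report["curation_iterations"] = curated.iterations
    report["curation_converged"] = curated.converged

    # classification tree over representatives + references + outgroup
    outgroup_ids = [rid for rid, _ in refs if ref_labels.get(rid) == "outgroup"]
    if external_tree is not None:
        rooted = external_tree if external_tree.is_rooted else root_tree(
            external_tree, outgroup_ids)
    else:
        if external_alignment is not None:
            aln = external_alignment
        else:
            pool = curated.representatives + list(refs)
            aln = trim_columns(progressive_align(pool, msa_params),
                               msa_params.min_occupancy)
        D = p_distance_matrix(aln, curation_params.gap_mode)
        tree = neighbor_joining(D)
        rooted = root_tree(tree, outgroup_ids) if outgroup_ids else tree
    assignments = clades.assign_clades(rooted, ref_labels, family)
    report["n_assigned"] = sum(1 for a in assignments.values()
                               if a.clade != "unassigned")

    # census: ledger tallies per species
    tallies: dict[str, int] = {}
    for e in curated.ledger:
        sp = species_of.get(e.sequence_id, "unknown")
        tallies[sp] = tallies.get(sp, 0) + 1
    clade_order = [c for c in simulate.CLADE_VOCAB.get(family, ())
                   ] or sorted({a.clade for a in assignments.values()})
    cens = clades.census(assignments, species_of, clade_order, tallies, family)

    # expression: collapse isoforms onto representatives, call stages
    gene_table = pd.DataFrame(columns=["gene_id", "species", "stage", "fpkm"])
    call_table = pd.DataFrame(columns=["gene_id", "species", "stage"])
    clade_stage = pd.DataFrame(columns=["species", "clade", "stage", "n"])
    clade_stage_none = pd.DataFrame(columns=["species", "clade", "n_none"])
    stage_set = None
    if expr is not None and not expr.empty:
        stage_set = _stage_masks_from_expression(expr)
        reps = set(curated.representative_ids)
        gene_map = {}
        for tid in set(expr["sequence_id"]):
            target = curated.collapse_target(tid)
            if target in reps:
                gene_map[tid] = target
        sub = expr[expr["sequence_id"].isin(gene_map)]
        gene_table = expression.gene_fpkm(sub, gene_map)
        call_table = expression.stage_calls(gene_table, stage_set)
        clade_of = {q: a.clade for q, a in assignments.items()}
        clade_stage, clade_stage_none = expression.clade_stage_summary(
            clade_of, call_table)
    report["n_stage_calls"] = len(call_table)

    # associations
    motif_assoc: dict[str, pd.DataFrame] = {}
    og_crosstab = pd.DataFrame()
    og_flags = pd.DataFrame()
    og_pref = pd.DataFrame()
    clade_of_seq: dict[str, str] = {}
    stage_of_seq: dict[str, str] = {}
    reps = set(curated.representative_ids)
    calls = {g: s for g, s in zip(call_table.get("gene_id", []),
                                  call_table.get("stage", []))}
    for tid in species_of:
        target = curated.collapse_target(tid)
        if target in reps and target in assignments:
            clade_of_seq[tid] = assignments[target].clade
            if target in calls:
                stage_of_seq[tid] = calls[target]
    if motif_hits is not None and not motif_hits.empty:
        fam_hits = motif_hits[motif_hits["sequence_id"].astype(str)
                              .isin(clade_of_seq)]
        if not fam_hits.empty:
            motif_assoc["clade"] = associations.motif_association(
                fam_hits, clade_of_seq, "clade")
            motif_assoc["species"] = associations.motif_association(
                fam_hits, species_of, "species")
            staged = fam_hits[fam_hits["sequence_id"].astype(str)
                              .isin(stage_of_seq)]
            if not staged.empty:
                motif_assoc["stage"] = associations.motif_association(
                    staged, stage_of_seq, "stage")
    if orthogroups is not None and not orthogroups.empty:
        og_crosstab, og_flags, _ = associations.orthogroup_clade_crosstab(
            orthogroups, clade_of_seq)
        og_pref = associations.orthogroup_stage_preference(
            orthogroups[orthogroups["sequence_id"].astype(str)
                        .isin(stage_of_seq)],
            stage_of_seq)
    return RunResult(candidates, confirmed, curated, rooted, assignments,
                     cens, gene_table, call_table, clade_stage,
                     clade_stage_none, motif_assoc, og_crosstab, og_flags,
                     og_pref, report)


def run_synthetic(config: SynthConfig,
                  scoring: homology.ScoringParams | None = None,
                  curation_params: curation.CurationParams | None = None,
                  msa_params: MsaParams | None = None,
                  ) -> tuple[RunResult, pd.DataFrame]:
    """Generate a synthetic bundle and run the full pipeline on it.

    Returns the run result and the generator's truth table.
    """
    panel = simulate.generate_reference_panel(config)
    txm = simulate.generate_transcriptome(panel, config)
    expr = simulate.generate_expression(txm.truth, config)
    hits = simulate.generate_motif_hits(txm.truth, config)
    ogs = simulate.generate_orthogroups(txm.truth)
    refs = panel.bait_records() + panel.outgroup
    ref_labels = panel.labels()
    species_of = dict(zip(txm.truth["transcript_id"], txm.truth["species"]))
    decoy_db = [(f"DB_{tid}", txm.proteins[tid])
                for tid in txm.truth.loc[txm.truth["role"] == "decoy",
                                          "transcript_id"]]
    result = run_core(txm.transcripts, refs, ref_labels, species_of,
                      expr=expr, motif_hits=hits, orthogroups=ogs,
                      decoy_db=decoy_db, family=config.family,
                      scoring=scoring, curation_params=curation_params,
                      msa_params=msa_params)
    return result, txm.truth


def evaluate_run(result: RunResult, truth: pd.DataFrame) -> dict:
    """Score a synthetic run against its truth table.

    Reported metrics: precision/recall/F1 of isoform identification (a
    true positive must also collapse onto a transcript of the same true
    gene), the number of true genes left without any representative, the
    fraction of planted outliers ledgered as long-branch outliers, the
    number of decoys surviving screening and confirmation, clade-assignment
    accuracy over representatives of true genes, and strongest-stage call
    accuracy over represented genes.
    """
    t = truth.set_index("transcript_id")
    curated = result.curated
    reps = set(curated.representative_ids)
    predicted_iso = {e.sequence_id: e for e in curated.ledger
                     if e.reason in ("duplicate", "isoform_of")}
    true_iso = set(t.index[t["role"] == "isoform"])
    tp = 0
    for sid in predicted_iso:
        if sid in true_iso:
            target = curated.collapse_target(sid)
            if target in t.index and \
                    t.loc[target, "true_gene"] == t.loc[sid, "true_gene"]:
                tp += 1
    fp = len(predicted_iso) - tp
    fn = len(true_iso) - tp
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) else 0.0)

    gene_ids = set(t.index[t["role"] == "gene"])
    represented = {t.loc[r, "true_gene"] for r in reps if r in t.index}
    genes_lost = sum(1 for g in gene_ids if g not in represented)

    outliers = set(t.index[t["role"] == "outlier"])
    flagged = {e.sequence_id for e in curated.ledger
               if e.reason == "long_branch_outlier"}
    outlier_recall = (len(outliers & flagged) / len(outliers)
                      if outliers else 1.0)

    decoys = set(t.index[t["role"] == "decoy"])
    decoys_screened = len(decoys & set(result.candidates))
    decoys_confirmed = len(decoys & set(result.confirmed))

    gene_reps = [r for r in reps
                 if r in t.index and t.loc[r, "role"] in ("gene", "isoform")]
    correct = sum(1 for r in gene_reps
                  if r in result.assignments
                  and result.assignments[r].clade == t.loc[r, "true_clade"])
    clade_acc = correct / len(gene_reps) if gene_reps else 0.0

    calls = {g: s for g, s in zip(result.stage_call_table.get("gene_id", []),
                                  result.stage_call_table.get("stage", []))}
    stage_hits = stage_total = 0
    for r in gene_reps:
        if r in calls:
            stage_total += 1
            if calls[r] == t.loc[r, "true_strongest_stage"]:
                stage_hits += 1
    stage_acc = stage_hits / stage_total if stage_total else 0.0

    return {"isoform_precision": precision, "isoform_recall": recall,
            "isoform_f1": f1, "isoform_tp": tp, "isoform_fp": fp,
            "isoform_fn": fn, "n_true_isoforms": len(true_iso),
            "genes_lost": genes_lost, "n_true_genes": len(gene_ids),
            "outlier_recall": outlier_recall, "n_outliers": len(outliers),
            "n_outliers_flagged": len(outliers & flagged),
            "decoys_screened": decoys_screened,
            "decoys_confirmed": decoys_confirmed, "n_decoys": len(decoys),
            "clade_accuracy": clade_acc, "n_gene_reps": len(gene_reps),
            "stage_call_accuracy": stage_acc, "n_stage_scored": stage_total}


def run_pipeline(config: PipelineConfig) -> RunResult:
    """File-based driver: read inputs, run every stage, write the bundle."""
    transcripts = io.read_fasta(config.transcripts_path)
    refs = io.read_fasta(config.refs_path)
    labels_df = io.read_tsv_table(config.refs_labels_path,
                                  required=("id", "clade"))
    ref_labels = dict(zip(labels_df["id"], labels_df["clade"]))
    expr = hits = ogs = None
    species_of: dict[str, str] = {}
    if config.expression_path:
        expr = io.read_tsv_table(config.expression_path,
                                 required=("sequence_id", "species", "stage",
                                           "fpkm"))
        expr["fpkm"] = expr["fpkm"].astype(float)
        species_of.update(dict(zip(expr["sequence_id"], expr["species"])))
    for tid, _ in transcripts:
        species_of.setdefault(tid, tid.split("_")[0])
    if config.motif_hits_path:
        hits = io.read_tsv_table(config.motif_hits_path,
                                 required=("sequence_id", "motif_id", "start",
                                           "stop"))
    if config.orthogroups_path:
        ogs = io.read_tsv_table(config.orthogroups_path,
                                required=("sequence_id", "orthogroup_id"))
    external_alignment = None
    if config.alignment_in:
        external_alignment = Alignment.from_records(
            io.read_fasta(config.alignment_in))
    external_tree = io.read_newick(config.tree_in) if config.tree_in else None

    result = run_core(transcripts, refs, ref_labels, species_of, expr=expr,
                      motif_hits=hits, orthogroups=ogs, family=config.family,
                      scoring=config.scoring,
                      curation_params=config.curation_params,
                      msa_params=config.msa_params,
                      external_alignment=external_alignment,
                      external_tree=external_tree)
    write_bundle(result, config.outdir)
    return result


def write_bundle(result: RunResult, outdir: str) -> None:
    """Write every output table, FASTA and tree under one run directory."""
    os.makedirs(outdir, exist_ok=True)

    def path(name: str) -> str:
        return os.path.join(outdir, name)

    cand_rows = [{"transcript_id": tid, "best_frame": rec["frame"],
                  "best_subject": rec["hit"].subject_id,
                  "score": rec["hit"].score, "evalue": rec["hit"].evalue}
                 for tid, rec in sorted(result.candidates.items())]
    io.write_tsv_table(pd.DataFrame(cand_rows), path("candidates.tsv"))
    io.write_fasta(result.curated.representatives, path("curated.fasta"))
    ledger_rows = [{"id": e.sequence_id, "reason": e.reason,
                    "target": e.target, "iteration": e.iteration}
                   for e in result.curated.ledger]
    io.write_tsv_table(pd.DataFrame(
        ledger_rows, columns=["id", "reason", "target", "iteration"]),
        path("ledger.tsv"))
    assign_rows = [{"sequence_id": a.sequence_id, "family": a.family,
                    "clade": a.clade, "method": a.method,
                    "support": a.support if a.support is not None else "",
                    "tied": a.tied}
                   for a in result.assignments.values()]
    io.write_tsv_table(pd.DataFrame(assign_rows), path("assignments.tsv"))
    io.write_tsv_table(result.census.to_frame(), path("census.tsv"))
    io.write_tsv_table(result.gene_table, path("gene_expression.tsv"))
    io.write_tsv_table(result.stage_call_table, path("stage_calls.tsv"))
    io.write_tsv_table(result.clade_stage, path("clade_stage_summary.tsv"))
    for key, df in result.motif_assoc.items():
        io.write_tsv_table(df, path(f"motif_assoc_{key}.tsv"))
    if not result.og_crosstab.empty:
        result.og_crosstab.to_csv(path("og_clade_crosstab.tsv"), sep="\t")
        io.write_tsv_table(result.og_flags, path("og_flags.tsv"))
        io.write_tsv_table(result.og_stage_pref, path("og_stage_pref.tsv"))
    io.write_newick(result.classification_tree, path("classification_tree.nwk"))
    if result.curated.tree is not None:
        io.write_newick(result.curated.tree, path("curation_tree.nwk"))
    with open(path("report.json"), "w") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True)
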