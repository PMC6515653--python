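"""Synthetic transcriptome panels with a machine-readable truth table.

Emulates the statistical structure the mining pipeline assumes: a protein
family split into clades, species-specific gene copies within each clade,
near-identical isoforms (some C-terminally truncated), fast-evolving
long-branch outliers, non-family decoys, planted ordered motif
architectures, orthogroup memberships that refine clades, and
stage-structured FPKM in which each gene has one designated strongest
developmental stage.

Sequence evolution is i.i.d. per-site substitution under a uniform
amino-acid replacement kernel (no rate heterogeneity): a site mutates with
probability ``x`` to one of the other 19 residues uniformly. Two lineages
evolved independently from a common ancestor at per-lineage rate ``x``
then differ at a site with probability ``1 - (1-x)^2 - x^2/19``, which
inverts in closed form, so pairwise divergence targets (isoform 0.004,
within-clade 0.15, between-clade 0.45) translate exactly into per-lineage
rates. Everything is a pure function of the configuration seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import io

AA20 = "ACDEFGHIKLMNPQRSTVWY"

STAGES = ("0", "1", "2", "3", "4.1", "4.2", "5.1", "5.2", "6.1", "6.2", "6.3")

# Clade vocabularies of the three sugar-transporter superfamilies.
CLADE_VOCAB = {
    "MST": ("ERD6", "pGLT_SGB", "INT", "TMT", "PMT", "VGT", "STP"),
    "SUT": ("SUT1", "SUT2", "SUT3", "SUT4", "SUT5"),
    "SWEET": ("SWEET_I", "SWEET_II", "SWEET_III", "SWEET_IV"),
}

# Most-frequent codon per residue (plant-biased, fixed); codon choice does
# not affect any downstream protein-level computation.
CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGA",
    "H": "CAT", "I": "ATT", "K": "AAG", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCA", "Q": "CAA", "R": "AGA", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SpeciesSpec:
    """A species id plus its developmental-stage availability mask."""

    name: str
    stages: tuple[str, ...]


def default_species() -> list[SpeciesSpec]:
    """Three parasite-like species; only the Triphysaria-like one reaches
    the late floral-maturation stage 6.3."""
    pre63 = tuple(s for s in STAGES if s != "6.3")
    return [
        SpeciesSpec("PhelLike", pre63),
        SpeciesSpec("StriLike", pre63),
        SpeciesSpec("TripLike", STAGES),
    ]


@dataclass
class SynthConfig:
    seed: int = 0
    family: str = "MST"
    n_clades: int = 3
    genes_per_clade_per_species: int = 2
    species: list[SpeciesSpec] = field(default_factory=default_species)
    protein_length: int = 540
    isoform_rate: float = 0.35
    isoform_divergence: float = 0.004
    paralog_divergence: float = 0.15
    inter_clade_divergence: float = 0.45
    outlier_rate: float = 0.10
    outlier_branch_scale: float = 10.0
    outlier_divergence_cap: float = 0.45
    decoy_count: int = 6
    decoy_similarity: float | None = None  # None -> unrelated random decoys
    truncation_rate: float = 0.3  # fraction of isoforms truncated
    truncation_fraction: tuple[float, float] = (0.3, 0.5)
    motif_grammar: dict[str, tuple[str, ...]] | None = None
    motif_width: int = 30
    orthogroup_splits: dict[str, int] = field(default_factory=dict)
    expression_background: float = 2.0
    expression_dynamic_range: float = 10.0
    expression_sigma: float = 0.3
    utr_max: int = 9

    def validate(self) -> None:
        if self.n_clades < 2:
            raise ConfigError("need at least two clades")
        if self.n_clades > len(CLADE_VOCAB[self.family]):
            raise ConfigError(
                f"family {self.family} defines only "
                f"{len(CLADE_VOCAB[self.family])} clades")
        if self.genes_per_clade_per_species < 1 or self.decoy_count < 0:
            raise ConfigError("non-positive counts")
        for r in (self.isoform_rate, self.outlier_rate, self.truncation_rate):
            if not 0.0 <= r <= 1.0:
                raise ConfigError("rates must lie in [0, 1]")
        if not (self.isoform_divergence < 0.01 < self.paralog_divergence):
            raise ConfigError("isoform divergence must be < 0.01 < paralog "
                              "divergence for the curation thresholds to "
                              "separate the classes")

    @property
    def clades(self) -> tuple[str, ...]:
        return CLADE_VOCAB[self.family][: self.n_clades]

    def grammar(self) -> dict[str, tuple[str, ...]]:
        if self.motif_grammar is not None:
            return dict(self.motif_grammar)
        # one family-wide motif followed by two clade-specific ones
        return {c: ("m0", f"m{i + 1}a", f"m{i + 1}b")
                for i, c in enumerate(self.clades)}


def lineage_rate(pairwise: float) -> float:
    """Per-lineage substitution rate giving a target pairwise divergence.

    Solves ``1 - (1-x)^2 - x^2/19 = pairwise`` for x (uniform 19-target
    replacement kernel, two independent lineages).
    """
    if not 0.0 <= pairwise < 0.95:
        raise ConfigError("pairwise divergence must lie in [0, 0.95)")
    return (19.0 / 20.0) * (1.0 - math.sqrt(1.0 - 20.0 * pairwise / 19.0))


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each site with probability ``rate`` to another residue."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        cur = arr[i].decode()
        choices = [a for a in AA20 if a != cur]
        arr[i] = rng.choice(choices).encode()
    return arr.tobytes().decode()


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def back_translate(protein: str) -> str:
    return "".join(CODON[a] for a in protein)


def p_distance(a: str, b: str) -> float:
    """Hamming fraction over the shared prefix of two unaligned proteins."""
    m = min(len(a), len(b))
    if m == 0:
        raise ConfigError("empty sequence in p_distance")
    return sum(1 for x, y in zip(a[:m], b[:m]) if x != y) / m


@dataclass
class ReferencePanel:
    """Labeled clade reference proteins plus an outgroup anchor."""

    references: list[tuple[str, str, str, str]]  # (id, family, clade, protein)
    outgroup: list[tuple[str, str]]  # (id, protein)
    clade_ancestors: dict[str, str]
    family_root: str

    def bait_records(self) -> list[tuple[str, str]]:
        return [(rid, seq) for rid, _, _, seq in self.references]

    def labels(self) -> dict[str, str]:
        d = {rid: clade for rid, _, clade, _ in self.references}
        d.update({oid: "outgroup" for oid, _ in self.outgroup})
        return d


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def generate_reference_panel(config: SynthConfig) -> ReferencePanel:
    """Clade-labeled reference proteins and a deeper outgroup protein.

    The outgroup diverges from the family root far enough that its distance
    to every clade exceeds any between-clade distance, which is what makes
    it usable for rooting.
    """
    config.validate()
    rng = _rng(config, 0)
    root = random_protein(config.protein_length, rng)
    x_inter = lineage_rate(config.inter_clade_divergence)
    x_para = lineage_rate(config.paralog_divergence)
    ancestors = {c: mutate(root, x_inter, rng) for c in config.clades}
    refs = [(f"REF_{c}", config.family, c, mutate(ancestors[c], x_para, rng))
            for c in config.clades]
    outgroup_seq = mutate(root, 2.0 * x_inter, rng)
    return ReferencePanel(refs, [("OUTGROUP_1", outgroup_seq)], ancestors, root)


@dataclass
class Transcriptome:
    transcripts: list[tuple[str, str]]  # (id, nucleotide sequence)
    proteins: dict[str, str]  # id -> planted protein (pre back-translation)
    truth: pd.DataFrame


TRUTH_COLUMNS = ("transcript_id", "species", "true_gene", "true_clade", "role",
                 "true_strongest_stage", "true_motif_architecture",
                 "true_orthogroup", "protein_length", "layout_length")


def _motif_layout(arch: tuple[str, ...], length: int,
                  width: int) -> list[tuple[str, int, int]]:
    """Deterministic 1-based inclusive motif coordinates for a protein."""
    out = []
    n = len(arch)
    for i, m in enumerate(arch):
        start = int(round(length * (0.05 + 0.85 * i / max(1, n))))
        start = max(1, min(start, max(1, length - width + 1)))
        out.append((m, start, min(length, start + width - 1)))
    return out


def _planted_architecture(grammar_arch: tuple[str, ...], length: int,
                          width: int, layout_length: int | None = None,
                          ) -> tuple[str, ...]:
    """Motifs that fit within a (possibly truncated) protein, in order.

    Coordinates live in the frame of ``layout_length`` (the parent gene's
    length for truncated isoforms), so a truncation drops the C-terminal
    motifs and leaves a prefix of the parent's architecture.
    """
    layout = _motif_layout(grammar_arch, layout_length or length, width)
    return tuple(m for m, s, e in layout if e <= length)


def generate_transcriptome(panel: ReferencePanel,
                           config: SynthConfig) -> Transcriptome:
    """Nucleotide transcripts plus a complete truth table.

    Genes are clade-ancestor descendants; isoforms are near-copies of their
    gene (point substitutions at the isoform divergence, sometimes
    C-terminally truncated); outliers carry ``outlier_branch_scale`` times
    the gene-level substitutions (capped so they remain detectable by
    homology); decoys share no planted motif grammar.
    """
    config.validate()
    rng = _rng(config, 1)
    x_para = lineage_rate(config.paralog_divergence)
    x_out = min(config.outlier_divergence_cap,
                config.outlier_branch_scale * x_para)
    grammar = config.grammar()
    splits = {c: max(1, config.orthogroup_splits.get(c, 1))
              for c in config.clades}
    # per-(clade, orthogroup) designated stage from the shared stage pool
    shared = [s for s in STAGES
              if all(s in sp.stages for sp in config.species)]
    og_stage: dict[str, str] = {}
    og_names: dict[tuple[str, int], str] = {}
    counter = 0
    for c in config.clades:
        for s in range(splits[c]):
            name = f"OG{1000 + counter}"
            og_names[(c, s)] = name
            og_stage[name] = shared[counter % len(shared)]
            counter += 1

    transcripts: list[tuple[str, str]] = []
    proteins: dict[str, str] = {}
    rows: list[dict] = []

    def add(tid: str, sp: str, gene: str, clade: str, role: str, stage: str,
            arch: tuple[str, ...], og: str, protein: str,
            layout_length: int | None = None) -> None:
        utr5 = "".join(rng.choice(list("ACGT"),
                                  size=int(rng.integers(0, config.utr_max + 1))))
        utr3 = "".join(rng.choice(list("ACGT"),
                                  size=int(rng.integers(0, config.utr_max + 1))))
        transcripts.append((tid, utr5 + back_translate(protein) + utr3))
        proteins[tid] = protein
        rows.append({"transcript_id": tid, "species": sp, "true_gene": gene,
                     "true_clade": clade, "role": role,
                     "true_strongest_stage": stage,
                     "true_motif_architecture": ",".join(arch),
                     "true_orthogroup": og, "protein_length": len(protein),
                     "layout_length": layout_length or len(protein)})

    for sp in config.species:
        for c in config.clades:
            for g in range(config.genes_per_clade_per_species):
                gid = f"{sp.name}_{c}_g{g}"
                prot = mutate(panel.clade_ancestors[c], x_para, rng)
                og = og_names[(c, g % splits[c])]
                stage = og_stage[og]
                if stage not in sp.stages:  # pragma: no cover - shared pool
                    stage = sp.stages[0]
                arch = _planted_architecture(grammar[c], len(prot),
                                             config.motif_width)
                add(gid, sp.name, gid, c, "gene", stage, arch, og, prot)
                if rng.random() < config.isoform_rate:
                    iso = mutate(prot, config.isoform_divergence, rng)
                    if rng.random() < config.truncation_rate:
                        lo, hi = config.truncation_fraction
                        cut = rng.uniform(lo, hi)
                        iso = iso[: int(round(len(iso) * (1.0 - cut)))]
                    iarch = _planted_architecture(grammar[c], len(iso),
                                                  config.motif_width,
                                                  layout_length=len(prot))
                    add(f"{gid}_i1", sp.name, gid, c, "isoform", stage,
                        iarch, og, iso, layout_length=len(prot))
                if rng.random() < config.outlier_rate:
                    oid = f"{sp.name}_{c}_out{g}"
                    oprot = mutate(panel.clade_ancestors[c], x_out, rng)
                    add(oid, sp.name, oid, c, "outlier", stage, (), "", oprot)
    for d in range(config.decoy_count):
        sp = config.species[d % len(config.species)]
        did = f"{sp.name}_decoy{d}"
        if config.decoy_similarity is None:
            dprot = random_protein(config.protein_length, rng)
        else:
            dprot = mutate(panel.family_root,
                           lineage_rate(config.decoy_similarity), rng)
        stage = sp.stages[int(rng.integers(0, len(sp.stages)))]
        add(did, sp.name, did, "", "decoy", stage, (), "", dprot)

    truth = pd.DataFrame(rows, columns=list(TRUTH_COLUMNS))
    return Transcriptome(transcripts, proteins, truth)


def generate_expression(truth: pd.DataFrame, config: SynthConfig) -> pd.DataFrame:
    """Per-isoform FPKM by stage, long format.

    Stage means are ``expression_background`` everywhere except the
    transcript's gene-designated strongest stage, which is scaled by the
    dynamic range; values carry mean-one log-normal noise. A gene's FPKM is
    split evenly in expectation across its isoforms so that the
    isoform-summed value keeps the designed stage profile. Stages outside a
    species' mask are omitted (missing, not zero).
    """
    config.validate()
    if truth.empty:
        return pd.DataFrame(columns=["sequence_id", "species", "stage", "fpkm"])
    rng = _rng(config, 2)
    masks = {sp.name: sp.stages for sp in config.species}
    sigma = config.expression_sigma
    n_iso = truth.groupby("true_gene")["transcript_id"].transform("count")
    rows = []
    for (_, row), n in zip(truth.iterrows(), n_iso):
        mask = masks[row["species"]]
        for stage in mask:
            mean = config.expression_background
            if stage == row["true_strongest_stage"]:
                mean *= config.expression_dynamic_range
            noise = math.exp(rng.normal(-0.5 * sigma ** 2, sigma))
            rows.append({"sequence_id": row["transcript_id"],
                         "species": row["species"], "stage": stage,
                         "fpkm": mean / n * noise})
    return pd.DataFrame(rows)


def generate_motif_hits(truth: pd.DataFrame, config: SynthConfig) -> pd.DataFrame:
    """Motif-hit table (1-based inclusive coordinates, starts increasing)."""
    config.validate()
    grammar = config.grammar()
    rows = []
    for _, row in truth.iterrows():
        arch = tuple(a for a in str(row["true_motif_architecture"]).split(",")
                     if a and a != "nan")
        # coordinates come from the full clade grammar in the parent frame,
        # so a truncated isoform's hits are a prefix of its parent's
        full = grammar.get(str(row["true_clade"]), arch)
        layout = _motif_layout(full, int(row["layout_length"]),
                               config.motif_width)
        plen = int(row["protein_length"])
        present = set(arch)
        for m, s, e in layout:
            if m in present and e <= plen:
                rows.append({"sequence_id": row["transcript_id"],
                             "motif_id": m, "start": s, "stop": e})
    return pd.DataFrame(rows, columns=["sequence_id", "motif_id", "start", "stop"])


def generate_orthogroups(truth: pd.DataFrame) -> pd.DataFrame:
    """Orthogroup membership for every truth row with an orthogroup."""
    sub = truth[truth["true_orthogroup"].astype(str).str.len() > 0]
    return sub[["transcript_id", "true_orthogroup"]].rename(
        columns={"transcript_id": "sequence_id",
                 "true_orthogroup": "orthogroup_id"}).reset_index(drop=True)


def write_bundle(config: SynthConfig, outdir: str) -> dict[str, str]:
    """Generate everything and write the on-disk bundle; returns paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    panel = generate_reference_panel(config)
    txm = generate_transcriptome(panel, config)
    expr = generate_expression(txm.truth, config)
    hits = generate_motif_hits(txm.truth, config)
    ogs = generate_orthogroups(txm.truth)
    paths = {}

    def p(name: str) -> str:
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    io.write_fasta(txm.transcripts, p("transcripts.fasta"))
    refs = [(rid, seq) for rid, _, _, seq in panel.references] + panel.outgroup
    io.write_fasta(refs, p("refs.fasta"))
    labels = pd.DataFrame(
        [{"id": rid, "family": fam, "clade": clade}
         for rid, fam, clade, _ in panel.references]
        + [{"id": oid, "family": "outgroup", "clade": "outgroup"}
           for oid, _ in panel.outgroup])
    io.write_tsv_table(labels, p("refs_labels.tsv"))
    io.write_tsv_table(expr, p("expression.tsv"))
    io.write_tsv_table(hits, p("motif_hits.tsv"))
    io.write_tsv_table(ogs, p("orthogroups.tsv"))
    io.write_tsv_table(txm.truth, p("truth.tsv"))
    return paths
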