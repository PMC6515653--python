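# Methods

This document records the algorithms, the statistical model behind the
synthetic panels, and the reasoning behind the default parameters.

## Homology screen

Each transcript is translated in all six reading frames (stops render as
`*`; codons containing `N` resolve to the unambiguous residue when every
resolution agrees, otherwise `X`). Each frame is locally aligned against
every bait protein with an affine-gap Smith–Waterman (BLOSUM62, gap open
12, extend 1; `*` scored −1000 so alignments never read through a stop).
Scores are converted to E-values with the Karlin–Altschul formula
`E = K·m·n·exp(−λS)` using the standard ungapped parameters for the matrix
(BLOSUM62: K = 0.041, λ = 0.267; BLOSUM45: K = 0.0615, λ = 0.2291). A
transcript is kept when its best hit reaches `E ≤ 1e-3`. Best-hit
confirmation then re-aligns each candidate against an annotated database
(family references plus decoys, top 50 hits audited) and drops candidates
whose best hit is a decoy.

Downstream curation works on the locally aligned (matched) region of the
best hit, which excludes untranslated-region junk from the frame
translation.

## Alignment and trimming

The progressive aligner builds a UPGMA guide tree from multiset-Jaccard
k-mer distances, then merges profiles with a vectorized affine-gap
profile–profile dynamic program. Trimming removes columns with occupancy
below 10% (boundary kept), then rows covering less than 50% of the
remaining columns (boundary kept), and iterates alignment→trim to a
fixpoint. The column threshold is deliberately permissive: the census must
keep genuinely short fragments alive until the isoform logic can claim
them, so only nearly-empty columns are dropped.

## Distances and trees

Pairwise distances are p-distances over alignment columns. The default
gap mode counts a residue-against-gap column as a difference
(`gaps_as_difference`), which penalises fragments and pulls truncated
isoforms away from their parents — that is why the isoform test has a
second, gap-insensitive route (below). `pairwise_deletion` is available
when only substitutions should count.

Trees are built with neighbor joining (Studier–Keppler update,
deterministic lexicographic tie-break on the Q matrix, negative branch
lengths clamped to zero). On additive matrices the reconstruction is exact
to floating-point precision, which the test suite verifies against an
independent tree-simulation oracle. Rooting uses the outgroup when it is
monophyletic and falls back to midpoint rooting with a warning otherwise.
Bootstrap supports are bipartition frequencies over seeded column
resamples.

## Curation loop

Each iteration: remove exact/substring duplicates (longer wins, ties to
the smaller id) → align and trim → p-distance NJ tree → isoform grouping →
long-branch flagging → collapse. Iterates to a fixpoint (cap 10).

Two sequences are isoform candidates when their motif architectures are
compatible (one an ordered prefix of the other, or equal) **and** either
their patristic tree distance is below 0.01 or their shared-column
p-distance (pairwise deletion over columns where both have residues) is
below 0.01. The second route exists because a C-terminally truncated
isoform can sit far from its parent in gap-scored tree distance while
being essentially identical on the columns it covers. Without motif data
the shared-column route additionally requires a clear length asymmetry
(shorter < 50% of longer), because two near-full-length sequences that
only agree on their overlap are paralogs, not isoforms. Groups are closed
transitively and collapsed onto the longest member (ties to the smaller
id); representatives keep their original, untrimmed sequences.

A leaf is a long-branch outlier when its pendant branch exceeds 0.3 and
all *context* branches within two internal nodes are below 0.1, where
context excludes neighbours whose own pendant exceeds 0.3 — two
co-occurring outliers attract one another on the tree and would otherwise
shield each other from the flag. Members of isoform groups are shielded
from outlier flagging, since truncated isoforms carry long gap-driven
branches by construction.

The thresholds (0.01 isoform, 0.1 related, 0.3 long-branch) sit between
the designed divergence scales of the problem: isoforms differ by ~0.004,
within-clade paralogs by ~0.15, clades by ~0.45. They are fixed a priori
from those scales, not fitted to runs.

## Clade assignment and census

Each query leaf walks up from its parent to the smallest enclosing clade
containing at least one reference; if that clade is label-pure the query
is assigned `monophyletic`, otherwise the nearest reference by patristic
distance decides (`nearest`), with exact ties flagged and resolved to the
lexicographically smallest label. Outgroup references never vote.

Census percentages are computed per species as count/total with decimal
ROUND_HALF_UP to two places — the convention that reproduces published
family tables exactly — and ledgered removals are reported as a separate
"isoforms and outliers" row, never inside the clade denominators.

## Expression profiles

Gene FPKM is the sum of its isoforms' FPKM per stage (one pandas
group-sum; no recomputation drift). The strongest stage is the argmax over
the stages available to the gene's species: absent life-cycle stages are
masked, never treated as zero, ties go to the earliest stage in the fixed
order `0, 1, 2, 3, 4.1, 4.2, 5.1, 5.2, 6.1, 6.2, 6.3`, and all-zero genes
are called `none`. Heatmap export writes the sentinel `NA` for masked
stages so downstream plotting shows an absent phase rather than a zero.

## Associations

Motif hits become per-sequence ordered architectures (sorted by start,
ties by motif id, bounds-checked). Per motif the modal group (clade,
stage, or species), its share of the motif's occurrences, exclusivity and
ties are reported; per-motif group percentages always sum to 100.
Orthogroups are cross-tabulated against clades with spread flags, and each
orthogroup's modal strongest-stage is computed with `none` calls not
voting.

## Synthetic model

Sequence evolution is i.i.d. per-site substitution under a uniform
19-target replacement kernel. Two lineages independently mutated at
per-site rate `x` differ at a site with probability
`1 − (1−x)² − x²/19`, which inverts in closed form:
`x = (19/20)(1 − sqrt(1 − 20d/19))`, so the pairwise divergence targets
(isoform 0.004, within-clade 0.15, between-clade 0.45) translate exactly
into lineage rates. Outliers carry 10× the paralog rate, capped at 0.45 so
they stay detectable by homology while exceeding the long-branch
threshold. Proteins are 540 residues — the scale of a 12-transmembrane
sugar transporter — which makes the per-isoform substitution count ~2.2
and keeps the Poisson tail above the 0.01 isoform threshold near 2%.
Truncated isoforms lose 30–50% of the C-terminus; motif layouts are
computed in the parent gene's frame so a truncation leaves an ordered
prefix of the parent architecture. Transcripts are fixed-codon
back-translations with 0–9 nt random UTRs. FPKM is
`background × (dynamic range at the designated stage) / n_isoforms` with
mean-one log-normal noise (σ = 0.3); species stage masks mirror a
three-species design in which only one species reaches the final stage.

All generator draws derive from `SeedSequence([seed, stream])`, so every
artifact is a pure function of the configuration seed.

## Verification strategy

Every numeric behaviour is tested against an independent oracle: a
hand-typed codon table for translation, a literal alignment-path
enumeration validating a vectorized reference DP which in turn validates
the production aligner, random additive trees (adjacency BFS) for NJ
exactness, an exhaustive 3D dynamic program for three-sequence alignment
quality, brute-force tree traversals for neighborhood queries, and decimal
arithmetic for the census. Pipeline-level claims (isoform F1, outlier
recall, clade and stage accuracy) are measured on 20 seeded synthetic runs
against the generator's truth tables, with pooled (micro-averaged)
statistics because per-run counts are small.

### Known limits

- The aligner is progressive: it is near-optimal (≥95% of the exact
  3-sequence optimum in tests) but not exact for n > 2.
- Long-branch detection assumes outliers are rare relative to their
  neighborhood; a clade consisting mostly of outliers would evade it.
- Karlin–Altschul parameters are ungapped estimates applied to gapped
  scores, the standard approximation for screening-stage E-values.
- The isoform length gate (no-architecture route) will merge a true
  half-length paralog whose overlap is nearly identical; with motif data
  the architecture gate removes this ambiguity.
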