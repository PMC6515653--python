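"""Screen a transcriptome with bait proteins, then curate the hits.

Screening six-frame-translates each transcript and keeps those whose best
local alignment against any bait reaches E <= 1e-3; best-hit confirmation
against a mixed family/decoy database then removes sequences more similar
to a decoy. The curation loop removes exact duplicates, collapses isoform
groups onto their longest member, and flags long-branch outliers, iterating
to a fixpoint with every removal ledgered.
"""

from sugarminer.curation import curate_family
from sugarminer.homology import screen_transcriptome
from sugarminer.simulate import (
    SynthConfig,
    generate_reference_panel,
    generate_transcriptome,
)

config = SynthConfig(seed=0)
panel = generate_reference_panel(config)
txm = generate_transcriptome(panel, config)

candidates = screen_transcriptome(panel.bait_records(), txm.transcripts)
print(f"{len(candidates)} / {len(txm.transcripts)} transcripts pass "
      "the E-value screen")

family = curate_family([(tid, rec["matched_region"])
                        for tid, rec in sorted(candidates.items())])
print(f"{len(family.representatives)} representatives after "
      f"{family.iterations} curation iteration(s)")
for entry in family.ledger:
    target = f" -> {entry.target}" if entry.target else ""
    print(f"  removed {entry.sequence_id}: {entry.reason}{target}")
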