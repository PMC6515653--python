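"""Generate a synthetic transcriptome bundle and inspect its truth table.

The generator plants a three-clade MST family across three species:
gene copies ~0.15 divergent within a clade, isoforms <0.01 divergent from
their gene (sometimes C-terminally truncated), fast-evolving outliers,
and unrelated decoys. Everything is a pure function of the seed.
"""

from sugarminer.simulate import (
    SynthConfig,
    generate_reference_panel,
    generate_transcriptome,
)

config = SynthConfig(seed=0)
panel = generate_reference_panel(config)
txm = generate_transcriptome(panel, config)

print(f"{len(txm.transcripts)} transcripts over "
      f"{txm.truth['species'].nunique()} species")
print(txm.truth["role"].value_counts().to_string())
print()
print(txm.truth.head(6)[["transcript_id", "true_clade", "role",
                         "true_strongest_stage"]].to_string(index=False))
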