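"""Associate motif architectures and orthogroups with clades and stages.

Motif hits become ordered per-sequence architectures; each motif is
summarised by its modal clade, the percentage of its occurrences there,
and whether it is exclusive to one clade. Orthogroup memberships are
cross-tabulated against clade assignments.
"""

from sugarminer.pipeline import run_synthetic
from sugarminer.simulate import SynthConfig

result, truth = run_synthetic(SynthConfig(seed=0))

print("motif-by-clade association:")
print(result.motif_assoc["clade"].to_string(index=False))

print()
print("orthogroup x clade cross-tabulation:")
print(result.og_crosstab.to_string())
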