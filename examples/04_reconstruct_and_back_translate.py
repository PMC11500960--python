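"""Rebuild variant pockets from mutation lists and emit codon-optimized DNA.

Applies each variant's mutation list to the wild-type pocket through the
inferred residue-number → pocket-index map, shows the per-variant diff
count, and back-translates the ROM19 pocket to DNA using the packaged
human codon-usage table (most-frequent codon per residue).  The 35-residue
pocket yields 105 nt that translate back to the same protein.
"""

from opsintune import (
    apply_mutations,
    back_translate,
    diff_sequences,
    load_reference_designs,
    translate,
)

designs = load_reference_designs()
pocket_map = designs.pocket_map()
wt = designs.wt_pocket.residues
print("wild-type pocket:", wt)

for name in ("ROM17", "ROM18", "ROM19"):
    rebuilt = apply_mutations(wt, designs.mutation_lists[name], pocket_map)
    diffs = diff_sequences(wt, rebuilt, pocket_map)
    print(f"{name}: {rebuilt}  ({len(diffs)} substitutions)")

rom19 = apply_mutations(wt, designs.mutation_lists["ROM19"], pocket_map)
dna = back_translate(rom19)
print(f"\nROM19 pocket DNA ({len(dna)} nt):")
print(dna)
print("translates back to input:", translate(dna) == rom19)
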