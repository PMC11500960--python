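"""Propose red-shifting substitutions and cut a nested variant series.

Uses a unanimous profile of the ROM19 pocket string as the red-class
target and compares it against the Opto-mGluR6 wild-type pocket: every
column where the conserved red consensus differs from the wild type
becomes a candidate, ranked by conservation x information content.
Cutting the ranked list at sizes 17/18/19 yields a nested series like
ROM17 ⊂ ROM18 ⊂ ROM19; the predicted λmax of each design is its target
class range (557–625 nm here), not a point estimate.
"""

from opsintune import (
    PocketSequence,
    build_class_profile,
    build_variant_series,
    design_report,
    load_reference_designs,
    propose_mutations,
)

designs = load_reference_designs()
pocket_map = designs.pocket_map()
target_class = designs.spectral_classes[-1]  # 557-625 nm

target_profile = build_class_profile(
    [PocketSequence(designs.variant_pockets["ROM19"].residues, source_id=str(i))
     for i in range(10)],
    target_class.label,
)
candidates = propose_mutations(designs.wt_pocket, target_profile, pocket_map)
print(f"{len(candidates)} candidate substitutions toward class "
      f"{target_class.label} nm:")
print(" ", ", ".join(str(c.spec) for c in candidates))

series = build_variant_series(
    candidates, [17, 18, 19], target_class, ["top17", "top18", "top19"]
)
report = design_report(series)
print()
print(report.designs.to_string(index=False))
print()
print("each design's mutations are a prefix of the ranked candidate list,")
print("so the series is nested under set inclusion.")
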