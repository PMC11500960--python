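"""Audit the packaged Opto-mGluR6/ROM design set.

Loads the curated wild-type and variant pocket strings plus their mutation
lists, rebuilds every variant pocket from the wild type, and prints the
audit.  The one expected note: the published ROM18 pocket string is
missing its F282Y column (pocket index 27) — a transcription inconsistency
in the source data, reported rather than corrected.
"""

from opsintune import load_reference_designs, validate_reference_designs

designs = load_reference_designs()
print(f"wild-type pocket ({len(designs.wt_pocket.residues)} aa):",
      designs.wt_pocket.residues)
for name, specs in designs.mutation_lists.items():
    lam = designs.lambda_max_nm[name]
    print(f"{name}: {len(specs)} mutations, lambda_max {lam:g} nm")

report = validate_reference_designs(designs)
print()
for name, passed, message in report.checks:
    print(f"[{'ok' if passed else 'FAIL'}] {name}: {message}")
for note in report.discrepancies:
    print(f"[note] {note['variant']}: pocket index(es) {note['pocket_indices']} "
          f"(residue number(s) {note['residue_numbers']}) — {note['note']}")
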