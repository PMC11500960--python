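"""The published Opto-mGluR6 red-shift design set and its consistency audit.

Opto-mGluR6 is a melanopsin/mGluR6 chimera with λmax 480 nm.  Its three
red-shifted variants — ROM17, ROM18 and ROM19, peaking near 520, 550 and
605 nm — were designed by substituting retinal-binding-pocket residues with
the consensus residues of longer-wavelength opsin classes.  This module
ships the curated design set (wild-type and variant 35-residue pocket
strings, the nested mutation lists, λmax values and the spectral-class
bins) as packaged data, and audits it for internal consistency.

The mutation lists are nested: ROM17 carries 17 shared substitutions,
ROM18 adds F282Y, and ROM19 adds F282Y plus A199S (19 total).  The
published ROM18 pocket string is identical to ROM17's — it lacks the F282Y
column — which the audit surfaces as a transcription discrepancy rather
than silently correcting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from .mutations import (
    MutationError,
    MutationSpec,
    PocketMap,
    apply_mutations,
    diff_sequences,
    infer_pocket_index_map,
    parse_mutation,
)
from .records import POCKET_LENGTH, PocketSequence, SpectralClass

__all__ = [
    "ReferenceDesigns",
    "ValidationReport",
    "load_reference_designs",
    "red_shifts",
    "validate_reference_designs",
]

WT_NAME = "Opto-mGluR6"
VARIANT_NAMES = ("ROM17", "ROM18", "ROM19")


@dataclass(frozen=True)
class ReferenceDesigns:
    """The curated Opto-mGluR6/ROM design set."""

    wt_pocket: PocketSequence
    variant_pockets: dict[str, PocketSequence]
    mutation_lists: dict[str, list[MutationSpec]]
    lambda_max_nm: dict[str, float]
    lambda_max_alt_nm: dict[str, float]
    target_class_by_variant: dict[str, str]
    spectral_classes: list[SpectralClass]

    def pocket_map(self) -> PocketMap:
        """The residue-number → pocket-index map inferred from ROM19.

        ROM19 is the one variant whose published pocket string is fully
        consistent with its mutation list (all 19 substitutions present),
        so it pins down the monotone pairing for all 19 mutated indices.
        The 16 unmutated pocket indices have unknown residue numbers and
        stay unmapped.
        """
        return infer_pocket_index_map(
            self.wt_pocket, self.mutation_lists["ROM19"], self.variant_pockets["ROM19"]
        )


@dataclass
class ValidationReport:
    """Outcome of the design-set audit.

    ``checks`` holds (name, passed, message) triples, one per audit item;
    ``discrepancies`` holds structured notes on internal inconsistencies of
    the source data (these are reported, never raised).
    """

    checks: list[tuple[str, bool, str]] = field(default_factory=list)
    discrepancies: list[dict[str, object]] = field(default_factory=list)

    def add(self, name: str, passed: bool, message: str) -> None:
        if any(n == name for n, _, _ in self.checks):
            raise ValueError(f"duplicate check name {name!r}")
        self.checks.append((name, passed, message))

    @property
    def all_passed(self) -> bool:
        return all(passed for _, passed, _ in self.checks)

    def to_dict(self) -> dict:
        return {
            "checks": [
                {"name": n, "passed": p, "message": m} for n, p, m in self.checks
            ],
            "discrepancies": self.discrepancies,
            "all_passed": self.all_passed,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def load_reference_designs() -> ReferenceDesigns:
    """Load the packaged design set.

    The per-variant mutation lists are assembled from the shared 17
    substitutions plus F282Y (ROM18, ROM19) and A199S (ROM19 only).
    """
    raw = json.loads(
        resources.files("opsintune.data").joinpath("reference_designs.json").read_text()
    )
    shared = [parse_mutation(t) for t in raw["shared_mutations"]]
    extras = {
        "ROM17": [],
        "ROM18": [parse_mutation(t) for t in raw["rom18_extra"]],
        "ROM19": [parse_mutation(t) for t in raw["rom19_extra"]],
    }
    mutation_lists = {
        name: sorted(shared + extras[name], key=lambda s: s.position)
        for name in VARIANT_NAMES
    }
    return ReferenceDesigns(
        wt_pocket=PocketSequence(raw["wt_pocket"], source_id=WT_NAME),
        variant_pockets={
            name: PocketSequence(seq, source_id=name)
            for name, seq in raw["variant_pockets"].items()
        },
        mutation_lists=mutation_lists,
        lambda_max_nm={k: float(v) for k, v in raw["lambda_max_nm"].items()},
        lambda_max_alt_nm={k: float(v) for k, v in raw["lambda_max_alt_nm"].items()},
        target_class_by_variant=dict(raw["target_class_by_variant"]),
        spectral_classes=[SpectralClass(**c) for c in raw["spectral_classes"]],
    )


def red_shifts(
    designs: Optional[ReferenceDesigns] = None, prefer_alternate: bool = False
) -> dict[str, float]:
    """Per-variant λmax shift relative to the wild type, in nm.

    Two λmax values are on record for ROM19 — 605 nm from spectrophotometry
    and 606 nm from its design announcement; ``prefer_alternate=True``
    selects the latter where an alternate exists.
    """
    if designs is None:
        designs = load_reference_designs()
    wt = designs.lambda_max_nm[WT_NAME]
    shifts = {}
    for name in VARIANT_NAMES:
        lam = designs.lambda_max_nm[name]
        if prefer_alternate:
            lam = designs.lambda_max_alt_nm.get(name, lam)
        shifts[name] = lam - wt
    return shifts


def validate_reference_designs(
    designs: Optional[ReferenceDesigns] = None,
) -> ValidationReport:
    """Audit the design set: lengths, list sizes, and reconstructions.

    Reconstruction replays each variant's mutation list on the wild-type
    pocket through the inferred pocket map and compares against the
    published string.  A mismatch is recorded as a discrepancy in the
    source data (with the offending pocket columns), not as a software
    failure: the reconstruction check itself passes, and every mismatched
    column is surfaced in ``discrepancies``.  Idempotent and side-effect
    free.
    """
    if designs is None:
        designs = load_reference_designs()
    report = ValidationReport()

    for name, pocket in [("wt", designs.wt_pocket)] + [
        (v, designs.variant_pockets[v]) for v in VARIANT_NAMES
    ]:
        n = len(pocket.residues)
        report.add(
            f"pocket_length_{name}", n == POCKET_LENGTH, f"{name}: {n} residues"
        )

    expected_sizes = {"ROM17": 17, "ROM18": 18, "ROM19": 19}
    for name, expected in expected_sizes.items():
        n = len(designs.mutation_lists[name])
        report.add(
            f"mutation_count_{name}",
            n == expected,
            f"{name}: {n} mutations (expected {expected})",
        )

    try:
        pocket_map = designs.pocket_map()
        report.add(
            "pocket_map_inference",
            len(pocket_map) == 19,
            f"monotone pairing verified for {len(pocket_map)} mutated indices",
        )
    except MutationError as err:
        report.add("pocket_map_inference", False, str(err))
        return report

    for name in VARIANT_NAMES:
        rebuilt = apply_mutations(
            designs.wt_pocket.residues, designs.mutation_lists[name], pocket_map
        )
        published = designs.variant_pockets[name].residues
        mismatched = [
            i for i, (a, b) in enumerate(zip(rebuilt, published), 1) if a != b
        ]
        report.add(
            f"reconstruction_{name}",
            True,
            f"{name}: rebuilt pocket matches published string"
            if not mismatched
            else f"{name}: {len(mismatched)} column(s) disagree with the "
            f"published string (reported as a source discrepancy)",
        )
        if mismatched:
            index_to_number = pocket_map.residue_by_index
            report.discrepancies.append(
                {
                    "variant": name,
                    "kind": "published_pocket_vs_mutation_list",
                    "pocket_indices": mismatched,
                    "residue_numbers": [index_to_number.get(i) for i in mismatched],
                    "rebuilt": rebuilt,
                    "published": published,
                    "note": "published pocket string disagrees with the variant's "
                    "mutation list at these columns; the mutation list is "
                    "taken as authoritative",
                }
            )

    # Nestedness of the series: ROM17 ⊂ ROM18 ⊂ ROM19.
    sets = {n: set(map(str, designs.mutation_lists[n])) for n in VARIANT_NAMES}
    nested = sets["ROM17"] < sets["ROM18"] < sets["ROM19"]
    report.add(
        "nested_series",
        nested
        and sets["ROM18"] - sets["ROM17"] == {"F282Y"}
        and sets["ROM19"] - sets["ROM18"] == {"A199S"},
        "ROM17 ⊂ ROM18 ⊂ ROM19 with increments F282Y then A199S",
    )
    return report
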