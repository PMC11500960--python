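"""Consensus-guided proposal and ranking of spectral-tuning substitutions.

The design rule that produced the ROM variant series: compare the
wild-type pocket column-by-column against the consensus profile of a
longer-wavelength spectral class, and propose substituting the wild-type
residue by the target consensus wherever that consensus is well conserved.
Candidates are ranked by ``conservation × information content`` — both the
agreement within the target class and the overall definedness of the
column — and nested variant series are cut from the ranked list by size
(e.g. top 17 / 18 / 19).

The ranking criterion is a choice of this package: the underlying design
procedure only requires that conserved target-class residues be recruited,
not a particular ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .mutations import MutationSpec, PocketMap
from .profiling import ClassProfile
from .records import AMINO_ACIDS, GAP, POCKET_LENGTH, PocketSequence, SpectralClass

__all__ = [
    "CandidateMutation",
    "VariantDesign",
    "DesignError",
    "DesignParams",
    "DesignReport",
    "propose_mutations",
    "build_variant_series",
    "design_report",
]


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class DesignParams:
    """Thresholds governing candidate selection.

    min_conservation : minimum target-class consensus fraction for a column
        to yield a candidate (default 0.5 — a majority residue).
    require_source_rarity / max_source_frequency : optional filter demanding
        the proposed residue be rare in the wild type's own class profile
        (off by default).
    """

    min_conservation: float = 0.5
    require_source_rarity: bool = False
    max_source_frequency: float = 0.1


@dataclass(frozen=True)
class CandidateMutation:
    """One proposed substitution with its ranking evidence."""

    pocket_index: int
    wt_residue: str
    proposed_residue: str
    position: Optional[int]  # full-sequence residue number, when mapped
    target_conservation: float
    target_info_bits: float
    wt_class_frequency: Optional[float]
    rank_score: float

    @property
    def spec(self) -> MutationSpec:
        if self.position is None:
            raise DesignError(
                f"candidate at pocket index {self.pocket_index} has no mapped "
                "full-sequence residue number"
            )
        return MutationSpec(self.position, self.wt_residue, self.proposed_residue)

    def label(self) -> str:
        pos = self.position if self.position is not None else f"p{self.pocket_index}"
        return f"{self.wt_residue}{pos}{self.proposed_residue}"


@dataclass(frozen=True)
class VariantDesign:
    """An ordered substitution set targeting one spectral class."""

    name: str
    candidates: tuple[CandidateMutation, ...]
    target_class: SpectralClass

    def __post_init__(self) -> None:
        indices = [c.pocket_index for c in self.candidates]
        if len(set(indices)) != len(indices):
            raise DesignError(f"design {self.name!r}: duplicate pocket indices")

    @property
    def mutations(self) -> list[MutationSpec]:
        return sorted((c.spec for c in self.candidates), key=lambda s: s.position)

    @property
    def predicted_lambda_range(self) -> tuple[float, float]:
        return (self.target_class.low_nm, self.target_class.high_nm)


def propose_mutations(
    wt_pocket: PocketSequence,
    target_profile: ClassProfile,
    pocket_map: Optional[PocketMap] = None,
    params: DesignParams = DesignParams(),
    source_profile: Optional[ClassProfile] = None,
) -> list[CandidateMutation]:
    """Propose substitutions moving the wild-type pocket toward a class consensus.

    A column yields a candidate when the target consensus residue differs
    from the wild-type residue, its conservation is at least
    ``params.min_conservation``, and the column is not low-coverage.
    Candidates are returned ranked by ``conservation × info_bits``
    descending, ties broken by ascending pocket index (and hence ascending
    residue number, the map being monotone).
    """
    if target_profile.n_columns != POCKET_LENGTH:
        raise DesignError(
            f"profile has {target_profile.n_columns} columns, expected {POCKET_LENGTH}"
        )
    if params.require_source_rarity and source_profile is None:
        raise DesignError("source rarity filter requires a source profile")

    residue_numbers = pocket_map.residue_by_index if pocket_map is not None else None
    low_coverage = target_profile.low_coverage
    candidates = []
    for i in range(POCKET_LENGTH):
        entry = target_profile.consensus[i]
        if entry is None or low_coverage[i]:
            continue
        residue, conservation = entry
        wt_residue = wt_pocket[i]
        if wt_residue in (GAP,) or residue == wt_residue:
            continue
        if conservation < params.min_conservation:
            continue
        source_freq = None
        if source_profile is not None:
            source_freq = float(
                source_profile.frequencies[i][AMINO_ACIDS.index(residue)]
            )
        if (
            params.require_source_rarity
            and source_freq is not None
            and source_freq > params.max_source_frequency
        ):
            continue
        index = i + 1
        position = residue_numbers.get(index) if residue_numbers is not None else index
        info = float(target_profile.info_bits[i])
        candidates.append(
            CandidateMutation(
                pocket_index=index,
                wt_residue=wt_residue,
                proposed_residue=residue,
                position=position,
                target_conservation=conservation,
                target_info_bits=info,
                wt_class_frequency=source_freq,
                rank_score=conservation * info,
            )
        )
    candidates.sort(key=lambda c: (-c.rank_score, c.pocket_index))
    return candidates


def build_variant_series(
    candidates: Sequence[CandidateMutation],
    sizes: Sequence[int],
    target_class: SpectralClass,
    names: Sequence[str],
) -> list[VariantDesign]:
    """Cut a nested series of designs from a ranked candidate list.

    For each size k the design holds the top-k candidates, so the series
    forms a chain under set inclusion.  Sizes must be ascending and within
    the candidate count; names pair with sizes.
    """
    if len(sizes) != len(names):
        raise DesignError("sizes and names must have equal length")
    if list(sizes) != sorted(sizes):
        raise DesignError("sizes must be ascending")
    if sizes and sizes[-1] > len(candidates):
        raise DesignError(
            f"size {sizes[-1]} exceeds the {len(candidates)} available candidates"
        )
    return [
        VariantDesign(name, tuple(candidates[:k]), target_class)
        for k, name in zip(sizes, names)
    ]


@dataclass(frozen=True)
class DesignReport:
    """Tabular view of a design series.

    ``mutations``: one row per (design, mutation), sorted by rank score
    descending within each design, carrying the pocket index, residue
    change, target-class conservation and information content, and rank
    score.  ``designs``: one row per design with its mutation count and
    predicted λmax range (the target class range — the procedure predicts
    a class, not a point estimate).
    """

    mutations: pd.DataFrame
    designs: pd.DataFrame


def design_report(designs: Sequence[VariantDesign]) -> DesignReport:
    """Build the per-mutation and per-design report tables."""
    mutation_rows = []
    design_rows = []
    for design in designs:
        ordered = sorted(
            design.candidates, key=lambda c: (-c.rank_score, c.pocket_index)
        )
        low, high = design.predicted_lambda_range
        design_rows.append(
            {
                "design": design.name,
                "n_mutations": len(design.candidates),
                "target_class": design.target_class.label,
                "predicted_lambda_low_nm": low,
                "predicted_lambda_high_nm": high,
            }
        )
        for c in ordered:
            mutation_rows.append(
                {
                    "design": design.name,
                    "mutation": c.label(),
                    "pocket_index": c.pocket_index,
                    "wt_residue": c.wt_residue,
                    "proposed_residue": c.proposed_residue,
                    "target_conservation": c.target_conservation,
                    "target_info_bits": c.target_info_bits,
                    "rank_score": c.rank_score,
                }
            )
    columns = [
        "design", "mutation", "pocket_index", "wt_residue", "proposed_residue",
        "target_conservation", "target_info_bits", "rank_score",
    ]
    return DesignReport(
        mutations=pd.DataFrame(mutation_rows, columns=columns),
        designs=pd.DataFrame(design_rows),
    )
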