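"""Substitution bookkeeping: parse, apply, diff, and pocket-index mapping.

Substitutions are written in the field's ``X<pos>Y`` notation (e.g. V75W:
valine at full-sequence position 75 replaced by tryptophan; numbering is
1-based throughout).  Pocket strings are only 35 residues long, so applying
a full-sequence mutation list to a pocket requires a :class:`PocketMap`
relating residue numbers to pocket indices 1..35.  When the map is not
known a priori it can be inferred from a wild-type/mutant pocket pair by
monotone constraint satisfaction (:func:`infer_pocket_index_map`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .records import AMINO_ACIDS, PocketSequence

__all__ = [
    "MutationSpec",
    "PocketMap",
    "MutationError",
    "parse_mutation",
    "parse_mutation_list",
    "apply_mutations",
    "diff_sequences",
    "infer_pocket_index_map",
]


class MutationError(ValueError):
    """Malformed or inapplicable substitution."""


_TOKEN = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


@dataclass(frozen=True, order=True)
class MutationSpec:
    """A single substitution ``<original><position><replacement>``."""

    position: int
    original: str
    replacement: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise MutationError(f"position must be >= 1, got {self.position}")
        for residue in (self.original, self.replacement):
            if residue not in AMINO_ACIDS:
                raise MutationError(f"invalid residue {residue!r}")
        if self.original == self.replacement:
            raise MutationError(
                f"identity substitution {self.original}{self.position}"
                f"{self.replacement} rejected"
            )

    def __str__(self) -> str:
        return f"{self.original}{self.position}{self.replacement}"


def parse_mutation(token: str) -> MutationSpec:
    """Parse ``"V75W"`` into a :class:`MutationSpec` (round-trips via str)."""
    m = _TOKEN.match(token.strip())
    if m is None:
        raise MutationError(f"malformed mutation token {token!r}")
    original, pos, replacement = m.groups()
    return MutationSpec(int(pos), original.upper(), replacement.upper())


def parse_mutation_list(text: str) -> list[MutationSpec]:
    """Parse a mutation-list file body: one token per line, ``#`` comments."""
    specs = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip().rstrip(",.")
        if line:
            specs.append(parse_mutation(line))
    return specs


@dataclass(frozen=True)
class PocketMap:
    """Ordered correspondence pocket index 1..35 ↔ full-sequence residue number.

    May be partial: only mapped indices are listed.  Monotone by
    construction — pocket indices increase iff residue numbers increase —
    and injective in both coordinates.
    """

    entries: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        idxs = [i for i, _ in self.entries]
        nums = [n for _, n in self.entries]
        if sorted(set(idxs)) != idxs or sorted(set(nums)) != nums:
            raise MutationError(
                "pocket map must be strictly increasing in both pocket index "
                "and residue number"
            )
        if any(not 1 <= i <= 35 for i in idxs) or any(n < 1 for n in nums):
            raise MutationError("pocket indices must be 1..35, residue numbers >= 1")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def index_by_residue(self) -> dict[int, int]:
        return {n: i for i, n in self.entries}

    @property
    def residue_by_index(self) -> dict[int, int]:
        return {i: n for i, n in self.entries}

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, int]]) -> "PocketMap":
        return cls(tuple(sorted(pairs)))

    @classmethod
    def identity(cls, length: int = 35) -> "PocketMap":
        """Map pocket index i to residue number i (for bare pocket strings)."""
        return cls(tuple((i, i) for i in range(1, length + 1)))

    def to_tsv(self, path: str | Path, wt_pocket: Optional[PocketSequence] = None) -> None:
        lines = ["pocket_index\tresidue_number\twt_residue"]
        for i, n in self.entries:
            wt = wt_pocket[i - 1] if wt_pocket is not None else ""
            lines.append(f"{i}\t{n}\t{wt}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PocketMap":
        pairs = []
        for line in Path(path).read_text().splitlines()[1:]:
            if line.strip():
                idx, num = line.split("\t")[:2]
                pairs.append((int(idx), int(num)))
        return cls.from_pairs(pairs)


def _resolve(position: int, pocket_map: Optional[PocketMap], length: int) -> int:
    """Return the 0-based string index for a full-sequence residue number."""
    if pocket_map is None:
        index = position
    else:
        index = pocket_map.index_by_residue.get(position)
        if index is None:
            raise MutationError(
                f"residue number {position} is not mapped to a pocket index"
            )
    if not 1 <= index <= length:
        raise MutationError(
            f"position {position} resolves to index {index}, outside 1..{length}"
        )
    return index - 1


def apply_mutations(
    sequence: str,
    mutations: Sequence[MutationSpec],
    pocket_map: Optional[PocketMap] = None,
) -> str:
    """Apply substitutions, verifying each original residue.

    With ``pocket_map=None`` positions are read as direct 1-based indices
    into ``sequence``; with a map they are full-sequence residue numbers
    translated through it.  The input is never modified.
    """
    out = list(sequence)
    seen: set[int] = set()
    for spec in mutations:
        i = _resolve(spec.position, pocket_map, len(sequence))
        if i in seen:
            raise MutationError(f"duplicate mutation at position {spec.position}")
        seen.add(i)
        if out[i] != spec.original:
            raise MutationError(
                f"{spec}: expected {spec.original!r} at position {spec.position}, "
                f"found {out[i]!r}"
            )
        out[i] = spec.replacement
    return "".join(out)


def diff_sequences(
    a: str, b: str, pocket_map: Optional[PocketMap] = None
) -> list[MutationSpec]:
    """One :class:`MutationSpec` per differing position, numbered through the map.

    Satisfies ``apply_mutations(a, diff_sequences(a, b), map) == b``.
    """
    if len(a) != len(b):
        raise MutationError(f"length mismatch: {len(a)} vs {len(b)}")
    residue_by_index = None if pocket_map is None else pocket_map.residue_by_index
    specs = []
    for i, (ra, rb) in enumerate(zip(a, b), start=1):
        if ra == rb:
            continue
        if residue_by_index is None:
            number = i
        else:
            number = residue_by_index.get(i)
            if number is None:
                raise MutationError(
                    f"pocket index {i} differs but has no mapped residue number"
                )
        specs.append(MutationSpec(number, ra, rb))
    return specs


def infer_pocket_index_map(
    wt_pocket: PocketSequence,
    mutations: Sequence[MutationSpec],
    mutant_pocket: PocketSequence,
) -> PocketMap:
    """Infer residue-number → pocket-index pairing by monotone matching.

    Both the mutation list (by residue number) and the differing pocket
    columns (by index) are ordered; because the map must be monotone, the
    only admissible pairing is order-by-order.  That pairing is then
    verified residue-by-residue — ``wt[index] == original`` and
    ``mutant[index] == replacement`` for every pair — and rejected, not
    repaired, on any failure.
    """
    diffs = [
        i
        for i, (ra, rb) in enumerate(zip(wt_pocket.residues, mutant_pocket.residues), 1)
        if ra != rb
    ]
    ordered = sorted(mutations, key=lambda s: s.position)
    if len(ordered) != len(diffs):
        raise MutationError(
            f"{len(ordered)} mutations but {len(diffs)} differing pocket positions"
        )
    positions = [s.position for s in ordered]
    if len(set(positions)) != len(positions):
        raise MutationError("duplicate residue numbers in mutation list")
    pairs = []
    for spec, index in zip(ordered, diffs):
        if wt_pocket[index - 1] != spec.original:
            raise MutationError(
                f"{spec}: wild-type pocket has {wt_pocket[index - 1]!r} at pocket "
                f"index {index}, expected {spec.original!r}"
            )
        if mutant_pocket[index - 1] != spec.replacement:
            raise MutationError(
                f"{spec}: mutant pocket has {mutant_pocket[index - 1]!r} at pocket "
                f"index {index}, expected {spec.replacement!r}"
            )
        pairs.append((index, spec.position))
    return PocketMap.from_pairs(pairs)
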