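"""Codon-usage tables and back-translation of designed proteins to DNA.

Designed variants are implemented on the wild-type gene by codon
optimization; here that means the simplest auditable rule — each amino
acid is encoded by its most-used codon in the supplied usage table, with
alphabetical tie-break.  A human usage table ships as the default; any
table with per-amino-acid codon fractions can be swapped in.  RNA folding
of the resulting sequence is left to external tools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

from Bio.Seq import Seq

from .records import AMINO_ACIDS

__all__ = ["CodonTable", "CodonError", "back_translate", "load_human_codon_table", "translate"]

_DNA = set("ACGT")


class CodonError(ValueError):
    pass


@dataclass(frozen=True)
class CodonTable:
    """Per-amino-acid codon usage fractions.

    Fractions are normalized to sum to 1 per amino acid at construction;
    every codon must be a valid DNA triplet that translates to its amino
    acid under the standard genetic code.
    """

    name: str
    usage: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        normalized: dict[str, dict[str, float]] = {}
        for aa, codons in self.usage.items():
            if aa not in AMINO_ACIDS:
                raise CodonError(f"unknown amino acid {aa!r}")
            if not codons:
                raise CodonError(f"no codons for {aa!r}")
            total = float(sum(codons.values()))
            if total <= 0:
                raise CodonError(f"non-positive usage total for {aa!r}")
            entry = {}
            for codon, fraction in codons.items():
                codon = codon.upper()
                if len(codon) != 3 or set(codon) - _DNA:
                    raise CodonError(f"invalid codon {codon!r} for {aa!r}")
                if str(Seq(codon).translate()) != aa:
                    raise CodonError(f"codon {codon!r} does not encode {aa!r}")
                entry[codon] = fraction / total
            normalized[aa] = entry
        object.__setattr__(self, "usage", normalized)

    def preferred_codon(self, amino_acid: str) -> str:
        """Highest-usage codon; alphabetical on ties."""
        codons = self.usage.get(amino_acid)
        if codons is None:
            raise CodonError(f"amino acid {amino_acid!r} absent from table")
        return max(sorted(codons), key=lambda c: codons[c])


def load_human_codon_table() -> CodonTable:
    """The packaged human codon-usage table."""
    raw = json.loads(
        resources.files("opsintune.data").joinpath("human_codon_usage.json").read_text()
    )
    return CodonTable(name=raw["name"], usage=raw["usage"])


def back_translate(
    protein: str, table: CodonTable | None = None, mode: str = "most-frequent"
) -> str:
    """Encode a protein as DNA, one preferred codon per residue.

    The output has length 3 × len(protein) and translates back to the
    input under the standard genetic code.
    """
    if mode != "most-frequent":
        raise CodonError(f"unsupported optimization mode {mode!r}")
    if table is None:
        table = load_human_codon_table()
    return "".join(table.preferred_codon(aa) for aa in protein)


def translate(dna: str) -> str:
    """Standard-code translation (convenience wrapper for round-trip checks)."""
    if len(dna) % 3:
        raise CodonError(f"DNA length {len(dna)} is not a multiple of 3")
    return str(Seq(dna).translate())
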