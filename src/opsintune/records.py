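"""Annotated opsin records, spectral-class bins, and FASTA/TSV I/O.

An opsin's absorption maximum (λmax, nm) is set largely by the residues
lining its retinal-binding pocket.  This module holds the basic containers:
one :class:`OpsinRecord` per annotated protein, :class:`SpectralClass`
wavelength bins used to stratify opsins before profiling, and the 35-residue
:class:`PocketSequence` extracted from the binding pocket.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AMINO_ACIDS",
    "GAP",
    "POCKET_LENGTH",
    "OpsinRecord",
    "SpectralClass",
    "PocketSequence",
    "assign_spectral_class",
    "default_spectral_classes",
    "read_opsin_fasta",
    "write_opsin_fasta",
]

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Allowed on input; excluded from frequency counts.
UNKNOWN_RESIDUE = "X"
GAP = "-"
#: Number of residues lining the retinal-binding pocket.
POCKET_LENGTH = 35

_INPUT_ALPHABET = set(AMINO_ACIDS) | {UNKNOWN_RESIDUE}

#: Valid λmax range for sanity checking annotations (nm).
LAMBDA_MIN_NM = 300.0
LAMBDA_MAX_NM = 700.0

ANNOTATION_COLUMNS = ("id", "species", "family", "lambda_max_nm")


class OpsinDataError(ValueError):
    """Malformed opsin input (sequence, annotation table, or class bins)."""


@dataclass(frozen=True)
class OpsinRecord:
    """One annotated opsin protein.

    Parameters
    ----------
    id : str
        Unique record identifier (FASTA id).
    sequence : str
        Amino-acid sequence over the 20-letter alphabet plus ``X``.
    lambda_max : float, optional
        Absorption maximum in nm, when known; must lie in [300, 700].
    species, family : str, optional
        Free-text species and opsin-family labels (e.g. ``melanopsin``,
        ``cone-red``).
    """

    id: str
    sequence: str
    lambda_max: Optional[float] = None
    species: Optional[str] = None
    family: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise OpsinDataError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _INPUT_ALPHABET
        if bad:
            raise OpsinDataError(
                f"record {self.id!r}: invalid residue(s) {sorted(bad)!r}"
            )
        if self.lambda_max is not None and not (
            LAMBDA_MIN_NM <= self.lambda_max <= LAMBDA_MAX_NM
        ):
            raise OpsinDataError(
                f"record {self.id!r}: lambda_max {self.lambda_max} nm outside "
                f"[{LAMBDA_MIN_NM:g}, {LAMBDA_MAX_NM:g}]"
            )


@dataclass(frozen=True)
class SpectralClass:
    """A named λmax bin, half-open [low_nm, high_nm) by default.

    ``closed_high=True`` makes the upper bound inclusive, used for the
    topmost bin so the bin set partitions its covered range.
    """

    label: str
    low_nm: float
    high_nm: float
    closed_high: bool = False

    def __post_init__(self) -> None:
        if not self.low_nm < self.high_nm:
            raise OpsinDataError(
                f"class {self.label!r}: low_nm must be < high_nm "
                f"({self.low_nm} vs {self.high_nm})"
            )

    def contains(self, lambda_max: float) -> bool:
        if self.closed_high:
            return self.low_nm <= lambda_max <= self.high_nm
        return self.low_nm <= lambda_max < self.high_nm


@dataclass(frozen=True)
class PocketSequence:
    """The 35 residues of a retinal-binding pocket, in pocket order.

    Gap characters (``-``) are permitted in aligned extractions where the
    query carries a deletion relative to the reference.
    """

    residues: str
    source_id: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) != POCKET_LENGTH:
            raise OpsinDataError(
                f"pocket from {self.source_id!r}: length {len(self.residues)} "
                f"!= {POCKET_LENGTH}"
            )
        bad = set(self.residues) - _INPUT_ALPHABET - {GAP}
        if bad:
            raise OpsinDataError(
                f"pocket from {self.source_id!r}: invalid residue(s) "
                f"{sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return POCKET_LENGTH

    def __getitem__(self, index: int) -> str:
        return self.residues[index]


def default_spectral_classes() -> list[SpectralClass]:
    """The four λmax bins used to stratify opsins for pocket profiling.

    Blue opsins at 332–340 nm and three red bins at 520–540, 540–557 and
    557–625 nm.  Shared boundaries are resolved half-open (a 540 nm opsin
    belongs to 540–557); the top bin includes its upper bound.
    """
    return [
        SpectralClass("332-340", 332.0, 340.0),
        SpectralClass("520-540", 520.0, 540.0),
        SpectralClass("540-557", 540.0, 557.0),
        SpectralClass("557-625", 557.0, 625.0, closed_high=True),
    ]


def _check_disjoint(classes: Sequence[SpectralClass]) -> None:
    ordered = sorted(classes, key=lambda c: (c.low_nm, c.high_nm))
    for a, b in zip(ordered, ordered[1:]):
        if b.low_nm < a.high_nm or (b.low_nm == a.high_nm and a.closed_high):
            raise OpsinDataError(
                f"overlapping spectral classes {a.label!r} and {b.label!r}"
            )


def assign_spectral_class(
    lambda_max: float, classes: Sequence[SpectralClass]
) -> Optional[SpectralClass]:
    """Return the unique class bin containing ``lambda_max``, or None.

    ``None`` means unclassified: no bin covers the wavelength.  The bins
    must be pairwise disjoint under the half-open membership rule;
    overlapping bins raise :class:`OpsinDataError`.
    """
    _check_disjoint(classes)
    hits = [c for c in classes if c.contains(lambda_max)]
    if not hits:
        return None
    return hits[0]


def _read_annotations(path: Path) -> pd.DataFrame:
    table = pd.read_csv(
        path, sep="\t", dtype={"id": str}, float_precision="round_trip"
    )
    if "id" not in table.columns or "lambda_max_nm" not in table.columns:
        raise OpsinDataError(
            f"{path}: annotation table needs columns 'id' and 'lambda_max_nm' "
            f"(got {list(table.columns)})"
        )
    dup = table["id"][table["id"].duplicated()]
    if not dup.empty:
        raise OpsinDataError(f"{path}: duplicate annotation id(s) {sorted(set(dup))}")
    lam = pd.to_numeric(table["lambda_max_nm"], errors="coerce")
    bad = table.loc[lam.isna() & table["lambda_max_nm"].notna(), "id"]
    if not bad.empty:
        raise OpsinDataError(
            f"{path}: non-numeric lambda_max_nm for id(s) {sorted(bad)}"
        )
    table["lambda_max_nm"] = lam
    return table


def read_opsin_fasta(path: str | Path, annotations: str | Path) -> list[OpsinRecord]:
    """Read a protein FASTA plus a TSV annotation table into records.

    The table has header ``id	species	family	lambda_max_nm`` (species and
    family optional).  FASTA order is preserved; entries without an
    annotation row get ``lambda_max=None`` with a logged warning; annotation
    rows whose id is absent from the FASTA raise an error.
    """
    path, annotations = Path(path), Path(annotations)
    table = _read_annotations(annotations)
    by_id = {row["id"]: row for _, row in table.iterrows()}

    records: list[OpsinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if not entry.id or len(entry.seq) == 0:
            raise OpsinDataError(f"{path}: malformed FASTA record {entry.id!r}")
        if entry.id in seen:
            raise OpsinDataError(f"{path}: duplicate FASTA id {entry.id!r}")
        seen.add(entry.id)
        row = by_id.get(entry.id)
        if row is None:
            logger.warning("FASTA record %r has no annotation row", entry.id)
            records.append(OpsinRecord(id=entry.id, sequence=str(entry.seq).upper()))
            continue
        lam = row["lambda_max_nm"]
        records.append(
            OpsinRecord(
                id=entry.id,
                sequence=str(entry.seq).upper(),
                lambda_max=None if pd.isna(lam) else float(lam),
                species=_opt(row, "species"),
                family=_opt(row, "family"),
            )
        )
    orphans = sorted(set(by_id) - seen)
    if orphans:
        raise OpsinDataError(
            f"{annotations}: annotation id(s) absent from FASTA: {orphans}"
        )
    return records


def _opt(row: pd.Series, key: str) -> Optional[str]:
    value = row.get(key)
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    return str(value)


def write_opsin_fasta(
    records: Sequence[OpsinRecord], path: str | Path, annotations: str | Path
) -> None:
    """Write records back to FASTA + TSV (inverse of :func:`read_opsin_fasta`)."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")
    frame = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "species": [r.species for r in records],
            "family": [r.family for r in records],
            # repr keeps the full float precision so a read-back is exact
            "lambda_max_nm": [
                "" if r.lambda_max is None else repr(r.lambda_max) for r in records
            ],
        }
    )
    frame.to_csv(annotations, sep="\t", index=False)
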