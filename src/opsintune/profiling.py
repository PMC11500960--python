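"""Per-column residue profiling of pocket alignments, sequence-logo style.

A :class:`ClassProfile` summarizes the 35 pocket columns of one spectral
class: gap-excluded residue frequencies, per-column Shannon information
content in bits (IC = log2 20 − H, the scale of sequence-logo letter
stacks), and the consensus residue with its conservation fraction.
Unknown residues (``X``) and gaps are excluded from the frequency counts;
the gap fraction is reported separately and columns that are mostly gaps
are flagged low-coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import AMINO_ACIDS, GAP, POCKET_LENGTH, UNKNOWN_RESIDUE, PocketSequence

__all__ = ["ClassProfile", "ProfileError", "information_content", "build_class_profile"]

MAX_BITS = float(np.log2(len(AMINO_ACIDS)))
LOW_COVERAGE_GAP_FRACTION = 0.5


class ProfileError(ValueError):
    pass


def information_content(freq: Sequence[float]) -> float:
    """Information content of one column's residue distribution, in bits.

    IC = log2(20) − H with H = −Σ f·log2 f; zero frequencies contribute
    nothing.  Frequencies must be non-negative and sum to 1 (±1e-9).
    """
    f = np.asarray(freq, dtype=float)
    if f.ndim != 1 or len(f) != len(AMINO_ACIDS):
        raise ProfileError(f"expected {len(AMINO_ACIDS)} frequencies, got {f.shape}")
    if (f < 0).any():
        raise ProfileError("negative frequency")
    if abs(f.sum() - 1.0) > 1e-9:
        raise ProfileError(f"frequencies sum to {f.sum()!r}, not 1")
    nz = f[f > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return max(0.0, MAX_BITS - entropy)


@dataclass(frozen=True)
class ClassProfile:
    """Column-wise residue statistics for one spectral class.

    ``frequencies`` is a 35 × 20 matrix over :data:`AMINO_ACIDS` (rows sum
    to 1 where the column has any residue coverage); ``consensus`` holds
    per column the argmax residue and its conservation fraction, with
    alphabetical tie-break, or ``None`` for an all-gap column.
    """

    class_label: str
    n_sequences: int
    frequencies: np.ndarray
    gap_fraction: np.ndarray
    info_bits: np.ndarray
    consensus: tuple[Optional[tuple[str, float]], ...]

    @property
    def n_columns(self) -> int:
        return self.frequencies.shape[0]

    @property
    def low_coverage(self) -> np.ndarray:
        return self.gap_fraction > LOW_COVERAGE_GAP_FRACTION

    @property
    def consensus_string(self) -> str:
        return "".join(c[0] if c else GAP for c in self.consensus)

    def to_frame(self) -> pd.DataFrame:
        """Tabular export: one row per column with frequencies and summaries."""
        frame = pd.DataFrame(
            self.frequencies, columns=list(AMINO_ACIDS),
            index=pd.RangeIndex(1, self.n_columns + 1, name="pocket_index"),
        )
        frame["gap_fraction"] = self.gap_fraction
        frame["info_bits"] = self.info_bits
        frame["consensus"] = [c[0] if c else GAP for c in self.consensus]
        frame["conservation"] = [c[1] if c else np.nan for c in self.consensus]
        frame["low_coverage"] = self.low_coverage
        return frame

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.6g")

    def logo_matrix(self) -> pd.DataFrame:
        """Letter heights (info_bits × frequency) for sequence-logo rendering."""
        heights = self.frequencies * self.info_bits[:, None]
        return pd.DataFrame(
            heights, columns=list(AMINO_ACIDS),
            index=pd.RangeIndex(1, self.n_columns + 1, name="pocket_index"),
        )


def build_class_profile(
    pockets: Sequence[PocketSequence], class_label: str
) -> ClassProfile:
    """Profile the pocket strings of one spectral class.

    Frequencies are computed over non-gap, non-``X`` residues; the
    consensus is the most frequent residue per column, ties broken
    alphabetically by one-letter code.
    """
    if not pockets:
        raise ProfileError("cannot profile an empty class")
    for p in pockets:
        if len(p.residues) != POCKET_LENGTH:
            raise ProfileError(
                f"pocket from {p.source_id!r} has length {len(p.residues)}"
            )

    residue_index = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
    n = len(pockets)
    counts = np.zeros((POCKET_LENGTH, len(AMINO_ACIDS)))
    gaps = np.zeros(POCKET_LENGTH)
    for p in pockets:
        for i, c in enumerate(p.residues):
            if c == GAP:
                gaps[i] += 1
            elif c != UNKNOWN_RESIDUE:
                counts[i, residue_index[c]] += 1

    coverage = counts.sum(axis=1)
    frequencies = np.zeros_like(counts)
    info = np.zeros(POCKET_LENGTH)
    consensus: list[Optional[tuple[str, float]]] = []
    for i in range(POCKET_LENGTH):
        if coverage[i] == 0:
            consensus.append(None)
            continue
        frequencies[i] = counts[i] / coverage[i]
        info[i] = information_content(frequencies[i])
        best = int(np.argmax(frequencies[i]))  # argmax takes the first, i.e.
        consensus.append((AMINO_ACIDS[best], float(frequencies[i, best])))
        # alphabetically smallest residue among ties (AMINO_ACIDS is sorted)

    return ClassProfile(
        class_label=class_label,
        n_sequences=n,
        frequencies=frequencies,
        gap_fraction=gaps / n,
        info_bits=info,
        consensus=tuple(consensus),
    )
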