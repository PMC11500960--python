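"""Reference-anchored pairwise global alignment and pocket-column extraction.

Pocket positions are defined as residue numbers of a reference sequence
(the Opto-mGluR6-like wild type), so each opsin is aligned to the reference
independently — a reference-anchored scheme rather than a joint progressive
MSA.  The aligner is Needleman–Wunsch with affine gaps (Gotoh's three-state
recurrence), maximizing substitution-matrix score with a gap of length L
costing ``gap_open + L * gap_extend``.

Traceback is deterministic: at equal score a diagonal step (match/mismatch)
is preferred over a gap in the query, which is preferred over a gap in the
reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
from Bio.Align import substitution_matrices

from .mutations import PocketMap
from .records import GAP, PocketSequence

__all__ = [
    "Alignment",
    "AlignmentError",
    "align_to_reference",
    "extract_pocket_columns",
    "load_substitution_matrix",
]

NEG_INF = -1e30

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class Alignment:
    """A gapped query/reference pair with its optimal global score.

    ``ref_coords[k]`` is the 0-based alignment column holding reference
    residue number ``k`` (1-based).
    """

    ref_aligned: str
    query_aligned: str
    score: float
    ref_coords: dict[int, int]

    def __post_init__(self) -> None:
        assert len(self.ref_aligned) == len(self.query_aligned)


@lru_cache(maxsize=8)
def load_substitution_matrix(name: str) -> tuple[str, np.ndarray]:
    """Load a named matrix (e.g. BLOSUM62) as (alphabet, dense array)."""
    try:
        matrix = substitution_matrices.load(name)
    except FileNotFoundError as err:
        raise AlignmentError(f"unknown substitution matrix {name!r}") from err
    alphabet = "".join(matrix.alphabet)
    return alphabet, np.asarray(matrix, dtype=float)


def _encode(sequence: str, alphabet: str, role: str) -> np.ndarray:
    index = {c: i for i, c in enumerate(alphabet)}
    try:
        return np.array([index[c] for c in sequence], dtype=np.intp)
    except KeyError as err:
        raise AlignmentError(f"{role} residue {err.args[0]!r} not in matrix alphabet")


def align_to_reference(
    query: str,
    reference: str,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> Alignment:
    """Optimal global alignment of ``query`` against ``reference``.

    A gap of length L costs ``gap_open + L * gap_extend`` (so the first
    gapped residue costs ``gap_open + gap_extend``).  The returned score is
    the maximum attainable under the scheme; the traceback is the unique
    alignment selected by the deterministic tie-break.
    """
    if not query or not reference:
        raise AlignmentError("empty sequence")
    alphabet, sub = load_substitution_matrix(matrix)
    q = _encode(query, alphabet, "query")
    r = _encode(reference, alphabet, "reference")
    n, m = len(r), len(q)
    first = gap_open + gap_extend  # cost of the first residue of a gap

    # Three-state Gotoh, rows over reference (i), columns over query (j):
    #   M: r_i aligned to q_j (diagonal)
    #   X: gap in query (reference residue consumed, query gap)
    #   Y: gap in reference (query residue consumed, reference gap)
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    M[0, 0] = 0.0
    X[1:, 0] = -(gap_open + gap_extend * np.arange(1, n + 1))
    Y[0, 1:] = -(gap_open + gap_extend * np.arange(1, m + 1))

    j_ext = gap_extend * np.arange(m + 1)
    score_rows = sub[r][:, q]  # n x m substitution scores
    for i in range(1, n + 1):
        best_prev = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = best_prev[:-1] + score_rows[i - 1]
        X[i] = np.maximum(
            np.maximum(M[i - 1], Y[i - 1]) - first, X[i - 1] - gap_extend
        )
        # Y within the row: Y[i,j] = max_{k<j} max(M,X)[i,k] - open - (j-k)*ext,
        # computed with a running maximum over max(M,X)[i,k] + k*ext.
        opener = np.maximum(M[i], X[i]) + j_ext
        running = np.maximum.accumulate(opener[:-1])
        Y[i, 1:] = running - gap_open - j_ext[1:]

    return _traceback(M, X, Y, query, reference, gap_open, gap_extend)


def _traceback(
    M: np.ndarray,
    X: np.ndarray,
    Y: np.ndarray,
    query: str,
    reference: str,
    gap_open: float,
    gap_extend: float,
) -> Alignment:
    n, m = len(reference), len(query)
    first = gap_open + gap_extend
    tol = 1e-9

    def pick(i: int, j: int) -> str:
        # tie-break priority: diagonal > gap-in-query (X) > gap-in-ref (Y)
        best = max(M[i, j], X[i, j], Y[i, j])
        for state, value in (("M", M[i, j]), ("X", X[i, j]), ("Y", Y[i, j])):
            if value >= best - tol:
                return state
        raise AssertionError

    i, j = n, m
    state = pick(i, j)
    score = max(M[i, j], X[i, j], Y[i, j])
    ref_out: list[str] = []
    qry_out: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            ref_out.append(reference[i - 1])
            qry_out.append(query[j - 1])
            i, j = i - 1, j - 1
            state = pick(i, j) if (i or j) else "M"
        elif state == "X":  # reference residue vs gap in query
            ref_out.append(reference[i - 1])
            qry_out.append(GAP)
            # came from M/Y (gap opened) or X (gap extended)?
            opened = max(M[i - 1, j], Y[i - 1, j]) - first
            extended = X[i - 1, j] - gap_extend
            if opened >= extended - tol:
                state = "M" if M[i - 1, j] >= Y[i - 1, j] - tol else "Y"
            i -= 1
        else:  # Y: query residue vs gap in reference
            ref_out.append(GAP)
            qry_out.append(query[j - 1])
            opened = max(M[i, j - 1], X[i, j - 1]) - first
            extended = Y[i, j - 1] - gap_extend
            if opened >= extended - tol:
                state = "M" if M[i, j - 1] >= X[i, j - 1] - tol else "X"
            j -= 1
    ref_aligned = "".join(reversed(ref_out))
    qry_aligned = "".join(reversed(qry_out))

    ref_coords: dict[int, int] = {}
    residue = 0
    for column, c in enumerate(ref_aligned):
        if c != GAP:
            residue += 1
            ref_coords[residue] = column
    return Alignment(ref_aligned, qry_aligned, float(score), ref_coords)


def extract_pocket_columns(
    alignment: Alignment, pocket_map: PocketMap
) -> PocketSequence:
    """Query residues aligned to the reference pocket positions, in order.

    The map must cover all 35 pocket indices with reference residue
    numbers; a gap character marks pocket positions deleted in the query.
    """
    residues = []
    for index, number in pocket_map.entries:
        column = alignment.ref_coords.get(number)
        if column is None:
            raise AlignmentError(
                f"pocket residue number {number} is beyond the reference length"
            )
        residues.append(alignment.query_aligned[column])
    return PocketSequence("".join(residues), source_id="aligned")
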