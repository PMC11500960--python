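"""Global affine-gap aligner vs independent oracles, and pocket extraction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from opsintune import align_to_reference, extract_pocket_columns
from opsintune.alignment import AlignmentError, load_substitution_matrix
from opsintune.mutations import PocketMap
from opsintune.records import GAP

ORACLE_ALPHABET = "ACDE"
GAP_OPEN, GAP_EXTEND = 11.0, 1.0


def _gap_runs(moves, kind):
    runs, length = [], 0
    for m in moves:
        if m == kind:
            length += 1
        elif length:
            runs.append(length)
            length = 0
    if length:
        runs.append(length)
    return runs


def oracle_best_score(query, reference, sub, alphabet):
    """Enumerate every global alignment (as a move string over diagonal /
    gap-in-query / gap-in-reference) and score it with affine gap costs.
    Exponential; only usable at tiny lengths."""
    index = {c: i for i, c in enumerate(alphabet)}
    n, m = len(reference), len(query)

    def paths(i, j):
        if i == n and j == m:
            yield ()
            return
        if i < n and j < m:
            for rest in paths(i + 1, j + 1):
                yield ("D",) + rest
        if i < n:
            for rest in paths(i + 1, j):
                yield ("X",) + rest  # reference consumed, gap in query
        if j < m:
            for rest in paths(i, j + 1):
                yield ("Y",) + rest  # query consumed, gap in reference

    best = -np.inf
    for moves in paths(0, 0):
        i = j = 0
        score = 0.0
        for move in moves:
            if move == "D":
                score += sub[index[reference[i]], index[query[j]]]
                i, j = i + 1, j + 1
            elif move == "X":
                i += 1
            else:
                j += 1
        for kind in ("X", "Y"):
            for length in _gap_runs(moves, kind):
                score -= GAP_OPEN + GAP_EXTEND * length
        best = max(best, score)
    return best


class TestAlignToReference:
    def test_self_alignment_is_gap_free_with_diagonal_score(self, designs):
        s = designs.wt_pocket.residues
        alphabet, sub = load_substitution_matrix("BLOSUM62")
        aln = align_to_reference(s, s)
        assert GAP not in aln.query_aligned and GAP not in aln.ref_aligned
        expected = sum(sub[alphabet.index(c), alphabet.index(c)] for c in s)
        assert aln.score == pytest.approx(expected)

    def test_single_deletion_lands_at_the_missing_column(self):
        aln = align_to_reference("ACDFG", "ACDEFG")
        assert aln.query_aligned == "ACD-FG"
        assert aln.ref_aligned == "ACDEFG"

    def test_score_is_symmetric_under_swap(self):
        a, b = "MKWVACDY", "MKWACDEY"
        assert align_to_reference(a, b).score == align_to_reference(b, a).score

    def test_empty_sequence_and_unknown_matrix_rejected(self):
        with pytest.raises(AlignmentError):
            align_to_reference("", "ACD")
        with pytest.raises(AlignmentError):
            align_to_reference("ACD", "ACD", matrix="NOSUCH99")

    @given(
        st.text(alphabet=ORACLE_ALPHABET, min_size=1, max_size=6),
        st.text(alphabet=ORACLE_ALPHABET, min_size=1, max_size=6),
    )
    def test_score_matches_exhaustive_enumeration(self, query, reference):
        """DP score equals brute-force enumeration of all alignments."""
        alphabet, sub = load_substitution_matrix("BLOSUM62")
        aln = align_to_reference(query, reference)
        assert aln.score == pytest.approx(
            oracle_best_score(query, reference, sub, alphabet)
        )

    @given(st.integers(min_value=0, max_value=10_000))
    def test_score_matches_reference_aligner(self, seed):
        """Cross-check against an independently implemented global aligner
        on longer random pairs."""
        from Bio import Align

        rng = np.random.default_rng(seed)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        query = "".join(rng.choice(aa, size=rng.integers(5, 40)))
        reference = "".join(rng.choice(aa, size=rng.integers(5, 40)))

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
        aligner.extend_gap_score = -GAP_EXTEND
        expected = aligner.score(reference, query)
        assert align_to_reference(query, reference).score == pytest.approx(expected)

    def test_alignment_strings_reduce_to_inputs(self):
        aln = align_to_reference("MKWVACDY", "MKWACDEY")
        assert aln.query_aligned.replace(GAP, "") == "MKWVACDY"
        assert aln.ref_aligned.replace(GAP, "") == "MKWACDEY"
        assert all(
            not (a == GAP and b == GAP)
            for a, b in zip(aln.query_aligned, aln.ref_aligned)
        )


class TestExtractPocketColumns:
    def test_self_alignment_recovers_reference_pocket(self, designs, pocket_map):
        """Aligning a surrogate full-length wild type to itself and pulling
        the mapped columns returns the wild-type pocket residues."""
        from opsintune.simulate import DEFAULT_POCKET_POSITIONS, default_two_class_config
        from opsintune import generate_family

        config = default_two_class_config(seed=5)
        _, truth = generate_family(config)
        reference = truth.class_reference("470-490")
        full_map = PocketMap.from_pairs(
            (i, p) for i, p in enumerate(DEFAULT_POCKET_POSITIONS, 1)
        )
        aln = align_to_reference(reference, reference)
        pocket = extract_pocket_columns(aln, full_map)
        assert pocket.residues == "".join(
            reference[p - 1] for p in DEFAULT_POCKET_POSITIONS
        )
        # the 19 designed indices carry the wild-type pocket residues
        for index, _ in pocket_map.entries:
            assert pocket[index - 1] == designs.wt_pocket[index - 1]

    def test_deletion_spanning_a_pocket_position_yields_gap(self):
        reference = "MKWVACDYEFGHIK" * 3  # 42 residues
        # delete reference residues 20-22 from the query
        query = reference[:19] + reference[22:]
        pairs = [(i, n) for i, n in enumerate(range(3, 38), 1)]
        aln = align_to_reference(query, reference)
        pocket = extract_pocket_columns(aln, PocketMap.from_pairs(pairs))
        gapped = [i for i, c in enumerate(pocket.residues, 1) if c == GAP]
        assert len(gapped) == 3

    def test_single_substitution_moves_exactly_one_column(self):
        reference = "MKWVACDYEFGHIKLMNPQRSTVWYACDEFGHIKL"
        query = reference[:10] + "W" + reference[11:]
        assert reference[10] != "W"
        full_map = PocketMap.identity(35)
        aln = align_to_reference(query, reference)
        pocket = extract_pocket_columns(aln, full_map)
        diffs = [i for i, (a, b) in enumerate(zip(pocket.residues, reference)) if a != b]
        assert diffs == [10]

    def test_position_beyond_reference_is_an_error(self):
        aln = align_to_reference("ACD", "ACD")
        with pytest.raises(AlignmentError):
            extract_pocket_columns(aln, PocketMap.from_pairs([(1, 9)]))
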