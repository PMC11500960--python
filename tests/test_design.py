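"""Consensus-guided candidate proposal, ranking, and variant series."""

import pytest

from opsintune import (
    DesignParams,
    PocketSequence,
    SpectralClass,
    build_class_profile,
    build_variant_series,
    design_report,
    propose_mutations,
)
from opsintune.design import DesignError


def _profile_from_copies(sequence, n, label="target"):
    return build_class_profile(
        [PocketSequence(sequence, source_id=str(i)) for i in range(n)], label
    )


@pytest.fixture()
def rom19_profile(designs):
    return _profile_from_copies(designs.variant_pockets["ROM19"].residues, 10)


class TestProposeMutations:
    def test_differing_conserved_column_yields_candidate(self, designs, pocket_map):
        wt = designs.wt_pocket
        target = "W" + wt.residues[1:]
        profile = _profile_from_copies(target, 5)
        candidates = propose_mutations(wt, profile, pocket_map)
        assert len(candidates) == 1
        c = candidates[0]
        assert (c.pocket_index, c.wt_residue, c.proposed_residue) == (1, "V", "W")
        assert str(c.spec) == "V75W"

    def test_identical_consensus_yields_empty_list(self, designs, pocket_map):
        profile = _profile_from_copies(designs.wt_pocket.residues, 5)
        assert propose_mutations(designs.wt_pocket, profile, pocket_map) == []

    def test_recovers_full_design_from_target_copies(
        self, designs, pocket_map, rom19_profile
    ):
        """A profile of unanimous ROM19 pockets proposes exactly the 19
        published substitutions."""
        candidates = propose_mutations(designs.wt_pocket, rom19_profile, pocket_map)
        assert len(candidates) == 19
        assert {str(c.spec) for c in candidates} == {
            str(m) for m in designs.mutation_lists["ROM19"]
        }
        assert all(c.target_conservation == 1.0 for c in candidates)

    def test_conservation_threshold_filters_candidates(self, designs, pocket_map):
        wt = designs.wt_pocket
        # column 1: W in 2 of 5 sequences -> consensus V (wt), no candidate;
        # make W the 3-of-5 majority instead
        seqs = ["W" + wt.residues[1:]] * 3 + [wt.residues] * 2
        profile = build_class_profile(
            [PocketSequence(s, source_id=str(i)) for i, s in enumerate(seqs)], "t"
        )
        default = propose_mutations(wt, profile, pocket_map)
        assert [c.proposed_residue for c in default] == ["W"]
        strict = propose_mutations(
            wt, profile, pocket_map, DesignParams(min_conservation=0.7)
        )
        assert strict == []

    def test_raising_min_conservation_never_adds_candidates(
        self, designs, pocket_map, rom19_profile
    ):
        lenient = propose_mutations(
            designs.wt_pocket, rom19_profile, pocket_map, DesignParams(0.3)
        )
        strict = propose_mutations(
            designs.wt_pocket, rom19_profile, pocket_map, DesignParams(0.9)
        )
        assert {c.label() for c in strict} <= {c.label() for c in lenient}

    def test_deterministic_ranking_ties_by_position(
        self, designs, pocket_map, rom19_profile
    ):
        candidates = propose_mutations(designs.wt_pocket, rom19_profile, pocket_map)
        again = propose_mutations(designs.wt_pocket, rom19_profile, pocket_map)
        assert candidates == again
        scores = [c.rank_score for c in candidates]
        assert scores == sorted(scores, reverse=True)
        # unanimous profile: all scores tie, so order falls back to position
        indices = [c.pocket_index for c in candidates]
        assert indices == sorted(indices)


class TestBuildVariantSeries:
    def test_prefix_sets_are_nested(self, designs, pocket_map, rom19_profile):
        target = designs.spectral_classes[-1]
        candidates = propose_mutations(designs.wt_pocket, rom19_profile, pocket_map)
        series = build_variant_series(
            candidates, [1, 2, 5], target, ["a", "b", "c"]
        )
        sets = [set(map(str, d.mutations)) for d in series]
        assert sets[0] < sets[1] < sets[2]
        assert [len(s) for s in sets] == [1, 2, 5]
        assert all(d.predicted_lambda_range == (557.0, 625.0) for d in series)

    def test_supplied_ranking_reproduces_published_series(self, designs, pocket_map):
        """With F282Y ranked 18th and A199S 19th, sizes 17/18/19 cut the
        published ROM17 ⊂ ROM18 ⊂ ROM19 sets."""
        rom19_profile = _profile_from_copies(
            designs.variant_pockets["ROM19"].residues, 10
        )
        candidates = propose_mutations(designs.wt_pocket, rom19_profile, pocket_map)
        last = {"F282Y": 1, "A199S": 2}
        ranked = sorted(candidates, key=lambda c: (last.get(str(c.spec), 0), c.pocket_index))
        series = build_variant_series(
            ranked, [17, 18, 19], designs.spectral_classes[-1],
            ["ROM17", "ROM18", "ROM19"],
        )
        for design in series:
            expected = {str(m) for m in designs.mutation_lists[design.name]}
            assert {str(m) for m in design.mutations} == expected

    def test_empty_design_is_wild_type(self, designs):
        series = build_variant_series([], [0], designs.spectral_classes[0], ["wt"])
        assert series[0].mutations == []

    def test_oversized_request_rejected(self, designs):
        with pytest.raises(DesignError):
            build_variant_series([], [1], designs.spectral_classes[0], ["x"])

    def test_non_ascending_sizes_rejected(self, designs, pocket_map, rom19_profile):
        candidates = propose_mutations(designs.wt_pocket, rom19_profile, pocket_map)
        with pytest.raises(DesignError):
            build_variant_series(
                candidates, [3, 2], designs.spectral_classes[-1], ["a", "b"]
            )


class TestDesignReport:
    def test_full_design_report_shape(self, designs, pocket_map, rom19_profile):
        target = designs.spectral_classes[-1]
        candidates = propose_mutations(designs.wt_pocket, rom19_profile, pocket_map)
        series = build_variant_series(candidates, [19], target, ["ROM19"])
        report = design_report(series)
        assert len(report.mutations) == 19
        row = report.designs.iloc[0]
        assert row["n_mutations"] == 19
        assert (row["predicted_lambda_low_nm"], row["predicted_lambda_high_nm"]) == (
            557.0, 625.0,
        )

    def test_empty_design_reports_zero_rows_with_class_range(self, designs):
        target = designs.spectral_classes[0]
        report = design_report(build_variant_series([], [0], target, ["wt"]))
        assert len(report.mutations) == 0
        assert report.designs.iloc[0]["n_mutations"] == 0
        assert report.designs.iloc[0]["predicted_lambda_low_nm"] == target.low_nm

    def test_rows_sorted_by_rank_score_descending(self, designs, pocket_map):
        wt = designs.wt_pocket
        # two candidate columns with different conservation -> distinct scores
        target = "W" + wt.residues[1:26] + "Y" + wt.residues[27:]
        seqs = [target] * 3 + ["W" + wt.residues[1:]] * 1
        profile = build_class_profile(
            [PocketSequence(s, source_id=str(i)) for i, s in enumerate(seqs)], "t"
        )
        candidates = propose_mutations(wt, profile, pocket_map)
        series = build_variant_series(
            candidates, [len(candidates)], designs.spectral_classes[-1], ["d"]
        )
        scores = design_report(series).mutations["rank_score"].to_list()
        assert scores == sorted(scores, reverse=True)
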