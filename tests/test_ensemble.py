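"""Voting committee construction, graded votes, and feature selection."""

import itertools

import numpy as np
import pytest

import lignoclass as lc
from lignoclass.annotation import AnnotationProfile
from lignoclass.ensemble import (
    DEFAULT_VOTE_SYMBOLS,
    EnsembleModel,
    build_ensemble,
    call_from_votes,
    load_ensemble,
    save_ensemble,
    select_features,
    vote,
)
from lignoclass.evaluation import CGrid, GridPoint, MetricSet, grid_search
from lignoclass.svm import SparseLinearModel


def manual_ensemble(weight_rows, family_ids=None, encoding=lc.BINARY):
    """Committee with hand-set weight vectors (for vote / selection rules)."""
    weight_rows = np.asarray(weight_rows, dtype=float)
    assert weight_rows.shape[0] == 5
    if family_ids is None:
        family_ids = [f"f{j}" for j in range(weight_rows.shape[1])]
    members = tuple(
        SparseLinearModel(w=row, C=0.1 * (k + 1), family_ids=list(family_ids),
                          encoding=encoding)
        for k, row in enumerate(weight_rows)
    )
    dummy = MetricSet(1.0, 1.0, 1.0)
    ranking = tuple(GridPoint(C=m.C, metrics=dummy) for m in members)
    return EnsembleModel(members=members, grid_ranking=ranking, scaler=None,
                         family_ids=list(family_ids), encoding=encoding)


class TestBuildEnsemble:
    def test_committee_has_five_members_from_the_grid(self, committee, binary_matrix):
        assert len(committee.members) == 5
        grid_values = set(CGrid.default().values)
        assert all(any(abs(c - g) < 1e-12 for g in grid_values)
                   for c in committee.member_cs)
        assert len(set(committee.member_cs)) == 5
        assert committee.family_ids == binary_matrix.family_ids

    def test_members_are_the_top_five_by_loo_macro_accuracy(self, separable_matrix):
        grid = CGrid(exponents=(-3.0, -2.0, -1.5, -1.0, -0.5, 0.0))
        ranking = grid_search(separable_matrix, grid)  # exhaustive ranking oracle
        committee = build_ensemble(separable_matrix, grid)
        assert committee.member_cs == [p.C for p in ranking[:5]]

    def test_separable_set_members_classify_training_data(self, separable_matrix):
        grid = CGrid(exponents=(-0.75, -0.5, -0.375, -0.25, 0.0))
        committee = build_ensemble(separable_matrix, grid)
        for member in committee.members:
            labels = np.where(separable_matrix.X @ member.w > 0, 1, -1)
            assert np.array_equal(labels, separable_matrix.labels)

    def test_grid_smaller_than_committee_rejected(self, separable_matrix):
        with pytest.raises(ValueError, match="at least 5"):
            build_ensemble(separable_matrix, CGrid(exponents=(-1.0, 0.0)))


class TestVote:
    def test_unanimous_positive_is_strong_degrader_call(self):
        ens = manual_ensemble(np.ones((5, 2)))
        result = vote(ens, AnnotationProfile("q", {"f0": 1}))
        assert (result.positive_votes, result.symbol, result.call) == (5, "++", "degrader")

    def test_unanimous_negative_is_strong_non_degrader_call(self):
        ens = manual_ensemble(-np.ones((5, 2)))
        result = vote(ens, AnnotationProfile("q", {"f0": 1}))
        assert (result.positive_votes, result.symbol, result.call) == (0, "--", "non-degrader")

    def test_three_positive_votes_are_ambiguous(self):
        rows = np.vstack([np.ones((3, 2)), -np.ones((2, 2))])
        result = vote(manual_ensemble(rows), AnnotationProfile("q", {"f0": 1}))
        assert (result.positive_votes, result.symbol, result.call) == (3, "0", "ambiguous")

    def test_four_votes_make_a_degrader_one_vote_does_not(self):
        four = np.vstack([np.ones((4, 2)), -np.ones((1, 2))])
        one = np.vstack([np.ones((1, 2)), -np.ones((4, 2))])
        assert vote(manual_ensemble(four), AnnotationProfile("q", {"f0": 1})).call == "degrader"
        r = vote(manual_ensemble(one), AnnotationProfile("q", {"f0": 1}))
        assert (r.symbol, r.call) == ("-", "non-degrader")

    def test_symbol_mapping_partitions_all_vote_counts(self):
        assert set(DEFAULT_VOTE_SYMBOLS) == set(range(6))
        assert {call_from_votes(v) for v in range(6)} == {
            "degrader", "ambiguous", "non-degrader"
        }

    def test_vote_is_deterministic(self, committee, synthetic_panel):
        profiles, _, _ = synthetic_panel
        first = vote(committee, profiles[0])
        again = vote(committee, profiles[0])
        assert first == again

    def test_empty_profile_under_frequency_encoding_rejected(self):
        ens = manual_ensemble(np.ones((5, 2)), encoding=lc.FREQUENCY)
        with pytest.raises(ValueError):
            vote(ens, AnnotationProfile("q", {}))


class TestSelectFeatures:
    def test_majority_positive_weight_rule(self):
        # column 0: positive in 3 of 5 -> selected with support 3
        # column 1: positive in 2 of 5 -> not selected
        # column 2: all zero -> not selected
        rows = np.array(
            [
                [0.5, 0.4, 0.0],
                [0.2, 0.1, 0.0],
                [0.1, 0.0, 0.0],
                [0.0, 0.0, 0.0],
                [-0.3, -0.2, 0.0],
            ]
        )
        ranking = select_features(manual_ensemble(rows))
        assert ranking.family_ids == ["f0"]
        (entry,) = ranking.selected
        assert entry.support == 3
        assert entry.mean_positive_weight == pytest.approx((0.5 + 0.2 + 0.1) / 3)

    def test_selection_invariant_under_member_permutation(self):
        rng = np.random.default_rng(17)
        rows = rng.normal(size=(5, 8))
        base = select_features(manual_ensemble(rows))
        for perm in itertools.islice(itertools.permutations(range(5)), 1, 6):
            permuted = select_features(manual_ensemble(rows[list(perm)]))
            assert permuted == base

    def test_ordering_is_support_then_weight_then_name(self):
        rows = np.array(
            [
                [0.1, 0.5, 0.5],
                [0.1, 0.5, 0.5],
                [0.1, 0.5, 0.5],
                [0.1, 0.0, 0.0],
                [0.1, 0.0, 0.0],
            ]
        )
        ranking = select_features(manual_ensemble(rows))
        assert ranking.family_ids == ["f0", "f1", "f2"]  # support 5 first, then name

    def test_planted_families_dominate_the_selection(self, committee, synthetic_panel):
        """On the default synthetic panel the selected families are planted ones.

        The committee recovers a sizeable fraction of the planted signal; the
        redundancy of the planted columns caps how many an L1-sparse model can
        assign positive weight (the panel is separable with ~9 of them).
        """
        _, _, planted = synthetic_panel
        ranking = select_features(committee)
        selected = set(ranking.family_ids)
        assert selected, "committee selected no families at all"
        background = selected - set(planted)
        assert len(background) <= 0.10 * len(selected)
        assert len(selected & set(planted)) >= 0.40 * len(planted)


class TestSerialization:
    def test_round_trip_preserves_votes_and_selection(self, committee, synthetic_panel,
                                                      tmp_path):
        profiles, _, _ = synthetic_panel
        path = tmp_path / "ensemble.json"
        save_ensemble(committee, path)
        back = load_ensemble(path)
        assert back.member_cs == committee.member_cs
        assert back.family_ids == committee.family_ids
        for profile in profiles[:5]:
            assert vote(back, profile) == vote(committee, profile)
        assert select_features(back) == select_features(committee)

    def test_loading_a_non_ensemble_file_fails_clearly(self, tmp_path):
        path = tmp_path / "bogus.json"
        path.write_text("{\"format\": \"something-else\"}\n")
        with pytest.raises(ValueError, match="format"):
            load_ensemble(path)
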