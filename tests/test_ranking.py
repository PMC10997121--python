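"""The selection loop: worked examples, ties, structural laws, estimator API."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.base import clone
from sklearn.pipeline import Pipeline

import rrvote as rv
from rrvote import (
    ItemDispersion,
    ParticipantState,
    ReweightedRangeVoting,
    ScoreMatrix,
    TieError,
    VotingConfig,
    run_ranking,
    select_next_winner,
    weighted_item_totals,
)

from .conftest import random_panel


# ---------------------------------------------------------------- primitives


class TestWeightedTotals:
    def test_unit_weights_with_abstention(self):
        m = ScoreMatrix(
            pd.DataFrame({"q": [5.0, 0.0, np.nan]}, index=list("abc")), scale_max=5
        )
        states = {p: ParticipantState(0.0, 1.0) for p in "abc"}
        assert weighted_item_totals(m, states, ["q"]) == {"q": 5.0}

    def test_weighted_column(self):
        m = ScoreMatrix(pd.DataFrame({"q": [5.0, 0.0]}, index=["a", "b"]), scale_max=5)
        states = {p: ParticipantState(4.0, 1 / 3) for p in "ab"}
        totals = weighted_item_totals(m, states, ["q"])
        assert totals["q"] == pytest.approx(5 / 3)

    def test_empty_unranked_set(self):
        m = ScoreMatrix(pd.DataFrame({"q": [1.0]}, index=["a"]), scale_max=5)
        assert weighted_item_totals(m, {"a": ParticipantState()}, []) == {}

    def test_unknown_item_rejected(self):
        m = ScoreMatrix(pd.DataFrame({"q": [1.0]}, index=["a"]), scale_max=5)
        with pytest.raises(KeyError):
            weighted_item_totals(m, {"a": ParticipantState()}, ["nope"])


class TestSelectNextWinner:
    CFG = VotingConfig(max_scale=10)

    def test_unique_max(self):
        assert select_next_winner({"P": 5, "Q": 8, "R": 5}, self.CFG) == ("Q", [], "none")

    def test_exact_tie_input_order(self):
        totals = {"P": 1.9230769, "R": 1.9230769}
        assert select_next_winner(totals, self.CFG) == ("P", ["R"], "input_order")

    def test_singleton(self):
        assert select_next_winner({"P": 3}, self.CFG) == ("P", [], "none")

    def test_error_policy_raises_listing_items(self):
        cfg = VotingConfig(max_scale=10, tie_policy="error")
        with pytest.raises(TieError, match="P"):
            select_next_winner({"P": 1.0, "R": 1.0}, cfg)

    def test_lowest_dispersion_breaks_tie(self):
        cfg = VotingConfig(max_scale=10, tie_policy="lowest_dispersion")
        disp = {
            "P": ItemDispersion("P", 3, 2.0, 2.0, 0, 4, 4),
            "R": ItemDispersion("R", 3, 2.0, 0.5, 1, 3, 2),
        }
        winner, ties, how = select_next_winner({"P": 1.0, "R": 1.0}, cfg, dispersion=disp)
        assert (winner, ties, how) == ("R", ["P"], "lowest_dispersion")

    def test_lowest_dispersion_falls_back_to_input_order_on_equal_sd(self):
        cfg = VotingConfig(max_scale=10, tie_policy="lowest_dispersion")
        disp = {k: ItemDispersion(k, 3, 2.0, 1.0, 1, 3, 2) for k in ("P", "R")}
        winner, _, _ = select_next_winner({"P": 1.0, "R": 1.0}, cfg, dispersion=disp)
        assert winner == "P"

    def test_empty_totals_rejected(self):
        with pytest.raises(ValueError):
            select_next_winner({}, self.CFG)


# ------------------------------------------------------------ worked example


def test_two_voter_worked_example(two_voter_matrix):
    """Q wins round 1 at total 8; P and R then tie exactly at 25/13."""
    res = run_ranking(two_voter_matrix, VotingConfig(max_scale=5))
    assert res.ranking == ["Q", "P", "R"]
    r1, r2, r3 = res.rounds
    assert r1.weighted_total == pytest.approx(8.0)
    assert (r1.tie_set, r1.tie_resolution) == ([], "none")
    assert r2.weighted_total == pytest.approx(25 / 13)
    assert (r2.tie_set, r2.tie_resolution) == (["R"], "input_order")
    assert [r.rank for r in res.rounds] == [1, 2, 3]
    # both voters scored 4 on Q; weight 0.5/(0.5 + 4/5) after round 1,
    # final sums 9 each after all three items are ranked
    for state in res.participant_final_states.values():
        assert state.ranked_winner_score_sum == pytest.approx(9.0)


def test_two_voter_tie_policy_error(two_voter_matrix):
    with pytest.raises(TieError) as err:
        run_ranking(two_voter_matrix, VotingConfig(max_scale=5, tie_policy="error"))
    assert err.value.rank == 2
    assert set(err.value.tied_items) == {"P", "R"}


# --------------------------------------------------------- proportionality


def test_bloc_60_40_proportional_split(bloc_60_40):
    """3:2 seat split in the top 5 mirrors the 60:40 bloc sizes."""
    res = run_ranking(bloc_60_40, VotingConfig(max_scale=10, top_n=5))
    assert res.ranking == ["A1", "B1", "A2", "B2", "A3"]
    # hand-traced totals: 600, 400, 200, 133.33, 120
    totals = [r.weighted_total for r in res.rounds]
    assert totals == pytest.approx([600, 400, 200, 400 / 3, 120])


def test_bloc_80_20_minority_promotion(bloc_80_20):
    """Aggressive decay lifts the minority's best item from rank 3 to rank 2."""
    regular = run_ranking(bloc_80_20, VotingConfig(max_scale=10, top_n=3))
    aggressive = run_ranking(
        bloc_80_20, VotingConfig(max_scale=10, top_n=3, decay_aggression=4.0)
    )
    assert regular.ranking[:2] == ["A1", "A2"]
    assert regular.rank_of("B1") == 3
    assert aggressive.ranking[:2] == ["A1", "B1"]
    assert aggressive.rank_of("B1") < regular.rank_of("B1")


# --------------------------------------------------------- structural laws


def test_first_winner_is_argmax_of_raw_sums():
    rng = np.random.default_rng(7)
    for _ in range(20):
        m = random_panel(rng)
        raw = np.nansum(m.values, axis=0)
        if (raw == raw.max()).sum() > 1 or raw.max() <= 0:
            continue
        for a in (0.5, 1.0, 4.0):
            res = run_ranking(m, VotingConfig(max_scale=m.scale_max, decay_aggression=a, top_n=1))
            assert res.rounds[0].winner == m.item_ids[int(raw.argmax())]
            assert res.rounds[0].weighted_total == pytest.approx(raw.max())


@given(a=st.sampled_from([0.5, 1.0, 2.0, 4.0]), c=st.sampled_from([0.1, 0.5, 2.0]))
def test_single_voter_orders_by_score(a, c):
    scores = [5.0, 2.0, 4.0, 1.0, 3.0]
    m = ScoreMatrix(
        pd.DataFrame([scores], index=["solo"], columns=list("PQRST")), scale_max=5
    )
    res = run_ranking(m, VotingConfig(constant=c, max_scale=5, decay_aggression=a))
    assert res.ranking == ["P", "R", "T", "Q", "S"]


def test_clone_panel_orders_by_score():
    row = [3.0, 5.0, 0.0, 4.0]
    m = ScoreMatrix(
        pd.DataFrame([row] * 6, index=[f"p{i}" for i in range(6)], columns=list("WXYZ")),
        scale_max=5,
    )
    res = run_ranking(m, VotingConfig(max_scale=5, decay_aggression=2.0))
    assert res.ranking == ["X", "Z", "W"]
    assert res.unranked_items == ["Y"]  # all-zero totals halt by default


def test_zero_total_rank_by_tie_policy_ranks_everything():
    m = ScoreMatrix(
        pd.DataFrame([[2.0, 0.0, 0.0]], index=["p"], columns=list("ABC")), scale_max=5
    )
    res = run_ranking(
        m, VotingConfig(max_scale=5, zero_total_policy="rank_by_tie_policy")
    )
    assert res.ranking == ["A", "B", "C"]
    assert res.rounds[1].tie_set == ["C"]
    assert res.unranked_items == []
    assert len(res.rounds) + len(res.unranked_items) == m.n_items


def test_null_participant_never_changes_winners():
    rng = np.random.default_rng(11)
    for filler in (0.0, np.nan):
        m = random_panel(rng, max_side=6)
        padded = ScoreMatrix(
            pd.concat(
                [m.scores, pd.DataFrame([[filler] * m.n_items], index=["null"], columns=m.item_ids)]
            ),
            scale_max=m.scale_max,
        )
        cfg = VotingConfig(max_scale=m.scale_max, decay_aggression=2.0)
        assert run_ranking(m, cfg).ranking == run_ranking(padded, cfg).ranking


def test_row_permutation_invariance():
    rng = np.random.default_rng(3)
    m = random_panel(rng, max_side=7)
    perm = rng.permutation(m.n_participants)
    shuffled = ScoreMatrix(m.scores.iloc[perm], scale_max=m.scale_max)
    cfg = VotingConfig(max_scale=m.scale_max)
    assert run_ranking(m, cfg).ranking == run_ranking(shuffled, cfg).ranking


def test_column_permutation_changes_only_tie_resolution():
    rng = np.random.default_rng(5)
    vals = rng.uniform(0.5, 5, size=(5, 6))  # continuous: ties a.s. absent
    m = ScoreMatrix(pd.DataFrame(vals, columns=list("ABCDEF")), scale_max=5)
    perm = rng.permutation(6)
    shuffled = ScoreMatrix(m.scores.iloc[:, perm], scale_max=5)
    cfg = VotingConfig(max_scale=5, decay_aggression=2.0)
    assert run_ranking(m, cfg).ranking == run_ranking(shuffled, cfg).ranking


def test_abstention_and_zero_score_both_preserve_weight(two_voter_matrix):
    """Scoring 0 on a winner and abstaining on it are equivalent for the
    weight update (neither spends influence)."""
    res_zero = run_ranking(two_voter_matrix, VotingConfig(max_scale=5, top_n=2))
    abstain = two_voter_matrix.scores.copy()
    abstain.loc["v2", "P"] = np.nan  # v2 scored P as 0; abstain instead
    res_abs = run_ranking(
        ScoreMatrix(abstain, scale_max=5), VotingConfig(max_scale=5, top_n=2)
    )
    assert res_zero.ranking == res_abs.ranking
    s0 = res_zero.participant_final_states["v2"]
    s1 = res_abs.participant_final_states["v2"]
    assert s0.weight == pytest.approx(s1.weight)
    assert s0.ranked_winner_score_sum == pytest.approx(s1.ranked_winner_score_sum)


def test_top_n_beyond_items_rejected(two_voter_matrix):
    with pytest.raises(ValueError):
        run_ranking(two_voter_matrix, VotingConfig(max_scale=5, top_n=4))


def test_invalid_matrix_rejected():
    m = ScoreMatrix(pd.DataFrame({"q": [7.0]}, index=["p"]), scale_max=5)
    with pytest.raises(ValueError, match="above_max"):
        run_ranking(m, VotingConfig(max_scale=5))


# ------------------------------------------------------------ conditions


def test_rank_under_conditions_presets(bloc_80_20):
    groups = {p: p.split("_")[0] for p in bloc_80_20.participant_ids}
    results = rv.rank_under_conditions(
        bloc_80_20, subgroup_map=groups, mild_a=0.5, top_n=4
    )
    assert set(results) == {
        "subgroup_mean_A1",
        "individual_A1",
        "individual_A0.5",
        "individual_A4",
    }
    # round 1 is weight-free: every condition on individual input opens alike
    firsts = {k: v.ranking[0] for k, v in results.items() if k.startswith("individual")}
    assert len(set(firsts.values())) == 1
    # subgroup means weight blocs equally: 2 seats each in the top 4
    sub = results["subgroup_mean_A1"].ranking
    assert sorted(i[0] for i in sub) == ["A", "A", "B", "B"]


def test_rank_under_conditions_requires_subgroups(bloc_80_20):
    bare = ScoreMatrix(bloc_80_20.scores, bloc_80_20.scale_max)  # labels stripped
    with pytest.raises(ValueError, match="subgroup"):
        rv.rank_under_conditions(bare, condition_set=[("subgroup_mean", 1.0)])


def test_rank_under_conditions_requires_mild_a(bloc_80_20):
    with pytest.raises(ValueError, match="mild_a"):
        rv.rank_under_conditions(bloc_80_20, subgroup_map={})


def test_identical_conditions_identical_results(two_voter_matrix):
    results = rv.rank_under_conditions(
        two_voter_matrix, condition_set=[("individual", 1.0), ("individual", 1.0)]
    )
    assert len(results) == 2
    r1, r2 = results.values()
    assert r1.ranking == r2.ranking
    assert [x.weighted_total for x in r1.rounds] == [x.weighted_total for x in r2.rounds]


def test_top_list_intersection():
    results = rv.rank_under_conditions(
        rv.disjoint_bloc_panel(60, 40),
        condition_set=[("individual", 1.0), ("individual", 4.0)],
        top_n=5,
    )
    common = rv.top_list_intersection(results, 5)
    for res in results.values():
        assert common <= set(res.ranking[:5])


# --------------------------------------------------------- estimator surface


class TestEstimatorAPI:
    def test_fit_attributes_and_transform(self, two_voter_matrix):
        est = ReweightedRangeVoting(max_scale=5).fit(two_voter_matrix)
        assert est.ranking_ == ["Q", "P", "R"]
        assert est.n_features_in_ == 3
        assert list(est.feature_names_in_) == ["P", "Q", "R"]
        out = est.transform(two_voter_matrix)
        assert list(out.columns) == ["Q", "P", "R"]
        assert est.get_support().all()

    def test_transform_top_n_array(self):
        X = np.array([[5.0, 4.0, 0.0], [0.0, 4.0, 5.0]])
        est = ReweightedRangeVoting(max_scale=5, top_n=1).fit(X)
        out = est.transform(X)
        assert out.shape == (2, 1)
        assert est.get_support().sum() == 1

    def test_get_set_params_and_clone(self):
        est = ReweightedRangeVoting(decay_aggression=4.0, top_n=3)
        params = est.get_params()
        assert params["decay_aggression"] == 4.0
        twin = clone(est)
        assert twin.get_params() == params
        est.set_params(constant=1.0)
        assert est.constant == 1.0

    def test_unfitted_transform_raises(self, two_voter_matrix):
        with pytest.raises(AttributeError, match="not fitted"):
            ReweightedRangeVoting(max_scale=5).transform(two_voter_matrix)

    def test_pipeline_with_subgroup_aggregation(self, bloc_80_20):
        pipe = Pipeline(
            [
                ("agg", rv.SubgroupMeanAggregator()),
                ("rrv", ReweightedRangeVoting(max_scale=10, top_n=4)),
            ]
        )
        pipe.fit(bloc_80_20)
        ranking = pipe.named_steps["rrv"].ranking_
        assert sorted(i[0] for i in ranking) == ["A", "A", "B", "B"]

    def test_max_scale_inferred_from_array(self):
        X = np.array([[5.0, 1.0], [3.0, 2.0]])
        est = ReweightedRangeVoting().fit(X)
        assert est.result_.config_echo.max_scale == 5.0
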