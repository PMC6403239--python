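from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_response_table
from lopnet import behavior


class TestRankEvents:
    def test_all_tied_falls_back_to_event_id_order(self):
        resp = make_response_table(np.ones((3, 5)))
        ranked = behavior.rank_events(resp)
        assert list(ranked["event_id"]) == [1, 2, 3, 4, 5]

    def test_orders_by_yes_count(self):
        # events A,B,C with yes-counts 3,1,2 -> order B,C,A
        yes = np.array([[1, 1, 0], [1, 0, 1], [1, 0, 1]])
        ranked = behavior.rank_events(make_response_table(yes))
        assert list(ranked["event_id"]) == [2, 3, 1]
        assert list(ranked["yes_count"]) == [1, 2, 3]

    def test_matches_independent_recount(self, rng):
        yes = rng.random((30, 100)) < 0.5
        resp = make_response_table(yes)
        ranked = behavior.rank_events(resp)
        counts = Counter()
        for _, row in resp.iterrows():
            if row["response"] == "yes":
                counts[row["event_id"]] += 1
        expected = sorted(range(1, 101), key=lambda e: (counts[e], e))
        assert list(ranked["event_id"]) == expected

    def test_empty_table(self):
        with pytest.raises(ValueError):
            behavior.rank_events(pd.DataFrame(columns=["participant_id", "event_id", "response"]))


class TestClassifyElaboration:
    def test_100_events_split_evenly(self, rng):
        resp = make_response_table(rng.random((20, 100)) < rng.random(100))
        labels = behavior.classify_elaboration(behavior.rank_events(resp))
        assert (labels["level"] == "high").sum() == 50
        assert (labels["level"] == "low").sum() == 50

    def test_eight_events_quartiles(self):
        # yes-counts 0..7 over 7 participants
        yes = np.array([[1 if p < e else 0 for e in range(8)] for p in range(7)])
        labels = behavior.classify_elaboration(
            behavior.rank_events(make_response_table(yes))
        ).set_index("event_id")
        low = {e for e in range(1, 9) if labels.loc[e, "level"] == "low"}
        assert low == {1, 2, 7, 8}

    def test_quartile_cut_uses_rank_position_not_yes_count(self):
        # all events tied: the cut still falls at rank floor(E/4)
        labels = behavior.classify_elaboration(
            behavior.rank_events(make_response_table(np.ones((3, 12))))
        )
        assert (labels["level"] == "low").sum() == 6

    def test_too_few_events(self):
        ranked = behavior.rank_events(make_response_table(np.ones((2, 6))))
        with pytest.raises(ValueError):
            behavior.classify_elaboration(ranked)

    @given(st.integers(min_value=8, max_value=200), st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_categories_partition_events(self, n_events, seed):
        rng = np.random.default_rng(seed)
        resp = make_response_table(rng.integers(0, 2, size=(5, n_events)))
        labels = behavior.classify_elaboration(behavior.rank_events(resp))
        q = n_events // 4
        counts = labels["category"].value_counts()
        assert counts.get("1", 0) == q
        assert counts.get("3", 0) == q
        assert (labels["level"] == "high").sum() == n_events - 2 * q


class TestClassifyCongruity:
    def test_individual_level_labels(self):
        yes = np.array([[1, 1, 1], [0, 0, 0]])
        labels = behavior.classify_congruity(make_response_table(yes))
        p1 = labels[labels["participant_id"] == 1]["level"]
        p2 = labels[labels["participant_id"] == 2]["level"]
        assert (p1 == "high").all() and (p2 == "low").all()

    def test_missing_responses_labeled_absent(self):
        resp = make_response_table(np.array([[1, 0, 1]]))
        resp.loc[1, "response"] = np.nan
        labels = behavior.classify_congruity(resp)
        assert list(labels["level"]) == ["high", "absent", "high"]

    def test_levels_partition_per_participant(self, rng):
        resp = make_response_table(rng.integers(0, 2, size=(4, 20)))
        labels = behavior.classify_congruity(resp)
        per = labels.groupby("participant_id")["level"].value_counts().unstack(fill_value=0)
        assert (per.sum(axis=1) == 20).all()


def _outcomes(n_events, source_hits, q3_wrong, rec_only=0, fas=0, pid=1):
    """Outcome table for one participant with exact hit/wrong counts."""
    rows = []
    for i in range(n_events):
        if i < source_hits:
            q1, q2, q3 = "yes", "yes", "correct"
        elif i < source_hits + q3_wrong:
            q1, q2, q3 = "yes", "yes", "wrong"
        elif i < source_hits + q3_wrong + rec_only:
            q1, q2, q3 = "yes", "no", "absent"
        else:
            q1, q2, q3 = "no", "absent", "absent"
        rows.append((pid, i + 1, True, q1, q2, q3))
    for i in range(n_events):
        rows.append((pid, n_events + i + 1, False,
                     "yes" if i < fas else "no", "absent", "absent"))
    return pd.DataFrame(rows, columns=["participant_id", "item_id", "old", "q1", "q2", "q3"])


def _labels(n_events, level="high"):
    elab = pd.DataFrame({"event_id": np.arange(1, n_events + 1),
                         "category": "2a", "level": level})
    congr = pd.DataFrame({"participant_id": 1,
                          "event_id": np.arange(1, n_events + 1), "level": level})
    return elab, congr


class TestScoreMemory:
    def test_source_and_corrected_percentages(self):
        out = _outcomes(100, source_hits=40, q3_wrong=5)
        elab, congr = _labels(100)
        scores = behavior.score_memory(out, elab, congr)
        overall = scores[scores["dimension"] == "all"].iloc[0]
        assert overall["source_pct"] == pytest.approx(40.0)
        assert overall["corrected_source_pct"] == pytest.approx(35.0)
        assert overall["n_trials"] == 100

    def test_corrected_score_floors_at_zero(self):
        out = _outcomes(20, source_hits=1, q3_wrong=5)
        elab, congr = _labels(20)
        scores = behavior.score_memory(out, elab, congr)
        defined = scores["corrected_source_pct"].dropna()
        assert len(defined) and (defined >= 0).all()

    def test_dprime_zero_when_hits_equal_false_alarms(self):
        out = _outcomes(50, source_hits=10, q3_wrong=0, fas=10)
        elab, congr = _labels(50)
        scores = behavior.score_memory(out, elab, congr)
        assert scores[scores["dimension"] == "all"].iloc[0]["d_prime"] == pytest.approx(0.0)

    def test_dprime_standard_value(self):
        # hit rate .84, FA .16 over 100 trials each -> d' ~ 1.989
        out = _outcomes(100, source_hits=84, q3_wrong=0, fas=16)
        elab, congr = _labels(100)
        scores = behavior.score_memory(out, elab, congr)
        assert scores[scores["dimension"] == "all"].iloc[0]["d_prime"] == pytest.approx(
            1.989, abs=1e-3
        )

    def test_dprime_monotone_in_hit_rate(self):
        elab, congr = _labels(50)
        d = [
            behavior.score_memory(_outcomes(50, h, 0, fas=8), elab, congr)
            .query("dimension == 'all'")["d_prime"].iloc[0]
            for h in (10, 20, 30, 40)
        ]
        assert np.all(np.diff(d) > 0)

    def test_empty_cell_marked_undefined(self):
        out = _outcomes(20, source_hits=5, q3_wrong=0)
        elab, congr = _labels(20, level="high")  # no 'low' trials at all
        scores = behavior.score_memory(out, elab, congr)
        low = scores[(scores["dimension"] == "elaboration") & (scores["level"] == "low")]
        assert low["n_trials"].iloc[0] == 0
        assert np.isnan(low["source_pct"].iloc[0])


def _score_row(pid, dim, level, n, hits, wrong=0):
    return {
        "participant_id": pid, "dimension": dim, "level": level,
        "n_trials": n, "n_source_hits": hits, "n_q3_wrong": wrong,
        "source_pct": 100 * hits / n if n else np.nan,
        "corrected_source_pct": 100 * max(hits - wrong, 0) / n if n else np.nan,
        "recognition_hit_rate": hits / n if n else np.nan,
        "false_alarm_rate": 0.1, "d_prime": 1.0,
    }


def _full_scores(pid, hits_per_cell=20, n_per_cell=40, overall_hits=None):
    rows = []
    for dim in ("elaboration", "congruity"):
        for level in ("high", "low"):
            rows.append(_score_row(pid, dim, level, n_per_cell, hits_per_cell))
    total = 2 * n_per_cell
    rows.append(_score_row(pid, "all", "all", total,
                           overall_hits if overall_hits is not None else hits_per_cell * 2))
    return rows


class TestFilterParticipants:
    def test_too_few_remembered_trials_excludes(self):
        rows = _full_scores(1)
        rows[2] = _score_row(1, "congruity", "high", 40, 9)  # 9 remembered < 10
        included, log = behavior.filter_participants(pd.DataFrame(rows))
        assert included == []
        assert any("congruity=high remembered" in r for r in log[0]["reasons"])

    def test_low_overall_source_memory_excludes(self):
        rows = _full_scores(1, hits_per_cell=18, overall_hits=7)  # 7/80 < 10%
        included, log = behavior.filter_participants(pd.DataFrame(rows))
        assert included == []
        assert any("overall source memory" in r for r in log[0]["reasons"])

    def test_sufficient_participant_included(self):
        included, log = behavior.filter_participants(pd.DataFrame(_full_scores(1)))
        assert included == [1]
        assert log[0]["excluded"] is False


class TestCompareConditions:
    def _scores_from_diffs(self, base, diffs):
        rows = []
        for pid, d in enumerate(diffs, start=1):
            rows.append(_score_row(pid, "elaboration", "high", 40, 0) | {
                "corrected_source_pct": base + d})
            rows.append(_score_row(pid, "elaboration", "low", 40, 0) | {
                "corrected_source_pct": base})
        return pd.DataFrame(rows)

    def test_identical_conditions(self):
        scores = self._scores_from_diffs(50.0, [0, 0, 0, 0])
        res = behavior.compare_conditions(scores)
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_closed_form_paired_t(self):
        scores = self._scores_from_diffs(40.0, [1, 2, 3, 4, 5])
        res = behavior.compare_conditions(scores)
        assert res["t"] == pytest.approx(3 / np.sqrt(2.5 / 5), rel=1e-12)
        assert res["df"] == 4
        assert res["bonferroni_alpha"] == pytest.approx(0.0125)

    def test_invariant_to_participant_order(self, rng):
        scores = self._scores_from_diffs(40.0, rng.normal(2, 1, size=12))
        shuffled = scores.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = behavior.compare_conditions(scores)
        b = behavior.compare_conditions(shuffled)
        assert a["t"] == pytest.approx(b["t"], rel=1e-12)

    def test_too_few_participants(self):
        scores = self._scores_from_diffs(40.0, [1, 2])
        with pytest.raises(ValueError):
            behavior.compare_conditions(scores)
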