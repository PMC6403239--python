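import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lopnet import inference


def make_table(values, densities=(0.2, 0.3), measure="closeness"):
    """Long CentralityTable from values[condition][participant, node]."""
    rows = []
    for cond in values:
        arr = np.asarray(values[cond], dtype=float)
        P, N = arr.shape
        for d in densities:
            for p in range(P):
                for node in range(N):
                    rows.append((p, cond, d, node, measure, arr[p, node]))
    return pd.DataFrame(
        rows, columns=["participant", "condition", "density", "node", "measure", "value"]
    )


class TestPairedNodeTests:
    def test_identical_conditions_give_zero_t_unit_p(self, rng):
        x = rng.standard_normal((6, 4))
        table = make_table({"a": x, "b": x})
        res = inference.paired_node_tests(table, "a", "b")
        assert (res["t"] == 0).all()
        assert (res["p"] == 1).all()
        assert res["zero_variance"].all()

    def test_closed_form_t(self):
        b = np.zeros((5, 2))
        a = b.copy()
        a[:, 0] = [1, 2, 3, 4, 5]
        table = make_table({"a": a, "b": b}, densities=(0.2,))
        res = inference.paired_node_tests(table, "a", "b")
        node0 = res[res["node"] == 0].iloc[0]
        assert node0["t"] == pytest.approx(3 / np.sqrt(2.5 / 5), rel=1e-12)
        assert node0["direction"] == 1

    def test_matches_scipy(self, rng):
        a, b = rng.standard_normal((8, 5)), rng.standard_normal((8, 5))
        table = make_table({"a": a, "b": b}, densities=(0.25,))
        res = inference.paired_node_tests(table, "a", "b").set_index("node")
        for node in range(5):
            t, p = stats.ttest_rel(a[:, node], b[:, node])
            assert res.loc[node, "t"] == pytest.approx(t, rel=1e-10)
            assert res.loc[node, "p"] == pytest.approx(p, rel=1e-10)

    def test_missing_condition_rejected(self, rng):
        x = rng.standard_normal((4, 3))
        table = make_table({"a": x, "b": x})
        table = table[~((table["condition"] == "b") & (table["participant"] == 0))]
        with pytest.raises(ValueError):
            inference.paired_node_tests(table, "a", "b")


class TestFDR:
    def test_all_tiny_p_all_significant(self):
        assert inference.fdr_correct([0.001] * 42).all()

    def test_all_large_p_none_significant(self):
        assert not inference.fdr_correct([0.9] * 42).any()

    def test_matches_hand_computed_step_up(self):
        p = np.concatenate([[0.001, 0.002, 0.004], np.linspace(0.02, 0.9, 39)])
        mask = inference.fdr_correct(p, q=0.05)
        # BH step-up by hand: largest k with p_(k) <= k/m * q
        order = np.argsort(p)
        m = len(p)
        thresh = (np.arange(1, m + 1) / m) * 0.05
        passing = np.nonzero(np.sort(p) <= thresh)[0]
        expected = np.zeros(m, dtype=bool)
        if len(passing):
            expected[order[: passing.max() + 1]] = True
        assert np.array_equal(mask, expected)

    def test_nan_p_never_significant(self):
        mask = inference.fdr_correct([0.001, np.nan, 0.002])
        assert not mask[1] and mask[0] and mask[2]


class TestConjunction:
    def _tests_frame(self, sig_pattern, direction=1):
        """One node; sig_pattern gives its p at each of 6 densities."""
        rows = []
        for i, sig in enumerate(sig_pattern):
            rows.append(
                {
                    "density": 0.2 + 0.02 * i,
                    "node": 0,
                    "t": 5.0 * direction if sig else 0.1,
                    "p": 1e-5 if sig else 0.8,
                    "direction": direction if sig else 1,
                    "zero_variance": False,
                }
            )
            # a second, never-significant node keeps BH honest
            rows.append(
                {
                    "density": 0.2 + 0.02 * i,
                    "node": 1,
                    "t": 0.0,
                    "p": 0.9,
                    "direction": 1,
                    "zero_variance": False,
                }
            )
        return pd.DataFrame(rows)

    def test_five_of_six_densities_excluded(self):
        res = inference.conjunction(self._tests_frame([1, 1, 1, 1, 1, 0]))
        assert res.nodes == []

    def test_all_densities_included(self):
        res = inference.conjunction(self._tests_frame([1] * 6))
        assert res.nodes == [0]
        assert res.increased == [0] and res.decreased == []

    def test_direction_must_be_consistent(self):
        frame = self._tests_frame([1] * 6)
        frame.loc[(frame["node"] == 0) & (frame["density"] > 0.28), "direction"] = -1
        assert inference.conjunction(frame).nodes == []

    def test_empty_input_conjunction_is_empty(self):
        res = inference.conjunction(self._tests_frame([0] * 6))
        assert res.nodes == []


class TestCentralityChange:
    def test_identical_conditions_zero_change(self, rng):
        x = rng.standard_normal((5, 4))
        table = make_table({"a": x, "b": x})
        change = inference.centrality_change(table, [0, 1], "a", "b")
        assert np.allclose(change, 0.0)

    def test_single_node_single_density_is_raw_difference(self, rng):
        a, b = rng.standard_normal((4, 3)), rng.standard_normal((4, 3))
        table = make_table({"a": a, "b": b}, densities=(0.2,))
        change = inference.centrality_change(table, [2], "a", "b")
        assert np.allclose(change.to_numpy(), a[:, 2] - b[:, 2])

    def test_linear_in_node_averaging(self, rng):
        a, b = rng.standard_normal((4, 6)), rng.standard_normal((4, 6))
        table = make_table({"a": a, "b": b})
        c1 = inference.centrality_change(table, [0, 1], "a", "b")
        c2 = inference.centrality_change(table, [2, 3, 4, 5], "a", "b")
        c_all = inference.centrality_change(table, list(range(6)), "a", "b")
        assert np.allclose(c_all, (2 * c1 + 4 * c2) / 6)

    def test_empty_node_set_rejected(self, rng):
        table = make_table({"a": rng.standard_normal((4, 3)),
                            "b": rng.standard_normal((4, 3))})
        with pytest.raises(ValueError):
            inference.centrality_change(table, [], "a", "b")


class TestMemoryCorrelation:
    def test_perfect_linear_relation(self):
        change = pd.Series([1.0, 2.0, 3.0, 4.0], index=[1, 2, 3, 4])
        scores = pd.Series([10.0, 20.0, 30.0, 40.0], index=[1, 2, 3, 4])
        res = inference.memory_correlation(change, scores)
        assert res["r"] == pytest.approx(1.0)

    def test_constant_input_rejected(self):
        change = pd.Series([1.0, 1.0, 1.0], index=[1, 2, 3])
        scores = pd.Series([1.0, 2.0, 3.0], index=[1, 2, 3])
        with pytest.raises(ValueError):
            inference.memory_correlation(change, scores)

    def test_matches_scipy(self, rng):
        x = pd.Series(rng.standard_normal(20))
        y = pd.Series(rng.standard_normal(20))
        res = inference.memory_correlation(x, y)
        r, p = stats.pearsonr(x, y)
        assert res["r"] == pytest.approx(r) and res["p"] == pytest.approx(p)


class TestCountSubsets:
    @pytest.mark.parametrize("pool,k,expected", [(38, 4, 73815), (39, 3, 9139), (5, 5, 1)])
    def test_exact_counts(self, pool, k, expected):
        assert inference.count_subsets(pool, k) == expected

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            inference.count_subsets(3, 5)


class TestExhaustivePermutation:
    def _setup(self, rng, n_nodes=8, n_participants=12):
        a = rng.standard_normal((n_participants, n_nodes))
        b = rng.standard_normal((n_participants, n_nodes))
        table = make_table({"remembered": a, "forgotten": b})
        scores = pd.Series(rng.standard_normal(n_participants),
                           index=np.arange(n_participants))
        return table, scores, a, b

    def test_matches_naive_pearson_loop(self, rng):
        from itertools import combinations

        table, scores, a, b = self._setup(rng)
        observed = [6, 7]
        null = inference.exhaustive_permutation(
            table, list(range(8)), observed, scores, k=2
        )
        pool = [n for n in range(8) if n not in observed]
        naive = []
        for subset in combinations(pool, 2):
            change = inference.centrality_change(table, list(subset),
                                                 "remembered", "forgotten")
            naive.append(stats.pearsonr(change.to_numpy(), scores.to_numpy())[0])
        assert np.allclose(null.r_null, naive, atol=1e-10)
        assert null.n_subsets == 15
        assert null.count_ge == int(np.sum(np.array(naive) >= null.r_observed))
        assert null.empirical_p == null.count_ge / 15

    def test_unbeatable_observed_r(self, rng):
        table, scores, a, b = self._setup(rng)
        # make the observed node's change equal the scores exactly: r = 1
        diff = scores.to_numpy()
        a2 = a.copy()
        a2[:, 0] = b[:, 0] + diff
        table = make_table({"remembered": a2, "forgotten": b})
        null = inference.exhaustive_permutation(table, list(range(8)), [0], scores, k=1)
        assert null.r_observed == pytest.approx(1.0)
        assert null.count_ge == 0
        assert null.empirical_p == 0.0
        assert 0 < null.empirical_p_smoothed < 1

    def test_invariant_to_participant_order(self, rng):
        table, scores, *_ = self._setup(rng)
        perm = rng.permutation(12)
        shuffled = table.copy()
        remap = {old: new for new, old in enumerate(perm)}
        shuffled["participant"] = shuffled["participant"].map(remap)
        res1 = inference.exhaustive_permutation(table, list(range(8)), [0, 1], scores)
        scores2 = pd.Series(scores.to_numpy()[perm], index=np.arange(12))
        res2 = inference.exhaustive_permutation(shuffled, list(range(8)), [0, 1], scores2)
        assert np.allclose(np.sort(res1.r_null), np.sort(res2.r_null))
        assert res1.count_ge == res2.count_ge

    def test_cap_exceeded_points_to_sampling(self, rng):
        table, scores, *_ = self._setup(rng)
        with pytest.raises(ValueError, match="sampled"):
            inference.exhaustive_permutation(
                table, list(range(8)), [0, 1], scores, max_subsets=3
            )
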