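"""Ranked-list construction, rank distances, and the three optimizers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clustagg.datatypes import (
    CandidateKey,
    MEASURE_SPECS,
    RankedList,
    ValidationScoreTable,
)
from clustagg.rankagg import (
    aggregate_ce,
    aggregate_ga,
    brute_force_aggregate,
    footrule_distance,
    kendall_distance,
    objective_phi,
    to_ranked_lists,
)
from clustagg.simulate import make_lists

A, B, C = CandidateKey("agnes", 2), CandidateKey("pam", 2), CandidateKey("zeta", 2)


def plain_list(order, measure="v", weight=1.0):
    return RankedList(order, np.linspace(1.0, 0.0, len(order)), weight, measure)


class TestToRankedLists:
    def table(self, measure, scores):
        return ValidationScoreTable(np.array([scores]), [MEASURE_SPECS[measure]], [A, B])

    def test_maximize_sorts_descending(self):
        lists = to_ranked_lists(self.table("silhouette", [0.8, 0.5]))
        assert lists[0].order == [A, B]
        assert lists[0].norm_scores.tolist() == [1.0, 0.0]

    def test_minimize_sorts_ascending(self):
        lists = to_ranked_lists(self.table("connectivity", [2.0, 5.0]))
        assert lists[0].order == [A, B]

    def test_tie_breaks_by_method_name_then_k(self):
        lists = to_ranked_lists(self.table("silhouette", [0.5, 0.5]))
        assert lists[0].order == [A, B]  # agnes < pam lexicographically
        tbl = ValidationScoreTable(
            np.array([[0.5, 0.5]]), [MEASURE_SPECS["silhouette"]],
            [CandidateKey("pam", 3), CandidateKey("pam", 2)],
        )
        assert to_ranked_lists(tbl)[0].order[0].k == 2

    def test_constant_row_normalizes_to_ones_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            lists = to_ranked_lists(self.table("silhouette", [0.5, 0.5]))
        assert lists[0].norm_scores.tolist() == [1.0, 1.0]

    def test_weights_must_be_positive(self):
        with pytest.raises(ValueError):
            to_ranked_lists(self.table("dunn", [1.0, 2.0]), weights=[0.0])


class TestDistances:
    def test_identity_is_zero(self):
        v = plain_list([A, B, C])
        assert footrule_distance([A, B, C], v) == 0.0
        assert kendall_distance([A, B, C], v) == 0.0

    def test_full_reversal(self):
        v = plain_list([C, B, A])
        assert footrule_distance([A, B, C], v, weighted=False) == 4.0
        assert kendall_distance([A, B, C], v, weighted=False) == 3.0

    def test_two_element_swap(self):
        v = plain_list([B, A])
        assert footrule_distance([A, B], v, weighted=False) == 2.0
        assert kendall_distance([A, B], v, weighted=False) == 1.0

    def test_key_set_mismatch_rejected(self):
        v = plain_list([A, B])
        with pytest.raises(ValueError, match="candidate set"):
            footrule_distance([A, C], v)

    @given(st.permutations(list(range(5))))
    @settings(deadline=None, max_examples=40)
    def test_unweighted_zero_iff_equal_and_symmetric(self, perm):
        keys = [CandidateKey(f"m{i}", 2) for i in range(5)]
        order = [keys[i] for i in perm]
        v = plain_list(keys)
        fd = footrule_distance(order, v, weighted=False)
        kd = kendall_distance(order, v, weighted=False)
        assert (fd == 0.0) == (order == keys)
        assert (kd == 0.0) == (order == keys)
        # symmetry of pure-permutation distances under argument exchange
        assert fd == footrule_distance(keys, plain_list(order), weighted=False)
        assert kd == kendall_distance(keys, plain_list(order), weighted=False)

    @pytest.mark.parametrize("kappa", [3, 4, 5])
    def test_weighted_footrule_closed_form_for_equally_spaced_scores(self, kappa):
        """With equally spaced scores the weighted footrule collapses to
        (sum of squared rank displacements) / (kappa - 1): each score gap
        spans exactly |rank difference| spacing units.  Checked against
        the closed form over every permutation; zero iff the orders agree."""
        import itertools

        keys = [CandidateKey(f"m{i}", 2) for i in range(kappa)]
        v = plain_list(keys)
        for perm in itertools.permutations(keys):
            disp = [abs(perm.index(t) - keys.index(t)) for t in keys]
            expect = sum(x * x for x in disp) / (kappa - 1)
            got = footrule_distance(list(perm), v, weighted=True)
            assert got == pytest.approx(expect, abs=1e-12)
            assert (got == 0.0) == (list(perm) == keys)


class TestObjective:
    def test_zero_when_l_equals_all_lists(self):
        lists = [plain_list([A, B, C], f"v{i}") for i in range(3)]
        assert objective_phi([A, B, C], lists) == 0.0

    def test_weighted_sum_hand_value(self):
        """Two identical lists at weights 1 and 2; L one adjacent swap away
        (unweighted footrule 2 per list) gives phi = 2*1 + 2*2 = 6."""
        lists = [plain_list([A, B, C], "v1", 1.0), plain_list([A, B, C], "v2", 2.0)]
        assert objective_phi([B, A, C], lists, weighted=False) == 6.0

    def test_linearity_in_weights(self):
        lists = [plain_list([A, B, C], "v1", 1.5), plain_list([C, A, B], "v2", 0.5)]
        doubled = [RankedList(l.order, l.norm_scores, 2 * l.weight, l.measure)
                   for l in lists]
        L = [B, C, A]
        assert objective_phi(L, doubled) == pytest.approx(2 * objective_phi(L, lists))

    def test_invariant_under_consistent_relabeling(self):
        lists, _ = make_lists(5, 3, consensus_noise=2, seed=8)
        L = list(lists[1].order)
        phi = objective_phi(L, lists, "kendall", True)
        rename = {key: CandidateKey(key.method + "x", key.k + 1) for key in L}
        lists2 = [RankedList([rename[t] for t in l.order], l.norm_scores,
                             l.weight, l.measure) for l in lists]
        assert objective_phi([rename[t] for t in L], lists2, "kendall", True) == pytest.approx(phi)

    def test_empty_list_set_rejected(self):
        with pytest.raises(ValueError):
            objective_phi([A, B], [], "footrule")


class TestBruteForce:
    def test_identical_lists_return_that_order(self):
        lists = [plain_list([B, A, C], f"v{i}") for i in range(4)]
        res = brute_force_aggregate(lists)
        assert res.best_order == [B, A, C] and res.phi == 0.0

    def test_reversal_pair_optimum(self):
        lists = [plain_list([A, B, C]), plain_list([C, B, A])]
        res = brute_force_aggregate(lists, "footrule", weighted=False)
        assert res.phi == 4.0

    def test_refuses_large_instances(self):
        keys = [CandidateKey(f"m{i}", 2) for i in range(9)]
        with pytest.raises(ValueError, match="kappa"):
            brute_force_aggregate([plain_list(keys)])


class TestOptimizers:
    def test_identical_lists_converge_to_zero(self):
        lists = [plain_list([C, A, B], f"v{i}") for i in range(3)]
        for res in (aggregate_ce(lists, seed=0), aggregate_ga(lists, seed=0)):
            assert res.phi == 0.0 and res.best_order == [C, A, B]

    def test_same_seed_identical_result_and_trace(self):
        lists, _ = make_lists(6, 3, consensus_noise=3, seed=4)
        a = aggregate_ce(lists, "kendall", True, seed=11)
        b = aggregate_ce(lists, "kendall", True, seed=11)
        assert a.best_order == b.best_order and a.trace == b.trace
        g1 = aggregate_ga(lists, "kendall", True, seed=11)
        g2 = aggregate_ga(lists, "kendall", True, seed=11)
        assert g1.best_order == g2.best_order and g1.trace == g2.trace

    @pytest.mark.parametrize("bad", [{"rho": 0.0}, {"rho": 1.0}, {"smoothing": 0.0},
                                     {"smoothing": 1.5}])
    def test_ce_invalid_params(self, bad):
        lists, _ = make_lists(4, 2, seed=0)
        with pytest.raises(ValueError):
            aggregate_ce(lists, params=bad, seed=0)

    def test_ga_invalid_params(self):
        lists, _ = make_lists(4, 2, seed=0)
        with pytest.raises(ValueError):
            aggregate_ga(lists, params={"cross_prob": 0.0}, seed=0)

    @pytest.mark.parametrize("distance", ["footrule", "kendall"])
    def test_optimizers_match_oracle_on_small_suites(self, distance):
        rng = np.random.default_rng(17)
        hits = 0
        for case in range(10):
            kappa, m = 5, 3
            keys = [CandidateKey(f"m{i}", 2) for i in range(kappa)]
            lists = [plain_list([keys[j] for j in rng.permutation(kappa)], f"v{i}")
                     for i in range(m)]
            oracle = brute_force_aggregate(lists, distance, True)
            ce = aggregate_ce(lists, distance, True, seed=500 + case)
            ga = aggregate_ga(lists, distance, True, seed=500 + case)
            assert ce.phi >= oracle.phi - 1e-9  # never beats the exact optimum
            assert ga.phi >= oracle.phi - 1e-9
            hits += (abs(ce.phi - oracle.phi) < 1e-9) + (abs(ga.phi - oracle.phi) < 1e-9)
        assert hits >= 18  # out of 20 optimizer runs

    def test_planted_consensus_recovered(self):
        lists, planted = make_lists(6, 4, consensus_noise=1, seed=2)
        res = aggregate_ce(lists, seed=2)
        assert res.best_order == planted
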