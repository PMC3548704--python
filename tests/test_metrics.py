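import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, fowlkes_mallows_score

from crocbmi import GoldSolution
from crocbmi.exceptions import ParameterError, UndefinedIndexError, UndefinedRateError
from crocbmi.metrics import (
    Partition,
    ROCPoint,
    adjusted_rand,
    balancing_error,
    bmi,
    connectivity_matrix,
    contingency,
    f_measure,
    fowlkes_mallows,
    misclassification_error,
    pair_confusion,
    roc_point,
)
from conftest import all_set_partitions

rng = np.random.default_rng(7)


def _part(labels_list, ids=None):
    ids = ids or [str(i + 1) for i in range(len(labels_list))]
    return Partition({i: str(l) for i, l in zip(ids, labels_list)})


class TestConnectivity:
    def test_worked_example(self):
        J = connectivity_matrix(_part([1, 1, 2]))
        np.testing.assert_array_equal(
            J.values.astype(int), [[1, 1, 0], [1, 1, 0], [0, 0, 1]]
        )

    def test_all_singletons_is_identity(self):
        J = connectivity_matrix(_part([1, 2, 3, 4]))
        np.testing.assert_array_equal(J.values, np.eye(4, dtype=bool))

    def test_transitivity_triple_loop_oracle(self):
        labels = rng.integers(0, 4, size=30)
        J = connectivity_matrix(_part(labels)).values
        n = 30
        for i, j, k in itertools.product(range(n), repeat=3):
            if J[i, j] and J[j, k]:
                assert J[i, k]


class TestPairConfusion:
    def test_hand_enumerated_example(self, four_item_gold, four_item_pred):
        gold_conn = connectivity_matrix(Partition.from_gold(four_item_gold))
        pred_conn = connectivity_matrix(four_item_pred)
        c = pair_confusion(pred_conn, gold_conn)
        assert (c.T0, c.F1, c.T1, c.F0) == (2, 2, 1, 1)

    def test_pred_equals_gold(self, four_item_gold):
        conn = connectivity_matrix(Partition.from_gold(four_item_gold))
        c = pair_confusion(conn, conn)
        assert c.F1 == 0 and c.F0 == 0

    def test_all_in_one_prediction(self, four_item_gold):
        gold_conn = connectivity_matrix(Partition.from_gold(four_item_gold))
        pred_conn = connectivity_matrix(_part([1, 1, 1, 1]))
        c = pair_confusion(pred_conn, gold_conn)
        assert c.T0 == 0 and c.F0 == 0

    def test_totals_sum_to_pair_count(self):
        for _ in range(20):
            n = int(rng.integers(3, 15))
            gold = connectivity_matrix(_part(rng.integers(0, 3, size=n)))
            pred = connectivity_matrix(
                _part(rng.integers(0, 4, size=n))
            )
            assert pair_confusion(pred, gold).total == n * (n - 1) // 2


class TestROCPoint:
    def test_gold_maps_to_corner(self, four_item_gold):
        conn = connectivity_matrix(Partition.from_gold(four_item_gold))
        p = roc_point(pair_confusion(conn, conn))
        assert (p.fpr, p.tpr) == (0.0, 1.0)

    def test_worked_confusion(self, four_item_gold, four_item_pred):
        gold_conn = connectivity_matrix(Partition.from_gold(four_item_gold))
        pred_conn = connectivity_matrix(four_item_pred)
        p = roc_point(pair_confusion(pred_conn, gold_conn))
        assert (p.fpr, p.tpr) == (0.5, 0.5)

    def test_all_singletons_maps_to_one_one(self, four_item_gold):
        gold_conn = connectivity_matrix(Partition.from_gold(four_item_gold))
        pred_conn = connectivity_matrix(_part([1, 2, 3, 4]))
        p = roc_point(pair_confusion(pred_conn, gold_conn))
        assert (p.fpr, p.tpr) == (1.0, 1.0)

    def test_degenerate_gold_rejected(self):
        one_class = connectivity_matrix(_part([1, 1, 1]))
        pred = connectivity_matrix(_part([1, 2, 3]))
        with pytest.raises(UndefinedRateError):
            roc_point(pair_confusion(pred, one_class))


class TestErrorsAndBMI:
    @pytest.mark.parametrize(
        "pt,em", [((0, 1), 0.0), ((1, 0), 2.0), ((0.3, 0.7), 0.6)]
    )
    def test_misclassification_error(self, pt, em):
        assert misclassification_error(ROCPoint(*pt)) == pytest.approx(em)

    @pytest.mark.parametrize(
        "pt,eb", [((0.3, 0.7), 0.0), ((1, 1), 1.0), ((0.2, 0.9), 0.1)]
    )
    def test_balancing_error(self, pt, eb):
        assert balancing_error(ROCPoint(*pt)) == pytest.approx(eb)

    @pytest.mark.parametrize(
        "pt,expected",
        [((0, 1), 0.0), ((1, 1), 1.0), ((0.5, 0.5), 0.7071067811865476)],
    )
    def test_bmi_values(self, pt, expected):
        assert bmi(ROCPoint(*pt)) == pytest.approx(expected, abs=1e-12)

    def test_bmi_weight_validation(self):
        with pytest.raises(ParameterError):
            bmi(ROCPoint(0.1, 0.9), alpha=0.7, beta=0.5)

    def test_bmi_equals_euclidean_distance_to_gold_corner(self):
        # the defining identity at alpha = beta = 0.5
        pts = rng.random((10_000, 2))
        for fpr, tpr in pts:
            d = np.hypot(fpr - 0.0, tpr - 1.0)
            assert abs(bmi(ROCPoint(fpr, tpr)) - d) < 1e-12

    def test_bmi_bounded_above_chance_diagonal(self):
        for _ in range(2000):
            fpr = rng.random()
            tpr = rng.uniform(fpr, 1.0)
            assert bmi(ROCPoint(fpr, tpr)) <= 1.0 + 1e-12


class TestContingency:
    def test_worked_example(self, four_item_gold, four_item_pred):
        ct = contingency(four_item_gold, four_item_pred)
        np.testing.assert_array_equal(ct.counts, [[1, 1], [0, 2]])

    def test_margins(self):
        for _ in range(20):
            n = int(rng.integers(4, 12))
            g_labels = rng.integers(0, 3, size=n)
            p_labels = rng.integers(0, 4, size=n)
            ids = [str(i) for i in range(n)]
            ct = contingency(
                GoldSolution({i: str(l) for i, l in zip(ids, g_labels)}),
                _part(p_labels, ids),
            )
            assert ct.N == n
            np.testing.assert_array_equal(ct.row_margins, ct.counts.sum(axis=1))
            np.testing.assert_array_equal(ct.col_margins, ct.counts.sum(axis=0))


class TestExternalIndices:
    def test_identical_partitions_score_one(self, four_item_gold):
        ct = contingency(four_item_gold, Partition.from_gold(four_item_gold))
        assert adjusted_rand(ct) == pytest.approx(1.0)
        assert fowlkes_mallows(ct) == pytest.approx(1.0)
        assert f_measure(ct) == pytest.approx(1.0)

    def test_worked_example_values(self, four_item_gold, four_item_pred):
        ct = contingency(four_item_gold, four_item_pred)
        assert adjusted_rand(ct) == pytest.approx(0.0, abs=1e-12)
        assert fowlkes_mallows(ct) == pytest.approx(2 / np.sqrt(24), abs=1e-12)
        assert f_measure(ct) == pytest.approx(0.73333, abs=1e-4)

    def test_fm_undefined_on_all_singletons(self, four_item_gold):
        ct = contingency(four_item_gold, _part([1, 2, 3, 4]))
        with pytest.raises(UndefinedIndexError):
            fowlkes_mallows(ct)

    def test_agreement_with_sklearn_on_random_partitions(self):
        for _ in range(30):
            n = int(rng.integers(5, 20))
            g = rng.integers(0, 4, size=n)
            p = rng.integers(0, 4, size=n)
            ids = [str(i) for i in range(n)]
            ct = contingency(
                GoldSolution({i: str(l) for i, l in zip(ids, g)}), _part(p, ids)
            )
            assert adjusted_rand(ct) == pytest.approx(
                adjusted_rand_score(g, p), abs=1e-10
            )
            try:
                fm = fowlkes_mallows(ct)
            except UndefinedIndexError:
                continue
            assert fm == pytest.approx(fowlkes_mallows_score(g, p), abs=1e-10)

    def test_exhaustive_small_partition_pairs_vs_pair_counting(self):
        """R_A and FM from the contingency table agree with brute-force pair
        enumeration over every pair of partitions of a 5-item set."""
        items = tuple("abcde")
        partitions = [
            {i: str(bi) for bi, block in enumerate(blocks) for i in block}
            for blocks in all_set_partitions(items)
        ]
        pairs = list(itertools.product(partitions, repeat=2))
        for g_labels, p_labels in pairs:
            gold = GoldSolution(g_labels)
            pred = Partition(p_labels)
            ct = contingency(gold, pred)
            # brute-force pair enumeration
            a = b = c = d = 0  # co/co, co/sep, sep/co, sep/sep
            for x, y in itertools.combinations(items, 2):
                g_co = g_labels[x] == g_labels[y]
                p_co = p_labels[x] == p_labels[y]
                a += g_co and p_co
                b += g_co and not p_co
                c += (not g_co) and p_co
                d += not g_co and not p_co
            total = a + b + c + d
            # adjusted Rand, pair-counting formulation
            exp = (a + b) * (a + c) / total
            mx = 0.5 * ((a + b) + (a + c))
            if mx - exp != 0:
                ari_oracle = (a - exp) / (mx - exp)
                assert adjusted_rand(ct) == pytest.approx(ari_oracle, abs=1e-10)
            # FM = sqrt(pair-precision * pair-recall)
            if (a + c) > 0 and (a + b) > 0:
                fm_oracle = a / np.sqrt((a + c) * (a + b))
                assert fowlkes_mallows(ct) == pytest.approx(fm_oracle, abs=1e-10)

    def test_f_measure_enumeration_oracle(self):
        """F from the contingency table equals the looped per-class best
        harmonic mean of precision and recall, on exhaustive 5-item pairs."""
        items = tuple("abcde")
        partitions = [
            {i: str(bi) for bi, block in enumerate(blocks) for i in block}
            for blocks in all_set_partitions(items)
        ]
        for g_labels in partitions[::3]:
            for p_labels in partitions[::3]:
                gold = GoldSolution(g_labels)
                pred = Partition(p_labels)
                classes = set(g_labels.values())
                clusters = set(p_labels.values())
                total = 0.0
                for ci in classes:
                    members = {i for i in items if g_labels[i] == ci}
                    best = 0.0
                    for pj in clusters:
                        cluster = {i for i in items if p_labels[i] == pj}
                        inter = len(members & cluster)
                        if inter == 0:
                            continue
                        prec = inter / len(cluster)
                        rec = inter / len(members)
                        best = max(best, 2 * prec * rec / (prec + rec))
                    total += len(members) / len(items) * best
                assert f_measure(contingency(gold, pred)) == pytest.approx(
                    total, abs=1e-10
                )

    def test_f_measure_monotone_under_refinement_toward_gold(self):
        # nested coarsenings moving toward the gold 2-block structure
        gold = GoldSolution(dict(zip("abcdef", "AAABBB")))
        worse = _part([1, 2, 3, 4, 5, 6], list("abcdef"))
        mid = _part([1, 1, 2, 3, 3, 4], list("abcdef"))
        exact = _part([1, 1, 1, 2, 2, 2], list("abcdef"))
        scores = [
            f_measure(contingency(gold, p)) for p in (worse, mid, exact)
        ]
        assert scores[0] <= scores[1] <= scores[2] == pytest.approx(1.0)
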