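"""Boolean signature classification, evaluation and exhaustive search."""

import itertools

import pytest

from panmarker import (GroupLabels, Signature, classify, evaluate_signature,
                       search_signatures)
from panmarker.matrix import MatrixError
from panmarker.simulate import paper_counts_fixture
from tests.conftest import random_matrix_and_labels


def brute_force_classify(row, present, absent):
    ok = all(row[c] == 1 for c in present) and all(row[c] == 0 for c in absent)
    return "target" if ok else "background"


def brute_force_evaluate(matrix, labels, sig):
    """Genome-by-genome independent confusion recount."""
    frame = matrix.to_frame()
    tp = fn = tn = fp = 0
    for g in matrix.genome_ids:
        predicted = brute_force_classify(frame.loc[g],
                                         sig.require_present,
                                         sig.require_absent)
        actual = labels.assignments[g]
        if actual == "target":
            tp += predicted == "target"
            fn += predicted == "background"
        else:
            tn += predicted == "background"
            fp += predicted == "target"
    return tp, fn, tn, fp


class TestClassify:
    def test_predator_rule_example(self):
        row = {"kynA": 1, "waaL": 1, "gntR": 0}
        sig = Signature(["kynA", "waaL"], ["gntR"])
        assert classify(row, sig) == "target"
        assert classify({"kynA": 1, "waaL": 1, "gntR": 1}, sig) == "background"
        assert classify({"kynA": 0, "waaL": 1, "gntR": 0}, sig) == "background"

    def test_empty_signature_is_vacuously_target(self):
        assert classify({"c1": 0, "c2": 1}, Signature()) == "target"

    def test_unknown_cluster_rejected(self):
        with pytest.raises(MatrixError, match="zz"):
            classify({"c1": 1}, Signature(["zz"]))

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="both present and absent"):
            Signature(["a"], ["a"])

    def test_random_rows_match_brute_force(self, rng):
        clusters = [f"c{i}" for i in range(6)]
        for _ in range(50):
            row = {c: int(rng.integers(0, 2)) for c in clusters}
            p = [c for c in clusters if rng.random() < 0.3]
            a = [c for c in clusters if c not in p and rng.random() < 0.3]
            sig = Signature(p, a)
            assert classify(row, sig) == brute_force_classify(row, p, a)


class TestEvaluateSignature:
    def test_published_confusion_counts(self):
        matrix, labels = paper_counts_fixture()
        cc = evaluate_signature(matrix, labels,
                                Signature(["kynA", "waaL"], ["gntR"]))
        assert (cc.tp, cc.fn, cc.tn, cc.fp) == (14, 0, 2255, 17)
        assert cc.sensitivity == 1.0
        assert cc.specificity == pytest.approx(2255 / 2272)
        assert len(cc.false_positive_ids) == 17

    def test_universal_absent_cluster_kills_sensitivity(self, small_matrix):
        labels = GroupLabels({"gA": "target", "gB": "target",
                              "gC": "background", "gD": "background",
                              "gE": "background"})
        # c1 is present in both target genomes; requiring it absent -> tp=0
        cc = evaluate_signature(small_matrix, labels,
                                Signature([], ["c1"]))
        assert cc.tp == 0
        assert cc.sensitivity == 0.0

    def test_random_instances_match_brute_force(self, rng):
        for _ in range(20):
            matrix, labels = random_matrix_and_labels(rng)
            clusters = matrix.cluster_ids
            p = [c for c in clusters if rng.random() < 0.2]
            a = [c for c in clusters if c not in p and rng.random() < 0.2]
            sig = Signature(p, a)
            cc = evaluate_signature(matrix, labels, sig)
            assert (cc.tp, cc.fn, cc.tn, cc.fp) == \
                brute_force_evaluate(matrix, labels, sig)

    def test_label_swap_permutes_confusion(self, rng):
        matrix, labels = random_matrix_and_labels(rng)
        sig = Signature([matrix.cluster_ids[0]])
        cc = evaluate_signature(matrix, labels, sig)
        sw = evaluate_signature(matrix, labels.swapped(), sig)
        assert (sw.tp, sw.fn, sw.tn, sw.fp) == (cc.fp, cc.tn, cc.fn, cc.tp)

    def test_adding_constraint_is_monotone(self, rng):
        for _ in range(20):
            matrix, labels = random_matrix_and_labels(rng)
            clusters = matrix.cluster_ids
            base = Signature([clusters[0]])
            extra_cluster = clusters[1]
            grown_p = Signature([clusters[0], extra_cluster])
            grown_a = Signature([clusters[0]], [extra_cluster])
            cc0 = evaluate_signature(matrix, labels, base)
            for grown in (grown_p, grown_a):
                cc1 = evaluate_signature(matrix, labels, grown)
                assert cc1.tp <= cc0.tp
                assert cc1.tn >= cc0.tn


def brute_force_search(matrix, labels, pool, max_present, max_absent):
    """Independent full enumeration with the documented ranking key."""
    results = []
    for p_size in range(max_present + 1):
        for P in itertools.combinations(sorted(pool), p_size):
            for a_size in range(max_absent + 1):
                for A in itertools.combinations(
                        [c for c in sorted(pool) if c not in P], a_size):
                    sig = Signature(P, A)
                    tp, fn, tn, fp = brute_force_evaluate(matrix, labels, sig)
                    acc = (tp + tn) / (tp + fn + tn + fp)
                    spec = tn / (tn + fp) if (tn + fp) else float("nan")
                    results.append(((-acc, -spec, sig.size, sig.sort_key()),
                                    sig))
    results.sort(key=lambda t: t[0])
    return [sig for _, sig in results]


class TestSearchSignatures:
    def test_recovers_published_three_gene_rule(self):
        matrix, labels = paper_counts_fixture()
        results = search_signatures(matrix, labels, ["kynA", "waaL", "gntR"],
                                    max_present=2, max_absent=1, top_k=3)
        sig, cc = results[0]
        assert sig == Signature(["kynA", "waaL"], ["gntR"])
        assert cc.accuracy == pytest.approx((14 + 2255) / 2286)

    def test_planted_perfect_cluster_wins_alone(self, rng):
        matrix, labels = random_matrix_and_labels(rng, n_genomes=12)
        frame = matrix.to_frame()
        frame["perfect"] = [
            1 if labels.assignments[g] == "target" else 0
            for g in matrix.genome_ids]
        from panmarker import PresenceAbsenceMatrix
        matrix = PresenceAbsenceMatrix(frame)
        results = search_signatures(matrix, labels, matrix.cluster_ids,
                                    max_present=1, max_absent=1, top_k=1)
        sig, cc = results[0]
        assert cc.accuracy == 1.0
        assert sig == Signature(["perfect"])

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(5):
            matrix, labels = random_matrix_and_labels(
                rng, n_genomes=12, n_clusters=8)
            pool = matrix.cluster_ids
            expected = brute_force_search(matrix, labels, pool, 2, 1)
            got = search_signatures(matrix, labels, pool, 2, 1,
                                    top_k=len(expected))
            assert [s for s, _ in got] == expected

    def test_invariant_under_pool_ordering(self, rng):
        matrix, labels = random_matrix_and_labels(
            rng, n_genomes=10, n_clusters=6)
        pool = matrix.cluster_ids
        a = search_signatures(matrix, labels, pool, 2, 1, top_k=5)
        b = search_signatures(matrix, labels, pool[::-1], 2, 1, top_k=5)
        assert [s for s, _ in a] == [s for s, _ in b]

    def test_pool_guard_raises_without_greedy(self, rng):
        matrix, labels = random_matrix_and_labels(
            rng, n_genomes=5, n_clusters=50)
        with pytest.raises(ValueError, match="greedy"):
            search_signatures(matrix, labels, matrix.cluster_ids)

    def test_greedy_finds_planted_perfect_cluster(self, rng):
        matrix, labels = random_matrix_and_labels(rng, n_genomes=15)
        frame = matrix.to_frame()
        frame["perfect"] = [
            1 if labels.assignments[g] == "target" else 0
            for g in matrix.genome_ids]
        from panmarker import PresenceAbsenceMatrix
        matrix = PresenceAbsenceMatrix(frame)
        (sig, cc), = search_signatures(matrix, labels, matrix.cluster_ids,
                                       greedy=True, top_k=1)
        assert cc.accuracy == 1.0

    def test_min_sensitivity_floor(self):
        matrix, labels = paper_counts_fixture()
        results = search_signatures(matrix, labels, ["kynA", "waaL", "gntR"],
                                    min_sensitivity=1.0, top_k=50)
        assert results
        assert all(cc.sensitivity == 1.0 for _, cc in results)
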