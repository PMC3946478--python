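"""Validity indices against hand examples and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vericlust import (UNASSIGNED, ConfusionMatrix, PairCounts,
                       confusion_matrix, davies_bouldin, dunn, entropy,
                       fowlkes_mallows, jaccard, max_diameter, pair_counts,
                       purity, rand, rmsstd)
from vericlust.errors import InputError

from conftest import WORKED_TABLE_ROW_MARGINS


# ---------------------------------------------------------------------------
# independent direct-formula oracles (plain loops, no shared code)
# ---------------------------------------------------------------------------

def oracle_pair_counts(predicted, truth):
    """Enumerate every object pair explicitly."""
    idx = [i for i, c in enumerate(predicted) if c != UNASSIGNED]
    a = b = c = d = 0
    for u in range(len(idx)):
        for v in range(u + 1, len(idx)):
            i, j = idx[u], idx[v]
            same_cluster = predicted[i] == predicted[j]
            same_class = truth[i] == truth[j]
            if same_cluster and same_class:
                a += 1
            elif same_cluster:
                b += 1
            elif same_class:
                c += 1
            else:
                d += 1
    return a, b, c, d


def oracle_dunn_diam(X, labels):
    """Direct all-pairs evaluation of Dunn and max diameter."""
    clusters = sorted(set(l for l in labels if l != UNASSIGNED))
    members = {c: [i for i, l in enumerate(labels) if l == c]
               for c in clusters}
    dist = lambda i, j: math.dist(X[i], X[j])
    diam = 0.0
    for c in clusters:
        for u in range(len(members[c])):
            for v in range(u + 1, len(members[c])):
                diam = max(diam, dist(members[c][u], members[c][v]))
    if len(clusters) < 2:
        return None, (diam if clusters else None)
    between = min(
        dist(i, j)
        for ci in range(len(clusters)) for cj in range(ci + 1, len(clusters))
        for i in members[clusters[ci]] for j in members[clusters[cj]]
    )
    return (math.inf if diam == 0 else between / diam), diam


def oracle_db(X, labels):
    clusters = sorted(set(labels))
    cent = {c: np.mean([X[i] for i, l in enumerate(labels) if l == c], axis=0)
            for c in clusters}
    s = {c: np.mean([math.dist(X[i], cent[c])
                     for i, l in enumerate(labels) if l == c])
         for c in clusters}
    total = 0.0
    for ci in clusters:
        total += max((s[ci] + s[cj]) / math.dist(cent[ci], cent[cj])
                     for cj in clusters if cj != ci)
    return total / len(clusters)


def oracle_rmsstd(X, labels):
    clusters = sorted(set(labels))
    ssw, dof = 0.0, 0
    for c in clusters:
        pts = np.array([X[i] for i, l in enumerate(labels) if l == c])
        ssw += ((pts - pts.mean(axis=0)) ** 2).sum()
        dof += len(pts) - 1
    dof *= X.shape[1]
    return 0.0 if dof == 0 else math.sqrt(ssw / dof)


# ---------------------------------------------------------------------------
# confusion matrix and external indices
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("predicted,truth,expected", [
    ([0, 0, 1, 1], list("AABB"), [[2, 0], [0, 2]]),
    ([0, 0, 0, 0], list("AABB"), [[2], [2]]),
    ([0, 0, 1, 1], list("ABAB"), [[1, 1], [1, 1]]),
])
def test_confusion_matrix_tabulation(predicted, truth, expected):
    cm = confusion_matrix(predicted, truth)
    assert cm.counts.tolist() == expected
    assert cm.n == sum(map(sum, expected))


def test_confusion_matrix_excludes_unassigned_and_rejects_mismatch():
    cm = confusion_matrix([0, UNASSIGNED, 1, 1], list("AABB"))
    assert cm.n == 3
    with pytest.raises(InputError):
        confusion_matrix([0, 1], list("ABC"))


def test_worked_table_margins_reproduce_print(worked_table_cm):
    # the printed row margins follow exactly from the printed cells
    assert worked_table_cm.class_totals.tolist() == WORKED_TABLE_ROW_MARGINS
    assert worked_table_cm.n == sum(WORKED_TABLE_ROW_MARGINS)
    assert worked_table_cm.cluster_totals.sum() == worked_table_cm.n


def test_purity_examples(worked_table_cm):
    # column maxima of the printed table: 1118 + 122 + 76 = 1316
    assert worked_table_cm.counts.max(axis=0).sum() == 1316
    assert purity(worked_table_cm) == pytest.approx(1316 / worked_table_cm.n)
    perfect = confusion_matrix([0, 0, 1, 1], list("AABB"))
    assert purity(perfect) == 1.0
    mixed = confusion_matrix([0] * 6, list("AAABBB"))
    assert purity(mixed) == 0.5


def test_entropy_examples(worked_table_cm):
    assert entropy(confusion_matrix([0, 0, 1, 1], list("AABB"))) == 0.0
    # one cluster, classes split 3/3, l=2: maximal confusion
    assert entropy(confusion_matrix([0] * 6, list("AAABBB"))) == pytest.approx(1.0)
    # frozen from the direct-formula oracle (weighted per-cluster class
    # entropy, natural log, normalized by log(4))
    assert entropy(worked_table_cm) == pytest.approx(0.5637598303003223)
    # single class: 0 by convention
    assert entropy(confusion_matrix([0, 1], list("AA"))) == 0.0


def test_entropy_zero_iff_pure():
    rng = np.random.default_rng(5)
    for _ in range(50):
        n = int(rng.integers(4, 15))
        pred = rng.integers(0, 3, size=n)
        truth = rng.integers(0, 3, size=n)
        cm = confusion_matrix(pred, truth)
        assert (entropy(cm) == 0.0) == (purity(cm) == 1.0) or cm.n_classes == 1


@pytest.mark.parametrize("predicted,truth,abcd", [
    ([0, 0, 1, 1], list("AABB"), (2, 0, 0, 4)),
    ([0, 0, 1, 1], list("ABAB"), (0, 2, 2, 2)),
])
def test_pair_count_hand_examples(predicted, truth, abcd):
    pc = pair_counts(predicted, truth)
    assert (pc.a, pc.b, pc.c, pc.d) == abcd
    assert pc.a + pc.b + pc.c + pc.d == 6


@settings(deadline=None, max_examples=60)
@given(st.lists(st.tuples(st.integers(-1, 3), st.integers(0, 2)),
                min_size=2, max_size=12))
def test_pair_counts_match_enumeration_and_conserve(pairs):
    predicted = [p for p, _ in pairs]
    truth = [t for _, t in pairs]
    n_assigned = sum(p != UNASSIGNED for p in predicted)
    if n_assigned < 2:
        with pytest.raises(InputError):
            pair_counts(predicted, truth)
        return
    pc = pair_counts(predicted, truth)
    assert (pc.a, pc.b, pc.c, pc.d) == oracle_pair_counts(predicted, truth)
    assert pc.a + pc.b + pc.c + pc.d == n_assigned * (n_assigned - 1) // 2


def test_pair_similarity_indices():
    identical = PairCounts(a=2, b=0, c=0, d=4, n=4)
    assert rand(identical) == jaccard(identical) == fowlkes_mallows(identical) == 1.0
    crossed = PairCounts(a=0, b=2, c=2, d=2, n=4)
    assert rand(crossed) == pytest.approx(1 / 3)
    assert jaccard(crossed) == 0.0
    assert fowlkes_mallows(crossed) == 0.0
    # genuinely degenerate denominators warn
    lonely = PairCounts(a=0, b=0, c=0, d=1, n=2)
    with pytest.warns(UserWarning):
        assert jaccard(lonely) == 0.0
    with pytest.warns(UserWarning):
        assert fowlkes_mallows(lonely) == 0.0


def test_pair_indices_against_sklearn():
    from sklearn.metrics import fowlkes_mallows_score, rand_score
    rng = np.random.default_rng(11)
    for _ in range(25):
        n = int(rng.integers(4, 20))
        pred = rng.integers(0, 4, size=n)
        truth = rng.integers(0, 3, size=n)
        pc = pair_counts(pred, truth)
        assert rand(pc) == pytest.approx(rand_score(truth, pred))
        assert fowlkes_mallows(pc) == pytest.approx(
            fowlkes_mallows_score(truth, pred))


# ---------------------------------------------------------------------------
# relative indices
# ---------------------------------------------------------------------------

def test_dunn_and_diameter_hand_geometry(two_far_pairs):
    labels = [0, 0, 1, 1]
    assert dunn(two_far_pairs, labels) == pytest.approx(10.0)
    assert max_diameter(two_far_pairs, labels) == pytest.approx(1.0)
    # ratio invariance under global rescaling
    assert dunn(two_far_pairs * 3, labels) == pytest.approx(10.0)


def test_dunn_degenerate_markers(two_far_pairs):
    assert dunn(two_far_pairs, [0, 0, 0, 0]) is None          # < 2 clusters
    assert dunn(two_far_pairs, [0, 1, 2, 3]) == math.inf      # all singletons
    assert max_diameter(two_far_pairs, [0, 1, 2, 3]) == 0.0
    assert max_diameter(two_far_pairs, [UNASSIGNED] * 4) is None
    assert dunn(two_far_pairs, [0, 0, UNASSIGNED, UNASSIGNED]) is None


def test_relative_indices_match_bruteforce_oracles():
    rng = np.random.default_rng(23)
    for _ in range(40):
        n = int(rng.integers(4, 13))
        X = rng.normal(size=(n, 2))
        labels = rng.integers(0, 3, size=n)
        labels[:3] = [0, 1, 2]  # ensure 3 non-empty clusters
        odunn, odiam = oracle_dunn_diam(X, labels.tolist())
        assert dunn(X, labels) == pytest.approx(odunn)
        assert max_diameter(X, labels) == pytest.approx(odiam)
        assert davies_bouldin(X, labels) == pytest.approx(oracle_db(X, labels))
        assert rmsstd(X, labels) == pytest.approx(oracle_rmsstd(X, labels))


def test_davies_bouldin_against_sklearn(two_far_pairs):
    from sklearn.metrics import davies_bouldin_score
    rng = np.random.default_rng(3)
    X = rng.normal(size=(12, 3))
    labels = np.array([0, 1, 2] * 4)
    assert davies_bouldin(X, labels) == pytest.approx(
        davies_bouldin_score(X, labels))
    # two well-separated tight clusters: near zero
    assert davies_bouldin(two_far_pairs, [0, 0, 1, 1]) < 0.2


def test_davies_bouldin_coincident_centroids():
    X = np.array([[0.0, 1.0], [0.0, -1.0], [1.0, 0.0], [-1.0, 0.0]])
    with pytest.raises(InputError, match="coincident"):
        davies_bouldin(X, [0, 0, 1, 1])


def test_rmsstd_degenerate_cases():
    X = np.zeros((3, 2))
    assert rmsstd(X, [0, 0, 0]) == 0.0          # identical points
    assert rmsstd(np.eye(3), [0, 1, 2]) == 0.0  # all singletons


def test_merging_clusters_never_decreases_diameter():
    rng = np.random.default_rng(7)
    for _ in range(25):
        X = rng.normal(size=(10, 2))
        labels = rng.integers(0, 3, size=10)
        merged = np.where(labels == 2, 1, labels)
        d0 = max_diameter(X, labels)
        d1 = max_diameter(X, merged)
        assert d1 >= d0 - 1e-12


def test_refinement_improves_purity_and_entropy():
    # splitting a mixed cluster into pure sub-clusters
    truth = list("AAABBB")
    coarse = confusion_matrix([0] * 6, truth)
    fine = confusion_matrix([0, 0, 0, 1, 1, 1], truth)
    assert purity(fine) >= purity(coarse)
    assert entropy(fine) <= entropy(coarse)


def test_bounded_indices_stay_in_unit_interval():
    rng = np.random.default_rng(17)
    for _ in range(1000):
        n = int(rng.integers(2, 10))
        pred = rng.integers(0, 4, size=n)
        truth = rng.integers(0, 3, size=n)
        cm = confusion_matrix(pred, truth)
        pc = pair_counts(pred, truth)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            values = [purity(cm), entropy(cm), rand(pc), jaccard(pc),
                      fowlkes_mallows(pc)]
        assert all(0.0 <= v <= 1.0 + 1e-12 for v in values)
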