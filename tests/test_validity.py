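"""Validity indices vs brute-force formula oracles; ensemble vote semantics."""

from itertools import combinations

import numpy as np
import pytest
from scipy.spatial.distance import pdist
from sklearn.metrics import silhouette_samples

from pdsubtypes.cluster import average_linkage
from pdsubtypes.refdata import TEN_CLUSTER_SIZES, THREE_CLUSTER_SIZES
from pdsubtypes.validity import (INDEX_REGISTRY, ensemble_vote,
                                 filter_small_clusters, validity_index)

# ---------------------------------------------------------------------------
# independent naive oracles (direct formula transcription, O(n^2) loops)
# ---------------------------------------------------------------------------


def _groups(X, labels):
    return {u: X[labels == u] for u in np.unique(labels)}


def oracle_calinski(X, labels):
    g = _groups(X, labels)
    n, k = len(X), len(g)
    overall = X.mean(axis=0)
    b = sum(len(v) * ((v.mean(axis=0) - overall) ** 2).sum() for v in g.values())
    w = sum(((v - v.mean(axis=0)) ** 2).sum() for v in g.values())
    return (b / (k - 1)) / (w / (n - k))


def oracle_silhouette(X, labels):
    vals = []
    for i in range(len(X)):
        same = [j for j in range(len(X)) if labels[j] == labels[i] and j != i]
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in same]) if same else 0.0
        b = min(np.mean([np.linalg.norm(X[i] - X[j])
                         for j in range(len(X)) if labels[j] == u])
                for u in np.unique(labels) if u != labels[i])
        vals.append(0.0 if not same else (b - a) / max(a, b))
    return float(np.mean(vals))


def oracle_dunn(X, labels):
    inter, diam = np.inf, 0.0
    for i, j in combinations(range(len(X)), 2):
        d = np.linalg.norm(X[i] - X[j])
        if labels[i] == labels[j]:
            diam = max(diam, d)
        else:
            inter = min(inter, d)
    return inter / diam


def oracle_c_index(X, labels):
    dists, within = [], []
    for i, j in combinations(range(len(X)), 2):
        d = np.linalg.norm(X[i] - X[j])
        dists.append(d)
        within.append(labels[i] == labels[j])
    dists, within = np.array(dists), np.array(within)
    nw = within.sum()
    sw = dists[within].sum()
    srt = np.sort(dists)
    return (sw - srt[:nw].sum()) / (srt[-nw:].sum() - srt[:nw].sum())


def oracle_mcclain(X, labels):
    dw = [np.linalg.norm(X[i] - X[j]) for i, j in combinations(range(len(X)), 2)
          if labels[i] == labels[j]]
    db = [np.linalg.norm(X[i] - X[j]) for i, j in combinations(range(len(X)), 2)
          if labels[i] != labels[j]]
    return np.mean(dw) / np.mean(db)


def oracle_point_biserial(X, labels):
    D, w = [], []
    for i, j in combinations(range(len(X)), 2):
        D.append(np.linalg.norm(X[i] - X[j]))
        w.append(labels[i] == labels[j])
    D, w = np.array(D), np.array(w)
    nw, nb, nt = w.sum(), (~w).sum(), len(D)
    return (D[~w].mean() - D[w].mean()) * np.sqrt(nw * nb / nt**2) / D.std()


def oracle_gamma(X, labels):
    dw = [np.linalg.norm(X[i] - X[j]) for i, j in combinations(range(len(X)), 2)
          if labels[i] == labels[j]]
    db = [np.linalg.norm(X[i] - X[j]) for i, j in combinations(range(len(X)), 2)
          if labels[i] != labels[j]]
    splus = sum(a < b for a in dw for b in db)
    sminus = sum(a > b for a in dw for b in db)
    return (splus - sminus) / (splus + sminus)


def oracle_xie_beni(X, labels):
    g = _groups(X, labels)
    wss = sum(((v - v.mean(axis=0)) ** 2).sum() for v in g.values())
    cents = [v.mean(axis=0) for v in g.values()]
    sep = min(np.linalg.norm(a - b) ** 2
              for a, b in combinations(cents, 2))
    return wss / (len(X) * sep)


def oracle_ball_hall(X, labels):
    g = _groups(X, labels)
    return np.mean([((v - v.mean(axis=0)) ** 2).sum() / len(v)
                    for v in g.values()])


def oracle_trace_w(X, labels):
    return sum(((v - v.mean(axis=0)) ** 2).sum()
               for v in _groups(X, labels).values())


def oracle_ratkowsky(X, labels):
    overall = X.mean(axis=0)
    tss = ((X - overall) ** 2).sum(axis=0)
    bgss = np.zeros(X.shape[1])
    for u in np.unique(labels):
        sel = labels == u
        bgss += sel.sum() * (X[sel].mean(axis=0) - overall) ** 2
    return np.mean(np.sqrt(bgss / tss)) / np.sqrt(len(np.unique(labels)))


ORACLES = {
    "calinski_harabasz": oracle_calinski,
    "silhouette": oracle_silhouette,
    "dunn": oracle_dunn,
    "c_index": oracle_c_index,
    "mcclain_rao": oracle_mcclain,
    "point_biserial": oracle_point_biserial,
    "gamma": oracle_gamma,
    "xie_beni": oracle_xie_beni,
    "ball_hall": oracle_ball_hall,
    "trace_w": oracle_trace_w,
    "ratkowsky_lance": oracle_ratkowsky,
}


# ---------------------------------------------------------------------------
# hand-computed examples
# ---------------------------------------------------------------------------

def test_calinski_harabasz_hand_example():
    X = np.array([[0.0], [1.0], [10.0], [11.0]])
    labels = np.array([0, 0, 1, 1])
    score, rule = validity_index("calinski_harabasz", X, labels)
    assert score == pytest.approx(200.0)
    assert rule == "max"


def test_dunn_hand_example():
    X = np.array([[0.0], [0.1], [10.0], [10.1]])
    score, _ = validity_index("dunn", X, np.array([0, 0, 1, 1]))
    assert score == pytest.approx(99.0)


def test_silhouette_of_single_point():
    X = np.array([[0.0], [1.0], [10.0], [11.0]])
    s = silhouette_samples(X, np.array([0, 0, 1, 1]))
    assert s[0] == pytest.approx((10.5 - 1) / 10.5)
    assert s[0] == pytest.approx(0.904762, abs=1e-6)


def test_unknown_index_rejected():
    with pytest.raises(KeyError, match="unknown"):
        validity_index("nope", np.zeros((4, 1)), np.array([0, 0, 1, 1]))


def test_single_cluster_rejected():
    with pytest.raises(ValueError):
        validity_index("dunn", np.zeros((4, 1)), np.zeros(4, int))


@pytest.mark.parametrize("name", sorted(ORACLES))
def test_index_matches_bruteforce_oracle(name, rng):
    """Every registry index equals its direct-formula oracle on random data."""
    for _ in range(5):
        n = int(rng.integers(10, 31))
        k = int(rng.integers(2, 5))
        X = rng.normal(size=(n, 3)) + 3 * rng.integers(0, k, n)[:, None]
        labels = rng.integers(0, k, n)
        while len(np.unique(labels)) < 2:
            labels = rng.integers(0, k, n)
        score, _ = validity_index(name, X, labels)
        assert score == pytest.approx(ORACLES[name](X, labels), rel=1e-9)


# ---------------------------------------------------------------------------
# ensemble vote
# ---------------------------------------------------------------------------

def _blobs(seed, k=3, n=40, gap=8.0):
    r = np.random.default_rng(seed)
    X = np.vstack([r.normal(gap * i, 1.0, (n, 3)) for i in range(k)])
    return X


def test_vote_recovers_three_blobs():
    hits = 0
    for seed in range(10):
        X = _blobs(seed)
        vote = ensemble_vote(X, average_linkage(X))
        hits += vote.winner == 3
    assert hits >= 9


def test_vote_invariant_to_index_ordering():
    X = _blobs(0)
    tree = average_linkage(X)
    a = ensemble_vote(X, tree, index_set=tuple(sorted(INDEX_REGISTRY)))
    b = ensemble_vote(X, tree, index_set=tuple(sorted(INDEX_REGISTRY, reverse=True)))
    assert a.winner == b.winner and a.tally == b.tally


def test_tie_breaks_toward_smaller_k(monkeypatch):
    X = _blobs(1)
    tree = average_linkage(X)
    # craft a registry where half the indices prefer k=2 and half k=10
    monkeypatch.setitem(INDEX_REGISTRY, "fake_low",
                        (lambda X, lab, D=None: -abs(len(np.unique(lab)) - 2), "max"))
    monkeypatch.setitem(INDEX_REGISTRY, "fake_high",
                        (lambda X, lab, D=None: -abs(len(np.unique(lab)) - 10), "max"))
    vote = ensemble_vote(X, tree, index_set=("fake_low", "fake_high"))
    assert vote.tally == {2: 1, 10: 1}
    assert vote.winner == 2
    assert vote.runner_up == 10


def test_nan_scores_cause_abstention(monkeypatch):
    X = _blobs(2)
    tree = average_linkage(X)
    monkeypatch.setitem(INDEX_REGISTRY, "fake_nan",
                        (lambda X, lab, D=None: np.nan, "max"))
    monkeypatch.setitem(INDEX_REGISTRY, "fake_three",
                        (lambda X, lab, D=None: -abs(len(np.unique(lab)) - 3), "max"))
    vote = ensemble_vote(X, tree, index_set=("fake_nan", "fake_three"))
    assert vote.votes["fake_nan"] is None
    assert sum(vote.tally.values()) == 1
    with pytest.raises(RuntimeError, match="abstained"):
        ensemble_vote(X, tree, index_set=("fake_nan",))


def test_empty_index_set_rejected():
    X = _blobs(3)
    with pytest.raises(ValueError):
        ensemble_vote(X, average_linkage(X), index_set=())


# ---------------------------------------------------------------------------
# minimum-size filter
# ---------------------------------------------------------------------------

def _labels_from_sizes(sizes):
    return np.concatenate([np.full(s, i) for i, s in enumerate(sizes)])


class TestFilterSmallClusters:
    def test_published_ten_cluster_sizes_retain_eight(self):
        sol = filter_small_clusters(_labels_from_sizes(TEN_CLUSTER_SIZES))
        assert sol.retained == 8
        assert sol.excluded_sizes == [8, 1]
        assert sorted(sol.cluster_sizes.values(), reverse=True) == \
            sorted([s for s in TEN_CLUSTER_SIZES if s >= 10], reverse=True)
        # renumbered by size: cl1 is the largest
        assert sol.cluster_sizes[1] == 189

    def test_three_cluster_sizes_all_retained(self):
        sol = filter_small_clusters(_labels_from_sizes(THREE_CLUSTER_SIZES))
        assert sol.retained == 3
        assert sol.excluded_sizes == []
        assert sol.cluster_sizes[1] == 302

    def test_all_small_is_error(self):
        with pytest.raises(ValueError, match="minimum size"):
            filter_small_clusters(_labels_from_sizes([9, 9]))

    def test_excluded_members_flagged_not_reassigned(self):
        sol = filter_small_clusters(_labels_from_sizes([20, 3]))
        assert (sol.labels == 0).sum() == 3
        assert sol.retained == 1
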