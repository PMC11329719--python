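"""Cluster-validity indices, ensemble voting and the minimum-size filter.

The number of clusters is chosen by majority vote: every index in the
registry scores each candidate partition over a k range and casts one vote
for the k it deems optimal under its own rule (maximize, minimize, or an
elbow/difference criterion for monotone indices); the winning k is the
modal vote, ties breaking toward the smaller k.  The runner-up (second
mode) is retained because a dominant-but-coarse solution can hide finer
structure worth characterizing.

Clusters smaller than ``min_size`` (default 10) are excluded from
characterization rather than reassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import (calinski_harabasz_score, davies_bouldin_score,
                             silhouette_score)

from .cluster import LinkageTree, cut_tree, relabel_by_size

# ---------------------------------------------------------------------------
# index implementations (points: (n, d); labels: integer array)
# ---------------------------------------------------------------------------


def _centroids(X, labels):
    uniq = np.unique(labels)
    return uniq, np.vstack([X[labels == u].mean(axis=0) for u in uniq])


def _within_ss(X, labels) -> float:
    uniq, cents = _centroids(X, labels)
    return float(sum(((X[labels == u] - c) ** 2).sum()
                     for u, c in zip(uniq, cents)))


def _pair_masks(labels):
    """Condensed-form boolean mask of within-cluster pairs."""
    lab = np.asarray(labels)
    same = lab[:, None] == lab[None, :]
    return squareform(same, checks=False).astype(bool)


def dunn_index(X, labels, D=None) -> float:
    """min between-cluster distance / max within-cluster diameter (max is best)."""
    D = pdist(X) if D is None else D
    within = _pair_masks(labels)
    if not within.any() or within.all():
        return np.nan
    diameter = D[within].max()
    separation = D[~within].min()
    if diameter == 0:
        return np.inf
    return float(separation / diameter)


def c_index(X, labels, D=None) -> float:
    """(Sw - Smin) / (Smax - Smin) over within-cluster pairs (min is best)."""
    D = pdist(X) if D is None else D
    within = _pair_masks(labels)
    nw = int(within.sum())
    if nw == 0 or nw == len(D):
        return np.nan
    sw = D[within].sum()
    srt = np.sort(D)
    smin, smax = srt[:nw].sum(), srt[-nw:].sum()
    if smax == smin:
        return np.nan
    return float((sw - smin) / (smax - smin))


def mcclain_rao(X, labels, D=None) -> float:
    """mean within-pair distance / mean between-pair distance (min is best)."""
    D = pdist(X) if D is None else D
    within = _pair_masks(labels)
    if not within.any() or within.all():
        return np.nan
    mb = D[~within].mean()
    if mb == 0:
        return np.nan
    return float(D[within].mean() / mb)


def point_biserial(X, labels, D=None) -> float:
    """Point-biserial correlation of distances with the between-pair indicator.

    (mean between - mean within) * sqrt(Nw * Nb) / (Nt * sd of distances);
    max is best.
    """
    D = pdist(X) if D is None else D
    within = _pair_masks(labels)
    nw, nb, nt = int(within.sum()), int((~within).sum()), len(D)
    if nw == 0 or nb == 0:
        return np.nan
    sd = D.std()
    if sd == 0:
        return np.nan
    return float((D[~within].mean() - D[within].mean())
                 * np.sqrt(nw * nb / nt**2) / sd)


def gamma_index(X, labels, D=None) -> float:
    """Baker-Hubert Gamma: (s+ - s-) / (s+ + s-) (max is best).

    s+ counts (within, between) distance pairs where the within distance is
    smaller; computed by sorting the between distances and binary search.
    """
    D = pdist(X) if D is None else D
    within = _pair_masks(labels)
    dw, db = D[within], np.sort(D[~within])
    if len(dw) == 0 or len(db) == 0:
        return np.nan
    # concordant: within distance smaller than the between distance
    s_plus = float((len(db) - np.searchsorted(db, dw, side="right")).sum())
    s_minus = float(np.searchsorted(db, dw, side="left").sum())
    if s_plus + s_minus == 0:
        return np.nan
    return (s_plus - s_minus) / (s_plus + s_minus)


def xie_beni(X, labels, D=None) -> float:
    """Within-cluster SS / (n * min squared inter-centroid gap) (min is best)."""
    uniq, cents = _centroids(X, labels)
    if len(uniq) < 2:
        return np.nan
    wss = _within_ss(X, labels)
    sep = pdist(cents) ** 2
    if sep.min() == 0:
        return np.nan
    return float(wss / (len(X) * sep.min()))


def ball_hall(X, labels, D=None) -> float:
    """Mean per-cluster mean dispersion, W/k-style (elbow on decrease)."""
    uniq, cents = _centroids(X, labels)
    disp = [(np.linalg.norm(X[labels == u] - c, axis=1) ** 2).mean()
            for u, c in zip(uniq, cents)]
    return float(np.mean(disp))


def trace_w(X, labels, D=None) -> float:
    """Total within-cluster sum of squares (elbow on decrease)."""
    return _within_ss(X, labels)


def ratkowsky_lance(X, labels, D=None) -> float:
    """mean_f sqrt(BGSS_f / TSS_f) / sqrt(k) (max is best)."""
    X = np.asarray(X, float)
    uniq = np.unique(labels)
    overall = X.mean(axis=0)
    tss = ((X - overall) ** 2).sum(axis=0)
    bgss = np.zeros(X.shape[1])
    for u in uniq:
        sel = labels == u
        bgss += sel.sum() * (X[sel].mean(axis=0) - overall) ** 2
    ok = tss > 0
    if not ok.any():
        return np.nan
    cbar = np.mean(np.sqrt(bgss[ok] / tss[ok]))
    return float(cbar / np.sqrt(len(uniq)))


def _safe(fn, X, labels, D):
    try:
        with np.errstate(all="ignore"):
            return fn(X, labels, D)
    except Exception:
        return np.nan


def _sk_calinski(X, labels, D=None):
    return calinski_harabasz_score(X, labels)


def _sk_silhouette(X, labels, D=None):
    return silhouette_score(X, labels)


def _sk_davies_bouldin(X, labels, D=None):
    return davies_bouldin_score(X, labels)


#: name -> (scorer, rule); rules: "max", "min", "elbow" (largest successive
#: decrease of a monotone index), "hartigan" (smallest k with H(k) <= 10,
#: H built from the trace_w sequence)
INDEX_REGISTRY = {
    "calinski_harabasz": (_sk_calinski, "max"),
    "silhouette": (_sk_silhouette, "max"),
    "davies_bouldin": (_sk_davies_bouldin, "min"),
    "dunn": (dunn_index, "max"),
    "c_index": (c_index, "min"),
    "mcclain_rao": (mcclain_rao, "min"),
    "point_biserial": (point_biserial, "max"),
    "gamma": (gamma_index, "max"),
    "xie_beni": (xie_beni, "min"),
    "ball_hall": (ball_hall, "elbow"),
    "trace_w": (trace_w, "elbow"),
    "hartigan": (trace_w, "hartigan"),
    "ratkowsky_lance": (ratkowsky_lance, "max"),
}

DEFAULT_INDICES = tuple(INDEX_REGISTRY)


def validity_index(name: str, points: np.ndarray, labels: np.ndarray,
                   D: np.ndarray | None = None) -> tuple[float, str]:
    """Score one partition under one index; returns (score, rule tag).

    NaN signals abstention (degenerate partition for that index).
    """
    if name not in INDEX_REGISTRY:
        raise KeyError(f"unknown validity index {name!r}; "
                       f"known: {sorted(INDEX_REGISTRY)}")
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 non-empty clusters")
    fn, rule = INDEX_REGISTRY[name]
    return _safe(fn, np.asarray(points, float), labels, D), rule


# ---------------------------------------------------------------------------
# ensemble vote
# ---------------------------------------------------------------------------

@dataclass
class VoteRecord:
    """Per-index optimal k and the resulting majority decision."""

    votes: dict                  # index name -> optimal k (None = abstained)
    k_range: list
    winner: int
    runner_up: int | None
    tally: dict                  # k -> number of votes
    scores: dict = field(default_factory=dict)  # index name -> {k: score}

    def to_dict(self) -> dict:
        return {"votes": self.votes, "k_range": list(self.k_range),
                "winner": self.winner, "runner_up": self.runner_up,
                "tally": {int(k): int(v) for k, v in self.tally.items()}}


def _vote_for(rule: str, ks: np.ndarray, vals: np.ndarray, n: int) -> int | None:
    ok = np.isfinite(vals)
    if rule in ("max", "min"):
        if not ok.any():
            return None
        idx = np.nanargmax(vals) if rule == "max" else np.nanargmin(vals)
        return int(ks[idx])
    if rule == "elbow":
        # largest successive decrease; needs at least two finite neighbours
        if ok.sum() < 2:
            return None
        drops = vals[:-1] - vals[1:]
        both = ok[:-1] & ok[1:]
        if not both.any():
            return None
        drops = np.where(both, drops, -np.inf)
        return int(ks[int(np.argmax(drops)) + 1])
    if rule == "hartigan":
        # vals are W_k; H(k) = (W_k / W_{k+1} - 1)(n - k - 1)
        if ok.sum() < 2:
            return None
        for i in range(len(ks) - 1):
            if ok[i] and ok[i + 1] and vals[i + 1] > 0:
                H = (vals[i] / vals[i + 1] - 1.0) * (n - ks[i] - 1)
                if H <= 10.0:
                    return int(ks[i])
        return None
    raise ValueError(f"unknown vote rule {rule!r}")


def ensemble_vote(points: np.ndarray, tree: LinkageTree,
                  k_range=range(2, 16),
                  index_set=DEFAULT_INDICES) -> VoteRecord:
    """Majority vote of validity indices over dendrogram cuts.

    Cuts the tree at every k in ``k_range``, scores each partition under
    every index, lets each index vote for its optimal k, and returns the
    modal k (ties toward smaller k) with the second mode as runner-up.
    """
    if not index_set:
        raise ValueError("index set is empty")
    X = np.asarray(points, float)
    n = X.shape[0]
    ks = np.array([k for k in k_range if 2 <= k <= n - 1])
    if len(ks) == 0:
        raise ValueError("k range contains no feasible k")
    D = pdist(X)
    cuts = {int(k): cut_tree(tree, int(k)) for k in ks}

    votes, scores = {}, {}
    for name in index_set:
        fn, rule = INDEX_REGISTRY[name]
        vals = np.array([_safe(fn, X, cuts[int(k)], D) for k in ks])
        scores[name] = {int(k): float(v) for k, v in zip(ks, vals)}
        votes[name] = _vote_for(rule, ks, vals, n)

    cast = [v for v in votes.values() if v is not None]
    if not cast:
        raise RuntimeError("every index abstained; no vote possible")
    tally: dict[int, int] = {}
    for v in cast:
        tally[v] = tally.get(v, 0) + 1
    ranked = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    winner = ranked[0][0]
    runner_up = ranked[1][0] if len(ranked) > 1 else None
    return VoteRecord(votes=votes, k_range=[int(k) for k in ks], winner=winner,
                      runner_up=runner_up, tally=tally, scores=scores)


# ---------------------------------------------------------------------------
# cluster solution & small-cluster filter
# ---------------------------------------------------------------------------

@dataclass
class ClusterSolution:
    """Subject labels for one cut, with small-cluster exclusions.

    ``labels`` uses 1..m for retained clusters numbered by descending size
    and 0 for members of excluded (sub-threshold) clusters.
    """

    labels: np.ndarray
    k: int
    excluded_sizes: list[int] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def retained(self) -> int:
        return int(len([u for u in np.unique(self.labels) if u != 0]))

    @property
    def cluster_sizes(self) -> dict:
        uniq, counts = np.unique(self.labels[self.labels != 0], return_counts=True)
        return {int(u): int(c) for u, c in zip(uniq, counts)}

    @property
    def included_mask(self) -> np.ndarray:
        return self.labels != 0


def filter_small_clusters(labels: np.ndarray, min_size: int = 10,
                          provenance: dict | None = None) -> ClusterSolution:
    """Exclude clusters with fewer than ``min_size`` members.

    Members of excluded clusters are flagged (label 0), never reassigned;
    retained clusters are renumbered 1..m by descending size.
    """
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    keep = uniq[counts >= min_size]
    if len(keep) == 0:
        raise ValueError(f"all clusters are below the minimum size {min_size}")
    excluded = sorted((int(c) for u, c in zip(uniq, counts) if u not in set(keep)),
                      reverse=True)
    out = np.zeros(len(labels), dtype=int)
    mask = np.isin(labels, keep)
    out[mask] = relabel_by_size(labels[mask])
    return ClusterSolution(labels=out, k=len(uniq), excluded_sizes=excluded,
                           provenance=provenance or {})
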