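"""Unsupervised random-forest proximity clustering.

The engine follows the unsupervised random-forest construction: a synthetic
contrast class is built by resampling each feature independently from its
own marginal (destroying the joint dependence structure), a forest is
trained to tell real from synthetic rows, and the fraction of trees in
which two real subjects share a terminal node defines their proximity.
Proximities are mapped to dissimilarities ``sqrt(1 - p)``, embedded with
classical (Torgerson) multidimensional scaling, and the low-dimensional
coordinates are clustered with average-linkage (UPGMA) agglomeration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import cut_tree as _scipy_cut_tree
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.ensemble import RandomForestClassifier


@dataclass
class ProximityMatrix:
    """Co-leaf similarity between observed subjects."""

    values: np.ndarray      # (n, n), symmetric, diag 1, entries in [0, 1]
    n_trees: int
    seed: int

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("proximity matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("proximity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("proximity diagonal must be 1")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("proximities must lie in [0, 1]")


@dataclass
class Embedding:
    """Classical-MDS coordinates with the eigenvalues behind them."""

    coordinates: np.ndarray   # (n, d)
    eigenvalues: np.ndarray   # all n, descending
    d: int


@dataclass
class LinkageTree:
    """Agglomeration history in the standard (n-1) x 4 merge-table form."""

    merges: np.ndarray
    method: str = "average"

    @property
    def n_leaves(self) -> int:
        return self.merges.shape[0] + 1

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


# ---------------------------------------------------------------------------
# unsupervised random forest
# ---------------------------------------------------------------------------

def synthetic_contrast(X: np.ndarray, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Build the two-class real-vs-synthetic training set.

    The synthetic class resamples each feature column independently with
    replacement from its own marginal, so it matches every univariate
    distribution but has no dependence between features.
    """
    X = np.asarray(X, float)
    n, p = X.shape
    if n < 10:
        raise ValueError("need at least 10 rows")
    if all(len(np.unique(X[:, j])) < 2 for j in range(p)):
        raise ValueError("all features are constant; no contrast to learn")
    rng = np.random.default_rng(seed)
    synth = np.column_stack([rng.choice(X[:, j], size=n, replace=True)
                             for j in range(p)])
    data = np.vstack([X, synth])
    labels = np.r_[np.zeros(n, int), np.ones(n, int)]
    return data, labels


def rf_proximity(X: np.ndarray, n_trees: int = 2000, seed: int = 0,
                 min_samples_leaf: int | str = "auto") -> ProximityMatrix:
    """Random-forest co-leaf proximity among the rows of ``X``.

    Trains a forest to separate the observed rows from their
    product-of-marginals synthetic counterpart and returns, for every pair
    of observed rows, the fraction of trees in which they land in the same
    terminal node.

    ``min_samples_leaf`` sets the terminal-node granularity.  With singleton
    leaves the proximity of all but immediate neighbours saturates at zero
    and the downstream MDS embedding loses its metric structure; the
    "auto" default (n/12, at least 5) keeps co-leaf rates informative
    across cluster-scale distances.
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    if min_samples_leaf == "auto":
        min_samples_leaf = max(5, n // 12)
    data, labels = synthetic_contrast(X, seed)
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=int(seed) % (2**31),
        min_samples_leaf=min_samples_leaf, n_jobs=1,
    ).fit(data, labels)
    leaves = forest.apply(X)                      # (n, n_trees)
    if np.all(leaves.max(axis=0) == leaves.min(axis=0)):
        raise RuntimeError(
            "degenerate forest: every tree is a single leaf; "
            "increase n_trees or tree depth")
    prox = np.zeros((n, n))
    for t in range(leaves.shape[1]):
        col = leaves[:, t]
        prox += (col[:, None] == col[None, :])
    prox /= leaves.shape[1]
    np.fill_diagonal(prox, 1.0)
    return ProximityMatrix((prox + prox.T) / 2.0, n_trees=n_trees, seed=seed)


def proximity_to_dissimilarity(P: ProximityMatrix,
                               transform: str = "sqrt") -> np.ndarray:
    """Map proximities to dissimilarities: ``sqrt(1-p)`` (default) or ``1-p``."""
    comp = np.clip(1.0 - P.values, 0.0, None)
    D = np.sqrt(comp) if transform == "sqrt" else comp
    np.fill_diagonal(D, 0.0)
    return D


# ---------------------------------------------------------------------------
# classical multidimensional scaling
# ---------------------------------------------------------------------------

def classical_mds(D: np.ndarray, d: int = 3) -> Embedding:
    """Torgerson scaling of a symmetric zero-diagonal dissimilarity matrix.

    Double-centers ``-D**2 / 2``, eigendecomposes, and returns the top-``d``
    eigenvectors scaled by the square roots of their (non-negative-clipped)
    eigenvalues.  Exact for Euclidean distance matrices.  If fewer than
    ``d`` eigenvalues are positive the remaining coordinates are zero.
    """
    D = np.asarray(D, float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("D must be symmetric with zero diagonal")
    if not 1 <= d <= n - 1:
        raise ValueError(f"target dimension must lie in [1, {n - 1}]")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    w, V = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    pos = np.clip(w[:d], 0.0, None)
    coords = V[:, :d] * np.sqrt(pos)
    return Embedding(coordinates=coords, eigenvalues=w, d=d)


def scree_select(eigenvalues: np.ndarray, max_d: int = 10,
                 override: int | None = None) -> int:
    """Pick the embedding dimension at the scree elbow.

    The elbow is the largest drop in successive eigenvalue ratios
    (``argmin λ_{i+1}/λ_i`` over the positive part of the spectrum), capped
    at ``max_d``.  ``override`` forces a dimension regardless of the
    spectrum (the production default fixes d = 3).
    """
    if override is not None:
        return int(override)
    w = np.asarray(eigenvalues, float)
    if np.any(np.diff(w) > 1e-12):
        raise ValueError("eigenvalues must be sorted descending")
    pos = w[w > 0]
    if len(pos) < 2:
        raise ValueError("need at least 2 positive eigenvalues")
    ratios = pos[1:] / pos[:-1]
    d = int(np.argmin(ratios)) + 1
    return min(d, max_d)


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

def average_linkage(data: np.ndarray, *, is_distance: bool = False) -> LinkageTree:
    """Average-linkage (UPGMA) agglomeration.

    ``data`` is either a point configuration (Euclidean distances computed
    first) or, with ``is_distance=True``, a square dissimilarity matrix.
    """
    X = np.asarray(data, float)
    if is_distance:
        if X.ndim != 2 or X.shape[0] != X.shape[1]:
            raise ValueError("distance input must be a square matrix")
        cond = squareform(X, checks=False)
    else:
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] < 2:
            raise ValueError("need at least 2 observations")
        cond = pdist(X)
    if np.isnan(cond).any():
        raise ValueError("NaN distances")
    Z = _scipy_linkage(cond, method="average")
    return LinkageTree(merges=Z, method="average")


def cut_tree(tree: LinkageTree, k: int) -> np.ndarray:
    """Cut the dendrogram into ``k`` clusters, numbered by descending size.

    Returns integer labels 1..k where cluster 1 is the largest.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    raw = _scipy_cut_tree(tree.merges, n_clusters=k).ravel()
    return relabel_by_size(raw)


def relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Renumber arbitrary labels to 1..k by descending cluster size.

    Ties in size break by first appearance, keeping the result deterministic.
    """
    labels = np.asarray(labels)
    uniq, first, counts = np.unique(labels, return_index=True, return_counts=True)
    order = sorted(range(len(uniq)), key=lambda i: (-counts[i], first[i]))
    mapping = {uniq[i]: rank + 1 for rank, i in enumerate(order)}
    return np.array([mapping[v] for v in labels], dtype=int)
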