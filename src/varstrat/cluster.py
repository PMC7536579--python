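"""k-means with validity-index-voted k, Ward.D2 hierarchical clustering on
retained principal-component coordinates, and a linkage-method comparison
harness.

The optimal cluster count is chosen by majority vote over five validity
indices (silhouette, Calinski-Harabasz, Davies-Bouldin, the gap statistic
with uniform bounding-box references and the one-standard-error rule, and
Hartigan's rule), ties resolved toward the smallest k.  A five-index vote is
a documented, auditable subset of the large index batteries used for this
purpose; the index set is pluggable.

Hierarchical clustering uses Ward's minimum-variance criterion in its D2
form (Lance-Williams recurrence on Euclidean distances, heights on the
distance scale), the variant that yields the highest-resolution clusters for
reference-variant separation on this kind of panel.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from sklearn.cluster import KMeans
from sklearn.metrics import (
    adjusted_rand_score,
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .dendro import Dendrogram
from .io import ReferenceRole

__all__ = [
    "KMeansResult",
    "KVote",
    "kmeans",
    "optimal_k",
    "ward_linkage",
    "cut_dendrogram",
    "compare_linkages",
    "VotedKMeans",
]


def _as_points(points) -> tuple[np.ndarray, list]:
    if isinstance(points, pd.DataFrame):
        return np.asarray(points, dtype=float), list(points.index)
    arr = np.asarray(points, dtype=float)
    return arr, list(range(arr.shape[0]))


@dataclass
class KMeansResult:
    assignment: pd.Series       # variant -> cluster id
    centroids: np.ndarray       # cluster x component
    within_ss: float            # total within-cluster sum of squares
    k: int
    seed: int
    n_init: int


def kmeans(points, k: int, seed: int = 0, n_init: int = 25) -> KMeansResult:
    """Best of ``n_init`` k-means++/Lloyd restarts by within-cluster sum of
    squares; deterministic given ``seed``.  Empty clusters are repaired
    internally by reassigning the point farthest from its centroid."""
    X, index = _as_points(points)
    if not 1 <= k <= X.shape[0]:
        raise ValueError(f"k must be in 1..{X.shape[0]}, got {k}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(X)
    return KMeansResult(
        assignment=pd.Series(labels, index=index, name="cluster"),
        centroids=km.cluster_centers_,
        within_ss=float(km.inertia_),
        k=k,
        seed=seed,
        n_init=n_init,
    )


# ---------------------------------------------------------------------------
# validity indices for the k vote
# ---------------------------------------------------------------------------

def _inertia(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for c in np.unique(labels):
        pts = X[labels == c]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


def _best_k_silhouette(X, solutions, ks, rng) -> int:
    scores = {k: silhouette_score(X, solutions[k].assignment.to_numpy()) for k in ks}
    return max(ks, key=lambda k: (scores[k], -k))


def _best_k_calinski_harabasz(X, solutions, ks, rng) -> int:
    scores = {k: calinski_harabasz_score(X, solutions[k].assignment.to_numpy()) for k in ks}
    return max(ks, key=lambda k: (scores[k], -k))


def _best_k_davies_bouldin(X, solutions, ks, rng) -> int:
    scores = {k: davies_bouldin_score(X, solutions[k].assignment.to_numpy()) for k in ks}
    return min(ks, key=lambda k: (scores[k], k))


def _best_k_gap(X, solutions, ks, rng, B: int = 50) -> int:
    """Gap statistic with uniform bounding-box references and the
    one-standard-error rule (smallest k with gap(k) >= gap(k+1) - s(k+1))."""
    lo, hi = X.min(axis=0), X.max(axis=0)
    ks_ext = list(ks) + [max(ks) + 1] if max(ks) + 1 <= X.shape[0] else list(ks)
    log_w = {}
    for k in ks_ext:
        if k in solutions:
            log_w[k] = np.log(max(solutions[k].within_ss, 1e-300))
        else:
            km = KMeans(n_clusters=k, n_init=5, random_state=int(rng.integers(2**31)))
            km.fit(X)
            log_w[k] = np.log(max(km.inertia_, 1e-300))
    gap, s = {}, {}
    for k in ks_ext:
        ref_log_w = np.empty(B)
        for b in range(B):
            ref = rng.uniform(lo, hi, size=X.shape)
            km = KMeans(n_clusters=k, n_init=5, random_state=int(rng.integers(2**31)))
            km.fit(ref)
            ref_log_w[b] = np.log(max(km.inertia_, 1e-300))
        gap[k] = float(ref_log_w.mean() - log_w[k])
        s[k] = float(ref_log_w.std(ddof=0) * np.sqrt(1.0 + 1.0 / B))
    for k in ks:
        nxt = k + 1
        if nxt in gap and gap[k] >= gap[nxt] - s[nxt]:
            return k
    return max(ks, key=lambda k: (gap[k], -k))


def _best_k_hartigan(X, solutions, ks, rng, threshold: float = 10.0) -> int:
    """Hartigan's rule: smallest k with H(k) = (W(k)/W(k+1) - 1)(n - k - 1)
    below 10; if none qualifies, the k with the smallest H (weakest evidence
    for a further split)."""
    n = X.shape[0]
    w = {k: solutions[k].within_ss for k in ks}
    k_next = max(ks) + 1
    if k_next <= n:
        km = KMeans(n_clusters=k_next, n_init=5, random_state=int(rng.integers(2**31)))
        km.fit(X)
        w[k_next] = float(km.inertia_)
    h = {}
    for k in ks:
        if k + 1 in w and w[k + 1] > 0:
            h[k] = (w[k] / w[k + 1] - 1.0) * (n - k - 1)
        elif k + 1 in w:
            h[k] = 0.0
    if not h:
        return min(ks)
    for k in sorted(h):
        if h[k] <= threshold:
            return k
    return min(h, key=lambda k: (h[k], k))


DEFAULT_INDICES: dict[str, Callable] = {
    "silhouette": _best_k_silhouette,
    "calinski_harabasz": _best_k_calinski_harabasz,
    "davies_bouldin": _best_k_davies_bouldin,
    "gap": _best_k_gap,
    "hartigan": _best_k_hartigan,
}


@dataclass
class KVote:
    votes: dict[str, int]   # validity index -> best k
    winner: int
    tie_break: str          # "majority" or "smallest-of-modal-set"


def optimal_k(
    points,
    k_range: Iterable[int] = range(2, 9),
    seed: int = 0,
    n_init: int = 25,
    indices: dict[str, Callable] | None = None,
) -> KVote:
    """Majority vote of validity indices over k-means solutions; ties go to
    the smallest k among the modal set."""
    X, _ = _as_points(points)
    if np.allclose(X, X[0]):
        raise ValueError("degenerate input: all points identical")
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] <= 1 or ks[-1] >= X.shape[0]:
        raise ValueError(f"k_range must lie within (1, {X.shape[0]})")
    indices = DEFAULT_INDICES if indices is None else indices
    rng = np.random.default_rng(seed)
    solutions = {k: kmeans(X, k, seed=seed, n_init=n_init) for k in ks}
    votes = {name: int(fn(X, solutions, ks, rng)) for name, fn in indices.items()}
    counts = Counter(votes.values())
    top = max(counts.values())
    modal = sorted(k for k, c in counts.items() if c == top)
    tie_break = "majority" if len(modal) == 1 else "smallest-of-modal-set"
    return KVote(votes=votes, winner=modal[0], tie_break=tie_break)


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

def hierarchical_linkage(points, method: str = "ward") -> Dendrogram:
    """Agglomerative clustering on Euclidean distances as a binary merge tree."""
    X, index = _as_points(points)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 points")
    if method not in LINKAGE_METHODS:
        raise ValueError(f"unknown linkage method {method!r}")
    Z = linkage(X, method=method)
    return Dendrogram.from_linkage(Z, index)


def ward_linkage(points) -> Dendrogram:
    """Ward.D2 agglomeration (minimum-variance merges, heights on the
    Euclidean-distance scale)."""
    return hierarchical_linkage(points, "ward")


def cut_dendrogram(dend: Dendrogram, k: int) -> pd.Series:
    """The k clusters obtained by removing the k-1 highest merges."""
    assignment = dend.cut(k)
    return pd.Series(assignment, name="cluster").sort_index()


LINKAGE_METHODS = ("ward", "complete", "single", "average")


def compare_linkages(
    points,
    roles: pd.Series,
    methods: Sequence[str] = LINKAGE_METHODS,
    k: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Score linkage methods by how cleanly their cut partitions separate
    wild-type from MODY-reference variants.

    For each method the tree is cut at ``k`` (vote-selected when None) and
    the Adjusted Rand Index is computed on the reference variants against
    the WILD_TYPE / MODY_REFERENCE dichotomy.  Returns a frame sorted by
    descending score.
    """
    X, index = _as_points(points)
    roles = roles.map(lambda r: r if isinstance(r, ReferenceRole) else ReferenceRole(r))
    ref_labels = {
        v: role
        for v, role in roles.items()
        if role in (ReferenceRole.WILD_TYPE, ReferenceRole.MODY_REFERENCE) and v in index
    }
    if not any(r is ReferenceRole.WILD_TYPE for r in ref_labels.values()) or not any(
        r is ReferenceRole.MODY_REFERENCE for r in ref_labels.values()
    ):
        raise ValueError("need both WILD_TYPE and MODY_REFERENCE variants to score linkages")
    if k is None:
        k = optimal_k(X, seed=seed).winner
    truth = [ref_labels[v].value for v in index if v in ref_labels]
    rows = []
    for method in methods:
        Z = linkage(X, method=method)
        dend = Dendrogram.from_linkage(Z, index)
        assignment = dend.cut(k)
        predicted = [assignment[v] for v in index if v in ref_labels]
        rows.append({"method": method, "k": k, "reference_ari": adjusted_rand_score(truth, predicted)})
    return (
        pd.DataFrame(rows)
        .sort_values(["reference_ari", "method"], ascending=[False, True])
        .reset_index(drop=True)
    )


class VotedKMeans(KMeans):
    """sklearn-style k-means whose k is chosen by the validity-index vote.

    ``fit`` first runs :func:`optimal_k` over ``k_range`` then fits a
    standard k-means with the winning k; the vote is exposed as ``k_vote_``.
    """

    def __init__(self, k_range: tuple[int, ...] = tuple(range(2, 9)), n_init: int = 25, random_state: int = 0):
        super().__init__(n_clusters=2, n_init=n_init, random_state=random_state, algorithm="lloyd")
        self.k_range = k_range

    def fit(self, X, y=None, sample_weight=None):
        vote = optimal_k(X, k_range=self.k_range, seed=self.random_state, n_init=self.n_init)
        self.k_vote_ = vote
        self.n_clusters = vote.winner
        return super().fit(np.asarray(X, dtype=float), y, sample_weight)
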