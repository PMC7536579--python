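import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from varstrat.cluster import (
    VotedKMeans,
    compare_linkages,
    cut_dendrogram,
    kmeans,
    optimal_k,
    ward_linkage,
)
from varstrat.io import ReferenceRole


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def partitions_upto_k(items, k):
    """Every set partition of `items` into at most k non-empty blocks."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in partitions_upto_k(rest, k):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1:]
        if len(smaller) < k:
            yield smaller + [[first]]


def exhaustive_min_wss(X, k):
    best = np.inf
    for part in partitions_upto_k(list(range(len(X))), k):
        wss = sum(
            float(((X[block] - X[block].mean(axis=0)) ** 2).sum()) for block in part
        )
        best = min(best, wss)
    return best


def brute_force_ward(X):
    """Ward.D2 by direct recomputation of the merge cost over all cluster
    pairs at every step (smallest-pair tie-break); returns (leafset, height)
    merges sorted like Dendrogram.merges()."""
    clusters = [[i] for i in range(len(X))]
    merges = []
    while len(clusters) > 1:
        best = None
        for (i, a), (j, b) in itertools.combinations(enumerate(clusters), 2):
            na, nb = len(a), len(b)
            d = np.sqrt(2.0 * na * nb / (na + nb)) * np.linalg.norm(
                X[a].mean(axis=0) - X[b].mean(axis=0)
            )
            if best is None or d < best[0] - 1e-15:
                best = (d, i, j)
        d, i, j = best
        merged = clusters[i] + clusters[j]
        merges.append((frozenset(merged), d))
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)] + [merged]
    return sorted(merges, key=lambda m: (m[1], sorted(map(str, m[0]))))


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------

class TestKMeans:
    def test_planted_blobs_recovered(self, blobs_3):
        X, labels = blobs_3
        result = kmeans(X, 3, seed=0)
        assert adjusted_rand_score(labels, result.assignment) == 1.0

    def test_k_equals_n_gives_zero_wss(self, rng):
        X = rng.normal(size=(6, 2))
        assert kmeans(X, 6, seed=0).within_ss == pytest.approx(0.0, abs=1e-12)

    def test_k_out_of_range_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValueError):
            kmeans(X, 6)
        with pytest.raises(ValueError):
            kmeans(X, 0)

    def test_matches_exhaustive_partition_optimum(self, rng):
        for _ in range(10):
            n, k = int(rng.integers(4, 8)), int(rng.integers(2, 4))
            X = rng.normal(size=(n, 2))
            result = kmeans(X, k, seed=1)
            assert result.within_ss == pytest.approx(
                exhaustive_min_wss(X, k), rel=1e-9, abs=1e-9
            )

    def test_more_restarts_never_worse(self, rng):
        X = rng.normal(size=(30, 3))
        assert kmeans(X, 4, seed=2, n_init=25).within_ss <= kmeans(
            X, 4, seed=2, n_init=1
        ).within_ss + 1e-12


class TestOptimalK:
    def test_three_planted_blobs_vote_3(self, blobs_3):
        X, _ = blobs_3
        assert optimal_k(X, range(2, 9), seed=0).winner == 3

    def test_blob_plus_far_singleton_votes_2(self, rng):
        X = np.vstack([rng.normal(0, 0.1, size=(15, 2)), [[10.0, 10.0]]])
        assert optimal_k(X, range(2, 5), seed=0).winner == 2

    def test_pairwise_disagreement_takes_smallest_modal(self, rng):
        X = rng.normal(size=(20, 2))
        fake = {f"idx{k}": (lambda k: lambda *a, **kw: k)(k) for k in (6, 3, 4, 5, 7)}
        vote = optimal_k(X, range(2, 9), seed=0, indices=fake)
        assert vote.winner == 3
        assert vote.tie_break == "smallest-of-modal-set"

    def test_degenerate_points_rejected(self):
        X = np.ones((10, 2))
        with pytest.raises(ValueError, match="degenerate"):
            optimal_k(X)


# ---------------------------------------------------------------------------
# Ward hierarchical clustering
# ---------------------------------------------------------------------------

class TestWardLinkage:
    def test_two_points_merge_at_their_distance(self):
        X = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["a", "b"])
        dend = ward_linkage(X)
        merges = dend.merges()
        assert len(merges) == 1
        assert merges[0][1] == pytest.approx(5.0, abs=1e-12)

    def test_heights_monotone(self, rng):
        X = rng.normal(size=(12, 3))
        heights = [h for _, h in ward_linkage(X).merges()]
        assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))

    def test_matches_brute_force_on_random_fixtures(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 9))
            X = rng.normal(size=(n, int(rng.integers(2, 4))))
            got = ward_linkage(X).merges()
            expected = brute_force_ward(X)
            for (set_g, h_g), (set_e, h_e) in zip(got, expected):
                assert set_g == set_e
                assert h_g == pytest.approx(h_e, abs=1e-9)


class TestCutDendrogram:
    def test_extremes(self, rng):
        X = rng.normal(size=(7, 2))
        dend = ward_linkage(X)
        assert cut_dendrogram(dend, 1).nunique() == 1
        assert cut_dendrogram(dend, 7).nunique() == 7

    def test_planted_blobs_recovered(self, blobs_3):
        X, labels = blobs_3
        cut = cut_dendrogram(ward_linkage(X), 3)
        assert adjusted_rand_score(labels, cut.loc[labels.index]) == 1.0

    def test_cuts_are_nested(self, rng):
        X = rng.normal(size=(10, 2))
        dend = ward_linkage(X)
        prev = cut_dendrogram(dend, 6)
        for k in (5, 4, 3, 2, 1):
            cur = cut_dendrogram(dend, k)
            # every cluster at k+1 is contained in one cluster at k
            for c in prev.unique():
                members = prev.index[prev == c]
                assert cur.loc[members].nunique() == 1
            prev = cur


class TestCompareLinkages:
    @staticmethod
    def reference_roles(wt, mody, everyone):
        roles = {v: ReferenceRole.NONE for v in everyone}
        roles.update({v: ReferenceRole.WILD_TYPE for v in wt})
        roles.update({v: ReferenceRole.MODY_REFERENCE for v in mody})
        return pd.Series(roles)

    def test_planted_reference_blobs_ward_scores_1(self, rng):
        X = np.vstack([rng.normal(0, 0.2, (6, 2)), rng.normal(8, 0.2, (6, 2))])
        index = [f"v{i}" for i in range(12)]
        frame = pd.DataFrame(X, index=index)
        roles = self.reference_roles(index[:3], index[6:9], index)
        report = compare_linkages(frame, roles, k=2)
        assert report.loc[report["method"] == "ward", "reference_ari"].iloc[0] == 1.0

    def test_chained_fixture_penalizes_single_linkage(self, rng):
        # blobs bridged by a tight chain, plus one far outlier: the single-link
        # k=2 cut isolates the outlier and leaves both reference groups merged
        blob_a = rng.normal(0, 0.05, (6, 1))
        blob_b = rng.normal(10, 0.05, (6, 1))
        chain = np.linspace(0.5, 9.5, 12).reshape(-1, 1) + rng.normal(0, 0.01, (12, 1))
        outlier = np.array([[25.0]])
        X = np.vstack([blob_a, chain, outlier, blob_b])
        index = [f"v{i}" for i in range(len(X))]
        frame = pd.DataFrame(X, index=index)
        roles = self.reference_roles(index[:6], index[-6:], index)
        report = compare_linkages(frame, roles, k=2).set_index("method")
        assert (
            report.loc["single", "reference_ari"] < report.loc["ward", "reference_ari"]
        )

    def test_single_method_report(self, rng):
        X = rng.normal(size=(8, 2))
        index = [f"v{i}" for i in range(8)]
        roles = self.reference_roles(index[:2], index[2:4], index)
        report = compare_linkages(pd.DataFrame(X, index=index), roles, methods=("ward",), k=2)
        assert len(report) == 1

    def test_requires_references(self, rng):
        X = pd.DataFrame(rng.normal(size=(8, 2)), index=[f"v{i}" for i in range(8)])
        roles = pd.Series({f"v{i}": ReferenceRole.NONE for i in range(8)})
        with pytest.raises(ValueError):
            compare_linkages(X, roles, k=2)


class TestVotedKMeans:
    def test_fits_with_voted_k(self, blobs_3):
        X, labels = blobs_3
        est = VotedKMeans(random_state=0).fit(X.to_numpy())
        assert est.n_clusters == 3
        assert adjusted_rand_score(labels, est.labels_) == 1.0
        assert est.get_params()["k_range"] == tuple(range(2, 9))
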