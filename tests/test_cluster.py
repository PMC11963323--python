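"""k-means, SSE/silhouette diagnostics and k-selection."""

import itertools

import numpy as np
import pytest

from placebomatch.cluster import assign, kmeans_fit, mean_silhouette, scan_k, sse
from placebomatch.dataio import Standardizer


def _embed(xs):
    """1-D points embedded in 3-D color space."""
    return np.column_stack([xs, np.zeros(len(xs)), np.zeros(len(xs))]).astype(float)


def _brute_force_sse(X, k):
    """Globally optimal within-cluster SSE by partition enumeration."""
    n = len(X)
    best = np.inf
    for labels in itertools.product(range(k), repeat=n):
        labels = np.array(labels)
        if len(np.unique(labels)) < k:
            continue
        total = 0.0
        for c in range(k):
            pts = X[labels == c]
            total += ((pts - pts.mean(axis=0)) ** 2).sum()
        best = min(best, total)
    return best


def _silhouette_oracle(X, labels):
    """Direct pairwise-distance silhouette, mean over points."""
    n = len(X)
    D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
    svals = []
    for i in range(n):
        own = np.flatnonzero((labels == labels[i]) & (np.arange(n) != i))
        if own.size == 0:
            svals.append(0.0)
            continue
        a = D[i, own].mean()
        b = min(D[i, labels == c].mean() for c in np.unique(labels) if c != labels[i])
        svals.append((b - a) / max(a, b))
    return float(np.mean(svals))


def _blobs(centers, n_per, sigma, seed):
    rng = np.random.default_rng(seed)
    return np.vstack([c + sigma * rng.standard_normal((n_per, 3)) for c in np.asarray(centers, float)])


class TestKMeans:
    def test_two_pairs_on_a_line(self):
        X = _embed([0, 1, 10, 11])
        m = kmeans_fit(X, 2, seed=0)
        assert m.sse == pytest.approx(1.0)  # each pair: 2 * 0.5^2
        assert m.labels[0] == m.labels[1] and m.labels[2] == m.labels[3]
        assert m.labels[0] != m.labels[2]
        # centroids equal their members' mean
        for c in range(2):
            assert m.centroids[c] == pytest.approx(X[m.labels == c].mean(axis=0), abs=1e-9)

    def test_identical_points_degenerate(self):
        X = np.ones((6, 3))
        m = kmeans_fit(X, 2, seed=0)
        assert m.sse == pytest.approx(0.0)

    def test_k_equals_n(self):
        X = _embed([0, 5, 9])
        m = kmeans_fit(X, 3, seed=0)
        assert m.sse == pytest.approx(0.0, abs=1e-12)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_fit(np.ones((2, 3)), 5)

    def test_restart_kmeans_finds_global_optimum_usually(self):
        # tiny unstructured instances are adversarial for Lloyd's
        # algorithm; with extra restarts the brute-force optimum is hit
        # in nearly every trial
        hits = 0
        trials = 20
        for t in range(trials):
            rng = np.random.default_rng(100 + t)
            X = rng.uniform(0, 10, (7, 3))
            m = kmeans_fit(X, 2, seed=t, n_init=30)
            assert m.sse >= _brute_force_sse(X, 2) - 1e-9
            hits += m.sse == pytest.approx(_brute_force_sse(X, 2), rel=1e-9)
        assert hits >= 0.95 * trials

    def test_sse_operation_matches_fit_and_oracle(self):
        rng = np.random.default_rng(11)
        X = rng.uniform(0, 5, (30, 3))
        m = kmeans_fit(X, 3, seed=1)
        assert sse(m, X) == pytest.approx(m.sse, rel=1e-9)
        # explicit two-point check: centroid (1,0,0), points at 0 and 2
        m.centroids = _embed([1.0])
        assert sse(m, _embed([0.0, 2.0])) == pytest.approx(2.0)


class TestSilhouette:
    def test_hand_computed_line_example(self):
        X = _embed([0, 1, 10, 11])
        labels = np.array([0, 0, 1, 1])
        # point 0: a=1, b=10.5; point 1: a=1, b=9.5; symmetric on the right
        expected = (9.5 / 10.5 + 8.5 / 9.5) * 2 / 4
        assert mean_silhouette(X, labels) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.8997, abs=5e-5)

    def test_coincident_clusters_score_zero(self):
        X = np.vstack([np.ones((3, 3)), np.ones((3, 3))])
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert mean_silhouette(X, labels) == pytest.approx(0.0)

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(12)
        X = rng.uniform(0, 10, (25, 3))
        labels = rng.integers(0, 3, 25)
        while len(np.unique(labels)) < 3:
            labels = rng.integers(0, 3, 25)
        assert mean_silhouette(X, labels) == pytest.approx(_silhouette_oracle(X, labels), abs=1e-12)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="single cluster"):
            mean_silhouette(np.ones((4, 3)), np.zeros(4))


class TestScanK:
    def test_recovers_two_blobs(self):
        X = _blobs([[0, 0, 0], [10, 0, 0]], 50, 0.1, seed=0)
        rep = scan_k(X, range(2, 8), seed=0)
        assert rep.chosen_k == 2
        assert rep.silhouette[0] == max(rep.silhouette)

    def test_recovers_three_blobs(self):
        X = _blobs([[0, 0, 0], [10, 0, 0], [0, 10, 0]], 40, 0.1, seed=1)
        rep = scan_k(X, range(2, 8), seed=1)
        assert rep.chosen_k == 3

    def test_sse_non_increasing_in_k(self):
        rng = np.random.default_rng(13)
        X = rng.uniform(0, 10, (60, 3))
        rep = scan_k(X, range(2, 12), seed=2)
        assert all(a >= b - 1e-9 for a, b in zip(rep.sse, rep.sse[1:]))

    def test_range_truncated_with_warning_on_small_n(self):
        X = _blobs([[0, 0, 0], [10, 0, 0]], 3, 0.1, seed=3)  # n = 6
        with pytest.warns(UserWarning, match="truncated"):
            rep = scan_k(X, range(2, 12), seed=0)
        assert rep.k_values[-1] <= 5


class TestAssign:
    def test_training_points_keep_their_labels(self):
        X = _blobs([[0, 0, 0], [8, 0, 0]], 20, 0.2, seed=4)
        m = kmeans_fit(X, 2, seed=0)
        assert np.array_equal(assign(m, X), m.labels)

    def test_tie_goes_to_lowest_index(self):
        m = kmeans_fit(_embed([0, 0, 2, 2]), 2, seed=0)
        midpoint = m.centroids[:, 0].mean()
        label = assign(m, np.array([[midpoint, 0, 0]]))[0]
        assert label == 0  # equidistant: first centroid wins

    def test_standardized_assignment_of_fresh_points(self):
        raw = _blobs([[50, 50, 50], [200, 200, 200]], 30, 2.0, seed=5)
        std = Standardizer().fit(raw)
        m = kmeans_fit(std.transform(raw), 2, seed=0)
        fresh = np.array([[52, 51, 49], [198, 201, 202]])
        labels = assign(m, fresh, std)
        assert labels[0] == m.labels[0] and labels[1] == m.labels[-1]
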