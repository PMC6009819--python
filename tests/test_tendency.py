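import itertools

import numpy as np
import pytest

from tagdnl.preprocess import qc_normalize
from tagdnl.synthetic import CohortSpec, generate_cohort
from tagdnl.tendency import hca_complete, hopkins, hopkins_by_class, kmeans_euclid


def hopkins_bruteforce(X, m, seed):
    """Independent Hopkins oracle: same seeded sampling, naive NN loops."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    lo, hi = X.min(axis=0), X.max(axis=0)
    rng = np.random.default_rng(seed)
    probes = rng.uniform(lo, hi, size=(m, X.shape[1]))
    u = np.array([min(np.sqrt(((x - p) ** 2).sum()) for x in X) for p in probes])
    idx = rng.choice(n, size=m, replace=False)
    w = np.array(
        [
            min(np.sqrt(((X[j] - X[i]) ** 2).sum()) for j in range(n) if j != i)
            for i in idx
        ]
    )
    return u.sum() / (u.sum() + w.sum())


def two_gaussians(n, d, sep, seed):
    rng = np.random.default_rng(seed)
    half = n // 2
    return np.vstack(
        [rng.normal(0, 1, size=(half, d)), rng.normal(sep, 1, size=(n - half, d))]
    )


class TestHopkins:
    def test_matches_bruteforce_oracle_and_detects_clusters(self):
        """Two well-separated Gaussians: oracle agreement to 1e-12, H > 0.6799."""
        X = two_gaussians(200, 2, sep=8.0, seed=3)
        res = hopkins(X, m=20, seed=42)
        assert res.H == pytest.approx(hopkins_bruteforce(X, 20, 42), abs=1e-12)
        assert res.H > 0.6799 and res.reject_null

    def test_reject_flag_follows_critical_value(self):
        X = two_gaussians(200, 2, sep=8.0, seed=3)
        res = hopkins(X, m=20, seed=0)
        assert res.reject_null == (res.H > res.critical_value)
        loose = hopkins(X, m=20, seed=0, critical_value=0.999)
        assert not loose.reject_null

    def test_identical_points_degenerate(self):
        with pytest.warns(UserWarning, match="identical"):
            res = hopkins(np.ones((10, 3)), m=3, seed=0)
        assert res.H == 1.0

    def test_m_bounds_enforced(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValueError):
            hopkins(X, m=10, seed=0)
        with pytest.raises(ValueError):
            hopkins(X, m=0, seed=0)

    def test_uniform_data_calibrates_to_half(self):
        """Uniform box data: mean H over seeds concentrates near 0.5."""
        rng = np.random.default_rng(0)
        hs = [
            hopkins(rng.uniform(size=(500, 2)), m=50, seed=s).H for s in range(40)
        ]
        assert abs(np.mean(hs) - 0.5) < 0.05

    def test_translation_and_scale_invariance(self):
        X = two_gaussians(150, 3, sep=4.0, seed=5)
        h0 = hopkins(X, m=15, seed=7).H
        h1 = hopkins(X * 3.7 + 11.0, m=15, seed=7).H
        assert h1 == pytest.approx(h0, abs=1e-9)

    def test_mean_h_monotone_in_separation(self):
        seps = [0.0, 2.0, 4.0, 8.0]
        means = []
        for sep in seps:
            means.append(
                np.mean(
                    [hopkins(two_gaussians(120, 2, sep, seed=s), m=12, seed=s).H
                     for s in range(25)]
                )
            )
        assert all(b >= a - 0.01 for a, b in zip(means, means[1:]))


class TestHopkinsByClass:
    def test_planted_tag_clusters_detected_others_not(self):
        """Only the TAG class (3 planted clusters) rejects; unstructured
        phospholipid / sphingolipid / CE classes do not, across seeds."""
        tag_rej, other_tests, other_rej = 0, 0, 0
        n_rep = 25
        for seed in range(n_rep):
            table, _ = generate_cohort(CohortSpec(n_subjects=250, n_plates=5, seed=seed))
            normed, _ = qc_normalize(table)
            res = hopkins_by_class(normed, seed=seed)
            tag_rej += res["TAG"].reject_null
            for cls in ("PC", "PE", "SM", "CE", "LPC"):
                other_tests += 1
                other_rej += res[cls].reject_null
        assert tag_rej >= 0.9 * n_rep
        assert other_rej <= 0.1 * other_tests

    def test_small_class_not_testable(self, normed_small_cohort):
        from tagdnl.containers import FeatureTable

        normed, _, _ = normed_small_cohort
        cols = [c for c in normed.intensities.columns if not c.startswith("PE")]
        cols += ["PE(34:1)", "PE(34:2)"]  # PE reduced below the 5-feature minimum
        sub = FeatureTable(normed.intensities[cols].copy(), normed.plate, normed.is_qc)
        with pytest.warns(UserWarning, match="not testable"):
            res = hopkins_by_class(sub, seed=0)
        assert res["PE"] is None

    def test_single_class_table(self, normed_small_cohort):
        normed, _, _ = normed_small_cohort
        res = hopkins_by_class(normed.select_class("TAG"), seed=0)
        assert set(res) == {"TAG"}


def complete_linkage_bruteforce(X, k):
    """O(n^3) farthest-neighbour agglomeration oracle -> partition at k."""
    n = X.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    d = {(i, j): np.linalg.norm(X[i] - X[j]) for i in range(n) for j in range(i + 1, n)}

    def cdist(a, b):
        return max(d[(min(i, j), max(i, j))] for i in a for j in b)

    while len(clusters) > k:
        best = min(
            ((cdist(a, b), ai, bi)
             for (ai, a), (bi, b) in itertools.combinations(enumerate(clusters), 2)),
        )
        _, ai, bi = best
        merged = clusters[ai] | clusters[bi]
        clusters = [c for i, c in enumerate(clusters) if i not in (ai, bi)] + [merged]
    return {frozenset(c) for c in clusters}


def labels_to_partition(labels):
    out = {}
    for i, lab in enumerate(labels):
        out.setdefault(lab, set()).add(i)
    return {frozenset(v) for v in out.values()}


class TestHca:
    def test_k_equals_items_gives_singletons(self):
        X = np.random.default_rng(0).normal(size=(6, 2))
        labels, _ = hca_complete(X, k=6)
        assert len(set(labels)) == 6

    def test_collinear_points_forced_split(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        labels, _ = hca_complete(X, k=2)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    @pytest.mark.parametrize("seed", range(5))
    def test_agreement_with_naive_linkage_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(rng.integers(8, 16), 3))
        for k in (2, 3, 4):
            labels, _ = hca_complete(X, k=k)
            assert labels_to_partition(labels) == complete_linkage_bruteforce(X, k)

    def test_k_exceeds_items_rejected(self):
        with pytest.raises(ValueError):
            hca_complete(np.zeros((3, 2)), k=4)


class TestKmeans:
    def test_two_blobs_recovered(self):
        X = two_gaussians(60, 2, sep=10.0, seed=1)
        labels, _ = kmeans_euclid(X, k=2, seed=0)
        assert len(set(labels[:30])) == 1 and len(set(labels[30:])) == 1
        assert labels[0] != labels[-1]

    def test_k1_inertia_is_total_ss(self):
        X = np.random.default_rng(2).normal(size=(25, 3))
        _, inertia = kmeans_euclid(X, k=1, seed=0)
        assert inertia == pytest.approx(((X - X.mean(axis=0)) ** 2).sum())

    def test_matches_exhaustive_two_partition_minimum(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 2))
        _, inertia = kmeans_euclid(X, k=2, seed=0, n_restarts=30)
        best = np.inf
        for mask in range(1, 2**7):  # fix point 0 in cluster 0
            sel = np.array([(mask >> i) & 1 for i in range(8)], dtype=bool)
            sel[0] = False
            if sel.all() or (~sel).all():
                continue
            ss = sum(
                ((X[g] - X[g].mean(axis=0)) ** 2).sum() for g in (sel, ~sel) if g.any()
            )
            best = min(best, ss)
        assert inertia == pytest.approx(best, rel=1e-9)

    def test_deterministic_given_seed(self):
        X = np.random.default_rng(4).normal(size=(40, 3))
        l1, i1 = kmeans_euclid(X, k=3, seed=5)
        l2, i2 = kmeans_euclid(X, k=3, seed=5)
        assert np.array_equal(l1, l2) and i1 == i2
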