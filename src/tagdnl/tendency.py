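"""Clustering tendency (Hopkins statistic) and reference clusterings.

The Hopkins statistic compares nearest-neighbour distances of ``m`` uniform
probes (drawn in the axis-aligned bounding box of the data) against
nearest-neighbour distances of ``m`` sampled real points:

    H = sum(u_i) / (sum(u_i) + sum(w_i))

H near 0.5 indicates spatial randomness, H -> 1 strong clustering. The null
of no substructure is rejected at the 95% level for H > 0.6799; the
threshold is approximate and applied irrespective of m. Per lipid class, the
lipid species are the points and (scaled) samples the dimensions, so the
statistic asks whether the species of that class fall into co-regulated
groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

from .containers import FeatureTable
from .preprocess import Scaler

__all__ = ["HopkinsResult", "hopkins", "hopkins_by_class", "hca_complete", "kmeans_euclid"]

HOPKINS_CRITICAL = 0.6799


@dataclass
class HopkinsResult:
    H: float
    m: int
    critical_value: float
    reject_null: bool
    seed: int

    def to_dict(self) -> dict:
        return {
            "H": self.H,
            "m": self.m,
            "critical": self.critical_value,
            "reject": self.reject_null,
            "seed": self.seed,
        }


def default_probe_count(n: int) -> int:
    return int(min(int(np.ceil(0.1 * n)), 50))


def hopkins(
    points,
    m: int | None = None,
    seed: int = 0,
    critical_value: float = HOPKINS_CRITICAL,
) -> HopkinsResult:
    """Hopkins clustering-tendency statistic with seeded sampling.

    Probes are uniform in the bounding hyper-rectangle of the data; both
    probe->data and sampled-point->remaining-data distances are Euclidean
    nearest neighbours. Degenerate all-identical data yield H = 1 with a
    warning.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("points must be a 2-D items x dimensions array")
    n = X.shape[0]
    if m is None:
        m = default_probe_count(n)
    if m < 1 or m >= n:
        raise ValueError(f"need 1 <= m < n items, got m={m}, n={n}")
    lo, hi = X.min(axis=0), X.max(axis=0)
    if np.all(hi == lo):
        warnings.warn("all data points identical; Hopkins statistic degenerate, returning H=1")
        return HopkinsResult(1.0, m, critical_value, True, seed)

    rng = np.random.default_rng(seed)
    tree = cKDTree(X)
    probes = rng.uniform(lo, hi, size=(m, X.shape[1]))
    u, _ = tree.query(probes, k=1)
    idx = rng.choice(n, size=m, replace=False)
    w, _ = tree.query(X[idx], k=2)
    w = w[:, 1]  # nearest neighbour excluding self
    denom = u.sum() + w.sum()
    H = 1.0 if denom == 0 else float(u.sum() / denom)
    return HopkinsResult(H, m, critical_value, H > critical_value, seed)


def hopkins_by_class(
    table: FeatureTable,
    seed: int = 0,
    scaling: str = "pareto",
    min_features: int = 5,
    m: int | None = None,
) -> dict[str, HopkinsResult | None]:
    """Hopkins statistic per lipid class, species as points in sample-space.

    Non-QC samples only; intensities are scaled per feature (default Pareto)
    before transposing so each lipid species becomes one point. Classes with
    fewer than ``min_features`` species are not testable and map to ``None``.
    """
    subj = table.subjects()
    results: dict[str, HopkinsResult | None] = {}
    for i, cls in enumerate(sorted(set(s.lipid_class for s in subj.species))):
        sub = subj.select_class(cls)
        if sub.n_features < min_features:
            warnings.warn(f"class {cls}: only {sub.n_features} features; Hopkins not testable")
            results[cls] = None
            continue
        Z = Scaler(method=scaling).fit_transform(sub.intensities.to_numpy())
        results[cls] = hopkins(Z.T, m=m, seed=seed + i)
    return results


def hca_complete(points, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Complete-linkage (farthest-neighbour) Euclidean hierarchical clustering.

    Returns 0-based flat labels for a cut into ``k`` clusters and the scipy
    linkage (merge-tree) matrix.
    """
    X = np.asarray(points, dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n items, got k={k}, n={n}")
    Z = hierarchy.linkage(X, method="complete", metric="euclidean")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust") - 1
    return labels, Z


def kmeans_euclid(points, k: int, seed: int = 0, n_restarts: int = 10) -> tuple[np.ndarray, float]:
    """Best-of-restarts Lloyd k-means with Euclidean distance; seeded."""
    X = np.asarray(points, dtype=float)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of items {X.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(X)
    return labels, float(km.inertia_)
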