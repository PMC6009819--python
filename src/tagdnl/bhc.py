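"""Bayesian hierarchical clustering of lipid profiles.

Greedy agglomeration in which each candidate merge is scored by the posterior
probability r_k that the merged items form a single cluster, under a
Dirichlet-process mixture prior with concentration ``alpha``:

    d_k  = alpha * Gamma(n_k) + d_i * d_j          (leaves: d = alpha)
    pi_k = alpha * Gamma(n_k) / d_k
    p(D_k | T_k) = pi_k p(D_k | H1) + (1 - pi_k) p(D_i | T_i) p(D_j | T_j)
    r_k  = pi_k p(D_k | H1) / p(D_k | T_k)

p(D|H1) is the marginal likelihood of all items in one Gaussian cluster under
a Normal-Inverse-Wishart prior (or its diagonal Normal-Inverse-Gamma
factorization when the dimensionality exceeds the item count). All
computation is in log space; the pair with the highest r_k is merged at each
step, ties broken on lowest item indices. Cutting the tree wherever
r_k < 0.5 (the posterior favouring a split) yields flat clusters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, multigammaln

from .containers import FeatureTable
from .lipids import LipidSpecies

__all__ = [
    "NiwPrior",
    "BhcNode",
    "BhcTree",
    "empirical_prior",
    "bhc_fit",
    "bhc_cut",
    "ClusterAssignment",
    "cluster_share",
    "cluster_composition",
    "label_dnl_cluster",
    "to_newick",
]


# ---------------------------------------------------------------------------
# Gaussian marginal likelihoods
# ---------------------------------------------------------------------------


@dataclass
class NiwPrior:
    """Normal-Inverse-Wishart prior (full or diagonal).

    ``scatter`` is the prior scatter matrix S0 (full mode: d x d matrix;
    diagonal mode: length-d vector of per-dimension scales). ``nu0`` must
    exceed d - 1 in full mode; the diagonal mode applies the univariate
    (d = 1) marginal per dimension with a shared ``nu0``.
    """

    mean: np.ndarray
    kappa0: float
    nu0: float
    scatter: np.ndarray
    diagonal: bool = False

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.scatter = np.asarray(self.scatter, dtype=float)
        d = self.mean.shape[0]
        if self.diagonal:
            if self.scatter.shape != (d,) or np.any(self.scatter <= 0):
                raise ValueError("diagonal prior scatter must be a positive length-d vector")
        else:
            if self.scatter.shape != (d, d):
                raise ValueError("full prior scatter must be d x d")
            try:
                np.linalg.cholesky(self.scatter)
            except np.linalg.LinAlgError as exc:
                raise ValueError("prior scatter matrix is not positive definite") from exc
            _, self._logdet0 = np.linalg.slogdet(self.scatter)
            if self.nu0 <= d - 1:
                raise ValueError(f"need nu0 > d-1 = {d - 1}, got {self.nu0}")

    def log_marglik(self, X: np.ndarray) -> float:
        """log p(X | H1): all rows of X belong to one Gaussian cluster."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n, d = X.shape
        kn = self.kappa0 + n
        nun = self.nu0 + n
        xbar = X.mean(axis=0)
        dev = X - xbar
        dmean = xbar - self.mean
        shrink = self.kappa0 * n / kn
        if self.diagonal:
            s0 = self.scatter
            sn = s0 + (dev**2).sum(axis=0) + shrink * dmean**2
            return float(
                -0.5 * n * d * math.log(math.pi)
                + d * (gammaln(nun / 2.0) - gammaln(self.nu0 / 2.0))
                + 0.5 * (self.nu0 * np.log(s0).sum() - nun * np.log(sn).sum())
                + 0.5 * d * (math.log(self.kappa0) - math.log(kn))
            )
        Sn = self.scatter + dev.T @ dev + shrink * np.outer(dmean, dmean)
        sign, logdetn = np.linalg.slogdet(Sn)
        if sign <= 0:
            raise ValueError("posterior scatter not positive definite")
        return float(
            -0.5 * n * d * math.log(math.pi)
            + multigammaln(nun / 2.0, d)
            - multigammaln(self.nu0 / 2.0, d)
            + 0.5 * (self.nu0 * self._logdet0 - nun * logdetn)
            + 0.5 * d * (math.log(self.kappa0) - math.log(kn))
        )


def empirical_prior(X: np.ndarray, diagonal: bool | None = None) -> NiwPrior:
    """Empirical-Bayes hyperparameters: prior mean = data mean, prior scatter
    = diagonal of the data covariance, kappa0 = 1, nu0 = d + 2 (full) or 3
    (per-dimension, diagonal mode).

    The diagonal factorization is used automatically (with a flag on the
    prior) whenever the dimensionality is not below the item count, where the
    full Wishart normalizer is ill-posed for an empirical scatter.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if diagonal is None:
        diagonal = d >= n
    var = X.var(axis=0, ddof=1) if n > 1 else np.ones(d)
    var = np.where(var > 0, var, 1.0)
    if diagonal:
        return NiwPrior(X.mean(axis=0), 1.0, 3.0, var, diagonal=True)
    return NiwPrior(X.mean(axis=0), 1.0, d + 2.0, np.diag(var), diagonal=False)


# ---------------------------------------------------------------------------
# Tree construction
# ---------------------------------------------------------------------------


def _log1mexp(x: float) -> float:
    """log(1 - exp(x)) for x < 0, numerically stable."""
    if x >= 0:
        return -math.inf
    if x > -math.log(2.0):
        return math.log(-math.expm1(x))
    return math.log1p(-math.exp(x))


@dataclass
class BhcNode:
    """One node of the merge tree; leaves have ``log_r`` undefined (None)."""

    members: tuple[int, ...]
    log_d: float
    log_ph1: float
    log_ptree: float
    log_pi: float = 0.0
    log_r: float | None = None
    left: "BhcNode | None" = None
    right: "BhcNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def r(self) -> float | None:
        return None if self.log_r is None else float(math.exp(self.log_r))


@dataclass
class BhcTree:
    root: BhcNode
    alpha: float
    prior: NiwPrior
    labels: list[str] = field(default_factory=list)

    @property
    def log_evidence(self) -> float:
        """log p(D | T) at the root."""
        return self.root.log_ptree


def _merge(i_node: BhcNode, j_node: BhcNode, log_alpha: float, log_ph1: float) -> BhcNode:
    members = tuple(sorted(i_node.members + j_node.members))
    nk = len(members)
    log_ad = log_alpha + gammaln(nk)
    log_dk = np.logaddexp(log_ad, i_node.log_d + j_node.log_d)
    log_pi = log_ad - log_dk
    log_joined = log_pi + log_ph1
    log_split = _log1mexp(log_pi) + i_node.log_ptree + j_node.log_ptree
    log_ptree = np.logaddexp(log_joined, log_split)
    return BhcNode(
        members=members,
        log_d=float(log_dk),
        log_ph1=float(log_ph1),
        log_ptree=float(log_ptree),
        log_pi=float(log_pi),
        log_r=float(log_joined - log_ptree),
        left=i_node,
        right=j_node,
    )


def bhc_fit(
    X,
    alpha: float = 1.0,
    prior: NiwPrior | None = None,
    labels: list[str] | None = None,
) -> BhcTree:
    """Fit the greedy merge tree over the rows of ``X`` (items x dimensions).

    Typical use clusters lipid features: rows are features, columns are the
    (TAG-percent, Pareto-scaled) samples. ``prior=None`` selects empirical-
    Bayes hyperparameters via :func:`empirical_prior`.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 1:
        raise ValueError("need at least one item")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if prior is None:
        prior = empirical_prior(X)
    if labels is None:
        labels = [str(i) for i in range(n)]
    log_alpha = math.log(alpha)

    nodes: dict[int, BhcNode] = {}
    for i in range(n):
        lp = prior.log_marglik(X[i : i + 1])
        nodes[i] = BhcNode(members=(i,), log_d=log_alpha, log_ph1=lp, log_ptree=lp)
    if n == 1:
        return BhcTree(nodes[0], alpha, prior, labels)

    candidates: dict[tuple[int, int], BhcNode] = {}

    def propose(a: int, b: int) -> None:
        key = (a, b) if a < b else (b, a)
        ph1 = prior.log_marglik(X[list(nodes[a].members + nodes[b].members)])
        candidates[key] = _merge(nodes[a], nodes[b], log_alpha, ph1)

    active = list(range(n))
    for ai in range(len(active)):
        for bi in range(ai + 1, len(active)):
            propose(active[ai], active[bi])

    next_id = n
    while len(active) > 1:
        # highest merge posterior wins; ties broken by lowest (i, j)
        best_key = max(candidates, key=lambda k: (candidates[k].log_r, (-k[0], -k[1])))
        merged = candidates[best_key]
        a, b = best_key
        active.remove(a)
        active.remove(b)
        del nodes[a], nodes[b]
        for key in [k for k in candidates if a in k or b in k]:
            del candidates[key]
        nodes[next_id] = merged
        for other in active:
            propose(other, next_id)
        active.append(next_id)
        next_id += 1

    return BhcTree(nodes[active[0]], alpha, prior, labels)


# ---------------------------------------------------------------------------
# Cutting and cluster summaries
# ---------------------------------------------------------------------------


@dataclass
class ClusterAssignment:
    """Feature label -> cluster id, plus member lists per cluster."""

    labels: list[str]
    assignment: dict[str, int]

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, cluster_id: int) -> list[str]:
        return [f for f, c in self.assignment.items() if c == cluster_id]

    def as_array(self) -> np.ndarray:
        return np.array([self.assignment[f] for f in self.labels])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.labels, "cluster": [self.assignment[f] for f in self.labels]}
        )


def bhc_cut(tree: BhcTree, r_threshold: float = 0.5) -> ClusterAssignment:
    """Flat clusters: descend from the root splitting nodes with r < threshold."""
    clusters: list[tuple[int, ...]] = []

    def descend(node: BhcNode) -> None:
        keep = node.is_leaf or (r_threshold <= 0) or (node.r >= r_threshold)
        if keep:
            clusters.append(node.members)
        else:
            descend(node.left)
            descend(node.right)

    descend(tree.root)
    clusters.sort(key=lambda ms: ms[0])
    assignment = {}
    for cid, ms in enumerate(clusters, start=1):
        for m in ms:
            assignment[tree.labels[m]] = cid
    return ClusterAssignment(labels=list(tree.labels), assignment=assignment)


def cluster_share(assign: ClusterAssignment, table: FeatureTable) -> pd.Series:
    """Fraction of total intensity (summed over samples) per cluster; sums to 1."""
    missing = [f for f in assign.labels if f not in table.intensities.columns]
    if missing:
        raise ValueError(f"assignment covers features absent from table: {missing[:5]}")
    totals = table.subjects().intensities[assign.labels].sum(axis=0)
    shares = totals.groupby(pd.Series(assign.assignment)).sum()
    shares = shares / shares.sum()
    shares.index.name = "cluster"
    return shares


def cluster_composition(assign: ClusterAssignment, species: list[LipidSpecies]) -> pd.DataFrame:
    """Per-cluster mean carbons / double bonds and % low-unsaturation species.

    A species counts as saturated/monounsaturated when its total double-bond
    count is <= 2 (at most ~one double bond per acyl chain at TAG level).
    """
    by_label = {s.label: s for s in species}
    rows = []
    for cid in sorted(set(assign.assignment.values())):
        mem = [by_label[f] for f in assign.members(cid)]
        dbs = np.array([s.double_bonds for s in mem], dtype=float)
        cs = np.array([s.carbons for s in mem], dtype=float)
        rows.append(
            {
                "cluster": cid,
                "n_species": len(mem),
                "mean_carbons": cs.mean(),
                "mean_double_bonds": dbs.mean(),
                "pct_sat_mono": 100.0 * float((dbs <= 2).mean()),
            }
        )
    return pd.DataFrame(rows).set_index("cluster")


def label_dnl_cluster(composition: pd.DataFrame) -> int:
    """Cluster id of the de novo lipogenesis cluster.

    The DNL cluster holds the saturated / monounsaturated species with 16-18
    carbon fatty acids, i.e. 46-54 total carbons: lowest mean double-bond
    count among clusters in that carbon range (all clusters if none falls in
    the range).
    """
    in_range = composition[
        (composition["mean_carbons"] >= 44) & (composition["mean_carbons"] <= 56)
    ]
    pool = in_range if len(in_range) else composition
    return int(pool["mean_double_bonds"].idxmin())


def to_newick(tree: BhcTree) -> str:
    """Newick export with the merge posterior r_k as internal node labels."""

    def fmt(node: BhcNode) -> str:
        if node.is_leaf:
            lbl = tree.labels[node.members[0]].replace(" ", "_").replace(",", "_")
            lbl = lbl.replace("(", "<").replace(")", ">").replace(":", "|")
            return lbl
        return f"({fmt(node.left)},{fmt(node.right)}){node.r:.4f}"

    return fmt(tree.root) + ";"
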