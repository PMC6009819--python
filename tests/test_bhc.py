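import math

import numpy as np
import pytest
from scipy.special import gammaln, logsumexp
from sklearn.metrics import adjusted_rand_score

from tagdnl.bhc import (
    NiwPrior,
    bhc_cut,
    bhc_fit,
    cluster_composition,
    cluster_share,
    empirical_prior,
    label_dnl_cluster,
    to_newick,
)
from tagdnl.lipids import parse_lipid_label
from tagdnl.preprocess import Scaler, tag_percent_normalize
from tagdnl.synthetic import CohortSpec, generate_cohort, planted_tag_assignment

from .conftest import tiny_table

# ---------------------------------------------------------------------------
# independent oracle: enumerate tree-consistent partitions with DP weights
# ---------------------------------------------------------------------------


def _subtree_leafsets(node, acc):
    acc.add(frozenset(node.members))
    if not node.is_leaf:
        _subtree_leafsets(node.left, acc)
        _subtree_leafsets(node.right, acc)
    return acc


def _partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for p in _partitions(rest):
        for i in range(len(p)):
            yield p[:i] + [[first] + p[i]] + p[i + 1:]
        yield p + [[first]]


def oracle_log_evidence(tree, X, alpha):
    """DP-weighted sum over the partitions consistent with the fitted tree."""
    nodesets = _subtree_leafsets(tree.root, set())
    la = math.log(alpha)
    num, den = [], []
    for part in _partitions(list(range(X.shape[0]))):
        blocks = [frozenset(b) for b in part]
        if not all(b in nodesets for b in blocks):
            continue
        w = sum(la + gammaln(len(b)) for b in blocks)
        den.append(w)
        num.append(w + sum(tree.prior.log_marglik(X[sorted(b)]) for b in blocks))
    return logsumexp(num) - logsumexp(den)


def fitted_tagpct_tree(table, alpha=1.0):
    tagpct = tag_percent_normalize(table.subjects())
    Z = Scaler("pareto").fit_transform(tagpct.intensities.to_numpy())
    return bhc_fit(Z.T, alpha=alpha, labels=tagpct.feature_labels), tagpct


class TestRecursion:
    def test_three_item_evidence_matches_enumeration(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(3, 2))
        tree = bhc_fit(X, alpha=1.0)
        assert tree.log_evidence == pytest.approx(
            oracle_log_evidence(tree, X, 1.0), abs=1e-10
        )

    def test_single_item_tree_is_leaf(self):
        tree = bhc_fit(np.array([[1.0, 2.0]]))
        assert tree.root.is_leaf and tree.root.log_r is None

    def test_merge_posteriors_in_unit_interval(self, small_cohort):
        table, _ = small_cohort
        tree, _ = fitted_tagpct_tree(table)

        def walk(node):
            if node.is_leaf:
                return
            # r in (0, 1); underflow of the split term can round r to 0 or 1
            # in double precision, so the check is on the finite log posterior
            assert np.isfinite(node.log_r) and node.log_r <= 0.0
            assert 0.0 <= node.r <= 1.0
            walk(node.left)
            walk(node.right)

        walk(tree.root)

    def test_feature_order_permutation_gives_same_clusters(self, small_cohort):
        table, _ = small_cohort
        tagpct = tag_percent_normalize(table.subjects())
        Z = Scaler("pareto").fit_transform(tagpct.intensities.to_numpy()).T
        labels = tagpct.feature_labels
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(labels))
        a1 = bhc_cut(bhc_fit(Z, labels=labels), 0.5)
        a2 = bhc_cut(bhc_fit(Z[perm], labels=[labels[i] for i in perm]), 0.5)
        part1 = {frozenset(a1.members(c)) for c in set(a1.assignment.values())}
        part2 = {frozenset(a2.members(c)) for c in set(a2.assignment.values())}
        assert part1 == part2

    def test_cluster_count_monotone_in_alpha(self, small_cohort):
        table, _ = small_cohort
        counts = []
        for alpha in (1e-4, 1.0, 1e4, 1e8):
            tree, _ = fitted_tagpct_tree(table, alpha=alpha)
            counts.append(bhc_cut(tree, 0.5).n_clusters)
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_bad_prior_scatter_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            NiwPrior(np.zeros(2), 1.0, 4.0, np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match="positive definite"):
            NiwPrior(np.zeros(2), 1.0, 4.0, -np.eye(2))

    def test_diagonal_fallback_when_wide(self):
        X = np.random.default_rng(2).normal(size=(4, 50))
        prior = empirical_prior(X)
        assert prior.diagonal


class TestCut:
    def test_threshold_zero_single_cluster(self, small_cohort):
        table, _ = small_cohort
        tree, _ = fitted_tagpct_tree(table)
        assert bhc_cut(tree, 0.0).n_clusters == 1

    def test_threshold_above_one_all_singletons(self, small_cohort):
        table, _ = small_cohort
        tree, tagpct = fitted_tagpct_tree(table)
        assert bhc_cut(tree, 1.0 + 1e-9).n_clusters == tagpct.n_features

    def test_recovers_three_planted_clusters(self, small_cohort):
        table, _ = small_cohort
        tree, _ = fitted_tagpct_tree(table)
        assign = bhc_cut(tree, 0.5)
        truth = planted_tag_assignment()
        ari = adjusted_rand_score(
            [truth[f] for f in assign.labels], assign.as_array()
        )
        assert assign.n_clusters == 3 and ari >= 0.9


class TestSummaries:
    def test_single_cluster_share_is_one(self):
        table = tiny_table([[3.0, 7.0]], plates=["A"], qc_flags=[False],
                           columns=["TAG(50:1)", "TAG(52:2)"])
        from tagdnl.bhc import ClusterAssignment

        assign = ClusterAssignment(["TAG(50:1)", "TAG(52:2)"],
                                   {"TAG(50:1)": 1, "TAG(52:2)": 1})
        shares = cluster_share(assign, table)
        assert shares.loc[1] == pytest.approx(1.0)

    def test_two_cluster_share_arithmetic(self):
        table = tiny_table([[30.0, 70.0]], plates=["A"], qc_flags=[False],
                           columns=["TAG(50:1)", "TAG(52:2)"])
        from tagdnl.bhc import ClusterAssignment

        assign = ClusterAssignment(["TAG(50:1)", "TAG(52:2)"],
                                   {"TAG(50:1)": 1, "TAG(52:2)": 2})
        shares = cluster_share(assign, table)
        assert shares.loc[1] == pytest.approx(0.3)
        assert shares.loc[2] == pytest.approx(0.7)
        assert shares.sum() == pytest.approx(1.0)

    def test_planted_shares_recovered(self):
        """Generator with shares (0.30, 0.46, 0.14): realized cluster shares
        of total TAG intensity land within 0.03 of the planted values."""
        spec = CohortSpec(n_subjects=2000, n_plates=10,
                          cluster_shares=(0.30, 0.46, 0.14), seed=21)
        table, _ = generate_cohort(spec)
        from tagdnl.synthetic import TAG_CLUSTERS

        subj = table.subjects()
        tag_cols = [c for c in table.feature_labels if c.startswith("TAG")]
        total = subj.intensities[tag_cols].sum().sum()
        for name, target in zip(("dnl", "poly", "short"), spec.cluster_shares):
            got = subj.intensities[TAG_CLUSTERS[name]].sum().sum() / total
            assert got == pytest.approx(target, abs=0.03)

    def test_composition_arithmetic(self):
        from tagdnl.bhc import ClusterAssignment

        species = [parse_lipid_label(s)
                   for s in ("TAG(48:1)", "TAG(50:1)", "TAG(56:7)", "TAG(56:8)")]
        assign = ClusterAssignment(
            [s.label for s in species],
            {"TAG(48:1)": 1, "TAG(50:1)": 1, "TAG(56:7)": 2, "TAG(56:8)": 2},
        )
        comp = cluster_composition(assign, species)
        assert comp.loc[1, "mean_double_bonds"] == pytest.approx(1.0)
        assert comp.loc[1, "mean_carbons"] == pytest.approx(49.0)
        assert comp.loc[2, "mean_double_bonds"] == pytest.approx(7.5)
        assert label_dnl_cluster(comp) == 1

    def test_dnl_label_lands_on_planted_saturated_cluster(self):
        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            table, _ = generate_cohort(CohortSpec(n_subjects=200, n_plates=4, seed=seed))
            tree, tagpct = fitted_tagpct_tree(table)
            assign = bhc_cut(tree, 0.5)
            comp = cluster_composition(assign, tagpct.species)
            members = set(assign.members(label_dnl_cluster(comp)))
            truth = {f for f, c in planted_tag_assignment().items() if c == "dnl"}
            hits += members == truth
        assert hits >= 0.95 * n_rep

    def test_newick_export_parses(self, small_cohort):
        table, _ = small_cohort
        tree, tagpct = fitted_tagpct_tree(table)
        nwk = to_newick(tree)
        assert nwk.endswith(";") and nwk.count("(") == tagpct.n_features - 1
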