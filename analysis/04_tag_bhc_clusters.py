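"""Bayesian hierarchical clustering of the TAG profile.

TAG intensities are expressed per sample as percent of total TAG signal,
Pareto scaled, and clustered as features in sample-space. Cutting the merge
tree at posterior r < 0.5 should recover three clusters: a saturated /
monounsaturated 46-52-carbon cluster (the DNL cluster, ~30% of the TAG
signal), a long polyunsaturated cluster (~46%) and a short-chain cluster.
"""

import json
from pathlib import Path

from tagdnl.bhc import (
    bhc_cut,
    bhc_fit,
    cluster_composition,
    cluster_share,
    label_dnl_cluster,
    to_newick,
)
from tagdnl.containers import FeatureTable
from tagdnl.preprocess import Scaler, tag_percent_normalize

ROOT = Path(__file__).resolve().parents[1]


def main(alpha: float = 1.0, r_threshold: float = 0.5) -> None:
    data = ROOT / "results" / "data"
    out = ROOT / "results"
    table = FeatureTable.from_tsv(data / "normalized_features.tsv")
    tagpct = tag_percent_normalize(table.subjects())
    Z = Scaler("pareto").fit_transform(tagpct.intensities.to_numpy())
    tree = bhc_fit(Z.T, alpha=alpha, labels=tagpct.feature_labels)
    assign = bhc_cut(tree, r_threshold=r_threshold)
    shares = cluster_share(assign, table)
    comp = cluster_composition(assign, tagpct.species)
    dnl_cluster = label_dnl_cluster(comp)

    (out / "bhc_tree.nwk").write_text(to_newick(tree))
    assign.to_frame().to_csv(out / "bhc_assignment.tsv", sep="\t", index=False)
    comp.to_csv(out / "bhc_composition.tsv", sep="\t")
    (out / "bhc_shares.json").write_text(
        json.dumps({int(k): float(v) for k, v in shares.items()}, indent=1, sort_keys=True)
    )
    print(f"{assign.n_clusters} TAG clusters at r < {r_threshold}")
    for cid, row in comp.iterrows():
        tag = "  <- DNL cluster" if cid == dnl_cluster else ""
        print(f"  cluster {cid}: {int(row.n_species)} species, "
              f"mean C {row.mean_carbons:.1f}, mean DB {row.mean_double_bonds:.1f}, "
              f"share {shares[cid]:.1%}{tag}")
    members = ", ".join(assign.members(dnl_cluster))
    print(f"DNL-cluster members: {members}")


if __name__ == "__main__":
    main()
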