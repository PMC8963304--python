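"""Pathway analysis: dual bias-corrected enrichment over the significant
miRNA set, plus cluster-wise pathway-union enrichment and the pathways common
to every cluster.
"""
import argparse
import json
from pathlib import Path

import pandas as pd

from mirtox import enrichment, io


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument(
        "--sig", type=Path, default=Path("results/diffexp/sig_mirnas.txt")
    )
    parser.add_argument(
        "--clusters", type=Path, default=Path("results/clusters/clusters.tsv")
    )
    parser.add_argument(
        "--network", type=Path, default=Path("results/inputs/target_network.tsv")
    )
    parser.add_argument("--gmt", type=Path, default=Path("results/inputs/pathways.gmt"))
    parser.add_argument("--bh-alpha", type=float, default=0.01)
    parser.add_argument("--union-alpha", type=float, default=0.05)
    parser.add_argument("--out", type=Path, default=Path("results/enrichment"))
    args = parser.parse_args()

    sig = [l.strip() for l in args.sig.read_text().splitlines() if l.strip()]
    network = io.read_network(args.network)
    ontology = io.read_gmt(args.gmt)
    p1 = enrichment.enrich_targets_method1(sig, network, ontology)
    p2 = enrichment.enrich_mirna_sets_method2(sig, network, ontology)
    dual = enrichment.combine_dual(p1, p2, args.bh_alpha)

    clusters = pd.read_csv(args.clusters, sep="\t")
    cluster_sets = {}
    for label, grp in clusters[clusters["cluster"] > 0].groupby("cluster"):
        union = enrichment.pathway_union_enrichment(
            sorted(grp["mirna"]), network, ontology, args.union_alpha
        )
        cluster_sets[int(label)] = set(union.loc[union["significant"], "pathway"])
    common = enrichment.common_pathways(cluster_sets) if cluster_sets else []

    out = io.ensure_dir(args.out)
    dual.sort_values("pathway").to_csv(
        out / "enrichment.tsv", sep="\t", index=False, float_format=io.FLOAT_FORMAT
    )
    with open(out / "cluster_pathways.json", "w") as fh:
        json.dump(
            {
                "per_cluster_significant": {str(c): sorted(s) for c, s in cluster_sets.items()},
                "common_pathways": common,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    top = dual[dual["rank"] > 0].sort_values("rank").head(5)
    print(f"{int(dual['significant_both'].sum())} pathway(s) significant in both methods")
    for row in top.itertuples():
        print(f"  rank {row.rank}: {row.pathway} (combined p = {row.fisher_combined_p:.3g})")
    print(f"common to all clusters: {common or 'none'}")


if __name__ == "__main__":
    main()
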