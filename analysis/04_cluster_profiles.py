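"""Cluster significant miRNAs on their log2 fold-change profiles with UPGMA
and the adaptive (dynamic) dendrogram cut.
"""
import argparse
from pathlib import Path

import pandas as pd

from mirtox import clustering, io


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument(
        "--differential", type=Path, default=Path("results/diffexp/differential.tsv")
    )
    parser.add_argument("--min-cluster-size", type=int, default=3)
    parser.add_argument("--deep-split", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/clusters"))
    args = parser.parse_args()

    table = pd.read_csv(args.differential, sep="\t")
    if "mapped" in table.columns:
        table = table[table["mapped"]]
    profile = clustering.build_profile(table)
    z, leaves = clustering.average_linkage_dendrogram(profile)
    assignment = clustering.dynamic_tree_cut(z, leaves, args.min_cluster_size, args.deep_split)

    out = io.ensure_dir(args.out)
    assignment.labels.rename("cluster").reset_index().to_csv(
        out / "clusters.tsv", sep="\t", index=False
    )
    (out / "dendrogram.nwk").write_text(clustering.dendrogram_newick(z, leaves) + "\n")
    sizes = [len(assignment.members(c)) for c in range(1, assignment.n_clusters + 1)]
    print(f"{assignment.n_clusters} cluster(s) with sizes {sizes} over {len(leaves)} miRNAs")


if __name__ == "__main__":
    main()
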