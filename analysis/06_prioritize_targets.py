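"""Target prioritization: the validated-target funnel with neurological
annotation filters, direction prediction, and signaling-cascade tracing
through the interaction graph.
"""
import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from mirtox import io, targets


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument(
        "--differential", type=Path, default=Path("results/diffexp/differential.tsv")
    )
    parser.add_argument(
        "--network", type=Path, default=Path("results/inputs/target_network.tsv")
    )
    parser.add_argument(
        "--catalog", type=Path, default=Path("results/inputs/neuro_catalog.tsv")
    )
    parser.add_argument(
        "--interactions", type=Path, default=Path("results/inputs/interactions.tsv")
    )
    parser.add_argument("--max-cascade-len", type=int, default=4)
    parser.add_argument("--out", type=Path, default=Path("results/targets"))
    args = parser.parse_args()

    table = pd.read_csv(args.differential, sep="\t")
    sig_rows = table[table["significant"]]
    if "mapped" in table.columns:
        sig_rows = sig_rows[sig_rows["mapped"]]
    sig = sorted(sig_rows["mirna"].unique())
    mean_l2fc = (
        sig_rows.assign(l2=lambda d: np.log2(d["fold_change"]))
        .groupby("mirna")["l2"].mean().to_dict()
    )
    network = io.read_network(args.network)
    survivors, audit = targets.prioritize_targets(
        sig, mean_l2fc, network, io.read_catalog(args.catalog)
    )
    ttable = targets.targets_table(survivors)

    graph = io.read_interactions(args.interactions)
    nodes = set(graph.graph.nodes)
    seeds = sorted(set(ttable["gene"]) & nodes)
    cascades = (
        targets.trace_cascades(graph, seeds, seeds, args.max_cascade_len) if seeds else []
    )
    edges, node_table = targets.merge_cascades(
        cascades, graph, notable_mirnas_by_gene={t.gene: t.supporting_mirnas for t in survivors}
    )

    out = io.ensure_dir(args.out)
    ttable.to_csv(out / "prioritized_targets.tsv", sep="\t", index=False)
    audit.to_csv(out / "target_audit.tsv", sep="\t", index=False)
    edges.to_csv(out / "cascade_network.tsv", sep="\t", index=False)
    node_table.to_csv(out / "cascade_nodes.tsv", sep="\t", index=False)
    print(
        f"{len(sig)} significant miRNA(s) -> {len(ttable)} prioritized target(s), "
        f"{len(cascades)} cascade(s), {len(edges)} merged edge(s)"
    )


if __name__ == "__main__":
    main()
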