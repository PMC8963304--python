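"""Generate the synthetic study inputs for one seed.

Writes the Ct matrix + sample sheet, apical endpoint wells, miRNA-target
network, pathway GMT, assay annotation, neurological catalog, and interaction
graph under results/inputs.
"""
import argparse
from pathlib import Path

from mirtox import io, pipeline


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results/inputs"))
    args = parser.parse_args()

    cfg = pipeline.PipelineConfig(seed=args.seed)
    scenario = pipeline.build_scenario(cfg)
    out = io.ensure_dir(args.out)
    io.write_ct_matrix(scenario.ct.ct, out / "ct_matrix.csv", out / "samples.tsv")
    io.write_apical(scenario.apical_records, out / "apical.csv")
    io.write_network(scenario.network, out / "target_network.tsv")
    io.write_gmt(scenario.ontology, out / "pathways.gmt")
    io.write_annotation(scenario.annotation, out / "mirna_annotation.tsv")
    io.write_catalog(scenario.catalog, out / "neuro_catalog.tsv")
    io.write_interactions(scenario.interactions, out / "interactions.tsv")
    (out / "spiked_mirnas.txt").write_text("\n".join(scenario.spiked_mirnas) + "\n")
    print(f"wrote inputs for seed {args.seed} to {out}")


if __name__ == "__main__":
    main()
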