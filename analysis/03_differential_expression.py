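"""Differential miRNA expression: detection-limit capping, plate-mean
normalization, paired t-tests with the joint fold-change + raw-p filter, and
annotation mapping of the significant panel assays.
"""
import argparse
from pathlib import Path

from mirtox import diffexp, io


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--ct", type=Path, default=Path("results/inputs/ct_matrix.csv"))
    parser.add_argument("--samples", type=Path, default=Path("results/inputs/samples.tsv"))
    parser.add_argument(
        "--annotation", type=Path, default=Path("results/inputs/mirna_annotation.tsv")
    )
    parser.add_argument("--out", type=Path, default=Path("results/diffexp"))
    args = parser.parse_args()

    ct = io.read_ct_matrix(args.ct, args.samples)
    capped = diffexp.cap_detection_limit(ct)
    table = diffexp.differential_table(diffexp.mean_center_normalize(capped), capped)
    amap, retained = diffexp.map_annotations(
        sorted(table.loc[table["significant"], "mirna"].unique()),
        io.read_annotation(args.annotation),
    )
    table["mapped"] = table["mirna"].isin(retained)
    sig = sorted(set(table.loc[table["significant"], "mirna"]) & set(retained))

    out = io.ensure_dir(args.out)
    table.to_csv(out / "differential.tsv", sep="\t", index=False, float_format=io.FLOAT_FORMAT)
    amap.to_csv(out / "annotation_map.tsv", sep="\t", index=False)
    (out / "sig_mirnas.txt").write_text("\n".join(sig) + "\n")
    print(
        f"{table.loc[table['significant'], 'mirna'].nunique()} significant miRNA(s), "
        f"{len(sig)} after annotation mapping"
    )


if __name__ == "__main__":
    main()
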