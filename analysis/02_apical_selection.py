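"""Apical endpoint analysis: percent-of-control normalization, Dunnett
many-to-one tests per chemical/endpoint, endpoint correlations, and the
low/high test-concentration selection rule.
"""
import argparse
from pathlib import Path

import pandas as pd

from mirtox import apical, io


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--records", type=Path, default=Path("results/inputs/apical.csv"))
    parser.add_argument("--alpha", type=float, default=0.05)
    parser.add_argument("--out", type=Path, default=Path("results/apical"))
    args = parser.parse_args()

    records = io.read_apical(args.records)
    normalized = apical.normalize_percent_of_control(records)
    dn = apical.dunnett_all(normalized)
    pairs = apical.select_concentrations(dn, args.alpha)
    corr = apical.correlate_endpoints(apical.endpoint_log2_foldchanges(normalized))

    out = io.ensure_dir(args.out)
    dn.to_csv(out / "dunnett.tsv", sep="\t", index=False, float_format=io.FLOAT_FORMAT)
    corr.to_csv(out / "endpoint_correlations.tsv", sep="\t", index=False,
                float_format=io.FLOAT_FORMAT)
    pd.DataFrame(
        [
            (c, p.low if p.low is not None else "", p.high, p.low_rationale, p.high_rationale)
            for c, p in sorted(pairs.items())
        ],
        columns=["chemical", "low_uM", "high_uM", "low_rationale", "high_rationale"],
    ).to_csv(out / "concentration_pairs.tsv", sep="\t", index=False)
    for chem, pair in sorted(pairs.items()):
        print(f"{chem}: low={pair.low} high={pair.high}")


if __name__ == "__main__":
    main()
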