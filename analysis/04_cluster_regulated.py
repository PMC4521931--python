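#!/usr/bin/env python
"""Hierarchically cluster the regulated proteins' z-score profiles.

Builds the (protein x channel) z matrix for proteins reaching the 95%
tier in either channel, clusters rows and columns (Euclidean, average
linkage), and writes the heat map, Newick dendrograms and reordered TSV.
"""

import argparse
from pathlib import Path

import pandas as pd

from silacq import clustering


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--records", type=Path, default=Path("results/regulation_calls.tsv"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    records = pd.read_csv(args.records, sep="\t")
    reg = records[(records["tier_ml"] >= 95.0) | (records["tier_hl"] >= 95.0)]
    mat = reg.set_index("protein")[["z_ml", "z_hl"]]
    result = clustering.cluster(mat, axis="both")

    args.out_dir.mkdir(parents=True, exist_ok=True)
    clustering.render_heatmap(
        result, str(args.out_dir / "heatmap.png"), str(args.out_dir / "heatmap.tsv")
    )
    (args.out_dir / "rows.nwk").write_text(
        clustering.to_newick(result.row_linkage, result.row_labels) + "\n"
    )
    (args.out_dir / "cols.nwk").write_text(
        clustering.to_newick(result.col_linkage, result.col_labels) + "\n"
    )
    print(f"clustered {mat.shape[0]} regulated proteins x {mat.shape[1]} channels")


if __name__ == "__main__":
    main()
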