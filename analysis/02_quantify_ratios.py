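#!/usr/bin/env python
"""Aggregate peptide evidence into per-protein M/L and H/L ratio averages.

Applies the 6-residue length filter, takes the median peptide intensity
ratio per protein and replicate, and keeps proteins quantified in both
replicates (the replicate-intersection rule that retained 1766 of 3721
proteins, 47.5%, in the cell-line study).
"""

import argparse
from pathlib import Path

from silacq import io, quantify


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--evidence", type=Path, default=Path("results/sim/evidence.tsv"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    evidence = io.read_evidence(args.evidence)
    n_total = evidence["protein"].nunique()
    filtered = quantify.filter_evidence(evidence, min_length=6)
    per_rep = quantify.aggregate_evidence(quantify.peptide_ratios(filtered))
    merged = quantify.merge_replicates(per_rep, required_replicates=2)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    io.write_records(per_rep, args.out_dir / "protein_ratios_per_replicate.tsv")
    io.write_records(merged, args.out_dir / "protein_ratios.tsv")
    print(
        f"{len(filtered)}/{len(evidence)} evidence rows pass the length filter; "
        f"{len(merged)}/{n_total} proteins quantified in both replicates "
        f"({100 * len(merged) / n_total:.1f}%)"
    )


if __name__ == "__main__":
    main()
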