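#!/usr/bin/env python
"""Simulate the default synthetic study and write it to disk.

Produces a toy reference genome, methylation / replication-timing /
gene-strand / replication-direction tracks, one PASS-only VCF per tumour, a
per-mutation truth table, and a tumour metadata table under --study-dir
(scratch/study by default; the VCFs are bulky and regenerable, so they stay
out of results/).  A compact cohort summary goes to results/.
"""

import argparse
from pathlib import Path

from mmrspect import signatures, simulate


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--study-dir", default="scratch/study")
    ap.add_argument("--results", default="results")
    args = ap.parse_args()

    sigs = signatures.load_signature_matrix()
    cfg = simulate.study_config(seed=args.seed)
    genome, tracks, mutations, meta = simulate.simulate_study(
        cfg, sigs, out_dir=args.study_dir)

    res = Path(args.results)
    res.mkdir(parents=True, exist_ok=True)
    summary = meta.groupby("group").agg(
        n=("purity", "size"), median_burden=("n_mutations", "median"),
        median_purity=("purity", "median"))
    summary.to_csv(res / "cohort_summary.tsv", sep="\t")
    print(f"wrote study to {args.study_dir} "
          f"({len(mutations):,} mutations, {len(meta)} tumours)")
    print(summary)


if __name__ == "__main__":
    main()
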