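#!/usr/bin/env python
"""CpG>TpG mutation rates across methylation and replication-timing bins.

Bins every CpG site and every CpG>TpG mutation by the local track value
(decile edges), normalises to mutations per million CpG sites, tests each
group for an ordered trend (Jonckheere-Terpstra), and compares per-sample
regression slopes between groups.
"""

import argparse
from pathlib import Path

import pandas as pd

from mmrspect import binning, core_io


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--study-dir", default="scratch/study")
    ap.add_argument("--results", default="results")
    args = ap.parse_args()

    study = Path(args.study_dir)
    genome = core_io.ReferenceGenome.from_fasta(study / "genome.fa")
    meta = pd.read_csv(study / "metadata.tsv", sep="\t", index_col="sample")
    muts = pd.concat([
        core_io.read_vcf(study / "vcf" / f"{s}.vcf", sample=s)
        for s in meta.index], ignore_index=True)

    res = Path(args.results)
    res.mkdir(parents=True, exist_ok=True)
    for feature, fname in (("methylation", "methylation.bedgraph"),
                           ("replication_timing",
                            "replication_timing.bedgraph")):
        track = core_io.read_track(study / fname, kind=feature)
        edges = binning.decile_edges(track.df["value"].to_numpy())
        rates = binning.per_sample_rates(muts, genome, track, edges)
        groups = meta.loc[rates.index, "group"]
        jt, slopes, between = binning.trend_and_slope(rates, groups)
        rates.to_csv(res / f"rates_{feature}.tsv", sep="\t")
        jt.to_csv(res / f"trend_{feature}.tsv", sep="\t")
        slopes.to_csv(res / f"slopes_{feature}.tsv", sep="\t")
        print(f"== {feature} ==")
        print(jt)
        med = slopes.groupby("group")["slope"].median().round(1)
        print("median slope per group:")
        print(med)
        for (ga, gb), t in between.items():
            print(f"slopes {ga} vs {gb}: rank-sum p={t.p_value:.3g}")


if __name__ == "__main__":
    main()
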