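"""Binning of CpG>TpG mutations by methylation state or replication timing,
normalised by the CpG content of each bin.

Rates follow M_x / (N_x / 1e6): mutations per million CpG sites, where N_x
counts the CpG dinucleotides (plus-strand CG) whose track value falls in bin
x and M_x the CpG>TpG mutations at such sites.  Bins are half-open on the
left, with the final bin closed so the top of the range is counted; default
edges are deciles of the observed track values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GenomeIntervals, ReferenceGenome, positions_in_intervals, \
    snv_mask
from .stats import TestResult, jonckheere_terpstra, rank_sum
from .strand import categorize_ct

logger = logging.getLogger(__name__)


@dataclass
class BinnedRates:
    edges: np.ndarray
    midpoints: np.ndarray
    M: np.ndarray  # mutations per bin
    N: np.ndarray  # CpG sites per bin
    rate: np.ndarray  # mutations per million CpG sites

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"midpoint": self.midpoints, "M": self.M,
                             "N": self.N, "rate": self.rate})


def decile_edges(values: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Quantile bin edges over observed track values (default deciles)."""
    qs = np.linspace(0, 1, n_bins + 1)
    edges = np.quantile(np.asarray(values, float), qs)
    return np.unique(edges)


def _bin_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open bins [e_i, e_{i+1}); the last bin includes its upper edge.
    Values outside the range return -1."""
    v = np.asarray(values, float)
    idx = np.searchsorted(edges, v, side="right") - 1
    idx = np.where(v == edges[-1], len(edges) - 2, idx)
    out_of_range = (v < edges[0]) | (v > edges[-1])
    return np.where(out_of_range, -1, idx).astype(np.int64)


def cpg_positions(genome: ReferenceGenome, chrom: str) -> np.ndarray:
    """1-based positions of the C of every plus-strand CG dinucleotide."""
    codes = genome.base_codes(chrom)
    is_cg = (codes[:-1] == 1) & (codes[1:] == 2)
    return np.nonzero(is_cg)[0] + 1


def track_values_at(track: GenomeIntervals, chrom: str,
                    pos: np.ndarray) -> np.ndarray:
    """Track value at each 1-based position; NaN where uncovered."""
    per = track.per_chrom()
    out = np.full(len(pos), np.nan)
    if chrom in per:
        iv = per[chrom]
        idx = positions_in_intervals(pos, iv["start"].to_numpy(),
                                     iv["end"].to_numpy())
        vals = iv["value"].to_numpy(float)
        ok = idx >= 0
        out[ok] = vals[idx[ok]]
    return out


def count_cpg_sites(genome: ReferenceGenome, track: GenomeIntervals,
                    bin_edges: np.ndarray) -> np.ndarray:
    """N_x: CpG dinucleotides per bin of the track value at their C.

    CpGs without track coverage are uncounted (logged).
    """
    n_bins = len(bin_edges) - 1
    counts = np.zeros(n_bins, dtype=np.int64)
    n_uncovered = 0
    for chrom in genome.chromosomes:
        pos = cpg_positions(genome, chrom)
        vals = track_values_at(track, chrom, pos)
        covered = ~np.isnan(vals)
        n_uncovered += int((~covered).sum())
        idx = _bin_index(vals[covered], bin_edges)
        counts += np.bincount(idx[idx >= 0], minlength=n_bins)
    if n_uncovered:
        logger.info("count_cpg_sites: %d CpG sites without track coverage",
                    n_uncovered)
    return counts


def bin_mutations(mutations: pd.DataFrame, genome: ReferenceGenome,
                  track: GenomeIntervals, bin_edges: np.ndarray,
                  category: str = "CpG>TpG") -> np.ndarray:
    """M_x: category mutations per bin of the track value at their site.

    For CpG>TpG calls the binning value is looked up at the C of the CpG
    (the position itself for C>T calls, position-1 for G>A calls, whose
    pyrimidine lies on the minus strand).
    """
    n_bins = len(bin_edges) - 1
    counts = np.zeros(n_bins, dtype=np.int64)
    if mutations.empty:
        return counts
    snvs = mutations[snv_mask(mutations)].reset_index(drop=True)
    cats = categorize_ct(snvs, genome)
    sel = snvs[cats == category]
    for chrom, grp in sel.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(np.int64)
        if category == "CpG>TpG":
            pos = np.where(grp["ref"].to_numpy() == "G", pos - 1, pos)
        vals = track_values_at(track, chrom, pos)
        covered = ~np.isnan(vals)
        idx = _bin_index(vals[covered], bin_edges)
        counts += np.bincount(idx[idx >= 0], minlength=n_bins)
    return counts


def normalized_rates(M: np.ndarray, N: np.ndarray,
                     bin_edges: np.ndarray) -> BinnedRates:
    """Mutations per million CpG sites per bin; N=0 bins report NaN."""
    M = np.asarray(M, float)
    N = np.asarray(N, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(N > 0, M / (N / 1e6), np.nan)
    edges = np.asarray(bin_edges, float)
    mid = (edges[:-1] + edges[1:]) / 2
    return BinnedRates(edges=edges, midpoints=mid, M=M.astype(np.int64),
                       N=N.astype(np.int64), rate=rate)


def per_sample_rates(mutations: pd.DataFrame, genome: ReferenceGenome,
                     track: GenomeIntervals, bin_edges: np.ndarray,
                     category: str = "CpG>TpG") -> pd.DataFrame:
    """Samples x bins rate table (shared N_x across samples)."""
    N = count_cpg_sites(genome, track, bin_edges)
    rows = {}
    for sample, grp in mutations.groupby("sample", sort=False):
        M = bin_mutations(grp.reset_index(drop=True), genome, track,
                          bin_edges, category)
        rows[sample] = normalized_rates(M, N, bin_edges).rate
    mid = (np.asarray(bin_edges)[:-1] + np.asarray(bin_edges)[1:]) / 2
    return pd.DataFrame(rows, index=mid).T


def trend_and_slope(rates: pd.DataFrame,
                    groups: pd.Series) -> tuple[pd.DataFrame, pd.DataFrame,
                                                dict[tuple, TestResult]]:
    """Trend tests and per-sample regression slopes of rate on bin midpoint.

    ``rates``: samples x ordered-bin-midpoint table; ``groups``: group label
    per sample.  Returns (per-group JT results, per-sample OLS slope /
    intercept table, between-group rank-sum on slopes for each group pair).
    """
    if rates.shape[1] < 3:
        raise ValueError("need at least three ordered bins")
    jt_rows = []
    for g, samples in groups.groupby(groups):
        sub = rates.loc[samples.index]
        ordered = [sub[c].dropna().to_numpy() for c in rates.columns]
        res = jonckheere_terpstra(ordered, sided="greater")
        jt_rows.append({"group": g, "statistic": res.statistic,
                        "p_value": res.p_value, "method": res.method})
    mids = rates.columns.to_numpy(float)
    slope_rows = []
    for sample, row in rates.iterrows():
        y = row.to_numpy(float)
        ok = ~np.isnan(y)
        slope, intercept = np.polyfit(mids[ok], y[ok], 1) if ok.sum() >= 2 \
            else (np.nan, np.nan)
        slope_rows.append({"sample": sample, "group": groups[sample],
                           "slope": slope, "intercept": intercept})
    slopes = pd.DataFrame(slope_rows).set_index("sample")
    between = {}
    gnames = list(dict.fromkeys(groups))
    for i, ga in enumerate(gnames):
        for gb in gnames[i + 1:]:
            between[(ga, gb)] = rank_sum(
                slopes.loc[slopes["group"] == ga, "slope"].dropna(),
                slopes.loc[slopes["group"] == gb, "slope"].dropna())
    return pd.DataFrame(jt_rows).set_index("group"), slopes, between
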