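"""Transcription- and replication-strand assignment of C>T mutations and the
per-tumour log2 strand-bias ratios.

All assignments reason about where the mutated pyrimidine sits.  A C>T call
has its pyrimidine (the reference C) on the plus strand; a G>A call is the
same substitution with the pyrimidine on the minus strand.

Transcription: a mutation inside genes annotated on exactly one strand is
"coding" when its pyrimidine lies on the gene's sense strand, else
"template"; positions under genes on both strands, or under none, are
excluded.

Replication: 20-kb regions carry a left/right-replicating label derived from
replication-origin maps.  Under the default convention a right-replicating
region has the minus strand as the leading-strand template, so a C>T with
its C on the plus strand is assigned "lagging" there and "leading" in a
left-replicating region; G>A mirrors this.  The convention is deliberately
concentrated in ONE predicate (:func:`_leading_for_plus_pyrimidine`) and can
be inverted with ``flip_convention=True``; outputs record which convention
produced them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GenomeIntervals, ReferenceGenome, positions_in_intervals
from .spectra import trinucleotide_codes
from .stats import TestResult, rank_sum, signed_rank

CATEGORIES = ("CpG>TpG", "non-CpG C>T", "all SBS")


@dataclass
class StrandCounts:
    sample: str
    category: str
    leading: int = 0
    lagging: int = 0
    coding: int = 0
    template: int = 0
    unassigned_replication: int = 0
    excluded_transcription: int = 0
    convention_flipped: bool = False


@dataclass
class ExpectedBias:
    base_log2: float
    neutral_fraction: float
    expected_log2: float


def _pyrimidine_on_plus(ref: pd.Series) -> np.ndarray:
    """True where the mutated pyrimidine lies on the plus strand."""
    return ref.isin(["C", "T"]).to_numpy()


def _leading_for_plus_pyrimidine(region_label: np.ndarray,
                                 flip: bool = False) -> np.ndarray:
    """The ONE home of the replication-strand convention.

    For a pyrimidine on the plus strand: left-replicating -> leading,
    right-replicating -> lagging.  ``flip`` inverts the convention.
    """
    leading = region_label == "left"
    return ~leading if flip else leading


def categorize_ct(mutations: pd.DataFrame, genome: ReferenceGenome) -> pd.Series:
    """Category per SNV row: 'CpG>TpG', 'non-CpG C>T' (covers C>T and G>A
    calls), or 'other'."""
    out = pd.Series("other", index=mutations.index, dtype=object)
    ct_plus = (mutations["ref"] == "C") & (mutations["alt"] == "T")
    ct_minus = (mutations["ref"] == "G") & (mutations["alt"] == "A")
    is_ct = ct_plus | ct_minus
    if not is_ct.any():
        return out
    sub = mutations[is_ct]
    codes = trinucleotide_codes(genome, sub.reset_index(drop=True))
    b5 = codes // 16
    b3 = codes % 4
    # CpG: C on plus followed by G (3' G, code 2); G on minus preceded by C
    # on plus (5' base C, code 1).  N-context (code 64) -> non-CpG bucket.
    plus = _pyrimidine_on_plus(sub["ref"])
    valid = codes < 64
    cpg = np.where(plus, b3 == 2, b5 == 1) & valid
    out.loc[sub.index] = np.where(cpg, "CpG>TpG", "non-CpG C>T")
    return out


def assign_transcription_strand(mutations: pd.DataFrame,
                                genes: GenomeIntervals) -> pd.Series:
    """Per-row assignment: coding / template / excluded."""
    out = pd.Series("excluded", index=mutations.index, dtype=object)
    gene_chroms = genes.per_chrom()
    for chrom, grp in mutations.groupby("chrom", sort=False):
        if chrom not in gene_chroms:
            continue
        iv = gene_chroms[chrom]
        pos = grp["pos"].to_numpy()
        on_plus_gene = _covered(pos, iv[iv["strand"] == "+"])
        on_minus_gene = _covered(pos, iv[iv["strand"] == "-"])
        single = on_plus_gene ^ on_minus_gene
        gene_plus = on_plus_gene & single
        pyr_plus = _pyrimidine_on_plus(grp["ref"])
        coding = single & (pyr_plus == gene_plus)
        vals = np.where(single, np.where(coding, "coding", "template"),
                        "excluded")
        out.loc[grp.index] = vals
    return out


def _covered(pos: np.ndarray, iv: pd.DataFrame) -> np.ndarray:
    if len(iv) == 0:
        return np.zeros(len(pos), dtype=bool)
    merged = GenomeIntervals(iv[["chrom", "start", "end"]], kind="region").merged()
    df = merged.df
    return positions_in_intervals(pos, df["start"].to_numpy(),
                                  df["end"].to_numpy()) >= 0


def assign_replication_strand(mutations: pd.DataFrame,
                              repl: GenomeIntervals,
                              flip_convention: bool = False) -> pd.Series:
    """Per-row assignment: leading / lagging / unassigned."""
    if repl.kind != "replication_direction":
        raise ValueError("need a replication_direction track")
    out = pd.Series("unassigned", index=mutations.index, dtype=object)
    per_chrom = repl.per_chrom()
    for chrom, grp in mutations.groupby("chrom", sort=False):
        if chrom not in per_chrom:
            continue
        iv = per_chrom[chrom]
        idx = positions_in_intervals(grp["pos"].to_numpy(),
                                     iv["start"].to_numpy(),
                                     iv["end"].to_numpy())
        labels = iv["label"].to_numpy(object)
        assigned = idx >= 0
        region = np.where(assigned, labels[np.clip(idx, 0, None)], "")
        pyr_plus = _pyrimidine_on_plus(grp["ref"])
        lead_plus = _leading_for_plus_pyrimidine(region, flip_convention)
        leading = np.where(pyr_plus, lead_plus, ~lead_plus)
        vals = np.where(assigned, np.where(leading, "leading", "lagging"),
                        "unassigned")
        out.loc[grp.index] = vals
    return out


def strand_counts(mutations: pd.DataFrame, genome: ReferenceGenome,
                  repl: GenomeIntervals, genes: GenomeIntervals | None = None,
                  flip_convention: bool = False) -> pd.DataFrame:
    """Per-sample, per-category leading/lagging (and coding/template) counts.

    Categories: the four-way CpG>TpG vs non-CpG C>T split of C>T calls, plus
    'all SBS' over every SNV.
    """
    from .core_io import snv_mask

    snvs = mutations[snv_mask(mutations)].reset_index(drop=True)
    cat = categorize_ct(snvs, genome)
    repl_side = assign_replication_strand(snvs, repl, flip_convention)
    trx_side = (assign_transcription_strand(snvs, genes)
                if genes is not None else pd.Series("excluded",
                                                    index=snvs.index))
    rows = []
    for sample, grp in snvs.groupby("sample", sort=False):
        for category in CATEGORIES:
            sel = grp.index if category == "all SBS" \
                else grp.index[cat[grp.index] == category]
            r = repl_side[sel]
            tx = trx_side[sel]
            rows.append(StrandCounts(
                sample=sample, category=category,
                leading=int((r == "leading").sum()),
                lagging=int((r == "lagging").sum()),
                coding=int((tx == "coding").sum()),
                template=int((tx == "template").sum()),
                unassigned_replication=int((r == "unassigned").sum()),
                excluded_transcription=int((tx == "excluded").sum()),
                convention_flipped=flip_convention,
            ).__dict__)
    return pd.DataFrame(rows)


def strand_log_ratio(leading: int, lagging: int) -> float:
    """log2(leading/lagging); zero on either side yields NaN (sample
    excluded from that summary)."""
    if leading <= 0 or lagging <= 0:
        return float("nan")
    return float(np.log2(leading / lagging))


def add_log_ratios(counts: pd.DataFrame) -> pd.DataFrame:
    counts = counts.copy()
    counts["log2_leading_lagging"] = [
        strand_log_ratio(le, la)
        for le, la in zip(counts["leading"], counts["lagging"])
    ]
    if "coding" in counts and "template" in counts:
        counts["log2_coding_template"] = [
            strand_log_ratio(c, t)
            for c, t in zip(counts["coding"], counts["template"])
        ]
    return counts


def expected_admixture_bias(base_log2: float,
                            neutral_fraction: float) -> ExpectedBias:
    """Expected log2(leading/lagging) when a fraction f of mutations is
    strand-neutral and the rest carry the base bias.

    With p = 2^b / (1 + 2^b) the leading share of the biased component,
    expected log2 = log2((f/2 + (1-f)p) / (f/2 + (1-f)(1-p))): the identity
    at f=0, exactly zero at f=1, and strictly decreasing in f for b > 0.
    """
    f = neutral_fraction
    if not (0 <= f <= 1):
        raise ValueError("neutral fraction must lie in [0, 1]")
    p = 2.0 ** base_log2 / (1.0 + 2.0 ** base_log2)
    num = f / 2 + (1 - f) * p
    den = f / 2 + (1 - f) * (1 - p)
    return ExpectedBias(base_log2=base_log2, neutral_fraction=f,
                        expected_log2=float(np.log2(num / den)))


def compare_strand_bias(group_a: pd.DataFrame, group_b: pd.DataFrame,
                        category: str = "CpG>TpG") -> dict[str, TestResult]:
    """The strand-bias test battery for one category.

    within_a / within_b: Wilcoxon signed-rank of per-sample (leading,
    lagging) count pairs; between: rank-sum of per-sample log2 ratios
    (NaN-ratio samples excluded, i.e. zero on either strand).
    """
    a = add_log_ratios(group_a[group_a["category"] == category])
    b = add_log_ratios(group_b[group_b["category"] == category])
    out = {
        "within_a": signed_rank(a[["leading", "lagging"]].to_numpy(float)),
        "within_b": signed_rank(b[["leading", "lagging"]].to_numpy(float)),
    }
    ra = a["log2_leading_lagging"].dropna()
    rb = b["log2_leading_lagging"].dropna()
    out["between"] = rank_sum(ra, rb)
    return out


def paired_category_bias(counts: pd.DataFrame, cat_a: str = "CpG>TpG",
                         cat_b: str = "non-CpG C>T") -> TestResult:
    """Signed-rank of paired per-sample log2 ratios between two categories
    within one group (e.g. CpG>TpG vs non-CpG C>T)."""
    wide = add_log_ratios(counts).pivot_table(
        index="sample", columns="category", values="log2_leading_lagging")
    paired = wide[[cat_a, cat_b]].dropna()
    return signed_rank(paired.to_numpy(float))
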