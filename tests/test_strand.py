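import numpy as np
import pandas as pd
import pytest

from mmrspect import core_io, strand
from mmrspect.core_io import GenomeIntervals, ReferenceGenome
from mmrspect.strand import (add_log_ratios, assign_replication_strand,
                             assign_transcription_strand, compare_strand_bias,
                             expected_admixture_bias, strand_counts,
                             strand_log_ratio)


def _muts(rows):
    return core_io.validate_mutations(
        pd.DataFrame(rows, columns=core_io.MUTATION_COLUMNS))


def _genes(rows):
    return GenomeIntervals(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "label",
                                    "strand"]), kind="gene")


def _repl(rows):
    return GenomeIntervals(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]),
        kind="replication_direction")


def test_transcription_strand_assignment():
    genes = _genes([("1", 0, 100, "gplus", "+"), ("1", 200, 300, "gminus", "-"),
                    ("1", 400, 500, "both_a", "+"), ("1", 400, 500, "both_b", "-")])
    df = _muts([
        ("1", 50, "C", "T", "s"),    # pyrimidine on plus inside + gene
        ("1", 60, "G", "A", "s"),    # pyrimidine on minus inside + gene
        ("1", 250, "C", "T", "s"),   # pyrimidine on plus inside - gene
        ("1", 450, "C", "T", "s"),   # covered by genes on both strands
        ("1", 150, "C", "T", "s"),   # intergenic
    ])
    out = assign_transcription_strand(df, genes)
    assert list(out) == ["coding", "template", "template", "excluded",
                         "excluded"]


def test_replication_strand_convention_and_flip():
    repl = _repl([("1", 0, 100, "left"), ("1", 100, 200, "right")])
    df = _muts([
        ("1", 50, "C", "T", "s"),    # C on plus, left-replicating
        ("1", 150, "C", "T", "s"),   # C on plus, right-replicating
        ("1", 50, "G", "A", "s"),    # C on minus, left-replicating
        ("1", 250, "C", "T", "s"),   # outside classified regions
    ])
    out = assign_replication_strand(df, repl)
    assert list(out) == ["leading", "lagging", "lagging", "unassigned"]
    flipped = assign_replication_strand(df, repl, flip_convention=True)
    assert list(flipped) == ["lagging", "leading", "leading", "unassigned"]


def test_label_involution_swaps_leading_and_lagging(default_cohort):
    muts = default_cohort["mutations"]
    sub = muts[muts["sample"] == muts["sample"].iloc[0]].head(4000)
    repl = default_cohort["tracks"]["replication_direction"]
    swapped_df = repl.df.copy()
    swapped_df["label"] = swapped_df["label"].map(
        {"left": "right", "right": "left"})
    swapped = GenomeIntervals(swapped_df, kind="replication_direction")
    a = assign_replication_strand(sub, repl)
    b = assign_replication_strand(sub, swapped)
    assert ((a == "leading") == (b == "lagging")).all()
    assert ((a == "unassigned") == (b == "unassigned")).all()


def test_counts_conserve_totals(default_cohort):
    muts = default_cohort["mutations"]
    sample = muts["sample"].iloc[0]
    sub = muts[muts["sample"] == sample]
    counts = strand_counts(sub, default_cohort["genome"],
                           default_cohort["tracks"]["replication_direction"])
    allsbs = counts[counts["category"] == "all SBS"].iloc[0]
    assert allsbs["leading"] + allsbs["lagging"] + \
        allsbs["unassigned_replication"] == len(sub)
    cpg = counts[counts["category"] == "CpG>TpG"].iloc[0]
    noncpg = counts[counts["category"] == "non-CpG C>T"].iloc[0]
    for row in (cpg, noncpg):
        assert row["leading"] + row["lagging"] + \
            row["unassigned_replication"] > 0


def test_strand_log_ratio_values():
    assert strand_log_ratio(100, 100) == pytest.approx(0.0)
    assert strand_log_ratio(200, 100) == pytest.approx(1.0)
    # the published dMutSα median leading/lagging counts
    assert strand_log_ratio(6704, 5959) == pytest.approx(0.1699, abs=5e-4)
    assert np.isnan(strand_log_ratio(0, 10))


def test_expected_admixture_bias_limits_and_value():
    assert expected_admixture_bias(0.172, 0.0).expected_log2 == \
        pytest.approx(0.172)
    assert expected_admixture_bias(0.172, 1.0).expected_log2 == \
        pytest.approx(0.0, abs=1e-12)
    # closed form at the reported mixture: ~0.105
    assert expected_admixture_bias(0.172, 0.39).expected_log2 == \
        pytest.approx(0.1048, abs=1e-3)


def test_expected_bias_strictly_decreasing_in_neutral_fraction():
    fs = np.linspace(0, 1, 51)
    vals = [expected_admixture_bias(0.25, f).expected_log2 for f in fs]
    assert np.all(np.diff(vals) < 0)


def _counts_frame(rng, n, log2_bias, total=2000, group="g"):
    p = 2.0 ** log2_bias / (1 + 2.0 ** log2_bias)
    rows = []
    for i in range(n):
        lead = rng.binomial(total, p)
        rows.append({"sample": f"{group}{i}", "category": "CpG>TpG",
                     "leading": lead, "lagging": total - lead})
    return pd.DataFrame(rows)


def test_compare_strand_bias_detects_injected_bias():
    rng = np.random.default_rng(0)
    biased = _counts_frame(rng, 30, 0.25)
    null = _counts_frame(rng, 30, 0.0, group="h")
    res = compare_strand_bias(biased, null)
    assert res["within_a"].p_value < 0.01
    assert res["between"].p_value < 0.01


def test_compare_strand_bias_no_bias_gives_p_one():
    rows = [{"sample": f"s{i}", "category": "CpG>TpG",
             "leading": 500, "lagging": 500} for i in range(10)]
    df = pd.DataFrame(rows)
    res = compare_strand_bias(df, df)
    assert res["within_a"].p_value == pytest.approx(1.0)


def test_rank_sum_type_one_error_on_null_strand_ratios():
    """Same-distribution per-sample ratios reject at roughly the nominal
    rate."""
    rng = np.random.default_rng(1)
    rejections = 0
    reps = 400
    for _ in range(reps):
        a = _counts_frame(rng, 12, 0.1)
        b = _counts_frame(rng, 12, 0.1, group="h")
        if compare_strand_bias(a, b)["between"].p_value <= 0.05:
            rejections += 1
    assert 0.02 <= rejections / reps <= 0.09
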