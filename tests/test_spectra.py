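import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import naive_channel, naive_spectrum
from mmrspect import core_io, spectra
from mmrspect.core_io import GenomeIntervals, ReferenceGenome
from mmrspect.spectra import (CHANNELS, CPG_TPG_CHANNELS, Spectrum96,
                              aggregate, build_spectrum, channel_of,
                              cosine_similarity, restrict_to_regions,
                              summarize_channels)


def _random_mutations(genome, n, seed, sample="s"):
    rng = np.random.default_rng(seed)
    seq = genome.slice("1", 0, genome.length("1"))
    pos = rng.integers(2, len(seq), size=n)
    ref = np.array([seq[p - 1] for p in pos])
    alt = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in ref])
    return core_io.validate_mutations(pd.DataFrame({
        "chrom": "1", "pos": pos, "ref": ref, "alt": alt, "sample": sample}))


def test_purine_reference_mutation_maps_to_pyrimidine_channel():
    # G>A with plus-strand context CGA is the minus-strand C>T in TCG
    g = ReferenceGenome({"1": "ACGAT"})
    df = core_io.validate_mutations(pd.DataFrame(
        {"chrom": ["1"], "pos": [3], "ref": ["G"], "alt": ["A"],
         "sample": ["s"]}))
    s = build_spectrum(df, g)
    assert s.total == 1
    assert s.counts[CHANNELS.index("T[C>T]G")] == 1
    assert channel_of("G", "A", "CGA") == "T[C>T]G"


def test_empty_mutation_list_gives_zero_spectrum(toy_genome):
    s = build_spectrum(pd.DataFrame(columns=core_io.MUTATION_COLUMNS),
                       toy_genome)
    assert s.total == 0 and (s.counts == 0).all()


def test_spectrum_matches_per_mutation_lookup_oracle(toy_genome):
    df = _random_mutations(toy_genome, 1000, seed=3)
    s = build_spectrum(df, toy_genome)
    seq = {"1": toy_genome.slice("1", 0, toy_genome.length("1"))}
    expected = naive_spectrum(
        df[["chrom", "pos", "ref", "alt"]].itertuples(index=False), seq)
    got = {c: int(n) for c, n in zip(CHANNELS, s.counts) if n}
    assert got == expected


def test_strand_symmetry_of_channel_assignment():
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for ref in "ACGT":
        for alt in "ACGT":
            if alt == ref:
                continue
            for five in "ACGT":
                for three in "ACGT":
                    ctx = five + ref + three
                    rc_ctx = comp[three] + comp[ref] + comp[five]
                    assert channel_of(ref, alt, ctx) == \
                        channel_of(comp[ref], comp[alt], rc_ctx)


def test_non_snvs_are_skipped_and_total_conserved(toy_genome):
    df = _random_mutations(toy_genome, 50, seed=4)
    indel = pd.DataFrame({"chrom": ["1"], "pos": [10], "ref": ["A"],
                          "alt": ["ATT"], "sample": ["s"]})
    s = build_spectrum(pd.concat([df, indel], ignore_index=True), toy_genome)
    assert s.total == 50
    assert s.n_non_snv == 1


def test_summarize_channels_cpg_split():
    counts = np.zeros(96, dtype=int)
    counts[CHANNELS.index("G[C>T]G")] = 10
    cs = summarize_channels(Spectrum96(counts, "s"))
    assert cs.burdens["CpG>TpG"] == 10
    assert cs.burdens["non-CpG C>T"] == 0

    uniform = summarize_channels(Spectrum96(np.ones(96, dtype=int), "u"))
    ct_total = uniform.burdens["CpG>TpG"] + uniform.burdens["non-CpG C>T"]
    assert ct_total == 16
    assert uniform.activities["CpG>TpG"] == pytest.approx(4 / 96)

    empty = summarize_channels(Spectrum96(np.zeros(96, dtype=int), "e"))
    assert np.isnan(empty.activities["C>A"])


@settings(max_examples=50, deadline=None)
@given(st.lists(st.integers(0, 50), min_size=96, max_size=96))
def test_cpg_plus_noncpg_equals_ct_total(counts):
    s = Spectrum96(np.array(counts), "p")
    cs = summarize_channels(s)
    assert cs.burdens["CpG>TpG"] + cs.burdens["non-CpG C>T"] == \
        s.six_channel()["C>T"]
    assert s.six_channel().sum() == s.total


def test_restrict_to_regions_boundary_and_empty(toy_genome):
    df = core_io.validate_mutations(pd.DataFrame(
        {"chrom": ["1"], "pos": [100], "ref": ["A"], "alt": ["C"],
         "sample": ["s"]}))
    region = GenomeIntervals(pd.DataFrame(
        {"chrom": ["1"], "start": [99], "end": [100]}), kind="region")
    assert len(restrict_to_regions(df, region)) == 1
    past = GenomeIntervals(pd.DataFrame(
        {"chrom": ["1"], "start": [100], "end": [101]}), kind="region")
    assert len(restrict_to_regions(df, past)) == 0
    empty = GenomeIntervals(pd.DataFrame(columns=["chrom", "start", "end"]),
                            kind="region")
    assert restrict_to_regions(df, empty).empty


def test_restrict_to_regions_matches_brute_force(toy_genome):
    from _oracles import naive_overlap
    rng = np.random.default_rng(5)
    df = _random_mutations(toy_genome, 200, seed=6)
    starts = np.sort(rng.choice(np.arange(0, 2900, 30), 40, replace=False))
    regions = GenomeIntervals(pd.DataFrame(
        {"chrom": "1", "start": starts,
         "end": starts + rng.integers(5, 40, 40)}), kind="region")
    got = set(restrict_to_regions(df, regions)["pos"])
    iv = list(zip(regions.merged().df["start"], regions.merged().df["end"]))
    expected = {int(p) for p in df["pos"] if naive_overlap(int(p), iv)}
    assert got == expected


def test_aggregate_sum_mean_and_equivalence(toy_genome):
    a = _random_mutations(toy_genome, 300, seed=7, sample="a")
    b = _random_mutations(toy_genome, 200, seed=8, sample="b")
    sa = build_spectrum(a, toy_genome, "a")
    sb = build_spectrum(b, toy_genome, "b")
    summed = aggregate([sa, sb], "sum")
    assert (summed.counts == sa.counts + sb.counts).all()
    doubled = aggregate([sa, sa], "sum")
    assert (doubled.counts == 2 * sa.counts).all()
    assert (aggregate([sa], "mean").counts == sa.counts).all()
    pooled = build_spectrum(pd.concat([a, b], ignore_index=True), toy_genome)
    assert (summed.counts == pooled.counts).all()
    with pytest.raises(ValueError):
        aggregate([], "sum")


def test_cosine_similarity_contract():
    u = np.array([1.0, 2.0, 3.0])
    assert cosine_similarity(u, u) == pytest.approx(1.0)
    assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
    assert cosine_similarity(u, 7.3 * u) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        cosine_similarity(u, np.zeros(3))


def test_cpg_channels_are_the_ncg_ct_channels():
    assert CPG_TPG_CHANNELS == ["A[C>T]G", "C[C>T]G", "G[C>T]G", "T[C>T]G"]
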