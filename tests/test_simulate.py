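import numpy as np
import pandas as pd
import pytest

from mmrspect import simulate, spectra
from mmrspect.spectra import CPG_TPG_IDX, cosine_similarity


@pytest.fixture(scope="module")
def small_cfg():
    return simulate.study_config(
        seed=9, n_chroms=1, chrom_length=800_000,
        group_sizes={"dMutLalpha": 3, "dMutSalpha": 2},
        burden_median=15_000.0)


@pytest.fixture(scope="module")
def small_study(small_cfg, sigs):
    return simulate.simulate_study(small_cfg, sigs)


def test_determinism_under_seed(small_cfg, sigs, tmp_path):
    g1, _, m1, meta1 = simulate.simulate_study(small_cfg, sigs)
    g2, _, m2, meta2 = simulate.simulate_study(small_cfg, sigs)
    pd.testing.assert_frame_equal(m1, m2)
    pd.testing.assert_frame_equal(meta1, meta2)
    g1.to_fasta(tmp_path / "a.fa")
    g2.to_fasta(tmp_path / "b.fa")
    assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()


def test_genome_cpg_density_and_no_n(small_study, small_cfg):
    genome = small_study[0]
    for chrom in genome.chromosomes:
        seq = genome.slice(chrom, 0, genome.length(chrom))
        assert "N" not in seq
        density = seq.count("CG") / len(seq)
        assert density == pytest.approx(small_cfg.cpg_density, rel=0.1)


def test_tracks_cover_every_cpg_and_partition_genome(small_study):
    genome, tracks = small_study[0], small_study[1]
    from mmrspect.binning import cpg_positions, track_values_at
    for chrom in genome.chromosomes:
        pos = cpg_positions(genome, chrom)
        vals = track_values_at(tracks["methylation"], chrom, pos)
        assert not np.isnan(vals).any()
        assert ((vals >= 0) & (vals <= 1)).all()
    repl = tracks["replication_direction"].df
    assert set(repl["label"]) == {"left", "right"}


def test_burdens_match_metadata(small_study):
    _, _, muts, meta = small_study
    per_sample = muts.groupby("sample").size()
    for sample, n in meta["n_mutations"].items():
        assert per_sample[sample] == n


def test_no_site_hit_twice_within_a_sample(small_study):
    muts = small_study[2]
    dup = muts.duplicated(["sample", "chrom", "pos"]).any()
    assert not dup


def test_ref_alleles_match_genome(small_study):
    genome, _, muts, _ = small_study
    sub = muts.sample(2000, random_state=0)
    for chrom, grp in sub.groupby("chrom"):
        seq = genome.slice(chrom, 0, genome.length(chrom))
        assert all(seq[p - 1] == r for p, r in zip(grp["pos"], grp["ref"]))


def test_generative_faithfulness_of_cohort_spectrum(default_cohort, sigs):
    """The cohort aggregate spectrum matches the configured signature
    mixture closely (cosine >= 0.98) at default burdens."""
    cfg = default_cohort["cfg"]
    genome = default_cohort["genome"]
    muts = default_cohort["mutations"]
    mix = cfg.group_mixtures["dMutLalpha"]
    expected = sum(w * sigs[name].to_numpy() for name, w in mix.items())
    sel = muts[muts["sample"].str.startswith("dMutLalpha")]
    spec = spectra.build_spectrum(sel, genome)
    assert cosine_similarity(spec.counts, expected) >= 0.98


def test_spike_fraction_realised_in_truth_table(default_cohort):
    cfg = default_cohort["cfg"]
    muts = default_cohort["mutations"]
    g = muts[muts["sample"].str.startswith("dMutSalpha")]
    spike = int(g["is_spike"].sum())
    # spike fraction is defined over the group's CpG>TpG mutations
    genome = default_cohort["genome"]
    spec = spectra.build_spectrum(g, genome)
    cpg_total = int(spec.counts[CPG_TPG_IDX].sum())
    assert spike / cpg_total == pytest.approx(
        cfg.spike_fraction["dMutSalpha"], abs=0.02)


def test_null_config_shows_no_spike_and_no_bias(sigs):
    cfg = simulate.null_config(
        seed=13, n_chroms=1, chrom_length=600_000,
        group_sizes={"dMutLalpha": 3, "dMutSalpha": 3},
        burden_median=12_000.0)
    genome, tracks, muts, _ = simulate.simulate_study(cfg, sigs)
    assert not muts["is_spike"].any()
    from mmrspect import admixture, strand
    base = spectra.build_spectrum(
        muts[muts["sample"].str.startswith("dMutLalpha")], genome)
    targ = spectra.build_spectrum(
        muts[muts["sample"].str.startswith("dMutSalpha")], genome)
    res = admixture.admixture_scan(
        base.counts[CPG_TPG_IDX], targ.counts[CPG_TPG_IDX],
        np.array([0.416, 0.243, 0.217, 0.124]))
    assert res.implied_fraction < 0.03
    counts = strand.add_log_ratios(strand.strand_counts(
        muts, genome, tracks["replication_direction"]))
    med = counts[counts["category"] == "all SBS"][
        "log2_leading_lagging"].median()
    assert abs(med) < 0.03


def test_mmr_variant_generator_vaf_calibration():
    cfg = simulate.SimConfig(purity_range=(1.0, 1.0))
    rng = np.random.default_rng(3)
    records, truth = simulate.simulate_mmr_variants(
        cfg, ["Lynch_dMutLalpha"] * 40, rng)
    vafs = []
    for rec in records:
        for v in rec.variants:
            if v.origin == "somatic" and v.alt_reads + v.ref_reads > 0:
                vafs.append(v.alt_reads / (v.alt_reads + v.ref_reads))
    # truth heterozygous at purity 1.0: VAF centred on 0.5
    assert np.mean(vafs) == pytest.approx(0.5, abs=0.03)


def test_write_cohort_round_trip(small_study, small_cfg, tmp_path):
    from mmrspect import core_io
    genome, tracks, muts, meta = small_study
    simulate.write_cohort(muts, meta, genome, tracks, tmp_path)
    sample = meta.index[0]
    back = core_io.read_vcf(tmp_path / "vcf" / f"{sample}.vcf", sample=sample)
    orig = muts[muts["sample"] == sample]
    key = ["chrom", "pos", "ref", "alt"]
    assert back.sort_values(key)[key].reset_index(drop=True).equals(
        orig.sort_values(key)[key].reset_index(drop=True))
    g2 = core_io.ReferenceGenome.from_fasta(tmp_path / "genome.fa")
    assert g2.slice("1", 0, 50) == genome.slice("1", 0, 50)
    meth = core_io.read_track(tmp_path / "methylation.bedgraph",
                              kind="methylation")
    assert len(meth) == len(tracks["methylation"])
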