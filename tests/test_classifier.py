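import numpy as np
import pytest

from mmrspect import simulate
from mmrspect.classifier import (DEFAULT_BLOCKLIST, GeneVariantCall,
                                 MMRdClass, TumourRecord, classify,
                                 classify_cohort, compute_tmb, zygosity_test)


def _record(variants, msi=True, tmb=15.0, purity=0.8, cn_data=True):
    return TumourRecord(sample="t", msi_positive=msi, purity=purity,
                        coding_mutation_count=int(tmb * 35),
                        coding_megabases=35.0, variants=variants,
                        has_copy_number_data=cn_data)


def _som(gene, alt=30, ref=30, pathogenic=True, protein="p.X1fs",
         cnloss=False):
    return GeneVariantCall(gene=gene, origin="somatic", pathogenic=pathogenic,
                           protein_change=protein, alt_reads=alt,
                           ref_reads=ref, copy_number_loss=cnloss)


def _germ(gene, protein="p.X1*"):
    return GeneVariantCall(gene=gene, origin="germline", pathogenic=True,
                           protein_change=protein, alt_reads=30, ref_reads=30)


def test_compute_tmb_and_strict_threshold():
    assert compute_tmb(350, 35) == pytest.approx(10.0)
    assert compute_tmb(0, 35) == 0.0
    # exactly 10/Mb is NOT greater than the threshold: record stays MMRp
    rec = _record([_som("MSH2", cnloss=True)], tmb=10.0)
    assert classify(rec).label == "MMRp"


def test_zygosity_classifications():
    # purity 1: het expectation 0.5, chi2 = 0 on a 30/30 split
    assert zygosity_test(30, 30, 1.0)[0] == "heterozygous"
    # 58 alt / 2 ref at purity 1: het model chi2 = (28^2/30)*2 = 52.3,
    # rejected; VAF 0.967 above expectation and compatible with the
    # (error-clamped) homozygous model
    assert zygosity_test(58, 2, 1.0)[0] == "homozygous"
    # purity 0.5: het expectation 0.25; 5/95 sits far below it
    assert zygosity_test(5, 95, 0.5)[0] == "subclonal"
    with pytest.raises(ValueError):
        zygosity_test(0, 0, 0.5)


def test_lynch_classification_with_germline_plus_copy_loss():
    rec = _record([GeneVariantCall(gene="MSH2", origin="germline",
                                   pathogenic=True, copy_number_loss=True,
                                   alt_reads=30, ref_reads=30)], tmb=12)
    assert classify(rec).label == "Lynch_dMutSalpha"


def test_blocklisted_msh6_frameshift_routes_to_presumed_methylation():
    rec = _record([_som("MSH6", protein="p.Thr1085fs")], tmb=15)
    out = classify(rec)
    assert out.label == "dMutLalpha_presumed_methylation"
    assert any("blocklisted" in r for r in out.reasons)


def test_msi_negative_is_mmrp_regardless_of_variants():
    rec = _record([_som("MSH2"), _som("MSH2", protein="p.Y2fs")], msi=False)
    assert classify(rec).label == "MMRp"


def test_polymerase_and_pms2_rules():
    assert classify(_record([_som("POLE", protein="p.P286R")])).label == \
        "excluded_polymerase"
    assert classify(_record([_som("PMS2")])).label == "MMRd_uncertain"


def test_contradictory_biallelic_evidence_is_uncertain():
    rec = _record([_som("MSH2", cnloss=True), _som("MLH1", cnloss=True)])
    assert classify(rec).label == "MMRd_uncertain"


def test_missing_copy_number_data_routes_to_uncertain():
    rec = _record([], cn_data=False)
    assert classify(rec).label == "MMRd_uncertain"


def test_monoallelic_hit_is_uncertain_and_no_hit_is_presumed_methylation():
    assert classify(_record([_som("MSH6")])).label == "MMRd_uncertain"
    assert classify(_record([])).label == "dMutLalpha_presumed_methylation"


def test_homozygous_somatic_counts_as_biallelic():
    rec = _record([_som("MLH1", alt=58, ref=2)], purity=1.0)
    assert classify(rec).label == "dMutLalpha_mutation"


TRUTH_LABELS = (["MMRp"] * 10 + ["dMutSalpha"] * 8 +
                ["Lynch_dMutSalpha"] * 7 + ["dMutLalpha_mutation"] * 10 +
                ["Lynch_dMutLalpha"] * 5 +
                ["dMutLalpha_presumed_methylation"] * 15 +
                ["MMRd_uncertain"] * 5)


def test_truth_table_recovery_on_synthetic_cohort():
    """60 synthetic tumours with known truth labels are recovered, the only
    tolerated discrepancies being biallelic cases conservatively routed to
    uncertain by the zygosity rule."""
    rng = np.random.default_rng(0)
    records, truth = simulate.simulate_mmr_variants(simulate.SimConfig(),
                                                    TRUTH_LABELS, rng)
    out = classify_cohort(records)
    merged = truth.join(out)
    correct = (merged["truth"] == merged["label"]).sum()
    assert correct >= 58
    mism = merged[merged["truth"] != merged["label"]]
    crossover = (
        (mism["truth"].str.contains("MutS") &
         mism["label"].str.contains("dMutLalpha")) |
        (mism["truth"].str.contains("dMutLalpha") &
         mism["label"].str.contains("MutS")))
    assert not crossover.any()


def test_blocklist_extension_never_creates_subtype_crossover():
    """Adding entries to the blocklist can only demote hits; it must never
    flip a tumour between the dMutSα and dMutLα mutation classes."""
    rng = np.random.default_rng(1)
    records, _ = simulate.simulate_mmr_variants(simulate.SimConfig(),
                                                TRUTH_LABELS, rng)
    base = classify_cohort(records)
    extended = DEFAULT_BLOCKLIST + (("MSH2", "p.A1fs"), ("MLH1", "p.A1fs"))
    perturbed = classify_cohort(records, blocklist=extended)
    for sample in base.index:
        a, b = base.loc[sample, "label"], perturbed.loc[sample, "label"]
        if a != b:
            assert not ("MutS" in a and "dMutLalpha_mutation" in b)
            assert not ("dMutLalpha" in a and "MutS" in b)


def test_every_record_gets_exactly_one_valid_label():
    rng = np.random.default_rng(2)
    genes = ["MLH1", "MSH2", "MSH6", "PMS2", "POLE", "POLD1", "MBD4"]
    for _ in range(200):
        n_var = rng.integers(0, 4)
        variants = [
            GeneVariantCall(
                gene=str(rng.choice(genes)),
                origin=str(rng.choice(["germline", "somatic"])),
                pathogenic=bool(rng.random() < 0.8),
                protein_change=str(rng.choice(
                    ["p.A1fs", "p.Thr1085fs", "p.Q2*"])),
                alt_reads=int(rng.integers(0, 60)),
                ref_reads=int(rng.integers(1, 60)),
                copy_number_loss=bool(rng.random() < 0.3))
            for _ in range(n_var)]
        rec = TumourRecord(
            sample="f", msi_positive=bool(rng.random() < 0.7),
            purity=float(rng.uniform(0.1, 1.0)),
            coding_mutation_count=int(rng.integers(0, 3000)),
            coding_megabases=35.0, variants=variants,
            has_copy_number_data=bool(rng.random() < 0.9))
        out = classify(rec)
        assert isinstance(out, MMRdClass)  # label validity checked on init
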