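"""Rule engine assigning MMRd tumours to mechanistic subtypes.

Tumours are assigned to MMRp, dMutSα (MutSα loss: biallelic MSH2/MSH6),
dMutLα (MLH1 mutation, or presumed MLH1 promoter methylation when no MMR
gene hit is identifiable), Lynch variants of either (a germline hit among
the two), MMRd of uncertain origin, or excluded for polymerase-proofreading
(POLE/POLD1) mutations.  "Pathogenic" is an input annotation: curation of
variant pathogenicity is upstream of this package.

The engine is deliberately specificity-first: blocklisted secondary indels
(hypermutable-repeat MSH6 frameshifts) and subclonal variants are removed
before hits are counted, so MLH1-silenced tumours cannot ride a passenger
frameshift into the dMutSα bin, and zygosity calls that fit neither the
heterozygous nor the homozygous read-count model fall back to heterozygous
(preventing false biallelic calls).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

MMR_GENES = ("MLH1", "MSH2", "MSH6", "PMS2")
MUTS_ALPHA_GENES = ("MSH2", "MSH6")
POLYMERASE_GENES = ("POLE", "POLD1")
BER_GENES = ("MBD4", "TDG", "UDG")
KNOWN_GENES = MMR_GENES + POLYMERASE_GENES + BER_GENES

#: secondary indels in hypermutable short repeats, excluded from hit counting
DEFAULT_BLOCKLIST = (
    ("MSH6", "p.Ile245fs"),
    ("MSH6", "p.Thr1085fs"),
    ("MSH6", "p.Thr1102fs"),
)

TMB_THRESHOLD = 10.0  # mutations/Mb; strictly greater-than qualifies as MMRd
VAF_ERROR_FLOOR = 0.01  # sequencing-error clamp on model VAFs

LABELS = (
    "MMRp", "dMutSalpha", "dMutLalpha_mutation",
    "dMutLalpha_presumed_methylation", "Lynch_dMutSalpha", "Lynch_dMutLalpha",
    "MMRd_uncertain", "excluded_polymerase",
)


@dataclass
class GeneVariantCall:
    gene: str
    origin: str  # germline | somatic
    pathogenic: bool
    consequence: str = ""
    protein_change: str = ""
    alt_reads: int = 0
    ref_reads: int = 0
    copy_number_loss: bool = False

    def __post_init__(self) -> None:
        if self.gene not in KNOWN_GENES:
            raise ValueError(f"unknown gene {self.gene!r}")
        if self.origin not in ("germline", "somatic"):
            raise ValueError(f"origin must be germline/somatic, got {self.origin!r}")


@dataclass
class TumourRecord:
    sample: str
    msi_positive: bool
    purity: float
    coding_mutation_count: int
    coding_megabases: float
    variants: list = field(default_factory=list)
    has_copy_number_data: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.purity <= 1):
            raise ValueError("purity must lie in (0, 1]")
        if self.coding_megabases <= 0:
            raise ValueError("coding_megabases must be positive")


@dataclass
class MMRdClass:
    label: str
    reasons: list

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.label != "MMRp" and not self.reasons:
            raise ValueError("non-MMRp classifications need at least one reason")


def compute_tmb(coding_mutation_count: int, coding_megabases: float) -> float:
    """Somatic coding mutations per megabase."""
    if coding_megabases <= 0:
        raise ValueError("coding_megabases must be positive")
    return coding_mutation_count / coding_megabases


def zygosity_test(alt_reads: int, ref_reads: int, purity: float,
                  tumour_copy_number: int = 2,
                  alpha: float = 0.05) -> tuple[str, bool]:
    """Classify a somatic variant as heterozygous / homozygous / subclonal
    from its read counts and the tumour purity.

    Expected VAFs under a diploid-normal contamination model:
    heterozygous rho*1/(rho*CN + (1-rho)*2), homozygous
    rho*CN/(rho*CN + (1-rho)*2); both clamped into
    [VAF_ERROR_FLOOR, 1 - VAF_ERROR_FLOOR] so the chi-square is defined at
    purity 1.  Each model is a 1-df goodness-of-fit of (alt, ref) against
    its expectation.  The variant is heterozygous if the het model is not
    rejected; homozygous if the het model is rejected with observed VAF
    above the het expectation and the hom model fits; subclonal if the het
    model is rejected with VAF below expectation.  If the het model is
    rejected, VAF is above expectation, and the hom model is also rejected,
    the call conservatively falls back to heterozygous with a warning flag.

    Returns (label, warning_flag).
    """
    n = alt_reads + ref_reads
    if n <= 0:
        raise ValueError("zygosity test needs reads")
    if not (0 < purity <= 1):
        raise ValueError("purity must lie in (0, 1]")
    denom = purity * tumour_copy_number + (1 - purity) * 2
    e_het = np.clip(purity * 1 / denom, VAF_ERROR_FLOOR, 1 - VAF_ERROR_FLOOR)
    e_hom = np.clip(purity * tumour_copy_number / denom,
                    VAF_ERROR_FLOOR, 1 - VAF_ERROR_FLOOR)
    vaf = alt_reads / n

    def p_model(e: float) -> float:
        exp = np.array([n * e, n * (1 - e)])
        stat = (((np.array([alt_reads, ref_reads]) - exp) ** 2) / exp).sum()
        return float(sps.chi2.sf(stat, df=1))

    if p_model(e_het) >= alpha:
        return "heterozygous", False
    if vaf < e_het:
        return "subclonal", False
    if p_model(e_hom) >= alpha:
        return "homozygous", False
    return "heterozygous", True


def _count_hits(variants: list[GeneVariantCall], gene: str, purity: float,
                blockset: set, reasons: list[str]) -> tuple[int, bool]:
    """Pathogenic hit count for one gene after blocklist/subclonal filtering.

    Two somatic variants in one gene are treated as biallelic without
    phasing information (flagged in the audit trail).  Returns
    (hits, any_germline_hit).
    """
    hits = 0
    germline = False
    somatic_variant_hits = 0
    for v in variants:
        if v.gene != gene or not v.pathogenic:
            continue
        if (v.gene, v.protein_change) in blockset:
            reasons.append(f"{gene}:{v.protein_change} blocklisted secondary indel")
            continue
        extra = 1 if v.copy_number_loss else 0
        if v.origin == "germline":
            hits += 1 + extra
            germline = True
            continue
        if v.alt_reads + v.ref_reads > 0:
            zyg, warned = zygosity_test(v.alt_reads, v.ref_reads, purity)
            if zyg == "subclonal":
                reasons.append(f"{gene} somatic variant subclonal; excluded")
                if v.copy_number_loss:
                    # the copy-number observation is independent of the
                    # variant's read support and is kept as a hit
                    reasons.append(f"{gene} copy-number loss retained")
                    hits += 1
                continue
            if warned:
                reasons.append(f"{gene} somatic variant fit neither read-count "
                               "model; counted as heterozygous")
            hits += (2 if zyg == "homozygous" else 1) + extra
            somatic_variant_hits += 1
        else:
            hits += 1 + extra
            somatic_variant_hits += 1
    if somatic_variant_hits >= 2:
        reasons.append(f"{gene}: two somatic variants treated as biallelic "
                       "(no phasing)")
    return hits, germline


def classify(t: TumourRecord,
             blocklist: tuple = DEFAULT_BLOCKLIST) -> MMRdClass:
    """Apply the subtype decision procedure to one tumour record.

    Rule order: MMRp screen (MSI and TMB > 10/Mb both required for MMRd);
    polymerase-proofreading exclusion; PMS2 uncertainty; blocklist/subclonal
    filtering; biallelic MSH2/MSH6 (dMutSα, Lynch_ prefix when a hit is
    germline); biallelic MLH1 (dMutLα mutation, Lynch_ likewise);
    mono-allelic hits or missing copy-number data route to uncertain; no hit
    at all is presumed MLH1 promoter methylation.
    """
    reasons: list[str] = []
    blockset = set(blocklist)
    tmb = compute_tmb(t.coding_mutation_count, t.coding_megabases)
    if not (t.msi_positive and tmb > TMB_THRESHOLD):
        return MMRdClass("MMRp", [])
    reasons.append(f"MSI+ and TMB {tmb:.1f}/Mb > {TMB_THRESHOLD:g}")
    if any(v.gene in POLYMERASE_GENES and v.pathogenic for v in t.variants):
        reasons.append("pathogenic POLE/POLD1 exonuclease-domain variant")
        return MMRdClass("excluded_polymerase", reasons)
    if any(v.gene == "PMS2" and v.pathogenic for v in t.variants):
        reasons.append("PMS2 variant (pseudogene ambiguity)")
        return MMRdClass("MMRd_uncertain", reasons)

    muts_hits = 0
    muts_germline = False
    muts_gene = ""
    for gene in MUTS_ALPHA_GENES:
        h, g = _count_hits(t.variants, gene, t.purity, blockset, reasons)
        if h > muts_hits:
            muts_hits, muts_germline, muts_gene = h, g, gene
    mlh1_hits, mlh1_germline = _count_hits(t.variants, "MLH1", t.purity,
                                           blockset, reasons)

    if muts_hits >= 2 and mlh1_hits >= 2:
        reasons.append("contradictory biallelic evidence in both MutSα and MLH1")
        return MMRdClass("MMRd_uncertain", reasons)
    if muts_hits >= 2:
        reasons.append(f"biallelic pathogenic {muts_gene}")
        label = "Lynch_dMutSalpha" if muts_germline else "dMutSalpha"
        return MMRdClass(label, reasons)
    if mlh1_hits >= 2:
        reasons.append("biallelic pathogenic MLH1")
        label = "Lynch_dMutLalpha" if mlh1_germline else "dMutLalpha_mutation"
        return MMRdClass(label, reasons)
    if not t.has_copy_number_data:
        reasons.append("copy number data unavailable")
        return MMRdClass("MMRd_uncertain", reasons)
    if muts_hits == 1 or mlh1_hits == 1:
        gene = muts_gene if muts_hits == 1 else "MLH1"
        reasons.append(f"mono-allelic {gene} hit only")
        return MMRdClass("MMRd_uncertain", reasons)
    reasons.append("no identifiable mismatch repair mutation; presumed MLH1 "
                   "promoter methylation")
    return MMRdClass("dMutLalpha_presumed_methylation", reasons)


def ber_gene_status(t: TumourRecord,
                    blocklist: tuple = DEFAULT_BLOCKLIST) -> dict[str, str]:
    """Biallelic/mono-allelic annotation for MBD4/TDG/UDG using the same
    two-hit logic.  Reported as annotation only; never changes the MMRd
    label."""
    out = {}
    blockset = set(blocklist)
    for gene in BER_GENES:
        hits, _ = _count_hits(t.variants, gene, t.purity, blockset, [])
        out[gene] = ("biallelic" if hits >= 2
                     else "monoallelic" if hits == 1 else "wildtype")
    return out


def classify_cohort(records: list[TumourRecord],
                    blocklist: tuple = DEFAULT_BLOCKLIST) -> pd.DataFrame:
    """Per-sample classification table with fired-rule audit trail."""
    rows = []
    for t in records:
        cls = classify(t, blocklist)
        rows.append({"sample": t.sample, "label": cls.label,
                     "reasons": "; ".join(cls.reasons),
                     **{f"{g}_status": s for g, s in
                        ber_gene_status(t, blocklist).items()}})
    return pd.DataFrame(rows).set_index("sample")
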