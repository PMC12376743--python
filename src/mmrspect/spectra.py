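"""Pyrimidine-normalised mutation spectra.

The 96 channels follow the conventional COSMIC ordering: substitution blocks
C>A, C>G, C>T, T>A, T>C, T>G; within a block the 5' base varies A,C,G,T on
the outer loop and the 3' base on the inner loop, so channel 0 is A[C>A]A and
channel 95 is T[T>G]T.  Purine-reference mutations (G>*, A>*) are
reverse-complemented onto their pyrimidine channel.

CpG>TpG means a C>T substitution in NCG context (channels A[C>T]G, C[C>T]G,
G[C>T]G, T[C>T]G) — the canonical product of 5-methylcytosine deamination —
and is repeatedly split out from the remaining C>T channels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import BASES, COMPLEMENT, GenomeIntervals, ReferenceGenome, \
    positions_in_intervals, snv_mask, trinucleotide_codes

logger = logging.getLogger(__name__)

SUBSTITUTIONS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]

CHANNELS: list[str] = [
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
]
CHANNEL_INDEX = {name: i for i, name in enumerate(CHANNELS)}

#: the four CpG>TpG channels, in channel order
CPG_TPG_CHANNELS = ["A[C>T]G", "C[C>T]G", "G[C>T]G", "T[C>T]G"]
CPG_TPG_IDX = np.array([CHANNEL_INDEX[c] for c in CPG_TPG_CHANNELS])
CT_BLOCK = np.arange(2 * 16, 3 * 16)
NON_CPG_CT_IDX = np.array([i for i in CT_BLOCK if i not in set(CPG_TPG_IDX)])

_BASE_IDX = {b: i for i, b in enumerate(BASES)}
_SUB_IDX = {s: i for i, s in enumerate(SUBSTITUTIONS)}

# channel lookup by (context_code, alt_code): context_code = 16*b5+4*ref+b3.
# Purine-reference entries point at the reverse-complement channel.
_CHANNEL_LUT = np.full((64, 4), -1, dtype=np.int16)
for _five in BASES:
    for _ref in BASES:
        for _three in BASES:
            code = 16 * _BASE_IDX[_five] + 4 * _BASE_IDX[_ref] + _BASE_IDX[_three]
            for _alt in BASES:
                if _alt == _ref:
                    continue
                ref, alt, five, three = _ref, _alt, _five, _three
                if ref in "AG":  # normalise to the pyrimidine strand
                    ref = ref.translate(COMPLEMENT)
                    alt = alt.translate(COMPLEMENT)
                    five, three = three.translate(COMPLEMENT), _five.translate(COMPLEMENT)
                sub = f"{ref}>{alt}"
                _CHANNEL_LUT[code, _BASE_IDX[_alt]] = (
                    16 * _SUB_IDX[sub] + 4 * _BASE_IDX[five] + _BASE_IDX[three]
                )


@dataclass
class Spectrum96:
    """Counts over the 96 trinucleotide channels for one tumour or cohort."""

    counts: np.ndarray
    sample: str = "cohort"
    n_non_snv: int = 0
    n_context_dropped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (96,):
            raise ValueError("Spectrum96 needs exactly 96 counts")
        if (self.counts < 0).any():
            raise ValueError("negative channel count")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def six_channel(self) -> pd.Series:
        """Collapse to the six substitution channels (preserves total)."""
        sums = self.counts.reshape(6, 16).sum(axis=1)
        return pd.Series(sums, index=SUBSTITUTIONS, name=self.sample)

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=CHANNELS, name=self.sample)


@dataclass
class ChannelSummary:
    """Six-channel burdens with the C>T channel split into CpG>TpG and
    non-CpG C>T, plus activities (proportions of total)."""

    sample: str
    burdens: dict = field(default_factory=dict)
    activities: dict = field(default_factory=dict)
    total: int = 0

    REPORTED = ["C>A", "C>G", "CpG>TpG", "non-CpG C>T", "T>A", "T>C", "T>G"]


def build_spectrum(mutations: pd.DataFrame, genome: ReferenceGenome,
                   sample: str = "cohort") -> Spectrum96:
    """Build a pyrimidine-normalised 96-channel spectrum.

    Non-SNV records are skipped (count logged); SNVs whose trinucleotide
    context contains N are dropped (count logged).  The spectrum total
    equals the number of usable SNVs.
    """
    counts = np.zeros(96, dtype=np.int64)
    if mutations.empty:
        return Spectrum96(counts, sample=sample)
    mutations = mutations.reset_index(drop=True)
    is_snv = snv_mask(mutations)
    n_non_snv = int((~is_snv).sum())
    snvs = mutations[is_snv]
    n_dropped = 0
    if len(snvs):
        codes = trinucleotide_codes(genome, snvs)
        alt_codes = np.array([_BASE_IDX[a] for a in snvs["alt"]], dtype=np.int64)
        valid = codes < 64
        n_dropped = int((~valid).sum())
        ch = _CHANNEL_LUT[codes[valid], alt_codes[valid]]
        counts = np.bincount(ch, minlength=96).astype(np.int64)
    if n_non_snv or n_dropped:
        logger.info("build_spectrum(%s): skipped %d non-SNVs, dropped %d N-context",
                    sample, n_non_snv, n_dropped)
    return Spectrum96(counts, sample=sample, n_non_snv=n_non_snv,
                      n_context_dropped=n_dropped)


def channel_of(ref: str, alt: str, context: str) -> str:
    """Channel name for a single mutation given its plus-strand context."""
    code = 16 * _BASE_IDX[context[0]] + 4 * _BASE_IDX[ref] + _BASE_IDX[context[2]]
    if context[1] != ref:
        raise ValueError("context centre must equal the reference allele")
    return CHANNELS[_CHANNEL_LUT[code, _BASE_IDX[alt]]]


def summarize_channels(s: Spectrum96) -> ChannelSummary:
    """Six-channel summary with the CpG>TpG / non-CpG C>T split.

    Activities are proportions of the spectrum total over the seven
    reported channels; with a zero total they are reported as missing
    (NaN) rather than zero.
    """
    six = s.six_channel()
    cpg = int(s.counts[CPG_TPG_IDX].sum())
    burdens = {
        "C>A": int(six["C>A"]), "C>G": int(six["C>G"]),
        "CpG>TpG": cpg, "non-CpG C>T": int(six["C>T"]) - cpg,
        "T>A": int(six["T>A"]), "T>C": int(six["T>C"]), "T>G": int(six["T>G"]),
    }
    total = s.total
    activities = {k: (v / total if total else float("nan"))
                  for k, v in burdens.items()}
    return ChannelSummary(sample=s.sample, burdens=burdens,
                          activities=activities, total=total)


def restrict_to_regions(mutations: pd.DataFrame,
                        regions: GenomeIntervals) -> pd.DataFrame:
    """Mutations overlapping any region (regions merged first).

    Serves both the kataegis-region and exome-restricted analyses.
    """
    if mutations.empty or len(regions) == 0:
        return mutations.iloc[0:0]
    merged = regions.merged()
    keep_parts = []
    per_chrom = merged.per_chrom()
    for chrom, grp in mutations.groupby("chrom", sort=False):
        if chrom not in per_chrom:
            continue
        iv = per_chrom[chrom]
        idx = positions_in_intervals(grp["pos"].to_numpy(),
                                     iv["start"].to_numpy(), iv["end"].to_numpy())
        keep_parts.append(grp[idx >= 0])
    if not keep_parts:
        return mutations.iloc[0:0]
    return pd.concat(keep_parts).sort_index()


def aggregate(spectra: list[Spectrum96], method: str = "sum") -> Spectrum96:
    """Element-wise sum or mean of spectra (cohort aggregates)."""
    if not spectra:
        raise ValueError("aggregate needs at least one spectrum")
    mat = np.stack([s.counts for s in spectra])
    if method == "sum":
        out = mat.sum(axis=0)
    elif method == "mean":
        out = mat.mean(axis=0)
        return Spectrum96(np.round(out).astype(np.int64), sample="cohort-mean")
    else:
        raise ValueError(f"unknown aggregation method {method!r}")
    return Spectrum96(out, sample="cohort")


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """u.v / (|u||v|); scale-invariant; zero vectors are an error."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors of unequal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for zero vector")
    return float(np.dot(u, v) / (nu * nv))


def spectra_to_matrix(spectra: list[Spectrum96]) -> pd.DataFrame:
    """96 x samples count matrix, channels as index."""
    return pd.DataFrame({s.sample: s.counts for s in spectra}, index=CHANNELS)
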