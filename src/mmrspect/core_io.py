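"""Shared genomic data types and readers/writers for the standard formats.

Coordinate conventions
----------------------
* VCF positions are 1-based (column ``pos``).
* All interval tracks are 0-based half-open (BED convention).
* A mutation at 1-based position ``p`` overlaps interval ``[s, e)`` iff
  ``s <= p - 1 < e``.  This conversion lives in :func:`positions_in_intervals`
  and nowhere else.

Chromosome names are normalised by stripping any leading ``"chr"`` prefix;
a name that still fails to match the reference after normalisation raises
rather than silently contributing zero overlap.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

BASES = "ACGT"
COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: columns of the bulk mutation container
MUTATION_COLUMNS = ["chrom", "pos", "ref", "alt", "sample"]

# ASCII -> 0..3 base codes (A,C,G,T); everything else (incl. N) -> 4
_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


class Mutation(NamedTuple):
    """One somatic substitution (or indel, carried but not spectrum-typed)."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    sample: str

    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and \
            self.ref in BASES and self.alt in BASES


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr`` prefix (case-insensitive)."""
    return name[3:] if name.lower().startswith("chr") else name


def mutations_to_frame(mutations: Iterable[Mutation]) -> pd.DataFrame:
    """Build the bulk mutation container from individual records."""
    df = pd.DataFrame(list(mutations), columns=MUTATION_COLUMNS)
    return validate_mutations(df)


def frame_to_mutations(df: pd.DataFrame) -> list[Mutation]:
    return [Mutation(*row) for row in df[MUTATION_COLUMNS].itertuples(index=False)]


def validate_mutations(df: pd.DataFrame) -> pd.DataFrame:
    """Check mutation-set invariants: pos >= 1, ref != alt, SNV alleles in ACGT."""
    if df.empty:
        return pd.DataFrame(columns=MUTATION_COLUMNS)
    df = df[MUTATION_COLUMNS].copy()
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["pos"] = df["pos"].astype(np.int64)
    if (df["pos"] < 1).any():
        raise ValueError("mutation positions must be >= 1 (1-based)")
    if (df["ref"] == df["alt"]).any():
        raise ValueError("ref allele equals alt allele")
    snv = (df["ref"].str.len() == 1) & (df["alt"].str.len() == 1)
    bad = snv & (~df["ref"].isin(list(BASES)) | ~df["alt"].isin(list(BASES)))
    if bad.any():
        raise ValueError(f"{int(bad.sum())} SNV records with alleles outside ACGT")
    return df


def snv_mask(df: pd.DataFrame) -> pd.Series:
    return (
        (df["ref"].str.len() == 1)
        & (df["alt"].str.len() == 1)
        & df["ref"].isin(list(BASES))
        & df["alt"].isin(list(BASES))
    )


class ReferenceGenome:
    """In-memory reference with random access to any (chrom, start, end) slice.

    Sequences are stored as uppercase ASCII byte arrays so per-cohort
    operations (context lookup for ~10^6 mutations) stay vectorised.
    """

    def __init__(self, sequences: dict[str, str]):
        self._seq: dict[str, np.ndarray] = {}
        for chrom, seq in sequences.items():
            arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
            self._seq[normalize_chrom(chrom)] = arr

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceGenome":
        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    @property
    def chromosomes(self) -> list[str]:
        return list(self._seq)

    def length(self, chrom: str) -> int:
        return len(self._chrom_array(chrom))

    def _chrom_array(self, chrom: str) -> np.ndarray:
        key = normalize_chrom(chrom)
        if key not in self._seq:
            raise KeyError(
                f"chromosome {chrom!r} not in reference "
                f"(known: {sorted(self._seq)})"
            )
        return self._seq[key]

    def slice(self, chrom: str, start: int, end: int) -> str:
        """0-based half-open slice, uppercase. Out-of-range is an error."""
        arr = self._chrom_array(chrom)
        if start < 0 or end > len(arr) or start >= end:
            raise IndexError(
                f"slice [{start},{end}) outside chromosome {chrom} "
                f"of length {len(arr)}"
            )
        return arr[start:end].tobytes().decode("ascii")

    def base_codes(self, chrom: str) -> np.ndarray:
        """Whole-chromosome 0..3 codes (4 for N); read-only view semantics."""
        return _BASE_CODE[self._chrom_array(chrom)]

    def to_fasta(self, path: str | Path, line_width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom, arr in self._seq.items():
                fh.write(f">{chrom}\n")
                seq = arr.tobytes().decode("ascii")
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")


TRACK_KINDS = ("gene", "replication_direction", "methylation",
               "replication_timing", "region")
_LABELLED = {"gene": None, "replication_direction": ("left", "right"),
             "region": None}


class GenomeIntervals:
    """A validated interval track (BED / bedGraph dialects).

    Backed by a DataFrame with columns chrom, start, end, label, strand,
    value; 0-based half-open coordinates.
    """

    def __init__(self, df: pd.DataFrame, kind: str):
        if kind not in TRACK_KINDS:
            raise ValueError(f"unknown track kind {kind!r}")
        self.kind = kind
        df = df.copy()
        for col, default in (("label", ""), ("strand", "."), ("value", np.nan)):
            if col not in df:
                df[col] = default
        df["chrom"] = df["chrom"].map(normalize_chrom)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValueError(
                f"interval with start >= end: {bad['chrom']}:{bad['start']}-{bad['end']}"
            )
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        self._validate(df)
        self.df = df[["chrom", "start", "end", "label", "strand", "value"]]

    def _validate(self, df: pd.DataFrame) -> None:
        if self.kind == "methylation":
            v = df["value"].to_numpy(float)
            if np.isnan(v).any() or (v < 0).any() or (v > 1).any():
                raise ValueError("methylation values must lie in [0, 1]")
        elif self.kind == "replication_timing":
            if df["value"].isna().any():
                raise ValueError("replication_timing intervals need a value")
        elif self.kind == "replication_direction":
            if not df["label"].isin(["left", "right"]).all():
                raise ValueError("replication_direction labels must be left/right")
            for _, grp in df.groupby("chrom", sort=False):
                if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                    raise ValueError("overlapping replication_direction intervals")
        elif self.kind == "gene":
            if not df["strand"].isin(["+", "-"]).all():
                raise ValueError("gene intervals need strand + or -")

    def __len__(self) -> int:
        return len(self.df)

    def per_chrom(self) -> dict[str, pd.DataFrame]:
        return {c: g for c, g in self.df.groupby("chrom", sort=False)}

    def merged(self) -> "GenomeIntervals":
        """Union of intervals (labels/values dropped), non-overlapping."""
        rows = []
        for chrom, grp in self.df.groupby("chrom", sort=False):
            cur_s = cur_e = None
            for s, e in zip(grp["start"], grp["end"]):
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    rows.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            if cur_s is not None:
                rows.append((chrom, cur_s, cur_e))
        return GenomeIntervals(
            pd.DataFrame(rows, columns=["chrom", "start", "end"]), kind="region"
        )


def read_track(path: str | Path, kind: str) -> GenomeIntervals:
    """Read a BED (gene/replication_direction/region) or bedGraph
    (methylation/replication_timing) file into validated intervals."""
    if kind not in TRACK_KINDS:
        raise ValueError(f"unknown track kind {kind!r}")
    if kind in ("methylation", "replication_timing"):
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                         names=["chrom", "start", "end", "value"],
                         dtype={"chrom": str})
    else:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "label", "score", "strand"],
                         dtype={"chrom": str})
        df = df.drop(columns=["score"])
        if df["strand"].isna().all():
            df["strand"] = "."
    return GenomeIntervals(df, kind=kind)


def write_track(track: GenomeIntervals, path: str | Path) -> None:
    df = track.df
    if track.kind in ("methylation", "replication_timing"):
        out = df[["chrom", "start", "end", "value"]]
    else:
        out = df.assign(score=0)[["chrom", "start", "end", "label", "score", "strand"]]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_vcf(path: str | Path, sample: str | None = None) -> pd.DataFrame:
    """Read PASS records from a VCF 4.x file into the mutation container.

    Only records whose FILTER is exactly PASS are returned; multi-allelic
    records are split into one row per alt allele.  An empty file after
    filtering yields an empty frame, not an error.
    """
    sample_id = sample if sample is not None else Path(path).stem.replace(".vcf", "")
    rows: list[tuple] = []
    try:
        vf = pysam.VariantFile(str(path))
        for rec in vf:
            filters = list(rec.filter.keys())
            if filters and filters != ["PASS"]:
                continue
            if not filters:  # '.' — undeclared, treated as non-PASS
                continue
            for alt in rec.alts or ():
                rows.append((rec.chrom, rec.pos, rec.ref, alt, sample_id))
    except (ValueError, OSError) as exc:
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    if not rows:
        return pd.DataFrame(columns=MUTATION_COLUMNS)
    return validate_mutations(pd.DataFrame(rows, columns=MUTATION_COLUMNS))


def write_vcf(df: pd.DataFrame, path: str | Path,
              contig_lengths: dict[str, int]) -> None:
    """Write a minimal, pysam-readable VCF 4.2 with FILTER=PASS records."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={normalize_chrom(chrom)},length={length}>\n")
        fh.write('##FILTER=<ID=PASS,Description="All filters passed">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        if df.empty:
            return
        body = pd.DataFrame({
            "chrom": df["chrom"].map(normalize_chrom),
            "pos": df["pos"].astype(np.int64),
            "id": ".",
            "ref": df["ref"],
            "alt": df["alt"],
            "qual": ".",
            "filter": "PASS",
            "info": ".",
        }).sort_values(["chrom", "pos"], kind="mergesort")
        body.to_csv(fh, sep="\t", header=False, index=False)


def trinucleotide_context(genome: ReferenceGenome, chrom: str, pos: int) -> str:
    """Plus-strand reference 3-mer centred on a 1-based SNV position.

    Positions at a chromosome edge (pos 1 or pos == length) have no full
    context and are a precondition error.  A context containing N is
    returned as-is; spectrum building drops such mutations with a logged
    count.
    """
    n = genome.length(chrom)
    if pos <= 1 or pos >= n:
        raise ValueError(f"position {pos} on {chrom} has no full trinucleotide context")
    return genome.slice(chrom, pos - 2, pos + 1)


def trinucleotide_codes(genome: ReferenceGenome, df: pd.DataFrame) -> np.ndarray:
    """Vectorised context codes for a mutation frame.

    Returns ``code = 16*b5 + 4*b0 + b3`` over base codes (A,C,G,T)=0..3 of
    the 5' base, the reference base, and the 3' base; any component equal
    to N yields code 64 (invalid).  Also validates that the frame's ref
    alleles match the reference genome.
    """
    codes = np.full(len(df), 64, dtype=np.int16)
    for chrom, grp in df.groupby("chrom", sort=False):
        arr = genome.base_codes(chrom)
        pos0 = grp["pos"].to_numpy(np.int64) - 1
        if (pos0 < 1).any() or (pos0 >= len(arr) - 1).any():
            raise ValueError(f"mutation without full context on chromosome {chrom}")
        b5, b0, b3 = arr[pos0 - 1], arr[pos0], arr[pos0 + 1]
        ref_code = _BASE_CODE[
            np.frombuffer("".join(grp["ref"]).encode(), dtype=np.uint8)
        ] if (grp["ref"].str.len() == 1).all() else None
        if ref_code is not None and not np.array_equal(ref_code, b0):
            bad = int(np.nonzero(ref_code != b0)[0][0])
            row = grp.iloc[bad]
            raise ValueError(
                f"ref allele mismatch at {row['chrom']}:{row['pos']} "
                f"(VCF {row['ref']}, reference {chr(genome._chrom_array(chrom)[row['pos']-1])})"
            )
        ok = (b5 < 4) & (b0 < 4) & (b3 < 4)
        c = np.where(ok, 16 * b5.astype(np.int16) + 4 * b0 + b3, 64)
        codes[df.index.get_indexer(grp.index)] = c
    return codes


def positions_in_intervals(pos: np.ndarray, starts: np.ndarray,
                           ends: np.ndarray) -> np.ndarray:
    """Index of the (sorted, non-overlapping) interval containing each
    1-based position, or -1.  The single home of the 1-based/0-based
    conversion: position p falls in [s, e) iff s <= p-1 < e."""
    p0 = np.asarray(pos, dtype=np.int64) - 1
    idx = np.searchsorted(starts, p0, side="right") - 1
    inside = (idx >= 0) & (p0 < ends[np.clip(idx, 0, None)])
    return np.where(inside, idx, -1)
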