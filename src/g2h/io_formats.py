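"""Readers and writers for the external representations used by the pipeline.

Three inputs are understood:

* a **genotype matrix**: tab-separated text with columns ``locus_id``,
  ``chrom``, ``pos`` followed by one column per sample, each cell a diploid
  call such as ``AA``/``AG``/``GG`` (or a missing code);
* a **haplotype-block map**: BED4 (0-based, half-open) tiling each chromosome
  seamlessly — the unit of background assessment;
* an optional **chromosome table**: TSV with physical (and, for simulation,
  genetic) lengths.

Internally every interval is 0-based half-open; human-facing output tables
are written 1-based inclusive.  Genotype calls are unordered allele pairs
("GA" is normalised to "AG"); phase is never used.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: internal missing-call sentinel
MISSING = "NN"

#: call strings treated as missing on input (configurable per reader call)
DEFAULT_MISSING_CODES = frozenset({"NN", "--", ".", "", "NA", "nan", "./.", "N"})

_BASES = frozenset("ACGT")

META_COLUMNS = ("locus_id", "chrom", "pos")

#: float precision of all written report tables (round-trip contract)
FLOAT_FORMAT = "%.6f"


class FormatError(ValueError):
    """Malformed input file (bad header, non-integer position, ...)."""


class ValidationError(ValueError):
    """Structurally valid file whose content violates an invariant."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class LocusTable:
    """SNP loci x samples genotype matrix.

    ``df`` holds ``locus_id, chrom, pos`` plus one normalised call column per
    sample, sorted by (chromosome first-appearance order, position).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        for col in META_COLUMNS:
            if col not in self.df.columns:
                raise FormatError(f"genotype table lacks required column {col!r}")
        if (self.df["pos"] < 1).any():
            raise ValidationError("positions must be >= 1 (1-based bp)")
        dup = self.df.duplicated(subset=["chrom", "pos", "locus_id"])
        if dup.any():
            first = self.df.loc[dup.idxmax()]
            raise ValidationError(
                f"duplicate locus {first['locus_id']} at {first['chrom']}:{first['pos']}"
            )

    @property
    def samples(self) -> list[str]:
        return [c for c in self.df.columns if c not in META_COLUMNS]

    @property
    def n_loci(self) -> int:
        return len(self.df)

    def calls(self, sample: str) -> np.ndarray:
        if sample not in self.df.columns or sample in META_COLUMNS:
            raise KeyError(f"unknown sample {sample!r}")
        return self.df[sample].to_numpy(dtype=object)

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy(dtype=object)

    @property
    def pos(self) -> np.ndarray:
        return self.df["pos"].to_numpy(dtype=np.int64)


@dataclass
class BlockMap:
    """Seamless tiling of each chromosome by haplotype blocks (0-based, half-open)."""

    df: pd.DataFrame  # chrom, start, end, block_id; ordered; global block index = row order
    chrom_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.chrom_order:
            self.chrom_order = list(pd.unique(self.df["chrom"]))
        self._validate()

    def _validate(self) -> None:
        df = self.df
        if (df["end"] <= df["start"]).any():
            bad = df.loc[(df["end"] <= df["start"]).idxmax()]
            raise ValidationError(f"block {bad['block_id']} has end <= start")
        for chrom, sub in df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            ids = sub["block_id"].to_numpy()
            gaps = starts[1:] != ends[:-1]
            if gaps.any():
                k = int(np.argmax(gaps))
                kind = "gap" if starts[k + 1] > ends[k] else "overlap"
                raise ValidationError(
                    f"{kind} on {chrom} between blocks {ids[k]} "
                    f"([{starts[k]},{ends[k]})) and {ids[k + 1]} "
                    f"([{starts[k + 1]},{ends[k + 1]}))"
                )

    @property
    def n_blocks(self) -> int:
        return len(self.df)

    def chrom_lengths(self) -> dict[str, int]:
        """Total tiled length per chromosome (== chromosome length for full tilings)."""
        out: dict[str, int] = {}
        for chrom, sub in self.df.groupby("chrom", sort=False):
            out[str(chrom)] = int((sub["end"] - sub["start"]).sum())
        return out

    def validate_against(self, chrom_table: "ChromTable") -> None:
        lengths = chrom_table.lengths()
        for chrom, tiled in self.chrom_lengths().items():
            if chrom in lengths and lengths[chrom] != tiled:
                raise ValidationError(
                    f"blocks on {chrom} tile {tiled} bp but chromosome length is "
                    f"{lengths[chrom]} bp"
                )


@dataclass
class ChromTable:
    """Chromosome physical lengths (bp) and optional genetic lengths (cM)."""

    df: pd.DataFrame  # chrom, length_bp[, genetic_length_cM]

    def __post_init__(self) -> None:
        if (self.df["length_bp"] <= 0).any():
            raise ValidationError("chromosome lengths must be positive")
        if "genetic_length_cM" in self.df.columns:
            gl = self.df["genetic_length_cM"].dropna()
            if (gl <= 0).any():
                raise ValidationError("genetic lengths must be positive")

    def lengths(self) -> dict[str, int]:
        return dict(zip(self.df["chrom"].astype(str), self.df["length_bp"].astype(int)))

    def genetic_lengths(self) -> dict[str, float]:
        if "genetic_length_cM" not in self.df.columns:
            return {}
        return dict(
            zip(self.df["chrom"].astype(str), self.df["genetic_length_cM"].astype(float))
        )


# ---------------------------------------------------------------------------
# call normalisation
# ---------------------------------------------------------------------------


def normalize_call(raw: object, missing_codes=DEFAULT_MISSING_CODES) -> str:
    """Normalise one diploid call to a sorted two-letter string or ``MISSING``.

    Accepts separators ("A/G", "A|G"); anything not a pair of ACGT bases —
    including explicit missing codes — maps to the missing sentinel.
    """
    s = str(raw).strip()
    if s in missing_codes:
        return MISSING
    s = s.upper().replace("/", "").replace("|", "")
    if s in missing_codes:
        return MISSING
    if len(s) == 2 and set(s) <= _BASES:
        return s if s[0] <= s[1] else s[1] + s[0]
    return MISSING


def _normalize_column(values: pd.Series, missing_codes) -> np.ndarray:
    # few distinct call strings per column -> translate via a small dict
    uniq = pd.unique(values)
    table = {u: normalize_call(u, missing_codes) for u in uniq}
    return values.map(table).to_numpy(dtype=object)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_genotype_matrix(path: str, missing_codes=DEFAULT_MISSING_CODES) -> LocusTable:
    """Read a TSV genotype matrix into a :class:`LocusTable`.

    The header row must contain ``locus_id``, ``chrom``, ``pos`` followed by
    unique sample names.  Loci are sorted by (chromosome first-appearance
    order, position); calls are normalised to unordered pairs.
    """
    missing_codes = frozenset(missing_codes) | {MISSING}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) != len(set(header)):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise FormatError(f"duplicate column names in header: {dups}")
    for col in META_COLUMNS:
        if col not in header:
            raise FormatError(f"missing required column {col!r}")

    df = pd.read_csv(path, sep="\t", dtype=str)
    try:
        df["pos"] = df["pos"].astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-integer position in {path}: {exc}") from None

    sample_cols = [c for c in df.columns if c not in META_COLUMNS]
    for col in sample_cols:
        df[col] = _normalize_column(df[col], missing_codes)

    df = _sort_loci(df)
    return LocusTable(df)


def _sort_loci(df: pd.DataFrame) -> pd.DataFrame:
    order = {c: i for i, c in enumerate(pd.unique(df["chrom"]))}
    key = df["chrom"].map(order)
    idx = np.lexsort((df["pos"].to_numpy(), key.to_numpy()))
    return df.iloc[idx].reset_index(drop=True)


def read_vcf(path: str) -> LocusTable:
    """Convenience reader: biallelic SNPs from a VCF (GT field only).

    Produces the same :class:`LocusTable` as :func:`read_genotype_matrix`;
    multi-allelic or non-SNP records are skipped.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(path, gts012=False)
    samples = list(vcf.samples)
    rows = []
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            continue
        alleles = (var.REF.upper(), var.ALT[0].upper())
        if not (set(alleles) <= _BASES):
            continue
        calls = []
        for gt in var.genotypes:  # [a0, a1, phased]
            a0, a1 = gt[0], gt[1]
            if a0 < 0 or a1 < 0:
                calls.append(MISSING)
            else:
                pair = alleles[a0] + alleles[a1]
                calls.append(pair if pair[0] <= pair[1] else pair[1] + pair[0])
        rows.append([var.ID or f"snp{i}", var.CHROM, var.POS] + calls)
    df = pd.DataFrame(rows, columns=list(META_COLUMNS) + samples)
    df["pos"] = df["pos"].astype(np.int64)
    return LocusTable(_sort_loci(df))


def read_block_map(path: str) -> BlockMap:
    """Read a BED4 block map (chrom, start, end, block_id; 0-based half-open)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "block_id"],
        dtype={"chrom": str, "block_id": str},
        comment="#",
    )
    try:
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-integer BED coordinate in {path}: {exc}") from None
    # order within chromosome by start; chromosome order = first appearance
    order = {c: i for i, c in enumerate(pd.unique(df["chrom"]))}
    idx = np.lexsort((df["start"].to_numpy(), df["chrom"].map(order).to_numpy()))
    df = df.iloc[idx].reset_index(drop=True)
    return BlockMap(df)


def read_chrom_table(path: str) -> ChromTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if "chrom" not in df.columns or "length_bp" not in df.columns:
        raise FormatError("chromosome table needs columns chrom, length_bp")
    return ChromTable(df)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

SUMMARY_COLUMNS = [
    "sample",
    "prpg",
    "htbr",
    "wgbr",
    "n_unrecovered_fragments",
    "cfdi",
    "high_recovery",
]

SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "n_blocks", "median", "state"]

BREAKPOINT_COLUMNS = ["sample", "chrom", "left_block", "right_block", "start", "end"]


def write_reports(
    summary: pd.DataFrame,
    segments: pd.DataFrame,
    breakpoints: pd.DataFrame,
    out_dir: str,
) -> dict[str, str]:
    """Write the per-individual summary, segment and breakpoint tables.

    Segments/breakpoints are converted from internal 0-based half-open to
    1-based inclusive coordinates.  Floats are printed at 6 decimals so that
    re-reading reproduces values at the printed precision.
    """
    if summary.empty or segments.empty:
        raise ValueError("write_reports requires non-empty summary and segments")
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "summary": os.path.join(out_dir, "summary.tsv"),
        "segments": os.path.join(out_dir, "segments.tsv"),
        "breakpoints": os.path.join(out_dir, "breakpoints.tsv"),
    }
    summary[SUMMARY_COLUMNS].to_csv(
        paths["summary"], sep="\t", index=False, float_format=FLOAT_FORMAT
    )
    seg = segments.copy()
    seg["start"] = seg["start"] + 1  # 0-based half-open -> 1-based inclusive
    seg[SEGMENT_COLUMNS].to_csv(
        paths["segments"], sep="\t", index=False, float_format=FLOAT_FORMAT
    )
    bp = breakpoints.copy()
    if not bp.empty:
        bp["start"] = bp["start"]  # already last base of left block, 1-based below
    bp[BREAKPOINT_COLUMNS].to_csv(
        paths["breakpoints"], sep="\t", index=False, float_format=FLOAT_FORMAT
    )
    return paths


def segments_to_internal(seg: pd.DataFrame) -> pd.DataFrame:
    """Invert the output coordinate convention (1-based inclusive -> 0-based half-open)."""
    out = seg.copy()
    out["start"] = out["start"] - 1
    return out
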