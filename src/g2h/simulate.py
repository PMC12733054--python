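"""Ground-truthed backcross population simulator.

Emulates the experimental substrate of a maize marker-assisted backcross
programme: two fully homozygous inbred parents polymorphic at every
simulated SNP, an F1 that is heterozygous genome-wide, and BC1/BC2 progeny
produced by recurrent crossing to the RP.  Meiosis draws the crossover
count per chromosome from a Poisson with mean equal to the genetic length
in Morgans (no interference) with crossover positions uniform along the
chromosome; the transmitted gamete alternates parental origin across
crossovers.  Donor chromatin in progeny is therefore always heterozygous —
donor homozygotes can only arise from injected genotyping error.

The genome default is 10 chromosomes at maize-like physical/genetic scale,
tiled seamlessly by ~6000 haplotype blocks drawn by stick-breaking with a
minimum-length floor, with 1 + Poisson-distributed SNPs per block (mean 8).
Genotyping error replaces a call with one of the two other possible
genotypes at the configured rate; missingness masks calls independently.
Everything is deterministic under a fixed seed.

The returned :class:`SimTruth` carries each individual's true donor
intervals, crossover positions and length-weighted RP fraction
(heterozygous segments count as non-recovered, matching the code-2
semantics of the scoring pipeline).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MISSING, BlockMap, ChromTable, LocusTable

# maize-like genome template (bp / cM per chromosome)
DEFAULT_CHROM_LENGTHS_BP = (
    308_452_000,
    243_675_000,
    238_017_000,
    250_330_000,
    226_353_000,
    181_357_000,
    185_808_000,
    182_411_000,
    163_004_000,
    152_435_000,
)
DEFAULT_GENETIC_LENGTHS_CM = (200.0, 180.0, 175.0, 170.0, 165.0, 150.0, 160.0, 150.0, 145.0, 140.0)


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Study-condition parameters of one simulated backcross population."""

    n_chrom: int = 10
    chrom_lengths_bp: tuple[int, ...] = DEFAULT_CHROM_LENGTHS_BP
    genetic_lengths_cM: tuple[float, ...] = DEFAULT_GENETIC_LENGTHS_CM
    n_blocks_total: int = 6000
    mean_snps_per_block: float = 8.0
    generation: int = 1  # 1 = BC1, 2 = BC2
    pop_size: int = 50
    error_rate: float = 0.02
    missing_rate: float = 0.05
    seed: int = 0
    #: validation aids: snap crossovers to block boundaries, keeping them at
    #: least `end_margin_blocks` blocks away from chromosome ends
    snap_crossovers: bool = False
    end_margin_blocks: int = 0
    sample_prefix: str = "BC"

    def __post_init__(self) -> None:
        self.chrom_lengths_bp = tuple(self.chrom_lengths_bp)[: self.n_chrom]
        self.genetic_lengths_cM = tuple(self.genetic_lengths_cM)[: self.n_chrom]
        if len(self.chrom_lengths_bp) != self.n_chrom:
            raise SimConfigError("need one physical length per chromosome")
        if len(self.genetic_lengths_cM) != self.n_chrom:
            raise SimConfigError("need one genetic length per chromosome")
        for rate in (self.error_rate, self.missing_rate):
            if not (0.0 <= rate <= 1.0):
                raise SimConfigError("rates must lie in [0, 1]")
        if self.pop_size < 1:
            raise SimConfigError("population size must be >= 1")
        if self.generation not in (1, 2):
            raise SimConfigError("generation must be 1 (BC1) or 2 (BC2)")
        if any(l <= 0 for l in self.chrom_lengths_bp) or any(
            g <= 0 for g in self.genetic_lengths_cM
        ):
            raise SimConfigError("chromosome lengths must be positive")

    @property
    def chroms(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]


@dataclass
class SimTruth:
    """Ground truth of a simulated population.

    ``true_rp_fraction`` counts heterozygous (donor) segments as fully
    non-recovered, matching the code-2 semantics of the scoring pipeline
    (expectation 0.5 in BC1, 0.75 in BC2).  ``true_rp_allele_fraction``
    counts them half-recovered — the classical allele-dosage expectation of
    backcross theory (0.75 in BC1, 0.875 in BC2).
    """

    donor_segments: pd.DataFrame  # sample, chrom, start, end (0-based half-open)
    crossovers: pd.DataFrame  # sample, chrom, pos (0-based bp)
    true_rp_fraction: pd.Series  # indexed by sample, in [0, 1]
    true_rp_allele_fraction: pd.Series = None

    def donor_intervals(self, sample: str, chrom: str) -> np.ndarray:
        sub = self.donor_segments
        sub = sub[(sub["sample"] == sample) & (sub["chrom"] == chrom)]
        return sub[["start", "end"]].to_numpy(dtype=np.int64)


@dataclass
class SimResult:
    locus_table: LocusTable
    block_map: BlockMap
    chrom_table: ChromTable
    truth: SimTruth
    config: SimConfig = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------


def _stick_break_blocks(length: int, n_blocks: int, rng) -> np.ndarray:
    """Seamless block boundaries: stick-breaking with a minimum-length floor."""
    floor = max(1, min(50_000, length // (2 * n_blocks)))
    free = length - n_blocks * floor
    w = rng.dirichlet(np.ones(n_blocks))
    extra = np.floor(w * free).astype(np.int64)
    extra[: free - extra.sum()] += 1  # distribute the rounding remainder
    lengths = floor + extra
    bounds = np.concatenate(([0], np.cumsum(lengths)))
    assert bounds[-1] == length
    return bounds


def _build_genome(config: SimConfig, rng):
    """Block map, per-block SNP counts and SNP positions for every chromosome."""
    total_bp = sum(config.chrom_lengths_bp)
    rows, snp_rows = [], []
    for ci, (chrom, length) in enumerate(zip(config.chroms, config.chrom_lengths_bp)):
        n_blocks = max(1, round(config.n_blocks_total * length / total_bp))
        bounds = _stick_break_blocks(length, n_blocks, rng)
        n_snps = 1 + rng.poisson(max(config.mean_snps_per_block - 1.0, 0.0), n_blocks)
        for b in range(n_blocks):
            start, end = int(bounds[b]), int(bounds[b + 1])
            rows.append((chrom, start, end, f"{chrom}_b{b + 1}"))
            # uniform unique SNP positions within the block, 1-based
            width = end - start
            k = min(int(n_snps[b]), width)
            offs = np.sort(rng.choice(width, size=k, replace=False))
            for pos0 in start + offs:
                snp_rows.append((chrom, int(pos0) + 1))
    block_df = pd.DataFrame(rows, columns=["chrom", "start", "end", "block_id"])
    snp_df = pd.DataFrame(snp_rows, columns=["chrom", "pos"])
    return BlockMap(block_df), snp_df


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------


def _intersect(intervals_a: list[tuple[int, int]], intervals_b) -> list[tuple[int, int]]:
    out = []
    for a0, a1 in intervals_a:
        for b0, b1 in intervals_b:
            s, e = max(a0, b0), min(a1, b1)
            if e > s:
                out.append((s, e))
    return out


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(iv) for iv in out]


def _draw_crossovers(
    length: int, morgans: float, rng, snap_boundaries, min_spacing: int = 0
) -> np.ndarray:
    """Crossover positions (bp) of one meiosis on one chromosome.

    In snap mode each crossover moves to the nearest allowed block boundary;
    crossovers landing on the same boundary cancel pairwise, and pairs of
    consecutive crossovers closer than ``min_spacing`` boundaries (which
    would create a segment too short to be callable) are removed together,
    preserving phase beyond them.
    """
    n_co = rng.poisson(morgans)
    xs = np.sort(rng.uniform(0, length, size=n_co))
    if snap_boundaries is not None and n_co:
        if len(snap_boundaries) == 0:
            return np.array([], dtype=np.int64)
        idx = np.clip(
            np.searchsorted(snap_boundaries, xs), 0, len(snap_boundaries) - 1
        )
        left_ok = idx > 0
        pick = np.where(
            left_ok
            & (
                np.abs(xs - snap_boundaries[np.maximum(idx - 1, 0)])
                < np.abs(xs - snap_boundaries[idx])
            ),
            idx - 1,
            idx,
        )
        counts = np.bincount(pick, minlength=len(snap_boundaries))
        chosen = list(np.flatnonzero(counts % 2 == 1))
        if min_spacing > 0:
            changed = True
            while changed and len(chosen) >= 2:
                changed = False
                for q in range(len(chosen) - 1):
                    if chosen[q + 1] - chosen[q] < min_spacing:
                        del chosen[q : q + 2]
                        changed = True
                        break
        xs = snap_boundaries[np.asarray(chosen, dtype=np.int64)].astype(float)
    return xs


def _gamete_donor(
    length: int,
    xs: np.ndarray,
    first_homolog: int,
    donor_a: list[tuple[int, int]],
    donor_b: list[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Donor intervals of the transmitted gamete.

    The gamete alternates between homolog A and B at each crossover; each
    homolog carries its own donor intervals (pure RP homolog: none)."""
    bounds = np.concatenate(([0.0], xs, [float(length)]))
    donor = (donor_a, donor_b)
    out: list[tuple[int, int]] = []
    h = first_homolog
    for s, e in zip(bounds[:-1], bounds[1:]):
        seg = (int(np.floor(s)), int(np.floor(e)))
        if seg[1] > seg[0]:
            out.extend(_intersect([seg], donor[h]))
        h = 1 - h
    return _merge(out)


def _backcross_progeny(config: SimConfig, block_map: BlockMap, rng, parent_donor=None):
    """One meiosis per chromosome against the RP; returns donor intervals + crossovers.

    ``parent_donor`` maps chrom -> donor intervals on the heterozygous
    parent's non-RP homolog (the whole chromosome for an F1 parent)."""
    donor_by_chrom: dict[str, list[tuple[int, int]]] = {}
    co_by_chrom: dict[str, np.ndarray] = {}
    bdf = block_map.df
    for chrom, length, cm in zip(
        config.chroms, config.chrom_lengths_bp, config.genetic_lengths_cM
    ):
        snap = None
        if config.snap_crossovers:
            sub = bdf[bdf["chrom"] == chrom]
            ends = sub["end"].to_numpy()[:-1]  # interior boundaries
            em = config.end_margin_blocks
            n = len(sub)
            # boundary t separates blocks t-1 | t; need em <= t <= n - em
            snap = ends[max(em - 1, 0) : max(n - em, 0)]
        xs = _draw_crossovers(
            length, cm / 100.0, rng, snap, min_spacing=config.end_margin_blocks
        )
        h0 = int(rng.integers(0, 2))
        if parent_donor is None:
            hom_b = [(0, length)]  # F1 parent: the non-RP homolog is pure donor
        else:
            hom_b = parent_donor.get(chrom, [])
        donor_by_chrom[chrom] = _gamete_donor(length, xs, h0, [], hom_b)
        co_by_chrom[chrom] = xs
    return donor_by_chrom, co_by_chrom


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------

_GENO_CHOICES = ("rp", "het", "dp")


def simulate_population(config: SimConfig) -> SimResult:
    """Simulate genotypes, block map, chromosome table and ground truth."""
    rng = np.random.default_rng(config.seed)
    block_map, snp_df = _build_genome(config, rng)

    n_snps = len(snp_df)
    bases = np.array(list("ACGT"))
    rp_idx = rng.integers(0, 4, size=n_snps)
    shift = rng.integers(1, 4, size=n_snps)
    dp_idx = (rp_idx + shift) % 4
    rp_al = bases[rp_idx]
    dp_al = bases[dp_idx]
    swap = rp_al > dp_al
    lo = np.where(swap, dp_al, rp_al)
    hi = np.where(swap, rp_al, dp_al)
    call_rp = np.char.add(rp_al, rp_al)
    call_het = np.char.add(lo, hi)
    call_dp = np.char.add(dp_al, dp_al)

    # BC2 descends from one internally simulated BC1 parent
    parent_donor = None
    if config.generation == 2:
        parent_donor, _ = _backcross_progeny(config, block_map, rng)

    samples = [f"{config.sample_prefix}{config.generation}-{i + 1}" for i in range(config.pop_size)]
    total_bp = sum(config.chrom_lengths_bp)
    chrom_pos0 = {
        chrom: snp_df.loc[snp_df["chrom"] == chrom, "pos"].to_numpy() - 1
        for chrom in config.chroms
    }

    geno_cols: dict[str, np.ndarray] = {}
    seg_rows, co_rows, frac_rows = [], [], []
    for sample in samples:
        donor, cos = _backcross_progeny(config, block_map, rng, parent_donor)
        het_mask = np.zeros(n_snps, dtype=bool)
        donor_len = 0
        offset = 0
        for chrom in config.chroms:
            pos0 = chrom_pos0[chrom]
            ivs = donor[chrom]
            for s, e in ivs:
                seg_rows.append((sample, chrom, s, e))
                donor_len += e - s
            if ivs:
                flat = np.array(ivs).ravel()
                inside = np.searchsorted(flat, pos0, side="right") % 2 == 1
                het_mask[offset : offset + len(pos0)] = inside
            for x in cos[chrom]:
                co_rows.append((sample, chrom, float(x)))
            offset += len(pos0)
        calls = np.where(het_mask, call_het, call_rp)

        if config.error_rate > 0:
            err = rng.random(n_snps) < config.error_rate
            # replace with one of the two *other* genotypes, uniformly
            truth_kind = np.where(het_mask, 1, 0)  # index into rp/het/dp
            alt_pick = rng.integers(0, 2, size=n_snps)
            stacked = np.stack([call_rp, call_het, call_dp])  # (3, n_snps)
            other_kind = (truth_kind + 1 + alt_pick) % 3
            others = stacked[other_kind, np.arange(n_snps)]
            calls = np.where(err, others, calls)
        if config.missing_rate > 0:
            miss = rng.random(n_snps) < config.missing_rate
            calls = np.where(miss, MISSING, calls)
        geno_cols[sample] = calls.astype(object)
        frac_rows.append(1.0 - donor_len / total_bp)

    columns = {
        "locus_id": [f"snp{i + 1}" for i in range(n_snps)],
        "chrom": snp_df["chrom"].to_numpy(),
        "pos": snp_df["pos"].to_numpy(),
        "RP": np.asarray(call_rp, dtype=object),
        "DP": np.asarray(call_dp, dtype=object),
    }
    columns.update(geno_cols)
    locus_table = LocusTable(pd.DataFrame(columns))

    chrom_table = ChromTable(
        pd.DataFrame(
            {
                "chrom": config.chroms,
                "length_bp": list(config.chrom_lengths_bp),
                "genetic_length_cM": list(config.genetic_lengths_cM),
            }
        )
    )
    truth = SimTruth(
        donor_segments=pd.DataFrame(
            seg_rows, columns=["sample", "chrom", "start", "end"]
        ),
        crossovers=pd.DataFrame(co_rows, columns=["sample", "chrom", "pos"]),
        true_rp_fraction=pd.Series(frac_rows, index=samples, name="true_rp_fraction"),
        true_rp_allele_fraction=pd.Series(
            [0.5 * (1.0 + f) for f in frac_rows],
            index=samples,
            name="true_rp_allele_fraction",
        ),
    )
    return SimResult(locus_table, block_map, chrom_table, truth, config)


# ---------------------------------------------------------------------------
# block-resolution truth
# ---------------------------------------------------------------------------


def rasterize_donor_to_blocks(
    donor_intervals: np.ndarray, block_starts: np.ndarray, block_ends: np.ndarray
) -> np.ndarray:
    """True/False per block: is > 50% of the block's length donor-covered?

    The majority rule mirrors the scoring pipeline's own threshold semantics.
    """
    n = len(block_starts)
    overlap = np.zeros(n, dtype=np.int64)
    for s, e in np.asarray(donor_intervals).reshape(-1, 2):
        first = int(np.searchsorted(block_ends, s, side="right"))
        last = int(np.searchsorted(block_starts, e, side="left"))
        for b in range(first, min(last, n)):
            overlap[b] += max(0, min(e, block_ends[b]) - max(s, block_starts[b]))
    return overlap * 2 > (block_ends - block_starts)


def truth_metrics(truth: SimTruth, block_map: BlockMap) -> pd.DataFrame:
    """Block-resolution truth per individual: true WGBR and fragment count."""
    bdf = block_map.df
    rows = []
    for sample in truth.true_rp_fraction.index:
        donor_bp = 0
        n_frag = 0
        total_bp = 0
        for chrom, sub in bdf.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            total_bp += int((ends - starts).sum())
            ivs = truth.donor_intervals(sample, chrom)
            flags = rasterize_donor_to_blocks(ivs, starts, ends)
            donor_bp += int((ends - starts)[flags].sum())
            # fragments = maximal runs of donor blocks
            padded = np.concatenate(([False], flags, [False]))
            n_frag += int(np.count_nonzero(padded[1:] & ~padded[:-1]))
        rows.append(
            {
                "sample": sample,
                "true_wgbr_blocks": 1.0 - donor_bp / total_bp,
                "n_fragments_blocks": n_frag,
            }
        )
    return pd.DataFrame(rows)


def flip_codes(codes: np.ndarray, rate: float, rng) -> np.ndarray:
    """Symmetric SNP-coding error: swap codes 1 <-> 2 at the given rate."""
    out = np.array(codes, copy=True)
    flip = (rng.random(out.shape) < rate) & (out != 0)
    out[flip] = 3 - out[flip]
    return out


# ---------------------------------------------------------------------------
# file export / config ingestion
# ---------------------------------------------------------------------------


def write_simulation(sim: SimResult, out_dir: str) -> dict[str, str]:
    """Write genotype TSV, BED block map, chromosome table and truth tables."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "genotypes": os.path.join(out_dir, "genotypes.tsv"),
        "blocks": os.path.join(out_dir, "blocks.bed"),
        "chroms": os.path.join(out_dir, "chromosomes.tsv"),
        "truth_segments": os.path.join(out_dir, "truth_donor_segments.tsv"),
        "truth_crossovers": os.path.join(out_dir, "truth_crossovers.tsv"),
        "truth_summary": os.path.join(out_dir, "truth_summary.tsv"),
    }
    sim.locus_table.df.to_csv(paths["genotypes"], sep="\t", index=False)
    sim.block_map.df.to_csv(paths["blocks"], sep="\t", index=False, header=False)
    sim.chrom_table.df.to_csv(paths["chroms"], sep="\t", index=False)
    sim.truth.donor_segments.to_csv(paths["truth_segments"], sep="\t", index=False)
    sim.truth.crossovers.to_csv(
        paths["truth_crossovers"], sep="\t", index=False, float_format="%.1f"
    )
    sim.truth.true_rp_fraction.rename_axis("sample").reset_index().to_csv(
        paths["truth_summary"], sep="\t", index=False, float_format="%.6f"
    )
    return paths


def load_sim_config(path: str) -> SimConfig:
    """Read a SimConfig from a YAML mapping of field names to values."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return SimConfig(**raw)
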