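"""Aggregation of SNP codes into haplotype-block proportions and states.

Each haplotype block accumulates the counts of recurrent (code 1) and
non-recurrent (code 2) SNPs of an individual; the block's recovery
proportion is ``p = n_recurrent / (n_recurrent + n_donor)`` (code-0 SNPs are
excluded, consistent with the missing-exclusion in PRPG).  A block with no
informative SNP is missing (state 0).  Given a threshold t a block is
*recovered* (state 1) iff ``p > t`` strictly, otherwise *unrecovered*
(state 2); the block-count recovery rate is

    HTBR = NS_HTP / N_HTP

over non-missing blocks.  The default threshold 0.5 can be re-derived from a
cohort with :func:`calibrate_threshold`, which contrasts block proportions on
nearly-fully-recovered chromosomes against nearly-fully-donor ones and picks
the first threshold where both class recovery-rate curves plateau.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coding import PolymorphicSet, UndefinedRateError
from .io_formats import BlockMap


class BlockMappingError(ValueError):
    """A polymorphic locus does not fall inside any block."""


class CalibrationError(ValueError):
    """Threshold calibration lacks an extreme chromosome class."""


DEFAULT_THRESHOLD = 0.5


# ---------------------------------------------------------------------------
# locus -> block assignment
# ---------------------------------------------------------------------------


def assign_loci_to_blocks(poly: PolymorphicSet, blocks: BlockMap) -> np.ndarray:
    """Map each polymorphic locus to its (unique) block's global row index.

    Blocks are 0-based half-open; locus positions are 1-based, so position
    ``pos`` lies in block [start, end) iff start < pos <= end.
    """
    out = np.full(poly.n, -1, dtype=np.int64)
    bdf = blocks.df
    for chrom, sub in bdf.groupby("chrom", sort=False):
        mask = poly.chrom == chrom
        if not mask.any():
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        pos0 = poly.pos[mask] - 1  # 0-based coordinate of the SNP
        k = np.searchsorted(starts, pos0, side="right") - 1
        ok = (k >= 0) & (pos0 < ends[np.clip(k, 0, len(ends) - 1)])
        local = np.where(ok, k, -1)
        rows = sub.index.to_numpy()
        idx = np.flatnonzero(mask)
        out[idx[ok]] = rows[local[ok]]
    bad = out < 0
    if bad.any():
        offenders = [
            f"{c}:{p}" for c, p in zip(poly.chrom[bad][:10], poly.pos[bad][:10])
        ]
        raise BlockMappingError(
            f"{int(bad.sum())} polymorphic loci outside all blocks, e.g. {offenders}"
        )
    return out


# ---------------------------------------------------------------------------
# block-state track
# ---------------------------------------------------------------------------


@dataclass
class BlockStateTrack:
    """Per-individual, per-block recovery counts, proportion and state.

    Arrays are (n_samples, n_blocks); ``p`` is NaN where a block has no
    informative SNP for that individual; ``states`` is 0 there, and in
    {1, 2} elsewhere once :func:`assign_block_states` has run.
    """

    samples: list[str]
    n_recurrent: np.ndarray
    n_donor: np.ndarray
    p: np.ndarray
    states: np.ndarray | None = field(default=None)

    @property
    def n_blocks(self) -> int:
        return self.n_recurrent.shape[1]


def aggregate_to_blocks(
    coded: np.ndarray,
    samples: list[str],
    locus_block: np.ndarray,
    n_blocks: int,
) -> BlockStateTrack:
    """Tally code-1/code-2 SNPs per block for every individual.

    ``coded`` is the (n_samples, n_loci) code matrix and ``locus_block`` the
    per-locus global block index from :func:`assign_loci_to_blocks`.
    """
    coded = np.atleast_2d(coded)
    n_samples = coded.shape[0]
    n1 = np.zeros((n_samples, n_blocks), dtype=np.int32)
    n2 = np.zeros_like(n1)
    for s in range(n_samples):
        row = coded[s]
        n1[s] = np.bincount(locus_block[row == 1], minlength=n_blocks)
        n2[s] = np.bincount(locus_block[row == 2], minlength=n_blocks)
    tot = n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, n1 / np.maximum(tot, 1), np.nan)
    return BlockStateTrack(samples=list(samples), n_recurrent=n1, n_donor=n2, p=p)


def assign_block_states(track: BlockStateTrack, threshold: float) -> BlockStateTrack:
    """Set block states: 1 iff ``p > threshold`` (strict), 2 iff defined and <=, 0 missing."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    defined = ~np.isnan(track.p)
    states = np.zeros(track.p.shape, dtype=np.uint8)
    states[defined & (track.p > threshold)] = 1
    states[defined & (track.p <= threshold)] = 2
    track.states = states
    return track


def htbr(states: np.ndarray) -> float:
    """Block-count recovery rate NS_HTP / N_HTP over one individual's states."""
    states = np.asarray(states)
    n = int(np.count_nonzero(states))
    if n == 0:
        raise UndefinedRateError("HTBR undefined: every block is missing")
    return int(np.count_nonzero(states == 1)) / n


# ---------------------------------------------------------------------------
# threshold calibration
# ---------------------------------------------------------------------------


def chromosome_snp_recovery(
    coded: np.ndarray, samples: list[str], locus_chrom: np.ndarray
) -> pd.DataFrame:
    """Per-(sample, chromosome) SNP recovery rate A/B; NaN where all codes 0."""
    coded = np.atleast_2d(coded)
    rows = []
    for chrom in pd.unique(pd.Series(locus_chrom)):
        mask = locus_chrom == chrom
        sub = coded[:, mask]
        b = (sub != 0).sum(axis=1)
        a = (sub == 1).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(b > 0, a / np.maximum(b, 1), np.nan)
        for s, r in zip(samples, rate):
            rows.append({"sample": s, "chrom": chrom, "snp_recovery": r})
    return pd.DataFrame(rows)


@dataclass
class ThresholdCalibration:
    """Result of the plateau-based threshold search."""

    grid: np.ndarray
    recovered_rates: np.ndarray  # class recovery-rate curve, recovered chromosomes
    unrecovered_rates: np.ndarray
    selected: float
    frac_recovered_above_half: float  # Fig-2b-style summary
    frac_unrecovered_below_half: float
    n_recovered_chroms: int
    n_unrecovered_chroms: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.grid,
                "recovered_class_rate": self.recovered_rates,
                "unrecovered_class_rate": self.unrecovered_rates,
            }
        )


def default_grid() -> np.ndarray:
    return np.round(np.arange(0.05, 0.951, 0.05), 2)


def calibrate_threshold(
    p_recovered: np.ndarray,
    p_unrecovered: np.ndarray,
    grid: np.ndarray | None = None,
    plateau_tol: float = 0.005,
) -> ThresholdCalibration:
    """Select the block-state threshold from extreme-chromosome block proportions.

    ``p_recovered`` / ``p_unrecovered`` pool the (non-missing) block
    proportions of individual-chromosomes whose SNP recovery is > 95% /
    <= 10%.  For every candidate threshold t the class recovery-rate curve is
    the fraction of class blocks with p > t.  The selected threshold is the
    smallest grid point after which both curves move by less than
    ``plateau_tol`` at each of the next two grid steps; if no such point
    exists the conventional 0.5 is returned.
    """
    p_rec = np.asarray(p_recovered, dtype=float)
    p_unr = np.asarray(p_unrecovered, dtype=float)
    p_rec = p_rec[~np.isnan(p_rec)]
    p_unr = p_unr[~np.isnan(p_unr)]
    if p_rec.size == 0 or p_unr.size == 0:
        raise CalibrationError(
            "calibration needs both extreme chromosome classes; "
            f"got {p_rec.size} recovered-class and {p_unr.size} unrecovered-class "
            "blocks — fall back to the default threshold 0.5"
        )
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)

    rec_curve = np.array([(p_rec > t).mean() for t in grid])
    unr_curve = np.array([(p_unr > t).mean() for t in grid])

    selected = DEFAULT_THRESHOLD
    for q in range(len(grid) - 2):
        d_rec = np.abs(np.diff(rec_curve[q : q + 3]))
        d_unr = np.abs(np.diff(unr_curve[q : q + 3]))
        if (d_rec < plateau_tol).all() and (d_unr < plateau_tol).all():
            selected = float(grid[q])
            break

    return ThresholdCalibration(
        grid=grid,
        recovered_rates=rec_curve,
        unrecovered_rates=unr_curve,
        selected=selected,
        frac_recovered_above_half=float((p_rec > 0.5).mean()),
        frac_unrecovered_below_half=float((p_unr < 0.5).mean()),
        n_recovered_chroms=-1,
        n_unrecovered_chroms=-1,
    )


def calibrate_from_cohort(
    track: BlockStateTrack,
    block_chrom: np.ndarray,
    coded: np.ndarray,
    locus_chrom: np.ndarray,
    recovered_min: float = 0.95,
    unrecovered_max: float = 0.10,
    grid: np.ndarray | None = None,
    plateau_tol: float = 0.005,
) -> ThresholdCalibration:
    """Cohort-level wrapper: classify extreme chromosomes by SNP recovery, then calibrate.

    An individual-chromosome joins the recovered class when its SNP recovery
    exceeds ``recovered_min`` and the unrecovered class when it is at most
    ``unrecovered_max``; its (non-missing) block proportions are pooled per
    class.
    """
    rec = chromosome_snp_recovery(coded, track.samples, locus_chrom)
    p_rec_parts, p_unr_parts = [], []
    n_rec = n_unr = 0
    sample_index = {s: i for i, s in enumerate(track.samples)}
    for _, row in rec.iterrows():
        r = row["snp_recovery"]
        if np.isnan(r):
            continue
        if r > recovered_min:
            cls = p_rec_parts
            n_rec += 1
        elif r <= unrecovered_max:
            cls = p_unr_parts
            n_unr += 1
        else:
            continue
        si = sample_index[row["sample"]]
        cls.append(track.p[si, block_chrom == row["chrom"]])
    if n_rec == 0 or n_unr == 0:
        raise CalibrationError(
            f"found {n_rec} recovered-class and {n_unr} unrecovered-class "
            "chromosomes; both classes are required — use the default threshold 0.5"
        )
    cal = calibrate_threshold(
        np.concatenate(p_rec_parts),
        np.concatenate(p_unr_parts),
        grid=grid,
        plateau_tol=plateau_tol,
    )
    cal.n_recovered_chroms = n_rec
    cal.n_unrecovered_chroms = n_unr
    return cal
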