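"""End-to-end orchestration: encode -> blocks -> segment -> metrics -> reports.

The four stages mirror the scanning workflow: (1) digital coding of each
individual against the recurrent parent, (2) aggregation into haplotype
blocks, (3) CBS smoothing into chromosome segments, (4) recovery metrics,
fragment extraction and ranking.  A run writes its resolved configuration
next to its outputs so that the manifest alone reproduces it.
"""

from __future__ import annotations

import dataclasses
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .blocks import (
    DEFAULT_THRESHOLD,
    ThresholdCalibration,
    aggregate_to_blocks,
    assign_block_states,
    assign_loci_to_blocks,
    calibrate_from_cohort,
    htbr,
)
from .coding import code_matrix, find_polymorphic_loci, prpg
from .io_formats import (
    BlockMap,
    LocusTable,
    read_block_map,
    read_chrom_table,
    read_genotype_matrix,
    write_reports,
)
from .metrics import HIGH_RECOVERY_WGBR, build_reports, rank_individuals
from .segmentation import (
    DEFAULT_ALPHA,
    DEFAULT_MIN_WIDTH,
    DEFAULT_N_PERM,
    DEFAULT_SEED,
    DEFAULT_UNDO_SD,
    call_breakpoints,
    cbs_segment,
    fill_monomorphic,
    finalize_segments,
)

log = logging.getLogger("g2h")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run."""

    genotypes: str
    blocks: str
    rp_sample: str
    dp_sample: str
    out_dir: str
    chrom_table: str | None = None
    samples: list[str] | None = None
    threshold: float = DEFAULT_THRESHOLD
    alpha: float = DEFAULT_ALPHA
    undo_sd: float = DEFAULT_UNDO_SD
    min_width: int = DEFAULT_MIN_WIDTH
    n_perm: int = DEFAULT_N_PERM
    seed: int = DEFAULT_SEED
    wgbr_floor: float = HIGH_RECOVERY_WGBR  # high-recovery classification floor
    rank_floor: float = 0.0  # WGBR filter applied before ranking
    cfdi_primary: bool = False

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["g2h_version"] = __version__
        return d


@dataclass
class CohortResult:
    """In-memory result of :func:`analyze_cohort`."""

    reports: pd.DataFrame
    segments: dict  # sample -> chrom -> [Segment]
    segments_df: pd.DataFrame
    breakpoints_df: pd.DataFrame
    samples: list[str]
    coded: np.ndarray = field(repr=False, default=None)
    poly: object = field(repr=False, default=None)
    locus_block: np.ndarray = field(repr=False, default=None)
    track: object = field(repr=False, default=None)


def analyze_cohort(
    locus_table: LocusTable,
    block_map: BlockMap,
    rp_sample: str,
    dp_sample: str,
    samples: list[str] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    undo_sd: float = DEFAULT_UNDO_SD,
    min_width: int = DEFAULT_MIN_WIDTH,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = DEFAULT_SEED,
    high_recovery_wgbr: float = HIGH_RECOVERY_WGBR,
) -> CohortResult:
    """Run the full scoring chain on an in-memory cohort.

    ``samples`` defaults to every column except the two parents.  The CBS
    seed for individual *s*, chromosome *c* is derived deterministically from
    ``(seed, s, c)``, so results do not depend on scheduling order.
    """
    t0 = time.perf_counter()
    if samples is None:
        samples = [s for s in locus_table.samples if s not in (rp_sample, dp_sample)]
    poly = find_polymorphic_loci(locus_table, rp_sample, dp_sample)
    coded = code_matrix(locus_table, samples, poly)
    log.info(
        "stage coding: %d polymorphic loci, %d individuals (%.1fs)",
        poly.n,
        len(samples),
        time.perf_counter() - t0,
    )

    t0 = time.perf_counter()
    locus_block = assign_loci_to_blocks(poly, block_map)
    track = aggregate_to_blocks(coded, samples, locus_block, block_map.n_blocks)
    assign_block_states(track, threshold)
    monomorphic = np.bincount(locus_block, minlength=block_map.n_blocks) == 0
    log.info("stage blocks: %d blocks (%.1fs)", block_map.n_blocks, time.perf_counter() - t0)

    t0 = time.perf_counter()
    bdf = block_map.df
    chrom_slices = {
        chrom: (sub.index.to_numpy(), sub["start"].to_numpy(), sub["end"].to_numpy())
        for chrom, sub in bdf.groupby("chrom", sort=False)
    }
    segments_by_sample: dict[str, dict] = {}
    seg_rows, bp_rows = [], []
    for si, sample in enumerate(samples):
        per_chrom = {}
        for ci, (chrom, (rows, starts, ends)) in enumerate(chrom_slices.items()):
            signal = fill_monomorphic(track.p[si, rows], monomorphic[rows])
            cuts = cbs_segment(
                signal,
                alpha=alpha,
                undo_sd=undo_sd,
                min_width=min_width,
                n_perm=n_perm,
                seed=[seed, si, ci],
            )
            segs = finalize_segments(signal, cuts, starts, ends, threshold)
            per_chrom[chrom] = segs
            for seg in segs:
                seg_rows.append(
                    (sample, chrom, seg.start, seg.end, seg.n_blocks, seg.median, seg.state)
                )
            for bp in call_breakpoints(segs):
                bp_rows.append(
                    (sample, chrom, bp.left_block, bp.right_block, bp.start, bp.end + 1)
                )
        segments_by_sample[sample] = per_chrom
    log.info("stage segmentation: done (%.1fs)", time.perf_counter() - t0)

    t0 = time.perf_counter()
    prpg_by = {s: prpg(coded[i]) for i, s in enumerate(samples)}
    htbr_by = {s: htbr(track.states[i]) for i, s in enumerate(samples)}
    reports = build_reports(
        prpg_by,
        htbr_by,
        segments_by_sample,
        block_map.chrom_lengths(),
        high_recovery_wgbr=high_recovery_wgbr,
    )
    log.info("stage metrics: done (%.1fs)", time.perf_counter() - t0)

    segments_df = pd.DataFrame(
        seg_rows,
        columns=["sample", "chrom", "start", "end", "n_blocks", "median", "state"],
    )
    breakpoints_df = pd.DataFrame(
        bp_rows,
        columns=["sample", "chrom", "left_block", "right_block", "start", "end"],
    )
    return CohortResult(
        reports=reports,
        segments=segments_by_sample,
        segments_df=segments_df,
        breakpoints_df=breakpoints_df,
        samples=list(samples),
        coded=coded,
        poly=poly,
        locus_block=locus_block,
        track=track,
    )


def _load_inputs(config: RunConfig):
    locus_table = read_genotype_matrix(config.genotypes)
    block_map = read_block_map(config.blocks)
    if config.chrom_table:
        block_map.validate_against(read_chrom_table(config.chrom_table))
    for parent in (config.rp_sample, config.dp_sample):
        if parent not in locus_table.samples:
            raise KeyError(f"parent sample {parent!r} not in genotype matrix")
    return locus_table, block_map


def run_pipeline(config: RunConfig) -> CohortResult:
    """File-to-file pipeline run; returns the in-memory result as well.

    On any stage failure the partially written outputs are removed and a
    :class:`PipelineError` naming the stage is raised.
    """
    written: list[str] = []
    stage = "input"
    try:
        locus_table, block_map = _load_inputs(config)
        stage = "analysis"
        result = analyze_cohort(
            locus_table,
            block_map,
            config.rp_sample,
            config.dp_sample,
            samples=config.samples,
            threshold=config.threshold,
            alpha=config.alpha,
            undo_sd=config.undo_sd,
            min_width=config.min_width,
            n_perm=config.n_perm,
            seed=config.seed,
            high_recovery_wgbr=config.wgbr_floor,
        )
        stage = "output"
        paths = write_reports(
            result.reports, result.segments_df, result.breakpoints_df, config.out_dir
        )
        written.extend(paths.values())
        ranking = rank_individuals(
            result.reports, wgbr_floor=config.rank_floor, cfdi_primary=config.cfdi_primary
        )
        rank_path = os.path.join(config.out_dir, "ranking.tsv")
        ranking.to_csv(rank_path, sep="\t", index=False, float_format="%.6f")
        written.append(rank_path)
        manifest_path = os.path.join(config.out_dir, "manifest.yaml")
        with open(manifest_path, "w") as fh:
            yaml.safe_dump(config.to_manifest(), fh, sort_keys=True)
        written.append(manifest_path)
        return result
    except Exception as exc:
        for path in written:
            if os.path.exists(path):
                os.remove(path)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc


def run_calibration(config: RunConfig) -> ThresholdCalibration:
    """Re-derive the block-state threshold from the cohort's extreme chromosomes.

    Writes the calibration curves and selected threshold under ``out_dir``.
    """
    locus_table, block_map = _load_inputs(config)
    samples = config.samples or [
        s for s in locus_table.samples if s not in (config.rp_sample, config.dp_sample)
    ]
    poly = find_polymorphic_loci(locus_table, config.rp_sample, config.dp_sample)
    coded = code_matrix(locus_table, samples, poly)
    locus_block = assign_loci_to_blocks(poly, block_map)
    track = aggregate_to_blocks(coded, samples, locus_block, block_map.n_blocks)
    block_chrom = block_map.df["chrom"].to_numpy()
    cal = calibrate_from_cohort(track, block_chrom, coded, poly.chrom)
    os.makedirs(config.out_dir, exist_ok=True)
    cal.as_frame().to_csv(
        os.path.join(config.out_dir, "calibration.tsv"),
        sep="\t",
        index=False,
        float_format="%.6f",
    )
    with open(os.path.join(config.out_dir, "calibration_selected.yaml"), "w") as fh:
        yaml.safe_dump(
            {
                "selected_threshold": cal.selected,
                "frac_recovered_above_half": cal.frac_recovered_above_half,
                "frac_unrecovered_below_half": cal.frac_unrecovered_below_half,
                "n_recovered_chroms": cal.n_recovered_chroms,
                "n_unrecovered_chroms": cal.n_unrecovered_chroms,
            },
            fh,
            sort_keys=True,
        )
    return cal
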