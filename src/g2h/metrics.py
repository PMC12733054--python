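"""Whole-genome recovery metrics and the fragment-distribution index.

After smoothing, each chromosome is a partition into recurrent (state 1)
and unrecovered (state 2) segments.  Metrics:

* ``WGBR = LS_HTP / L_HTP`` — length-weighted fraction of the genome in the
  recurrent state;
* fragments — the state-2 segments, whose count N and per-chromosome length
  proportion feed the Chromosomal Fragment Distribution Index

      CFDI = 0.5 * N{*} + 0.5 * P{*},
      N{*} = (N - N_min) / (N_max - N_min)   (cohort min-max),
      P{*} = mean over chromosomes of (unrecovered bp / chromosome bp).

  CFDI is in [0, 1]; lower means fewer and more consolidated residual donor
  fragments, the easier material to purify in later generations.  N* is
  cohort-relative, so a CFDI is only comparable within the cohort it was
  computed on.

Individuals with WGBR >= 95% are flagged high-recovery; ranking orders by
(descending WGBR, ascending CFDI), or by CFDI first when structure matters
more than raw recovery.
"""

from __future__ import annotations

import pandas as pd

from .segmentation import Segment

HIGH_RECOVERY_WGBR = 0.95

#: segments container: {sample: {chrom: [Segment, ...]}}
SegmentsBySample = dict[str, dict[str, list[Segment]]]


def wgbr(segments_by_chrom: dict[str, list[Segment]]) -> float:
    """Length-weighted recurrent fraction for one individual."""
    ls = total = 0
    for segs in segments_by_chrom.values():
        for seg in segs:
            total += seg.length
            if seg.state == 1:
                ls += seg.length
    if total == 0:
        raise ValueError("WGBR undefined: empty segment set")
    return ls / total


def extract_fragments(segments_by_chrom: dict[str, list[Segment]]) -> pd.DataFrame:
    """Unrecovered (state-2) segments of one individual, ordered by (chrom, start)."""
    rows = [
        {
            "chrom": chrom,
            "start": seg.start,
            "end": seg.end,
            "length": seg.length,
            "first_block": seg.first_block,
            "last_block": seg.last_block,
        }
        for chrom, segs in segments_by_chrom.items()
        for seg in segs
        if seg.state == 2
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "length", "first_block", "last_block"]
    )


def cfdi(
    fragments_by_sample: dict[str, pd.DataFrame],
    chrom_lengths: dict[str, int],
) -> pd.DataFrame:
    """Per-individual CFDI over one cohort.

    ``chrom_lengths`` must cover every chromosome of the block map; a
    chromosome without fragments contributes proportion 0 to P*.  Degenerate
    cohorts with N_max == N_min get N* = 0 for everyone.
    """
    if not fragments_by_sample:
        raise ValueError("CFDI needs at least one individual")
    rows = []
    for sample, frags in fragments_by_sample.items():
        n = len(frags)
        per_chrom = frags.groupby("chrom")["length"].sum() if n else pd.Series(dtype=float)
        p_star = sum(
            per_chrom.get(chrom, 0) / length for chrom, length in chrom_lengths.items()
        ) / len(chrom_lengths)
        rows.append({"sample": sample, "n_fragments": n, "p_star": p_star})
    df = pd.DataFrame(rows)
    n_min, n_max = df["n_fragments"].min(), df["n_fragments"].max()
    if n_max == n_min:
        df["n_star"] = 0.0
    else:
        df["n_star"] = (df["n_fragments"] - n_min) / (n_max - n_min)
    df["cfdi"] = 0.5 * df["n_star"] + 0.5 * df["p_star"]
    return df[["sample", "n_fragments", "n_star", "p_star", "cfdi"]]


def build_reports(
    prpg_by_sample: dict[str, float],
    htbr_by_sample: dict[str, float],
    segments: SegmentsBySample,
    chrom_lengths: dict[str, int],
    high_recovery_wgbr: float = HIGH_RECOVERY_WGBR,
) -> pd.DataFrame:
    """Assemble the per-individual summary table (one cohort)."""
    frags = {s: extract_fragments(segs) for s, segs in segments.items()}
    cf = cfdi(frags, chrom_lengths).set_index("sample")
    rows = []
    for sample in segments:
        w = wgbr(segments[sample])
        rows.append(
            {
                "sample": sample,
                "prpg": prpg_by_sample[sample],
                "htbr": htbr_by_sample[sample],
                "wgbr": w,
                "n_unrecovered_fragments": int(cf.loc[sample, "n_fragments"]),
                "cfdi": float(cf.loc[sample, "cfdi"]),
                "high_recovery": bool(w >= high_recovery_wgbr),
            }
        )
    return pd.DataFrame(rows)


def rank_individuals(
    reports: pd.DataFrame,
    wgbr_floor: float = 0.0,
    cfdi_primary: bool = False,
) -> pd.DataFrame:
    """Selection ranking of one cohort's reports.

    Filters to ``wgbr >= wgbr_floor`` then sorts by (descending WGBR,
    ascending CFDI); with ``cfdi_primary`` the keys swap, prioritising
    fragment architecture over raw recovery.
    """
    kept = reports[reports["wgbr"] >= wgbr_floor].copy()
    if cfdi_primary:
        kept = kept.sort_values(
            ["cfdi", "wgbr"], ascending=[True, False], kind="mergesort"
        )
    else:
        kept = kept.sort_values(
            ["wgbr", "cfdi"], ascending=[False, True], kind="mergesort"
        )
    kept.insert(0, "rank", range(1, len(kept) + 1))
    return kept.reset_index(drop=True)


def plot_recovery_paint(
    segments: SegmentsBySample,
    chrom_lengths: dict[str, int],
    path: str,
    samples: list[str] | None = None,
) -> None:
    """Diagnostic chromosome paint: recurrent segments in blue, donor in orange."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    samples = samples or list(segments)
    chroms = list(chrom_lengths)
    fig, axes = plt.subplots(
        len(samples), 1, figsize=(10, 1.2 * len(samples)), squeeze=False, sharex=True
    )
    colors = {1: "#3b6fb5", 2: "#e8a33d"}
    for ax, sample in zip(axes[:, 0], samples):
        for ci, chrom in enumerate(chroms):
            for seg in segments[sample].get(chrom, []):
                ax.barh(
                    y=ci,
                    width=seg.length,
                    left=seg.start,
                    height=0.7,
                    color=colors[seg.state],
                    linewidth=0,
                )
        ax.set_yticks(range(len(chroms)), chroms, fontsize=6)
        ax.set_ylabel(sample, rotation=0, ha="right", fontsize=7)
        ax.invert_yaxis()
    axes[-1, 0].set_xlabel("position (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
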