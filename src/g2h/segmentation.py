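"""Circular binary segmentation of per-chromosome block signals.

The input signal is the continuous per-block recovery proportion, with
blocks monomorphic between parents filled with 1.0 (they are recurrent by
definition) and blocks that carried only code-0 SNPs left missing (NaN);
missing blocks are excluded from the statistics but keep their position and
inherit the state of the segment that encloses them.

The changepoint search is the classic circular scheme: on the segment under
test, joined into a circle, find the arc (i, j] maximising the absolute
two-sample t-like contrast between arc and complement,

    T(i, j) = (mean_arc - mean_comp) / (sd * sqrt(1/k + 1/(m - k))),

with ``sd`` the overall standard deviation of the segment and
``k = j - i``.  The split is accepted when its permutation p-value is below
``alpha`` and both arc and complement span at least ``min_width`` blocks;
accepted cuts recurse.  A final "sd-undo" pass merges adjacent segments
whose mean difference falls below ``undo_sd`` pooled within-segment standard
deviations.  Defaults (alpha 0.001, undo_sd 1.5, min_width 5) follow the
standard parameterisation for this smoothing task.

Two exact/conservative shortcuts keep the permutation test affordable:

* sampling stops as soon as the exceedance count already guarantees
  p >= alpha (curtailment), and accepts early when the first ceil(1/alpha)
  permutations show no exceedance at all;
* because block proportions are bounded in [0, 1], Hoeffding/Bernstein
  bounds for sampling without replacement, union-bounded over all admissible
  arcs, can certify p < alpha without drawing any permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_ALPHA = 0.001
DEFAULT_UNDO_SD = 1.5
DEFAULT_MIN_WIDTH = 5
DEFAULT_N_PERM = 10_000
DEFAULT_SEED = 17

_PERM_CHUNKS = (64, 192, 768, 2048)  # escalating batch sizes


# ---------------------------------------------------------------------------
# split statistic
# ---------------------------------------------------------------------------


def max_split_statistic(
    values: np.ndarray, min_width: int = DEFAULT_MIN_WIDTH
) -> tuple[float, int | None, int | None]:
    """Maximal circular split statistic and its arc (i, j].

    Scans every arc with ``min_width <= j - i <= m - min_width``; ties break
    toward the smallest i, then the smallest j.  Returns ``(0.0, None,
    None)`` when no arc is admissible or the segment is constant.
    """
    x = np.asarray(values, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("split statistic requires finite values")
    m = len(x)
    if m < 2 * min_width:
        return 0.0, None, None
    sd = x.std(ddof=1)
    if sd == 0.0:
        return 0.0, None, None
    w = np.concatenate(([0.0], np.cumsum(x - x.mean())))
    best_t, best_i, best_j = 0.0, None, None
    for k in range(min_width, m - min_width + 1):
        d = np.abs(w[k:] - w[: m - k + 1])  # |W[i+k] - W[i]| for i = 0..m-k
        scale = np.sqrt(k * (m - k) / m)
        tmax = d.max() / scale / sd
        if tmax > best_t:
            i = int(np.argmax(d))
            best_t, best_i, best_j = float(tmax), i, i + k
        elif tmax == best_t and best_i is not None:
            i = int(np.argmax(d))
            if (i, i + k) < (best_i, best_j):
                best_i, best_j = i, i + k
    return best_t, best_i, best_j


def _tail_pvalue_bound(x: np.ndarray, t_max: float, min_width: int) -> float:
    """Conservative upper bound on the permutation p-value of the max statistic.

    Under permutation the centred arc sum is a simple-random-sample sum of
    bounded values, so each arc's tail obeys both Hoeffding's and a
    Bernstein-type inequality for sampling without replacement (the latter
    much tighter when the population variance is small); the per-arc bound
    takes the better of the two and a union bound over all admissible arcs
    bounds the maximum.  Never anti-conservative.
    """
    m = len(x)
    r = float(x.max() - x.min())
    if r == 0.0:
        return 1.0
    sd1 = x.std(ddof=1)
    var0 = x.var(ddof=0)
    ks = np.arange(min_width, m - min_width + 1, dtype=float)
    thresh = t_max * sd1 * np.sqrt(ks * (m - ks) / m)  # |D| needed at each k
    n_arcs = m - ks + 1
    k_eff = np.minimum(ks, m - ks)  # arc/complement symmetry
    hoeff = 2.0 * thresh**2 / (k_eff * r * r)
    bern = thresh**2 / (2.0 * k_eff * var0 + (2.0 / 3.0) * r * thresh)
    expo = np.maximum(hoeff, bern)
    return float(np.sum(n_arcs * 2.0 * np.exp(-expo)))


def _perm_max_stats(x: np.ndarray, min_width: int, n: int, rng) -> np.ndarray:
    """Max split statistic (sd-normalised) for ``n`` random permutations of x."""
    m = len(x)
    mat = rng.permuted(np.tile(x, (n, 1)), axis=1)
    w = np.cumsum(mat - mat.mean(axis=1, keepdims=True), axis=1)
    w = np.concatenate((np.zeros((n, 1)), w), axis=1)
    best = np.zeros(n)
    for k in range(min_width, m - min_width + 1):
        d = np.abs(w[:, k:] - w[:, : m - k + 1]).max(axis=1)
        np.maximum(best, d / np.sqrt(k * (m - k) / m), out=best)
    return best / x.std(ddof=1)


def _split_is_significant(
    x: np.ndarray,
    t_max: float,
    alpha: float,
    n_perm: int,
    min_width: int,
    rng,
) -> bool:
    """Permutation test of the observed max statistic, with curtailment.

    Sampling stops as soon as the exceedance count forces
    p = (c + 1)/(n_perm + 1) >= alpha (decision-exact), or — when no
    exceedance at all has been seen in the first ceil(1/alpha) permutations —
    accepts the split early (the point estimate of p is then already at
    alpha's resolution).  Genuinely borderline splits run to the full n_perm.
    """
    if t_max <= 0.0:
        return False
    if _tail_pvalue_bound(x, t_max, min_width) < alpha:
        return True
    c_stop = int(np.ceil(alpha * (n_perm + 1) - 1.0))
    early_sig = min(n_perm, int(np.ceil(1.0 / alpha)))
    tol = t_max * (1.0 - 1e-12)
    c = done = 0
    chunk_iter = list(_PERM_CHUNKS)
    while done < n_perm:
        b = chunk_iter.pop(0) if chunk_iter else n_perm - done
        b = min(b, n_perm - done)
        c += int(np.count_nonzero(_perm_max_stats(x, min_width, b, rng) >= tol))
        done += b
        if c >= c_stop:
            return False
        if c == 0 and done >= early_sig:
            return True
    return (c + 1) / (n_perm + 1) < alpha


# ---------------------------------------------------------------------------
# recursive CBS + sd-undo
# ---------------------------------------------------------------------------


def _segment_recursive(x, lo, hi, alpha, min_width, n_perm, rng, cuts):
    m = hi - lo
    if m < 2 * min_width:
        return
    seg = x[lo:hi]
    t_max, i, j = max_split_statistic(seg, min_width)
    if i is None:
        return
    if not _split_is_significant(seg, t_max, alpha, n_perm, min_width, rng):
        return
    pieces = [lo]
    for c in (i, j):
        if 0 < c < m:
            cuts.add(lo + c)
            pieces.append(lo + c)
    pieces.append(hi)
    for a, b in zip(pieces[:-1], pieces[1:]):
        _segment_recursive(x, a, b, alpha, min_width, n_perm, rng, cuts)


def _sd_undo(x: np.ndarray, cuts: list[int], undo_sd: float) -> list[int]:
    """Iteratively merge adjacent segments closer than undo_sd pooled SDs.

    The most similar pair (smallest mean difference in pooled-SD units)
    merges first; repeats until stable.  Two exactly-constant segments with
    different values have pooled SD 0 and are never merged.
    """
    bounds = [0] + sorted(cuts) + [len(x)]
    while len(bounds) > 2:
        stats = []
        for q in range(1, len(bounds) - 1):
            left = x[bounds[q - 1] : bounds[q]]
            right = x[bounds[q] : bounds[q + 1]]
            nl, nr = len(left), len(right)
            diff = abs(left.mean() - right.mean())
            ss = 0.0
            if nl > 1:
                ss += (nl - 1) * left.var(ddof=1)
            if nr > 1:
                ss += (nr - 1) * right.var(ddof=1)
            dof = nl + nr - 2
            pooled = np.sqrt(ss / dof) if dof > 0 else 0.0
            if pooled == 0.0:
                ratio = 0.0 if diff == 0.0 else np.inf
            else:
                ratio = diff / pooled
            stats.append((ratio, q))
        ratio, q = min(stats)
        if ratio >= undo_sd:
            break
        del bounds[q]
    return bounds[1:-1]


def cbs_segment(
    signal: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    undo_sd: float = DEFAULT_UNDO_SD,
    min_width: int = DEFAULT_MIN_WIDTH,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.SeedSequence | list = DEFAULT_SEED,
) -> list[int]:
    """Breakpoint block indices of one chromosome's signal.

    ``signal`` may contain NaN (missing blocks); those are dropped for the
    statistics and re-inserted when mapping breakpoints back, attaching to
    the left segment.  A returned breakpoint ``b`` means a new segment starts
    at block ``b``.  Fully deterministic for fixed seed and n_perm.
    """
    signal = np.asarray(signal, dtype=float)
    if np.isinf(signal).any():
        raise ValueError("signal contains non-finite (infinite) values")
    keep = ~np.isnan(signal)
    x = signal[keep]
    if len(x) < 2 * min_width:
        return []
    rng = np.random.default_rng(seed)
    cuts: set[int] = set()
    _segment_recursive(x, 0, len(x), alpha, min_width, n_perm, rng, cuts)
    merged = _sd_undo(x, sorted(cuts), undo_sd)
    # map compressed indices back to original block coordinates
    orig = np.flatnonzero(keep)
    return [int(orig[c]) for c in merged]


# ---------------------------------------------------------------------------
# signal construction and segment finalisation
# ---------------------------------------------------------------------------


def fill_monomorphic(p_row: np.ndarray, monomorphic: np.ndarray) -> np.ndarray:
    """Per-block signal for one individual: monomorphic blocks become 1.0.

    ``p_row`` is the raw per-block proportion (NaN where no informative SNP);
    blocks in ``monomorphic`` (no parental polymorphic SNP at all) are set to
    1.0 — they are recurrent-parent by definition.  Blocks that are
    polymorphic in the parents but all-code-0 in this individual stay NaN and
    are later absorbed into the surrounding segment.
    """
    signal = np.array(p_row, dtype=float)
    signal[np.asarray(monomorphic, dtype=bool)] = 1.0
    return signal


@dataclass
class Segment:
    """A maximal run of blocks sharing one final background state."""

    first_block: int  # chromosome-local block index
    last_block: int  # inclusive
    start: int  # bp, 0-based half-open with `end`
    end: int
    median: float  # median of non-missing raw signal values
    state: int  # 1 recurrent, 2 donor/heterozygous

    @property
    def n_blocks(self) -> int:
        return self.last_block - self.first_block + 1

    @property
    def length(self) -> int:
        return self.end - self.start


def finalize_segments(
    signal: np.ndarray,
    breakpoints: list[int],
    block_starts: np.ndarray,
    block_ends: np.ndarray,
    threshold: float = 0.5,
) -> list[Segment]:
    """Turn breakpoints into state-labelled segments for one chromosome.

    Each segment gets the median of its non-missing raw values; state 1 if
    the median exceeds the threshold, else 2.  All-missing segments take the
    state of the nearest non-missing segment (left wins ties).  Adjacent
    segments with equal state are merged, so the result alternates states.
    """
    m = len(signal)
    bounds = [0] + sorted(breakpoints) + [m]
    if bounds != sorted(set(bounds)) or bounds[-1] != m or bounds[0] != 0:
        raise ValueError("breakpoints must be sorted, unique and within range")
    raw: list[tuple[int, int, float]] = []  # (first, last, median or nan)
    for a, b in zip(bounds[:-1], bounds[1:]):
        vals = signal[a:b]
        vals = vals[~np.isnan(vals)]
        med = float(np.median(vals)) if vals.size else np.nan
        raw.append((a, b - 1, med))

    states = [np.nan if np.isnan(med) else (1 if med > threshold else 2) for _, _, med in raw]
    # resolve all-missing segments from the nearest defined neighbour
    defined = [q for q, s in enumerate(states) if not np.isnan(s)]
    if not defined:
        raise ValueError("every segment on the chromosome is missing")
    for q, s in enumerate(states):
        if np.isnan(s):
            best = min(defined, key=lambda d: (abs(d - q), d > q))  # left wins ties
            states[q] = states[best]

    segments: list[Segment] = []
    for (a, b, med), st in zip(raw, states):
        st = int(st)
        if segments and segments[-1].state == st:
            prev = segments[-1]
            vals = signal[prev.first_block : b + 1]
            vals = vals[~np.isnan(vals)]
            segments[-1] = Segment(
                first_block=prev.first_block,
                last_block=b,
                start=prev.start,
                end=int(block_ends[b]),
                median=float(np.median(vals)) if vals.size else prev.median,
                state=st,
            )
        else:
            segments.append(
                Segment(
                    first_block=a,
                    last_block=b,
                    start=int(block_starts[a]),
                    end=int(block_ends[b]),
                    median=med if not np.isnan(med) else float("nan"),
                    state=st,
                )
            )
    return segments


@dataclass
class Breakpoint:
    """Boundary interval between adjacent segments of differing state."""

    left_block: int
    right_block: int
    start: int  # bp of the boundary, 0-based: end of left block
    end: int  # bp: start of right block (== start for seamless tilings)


def call_breakpoints(segments: list[Segment]) -> list[Breakpoint]:
    """Recombination-containing intervals between state-1/state-2 neighbours."""
    out = []
    for left, right in zip(segments[:-1], segments[1:]):
        if left.state != right.state:
            out.append(
                Breakpoint(
                    left_block=left.last_block,
                    right_block=right.first_block,
                    start=left.end,
                    end=right.start,
                )
            )
    return out
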