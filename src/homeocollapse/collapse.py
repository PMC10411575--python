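"""Collapsed-region detection from doubled-haploid read depth.

A region where two near-identical homeologs were merged into one
assembly sequence receives reads from both copies, so its windowed mean
depth sits near twice the genome-wide level. The detector averages
depth in fixed windows (1 Mbp by default; 10 kbp for association-peak
checks), then iteratively flags windows more than ``k_sd`` standard
deviations above the mean of *all other* (unflagged) windows until the
flagged set stabilises, merges adjacent flagged windows into regions
and length-filters them (>= 3 Mbp by default). A soft-masked-fraction
windower supports the repeat ring of the genome overview.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .types import Interval

log = logging.getLogger(__name__)

Z_CLASSES = ("below", "normal", "high", "collapsed")


@dataclass
class DepthWindow:
    interval: Interval
    mean_depth: float
    n_bases_covered: int
    z_class: str = "normal"


@dataclass
class CollapsedRegion:
    interval: Interval
    mean_depth: float
    n_windows: int


def window_depth(
    depth_track: dict[str, list[tuple[int, int, float]]],
    seq_lengths: dict[str, int],
    window_bp: int = 1_000_000,
) -> list[DepthWindow]:
    """Mean depth per fixed window over each sequence.

    The track is run-length (start, end, depth); bases absent from the
    track count as depth 0. A terminal partial window is retained iff it
    covers at least half of ``window_bp``, otherwise dropped and logged.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    windows: list[DepthWindow] = []
    n_dropped = 0
    for seq_id in sorted(seq_lengths):
        L = seq_lengths[seq_id]
        runs = depth_track.get(seq_id, [])
        sums = np.zeros((L + window_bp - 1) // window_bp)
        covered = np.zeros_like(sums, dtype=np.int64)
        for start, end, value in runs:
            end = min(end, L)
            pos = start
            while pos < end:
                w = pos // window_bp
                upto = min(end, (w + 1) * window_bp)
                sums[w] += value * (upto - pos)
                covered[w] += upto - pos
                pos = upto
        for w in range(sums.size):
            ws = w * window_bp
            we = min(ws + window_bp, L)
            width = we - ws
            if width < window_bp and width < window_bp / 2:
                n_dropped += 1
                continue
            windows.append(
                DepthWindow(
                    interval=Interval(seq_id, ws, we),
                    mean_depth=float(sums[w] / width),
                    n_bases_covered=int(covered[w]),
                )
            )
    if n_dropped:
        log.info("dropped %d terminal windows shorter than half a window", n_dropped)
    return windows


def call_collapsed(
    windows: list[DepthWindow], k_sd: float = 2.0, iterative: bool = True, max_iter: int = 25
) -> list[DepthWindow]:
    """Assign z-classes; 'collapsed' = depth strictly above mean + k_sd*sd
    of all other (unflagged) windows.

    The reference statistics exclude already-flagged windows and the
    flagging is repeated to a fixed point (at most ``max_iter`` rounds),
    so one massive collapsed block cannot inflate the baseline it is
    judged against. ``iterative=False`` gives the single-pass variant
    for comparison. With a degenerate sd of 0 nothing is flagged.
    """
    if len(windows) < 10:
        raise ValueError("need >= 10 windows for depth statistics")
    depths = np.array([w.mean_depth for w in windows])
    flagged = np.zeros(depths.size, dtype=bool)
    rounds = 1 if not iterative else max_iter
    for _ in range(rounds):
        ref = depths[~flagged]
        mu = float(np.mean(ref))
        sd = float(np.std(ref, ddof=1)) if ref.size > 1 else 0.0
        if sd == 0.0:
            if not flagged.any():
                log.warning("zero depth variance: no window can be flagged collapsed")
            break
        new_flagged = depths > mu + k_sd * sd
        if np.array_equal(new_flagged, flagged):
            break
        flagged = new_flagged
    ref = depths[~flagged]
    mu = float(np.mean(ref)) if ref.size else 0.0
    sd = float(np.std(ref, ddof=1)) if ref.size > 1 else 0.0
    for i, w in enumerate(windows):
        if flagged[i]:
            w.z_class = "collapsed"
        elif w.mean_depth <= mu - sd:
            w.z_class = "below"
        elif w.mean_depth <= mu + sd:
            w.z_class = "normal"
        else:
            w.z_class = "high"
    return windows


def merge_collapsed(windows: list[DepthWindow]) -> list[CollapsedRegion]:
    """Merge adjacent collapsed windows on each sequence (no gap
    tolerance) into regions."""
    regions: list[CollapsedRegion] = []
    run: list[DepthWindow] = []

    def close() -> None:
        if run:
            iv = Interval(run[0].interval.seq_id, run[0].interval.start, run[-1].interval.end)
            regions.append(
                CollapsedRegion(
                    interval=iv,
                    mean_depth=float(np.mean([w.mean_depth for w in run])),
                    n_windows=len(run),
                )
            )
            run.clear()

    ordered = sorted(windows, key=lambda w: (w.interval.seq_id, w.interval.start))
    for w in ordered:
        if w.z_class != "collapsed":
            close()
            continue
        if run and (
            run[-1].interval.seq_id != w.interval.seq_id
            or run[-1].interval.end != w.interval.start
        ):
            close()
        run.append(w)
    close()
    return regions


def filter_min_length(
    regions: list[CollapsedRegion], min_bp: int = 3_000_000
) -> list[CollapsedRegion]:
    """Keep regions with length >= min_bp (inclusive; boundary logged)."""
    kept = []
    for r in regions:
        length = len(r.interval)
        if length >= min_bp:
            if length == min_bp:
                log.info("region %s:%d-%d exactly at the %d bp minimum; kept (>= rule)",
                         r.interval.seq_id, r.interval.start, r.interval.end, min_bp)
            kept.append(r)
    return kept


def genome_collapse_summary(
    regions: list[CollapsedRegion], assembly_lengths: dict[str, int]
) -> tuple[int, float]:
    """Total collapsed bp and its fraction of the assembly length."""
    total = sum(len(r.interval) for r in regions)
    genome = sum(assembly_lengths.values())
    return total, (total / genome if genome else 0.0)


def repeat_fraction(
    masked_fasta: dict[str, str], window_bp: int = 1_000_000
) -> list[tuple[Interval, float, str]]:
    """Per-window soft-masked (lowercase) base fraction with the plotting
    bins low (<=45%), mid (>45, <=60%), high (>60%)."""
    out = []
    for seq_id in sorted(masked_fasta):
        seq = masked_fasta[seq_id]
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_lower = (arr >= 97) & (arr <= 122)
        L = len(seq)
        for ws in range(0, L, window_bp):
            we = min(ws + window_bp, L)
            frac = float(np.mean(is_lower[ws:we]))
            label = "low" if frac <= 0.45 else ("mid" if frac <= 0.60 else "high")
            out.append((Interval(seq_id, ws, we), frac, label))
    return out
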