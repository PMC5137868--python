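"""Window-based depth-of-coverage (DOC) CNV detection.

Reads are counted into adjacent fixed-width windows (100 bp by default), each
mapped primary read assigned to the window containing its leftmost aligned
base.  A test/control DOC ratio is formed after scaling each track by its own
mean count over a normalization region (typically the chromosome minus the
candidate amplification, found in two passes).  Runs of elevated smoothed
ratio become amplified segments with integer copy-number estimates; runs of
depressed ratio inside an amplified segment become intra-amplicon deletion
calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .sam import AlignmentRecord

__all__ = [
    "WindowTrack",
    "RatioTrack",
    "RatioSegment",
    "window_counts",
    "doc_ratio",
    "call_amplified_segments",
    "call_internal_deletions",
    "two_pass_ratio",
]


@dataclass
class WindowTrack:
    """Per-window primary-read counts over one chromosome."""

    chromosome: str
    window: int
    counts: np.ndarray
    n_reads: int

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window size must be positive")
        if int(self.counts.sum()) != self.n_reads:
            raise ValueError("window counts do not sum to the counted-read total")


@dataclass
class RatioTrack:
    """Windowed test/control DOC ratios; NaN where the control count is 0."""

    chromosome: str
    window: int
    ratio: np.ndarray
    defined: np.ndarray
    normalization_exclusion: tuple[tuple[int, int], ...] = ()

    @property
    def n_windows(self) -> int:
        return len(self.ratio)


@dataclass
class RatioSegment:
    """A contiguous called region, 1-based inclusive bp coordinates."""

    start: int
    end: int
    mean_ratio: float
    copies: int
    kind: str  # "amplified" | "internal-deletion"
    fractional_drop: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def window_counts(
    alignments: Iterable[AlignmentRecord],
    lengths: dict[str, int],
    window: int = 100,
) -> dict[str, WindowTrack]:
    """Count mapped primary reads into adjacent windows, one track per chromosome.

    Each read is counted exactly once, in the window containing its leftmost
    aligned base; unmapped and secondary records are ignored.  Records on a
    chromosome absent from ``lengths`` raise a ``ValueError`` naming the record.
    """
    if window <= 0:
        raise ValueError("window size must be positive")
    counts = {name: np.zeros(-(-length // window), dtype=np.int64) for name, length in lengths.items()}
    totals = {name: 0 for name in lengths}
    for rec in alignments:
        if rec.is_unmapped or rec.is_secondary:
            continue
        if rec.chrom not in counts:
            raise ValueError(f"record {rec.qname!r} maps to unknown chromosome {rec.chrom!r}")
        counts[rec.chrom][rec.pos // window] += 1
        totals[rec.chrom] += 1
    return {
        name: WindowTrack(name, window, counts[name], totals[name]) for name in lengths
    }


def _excluded_windows(n: int, window: int, exclusion: Sequence[tuple[int, int]]) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for start, end in exclusion:
        first = max(0, start // window)
        last = min(n, -(-end // window))
        mask[first:last] = True
    return mask


def doc_ratio(
    test: WindowTrack,
    control: WindowTrack,
    normalization_exclusion: Sequence[tuple[int, int]] = (),
) -> RatioTrack:
    """Library-size-normalized test/control ratio per window.

    Each track is first scaled by its own mean count over all windows outside
    the exclusion intervals (0-based half-open bp), so library size cancels.
    Windows with a zero control count are flagged undefined (NaN), never
    imputed.
    """
    if test.chromosome != control.chromosome or test.window != control.window:
        raise ValueError("test and control tracks must share chromosome and window size")
    if len(test.counts) != len(control.counts):
        raise ValueError("test and control tracks must have the same number of windows")
    excluded = _excluded_windows(len(test.counts), test.window, normalization_exclusion)
    keep = ~excluded
    if not keep.any():
        raise ValueError("normalization exclusion leaves no windows")
    t_norm = test.counts[keep].mean()
    c_norm = control.counts[keep].mean()
    if t_norm == 0 or c_norm == 0:
        raise ValueError("a track has zero mean count over the normalization region")
    t = test.counts / t_norm
    c = control.counts / c_norm
    defined = control.counts > 0
    ratio = np.full(len(t), np.nan)
    ratio[defined] = t[defined] / c[defined]
    return RatioTrack(
        test.chromosome, test.window, ratio, defined,
        tuple((int(s), int(e)) for s, e in normalization_exclusion),
    )


def _running_median(values: np.ndarray, width: int) -> np.ndarray:
    """Running median that ignores NaNs; odd ``width`` centred on each window."""
    import pandas as pd

    return (
        pd.Series(values)
        .rolling(width, center=True, min_periods=1)
        .median()
        .to_numpy()
    )


def _runs(mask: np.ndarray, close_gaps: int = 0) -> list[tuple[int, int]]:
    """Maximal True runs as half-open window-index intervals.

    Runs separated by fewer than ``close_gaps`` False windows are merged:
    a brief dip inside a long supported run is smoothing noise, not two
    events."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    runs = [(int(s), int(e)) for s, e in zip(idx[::2], idx[1::2])]
    if close_gaps <= 0 or len(runs) < 2:
        return runs
    merged = [runs[0]]
    for s, e in runs[1:]:
        if s - merged[-1][1] < close_gaps:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def call_amplified_segments(
    ratios: RatioTrack,
    threshold: float = 1.5,
    min_run: int = 20,
    control_copies_per_chromosome: int = 1,
    smooth_window: int = 21,
) -> list[RatioSegment]:
    """Call amplified segments from a DOC-ratio track.

    Maximal runs of at least ``min_run`` consecutive windows whose
    median-smoothed ratio is >= ``threshold`` become amplified segments.  The
    reported mean is over the raw (unsmoothed) defined ratios in the run, and
    copies per chromosome = round(mean ratio x control copies per chromosome).
    """
    smoothed = _running_median(ratios.ratio, smooth_window)
    mask = np.nan_to_num(smoothed, nan=0.0) >= threshold
    segments = []
    for s, e in _runs(mask, close_gaps=min_run):
        if e - s < min_run:
            continue
        raw = ratios.ratio[s:e]
        mean = float(np.nanmean(raw))
        segments.append(
            RatioSegment(
                start=s * ratios.window + 1,
                end=e * ratios.window,
                mean_ratio=mean,
                copies=int(round(mean * control_copies_per_chromosome)),
                kind="amplified",
            )
        )
    return segments


def call_internal_deletions(
    ratios: RatioTrack,
    amplified: RatioSegment,
    step: float = 0.25,
    min_run: int = 20,
    control_copies_per_chromosome: int = 1,
    smooth_window: int = 21,
) -> list[RatioSegment]:
    """Find intra-amplicon deletion runs inside an amplified segment.

    A run of >= ``min_run`` windows whose smoothed ratio sits at least
    ``step`` below the segment mean is called a deletion.  The number of
    deleted copies is round((flank mean - run mean) x control copies), with
    the flank mean taken over amplicon windows outside all deletion runs so a
    wide deletion does not dilute its own baseline.  ``fractional_drop`` is
    (flank - run) / flank, the per-copy fraction of coverage lost.
    """
    w = ratios.window
    first = (amplified.start - 1) // w
    last = amplified.end // w  # exclusive
    inside = ratios.ratio[first:last]
    smoothed = _running_median(inside, smooth_window)
    seg_mean = float(np.nanmean(inside))
    mask = np.nan_to_num(smoothed, nan=np.inf) <= seg_mean - step
    runs = [(s, e) for s, e in _runs(mask, close_gaps=min_run) if e - s >= min_run]
    if not runs:
        return []
    flank_mask = np.ones(len(inside), dtype=bool)
    for s, e in runs:
        flank_mask[s:e] = False
    flank_mean = float(np.nanmean(inside[flank_mask])) if flank_mask.any() else seg_mean
    calls = []
    for s, e in runs:
        run_mean = float(np.nanmean(inside[s:e]))
        drop = flank_mean - run_mean
        calls.append(
            RatioSegment(
                start=(first + s) * w + 1,
                end=(first + e) * w,
                mean_ratio=run_mean,
                copies=int(round(drop * control_copies_per_chromosome)),
                kind="internal-deletion",
                fractional_drop=drop / flank_mean if flank_mean else None,
            )
        )
    return calls


def two_pass_ratio(
    test: WindowTrack,
    control: WindowTrack,
    threshold: float = 1.5,
    min_run: int = 20,
    control_copies_per_chromosome: int = 1,
    smooth_window: int = 21,
) -> tuple[RatioTrack, list[RatioSegment]]:
    """Ratio + segmentation with self-calibrating normalization.

    Pass 1 normalizes over the whole chromosome to locate candidate amplified
    segments; pass 2 re-normalizes excluding those candidates (the single-copy
    background then sits at ratio 1) and re-calls the segments.
    """
    first = doc_ratio(test, control)
    candidates = call_amplified_segments(
        first, threshold, min_run, control_copies_per_chromosome, smooth_window
    )
    if not candidates:
        return first, []
    exclusion = [(seg.start - 1, seg.end) for seg in candidates]
    second = doc_ratio(test, control, exclusion)
    segments = call_amplified_segments(
        second, threshold, min_run, control_copies_per_chromosome, smooth_window
    )
    return second, segments
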