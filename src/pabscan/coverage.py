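"""Male:female depth-ratio windows and PAR / X-specific segmentation.

The pseudoautosomal region (PAR) recombines in both sexes and is present in
two copies in males and females alike, so the normalized male:female depth
ratio there is 1.  The X-specific region is hemizygous in males, giving a
ratio of 0.5.  The pseudoautosomal boundary (PAB) is the step between the
two levels.  The pipeline follows the classic recipe: normalize each sex by
its own autosomal mean depth, take the per-position ratio, summarise it as
a sliding-window average (150 kb windows, 10 kb steps by default), and
segment the window track by thresholding at the midpoint between the two
expected levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import (
    ANOMALOUS,
    PAR,
    X_SPECIFIC,
    DepthTrack,
    Segment,
    SegmentCall,
    WindowSeries,
)

__all__ = [
    "NormalizationConstants",
    "RatioWindowConfig",
    "autosome_mean_depth",
    "normalized_ratio_per_position",
    "sliding_window_mean",
    "segment_ratio_track",
]


@dataclass(frozen=True)
class NormalizationConstants:
    """Per-sex autosomal mean depths used to normalize the X tracks."""

    male_autosome_mean: float
    female_autosome_mean: float

    def __post_init__(self) -> None:
        if self.male_autosome_mean <= 0 or self.female_autosome_mean <= 0:
            raise ValueError("autosome mean depths must be positive")


@dataclass(frozen=True)
class RatioWindowConfig:
    """Sliding-window geometry for the depth-ratio track.

    Defaults are 150 kb windows advancing by 10 kb.  A window whose
    informative fraction (positions with usable ratio values) is below
    ``min_informative_fraction`` is reported as undefined.
    """

    window_size: int = 150_000
    step: int = 10_000
    min_informative_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.window_size):
            raise ValueError("require 0 < step <= window_size")
        if not (0 <= self.min_informative_fraction <= 1):
            raise ValueError("min_informative_fraction must be in [0, 1]")


def autosome_mean_depth(track: DepthTrack, length: int | None = None) -> float:
    """Mean per-position depth of an autosome track, zero-depth sites included.

    Positions missing from the track count as depth 0; the denominator is
    ``length`` if given, otherwise the largest listed position.
    """
    return track.mean_depth(length=length)


def normalized_ratio_per_position(
    male: DepthTrack,
    female: DepthTrack,
    norm: NormalizationConstants,
    length: int | None = None,
) -> np.ndarray:
    """Per-position normalized male:female depth ratio as a dense array.

    Index i holds the ratio at 1-based position i+1:
    ``(male_depth / male_autosome_mean) / (female_depth / female_autosome_mean)``.
    Positions where the female has depth 0 are uninformative and set to NaN
    (never 0 or infinity).
    """
    if male.sequence_id != female.sequence_id:
        raise ValueError(
            f"tracks are on different sequences: {male.sequence_id!r} vs "
            f"{female.sequence_id!r}"
        )
    if length is None:
        length = int(
            max(
                male.positions.max() if len(male) else 0,
                female.positions.max() if len(female) else 0,
            )
        )
    m = male.to_dense(length) / norm.male_autosome_mean
    f = female.to_dense(length) / norm.female_autosome_mean
    ratio = np.full(length, np.nan)
    ok = f > 0
    ratio[ok] = m[ok] / f[ok]
    return ratio


def sliding_window_mean(
    series: np.ndarray,
    cfg: RatioWindowConfig,
    sequence_id: str = "chrX",
) -> WindowSeries:
    """Average a dense per-position series over sliding windows.

    ``series`` is indexed from genomic position 1 (index 0); NaN entries are
    uninformative and excluded from window means.  Windows are 0-based
    half-open ``[k*step, k*step + window_size)`` clipped at the sequence
    end; the final partial window is reported like any other but its
    smaller size is visible from its coordinates.  Windows whose
    informative fraction falls below the configured minimum are NaN.
    """
    n = int(np.asarray(series).size)
    if n == 0:
        e = np.array([], dtype=np.int64)
        return WindowSeries(sequence_id, e, e, np.array([]), e)
    finite = np.isfinite(series)
    vals = np.where(finite, series, 0.0)
    # prefix sums for O(1) window aggregation
    cs_val = np.concatenate([[0.0], np.cumsum(vals)])
    cs_n = np.concatenate([[0], np.cumsum(finite.astype(np.int64))])

    starts = np.arange(0, n, cfg.step, dtype=np.int64)
    ends = np.minimum(starts + cfg.window_size, n)
    sums = cs_val[ends] - cs_val[starts]
    counts = cs_n[ends] - cs_n[starts]
    widths = ends - starts

    values = np.full(starts.size, np.nan)
    defined = counts >= np.maximum(1, cfg.min_informative_fraction * widths)
    values[defined] = sums[defined] / counts[defined]
    return WindowSeries(sequence_id, starts, ends, values, counts)


def _smooth_states(states: np.ndarray, min_run: int) -> np.ndarray:
    """Absorb runs shorter than ``min_run`` into the flanking state.

    Iterates until stable; the longer flank wins, ties go to the left
    flank, and terminal short runs merge inward.
    """
    states = states.copy()
    changed = True
    while changed:
        changed = False
        runs = _runs(states)
        if len(runs) <= 1:
            break
        for i, (s, e, st) in enumerate(runs):
            if e - s >= min_run:
                continue
            left = runs[i - 1] if i > 0 else None
            right = runs[i + 1] if i + 1 < len(runs) else None
            if left is None and right is None:
                continue
            if left is None:
                new = right[2]
            elif right is None:
                new = left[2]
            else:
                new = left[2] if (left[1] - left[0]) >= (right[1] - right[0]) else right[2]
            if new != st:
                states[s:e] = new
                changed = True
                break
    return states


def _runs(states: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant runs as (start, end, state) index triples."""
    out = []
    s = 0
    for i in range(1, states.size + 1):
        if i == states.size or states[i] != states[s]:
            out.append((s, i, int(states[s])))
            s = i
    return out


def segment_ratio_track(
    ws: WindowSeries,
    par_level: float = 1.0,
    x_level: float = 0.5,
    threshold: float = 0.75,
    min_run: int = 5,
) -> SegmentCall:
    """Segment a windowed ratio track into PAR / X-specific / anomalous zones.

    Windows with mean ratio above ``threshold`` (default: the midpoint of
    the two expected levels, 0.75) are high state, the rest low
    (X-specific).  Undefined windows inherit the preceding state so sparse
    regions do not flip calls.  Runs shorter than ``min_run`` windows are
    absorbed into their flank.  High-state runs touching a chromosome end
    are PAR; high runs enclosed in the X-specific zone are ANOMALOUS
    (autosomal-like islands).  The PAB is the midpoint between the window
    centres flanking the terminal PAR / X-specific transition.
    """
    if len(ws) == 0 or not ws.defined.any():
        raise ValueError("cannot segment a track with no defined windows")

    high = np.zeros(len(ws), dtype=np.int8)  # 0 = low/X, 1 = high
    state = None
    vals = ws.values
    # first defined window seeds the leading undefined stretch
    first_def = int(np.flatnonzero(ws.defined)[0])
    state = 1 if vals[first_def] > threshold else 0
    for i in range(len(ws)):
        if ws.defined[i]:
            state = 1 if vals[i] > threshold else 0
        high[i] = state

    high = _smooth_states(high, min_run)
    runs = _runs(high)

    # label high runs: terminal -> PAR, interior -> ANOMALOUS
    labels = []
    for idx, (s, e, st) in enumerate(runs):
        if st == 0:
            labels.append(X_SPECIFIC)
        elif idx == 0 or idx == len(runs) - 1:
            labels.append(PAR)
        else:
            labels.append(ANOMALOUS)

    centers = ws.midpoints
    analyzed_start = int(ws.starts[0])
    analyzed_end = int(ws.ends[-1])
    boundaries = [analyzed_start]
    for (s1, e1, _), (s2, _, _) in zip(runs, runs[1:]):
        boundaries.append(int(round((centers[e1 - 1] + centers[s2]) / 2.0)))
    boundaries.append(analyzed_end)

    segments = [
        Segment(boundaries[i], boundaries[i + 1], labels[i]) for i in range(len(runs))
    ]
    call = SegmentCall(ws.sequence_id, segments)

    # PAB: transition between a terminal PAR run and its X-specific neighbour
    pab_candidates = []
    for i in range(len(segments) - 1):
        a, b = segments[i], segments[i + 1]
        if {a.state, b.state} == {PAR, X_SPECIFIC}:
            pab_candidates.append(a.end)
    if len(pab_candidates) >= 1:
        call.pab_position = pab_candidates[0]
    return call
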