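"""Text formats and coordinate conventions shared by the pipeline.

Per-position inputs (depth tables, pileup nucleotide profiles) use 1-based
coordinates, following ``samtools depth`` and pileup conventions.  All
interval outputs (windows, segment calls) are 0-based half-open, following
BED.  The conversion happens exactly once, when per-position records are
binned into windows.

A position absent from a depth file is treated as depth 0, matching the
default behaviour of ``samtools depth`` (which omits zero-depth sites
unless run with ``-a``).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "DepthTrack",
    "PileupProfile",
    "PileupTable",
    "WindowSeries",
    "SegmentCall",
    "Segment",
    "FormatError",
    "read_depth_table",
    "write_depth_table",
    "read_pileup_profiles",
    "write_pileup_profiles",
    "read_segments_bed",
    "write_segments_bed",
]

#: Segment states used by the coverage segmentation.
PAR = "PAR"
X_SPECIFIC = "X_SPECIFIC"
ANOMALOUS = "ANOMALOUS"
_STATES = (PAR, X_SPECIFIC, ANOMALOUS)


class FormatError(ValueError):
    """Raised for malformed input files; the message names the offending line."""


@dataclass
class DepthTrack:
    """Per-position read depth for one sample on one sequence.

    Positions are 1-based and strictly increasing; a position not listed is
    depth 0.  ``sample_sex`` is optional metadata ("male"/"female").
    """

    sequence_id: str
    positions: np.ndarray  # 1-based, strictly increasing, int64
    depth: np.ndarray  # non-negative int64, same length
    sample_sex: str | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.positions.shape != self.depth.shape:
            raise ValueError("positions and depth must have equal length")
        if self.positions.size and self.positions.min() < 1:
            raise ValueError("positions are 1-based; found position < 1")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.depth.size and self.depth.min() < 0:
            raise ValueError("depth must be non-negative")

    def __len__(self) -> int:
        return int(self.positions.size)

    def to_dense(self, length: int | None = None) -> np.ndarray:
        """Depth as a dense 0-indexed array of ``length`` (default: max position).

        Index i holds the depth at 1-based position i+1; unlisted positions
        are 0.
        """
        if length is None:
            length = int(self.positions.max()) if len(self) else 0
        dense = np.zeros(length, dtype=np.int64)
        inside = self.positions <= length
        dense[self.positions[inside] - 1] = self.depth[inside]
        return dense

    def mean_depth(self, length: int | None = None) -> float:
        """Arithmetic mean depth including implicit zero-depth positions.

        With ``length`` unset the denominator is the largest listed position.
        """
        if len(self) == 0:
            raise ValueError("cannot take the mean depth of an empty track")
        n = int(self.positions.max()) if length is None else int(length)
        if n < 1:
            raise ValueError("length must be >= 1")
        return float(self.depth[self.positions <= n].sum() / n)


@dataclass(frozen=True)
class PileupProfile:
    """Nucleotide read counts (A, C, G, T) for one sample at one 1-based site."""

    sequence_id: str
    position: int
    counts: tuple[int, int, int, int]

    @property
    def coverage(self) -> int:
        return sum(self.counts)


@dataclass
class PileupTable:
    """Columnar container for many :class:`PileupProfile` records on one sequence.

    ``counts`` is an (n, 4) array in A, C, G, T order.  Iteration yields
    :class:`PileupProfile` records in position order, so a PileupTable can be
    used anywhere a profile stream is expected.
    """

    sequence_id: str
    positions: np.ndarray  # 1-based int64
    counts: np.ndarray  # (n, 4) int64

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape != (self.positions.size, 4):
            raise ValueError("counts must be (n, 4) matching positions")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("negative nucleotide count")
        if self.positions.size:
            dup = np.flatnonzero(np.diff(self.positions) == 0)
            if dup.size:
                raise FormatError(
                    f"duplicate position {int(self.positions[dup[0]])} "
                    f"on {self.sequence_id}"
                )
            if np.any(np.diff(self.positions) < 0):
                raise ValueError("positions must be sorted")

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def __len__(self) -> int:
        return int(self.positions.size)

    def __iter__(self) -> Iterator[PileupProfile]:
        for i in range(len(self)):
            yield PileupProfile(
                self.sequence_id,
                int(self.positions[i]),
                tuple(int(c) for c in self.counts[i]),
            )


@dataclass
class WindowSeries:
    """Sliding-window statistic values with 0-based half-open coordinates.

    ``values`` uses NaN for undefined windows (too few informative
    positions); undefined is an explicit flag, never silently 0.
    ``n_informative`` counts the positions/sites that contributed to each
    window.
    """

    sequence_id: str
    starts: np.ndarray  # 0-based window starts
    ends: np.ndarray  # half-open window ends
    values: np.ndarray  # float, NaN = undefined
    n_informative: np.ndarray  # int64

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        self.n_informative = np.asarray(self.n_informative, dtype=np.int64)
        n = self.starts.size
        if not (self.ends.size == self.values.size == self.n_informative.size == n):
            raise ValueError("all WindowSeries columns must have equal length")
        if n and np.any(np.diff(self.starts) < 0):
            raise ValueError("windows must be ordered by start")
        if np.any(self.ends <= self.starts):
            raise ValueError("window_end must exceed window_start")

    def __len__(self) -> int:
        return int(self.starts.size)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) / 2.0

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("#sequence\tstart\tend\tvalue\tn_informative\n")
            for s, e, v, n in zip(self.starts, self.ends, self.values, self.n_informative):
                val = "NA" if np.isnan(v) else f"{v:.6g}"
                fh.write(f"{self.sequence_id}\t{s}\t{e}\t{val}\t{n}\n")


@dataclass(frozen=True)
class Segment:
    start: int  # 0-based
    end: int  # half-open
    state: str

    def __post_init__(self) -> None:
        if self.state not in _STATES:
            raise ValueError(f"unknown segment state {self.state!r}")
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")


@dataclass
class SegmentCall:
    """Chromosome partition into PAR / X-specific / anomalous zones.

    ``pab_position`` is the estimated pseudoautosomal boundary — the
    coordinate of the PAR to X-specific transition — or None when the
    chromosome shows a single state.
    """

    sequence_id: str
    segments: list[Segment]
    pab_position: int | None = None

    def __post_init__(self) -> None:
        for a, b in zip(self.segments, self.segments[1:]):
            if b.start != a.end:
                raise ValueError(
                    f"segments must tile without gap/overlap; "
                    f"found [..,{a.end}) then [{b.start},..)"
                )


# ---------------------------------------------------------------------------
# Depth tables (samtools-depth-style TSV: sequence, 1-based position, depth)
# ---------------------------------------------------------------------------

def read_depth_table(path: str | os.PathLike, sample_sex: str | None = None) -> list[DepthTrack]:
    """Parse a ``samtools depth``-style TSV into one DepthTrack per sequence.

    Lines are ``sequence_id<TAB>position<TAB>depth`` with 1-based positions.
    Malformed lines raise :class:`FormatError` naming the line number.
    """
    per_seq: dict[str, tuple[list[int], list[int]]] = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 tab-separated fields")
            seq, pos_s, depth_s = parts
            try:
                pos, depth = int(pos_s), int(depth_s)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer position or depth"
                ) from None
            if pos < 1:
                raise FormatError(f"{path}:{lineno}: position must be >= 1")
            if depth < 0:
                raise FormatError(f"{path}:{lineno}: negative depth")
            per_seq.setdefault(seq, ([], []))[0].append(pos)
            per_seq[seq][1].append(depth)
            n_lines += 1
    if n_lines == 0:
        raise FormatError(f"{path}: empty depth table")
    return [
        DepthTrack(seq, np.array(p), np.array(d), sample_sex=sample_sex)
        for seq, (p, d) in per_seq.items()
    ]


def write_depth_table(tracks: DepthTrack | Sequence[DepthTrack], path: str | os.PathLike) -> None:
    if isinstance(tracks, DepthTrack):
        tracks = [tracks]
    with open(path, "w") as fh:
        for tr in tracks:
            for pos, depth in zip(tr.positions, tr.depth):
                fh.write(f"{tr.sequence_id}\t{pos}\t{depth}\n")


# ---------------------------------------------------------------------------
# Pileup nucleotide profiles (sam2pro-style TSV: sequence, position, A, C, G, T)
# ---------------------------------------------------------------------------

def read_pileup_profiles(path: str | os.PathLike) -> list[PileupTable]:
    """Parse a nucleotide-profile TSV into one PileupTable per sequence.

    Columns are ``sequence_id, position, A, C, G, T`` (fixed order, no
    IUPAC/N column).  Duplicate positions and negative counts are errors.
    """
    per_seq: dict[str, tuple[list[int], list[list[int]]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 tab-separated fields")
            seq = parts[0]
            try:
                pos = int(parts[1])
                counts = [int(x) for x in parts[2:]]
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer field") from None
            if min(counts) < 0:
                raise FormatError(f"{path}:{lineno}: negative nucleotide count")
            per_seq.setdefault(seq, ([], []))[0].append(pos)
            per_seq[seq][1].append(counts)
    tables = []
    for seq, (pos, counts) in per_seq.items():
        pos_arr = np.array(pos, dtype=np.int64)
        counts_arr = np.array(counts, dtype=np.int64).reshape(-1, 4)
        order = np.argsort(pos_arr, kind="stable")
        tables.append(PileupTable(seq, pos_arr[order], counts_arr[order]))
    return tables


def write_pileup_profiles(
    tables: PileupTable | Iterable[PileupProfile] | Sequence[PileupTable],
    path: str | os.PathLike,
) -> None:
    if isinstance(tables, PileupTable):
        tables = [tables]
    with open(path, "w") as fh:
        for item in tables:
            records: Iterable[PileupProfile] = item if not isinstance(item, PileupProfile) else [item]
            for rec in records:
                a, c, g, t = rec.counts
                fh.write(f"{rec.sequence_id}\t{rec.position}\t{a}\t{c}\t{g}\t{t}\n")


# ---------------------------------------------------------------------------
# Segment calls (BED3+1: chrom, start, end, state)
# ---------------------------------------------------------------------------

_BED_HEADER = "#chrom\tstart\tend\tstate"


def write_segments_bed(call: SegmentCall, path: str | os.PathLike) -> None:
    """Serialize a SegmentCall as BED3+1 (0-based half-open, state in column 4)."""
    # SegmentCall.__post_init__ already rejects overlap; re-check defensively
    for a, b in zip(call.segments, call.segments[1:]):
        if b.start < a.end:
            raise ValueError("refusing to write overlapping segments")
    with open(path, "w") as fh:
        fh.write(_BED_HEADER + "\n")
        for seg in call.segments:
            fh.write(f"{call.sequence_id}\t{seg.start}\t{seg.end}\t{seg.state}\n")


def read_segments_bed(path: str | os.PathLike) -> SegmentCall:
    segments: list[Segment] = []
    seq_id = ""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 BED fields")
            seq_id = parts[0]
            segments.append(Segment(int(parts[1]), int(parts[2]), parts[3]))
    call = SegmentCall(seq_id or "unknown", segments)
    # recover the PAB from the segment structure when present
    for a, b in zip(segments, segments[1:]):
        if {a.state, b.state} == {PAR, X_SPECIFIC}:
            call.pab_position = a.end
            break
    return call
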