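"""Sex-contrasted SNP density from pileup nucleotide profiles.

Old evolutionary strata are hemizygous in males, so male SNP (heterozygous
site) density drops below the female's there; recent strata instead show an
excess of apparent male SNPs because fixed X-Y differences pile up while X
and Y reads still co-map.  The contrast statistic is a windowed
log-density ratio, ln(male SNPs + c) − ln(female SNPs + c) with a small
pseudocount c, compared against the range the same statistic takes on an
autosome (mean and 2.5%/97.5% quantiles).

SNP calling follows a simple count rule: a site is a SNP when its coverage
is at least ``min_coverage`` (default 5) and its second-highest nucleotide
count is at least ``minor_allele_fraction`` (default 0.3) times the
coverage.  The boundary is inclusive (>=) and configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .io_formats import PileupProfile, PileupTable, WindowSeries

__all__ = [
    "SnpCallConfig",
    "AutosomeBaseline",
    "StratumCandidate",
    "call_snps",
    "windowed_log_density_ratio",
    "autosome_baseline",
    "classify_recent_strata",
]


@dataclass(frozen=True)
class SnpCallConfig:
    """Thresholds for SNP calling and window geometry for the density ratio."""

    min_coverage: int = 5
    minor_allele_fraction: float = 0.3
    strict_boundary: bool = False  # True: require strictly greater than the threshold
    pseudocount: float = 0.001
    window_size: int = 600_000
    step: int = 10_000

    def __post_init__(self) -> None:
        if not (0 < self.minor_allele_fraction <= 0.5):
            raise ValueError("minor_allele_fraction must be in (0, 0.5]")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if not (0 < self.step <= self.window_size):
            raise ValueError("require 0 < step <= window_size")


@dataclass(frozen=True)
class AutosomeBaseline:
    """Autosomal distribution summary of the windowed log M:F SNP-density ratio."""

    mean_log_ratio: float
    q975: float
    q025: float

    def __post_init__(self) -> None:
        if not (self.q025 <= self.mean_log_ratio <= self.q975):
            raise ValueError("require q025 <= mean <= q975")


@dataclass(frozen=True)
class StratumCandidate:
    """A maximal run of outlier windows on the X.

    ``kind`` is "recent" for runs above the autosomal 97.5% quantile
    (recent-stratum candidates) or "old_consistent" for runs below the 2.5%
    quantile (consistent with an old, male-hemizygous stratum).
    """

    start: int  # 0-based
    end: int  # half-open
    kind: str
    n_windows: int


def call_snps(
    profiles: PileupTable | Iterable[PileupProfile], cfg: SnpCallConfig = SnpCallConfig()
) -> np.ndarray:
    """Call SNP positions from nucleotide-count profiles.

    A site is a SNP iff its coverage is >= ``cfg.min_coverage`` and its
    second-highest nucleotide count reaches ``cfg.minor_allele_fraction``
    times the coverage (>= by default, > with ``strict_boundary``).
    Returns the sorted 1-based SNP positions.
    """
    if isinstance(profiles, PileupTable):
        positions = profiles.positions
        counts = profiles.counts
    else:
        recs = list(profiles)
        if not recs:
            return np.array([], dtype=np.int64)
        positions = np.array([r.position for r in recs], dtype=np.int64)
        counts = np.array([r.counts for r in recs], dtype=np.int64)
    if positions.size == 0:
        return np.array([], dtype=np.int64)
    cov = counts.sum(axis=1)
    part = np.sort(counts, axis=1)
    second = part[:, -2]  # minor allele = second-highest of the four counts
    thresh = cfg.minor_allele_fraction * cov
    if cfg.strict_boundary:
        is_snp = (cov >= cfg.min_coverage) & (second > thresh)
    else:
        is_snp = (cov >= cfg.min_coverage) & (second >= thresh)
    return np.sort(positions[is_snp])


def _window_counts(
    snps: np.ndarray, starts: np.ndarray, ends: np.ndarray
) -> np.ndarray:
    """SNPs per 0-based half-open window; SNP positions are 1-based."""
    zero_based = np.sort(np.asarray(snps, dtype=np.int64)) - 1
    return np.searchsorted(zero_based, ends) - np.searchsorted(zero_based, starts)


def windowed_log_density_ratio(
    male_snps: np.ndarray,
    female_snps: np.ndarray,
    cfg: SnpCallConfig = SnpCallConfig(),
    sequence_length: int | None = None,
    sequence_id: str = "chrX",
) -> WindowSeries:
    """Windowed log male:female SNP-density contrast.

    Per window the value is ``ln(m + c) − ln(f + c)`` where m and f are the
    male and female SNP counts in the window and c the pseudocount (added
    to the window sums, so empty/empty windows are exactly 0).  Natural
    logarithm throughout.
    """
    male_snps = np.asarray(male_snps, dtype=np.int64)
    female_snps = np.asarray(female_snps, dtype=np.int64)
    if sequence_length is None:
        sequence_length = int(
            max(
                male_snps.max() if male_snps.size else 0,
                female_snps.max() if female_snps.size else 0,
            )
        )
    if sequence_length == 0:
        e = np.array([], dtype=np.int64)
        return WindowSeries(sequence_id, e, e, np.array([]), e)
    starts = np.arange(0, sequence_length, cfg.step, dtype=np.int64)
    ends = np.minimum(starts + cfg.window_size, sequence_length)
    m = _window_counts(male_snps, starts, ends)
    f = _window_counts(female_snps, starts, ends)
    values = np.log(m + cfg.pseudocount) - np.log(f + cfg.pseudocount)
    return WindowSeries(sequence_id, starts, ends, values, m + f)


def autosome_baseline(
    male_snps_auto: np.ndarray,
    female_snps_auto: np.ndarray,
    cfg: SnpCallConfig = SnpCallConfig(),
    sequence_length: int | None = None,
) -> AutosomeBaseline:
    """Autosomal mean and 2.5%/97.5% quantiles of the windowed log ratio.

    Quantiles are empirical with linear interpolation (the default of
    mainstream statistical environments).  Fewer than 20 windows triggers a
    warning: the tail quantiles are then unstable.
    """
    ws = windowed_log_density_ratio(
        male_snps_auto,
        female_snps_auto,
        cfg,
        sequence_length=sequence_length,
        sequence_id="autosome",
    )
    vals = ws.values[ws.defined]
    if vals.size == 0:
        raise ValueError("no defined autosomal windows")
    if vals.size < 20:
        warnings.warn(
            f"only {vals.size} autosomal windows; baseline quantiles are unstable",
            stacklevel=2,
        )
    return AutosomeBaseline(
        mean_log_ratio=float(vals.mean()),
        q975=float(np.quantile(vals, 0.975)),
        q025=float(np.quantile(vals, 0.025)),
    )


def classify_recent_strata(
    ws: WindowSeries, baseline: AutosomeBaseline, min_run: int = 5
) -> list[StratumCandidate]:
    """Locate runs of X windows outside the autosomal quantile envelope.

    Maximal runs of at least ``min_run`` consecutive windows above the
    97.5% autosomal quantile are recent-stratum candidates; runs below the
    2.5% quantile are annotated old-stratum-consistent.  Candidate
    coordinates span from the first window's start to the last window's
    end.  An empty list is the no-recent-strata outcome.
    """
    out: list[StratumCandidate] = []
    vals = ws.values
    for kind, mask in (
        ("recent", vals > baseline.q975),
        ("old_consistent", vals < baseline.q025),
    ):
        mask = mask & ws.defined
        i = 0
        n = len(ws)
        while i < n:
            if not mask[i]:
                i += 1
                continue
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i >= min_run:
                out.append(
                    StratumCandidate(
                        start=int(ws.starts[i]),
                        end=int(ws.ends[j - 1]),
                        kind=kind,
                        n_windows=j - i,
                    )
                )
            i = j
    out.sort(key=lambda c: c.start)
    return out
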