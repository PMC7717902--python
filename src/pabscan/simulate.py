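"""Synthetic male/female sequencing data over a structured sex chromosome.

The generator emulates the data the pipeline consumes: per-position depth
tracks and pileup nucleotide profiles for one male and one female sample,
over a chromosome partitioned into segment classes with known expected
signals:

============== ================== ==========================
class          expected M:F depth expected M:F SNP density
============== ================== ==========================
PAR            1                  ~1
OLD_STRATUM    0.5                < 1 (male haploidy)
RECENT_STRATUM 1                  > 1 (fixed X-Y differences)
AUTOSOMAL_INSERT 1                ~1
============== ================== ==========================

Depth noise is Poisson by default; a negative-binomial option with a
dispersion knob is provided because real Illumina depth is overdispersed.
A single integer seed governs all draws; independent substreams are derived
deterministically per output track, so identical seeds give byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .io_formats import DepthTrack, PileupTable, Segment, SegmentCall

__all__ = [
    "PAR",
    "OLD_STRATUM",
    "RECENT_STRATUM",
    "AUTOSOMAL_INSERT",
    "ChromosomeArchitecture",
    "SimulationConfig",
    "default_architecture",
    "simulate_depth_tracks",
    "simulate_pileup_profiles",
    "simulate_strata_counts",
]

PAR = "PAR"
OLD_STRATUM = "OLD_STRATUM"
RECENT_STRATUM = "RECENT_STRATUM"
AUTOSOMAL_INSERT = "AUTOSOMAL_INSERT"
_CLASSES = (PAR, OLD_STRATUM, RECENT_STRATUM, AUTOSOMAL_INSERT)

#: expected male:female depth ratio per segment class (diploid male mean is
#: halved only where the male is hemizygous)
_MALE_DEPTH_FACTOR = {PAR: 1.0, OLD_STRATUM: 0.5, RECENT_STRATUM: 1.0, AUTOSOMAL_INSERT: 1.0}


@dataclass(frozen=True)
class ArchSegment:
    start: int  # 0-based
    end: int  # half-open
    seg_class: str

    def __post_init__(self) -> None:
        if self.seg_class not in _CLASSES:
            raise ValueError(f"unknown segment class {self.seg_class!r}")
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")


@dataclass
class ChromosomeArchitecture:
    """True segment structure of the simulated sex chromosome.

    Segments must tile ``[0, length)``.  ``reference_autosome_length`` sizes
    the autosome simulated alongside for depth normalisation and the SNP
    baseline.
    """

    length: int
    segments: list[ArchSegment]
    reference_autosome_length: int = 5_000_000
    sequence_id: str = "chrX_sim"
    autosome_id: str = "chr4_sim"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("architecture length must be positive")
        if not self.segments:
            raise ValueError("architecture must have at least one segment")
        pos = 0
        for seg in self.segments:
            if seg.start != pos:
                raise ValueError("segments must tile [0, length) without gaps")
            pos = seg.end
        if pos != self.length:
            raise ValueError("segments must end exactly at the architecture length")

    def class_array(self) -> np.ndarray:
        """Per-position segment-class index (order of ``_CLASSES``)."""
        arr = np.empty(self.length, dtype=np.int8)
        for seg in self.segments:
            arr[seg.start : seg.end] = _CLASSES.index(seg.seg_class)
        return arr

    def truth_segments(self) -> SegmentCall:
        """The architecture as a coverage-state truth call (for assertions).

        PAR maps to PAR, AUTOSOMAL_INSERT to ANOMALOUS, and both strata
        classes to X-specific depth state only where the depth signal says
        so: RECENT_STRATUM has depth ratio 1 and is therefore expected to
        look pseudoautosomal to the coverage stage.
        """
        state_map = {
            PAR: "PAR",
            OLD_STRATUM: "X_SPECIFIC",
            RECENT_STRATUM: "PAR",
            AUTOSOMAL_INSERT: "ANOMALOUS",
        }
        merged: list[Segment] = []
        for seg in self.segments:
            st = state_map[seg.seg_class]
            if merged and merged[-1].state == st:
                merged[-1] = Segment(merged[-1].start, seg.end, st)
            else:
                merged.append(Segment(seg.start, seg.end, st))
        call = SegmentCall(self.sequence_id, merged)
        for a, b in zip(merged, merged[1:]):
            if a.state == "PAR" and b.state == "X_SPECIFIC":
                call.pab_position = a.end
                break
        return call


def default_architecture() -> ChromosomeArchitecture:
    """Default study-like chromosome: 8 Mb PAR, 60 Mb old stratum, 5 Mb recent stratum."""
    return ChromosomeArchitecture(
        length=73_000_000,
        segments=[
            ArchSegment(0, 8_000_000, PAR),
            ArchSegment(8_000_000, 68_000_000, OLD_STRATUM),
            ArchSegment(68_000_000, 73_000_000, RECENT_STRATUM),
        ],
    )


@dataclass
class SimulationConfig:
    """Noise and SNP-rate settings for the synthetic data generator.

    ``mean_depth_male_diploid`` is the male mean where he carries two copies
    (PAR, autosome); on OLD_STRATUM segments the realized mean is half of
    it.  SNP rates are per-bp heterozygous-site rates; the male rate in a
    segment class is the female rate times the class factor.
    """

    mean_depth_female: float = 30.0
    mean_depth_male_diploid: float = 30.0
    depth_noise: Literal["poisson", "negative_binomial", "none"] = "poisson"
    nb_dispersion: float = 5.0  # NB size parameter; larger = closer to Poisson
    snp_rate_par: float = 1e-3
    old_stratum_male_snp_factor: float = 0.5
    recent_stratum_male_snp_factor: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth_female < 0 or self.mean_depth_male_diploid < 0:
            raise ValueError("mean depths must be non-negative")
        if self.snp_rate_par < 0:
            raise ValueError("SNP rate must be non-negative")
        if self.old_stratum_male_snp_factor <= 0 or self.recent_stratum_male_snp_factor <= 0:
            raise ValueError("SNP-rate factors must be positive")
        if self.depth_noise not in ("poisson", "negative_binomial", "none"):
            raise ValueError(f"unknown depth noise model {self.depth_noise!r}")

    def male_snp_factor(self, seg_class: str) -> float:
        return {
            PAR: 1.0,
            OLD_STRATUM: self.old_stratum_male_snp_factor,
            RECENT_STRATUM: self.recent_stratum_male_snp_factor,
            AUTOSOMAL_INSERT: 1.0,
        }[seg_class]


def _substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic named substream of the global seed.

    Uses CRC32 of the label (stable across processes, unlike ``hash``).
    """
    import zlib

    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(label.encode())]))


def _draw_depth(rng: np.random.Generator, mean: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    if cfg.depth_noise == "none":
        return np.asarray(np.round(mean), dtype=np.int64)
    if cfg.depth_noise == "poisson":
        return rng.poisson(mean).astype(np.int64)
    # negative binomial with mean m and size r: p = r / (r + m)
    r = cfg.nb_dispersion
    if r <= 0:
        raise ValueError("nb_dispersion must be positive")
    p = r / (r + np.asarray(mean, dtype=float))
    return rng.negative_binomial(r, p).astype(np.int64)


def simulate_depth_tracks(
    arch: ChromosomeArchitecture, cfg: SimulationConfig
) -> tuple[DepthTrack, DepthTrack, DepthTrack, DepthTrack]:
    """Simulate per-position depth for both sexes on the X and an autosome.

    Returns ``(male_x, female_x, male_autosome, female_autosome)``.  Female
    mean depth is uniform; the male mean is halved on OLD_STRATUM segments
    (hemizygosity) and diploid elsewhere.  Autosome tracks use each
    sample's diploid mean.
    """
    classes = arch.class_array()
    factor = np.array([_MALE_DEPTH_FACTOR[c] for c in _CLASSES])[classes]
    male_mean = cfg.mean_depth_male_diploid * factor
    female_mean = np.full(arch.length, cfg.mean_depth_female)

    pos_x = np.arange(1, arch.length + 1, dtype=np.int64)
    pos_a = np.arange(1, arch.reference_autosome_length + 1, dtype=np.int64)
    male_x = DepthTrack(
        arch.sequence_id,
        pos_x,
        _draw_depth(_substream(cfg.seed, "depth/male/X"), male_mean, cfg),
        sample_sex="male",
    )
    female_x = DepthTrack(
        arch.sequence_id,
        pos_x,
        _draw_depth(_substream(cfg.seed, "depth/female/X"), female_mean, cfg),
        sample_sex="female",
    )
    male_auto = DepthTrack(
        arch.autosome_id,
        pos_a,
        _draw_depth(
            _substream(cfg.seed, "depth/male/autosome"),
            np.full(arch.reference_autosome_length, cfg.mean_depth_male_diploid),
            cfg,
        ),
        sample_sex="male",
    )
    female_auto = DepthTrack(
        arch.autosome_id,
        pos_a,
        _draw_depth(
            _substream(cfg.seed, "depth/female/autosome"),
            np.full(arch.reference_autosome_length, cfg.mean_depth_female),
            cfg,
        ),
        sample_sex="female",
    )
    return male_x, female_x, male_auto, female_auto


def _plant_profiles(
    rng: np.random.Generator,
    seq_id: str,
    length: int,
    mean_depth: float,
    het_rate: float,
    cfg: SimulationConfig,
) -> PileupTable:
    """Uniform-mean convenience wrapper over :func:`_plant_profiles_per_site`."""
    return _plant_profiles_per_site(
        rng,
        seq_id,
        np.full(length, float(mean_depth)),
        np.full(length, float(het_rate)),
        cfg,
    )


def simulate_pileup_profiles(
    arch: ChromosomeArchitecture, cfg: SimulationConfig, include_autosome: bool = False
) -> tuple[PileupTable, PileupTable] | tuple[PileupTable, PileupTable, PileupTable, PileupTable]:
    """Simulate nucleotide-count profiles for both sexes on the X.

    The female heterozygous-site rate is ``snp_rate_par`` in every class;
    the male rate is the female rate times the class factor (<1 on old
    strata, >1 on recent strata).  With ``include_autosome`` two autosomal
    tables (rate ``snp_rate_par`` for both sexes) are appended.
    """
    classes = arch.class_array()
    male_factor = np.array([cfg.male_snp_factor(c) for c in _CLASSES])[classes]
    female_rate = cfg.snp_rate_par
    male_rate = female_rate * male_factor
    # male coverage mean is class-dependent (hemizygous on old strata)
    male = _plant_profiles_per_site(
        _substream(cfg.seed, "pileup/male/X"),
        arch.sequence_id,
        cfg.mean_depth_male_diploid
        * np.array([_MALE_DEPTH_FACTOR[c] for c in _CLASSES])[classes],
        male_rate,
        cfg,
    )
    female = _plant_profiles(
        _substream(cfg.seed, "pileup/female/X"),
        arch.sequence_id,
        arch.length,
        cfg.mean_depth_female,
        female_rate,
        cfg,
    )
    if not include_autosome:
        return male, female
    male_auto = _plant_profiles(
        _substream(cfg.seed, "pileup/male/autosome"),
        arch.autosome_id,
        arch.reference_autosome_length,
        cfg.mean_depth_male_diploid,
        female_rate,
        cfg,
    )
    female_auto = _plant_profiles(
        _substream(cfg.seed, "pileup/female/autosome"),
        arch.autosome_id,
        arch.reference_autosome_length,
        cfg.mean_depth_female,
        female_rate,
        cfg,
    )
    return male, female, male_auto, female_auto


def _plant_profiles_per_site(
    rng: np.random.Generator,
    seq_id: str,
    mean_depth: np.ndarray,
    het_rate: np.ndarray,
    cfg: SimulationConfig,
) -> PileupTable:
    """Draw per-site coverage and nucleotide counts with planted heterozygous sites.

    Planted sites get a minor-allele count of at least ``ceil(0.3*coverage)``
    so they are callable by design; background sites are homozygous.  Sites
    with zero realized coverage are omitted (a pileup has no line for them).
    """
    length = mean_depth.size
    cov = _draw_depth(rng, np.asarray(mean_depth, dtype=float), cfg)
    het = rng.random(length) < het_rate
    idx = np.flatnonzero(cov > 0)
    cov_c = cov[idx]
    het_c = het[idx]
    n = idx.size
    counts = np.zeros((n, 4), dtype=np.int64)
    major = rng.integers(0, 4, size=n)
    counts[np.arange(n), major] = cov_c
    h = np.flatnonzero(het_c)
    if h.size:
        cov_h = cov_c[h]
        minor = rng.binomial(cov_h, 0.5)
        minor = np.minimum(minor, cov_h - minor)
        floor = np.ceil(0.3 * cov_h).astype(np.int64)
        minor = np.clip(np.maximum(minor, floor), 0, cov_h // 2)
        alt = (major[h] + 1 + rng.integers(0, 3, size=h.size)) % 4
        counts[h, major[h]] = cov_h - minor
        counts[h, alt] = minor
    return PileupTable(seq_id, idx.astype(np.int64) + 1, counts)


def simulate_strata_counts(
    dt1: float, dt2: float, lambda0: float, n_reps: int, seed: int = 0
) -> list[tuple[int, int]]:
    """Draw replicate strata counts under a common formation rate.

    Each replicate draws ``S1 ~ Poisson(lambda0*dt1)`` and
    ``S2 ~ Poisson(lambda0*dt2)`` independently — the null hypothesis of
    the strata-rate test.
    """
    if dt1 < 0 or dt2 < 0 or lambda0 < 0:
        raise ValueError("branch lengths and rate must be non-negative")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = _substream(seed, "strata_counts")
    s1 = rng.poisson(lambda0 * dt1, size=n_reps)
    s2 = rng.poisson(lambda0 * dt2, size=n_reps)
    return list(zip(s1.tolist(), s2.tolist()))
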