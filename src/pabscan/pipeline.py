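"""End-to-end pipeline configuration and the self-contained synthetic demo.

``run_demo`` exercises every stage on simulated data: it builds a
chromosome with a known PAR / old-stratum / recent-stratum architecture,
simulates depth and pileup data for both sexes, runs the coverage and
SNP-density analyses, the strata-rate test (on the published branch-length
totals), and the dimorphism statistics on the packaged phenotype table,
then writes a machine-readable JSON report comparing estimates with the
simulator truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import coverage, dimorphism, simulate, snpdensity, stratatest
from .io_formats import SegmentCall, write_segments_bed

__all__ = ["PipelineConfig", "validate_config", "run_demo"]

log = logging.getLogger("pabscan")


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters; defaults are the study settings.

    Depth-ratio windows: 150 kb sliding by 10 kb.  SNP-density windows:
    600 kb sliding by 10 kb.  SNP calling: coverage >= 5, minor-allele
    count >= 0.3 x coverage, pseudocount 0.001 on window sums.
    """

    coverage_window: int = 150_000
    coverage_step: int = 10_000
    snp_window: int = 600_000
    snp_step: int = 10_000
    min_coverage: int = 5
    minor_allele_fraction: float = 0.3
    pseudocount: float = 0.001
    segmentation_threshold: float = 0.75
    min_run: int = 5
    min_informative_fraction: float = 0.2
    timescale: str = "years"
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def validate_config(raw: dict | PipelineConfig) -> PipelineConfig:
    """Fill defaults and sanity-check a raw key-value configuration.

    Unknown keys warn (forward compatibility); every violated constraint is
    collected and reported in a single aggregated error.
    """
    if isinstance(raw, PipelineConfig):
        cfg = raw
    else:
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        unknown = sorted(set(raw) - known)
        for key in unknown:
            warnings.warn(f"unknown config key {key!r} ignored", stacklevel=2)
        cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})

    problems = []
    if not (0 < cfg.coverage_step <= cfg.coverage_window):
        problems.append("require 0 < coverage_step <= coverage_window")
    if not (0 < cfg.snp_step <= cfg.snp_window):
        problems.append("require 0 < snp_step <= snp_window")
    if cfg.min_coverage < 1:
        problems.append("min_coverage must be >= 1")
    if not (0 < cfg.minor_allele_fraction <= 0.5):
        problems.append("minor_allele_fraction must be in (0, 0.5]")
    if cfg.pseudocount <= 0:
        problems.append("pseudocount must be positive")
    if not (0 < cfg.segmentation_threshold < 1.5):
        problems.append("segmentation_threshold out of range")
    if cfg.min_run < 1:
        problems.append("min_run must be >= 1")
    if cfg.timescale not in ("years", "generations"):
        problems.append("timescale must be 'years' or 'generations'")
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    return cfg


#: published subtree totals and strata counts used by the demo's rate test
PUBLISHED_STRATA = {
    "s1": 3,
    "s2": 0,
    "dt_my": (188.52, 321.32),
    "dt_mgen": (44.23, 158.52),
}


def _demo_architecture() -> simulate.ChromosomeArchitecture:
    """20 Mb chromosome (5 Mb PAR, 13 Mb old stratum, 2 Mb recent) + 5 Mb autosome."""
    return simulate.ChromosomeArchitecture(
        length=20_000_000,
        segments=[
            simulate.ArchSegment(0, 5_000_000, simulate.PAR),
            simulate.ArchSegment(5_000_000, 18_000_000, simulate.OLD_STRATUM),
            simulate.ArchSegment(18_000_000, 20_000_000, simulate.RECENT_STRATUM),
        ],
        reference_autosome_length=5_000_000,
    )


def run_demo(
    seed: int = 0,
    out_dir: str | os.PathLike | None = None,
    config: PipelineConfig | None = None,
    arch: simulate.ChromosomeArchitecture | None = None,
) -> dict:
    """Run every pipeline stage on synthetic data and return the JSON report."""
    cfg = validate_config(config or PipelineConfig(seed=seed))
    cfg.seed = seed
    if arch is None:
        arch = _demo_architecture()
    sim_cfg = simulate.SimulationConfig(seed=seed)
    report: dict = {
        "seed": seed,
        "config_hash": cfg.config_hash(),
        "config": dataclasses.asdict(cfg),
    }

    # --- coverage stage ---------------------------------------------------
    log.info("simulating depth tracks (length=%d)", arch.length)
    male_x, female_x, male_a, female_a = simulate.simulate_depth_tracks(arch, sim_cfg)
    norm = coverage.NormalizationConstants(
        male_autosome_mean=coverage.autosome_mean_depth(male_a),
        female_autosome_mean=coverage.autosome_mean_depth(female_a),
    )
    ratio = coverage.normalized_ratio_per_position(male_x, female_x, norm, length=arch.length)
    wcfg = coverage.RatioWindowConfig(
        window_size=cfg.coverage_window,
        step=cfg.coverage_step,
        min_informative_fraction=cfg.min_informative_fraction,
    )
    ws = coverage.sliding_window_mean(ratio, wcfg, sequence_id=arch.sequence_id)
    call = coverage.segment_ratio_track(
        ws, threshold=cfg.segmentation_threshold, min_run=cfg.min_run
    )
    truth = arch.truth_segments()
    pab_err = (
        abs(call.pab_position - truth.pab_position)
        if call.pab_position is not None and truth.pab_position is not None
        else None
    )
    classes = arch.class_array()
    centers = ws.midpoints.astype(int)
    par_mask = classes[np.clip(centers, 0, arch.length - 1)] == 0
    old_mask = classes[np.clip(centers, 0, arch.length - 1)] == 1
    report["coverage"] = {
        "normalization": {"male": norm.male_autosome_mean, "female": norm.female_autosome_mean},
        "pab_true": truth.pab_position,
        "pab_estimated": call.pab_position,
        "pab_error_bp": pab_err,
        "mean_ratio_par_windows": float(np.nanmean(ws.values[par_mask])),
        "mean_ratio_old_stratum_windows": float(np.nanmean(ws.values[old_mask])),
        "n_windows": len(ws),
    }

    # --- SNP-density stage ------------------------------------------------
    log.info("simulating pileup profiles")
    m_pro, f_pro, ma_pro, fa_pro = simulate.simulate_pileup_profiles(
        arch, sim_cfg, include_autosome=True
    )
    scfg = snpdensity.SnpCallConfig(
        min_coverage=cfg.min_coverage,
        minor_allele_fraction=cfg.minor_allele_fraction,
        pseudocount=cfg.pseudocount,
        window_size=cfg.snp_window,
        step=cfg.snp_step,
    )
    m_snps = snpdensity.call_snps(m_pro, scfg)
    f_snps = snpdensity.call_snps(f_pro, scfg)
    baseline = snpdensity.autosome_baseline(
        snpdensity.call_snps(ma_pro, scfg),
        snpdensity.call_snps(fa_pro, scfg),
        scfg,
        sequence_length=arch.reference_autosome_length,
    )
    sws = snpdensity.windowed_log_density_ratio(
        m_snps, f_snps, scfg, sequence_length=arch.length, sequence_id=arch.sequence_id
    )
    candidates = snpdensity.classify_recent_strata(sws, baseline, min_run=cfg.min_run)
    recent = [c for c in candidates if c.kind == "recent"]
    report["snp_density"] = {
        "n_male_snps": int(m_snps.size),
        "n_female_snps": int(f_snps.size),
        "baseline": dataclasses.asdict(baseline),
        "recent_stratum_candidates": [dataclasses.asdict(c) for c in recent],
        "old_consistent_runs": [
            dataclasses.asdict(c) for c in candidates if c.kind == "old_consistent"
        ],
        "recent_stratum_truth": [
            [s.start, s.end] for s in arch.segments if s.seg_class == simulate.RECENT_STRATUM
        ],
    }

    # --- strata-rate test -------------------------------------------------
    s1, s2 = PUBLISHED_STRATA["s1"], PUBLISHED_STRATA["s2"]
    _, p_my = stratatest.strata_rate_analysis(s1, s2, *PUBLISHED_STRATA["dt_my"])
    _, p_gen = stratatest.strata_rate_analysis(
        s1, s2, *PUBLISHED_STRATA["dt_mgen"], timescale="generations"
    )
    report["strata_test"] = {
        "per_my": {"s1": s1, "s2": s2, "dt1": 188.52, "dt2": 321.32, "p_value": p_my},
        "per_generation": {"s1": s1, "s2": s2, "dt1": 44.23, "dt2": 158.52, "p_value": p_gen},
        "reproduction": [
            f"one-tailed binomial test, p={p_my:.3f} (per-My timescale)",
            f"one-tailed binomial test, p={p_gen:.3f} (per-generation timescale)",
        ],
    }

    # --- dimorphism stage ---------------------------------------------------
    table = dimorphism.load_reference_table()
    ssd_sum = dimorphism.group_summary(dimorphism.ssd(table), table["group"])
    csd_sum = dimorphism.group_summary(dimorphism.csd(table), table["group"])
    rtm_sum = dimorphism.group_summary(dimorphism.relative_testes_mass(table), table["group"])
    report["dimorphism"] = {
        stat: {g: dataclasses.asdict(s) for g, s in summ.items()}
        for stat, summ in (("ssd", ssd_sum), ("csd", csd_sum), ("rtm", rtm_sum))
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ws.to_tsv(out / "coverage_windows.tsv")
        sws.to_tsv(out / "snp_density_windows.tsv")
        write_segments_bed(call, out / "segments.bed")
        write_segments_bed(truth, out / "truth_segments.bed")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
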