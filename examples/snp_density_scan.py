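"""Detect a recent evolutionary stratum from the M:F SNP-density contrast.

Recent strata are invisible to the depth ratio (X and Y reads co-map) but
show an excess of apparent male heterozygous sites from fixed X-Y
differences.  This example simulates pileup profiles, calls SNPs per sex
(coverage >= 5, minor-allele count >= 0.3 x coverage), and flags windows
outside the autosomal 2.5-97.5% envelope.
"""

from pabscan import simulate as sim
from pabscan import snpdensity as snp

arch = sim.ChromosomeArchitecture(
    length=4_000_000,
    segments=[
        sim.ArchSegment(0, 1_000_000, sim.PAR),
        sim.ArchSegment(1_000_000, 3_200_000, sim.OLD_STRATUM),
        sim.ArchSegment(3_200_000, 4_000_000, sim.RECENT_STRATUM),
    ],
    reference_autosome_length=2_000_000,
)
male, female, male_auto, female_auto = sim.simulate_pileup_profiles(
    arch, sim.SimulationConfig(seed=0), include_autosome=True
)

cfg = snp.SnpCallConfig(window_size=200_000, step=10_000)
male_snps = snp.call_snps(male, cfg)
female_snps = snp.call_snps(female, cfg)
baseline = snp.autosome_baseline(
    snp.call_snps(male_auto, cfg), snp.call_snps(female_auto, cfg), cfg,
    sequence_length=arch.reference_autosome_length,
)
windows = snp.windowed_log_density_ratio(
    male_snps, female_snps, cfg, sequence_length=arch.length
)
candidates = snp.classify_recent_strata(windows, baseline, min_run=5)

print(f"SNPs called: {male_snps.size} male, {female_snps.size} female")
print(
    f"autosomal baseline ln(M:F): mean {baseline.mean_log_ratio:+.3f}, "
    f"envelope [{baseline.q025:+.3f}, {baseline.q975:+.3f}]"
)
for c in candidates:
    label = "recent-stratum candidate" if c.kind == "recent" else "old-stratum-consistent"
    print(f"  {label}: [{c.start:,} - {c.end:,}) over {c.n_windows} windows")
print(
    "Windows above the autosomal envelope mark a candidate recent stratum "
    "(true recent stratum: 3,200,000 - 4,000,000); runs below it are "
    "consistent with old, male-hemizygous strata."
)
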