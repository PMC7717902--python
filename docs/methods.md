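# Methods

## Model and procedure

### Coverage analysis

Per-position read depth for one male and one female sample on the X is
normalized by each sample's mean depth on a reference autosome, so
library-size differences cancel and the expected normalized M:F ratio is
1 where males carry two copies (PAR, autosomal material, recent strata
whose Y-derived reads still co-map to the X) and 0.5 where they are
hemizygous (older X-specific sequence).  The ratio is formed **per
position** and then averaged over sliding windows — not as a ratio of
window means.  Positions where the female has zero depth are excluded
from the window mean as uninformative rather than mapped to 0 or
infinity; windows whose informative fraction falls below a threshold
(default 0.2) are reported as undefined, and segmentation carries the
preceding state across them so sparse mapping cannot flip a call.

One numerical property of the per-position formulation is worth knowing:
for independent Poisson depths with mean λ, E[m/f | f>0] exceeds
E[m]/E[f] by a factor ≈ 1 + 1/λ (Jensen's inequality applied to 1/f), so
at 30× the PAR level sits near 1.034 and the X-specific level near 0.517
rather than exactly 1 and 0.5.  The bias shrinks with depth, affects both
levels proportionally, and is far smaller than the gap between levels, so
the midpoint threshold is unaffected.  It is visible in the package's own
outputs and tests.

### Segmentation and the PAB

Published analyses of this kind identify the boundary visually; the
package uses the simplest reproducible rule instead.  Defined windows are
classified high (> 0.75, the midpoint of the two expected levels) or low;
runs shorter than `min_run` windows (default 5) are absorbed into the
longer flank, suppressing isolated noisy windows; high runs touching a
chromosome end are PAR while interior high runs are ANOMALOUS
(autosomal-like islands inside the X-specific zone, matching the
depth-ratio-1 contaminant regions real assemblies show); the PAB is
placed midway between the window centres flanking the terminal
PAR/X-specific transition.  With overlapping windows this lands within
one step (10 kb) of a sharp true boundary on noiseless input; the final
partial window at the chromosome end is reported, its shorter span
visible from its coordinates.  If both chromosome ends are high-state,
the first transition supplies the single reported PAB.

### SNP-density contrast

SNPs are called per sex directly from nucleotide-count profiles: a site
needs coverage ≥ 5, and its **second-highest** nucleotide count (the
minor allele, also at triallelic sites) must reach 0.3 × coverage.  The
comparison is inclusive (≥) at the boundary; a strict (>) variant is a
config switch since published threshold descriptions rarely pin this
down.  Window values are ln(m + c) − ln(f + c) with the pseudocount
c = 0.001 added to the window **sums**, which makes empty/empty windows
exactly 0 and the statistic exactly antisymmetric under sex swap.
Natural log throughout.  The X track is interpreted against the mean and
empirical 2.5%/97.5% quantiles (linear-interpolation type) of the same
statistic on an autosome; maximal runs of ≥ `min_run` windows above the
upper quantile are recent-stratum candidates, runs below the lower
quantile are annotated old-stratum-consistent.  Because a 600 kb window
overlapping a stratum edge mixes both regimes, candidate boundaries are
localized only to about one window size — the tests assert exactly that,
not step-level precision.

### Strata-formation rate test

Strata formation on a subtree of total branch length Δt is
Poisson(λΔt).  Conditioning on the total count across two subtrees
eliminates the unknown rate: S₁ | S₁+S₂ ~ Binomial(k₁+k₂,
Δt₁/(Δt₁+Δt₂)).  The reported p-value is the one-tailed upper tail
P(S₁ ≥ k₁); a two-sided variant (doubled smaller tail) is exposed but not
the default.  With zero events in total the p-value is 1 — no events, no
evidence.  The test depends only on the ratio Δt₁:Δt₂, which the tests
verify directly.  Stratum counts and clade labels are supplied by the
user (counts of this kind come from comparative literature, not from the
depth pipeline); published subtree totals can be passed directly in place
of a tree.

### Generation-time rescaling

γ(t), the instantaneous generation time along a branch, is assumed linear
between the branch's endpoint values, giving the closed form
(t_d − t_a)/(γ_d − γ_a) · ln(γ_d/γ_a) for the generations elapsed; at
relative endpoint differences below 1e-9 the implementation switches to
the analytic limit (t_d − t_a)/γ to avoid catastrophic cancellation
(checked against the limit at relative differences 1e-3, 1e-6, 1e-9, and
against numerical quadrature elsewhere).  Endpoint values: tips use age
at first reproduction (years); internal nodes use maximum-likelihood
Brownian-motion ancestral states, computed by solving the joint-ML normal
equations (each internal node the harmonic-branch-length-weighted average
of its neighbours — for a Gaussian process the joint mode equals the
per-node GLS/re-rooting estimates, so this reproduces `fastAnc`-style
values, which the tests confirm both against a frozen independent
reference and against brute-force likelihood maximization).  Node times
are distances from the root in My.  Applying the branch formula with
lengths in My and γ in years yields millions of generations directly,
since the 10⁶ factors cancel.  Only point estimates are produced;
uncertainty in the reconstruction is not propagated.

### Dimorphism statistics

SSD and CSD are plain log male:female ratios; species missing a
measurement are skipped per statistic (the reference table has one
species without canine data and two without testes data).  RTM fits one
OLS line of ln(testes) on ln(male mass) across **all** complete records
jointly and takes per-species residuals, so residuals sum to zero across
the fitted set and are invariant to common mass rescaling.  The group
comparison is deliberately non-phylogenetic (Welch t by default,
rank-sum optional, always labelled) — phylogenetically corrected variants
are out of scope.  Group standard errors are sample SD/√n; published ±
values for such data do not always follow this convention, so the
package reports SEs for description, and its regression tests pin only
the group means.  The ANCOVA ln(testes) ~ ln(mass) + group reports the
group coefficient with a residual-t p-value; when the groups have
identical mass distributions it coincides with the difference of group
residual means (checked numerically).

## Synthetic data generator

The generator emulates exactly the statistical structure the pipeline
consumes, over a chromosome tiled by PAR / OLD_STRATUM / RECENT_STRATUM /
AUTOSOMAL_INSERT segments: female depth has one mean everywhere; male
depth has the diploid mean except on OLD_STRATUM where it is halved;
depth noise is Poisson by default (negative binomial with a dispersion
knob available, since real Illumina depth is overdispersed).
Heterozygous sites are planted per class and sex — female rate uniform
(default 10⁻³/bp), male rate multiplied by 0.5 on old strata and 3.0 on
recent strata — and every planted site receives a minor-allele count of
at least ⌈0.3 × coverage⌉, so simulator correctness is decoupled from
caller sensitivity in unit tests.  Default depth is 30× for both sexes,
matching moderate-coverage resequencing designs.  A single seed drives
CRC-derived named substreams, so identical seeds give byte-identical
outputs across processes.

What it does **not** model: read-level artefacts (mapping bias, GC bias,
repeats, duplicates), cross-species mapping divergence, assembly
fragmentation, or linkage structure in SNP placement.  Passing
parameter-recovery tests therefore demonstrates the statistical machinery
is correct under the stated model, not robustness to those artefacts;
the noisy ratio tracks real cross-species mapping produces may need the
larger windows the window parameters allow.

## Problem sizes and numerical choices

The self-contained demo runs on a 20 Mb chromosome (5 Mb PAR / 13 Mb old
stratum / 2 Mb recent stratum) with a 5 Mb autosome; the depth-ratio
recovery experiment in `scripts/acceptance.py` uses the default 73 Mb
architecture (8 Mb PAR / 60 Mb old stratum / 5 Mb recent stratum), sizes
chosen to mirror a primate X while keeping a laptop-scale footprint.
Windowed means use prefix sums (exact to floating point, verified against
brute-force recomputation); quantiles are linear-interpolation empirical
quantiles; the binomial tail is computed by the survival function of a
standard library, not by summation.  Degenerate inputs have defined
behaviour throughout: empty depth files and all-undefined window tracks
are errors, zero-coverage pileup sites parse but never call, female-zero
positions are uninformative, and S₁=S₂=0 gives p = 1.

## Known limitations

- Stratum counts are inputs; the package does not infer strata from
  sequence alignments, and the per-generation test inherits whatever
  uncertainty the supplied counts and divergence times carry.
- The segmentation is a two-level threshold rule, not an HMM/changepoint
  model; chromosomes whose true ratio drifts between levels (strong
  mapping bias) may need per-species window and threshold settings.
- Calibration of the conditional test is conservative because the
  binomial is discrete: at α = 0.05 the null rejection rate measured over
  10,000 simulated histories stays at or below 0.06 but can sit well
  below 0.05 for small expected counts.
- The PAB is a boundary estimate only; PAR size is not meaningful when
  autosomal material is interleaved, which is why ANOMALOUS islands are
  reported separately rather than merged into the PAR.
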