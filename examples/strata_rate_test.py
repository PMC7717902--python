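"""Compare strata-formation rates between two clades.

Haplorrhine primates accumulated 3 new evolutionary strata (4, 5, and 4')
over 188.52 My of summed lineage time (44.23 million generations), while
strepsirrhines formed none over 321.32 My (158.52 Mgen).  Under a common
Poisson formation rate, S1 conditional on the total is binomial with
p = dt1/(dt1+dt2), independent of the rate itself.
"""

from pabscan import stratatest as strata

for label, dt1, dt2, unit in (
    ("per million years", 188.52, 321.32, "My"),
    ("per million generations", 44.23, 158.52, "Mgen"),
):
    obs, p = strata.strata_rate_analysis(3, 0, dt1, dt2)
    frac = dt1 / (dt1 + dt2)
    print(
        f"{label:>25}: S=(3, 0), dt=({dt1}, {dt2}) {unit}, "
        f"coin bias p={frac:.3f} -> one-tailed p = {p:.4f}"
    )

print(
    "\nOn the year timescale the excess is marginal (p = 0.051); after "
    "rescaling branch lengths by generation time the haplorrhine rate "
    "excess is significant (p = 0.010): strepsirrhines' longer summed "
    "generation count makes their zero count more surprising."
)
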