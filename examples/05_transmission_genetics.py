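"""Gametophytic transmission statistics from reciprocal crosses.

For a heterozygote x wild-type cross of a gametophyte-acting allele, the
progeny are WT or heterozygous (1:1:0 under Mendelian transmission).
Transmission efficiency TE = 100 * het / WT measures mutant-allele
transmission through the segregating gamete; a chi-square test against
1:1:0 plus TE < 50% flags segregation distortion.
"""

from pollenpref import CrossCounts, analyze_cross, gen_cross_progeny, proportion

# printed counts from a reciprocal crossing experiment
crosses = [CrossCounts("het-female x WT-male", 33, 28),
           CrossCounts("WT-female x het-male", 35, 0)]
for c in crosses:
    r = analyze_cross(c)
    print(f"{c.cross_label}: WT={c.n_wild_type} het={c.n_heterozygote} "
          f"TE={r.te}% chi2={r.chi2:.3f} (df={r.df}) p={r.p_value:.3f} "
          f"distorted={r.distorted}")

# a simulated cross with known true TE
sim = gen_cross_progeny(true_te_percent=85.0, n_progeny=60, seed=4)
r = analyze_cross(sim)
pct, (lo, hi) = proportion(sim.n_heterozygote, sim.total)
print(f"simulated TE 85%: observed TE={r.te}%, het fraction {pct}% "
      f"(95% CI {lo:.1f}-{hi:.1f})")
# TE near 100% means both alleles transmit equally; TE = 0 with a
# significant chi-square means the mutant allele never passes through
# that gamete class (male transmission defect).
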