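"""Cohort comparison: ring-bearing vs intermixed islets.

Islets are characterized by beta-cell fraction and ln(1 + total cells); the
two group densities are compared by KL divergence between their kernel
density estimates and by a two-sample two-dimensional KS test, and the
maximum-persistence distributions by the Mann-Whitney U test.
"""

from isletrings import (
    analyze_cohort,
    cohort_summary,
    gen_cohort,
    islet_summary_record,
)

rings = gen_cohort(40, [(1.0, "ring")], seed=1, group="ring")
mixed = gen_cohort(40, [(1.0, "intermixed")], seed=2, group="intermixed")
results = analyze_cohort(rings + mixed, morphometry=False)
report = cohort_summary([islet_summary_record(r) for r in results])

for name, g in report["groups"].items():
    print(
        f"{name}: {g['n_islets']} islets, "
        f"{g['pct_ns_in_cycle_ad_around_b']:.0f}% with a NS beta component "
        f"inside a mantle cycle, median max-H1(alphadelta) = "
        f"{g['max_persistence_alphadelta_median']:.2f}"
    )
pair = report["pairwise"]["intermixed|ring"]
print(f"KL(intermixed || ring) = {pair['kl_ab']:.2f}")
print(f"2D KS p-value = {pair['ks2d_p']:.3g}")
print(f"Mann-Whitney p (max-H1 alphadelta) = {pair['mw_max_persistence_alphadelta_p']:.3g}")
# Ring islets score high on both the cycle percentage and the mantle-class
# persistence; the intermixed group scores near zero on both, and the
# between-group tests reject equality.
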