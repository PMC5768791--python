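"""Cohort statistics: permutation null, family enrichment, group contrasts.

Compares the observed self/family/unrelated assignment of palm reads with
a null in which every read lands on any source sample with equal chance
(CMH test, one stratum per palm), and contrasts site compositions across
age classes with Mann-Whitney U tests.
"""

import handtracer as ht
from handtracer.attribution_stats import (cmh_enrichment,
                                          observed_relation_counts,
                                          permute_null, summarize_cohort,
                                          summarize_palm)
from handtracer.st_core import GibbsParams, fit_all

cohort = ht.generate_population(ht.default_spec(n_families=4, seed=1))
estimates = fit_all(cohort.table, cohort.metadata, GibbsParams(seed=42))
summaries = [summarize_palm(e, cohort.metadata) for e in estimates]

null = permute_null(estimates, cohort.metadata, n_perm=25, seed=5)
observed = observed_relation_counts(estimates, cohort.metadata)
stat, p = cmh_enrichment(observed, null)
print(f"null self/family/unrelated fractions: {null.summary_mean.round(3)}")
print(f"CMH self+family enrichment vs null:   stat={stat:.1f}, p={p:.3g}")

report = summarize_cohort(summaries, cohort.metadata)
print("\nmedian attribution per site across palms:")
print(report.site_summary.round(3))
print(f"\npalms with stool signal above noise: "
      f"{report.above_noise_fractions.loc['stool', 'frac_palms']:.0%}")

tests = report.tests
age = tests[(tests.grouping == "age_class")
            & (tests.variable == "site_tongue")]
print("\nage-class contrasts on tongue-derived signal (Mann-Whitney):")
print(age[["group1", "group2", "n1", "n2", "U", "p"]].to_string(index=False))
print("\nA small p with children > adults reflects the generator's truth: "
      "young palms carry more of their own oral bacteria.")
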