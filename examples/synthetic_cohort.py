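"""Generate a synthetic cohort, score it, and compare with the exact law.

Individuals draw one level per factor from the configured prevalences
(independent factors); 10% of assignments are masked missing to exercise
the population-average imputation policy.
"""

import numpy as np

import polyrisk as pr

factors = pr.default_factor_table()
table = pr.build_scoring_table(factors)

spec = pr.CohortSpec(n_individuals=50_000, seed=42, missingness_rate=0.10)
cohort = pr.generate_cohort(factors, spec)
results = pr.score_cohort(table, cohort, missing_policy="population_average")

totals = np.array([r.total_pps for r in results])
exact = pr.enumerate_distribution(table)
print(f"cohort of {spec.n_individuals} individuals (seed {spec.seed}, "
      f"{spec.missingness_rate:.0%} of assignments missing)")
print(f"empirical mean score {totals.mean():+.3f} vs exact {exact.mean():+.3f}")
print(f"share with negative score: {(totals < 0).mean():.1%} vs exact "
      f"{pr.summarize(exact).frac_negative:.1%}")
print(f"mean imputed factors per person: "
      f"{np.mean([r.n_missing for r in results]):.2f} of {len(table)}")
print("\nWith missing factors imputed at the population average, the cohort")
print("distribution shrinks slightly toward 0 but keeps the exact mean.")
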