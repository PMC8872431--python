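"""Odds ratios of misutilization across patient characteristics.

For each non-reference level, the odds of a visit being labelled under-
(or over-) utilized relative to the reference group, with Wald 95%
confidence intervals — the per-patient equity view of misutilization.
"""

import misutil as mu

config = mu.SyntheticConfig(n_facilities=150, total_visits_target=20000, seed=42)
cohort, _ = mu.generate_cohort(config)
cohort, _ = mu.collapse_categories(cohort)
y = cohort["outcome_used"].to_numpy()

fit = mu.fit_logistic(mu.build_design(cohort, "a"), y)
curve = mu.net_benefit_curve(fit.fitted_probabilities, y)
t, _ = mu.calibrate_threshold(fit.fitted_probabilities, y, curve)
labels, _ = mu.classify_visits(fit.fitted_probabilities, y, t)

rows = mu.misuse_odds_ratios(labels, cohort, "race", reference_level="white")
print("odds ratios vs White patients:")
for r in rows:
    if not r.defined:
        print(f"  {r.outcome_kind:<6} {r.level:<16} (no events; undefined)")
        continue
    print(f"  {r.outcome_kind:<6} {r.level:<16} OR {r.odds_ratio:.2f} "
          f"(95% CI {r.ci95[0]:.2f}-{r.ci95[1]:.2f}, p = {r.p:.3g})")
# An OR above 1 for "under" means that group's visits are more often left
# without the resource when the model expected it to be used.

forest = mu.forest_data(rows)
print(f"\nforest-plot table: {len(forest)} rows "
      f"(reference level at log-OR 0 with no interval)")
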