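"""Simulate a direction-task cohort and run the group threshold analysis.

Generates 12 synthetic participants with the default population (higher
incongruent sensitivity threshold plus a head-direction response bias),
screens and fits per-cell psychometric functions, and runs the
repeated-measures ANOVA, Bonferroni post-hocs and the stepwise
mixed-model comparison.
"""

from rotovis import generate_cohort, lme_stepwise, posthoc_bonferroni, rm_anova_2x3
from rotovis.psychfit import build_threshold_table, collapse_directions

cohort = generate_cohort("exp1", 12, seed=11, with_trajectories=False)
table = build_threshold_table(cohort.trials, cohort.traces)
print(f"{len(cohort.trials)} trials, "
      f"{int(table['excluded'].sum())} of {len(table)} cells excluded")

means = collapse_directions(table).groupby("congruence")["threshold"].mean()
print("\ngroup mean thresholds (signal intensity):")
print(means.round(3).to_string())

print("\nrepeated-measures ANOVA (complete cases):")
for r in rm_anova_2x3(table):
    print(f"  {r.effect:12s} F({r.df_num},{r.df_den}) = {r.F:6.2f}, "
          f"p = {r.p:.4f}, partial eta^2 = {r.partial_eta_sq:.2f}")

print("\nBonferroni post-hocs (paired, direction-collapsed):")
for r in posthoc_bonferroni(table):
    print(f"  {r.contrast:26s} t({r.df}) = {r.t:6.2f}, "
          f"p_bonf = {r.p_bonferroni:.4f}, d = {r.cohen_d:5.2f}")

lme = lme_stepwise(table)
print("\nmixed-model comparison (ML, random intercept per participant):")
for s in lme.steps:
    print(f"  {s.comparison:34s} chi2({s.df}) = {s.chi_sq:6.2f}, p = {s.p:.4f}")
print(f"  winning model: {lme.winning_formula}")
for c in lme.coefficients:
    print(f"  {c.name:26s} beta = {c.beta:+.3f} "
          f"[{c.ci_low:+.3f}, {c.ci_high:+.3f}], t({c.df}) = {c.t:.2f}")
print("\n-> incongruent thresholds sit highest; direction adds nothing,")
print("   matching the pattern the head-direction bias produces on this task.")
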