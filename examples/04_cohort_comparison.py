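"""Do retained genes encode more abundant proteins?

Simulates a labelled abundance table in which the retained (R) cohort sits
one order of magnitude above the lost (L) and transferred (T) cohorts, then
runs the one-way ANOVA + Tukey letter analysis that tests the pattern.
"""

from egtcost import CohortSpec, compare_cohorts, generate_cohorts

table = generate_cohorts(
    CohortSpec(n_per_group=50, base_log10_ppm=2.0, retained_shift=1.0, noise_sd=0.5, seed=42)
)
result = compare_cohorts(table)  # log10-transformed by default

print(f"one-way ANOVA: F = {result.f_stat:.1f}, p = {result.p_value:.2e}\n")
print("group  n   mean log10(ppm)  letters")
for g in sorted(result.letters):
    print(f"  {g}   {result.group_sizes[g]:3d}      {result.group_means[g]:6.2f}       "
          f"{result.letters[g]}")
print("\nGroups sharing a letter are not significantly different (alpha=0.05).")
print(f"Cohorts with their own letter: {result.distinct_groups()}")
print("The retained cohort separates cleanly: high required abundance is")
print("exactly the condition under which organellar encoding stays cheaper.")
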