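"""Bin genotypes into SIIG classes and pick the superior set.

Uses the published per-genotype SIIG values: the mean-of-environments
column for group binning (default cuts at 0.70/0.60/0.50/0.40) and the
per-environment columns for threshold selection at SIIG >= 0.60, the
conventional cut for calling a genotype superior.
"""

from siig import (
    assign_groups,
    group_summary,
    load_fixture,
    table3_environment,
    table4_trait_matrix,
    threshold_count,
)

siig = load_fixture("table4")["SIIG"]
labels = assign_groups(siig)
table = group_summary(labels, table4_trait_matrix())
print("Group sizes and trait means (group 1 = SIIG >= 0.70, best):")
print(table.summary.round(1))

print("\nSuperior genotypes (SIIG >= 0.60) per environment:")
for env in ("Ahvaz", "Gonbad", "Zabol", "Darab"):
    count, ids = threshold_count(table3_environment(env)["SIIG"], 0.60)
    print(f"  {env:7s}: {count:2d} genotypes, best first: {', '.join(ids[:5])} ...")
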