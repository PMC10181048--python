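"""How strongly does the selection index track yield and the other traits?

Computes Pearson correlations (with two-tier significance stars: * p<0.05,
** p<0.01) between the per-environment SIIG values and grain yield, then
the full trait x trait correlation matrix for the across-environment
means with a freshly recomputed SIIG column appended. A large positive
SIIG-YLD correlation is what makes the index useful for yield selection.
"""

from siig import (
    WARM_BARLEY,
    compute_siig,
    correlate,
    correlation_matrix,
    table3_environment,
    table4_trait_matrix,
)

print("SIIG vs grain yield per environment:")
for env in ("Ahvaz", "Gonbad", "Zabol", "Darab"):
    sub = table3_environment(env)
    c = correlate(sub["SIIG"], sub["YLD"])
    print(f"  {env:7s}: r = {c.r:5.2f} {c.stars:2s} (n = {c.n})")

matrix = table4_trait_matrix()
siig = compute_siig(matrix, WARM_BARLEY).siig
report = correlation_matrix(matrix, siig=siig)
print("\nTrait correlations (means over environments, recomputed SIIG):")
print((report.r.round(2).astype(str) + report.stars).to_string())
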