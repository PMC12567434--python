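"""Bottom-up GUM budget of the packaged HPLC-UV assay.

Loads the packaged Metopimazine budget, combines the eleven relative standard
uncertainties in quadrature, expands with k = 2 and prints the Pareto-ordered
variance contributions.
"""

from mubudget import budget_table, gum_budget, mpz_budget
from mubudget.report import gum_text_summary

budget = mpz_budget()

result = gum_budget(budget)  # content evaluated from the model
print(gum_text_summary(result))
print()

sheet = gum_budget(budget, content="reported")  # the published sheet's multiplier
print(
    f"with the sheet's reported content {sheet.content:g}%: "
    f"u = {sheet.u_c:.4f}%, U(k=2) = {sheet.expanded_u:.4f}%"
)
print()
print(budget_table(budget, result).to_string(index=False))
print()
print(
    "The two dominant rows (sample volume and the calibration-prediction\n"
    "factor) together carry about 70% of the variance of the content;\n"
    "the expanded uncertainty of ±0.69% sits well inside a ±5% release\n"
    "specification, so the assay is fit for purpose."
)
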