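"""Screen panel genes for tumour-vs-normal differential expression.

A moderated two-sample t (empirical-Bayes variance shrinkage) with BH FDR,
summarised per repair pathway; multi-pathway genes count once per pathway
but only once in the Total row.
"""

from dysreg import (
    SyntheticConfig, default_panel, differential_expression, generate_cohort,
    pathway_summary,
)

config = SyntheticConfig(n_panel_genes=30, n_tfs=60, seed=2)
bundle, truth = generate_cohort(config)

res = differential_expression(bundle, fdr_threshold=0.05)
print(res.head().round(4))

summary = pathway_summary(res, default_panel(config))
print("\nper-pathway tally (present / DE / up / down):")
print(summary)

total = summary.loc["Total"]
print(f"\n{total['de']}/{total['present']} genes are differentially expressed; "
      f"{100 * total['up'] / max(total['de'], 1):.0f}% of the DE genes are up-regulated.")
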