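"""Generate a small multi-omics cohort with planted ground truth.

The generator emulates a tumour/normal cohort: panel-gene mRNA depends
positively on own-gene copy number, weakly negatively on promoter
methylation, and on a small planted set of transcription factors.
"""

from dysreg import SyntheticConfig, generate_cohort, planted_variance_fractions

config = SyntheticConfig(
    n_tumour=200, n_normal=60, n_panel_genes=10, n_tfs=40,
    true_tfs_per_gene=3, seed=1,
)
bundle, truth = generate_cohort(config)

print(f"expression matrix: {bundle.expression.shape[0]} samples x "
      f"{bundle.expression.shape[1]} genes (panel + TFs)")
print(f"tumour-only CNA/DM matrices: {bundle.cna.shape}")

gene = bundle.panel_genes[0]
print(f"\n{gene}: planted regulators {sorted(truth.true_tf_sets[gene])}")
vf = planted_variance_fractions(truth, config).loc[gene]
print("planted variance split (fractions of tumour expression variance):")
print(f"  copy number {vf.var_cna / (vf[['var_cna','var_dm','var_tf','var_noise']].sum()):.2f}, "
      f"methylation {vf.var_dm / (vf[['var_cna','var_dm','var_tf','var_noise']].sum()):.2f}, "
      f"TFs {vf.var_tf / (vf[['var_cna','var_dm','var_tf','var_noise']].sum()):.2f}")
# These fractions are what the cis-association and model-comparison stages
# should rediscover from the data alone.
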