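"""Simulate a small longitudinal microbiome study and test every feature.

Generates 60 taxa (12 truly differentially abundant) for 15 subjects per
condition over 8 time points with AR(1) serial dependence, fits the
two-part GEE model per feature, and prints the confusion counts after
Benjamini-Hochberg adjustment at FDR 0.05.
"""

from corrzidf import SimScenario, fit_study, simulate_study
from corrzidf.io import panels_from_tables

scenario = SimScenario(n_per_group=15, M=8, n_features=60, n_daf=12,
                       structure="ar1", rho=0.6, seed=7)
study = simulate_study(scenario)
panels = panels_from_tables(study.counts, study.metadata)
summary = fit_study(panels, structure="ar1", fdr=0.05, truth=study.truth)

table = summary["table"]
print(table.head(8).to_string(index=False))
print(f"\nfeatures tested : {summary['n_tested']} / {summary['n_features']}")
print(f"significant (BH): {summary['n_significant']}")
print(f"TPR / FPR       : {summary['tpr']:.2f} / {summary['fpr']:.3f}")
print(f"median alpha-hat: {summary['alpha_hat_median']:.3f}")
print("\nTPR is the fraction of the 12 planted differentially abundant taxa"
      "\nrecovered at FDR 0.05; FPR the fraction of stable taxa flagged;"
      "\nalpha-hat the estimated lag-1 working correlation per feature.")
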