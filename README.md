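# corrzidf

Distribution-free differential-abundance testing for **longitudinal
zero-inflated count data**, built for microbiome and metagenomic studies in
which each taxon is observed repeatedly over time for every subject, most
counts are zero, and the serial correlation within a subject cannot be
ignored.

## The model

For taxon counts `y_ij` (subject `i = 1..N`, time `j = 1..M`) the package
models two response functions jointly instead of a likelihood:

```
f1_ij = I(y_ij = 0)          (zero indicator)
f2_ij = y_ij                 (count)

E f1_ij = h1_ij = rho_ij + (1 - rho_ij) exp(-mu_ij)
E f2_ij = h2_ij = (1 - rho_ij) mu_ij

logit(rho_ij) = u_ij' beta_u      (structural-zero part)
log(mu_ij)    = v_ij' beta_v      (count part)
```

Only these first moments plus zero-inflated-Poisson working variances
`Var(f1) = h1(1-h1)` and `Var(f2) = (1-rho) mu (1 + rho mu)` are assumed, so
inference stays valid when the data are not ZIP — overdispersed, ZINB-like,
or otherwise — as long as the mean models hold.

Coefficients solve the generalized estimating equations

```
sum_i D_i V_i^{-1} (f_i - h_i) = 0,     V_i = A_i^{1/2} R(alpha) A_i^{1/2}
```

where the stacked vector interleaves the two components by time and the
working correlation `R(alpha)` is built from 2x2 blocks: identity within a
time point and `alpha^|j-l| J2` (AR(1)) or `alpha J2` (exchangeable) between
time points, with `alpha` estimated from pooled bivariate Pearson residuals.
Coefficient covariance uses the robust sandwich estimator, so a misspecified
working correlation costs efficiency, never validity. Each taxon's
count-part group effect is tested with a Wald chi-square statistic and
p-values are adjusted across taxa with Benjamini–Hochberg FDR control.

A Gaussian-copula simulator generates synthetic two-group studies with exact
ZIP margins, mean-dependent zero fractions, and AR(1)/exchangeable serial
dependence, for power/type-I evaluation and reproducible fixtures.

## Worked example

```python
from corrzidf import SimScenario, fit_study, simulate_study
from corrzidf.io import panels_from_tables

scenario = SimScenario(n_per_group=15, M=8, n_features=60, n_daf=12,
                       structure="ar1", rho=0.6, seed=7)
study = simulate_study(scenario)
summary = fit_study(panels_from_tables(study.counts, study.metadata),
                    structure="ar1", fdr=0.05, truth=study.truth)
```

prints (`examples/simulate_and_fit.py`):

```
features tested : 60 / 60
significant (BH): 8
TPR / FPR       : 0.67 / 0.000
median alpha-hat: 0.463
```

Eight of the twelve planted differentially abundant taxa are recovered at
FDR 0.05 with no false positives; the median estimated lag-1 working
correlation of 0.46 reflects the serial dependence injected by the copula
(latent correlation 0.6, attenuated on the count scale). More scripts live
in `examples/`: a single-feature fit showing both coefficient vectors with
robust SEs, and a tour of the working-correlation structures.

## Command line

```bash
corrzidf simulate --config scenario.yaml --out-dir study/
corrzidf fit --counts study/counts.tsv --metadata study/metadata.tsv \
             --structure ar1 --fdr 0.05 --out results.tsv
```

`fit` reads a feature-by-sample TSV count table plus a metadata TSV
(`sample_id`, `subject_id`, `time`, `group`) and writes one row per feature:
estimate, sandwich SE, `alpha_hat`, Wald statistic, raw and BH-adjusted
p-values, and a status flag (`ok`, `all_zero`, `no_zeros`, `not_converged`).

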