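"""Genome-wide collapsed double-heterozygosity (GCDH) scan.

Collapses nearby SNP pairs (k = 300 partners within d = 500 kb, marginal
p-filter 0.1) into additive pseudo-markers, tests each against height and
assigns the window's minimum P to the index SNP. Significance uses the
per-window Bonferroni threshold 5e-8 / 300 = 1.67e-10.
"""

import numpy as np

from gcdh import (
    PairEffect,
    SimulationConfig,
    SingleEffect,
    WindowSpec,
    gcdh_scan,
    genomic_lambda,
    run_gwas,
    simulate_cohort,
)

cohort = simulate_cohort(SimulationConfig(
    n_individuals=4000, n_snps=500, n_chromosomes=2, residual_sd=2.8, seed=3,
    planted_pair_effects=[PairEffect(100, 104, 0.8, "trans", maf1=0.05, maf2=0.05)],
    planted_single_effects=[SingleEffect(300, 0.5)],
))

spec = WindowSpec()  # k=300, d=500 kb, p-filter 0.1, additive collapsing
print(f"GCDH genome-wide threshold = alpha/k = {spec.threshold:.3g}")

marginal = run_gwas(cohort.panel, cohort.phenotypes, cohort.covariate_names)
scan = gcdh_scan(cohort.panel, cohort.phenotypes, cohort.covariate_names,
                 spec, marginal=marginal)

lam_scan, _ = genomic_lambda(scan["min_p"].to_numpy())
lam_single, _ = genomic_lambda(marginal["p"].to_numpy())
print(f"lambda(scan min-P) = {lam_scan:.2f} vs lambda(single-SNP) = "
      f"{lam_single:.2f}  (min-P selection inflates the scan statistics,\n"
      " which is why significance is judged against alpha/k and an\n"
      " empirical permutation null, not against a plain chi-square)")

sig = scan[scan["significant"]].sort_values("min_p")
print(f"\nsignificant index SNPs ({len(sig)}):")
print(sig[["index_snp", "partner_snp", "min_p", "beta"]].head(8).to_string(index=False))
# The planted pair snp00100_snp00104 tops the scan with beta near the
# planted +0.8 cm per pseudo-genotype unit, even though example 02 showed
# both members are far from single-SNP significance.
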