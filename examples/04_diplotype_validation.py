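"""Cis/trans diplotype inference at a significant pair.

The additive pseudo-marker cannot tell a compound heterozygote (minor
alleles on opposite haplotypes, trans) from a cis double heterozygote.
This example estimates two-locus haplotype frequencies by EM, computes
each double heterozygote's posterior probability of being trans, and
applies the direction-of-effect rule: the pair's compound-het model is
supported when the trans carriers' mean adjusted height moves in the
same direction as the scan beta.
"""

import numpy as np

from gcdh import (
    PairEffect,
    SimulationConfig,
    WindowSpec,
    adjust_trait,
    em_haplotype_freqs,
    gcdh_scan,
    p_trans,
    simulate_cohort,
    validate_ch,
)

cohort = simulate_cohort(SimulationConfig(
    n_individuals=4000, n_snps=100, n_chromosomes=1, residual_sd=2.8, seed=11,
    planted_pair_effects=[PairEffect(40, 45, 0.8, "trans", maf1=0.08, maf2=0.08)],
))
scan = gcdh_scan(cohort.panel, cohort.phenotypes, cohort.covariate_names, WindowSpec())
top = scan.loc[scan["min_p"].idxmin()]
print(f"top pair: {top['index_snp']}_{top['partner_snp']}  "
      f"P = {top['min_p']:.2e}, beta = {top['beta']:+.2f}")

g1 = cohort.panel.calls[:, cohort.panel.index_of(top["index_snp"])]
g2 = cohort.panel.calls[:, cohort.panel.index_of(top["partner_snp"])]
freqs = em_haplotype_freqs(g1, g2)
print(f"\nEM haplotype frequencies (A/B major, a/b minor):")
print(f"  f_AB = {freqs.f_AB:.4f}  f_Ab = {freqs.f_Ab:.4f}  "
      f"f_aB = {freqs.f_aB:.4f}  f_ab = {freqs.f_ab:.4f}")
print(f"  converged in {freqs.iterations} iterations")
print(f"P(trans | double het) = {p_trans(freqs):.3f} "
      "(both-minor haplotype ab is absent, so double hets must be trans)")

adj = adjust_trait(
    cohort.phenotypes["height"].to_numpy(),
    cohort.phenotypes[cohort.covariate_names].to_numpy(float),
)
report = validate_ch(top["index_snp"], top["partner_snp"], g1, g2, adj, top["beta"])
print(f"\nCH group n = {report.n_ch}, reference (pseudo-genotype 0) n = "
      f"{report.n_reference}")
print(f"mean adjusted height: CH {report.mean_ch:+.2f} vs reference "
      f"{report.mean_reference:+.2f} cm")
print(f"verdict: {report.verdict}")
# CH_supported: the compound-het carriers are taller than the reference
# group in the same direction as the scan's positive beta.
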