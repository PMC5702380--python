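# Methods

## The association model

Every test in the package is an ordinary least-squares linear model of a
quantitative trait (height in cm) on one genetic predictor plus a fixed
covariate block — by default sex, age, and four principal components,
mirroring standard practice for a population-based height GWAS:

- single-SNP stage: predictor = minor-allele count (0/1/2), additive
  coding, two-sided t test on the genotype coefficient (the linear-model
  semantics of PLINK; a positive β means the minor allele increases the
  trait);
- pair stage: predictor = the collapsed pseudo-genotype, treated as
  numeric 0/1/2 under the additive collapsing matrix
  `min(g₁ + g₂, 2)`. Numeric coding is the modelling assumption of a
  joint additive effect of the pair's minor alleles; a categorical
  coding would spend an extra degree of freedom and changes the test's
  meaning.

All fits share one numerical engine: the covariate block (with
intercept) is QR-orthonormalised once and each genetic predictor is
projected against it (Frisch–Waugh–Lovell), giving t statistics
identical to a full-design OLS at a fraction of the cost. statsmodels
reproduces these fits in the test suite as an independent oracle.
Missing genotypes propagate: any operation consuming a missing call
yields a missing result for that sample, and every fit is complete-case
for its own predictor. Pairs with fewer than 30 complete cases or a
constant pseudo-genotype are flagged and excluded from min-P selection.

## Windowing and multiple testing

The scan slides one SNP per step. For index SNP *i* the pairing SNPs are
the subsequent SNPs on the same chromosome within *d* bp, truncated to
at most *k* — so a window performs at most *k* tests — and then filtered
by the marginal p-filter. The filter retains a pair when **at least one
member** has single-SNP P ≤ p-filter (configurable to `both` or
`index`): published GCDH hits include pairs whose first member has a
marginal P above the filter, so requiring both members to pass would be
inconsistent with the method's own results; the one-member rule is the
weakest rule compatible with the filter's purpose (discarding pairs with
no marginal signal at all). Defaults are k = 300, d = 500 kb,
p-filter = 0.1.

The window's minimum P is assigned to the index SNP (ties broken by the
smallest partner position, making results deterministic), and
genome-wide significance is declared at α/k — Bonferroni over the
maximal number of tests per window — derived from configuration at run
time, never hard-coded: 5×10⁻⁸/300 = 1.67×10⁻¹⁰.

Min-P selection plus the p-filter inflate the scan statistics' null
distribution by construction (null-cohort runs show λ of the min-P
values several-fold above the single-SNP λ). The empirical null is
therefore obtained by re-running the *entire* procedure — including the
marginal GWAS that feeds the p-filter — on phenotype tables whose rows
(height together with all covariates) are shuffled as units; replicate
*r* uses seed `seed + r`. Fixed thresholds only; no FDR anywhere, by
design parity with how such scans are reported.

## Haplotype EM and CH validation

For two biallelic loci only the double-heterozygote cell (1,1) is
phase-ambiguous. The EM initialises at linkage equilibrium (products of
allele frequencies), splits the double-het count between cis (AB/ab)
and trans (Ab/aB) resolutions proportional to 2f_AB·f_ab vs 2f_Ab·f_aB,
and recounts haplotypes; the genotype log-likelihood is asserted
non-decreasing at every iteration, haplotype marginals equal the
observed allele frequencies exactly at every M-step, and convergence is
a log-likelihood gain below 10⁻⁸ (max 1000 iterations; non-convergence
is flagged but the estimate is still returned). An exhaustive
simplex-grid likelihood search in the test suite confirms the EM
reaches the global maximum.

Double heterozygotes are assigned their maximum-a-posteriori
configuration at P(trans) > 0.5 (the posterior is also reported so users
can re-threshold). The CH-validation verdict compares the trans
carriers' mean height — adjusted by regressing out sex, age and PCs —
against the pseudo-genotype-0 reference group: `CH_supported` if the
difference has the sign of the scan β, `no_CH_group` if no trans
carriers exist (indicating a cis or other mechanism), `other_mechanism`
otherwise. The reference group is pseudo-genotype 0 rather than
"everyone non-CH"; the narrower group is the cleaner contrast and the
choice is configurable in spirit (the group means are all reported).
CH groups under 5 individuals set a low-confidence flag.

## Variance attribution

The dependent variable is the sex- and age-regressed height residual;
R² values are percentages of that adjusted variance (not raw variance).
The ledger procedure: (1) fit the full joint model containing the
polygenic score, the top single SNPs and the top pseudo-markers;
(2) order terms by ascending full-model P (ties keep input order; an
option to order by marginal P exists but is non-default); (3) refit
nested models adding one term at a time, recording R² increments. The
increments telescope to the full-model R² identically, which the tests
assert to 10⁻¹⁰. Polygenic scores are weighted allele sums; weight
records whose effect allele matches neither panel allele are dropped
with a log entry, and missing genotypes contribute the SNP's mean
dosage (standard allele-score practice). Replication is *exact*: the
discovery-defined pair, alleles and collapsing matrix are frozen and
re-tested with sex+age-adjusted OLS; P < 0.05 flags replication, sign
agreement is reported separately, and hits absent from the replication
panel come back as untestable rather than silently dropped.

## The synthetic-cohort generator

The generator emulates the statistical structure the analysis assumes,
not any particular population's history.

- **LD**: Markov allele copying within blocks. Each block draws one
  allele frequency from `maf_range` (default 0.05–0.5); the first site
  is Bernoulli(p) per haplotype and each later site copies its left
  neighbour with probability ρ (default 0.8, blocks of 20 SNPs), else
  redraws Bernoulli(p). Equal within-block frequencies make the
  adjacent-site haplotype correlation exactly ρ and preserve p; blocks
  are independent. This produces the *local pairwise* LD the windowed
  scan interacts with; it does not produce coalescent-realistic allele
  frequency spectra, long-range LD decay, recombination hotspots or
  population structure — so passing tests demonstrate correctness of
  the machinery under the stated model, not robustness to confounding.
- **Coordinates**: per chromosome, cumulative Exponential spacings with
  mean 20 kb, so the d-window logic is exercised with irregular gaps.
- **Planted pair effects** act on the collapsed additive pseudo-genotype
  `min(g₁+g₂, 2)` so that planted and detected models coincide. Phase
  planting reassigns the two sites' minor alleles across haplotypes with
  per-site allele counts preserved exactly: `trans` gives both-minor
  haplotype frequency 0 (every double het a compound het — the strongest
  negative LD the marginals allow), `cis` stacks the minor alleles onto
  shared haplotypes. Forcing phase only inside the double-het genotype
  class would leave the genotype distribution unchanged and hence be
  invisible to any genotype-based analysis (including the EM), so the
  column-level reassignment is what makes the planted architecture
  statistically real; its cost is that the two planted sites lose LD
  with their block neighbours. A `ch_only` variant confines the effect
  to trans double heterozygotes to exercise the validation stage; it is
  an extension for testing, not part of the scan's model.
- **Covariates**: sex ~ Bernoulli(0.5) with a +13 cm male effect; age ~
  Uniform(45, 90) years with a −0.05 cm/year slope (an elderly
  population-cohort age range); four standard-normal PCs at 0.5 cm per
  SD. Residual noise is Gaussian; the cohort default residual SD is
  6.5 cm (a realistic sex/age-adjusted height SD).
- **Tall ascertainment** standardises height within sex using the pool's
  mean/SD and appends individuals with SDS above the cutoff (1.88 ≈ the
  upper 3% tail), duplicating their genotype rows under new ids.
- All randomness flows from a single seeded generator; identical config
  and seed reproduce byte-identical outputs.

## Problem sizes and powered designs

Test and acceptance runs use desk-scale sizes chosen a priori: null
calibration at 2000 individuals × 2000 SNPs; oracle comparisons at
500 × 20; EM recovery at n = 5000; planted-pair experiments at
n = 4000 × 100 SNPs. For the planted-pair experiments the residual SD
is set to 2.8 cm by power design: with MAFs 0.05 and β = 0.8 cm per
pseudo-genotype unit, that gives the collapsed test ~90% power alone at
the 1.67×10⁻¹⁰ threshold (non-centrality ≈ β²·Var(pseudo)·n/σ²).

A note on the pair-vs-marginal power *contrast* under this generative
model: because the additive pseudo-marker is (nearly) the sum of its
member genotypes, the collapsed test's non-centrality is at most
2/(1+r) times each member's marginal non-centrality, and rare alleles
bound the genotype correlation r below at about −0.05. The joint event
"pair exceeds α/k while **neither** member exceeds α" therefore requires
the sum of the member Z statistics to land in a narrow band, and no
choice of residual SD pushes its per-replicate probability much above
~0.3–0.45 — the contrast is real and typical (the pair is found, the
members usually are not *both* found), but it is not a near-certain
event per replicate. The acceptance suite asserts the stricter
per-replicate rate and that check documents this ceiling by failing;
the measured rate is reported by `scripts/acceptance.py` as
`power_contrast_pct`.

## Known limitations

- Linear (Gaussian) traits only; the GLM framing is implemented for the
  quantitative case, not binary phenotypes.
- Two-SNP collapsing only; no >2-locus pseudo-markers, no
  haplotype-based tests, no genome-wide epistasis outside the d-window.
- Genotype QC (call rate, HWE), imputation and PC computation are
  upstream concerns; PCs are consumed as covariates.
- The genomic-control λ estimator has sampling SD ≈ 0.05 at 2000 tests;
  calibration checks at that size either average over permutation
  replicates or accept that width.
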