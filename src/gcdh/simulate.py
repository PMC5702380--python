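"""Synthetic cohorts with LD blocks, planted effects and tall ascertainment.

The generator emulates the data structure a compound-heterozygosity scan
assumes: unrelated individuals, biallelic SNPs with MAF >= 0.01 arranged in
LD blocks along chromosomes with bp coordinates, sex/age/PC covariates, and
a Gaussian quantitative trait (height, cm) carrying planted additive
single-SNP effects and two-SNP pair effects that act through the collapsed
pseudo-genotype min(g1 + g2, 2). An optional extreme-tall ascertainment step
appends individuals from the upper tail of the height distribution
(standard-deviation score above a cutoff, 1.88 for the upper ~3%).

LD model: Markov allele copying. Each block has one allele frequency p
drawn from ``maf_range``; the first site of a block is Bernoulli(p) per
haplotype and each subsequent site copies the previous site's allele with
probability rho, else redraws Bernoulli(p). For equal-frequency sites this
gives adjacent-site haplotype correlation exactly rho and preserves p.
Blocks are independent of one another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypePanel, _orient_and_annotate, _sort_panel

logger = logging.getLogger(__name__)


@dataclass
class SingleEffect:
    """Additive single-SNP effect: ``beta`` cm per minor allele."""

    snp: int
    beta: float


@dataclass
class PairEffect:
    """Two-SNP effect of ``beta`` cm per collapsed pseudo-genotype unit.

    ``phase`` controls the haplotype arrangement forced on double
    heterozygotes before the phenotype is drawn: ``trans`` makes them
    compound heterozygotes, ``cis`` double heterozygotes, ``random`` leaves
    the simulated phase untouched. With ``ch_only`` the effect is confined
    to trans double heterozygotes (an extension used to exercise diplotype
    validation; the genome scan's own model is the additive pseudo-marker).
    """

    snp1: int
    snp2: int
    beta: float
    phase: str = "trans"
    ch_only: bool = False
    #: optional target MAFs realised at the two sites when the phase is
    #: forced (None keeps the sites' simulated allele counts)
    maf1: float | None = None
    maf2: float | None = None


@dataclass
class SimulationConfig:
    n_individuals: int = 2000
    n_snps: int = 2000
    n_chromosomes: int = 2
    block_length_snps: int = 20
    within_block_correlation: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    bp_spacing_mean: float = 20_000.0
    planted_single_effects: list[SingleEffect] = field(default_factory=list)
    planted_pair_effects: list[PairEffect] = field(default_factory=list)
    residual_sd: float = 6.5
    mean_height: float = 170.0
    sex_effect: float = 13.0
    age_slope: float = -0.05
    pc_effect: float = 0.5
    n_pcs: int = 4
    tall_ascertainment: tuple[float, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"invalid maf_range {self.maf_range}")
        if not 0 <= self.within_block_correlation < 1:
            raise ValueError("within_block_correlation must be in [0, 1)")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        for e in self.planted_single_effects:
            if not 0 <= e.snp < self.n_snps:
                raise ValueError(f"single-effect SNP index {e.snp} out of range")
        for e in self.planted_pair_effects:
            for s in (e.snp1, e.snp2):
                if not 0 <= s < self.n_snps:
                    raise ValueError(f"pair-effect SNP index {s} out of range")
            if e.phase not in ("trans", "cis", "random"):
                raise ValueError(f"unknown phase {e.phase!r}")


def variant_map(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Chromosome labels and bp positions (cumulative Exponential spacings)."""
    per_chrom = np.array_split(np.arange(config.n_snps), config.n_chromosomes)
    chroms = np.empty(config.n_snps, dtype=object)
    pos = np.empty(config.n_snps, dtype=np.int64)
    for c, idx in enumerate(per_chrom, start=1):
        gaps = rng.exponential(config.bp_spacing_mean, size=len(idx))
        pos[idx] = 1 + np.cumsum(np.maximum(1, np.round(gaps))).astype(np.int64)
        chroms[idx] = str(c)
    ids = np.array([f"snp{j:05d}" for j in range(config.n_snps)], dtype=object)
    return pd.DataFrame({"id": ids, "chrom": chroms, "pos": pos})


def simulate_haplotypes(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Phased haplotypes (2n x n_snps, {0,1}) and per-site allele freqs."""
    n_hap = 2 * config.n_individuals
    m = config.n_snps
    rho = config.within_block_correlation
    haps = np.empty((n_hap, m), dtype=np.int8)
    freqs = np.empty(m)
    per_chrom = np.array_split(np.arange(m), config.n_chromosomes)
    for idx in per_chrom:
        for start in range(0, len(idx), config.block_length_snps):
            block = idx[start : start + config.block_length_snps]
            p = rng.uniform(*config.maf_range)
            freqs[block] = p
            col = (rng.random(n_hap) < p).astype(np.int8)
            haps[:, block[0]] = col
            for j in block[1:]:
                copy = rng.random(n_hap) < rho
                fresh = (rng.random(n_hap) < p).astype(np.int8)
                col = np.where(copy, col, fresh)
                haps[:, j] = col
    return haps, freqs


def plant_pair_effect(
    haps: np.ndarray,
    snp1: int,
    snp2: int,
    phase: str,
    rng: np.random.Generator,
    maf1: float | None = None,
    maf2: float | None = None,
) -> pd.DataFrame:
    """Realise a trans (CH) or cis (DH) haplotype architecture at a pair.

    The two sites' minor alleles are reassigned across the 2n haplotypes
    (in place) so that per-site allele counts are preserved exactly while
    the joint architecture matches the requested phase:

    - ``trans``: the minor alleles of the two SNPs never share a haplotype
      (both-minor haplotype frequency 0, the strongest negative LD the
      marginals allow) — every double heterozygote is a compound
      heterozygote;
    - ``cis``: the minor alleles are stacked onto shared haplotypes
      (maximal both-minor frequency) — every double heterozygote carries
      one both-minor haplotype;
    - ``random``: the haplotypes are left untouched.

    Phase forcing restricted to double heterozygotes alone would leave the
    genotype distribution unchanged and hence be invisible to any
    genotype-based analysis; reassigning the haplotype columns makes the
    planted architecture statistically real. LD between the pair's sites
    and their block neighbours is sacrificed. Returns one truth row per
    double-heterozygous individual with the realised phase.
    """
    if phase not in ("trans", "cis", "random"):
        raise ValueError(f"unknown phase {phase!r}")
    n_hap = haps.shape[0]
    if phase != "random":
        n_a = int(round(n_hap * maf1)) if maf1 is not None else int(haps[:, snp1].sum())
        n_b = int(round(n_hap * maf2)) if maf2 is not None else int(haps[:, snp2].sum())
        if n_a == 0 or n_b == 0:
            raise ValueError("both SNPs must be polymorphic to plant a pair effect")
        perm = rng.permutation(n_hap)
        col1 = np.zeros(n_hap, dtype=np.int8)
        col2 = np.zeros(n_hap, dtype=np.int8)
        if phase == "trans":
            if n_a + n_b > n_hap:
                raise ValueError("allele counts too high for a fully trans pair")
            col1[perm[:n_a]] = 1
            col2[perm[n_a : n_a + n_b]] = 1
        else:  # cis: both-minor haplotypes as frequent as possible
            col1[perm[:n_a]] = 1
            col2[perm[:n_b]] = 1
        haps[:, snp1] = col1
        haps[:, snp2] = col2
    h1, h2 = haps[0::2], haps[1::2]
    g1 = h1[:, snp1] + h2[:, snp1]
    g2 = h1[:, snp2] + h2[:, snp2]
    dh = np.flatnonzero((g1 == 1) & (g2 == 1))
    if dh.size < 10:
        logger.warning(
            "only %d double-heterozygote carriers at pair (%d, %d)",
            dh.size, snp1, snp2,
        )
    both_minor_same_hap = (h1[dh, snp1] & h1[dh, snp2]) | (h2[dh, snp1] & h2[dh, snp2])
    realised = pd.DataFrame(
        {
            "individual": dh.astype(int),
            "phase": np.where(both_minor_same_hap.astype(bool), "cis", "trans"),
        }
    )
    return realised


def genotypes_from_haplotypes(haps: np.ndarray) -> np.ndarray:
    return (haps[0::2] + haps[1::2]).astype(np.int8)


def generate_phenotype(
    genotypes: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    trans_carriers: dict[tuple[int, int], np.ndarray] | None = None,
) -> pd.DataFrame:
    """Height plus simulated covariates under the planted-effect model.

    height = mean + sum_single beta*g + sum_pair beta*min(g1+g2, 2)
             + sex_effect*sex + age_slope*age + pc_effect*PCs + N(0, sd).
    For ``ch_only`` pair effects the genetic term is beta*2 for trans
    double heterozygotes only (``trans_carriers`` supplies their indices).
    """
    n = genotypes.shape[0]
    sex = rng.integers(0, 2, size=n)
    age = rng.uniform(45, 90, size=n)
    pcs = rng.standard_normal((n, config.n_pcs))
    genetic = np.zeros(n)
    for e in config.planted_single_effects:
        genetic += e.beta * genotypes[:, e.snp]
    for e in config.planted_pair_effects:
        if e.ch_only:
            idx = (trans_carriers or {}).get((e.snp1, e.snp2), np.array([], int))
            contrib = np.zeros(n)
            contrib[idx] = 2.0
            genetic += e.beta * contrib
        else:
            pseudo = np.minimum(genotypes[:, e.snp1] + genotypes[:, e.snp2], 2)
            genetic += e.beta * pseudo
    height = (
        config.mean_height
        + genetic
        + config.sex_effect * sex
        + config.age_slope * age
        + config.pc_effect * pcs.sum(axis=1)
        + rng.normal(0.0, config.residual_sd, size=n)
    )
    out = pd.DataFrame(
        {
            "sample_id": [f"ind{i:06d}" for i in range(n)],
            "height": height,
            "sex": sex,
            "age": age,
        }
    )
    for k in range(config.n_pcs):
        out[f"PC{k + 1}"] = pcs[:, k]
    return out


def ascertain_tall(
    pheno: pd.DataFrame,
    sds_cutoff: float,
    n_extra: int,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Append ``n_extra`` individuals from the tall tail of the pool.

    Heights are standardised within sex using the pool's mean and SD; the
    tail is SDS > ``sds_cutoff`` (1.88 corresponds to the upper ~3%).
    Returns the augmented table and the pool row indices that were
    duplicated (so genotype rows can be copied alongside).
    """
    h = pheno["height"].to_numpy(dtype=float)
    sds = np.empty_like(h)
    for s in np.unique(pheno["sex"]):
        m = (pheno["sex"] == s).to_numpy()
        sd = h[m].std(ddof=1)
        sds[m] = (h[m] - h[m].mean()) / (sd if sd > 0 else 1.0)
    eligible = np.flatnonzero(sds > sds_cutoff)
    if eligible.size < n_extra:
        frac = max(eligible.size / max(len(h), 1), 1e-12)
        raise ValueError(
            f"only {eligible.size} individuals above SDS {sds_cutoff}; "
            f"need a pool of ~{int(np.ceil(n_extra / frac))} for {n_extra} extras"
        )
    chosen = rng.choice(eligible, size=n_extra, replace=False)
    extra = pheno.iloc[chosen].copy()
    extra["sample_id"] = [f"tall{i:05d}" for i in range(n_extra)]
    out = pd.concat([pheno, extra], ignore_index=True)
    return out, chosen


@dataclass
class Cohort:
    panel: GenotypePanel
    phenotypes: pd.DataFrame
    truth: pd.DataFrame
    covariate_names: list[str]


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """End-to-end cohort: haplotypes -> planted effects -> trait -> panel.

    The panel's calls are re-oriented to the empirical minor allele, which
    for a simulated frequency near 0.5 may be the opposite of the allele
    the effect was planted on (the truth table records the planted allele
    as 'sim').
    """
    rng = np.random.default_rng(config.seed)
    vmap = variant_map(config, rng)
    haps, freqs = simulate_haplotypes(config, rng)
    trans_carriers: dict[tuple[int, int], np.ndarray] = {}
    truth_rows = []
    for e in config.planted_pair_effects:
        realised = plant_pair_effect(
            haps, e.snp1, e.snp2, e.phase, rng, maf1=e.maf1, maf2=e.maf2
        )
        trans_carriers[(e.snp1, e.snp2)] = realised.loc[
            realised["phase"] == "trans", "individual"
        ].to_numpy()
        truth_rows.append(
            {
                "kind": "pair",
                "snp1": vmap["id"][e.snp1],
                "snp2": vmap["id"][e.snp2],
                "beta": e.beta,
                "phase": e.phase,
                "ch_only": e.ch_only,
            }
        )
    for e in config.planted_single_effects:
        truth_rows.append(
            {
                "kind": "single",
                "snp1": vmap["id"][e.snp],
                "snp2": "",
                "beta": e.beta,
                "phase": "",
                "ch_only": False,
            }
        )
    genotypes = genotypes_from_haplotypes(haps)
    pheno = generate_phenotype(genotypes, config, rng, trans_carriers)
    if config.tall_ascertainment is not None:
        cutoff, n_extra = config.tall_ascertainment
        pheno, chosen = ascertain_tall(pheno, cutoff, n_extra, rng)
        genotypes = np.vstack([genotypes, genotypes[chosen]])
    alleles_a = np.full(config.n_snps, "A", dtype=object)  # simulated (planted) allele
    alleles_b = np.full(config.n_snps, "G", dtype=object)
    calls, variants = _orient_and_annotate(
        genotypes, vmap["id"], vmap["chrom"], vmap["pos"], alleles_a, alleles_b
    )
    panel = _sort_panel(pheno["sample_id"].tolist(), calls, variants)
    covars = ["sex", "age"] + [f"PC{k + 1}" for k in range(config.n_pcs)]
    truth = pd.DataFrame(
        truth_rows, columns=["kind", "snp1", "snp2", "beta", "phase", "ch_only"]
    )
    return Cohort(panel=panel, phenotypes=pheno, truth=truth, covariate_names=covars)
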