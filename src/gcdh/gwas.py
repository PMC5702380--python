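"""Conventional single-SNP GWAS: additive OLS, genomic inflation, QQ data.

Each SNP is tested with an ordinary least-squares model
``height ~ minor_allele_count + covariates`` and a two-sided t test on the
genotype coefficient (the linear-model semantics of PLINK). A positive
beta means the minor allele increases height. The marginal P values feed
the pair scan's p-filter; the genomic inflation factor lambda summarises
their calibration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import CovariateProjector, marginal_ols, single_fit
from .io import GenotypePanel

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # 0.4549364...

#: genome-wide significance for single-SNP tests
GENOME_WIDE_ALPHA = 5e-8

ASSOC_COLUMNS = ["snp", "effect_allele", "beta", "se", "p", "n_used", "flag"]


def run_gwas(
    panel: GenotypePanel,
    pheno: pd.DataFrame,
    covariate_names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-SNP additive association scan.

    ``pheno`` must be row-aligned with ``panel.samples`` (see
    :func:`gcdh.io.align_samples`). Missing genotypes are handled
    complete-case per SNP. Monomorphic SNPs get P = 1, beta = 0 and the
    flag ``monomorphic``.

    Returns a DataFrame with columns ``snp, effect_allele, beta, se, p,
    n_used, flag`` in panel variant order.
    """
    if list(pheno["sample_id"]) != list(panel.samples):
        raise ValueError("phenotype rows are not aligned with panel samples")
    y = pheno["height"].to_numpy(dtype=float)
    covars = (
        pheno[list(covariate_names)].to_numpy(dtype=float)
        if covariate_names
        else None
    )
    n, m = panel.calls.shape
    beta = np.zeros(m)
    se = np.full(m, np.nan)
    p = np.ones(m)
    n_used = np.full(m, n, dtype=int)
    flag = np.full(m, "", dtype=object)

    complete = ~(panel.calls < 0).any(axis=0)
    mono = np.array([len(np.unique(panel.calls[panel.calls[:, j] >= 0, j])) < 2
                     for j in range(m)])
    flag[mono] = "monomorphic"

    fast = complete & ~mono
    if fast.any():
        proj = CovariateProjector(covars, n)
        G = panel.calls[:, fast].astype(float)
        b, s, pv = marginal_ols(
            proj.residualize(y), proj.residualize(G), n - proj.rank - 1
        )
        beta[fast], se[fast], p[fast] = b, s, pv
    for j in np.flatnonzero(~complete & ~mono):
        beta[j], se[j], p[j], n_used[j] = single_fit(y, panel.calls[:, j], covars)
    return pd.DataFrame(
        {
            "snp": panel.variants["id"].to_numpy(),
            "effect_allele": panel.variants["allele_minor"].to_numpy(),
            "beta": beta,
            "se": se,
            "p": p,
            "n_used": n_used,
            "flag": flag,
        }
    )


def genomic_lambda(p_values: np.ndarray) -> tuple[float, int]:
    """Genomic inflation factor: median association chi2 / 0.4549.

    P values are converted back to 1-df chi-square quantiles; lambda near 1
    indicates calibrated tests, lambda >> 1 inflation (expected for min-P
    scan statistics). Returns (lambda, n_tests).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("cannot compute lambda from zero P values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("P values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1_MEDIAN), int(p.size)


def qq_table(p_values: np.ndarray) -> pd.DataFrame:
    """Observed vs expected -log10 P, expected_i = -log10((i - 0.5) / m)."""
    p = np.sort(np.asarray(p_values, dtype=float))  # most significant first
    m = p.size
    ranks = np.arange(1, m + 1)
    expected = -np.log10((ranks - 0.5) / m)  # descending
    observed = -np.log10(p)
    return pd.DataFrame({"expected": expected, "observed": observed})


def manhattan_table(records: pd.DataFrame, variants: pd.DataFrame) -> pd.DataFrame:
    """(chrom, pos, -log10 P) join of association records with the map."""
    merged = records.merge(
        variants[["id", "chrom", "pos"]], left_on="snp", right_on="id", how="inner"
    )
    return pd.DataFrame(
        {
            "chrom": merged["chrom"],
            "pos": merged["pos"],
            "snp": merged["snp"],
            "neglog10_p": -np.log10(merged["p"].to_numpy(dtype=float)),
        }
    )


def export_qq_manhattan(
    records: pd.DataFrame, variants: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-data tables for a Manhattan plot and a QQ plot."""
    if records.empty:
        raise ValueError("no association records to export")
    return manhattan_table(records, variants), qq_table(records["p"].to_numpy())
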