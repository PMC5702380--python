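"""Genome-wide collapsed double-heterozygosity (GCDH) scan.

Nearby SNP pairs are collapsed into pseudo-markers through a collapsing
matrix — a total map from the 3x3 grid of two-SNP genotypes to
pseudo-genotype categories encoding a joint genetic model. Under the
additive model used here the pseudo-genotype is min(g1 + g2, 2), i.e. 0, 1,
or "2 or more" minor alleles over the pair; compound (trans) and cis double
heterozygotes fall in the same category and are only separated later by
diplotype inference. Each pseudo-marker is tested against the trait with
the same linear model as a single SNP; a sliding window (at most ``k``
pairing SNPs within ``d`` bp downstream of each index SNP) assigns the
window's minimum P value to the index SNP, and genome-wide significance
uses the per-window Bonferroni threshold alpha / k (1.67e-10 for
alpha = 5e-8, k = 300).

The min-P assignment plus the marginal p-filter make the scan statistic
null distribution strongly inflated relative to single-SNP tests, so an
empirical null is obtained by re-running the full scan on
phenotype-permuted data (:func:`permutation_null`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import CovariateProjector, marginal_ols, single_fit
from .gwas import GENOME_WIDE_ALPHA, run_gwas
from .io import GenotypePanel

logger = logging.getLogger(__name__)

PAIR_COLUMNS = [
    "index_snp", "partner_snp", "n_cat0", "n_cat1", "n_cat2",
    "beta", "se", "p", "n_used", "flag",
]
SCAN_COLUMNS = [
    "index_snp", "partner_snp", "min_p", "beta", "tests_performed", "significant",
]

#: minimum complete-case sample size for a pair fit
MIN_PAIR_N = 30


@dataclass(frozen=True)
class CollapsingMatrix:
    """Total map from the 3x3 two-SNP genotype grid to pseudo-genotypes."""

    name: str
    table: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=np.int8)
        if t.shape != (3, 3):
            raise ValueError("collapsing matrix must be 3x3")
        cats = np.unique(t)
        if not np.array_equal(cats, np.arange(cats.size)):
            raise ValueError("categories must be consecutive integers from 0")
        object.__setattr__(self, "table", t)

    @classmethod
    def additive(cls) -> "CollapsingMatrix":
        """Joint additive model: 0, 1, or >= 2 minor alleles (3 categories)."""
        g = np.add.outer(np.arange(3), np.arange(3))
        return cls("additive_alternative", np.minimum(g, 2))

    @classmethod
    def recessive(cls) -> "CollapsingMatrix":
        """Joint recessive default: <= 1 vs >= 2 minor alleles (2 categories)."""
        g = np.add.outer(np.arange(3), np.arange(3))
        return cls("recessive_default", (g >= 2).astype(np.int8))

    @classmethod
    def by_name(cls, name: str) -> "CollapsingMatrix":
        if name in ("additive", "additive_alternative"):
            return cls.additive()
        if name in ("recessive", "recessive_default"):
            return cls.recessive()
        raise ValueError(f"unknown collapsing matrix {name!r}")

    @property
    def n_categories(self) -> int:
        return int(self.table.max()) + 1


def collapse_pair(
    g1: np.ndarray, g2: np.ndarray, matrix: CollapsingMatrix
) -> np.ndarray:
    """Elementwise collapsing; missing (-1) in either SNP propagates."""
    g1 = np.asarray(g1, dtype=np.int8)
    g2 = np.asarray(g2, dtype=np.int8)
    if g1.shape != g2.shape:
        raise ValueError("genotype vectors differ in length")
    ok = (g1 >= 0) & (g2 >= 0)
    out = np.full(g1.shape, -1, dtype=np.int8)
    out[ok] = matrix.table[g1[ok], g2[ok]]
    return out


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window parameters: k pairs, d bp, marginal p-filter.

    ``p_filter_mode`` decides which member(s) must pass the marginal
    filter for a pair to be tested: ``either`` (default; the weakest rule
    consistent with published GCDH hits), ``both``, or ``index``.
    """

    k: int = 300
    d: int = 500_000
    p_filter: float = 0.1
    p_filter_mode: str = "either"
    alpha: float = GENOME_WIDE_ALPHA

    def __post_init__(self) -> None:
        if self.k < 1 or self.d < 1:
            raise ValueError("k and d must be >= 1")
        if not 0 < self.p_filter <= 1:
            raise ValueError("p_filter must be in (0, 1]")
        if self.p_filter_mode not in ("either", "both", "index"):
            raise ValueError(f"unknown p_filter_mode {self.p_filter_mode!r}")

    @property
    def threshold(self) -> float:
        """Per-window Bonferroni genome-wide threshold, alpha / k."""
        return self.alpha / self.k


def enumerate_windows(
    variants: pd.DataFrame, spec: WindowSpec, marginal_p: np.ndarray
):
    """Yield (index, partner_indices) for every index SNP with >= 1 pair.

    Partners are the subsequent SNPs on the same chromosome within ``d``
    bp, truncated to at most ``k``, then filtered by the marginal p-filter
    rule — so a window performs at most k tests.
    """
    chrom = variants["chrom"].to_numpy()
    pos = variants["pos"].to_numpy()
    p = np.asarray(marginal_p, dtype=float)
    m = len(variants)
    for i in range(m):
        hi = i
        while hi + 1 < m and chrom[hi + 1] == chrom[i] and pos[hi + 1] - pos[i] <= spec.d:
            hi += 1
        partners = np.arange(i + 1, hi + 1)[: spec.k]
        if partners.size == 0:
            continue
        if spec.p_filter_mode == "either":
            keep = (p[i] <= spec.p_filter) | (p[partners] <= spec.p_filter)
        elif spec.p_filter_mode == "both":
            keep = (p[i] <= spec.p_filter) & (p[partners] <= spec.p_filter)
        else:  # index
            keep = np.full(partners.size, p[i] <= spec.p_filter)
        partners = partners[keep]
        if partners.size:
            yield i, partners


def fit_pseudo_glm(
    pseudo: np.ndarray,
    y: np.ndarray,
    covars: np.ndarray | None,
) -> tuple[float, float, float, int, str]:
    """OLS of the trait on one numeric pseudo-genotype + covariates.

    Returns (beta, se, p, n_used, flag); flag is ``degenerate`` when fewer
    than two distinct non-missing categories remain.
    """
    pseudo = np.asarray(pseudo)
    obs = pseudo[pseudo >= 0]
    if obs.size == 0 or np.unique(obs).size < 2:
        return 0.0, float("nan"), 1.0, int(obs.size), "degenerate"
    beta, se, p, n_used = single_fit(np.asarray(y, float), pseudo, covars)
    return beta, se, p, n_used, ""


def gcdh_scan(
    panel: GenotypePanel,
    pheno: pd.DataFrame,
    covariate_names: list[str] | None = None,
    spec: WindowSpec | None = None,
    matrix: CollapsingMatrix | None = None,
    marginal: pd.DataFrame | None = None,
    return_pairs: bool = False,
):
    """Run the sliding-window pseudo-marker scan.

    Parameters
    ----------
    marginal : optional precomputed single-SNP GWAS table (from
        :func:`gcdh.gwas.run_gwas`); computed internally when absent.
    return_pairs : also return the full per-pair result table.

    Returns
    -------
    scan : DataFrame with one row per index SNP that had >= 1 eligible,
        non-degenerate pair — columns ``index_snp, partner_snp, min_p,
        beta, tests_performed, significant``. Ties in min P are broken by
        the smallest partner position.
    pairs : DataFrame of every tested pair (only if ``return_pairs``).
    """
    spec = spec or WindowSpec()
    matrix = matrix or CollapsingMatrix.additive()
    if marginal is None:
        marginal = run_gwas(panel, pheno, covariate_names)
    mp = marginal["p"].to_numpy(dtype=float)
    y = pheno["height"].to_numpy(dtype=float)
    covars = (
        pheno[list(covariate_names)].to_numpy(dtype=float)
        if covariate_names
        else None
    )
    n = panel.n_samples
    calls = panel.calls
    ids = panel.variants["id"].to_numpy()
    complete_col = ~(calls < 0).any(axis=0)
    proj = CovariateProjector(covars, n)
    y_res = proj.residualize(y)
    df_resid = n - proj.rank - 1

    n_skipped = 0
    scan_rows = []
    pair_rows = [] if return_pairs else None
    for i, partners in enumerate_windows(panel.variants, spec, mp):
        g1 = calls[:, i]
        fast = complete_col[i] and bool(complete_col[partners].all())
        if fast:
            pseudo_mat = matrix.table[g1[:, None], calls[:, partners]]
            degen = pseudo_mat.max(axis=0) == pseudo_mat.min(axis=0)
            beta = np.zeros(partners.size)
            se = np.full(partners.size, np.nan)
            pv = np.ones(partners.size)
            ok = ~degen
            flags = np.where(degen, "degenerate", "")
            if n < MIN_PAIR_N:
                flags = np.where(degen, "degenerate", "small_n")
            elif ok.any():
                b, s, q = marginal_ols(
                    y_res,
                    proj.residualize(pseudo_mat[:, ok].astype(float)),
                    df_resid,
                )
                beta[ok], se[ok], pv[ok] = b, s, q
            n_used = np.full(partners.size, n)
        else:
            beta = np.zeros(partners.size)
            se = np.full(partners.size, np.nan)
            pv = np.ones(partners.size)
            n_used = np.zeros(partners.size, dtype=int)
            flags = np.empty(partners.size, dtype=object)
            pseudo_mat = np.column_stack(
                [collapse_pair(g1, calls[:, j], matrix) for j in partners]
            )
            for c in range(partners.size):
                b, s, q, nu, fl = fit_pseudo_glm(pseudo_mat[:, c], y, covars)
                if not fl and nu < MIN_PAIR_N:
                    fl, q, b = "small_n", 1.0, 0.0
                beta[c], se[c], pv[c], n_used[c], flags[c] = b, s, q, nu, fl

        usable = np.asarray(flags) == ""
        n_skipped += int((~usable).sum())
        if return_pairs:
            for c, j in enumerate(partners):
                counts = np.bincount(
                    pseudo_mat[pseudo_mat[:, c] >= 0, c], minlength=3
                )
                pair_rows.append(
                    (
                        ids[i], ids[j], int(counts[0]), int(counts[1]),
                        int(counts[2]) if counts.size > 2 else 0,
                        beta[c], se[c], pv[c], int(n_used[c]), flags[c],
                    )
                )
        if not usable.any():
            continue
        cand = np.flatnonzero(usable)
        best = cand[int(np.argmin(pv[cand]))]  # argmin keeps smallest position on ties
        scan_rows.append(
            (
                ids[i], ids[partners[best]], float(pv[best]), float(beta[best]),
                int(partners.size), bool(pv[best] < spec.threshold),
            )
        )
    if n_skipped:
        logger.info("skipped %d degenerate/underpowered pairs", n_skipped)
    scan = pd.DataFrame(scan_rows, columns=SCAN_COLUMNS)
    if scan.empty:
        logger.warning("no eligible pairs anywhere in the genome")
    if return_pairs:
        pairs = pd.DataFrame(pair_rows, columns=PAIR_COLUMNS)
        return scan, pairs
    return scan


def shuffle_phenotypes(
    pheno: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Break the genotype-phenotype link by permuting whole phenotype rows.

    Height and covariates travel together (row integrity); sample ids stay
    in place so panel alignment is preserved.
    """
    perm = rng.permutation(len(pheno))
    out = pheno.copy()
    value_cols = [c for c in pheno.columns if c != "sample_id"]
    out[value_cols] = pheno[value_cols].to_numpy()[perm]
    return out


def permutation_null(
    panel: GenotypePanel,
    pheno: pd.DataFrame,
    covariate_names: list[str] | None,
    spec: WindowSpec,
    matrix: CollapsingMatrix,
    n_perm: int = 5,
    seed: int = 0,
) -> tuple[list[pd.DataFrame], np.ndarray]:
    """Empirical scan null: re-run the full GCDH scan on permuted traits.

    Each replicate r shuffles the phenotype rows with seed ``seed + r``,
    recomputes the marginal GWAS (so the p-filter uses the permuted
    marginals, exactly as an honest re-run would) and repeats the scan.
    Returns the per-replicate scan tables and the pooled min-P values.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    replicates = []
    pooled = []
    for r in range(n_perm):
        rng = np.random.default_rng(seed + r)
        pheno_r = shuffle_phenotypes(pheno, rng)
        scan_r = gcdh_scan(panel, pheno_r, covariate_names, spec, matrix)
        replicates.append(scan_r)
        pooled.append(scan_r["min_p"].to_numpy(dtype=float))
    pooled_arr = np.concatenate(pooled) if pooled else np.array([])
    return replicates, pooled_arr
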