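"""Polygenic score, iterative incremental-R2 ledger, and exact replication.

The variance ledger reproduces the iterative multivariable procedure used
to partition trait variance among a polygenic score, top single SNPs and
top pseudo-markers: fit the full joint model, rank terms by their
full-model P values, then add terms one at a time in that order, recording
each term's R2 increment. The increments telescope to the full-model R2 by
construction. The dependent variable is the sex- and age-regressed height
residual; R2 values are reported as percentages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._stats import single_fit
from .io import GenotypePanel
from .scan import CollapsingMatrix, collapse_pair

logger = logging.getLogger(__name__)


def compute_prs(panel: GenotypePanel, weights: pd.DataFrame) -> np.ndarray:
    """Weighted allele-sum polygenic score per sample.

    ``weights`` columns: snp, effect_allele, weight. The effect allele must
    match one of the panel's two alleles at that SNP (records that do not
    are dropped with a log entry); missing genotypes contribute the SNP's
    mean dosage.
    """
    v = panel.variants
    idx_by_id = {sid: j for j, sid in enumerate(v["id"])}
    score = np.zeros(panel.n_samples)
    n_used = 0
    n_dropped = 0
    for _, row in weights.iterrows():
        j = idx_by_id.get(row["snp"])
        if j is None:
            n_dropped += 1
            continue
        calls = panel.calls[:, j].astype(float)
        obs = calls >= 0
        mean_dose = calls[obs].mean() if obs.any() else 0.0
        dose = np.where(obs, calls, mean_dose)
        if row["effect_allele"] == v["allele_minor"].iloc[j]:
            pass
        elif row["effect_allele"] == v["allele_major"].iloc[j]:
            dose = 2.0 - dose
        else:
            n_dropped += 1
            continue
        score += float(row["weight"]) * dose
        n_used += 1
    if n_dropped:
        logger.info("dropped %d weight records with no matching panel allele", n_dropped)
    if n_used == 0:
        raise ValueError("no weight record matched the panel")
    return score


@dataclass
class VarianceLedger:
    """Ordered incremental-R2 table plus class subtotals (percent)."""

    table: pd.DataFrame  # term, kind, neglog10_p, r2_increment_pct
    total_pct: float
    subtotal_pct: dict[str, float]


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    model = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    return float(model.rsquared)


def iterative_r2(
    y: np.ndarray,
    predictors: pd.DataFrame,
    kinds: dict[str, str] | None = None,
) -> VarianceLedger:
    """Iterative multivariable R2 decomposition.

    Parameters
    ----------
    y : dependent variable (sex- and age-regressed height residuals).
    predictors : one column per term (PRS, single-SNP dosages,
        pseudo-marker dosages), complete cases only.
    kinds : optional map term -> class label ("prs" | "snp" |
        "pseudo_marker") used for the subtotals.

    Procedure: (1) fit the full joint OLS and record each term's
    -log10 P; (2) order terms by ascending full-model P (ties keep input
    order); (3) refit nested models adding one term at a time in that
    order, recording R2 increments. Increments sum to the full-model R2
    exactly; a near-zero increment marks a collinear term.
    """
    y = np.asarray(y, dtype=float)
    X = predictors.to_numpy(dtype=float)
    full = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    pvals = np.asarray(full.pvalues)[1:]
    order = np.argsort(pvals, kind="stable")
    terms = list(predictors.columns)
    rows = []
    prev_r2 = 0.0
    added: list[int] = []
    for rank, t in enumerate(order):
        added.append(t)
        r2 = _r2(y, X[:, added])
        inc = r2 - prev_r2
        if inc < -1e-10:
            raise AssertionError(f"negative R2 increment {inc} at term {terms[t]}")
        inc = max(inc, 0.0)
        flag = "collinear" if inc < 1e-12 and rank > 0 else ""
        rows.append(
            {
                "term": terms[t],
                "kind": (kinds or {}).get(terms[t], "term"),
                "neglog10_p": float(-np.log10(max(pvals[t], 1e-320))),
                "r2_increment_pct": 100.0 * inc,
                "flag": flag,
            }
        )
        prev_r2 = r2
    table = pd.DataFrame(rows)
    subtotal = table.groupby("kind")["r2_increment_pct"].sum().to_dict()
    return VarianceLedger(
        table=table,
        total_pct=100.0 * float(full.rsquared),
        subtotal_pct=subtotal,
    )


def compare_pair_vs_pseudo(
    adjusted_y: np.ndarray,
    g1: np.ndarray,
    g2: np.ndarray,
    pseudo: np.ndarray,
) -> dict[str, float]:
    """R2 of the pseudo-marker vs its member SNPs, same complete cases.

    Returns R2 for: the pseudo-marker alone, SNP1 alone, SNP2 alone, and
    SNP1 + SNP2 jointly. The pseudo-marker is a (nonlinear) function of the
    pair, so its R2 can exceed either single SNP but is typically close to
    the joint two-SNP fit.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    pseudo = np.asarray(pseudo)
    ok = (g1 >= 0) & (g2 >= 0) & (pseudo >= 0)
    y = np.asarray(adjusted_y, dtype=float)[ok]
    a, b, ps = g1[ok].astype(float), g2[ok].astype(float), pseudo[ok].astype(float)
    return {
        "r2_pseudo": _r2(y, ps[:, None]),
        "r2_snp1": _r2(y, a[:, None]),
        "r2_snp2": _r2(y, b[:, None]),
        "r2_joint": _r2(y, np.column_stack([a, b])),
    }


REPLICATION_ALPHA = 0.05

REPLICATION_COLUMNS = [
    "hit", "kind", "beta_discovery", "beta", "se", "p",
    "replicated", "sign_agrees", "status",
]


def replicate(
    hits: pd.DataFrame,
    panel: GenotypePanel,
    pheno: pd.DataFrame,
    covariate_names: tuple[str, ...] = ("sex", "age"),
    matrix: CollapsingMatrix | None = None,
    alpha: float = REPLICATION_ALPHA,
) -> pd.DataFrame:
    """Exact replication of discovery hits in an independent cohort.

    ``hits`` rows: ``hit`` (SNP id, or "id1_id2" for a pair), ``kind``
    ("snp" | "pair"), ``beta_discovery``. The discovery definition is
    frozen: the same collapsing matrix is applied to the replication
    genotypes, the model adjusts for the given covariates (sex and age by
    default), and ``replicated`` is P < ``alpha``; sign agreement with the
    discovery beta is reported separately. Hits absent from the
    replication panel are returned as untestable.
    """
    matrix = matrix or CollapsingMatrix.additive()
    if list(pheno["sample_id"]) != list(panel.samples):
        raise ValueError("phenotype rows are not aligned with panel samples")
    y = pheno["height"].to_numpy(dtype=float)
    covars = pheno[list(covariate_names)].to_numpy(dtype=float)
    rows = []
    for _, hit in hits.iterrows():
        name, kind = hit["hit"], hit["kind"]
        b_disc = float(hit["beta_discovery"])
        try:
            if kind == "pair":
                id1, id2 = name.split("_", 1)
                x = collapse_pair(
                    panel.calls[:, panel.index_of(id1)],
                    panel.calls[:, panel.index_of(id2)],
                    matrix,
                )
            else:
                x = panel.calls[:, panel.index_of(name)]
        except KeyError:
            rows.append((name, kind, b_disc, np.nan, np.nan, np.nan,
                         False, False, "untestable"))
            continue
        beta, se, p, _ = single_fit(y, x, covars)
        rows.append(
            (
                name, kind, b_disc, beta, se, p,
                bool(p < alpha), bool(np.sign(beta) == np.sign(b_disc)), "tested",
            )
        )
    return pd.DataFrame(rows, columns=REPLICATION_COLUMNS)
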