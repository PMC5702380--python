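"""Genotype, phenotype and weight-table I/O and the shared data model.

Genotypes are held as a sample-by-variant matrix of minor-allele counts
(``int8``: 0, 1, 2; ``-1`` for missing). Variants are always oriented so
that the counted allele is the minor allele (empirical frequency <= 0.5),
with a lexicographic tie-break at exactly 0.5. PLINK bed/bim/fam (SNP-major
v1.00) and biallelic-SNP VCF (GT or DS) are supported on input; PLINK and
TSV on output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = np.int8(-1)

_PLINK_MAGIC = bytes([0x6C, 0x1B, 0x01])

#: columns every variant map carries, in fixed order
VARIANT_COLUMNS = ["id", "chrom", "pos", "allele_minor", "allele_major", "maf"]


@dataclass
class GenotypePanel:
    """Hard-call genotype matrix plus its sorted variant map.

    Attributes
    ----------
    samples : list of str
        Ordered sample ids.
    variants : pandas.DataFrame
        One row per variant with columns ``id, chrom, pos, allele_minor,
        allele_major, maf``, sorted by (chrom, pos).
    calls : numpy.ndarray
        ``int8`` matrix of shape (n_samples, n_variants) counting copies of
        the minor allele; -1 marks a missing call.
    """

    samples: list[str]
    variants: pd.DataFrame
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset_variants(self, mask: np.ndarray) -> "GenotypePanel":
        idx = np.flatnonzero(mask)
        return GenotypePanel(
            samples=list(self.samples),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            calls=self.calls[:, idx],
        )

    def subset_samples(self, indices: np.ndarray) -> "GenotypePanel":
        indices = np.asarray(indices)
        return GenotypePanel(
            samples=[self.samples[i] for i in indices],
            variants=self.variants.copy(),
            calls=self.calls[indices, :],
        )

    def index_of(self, snp_id: str) -> int:
        hits = np.flatnonzero(self.variants["id"].to_numpy() == snp_id)
        if hits.size == 0:
            raise KeyError(f"SNP {snp_id!r} not in panel")
        return int(hits[0])


def _orient_and_annotate(
    calls: np.ndarray, ids, chroms, poss, allele_counted, allele_other
) -> tuple[np.ndarray, pd.DataFrame]:
    """Flip columns so calls count the minor allele; compute MAF.

    ``calls`` counts ``allele_counted`` on entry. Ties at frequency 0.5 are
    broken lexicographically: the alphabetically smaller allele is minor.
    """
    calls = np.asarray(calls, dtype=np.int8)
    n_var = calls.shape[1]
    a_minor = np.asarray(allele_counted, dtype=object).copy()
    a_major = np.asarray(allele_other, dtype=object).copy()
    maf = np.empty(n_var)
    for j in range(n_var):
        col = calls[:, j]
        obs = col[col >= 0]
        freq = float(obs.mean() / 2.0) if obs.size else 0.0
        flip = freq > 0.5 or (freq == 0.5 and str(a_minor[j]) > str(a_major[j]))
        if flip:
            calls[col >= 0, j] = 2 - col[col >= 0]
            a_minor[j], a_major[j] = a_major[j], a_minor[j]
            freq = 1.0 - freq
        maf[j] = freq
    variants = pd.DataFrame(
        {
            "id": np.asarray(ids, dtype=object),
            "chrom": np.asarray(chroms, dtype=object).astype(str),
            "pos": np.asarray(poss, dtype=np.int64),
            "allele_minor": a_minor,
            "allele_major": a_major,
            "maf": maf,
        }
    )
    return calls, variants


def _sort_panel(samples, calls, variants) -> GenotypePanel:
    order = np.lexsort((variants["pos"].to_numpy(), variants["chrom"].to_numpy()))
    return GenotypePanel(
        samples=list(samples),
        variants=variants.iloc[order].reset_index(drop=True),
        calls=calls[:, order],
    )


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------

def _read_plink(prefix: str | Path) -> GenotypePanel:
    prefix = str(prefix)
    bim = pd.read_csv(
        prefix + ".bim",
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix + ".fam",
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"iid": str},
    )
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix + ".bed", dtype=np.uint8)
    if raw[:3].tobytes() != _PLINK_MAGIC:
        raise ValueError(f"{prefix}.bed: not a SNP-major PLINK v1.00 bed file")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_snp * m:
        raise ValueError(
            f"{prefix}.bed: {body.size} data bytes inconsistent with "
            f"{n} samples x {m} variants from fam/bim"
        )
    blocks = body.reshape(m, bytes_per_snp)
    # unpack 2-bit codes, sample-fastest within each byte (little-endian pairs)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (blocks[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, bytes_per_snp * 4)[:, :n]
    # PLINK: 00 -> hom A1 (2 copies of A1), 10 -> het, 11 -> hom A2, 01 -> missing
    calls_a1 = np.empty((m, n), dtype=np.int8)
    calls_a1[codes == 0b00] = 2
    calls_a1[codes == 0b10] = 1
    calls_a1[codes == 0b11] = 0
    calls_a1[codes == 0b01] = MISSING
    calls, variants = _orient_and_annotate(
        calls_a1.T, bim["id"], bim["chrom"], bim["pos"], bim["a1"], bim["a2"]
    )
    return _sort_panel(fam["iid"].tolist(), calls, variants)


def write_panel(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write a panel as a PLINK bed/bim/fam triplet (A1 = minor allele)."""
    prefix = str(prefix)
    n, m = panel.n_samples, panel.n_variants
    v = panel.variants
    with open(prefix + ".bim", "w") as fh:
        for _, row in v.iterrows():
            fh.write(
                f"{row['chrom']}\t{row['id']}\t0\t{row['pos']}\t"
                f"{row['allele_minor']}\t{row['allele_major']}\n"
            )
    with open(prefix + ".fam", "w") as fh:
        for sid in panel.samples:
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t-9\n")
    # encode: calls count A1 (minor): 2 -> 00, 1 -> 10, 0 -> 11, missing -> 01
    codes = np.empty((m, n), dtype=np.uint8)
    ct = panel.calls.T
    codes[ct == 2] = 0b00
    codes[ct == 1] = 0b10
    codes[ct == 0] = 0b11
    codes[ct == MISSING] = 0b01
    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes
    padded = padded.reshape(m, bytes_per_snp, 4)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (padded << shifts[None, None, :]).sum(axis=2).astype(np.uint8)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_PLINK_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _read_vcf(path: str | Path) -> GenotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, a_alt, a_ref, cols = [], [], [], [], [], []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        ds = rec.format("DS")
        if ds is not None:
            # hard-call imputed dosages: round-half-to-even to nearest integer
            dvec = np.asarray(ds, dtype=float).reshape(-1)
            alt = np.rint(dvec).astype(np.int8)
            alt[~np.isfinite(dvec)] = MISSING
        else:
            gts = rec.genotype.array()
            alleles = gts[:, :2]
            alt = np.where(
                (alleles < 0).any(axis=1), MISSING, (alleles == 1).sum(axis=1)
            ).astype(np.int8)
        ids.append(rec.ID if rec.ID else f"{rec.CHROM}:{rec.POS}")
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        a_alt.append(rec.ALT[0])
        a_ref.append(rec.REF)
        cols.append(alt)
    if n_skipped:
        logger.info("skipped %d non-biallelic-SNP VCF records", n_skipped)
    if not cols:
        raise ValueError(f"{path}: no biallelic SNP records")
    calls = np.column_stack(cols)
    calls, variants = _orient_and_annotate(calls, ids, chroms, poss, a_alt, a_ref)
    return _sort_panel(samples, calls, variants)


def read_panel(path: str | Path) -> GenotypePanel:
    """Read a genotype panel from a PLINK fileset prefix or a VCF file.

    A path ending in ``.vcf``/``.vcf.gz`` is parsed as VCF (biallelic SNPs
    only; DS dosages are hard-called by rounding); anything else is treated
    as a PLINK bed/bim/fam prefix.
    """
    s = str(path)
    if s.endswith(".vcf") or s.endswith(".vcf.gz"):
        return _read_vcf(s)
    return _read_plink(s)


# ---------------------------------------------------------------------------
# Filters and tables
# ---------------------------------------------------------------------------

def apply_maf_filter(panel: GenotypePanel, min_maf: float) -> GenotypePanel:
    """Retain variants with MAF strictly greater than ``min_maf``."""
    if not 0 <= min_maf < 0.5:
        raise ValueError(f"min_maf must be in [0, 0.5), got {min_maf}")
    keep = panel.variants["maf"].to_numpy() > min_maf
    if not keep.any():
        raise ValueError(f"MAF filter > {min_maf} removed every variant")
    return panel.subset_variants(keep)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Load a phenotype/covariate TSV (sample_id, height, sex, age, ...).

    Rows with any missing value are dropped (complete-case) and logged.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns or "height" not in df.columns:
        raise ValueError(f"{path}: phenotype table needs sample_id and height columns")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    n0 = len(df)
    df = df.dropna()
    if len(df) < n0:
        logger.info("dropped %d incomplete phenotype rows", n0 - len(df))
    return df.reset_index(drop=True)


def read_weights(path: str | Path) -> pd.DataFrame:
    """Load a polygenic-score weight table (snp, effect_allele, weight)."""
    df = pd.read_csv(path, sep="\t", dtype={"snp": str, "effect_allele": str})
    need = {"snp", "effect_allele", "weight"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: weight table needs columns {sorted(need)}")
    if df["snp"].duplicated().any():
        raise ValueError(f"{path}: duplicate SNP ids in weight table")
    return df.reset_index(drop=True)


def align_samples(
    panel: GenotypePanel, pheno: pd.DataFrame
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Complete-case intersection of panel and phenotype, in panel order."""
    by_id = {sid: i for i, sid in enumerate(pheno["sample_id"])}
    keep = [i for i, sid in enumerate(panel.samples) if sid in by_id]
    n_lost = panel.n_samples - len(keep)
    if n_lost:
        logger.info("%d panel samples had no phenotype row", n_lost)
    if not keep:
        raise ValueError("no overlapping samples between panel and phenotype table")
    sub = panel.subset_samples(np.asarray(keep))
    rows = [by_id[sid] for sid in sub.samples]
    return sub, pheno.iloc[rows].reset_index(drop=True)


def write_results(records: pd.DataFrame, path: str | Path, columns=None) -> None:
    """Write a result table as TSV with a fixed column order.

    P-value-like columns (``p``, ``*_p``, ``p_*``) are serialised in
    scientific notation with at least 3 significant digits (and as many as
    needed to round-trip exactly); other floats use their shortest exact
    representation. An empty table yields a header-only file.
    """
    df = records.copy()
    if columns is not None:
        df = df[list(columns)]

    def _sci(v) -> str:
        if pd.isna(v):
            return "NA"
        return np.format_float_scientific(float(v), unique=True, min_digits=2)

    def _fmt(col: str):
        if col == "p" or col.endswith("_p") or col.startswith("p_"):
            return _sci
        return None

    formatters = {c: _fmt(c) for c in df.columns}
    with open(path, "w") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for _, row in df.iterrows():
            out = []
            for c in df.columns:
                f = formatters.get(c)
                v = row[c]
                out.append(f(v) if f else str(v))
            fh.write("\t".join(out) + "\n")
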