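import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from gcdh import GenotypePanel, SimulationConfig, simulate_cohort
from gcdh.io import _orient_and_annotate, _sort_panel

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_random_panel(
    rng: np.random.Generator,
    n_samples: int = 50,
    n_variants: int = 100,
    missing_rate: float = 0.02,
    n_chromosomes: int = 2,
) -> GenotypePanel:
    """Small random panel with missing calls, minor-allele oriented."""
    freqs = rng.uniform(0.05, 0.5, size=n_variants)
    calls = rng.binomial(2, freqs, size=(n_samples, n_variants)).astype(np.int8)
    miss = rng.random((n_samples, n_variants)) < missing_rate
    calls[miss] = -1
    per_chrom = np.array_split(np.arange(n_variants), n_chromosomes)
    chroms = np.empty(n_variants, dtype=object)
    pos = np.empty(n_variants, dtype=np.int64)
    for c, idx in enumerate(per_chrom, start=1):
        chroms[idx] = str(c)
        pos[idx] = np.sort(rng.choice(np.arange(1, 10_000_000), len(idx), replace=False))
    ids = [f"rs{j:04d}" for j in range(n_variants)]
    a = np.array(["A"] * n_variants, dtype=object)
    g = np.array(["G"] * n_variants, dtype=object)
    calls, variants = _orient_and_annotate(calls, ids, chroms, pos, a, g)
    return _sort_panel([f"s{i:03d}" for i in range(n_samples)], calls, variants)


@pytest.fixture(scope="session")
def null_cohort():
    """2000 x 2000 cohort with no planted effects (shared, read-only)."""
    return simulate_cohort(SimulationConfig(n_individuals=2000, n_snps=2000, seed=42))


@pytest.fixture(scope="session")
def planted_pair_cohort():
    """n = 4000 cohort with one planted trans pair (MAFs 0.05, beta 0.8).

    Residual SD 2.8 cm gives the collapsed pseudo-marker test ~90% power
    alone at the per-window Bonferroni threshold.
    """
    from gcdh import PairEffect

    return simulate_cohort(
        SimulationConfig(
            n_individuals=4000,
            n_snps=100,
            n_chromosomes=1,
            residual_sd=2.8,
            seed=7,
            planted_pair_effects=[
                PairEffect(40, 45, 0.8, "trans", maf1=0.05, maf2=0.05)
            ],
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
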