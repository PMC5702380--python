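"""GCDH scan: collapsing, windowing, min-P assignment, permutation null."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st

from gcdh import (
    CollapsingMatrix,
    PairEffect,
    SimulationConfig,
    WindowSpec,
    collapse_pair,
    enumerate_windows,
    fit_pseudo_glm,
    gcdh_scan,
    permutation_null,
    run_gwas,
    shuffle_phenotypes,
    simulate_cohort,
)
from gcdh.io import _orient_and_annotate, _sort_panel

from conftest import make_random_panel


def _variant_map(positions, chrom="1"):
    m = len(positions)
    return pd.DataFrame(
        {
            "id": [f"rs{j}" for j in range(m)],
            "chrom": [chrom] * m,
            "pos": np.asarray(positions, dtype=np.int64),
            "allele_minor": ["A"] * m,
            "allele_major": ["G"] * m,
            "maf": [0.2] * m,
        }
    )


class TestCollapsingMatrices:
    def test_additive_equals_min_rule_on_all_nine_cells(self):
        mtx = CollapsingMatrix.additive()
        for g1 in range(3):
            for g2 in range(3):
                assert mtx.table[g1, g2] == min(g1 + g2, 2)
        assert mtx.n_categories == 3

    def test_recessive_default_two_categories(self):
        mtx = CollapsingMatrix.recessive()
        for g1 in range(3):
            for g2 in range(3):
                assert mtx.table[g1, g2] == (0 if g1 + g2 <= 1 else 1)
        assert mtx.n_categories == 2
        assert mtx.table[1, 0] == 0 and mtx.table[2, 0] == 1

    @given(
        g1=st.lists(st.integers(-1, 2), min_size=1, max_size=30),
        g2=st.lists(st.integers(-1, 2), min_size=1, max_size=30),
        name=st.sampled_from(["additive", "recessive"]),
    )
    def test_collapse_symmetry_and_missing_propagation(self, g1, g2, name):
        k = min(len(g1), len(g2))
        a = np.array(g1[:k], dtype=np.int8)
        b = np.array(g2[:k], dtype=np.int8)
        mtx = CollapsingMatrix.by_name(name)
        ab = collapse_pair(a, b, mtx)
        ba = collapse_pair(b, a, mtx)
        np.testing.assert_array_equal(ab, ba)
        missing = (a < 0) | (b < 0)
        assert (ab[missing] == -1).all()
        assert (ab[~missing] >= 0).all()


class TestWindowEnumeration:
    def test_far_apart_pair_excluded(self):
        vmap = _variant_map([1, 600_001])
        spec = WindowSpec(d=500_000, p_filter=1.0)
        assert list(enumerate_windows(vmap, spec, np.ones(2))) == []

    def test_ten_snp_toy_distance_window(self):
        vmap = _variant_map(np.arange(10) * 10_000 + 1)
        spec = WindowSpec(k=300, d=35_000, p_filter=1.0)
        wins = {i: list(ps) for i, ps in enumerate_windows(vmap, spec, np.ones(10))}
        assert wins[0] == [1, 2, 3]
        # brute-force distance oracle over all indices
        pos = vmap["pos"].to_numpy()
        for i in range(10):
            expect = [j for j in range(i + 1, 10) if pos[j] - pos[i] <= 35_000]
            assert wins.get(i, []) == expect

    def test_k_truncation_caps_tests_per_window(self):
        vmap = _variant_map(np.arange(401) * 1000 + 1)
        spec = WindowSpec(k=300, d=500_000, p_filter=1.0)
        i, partners = next(iter(enumerate_windows(vmap, spec, np.ones(401))))
        assert i == 0 and len(partners) == 300

    def test_cross_chromosome_pairs_forbidden(self):
        vmap = _variant_map([1, 1000])
        vmap.loc[1, "chrom"] = "2"
        spec = WindowSpec(d=500_000, p_filter=1.0)
        assert list(enumerate_windows(vmap, spec, np.ones(2))) == []

    @pytest.mark.parametrize(
        "mode,expected",
        [
            ("either", {0: [1, 2], 1: [2, 3], 2: [3]}),
            ("both", {1: [2]}),
            ("index", {1: [2, 3], 2: [3]}),
        ],
    )
    def test_p_filter_modes(self, mode, expected):
        # marginal P: rs0 = 0.5, rs1 = 0.05, rs2 = 0.01, rs3 = 0.9
        vmap = _variant_map([1, 1001, 2001, 3001])
        spec = WindowSpec(k=300, d=500_000, p_filter=0.1, p_filter_mode=mode)
        mp = np.array([0.5, 0.05, 0.01, 0.9])
        wins = {i: list(ps) for i, ps in enumerate_windows(vmap, spec, mp)}
        assert wins == expected


def _aligned_pheno(panel, rng, covars=True):
    n = panel.n_samples
    df = pd.DataFrame(
        {
            "sample_id": panel.samples,
            "height": rng.normal(170, 7, n),
            "sex": rng.integers(0, 2, n),
            "age": rng.uniform(45, 90, n),
        }
    )
    return df


class TestScan:
    def test_monomorphic_partner_reduces_to_single_snp_p_exactly(self, rng):
        panel = make_random_panel(rng, 200, 6, missing_rate=0, n_chromosomes=1)
        panel.calls[:, 1] = 0  # partner of rs0 monomorphic
        pheno = _aligned_pheno(panel, rng)
        marginal = run_gwas(panel, pheno, ["sex", "age"])
        spec = WindowSpec(k=1, d=100_000_000, p_filter=1.0)
        scan = gcdh_scan(panel, pheno, ["sex", "age"], spec, marginal=marginal)
        row = scan[scan["index_snp"] == panel.variants["id"].iloc[0]].iloc[0]
        # analytically identical models on identical samples; agreement to
        # float round-off (batched BLAS paths differ in the last ulp)
        assert row["min_p"] == pytest.approx(marginal["p"].iloc[0], rel=1e-12)
        assert row["beta"] == pytest.approx(marginal["beta"].iloc[0], rel=1e-12)

    def test_min_p_matches_exhaustive_bruteforce_oracle(self):
        cohort = simulate_cohort(
            SimulationConfig(n_individuals=500, n_snps=20, n_chromosomes=1, seed=55)
        )
        panel, pheno = cohort.panel, cohort.phenotypes
        names = cohort.covariate_names
        spec = WindowSpec(k=300, d=200_000, p_filter=0.5)
        marginal = run_gwas(panel, pheno, names)
        scan = gcdh_scan(panel, pheno, names, spec, marginal=marginal)

        # independent oracle: statsmodels OLS for every eligible pair
        mp = marginal["p"].to_numpy()
        pos = panel.variants["pos"].to_numpy()
        y = pheno["height"].to_numpy()
        X_cov = pheno[names].to_numpy(float)
        mtx = CollapsingMatrix.additive()
        for _, row in scan.iterrows():
            i = panel.index_of(row["index_snp"])
            best_p, n_tests = np.inf, 0
            for j in range(i + 1, panel.n_variants):
                if pos[j] - pos[i] > spec.d:
                    break
                if n_tests >= spec.k:
                    break
                if not (mp[i] <= 0.5 or mp[j] <= 0.5):
                    continue
                n_tests += 1
                pseudo = np.minimum(panel.calls[:, i] + panel.calls[:, j], 2)
                if np.unique(pseudo).size < 2:
                    continue
                X = sm.add_constant(np.column_stack([pseudo, X_cov]))
                p = sm.OLS(y, X).fit().pvalues[1]
                best_p = min(best_p, p)
            assert row["min_p"] == pytest.approx(best_p, rel=1e-9)

    def test_scan_min_p_dominated_by_every_recomputed_pair(self):
        cohort = simulate_cohort(
            SimulationConfig(n_individuals=400, n_snps=15, n_chromosomes=1, seed=56)
        )
        spec = WindowSpec(k=5, d=10**9, p_filter=1.0)
        scan, pairs = gcdh_scan(
            cohort.panel, cohort.phenotypes, cohort.covariate_names, spec,
            return_pairs=True,
        )
        merged = pairs[pairs["flag"] == ""].merge(
            scan[["index_snp", "min_p"]], on="index_snp"
        )
        assert (merged["min_p"] <= merged["p"] + 1e-15).all()

    def test_planted_trans_pair_is_genomewide_minimum(self, planted_pair_cohort):
        c = planted_pair_cohort
        scan = gcdh_scan(c.panel, c.phenotypes, c.covariate_names, WindowSpec())
        top = scan.loc[scan["min_p"].idxmin()]
        assert top["index_snp"] == c.truth["snp1"].iloc[0]
        assert top["partner_snp"] == c.truth["snp2"].iloc[0]
        assert top["significant"]

    def test_tie_broken_by_smallest_partner_position(self, rng):
        panel = make_random_panel(rng, 100, 4, missing_rate=0, n_chromosomes=1)
        panel.calls[:, 2] = panel.calls[:, 1]  # identical partners -> equal P
        panel.variants.loc[2, ["allele_minor", "allele_major", "maf"]] = (
            panel.variants.loc[1, ["allele_minor", "allele_major", "maf"]]
        )
        pheno = _aligned_pheno(panel, rng)
        spec = WindowSpec(k=300, d=10**9, p_filter=1.0)
        scan = gcdh_scan(panel, pheno, ["sex", "age"], spec)
        row = scan[scan["index_snp"] == panel.variants["id"].iloc[0]].iloc[0]
        assert row["partner_snp"] == panel.variants["id"].iloc[1]

    def test_degenerate_pairs_flagged_and_excluded(self, rng):
        panel = make_random_panel(rng, 100, 3, missing_rate=0, n_chromosomes=1)
        panel.calls[:, 0] = 2  # index SNP constant at 2: additive pseudo constant
        pheno = _aligned_pheno(panel, rng)
        spec = WindowSpec(k=300, d=10**9, p_filter=1.0)
        scan, pairs = gcdh_scan(panel, pheno, ["sex", "age"], spec, return_pairs=True)
        assert (pairs.loc[pairs["index_snp"] == panel.variants["id"].iloc[0], "flag"]
                == "degenerate").all()
        assert panel.variants["id"].iloc[0] not in set(scan["index_snp"])

    def test_threshold_derived_from_alpha_over_k(self):
        assert WindowSpec(k=300).threshold == pytest.approx(5e-8 / 300)
        assert WindowSpec(k=100).threshold == pytest.approx(5e-10)


class TestPermutationNull:
    def test_shuffle_preserves_height_multiset_and_row_tuples(self, rng):
        pheno = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(50)],
                "height": rng.normal(170, 7, 50),
                "sex": rng.integers(0, 2, 50),
                "age": rng.uniform(45, 90, 50),
            }
        )
        shuffled = shuffle_phenotypes(pheno, np.random.default_rng(1))
        assert sorted(shuffled["height"]) == sorted(pheno["height"])
        assert list(shuffled["sample_id"]) == list(pheno["sample_id"])
        orig = {tuple(r) for r in pheno[["height", "sex", "age"]].to_numpy()}
        new = {tuple(r) for r in shuffled[["height", "sex", "age"]].to_numpy()}
        assert orig == new

    def test_replicates_are_seed_deterministic(self):
        cohort = simulate_cohort(
            SimulationConfig(n_individuals=300, n_snps=50, seed=57)
        )
        spec = WindowSpec(k=5, d=10**9, p_filter=1.0)
        mtx = CollapsingMatrix.additive()
        reps1, pooled1 = permutation_null(
            cohort.panel, cohort.phenotypes, cohort.covariate_names, spec, mtx, 2, 9
        )
        reps2, pooled2 = permutation_null(
            cohort.panel, cohort.phenotypes, cohort.covariate_names, spec, mtx, 2, 9
        )
        np.testing.assert_array_equal(pooled1, pooled2)
        for a, b in zip(reps1, reps2):
            pd.testing.assert_frame_equal(a, b)

    def test_scan_rerun_is_byte_identical(self):
        cohort = simulate_cohort(
            SimulationConfig(n_individuals=300, n_snps=60, seed=58)
        )
        spec = WindowSpec(k=10, d=10**9, p_filter=1.0)
        s1 = gcdh_scan(cohort.panel, cohort.phenotypes, cohort.covariate_names, spec)
        s2 = gcdh_scan(cohort.panel, cohort.phenotypes, cohort.covariate_names, spec)
        assert s1.to_csv() == s2.to_csv()
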