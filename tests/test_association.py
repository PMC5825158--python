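import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from herbclock.association import (
    associate,
    chip_heritability,
    double_bonferroni,
    grantham_matrix,
    grantham_score,
    gwa_scan,
    hit_overlap_enrichment,
    kinship_matrix,
    ld_statistics,
    permutation_threshold,
)
from herbclock.io_core import HerbclockError
from herbclock.synthetic_data import SimConfig, simulate_lineage

from conftest import make_variant_table


class TestGrantham:
    @pytest.mark.parametrize("a,b,score", [
        ("C", "W", 215),  # most radical change in the matrix
        ("Y", "S", 144),
        ("A", "P", 27),
        ("P", "A", 27),
        ("A", "G", 60),
        ("A", "A", 0),
    ])
    def test_known_pairs(self, a, b, score):
        assert grantham_score(a, b) == score

    def test_matrix_properties(self):
        M = grantham_matrix().to_numpy()
        assert (M == M.T).all()
        assert (np.diag(M) == 0).all()
        assert M.max() == 215
        assert M.min() == 0
        # max is attained exactly at Cys-Trp
        letters = grantham_matrix().index.tolist()
        i, j = np.unravel_index(M.argmax(), M.shape)
        assert {letters[i], letters[j]} == {"C", "W"}

    def test_range(self):
        M = grantham_matrix().to_numpy()
        off = M[~np.eye(20, dtype=bool)]
        assert off.min() >= 5  # Leu-Ile is the most conservative pair

    def test_unknown_amino_acid(self):
        with pytest.raises(HerbclockError):
            grantham_score("B", "A")

    def test_case_insensitive(self):
        assert grantham_score("c", "w") == 215


class TestKinship:
    def test_duplicated_samples_maximal_entry(self):
        rng = np.random.default_rng(0)
        calls = rng.choice([0, 1], size=(40, 8), p=[0.6, 0.4])
        calls[:, 1] = calls[:, 0]  # samples 0 and 1 are genotype-identical
        v = make_variant_table(calls)
        K = kinship_matrix(v, maf_min=0.05)
        off = K[~np.eye(8, dtype=bool)]
        assert K[0, 1] == pytest.approx(off.max())
        assert K[0, 1] == pytest.approx(K[0, 0], rel=1e-9)

    def test_block_structure(self):
        rng = np.random.default_rng(1)
        S, n = 50, 10
        calls = np.zeros((S, n), dtype=np.int8)
        calls[: S // 2, : n // 2] = rng.choice([0, 1], size=(S // 2, 1), p=[0.5, 0.5])
        calls[S // 2:, n // 2:] = rng.choice([0, 1], size=(S - S // 2, 1), p=[0.5, 0.5])
        v = make_variant_table(calls)
        K = kinship_matrix(v, maf_min=0.05)
        within = np.mean([K[i, j] for i in range(5) for j in range(5) if i != j])
        between = np.mean([K[i, j] for i in range(5) for j in range(5, 10)])
        assert within > between

    def test_no_passing_sites_fatal(self):
        calls = np.zeros((5, 20), dtype=np.int8)
        calls[:, 0] = 1  # all singletons, MAF = 0.05 fails at maf_min=0.2
        v = make_variant_table(calls)
        with pytest.raises(HerbclockError, match="MAF"):
            kinship_matrix(v, maf_min=0.2)

    def test_psd(self):
        rng = np.random.default_rng(2)
        calls = rng.choice([0, 1], size=(40, 15), p=[0.7, 0.3])
        v = make_variant_table(calls)
        K = kinship_matrix(v, maf_min=0.05)
        assert np.linalg.eigvalsh(K).min() > -1e-8


class TestChipHeritability:
    def test_pure_noise_near_zero(self):
        rng = np.random.default_rng(3)
        calls = rng.choice([0, 1], size=(100, 60), p=[0.7, 0.3])
        v = make_variant_table(calls)
        K = kinship_matrix(v, maf_min=0.05)
        h2s = [chip_heritability(rng.normal(size=60), K).h2 for _ in range(10)]
        assert np.median(h2s) < 0.35

    def test_strong_signal_detected(self):
        rng = np.random.default_rng(4)
        calls = rng.choice([0, 1], size=(80, 80), p=[0.6, 0.4])
        v = make_variant_table(calls)
        K = kinship_matrix(v, maf_min=0.05)
        # genetic value from the kinship itself: g ~ N(0, K)
        L = np.linalg.cholesky(K + 1e-8 * np.eye(80))
        g = L @ rng.normal(size=80)
        y = g + 0.3 * rng.normal(size=80)
        res = chip_heritability(y, K)
        assert res.h2 > 0.5
        assert res.lrt_p < 0.05

    def test_too_few_accessions(self):
        with pytest.raises(HerbclockError, match="accessions"):
            chip_heritability(np.zeros(5), np.eye(5))

    def test_h2_bounds(self):
        rng = np.random.default_rng(5)
        calls = rng.choice([0, 1], size=(50, 30), p=[0.6, 0.4])
        v = make_variant_table(calls)
        K = kinship_matrix(v, maf_min=0.05)
        res = chip_heritability(rng.normal(size=30), K)
        assert 0.0 <= res.h2 <= 1.0
        assert res.sigma_g >= 0 and res.sigma_e >= 0


class TestGwaScan:
    def _panel(self, seed=0, n=60, S=120):
        rng = np.random.default_rng(seed)
        calls = rng.choice([0, 1], size=(S, n), p=[0.7, 0.3])
        return make_variant_table(calls), rng

    def test_null_p_uniform(self):
        v, rng = self._panel()
        y = rng.normal(size=60)
        scan = gwa_scan(y, v, maf_min=0.05)
        ks = stats.kstest(scan["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_planted_causal_top_hit(self):
        v, rng = self._panel(seed=1)
        x = v.calls[10].astype(float)
        y = 3.0 * x + 0.1 * rng.normal(size=60)
        scan = gwa_scan(y, v, maf_min=0.05)
        assert scan.loc[scan["p"].idxmin(), "site_index"] == 10

    def test_monomorphic_skipped(self):
        calls = np.vstack([np.zeros((1, 30)), np.random.default_rng(0).choice([0, 1], size=(20, 30))])
        v = make_variant_table(calls)
        scan = gwa_scan(np.random.default_rng(1).normal(size=30), v, maf_min=0.0)
        assert 0 not in scan["site_index"].to_numpy()

    def test_covariate_removes_confounded_signal(self):
        v, rng = self._panel(seed=2)
        conf = rng.normal(size=60)
        # phenotype driven purely by the confounder; genotype 5 correlated with it
        x = (conf > 0).astype(float)
        vv = make_variant_table(np.vstack([v.calls, x[None, :]]))
        y = 2 * conf + 0.5 * rng.normal(size=60)
        raw = gwa_scan(y, vv, maf_min=0.05)
        adj = gwa_scan(y, vv, covariates=conf, maf_min=0.05)
        site = vv.n_sites - 1
        p_raw = raw.loc[raw.site_index == site, "p"].iloc[0]
        p_adj = adj.loc[adj.site_index == site, "p"].iloc[0]
        assert p_adj > p_raw

    def test_length_mismatch(self):
        v, _ = self._panel()
        with pytest.raises(HerbclockError):
            gwa_scan(np.zeros(10), v)


class TestPermutationThreshold:
    def test_zero_perms_error(self):
        v = make_variant_table(np.random.default_rng(0).choice([0, 1], size=(20, 30)))
        with pytest.raises(HerbclockError):
            permutation_threshold(np.zeros(30), v, n_perm=0)

    def test_pooled_calibration(self):
        # on null data ~alpha of sites pass the pooled threshold
        rng = np.random.default_rng(6)
        rates = []
        for rep in range(30):
            calls = rng.choice([0, 1], size=(100, 50), p=[0.6, 0.4])
            v = make_variant_table(calls)
            y = rng.normal(size=50)
            scan = gwa_scan(y, v, maf_min=0.05)
            thr = permutation_threshold(y, v, n_perm=150, seed=rep, maf_min=0.05)
            rates.append((scan["p"] < thr).mean())
        assert abs(np.mean(rates) - 0.05) < 0.02

    def test_minp_stricter_than_pooled(self):
        rng = np.random.default_rng(7)
        calls = rng.choice([0, 1], size=(100, 50), p=[0.6, 0.4])
        v = make_variant_table(calls)
        y = rng.normal(size=50)
        pooled = permutation_threshold(y, v, n_perm=200, seed=0, mode="pooled")
        minp = permutation_threshold(y, v, n_perm=200, seed=0, mode="minp")
        assert minp < pooled


class TestDoubleBonferroni:
    def test_reference_arithmetic(self):
        assert double_bonferroni(0.05, 391, 109) == pytest.approx(1e-4)

    def test_plain_bonferroni(self):
        assert double_bonferroni(0.05, 100, 0) == pytest.approx(5e-4)

    def test_single_test(self):
        assert double_bonferroni(0.05, 1, 0) == 0.05

    def test_validation(self):
        with pytest.raises(HerbclockError):
            double_bonferroni(0.05, 0, 0)


def brute_force_ld(x1, x2):
    ok = (x1 >= 0) & (x2 >= 0)
    h = list(zip(x1[ok], x2[ok]))
    n = len(h)
    pAB = sum(1 for a, b in h if a == 1 and b == 1) / n
    pA = sum(1 for a, _ in h if a == 1) / n
    pB = sum(1 for _, b in h if b == 1) / n
    D = pAB - pA * pB
    r2 = D**2 / (pA * (1 - pA) * pB * (1 - pB))
    dmax = min(pA * (1 - pB), (1 - pA) * pB) if D >= 0 else min(pA * pB, (1 - pA) * (1 - pB))
    return D, D / dmax, r2


class TestLdStatistics:
    def test_perfect_linkage(self):
        col = np.array([1, 1, 1, 0, 0, 0, 1, 0])
        v = make_variant_table(np.vstack([col, col]))
        out = ld_statistics(v)
        assert out["r2"][0, 1] == pytest.approx(1.0)
        assert out["Dprime"][0, 1] == pytest.approx(1.0)

    def test_independent_sites_low_r2(self):
        rng = np.random.default_rng(8)
        a = rng.choice([0, 1], size=500)
        b = rng.choice([0, 1], size=500)
        v = make_variant_table(np.vstack([a, b]))
        out = ld_statistics(v)
        assert out["r2"][0, 1] < 0.02

    def test_worked_fixture_matches_brute_force(self):
        x1 = np.array([1, 1, 1, 0, 0, 1, 0, 0])
        x2 = np.array([1, 0, 1, 0, 1, 1, 0, 0])
        v = make_variant_table(np.vstack([x1, x2]))
        out = ld_statistics(v)
        D, dp, r2 = brute_force_ld(x1, x2)
        assert out["D"][0, 1] == pytest.approx(D)
        assert out["Dprime"][0, 1] == pytest.approx(dp)
        assert out["r2"][0, 1] == pytest.approx(r2)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_bounds_property(self, seed):
        rng = np.random.default_rng(seed)
        calls = rng.choice([0, 1], size=(3, 20))
        # ensure polymorphism
        calls[:, 0] = 0
        calls[:, 1] = 1
        v = make_variant_table(calls)
        out = ld_statistics(v)
        r2 = out["r2"][np.isfinite(out["r2"])]
        dp = out["Dprime"][np.isfinite(out["Dprime"])]
        assert ((r2 >= -1e-12) & (r2 <= 1 + 1e-12)).all()
        assert (np.abs(dp) <= 1 + 1e-9).all()

    def test_r2_equals_dprime_sq_at_half_frequency(self):
        x1 = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        x2 = np.array([1, 1, 1, 0, 1, 0, 0, 0])
        v = make_variant_table(np.vstack([x1, x2]))
        out = ld_statistics(v)
        assert out["r2"][0, 1] == pytest.approx(out["Dprime"][0, 1] ** 2)

    def test_monomorphic_nan(self):
        v = make_variant_table(np.vstack([np.ones(10), np.random.default_rng(0).choice([0, 1], 10)]))
        out = ld_statistics(v)
        assert np.isnan(out["r2"][0, 1])

    def test_partner_counts(self):
        col = np.array([1, 1, 0, 0, 1, 0])
        v = make_variant_table(np.vstack([col, col, 1 - col]))
        out = ld_statistics(v)
        assert (out["partners"] == 2).all()  # every site in perfect LD with the other two


class TestHitOverlap:
    def test_identical_sets(self):
        r = hit_overlap_enrichment({1, 2, 3}, {1, 2, 3}, universe=100)
        assert r.odds_ratio > 100
        assert r.p_value < 1e-4

    def test_disjoint_sets(self):
        r = hit_overlap_enrichment({1, 2, 3}, {4, 5, 6}, universe=1000)
        assert r.p_value > 0.5

    def test_planted_overlap(self):
        r = hit_overlap_enrichment(set(range(20)), set(range(10, 30)), universe=500)
        assert r.odds_ratio > 1
        assert r.p_value < 0.01

    def test_empty_universe(self):
        with pytest.raises(HerbclockError):
            hit_overlap_enrichment({1}, {1}, universe=0)


class TestAssociate:
    def test_end_to_end_flags(self):
        rng = np.random.default_rng(9)
        calls = rng.choice([0, 1], size=(80, 60), p=[0.6, 0.4])
        v = make_variant_table(calls)
        x = v.calls[7].astype(float)
        y = 2.5 * x + 0.3 * rng.normal(size=60)
        res = associate(y, v, n_perm=150, n_phenos=3, seed=0)
        hit = res[res.site_index == 7].iloc[0]
        assert hit["passes_permutation"]
        assert hit["passes_double_bonferroni"]
        assert (res["empirical_p"] >= 1 / (150 * len(res) + 1)).all()
        assert (res["empirical_p"] <= 1.0).all()
        assert res.attrs["bonferroni_threshold"] == pytest.approx(0.05 / (len(res) + 3))
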