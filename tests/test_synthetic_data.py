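import numpy as np
import pytest
from scipy import stats

from herbclock.io_core import MISSING, HerbclockError
from herbclock.synthetic_data import (
    SimConfig,
    historical_sampling_years,
    simulate_climate,
    simulate_lineage,
    simulate_ma_lines,
    simulate_phenotypes,
)


def star_config(**kw):
    base = dict(
        seed=0,
        sample_years=[(2000, "modern"), (1990, "modern"), (1900, "herbarium")],
        founder_year=1800,
        mu_per_site_year=1e-7,
        accessible_length={"intergenic": 1e6},
        genealogy="star",
    )
    base.update(kw)
    return SimConfig(**base)


class TestSimulateLineage:
    def test_mu_zero_no_sites(self):
        v, meta, truth = simulate_lineage(star_config(mu_per_site_year=0.0))
        assert v.n_sites == 0

    def test_star_poisson_mean(self):
        # one sample 100 years from founder, mu*L*t = 1e-8 * 1e7 * 100 = 10
        counts = []
        for seed in range(1000):
            cfg = SimConfig(seed=seed, sample_years=[(1700, "modern")], founder_year=1600,
                            mu_per_site_year=1e-8, accessible_length={"intergenic": 1e7},
                            genealogy="star")
            v, _, _ = simulate_lineage(cfg)
            counts.append(v.n_sites)
        mean = np.mean(counts)
        # central 99% interval for the mean of 1000 Poisson(10) draws
        se = np.sqrt(10 / 1000)
        assert 10 - 2.58 * se < mean < 10 + 2.58 * se

    def test_deterministic_same_seed(self):
        v1, m1, _ = simulate_lineage(star_config(seed=42))
        v2, m2, _ = simulate_lineage(star_config(seed=42))
        assert (v1.calls == v2.calls).all()
        assert (v1.sites["pos"] == v2.sites["pos"]).all()
        assert m1 == m2

    def test_different_seeds_differ(self):
        v1, _, _ = simulate_lineage(star_config(seed=1))
        v2, _, _ = simulate_lineage(star_config(seed=2))
        assert v1.n_sites != v2.n_sites or not np.array_equal(
            v1.sites["pos"].to_numpy(), v2.sites["pos"].to_numpy()
        )

    def test_per_class_counts_proportional_to_length(self):
        # no selection: chi-square GOF of class counts vs class lengths
        lengths = {"coding": 3e5, "intronic": 1e5, "intergenic": 6e5}
        observed = {c: 0 for c in lengths}
        for seed in range(5):
            cfg = star_config(seed=seed, accessible_length=lengths,
                              mu_per_site_year=2e-7)
            v, _, truth = simulate_lineage(cfg)
            for c, k in truth.per_class_counts.items():
                observed[c] += k
        total = sum(observed.values())
        expected = np.array([lengths[c] for c in observed]) / 1e6 * total
        chi2 = ((np.array(list(observed.values())) - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=2) > 0.001

    def test_selection_thinning_depletes_coding(self):
        from herbclock.selection import annotation_depletion_test

        lengths = {"coding": 5e5, "intergenic": 5e5}
        cfg = star_config(accessible_length=lengths, mu_per_site_year=5e-7,
                          selection_coding=0.5)
        v, _, _ = simulate_lineage(cfg)
        r = annotation_depletion_test(v, "coding", "intergenic")
        assert r.odds_ratio < 1

    def test_era_missingness(self):
        cfg = star_config(missing_rate_herbarium=0.3, missing_rate_modern=0.0,
                          mu_per_site_year=5e-7)
        v, meta, _ = simulate_lineage(cfg)
        herb_col = [i for i, m in enumerate(meta) if m.era == "herbarium"]
        mod_col = [i for i, m in enumerate(meta) if m.era == "modern"]
        herb_missing = (v.calls[:, herb_col] == MISSING).mean()
        mod_missing = (v.calls[:, mod_col] == MISSING).mean()
        assert mod_missing == 0.0
        assert 0.2 < herb_missing < 0.4

    def test_sites_sorted_and_callable(self):
        v, _, _ = simulate_lineage(star_config(mu_per_site_year=5e-7))
        pos = v.sites["pos"].to_numpy()
        assert (np.diff(pos) > 0).all()
        assert ((v.calls != MISSING).sum(axis=1) >= 1).all()

    def test_mutation_cap(self):
        cfg = star_config(mu_per_site_year=1.0, accessible_length={"intergenic": 1e9})
        with pytest.raises(HerbclockError, match="cap"):
            simulate_lineage(cfg)

    def test_founder_year_validation(self):
        with pytest.raises(HerbclockError, match="founder_year"):
            SimConfig(sample_years=[(1700, "modern")], founder_year=1800)

    def test_coalescent_colonization_regime(self):
        from herbclock.diversity import tajimas_d
        from herbclock.lineage_qc import four_gamete_screen

        cfg = SimConfig(seed=11, sample_years=historical_sampling_years(), founder_year=1600,
                        mu_per_site_year=2.11e-9,
                        accessible_length={"intergenic": 1.08e8},
                        genealogy="coalescent", growth_rate=10)
        v, meta, _ = simulate_lineage(cfg)
        assert 2000 < v.n_sites < 12000  # "thousands of segregating sites"
        assert tajimas_d(v) < -1.5
        n_bad, _ = four_gamete_screen(v)
        assert n_bad == 0  # no recombination in a clonal genealogy

    def test_forward_wf_runs(self):
        cfg = SimConfig(seed=3, sample_years=[(1900, "herbarium"), (1950, "modern"),
                                              (2000, "modern")],
                        founder_year=1850, mu_per_site_year=2e-7,
                        accessible_length={"coding": 5e5, "intergenic": 5e5},
                        genealogy="forward_wf", wf_pop_size=30,
                        selection_coding=0.8)
        v, meta, truth = simulate_lineage(cfg)
        assert v.n_samples == 3
        assert set(np.unique(v.calls)) <= {0, 1}


class TestSimulatePhenotypes:
    def _sim(self, **kw):
        # coalescent mode: shared branches create the common variants that
        # the MAF filter needs (star trees yield only singletons)
        cfg = star_config(
            seed=8, mu_per_site_year=2e-6, genealogy="coalescent", growth_rate=3,
            sample_years=[(2000, "modern")] * 40 + [(1900, "herbarium")] * 10,
            **kw,
        )
        return simulate_lineage(cfg), cfg

    def test_h2_zero_independent(self):
        (v, meta, _), cfg = self._sim(target_h2=0.0)
        pheno, truth = simulate_phenotypes(v, cfg)
        assert truth.realized_h2 == 0.0
        assert truth.causal_sites == []

    def test_realized_h2_matches_target(self):
        (v, meta, _), cfg = self._sim(target_h2=0.6, n_causal=5)
        pheno, truth = simulate_phenotypes(v, cfg)
        assert truth.realized_h2 == pytest.approx(0.6, abs=0.02)
        assert len(truth.causal_sites) == 5

    def test_single_causal_large_effect_top_hit(self):
        from herbclock.association import gwa_scan

        (v, meta, _), cfg = self._sim(target_h2=0.999, n_causal=1)
        pheno, truth = simulate_phenotypes(v, cfg)
        y = pheno.accession_means("trait1").loc[v.samples].to_numpy()
        scan = gwa_scan(y, v, maf_min=0.05)
        # perfect-LD partners (same-branch mutations) tie with the causal site
        p_causal = scan.loc[scan.site_index == truth.causal_sites[0], "p"].iloc[0]
        assert p_causal <= scan["p"].min() * 1.05

    def test_too_few_common_sites_fatal(self):
        (v, meta, _), cfg = self._sim(target_h2=0.5, n_causal=10**6)
        with pytest.raises(HerbclockError, match="MAF"):
            simulate_phenotypes(v, cfg)

    def test_replicates_emitted(self):
        (v, meta, _), cfg = self._sim(target_h2=0.5, n_replicates=4,
                                      replicate_noise_sd=0.1)
        pheno, _ = simulate_phenotypes(v, cfg)
        assert set(pheno.data["replicate"]) == {0, 1, 2, 3}


class TestMaLines:
    def test_mu_zero(self):
        assert (simulate_ma_lines(5, 10, 0.0, 1000, seed=0) == 0).all()

    def test_poisson_mean(self):
        # 12 lines, mu_g * G * L = 7.1e-9 * 30 * 1e8 = 21.3 per line
        means = [simulate_ma_lines(12, 30, 7.1e-9, 10**8, seed=s).mean()
                 for s in range(50)]
        grand = np.mean(means)
        se = np.sqrt(21.3 / (12 * 50))
        assert abs(grand - 21.3) < 3.5 * se

    def test_single_site_single_generation(self):
        counts = simulate_ma_lines(200, 1, 1e-3, 1, seed=1)
        assert set(np.unique(counts)) <= {0, 1}

    def test_validation(self):
        with pytest.raises(HerbclockError):
            simulate_ma_lines(0, 10, 1e-9, 100, seed=0)


class TestClimate:
    def _base(self):
        cfg = star_config(seed=5, mu_per_site_year=2e-6, genealogy="coalescent",
                          growth_rate=3, sample_years=[(2000, "modern")] * 50)
        return simulate_lineage(cfg)

    def test_coupling_zero_independent_given_latlon(self):
        v, meta, _ = self._base()
        df = simulate_climate(meta, v, coupling=0.0, seed=0)
        focal = int(df["focal_site"].iloc[0])
        x = v.calls[focal].astype(float)
        # residualize climate on lat/lon, then correlate with the focal genotype
        C = np.column_stack([np.ones(len(df)), df["latitude"], df["longitude"]])
        resid = df["climate"] - C @ np.linalg.lstsq(C, df["climate"], rcond=None)[0]
        r = np.corrcoef(x, resid)[0, 1]
        assert abs(r) < 0.35

    def test_coupling_one_recovers_driver(self):
        from herbclock.association import gwa_scan

        v, meta, _ = self._base()
        df = simulate_climate(meta, v, coupling=1.0, seed=0, noise_sd=1e-6)
        scan = gwa_scan(df["climate"].to_numpy(), v, maf_min=0.05)
        focal = int(df["focal_site"].iloc[0])
        p_focal = scan.loc[scan.site_index == focal, "p"].iloc[0]
        assert p_focal <= scan["p"].min() * 1.05

    def test_bad_coupling(self):
        v, meta, _ = self._base()
        with pytest.raises(HerbclockError):
            simulate_climate(meta, v, coupling=1.5, seed=0)
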