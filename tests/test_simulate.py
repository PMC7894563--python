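import numpy as np
import pandas as pd
import pytest

from phenomatch.params import SimulationParams
from phenomatch.simulate import (draw_year_effects, simulate_breeding,
                                 simulate_dataset, simulate_diet,
                                 simulate_phenology, simulate_sst)
from phenomatch.transforms import inv_logit_offset


class TestSST:
    def test_noise_free_series_is_constant(self):
        p = SimulationParams(sst_trend=0.0, sst_sd=0.0)
        sst = simulate_sst(p, seed=1)
        assert np.allclose(sst["sst"], p.sst_mean)

    def test_prev_column_is_lag(self):
        sst = simulate_sst(SimulationParams(), seed=2)
        assert np.allclose(sst["sst_prev"].to_numpy()[1:],
                           sst["sst"].to_numpy()[:-1])

    def test_nonstationary_phi_rejected(self):
        with pytest.raises(ValueError, match="phi"):
            simulate_sst(SimulationParams(sst_ar_phi=1.0), seed=1)

    def test_lag1_autocorrelation_matches_phi(self):
        # long detrended series: empirical ACF is the independent oracle
        p = SimulationParams(n_years=10_000, sst_trend=0.0, gap_years=())
        x = simulate_sst(p, seed=42)["sst"].to_numpy()
        x = x - x.mean()
        acf1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert acf1 == pytest.approx(0.27, abs=0.02)


class TestPhenology:
    def test_deterministic_annual_means_equal_intercept(self):
        p = SimulationParams(laydate_trend=0.0, laydate_sst_slope=0.0,
                             laydate_year_sd=0.0, laydate_within_sd=0.0)
        phen = simulate_phenology(p, simulate_sst(p, 1), seed=3)
        means = phen.groupby("year")["lay_date"].mean()
        assert np.allclose(means, p.laydate_intercept)

    def test_within_year_centring_identity(self):
        p = SimulationParams()
        phen = simulate_phenology(p, simulate_sst(p, 1), seed=4)
        rel = phen["lay_date"] - phen.groupby("year")["lay_date"] \
            .transform("mean")
        assert np.allclose(rel.groupby(phen["year"]).sum(), 0.0, atol=1e-8)

    def test_gap_years_dropped(self):
        p = SimulationParams(gap_years=(1993, 2003))
        phen = simulate_phenology(p, simulate_sst(p, 1), seed=5)
        assert not set(phen["year"]) & {1993, 2003}
        assert phen["year"].nunique() == p.n_years - 2

    def test_nest_counts_in_range(self):
        p = SimulationParams(nests_per_year=(35, 266))
        phen = simulate_phenology(p, simulate_sst(p, 1), seed=6)
        counts = phen.groupby("year").size()
        assert counts.between(35, 266).all()

    def test_trend_recovered_across_seeds(self):
        # GLS slope across 60 seeds; the simulation is the oracle
        from phenomatch.trends import fit_gls_ar1
        # decouple the SST-mediated drift so the direct trend is isolated
        p = SimulationParams(sst_trend=0.0)
        slopes = []
        for s in range(60):
            phen = simulate_phenology(p, simulate_sst(p, 900 + s),
                                      seed=1900 + s)
            annual = phen.groupby("year")["lay_date"].mean()
            slopes.append(fit_gls_ar1(annual.index.to_numpy(float),
                                      annual.to_numpy()).slope)
        slopes = np.asarray(slopes)
        mcse = slopes.std(ddof=1) / np.sqrt(slopes.size)
        assert abs(slopes.mean() - (-0.94)) < 2 * mcse + 0.05


class TestBreeding:
    def test_support_and_reproducibility(self):
        p = SimulationParams(n_years=5, nests_per_year=(20, 30),
                             gap_years=())
        phen = simulate_phenology(p, simulate_sst(p, 1), seed=7)
        b1 = simulate_breeding(phen, p, seed=8)
        b2 = simulate_breeding(phen, p, seed=8)
        pd.testing.assert_frame_equal(b1, b2)
        assert b1["n_fledged"].between(0, 4).all()

    def test_null_model_symmetric_around_two(self):
        p = SimulationParams(n_years=4, nests_per_year=(4000, 4000),
                             gap_years=(), mu=0.0, beta_B=0.0, beta_W=0.0,
                             gamma=0.0, sigma2_int=0.0, sigma2_slope=0.0,
                             cov_BSh_BSa=0.0, cov_WSh_WSa=0.0)
        phen = simulate_phenology(p, simulate_sst(p, 1), seed=9)
        b = simulate_breeding(phen, p, seed=10)
        assert b["n_fledged"].mean() == pytest.approx(2.0, abs=0.05)

    def test_non_psd_cross_cov_rejected(self):
        bad = np.eye(4)
        bad[0, 1] = bad[1, 0] = 5.0
        with pytest.raises(ValueError, match="cross_cov"):
            SimulationParams(cross_cov=bad)


class TestDiet:
    def test_degenerate_proportions_constant(self):
        p = SimulationParams(n_years=5, gap_years=(),
                             diet_within_slope=0.0, diet_sigma2_int=0.0,
                             diet_sigma2_slope=0.0, diet_resid_sd=0.0,
                             cov_BSh_BSa=0.0, cov_WSh_WSa=0.0)
        phen = simulate_phenology(p, simulate_sst(p, 1), seed=11)
        diet = simulate_diet(phen, p, seed=12)
        assert np.allclose(diet["prop_oneplus"],
                           inv_logit_offset(p.diet_mu))

    def test_proportions_in_unit_interval(self):
        p = SimulationParams(n_years=6, gap_years=())
        phen = simulate_phenology(p, simulate_sst(p, 1), seed=13)
        diet = simulate_diet(phen, p, seed=14)
        assert diet["prop_oneplus"].between(0, 1).all()

    def test_collection_dates_track_lay_dates(self):
        from phenomatch.trends import pearson_ci
        p = SimulationParams()
        phen = simulate_phenology(p, simulate_sst(p, 1), seed=15)
        diet = simulate_diet(phen, p, seed=16)
        med = phen.groupby("year")["lay_date"].median()
        med_s = diet.groupby("year")["sample_date"].median()
        r = pearson_ci(med.to_numpy(float), med_s.to_numpy(float)).r
        assert r > 0.6


class TestDataset:
    def test_shared_year_effects_and_truth_roundtrip(self, tmp_path):
        from phenomatch.params import GroundTruth
        p = SimulationParams(n_years=6, nests_per_year=(10, 15),
                             gap_years=())
        data = simulate_dataset(p, seed=21, outdir=tmp_path)
        truth = GroundTruth.from_json(tmp_path / "truth.json")
        assert truth.year_effects.shape == (6, 4)
        np.testing.assert_allclose(truth.year_effects,
                                   data["truth"].year_effects)
        assert (tmp_path / "breeding.csv").exists()
        assert (tmp_path / "env.csv").exists()

    def test_byte_identical_given_seed(self, tmp_path):
        p = SimulationParams(n_years=5, nests_per_year=(10, 12),
                             gap_years=())
        simulate_dataset(p, seed=33, outdir=tmp_path / "a")
        simulate_dataset(p, seed=33, outdir=tmp_path / "b")
        for name in ("breeding.csv", "env.csv", "diet.csv", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_year_effects_deterministic(self):
        p = SimulationParams()
        years = p.kept_years()
        a = draw_year_effects(p, years, 5)
        b = draw_year_effects(p, years, 5)
        np.testing.assert_array_equal(a, b)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            SimulationParams(n_years=2)
        with pytest.raises(ValueError):
            SimulationParams(nests_per_year=(0, 5))
        with pytest.raises(ValueError):
            SimulationParams(samples_per_year=(0, 5))
        with pytest.raises(ValueError):
            SimulationParams(sigma2_int=-1.0)
        with pytest.raises(ValueError):
            SimulationParams(rho_int_slope=1.5)
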