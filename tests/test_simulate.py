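import numpy as np
import pytest

import uavpheno as u
from uavpheno.simulate import (LEAF_TEMPLATE, SOIL_SPECTRUM, TRAITS,
                               leaf_reflectance)


class TestGenotypeEffects:
    def test_zero_variance_gives_exactly_zero_effects(self, gconf):
        cfg = u.GeneticConfig(
            traits=gconf.traits, mean=gconf.mean,
            sigma2_g={t: 0.0 for t in gconf.traits},
            sigma2_e=gconf.sigma2_e, genetic_corr=gconf.genetic_corr)
        eff = u.simulate_genotype_effects(cfg, 50, seed=1)
        assert np.all(eff == 0.0)

    def test_same_seed_reproduces_effects(self, gconf):
        a = u.simulate_genotype_effects(gconf, 100, seed=7)
        b = u.simulate_genotype_effects(gconf, 100, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_large_sample_variance_matches_configured(self, gconf):
        cfg = u.GeneticConfig(
            traits=("a", "b"), mean={"a": 0, "b": 0},
            sigma2_g={"a": 4.0, "b": 1.0},
            sigma2_e={"a": 1.0, "b": 1.0},
            genetic_corr=np.array([[1.0, 0.5], [0.5, 1.0]]))
        eff = u.simulate_genotype_effects(cfg, 10000, seed=3)
        assert eff[:, 0].var() == pytest.approx(4.0, rel=0.05)

    def test_realized_covariance_converges(self, gconf):
        eff = u.simulate_genotype_effects(gconf, 5000, seed=11)
        sd = np.sqrt([gconf.sigma2_g[t] for t in gconf.traits])
        target = gconf.genetic_corr * np.outer(sd, sd)
        realized = np.cov(eff, rowvar=False)
        np.testing.assert_allclose(realized, target, rtol=0.06, atol=0.02)

    def test_non_psd_correlation_rejected_naming_eigenvalue(self, gconf):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9],
                        [-0.9, 0.9, 1.0]])
        with pytest.raises(ValueError, match="eigenvalue"):
            u.GeneticConfig(
                traits=("a", "b", "c"), mean={t: 0 for t in "abc"},
                sigma2_g={t: 1.0 for t in "abc"},
                sigma2_e={t: 1.0 for t in "abc"}, genetic_corr=bad)


class TestSimulateTrial:
    def test_deterministic_config_returns_mu_everywhere(self, gconf):
        cfg = u.GeneticConfig(
            traits=("GY",), mean={"GY": 5000.0}, sigma2_g={"GY": 0.0},
            sigma2_e={"GY": 0.0}, genetic_corr=np.eye(1),
            rep_effect_scale=0.0)
        plots = u.simulate_trial(u.TrialDesign("T", 5, 3), cfg, seed=1)
        assert all(p.traits["GY"] == 5000.0 for p in plots)

    def test_study_scale_yields_220_records(self, gconf):
        plots = (u.simulate_trial(u.TrialDesign("CVT1", 25, 4), gconf, 1)
                 + u.simulate_trial(u.TrialDesign("CVT2", 30, 4), gconf, 2))
        assert len(plots) == 220

    def test_balanced_design_every_pair_once(self, gconf):
        plots = u.simulate_trial(u.TrialDesign("T", 7, 3), gconf, 5)
        pairs = {(p.genotype_id, p.replicate) for p in plots}
        assert len(plots) == 21 and len(pairs) == 21

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            u.TrialDesign("T", 10, 1)

    def test_trait_values_respect_physical_ranges(self, gconf):
        plots = u.simulate_trial(u.TrialDesign("T", 50, 4), gconf, 9)
        for p in plots:
            assert 0.0 <= p.traits["fAPAR"] <= 1.0
            assert 0.0 <= p.traits["fCover"] <= 1.0
            assert p.traits["GY"] >= 0 and p.traits["LAI"] >= 0

    def test_heavy_clipping_warns(self, gconf):
        cfg = u.GeneticConfig(
            traits=("fCover",), mean={"fCover": 0.95},
            sigma2_g={"fCover": 0.2}, sigma2_e={"fCover": 0.2},
            genetic_corr=np.eye(1))
        with pytest.warns(UserWarning, match="clipped"):
            u.simulate_trial(u.TrialDesign("T", 50, 4), cfg, 3)

    def test_entry_mean_h2_recovered_downstream(self, gconf):
        """Monte-Carlo oracle: configured H2=0.8 recovered within 0.05."""
        cfg = u.GeneticConfig(
            traits=("y",), mean={"y": 100.0}, sigma2_g={"y": 4.0},
            sigma2_e={"y": 4.0}, genetic_corr=np.eye(1))
        # sigma2_g/(sigma2_g + sigma2_e/4) = 4/5 = 0.8 by construction
        h2s = []
        for rep in range(200):
            plots = u.simulate_trial(u.TrialDesign("T", 200, 4), cfg, rep)
            df = u.plots_to_frame(plots)
            obs = u.TraitObservations.from_frame(df, "y")
            h2s.append(u.heritability(u.fit_one_way_mixed(obs)).entry_mean)
        assert np.mean(h2s) == pytest.approx(0.8, abs=0.05)


class TestForwardReflectance:
    def _plot(self, **traits):
        return u.PlotRecord("T-001-r1", "T", "T-G001", 1, traits)

    def test_zero_cover_returns_soil_spectrum(self):
        p = self._plot(LAI=0.0, fCover=0.0, LCC=400.0)
        (s,) = u.forward_reflectance([p], "P4M", noise_sd=0.0)
        for band in u.P4M.bands:
            assert s.reflectance[band.center_nm] == pytest.approx(
                SOIL_SPECTRUM[band.name])

    def test_full_cover_returns_leaf_template(self):
        p = self._plot(LAI=6.0, fCover=1.0, LCC=400.0)
        (s,) = u.forward_reflectance([p], "P4M", noise_sd=0.0)
        for band in u.P4M.bands:
            assert s.reflectance[band.center_nm] == pytest.approx(
                LEAF_TEMPLATE[band.name])

    def test_half_cover_mixes_linearly(self):
        p = self._plot(LAI=2.0, fCover=0.5, LCC=400.0)
        soil = {name: 0.30 for name in SOIL_SPECTRUM}
        (s,) = u.forward_reflectance([p], "P4M", soil_spectrum=soil,
                                     noise_sd=0.0)
        # NIR: 0.5*0.50 + 0.5*0.30 = 0.40
        assert s.reflectance[840.0] == pytest.approx(0.40)

    def test_red_reflectance_decreases_with_chlorophyll(self):
        lccs = [250.0, 350.0, 450.0]
        reds = [leaf_reflectance("R", c) for c in lccs]
        assert reds == sorted(reds, reverse=True)

    def test_nir_increases_with_cover_when_leaf_brighter_than_soil(self):
        vals = []
        for fc in (0.2, 0.5, 0.8):
            (s,) = u.forward_reflectance(
                [self._plot(LAI=2.0, fCover=fc, LCC=400.0)], "P4M",
                noise_sd=0.0)
            vals.append(s.reflectance[840.0])
        assert vals == sorted(vals)

    def test_missing_trait_error_names_plot(self):
        p = u.PlotRecord("T-007-r1", "T", "G", 1, {"LAI": 2.0})
        with pytest.raises(ValueError, match="T-007-r1"):
            u.forward_reflectance([p], "P4M")

    def test_fcover_derived_from_lai_when_absent(self):
        p = u.PlotRecord("T-001-r1", "T", "G", 1, {"LAI": 2.0, "LCC": 400.0})
        (s,) = u.forward_reflectance([p], "P4M", noise_sd=0.0)
        fc = 1.0 - np.exp(-0.5 * 2.0)
        expect = fc * LEAF_TEMPLATE["NIR"] + (1 - fc) * SOIL_SPECTRUM["NIR"]
        assert s.reflectance[840.0] == pytest.approx(expect)


class TestSoilSamples:
    def test_zero_samples_empty(self):
        assert u.make_soil_samples(0, "PS") == []

    def test_noise_free_samples_identical_to_spectrum(self):
        samples = u.make_soil_samples(10, "P4M", noise_sd=0.0)
        for s in samples:
            assert s.is_soil and s.plot_id is None
            for band in u.P4M.bands:
                assert s.reflectance[band.center_nm] == pytest.approx(
                    SOIL_SPECTRUM[band.name])

    def test_noise_sd_realized(self):
        samples = u.make_soil_samples(1000, "P4M", noise_sd=0.01, seed=5)
        nir = np.array([s.reflectance[840.0] for s in samples])
        assert np.std(nir) == pytest.approx(0.01, rel=0.15)


class TestGroundNdvi:
    def _sample(self, refl):
        return u.SpectralSample("s", "p", "PS", "M1", refl)

    def test_equal_bands_give_zero(self):
        assert u.emulate_ground_ndvi(
            self._sample({660.0: 0.2, 790.0: 0.2})) == 0.0

    def test_hand_example(self):
        assert u.emulate_ground_ndvi(
            self._sample({660.0: 0.1, 790.0: 0.4})) == pytest.approx(0.6)

    def test_zero_red_boundary(self):
        assert u.emulate_ground_ndvi(
            self._sample({660.0: 0.0, 790.0: 0.3})) == 1.0

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            u.emulate_ground_ndvi(self._sample({660.0: 0.0, 790.0: 0.0}))


def test_fapar_follows_fcover_convention(gconf):
    plots = u.simulate_trial(u.TrialDesign("T", 60, 4), gconf, 21)
    fap = np.array([p.traits["fAPAR"] for p in plots])
    fcv = np.array([p.traits["fCover"] for p in plots])
    resid = fap - np.clip(0.95 * fcv, None, 1.0)
    assert np.abs(resid).mean() < 0.02  # slope 0.95 plus small noise


def test_full_determinism_under_fixed_seed(gconf):
    a = u.simulate_trial(u.TrialDesign("T", 10, 4), gconf, 13)
    b = u.simulate_trial(u.TrialDesign("T", 10, 4), gconf, 13)
    assert [p.traits for p in a] == [p.traits for p in b]
    sa = u.forward_reflectance(a, "PS", noise_sd=0.01, seed=2)
    sb = u.forward_reflectance(b, "PS", noise_sd=0.01, seed=2)
    assert [s.reflectance for s in sa] == [s.reflectance for s in sb]


def test_trait_list_covers_study_traits(gconf):
    assert set(TRAITS) == {"GY", "LAI", "fAPAR", "fCover", "LCC", "NDVI"}
    assert set(gconf.traits) == set(TRAITS)
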