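"""Synthetic survey generator: cover field, responses, specimens, determinism."""
import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from noduleco import qc_filter
from noduleco.simulate import (ConfigError, CoverField, ResponseCurve,
                               SimulationConfig, preset_config,
                               response_density, simulate_cover_field,
                               simulate_specimens, simulate_survey,
                               ground_truth_table, default_species_pool, _sp)

from conftest import make_image


class TestCoverField:
    def test_degenerate_full_zero_inflation(self, rng):
        f = CoverField(rho=0.0, zero_inflation=1.0)
        assert (simulate_cover_field(f, 50, rng) == 0.0).all()

    def test_log_scale_autocorrelation(self, rng):
        f = CoverField(median_pct=5.0, log_sd=0.8, rho=0.9,
                       zero_inflation=0.0, cap_pct=100.0)
        c = simulate_cover_field(f, 2000, rng)
        x = np.log(c)
        r = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r - 0.9) < 0.05

    def test_default_calibration_mean_and_max(self):
        # pooled over the three landscape fields at survey scale
        cfg = SimulationConfig()
        rng = np.random.default_rng(3)
        chunks = [simulate_cover_field(f, 3400, rng)
                  for f in cfg.cover.values()]
        c = np.concatenate(chunks)
        assert 5.0 <= c.mean() <= 8.0
        assert c.max() <= 37.0

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            CoverField(rho=1.0)
        with pytest.raises(ConfigError):
            CoverField(zero_inflation=1.5)


class TestResponseCurves:
    def test_flat_constant(self):
        curve = ResponseCurve("flat", {"d0": 0.4})
        assert response_density(curve, 0.0) == 0.4
        assert response_density(curve, 87.0) == 0.4

    def test_saturating_worked_values(self):
        curve = ResponseCurve("saturating", {"d0": 0.2, "dmax": 0.3, "h": 1.5})
        assert response_density(curve, 1.0) == pytest.approx(0.32)
        assert response_density(curve, 3.0) == pytest.approx(0.4)

    def test_unimodal_maximum_at_optimum(self):
        curve = ResponseCurve("unimodal", {"A": 0.1, "mu": 5.0, "sigma": 2.0})
        assert response_density(curve, 5.0) == pytest.approx(0.1)
        c = np.linspace(0, 100, 500)
        assert response_density(curve, c).max() <= 0.1 + 1e-12

    def test_nonnegative_everywhere(self):
        c = np.linspace(0.0, 100.0, 300)
        for spec in default_species_pool():
            assert (response_density(spec.response, c) >= 0).all()

    def test_missing_param_rejected(self):
        with pytest.raises(ConfigError):
            ResponseCurve("saturating", {"d0": 0.2})


class TestSpecimens:
    def test_all_flat_zero_gives_no_specimens(self, rng):
        image = make_image(0, 5.0)
        pool = [_sp("a-msp1", "metazoan", "NA", "suspension",
                    "flat", {"d0": 0.0})]
        assert simulate_specimens(image, pool, rng) == []

    def test_poisson_mean_matches_area_times_density(self, rng):
        pool = [_sp("a-msp1", "metazoan", "NA", "suspension",
                    "flat", {"d0": 2.0})]
        counts = [len(simulate_specimens(make_image(i, 5.0), pool, rng))
                  for i in range(4000)]
        # lam = 1.71 * 2.0 = 3.42; MC tolerance ~3 sd of the mean
        assert np.mean(counts) == pytest.approx(3.42, rel=0.03)

    def test_biovolume_is_ellipsoid_of_length(self, rng):
        pool = [_sp("a-msp1", "metazoan", "NA", "suspension",
                    "flat", {"d0": 5.0}, length=2.0, aspect=0.5)]
        specs = simulate_specimens(make_image(0, 5.0), pool, rng)
        assert len(specs) > 0
        for sp in specs:
            expected = (math.pi / 6.0) * 0.25 * sp.body_length ** 3
            assert sp.biovolume == pytest.approx(expected)

    def test_xenophyophores_carry_no_biovolume(self, rng):
        pool = [_sp("xeno-msp1", "xenophyophore", "NA", "suspension",
                    "flat", {"d0": 5.0})]
        specs = simulate_specimens(make_image(0, 5.0), pool, rng)
        assert specs and all(sp.biovolume is None for sp in specs)


class TestSurvey:
    def test_same_seed_identical_datasets(self):
        cfg = SimulationConfig(n_transects=1, images_per_transect=80, seed=9)
        a = simulate_survey(cfg)
        b = simulate_survey(cfg)
        assert a.images == b.images and a.specimens == b.specimens

    def test_distinct_seeds_differ(self):
        a = simulate_survey(SimulationConfig(n_transects=1,
                                             images_per_transect=80, seed=1))
        b = simulate_survey(SimulationConfig(n_transects=1,
                                             images_per_transect=80, seed=2))
        assert a.images != b.images

    def test_provenance_records_seed_and_proxy(self):
        ds = simulate_survey(SimulationConfig(n_transects=1,
                                              images_per_transect=30, seed=4))
        assert ds.provenance["seed"] == 4
        assert "ellipsoid" in ds.provenance["biovolume_proxy"]

    def test_ground_truth_covers_pool(self):
        pool = default_species_pool()
        gt = ground_truth_table(pool)
        assert set(gt["morphospecies"]) == {s.morphospecies for s in pool}
        assert set(gt["form"]) == {"flat", "saturating", "declining",
                                   "unimodal", "increasing"}

    def test_nodule_size_increases_with_cover(self):
        cfg = SimulationConfig(n_transects=1, images_per_transect=1200, seed=6)
        ds = simulate_survey(cfg)
        pairs = [(im.cover, float(np.median(im.nodule_areas)))
                 for im in ds.images if im.nodule_areas]
        cover, size = map(np.array, zip(*pairs))
        lo = np.median(size[cover <= np.percentile(cover, 10)])
        hi = np.median(size[cover >= np.percentile(cover, 90)])
        assert lo < hi
        assert spearmanr(cover, size).statistic > 0

    def test_count_means_track_ground_truth_density(self):
        # law of large numbers: one flat species, empirical mean within 2%
        pool = [_sp("a-msp1", "metazoan", "NA", "suspension",
                    "flat", {"d0": 2.0})]
        cfg = SimulationConfig(n_transects=4, images_per_transect=2500,
                               species_pool=pool, emit_nodule_areas=False,
                               altitude_sd_m=0.0, seed=8)
        ds = simulate_survey(cfg)
        per_image = len(ds.specimens) / len(ds.images)
        assert per_image == pytest.approx(2.0 * 1.71, rel=0.02)


class TestPresets:
    @pytest.mark.parametrize("preset", ["null_flat", "saturating_stock",
                                        "turnover_gradient", "full_survey"])
    def test_presets_simulate_and_pass_qc(self, preset):
        cfg = preset_config(preset, seed=2)
        if preset == "full_survey":
            cfg.n_transects = 1
            cfg.images_per_transect = 200
        ds = simulate_survey(cfg)
        kept = qc_filter(ds.images)
        assert 0 < len(kept) < len(ds.images)

    def test_null_flat_pool_is_all_flat(self):
        cfg = preset_config("null_flat")
        assert {s.response.form for s in cfg.species_pool} == {"flat"}

    def test_turnover_optima_span_gradient(self):
        cfg = preset_config("turnover_gradient")
        mus = [s.response.params["mu"] for s in cfg.species_pool
               if s.response.form == "unimodal"]
        assert min(mus) <= 1.5 and max(mus) >= 19.0

    def test_unknown_preset_rejected(self):
        with pytest.raises(ConfigError):
            preset_config("bogus")
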