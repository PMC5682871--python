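"""Phantom, cine, histology-image and cohort generators against closed forms."""

import numpy as np
import pytest

import fibrocmr as f
from fibrocmr.synthetic import thickening_profile_mm

from conftest import random_phantom_spec


class TestPhantomSlice:
    def test_noiseless_fully_transmural_wedge_hits_scar_intensity(self):
        spec = f.PhantomSpec(
            noise_sd=0.0, scar_transmurality_frac=1.0, scar_fibrosis_frac=1.0
        )
        _, lge, fib = f.generate_phantom_slice(spec)
        r, ang = lge.polar(spec.center)
        wedge = (
            lge.myocardial_mask
            & (np.minimum(np.abs(ang - 180.0), 360.0 - np.abs(ang - 180.0)) <= 45.0)
        )
        assert wedge.any()
        assert np.all(lge.pixels[wedge] == spec.lge_scar_intensity)

    def test_wedge_pixel_count_matches_analytic_area(self):
        spec = f.PhantomSpec(
            noise_sd=0.0, scar_width_deg=90.0, scar_transmurality_frac=0.5
        )
        _, _, fib = f.generate_phantom_slice(spec)
        n_scar = int(np.count_nonzero(fib.pixels > spec.remote_fibrosis_frac))
        r_out = spec.endo_radius_mm + 0.5 * (spec.epi_radius_mm - spec.endo_radius_mm)
        area = (90.0 / 360.0) * np.pi * (r_out**2 - spec.endo_radius_mm**2)
        expected = area / spec.pixel_spacing_mm**2
        # rasterization tolerance: about one pixel layer along the wedge outline
        perimeter = (
            np.radians(90.0) * (r_out + spec.endo_radius_mm)
            + 2 * (r_out - spec.endo_radius_mm)
        )
        tol = perimeter / spec.pixel_spacing_mm
        assert abs(n_scar - expected) <= tol

    def test_same_seed_is_bit_identical(self):
        spec = f.PhantomSpec(noise_sd=5.0, seed=42)
        _, lge1, fib1 = f.generate_phantom_slice(spec)
        _, lge2, fib2 = f.generate_phantom_slice(spec)
        np.testing.assert_array_equal(lge1.pixels, lge2.pixels)
        np.testing.assert_array_equal(fib1.pixels, fib2.pixels)

    @pytest.mark.parametrize(
        "field,value",
        [
            ("epi_radius_mm", 10.0),          # below endo radius
            ("scar_width_deg", 400.0),
            ("scar_transmurality_frac", 1.5),
            ("noise_sd", -1.0),
            ("n_frames", 1),
            ("lge_scar_intensity", 5.0),      # below remote intensity
        ],
    )
    def test_invalid_spec_names_field(self, field, value):
        with pytest.raises(ValueError):
            f.PhantomSpec(**{field: value})


class TestSimulateCine:
    def test_no_motion_keeps_all_frames_identical(self):
        spec = f.PhantomSpec(
            noise_sd=0.0, thickening_healthy_mm=0.0, thickening_scar_mm=0.0
        )
        geom = f.simulate_cine(spec)
        for frame in range(1, geom.n_frames):
            np.testing.assert_array_equal(geom.endo_mm[frame], geom.endo_mm[0])
            np.testing.assert_array_equal(geom.epi_mm[frame], geom.epi_mm[0])

    def test_uniform_thickening_without_scar(self):
        spec = f.PhantomSpec(
            noise_sd=0.0, scar_width_deg=0.0, thickening_healthy_mm=4.0
        )
        geom = f.simulate_cine(spec)
        wt_es = geom.wall_thickness_mm(geom.n_frames - 1)
        expected = (spec.epi_radius_mm - spec.endo_radius_mm) + 4.0
        np.testing.assert_allclose(wt_es, expected, atol=1e-12)

    def test_akinetic_scar_thickens_less_than_remote(self):
        spec = f.PhantomSpec(
            noise_sd=0.0, thickening_scar_mm=0.0, thickening_healthy_mm=4.0
        )
        geom = f.simulate_cine(spec)
        wt_es = geom.wall_thickness_mm(geom.n_frames - 1)
        scar_core = np.minimum(
            np.abs(geom.theta_deg - 180.0), 360.0 - np.abs(geom.theta_deg - 180.0)
        ) <= 30.0
        remote = np.minimum(
            np.abs(geom.theta_deg - 0.0), 360.0 - np.abs(geom.theta_deg - 0.0)
        ) <= 30.0
        assert wt_es[scar_core].max() < wt_es[remote].min()

    def test_cavity_area_strictly_decreases(self):
        geom = f.simulate_cine(f.PhantomSpec(noise_sd=0.0))
        areas = [geom.cavity_area_mm2(k) for k in range(geom.n_frames)]
        assert all(a1 < a0 for a0, a1 in zip(areas, areas[1:]))

    def test_cavity_collapse_raises(self):
        with pytest.raises(ValueError, match="cavity"):
            f.simulate_cine(f.PhantomSpec(noise_sd=0.0, thickening_healthy_mm=25.0))

    def test_border_ramp_is_between_scar_and_healthy(self):
        spec = f.PhantomSpec(
            noise_sd=0.0, thickening_scar_mm=0.0, thickening_healthy_mm=4.0
        )
        theta = np.linspace(0.0, 360.0, 1441)
        delta = thickening_profile_mm(spec, theta)
        assert delta.min() >= 0.0 and delta.max() <= 4.0 + 1e-12

    def test_epi_always_exceeds_endo_on_random_specs(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            geom = f.simulate_cine(random_phantom_spec(rng))
            assert np.all(geom.epi_mm > geom.endo_mm)


class TestHistologyImage:
    def test_pure_fibrosis_is_all_connective(self):
        sec = f.generate_histology_image(1.0, 0.0, size_px=(40, 40), seed=1)
        assert np.all(sec.labels == 0)
        assert sec.true_fractions == (1.0, 0.0, 0.0)

    def test_no_fibrosis_no_adipose_is_all_myocyte(self):
        sec = f.generate_histology_image(0.0, 0.0, size_px=(40, 40), seed=1)
        assert np.all(sec.labels == 1)

    def test_realized_fraction_within_binomial_bound(self):
        p = 0.3
        sec = f.generate_histology_image(p, 0.1, size_px=(400, 250), seed=5)
        n = sec.labels.size
        sd = np.sqrt(p * (1 - p) / n)
        assert abs(sec.true_fractions[0] - p) <= 3 * sd

    def test_fraction_sum_above_one_raises(self):
        with pytest.raises(ValueError):
            f.generate_histology_image(0.7, 0.5, seed=0)

    def test_class_fractions_sum_to_one_exactly(self):
        sec = f.generate_histology_image(0.25, 0.15, size_px=(50, 50), seed=3)
        assert sum(sec.true_fractions) == 1.0


class TestCohort:
    def test_row_count(self):
        spec = f.CohortSpec(n_animals=15, sections_per_animal=8, seed=0)
        table, _ = f.generate_cohort(spec)
        assert len(table) == 120

    def test_deterministic_limit_recovers_linear_predictor(self):
        spec = f.CohortSpec(
            n_animals=3, sections_per_animal=4, beta0=1.5, beta1=0.5,
            sigma2=0.0, tau00=0.0, seed=2,
        )
        table, _ = f.generate_cohort(spec)
        np.testing.assert_allclose(
            table["log_fibrosis_true"],
            1.5 + 0.5 * table["covariate"],
            atol=1e-12,
        )

    def test_moment_oracle_recovers_tau00(self):
        # between/within decomposition: var(animal means) - sigma2/m -> tau00
        spec = f.CohortSpec(
            n_animals=200, sections_per_animal=20, beta1=0.0,
            sigma2=1.0, tau00=0.25, seed=9,
        )
        table, _ = f.generate_cohort(spec)
        g = table.groupby("animal_id")["log_fibrosis_true"]
        within = g.var().mean()
        between = g.mean().var()
        tau_hat = between - within / 20
        assert abs(tau_hat - 0.25) / 0.25 < 0.20
        assert abs(within - 1.0) < 0.15

    def test_same_seed_reproduces_table(self):
        spec = f.CohortSpec(seed=4)
        t1, _ = f.generate_cohort(spec)
        t2, _ = f.generate_cohort(spec)
        assert t1.equals(t2)

    def test_fibrosis_capped_at_100(self):
        spec = f.CohortSpec(beta0=6.0, sigma2=1.0, tau00=0.0, seed=1)
        table, _ = f.generate_cohort(spec)
        assert table["fibrosis_pct"].max() <= 100.0

    def test_artifacts_spawned_per_animal(self, noiseless_spec):
        spec = f.CohortSpec(n_animals=3, seed=0)
        _, artifacts = f.generate_cohort(spec, pspec_template=noiseless_spec)
        assert set(artifacts) == {"a001", "a002", "a003"}
        seeds = {a.seed for a in artifacts.values()}
        assert len(seeds) == 3
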