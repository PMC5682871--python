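"""Scar delineation thresholds, transmurality and MSI sector exports."""

import math

import numpy as np
import pytest

import fibrocmr as f
from fibrocmr.core import IntensityImage
from fibrocmr.lge import remote_region_from_span

from conftest import random_phantom_spec


def two_level_phantom(noise_sd=0.0, **kw):
    spec = f.PhantomSpec(noise_sd=noise_sd, **kw)
    geom, lge, fib = f.generate_phantom_slice(spec)
    return spec, geom, lge, fib


def remote_band(spec, lge, geom, center_deg=0.0, half=30.0):
    return remote_region_from_span(lge, geom, center_deg, half)


def brute_force_tm(mask, geom, K=360):
    """Independent per-pixel tally with scalar math, no shared helpers."""
    h, w = mask.scar.shape
    cx, cy = geom.center_xy_mm
    sp = mask.pixel_spacing_mm
    myo_counts = [0] * K
    scar_counts = [0] * K
    for row in range(h):
        for col in range(w):
            if not mask.myocardium[row, col]:
                continue
            x = (col + 0.5) * sp - cx
            y = (row + 0.5) * sp - cy
            ang = math.degrees(math.atan2(y, x)) % 360.0
            k = min(int(ang // (360.0 / K)), K - 1)
            myo_counts[k] += 1
            if mask.scar[row, col]:
                scar_counts[k] += 1
    return [
        100.0 * s / m if m else float("nan")
        for s, m in zip(scar_counts, myo_counts)
    ]


class TestFWHM:
    def test_threshold_is_half_plateau_and_scar_equals_wedge(self):
        spec, geom, lge, fib = two_level_phantom()
        mask = f.fwhm_mask(lge)
        assert mask.threshold_used == 50.0
        wedge = fib.pixels > spec.remote_fibrosis_frac
        np.testing.assert_array_equal(mask.scar, wedge)

    def test_uniform_myocardium_is_fully_flagged(self):
        myo = np.zeros((16, 16), dtype=bool)
        myo[4:12, 4:12] = True
        img = IntensityImage(np.full((16, 16), 40.0), 1.0, myo)
        mask = f.fwhm_mask(img)
        assert mask.threshold_used == 20.0
        np.testing.assert_array_equal(mask.scar, myo)

    def test_boundary_pixels_at_threshold_included(self):
        # scar exactly twice remote: remote sits exactly at the threshold
        spec, geom, lge, _ = two_level_phantom(
            lge_scar_intensity=40.0, lge_remote_intensity=20.0
        )
        mask = f.fwhm_mask(lge)
        assert mask.threshold_used == 20.0
        np.testing.assert_array_equal(mask.scar, lge.myocardial_mask)

    def test_empty_seed_region_rejected(self):
        _, _, lge, _ = two_level_phantom()
        with pytest.raises(ValueError, match="empty"):
            f.fwhm_mask(lge, seed_region=np.zeros(lge.shape, dtype=bool))


class TestSDRemote:
    def test_threshold_arithmetic(self):
        myo = np.zeros((4, 4), dtype=bool)
        myo[:2] = True
        px = np.zeros((4, 4))
        px[0] = 8.0
        px[1] = 12.0  # mean 10, population SD 2
        img = IntensityImage(px, 1.0, myo)
        mask = f.sd_remote_mask(img, myo, 5)
        assert mask.threshold_used == pytest.approx(20.0)
        assert mask.method_tag == "SD5"

    def test_zero_variance_remote_is_valid(self):
        _, geom, lge, _ = two_level_phantom()
        remote = remote_band(None, lge, geom)
        mask = f.sd_remote_mask(lge, remote, 3)
        assert mask.threshold_used == pytest.approx(20.0)

    def test_singleton_remote_rejected(self):
        _, _, lge, _ = two_level_phantom()
        region = np.zeros(lge.shape, dtype=bool)
        region[tuple(np.argwhere(lge.myocardial_mask)[0])] = True
        with pytest.raises(ValueError, match="two pixels"):
            f.sd_remote_mask(lge, region, 2)

    def test_nesting_on_noisy_phantoms(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            spec = random_phantom_spec(rng, noise_sd=5.0)
            geom, lge, _ = f.generate_phantom_slice(spec)
            remote = remote_region_from_span(
                lge, geom, (spec.scar_center_deg + 180.0) % 360.0, 30.0
            )
            m2 = f.sd_remote_mask(lge, remote, 2)
            m3 = f.sd_remote_mask(lge, remote, 3)
            m5 = f.sd_remote_mask(lge, remote, 5)
            assert np.all(m5.scar <= m3.scar)
            assert np.all(m3.scar <= m2.scar)

    def test_gaussian_tail_false_positive_rate(self):
        # fine grid so the remote side holds >1e4 pixels
        spec = f.PhantomSpec(
            image_size_px=(512, 512), pixel_spacing_mm=0.25,
            noise_sd=2.0, lge_remote_intensity=20.0, lge_scar_intensity=100.0,
            seed=17,
        )
        geom, lge, fib = f.generate_phantom_slice(spec)
        remote = remote_region_from_span(lge, geom, 0.0, 30.0)
        mask = f.sd_remote_mask(lge, remote, 2)
        wedge = fib.pixels > spec.remote_fibrosis_frac
        assert mask.scar.sum() >= wedge.sum()  # threshold below the plateau
        clean = lge.myocardial_mask & ~wedge
        fp = mask.scar[clean].mean()
        p = 0.02275  # one-sided P(Z > 2)
        n = clean.sum()
        assert abs(fp - p) <= 3 * np.sqrt(p * (1 - p) / n) + 0.002


class TestManualCorrection:
    def test_empty_exclusion_is_identity(self):
        _, _, lge, _ = two_level_phantom()
        mask = f.fwhm_mask(lge)
        out = f.apply_manual_correction(mask, np.zeros(lge.shape, dtype=bool))
        np.testing.assert_array_equal(out.scar, mask.scar)
        assert out.method_tag == "FWHMm"

    def test_total_exclusion_empties_scar(self):
        _, _, lge, _ = two_level_phantom()
        out = f.apply_manual_correction(
            f.fwhm_mask(lge), np.ones(lge.shape, dtype=bool)
        )
        assert not out.scar.any()

    def test_correction_confines_noisy_mask_to_true_wedge(self):
        spec = f.PhantomSpec(noise_sd=8.0, seed=5)
        geom, lge, fib = f.generate_phantom_slice(spec)
        remote = remote_region_from_span(lge, geom, 0.0, 30.0)
        noisy = f.sd_remote_mask(lge, remote, 2)
        wedge = fib.pixels > spec.remote_fibrosis_frac
        corrected = f.apply_manual_correction(noisy, ~wedge)
        assert np.all(corrected.scar <= wedge)
        assert corrected.method_tag == "SD2m"


class TestProfiles:
    def test_fully_scarred_wedge_sectors_read_100(self):
        spec, geom, lge, _ = two_level_phantom(scar_transmurality_frac=1.0)
        tm = f.transmurality_profile(f.fwhm_mask(lge), geom)
        centers = tm.sector_centers_deg()
        core = np.minimum(np.abs(centers - 180), 360 - np.abs(centers - 180)) <= 30
        vals = tm.values[core]
        np.testing.assert_allclose(vals[np.isfinite(vals)], 100.0)

    def test_half_transmural_scar_center_sectors(self):
        spec, geom, lge, _ = two_level_phantom(
            scar_transmurality_frac=0.5, scar_width_deg=90.0
        )
        tm = f.transmurality_profile(f.fwhm_mask(lge), geom)
        centers = tm.sector_centers_deg()
        core = np.minimum(np.abs(centers - 180), 360 - np.abs(centers - 180)) <= 20
        assert np.nanmean(tm.values[core]) == pytest.approx(50.0, abs=3.0)

    def test_empty_scar_gives_all_zero(self):
        _, geom, lge, _ = two_level_phantom()
        empty = f.apply_manual_correction(
            f.fwhm_mask(lge), np.ones(lge.shape, dtype=bool)
        )
        tm = f.transmurality_profile(empty, geom)
        vals = tm.values[np.isfinite(tm.values)]
        np.testing.assert_array_equal(vals, 0.0)

    def test_brute_force_equivalence(self):
        rng = np.random.default_rng(33)
        for _ in range(3):
            spec = random_phantom_spec(rng, noise_sd=4.0)
            geom, lge, _ = f.generate_phantom_slice(spec)
            mask = f.fwhm_mask(lge)
            tm = f.transmurality_profile(mask, geom, K=90)
            oracle = brute_force_tm(mask, geom, K=90)
            np.testing.assert_array_equal(
                tm.values[np.isfinite(tm.values)],
                np.asarray(oracle)[np.isfinite(tm.values)],
            )

    def test_msi_uniform_and_two_level(self):
        myo = np.zeros((32, 32), dtype=bool)
        myo[8:24, 8:24] = True
        img = IntensityImage(np.full((32, 32), 7.0), 1.0, myo)
        geom = f.generate_phantom_slice(f.PhantomSpec(noise_sd=0.0))[0]
        geom_small = f.SliceGeometry(
            (16.0, 16.0), geom.theta_deg,
            np.full((1, geom.theta_deg.size), 1.0),
            np.full((1, geom.theta_deg.size), 2.0),
        )
        msi = f.msi_profile(img, geom_small)
        vals = msi.values[np.isfinite(msi.values)]
        np.testing.assert_allclose(vals, 7.0)

        spec, geom2, lge, _ = two_level_phantom(scar_transmurality_frac=1.0)
        msi2 = f.msi_profile(lge, geom2)
        centers = msi2.sector_centers_deg()
        core = np.minimum(np.abs(centers - 180), 360 - np.abs(centers - 180)) <= 30
        remote = np.minimum(np.abs(centers), 360 - np.abs(centers)) <= 30
        assert np.nanmean(msi2.values[core]) == pytest.approx(100.0)
        assert np.nanmean(msi2.values[remote]) == pytest.approx(20.0)

    def test_disjoint_frames_rejected(self):
        _, geom, lge, _ = two_level_phantom()
        far = f.SliceGeometry(
            (10_000.0, 10_000.0), geom.theta_deg,
            geom.endo_mm, geom.epi_mm,
        )
        with pytest.raises(ValueError, match="frame"):
            f.transmurality_profile(f.fwhm_mask(lge), far)

    def test_tm_range_and_msi_nonnegative(self):
        rng = np.random.default_rng(8)
        spec = random_phantom_spec(rng, noise_sd=6.0)
        geom, lge, _ = f.generate_phantom_slice(spec)
        tm = f.transmurality_profile(f.fwhm_mask(lge), geom)
        finite = tm.values[np.isfinite(tm.values)]
        assert np.all((finite >= 0) & (finite <= 100))
        msi = f.msi_profile(lge, geom)
        assert np.all(msi.values[np.isfinite(msi.values)] >= 0)
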