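"""Bead segmentation/measurement, temporal stats, mass, darkfield SNR."""

import numpy as np
import pandas as pd
import pytest

import ledscope as ls
from ledscope.validate import (background_vs_inner_radius, darkfield_snr,
                               mass_from_optical_volume, measure_beads,
                               optical_volume, refractive_index, segment_beads,
                               temporal_stats)


@pytest.fixture(scope="module")
def recon_phase(small_specimen, optics, geom):
    """Noise-free reconstruction of the 3-bead phantom at sigma 2.1."""
    return ls.simulate_and_reconstruct(small_specimen, optics, geom, 2.1, reg2=1e-3)


class TestSegmentation:
    def test_empty_phase_yields_no_beads(self):
        pm = ls.PhaseMap(np.zeros((64, 64)), 0.586, 0.63)
        assert segment_beads(pm).max() == 0

    def test_three_beads_found_at_phantom_centers(self, recon_phase, small_phantom):
        labels = segment_beads(recon_phase)
        assert labels.max() == 3
        meas = measure_beads(recon_phase, labels)
        px = recon_phase.pixel_size_um
        found = {(round(r["centroid_col"] * px), round(r["centroid_row"] * px))
                 for _, r in meas.iterrows()}
        for cx, cy, _ in small_phantom.beads:
            assert any(abs(fx - cx) <= 1 and abs(fy - cy) <= 1
                       for fx, fy in found)

    def test_segmented_area_matches_bead_cross_section(self, recon_phase):
        meas = measure_beads(recon_phase)
        # pi R^2 = 78.5 µm² for R = 5 µm
        for area in meas["area_um2"]:
            assert area == pytest.approx(np.pi * 25.0, rel=0.05)

    def test_border_touching_components_removed(self):
        phase = np.zeros((64, 64))
        phase[:10, :10] = 1.0            # touches the border
        phase[30:40, 30:40] = 1.0
        labels = segment_beads(ls.PhaseMap(phase, 0.586, 0.63), min_area_px=20)
        assert labels.max() == 1
        assert labels[:5, :5].max() == 0


class TestOpticalVolume:
    def test_closed_form_uniform_patch(self):
        # 100 px of 0.25 µm² at φ = 0.5 rad, λ = 0.63: OV = 1.2533 µm³
        phase = np.zeros((32, 32))
        phase[10:20, 10:20] = 0.5
        labels = (phase > 0).astype(np.int32)
        pm = ls.PhaseMap(phase, 0.5, 0.63)
        ov = optical_volume(pm, labels)
        assert ov.loc[1] == pytest.approx(100 * 0.25 * 0.5 * 0.63 / (2 * np.pi),
                                          rel=1e-12)
        assert ov.loc[1] == pytest.approx(1.2533, abs=2e-4)

    def test_zero_phase_gives_zero_volume(self):
        pm = ls.PhaseMap(np.zeros((16, 16)), 0.5, 0.63)
        labels = np.ones((16, 16), dtype=np.int32)
        assert optical_volume(pm, labels).loc[1] == 0

    def test_additive_over_disjoint_labels(self, recon_phase):
        labels = segment_beads(recon_phase)
        per_label = optical_volume(recon_phase, labels)
        merged = (labels > 0).astype(np.int32)
        assert optical_volume(recon_phase, merged).loc[1] == pytest.approx(
            per_label.sum(), rel=1e-12)

    def test_mask_dilation_insensitive_after_background_subtraction(
            self, small_specimen, optics):
        """Growing the mask into true (noisy, offset) background barely
        changes the OV once the background median is subtracted."""
        from scipy import ndimage

        rng = np.random.default_rng(0)
        phi = ls.opl_to_phase(small_specimen, optics.wavelength_um)
        phi = phi + 0.03 + rng.normal(0, 0.005, phi.shape)   # offset + noise
        pm = ls.PhaseMap(phi, small_specimen.pixel_size_um, optics.wavelength_um)
        labels = segment_beads(pm)
        bg = np.median(pm.phase[labels == 0])
        pm_corr = ls.PhaseMap(pm.phase - bg, pm.pixel_size_um, pm.wavelength_um)
        ov0 = optical_volume(pm_corr, labels).sum()
        dilated, _ = ndimage.label(ndimage.binary_dilation(labels > 0,
                                                           iterations=3))
        ov1 = optical_volume(pm_corr, dilated.astype(np.int32)).sum()
        assert ov1 == pytest.approx(ov0, rel=0.01)

    def test_recovered_bead_ov_within_five_percent(self, recon_phase, small_phantom):
        meas = measure_beads(recon_phase)
        expected = small_phantom.analytic_optical_volumes().mean()  # 12.04 µm³
        assert meas["optical_volume_um3"].mean() == pytest.approx(expected, rel=0.05)


class TestRefractiveIndex:
    def test_exact_inverse_of_construction(self):
        d, dn = 10.0, 0.023
        ov = dn * 4 / 3 * np.pi * (d / 2) ** 3
        assert refractive_index(ov, d, 1.56) == pytest.approx(1.56 + dn, rel=1e-12)

    def test_zero_volume_returns_medium_index(self):
        assert refractive_index(0.0, 10.0, 1.56) == 1.56

    def test_zero_diameter_rejected(self):
        with pytest.raises(ValueError):
            refractive_index(1.0, 0.0, 1.56)

    def test_pipeline_recovers_bead_index(self, recon_phase, small_phantom):
        meas = measure_beads(recon_phase, n_medium=small_phantom.n_medium)
        n = meas["n_bead"].mean()
        assert abs(n - 1.583) / 1.583 < 0.002


class TestTemporal:
    def _frame(self, ovs, jitter=0.0):
        return pd.DataFrame({
            "centroid_row": [20.0 + jitter, 60.0],
            "centroid_col": [20.0, 60.0 - jitter],
            "optical_volume_um3": ovs,
        })

    def test_identical_frames_have_zero_cv(self):
        frames = [self._frame([10.0, 12.0]) for _ in range(5)]
        stats = temporal_stats(frames)
        assert np.allclose(stats.summary["cv"], 0.0)
        assert np.allclose(stats.summary["mean"], [10.0, 12.0])

    def test_beads_matched_despite_small_centroid_jitter(self):
        frames = [self._frame([10.0, 12.0], jitter=j) for j in (0, 1.5, -1.5, 2.0)]
        stats = temporal_stats(frames)
        assert len(stats.summary) == 2
        assert stats.summary["n_frames"].tolist() == [4, 4]

    def test_lost_bead_flagged_and_excluded(self):
        frames = [self._frame([10.0, 12.0]) for _ in range(10)]
        for f in frames[1:5]:                # bead 0 missing in 40% of frames
            f.drop(index=0, inplace=True)
        with pytest.warns(UserWarning, match="lost"):
            stats = temporal_stats(frames)
        assert stats.excluded == [0]
        assert stats.summary["bead"].tolist() == [1]

    def test_noisy_series_cv_shrinks_with_photon_count(self, small_specimen,
                                                       optics, geom, small_phantom):
        cvs = {}
        for photons in (500, 50000):
            frames = []
            for i in range(3):
                pm = ls.simulate_and_reconstruct(
                    small_specimen, optics, geom, 1.5, reg2=1e-3,
                    noise_model=ls.NoiseModel(photons_at_unity=photons, seed=1),
                    seed=100 + i)
                frames.append(measure_beads(pm, n_medium=small_phantom.n_medium))
            stats = temporal_stats(frames)
            cvs[photons] = stats.summary["cv"].mean()
        assert 0 < cvs[50000] < cvs[500]


class TestMass:
    def test_unit_conversion(self):
        assert mass_from_optical_volume(0.18) == pytest.approx(1.0)
        assert mass_from_optical_volume(77.76) == pytest.approx(432.0)

    def test_linearity(self):
        assert mass_from_optical_volume(2.0) == 2 * mass_from_optical_volume(1.0)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            mass_from_optical_volume(1.0, alpha_um3_per_pg=0.0)


class TestDarkfieldSNR:
    def test_constructed_region_arithmetic(self):
        img = np.full((20, 20), 10.0)
        img[5:10, 5:10] = 120.0              # bead mean 120, empty mean 10
        rng = np.random.default_rng(0)
        bead = np.zeros((20, 20), bool)
        bead[5:10, 5:10] = True
        empty = ~bead
        img[empty] += rng.normal(0, 2.0, empty.sum())
        rep = darkfield_snr(img, bead, empty)
        assert rep.snr == pytest.approx((120 - img[empty].mean())
                                        / img[empty].std(ddof=1))
        assert rep.snr == pytest.approx(50.0, rel=0.15)

    def test_equal_means_give_zero_snr(self):
        rng = np.random.default_rng(1)
        img = rng.normal(50, 3, (20, 20))
        bead = np.zeros((20, 20), bool)
        bead[:5] = True
        img[bead] = img[~bead][:100].mean()
        rep = darkfield_snr(img, bead, ~bead)
        assert abs(rep.snr) < 1.0

    def test_zero_empty_sd_is_undefined(self):
        img = np.full((10, 10), 5.0)
        bead = np.zeros((10, 10), bool)
        bead[2:4, 2:4] = True
        with pytest.raises(ZeroDivisionError):
            darkfield_snr(img, bead, ~bead)

    def test_overlapping_masks_rejected(self):
        img = np.ones((10, 10))
        mask = np.ones((10, 10), bool)
        with pytest.raises(ValueError, match="overlap"):
            darkfield_snr(img, mask, mask)

    def test_simulated_bead_snr_matches_noise_model_moments(self, optics, geom110,
                                                            pixel_size):
        """On a synthetic darkfield image the estimator agrees with the
        closed-form prediction from the camera-noise parameters."""
        c = 128 * pixel_size / 2
        spec = ls.bead_opl_map(ls.BeadPhantom(((c, c, 5.0),), field_size=(128, 128),
                                              pixel_size_um=pixel_size))
        img = ls.abbe_image(spec, ls.make_annulus_pattern(geom110, 8, 12), optics)
        scale = 0.02 / img.max()             # dim darkfield exposure
        model = ls.NoiseModel(photons_at_unity=10000, read_noise_sd=5.0,
                              offset=100.0, seed=6)
        counts = ls.apply_noise(img * scale, model, seed=6)
        bead = img * scale * model.photons_at_unity > 10.0
        from scipy import ndimage

        empty = ~ndimage.binary_dilation(bead, iterations=8)
        rep = darkfield_snr(counts, bead, empty)
        mu_signal = (img * scale)[bead].mean() * model.photons_at_unity
        sigma_pred = model.read_noise_sd     # empty region: read noise only
        assert rep.snr == pytest.approx(mu_signal / sigma_pred, rel=0.10)


class TestDarkfieldDesign:
    def test_background_curve_vs_inner_radius(self, optics, geom110):
        noise = ls.NoiseModel(photons_at_unity=10000, read_noise_sd=5.0,
                              offset=100.0, seed=5)
        df = background_vs_inner_radius(geom110, optics, noise, [5, 6, 7, 8], 10,
                                        seed=5, field_shape=(128, 128))
        assert len(df) == 4                          # one row per radius
        means = df["mean_counts"].to_numpy()
        assert np.all(np.diff(means) <= noise.read_noise_sd)   # non-increasing
        # radii whose inner NA exceeds the objective NA sit at the floor
        dark = df["inner_na_exact"] > optics.na_objective
        assert df.loc[dark, "dark_limited"].all()
        assert not df.loc[~dark, "dark_limited"].any()

    def test_inverted_radii_rejected(self, optics, geom110):
        with pytest.raises(ValueError):
            background_vs_inner_radius(geom110, optics, ls.NoiseModel(), [8], 8,
                                       field_shape=(64, 64))
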