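"""Geometry, coherence arithmetic and illumination-pattern algebra."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ledscope as ls
from ledscope.exceptions import SigmaOutOfRangeError
from ledscope.optics import config_dict, pattern_sigma


class TestScalars:
    @pytest.mark.parametrize("na_ill,na_obj,expected", [
        (0.39, 0.25, 1.56),      # darkfield inner boundary
        (0.25, 0.25, 1.0),       # illumination filling the pupil
        (0.0, 0.25, 0.0),
    ])
    def test_coherence_parameter(self, na_ill, na_obj, expected):
        assert ls.coherence_parameter(na_ill, na_obj) == pytest.approx(expected)

    def test_coherence_parameter_rejects_bad_na(self):
        with pytest.raises(ValueError):
            ls.coherence_parameter(0.3, 0.0)
        with pytest.raises(ValueError):
            ls.coherence_parameter(-0.1, 0.25)

    @pytest.mark.parametrize("r,d,mode,expected", [
        (0.0, 110.0, "exact", 0.0),
        (110.0, 110.0, "exact", math.sin(math.pi / 4)),       # 45 degrees
        (32.5, 110.0, "exact", 32.5 / math.hypot(32.5, 110)),  # 0.28335
        (32.5, 110.0, "paper_literal", 32.5 / 110.0),          # 0.29545
    ])
    def test_illumination_na(self, r, d, mode, expected):
        assert ls.illumination_na(r, d, mode) == pytest.approx(expected, rel=1e-6)

    def test_illumination_na_literal_warns_when_nonphysical(self):
        with pytest.warns(UserWarning, match="exceeds 1"):
            assert ls.illumination_na(200.0, 110.0, "paper_literal") > 1

    def test_illumination_na_rejects_bad_distance(self):
        with pytest.raises(ValueError):
            ls.illumination_na(10.0, 0.0)

    @settings(max_examples=50, derandomize=True)
    @given(r=st.floats(0.01, 500), d=st.floats(1.0, 500))
    def test_exact_na_bounded_and_monotone(self, r, d):
        na = ls.illumination_na(r, d)
        assert 0.0 <= na < 1.0
        assert ls.illumination_na(r * 1.1, d) > na       # increasing in r
        assert ls.illumination_na(r, d * 1.1) < na       # decreasing in d

    def test_led_spatial_frequency(self):
        assert ls.led_spatial_frequency((0, 0), 110, 0.63) == (0.0, 0.0)
        ux, uy = ls.led_spatial_frequency((110, 0), 110, 0.63)
        assert ux == pytest.approx(math.sin(math.pi / 4) / 0.63, rel=1e-5)
        assert uy == 0.0

    @settings(max_examples=30, derandomize=True)
    @given(x=st.floats(-60, 60), y=st.floats(-35, 35))
    def test_led_frequency_magnitude_matches_na(self, x, y):
        ux, uy = ls.led_spatial_frequency((x, y), 110, 0.63)
        na = ls.illumination_na(math.hypot(x, y), 110)
        assert math.hypot(ux, uy) == pytest.approx(na / 0.63, abs=1e-12)

    def test_magnified_pixel_size(self):
        assert ls.OpticalSystem(camera_pixel_pitch_um=5.86,
                                magnification=10).magnified_pixel_size_um == pytest.approx(0.586)
        assert ls.OpticalSystem(camera_pixel_pitch_um=4.8,
                                magnification=10).magnified_pixel_size_um == pytest.approx(0.48)
        assert ls.OpticalSystem(camera_pixel_pitch_um=3.3,
                                magnification=1).magnified_pixel_size_um == pytest.approx(3.3)

    @pytest.mark.parametrize("um_per_rev,steps,expected", [
        (50, 400, 0.125), (50, 50, 1.0), (100, 400, 0.25),
    ])
    def test_z_step_size(self, um_per_rev, steps, expected):
        assert ls.z_step_size(um_per_rev, steps) == pytest.approx(expected)


class TestPatterns:
    def test_opposing_halves_are_disjoint_and_union_to_full(self, geom):
        for a, b in (("left", "right"), ("top", "bottom")):
            pa = ls.make_half_pattern(geom, a, 8)
            pb = ls.make_half_pattern(geom, b, 8)
            full = ls.make_full_pattern(geom, 8)
            assert not (pa.lit & pb.lit).any()
            # even grid: no LED sits on the axis, so the union is the circle
            assert ((pa.lit | pb.lit) == full.lit).all()

    def test_all_four_halves_have_equal_led_counts(self, geom):
        counts = {d: ls.make_half_pattern(geom, d, 7).n_lit
                  for d in ("left", "right", "top", "bottom")}
        assert len(set(counts.values())) == 1

    def test_radius_one_left_half(self, geom):
        pat = ls.make_half_pattern(geom, "left", 1)
        x, _ = pat.lit_positions_mm()
        assert pat.n_lit > 0 and (x < 0).all()

    def test_oversized_radius_clips_with_warning(self, geom):
        with pytest.warns(UserWarning, match="clipped"):
            pat = ls.make_full_pattern(geom, 50)
        assert pat.n_lit == geom.n_rows * geom.n_cols

    def test_annulus_disjoint_from_inner_full(self, geom):
        ann = ls.make_annulus_pattern(geom, 6, 8)
        assert not (ann.lit & ls.make_full_pattern(geom, 6).lit).any()

    def test_annuli_nest(self, geom):
        wide = ls.make_annulus_pattern(geom, 4, 8)
        narrow = ls.make_annulus_pattern(geom, 6, 8)
        assert (wide.lit | narrow.lit == wide.lit).all()

    def test_annulus_lit_leds_exceed_inner_na(self, geom110):
        ann = ls.make_annulus_pattern(geom110, 6, 8)
        na_min = ls.illumination_na(6 * geom110.pitch_mm, geom110.distance_mm)
        x, y = ann.lit_positions_mm()
        for xi, yi in zip(x, y):
            assert ls.illumination_na(math.hypot(xi, yi),
                                      geom110.distance_mm) >= na_min - 1e-12

    def test_annulus_rejects_inverted_radii(self, geom):
        with pytest.raises(ValueError):
            ls.make_annulus_pattern(geom, 8, 6)

    def test_dark_pattern_has_no_lit_leds(self, geom):
        assert ls.make_dark_pattern(geom).n_lit == 0

    def test_pattern_text_round_trip(self, geom):
        pat = ls.make_half_pattern(geom, "top", 6)
        back = ls.IlluminationPattern.from_text(pat.to_text(), geom)
        assert (back.lit == pat.lit).all()

    def test_lit_table_lists_every_lit_led(self, geom):
        pat = ls.make_full_pattern(geom, 5)
        table = pat.lit_table()
        assert len(table) == pat.n_lit
        assert {"row", "col", "x_mm", "y_mm"} <= set(table.columns)


class TestSigmaRadius:
    def test_zero_sigma_needs_no_leds(self, optics, geom):
        assert ls.sigma_to_led_radius(0.0, optics, geom) == 0

    def test_sigma_one_at_paper_distance_needs_seven_leds(self, optics, geom110):
        # the geometry, not the printed "4 LEDs", decides
        assert ls.sigma_to_led_radius(1.0, optics, geom110) == 7

    @settings(max_examples=30, derandomize=True)
    @given(s1=st.floats(0.1, 1.9), s2=st.floats(0.1, 1.9))
    def test_radius_monotone_in_sigma(self, optics, geom, s1, s2):
        lo, hi = sorted((s1, s2))
        assert (ls.sigma_to_led_radius(lo, optics, geom)
                <= ls.sigma_to_led_radius(hi, optics, geom))

    @pytest.mark.parametrize("sigma", [0.5, 1.0, 1.5, 2.0])
    def test_realized_sigma_covers_request_within_one_led(self, optics, geom, sigma):
        k = ls.sigma_to_led_radius(sigma, optics, geom)
        assert pattern_sigma(k, optics, geom) >= sigma
        if k > 1:
            assert pattern_sigma(k - 1, optics, geom) < sigma

    def test_unattainable_sigma_reports_maximum(self, optics, geom):
        with pytest.raises(SigmaOutOfRangeError) as err:
            ls.sigma_to_led_radius(3.0, optics, geom)
        assert 2.0 < err.value.max_sigma < 2.5


class TestConfig:
    def test_yaml_config_round_trip(self, tmp_path, optics, geom):
        import yaml

        path = tmp_path / "scope.yaml"
        path.write_text(yaml.safe_dump(config_dict(optics, geom)))
        opt2, geom2 = ls.load_config(path)
        assert opt2 == optics
        assert geom2 == geom

    def test_json_config_with_defaults(self, tmp_path):
        path = tmp_path / "scope.json"
        path.write_text('{"na_objective": 0.3, "led": {"distance_mm": 80}}')
        opt, geom = ls.load_config(path)
        assert opt.na_objective == 0.3
        assert geom.distance_mm == 80
        assert geom.n_rows == 16 and geom.pitch_mm == 4.7

    def test_invalid_config_raises(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("na_objective: -2\n")
        with pytest.raises(ls.ConfigError):
            ls.load_config(path)
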