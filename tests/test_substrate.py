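"""Geometry of patterned substrates: areas, hits, normals, rasterization."""

import math

import numpy as np
import pytest

from neuroculture.errors import ConfigurationError, GeometryError
from neuroculture.substrate import (
    ObstacleSpec,
    SubstratePattern,
    area_fraction,
    build_pattern,
    first_hit,
    load_mask,
    pattern_from_json,
    pattern_to_json,
    rasterize,
    save_mask,
)


class TestAreaFractions:
    @pytest.mark.parametrize("kind, diameter, expected", [
        ("crosses_full", 2, 0.136),
        ("crosses_1array", 2, 0.024),
        ("crosses_2arrays", 2, 0.048),
        ("circles_full", 2, 0.450),
        ("triangles_full", 2, 0.3595),
        ("empty", 2, 0.0),
        ("crosses_1array", 4, 0.006),
        ("crosses_4arrays", 4, 0.024),
    ])
    def test_builtin_fractions(self, kind, diameter, expected):
        frac = area_fraction(build_pattern(kind, diameter))
        assert frac == pytest.approx(expected, abs=0.002)

    def test_single_circle_closed_form(self):
        pat = SubstratePattern(diameter=2.0, obstacles=(
            ObstacleSpec("circle", (0.2, 0.1), (0.120,)),))
        assert area_fraction(pat) == pytest.approx(math.pi * 0.06**2 / math.pi, rel=1e-12)

    @pytest.mark.parametrize("scale", [2, 3, 6])
    def test_scaling_preserves_fraction_and_scales_coordinates(self, scale):
        base = build_pattern("crosses_full", 2, 1)
        scaled = build_pattern("crosses_full", 2, scale)
        assert area_fraction(scaled) == pytest.approx(area_fraction(base), rel=1e-9)
        a0 = np.array(sorted(o.anchor for o in base.obstacles))
        a1 = np.array(sorted(o.anchor for o in scaled.obstacles))
        assert np.allclose(a1, scale * a0, atol=1e-12)
        assert scaled.diameter == scale * base.diameter

    def test_invalid_configurations(self):
        with pytest.raises(ConfigurationError):
            build_pattern("crosses_4arrays", 2)
        with pytest.raises(ConfigurationError):
            build_pattern("nonsense", 2)
        with pytest.raises(ConfigurationError):
            build_pattern("empty", 3)
        with pytest.raises(ConfigurationError):
            build_pattern("empty", 2, 5)


class TestFirstHit:
    def test_radial_hit_on_circle(self):
        pat = SubstratePattern(diameter=2.0, obstacles=(
            ObstacleSpec("circle", (0.5, 0.0), (0.120,)),))
        hit = first_hit([[0.0, 0.0], [0.5, 0.0]], pat)
        assert hit is not None and hit.boundary == "obstacle"
        assert hit.point[0] == pytest.approx(0.44, abs=1e-12)
        # normal points back along the segment
        assert hit.normal == pytest.approx((-1.0, 0.0), abs=1e-12)

    def test_miss_returns_none(self):
        pat = SubstratePattern(diameter=2.0, obstacles=(
            ObstacleSpec("circle", (0.5, 0.5), (0.120,)),))
        assert first_hit([[0.0, 0.0], [0.3, 0.0]], pat) is None

    def test_rim_hit_normal_inward(self):
        pat = build_pattern("empty", 2)
        hit = first_hit([[0.8, 0.0], [1.5, 0.0]], pat)
        assert hit is not None and hit.boundary == "rim"
        assert hit.point[0] == pytest.approx(1.0, abs=1e-12)
        assert hit.normal == pytest.approx((-1.0, 0.0), abs=1e-12)

    def test_start_inside_obstacle_raises(self):
        pat = SubstratePattern(diameter=2.0, obstacles=(
            ObstacleSpec("circle", (0.0, 0.0), (0.120,)),))
        with pytest.raises(GeometryError):
            first_hit([[0.0, 0.0], [0.5, 0.0]], pat)

    def test_normal_is_unit_and_opposes_direction(self):
        pat = build_pattern("crosses_full", 2)
        rng = np.random.default_rng(3)
        found = 0
        while found < 50:
            p = rng.uniform(-0.9, 0.9, 2)
            if pat.point_in_obstacle(p[None])[0]:
                continue
            th = rng.uniform(0, 2 * np.pi)
            q = p + 0.4 * np.array([np.cos(th), np.sin(th)])
            hit = first_hit([p, q], pat)
            if hit is None:
                continue
            found += 1
            n = np.array(hit.normal)
            d = q - p
            assert np.hypot(*n) == pytest.approx(1.0, abs=1e-9)
            assert float(n @ d) < 0

    def test_grazing_cross_vs_dense_sampling_oracle(self):
        # oracle: march the segment at 0.1 um steps and find the first entry
        # into the obstacle by point membership
        pat = build_pattern("crosses_full", 2)
        rng = np.random.default_rng(12)
        checked = 0
        while checked < 30:
            p = rng.uniform(-0.5, 0.5, 2)
            if pat.point_in_obstacle(p[None])[0]:
                continue
            th = rng.uniform(0, 2 * np.pi)
            q = p + rng.uniform(0.05, 0.3) * np.array([np.cos(th), np.sin(th)])
            hit = first_hit([p, q], pat)
            n_steps = int(np.linalg.norm(q - p) / 1e-4)
            ts = np.linspace(0, 1, n_steps + 1)
            pts = p[None] + ts[:, None] * (q - p)[None]
            inside = pat.point_in_obstacle(pts)
            if hit is None or hit.boundary == "rim":
                assert not inside.any()
            else:
                first = np.flatnonzero(inside)
                assert len(first) > 0
                assert hit.t == pytest.approx(ts[first[0]], abs=2e-4 / np.linalg.norm(q - p))
            checked += 1


class TestRasterize:
    def test_empty_disc_pixel_count(self):
        mask = rasterize(build_pattern("empty", 2), resolution=0.002)
        # allowed area ~ pi R^2 within a one-pixel-perimeter band
        expected = math.pi / 0.002**2
        band = 2 * math.pi / 0.002
        assert abs(mask.allowed.sum() - expected) < band

    @pytest.mark.parametrize("kind", ["crosses_full", "circles_full",
                                      "triangles_full", "crosses_1array"])
    def test_raster_matches_analytic_fraction(self, kind):
        pat = build_pattern(kind, 2)
        mask = rasterize(pat, resolution=0.001)
        assert abs(mask.obstacle_fraction - area_fraction(pat)) < 0.002

    def test_mask_round_trip_bit_identical(self, tmp_path):
        pat = build_pattern("crosses_1array", 2)
        mask = rasterize(pat, resolution=0.005)
        save_mask(mask, tmp_path / "m.png")
        back = load_mask(tmp_path / "m.png")
        assert np.array_equal(mask.obstacle, back.obstacle)
        assert np.array_equal(mask.allowed, back.allowed)
        assert back.resolution == mask.resolution

    def test_bad_resolution(self):
        with pytest.raises(ConfigurationError):
            rasterize(build_pattern("empty", 2), resolution=0.0)


def test_pattern_json_round_trip():
    pat = build_pattern("circles_full", 2)
    back = pattern_from_json(pattern_to_json(pat))
    assert back.diameter == pat.diameter
    assert len(back.obstacles) == len(pat.obstacles)
    assert back.obstacles[0] == pat.obstacles[0]
    assert area_fraction(back) == pytest.approx(area_fraction(pat), rel=1e-12)
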