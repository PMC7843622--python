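import math

import numpy as np
import pytest

from betaplus import (
    DNAGeometry,
    Region,
    SourceVolume,
    backbone_point,
    build_geometry,
    classify_point,
    classify_points,
    default_source,
)
from betaplus.geometry import isotropic_directions, sample_source_points


def oracle_classify(geom, p):
    """Independent scalar point-in-solid test, written from the sector
    definitions directly (no shared code with classify_points)."""
    x, y, z = p
    if z < 0 or z >= geom.total_length:
        return ("outside", None, None)
    k = int(z // geom.rise_per_base)
    if k >= geom.n_bases:
        return ("outside", None, None)
    r = math.sqrt(x * x + y * y)
    if r >= geom.outer_radius:
        return ("outside", None, None)
    ang = math.degrees(math.atan2(y, x)) - geom.twist_per_base_deg * k
    ang %= 360.0
    if r < geom.base_radius:
        # strand 0 half-cylinder spans [-90, 90)
        strand = 0 if (ang < 90.0 or ang >= 270.0) else 1
        return ("base", strand, k)
    # backbone quarter sectors centred at 0 and 180 deg
    if ang < 45.0 or ang >= 315.0:
        return ("backbone", 0, k)
    if 135.0 <= ang < 225.0:
        return ("backbone", 1, k)
    return ("outside", None, None)


class TestBuildGeometry:
    def test_default_dimensions(self, geom):
        assert geom.n_bases == 100
        assert geom.total_length == 34.0
        assert geom.rise_per_base == pytest.approx(0.34)
        assert geom.outer_diameter == 2.37
        assert geom.base_diameter == 1.0
        # 2 strands x 100 bases of backbone and base volumes
        assert 2 * geom.n_bases == 200

    def test_single_base_geometry(self):
        g = build_geometry(n_bases=1)
        assert g.rise_per_base == g.total_length

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            build_geometry(base_diameter=3.0)  # larger than outer
        with pytest.raises(ValueError):
            build_geometry(n_bases=0)
        with pytest.raises(ValueError):
            build_geometry(total_length=-1.0)

    def test_yaml_round_trip(self, geom):
        assert DNAGeometry.from_yaml(geom.to_yaml()) == geom


class TestClassifyPoint:
    def test_axis_point_is_base(self, geom):
        vid = classify_point(geom, (0.0, 0.0, 17.0))
        assert vid.region is Region.BASE
        assert vid.base_index == 49  # slab floor(17/0.34)
        assert vid.strand == 0

    def test_far_point_outside(self, geom):
        vid = classify_point(geom, (2 * geom.outer_diameter, 0.0, 17.0))
        assert vid.region is Region.OUTSIDE
        assert vid.strand is None and vid.base_index is None

    def test_backbone_sectors(self, geom):
        r = 0.5 * (geom.base_radius + geom.outer_radius)
        v0 = classify_point(geom, (r, 0.0, 1.0))
        v1 = classify_point(geom, (-r, 0.0, 1.0))
        assert v0.region is Region.BACKBONE and v0.strand == 0
        assert v1.region is Region.BACKBONE and v1.strand == 1
        # annulus at 90 deg is void between the backbone sectors
        v_void = classify_point(geom, (0.0, r, 1.0))
        assert v_void.region is Region.OUTSIDE

    def test_agrees_with_brute_force_oracle(self, geom, rng):
        pts = rng.uniform([-2, -2, -2], [2, 2, 36], size=(100_000, 3))
        region, strand, base = classify_points(geom, pts)
        names = {0: "outside", 1: "backbone", 2: "base"}
        for i in rng.choice(len(pts), size=5000, replace=False):
            want = oracle_classify(geom, pts[i])
            got = (
                names[int(region[i])],
                None if region[i] == 0 else int(strand[i]),
                None if region[i] == 0 else int(base[i]),
            )
            assert got == want, pts[i]

    def test_agrees_with_oracle_when_twisted(self, rng):
        g = DNAGeometry(twist_per_base_deg=36.0)
        pts = rng.uniform([-1.5, -1.5, 0], [1.5, 1.5, 34], size=(3000, 3))
        region, strand, base = classify_points(g, pts)
        names = {0: "outside", 1: "backbone", 2: "base"}
        for i in range(len(pts)):
            want = oracle_classify(g, pts[i])
            got = (
                names[int(region[i])],
                None if region[i] == 0 else int(strand[i]),
                None if region[i] == 0 else int(base[i]),
            )
            assert got == want, pts[i]

    def test_purity(self, geom):
        p = (0.8, 0.1, 12.3)
        assert classify_point(geom, p) == classify_point(geom, p)

    def test_strand_parity_under_180_rotation(self, geom, rng):
        pts = rng.uniform([-1.2, -1.2, 0], [1.2, 1.2, 34], size=(20_000, 3))
        rotated = np.column_stack([-pts[:, 0], -pts[:, 1], pts[:, 2]])
        r1, s1, b1 = classify_points(geom, pts)
        r2, s2, b2 = classify_points(geom, rotated)
        np.testing.assert_array_equal(r1, r2)
        np.testing.assert_array_equal(b1, b2)
        inside = r1 != 0
        np.testing.assert_array_equal(s2[inside], 1 - s1[inside])

    def test_volume_fractions_match_analytic(self, geom, rng):
        # MC volume estimate over the bounding cylinder vs closed-form
        # sector volumes: bases fill the inner cylinder, backbones half
        # the annulus.
        n = 400_000
        r = geom.outer_radius * np.sqrt(rng.random(n))
        phi = rng.random(n) * 2 * np.pi
        z = rng.random(n) * geom.total_length
        pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
        region, _, _ = classify_points(geom, pts)
        cyl_area = np.pi * geom.outer_radius**2
        frac_base = np.pi * geom.base_radius**2 / cyl_area
        frac_backbone = 0.5 * (cyl_area - np.pi * geom.base_radius**2) / cyl_area
        got_base = np.mean(region == Region.BASE.value)
        got_backbone = np.mean(region == Region.BACKBONE.value)
        assert got_base == pytest.approx(frac_base, abs=4 / math.sqrt(n))
        assert got_backbone == pytest.approx(frac_backbone, abs=4 / math.sqrt(n))
        # partitions sum to the bounding cylinder
        assert got_base + got_backbone + np.mean(region == 0) == 1.0

    def test_backbone_point_helper_lands_in_its_volume(self, geom):
        for strand in (0, 1):
            for base in (0, 42, 99):
                vid = classify_point(geom, backbone_point(geom, strand, base))
                assert vid.region is Region.BACKBONE
                assert (vid.strand, vid.base_index) == (strand, base)


class TestSource:
    def test_default_source_encloses_dna(self, geom, source):
        assert source.encloses(geom)
        assert source.radius == pytest.approx(2 * geom.outer_radius)

    def test_samples_inside_bounds(self, source, rng):
        pts = sample_source_points(source, rng, 10_000)
        r = np.hypot(pts[:, 0], pts[:, 1])
        assert np.all(r <= source.radius)
        assert np.all(pts[:, 2] >= source.z_min)
        assert np.all(pts[:, 2] <= source.z_min + source.length)

    def test_mean_position_near_center(self, source, rng):
        n = 1_000_000
        pts = sample_source_points(source, rng, n)
        center_z = source.z_min + source.length / 2
        # CLT: mean within 3 sigma of the center
        for axis, mu, sigma in [
            (0, 0.0, source.radius / 2),
            (1, 0.0, source.radius / 2),
            (2, center_z, source.length / math.sqrt(12)),
        ]:
            assert abs(pts[:, axis].mean() - mu) < 3 * sigma / math.sqrt(n)

    def test_isotropic_directions_normalized(self, rng):
        v = isotropic_directions(rng, 50_000)
        np.testing.assert_allclose(np.linalg.norm(v, axis=1), 1.0, atol=1e-12)
        assert np.all(np.abs(v.mean(axis=0)) < 0.02)

    def test_invalid_source_rejected(self):
        with pytest.raises(ValueError):
            SourceVolume(radius=0.0, length=1.0)
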