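"""Centroids, axis fitting and beam casting against independent oracles."""

import numpy as np
import pytest
import shapely

from surrocor.geometry import (
    BEAM_ANGLES_DEG,
    ContourSlice,
    beam_direction,
    build_beam_length_field,
    cast_beam,
    cast_rays,
    fit_axis,
    polygon_centroid,
    ts_centroid_z,
)

from conftest import circle_contour, random_star_polygon


class TestPolygonCentroid:
    @pytest.mark.parametrize(
        "vertices,expected",
        [
            ([(0, 0), (1, 0), (1, 1), (0, 1)], (0.5, 0.5)),
            ([(0, 0), (6, 0), (0, 3)], (2.0, 1.0)),
        ],
    )
    def test_known_shapes(self, vertices, expected):
        c = polygon_centroid(ContourSlice(z=0, vertices=np.array(vertices, float)))
        assert c == pytest.approx(expected)

    def test_circle_360gon(self):
        c = polygon_centroid(circle_contour(center=(3.0, -2.0), r=10.0, n=360))
        assert c == pytest.approx((3.0, -2.0), abs=1e-9)

    def test_invariant_to_start_vertex_and_direction(self, rng):
        poly = random_star_polygon(rng)
        ref = polygon_centroid(poly)
        rolled = ContourSlice(z=0, vertices=np.roll(poly.vertices, 7, axis=0))
        reversed_ = ContourSlice(z=0, vertices=poly.vertices[::-1])
        assert polygon_centroid(rolled) == pytest.approx(ref, abs=1e-9)
        assert polygon_centroid(reversed_) == pytest.approx(ref, abs=1e-9)

    def test_uneven_vertex_density_does_not_bias(self):
        # same square, one edge heavily oversampled: area centroid unmoved
        dense = np.linspace(0, 1, 50)[:-1]
        v = np.vstack(
            [
                np.column_stack([dense, np.zeros_like(dense)]),
                [[1, 0], [1, 1], [0, 1]],
            ]
        )
        assert polygon_centroid(ContourSlice(z=0, vertices=v)) == pytest.approx(
            (0.5, 0.5)
        )

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError):
            ContourSlice(z=0, vertices=np.array([[0, 0], [1, 1], [2, 2]], float))


class TestFitAxis:
    def test_collinear_exact_recovery(self):
        zs = np.array([0.0, 5.0, 10.0, 20.0])
        cents = [((1.0 + 0.5 * z, -2.0), z) for z in zs]
        ax = fit_axis(cents)
        assert (ax.x_intercept, ax.x_slope) == pytest.approx((1.0, 0.5), abs=1e-12)
        assert (ax.y_intercept, ax.y_slope) == pytest.approx((-2.0, 0.0), abs=1e-12)

    def test_symmetric_perturbations_cancel(self):
        # perturbation pattern +d, -d, -d, +d is orthogonal to (z - mean z),
        # so the fitted slope is untouched
        cents = [((z, 0.0), z) for z in [0.0, 1.0, 2.0, 3.0]]
        d = 0.3
        pert = [
            ((0.0 + d, 0.0), 0.0),
            ((1.0 - d, 0.0), 1.0),
            ((2.0 - d, 0.0), 2.0),
            ((3.0 + d, 0.0), 3.0),
        ]
        assert fit_axis(pert).x_slope == pytest.approx(fit_axis(cents).x_slope)

    def test_three_point_closed_form(self):
        # OLS of x on z through (0,0), (1,1), (2,1): slope 1/2, intercept 1/6
        ax = fit_axis([((0.0, 0.0), 0.0), ((1.0, 0.0), 1.0), ((1.0, 0.0), 2.0)])
        assert ax.x_slope == pytest.approx(0.5)
        assert ax.x_intercept == pytest.approx(1.0 / 6.0)

    def test_slice_order_invariance(self, rng):
        cents = [((float(rng.normal()), float(rng.normal())), float(z)) for z in range(6)]
        a1, a2 = fit_axis(cents), fit_axis(cents[::-1])
        assert (a1.x_intercept, a1.x_slope, a1.y_intercept, a1.y_slope) == pytest.approx(
            (a2.x_intercept, a2.x_slope, a2.y_intercept, a2.y_slope)
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_axis([((0.0, 0.0), 1.0), ((1.0, 1.0), 1.0)])
        with pytest.raises(ValueError):
            fit_axis([((0.0, 0.0), 1.0)])


class TestCastBeam:
    def test_circle_from_center_equals_radius_every_angle(self):
        c = circle_contour(r=10.0, n=720)
        lengths = cast_rays((0.0, 0.0), BEAM_ANGLES_DEG, c)
        assert lengths == pytest.approx(np.full(180, 10.0), abs=1e-3)

    def test_offcenter_ray_circle_quadratic(self):
        c = circle_contour(r=10.0, n=14400)  # fine polygon ~ circle
        # direction (-1, 0): exits at (-10, 0), length 13
        assert cast_beam((3.0, 0.0), 0.0, c) == pytest.approx(13.0, abs=1e-3)
        # direction (0, 1): length sqrt(100 - 9)
        assert cast_beam((3.0, 0.0), 90.0, c) == pytest.approx(
            np.sqrt(91.0), abs=1e-3
        )

    def test_outermost_crossing_taken(self):
        # C-shaped fold: the +y ray from the origin crosses the boundary at
        # y = 1 (exit), 6 (re-enter) and 8 (exit); the outermost crossing is
        # the skin an optical camera sees
        v = np.array(
            [
                [-5, -1], [5, -1], [5, 8], [-5, 8],
                [-5, 6], [3, 6], [3, 1], [-5, 1],
            ],
            dtype=float,
        )
        poly = ContourSlice(z=0, vertices=v)
        assert cast_beam((0.0, 0.0), 90.0, poly) == pytest.approx(8.0, abs=1e-9)

    def test_origin_outside_is_flagged(self):
        c = circle_contour(r=10.0)
        assert np.isnan(cast_rays((30.0, 0.0), [90.0], c)[0])
        with pytest.raises(ValueError):
            cast_beam((30.0, 0.0), 90.0, c)

    def test_agrees_with_shapely_oracle_on_star_polygons(self, rng):
        for _ in range(25):
            poly = random_star_polygon(rng)
            shp = shapely.Polygon(poly.vertices)
            far = 1e4
            for theta in rng.uniform(0.0, 180.0, size=8):
                d = beam_direction(theta)
                seg = shapely.LineString([(0, 0), tuple(far * d)])
                inter = shp.boundary.intersection(seg)
                expected = max(
                    pt.distance(shapely.Point(0, 0))
                    for pt in getattr(inter, "geoms", [inter])
                )
                got = cast_rays((0.0, 0.0), [theta], poly)[0]
                assert got == pytest.approx(expected, abs=1e-6)


class TestBeamLengthField:
    def test_static_torso_constant_across_phases(self, small_phantom_config):
        from dataclasses import replace

        from surrocor.phantom import constant_field, generate_torso
        from surrocor.geometry import BodyAxis

        cfg = replace(small_phantom_config, amplitude_field=constant_field(0.0))
        phase_sets, _ = generate_torso(cfg)
        field = build_beam_length_field(phase_sets, BodyAxis(0, 0, 0, 0))
        assert np.allclose(field.lengths, field.lengths[0], atol=1e-12)

    def test_shape_contract(self, small_phantom_config):
        from surrocor.phantom import generate_torso
        from surrocor.geometry import BodyAxis

        phase_sets, _ = generate_torso(small_phantom_config)
        field = build_beam_length_field(phase_sets, BodyAxis(0, 0, 0, 0))
        assert field.lengths.shape == (10, 5, 180)
        assert field.valid.all()

    def test_anterior_lobe_moves_5mm_at_90deg(self):
        from surrocor.phantom import PhantomConfig, gaussian_lobe, generate_torso
        from surrocor.geometry import BodyAxis

        cfg = PhantomConfig(
            slice_zs=np.arange(0.0, 3.0),
            amplitude_field=gaussian_lobe(5.0, center_deg=90.0, width_deg=30.0),
        )
        phase_sets, _ = generate_torso(cfg)
        field = build_beam_length_field(phase_sets, BodyAxis(0, 0, 0, 0))
        excursion = field.lengths[:, :, 90].max(axis=0) - field.lengths[:, :, 90].min(
            axis=0
        )
        assert excursion == pytest.approx(np.full(3, 5.0), rel=0.02)


class TestTSCentroid:
    def test_weighted_and_symmetric_cases(self):
        single = [[circle_contour(z=100.0)] for _ in range(10)]
        assert ts_centroid_z(single).z_per_phase == pytest.approx(np.full(10, 100.0))

        two_equal = [[circle_contour(z=100.0), circle_contour(z=102.0)]]
        assert ts_centroid_z(two_equal).z_per_phase[0] == pytest.approx(101.0)

        # areas 1 and 3 at z = 100, 104 -> weighted mean 103
        r1, r3 = np.sqrt(1 / np.pi), np.sqrt(3 / np.pi)
        stack = [[circle_contour(z=100.0, r=r1, n=3600), circle_contour(z=104.0, r=r3, n=3600)]]
        assert ts_centroid_z(stack).z_per_phase[0] == pytest.approx(103.0, abs=1e-4)

    def test_empty_phase_rejected(self):
        with pytest.raises(ValueError):
            ts_centroid_z([[circle_contour()], []])
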