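"""Reference (CETCEM) measurement: circle fits, radial profiles, oracle checks."""

import numpy as np
import pytest

import cetcem as c
from cetcem.errors import DegenerateFitError, EdgeExtractionError, InterpolationError
from cetcem.phantom import tibia_medial_x
from cetcem.reference import FittedCircle, extract_medial_edge, point_angles_deg


class TestFitCircle:
    def test_unit_circumcircle(self):
        fc = c.fit_circle([(1.0, 0.0), (0.0, 1.0), (-1.0, 0.0)])
        assert (fc.centre_ap, fc.centre_ml) == pytest.approx((0.0, 0.0), abs=1e-9)
        assert fc.radius == pytest.approx(1.0, abs=1e-9)

    def test_analytic_circumcircle_of_three_points(self):
        # circumcircle of (3,4), (-3,4), (0,-1): centre (0, 2.4), radius 3.4
        fc = c.fit_circle([(3.0, 4.0), (-3.0, 4.0), (0.0, -1.0)])
        assert (fc.centre_ap, fc.centre_ml) == pytest.approx((0.0, 2.4), abs=1e-9)
        assert fc.radius == pytest.approx(3.4, abs=1e-9)

    def test_exact_circle_points_fit_to_machine_precision(self):
        th = np.linspace(0.2, 2.6, 57)
        pts = np.column_stack([2.0 + 5.0 * np.cos(th), 3.0 + 5.0 * np.sin(th)])
        fc = c.fit_circle(pts)
        assert fc.rms_residual < 1e-9
        assert fc.radius == pytest.approx(5.0, abs=1e-9)

    def test_noisy_circle_recovered_within_noise_scale(self):
        rng = np.random.default_rng(42)
        th = rng.uniform(0, 2 * np.pi, 100)
        r = 5.0 + rng.normal(0, 0.01, 100)
        pts = np.column_stack([2.0 + r * np.cos(th), 3.0 + r * np.sin(th)])
        fc = c.fit_circle(pts)
        assert (fc.centre_ap, fc.centre_ml) == pytest.approx((2.0, 3.0), abs=0.01)
        assert fc.radius == pytest.approx(5.0, abs=0.01)

    def test_collinear_points_rejected(self):
        xs = np.linspace(0, 10, 20)
        with pytest.raises(DegenerateFitError):
            c.fit_circle(np.column_stack([xs, 2 * xs + 1]))

    def test_near_collinear_points_rejected(self):
        xs = np.linspace(0, 10, 50)
        ys = 2 * xs + 1e-9 * (xs - 5) ** 2
        with pytest.raises(DegenerateFitError):
            c.fit_circle(np.column_stack([xs, ys]))


class TestInterpolateEdge:
    def _trace(self, pts):
        return c.EdgeTrace("tibia", "anterior", np.asarray(pts, dtype=float), 1.0)

    def test_linear_midpoint_inserted(self):
        out = c.interpolate_edge(self._trace([(0.0, 0.0), (10.0, 10.0)]), 5.0)
        assert np.allclose(out.points, [[0, 0], [5, 5], [10, 10]])

    def test_idempotent_on_nodes(self):
        trace = self._trace([(0.0, 1.0), (0.5, 1.2), (1.0, 1.1), (1.5, 0.9)])
        out = c.interpolate_edge(trace, 0.5)
        for ap, ml in trace.points:
            i = np.argmin(np.abs(out.ap - ap))
            assert out.ml[i] == pytest.approx(ml, abs=1e-12)

    def test_single_point_rejected(self):
        with pytest.raises(InterpolationError):
            c.interpolate_edge(self._trace([(0.0, 0.0)]), 0.5)

    def test_circle_radii_insensitive_to_slice_gap_size(self):
        """Phantoms meshed at 2 mm vs 0.5 mm slices fit to radii within 0.05 mm."""
        radii = {}
        for gap in (2.0, 0.5):
            spec = c.uniform_offset_spec(slice_thickness=gap)
            tibia, meniscus, _tr = c.make_phantom(spec)
            det = c.cetcem_analyse(
                c.KneeSpecimen("g", "right", tibia, meniscus), bin_mm=gap
            )
            radii[gap] = det.tibia_circles["anterior"].radius
        assert abs(radii[2.0] - radii[0.5]) < 0.05

    def test_interpolation_fills_slice_gaps(self):
        spec = c.uniform_offset_spec(slice_thickness=2.0)
        tibia, _m, _tr = c.make_phantom(spec)
        frame = c.align_to_long_axis(tibia, "right")
        lm = c.locate_spine_apex(tibia, frame)
        ant, _post = extract_medial_edge(tibia, frame, lm, "tibia", bin_mm=2.0)
        dense = c.interpolate_edge(ant, 0.1)
        assert np.max(np.diff(dense.ap)) <= 0.1 + 1e-9


class TestExtractMedialEdge:
    def test_noiseless_tibial_picks_lie_on_circle(self, uniform_phantom):
        spec, tibia, _m, _truth = uniform_phantom
        frame = c.align_to_long_axis(tibia, "right")
        lm = c.locate_spine_apex(tibia, frame)
        canon = frame.transform_points(tibia.vertices)
        for trace in extract_medial_edge(tibia, frame, lm, "tibia"):
            # picks are genuine mesh vertices; match them back and verify
            # each original vertex sits on the generating circle
            for ap, ml in trace.points:
                d2 = (canon[:, 0] - ml) ** 2 + (canon[:, 1] - ap) ** 2
                candidates = tibia.vertices[d2 < 1e-16]
                assert len(candidates)
                x, y = candidates[0][0], candidates[0][1]
                assert abs(x - float(tibia_medial_x(spec, y))) < 1e-6

    def test_split_partitions_at_apex(self, uniform_phantom):
        _spec, tibia, meniscus, _truth = uniform_phantom
        frame = c.align_to_long_axis(tibia, "right")
        lm = c.locate_spine_apex(tibia, frame)
        ant, post = extract_medial_edge(meniscus, frame, lm, "meniscus")
        assert ant.ap.max() < lm.spine_apex_ap <= post.ap.min()

    def test_strictly_ordered_in_ap(self, bump_specimen):
        det = c.cetcem_analyse(bump_specimen)
        for trace in det.meniscus_traces.values():
            assert np.all(np.diff(trace.ap) > 0)

    def test_too_few_points_is_edge_error(self, uniform_phantom):
        _spec, tibia, _m, _truth = uniform_phantom
        frame = c.align_to_long_axis(tibia, "right")
        lm = c.locate_spine_apex(tibia, frame)
        tiny = c.TriangleSurface(
            np.array([[30.0, 1.0, 1.0], [30.0, 2.0, 1.0], [30.0, 3.0, 1.0]]),
            np.empty((0, 3), dtype=int),
        )
        with pytest.raises(EdgeExtractionError):
            extract_medial_edge(tiny, frame, lm, "meniscus")


class TestRadialExtrusion:
    def test_concentric_circles_uniform_offset(self):
        tib = FittedCircle(0.0, 0.0, 25.0, 0.0, 100)
        men = FittedCircle(0.0, 0.0, 28.0, 0.0, 100)
        prof = c.radial_extrusion(tib, men, (-60.0, 60.0))
        assert prof.extrusion_mm == pytest.approx(3.0, abs=1e-12)

    def test_offset_meniscus_circle_closed_form(self):
        # men centre 1 mm medial of tib centre: e(medial ray) = 28-25 = 3,
        # e(lateral ray) = 26-25 = 1
        tib = FittedCircle(0.0, 0.0, 25.0, 0.0, 100)
        men = FittedCircle(0.0, 1.0, 27.0, 0.0, 100)
        toward_medial = c.radial_extrusion(tib, men, (-1e-9, 1e-9))
        assert toward_medial.extrusion_mm[0] == pytest.approx(3.0, abs=1e-9)
        toward_lateral = c.radial_extrusion(tib, men, (180.0 - 1e-9, 180.0 + 1e-9))
        assert toward_lateral.extrusion_mm[0] == pytest.approx(1.0, abs=1e-9)

    def test_meniscus_inside_rim_gives_negative_extrusion(self):
        tib = FittedCircle(0.0, 0.0, 25.0, 0.0, 100)
        men = FittedCircle(0.0, 0.0, 24.0, 0.0, 100)
        prof = c.radial_extrusion(tib, men, (-45.0, 45.0))
        assert prof.extrusion_mm == pytest.approx(-1.0, abs=1e-12)

    def test_missed_rays_dropped_with_warning(self):
        tib = FittedCircle(0.0, 0.0, 25.0, 0.0, 100)
        men = FittedCircle(0.0, 40.0, 5.0, 0.0, 100)  # small, far medial
        with pytest.warns(UserWarning, match="dropped"):
            prof = c.radial_extrusion(tib, men, (-80.0, 80.0))
        assert len(prof.angle_deg) < 161

    def test_no_overlap_is_error(self):
        tib = FittedCircle(0.0, 0.0, 25.0, 0.0, 100)
        men = FittedCircle(200.0, 0.0, 5.0, 0.0, 100)
        with pytest.raises(c.CetcemError):
            c.radial_extrusion(tib, men, (-10.0, 10.0))


class TestCetcemMeasure:
    def test_uniform_phantom_measures_three_mm(self, uniform_specimen):
        res = c.cetcem_measure(uniform_specimen)
        assert res.method == "CETCEM"
        assert res.max_extrusion == pytest.approx(3.0, abs=0.05)
        assert res.extruded is c.classify_extruded(res.max_extrusion)

    def test_bump_phantom_peak_recovered(self, bump_phantom, bump_specimen):
        spec, _t, _m, truth = bump_phantom
        res = c.cetcem_measure(bump_specimen)
        assert res.max_extrusion == pytest.approx(truth.true_max_extrusion, abs=0.2)
        assert res.location_ap == pytest.approx(truth.true_max_ap_location, abs=1.0)

    def test_location_pct_consistent(self, bump_specimen):
        det = c.cetcem_analyse(bump_specimen)
        res = det.result
        assert res.location_pct == pytest.approx(
            100.0 * res.location_ap / det.landmarks.ap_breadth
        )

    def test_support_not_extrapolated_beyond_horns(self, bump_specimen):
        det = c.cetcem_analyse(bump_specimen)
        for region, prof in det.profiles.items():
            raw = det.meniscus_traces[region]
            angles = point_angles_deg(det.tibia_circles[region], raw.points)
            assert prof.angle_deg.min() >= angles.min() - 2.0 - 1e-9
            assert prof.angle_deg.max() <= angles.max() + 2.0 + 1e-9


class TestOracle:
    def test_uniform_phantom_oracle_constant(self):
        spec = c.uniform_offset_spec(slice_thickness=0.25)
        tibia, meniscus, _tr = c.make_phantom(spec)
        det = c.cetcem_analyse(
            c.KneeSpecimen("u", "right", tibia, meniscus), bin_mm=0.25
        )
        for region in ("anterior", "posterior"):
            orc = c.oracle_perpendicular_extrusion(
                det.tibia_traces[region], det.meniscus_traces[region]
            )
            inner = orc[(orc[:, 0] > orc[:, 0].min() + 1.5) & (orc[:, 0] < orc[:, 0].max() - 1.5)]
            assert inner[:, 1] == pytest.approx(3.0, abs=0.01)

    def test_coincident_point_gives_zero(self):
        tib = c.EdgeTrace(
            "tibia", "anterior", np.array([[0.0, 0.0], [1.0, 0.5], [2.0, 0.7]]), 1.0
        )
        men = c.EdgeTrace("meniscus", "anterior", np.array([[1.0, 0.5], [1.5, 0.6], [2.0, 0.7]]), 1.0)
        orc = c.oracle_perpendicular_extrusion(tib, men)
        assert orc[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_oracle_matches_circle_profile_on_circular_phantoms(self):
        """Model-free polyline oracle vs circle-based profile, 3 phantoms."""
        rng = np.random.default_rng(5)
        for _ in range(3):
            spec = c.PhantomSpec.standard(
                ap_breadth=float(rng.uniform(48, 58)),
                spine_apex_ap=float(rng.uniform(28, 32)),
                r_ant=28.0,
                extrusion=c.ExtrusionModel(float(rng.uniform(1, 5)), 0.0),
                meniscus_support_deg=(-60.0, 40.0),
                slice_thickness=0.5,
            )
            tibia, meniscus, _tr = c.make_phantom(spec)
            det = c.cetcem_analyse(c.KneeSpecimen("o", "right", tibia, meniscus))
            for region in ("anterior", "posterior"):
                prof = det.profiles[region]
                orc = c.oracle_perpendicular_extrusion(
                    det.tibia_traces[region], det.meniscus_traces[region]
                )
                order = np.argsort(orc[:, 0])
                o_ap, o_d = orc[order, 0], orc[order, 1]
                sel = (prof.ap_mm >= o_ap[0] + 1.5) & (prof.ap_mm <= o_ap[-1] - 1.5)
                got = prof.extrusion_mm[sel]
                want = np.interp(prof.ap_mm[sel], o_ap, o_d)
                assert np.abs(got - want).max() < 0.1
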