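import numpy as np
import pytest

from bifusion.angio_centerline import Centerline3D
from bifusion.contour_io import Contour, IVUSFrame, Pullback
from bifusion.frame_geometry import (
    CatheterPath,
    FrameGeometryError,
    _rotate2d,
    compute_rmf,
    correct_catheter_path,
    correct_relative_twist,
    frame_spacing,
    pairwise_twist,
    place_frames,
    radial_profile,
    register_carina,
    select_gated_frames,
)
from conftest import circle_points, ellipse_points, star_points


def make_pullback(n_frames, gated_every=1, contours_for=None, speed=0.5, rate=30.0,
                  carina_frame=0, carina_direction=0.0):
    frames = []
    for i in range(n_frames):
        cs = []
        if contours_for is not None:
            cs = contours_for(i)
        frames.append(
            IVUSFrame(
                frame_index=i,
                catheter_point=np.zeros(2),
                contours=cs,
                gated=(i % gated_every == 0),
            )
        )
    return Pullback(
        branch="MV", frames=frames, pullback_speed=speed, frame_rate=rate,
        carina_frame=carina_frame, carina_direction=carina_direction,
    )


class TestFrameSpacing:
    def test_half_speed_printed_value(self):
        # 0.5 mm/s at 30 frames/s: printed inter-frame distance 0.017 mm
        assert round(frame_spacing(0.5, 30.0), 3) == 0.017

    def test_full_speed_printed_value(self):
        # 1.0 mm/s at 30 frames/s: printed inter-frame distance 0.033 mm
        assert round(frame_spacing(1.0, 30.0), 3) == 0.033

    @pytest.mark.parametrize("speed,rate", [(0, 30), (0.5, 0), (-1, 30)])
    def test_nonpositive_inputs_rejected(self, speed, rate):
        with pytest.raises(FrameGeometryError):
            frame_spacing(speed, rate)


class TestGating:
    def test_every_30th_gated(self):
        p = make_pullback(300, gated_every=30)
        out = select_gated_frames(p)
        assert len(out.frames) == 10
        assert [f.frame_index for f in out.frames] == list(range(0, 300, 30))

    def test_all_gated_identity(self):
        p = make_pullback(20)
        out = select_gated_frames(p)
        assert len(out.frames) == 20

    def test_ungated_carina_rejected(self):
        p = make_pullback(10, gated_every=2, carina_frame=3)
        with pytest.raises(FrameGeometryError, match="carina"):
            select_gated_frames(p)

    def test_zero_gated_rejected(self):
        p = make_pullback(5)
        for f in p.frames:
            f.gated = False
        with pytest.raises(FrameGeometryError):
            select_gated_frames(p)


class TestRMF:
    def test_straight_line_constant_triads(self):
        cl = Centerline3D(points=np.stack([np.zeros(20), np.zeros(20), np.linspace(0, 10, 20)], axis=1))
        tr = compute_rmf(cl)
        for t in tr:
            np.testing.assert_allclose(t, tr[0], atol=1e-12)

    def test_orthonormal_right_handed(self, rng):
        t = np.linspace(0, 4 * np.pi, 150)
        cl = Centerline3D(points=np.stack([2 * np.cos(t), 2 * np.sin(t), 3 * t], axis=1))
        tr = compute_rmf(cl)
        gram = np.einsum("nij,nkj->nik", tr, tr)
        assert np.abs(gram - np.eye(3)).max() < 1e-9
        assert np.linalg.det(tr).min() > 1 - 1e-9

    def test_planar_semicircle_zero_twist(self):
        t = np.linspace(0, np.pi, 100)
        cl = Centerline3D(points=np.stack([np.cos(t), np.sin(t), np.zeros_like(t)], axis=1))
        tr = compute_rmf(cl)
        # the out-of-plane axis stays fixed; in-plane twist is zero
        normal = np.array([0.0, 0.0, 1.0])
        out_of_plane = tr[:, 1] if abs(tr[0, 1] @ normal) > 0.9 else tr[:, 2]
        assert np.abs(np.abs(out_of_plane @ normal) - 1).max() < 1e-9

    def test_helix_vs_fine_transport_oracle(self):
        # oracle: the same transport at 100x resolution; compare twist about
        # the (slightly different) local tangent
        t1 = np.linspace(0, 2 * np.pi, 100)
        t2 = np.linspace(0, 2 * np.pi, 10000)

        def helix(t):
            return np.stack([2 * np.cos(t), 2 * np.sin(t), 10 * t / (2 * np.pi)], axis=1)

        tr1 = compute_rmf(Centerline3D(points=helix(t1)))
        tr2 = compute_rmf(Centerline3D(points=helix(t2)))
        devs = []
        for i in range(100):
            j = round(i * 9999 / 99)
            tt, uu, vv = tr2[j]
            u1 = tr1[i, 1]
            up = u1 - (u1 @ tt) * tt
            up /= np.linalg.norm(up)
            devs.append(np.degrees(np.arctan2(up @ vv, up @ uu)))
        assert np.abs(devs).max() < 0.1

    def test_zero_length_segment_rejected(self):
        from bifusion.angio_centerline import AngioError

        with pytest.raises((FrameGeometryError, AngioError)):
            cl = Centerline3D(points=np.array([[0, 0, 0], [0, 0, 0], [0, 0, 1.0]]))
            compute_rmf(cl)


class TestPlaceFrames:
    def _line(self, length=10.0, n=101):
        return Centerline3D(
            points=np.stack([np.zeros(n), np.zeros(n), np.linspace(0, length, n)], axis=1)
        )

    def test_eleven_frames_spacing_one(self):
        p = make_pullback(11, speed=30.0, rate=30.0)  # 1 mm per frame
        pls = place_frames(p, self._line(10.0))
        np.testing.assert_allclose([pl.s for pl in pls], np.arange(11.0), atol=1e-9)

    def test_centered_circle_centroid_on_centerline(self):
        def contours(i):
            return [Contour(frame_index=i, label="lumen", points=circle_points(64, 1.0))]

        p = make_pullback(5, contours_for=contours, speed=30.0, rate=30.0)
        pls = place_frames(p, self._line(10.0))
        for f, pl in zip(p.frames, pls):
            pts3 = pl.to_world(f.contour("lumen").points)
            centroid = pts3.mean(axis=0)
            cl_point = pl.origin
            assert np.linalg.norm(centroid - cl_point) < 1e-9

    def test_overhang_rejected_with_length(self):
        p = make_pullback(12, speed=30.0, rate=30.0)
        with pytest.raises(FrameGeometryError, match="exceeds"):
            place_frames(p, self._line(10.0))

    def test_span_equals_gated_spacing_times_gaps(self):
        p = make_pullback(300, gated_every=30, speed=0.5, rate=30.0)
        gated = select_gated_frames(p)
        cl = self._line(20.0)
        pls = place_frames(gated, cl)
        spacing = frame_spacing(0.5, 30.0) * 30
        assert pls[-1].s - pls[0].s == pytest.approx(
            (len(gated.frames) - 1) * spacing, abs=1e-12
        )


class TestTwist:
    def test_injected_rotation_recovered(self):
        ell = ellipse_points(180, 2.0, 1.0)
        frames = [_rotate2d(ell, 15.0 * k) for k in range(5)]

        def contours(i):
            return [Contour(frame_index=i, label="lumen", points=frames[i])]

        p = make_pullback(5, contours_for=contours)
        cum = correct_relative_twist(p)
        np.testing.assert_allclose(cum, [-15.0 * k for k in range(5)], atol=0.11)

    def test_circles_tie_break_to_zero(self):
        circ = circle_points(360, 1.0)

        def contours(i):
            return [Contour(frame_index=i, label="lumen", points=circ.copy())]

        p = make_pullback(4, contours_for=contours)
        cum = correct_relative_twist(p)
        np.testing.assert_allclose(cum, 0.0, atol=1e-12)

    def test_matches_exhaustive_brute_force(self, rng):
        # oracle: exhaustive 0.1-degree scan of the same radial-profile MSE
        from bifusion.frame_geometry import _pick_by_tiebreak, _profile_mse

        for _ in range(10):
            fixed = star_points(rng)
            true = rng.uniform(-30, 30)
            moving = _rotate2d(fixed, true)
            got = pairwise_twist(fixed, moving)

            f0 = fixed - fixed.mean(axis=0)
            m0 = moving - moving.mean(axis=0)
            pf, _ = radial_profile(f0, 360)
            pm, _ = radial_profile(m0, 360)
            thetas = np.arange(-45.0, 45.05, 0.1)
            costs = _profile_mse(pm, pf, thetas)
            oracle = _pick_by_tiebreak(thetas, costs)
            assert abs(got - oracle) <= 0.1 + 1e-9

    def test_random_walk_recovery_rmse(self, rng):
        base = star_points(np.random.default_rng(7), n=240)
        for seed in range(5):
            r = np.random.default_rng(seed)
            tw = np.concatenate([[0.0], np.cumsum(r.normal(0, 2.0, 49))])
            frames = [_rotate2d(base, w) for w in tw]

            def contours(i):
                return [Contour(frame_index=i, label="lumen", points=frames[i])]

            p = make_pullback(50, contours_for=contours)
            cum = correct_relative_twist(p)
            rmse = np.sqrt(np.mean((cum + tw) ** 2))
            assert rmse < 2.0

    def test_missing_lumen_names_frame(self):
        def contours(i):
            if i == 2:
                return []
            return [Contour(frame_index=i, label="lumen", points=circle_points(32))]

        p = make_pullback(4, contours_for=contours)
        with pytest.raises(FrameGeometryError, match="2"):
            correct_relative_twist(p)


class TestRegisterCarina:
    def _scenario(self, angle_deg, carina_direction=90.0):
        """Straight MV along z, SB leaving at `angle_deg` toward +x."""
        from bifusion.phantom_sim import PhantomSpec, RadiusProfile, make_phantom, simulate_pullback

        spec = PhantomSpec(
            mv_control_points=np.array(
                [[0, 0, 0], [5, 0.4, 0.2], [10, 0.8, 0.5], [15, 0.5, 0.9], [20, 0.1, 1.3]]
            ),
            sb_takeoff_s=11.0,
            sb_length=7.0,
            bifurcation_angle=angle_deg,
            seed=3,
        )
        ph = make_phantom(spec, with_meshes=False)
        mv_pb, _ = simulate_pullback(ph, "MV", seed=4)
        sb_pb, _ = simulate_pullback(ph, "SB", seed=5)
        return ph, mv_pb, sb_pb

    @pytest.mark.parametrize("angle", np.linspace(30, 90, 10))
    def test_residual_below_half_degree(self, angle):
        ph, mv_pb, sb_pb = self._scenario(angle)
        mv_pl = place_frames(mv_pb, ph.mv_centerline)
        sb_pl = place_frames(sb_pb, ph.sb_centerline)
        _, _, res = register_carina(
            mv_pl, sb_pl, mv_pb, sb_pb, ph.mv_centerline, ph.sb_centerline
        )
        assert res["MV"] < 0.5
        assert res["SB"] < 0.5

    def test_aligned_input_zero_roll(self):
        ph, mv_pb, sb_pb = self._scenario(60.0)
        mv_pl = place_frames(mv_pb, ph.mv_centerline)
        sb_pl = place_frames(sb_pb, ph.sb_centerline)
        mv_out, sb_out, _ = register_carina(
            mv_pl, sb_pl, mv_pb, sb_pb, ph.mv_centerline, ph.sb_centerline
        )
        # simulator annotations already use the geometric convention, so the
        # global roll is (nearly) zero
        assert abs(mv_out[0].roll) < 0.5
        assert abs(sb_out[0].roll) < 0.5

    def test_missing_carina_frame_rejected(self):
        ph, mv_pb, sb_pb = self._scenario(60.0)
        mv_pl = place_frames(mv_pb, ph.mv_centerline)[1:]  # drop the frame list head
        sb_pl = place_frames(sb_pb, ph.sb_centerline)
        if mv_pb.carina_frame == mv_pl[0].frame_index:
            pytest.skip("carina frame not at list head in this scenario")
        mv_pl = [pl for pl in mv_pl if pl.frame_index != mv_pb.carina_frame]
        with pytest.raises(FrameGeometryError):
            register_carina(mv_pl, sb_pl, mv_pb, sb_pb, ph.mv_centerline, ph.sb_centerline)


class TestPlacementExport:
    def test_csv_round_trip_fields(self, tmp_path):
        import csv

        from bifusion.frame_geometry import write_placements_csv

        cl = Centerline3D(
            points=np.stack([np.zeros(21), np.zeros(21), np.linspace(0, 10, 21)], axis=1)
        )
        p = make_pullback(6, speed=30.0, rate=30.0)
        pls = place_frames(p, cl)
        path = tmp_path / "placements.csv"
        write_placements_csv(path, pls)
        rows = list(csv.DictReader(open(path)))
        assert len(rows) == 6
        from scipy.spatial.transform import Rotation

        for row, pl in zip(rows, pls):
            assert int(row["frame_index"]) == pl.frame_index
            assert float(row["s_mm"]) == pytest.approx(pl.s, abs=1e-6)
            q = [float(row[k]) for k in ("qx", "qy", "qz", "qw")]
            m = Rotation.from_quat(q).as_matrix()
            np.testing.assert_allclose(m.T, pl.triad, atol=1e-9)


class TestCatheterPath:
    def test_collinear_unchanged(self):
        pts = np.stack([np.zeros(20), np.zeros(20), np.linspace(0, 10, 20)], axis=1)
        out = correct_catheter_path(CatheterPath(points=pts))
        assert not out.outlier_mask.any()
        np.testing.assert_allclose(out.points, pts, atol=1e-9)

    def test_single_displaced_point_recovered(self):
        pts = np.stack([np.linspace(0, 20, 41), np.zeros(41), np.zeros(41)], axis=1)
        pts[20, 1] += 1.0
        out = correct_catheter_path(CatheterPath(points=pts))
        assert out.outlier_mask[20]
        assert abs(out.points[20, 1]) < 0.05

    def test_noise_mse_reduced(self):
        t = np.linspace(0, 4 * np.pi, 80)
        truth = np.stack([t, np.sin(t / 2), 0.2 * t], axis=1)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            noisy = truth + rng.normal(0, 0.1, truth.shape)
            out = correct_catheter_path(CatheterPath(points=noisy))
            mse_raw = np.mean((noisy - truth) ** 2)
            mse_corr = np.mean((out.points - truth) ** 2)
            assert mse_corr < mse_raw

    def test_too_few_points_rejected(self):
        with pytest.raises(FrameGeometryError):
            correct_catheter_path(CatheterPath(points=np.zeros((4, 3))))
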