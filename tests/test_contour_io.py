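import json

import numpy as np
import pytest

from bifusion.contour_io import (
    Contour,
    ContourValidationError,
    IVUSFrame,
    Pullback,
    SchemaError,
    SurfaceMesh,
    read_contour_stack,
    read_mesh,
    read_ply,
    shoelace_area,
    write_contour_stack,
    write_mesh,
    write_metrics_report,
)
from conftest import circle_points, tube_mesh


def simple_pullback(branch="MV"):
    frames = [
        IVUSFrame(
            frame_index=i,
            catheter_point=np.array([0.05 * i, -0.02 * i]),
            contours=[
                Contour(frame_index=i, label="lumen", points=circle_points(32, 1.5)),
                Contour(frame_index=i, label="eem", points=circle_points(32, 2.2)),
                Contour(
                    frame_index=i,
                    label="calcium",
                    points=circle_points(16, 0.2, center=(1.8, 0.0)),
                ),
            ],
            gated=(i % 2 == 0),
        )
        for i in range(5)
    ]
    return Pullback(
        branch=branch,
        frames=frames,
        pullback_speed=0.5,
        frame_rate=30.0,
        carina_frame=2,
        carina_direction=45.0,
    )


class TestContour:
    def test_rejects_two_point_polygon(self):
        with pytest.raises(ContourValidationError):
            Contour(frame_index=0, label="lumen", points=[[0, 0], [1, 1]])

    def test_rejects_self_intersection(self):
        bowtie = [[0, 0], [1, 1], [1, 0], [0, 1]]
        with pytest.raises(ContourValidationError, match="frame 3"):
            Contour(frame_index=3, label="lumen", points=bowtie)

    def test_rejects_unknown_label(self):
        with pytest.raises(ContourValidationError):
            Contour(frame_index=0, label="thrombus", points=circle_points(8))

    def test_rejects_nonfinite(self):
        pts = circle_points(8)
        pts[2, 0] = np.nan
        with pytest.raises(ContourValidationError):
            Contour(frame_index=0, label="lumen", points=pts)

    def test_clockwise_rewound_with_area_preserved(self, rng):
        # oracle: shoelace area of the raw (reversed) ring
        for _ in range(20):
            pts = circle_points(24, rng.uniform(0.5, 2.0))
            pts += rng.normal(0, 0.02, pts.shape)
            raw_area = abs(shoelace_area(pts))
            c = Contour(frame_index=0, label="lumen", points=pts[::-1])
            assert shoelace_area(c.points) > 0  # CCW after normalization
            assert c.area == pytest.approx(raw_area, abs=1e-12)

    def test_winding_area_matches_shoelace_for_random_polygons(self, rng):
        from conftest import star_points

        for _ in range(100):
            pts = star_points(rng)
            if rng.random() < 0.5:
                pts = pts[::-1]
            c = Contour(frame_index=0, label="lumen", points=pts)
            assert c.area == pytest.approx(abs(shoelace_area(pts)), rel=1e-12)


class TestIVUSFrame:
    def test_two_lumens_rejected(self):
        cs = [
            Contour(frame_index=0, label="lumen", points=circle_points(16, 1.0)),
            Contour(frame_index=0, label="lumen", points=circle_points(16, 1.1)),
        ]
        with pytest.raises(ContourValidationError):
            IVUSFrame(frame_index=0, catheter_point=np.zeros(2), contours=cs)

    def test_eem_must_enclose_lumen(self):
        cs = [
            Contour(frame_index=0, label="lumen", points=circle_points(16, 2.0)),
            Contour(frame_index=0, label="eem", points=circle_points(16, 1.0)),
        ]
        with pytest.raises(ContourValidationError, match="EEM"):
            IVUSFrame(frame_index=0, catheter_point=np.zeros(2), contours=cs)

    def test_plaque_outside_eem_rejected(self):
        cs = [
            Contour(frame_index=0, label="eem", points=circle_points(16, 1.0)),
            Contour(
                frame_index=0,
                label="calcium",
                points=circle_points(16, 0.3, center=(5.0, 0.0)),
            ),
        ]
        with pytest.raises(ContourValidationError, match="calcium"):
            IVUSFrame(frame_index=0, catheter_point=np.zeros(2), contours=cs)


class TestPullback:
    def test_frame_indices_strictly_increasing(self):
        f = [
            IVUSFrame(frame_index=i, catheter_point=np.zeros(2))
            for i in (0, 1, 1)
        ]
        with pytest.raises(ContourValidationError):
            Pullback(
                branch="MV", frames=f, pullback_speed=0.5, frame_rate=30,
                carina_frame=0, carina_direction=0.0,
            )

    def test_carina_frame_must_exist(self):
        f = [IVUSFrame(frame_index=i, catheter_point=np.zeros(2)) for i in range(3)]
        with pytest.raises(ContourValidationError):
            Pullback(
                branch="MV", frames=f, pullback_speed=0.5, frame_rate=30,
                carina_frame=7, carina_direction=0.0,
            )

    @pytest.mark.parametrize("speed", [0.0, -1.0])
    def test_positive_speed_required(self, speed):
        f = [IVUSFrame(frame_index=0, catheter_point=np.zeros(2))]
        with pytest.raises(ContourValidationError):
            Pullback(
                branch="MV", frames=f, pullback_speed=speed, frame_rate=30,
                carina_frame=0, carina_direction=0.0,
            )


class TestContourStackIO:
    def test_round_trip_identity(self, tmp_path):
        p = simple_pullback()
        path = tmp_path / "stack.json"
        write_contour_stack(path, p)
        q = read_contour_stack(path)
        assert q.branch == p.branch
        assert q.pullback_speed == p.pullback_speed
        assert q.frame_rate == p.frame_rate
        assert q.carina_frame == p.carina_frame
        assert q.carina_direction == p.carina_direction
        assert [f.frame_index for f in q.frames] == [f.frame_index for f in p.frames]
        for fa, fb in zip(p.frames, q.frames):
            assert fa.gated == fb.gated
            np.testing.assert_allclose(fa.catheter_point, fb.catheter_point, atol=1e-9)
            for ca, cb in zip(fa.contours, fb.contours):
                assert ca.label == cb.label
                np.testing.assert_allclose(ca.points, cb.points, atol=1e-9)

    def test_degenerate_polygon_in_file_rejected(self, tmp_path):
        doc = {
            "branch": "MV",
            "pullback_speed_mm_s": 0.5,
            "frame_rate_fps": 30,
            "carina_frame": 0,
            "carina_direction_deg": 0,
            "frames": [
                {
                    "frame_index": 0,
                    "gated": True,
                    "catheter_point_mm": [0, 0],
                    "contours": [
                        {"label": "lumen", "component_id": 0, "points_mm": [[0, 0], [1, 1]]}
                    ],
                }
            ],
        }
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ContourValidationError):
            read_contour_stack(path)

    def test_schema_error_names_missing_field(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"branch": "MV", "frames": []}))
        with pytest.raises(SchemaError, match="pullback_speed_mm_s"):
            read_contour_stack(path)

    def test_clockwise_polygon_accepted_and_rewound(self, tmp_path):
        pts = circle_points(16, 1.0)[::-1]  # CW in file
        doc = {
            "branch": "SB",
            "pullback_speed_mm_s": 1.0,
            "frame_rate_fps": 30,
            "carina_frame": 0,
            "carina_direction_deg": 0,
            "frames": [
                {
                    "frame_index": 0,
                    "gated": True,
                    "catheter_point_mm": [0, 0],
                    "contours": [
                        {"label": "lumen", "component_id": 0, "points_mm": pts.tolist()}
                    ],
                }
            ],
        }
        path = tmp_path / "cw.json"
        path.write_text(json.dumps(doc))
        pb = read_contour_stack(path)
        c = pb.frames[0].contour("lumen")
        assert shoelace_area(c.points) > 0
        assert c.area == pytest.approx(abs(shoelace_area(pts)), rel=1e-12)


class TestMeshIO:
    def test_unit_cube_stl_has_12_facets(self, tmp_path):
        v = np.array(
            [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], dtype=float
        )
        f = np.array(
            [
                [0, 1, 3], [0, 3, 2], [4, 6, 7], [4, 7, 5],
                [0, 4, 5], [0, 5, 1], [2, 3, 7], [2, 7, 6],
                [0, 2, 6], [0, 6, 4], [1, 5, 7], [1, 7, 3],
            ]
        )
        mesh = SurfaceMesh(vertices=v, triangles=f, label="cube")
        path = tmp_path / "cube.stl"
        write_mesh(mesh, path, format="stl")
        back = read_mesh(path)
        assert len(back.triangles) == 12

    def test_ply_round_trip(self, tmp_path):
        mesh = tube_mesh([1.0, 1.0, 1.0], 0.5, n_theta=32)
        path = tmp_path / "tube.ply"
        write_mesh(mesh, path, format="ply")
        back = read_ply(path)
        assert len(back.vertices) == len(mesh.vertices)
        assert len(back.triangles) == len(mesh.triangles)
        np.testing.assert_allclose(back.vertices, mesh.vertices, atol=1e-6)

    def test_empty_mesh_rejected(self, tmp_path):
        mesh = SurfaceMesh(vertices=np.zeros((0, 3)), triangles=np.zeros((0, 3), int))
        with pytest.raises(ValueError):
            write_mesh(mesh, tmp_path / "empty.stl")

    def test_non_watertight_warns_but_writes(self, tmp_path):
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        f = np.array([[0, 1, 2]])
        mesh = SurfaceMesh(vertices=v, triangles=f, label="open")
        path = tmp_path / "open.stl"
        with pytest.warns(UserWarning, match="watertight"):
            write_mesh(mesh, path, format="stl")
        assert path.exists()

    def test_stl_preserves_triangle_count(self, tmp_path):
        mesh = tube_mesh([1.0, 1.2, 1.1], 0.5, n_theta=48)
        path = tmp_path / "t.stl"
        write_mesh(mesh, path)
        assert len(read_mesh(path).triangles) == len(mesh.triangles)


class TestMetricsReportIO:
    def _report(self, n=5):
        from bifusion.validation_metrics import ComparisonReport

        rep = ComparisonReport()
        rep.branches["MV"] = {
            "slope": 1.0, "intercept": 0.0, "r_squared": 0.99, "p_value": 1e-10,
            "n_matched": n, "n_dropped": 0, "bland_altman": (0.001, -0.01, 0.012),
            "shape_median_a": 0.9, "shape_iqr_a": 0.05,
            "shape_median_b": 0.91, "shape_iqr_b": 0.04,
        }
        rep.sections = [
            {
                "branch": "MV", "s_mm": 0.1 * i, "diameter_a_mm": 3.0 + 0.01 * i,
                "diameter_b_mm": 3.0, "shape_ratio_a": 0.9, "shape_ratio_b": 0.91,
            }
            for i in range(n)
        ]
        return rep

    def test_row_count_and_summary(self, tmp_path):
        import csv

        path = tmp_path / "report.csv"
        write_metrics_report(self._report(5), path)
        rows = list(csv.reader(open(path)))
        header = rows[0]
        data = [r for r in rows[1:] if r and r[0] == "MV"]
        assert len(data) == 5
        assert any(r and r[0] == "MV_slope" for r in rows)

    def test_reread_values_match(self, tmp_path):
        import csv

        rep = self._report(4)
        path = tmp_path / "report.csv"
        write_metrics_report(rep, path)
        rows = [r for r in csv.reader(open(path)) if r and r[0] == "MV"]
        for row, sec in zip(rows, rep.sections):
            assert float(row[1]) == pytest.approx(sec["s_mm"], abs=1e-6)
            assert float(row[2]) == pytest.approx(sec["diameter_a_mm"], rel=1e-5)

    def test_empty_sections_header_only_with_warning(self, tmp_path):
        from bifusion.validation_metrics import ComparisonReport

        rep = ComparisonReport()
        path = tmp_path / "empty.csv"
        with pytest.warns(UserWarning):
            write_metrics_report(rep, path)
        content = path.read_text().strip().splitlines()
        assert content[0].startswith("branch,")
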