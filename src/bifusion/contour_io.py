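"""Data model for segmented IVUS pullbacks and file I/O.

Contour stacks travel as JSON (one file per pullback); meshes as binary STL
or ASCII PLY; metric reports as RFC-4180 CSV.  Contour coordinates are 2D mm
in the frame plane with the catheter (transducer) point at the origin.
Frames are ordered distal-to-proximal, the pullback direction.
"""

from __future__ import annotations

import json
import logging
import struct
import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

from . import _mesh
from .angio_centerline import Centerline3D

log = logging.getLogger(__name__)

CONTOUR_LABELS = ("lumen", "eem", "calcium", "fibrosis", "fibrolipid")


class ContourValidationError(ValueError):
    """A contour or pullback violates its structural invariants."""


class SchemaError(ValueError):
    """A contour-stack file does not conform to the JSON schema."""


def shoelace_area(points: np.ndarray) -> float:
    """Signed polygon area; positive for counter-clockwise winding."""
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass
class Contour:
    """A closed 2D ring in a frame plane (mm, catheter point at the origin)."""

    frame_index: int
    label: str
    points: np.ndarray  # (n, 2), CCW
    component_id: int = 0

    def __post_init__(self):
        if self.label not in CONTOUR_LABELS:
            raise ContourValidationError(
                f"unknown contour label {self.label!r}; expected one of {CONTOUR_LABELS}"
            )
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ContourValidationError(
                f"frame {self.frame_index}: contour points must be an (n, 2) array"
            )
        if len(pts) < 3:
            raise ContourValidationError(
                f"frame {self.frame_index}: polygon needs >= 3 points, got {len(pts)}"
            )
        if not np.all(np.isfinite(pts)):
            raise ContourValidationError(
                f"frame {self.frame_index}: non-finite contour coordinates"
            )
        # drop an explicitly repeated closing point
        if np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        poly = _ShapelyPolygon(pts)
        if not poly.is_simple or poly.area <= 0:
            raise ContourValidationError(
                f"frame {self.frame_index}: self-intersecting or degenerate "
                f"{self.label} polygon"
            )
        if shoelace_area(pts) < 0:  # normalize winding, keep geometry
            pts = pts[::-1].copy()
        self.points = pts

    @property
    def area(self) -> float:
        return shoelace_area(self.points)

    @property
    def centroid(self) -> np.ndarray:
        return np.asarray(_ShapelyPolygon(self.points).centroid.coords[0])

    def polygon(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.points)


@dataclass
class IVUSFrame:
    frame_index: int
    catheter_point: np.ndarray  # 2D image mm
    contours: list[Contour] = field(default_factory=list)
    gated: bool = True

    def __post_init__(self):
        self.catheter_point = np.asarray(self.catheter_point, dtype=float)
        if self.catheter_point.shape != (2,):
            raise ContourValidationError(
                f"frame {self.frame_index}: catheter point must be a 2D coordinate"
            )
        lumens = [c for c in self.contours if c.label == "lumen"]
        if len(lumens) > 1:
            raise ContourValidationError(
                f"frame {self.frame_index}: more than one lumen contour"
            )
        eems = [c for c in self.contours if c.label == "eem"]
        if eems and lumens:
            eem_poly = eems[0].polygon().buffer(1e-6)
            if not eem_poly.contains(lumens[0].polygon()):
                raise ContourValidationError(
                    f"frame {self.frame_index}: EEM does not enclose the lumen"
                )
        if eems:
            eem_poly = eems[0].polygon().buffer(1e-6)
            for c in self.contours:
                if c.label in ("calcium", "fibrosis", "fibrolipid"):
                    if not eem_poly.contains(c.polygon()):
                        raise ContourValidationError(
                            f"frame {self.frame_index}: {c.label} component "
                            f"{c.component_id} lies outside the EEM"
                        )

    def contour(self, label: str) -> Contour | None:
        for c in self.contours:
            if c.label == label:
                return c
        return None


@dataclass
class Pullback:
    branch: str  # "MV" or "SB"
    frames: list[IVUSFrame]
    pullback_speed: float  # mm/s
    frame_rate: float  # frames/s
    carina_frame: int
    carina_direction: float  # degrees in the carina frame's plane

    def __post_init__(self):
        if self.branch not in ("MV", "SB"):
            raise ContourValidationError(f"branch must be 'MV' or 'SB', got {self.branch!r}")
        if self.pullback_speed <= 0:
            raise ContourValidationError("pullback_speed must be positive")
        if self.frame_rate <= 0:
            raise ContourValidationError("frame_rate must be positive")
        idx = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ContourValidationError("frame indices must be strictly increasing")
        if self.carina_frame not in idx:
            raise ContourValidationError(
                f"carina_frame {self.carina_frame} not present among frames"
            )

    @property
    def frame_indices(self) -> list[int]:
        return [f.frame_index for f in self.frames]

    def frame(self, frame_index: int) -> IVUSFrame:
        for f in self.frames:
            if f.frame_index == frame_index:
                return f
        raise KeyError(frame_index)


@dataclass
class SurfaceMesh:
    vertices: np.ndarray  # (n, 3) mm
    triangles: np.ndarray  # (m, 3) int
    label: str = ""

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)

    @property
    def is_watertight(self) -> bool:
        return _mesh.is_watertight(self.triangles)

    @property
    def volume(self) -> float:
        return _mesh.signed_volume(self.vertices, self.triangles)

    @property
    def area(self) -> float:
        return _mesh.surface_area(self.vertices, self.triangles)


@dataclass
class BifurcationModel:
    lumen: SurfaceMesh
    mv_centerline: Centerline3D
    sb_centerline: Centerline3D | None = None
    carina_point: np.ndarray | None = None
    eem: SurfaceMesh | None = None
    plaques: list[tuple[str, SurfaceMesh]] = field(default_factory=list)

    def __post_init__(self):
        if self.carina_point is not None:
            self.carina_point = np.asarray(self.carina_point, dtype=float)


# ---------------------------------------------------------------------------
# contour-stack JSON
# ---------------------------------------------------------------------------

def _require(doc: dict, key: str, where: str):
    if key not in doc:
        raise SchemaError(f"missing field {key!r} in {where}")
    return doc[key]


def read_contour_stack(path) -> Pullback:
    """Parse and validate a contour-stack JSON file."""
    with open(path) as fh:
        doc = json.load(fh)
    frames = []
    for fdoc in _require(doc, "frames", "top level"):
        idx = _require(fdoc, "frame_index", "frame")
        contours = [
            Contour(
                frame_index=idx,
                label=_require(cdoc, "label", f"frame {idx} contour"),
                component_id=cdoc.get("component_id", 0),
                points=np.asarray(_require(cdoc, "points_mm", f"frame {idx} contour")),
            )
            for cdoc in fdoc.get("contours", [])
        ]
        frames.append(
            IVUSFrame(
                frame_index=idx,
                catheter_point=np.asarray(
                    _require(fdoc, "catheter_point_mm", f"frame {idx}")
                ),
                contours=contours,
                gated=bool(fdoc.get("gated", True)),
            )
        )
    return Pullback(
        branch=_require(doc, "branch", "top level"),
        frames=frames,
        pullback_speed=_require(doc, "pullback_speed_mm_s", "top level"),
        frame_rate=_require(doc, "frame_rate_fps", "top level"),
        carina_frame=_require(doc, "carina_frame", "top level"),
        carina_direction=_require(doc, "carina_direction_deg", "top level"),
    )


def write_contour_stack(path, p: Pullback) -> None:
    doc = {
        "branch": p.branch,
        "pullback_speed_mm_s": p.pullback_speed,
        "frame_rate_fps": p.frame_rate,
        "carina_frame": p.carina_frame,
        "carina_direction_deg": p.carina_direction,
        "frames": [
            {
                "frame_index": f.frame_index,
                "gated": f.gated,
                "catheter_point_mm": f.catheter_point.tolist(),
                "contours": [
                    {
                        "label": c.label,
                        "component_id": c.component_id,
                        "points_mm": c.points.tolist(),
                    }
                    for c in f.contours
                ],
            }
            for f in p.frames
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# meshes: binary STL / ASCII PLY
# ---------------------------------------------------------------------------

def write_mesh(mesh: SurfaceMesh, path, format: str | None = None) -> None:
    """Write a mesh as binary STL or ASCII PLY (inferred from the suffix)."""
    if len(mesh.triangles) == 0:
        raise ValueError("refusing to write an empty mesh")
    if format is None:
        format = "ply" if str(path).lower().endswith(".ply") else "stl"
    format = format.lower()
    if not mesh.is_watertight:
        log.warning("mesh %r is not watertight; writing anyway", mesh.label)
        warnings.warn(f"mesh {mesh.label!r} is not watertight", stacklevel=2)
    if format == "stl":
        _write_stl(mesh, path)
    elif format == "ply":
        _write_ply(mesh, path)
    else:
        raise ValueError(f"unsupported mesh format {format!r}")


def _write_stl(mesh: SurfaceMesh, path) -> None:
    tris = mesh.vertices[mesh.triangles]
    normals = np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0])
    lens = np.linalg.norm(normals, axis=1)
    normals = normals / np.where(lens == 0, 1.0, lens)[:, None]
    with open(path, "wb") as fh:
        header = mesh.label.encode()[:80].ljust(80, b"\0")
        fh.write(header)
        fh.write(struct.pack("<I", len(tris)))
        rec = np.zeros(
            len(tris), dtype=[("n", "<f4", (3,)), ("v", "<f4", (3, 3)), ("attr", "<u2")]
        )
        rec["n"] = normals.astype(np.float32)
        rec["v"] = tris.astype(np.float32)
        fh.write(rec.tobytes())


def read_stl(path) -> SurfaceMesh:
    with open(path, "rb") as fh:
        header = fh.read(80)
        (n,) = struct.unpack("<I", fh.read(4))
        rec = np.frombuffer(
            fh.read(n * 50),
            dtype=[("n", "<f4", (3,)), ("v", "<f4", (3, 3)), ("attr", "<u2")],
        )
    tris = rec["v"].astype(float).reshape(-1, 3)
    v, f = _mesh.merge_close_vertices(tris, np.arange(len(tris)).reshape(-1, 3))
    return SurfaceMesh(vertices=v, triangles=f, label=header.rstrip(b"\0").decode(errors="replace"))


def _write_ply(mesh: SurfaceMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"comment label {mesh.label}\n")
        fh.write(f"element vertex {len(mesh.vertices)}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write(f"element face {len(mesh.triangles)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.12g} {v[1]:.12g} {v[2]:.12g}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def read_ply(path) -> SurfaceMesh:
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ValueError(f"{path} is not a PLY file")
        n_vert = n_face = 0
        label = ""
        while True:
            line = fh.readline()
            if not line:
                raise ValueError("unexpected end of PLY header")
            tok = line.split()
            if tok[:2] == ["comment", "label"]:
                label = " ".join(tok[2:])
            elif tok[:2] == ["element", "vertex"]:
                n_vert = int(tok[2])
            elif tok[:2] == ["element", "face"]:
                n_face = int(tok[2])
            elif tok[0] == "end_header":
                break
        verts = np.array(
            [[float(x) for x in fh.readline().split()[:3]] for _ in range(n_vert)]
        )
        faces = np.array(
            [[int(x) for x in fh.readline().split()[1:4]] for _ in range(n_face)]
        )
    return SurfaceMesh(vertices=verts, triangles=faces, label=label)


def read_mesh(path) -> SurfaceMesh:
    if str(path).lower().endswith(".ply"):
        return read_ply(path)
    return read_stl(path)


# ---------------------------------------------------------------------------
# metrics report CSV
# ---------------------------------------------------------------------------

def write_metrics_report(report, path) -> None:
    """One CSV row per paired cross-section plus a key,value summary block."""
    import csv

    if not report.sections:
        warnings.warn("metrics report has no cross-sections", stacklevel=2)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            [
                "branch",
                "s_mm",
                "diameter_a_mm",
                "diameter_b_mm",
                "shape_ratio_a",
                "shape_ratio_b",
            ]
        )
        for row in report.sections:
            w.writerow(
                [
                    row["branch"],
                    f"{row['s_mm']:.6g}",
                    f"{row['diameter_a_mm']:.6g}",
                    f"{row['diameter_b_mm']:.6g}",
                    f"{row['shape_ratio_a']:.6g}",
                    f"{row['shape_ratio_b']:.6g}",
                ]
            )
        w.writerow([])
        w.writerow(["summary_key", "summary_value"])
        for key, val in report.summary().items():
            w.writerow([key, f"{val:.9g}" if isinstance(val, float) else val])
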