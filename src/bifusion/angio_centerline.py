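"""Biplane angiographic centerline reconstruction.

A C-arm cone-beam camera model (forward projector), epipolar triangulation
of a vessel centerline from two projections, and arc-length utilities used
throughout the pipeline.

Conventions
-----------
World frame: isocenter at the origin, patient axes (x right-to-left,
y posterior-to-anterior, z caudal-to-cranial).  The neutral view looks
along -y (source anterior).  `rao_lao_angle` rotates the gantry about the
patient long axis (z); `cran_caud_angle` then tilts about the rotated
detector-horizontal axis.  Detector coordinates are in mm; a point at the
isocenter projects onto the principal point.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import interp1d


class AngioError(ValueError):
    """Raised for invalid projection geometry or triangulation failures."""


@dataclass(frozen=True)
class ProjectionGeometry:
    rao_lao_angle: float  # degrees
    cran_caud_angle: float  # degrees
    source_isocenter_distance: float = 750.0  # mm
    source_detector_distance: float = 1100.0  # mm
    detector_pixel_spacing: float = 0.2  # mm / px
    principal_point: tuple[float, float] = (0.0, 0.0)  # px

    def __post_init__(self):
        if self.source_isocenter_distance <= 0 or self.source_detector_distance <= 0:
            raise AngioError("projection distances must be positive")
        if self.source_detector_distance < self.source_isocenter_distance:
            raise AngioError("source-detector distance must be >= source-isocenter distance")

    @property
    def principal_point_mm(self) -> np.ndarray:
        return np.asarray(self.principal_point, dtype=float) * self.detector_pixel_spacing

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(n, u, v): view axis (source->isocenter) and detector axes."""
        a = np.radians(self.rao_lao_angle)
        b = np.radians(self.cran_caud_angle)
        rz = np.array(
            [[np.cos(a), -np.sin(a), 0.0], [np.sin(a), np.cos(a), 0.0], [0.0, 0.0, 1.0]]
        )
        n0 = rz @ np.array([0.0, -1.0, 0.0])
        u0 = rz @ np.array([1.0, 0.0, 0.0])
        # tilt about the detector-horizontal axis u0
        c, s = np.cos(b), np.sin(b)
        k = u0

        def rot(vec):
            return vec * c + np.cross(k, vec) * s + k * (k @ vec) * (1 - c)

        n = rot(n0)
        v = rot(np.array([0.0, 0.0, 1.0]))
        return n, u0, v

    @property
    def source(self) -> np.ndarray:
        n, _, _ = self.basis()
        return -self.source_isocenter_distance * n

    def matrix(self) -> np.ndarray:
        """3x4 homogeneous projection matrix onto detector mm coordinates."""
        n, u, v = self.basis()
        src = self.source
        mag = self.source_detector_distance
        pp = self.principal_point_mm
        rows = np.stack([mag * u + pp[0] * n, mag * v + pp[1] * n, n])
        p = np.zeros((3, 4))
        p[:, :3] = rows
        p[:, 3] = -rows @ src
        return p


@dataclass
class Curve2D:
    points: np.ndarray  # (n, 2) detector mm
    branch: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 2:
            raise AngioError("Curve2D requires >= 2 two-dimensional points")


@dataclass
class Centerline3D:
    points: np.ndarray  # (n, 3) mm
    reprojection_rms: float | None = None
    arclength: np.ndarray = field(init=False)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise AngioError("Centerline3D requires >= 2 three-dimensional points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg <= 0):
            raise AngioError("centerline contains a zero-length segment")
        self.arclength = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    def point_at(self, s: float) -> np.ndarray:
        if s < -1e-9 or s > self.length + 1e-9:
            raise AngioError(f"arclength {s} outside [0, {self.length}]")
        s = min(max(s, 0.0), self.length)
        return np.array(
            [
                interp1d(self.arclength, self.points[:, i])(s)
                for i in range(3)
            ]
        )


def project_centerline(cl: Centerline3D, geom: ProjectionGeometry, branch: str = "") -> Curve2D:
    """Cone-beam projection of the centerline onto the detector plane (mm)."""
    pts = project_points(cl.points, geom)
    return Curve2D(points=pts, branch=branch)


def project_points(points: np.ndarray, geom: ProjectionGeometry) -> np.ndarray:
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n, u, v = geom.basis()
    src = geom.source
    rel = points - src
    depth = rel @ n
    if np.any(depth <= 0):
        raise AngioError("point at or behind the X-ray source")
    t = geom.source_detector_distance / depth
    hit = src + rel * t[:, None]
    det_center = src + geom.source_detector_distance * n
    off = hit - det_center
    return np.stack([off @ u, off @ v], axis=1) + geom.principal_point_mm


def _detector_ray(pt_mm: np.ndarray, geom: ProjectionGeometry) -> tuple[np.ndarray, np.ndarray]:
    """World-space ray (origin=source, unit direction) through a detector point."""
    n, u, v = geom.basis()
    src = geom.source
    off = np.asarray(pt_mm, dtype=float) - geom.principal_point_mm
    target = src + geom.source_detector_distance * n + off[0] * u + off[1] * v
    d = target - src
    return src, d / np.linalg.norm(d)


def _ray_midpoint(o1, d1, o2, d2) -> tuple[np.ndarray, float]:
    """Midpoint of the common perpendicular of two rays, plus the gap."""
    w0 = o1 - o2
    a = d1 @ d1
    b = d1 @ d2
    c = d2 @ d2
    d = d1 @ w0
    e = d2 @ w0
    den = a * c - b * b
    if abs(den) < 1e-12:
        raise AngioError("back-projection rays are parallel")
    t1 = (b * e - c * d) / den
    t2 = (a * e - b * d) / den
    p1 = o1 + t1 * d1
    p2 = o2 + t2 * d2
    return 0.5 * (p1 + p2), float(np.linalg.norm(p1 - p2))


def view_separation_deg(geom_a: ProjectionGeometry, geom_b: ProjectionGeometry) -> float:
    na, _, _ = geom_a.basis()
    nb, _, _ = geom_b.basis()
    return float(np.degrees(np.arccos(np.clip(na @ nb, -1.0, 1.0))))


def _epipolar_candidates(curve: Curve2D, line_p: np.ndarray, line_d: np.ndarray):
    """Intersections of the polyline with a 2D line: (point, cum. arclength)."""
    nrm = np.array([-line_d[1], line_d[0]])
    sd = (curve.points - line_p) @ nrm
    pts = curve.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    out = []
    for i in range(len(pts) - 1):
        a, b = sd[i], sd[i + 1]
        if a == 0.0:
            out.append((pts[i], cum[i]))
        elif (a > 0) != (b > 0):
            t = a / (a - b)
            out.append((pts[i] + t * (pts[i + 1] - pts[i]), cum[i] + t * seg[i]))
    if len(pts) and sd[-1] == 0.0:
        out.append((pts[-1], cum[-1]))
    return out


def _triangulate_one_way(
    curve_a: Curve2D,
    geom_a: ProjectionGeometry,
    curve_b: Curve2D,
    geom_b: ProjectionGeometry,
    miss_tolerance: float,
) -> np.ndarray:
    pts3d = []
    last_s = -np.inf
    for i, pa in enumerate(curve_a.points):
        src_a, dir_a = _detector_ray(pa, geom_a)
        # epipolar line in view B = projection of ray A
        q1 = project_points(src_a + dir_a * geom_a.source_isocenter_distance * 0.5, geom_b)[0]
        q2 = project_points(src_a + dir_a * geom_a.source_isocenter_distance * 1.5, geom_b)[0]
        ld = q2 - q1
        nl = np.linalg.norm(ld)
        if nl < 1e-12:
            raise AngioError(f"degenerate epipolar line for point {i}")
        cands = _epipolar_candidates(curve_b, q1, ld / nl)
        if not cands:
            # tangency or a small endpoint miss: fall back to the closest
            # polyline vertex if it is within tolerance of the epipolar line
            nrm = np.array([-ld[1], ld[0]]) / nl
            sd = np.abs((curve_b.points - q1) @ nrm)
            jmin = int(np.argmin(sd))
            if sd[jmin] > miss_tolerance:
                raise AngioError(
                    f"epipolar line misses the second curve at point index {i}"
                )
            seg = np.linalg.norm(np.diff(curve_b.points, axis=0), axis=1)
            cum = np.concatenate([[0.0], np.cumsum(seg)])
            cands = [(curve_b.points[jmin], cum[jmin])]
        ahead = [cc for cc in cands if cc[1] >= last_s - 1e-9]
        pool = ahead if ahead else cands
        pb, sb = min(pool, key=lambda cc: cc[1])
        last_s = max(last_s, sb)
        src_b, dir_b = _detector_ray(pb, geom_b)
        p, _ = _ray_midpoint(src_a, dir_a, src_b, dir_b)
        pts3d.append(p)
    return np.asarray(pts3d)


def _points_to_polyline_rms(points: np.ndarray, poly: np.ndarray) -> float:
    a = poly[:-1]
    b = poly[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom = np.where(denom == 0, 1.0, denom)
    ap = points[:, None, :] - a[None, :, :]
    t = np.clip(np.einsum("psj,sj->ps", ap, ab) / denom, 0.0, 1.0)
    proj = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    d = np.linalg.norm(points[:, None, :] - proj, axis=2).min(axis=1)
    return float(np.sqrt(np.mean(d**2)))


def triangulate_centerlines(
    curve_a: Curve2D,
    geom_a: ProjectionGeometry,
    curve_b: Curve2D,
    geom_b: ProjectionGeometry,
    miss_tolerance: float = 2.0,
) -> Centerline3D:
    """Triangulate a 3D centerline from two projections.

    For each point of curve A the epipolar line in view B is intersected
    with curve B (monotone-ordering constraint along the curve; ties broken
    toward the smallest arc length); the 3D point is the midpoint of the
    common perpendicular of the two back-projection rays.

    `reprojection_rms` is the RMS discrepancy (mm) between this A-driven
    reconstruction and the reverse B-driven one — zero for consistent
    projections, growing with 2D noise.
    """
    sep = view_separation_deg(geom_a, geom_b)
    if sep < 15.0:
        raise AngioError(f"view separation {sep:.1f} deg < 15 deg: triangulation rejected")
    if sep < 30.0:
        warnings.warn(
            f"view separation {sep:.1f} deg is below the recommended 30 deg",
            stacklevel=2,
        )
    pts3d = _triangulate_one_way(curve_a, geom_a, curve_b, geom_b, miss_tolerance)
    reverse = _triangulate_one_way(curve_b, geom_b, curve_a, geom_a, miss_tolerance)
    rms = _points_to_polyline_rms(pts3d, reverse)
    return Centerline3D(points=pts3d, reprojection_rms=rms)


def resample_by_arclength(cl: Centerline3D, step: float) -> Centerline3D:
    """Equally spaced resampling along the polyline; endpoints preserved."""
    if step <= 0:
        raise AngioError("step must be positive")
    total = cl.length
    if step > total:
        raise AngioError(f"step {step} exceeds total length {total}")
    n = int(np.floor(total / step + 1e-9)) + 1
    s = np.linspace(0.0, total, max(n, 2))
    if s[-1] < total - 1e-12:
        s = np.append(s, total)
    pts = np.stack(
        [np.interp(s, cl.arclength, cl.points[:, i]) for i in range(3)], axis=1
    )
    return Centerline3D(points=pts, reprojection_rms=cl.reprojection_rms)


def tangent_at(cl: Centerline3D, s: float) -> np.ndarray:
    """Unit tangent (central difference), linearly interpolated in arclength."""
    if s < -1e-9 or s > cl.length + 1e-9:
        raise AngioError(f"arclength {s} outside [0, {cl.length}]")
    pts = cl.points
    tans = np.empty_like(pts)
    tans[0] = pts[1] - pts[0]
    tans[-1] = pts[-1] - pts[-2]
    tans[1:-1] = pts[2:] - pts[:-2]
    tans /= np.linalg.norm(tans, axis=1, keepdims=True)
    s = min(max(s, 0.0), cl.length)
    t = np.stack([np.interp(s, cl.arclength, tans[:, i]) for i in range(3)])
    return t / np.linalg.norm(t)


def tangents(cl: Centerline3D) -> np.ndarray:
    """Unit tangents at every centerline point (central differences)."""
    pts = cl.points
    tans = np.empty_like(pts)
    tans[0] = pts[1] - pts[0]
    tans[-1] = pts[-1] - pts[-2]
    tans[1:-1] = pts[2:] - pts[:-2]
    return tans / np.linalg.norm(tans, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# JSON / CSV plumbing
# ---------------------------------------------------------------------------

def read_curve_json(path) -> tuple[Curve2D, ProjectionGeometry]:
    with open(path) as fh:
        doc = json.load(fh)
    geom = ProjectionGeometry(
        rao_lao_angle=doc["rao_lao_deg"],
        cran_caud_angle=doc["cran_caud_deg"],
        source_isocenter_distance=doc.get("sid_mm", 750.0),
        source_detector_distance=doc.get("sdd_mm", 1100.0),
        detector_pixel_spacing=doc.get("pixel_spacing_mm", 0.2),
        principal_point=tuple(doc.get("principal_point_px", (0.0, 0.0))),
    )
    return Curve2D(points=np.asarray(doc["points_mm"], dtype=float), branch=doc.get("branch", "")), geom


def write_curve_json(path, curve: Curve2D, geom: ProjectionGeometry) -> None:
    doc = {
        "branch": curve.branch,
        "points_mm": np.asarray(curve.points).tolist(),
        "rao_lao_deg": geom.rao_lao_angle,
        "cran_caud_deg": geom.cran_caud_angle,
        "sid_mm": geom.source_isocenter_distance,
        "sdd_mm": geom.source_detector_distance,
        "pixel_spacing_mm": geom.detector_pixel_spacing,
        "principal_point_px": list(geom.principal_point),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def write_centerline_csv(path, cl: Centerline3D) -> None:
    np.savetxt(path, cl.points, delimiter=",", header="x_mm,y_mm,z_mm", comments="")


def read_centerline_csv(path) -> Centerline3D:
    pts = np.loadtxt(path, delimiter=",", skiprows=1)
    return Centerline3D(points=pts)
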