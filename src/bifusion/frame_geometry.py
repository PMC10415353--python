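"""Placement of gated IVUS frames along the 3D centerline.

Covers ECG-gated frame selection, frame spacing from pullback kinematics,
rotation-minimizing frames (double-reflection transport), in-plane twist
correction by aligning consecutive lumen radial profiles, carina-reference
roll registration between the two branch stacks, and automated smoothing of
the virtual catheter path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import make_smoothing_spline
from shapely.geometry import LineString, Point

from .angio_centerline import Centerline3D, tangent_at, tangents
from .contour_io import Pullback


class FrameGeometryError(ValueError):
    pass


@dataclass
class FramePlacement:
    frame_index: int
    origin: np.ndarray  # 3D mm on the centerline
    triad: np.ndarray  # rows (t, u, v), orthonormal, right-handed
    roll: float = 0.0  # degrees, in-plane rotation about t
    s: float = 0.0  # arclength mm

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.triad = np.asarray(self.triad, dtype=float)

    @property
    def t(self) -> np.ndarray:
        return self.triad[0]

    @property
    def u(self) -> np.ndarray:
        return self.triad[1]

    @property
    def v(self) -> np.ndarray:
        return self.triad[2]

    def inplane_axes(self) -> tuple[np.ndarray, np.ndarray]:
        """Roll-corrected in-plane axes."""
        r = np.radians(self.roll)
        u = np.cos(r) * self.u + np.sin(r) * self.v
        v = -np.sin(r) * self.u + np.cos(r) * self.v
        return u, v

    def to_world(self, points2d: np.ndarray) -> np.ndarray:
        """Map frame-plane 2D mm coordinates into 3D."""
        p = np.atleast_2d(np.asarray(points2d, dtype=float))
        u, v = self.inplane_axes()
        return self.origin + p[:, [0]] * u + p[:, [1]] * v


@dataclass
class CatheterPath:
    points: np.ndarray  # (n, 3)
    outlier_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.outlier_mask is None:
            self.outlier_mask = np.zeros(len(self.points), dtype=bool)
        else:
            self.outlier_mask = np.asarray(self.outlier_mask, dtype=bool)
        if len(self.outlier_mask) != len(self.points):
            raise FrameGeometryError("outlier mask length mismatch")


def frame_spacing(speed: float, frame_rate: float) -> float:
    """Axial distance between consecutive frames: pullback speed / frame rate."""
    if speed <= 0 or frame_rate <= 0:
        raise FrameGeometryError("speed and frame rate must be positive")
    return speed / frame_rate


def select_gated_frames(p: Pullback) -> Pullback:
    """Keep only ECG-gated frames (bench mode: every frame is gated)."""
    gated = [f for f in p.frames if f.gated]
    if not gated:
        raise FrameGeometryError("no gated frames in pullback")
    if not p.frame(p.carina_frame).gated:
        raise FrameGeometryError(f"carina frame {p.carina_frame} is not gated")
    return replace(p, frames=gated)


# ---------------------------------------------------------------------------
# rotation-minimizing frames
# ---------------------------------------------------------------------------

def _initial_normal(t: np.ndarray) -> np.ndarray:
    ref = np.zeros(3)
    ref[int(np.argmin(np.abs(t)))] = 1.0
    u = ref - (ref @ t) * t
    return u / np.linalg.norm(u)


def _double_reflection_step(x0, t0, u0, x1, t1):
    v1 = x1 - x0
    c1 = v1 @ v1
    if c1 <= 0:
        raise FrameGeometryError("zero-length centerline segment")
    ul = u0 - (2.0 / c1) * (v1 @ u0) * v1
    tl = t0 - (2.0 / c1) * (v1 @ t0) * v1
    v2 = t1 - tl
    c2 = v2 @ v2
    if c2 <= 0:
        return ul
    return ul - (2.0 / c2) * (v2 @ ul) * v2


def compute_rmf(cl: Centerline3D, u0: np.ndarray | None = None) -> np.ndarray:
    """Rotation-minimizing frames at every centerline point.

    Returns an (n, 3, 3) array of triads with rows (t, u, v); transport by
    the double-reflection method, which is free of tangent-axis spin.
    """
    pts = cl.points
    tans = tangents(cl)
    n = len(pts)
    triads = np.empty((n, 3, 3))
    u = _initial_normal(tans[0]) if u0 is None else np.asarray(u0, dtype=float)
    u = u - (u @ tans[0]) * tans[0]
    u = u / np.linalg.norm(u)
    triads[0] = np.stack([tans[0], u, np.cross(tans[0], u)])
    for i in range(n - 1):
        u = _double_reflection_step(pts[i], tans[i], triads[i, 1], pts[i + 1], tans[i + 1])
        u = u - (u @ tans[i + 1]) * tans[i + 1]
        u = u / np.linalg.norm(u)
        triads[i + 1] = np.stack([tans[i + 1], u, np.cross(tans[i + 1], u)])
    return triads


def rmf_at(cl: Centerline3D, triads: np.ndarray, s: float) -> tuple[np.ndarray, np.ndarray]:
    """Origin and triad at arbitrary arclength, by one transport step from
    the nearest preceding centerline node."""
    i = int(np.searchsorted(cl.arclength, s, side="right") - 1)
    i = max(0, min(i, len(cl.points) - 1))
    origin = cl.point_at(s)
    t = tangent_at(cl, s)
    if np.linalg.norm(origin - cl.points[i]) < 1e-12:
        u = triads[i, 1]
    else:
        u = _double_reflection_step(cl.points[i], triads[i, 0], triads[i, 1], origin, t)
    u = u - (u @ t) * t
    u = u / np.linalg.norm(u)
    return origin, np.stack([t, u, np.cross(t, u)])


# ---------------------------------------------------------------------------
# frame placement
# ---------------------------------------------------------------------------

def place_frames(p: Pullback, cl: Centerline3D, s0: float = 0.0) -> list[FramePlacement]:
    """Distribute gated frames along the centerline at the pullback spacing.

    Frame k sits at s0 + (frame_index_k - frame_index_0) * frame_spacing;
    contour coordinates are interpreted with the catheter point at the
    frame origin on the centerline.
    """
    if not p.frames:
        raise FrameGeometryError("pullback has no frames")
    spacing = frame_spacing(p.pullback_speed, p.frame_rate)
    idx0 = p.frames[0].frame_index
    span = (p.frames[-1].frame_index - idx0) * spacing
    avail = cl.length - s0
    if span > avail + 1e-9:
        raise FrameGeometryError(
            f"pullback span {span:.3f} mm exceeds centerline by {span - avail:.3f} mm"
        )
    triads = compute_rmf(cl)
    placements = []
    for f in p.frames:
        s = s0 + (f.frame_index - idx0) * spacing
        origin, triad = rmf_at(cl, triads, s)
        placements.append(
            FramePlacement(frame_index=f.frame_index, origin=origin, triad=triad, s=s)
        )
    return placements


# ---------------------------------------------------------------------------
# relative twist correction
# ---------------------------------------------------------------------------

def radial_profile(points: np.ndarray, n_samples: int = 360) -> tuple[np.ndarray, bool]:
    """Boundary radius r(phi) about the origin at equiangular samples.

    Returns (profile, star_shaped).  For non-star-shaped rings the outermost
    crossing is kept and the flag is False.
    """
    p = np.asarray(points, dtype=float)
    p1 = p
    p2 = np.roll(p, -1, axis=0)
    e = p2 - p1
    phi = 2 * np.pi * np.arange(n_samples) / n_samples
    d = np.stack([np.cos(phi), np.sin(phi)], axis=1)  # (K, 2)
    # r*(d x e) = p1 x e ; t*(d x e) = p1 x d
    dxe = d[:, None, 0] * e[None, :, 1] - d[:, None, 1] * e[None, :, 0]
    p1xe = p1[:, 0] * e[:, 1] - p1[:, 1] * e[:, 0]
    p1xd = p1[None, :, 0] * d[:, None, 1] - p1[None, :, 1] * d[:, None, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = p1xe[None, :] / dxe
        t = p1xd / dxe
    # tolerant bounds so rays through a vertex hit at least one adjacent edge
    eps = 1e-9
    valid = (dxe != 0) & (t >= -eps) & (t < 1.0 + eps) & (r > 0)
    counts = valid.sum(axis=1)
    if np.any(counts == 0):
        raise FrameGeometryError("catheter point lies outside the lumen contour")
    star = bool(np.all(counts <= 2))
    r = np.where(valid, r, -np.inf)
    return r.max(axis=1), star


def _rotate2d(points: np.ndarray, deg: float) -> np.ndarray:
    a = np.radians(deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    return np.asarray(points, dtype=float) @ rot.T


def _pick_by_tiebreak(thetas: np.ndarray, costs: np.ndarray) -> float:
    """Minimum cost; ties resolved to smallest |theta|, negative first."""
    best = costs.min()
    tol = max(1e-12, 1e-9 * abs(best))
    tied = np.flatnonzero(costs <= best + tol)
    order = sorted(tied, key=lambda i: (abs(thetas[i]), thetas[i]))
    return float(thetas[order[0]])


def _profile_mse(prof_moving: np.ndarray, prof_fixed: np.ndarray, thetas: np.ndarray) -> np.ndarray:
    k = len(prof_moving)
    grid_angles = 360.0 * np.arange(k) / k
    ext_ang = np.concatenate([grid_angles, [360.0]])
    ext_prof = np.concatenate([prof_moving, [prof_moving[0]]])
    costs = np.empty(len(thetas))
    for j, th in enumerate(thetas):
        shifted = np.interp((grid_angles - th) % 360.0, ext_ang, ext_prof)
        costs[j] = np.mean((shifted - prof_fixed) ** 2)
    return costs


def _polygon_mean_distance(moving: np.ndarray, fixed: np.ndarray, thetas: np.ndarray) -> np.ndarray:
    ring = LineString(np.vstack([fixed, fixed[:1]]))
    costs = np.empty(len(thetas))
    for j, th in enumerate(thetas):
        rp = _rotate2d(moving, th)
        costs[j] = np.mean([ring.distance(Point(q)) for q in rp])
    return costs


def pairwise_twist(
    fixed: np.ndarray,
    moving: np.ndarray,
    grid_deg: float = 1.0,
    refine_deg: float = 0.1,
    search_deg: float = 45.0,
    n_samples: int = 360,
) -> float:
    """In-plane rotation angle aligning `moving` onto `fixed`.

    Profiles are taken about each ring's centroid, which makes the estimate
    invariant to catheter-offset translation; the recovered angle applies to
    the rotation about the catheter center all the same.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    fixed = fixed - fixed.mean(axis=0)
    moving = moving - moving.mean(axis=0)
    try:
        prof_f, star_f = radial_profile(fixed, n_samples)
        prof_m, star_m = radial_profile(moving, n_samples)
        star = star_f and star_m
    except FrameGeometryError:
        star = False
    coarse = np.arange(-search_deg, search_deg + 0.5 * grid_deg, grid_deg)
    if star:
        costs = _profile_mse(prof_m, prof_f, coarse)
    else:
        costs = _polygon_mean_distance(moving, fixed, coarse)
    theta0 = _pick_by_tiebreak(coarse, costs)
    fine = theta0 + np.arange(-grid_deg, grid_deg + 0.5 * refine_deg, refine_deg)
    if star:
        fcosts = _profile_mse(prof_m, prof_f, fine)
    else:
        fcosts = _polygon_mean_distance(moving, fixed, fine)
    return _pick_by_tiebreak(
        np.concatenate([coarse, fine]), np.concatenate([costs, fcosts])
    )


def correct_relative_twist(
    p: Pullback,
    grid_deg: float = 1.0,
    refine_deg: float = 0.1,
    search_deg: float = 45.0,
    n_samples: int = 360,
) -> np.ndarray:
    """Cumulative in-plane correction angle (degrees) per gated frame.

    Each consecutive lumen pair is aligned by grid search over the radial
    profile mean-squared difference; corrections accumulate and apply
    identically to every contour label of the frame.
    """
    profiles = []
    for f in p.frames:
        lum = f.contour("lumen")
        if lum is None:
            raise FrameGeometryError(f"frame {f.frame_index} has no lumen contour")
        profiles.append(lum.points)
    cum = np.zeros(len(p.frames))
    for k in range(1, len(p.frames)):
        delta = pairwise_twist(
            profiles[k - 1],
            profiles[k],
            grid_deg=grid_deg,
            refine_deg=refine_deg,
            search_deg=search_deg,
            n_samples=n_samples,
        )
        cum[k] = cum[k - 1] + delta
    return cum


def write_placements_csv(path, placements: list[FramePlacement]) -> None:
    """Export placements as CSV: frame_index, s, origin xyz, triad quaternion
    (x, y, z, w), roll in degrees."""
    from scipy.spatial.transform import Rotation

    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["frame_index", "s_mm", "x_mm", "y_mm", "z_mm", "qx", "qy", "qz", "qw", "roll_deg"]
        )
        for pl in placements:
            # triad rows are (t, u, v): the rotation mapping e_x,e_y,e_z onto them
            q = Rotation.from_matrix(pl.triad.T).as_quat()
            w.writerow(
                [pl.frame_index, f"{pl.s:.6g}"]
                + [f"{c:.9g}" for c in pl.origin]
                + [f"{c:.12g}" for c in q]
                + [f"{pl.roll:.6g}"]
            )


# ---------------------------------------------------------------------------
# carina registration
# ---------------------------------------------------------------------------

def takeoff_direction(other_cl: Centerline3D, near_point: np.ndarray) -> np.ndarray:
    """Distal-pointing tangent of the other branch at its point closest to
    the carina region."""
    d = np.linalg.norm(other_cl.points - np.asarray(near_point), axis=1)
    s = float(other_cl.arclength[int(np.argmin(d))])
    return -tangent_at(other_cl, s)


def _register_stack(
    placements: list[FramePlacement],
    pullback: Pullback,
    other_cl: Centerline3D,
    twist: np.ndarray | None = None,
) -> tuple[list[FramePlacement], float]:
    by_index = {pl.frame_index: (i, pl) for i, pl in enumerate(placements)}
    if pullback.carina_frame not in by_index:
        raise FrameGeometryError(
            f"carina frame {pullback.carina_frame} is not among placed frames"
        )
    i, car = by_index[pullback.carina_frame]
    takeoff = takeoff_direction(other_cl, car.origin)
    proj = takeoff - (takeoff @ car.t) * car.t
    norm = np.linalg.norm(proj)
    if norm < 1e-6:
        raise FrameGeometryError(
            "other-branch take-off is parallel to the carina frame normal"
        )
    proj /= norm
    target_angle = np.degrees(np.arctan2(proj @ car.v, proj @ car.u))
    current = pullback.carina_direction + car.roll
    if twist is not None:
        current += twist[i]
    droll = (target_angle - current + 180.0) % 360.0 - 180.0
    out = [replace(pl, roll=pl.roll + droll) for pl in placements]
    # residual after registration
    _, car2 = {pl.frame_index: (j, pl) for j, pl in enumerate(out)}[pullback.carina_frame]
    u2, v2 = car2.inplane_axes()
    ang = pullback.carina_direction + (twist[i] if twist is not None else 0.0)
    vec = np.cos(np.radians(ang)) * u2 + np.sin(np.radians(ang)) * v2
    residual = np.degrees(np.arccos(np.clip(vec @ proj, -1.0, 1.0)))
    return out, float(residual)


def register_carina(
    mv_placements: list[FramePlacement],
    sb_placements: list[FramePlacement],
    mv_pullback: Pullback,
    sb_pullback: Pullback,
    mv_cl: Centerline3D,
    sb_cl: Centerline3D,
    mv_twist: np.ndarray | None = None,
    sb_twist: np.ndarray | None = None,
) -> tuple[list[FramePlacement], list[FramePlacement], dict[str, float]]:
    """Apply one global roll per stack so the annotated carina direction maps
    onto the other branch's take-off direction; returns residual angles."""
    mv_out, mv_res = _register_stack(mv_placements, mv_pullback, sb_cl, mv_twist)
    sb_out, sb_res = _register_stack(sb_placements, sb_pullback, mv_cl, sb_twist)
    return mv_out, sb_out, {"MV": mv_res, "SB": sb_res}


# ---------------------------------------------------------------------------
# virtual catheter path correction
# ---------------------------------------------------------------------------

def correct_catheter_path(path: CatheterPath, k: float = 3.0) -> CatheterPath:
    """Flag catheter points deviating from a GCV smoothing spline by more
    than k * MAD of the residuals and replace them with the spline value."""
    pts = path.points
    if len(pts) < 5:
        raise FrameGeometryError("catheter path needs at least 5 points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    x = np.concatenate([[0.0], np.cumsum(np.maximum(seg, 1e-9))])

    def fit(xs, ys):
        return np.stack(
            [make_smoothing_spline(xs, ys[:, i])(x) for i in range(3)], axis=1
        )

    smooth = fit(x, pts)
    resid = np.linalg.norm(pts - smooth, axis=1)
    mad = np.median(np.abs(resid - np.median(resid)))
    scale = max(float(x[-1]), 1.0)
    thresh = max(k * mad, 1e-8 * scale)
    mask = resid > thresh
    corrected = pts.copy()
    if np.any(mask) and np.sum(~mask) >= 4:
        smooth2 = fit(x[~mask], pts[~mask])
        # cubic splines extrapolate badly: outside the refit support, fall
        # back to the full-data spline
        in_range = (x >= x[~mask].min()) & (x <= x[~mask].max())
        use2 = mask & in_range
        corrected[use2] = smooth2[use2]
        corrected[mask & ~in_range] = smooth[mask & ~in_range]
    elif np.any(mask):
        corrected[mask] = smooth[mask]
    return CatheterPath(points=corrected, outlier_mask=mask)
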