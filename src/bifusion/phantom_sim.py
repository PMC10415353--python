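"""Synthetic coronary bifurcation phantoms with known ground truth.

Stands in for bench acquisitions: swept elliptical lumens along a curved MV
and an angled SB, optional Gaussian stenosis and Murray-law radius coupling,
plus virtual IVUS pullbacks (twist random walk, catheter offset field,
contour noise) and virtual biplane centerline projections.  Every generator
is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import least_squares

from .angio_centerline import (
    Centerline3D,
    Curve2D,
    ProjectionGeometry,
    project_centerline,
    resample_by_arclength,
    tangent_at,
)
from .contour_io import BifurcationModel, Contour, IVUSFrame, Pullback, SurfaceMesh
from .frame_geometry import FramePlacement, compute_rmf, rmf_at, takeoff_direction
from .surface_builder import PlacedContour, loft_surface, merge_branches


class PhantomError(ValueError):
    pass


@dataclass(frozen=True)
class RadiusProfile:
    """Base radius with an optional Gaussian stenosis and a proximal step."""

    base: float
    stenosis_center: float | None = None
    stenosis_depth: float = 0.0  # fraction of base removed at the throat
    stenosis_width: float = 2.0  # mm (Gaussian sigma)
    proximal_radius: float | None = None  # blends in beyond `step_s`
    step_s: float | None = None
    step_width: float = 1.5

    def __post_init__(self):
        if self.base <= 0:
            raise PhantomError("base radius must be positive")
        if not (0.0 <= self.stenosis_depth < 1.0):
            raise PhantomError("stenosis depth fraction must be in [0, 1)")

    def __call__(self, s):
        s = np.asarray(s, dtype=float)
        r = np.full_like(s, self.base, dtype=float)
        if self.proximal_radius is not None and self.step_s is not None:
            w = 0.5 * (1.0 + np.tanh((s - self.step_s) / self.step_width))
            r = (1 - w) * self.base + w * self.proximal_radius
        if self.stenosis_center is not None and self.stenosis_depth > 0:
            r = r * (
                1.0
                - self.stenosis_depth
                * np.exp(-0.5 * ((s - self.stenosis_center) / self.stenosis_width) ** 2)
            )
        return r if r.ndim else float(r)


@dataclass(frozen=True)
class PlaqueSpec:
    label: str
    s_range: tuple[float, float]
    angle_range_deg: tuple[float, float]
    thickness: float  # mm, radial


@dataclass
class PhantomSpec:
    mv_control_points: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [0.0, 0.0, 0.0],
                [6.0, 1.2, 0.4],
                [12.0, 2.0, 1.0],
                [18.0, 1.6, 1.8],
                [24.0, 0.8, 2.4],
            ]
        )
    )
    sb_takeoff_s: float = 14.0
    sb_length: float = 10.0
    bifurcation_angle: float = 60.0  # degrees
    mv_radius: RadiusProfile = field(default_factory=lambda: RadiusProfile(base=1.5))
    sb_radius: RadiusProfile = field(default_factory=lambda: RadiusProfile(base=1.2))
    ellipticity: float = 0.9  # minor/major axis ratio of lumen sections
    eem_offset: float | None = None  # wall thickness; None = no EEM
    plaques: list[PlaqueSpec] = field(default_factory=list)
    murray: bool = False
    murray_exponent: float = 3.0
    n_theta: int = 128
    ring_spacing: float = 0.25  # mm between lofted ground-truth rings
    union_pitch: float = 0.12  # mm SDF voxel pitch for the ground-truth union
    seed: int = 0

    def __post_init__(self):
        self.mv_control_points = np.asarray(self.mv_control_points, dtype=float)
        if not (15.0 < self.bifurcation_angle < 120.0):
            raise PhantomError("bifurcation angle must be in (15, 120) degrees")
        if self.murray:
            r_prox = (
                self.sb_radius.base**self.murray_exponent
                + self.mv_radius.base**self.murray_exponent
            ) ** (1.0 / self.murray_exponent)
            self.mv_radius = _dc_replace(
                self.mv_radius, proximal_radius=r_prox, step_s=self.sb_takeoff_s
            )


@dataclass
class Phantom:
    spec: PhantomSpec
    mv_centerline: Centerline3D
    sb_centerline: Centerline3D
    mv_mesh: SurfaceMesh
    sb_mesh: SurfaceMesh
    lumen: SurfaceMesh
    carina_point: np.ndarray
    _mv_triads: np.ndarray = None
    _sb_triads: np.ndarray = None

    def centerline(self, branch: str) -> Centerline3D:
        return self.mv_centerline if branch == "MV" else self.sb_centerline

    def triads(self, branch: str) -> np.ndarray:
        return self._mv_triads if branch == "MV" else self._sb_triads

    def radius_profile(self, branch: str) -> RadiusProfile:
        return self.spec.mv_radius if branch == "MV" else self.spec.sb_radius

    def placement_at(self, branch: str, s: float) -> FramePlacement:
        cl = self.centerline(branch)
        origin, triad = rmf_at(cl, self.triads(branch), s)
        return FramePlacement(frame_index=0, origin=origin, triad=triad, s=s)

    def section_polygon(self, branch: str, s: float, n: int = 128) -> np.ndarray:
        """True lumen cross-section (2D, frame-plane mm, centered)."""
        r = float(self.radius_profile(branch)(s))
        b = r * self.spec.ellipticity
        phi = 2 * np.pi * np.arange(n) / n
        return np.stack([r * np.cos(phi), b * np.sin(phi)], axis=1)

    def model(self) -> BifurcationModel:
        return BifurcationModel(
            lumen=self.lumen,
            mv_centerline=self.mv_centerline,
            sb_centerline=self.sb_centerline,
            carina_point=self.carina_point,
        )


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def _spline_centerline(control: np.ndarray, step: float = 0.05) -> Centerline3D:
    t = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(control, axis=0), axis=1))]
    )
    cs = CubicSpline(t, control, axis=0)
    fine = cs(np.linspace(0, t[-1], max(int(t[-1] / 0.02), 50)))
    cl = Centerline3D(points=fine)
    return resample_by_arclength(cl, step)


def _branch_rings(
    ph_spec: PhantomSpec, cl: Centerline3D, triads, radius: RadiusProfile
) -> list[PlacedContour]:
    svals = np.arange(0.0, cl.length + 1e-9, ph_spec.ring_spacing)
    out = []
    for i, s in enumerate(svals):
        origin, triad = rmf_at(cl, triads, min(s, cl.length))
        r = float(radius(s))
        b = r * ph_spec.ellipticity
        phi = 2 * np.pi * np.arange(ph_spec.n_theta) / ph_spec.n_theta
        ring = np.stack([r * np.cos(phi), b * np.sin(phi)], axis=1)
        pl = FramePlacement(frame_index=i, origin=origin, triad=triad, s=float(s))
        out.append(
            PlacedContour(
                contour=Contour(frame_index=i, label="lumen", points=ring),
                placement=pl,
            )
        )
    return out


def _implicit(ph: Phantom, branch: str, p: np.ndarray) -> float:
    """Elliptical tube implicit: <0 inside, 0 on the analytic surface."""
    cl = ph.centerline(branch)
    d = np.linalg.norm(cl.points - p, axis=1)
    i = int(np.argmin(d))
    s = float(cl.arclength[i])
    origin, triad = rmf_at(cl, ph.triads(branch), s)
    # one Newton-ish foot-point refinement along the tangent
    s = float(np.clip(s + (p - origin) @ triad[0], 0.0, cl.length))
    origin, triad = rmf_at(cl, ph.triads(branch), s)
    rel = p - origin
    x, y = rel @ triad[1], rel @ triad[2]
    a = float(ph.radius_profile(branch)(s))
    b = a * ph.spec.ellipticity
    return float(np.hypot(x / a, y / b) - 1.0)


def _locate_carina(ph: Phantom) -> np.ndarray:
    spec = ph.spec
    s_star = spec.sb_takeoff_s
    mv_cl = ph.mv_centerline
    p0, triad = rmf_at(mv_cl, ph._mv_triads, s_star)
    t_mv = triad[0]
    d_sb = takeoff_direction(ph.sb_centerline, p0)  # distal SB direction
    w = -t_mv + d_sb
    w = w / np.linalg.norm(w)

    def g(r):
        q = p0 + r * w
        return max(_implicit(ph, "MV", q), _implicit(ph, "SB", q))

    lo, hi = 0.0, 4.0 * max(spec.mv_radius.base, spec.sb_radius.base)
    if g(lo) > 0:
        lo = 1e-6
    while g(hi) < 0 and hi < 50:
        hi *= 1.5
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if g(mid) <= 0:
            lo = mid
        else:
            hi = mid
    start = p0 + 0.5 * (lo + hi) * w

    res = least_squares(
        lambda q: [_implicit(ph, "MV", q), _implicit(ph, "SB", q)],
        start,
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    return res.x


def make_phantom(spec: PhantomSpec, with_meshes: bool = True) -> Phantom:
    """Build ground-truth branch tubes, their union, and the carina point.

    `with_meshes=False` skips lofting/merging (centerlines, analytic tubes
    and the carina point only) for cheap geometric fixtures.
    """
    mv_cl = _spline_centerline(spec.mv_control_points)
    if spec.sb_takeoff_s <= 0 or spec.sb_takeoff_s >= mv_cl.length:
        raise PhantomError("SB take-off arclength outside the MV centerline")
    mv_triads = compute_rmf(mv_cl)
    p0, triad0 = rmf_at(mv_cl, mv_triads, spec.sb_takeoff_s)
    t_mv, u_mv = triad0[0], triad0[1]
    alpha = np.radians(spec.bifurcation_angle)
    d_sb = np.cos(alpha) * (-t_mv) + np.sin(alpha) * u_mv  # distal SB direction
    ells = np.linspace(spec.sb_length, 0.0, max(int(spec.sb_length / 0.05), 30))
    sb_cl = Centerline3D(points=p0 + np.outer(ells, d_sb))
    sb_triads = compute_rmf(sb_cl)

    mv_rings = None
    ph = Phantom(
        spec=spec,
        mv_centerline=mv_cl,
        sb_centerline=sb_cl,
        mv_mesh=None,
        sb_mesh=None,
        lumen=None,
        carina_point=np.zeros(3),
        _mv_triads=mv_triads,
        _sb_triads=sb_triads,
    )
    if with_meshes:
        mv_rings = _branch_rings(spec, mv_cl, mv_triads, spec.mv_radius)
        sb_rings = _branch_rings(spec, sb_cl, sb_triads, spec.sb_radius)
        ph.mv_mesh = loft_surface(mv_rings, n_theta=spec.n_theta, label="lumen")
        ph.sb_mesh = loft_surface(sb_rings, n_theta=spec.n_theta, label="lumen")
        ph.lumen = merge_branches(ph.mv_mesh, ph.sb_mesh, pitch=spec.union_pitch)
    ph.carina_point = _locate_carina(ph)
    return ph


# ---------------------------------------------------------------------------
# virtual pullback
# ---------------------------------------------------------------------------

def _rot2(deg: float) -> np.ndarray:
    a = np.radians(deg)
    return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])


def _smooth_field(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    if sigma <= 0 or n < 2:
        return np.zeros((n, 2))
    raw = rng.normal(size=(n, 2))
    sm = gaussian_filter1d(raw, sigma=5.0, axis=0, mode="nearest")
    sd = sm.std()
    if sd > 0:
        sm *= sigma / sd
    return sm


def _plaque_polygon(
    section: np.ndarray, spec: PlaqueSpec, n_arc: int = 32
) -> np.ndarray:
    """Annular sector hugging the lumen boundary, `thickness` mm outward."""
    a0, a1 = np.radians(spec.angle_range_deg)
    phi = np.linspace(a0, a1, n_arc)
    # boundary radius of the (elliptical) section at each angle
    ang_sec = np.arctan2(section[:, 1], section[:, 0])
    r_sec = np.hypot(section[:, 0], section[:, 1])
    order = np.argsort(ang_sec)
    r_in = np.interp(
        (phi + np.pi) % (2 * np.pi) - np.pi,
        ang_sec[order],
        r_sec[order],
        period=2 * np.pi,
    )
    inner = np.stack([r_in * np.cos(phi), r_in * np.sin(phi)], axis=1)
    r_out = r_in + spec.thickness
    outer = np.stack([r_out * np.cos(phi), r_out * np.sin(phi)], axis=1)
    return np.vstack([inner, outer[::-1]])


def simulate_pullback(
    ph: Phantom,
    branch: str,
    speed: float = 0.5,
    frame_rate: float = 30.0,
    gating_stride: int = 30,
    twist_sigma_deg: float = 0.0,
    offset_sigma_mm: float = 0.0,
    contour_noise_mm: float = 0.0,
    carina_spike_mm: float = 0.0,
    seed: int = 0,
    n_points: int = 128,
) -> tuple[Pullback, dict]:
    """Sample true planar sections at the gated pullback spacing and corrupt
    them with twist, catheter offset, and radial contour noise.

    Returns the Pullback plus a ground-truth dict (placements, cumulative
    twist, offsets) for recovery tests.
    """
    if branch not in ("MV", "SB"):
        raise PhantomError("branch must be 'MV' or 'SB'")
    cl = ph.centerline(branch)
    spacing = speed / frame_rate
    gated_spacing = spacing * gating_stride
    n_frames = int(np.floor(cl.length / gated_spacing + 1e-9)) + 1
    if (n_frames - 1) * gated_spacing > cl.length + 1e-9:
        raise PhantomError("pullback exceeds branch length")

    rng = np.random.default_rng(seed)
    twist = np.concatenate(
        [[0.0], np.cumsum(rng.normal(0.0, twist_sigma_deg, n_frames - 1))]
    )
    offsets = _smooth_field(rng, n_frames, offset_sigma_mm)

    s_carina = _closest_arclength(cl, ph.carina_point)
    if carina_spike_mm > 0:
        svals_all = np.arange(n_frames) * gated_spacing
        bump = carina_spike_mm * np.exp(-0.5 * ((svals_all - s_carina) / 0.4) ** 2)
        offsets = offsets + bump[:, None] * np.array([1.0, 0.5]) / np.hypot(1.0, 0.5)

    frames = []
    placements = []
    carina_frame_idx = None
    best_ds = np.inf
    other_cl = ph.centerline("SB" if branch == "MV" else "MV")
    for k in range(n_frames):
        s = k * gated_spacing
        pl = ph.placement_at(branch, min(s, cl.length))
        placements.append(pl)
        section = ph.section_polygon(branch, s, n=n_points)
        if contour_noise_mm > 0:
            r = np.hypot(section[:, 0], section[:, 1])
            noise = rng.normal(0.0, contour_noise_mm, len(section))
            section = section * ((r + noise) / r)[:, None]
        e = offsets[k]
        rot = _rot2(twist[k])
        pts = (section - e) @ rot.T
        contours = [
            Contour(frame_index=k * gating_stride, label="lumen", points=pts)
        ]
        if ph.spec.eem_offset is not None:
            eem = ph.section_polygon(branch, s, n=n_points) * (
                1.0 + ph.spec.eem_offset / ph.radius_profile(branch)(s)
            )
            contours.append(
                Contour(
                    frame_index=k * gating_stride,
                    label="eem",
                    points=(eem - e) @ rot.T,
                )
            )
        for pi, pspec in enumerate(ph.spec.plaques):
            if pspec.s_range[0] <= s <= pspec.s_range[1]:
                poly = _plaque_polygon(ph.section_polygon(branch, s, n=n_points), pspec)
                contours.append(
                    Contour(
                        frame_index=k * gating_stride,
                        label=pspec.label,
                        component_id=pi,
                        points=(poly - e) @ rot.T,
                    )
                )
        frames.append(
            IVUSFrame(
                frame_index=k * gating_stride,
                catheter_point=(e @ rot.T),
                contours=contours,
                gated=True,
            )
        )
        if abs(s - s_carina) < best_ds:
            best_ds = abs(s - s_carina)
            carina_frame_idx = k

    # annotated carina direction, in the (twisted) image plane of that frame
    car_pl = placements[carina_frame_idx]
    takeoff = takeoff_direction(other_cl, car_pl.origin)
    proj = takeoff - (takeoff @ car_pl.t) * car_pl.t
    proj /= np.linalg.norm(proj)
    base_angle = np.degrees(np.arctan2(proj @ car_pl.v, proj @ car_pl.u))
    carina_direction = base_angle + twist[carina_frame_idx]

    pullback = Pullback(
        branch=branch,
        frames=frames,
        pullback_speed=speed,
        frame_rate=frame_rate,
        carina_frame=carina_frame_idx * gating_stride,
        carina_direction=float(carina_direction),
    )
    truth = {
        "placements": placements,
        "twist_deg": twist,
        "offsets_mm": offsets,
        "gated_spacing": gated_spacing,
        "s_carina": s_carina,
    }
    return pullback, truth


def _closest_arclength(cl: Centerline3D, point: np.ndarray) -> float:
    d = np.linalg.norm(cl.points - np.asarray(point, dtype=float), axis=1)
    return float(cl.arclength[int(np.argmin(d))])


# ---------------------------------------------------------------------------
# virtual biplane angiography
# ---------------------------------------------------------------------------

def simulate_biplane(
    ph: Phantom,
    geom_a: ProjectionGeometry,
    geom_b: ProjectionGeometry,
    noise_mm: float = 0.0,
    seed: int = 0,
) -> dict[str, tuple[Curve2D, Curve2D]]:
    """Forward-project both branch centerlines into the two views."""
    rng = np.random.default_rng(seed)
    out = {}
    for branch in ("MV", "SB"):
        cl = resample_by_arclength(ph.centerline(branch), 0.25)
        ca = project_centerline(cl, geom_a, branch=branch)
        cb = project_centerline(cl, geom_b, branch=branch)
        if noise_mm > 0:
            ca = Curve2D(ca.points + rng.normal(0, noise_mm, ca.points.shape), branch)
            cb = Curve2D(cb.points + rng.normal(0, noise_mm, cb.points.shape), branch)
        out[branch] = (ca, cb)
    return out
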