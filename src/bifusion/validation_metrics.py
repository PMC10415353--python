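"""Geometric comparison machinery for reconstructed bifurcation models.

Carina co-registration, serial cross-sections every 0.1 mm, diameter and
shape (distance Y / distance X) metrics, z-score normalization, ordinary
least squares regression and Bland-Altman agreement.  The significance
convention reported alongside regressions is p < 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats
from scipy.spatial import ConvexHull

from . import _mesh
from .angio_centerline import Centerline3D, tangent_at
from .contour_io import BifurcationModel, SurfaceMesh, shoelace_area

P_SIGNIFICANCE = 0.01


class MetricsError(ValueError):
    pass


@dataclass
class CrossSectionMetrics:
    s: float  # arclength mm from the carina (positive = proximal)
    area: float
    diameter: float  # area-equivalent by default
    dist_x: float  # max chord
    dist_y: float  # extent perpendicular to the max chord
    max_chord: float = 0.0

    def __post_init__(self):
        if self.area <= 0:
            raise MetricsError("cross-section area must be positive")
        if not self.max_chord:
            self.max_chord = self.dist_x

    @property
    def shape_ratio(self) -> float:
        return self.dist_y / self.dist_x


@dataclass
class ComparisonReport:
    branches: dict[str, dict] = field(default_factory=dict)
    sections: list[dict] = field(default_factory=list)

    def summary(self) -> dict:
        out: dict[str, float | str | bool] = {}
        for br, res in self.branches.items():
            for key in ("slope", "intercept", "r_squared", "p_value", "n_matched", "n_dropped"):
                out[f"{br}_{key}"] = res[key]
            md, lo, hi = res["bland_altman"]
            out[f"{br}_ba_mean_difference"] = md
            out[f"{br}_ba_loa_low"] = lo
            out[f"{br}_ba_loa_high"] = hi
            out[f"{br}_shape_median_a"] = res["shape_median_a"]
            out[f"{br}_shape_iqr_a"] = res["shape_iqr_a"]
            out[f"{br}_shape_median_b"] = res["shape_median_b"]
            out[f"{br}_shape_iqr_b"] = res["shape_iqr_b"]
            out[f"{br}_significant"] = bool(res["p_value"] < P_SIGNIFICANCE)
        return out


# ---------------------------------------------------------------------------
# polygon metrics
# ---------------------------------------------------------------------------

def densify_ring(points: np.ndarray, n: int = 512) -> np.ndarray:
    """Arc-length-uniform resampling of a closed ring to n points."""
    pts = np.asarray(points, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] == 0:
        raise MetricsError("degenerate ring")
    t = cum[-1] * np.arange(n) / n
    return np.stack([np.interp(t, cum, closed[:, i]) for i in range(pts.shape[1])], axis=1)


def max_chord_and_width(polygon: np.ndarray, n_densify: int = 512) -> tuple[float, float, float]:
    """(distance X, distance Y, Y/X): longest chord of the densified ring and
    the polygon extent perpendicular to it."""
    pts = np.asarray(polygon, dtype=float)
    if len(pts) < 3:
        raise MetricsError("polygon needs >= 3 vertices")
    if abs(shoelace_area(pts)) <= 0:
        raise MetricsError("degenerate (zero-area) polygon")
    dense = densify_ring(pts, n_densify)
    try:
        hull = ConvexHull(dense)
        hv = np.sort(hull.vertices)
    except Exception:
        hv = np.arange(len(dense))
    hp = dense[hv]
    diff = hp[:, None, :] - hp[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    flat = int(np.argmax(d2))  # first occurrence = lexicographically smallest pair
    i, j = divmod(flat, len(hp))
    dist_x = float(np.sqrt(d2[i, j]))
    if dist_x == 0:
        raise MetricsError("degenerate polygon: zero diameter")
    direction = (hp[j] - hp[i]) / dist_x
    perp = np.array([-direction[1], direction[0]])
    proj = dense @ perp
    dist_y = float(proj.max() - proj.min())
    return dist_x, dist_y, dist_y / dist_x


def equivalent_diameter(polygon: np.ndarray) -> float:
    """Diameter of the circle with the same (shoelace) area."""
    area = abs(shoelace_area(np.asarray(polygon, dtype=float)))
    if area <= 0:
        raise MetricsError("polygon has zero area")
    return 2.0 * float(np.sqrt(area / np.pi))


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def zscore_normalize(series: np.ndarray) -> np.ndarray:
    """(x - mean) / sample SD; output has mean 0 and unit variance."""
    x = np.asarray(series, dtype=float)
    if len(x) < 2:
        raise MetricsError("z-score needs at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise MetricsError("cannot z-score a constant series")
    return (x - x.mean()) / sd


def linear_regression(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """OLS (slope, intercept, r^2, two-sided p for the slope)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise MetricsError("regression needs matched series with n >= 3")
    if x.std() == 0:
        raise MetricsError("zero variance in x")
    res = _stats.linregress(x, y)
    return (
        float(res.slope),
        float(res.intercept),
        float(res.rvalue**2),
        float(res.pvalue),
    )


def bland_altman(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """(mean difference a-b, lower and upper 1.96-SD limits of agreement)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise MetricsError("Bland-Altman requires equal-length series")
    if len(a) < 2:
        raise MetricsError("Bland-Altman needs n >= 2")
    d = a - b
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    return md, md - 1.96 * sd, md + 1.96 * sd


# ---------------------------------------------------------------------------
# cross-section sampling
# ---------------------------------------------------------------------------

def _plane_basis(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.zeros(3)
    ref[int(np.argmin(np.abs(t)))] = 1.0
    u = ref - (ref @ t) * t
    u /= np.linalg.norm(u)
    return u, np.cross(t, u)


def carina_arclength(cl: Centerline3D, carina_point: np.ndarray) -> float:
    """Arclength of the centerline point closest to the carina."""
    d = np.linalg.norm(cl.points - np.asarray(carina_point, dtype=float), axis=1)
    return float(cl.arclength[int(np.argmin(d))])


def sample_cross_sections(
    mesh: SurfaceMesh,
    cl: Centerline3D,
    step: float = 0.1,
    carina_s: float = 0.0,
    max_centroid_offset: float | None = None,
    exclude_other_cl: Centerline3D | None = None,
    exclusion_margin: float = 0.3,
    end_margin: float = 0.0,
    junction_clearance: float = 0.0,
) -> list[CrossSectionMetrics]:
    """Serial cross-sections every `step` mm perpendicular to the centerline.

    Planes are placed at every multiple of `step` of absolute arclength; the
    reported s is re-origined at `carina_s` (positive = proximal).  The slice
    loop whose centroid is nearest the centerline point is measured; empty
    slices are skipped with a warning.  Sections whose loop crosses the other
    branch's domain (the other centerline pierces the loop, within margin)
    are excluded, as are sections within `end_margin` of either tube end.
    """
    if step <= 0:
        raise MetricsError("step must be positive")
    from shapely.geometry import Point as _Point
    from shapely.geometry import Polygon as _Poly

    out = []
    n = int(np.floor(cl.length / step + 1e-9))
    for k in range(n + 1):
        s = k * step
        if end_margin > 0 and (s < end_margin or s > cl.length - end_margin):
            continue
        origin = cl.point_at(s)
        if (
            exclude_other_cl is not None
            and junction_clearance > 0
            and _polyline_distance(exclude_other_cl.points, origin) < junction_clearance
        ):
            continue
        t = tangent_at(cl, s)
        loops = _mesh.slice_mesh_plane(mesh.vertices, mesh.triangles, origin, t)
        if not loops:
            # a plane coinciding exactly with an end cap: nudge inward
            for off in (1e-6, -1e-6):
                loops = _mesh.slice_mesh_plane(
                    mesh.vertices, mesh.triangles, origin + off * t, t
                )
                if loops:
                    break
        if not loops:
            warnings.warn(f"empty slice at s={s:.2f} mm; section skipped", stacklevel=2)
            continue
        cents = [lp.mean(axis=0) for lp in loops]
        offs = [np.linalg.norm(c - origin) for c in cents]
        pick = int(np.argmin(offs))
        if max_centroid_offset is not None and offs[pick] > max_centroid_offset:
            warnings.warn(
                f"slice at s={s:.2f} mm only matches a far loop; skipped", stacklevel=2
            )
            continue
        u, v = _plane_basis(t)
        rel = loops[pick] - origin
        poly = np.stack([rel @ u, rel @ v], axis=1)
        if shoelace_area(poly) < 0:
            poly = poly[::-1]
        area = shoelace_area(poly)
        if area <= 0:
            continue
        if exclude_other_cl is not None and _crosses_other_domain(
            exclude_other_cl, origin, t, u, v, poly, exclusion_margin
        ):
            continue
        dx, dy, _ = max_chord_and_width(poly)
        out.append(
            CrossSectionMetrics(
                s=s - carina_s,
                area=area,
                diameter=equivalent_diameter(poly),
                dist_x=dx,
                dist_y=dy,
            )
        )
    return out


def _polyline_distance(points: np.ndarray, p: np.ndarray) -> float:
    """Distance from point p to a 3D polyline."""
    a = points[:-1]
    b = points[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom = np.where(denom == 0, 1.0, denom)
    t = np.clip(np.einsum("j,ij->i", p, ab) - np.einsum("ij,ij->i", a, ab), 0, None)
    t = np.clip(t / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.linalg.norm(proj - p, axis=1).min())


def _crosses_other_domain(other_cl, origin, t, u, v, poly, margin) -> bool:
    """True when the other branch's centerline pierces this section loop."""
    from shapely.geometry import Point as _Point
    from shapely.geometry import Polygon as _Poly

    d = (other_cl.points - origin) @ t
    sgn = np.sign(d)
    crossing_idx = np.flatnonzero(sgn[:-1] * sgn[1:] < 0)
    if len(crossing_idx) == 0:
        return False
    shp = _Poly(poly).buffer(margin)
    for i in crossing_idx:
        a, b = other_cl.points[i], other_cl.points[i + 1]
        w = d[i] / (d[i] - d[i + 1])
        p = a + w * (b - a)
        rel = p - origin
        if shp.contains(_Point(rel @ u, rel @ v)):
            return True
    return False


def coregister_at_carina(
    model_a: BifurcationModel, model_b: BifurcationModel
) -> dict[str, tuple[float, float]]:
    """Carina arclength per branch for both models (the shared s=0 origin)."""
    for name, m in (("A", model_a), ("B", model_b)):
        if m.carina_point is None or not np.all(np.isfinite(m.carina_point)):
            raise MetricsError(f"model {name} is missing its carina point")
    return {
        "MV": (
            carina_arclength(model_a.mv_centerline, model_a.carina_point),
            carina_arclength(model_b.mv_centerline, model_b.carina_point),
        ),
        "SB": (
            carina_arclength(model_a.sb_centerline, model_a.carina_point),
            carina_arclength(model_b.sb_centerline, model_b.carina_point),
        ),
    }


def _branch_radius_estimate(model: BifurcationModel, branch: str) -> float:
    """Median equivalent radius of a handful of stations along the branch."""
    cl = model.mv_centerline if branch == "MV" else model.sb_centerline
    radii = []
    for frac in (0.15, 0.3, 0.5, 0.7, 0.85):
        s = frac * cl.length
        origin = cl.point_at(s)
        t = tangent_at(cl, s)
        loops = _mesh.slice_mesh_plane(model.lumen.vertices, model.lumen.triangles, origin, t)
        if not loops:
            continue
        cents = [lp.mean(axis=0) for lp in loops]
        loop = loops[int(np.argmin([np.linalg.norm(c - origin) for c in cents]))]
        u, v = _plane_basis(t)
        rel = loop - origin
        poly = np.stack([rel @ u, rel @ v], axis=1)
        area = abs(shoelace_area(poly))
        if area > 0:
            radii.append(np.sqrt(area / np.pi))
    return float(np.median(radii)) if radii else 1.5


def _auto_junction_clearance(model: BifurcationModel, branch: str) -> float:
    """Exclusion radius around the junction: both tubes overlap out to about
    the sum of the branch radii; 1.2x margin covers proximal widening."""
    other = "SB" if branch == "MV" else "MV"
    return 1.2 * (
        _branch_radius_estimate(model, branch) + _branch_radius_estimate(model, other)
    )


def compare_models(
    model_a: BifurcationModel,
    model_b: BifurcationModel,
    step: float = 0.1,
    diameter: str = "equivalent",
    min_matched: int = 10,
    end_margin: float = 0.5,
    junction_clearance: float | None = None,
) -> ComparisonReport:
    """Per-branch paired comparison of two bifurcation models.

    Sections are matched on arclength from the co-registered carina,
    diameters are z-scored then regressed (A on B), lumen shape is compared
    by medians/IQR and Bland-Altman of the shape ratios.
    """
    if diameter not in ("equivalent", "max_chord"):
        raise MetricsError(f"unknown diameter definition {diameter!r}")
    origins = coregister_at_carina(model_a, model_b)
    report = ComparisonReport()
    for branch in ("MV", "SB"):
        cl_a = model_a.mv_centerline if branch == "MV" else model_a.sb_centerline
        cl_b = model_b.mv_centerline if branch == "MV" else model_b.sb_centerline
        other_a = model_a.sb_centerline if branch == "MV" else model_a.mv_centerline
        other_b = model_b.sb_centerline if branch == "MV" else model_b.mv_centerline
        sa, sb = origins[branch]
        jc_a = (
            junction_clearance
            if junction_clearance is not None
            else _auto_junction_clearance(model_a, branch)
        )
        jc_b = (
            junction_clearance
            if junction_clearance is not None
            else _auto_junction_clearance(model_b, branch)
        )
        sec_a = sample_cross_sections(
            model_a.lumen, cl_a, step=step, carina_s=sa,
            exclude_other_cl=other_a, end_margin=end_margin,
            junction_clearance=jc_a,
        )
        sec_b = sample_cross_sections(
            model_b.lumen, cl_b, step=step, carina_s=sb,
            exclude_other_cl=other_b, end_margin=end_margin,
            junction_clearance=jc_b,
        )
        key_a = {round(m.s / step): m for m in sec_a}
        key_b = {round(m.s / step): m for m in sec_b}
        common = sorted(set(key_a) & set(key_b))
        n_dropped = len(set(key_a) ^ set(key_b))
        if len(common) < min_matched:
            raise MetricsError(
                f"branch {branch}: only {len(common)} matched sections (< {min_matched})"
            )
        ma = [key_a[k] for k in common]
        mb = [key_b[k] for k in common]

        def diam(m: CrossSectionMetrics) -> float:
            return m.diameter if diameter == "equivalent" else m.max_chord

        da = np.array([diam(m) for m in ma])
        db = np.array([diam(m) for m in mb])
        za = zscore_normalize(da)
        zb = zscore_normalize(db)
        slope, intercept, r2, p = linear_regression(zb, za)
        shapes_a = np.array([m.shape_ratio for m in ma])
        shapes_b = np.array([m.shape_ratio for m in mb])
        ba = bland_altman(shapes_a, shapes_b)
        q1a, q3a = np.percentile(shapes_a, [25, 75])
        q1b, q3b = np.percentile(shapes_b, [25, 75])
        report.branches[branch] = {
            "slope": slope,
            "intercept": intercept,
            "r_squared": r2,
            "p_value": p,
            "n_matched": len(common),
            "n_dropped": n_dropped,
            "bland_altman": ba,
            "shape_median_a": float(np.median(shapes_a)),
            "shape_iqr_a": float(q3a - q1a),
            "shape_median_b": float(np.median(shapes_b)),
            "shape_iqr_b": float(q3b - q1b),
        }
        for k, a, b in zip(common, ma, mb):
            report.sections.append(
                {
                    "branch": branch,
                    "s_mm": k * step,
                    "diameter_a_mm": diam(a),
                    "diameter_b_mm": diam(b),
                    "shape_ratio_a": a.shape_ratio,
                    "shape_ratio_b": b.shape_ratio,
                }
            )
    return report
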