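"""Surface construction: contour lofting, branch union, plaque solids,
mapping-back checks and contour-driven refinement.

Lofting correspondence is by normalized angle from each frame's u axis,
which keeps the seam continuous once twist/carina rolls are applied.  The
MV/SB union is realized on a signed-distance grid (pitch-controlled) with
marching-cubes extraction, which stays robust at near-tangent carinas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from shapely.geometry import Polygon as _ShapelyPolygon

from . import _mesh
from .contour_io import Contour, SurfaceMesh
from .frame_geometry import FramePlacement, radial_profile


class SurfaceBuildError(ValueError):
    pass


@dataclass
class PlacedContour:
    contour: Contour
    placement: FramePlacement
    points3d: np.ndarray = field(init=False)

    def __post_init__(self):
        self.points3d = self.placement.to_world(self.contour.points)

    @property
    def s(self) -> float:
        return self.placement.s

    def inplane_points(self) -> np.ndarray:
        """Ring coordinates in the frame's (u, v) basis (roll folded in)."""
        rel = self.points3d - self.placement.origin
        return np.stack([rel @ self.placement.u, rel @ self.placement.v], axis=1)


# ---------------------------------------------------------------------------
# ring resampling and cap triangulation
# ---------------------------------------------------------------------------

def resample_ring(points2d: np.ndarray, n_theta: int) -> np.ndarray:
    """Resample a CCW ring to n_theta points starting at angle 0.

    Star-shaped rings (about their centroid) are sampled at equiangular
    boundary radii; otherwise arc-length-uniform with the start point at the
    boundary angle closest to zero.
    """
    pts = np.asarray(points2d, dtype=float)
    centroid = np.asarray(_ShapelyPolygon(pts).centroid.coords[0])
    rel = pts - centroid
    try:
        prof, star = radial_profile(rel, n_theta)
    except Exception:
        prof, star = None, False
    if star:
        phi = 2 * np.pi * np.arange(n_theta) / n_theta
        return centroid + prof[:, None] * np.stack([np.cos(phi), np.sin(phi)], axis=1)
    # fallback: arc-length-uniform, rotated so the start sits near angle 0
    ang = np.arctan2(rel[:, 1], rel[:, 0])
    start = int(np.argmin(np.abs((ang + np.pi) % (2 * np.pi) - np.pi)))
    ring = np.vstack([pts[start:], pts[:start]])
    closed = np.vstack([ring, ring[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = cum[-1] * np.arange(n_theta) / n_theta
    out = np.stack(
        [np.interp(targets, cum, closed[:, i]) for i in range(2)], axis=1
    )
    return out


def earclip(points2d: np.ndarray) -> list[tuple[int, int, int]]:
    """Ear-clipping triangulation of a simple CCW polygon (indices)."""
    pts = np.asarray(points2d, dtype=float)
    n = len(pts)
    idx = list(range(n))
    tris: list[tuple[int, int, int]] = []

    def cross(o, a, b):
        return (pts[a, 0] - pts[o, 0]) * (pts[b, 1] - pts[o, 1]) - (
            pts[a, 1] - pts[o, 1]
        ) * (pts[b, 0] - pts[o, 0])

    guard = 0
    while len(idx) > 3 and guard < 10 * n * n:
        guard += 1
        n_cur = len(idx)
        clipped = False
        for k in range(n_cur):
            i0, i1, i2 = idx[k - 1], idx[k], idx[(k + 1) % n_cur]
            if cross(i0, i1, i2) <= 1e-14:
                continue  # reflex or degenerate corner
            ear = True
            a, b, c = pts[i0], pts[i1], pts[i2]
            for j in idx:
                if j in (i0, i1, i2):
                    continue
                p = pts[j]
                d0 = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
                d1 = (c[0] - b[0]) * (p[1] - b[1]) - (c[1] - b[1]) * (p[0] - b[0])
                d2 = (a[0] - c[0]) * (p[1] - c[1]) - (a[1] - c[1]) * (p[0] - c[0])
                if d0 >= 0 and d1 >= 0 and d2 >= 0:
                    ear = False
                    break
            if ear:
                tris.append((i0, i1, i2))
                idx.pop(k)
                clipped = True
                break
        if not clipped:
            # numerically stuck: fan the remainder
            for k in range(1, len(idx) - 1):
                tris.append((idx[0], idx[k], idx[k + 1]))
            return tris
    if len(idx) == 3:
        tris.append((idx[0], idx[1], idx[2]))
    return tris


# ---------------------------------------------------------------------------
# lofting
# ---------------------------------------------------------------------------

def loft_surface(
    contours: list[PlacedContour], n_theta: int = 256, label: str | None = None
) -> SurfaceMesh:
    """Loft ordered placed contours into a watertight capped tube."""
    if n_theta < 8:
        raise SurfaceBuildError("n_theta must be >= 8")
    if len(contours) < 2:
        raise SurfaceBuildError("lofting needs at least two contours")
    labels = {pc.contour.label for pc in contours}
    if len(labels) > 1:
        raise SurfaceBuildError(f"mixed contour labels {labels} in one loft")
    svals = np.array([pc.s for pc in contours])
    if np.any(np.diff(svals) <= 0):
        raise SurfaceBuildError("contour rings cross in arclength (s not increasing)")

    rings3d = []
    for pc in contours:
        ring2 = resample_ring(pc.inplane_points(), n_theta)
        pl = pc.placement
        rings3d.append(
            pl.origin + ring2[:, [0]] * pl.u + ring2[:, [1]] * pl.v
        )
    rings3d = np.asarray(rings3d)  # (m, n_theta, 3)
    m = len(rings3d)

    verts = rings3d.reshape(-1, 3)
    faces: list[tuple[int, int, int]] = []
    for k in range(m - 1):
        a0 = k * n_theta
        b0 = (k + 1) * n_theta
        for j in range(n_theta):
            j1 = (j + 1) % n_theta
            faces.append((a0 + j, a0 + j1, b0 + j1))
            faces.append((a0 + j, b0 + j1, b0 + j))

    # caps reuse the ring vertices (ear clipping keeps the mesh watertight)
    first2d = _ring_in_plane(contours[0], rings3d[0])
    last2d = _ring_in_plane(contours[-1], rings3d[-1])
    for i0, i1, i2 in earclip(first2d):
        faces.append((i2, i1, i0))  # outward = -t at the distal end
    base = (m - 1) * n_theta
    for i0, i1, i2 in earclip(last2d):
        faces.append((base + i0, base + i1, base + i2))

    f = np.asarray(faces)
    if _mesh.signed_volume(verts, f) < 0:
        f = f[:, ::-1]
    mesh = SurfaceMesh(vertices=verts, triangles=f, label=label or contours[0].contour.label)
    return mesh


def _ring_in_plane(pc: PlacedContour, ring3d: np.ndarray) -> np.ndarray:
    rel = ring3d - pc.placement.origin
    return np.stack([rel @ pc.placement.u, rel @ pc.placement.v], axis=1)


# ---------------------------------------------------------------------------
# branch union
# ---------------------------------------------------------------------------

def _grid_axes(lo, hi, pitch, margin):
    start = lo - margin
    n = int(np.ceil((hi + margin - start) / pitch)) + 1
    return start + pitch * np.arange(n)


def merge_branches(
    mv: SurfaceMesh, sb: SurfaceMesh, pitch: float = 0.1, label: str = "lumen"
) -> SurfaceMesh:
    """Boolean union of two watertight meshes on a signed-distance grid."""
    for m, name in ((mv, "MV"), (sb, "SB")):
        if not m.is_watertight:
            raise SurfaceBuildError(f"{name} mesh is not watertight")
    lo_a, hi_a = mv.vertices.min(axis=0), mv.vertices.max(axis=0)
    lo_b, hi_b = sb.vertices.min(axis=0), sb.vertices.max(axis=0)
    if np.any(lo_a > hi_b) or np.any(lo_b > hi_a):
        raise SurfaceBuildError("branches do not intersect")

    margin = 4 * pitch
    lo = np.minimum(lo_a, lo_b)
    hi = np.maximum(hi_a, hi_b)
    xs = _grid_axes(lo[0], hi[0], pitch, margin)
    ys = _grid_axes(lo[1], hi[1], pitch, margin)
    zs = _grid_axes(lo[2], hi[2], pitch, margin)

    sd_a = _mesh.signed_distance_grid(mv.vertices, mv.triangles, xs, ys, zs)
    sd_b = _mesh.signed_distance_grid(sb.vertices, sb.triangles, xs, ys, zs)
    if float(np.maximum(sd_a, sd_b).min()) > 0:
        raise SurfaceBuildError("branches do not intersect")
    field = np.minimum(sd_a, sd_b)
    v, f = _mesh.extract_isosurface(field, xs, ys, zs)
    v, f = _largest_component(v, f)
    return SurfaceMesh(vertices=v, triangles=f, label=label)


def _largest_component(v: np.ndarray, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    g = coo_matrix(
        (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(len(v), len(v))
    )
    n_comp, comp = connected_components(g, directed=False)
    if n_comp == 1:
        return v, f
    sizes = np.bincount(comp)
    keep = comp[f[:, 0]] == np.argmax(sizes)
    f2 = f[keep]
    used = np.unique(f2)
    remap = -np.ones(len(v), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return v[used], remap[f2]


# ---------------------------------------------------------------------------
# plaque solids
# ---------------------------------------------------------------------------

def loft_plaque_components(
    contours: list[PlacedContour],
    label: str,
    overlap_tau: float = 0.3,
    n_theta: int = 64,
    cap_thickness: float | None = None,
) -> list[SurfaceMesh]:
    """Link same-label components across consecutive frames by frame-plane
    polygon overlap and loft each chain into a closed solid.

    Overlap = intersection area / smaller polygon area, thresholded at
    `overlap_tau`.  A chain seen on a single frame becomes a thin capped
    disc of the given thickness (default: the local frame spacing).
    """
    pcs = [pc for pc in contours if pc.contour.label == label]
    if not pcs:
        return []
    # group by frame s
    frames: dict[float, list[PlacedContour]] = {}
    for pc in pcs:
        frames.setdefault(round(pc.s, 9), []).append(pc)
    svals = sorted(frames)
    if cap_thickness is None:
        cap_thickness = float(np.median(np.diff(svals))) if len(svals) > 1 else 0.5

    chains: list[list[PlacedContour]] = []
    open_chains: dict[int, list[PlacedContour]] = {}  # keyed by id of last pc
    prev: list[PlacedContour] = []
    for s in svals:
        cur = frames[s]
        pairs = []
        for a in prev:
            pa = _ShapelyPolygon(a.inplane_points())
            for b in cur:
                pb = _ShapelyPolygon(b.inplane_points())
                inter = pa.intersection(pb).area
                smaller = min(pa.area, pb.area)
                if smaller > 0 and inter / smaller >= overlap_tau:
                    pairs.append((inter / smaller, a, b))
        pairs.sort(key=lambda t: -t[0])
        matched_a: set[int] = set()
        matched_b: set[int] = set()
        next_open: dict[int, list[PlacedContour]] = {}
        for ov, a, b in pairs:
            if id(a) in matched_a or id(b) in matched_b:
                continue
            matched_a.add(id(a))
            matched_b.add(id(b))
            chain = open_chains.pop(id(a))
            chain.append(b)
            next_open[id(b)] = chain
        # unmatched previous components terminate their chains
        for key, chain in open_chains.items():
            chains.append(chain)
        # unmatched current components start new chains
        for b in cur:
            if id(b) not in matched_b:
                next_open[id(b)] = [b]
        open_chains = next_open
        prev = cur
    chains.extend(open_chains.values())

    meshes = []
    for chain in chains:
        if len(chain) == 1:
            chain = _thicken_single(chain[0], cap_thickness)
        mesh = loft_surface(chain, n_theta=n_theta, label=label)
        meshes.append(mesh)
    return meshes


def _thicken_single(pc: PlacedContour, thickness: float) -> list[PlacedContour]:
    from dataclasses import replace as _replace

    half = 0.5 * thickness
    out = []
    for sign in (-1.0, 1.0):
        pl = _replace(
            pc.placement,
            origin=pc.placement.origin + sign * half * pc.placement.t,
            s=pc.placement.s + sign * half,
        )
        out.append(PlacedContour(contour=pc.contour, placement=pl))
    return out


# ---------------------------------------------------------------------------
# mapping back
# ---------------------------------------------------------------------------

def _point_polyline_distance(points: np.ndarray, loop: np.ndarray) -> np.ndarray:
    """Distance from each 3D point to a closed polyline."""
    a = loop
    b = np.roll(loop, -1, axis=0)
    ab = b - a  # (S, 3)
    denom = np.einsum("ij,ij->i", ab, ab)
    denom = np.where(denom == 0, 1.0, denom)
    ap = points[:, None, :] - a[None, :, :]  # (P, S, 3)
    t = np.clip(np.einsum("psj,sj->ps", ap, ab) / denom, 0.0, 1.0)
    proj = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    d = np.linalg.norm(points[:, None, :] - proj, axis=2)
    return d.min(axis=1)


def map_back_check(
    mesh: SurfaceMesh,
    contours: list[PlacedContour],
    point_masks: dict[int, np.ndarray] | None = None,
    strict: bool = True,
) -> dict[int, dict[str, float]]:
    """Slice the mesh at every frame plane and measure contour deviation.

    Returns per-frame {'mean': .., 'max': ..} point-to-slice-loop distances,
    using the slice loop whose centroid is nearest the frame origin.
    `point_masks` (keyed by frame_index, True = keep) restricts which contour
    points are scored, e.g. to drop points interior to the other branch.
    """
    if not mesh.is_watertight:
        raise SurfaceBuildError("map-back requires a watertight mesh")
    out: dict[int, dict[str, float]] = {}
    for pc in contours:
        pl = pc.placement
        loops = _mesh.slice_mesh_plane(mesh.vertices, mesh.triangles, pl.origin, pl.t)
        if not loops:
            # end frames can coincide exactly with a cap plane: nudge inward
            for off in (1e-6, -1e-6):
                loops = _mesh.slice_mesh_plane(
                    mesh.vertices, mesh.triangles, pl.origin + off * pl.t, pl.t
                )
                if loops:
                    break
        if not loops:
            if strict:
                raise SurfaceBuildError(
                    f"frame {pc.contour.frame_index}: slicing plane misses the mesh"
                )
            continue
        cents = [lp.mean(axis=0) for lp in loops]
        loop = loops[int(np.argmin([np.linalg.norm(c - pl.origin) for c in cents]))]
        pts = pc.points3d
        if point_masks is not None and pc.contour.frame_index in point_masks:
            keep = point_masks[pc.contour.frame_index]
            if np.sum(keep) < 3:
                continue
            pts = pts[keep]
        d = _point_polyline_distance(pts, loop)
        out[pc.contour.frame_index] = {"mean": float(d.mean()), "max": float(d.max())}
    return out


def mean_map_back_deviation(stats: dict[int, dict[str, float]]) -> float:
    return float(np.mean([v["mean"] for v in stats.values()]))


# ---------------------------------------------------------------------------
# refinement
# ---------------------------------------------------------------------------

def _vertex_adjacency(n_vertices: int, faces: np.ndarray):
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e = np.concatenate([e, e[:, ::-1]])
    w = np.ones(len(e))
    g = coo_matrix((w, (e[:, 0], e[:, 1])), shape=(n_vertices, n_vertices)).tocsr()
    g.data[:] = 1.0
    deg = np.asarray(g.sum(axis=1)).ravel()
    return g, np.where(deg == 0, 1.0, deg)


def refine_to_contours(
    mesh: SurfaceMesh,
    contours: list[PlacedContour],
    tol: float = 0.05,
    max_iter: int = 10,
    smooth_passes: int = 2,
) -> SurfaceMesh:
    """Iteratively pull near-plane vertices toward the segmented contours.

    Closest-point pull weighted by axial distance to the frame plane, with
    Laplacian smoothing of the displacement field; stops at `tol` mean
    map-back deviation or `max_iter`.  The mean deviation never increases:
    a worsening step is reverted and iteration stops.
    """
    stats = map_back_check(mesh, contours, strict=False)
    if not stats:
        raise SurfaceBuildError("no frame plane intersects the mesh")
    best_dev = mean_map_back_deviation(stats)
    best = SurfaceMesh(
        vertices=mesh.vertices.copy(), triangles=mesh.triangles.copy(), label=mesh.label
    )
    if best_dev <= tol:
        return best

    svals = np.array(sorted(pc.s for pc in contours))
    halfwin = 0.75 * (float(np.median(np.diff(svals))) if len(svals) > 1 else 0.5)
    adj, deg = _vertex_adjacency(len(mesh.vertices), mesh.triangles)

    cur = best
    for _ in range(max_iter):
        v = cur.vertices.copy()
        disp = np.zeros_like(v)
        wsum = np.zeros(len(v))
        for pc in contours:
            pl = pc.placement
            dz = (v - pl.origin) @ pl.t
            sel = np.abs(dz) < halfwin
            if not np.any(sel):
                continue
            w = 1.0 - np.abs(dz[sel]) / halfwin
            rel = v[sel] - pl.origin
            p2 = np.stack([rel @ pl.u, rel @ pl.v], axis=1)
            ring = _ring_in_plane(pc, pc.points3d)
            tgt = _closest_on_ring(p2, ring)
            dxy = tgt - p2
            disp[sel] += w[:, None] * (dxy[:, [0]] * pl.u + dxy[:, [1]] * pl.v)
            wsum[sel] += w
        nz = wsum > 0
        disp[nz] /= wsum[nz, None]
        for _ in range(smooth_passes):
            disp = 0.5 * disp + 0.5 * (adj @ disp) / deg[:, None]
        v = v + disp
        cand = SurfaceMesh(vertices=v, triangles=cur.triangles, label=cur.label)
        cand_stats = map_back_check(cand, contours, strict=False)
        if not cand_stats:
            break
        dev = mean_map_back_deviation(cand_stats)
        if dev >= best_dev:
            break
        best, best_dev = cand, dev
        cur = cand
        if best_dev <= tol:
            return best
    if best_dev > tol:
        warnings.warn(
            f"refinement stopped at mean deviation {best_dev:.4f} mm (> tol {tol})",
            stacklevel=2,
        )
    return best


def _closest_on_ring(points2d: np.ndarray, ring: np.ndarray) -> np.ndarray:
    a = ring
    b = np.roll(ring, -1, axis=0)
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom = np.where(denom == 0, 1.0, denom)
    ap = points2d[:, None, :] - a[None, :, :]
    t = np.clip(np.einsum("psj,sj->ps", ap, ab) / denom, 0.0, 1.0)
    proj = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    d2 = np.sum((points2d[:, None, :] - proj) ** 2, axis=2)
    j = np.argmin(d2, axis=1)
    return proj[np.arange(len(points2d)), j]
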