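"""Low-level triangle-mesh kernel.

Watertightness / volume checks, exact point-triangle distances, plane
slicing, z-column parity occupancy, signed-distance grids and marching-cubes
extraction.  Everything operates on plain (V, F) arrays: V float64 (n, 3),
F int (m, 3).  Kept free of the domain types so the geometry modules can
share it.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes as _marching_cubes

__all__ = [
    "edge_counts",
    "is_watertight",
    "is_consistently_oriented",
    "signed_volume",
    "surface_area",
    "merge_close_vertices",
    "point_triangle_distance",
    "MeshDistance",
    "slice_mesh_plane",
    "occupancy_columns",
    "signed_distance_grid",
    "extract_isosurface",
    "mean_symmetric_distance",
]


def _sorted_edges(faces: np.ndarray) -> np.ndarray:
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    return np.sort(e, axis=1)


def edge_counts(faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique undirected edges and how many faces share each."""
    e = _sorted_edges(np.asarray(faces))
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    return uniq, counts


def is_watertight(faces: np.ndarray) -> bool:
    """Every undirected edge is shared by exactly two faces."""
    if len(faces) == 0:
        return False
    _, counts = edge_counts(faces)
    return bool(np.all(counts == 2))


def is_consistently_oriented(faces: np.ndarray) -> bool:
    """Each undirected edge is traversed once in each direction."""
    if len(faces) == 0:
        return False
    faces = np.asarray(faces)
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    # directed edge (a, b) must appear exactly once, and (b, a) exactly once
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    if np.any(counts != 1):
        return False
    rev = uniq[:, ::-1]
    combined = np.concatenate([uniq, rev])
    u2, c2 = np.unique(combined, axis=0, return_counts=True)
    return bool(np.all(c2 == 2))


def signed_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    """Divergence-theorem volume; positive for outward-oriented meshes."""
    v = np.asarray(vertices, dtype=float)
    t = v[np.asarray(faces)]
    return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)


def surface_area(vertices: np.ndarray, faces: np.ndarray) -> float:
    t = np.asarray(vertices, dtype=float)[np.asarray(faces)]
    n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
    return float(0.5 * np.linalg.norm(n, axis=1).sum())


def merge_close_vertices(
    vertices: np.ndarray, faces: np.ndarray, tol: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Weld duplicate vertices (within `tol`) and drop collapsed faces."""
    v = np.asarray(vertices, dtype=float)
    f = np.asarray(faces)
    if tol > 0:
        key = np.round(v / tol).astype(np.int64)
    else:
        key = v
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    v_out = v[first]
    f_out = inverse[f]
    keep = (
        (f_out[:, 0] != f_out[:, 1])
        & (f_out[:, 1] != f_out[:, 2])
        & (f_out[:, 2] != f_out[:, 0])
    )
    return v_out, f_out[keep]


# ---------------------------------------------------------------------------
# exact point-triangle distance (vectorized, Ericson's region decomposition)
# ---------------------------------------------------------------------------

def point_triangle_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Distance from each point p[i] to its triangle (a[i], b[i], c[i])."""
    p = np.atleast_2d(np.asarray(p, dtype=float))
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    c = np.atleast_2d(np.asarray(c, dtype=float))

    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)

    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)

    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    closest = np.empty_like(p)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    closest[m] = a[m]
    m2 = (d3 >= 0) & (d4 <= d3)
    closest[m2 & ~m] = b[m2 & ~m]
    done = m | m2
    m3 = (d6 >= 0) & (d5 <= d6)
    closest[m3 & ~done] = c[m3 & ~done]
    done |= m3

    # edge AB
    vc = d1 * d4 - d3 * d2
    m4 = (vc <= 0) & (d1 >= 0) & (d3 <= 0) & ~done
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(d1 - d3 != 0, d1 / np.where(d1 - d3 == 0, 1.0, d1 - d3), 0.0)
    closest[m4] = a[m4] + t[m4, None] * ab[m4]
    done |= m4

    # edge AC
    vb = d5 * d2 - d1 * d6
    m5 = (vb <= 0) & (d2 >= 0) & (d6 <= 0) & ~done
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(d2 - d6 != 0, d2 / np.where(d2 - d6 == 0, 1.0, d2 - d6), 0.0)
    closest[m5] = a[m5] + w[m5, None] * ac[m5]
    done |= m5

    # edge BC
    va = d3 * d6 - d5 * d4
    m6 = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0) & ~done
    denom = (d4 - d3) + (d5 - d6)
    with np.errstate(invalid="ignore", divide="ignore"):
        w2 = np.where(denom != 0, (d4 - d3) / np.where(denom == 0, 1.0, denom), 0.0)
    closest[m6] = b[m6] + w2[m6, None] * (c[m6] - b[m6])
    done |= m6

    # interior
    inner = ~done
    denom2 = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        safe = np.where(denom2 == 0, 1.0, denom2)
        v = vb / safe
        w3 = vc / safe
    closest[inner] = a[inner] + v[inner, None] * ab[inner] + w3[inner, None] * ac[inner]

    return np.linalg.norm(p - closest, axis=1)


class MeshDistance:
    """Fast unsigned distance queries against a fixed triangle mesh.

    Candidate triangles come from a k-NN query on triangle centroids plus a
    surface-sample KD-tree upper bound, then exact point-triangle distances
    decide.  Exact in practice for the well-shaped meshes produced here.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        self.v = np.asarray(vertices, dtype=float)
        self.f = np.asarray(faces)
        tris = self.v[self.f]
        self._tris = tris
        self._centroids = tris.mean(axis=1)
        samples = np.concatenate(
            [
                self.v,
                self._centroids,
                0.5 * (tris[:, 0] + tris[:, 1]),
                0.5 * (tris[:, 1] + tris[:, 2]),
                0.5 * (tris[:, 2] + tris[:, 0]),
            ]
        )
        self._sample_tree = cKDTree(samples)
        self._centroid_tree = cKDTree(self._centroids)

    def distance(
        self, points: np.ndarray, k: int = 12, upper_bound: np.ndarray | None = None
    ) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        ub = upper_bound if upper_bound is not None else self._sample_tree.query(points)[0]
        k = min(k, len(self.f))
        _, idx = self._centroid_tree.query(points, k=k)
        idx = np.atleast_2d(idx.reshape(len(points), -1))
        best = np.asarray(ub, dtype=float).copy()
        rep = np.repeat(points, idx.shape[1], axis=0)
        tri = self._tris[idx.ravel()]
        d = point_triangle_distance(rep, tri[:, 0], tri[:, 1], tri[:, 2])
        d = d.reshape(len(points), -1).min(axis=1)
        np.minimum(best, d, out=best)
        return best


# ---------------------------------------------------------------------------
# plane slicing
# ---------------------------------------------------------------------------

def slice_mesh_plane(
    vertices: np.ndarray, faces: np.ndarray, origin: np.ndarray, normal: np.ndarray
) -> list[np.ndarray]:
    """Intersect a closed mesh with a plane; return closed loops of 3D points.

    Each loop is an (n, 3) array, unclosed (last point connects to first).
    Returns an empty list when the plane misses the mesh.
    """
    v = np.asarray(vertices, dtype=float)
    f = np.asarray(faces)
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    d = (v - np.asarray(origin, dtype=float)) @ n
    # nudge exact-on-plane vertices to avoid degenerate crossings
    eps = 1e-12 * max(1.0, float(np.abs(d).max(initial=0.0)))
    d = np.where(d == 0.0, eps, d)

    s = d[f]  # (m, 3) signed distances per face corner
    pos = s > 0
    npos = pos.sum(axis=1)
    crossing = (npos == 1) | (npos == 2)
    if not np.any(crossing):
        return []

    cross_faces = f[crossing]
    cross_s = s[crossing]

    # for each crossing face, find its two crossed edges
    edge_local = [(0, 1), (1, 2), (2, 0)]
    seg_edges = []  # per face: two canonical edge keys
    pts_cache: dict[tuple[int, int], np.ndarray] = {}
    for face, sv in zip(cross_faces, cross_s):
        keys = []
        for i, j in edge_local:
            if (sv[i] > 0) != (sv[j] > 0):
                a, b = int(face[i]), int(face[j])
                key = (a, b) if a < b else (b, a)
                if key not in pts_cache:
                    t = d[a] / (d[a] - d[b])
                    pts_cache[key] = v[a] + t * (v[b] - v[a])
                keys.append(key)
        if len(keys) == 2:
            seg_edges.append((keys[0], keys[1]))

    # chain segments into loops; each edge key touches exactly 2 segments
    adj: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for a, b in seg_edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)

    visited: set[tuple[int, int]] = set()
    loops = []
    for start in adj:
        if start in visited:
            continue
        loop_keys = [start]
        visited.add(start)
        prev = None
        cur = start
        while True:
            nxts = [k for k in adj[cur] if k != prev]
            if not nxts:
                break
            nxt = nxts[0]
            if nxt == start:
                break
            if nxt in visited:
                break
            loop_keys.append(nxt)
            visited.add(nxt)
            prev, cur = cur, nxt
        if len(loop_keys) >= 3:
            loops.append(np.array([pts_cache[k] for k in loop_keys]))
    return loops


# ---------------------------------------------------------------------------
# occupancy + signed-distance grids
# ---------------------------------------------------------------------------

def occupancy_columns(
    vertices: np.ndarray,
    faces: np.ndarray,
    xs: np.ndarray,
    ys: np.ndarray,
    zs: np.ndarray,
) -> np.ndarray:
    """Boolean inside/outside by z-ray crossing parity on a grid.

    xs, ys, zs are the 1D grid coordinates.  Rays travel along +z through
    each (x, y) column.  Column coordinates are nudged off exact edge hits.
    """
    v = np.asarray(vertices, dtype=float)
    f = np.asarray(faces)
    tris = v[f]
    # generic-position nudge so rays do not pass through shared edges
    jitter_x = 0.5000004371 * (xs[1] - xs[0]) * 1e-5 if len(xs) > 1 else 1e-9
    jitter_y = 0.4999991943 * (ys[1] - ys[0]) * 1e-5 if len(ys) > 1 else 1e-9
    xq = xs + jitter_x
    yq = ys + jitter_y

    t2d = tris[:, :, :2]
    zmat = tris[:, :, 2]
    xmin = t2d[:, :, 0].min(axis=1)
    xmax = t2d[:, :, 0].max(axis=1)
    ymin = t2d[:, :, 1].min(axis=1)
    ymax = t2d[:, :, 1].max(axis=1)
    ix0 = np.searchsorted(xq, xmin, side="left")
    ix1 = np.searchsorted(xq, xmax, side="right")
    iy0 = np.searchsorted(yq, ymin, side="left")
    iy1 = np.searchsorted(yq, ymax, side="right")

    nx = np.maximum(ix1 - ix0, 0)
    ny = np.maximum(iy1 - iy0, 0)
    nxy = nx * ny
    occ = np.zeros((len(xs), len(ys), len(zs)), dtype=bool)
    total = int(nxy.sum())
    if total == 0:
        return occ

    # flat enumeration of all (triangle, candidate column) pairs
    tri_ids = np.repeat(np.arange(len(tris)), nxy)
    starts = np.concatenate([[0], np.cumsum(nxy)[:-1]])
    off = np.arange(total) - starts[tri_ids]
    ny_t = ny[tri_ids]
    lx = off // ny_t
    ly = off - lx * ny_t
    ix = ix0[tri_ids] + lx
    iy = iy0[tri_ids] + ly
    px = xq[ix]
    py = yq[iy]

    a = t2d[tri_ids, 0]
    b = t2d[tri_ids, 1]
    c = t2d[tri_ids, 2]
    det = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (c[:, 0] - a[:, 0]) * (
        b[:, 1] - a[:, 1]
    )
    ok = det != 0  # vertical triangles contribute no z-parity
    with np.errstate(divide="ignore", invalid="ignore"):
        w0 = ((b[:, 0] - px) * (c[:, 1] - py) - (c[:, 0] - px) * (b[:, 1] - py)) / det
        w1 = ((c[:, 0] - px) * (a[:, 1] - py) - (a[:, 0] - px) * (c[:, 1] - py)) / det
    w2 = 1.0 - w0 - w1
    inside = ok & (w0 > 0) & (w1 > 0) & (w2 > 0)
    if not np.any(inside):
        return occ
    zh = (
        w0[inside] * zmat[tri_ids[inside], 0]
        + w1[inside] * zmat[tri_ids[inside], 1]
        + w2[inside] * zmat[tri_ids[inside], 2]
    )
    cols = ix[inside] * len(ys) + iy[inside]
    order = np.lexsort((zh, cols))
    cols = cols[order]
    zh = zh[order]
    uniq_cols, starts = np.unique(cols, return_index=True)
    starts = list(starts) + [len(cols)]
    for u, s0, s1 in zip(uniq_cols, starts[:-1], starts[1:]):
        zhits = zh[s0:s1]
        parity = np.searchsorted(zhits, zs, side="left") % 2 == 1
        ix, iy = divmod(int(u), len(ys))
        occ[ix, iy, :] = parity
    return occ


def near_surface_mask(
    vertices: np.ndarray,
    faces: np.ndarray,
    xs: np.ndarray,
    ys: np.ndarray,
    zs: np.ndarray,
    band: float,
) -> np.ndarray:
    """Boolean flat mask of grid nodes within `band` of some triangle bbox."""
    v = np.asarray(vertices, dtype=float)
    tris = v[np.asarray(faces)]
    shape = (len(xs), len(ys), len(zs))
    mask = np.zeros(int(np.prod(shape)), dtype=bool)
    axes = (xs, ys, zs)
    chunk = 8192
    for t0 in range(0, len(tris), chunk):
        tt = tris[t0 : t0 + chunk]
        lo = tt.min(axis=1) - band
        hi = tt.max(axis=1) + band
        i0 = [np.searchsorted(axes[a], lo[:, a], side="left") for a in range(3)]
        i1 = [np.searchsorted(axes[a], hi[:, a], side="right") for a in range(3)]
        n = [np.maximum(i1[a] - i0[a], 0) for a in range(3)]
        counts = n[0] * n[1] * n[2]
        total = int(counts.sum())
        if total == 0:
            continue
        tri_ids = np.repeat(np.arange(len(tt)), counts)
        starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        off = np.arange(total) - starts[tri_ids]
        nyz = n[1][tri_ids] * n[2][tri_ids]
        lx = off // nyz
        rem = off - lx * nyz
        ly = rem // n[2][tri_ids]
        lz = rem - ly * n[2][tri_ids]
        flat = (
            (i0[0][tri_ids] + lx) * (shape[1] * shape[2])
            + (i0[1][tri_ids] + ly) * shape[2]
            + (i0[2][tri_ids] + lz)
        )
        mask[flat] = True
    return mask


def signed_distance_grid(
    vertices: np.ndarray,
    faces: np.ndarray,
    xs: np.ndarray,
    ys: np.ndarray,
    zs: np.ndarray,
    band: float | None = None,
) -> np.ndarray:
    """Signed distance (negative inside) sampled on the given grid.

    Distances are exact (point-triangle) within ~2 voxels of the surface —
    everywhere marching cubes interpolates — and coarse upper bounds beyond.
    """
    pitch = float(xs[1] - xs[0]) if len(xs) > 1 else 1.0
    if band is None or band < 2.0 * pitch:
        band = 2.0 * pitch
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    v = np.asarray(vertices, dtype=float)
    tris = v[np.asarray(faces)]
    stride = max(1, len(v) // 1500)
    coarse = cKDTree(np.concatenate([v[::stride], tris.mean(axis=1)]))
    d, _ = coarse.query(pts)

    near = near_surface_mask(vertices, faces, xs, ys, zs, band)
    if np.any(near):
        md = MeshDistance(vertices, faces)
        ub, _ = md._sample_tree.query(pts[near])
        d[near] = md.distance(pts[near], k=8, upper_bound=ub)

    occ = occupancy_columns(vertices, faces, xs, ys, zs)
    sd = np.where(occ.ravel(), -d, d)
    return sd.reshape(len(xs), len(ys), len(zs))


def extract_isosurface(
    field: np.ndarray,
    xs: np.ndarray,
    ys: np.ndarray,
    zs: np.ndarray,
    level: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Marching cubes at `level`; returns (V, F) welded, outward-oriented."""
    spacing = (xs[1] - xs[0], ys[1] - ys[0], zs[1] - zs[0])
    # avoid exact zeros so no vertex lands on a grid node (keeps MC watertight)
    eps = 1e-12 * max(spacing)
    field = np.where(field == level, level + eps, field)
    verts, faces_mc, _, _ = _marching_cubes(field, level=level, spacing=spacing)
    verts = verts + np.array([xs[0], ys[0], zs[0]])
    v, f = verts, np.asarray(faces_mc, dtype=np.int64)
    if signed_volume(v, f) < 0:
        f = f[:, ::-1]
    return v, f


def mean_symmetric_distance(
    va: np.ndarray, fa: np.ndarray, vb: np.ndarray, fb: np.ndarray
) -> float:
    """Mean symmetric surface distance between two meshes (vertex sampled)."""
    da = MeshDistance(vb, fb).distance(va)
    db = MeshDistance(va, fa).distance(vb)
    return float(0.5 * (da.mean() + db.mean()))
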