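"""High-density grid interpolation and dural-surface projection.

High-density subdural grids (e.g. 16 x 16, 4 mm pitch) are hard to mark
electrode-by-electrode in a clinical CT, so only the four corners are
identified and the full grid is interpolated bilinearly between them.
Postoperative brain shift then leaves grid electrodes apparently buried
beneath the preoperative pial surface; they are corrected by projecting
each electrode outward, along the mean of the four corner normals, onto a
smoothed dural envelope (a subdivided, Taubin-smoothed convex hull of the
pial mesh).

Corner/channel convention (row-major channel numbering, the convention of
a 256-channel grid): corner 1 is channel 1, corner 2 is channel ``ncols``,
corner 3 is channel ``(nrows-1)*ncols + 1`` (241 for 16 x 16), corner 4 is
channel ``nrows*ncols``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull

from .core_io import TriMesh

__all__ = [
    "GridFrame", "DuralSurface", "ProjectionResult",
    "interp_grid", "grid_frame", "dural_surface", "project_electrodes", "interp_line",
]


@dataclass
class GridFrame:
    """Corner geometry of a rectangular grid: edges, normals, mean normal."""

    corners: np.ndarray          # 4 x 3, channel order
    nrows: int
    ncols: int
    outline_vectors: np.ndarray  # 4 x 3, directed edges of the corner quad
    corner_normals: np.ndarray   # 4 x 3, unit, mutually sign-consistent
    mean_normal: np.ndarray      # unit 3-vector


@dataclass
class DuralSurface:
    mesh: TriMesh
    kind: str  # convex_hull | smoothed_hull | ofc_submesh


@dataclass
class ProjectionResult:
    coords: np.ndarray   # K x 3, on-surface positions
    missed: np.ndarray   # K bool, True where the ray missed and the
                         # nearest surface point was used instead
    displacement: np.ndarray  # K, mm moved


def interp_grid(corners: np.ndarray, nrows: int, ncols: int) -> np.ndarray:
    """Bilinear interpolation of a full grid from its 4 corners.

    position(r, c) = (1-u)(1-v) C1 + (1-u)v C2 + u(1-v) C3 + uv C4 with
    u = r/(nrows-1), v = c/(ncols-1); output is row-major in channel order
    and reproduces the corners exactly.
    """
    corners = np.asarray(corners, dtype=float)
    if corners.shape != (4, 3):
        raise ValueError("corners must be 4 x 3")
    if nrows < 2 or ncols < 2:
        raise ValueError("nrows and ncols must be >= 2")
    _check_noncollinear(corners)
    u = (np.arange(nrows) / (nrows - 1))[:, None, None]
    v = (np.arange(ncols) / (ncols - 1))[None, :, None]
    c1, c2, c3, c4 = corners
    grid = (1 - u) * (1 - v) * c1 + (1 - u) * v * c2 + u * (1 - v) * c3 + u * v * c4
    return grid.reshape(nrows * ncols, 3)


def _check_noncollinear(corners: np.ndarray) -> None:
    d = corners - corners[0]
    if np.linalg.matrix_rank(d[1:], tol=1e-9) < 2:
        raise ValueError("degenerate grid: corners are collinear")


def grid_frame(
    corners: np.ndarray,
    nrows: int,
    ncols: int,
    orient_away_from: np.ndarray | None = None,
) -> GridFrame:
    """Corner edge vectors, per-corner normals, and their mean.

    Each corner normal is the normalized cross product of that corner's
    two adjacent outline edges; signs are flipped so all four lie in the
    same half-space.  ``orient_away_from`` (e.g. the pial centroid) flips
    the whole frame so the mean normal points outward, away from it.
    """
    corners = np.asarray(corners, dtype=float)
    if corners.shape != (4, 3):
        raise ValueError("corners must be 4 x 3")
    _check_noncollinear(corners)
    # quadrilateral cycle in spatial order: C1 -> C2 -> C4 -> C3 -> C1
    cycle = corners[[0, 1, 3, 2]]
    edges = np.roll(cycle, -1, axis=0) - cycle  # edge k leaves cycle vertex k
    normals = np.cross(edges, -np.roll(edges, 1, axis=0))  # leaving x entering(rev)
    norms = np.linalg.norm(normals, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("degenerate grid corners")
    normals /= norms[:, None]
    ref = normals[0]
    flip = (normals @ ref) < 0
    normals[flip] *= -1
    mean = normals.mean(axis=0)
    mean /= np.linalg.norm(mean)
    if orient_away_from is not None:
        outward = corners.mean(axis=0) - np.asarray(orient_away_from, dtype=float)
        if mean @ outward < 0:
            mean = -mean
            normals = -normals
    # undo the cycle permutation so rows match channel-order corners
    inv = np.argsort([0, 1, 3, 2])
    return GridFrame(
        corners=corners,
        nrows=nrows,
        ncols=ncols,
        outline_vectors=edges,
        corner_normals=normals[inv],
        mean_normal=mean,
    )


# ---------------------------------------------------------------------------
# dural surface

def _hull_mesh(points: np.ndarray) -> TriMesh:
    """Convex hull as a TriMesh with outward-consistent facet orientation."""
    points = np.asarray(points, dtype=float)
    hull = ConvexHull(points)
    verts = points[hull.vertices]
    remap = np.full(len(points), -1, dtype=np.int64)
    remap[hull.vertices] = np.arange(len(hull.vertices))
    tris = remap[hull.simplices]
    centroid = verts.mean(axis=0)
    a, b, c = verts[tris[:, 0]], verts[tris[:, 1]], verts[tris[:, 2]]
    n = np.cross(b - a, c - a)
    inward = np.einsum("ij,ij->i", n, (a + b + c) / 3 - centroid) < 0
    tris[inward] = tris[inward][:, [0, 2, 1]]
    return TriMesh(verts, tris)


def dural_surface(
    pial: TriMesh,
    kind: str = "smoothed_hull",
    smoothing_iters: int = 30,
    max_edge_mm: float = 3.0,
    annot: np.ndarray | None = None,
    exclude_labels: set | None = None,
) -> DuralSurface:
    """Dural envelope of a pial mesh.

    kind:
      * ``convex_hull`` — exact 3D hull of the pial vertices.
      * ``smoothed_hull`` — hull subdivided until no edge exceeds
        ``max_edge_mm``, then Taubin (shrinkage-corrected Laplacian)
        smoothed ``smoothing_iters`` times.  ``smoothing_iters=0`` gives
        the subdivided hull unchanged.
      * ``ofc_submesh`` — hull of the vertex subset whose annotation label
        is *not* in ``exclude_labels`` (used for orbitofrontal coverage,
        where the hull of the full cortex including the temporal lobe
        would bridge across the Sylvian fissure).
    """
    import trimesh as tm

    if kind == "ofc_submesh":
        if annot is None or exclude_labels is None:
            raise ValueError("ofc_submesh needs annot and exclude_labels")
        keep = ~np.isin(np.asarray(annot), list(exclude_labels))
        pts = pial.vertices[keep]
    else:
        pts = pial.vertices
    if len(pts) < 4:
        raise ValueError("need at least 4 non-coplanar vertices for a hull")
    hull = _hull_mesh(pts)
    if kind == "convex_hull" or kind == "ofc_submesh":
        return DuralSurface(hull, kind)
    if kind != "smoothed_hull":
        raise ValueError(f"unknown dural surface kind {kind!r}")
    mesh = tm.Trimesh(hull.vertices, hull.triangles, process=True)
    while mesh.edges_unique_length.max() > max_edge_mm:
        v, f = tm.remesh.subdivide(mesh.vertices, mesh.faces)
        mesh = tm.Trimesh(v, f, process=True)
    if smoothing_iters > 0:
        tm.smoothing.filter_taubin(mesh, lamb=0.5, nu=0.53, iterations=smoothing_iters)
    return DuralSurface(TriMesh(np.asarray(mesh.vertices), np.asarray(mesh.faces)), kind)


# ---------------------------------------------------------------------------
# ray projection

def _ray_mesh_first_hit(origin, direction, verts, tris, eps=1e-12):
    """Möller–Trumbore over all triangles; smallest non-negative t wins,
    ties broken by lowest triangle index.  Returns t or None."""
    a = verts[tris[:, 0]]
    e1 = verts[tris[:, 1]] - a
    e2 = verts[tris[:, 2]] - a
    p = np.cross(direction[None, :], e2)
    det = np.einsum("ij,ij->i", e1, p)
    ok = np.abs(det) > eps
    if not ok.any():
        return None
    inv_det = np.zeros_like(det)
    inv_det[ok] = 1.0 / det[ok]
    s = origin[None, :] - a
    u = np.einsum("ij,ij->i", s, p) * inv_det
    q = np.cross(s, e1)
    v = (q @ direction) * inv_det
    t = np.einsum("ij,ij->i", e2, q) * inv_det
    tol = 1e-9
    hit = ok & (u >= -tol) & (v >= -tol) & (u + v <= 1 + tol) & (t >= -1e-9)
    if not hit.any():
        return None
    idx = np.flatnonzero(hit)
    # argmin returns the first minimum -> lowest triangle index on ties
    return float(t[idx[np.argmin(t[idx])]])


def project_electrodes(
    elecs: np.ndarray,
    surface: DuralSurface,
    direction: np.ndarray,
) -> ProjectionResult:
    """Project electrodes along ``+direction`` onto the dural surface.

    Each electrode moves along the ray to its first intersection with the
    surface; electrodes whose ray misses fall back to the nearest point on
    the surface and are flagged.  Projection is idempotent: a point
    already on the surface moves < 1e-6 mm.
    """
    elecs = np.asarray(elecs, dtype=float).reshape(-1, 3)
    direction = np.asarray(direction, dtype=float)
    nrm = np.linalg.norm(direction)
    if abs(nrm - 1.0) > 1e-6:
        direction = direction / nrm
    verts, tris = surface.mesh.vertices, surface.mesh.triangles
    out = np.empty_like(elecs)
    missed = np.zeros(len(elecs), dtype=bool)
    misses = []
    for i, e in enumerate(elecs):
        t = _ray_mesh_first_hit(e, direction, verts, tris)
        if t is None:
            missed[i] = True
            misses.append(i)
        else:
            out[i] = e + t * direction
    if misses:
        for i in misses:
            out[i] = _closest_point_on_mesh(elecs[i], verts, tris)
    disp = np.linalg.norm(out - elecs, axis=1)
    return ProjectionResult(coords=out, missed=missed, displacement=disp)


def _closest_point_on_mesh(p: np.ndarray, verts: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Nearest point on any triangle (Ericson's region classification),
    vectorized over triangles for a single query point."""
    a, b, c = verts[tris[:, 0]], verts[tris[:, 1]], verts[tris[:, 2]]
    ab, ac, ap = b - a, c - a, p[None, :] - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p[None, :] - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p[None, :] - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
    cand = a + v[:, None] * ab + w[:, None] * ac  # interior foot point
    # vertex regions
    cand = np.where(((d1 <= 0) & (d2 <= 0))[:, None], a, cand)
    cand = np.where(((d3 >= 0) & (d4 <= d3))[:, None], b, cand)
    cand = np.where(((d6 >= 0) & (d5 <= d6))[:, None], c, cand)
    # edge regions
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        t_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        t_bc = np.where((d4 - d3) + (d5 - d6) != 0,
                        (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0)
    on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    on_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    cand = np.where(on_bc[:, None], b + np.clip(t_bc, 0, 1)[:, None] * (c - b), cand)
    cand = np.where(on_ac[:, None], a + np.clip(t_ac, 0, 1)[:, None] * ac, cand)
    cand = np.where(on_ab[:, None], a + np.clip(t_ab, 0, 1)[:, None] * ab, cand)
    d = np.linalg.norm(cand - p[None, :], axis=1)
    return cand[int(np.argmin(d))]


def interp_line(endpoints: np.ndarray, n: int) -> np.ndarray:
    """``n`` evenly spaced points between two endpoints, inclusive.

    The depth-electrode shortcut: mark the first and last contact and
    interpolate the rest (e.g. 10 contacts at 5 mm pitch span 45 mm).
    """
    endpoints = np.asarray(endpoints, dtype=float).reshape(2, 3)
    if n < 2:
        raise ValueError("need n >= 2 points")
    w = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - w) * endpoints[0] + w * endpoints[1]
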