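"""Surface incision modelling with quadratic Bezier curves.

The cut on the surface mesh is built in five steps: extract the on-path
vertices, collect the one-ring affected region, split the affected vertices
by the chord through the cut's endpoints, pick the extremal vertex on each
side as a Bezier control point, and sample the two quadratic curves that
outline the open wound.  The affected region is then retriangulated so the
two sampled polylines become free boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np

from .errors import (
    InvalidChordError,
    InvalidParameterError,
    NoCutError,
    UnsupportedPathError,
)
from .geometry import FLAG_AFFECTED, FLAG_BOUNDARY, FLAG_ON_PATH, SurfaceMesh

_DEG_TOL = 1e-9  # relative chord-length tolerance for degenerate curves


def bernstein(i: int, n: int, t):
    """Bernstein basis B_{i,n}(t) = C(n,i) t^i (1-t)^(n-i).

    ``t`` may be a scalar or array in [0, 1]; the basis is a partition of
    unity over i = 0..n.
    """
    if not (0 <= i <= n):
        raise InvalidParameterError(f"bernstein index i={i} outside 0..{n}")
    t = np.asarray(t, dtype=np.float64)
    return comb(n, i) * t ** i * (1.0 - t) ** (n - i)


def bezier_quadratic(p0, p1, p2, t):
    """Quadratic Bezier point(s) (1-t)^2 P0 + 2t(1-t) P1 + t^2 P2.

    Evaluated in Bernstein form so the endpoints interpolate exactly:
    P(0) = P0 and P(1) = P2 bit-for-bit.
    """
    p0 = np.asarray(p0, dtype=np.float64)
    p1 = np.asarray(p1, dtype=np.float64)
    p2 = np.asarray(p2, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    tt = t[..., None] if t.ndim else t
    return (1.0 - tt) ** 2 * p0 + 2.0 * tt * (1.0 - tt) * p1 + tt ** 2 * p2


@dataclass
class IncisionCurves:
    """The two sampled Bezier curves outlining an incision.

    Both polylines run from chord endpoint A (t=0) to B (t=1); C and D are
    the positive/negative-side control points.  The path vertex set is the
    ordered on-path chain (the paper's P1), the affected set its one-ring
    closure (P2).
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray
    left_polyline: np.ndarray  # (S, 3), positive/C side
    right_polyline: np.ndarray  # (S, 3), negative/D side
    t_values: np.ndarray  # (S,)
    path_vertex_set: np.ndarray  # ordered indices (P1)
    affected_vertex_set: np.ndarray  # indices (P2)
    surface_normal: np.ndarray = field(default=None)
    side_normal: np.ndarray = field(default=None)  # unit, toward positive side

    @property
    def chord(self) -> np.ndarray:
        return self.B - self.A

    def is_degenerate(self) -> bool:
        """True when both curves collapse onto the chord."""
        scale = max(np.linalg.norm(self.chord), 1.0)
        dev = max(_max_line_distance(self.left_polyline, self.A, self.B),
                  _max_line_distance(self.right_polyline, self.A, self.B))
        return dev <= _DEG_TOL * scale


def _max_line_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    d = b - a
    nd = np.linalg.norm(d)
    if nd == 0:
        return float(np.max(np.linalg.norm(points - a, axis=1), initial=0.0))
    cr = np.cross(points - a, d / nd)
    return float(np.max(np.linalg.norm(cr, axis=1), initial=0.0))


def collect_affected(mesh: SurfaceMesh, path_vertices) -> np.ndarray:
    """Union of vertices of all triangles incident to a path vertex (P2)."""
    path = np.asarray(path_vertices, dtype=np.int64)
    if path.size == 0:
        return np.empty(0, dtype=np.int64)
    if path.min() < 0 or path.max() >= len(mesh.vertices):
        raise InvalidParameterError("path vertex index out of range")
    on_path = np.zeros(len(mesh.vertices), dtype=bool)
    on_path[path] = True
    hit = on_path[mesh.triangles].any(axis=1)
    return np.unique(mesh.triangles[hit])


def split_by_chord(points, a, b, surface_normal):
    """Classify points by side of chord AB in the surface tangent plane.

    Sign of ((B-A) x (P-A)) . n; zero (on-chord) counts as positive.
    Returns (positive_indices, negative_indices) into ``points``.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if np.array_equal(a, b):
        raise InvalidChordError("chord endpoints coincide")
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    n = np.asarray(surface_normal, dtype=np.float64)
    s = np.cross(b - a, pts - a) @ n
    idx = np.arange(len(pts))
    return idx[s >= 0], idx[s < 0]


def _line_distances(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = b - a
    nd = np.linalg.norm(d)
    if nd == 0:
        raise InvalidChordError("chord endpoints coincide")
    return np.linalg.norm(np.cross(points - a, d / nd), axis=1)


def select_control_points(positive_points, negative_points, a, b):
    """Extremal vertex on each side of the chord (max point-to-line distance).

    An empty side degenerates to the chord midpoint, collapsing that curve
    onto the chord.  Distance ties resolve to the lowest index.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    mid = 0.5 * (a + b)
    out = []
    for pts in (positive_points, negative_points):
        pts = np.asarray(pts, dtype=np.float64).reshape(-1, 3)
        if len(pts) == 0:
            out.append(mid.copy())
            continue
        d = _line_distances(pts, a, b)
        out.append(pts[int(np.argmax(d))].copy())  # argmax keeps lowest index on ties
    return out[0], out[1]


def _region_normal(mesh: SurfaceMesh, tri_mask: np.ndarray) -> np.ndarray:
    tris = mesh.triangles[tri_mask]
    v = mesh.vertices
    n = np.cross(v[tris[:, 1]] - v[tris[:, 0]], v[tris[:, 2]] - v[tris[:, 0]])
    total = n.sum(axis=0)  # area-weighted
    nn = np.linalg.norm(total)
    if nn < 1e-14:
        return np.array([0.0, 0.0, 1.0])
    return total / nn


def build_incision(mesh: SurfaceMesh, path_vertices, samples_per_curve: int = 16
                   ) -> IncisionCurves:
    """Construct the two quadratic Bezier curves representing the incision.

    The chord runs from the first to the last path vertex; side splitting
    and control-point distances are evaluated in the tangent plane of the
    affected region (projecting along its average surface normal).
    """
    path = np.asarray(path_vertices, dtype=np.int64)
    if path.size < 2:
        raise NoCutError("cutting path needs at least 2 vertices")
    if samples_per_curve < 2:
        raise InvalidParameterError("samples_per_curve must be >= 2")
    verts = mesh.vertices
    a = verts[path[0]].copy()
    b = verts[path[-1]].copy()
    if np.allclose(a, b):
        raise InvalidChordError("path start and end coincide")

    affected = collect_affected(mesh, path)
    on_path = np.zeros(len(verts), dtype=bool)
    on_path[path] = True
    tri_mask = on_path[mesh.triangles].any(axis=1)
    normal = _region_normal(mesh, tri_mask)

    # work in the tangent plane through A
    pts = verts[affected]
    proj = pts - np.outer((pts - a) @ normal, normal)
    pos_idx, neg_idx = split_by_chord(proj, a, b, normal)
    scale = np.linalg.norm(b - a)

    def _pick(side_idx):
        if len(side_idx) == 0:
            return 0.5 * (a + b)
        d = _line_distances(proj[side_idx], a, b)
        if np.max(d) <= _DEG_TOL * scale:
            return 0.5 * (a + b)  # collinear side: curve equals the chord
        return verts[affected[side_idx[int(np.argmax(d))]]].copy()

    c = _pick(pos_idx)
    d = _pick(neg_idx)

    t = np.linspace(0.0, 1.0, samples_per_curve)
    left = bezier_quadratic(a, c, b, t)
    right = bezier_quadratic(a, d, b, t)

    chord_dir = (b - a) / scale
    side = np.cross(normal, chord_dir)
    ns = np.linalg.norm(side)
    side = side / ns if ns > 1e-14 else np.array([0.0, 1.0, 0.0])
    # orient toward the positive (C) side
    if (c - 0.5 * (a + b)) @ side < 0:
        side = -side

    return IncisionCurves(a, b, c, d, left, right, t, path, affected,
                          surface_normal=normal, side_normal=side)


# -- retriangulation ----------------------------------------------------------

def _triangle_areas(verts: np.ndarray, tris: np.ndarray) -> np.ndarray:
    n = np.cross(verts[tris[:, 1]] - verts[tris[:, 0]],
                 verts[tris[:, 2]] - verts[tris[:, 0]])
    return 0.5 * np.linalg.norm(n, axis=1)


def _zip_band(chain_ids, chain_t, samp_ids, samp_t, verts, normal):
    """Triangulate the monotone band between two chains sharing endpoints."""
    tris = []
    i = j = 0
    while i < len(chain_ids) - 1 or j < len(samp_ids) - 1:
        adv_chain = (j == len(samp_ids) - 1 or
                     (i < len(chain_ids) - 1 and chain_t[i + 1] <= samp_t[j + 1]))
        if adv_chain:
            tri = (chain_ids[i], chain_ids[i + 1], samp_ids[j])
            i += 1
        else:
            tri = (chain_ids[i], samp_ids[j + 1], samp_ids[j])
            j += 1
        if len(set(tri)) == 3:
            tris.append(tri)
    if not tris:
        return np.empty((0, 3), dtype=np.int64)
    tris = np.asarray(tris, dtype=np.int64)
    # keep winding consistent with the surface orientation
    n = np.cross(verts[tris[:, 1]] - verts[tris[:, 0]],
                 verts[tris[:, 2]] - verts[tris[:, 0]])
    flip = n @ normal < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]
    areas = _triangle_areas(verts, tris)
    return tris[areas > 1e-12]


def remesh_incision(mesh: SurfaceMesh, curves: IncisionCurves) -> SurfaceMesh:
    """Open the wound: duplicate the path into left/right copies and make the
    sampled Bezier polylines the free boundary of the affected region.

    Interior path vertices are duplicated so the surface separates along the
    cut; per side, a strip of triangles bridges the separated path chain to
    the inserted curve samples, leaving the polyline as an open boundary.
    The non-incision boundary of the mesh is untouched.
    """
    path = np.asarray(curves.path_vertex_set, dtype=np.int64)
    if path.size == 0:
        return mesh.copy()
    if path.size < 2:
        return mesh.copy()
    if len(np.unique(path)) != len(path):
        raise UnsupportedPathError("self-intersecting cutting path")

    edge_set = {tuple(e) for e in mesh.edges_unique()}
    for u, v in zip(path[:-1], path[1:]):
        if (min(u, v), max(u, v)) not in edge_set:
            raise UnsupportedPathError(
                f"path vertices {u} and {v} are not mesh-edge adjacent")

    a, b = curves.A, curves.B
    chord = b - a
    clen = np.linalg.norm(chord)
    normal = curves.surface_normal
    if normal is None:
        normal = np.array([0.0, 0.0, 1.0])

    dev_left = _max_line_distance(curves.left_polyline, a, b)
    dev_right = _max_line_distance(curves.right_polyline, a, b)
    deg_left = dev_left <= _DEG_TOL * max(clen, 1.0)
    deg_right = dev_right <= _DEG_TOL * max(clen, 1.0)

    if path.size == 2 and deg_left and deg_right:
        return mesh.copy()  # zero-width, zero-length cut

    verts = [mesh.vertices.copy()]
    flags = [mesh.vertex_flags.copy()]
    next_id = len(mesh.vertices)
    tris = mesh.triangles.copy()

    on_path = np.zeros(len(mesh.vertices), dtype=bool)
    on_path[path] = True
    touch = on_path[tris].any(axis=1)
    centroids = mesh.vertices[tris[touch]].mean(axis=1)
    side_sign = np.cross(chord, centroids - a) @ normal
    touch_idx = np.flatnonzero(touch)
    right_tris = touch_idx[side_sign < 0]

    # duplicate interior path vertices for the right side
    dup_of = {}
    new_rows = []
    for vi in path[1:-1]:
        dup_of[int(vi)] = next_id
        new_rows.append(mesh.vertices[vi])
        next_id += 1
    if new_rows:
        verts.append(np.asarray(new_rows))
        flags.append(np.full(len(new_rows), FLAG_ON_PATH, dtype=np.uint8))
        remap = np.arange(next_id)
        for old, new in dup_of.items():
            remap[old] = new
        tris[right_tris] = remap[tris[right_tris]]

    chain_left = [int(path[0])] + [int(v) for v in path[1:-1]] + [int(path[-1])]
    chain_right = [int(path[0])] + [dup_of[int(v)] for v in path[1:-1]] + [int(path[-1])]

    all_verts = np.vstack(verts)
    chord_dir = chord / clen

    def chain_params(ids):
        return np.clip((all_verts[ids] - a) @ chord_dir / clen, 0.0, 1.0)

    band_tris = []
    for chain, poly, degenerate in ((chain_left, curves.left_polyline, deg_left),
                                    (chain_right, curves.right_polyline, deg_right)):
        if degenerate:
            continue  # boundary stays the separated path chain on this side
        interior = poly[1:-1]
        samp_ids = [chain[0]] + list(range(next_id, next_id + len(interior))) + [chain[-1]]
        next_id += len(interior)
        verts.append(interior)
        flags.append(np.full(len(interior), FLAG_BOUNDARY, dtype=np.uint8))
        all_verts = np.vstack(verts)
        band = _zip_band(np.asarray(chain), chain_params(np.asarray(chain)),
                         np.asarray(samp_ids), curves.t_values,
                         all_verts, normal)
        band_tris.append(band)

    out_tris = np.vstack([tris] + band_tris) if band_tris else tris
    out_flags = np.concatenate(flags)
    out_flags[curves.affected_vertex_set] |= FLAG_AFFECTED
    out_flags[path] |= FLAG_ON_PATH
    return SurfaceMesh(np.vstack(verts), out_tris, out_flags)


# -- cutting-path extraction (collision-detection surrogate) ------------------

def extract_path(mesh: SurfaceMesh, blade_point, blade_normal, up_point, up_dir,
                 t_range=None) -> np.ndarray:
    """On-path surface vertices from analytic blade-plane/mesh intersection.

    Mesh edges crossing the blade plane are snapped to their nearest
    endpoint; candidates below the vertical (cut-bottom) plane are dropped;
    survivors are ordered along the in-plane horizontal direction and
    stitched into an edge-connected chain.  ``t_range`` (min, max, in mm
    along the sweep direction) limits the path to the swept extent.
    """
    bp = np.asarray(blade_point, dtype=np.float64)
    bn = np.asarray(blade_normal, dtype=np.float64)
    up = np.asarray(up_dir, dtype=np.float64)
    vp = np.asarray(up_point, dtype=np.float64)

    phi = (mesh.vertices - bp) @ bn
    psi = (mesh.vertices - vp) @ up

    edges = mesh.edges_unique()
    sa, sb = phi[edges[:, 0]], phi[edges[:, 1]]
    crossing = (sa * sb <= 0) & ~((sa == 0) & (sb == 0))
    snapped = np.where(np.abs(sa[crossing]) <= np.abs(sb[crossing]),
                       edges[crossing, 0], edges[crossing, 1])
    snapped = np.unique(snapped)
    snapped = snapped[psi[snapped] > 0]
    if snapped.size == 0:
        return np.empty(0, dtype=np.int64)

    sweep = np.cross(up, bn)
    ns = np.linalg.norm(sweep)
    if ns < 1e-14:
        return np.empty(0, dtype=np.int64)
    sweep = sweep / ns
    tvals = mesh.vertices[snapped] @ sweep
    if t_range is not None:
        keep = (tvals >= t_range[0]) & (tvals <= t_range[1])
        snapped, tvals = snapped[keep], tvals[keep]
    if snapped.size < 2:
        return snapped.astype(np.int64)

    order = np.argsort(tvals, kind="stable")
    chain = [int(v) for v in snapped[order]]

    # splice in shortest mesh-graph paths where consecutive snaps are not adjacent
    adj: dict[int, set[int]] = {}
    for u, v in edges:
        adj.setdefault(int(u), set()).add(int(v))
        adj.setdefault(int(v), set()).add(int(u))

    def bfs(src: int, dst: int) -> list[int]:
        from collections import deque
        prev = {src: None}
        q = deque([src])
        while q:
            cur = q.popleft()
            if cur == dst:
                out = []
                while cur is not None:
                    out.append(cur)
                    cur = prev[cur]
                return out[::-1]
            for nxt in sorted(adj.get(cur, ())):
                if nxt not in prev:
                    prev[nxt] = cur
                    q.append(nxt)
        raise UnsupportedPathError(f"no mesh path between {src} and {dst}")

    full = [chain[0]]
    for nxt in chain[1:]:
        if nxt in adj.get(full[-1], ()):
            full.append(nxt)
        else:
            full.extend(bfs(full[-1], nxt)[1:])
    seen = set()
    out = []
    for v in full:
        if v in seen:
            raise UnsupportedPathError("extracted path revisits a vertex")
        seen.add(v)
        out.append(v)
    return np.asarray(out, dtype=np.int64)
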