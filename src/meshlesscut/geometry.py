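"""Two-part tissue model: surface triangle mesh plus internal point elements.

The virtual organ is represented the way coupled surgical simulators build
it: a closed triangle mesh bounds the tissue (used for rendering and for
carving the incision) while the interior is discretized as independent
point elements produced by equal-distance interpolation -- an axis-aligned
lattice clipped to the solid.  Units are mm, g, s throughout; the frame is
right-handed with +z "up" unless a config overrides the vertical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from .errors import FormatError, InvalidParameterError

# vertex flag bits
FLAG_ON_PATH = 1
FLAG_AFFECTED = 2
FLAG_BOUNDARY = 4

# point element region labels
UNAFFECTED = 0
AFFECTED_PLUS = 1
AFFECTED_MINUS = 2
VIRTUAL = 3

LABEL_NAMES = {
    UNAFFECTED: "unaffected",
    AFFECTED_PLUS: "affected_plus",
    AFFECTED_MINUS: "affected_minus",
    VIRTUAL: "virtual",
}


@dataclass
class SurfaceMesh:
    """Triangle mesh bounding the tissue; carries per-vertex incision flags."""

    vertices: np.ndarray  # (V, 3) float64, mm
    triangles: np.ndarray  # (F, 3) int64
    vertex_flags: np.ndarray = None  # (V,) uint8 bitmask

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise InvalidParameterError("vertices must be (V, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise InvalidParameterError("triangles must be (F, 3)")
        if self.triangles.size:
            if self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices):
                raise InvalidParameterError("triangle index out of range")
            t = self.triangles
            if np.any((t[:, 0] == t[:, 1]) | (t[:, 1] == t[:, 2]) | (t[:, 0] == t[:, 2])):
                raise InvalidParameterError("degenerate triangle (repeated index)")
        if self.vertex_flags is None:
            self.vertex_flags = np.zeros(len(self.vertices), dtype=np.uint8)
        else:
            self.vertex_flags = np.asarray(self.vertex_flags, dtype=np.uint8)
            if len(self.vertex_flags) != len(self.vertices):
                raise InvalidParameterError("vertex_flags length mismatch")

    # -- connectivity helpers -------------------------------------------------

    def edges_unique(self) -> np.ndarray:
        """Undirected unique edges, each row sorted (a < b)."""
        e = np.vstack([self.triangles[:, [0, 1]],
                       self.triangles[:, [1, 2]],
                       self.triangles[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def euler_characteristic(self) -> int:
        v = len(np.unique(self.triangles)) if self.triangles.size else len(self.vertices)
        return v - len(self.edges_unique()) + len(self.triangles)

    def boundary_edges(self) -> np.ndarray:
        """Edges incident to exactly one triangle (sorted rows)."""
        e = np.vstack([self.triangles[:, [0, 1]],
                       self.triangles[:, [1, 2]],
                       self.triangles[:, [2, 0]]])
        e.sort(axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq[counts == 1]

    def vertex_triangles(self) -> list[np.ndarray]:
        """For each vertex, indices of incident triangles."""
        out = [[] for _ in range(len(self.vertices))]
        for fi, tri in enumerate(self.triangles):
            for v in tri:
                out[v].append(fi)
        return [np.asarray(a, dtype=np.int64) for a in out]

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.triangles.copy(),
                           self.vertex_flags.copy())


def boundary_loops(mesh: SurfaceMesh) -> list[list[int]]:
    """Connected components of the boundary-edge graph, as vertex lists.

    Loops are reported as unordered components (a pinched slit is a single
    component even though it is not a simple cycle).
    """
    be = mesh.boundary_edges()
    if not len(be):
        return []
    parent: dict[int, int] = {}

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in be:
        parent.setdefault(int(a), int(a))
        parent.setdefault(int(b), int(b))
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[ra] = rb
    comps: dict[int, list[int]] = {}
    for v in parent:
        comps.setdefault(find(v), []).append(v)
    return [sorted(c) for c in comps.values()]


@dataclass
class PointElementSet:
    """Internal meshless point elements.

    Rest positions are cached at construction; current positions are always
    rest + displacement, so integration never accumulates drift.
    """

    positions: np.ndarray  # (N, 3) current, mm
    masses: np.ndarray  # (N,) g
    volumes: np.ndarray  # (N,) mm^3
    displacements: np.ndarray = None  # (N, 3) mm
    velocities: np.ndarray = None  # (N, 3) mm/s
    labels: np.ndarray = None  # (N,) int8 region labels
    rest_positions: np.ndarray = None  # (N, 3) mm

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        n = len(self.positions)
        self.masses = np.asarray(self.masses, dtype=np.float64)
        self.volumes = np.asarray(self.volumes, dtype=np.float64)
        if np.any(self.masses <= 0) or np.any(self.volumes <= 0):
            raise InvalidParameterError("masses and volumes must be strictly positive")
        if self.displacements is None:
            self.displacements = np.zeros((n, 3))
        if self.velocities is None:
            self.velocities = np.zeros((n, 3))
        if self.labels is None:
            self.labels = np.full(n, UNAFFECTED, dtype=np.int8)
        if self.rest_positions is None:
            self.rest_positions = self.positions.copy()
        for arr, name in ((self.displacements, "displacements"),
                          (self.velocities, "velocities"),
                          (self.rest_positions, "rest_positions")):
            if np.asarray(arr).shape != (n, 3):
                raise InvalidParameterError(f"{name} must have shape ({n}, 3)")
        self.displacements = np.ascontiguousarray(self.displacements, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.rest_positions = np.ascontiguousarray(self.rest_positions, dtype=np.float64)
        if len(self.labels) != n:
            raise InvalidParameterError("labels length mismatch")
        self.labels = np.asarray(self.labels, dtype=np.int8)

    def __len__(self) -> int:
        return len(self.positions)

    def copy(self) -> "PointElementSet":
        return PointElementSet(self.positions.copy(), self.masses.copy(),
                               self.volumes.copy(), self.displacements.copy(),
                               self.velocities.copy(), self.labels.copy(),
                               self.rest_positions.copy())


# -- synthetic generators -----------------------------------------------------

def _lattice_axis(extent: float, spacing: float) -> np.ndarray:
    n = int(np.floor(extent / spacing + 1e-12)) + 1
    return np.arange(n) * spacing


def _check_spacing(extent, spacing) -> np.ndarray:
    extent = np.asarray(extent, dtype=np.float64)
    if extent.shape != (3,) or np.any(extent <= 0):
        raise InvalidParameterError("extent must be 3 positive lengths")
    if spacing <= 0:
        raise InvalidParameterError("spacing must be positive")
    if spacing > extent.min():
        raise InvalidParameterError("spacing exceeds an extent")
    return extent


def _box_surface(extent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Minimal 12-triangle box anchored at the origin, outward-oriented."""
    tm = trimesh.creation.box(extents=extent)
    verts = np.asarray(tm.vertices) + extent / 2.0
    return verts, np.asarray(tm.faces, dtype=np.int64)


def _box_surface_refined(axes: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Box surface whose vertices are the boundary lattice points.

    Each face is a grid of quads split into triangles with outward winding,
    so path extraction can snap onto lattice-aligned surface vertices.
    """
    nx, ny, nz = (len(a) for a in axes)
    index: dict[tuple[int, int, int], int] = {}
    verts: list[tuple[float, float, float]] = []

    def vid(i: int, j: int, k: int) -> int:
        key = (i, j, k)
        if key not in index:
            index[key] = len(verts)
            verts.append((axes[0][i], axes[1][j], axes[2][k]))
        return index[key]

    faces: list[tuple[int, int, int]] = []

    def emit(quad: tuple[int, int, int, int], flip: bool) -> None:
        a, b, c, d = quad
        if flip:
            faces.append((a, c, b))
            faces.append((a, d, c))
        else:
            faces.append((a, b, c))
            faces.append((a, c, d))

    for k, flip in ((0, True), (nz - 1, False)):  # z faces
        for i in range(nx - 1):
            for j in range(ny - 1):
                emit((vid(i, j, k), vid(i + 1, j, k),
                      vid(i + 1, j + 1, k), vid(i, j + 1, k)), flip)
    for j, flip in ((0, False), (ny - 1, True)):  # y faces
        for i in range(nx - 1):
            for k in range(nz - 1):
                emit((vid(i, j, k), vid(i + 1, j, k),
                      vid(i + 1, j, k + 1), vid(i, j, k + 1)), flip)
    for i, flip in ((0, True), (nx - 1, False)):  # x faces
        for j in range(ny - 1):
            for k in range(nz - 1):
                emit((vid(i, j, k), vid(i, j + 1, k),
                      vid(i, j + 1, k + 1), vid(i, j, k + 1)), flip)
    return np.asarray(verts, dtype=np.float64), np.asarray(faces, dtype=np.int64)


def make_box_model(extent, spacing: float, density: float = 1.0,
                   refine_surface: bool = False) -> tuple[SurfaceMesh, PointElementSet]:
    """Box tissue model: triangulated surface + equal-distance interior lattice.

    The lattice is anchored at the minimum corner and spans the box inclusive
    of its faces; each point carries volume spacing^3 and mass density*volume.
    With ``refine_surface`` the surface is subdivided so its vertices coincide
    with the boundary lattice points (needed for cutting-path snapping).
    """
    extent = _check_spacing(extent, spacing)
    axes = [_lattice_axis(e, spacing) for e in extent]
    grid = np.meshgrid(*axes, indexing="ij")
    pos = np.stack([g.ravel() for g in grid], axis=1)
    n = len(pos)
    vol = np.full(n, spacing ** 3)
    points = PointElementSet(pos, density * vol, vol)
    if refine_surface:
        verts, faces = _box_surface_refined(axes)
    else:
        verts, faces = _box_surface(extent)
    return SurfaceMesh(verts, faces), points


def make_ellipsoid_model(semi_axes, spacing: float, mesh_resolution: int = 2,
                         density: float = 1.0) -> tuple[SurfaceMesh, PointElementSet]:
    """Ellipsoid ("liver-like") model centred at the origin.

    Interior points are the lattice points k*spacing with
    (x/a)^2 + (y/b)^2 + (z/c)^2 <= 1; the surface is a subdivided icosphere
    scaled to the semi-axes.
    """
    semi = np.asarray(semi_axes, dtype=np.float64)
    if semi.shape != (3,) or np.any(semi <= 0):
        raise InvalidParameterError("semi_axes must be 3 positive lengths")
    if spacing <= 0:
        raise InvalidParameterError("spacing must be positive")
    ks = [np.arange(-int(np.floor(a / spacing)), int(np.floor(a / spacing)) + 1)
          for a in semi]
    grid = np.meshgrid(*[k * spacing for k in ks], indexing="ij")
    pos = np.stack([g.ravel() for g in grid], axis=1)
    inside = np.sum((pos / semi) ** 2, axis=1) <= 1.0 + 1e-12
    pos = pos[inside]
    n = len(pos)
    vol = np.full(n, spacing ** 3)
    points = PointElementSet(pos, density * vol, vol)
    sphere = trimesh.creation.icosphere(subdivisions=max(1, int(mesh_resolution)))
    verts = np.asarray(sphere.vertices) * semi
    return SurfaceMesh(verts, np.asarray(sphere.faces, dtype=np.int64)), points


# -- I/O ----------------------------------------------------------------------

_MESH_EXT = {".obj", ".off", ".ply"}


def write_mesh(mesh: SurfaceMesh, path: str | os.PathLike) -> None:
    """Export to OBJ/OFF/PLY (ASCII), format inferred from the extension."""
    ext = os.path.splitext(str(path))[1].lower()
    if ext not in _MESH_EXT:
        raise FormatError(f"unknown mesh extension '{ext}'")
    tm = trimesh.Trimesh(mesh.vertices, mesh.triangles, process=False)
    kwargs = {"encoding": "ascii"} if ext == ".ply" else {}
    data = tm.export(file_type=ext[1:], **kwargs)
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)


def read_mesh(path: str | os.PathLike) -> SurfaceMesh:
    """Load an OBJ/OFF/PLY triangle mesh, preserving vertex/face order."""
    ext = os.path.splitext(str(path))[1].lower()
    if ext not in _MESH_EXT:
        raise FormatError(f"unknown mesh extension '{ext}'")
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    try:
        tm = trimesh.load(str(path), file_type=ext[1:], process=False,
                          maintain_order=True, force="mesh")
    except Exception as exc:  # noqa: BLE001 - wrap parser diagnostics
        raise FormatError(f"failed to parse {path}: {exc}") from exc
    return SurfaceMesh(np.asarray(tm.vertices, dtype=np.float64),
                       np.asarray(tm.faces, dtype=np.int64))


_POINT_COLUMNS = ["x", "y", "z", "mass", "volume"]


def write_points(points: PointElementSet, path: str | os.PathLike) -> None:
    """Write point elements as CSV (x,y,z,mass,volume) or bare XYZ."""
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".csv":
        df = pd.DataFrame(points.positions, columns=["x", "y", "z"])
        df["mass"] = points.masses
        df["volume"] = points.volumes
        df.to_csv(path, index=False, float_format="%.17g")
    elif ext == ".xyz":
        np.savetxt(path, points.positions, fmt="%.17g")
    else:
        raise FormatError(f"unknown points extension '{ext}'")


def read_points(path: str | os.PathLike) -> PointElementSet:
    """Read point elements; CSV needs the x,y,z,mass,volume header."""
    ext = os.path.splitext(str(path))[1].lower()
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    if ext == ".csv":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"failed to parse {path}: {exc}") from exc
        for col in _POINT_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"missing column '{col}' in {path}")
        bad = df[_POINT_COLUMNS].apply(pd.to_numeric, errors="coerce").isna()
        if bad.to_numpy().any():
            row = int(np.argwhere(bad.to_numpy().any(axis=1))[0][0])
            raise FormatError(f"non-numeric value at data line {row + 2} of {path}")
        num = df[_POINT_COLUMNS].astype(float)
        return PointElementSet(num[["x", "y", "z"]].to_numpy(),
                               num["mass"].to_numpy(), num["volume"].to_numpy())
    if ext == ".xyz":
        try:
            pos = np.loadtxt(path, dtype=np.float64, ndmin=2)
        except ValueError as exc:
            raise FormatError(f"failed to parse {path}: {exc}") from exc
        if pos.shape[1] != 3:
            raise FormatError(f"expected 3 columns in {path}, got {pos.shape[1]}")
        n = len(pos)
        return PointElementSet(pos, np.ones(n), np.ones(n))
    raise FormatError(f"unknown points extension '{ext}'")
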