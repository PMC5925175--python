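"""Mesh-meshless coupling through virtual boundary points.

The surface incision and the interior point elements are independent
models; virtual points bridge them.  They are linearly interpolated along
the incision-boundary polylines, carry prescribed displacements derived
from the local opening of the two Bezier curves (equal and opposite across
the blade plane), and enter the meshless solve as ordinary neighbors whose
displacements are held fixed (Dirichlet-style).  They are constraints, not
matter: never rendered, never integrated, excluded from momentum
bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .deformation import (
    MaterialParams,
    Neighborhood,
    build_neighborhoods,
    compute_states,
    integrate,
    internal_forces,
)
from .geometry import (
    AFFECTED_MINUS,
    AFFECTED_PLUS,
    VIRTUAL,
    PointElementSet,
    SurfaceMesh,
)
from .incision import IncisionCurves
from .levelset import RegionLabels

SIDE_PLUS = 1
SIDE_MINUS = -1


@dataclass
class VirtualPointSet:
    """Interpolated incision-boundary points with prescribed displacements."""

    rest_positions: np.ndarray  # (M, 3)
    parent_edges: np.ndarray  # (M, 2) indices into the side's polyline
    lambdas: np.ndarray  # (M,) interpolation weight in [0, 1]
    sides: np.ndarray  # (M,) SIDE_PLUS or SIDE_MINUS
    t_params: np.ndarray  # (M,) curve parameter of each virtual point
    prescribed: np.ndarray = None  # (M, 3) displacements

    def __post_init__(self) -> None:
        if self.prescribed is None:
            self.prescribed = np.zeros_like(self.rest_positions)

    def __len__(self) -> int:
        return len(self.rest_positions)


def generate_virtual_points(mesh: SurfaceMesh, curves: IncisionCurves | None,
                            per_edge: int = 1) -> VirtualPointSet:
    """Virtual points on each incision-boundary edge at uniform lambda.

    Each polyline segment (between consecutive curve samples) receives
    ``per_edge`` points at lambda = m/(per_edge+1); plus/minus tags follow
    the polyline side.  No incision yields an empty set.
    """
    del mesh  # boundary geometry is carried by the curves' polylines
    if curves is None or len(curves.path_vertex_set) == 0:
        z = np.zeros((0, 3))
        return VirtualPointSet(z, np.zeros((0, 2), dtype=np.int64),
                               np.zeros(0), np.zeros(0, dtype=np.int64),
                               np.zeros(0))
    if per_edge < 1:
        from .errors import InvalidParameterError
        raise InvalidParameterError("per_edge must be >= 1")
    lam = np.arange(1, per_edge + 1) / (per_edge + 1.0)
    rows, edges, lams, sides, ts = [], [], [], [], []
    for side, poly in ((SIDE_PLUS, curves.left_polyline),
                       (SIDE_MINUS, curves.right_polyline)):
        tv = curves.t_values
        for k in range(len(poly) - 1):
            va, vb = poly[k], poly[k + 1]
            for l in lam:
                rows.append((1.0 - l) * va + l * vb)
                edges.append((k, k + 1))
                lams.append(l)
                sides.append(side)
                ts.append((1.0 - l) * tv[k] + l * tv[k + 1])
    return VirtualPointSet(np.asarray(rows), np.asarray(edges, dtype=np.int64),
                           np.asarray(lams), np.asarray(sides, dtype=np.int64),
                           np.asarray(ts))


def _polyline_at(poly: np.ndarray, tv: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Linear interpolation of a sampled polyline at curve parameters t."""
    out = np.empty((len(t), 3))
    for k in range(3):
        out[:, k] = np.interp(t, tv, poly[:, k])
    return out


def prescribe_displacements(vp: VirtualPointSet, curves: IncisionCurves,
                            opening_scale: float = 1.0,
                            blade_normal=None) -> VirtualPointSet:
    """Set virtual-point displacements from the local incision opening.

    s(t) is half the separation of the two Bezier polylines at matched
    parameter t; plus-side points get +opening_scale*s(t)*n_b, minus-side
    the exact opposite, where n_b is the blade-plane normal (the curves'
    positive-side normal when no plane is supplied).  Degenerate chordal
    curves give zero displacements.
    """
    if len(vp) == 0:
        return vp
    nb = np.asarray(blade_normal, dtype=np.float64) if blade_normal is not None \
        else curves.side_normal
    nb = nb / np.linalg.norm(nb)
    left = _polyline_at(curves.left_polyline, curves.t_values, vp.t_params)
    right = _polyline_at(curves.right_polyline, curves.t_values, vp.t_params)
    s = 0.5 * np.linalg.norm(left - right, axis=1)
    vp.prescribed = (opening_scale * s)[:, None] * nb[None, :] * vp.sides[:, None]
    return vp


@dataclass
class CoupledSystem:
    """Real + virtual points merged for one solver configuration.

    The first ``n_real`` entries of every array belong to the tissue's
    point elements; the virtual tail is constrained.  Neighborhoods are
    built over the joint rest positions once per (pose, virtual set).
    """

    points: PointElementSet  # extended set (real + virtual)
    n_real: int
    nb: Neighborhood
    isolated_virtual: np.ndarray  # virtual points with no real neighbor in support


def build_coupled_system(points: PointElementSet, vp: VirtualPointSet,
                         labels: RegionLabels,
                         params: MaterialParams) -> CoupledSystem:
    """Merge tissue and virtual points and build joint neighborhoods.

    The cut severs elastic interaction across the blade plane: supports of
    "+"-side points (real or virtual) never contain "-"-side points and
    vice versa, while the unaffected region stays fully connected to both.
    """
    n = len(points)
    m = len(vp)
    pos = np.vstack([points.rest_positions, vp.rest_positions])
    disp = np.vstack([points.displacements, vp.prescribed])
    vel = np.vstack([points.velocities, np.zeros((m, 3))])
    masses = np.concatenate([points.masses, np.ones(m)])
    volumes = np.concatenate([points.volumes,
                              np.full(m, float(np.median(points.volumes)))])
    lab = np.concatenate([labels.labels, np.full(m, VIRTUAL, dtype=np.int8)])
    ext = PointElementSet(pos + disp, masses, volumes, disp, vel, lab,
                          rest_positions=pos)
    sides = np.zeros(n + m, dtype=np.int8)
    sides[:n][labels.labels == AFFECTED_PLUS] = 1
    sides[:n][labels.labels == AFFECTED_MINUS] = -1
    sides[n:] = vp.sides
    nb = build_neighborhoods(ext, params, sides=sides)
    isolated = []
    for k in range(n, n + m):
        js = nb.edge_j[nb.start[k]:nb.start[k + 1]]
        if not np.any(js < n):
            isolated.append(k - n)
    if isolated:
        import warnings
        warnings.warn(f"{len(isolated)} virtual point(s) have no real neighbor "
                      "in support", stacklevel=2)
    return CoupledSystem(ext, n, nb, np.asarray(isolated, dtype=np.int64))


def coupled_step(system: CoupledSystem, params: MaterialParams,
                 counters: dict | None = None) -> np.ndarray:
    """One meshless step with virtual points as Dirichlet neighbors.

    Gradients, strains and forces are evaluated only for the affected real
    points (the level-set efficiency contract); virtual displacements stay
    prescribed, unaffected points stay bit-identical.  Returns the force
    array over the extended set (virtual entries hold the reaction force).
    """
    pts = system.points
    lab = pts.labels
    active = np.flatnonzero((lab == AFFECTED_PLUS) | (lab == AFFECTED_MINUS))
    if counters is not None:
        counters["gradient_evals"] = counters.get("gradient_evals", 0) + len(active)
        counters["steps"] = counters.get("steps", 0) + 1
    states = compute_states(pts.displacements, system.nb, pts.volumes,
                            params, active=active)
    forces = internal_forces(pts, system.nb, states, params)
    integrate(pts, forces, params)
    # hard constraint: virtual points never move or pick up velocity
    vmask = lab == VIRTUAL
    pts.velocities[vmask] = 0.0
    pts.positions[vmask] = pts.rest_positions[vmask] + pts.displacements[vmask]
    return forces


def split_real(system: CoupledSystem, points: PointElementSet) -> PointElementSet:
    """Copy the real-point state of a coupled system back into ``points``."""
    n = system.n_real
    points.displacements[:] = system.points.displacements[:n]
    points.velocities[:] = system.points.velocities[:n]
    points.positions[:] = system.points.positions[:n]
    return points


def export_virtual_csv(vp: VirtualPointSet, path) -> None:
    """Debug dump of virtual points (flagged virtual=1, never rendered)."""
    import pandas as pd
    df = pd.DataFrame(vp.rest_positions, columns=["x", "y", "z"])
    df["ux"], df["uy"], df["uz"] = vp.prescribed.T
    df["side"] = vp.sides
    df["t"] = vp.t_params
    df["virtual"] = 1
    df.to_csv(path, index=False)
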