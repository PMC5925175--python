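"""Meshless point-element elasticity via MLS displacement gradients.

Each point element estimates its 3x3 displacement gradient from weighted
differences to neighbors inside a compact support radius h, through the
moment matrix M_i = sum_j x_ij x_ij^T w_ij.  Green strain and a
single-parameter Hookean stress follow, and elastic forces are assembled
pairwise (equal and opposite), so linear momentum is conserved exactly.
Time integration is explicit Euler on velocities and displacements, with
optional per-step velocity damping for long quasi-static runs; current
positions are always rest + displacement.

The offset convention in the pairwise formulas is x_ij = x_i - x_j; the
gradient returned here is the sign-corrected *physical* gradient (it
reproduces any affine field exactly), and the force pair term uses the
neighbor-pointing offset so that stretching produces restoring forces and
rigid motions produce none.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    InvalidParameterError,
    NumericalBlowupError,
    SingularMomentError,
)
from .geometry import AFFECTED_MINUS, AFFECTED_PLUS, VIRTUAL, PointElementSet

_COND_THRESHOLD = 1e8  # moment-matrix condition number beyond which we regularize


@dataclass
class MaterialParams:
    """Material and integration parameters.

    E is the single Hookean stiffness (Pa = g/(mm s^2)); h the kernel
    support radius (mm, typically 2.2x the lattice spacing); dt the explicit
    time step (s); damping the per-step velocity retention loss in [0, 1]
    (0 reproduces the undamped integrator); density in g/mm^3.
    """

    E: float = 3000.0
    support_radius: float = 8.8
    dt: float = 1e-3
    damping: float = 0.0
    density: float = 1.0

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise InvalidParameterError("E must be positive")
        if self.support_radius <= 0:
            raise InvalidParameterError("support radius must be positive")
        if self.dt <= 0:
            raise InvalidParameterError("dt must be positive")
        if not (0.0 <= self.damping <= 1.0):
            raise InvalidParameterError("damping must be in [0, 1]")


@dataclass
class Neighborhood:
    """CSR-style neighbor structure with per-point moment matrices.

    Edge e runs from point ``edge_i[e]`` to neighbor ``edge_j[e]`` with
    offset x_ij = x_i - x_j and kernel weight w_ij; ``start[i]:start[i+1]``
    slices point i's edges.  ``minv`` holds (regularized) inverses of the
    moment matrices; ``singular`` flags points whose M needed regularization
    or had fewer than 4 neighbors (treated as rigid).
    """

    start: np.ndarray  # (N+1,)
    edge_i: np.ndarray  # (E,)
    edge_j: np.ndarray  # (E,)
    x_ij: np.ndarray  # (E, 3), x_i - x_j
    weights: np.ndarray  # (E,)
    moment: np.ndarray  # (N, 3, 3)
    minv: np.ndarray  # (N, 3, 3)
    singular: np.ndarray  # (N,) bool
    support_radius: float = 0.0

    @property
    def n_points(self) -> int:
        return len(self.start) - 1

    def neighbor_counts(self) -> np.ndarray:
        return np.diff(self.start)


def weight(r, h: float):
    """Compactly supported C^2 kernel w(r) = (1 - (r/h)^2)^3 for r < h, else 0."""
    if h <= 0:
        raise InvalidParameterError("support h must be positive")
    r = np.asarray(r, dtype=np.float64)
    q = np.clip(r / h, 0.0, None)
    w = np.where(q < 1.0, (1.0 - q ** 2) ** 3, 0.0)
    return w if w.ndim else float(w)


def build_neighborhoods(points: PointElementSet | np.ndarray,
                        params: MaterialParams, sides=None) -> Neighborhood:
    """Neighbor lists, kernel weights, and moment matrices on rest positions.

    ``sides`` (optional, per point: +1 / -1 / 0) severs supports across the
    cut: pairs whose side product is negative are dropped, so the two
    separated halves of a cut region stop interacting elastically while
    neutral (uncut) points keep all their neighbors.

    Points with fewer than 4 neighbors (or a near-singular M) are flagged
    and their inverse Tikhonov-regularized with eps = 1e-9 tr(M)/3, which
    leaves them effectively rigid in degenerate directions.
    """
    if isinstance(points, PointElementSet):
        pos = points.rest_positions
    else:
        pos = np.asarray(points, dtype=np.float64)
    n = len(pos)
    h = params.support_radius
    tree = cKDTree(pos)
    neighbor_lists = tree.query_ball_point(pos, r=h)
    if sides is not None:
        sides = np.asarray(sides)

    counts = np.zeros(n, dtype=np.int64)
    ei, ej = [], []
    for i, lst in enumerate(neighbor_lists):
        js = sorted(j for j in lst if j != i)
        if sides is not None:
            js = [j for j in js if sides[i] * sides[j] >= 0]
        counts[i] = len(js)
        ei.extend([i] * len(js))
        ej.extend(js)
    start = np.concatenate([[0], np.cumsum(counts)])
    edge_i = np.asarray(ei, dtype=np.int64)
    edge_j = np.asarray(ej, dtype=np.int64)
    x_ij = pos[edge_i] - pos[edge_j]
    r = np.linalg.norm(x_ij, axis=1)
    w = weight(r, h)

    outer = w[:, None, None] * x_ij[:, :, None] * x_ij[:, None, :]
    moment = np.zeros((n, 3, 3))
    np.add.at(moment, edge_i, outer)

    minv = np.empty_like(moment)
    singular = counts < 4
    for i in range(n):
        m = moment[i]
        tr = np.trace(m)
        if tr <= 0:
            singular[i] = True
            minv[i] = np.zeros((3, 3))
            continue
        cond = np.linalg.cond(m)
        if not np.isfinite(cond) or cond > _COND_THRESHOLD:
            singular[i] = True
            m = m + (1e-9 * tr / 3.0) * np.eye(3)
        minv[i] = np.linalg.inv(m)
    return Neighborhood(start, edge_i, edge_j, x_ij, w, moment, minv,
                        singular, support_radius=h)


def displacement_gradients(displacements: np.ndarray, nb: Neighborhood,
                           indices=None) -> np.ndarray:
    """Physical MLS displacement gradients for the selected points.

    grad U_i = -(sum_j w_ij (U_j - U_i) x_ij^T) M_i^{-1}; the leading sign
    corrects the x_ij = x_i - x_j offset convention so any affine field
    U(x) = A(x - x_i) is reproduced with gradient exactly A.  Rigid points
    (flagged singular without regularized inverse) return zero.
    """
    u = np.asarray(displacements, dtype=np.float64)
    if indices is None:
        indices = np.arange(nb.n_points)
    indices = np.asarray(indices, dtype=np.int64)
    du = u[nb.edge_j] - u[nb.edge_i]  # (E, 3)
    contrib = nb.weights[:, None, None] * du[:, :, None] * nb.x_ij[:, None, :]
    p = np.zeros((nb.n_points, 3, 3))
    np.add.at(p, nb.edge_i, contrib)
    grads = -np.einsum("nab,nbc->nac", p[indices], nb.minv[indices])
    return grads


def displacement_gradient(i: int, displacements: np.ndarray,
                          nb: Neighborhood, strict: bool = False) -> np.ndarray:
    """Single-point convenience wrapper around :func:`displacement_gradients`.

    With ``strict`` a singular (unregularizable) moment matrix raises
    instead of returning the rigid zero gradient.
    """
    if strict and nb.singular[i] and np.allclose(nb.minv[i], 0):
        raise SingularMomentError(f"moment matrix singular at point {i}")
    return displacement_gradients(displacements, nb, indices=[i])[0]


def green_strain(grad_u: np.ndarray) -> np.ndarray:
    """Green strain eps = (grad U + grad U^T + grad U^T grad U) / 2.

    The quadratic term makes the strain vanish exactly under rigid
    rotations (grad U = R - I with R orthonormal).
    """
    g = np.asarray(grad_u, dtype=np.float64)
    gt = np.swapaxes(g, -1, -2)
    return 0.5 * (g + gt + gt @ g)


def stress(strain: np.ndarray, E: float) -> np.ndarray:
    """Single-parameter Hookean law sigma = E * eps, componentwise."""
    return E * np.asarray(strain, dtype=np.float64)


@dataclass
class StrainStressState:
    """Per-point kinematic and constitutive state for the active set."""

    indices: np.ndarray  # active point ids
    grad_u: np.ndarray  # (K, 3, 3)
    strain: np.ndarray  # (K, 3, 3)
    stress: np.ndarray  # (K, 3, 3)
    B: np.ndarray  # (K, 3, 3) force matrices


def compute_states(points_disp: np.ndarray, nb: Neighborhood,
                   volumes: np.ndarray, params: MaterialParams,
                   active=None) -> StrainStressState:
    """Gradient -> strain -> stress -> B for the active point set.

    B_i = -2 v_i (grad U_i + I) sigma_i M_i^{-1} is the per-point force
    matrix whose products with neighbor offsets give the pair forces.
    """
    if active is None:
        active = np.arange(nb.n_points)
    active = np.asarray(active, dtype=np.int64)
    g = displacement_gradients(points_disp, nb, indices=active)
    eps = green_strain(g)
    sig = stress(eps, params.E)
    eye = np.eye(3)
    b = -2.0 * volumes[active][:, None, None] * ((g + eye) @ sig) @ nb.minv[active]
    return StrainStressState(active, g, eps, sig, b)


def internal_forces(points: PointElementSet, nb: Neighborhood,
                    states: StrainStressState,
                    params: MaterialParams) -> np.ndarray:
    """Pairwise elastic forces from the active points' B matrices.

    For each active i and neighbor j the pair term t = B_i (x_j - x_i) w_ij
    is added to f_j and subtracted from f_i, so the total force sums to
    zero by construction.  Points outside the active set accumulate force
    from active neighbors but generate none themselves.
    """
    n = nb.n_points
    forces = np.zeros((n, 3))
    if len(states.indices) == 0:
        return forces
    active_mask = np.zeros(n, dtype=bool)
    active_mask[states.indices] = True
    sel = active_mask[nb.edge_i]
    if not np.any(sel):
        return forces
    b_of = np.zeros((n, 3, 3))
    b_of[states.indices] = states.B
    ei, ej = nb.edge_i[sel], nb.edge_j[sel]
    t = np.einsum("eab,eb->ea", b_of[ei], -nb.x_ij[sel]) * nb.weights[sel][:, None]
    np.add.at(forces, ej, t)
    np.add.at(forces, ei, -t)
    return forces


def integrate(points: PointElementSet, forces: np.ndarray,
              params: MaterialParams, integrate_all: bool = False
              ) -> PointElementSet:
    """Explicit Euler step on the affected points (in place).

    v <- (1-c)(v + dt f/m); U <- U + dt v; x <- rest + U.  Unaffected
    points are untouched; virtual points keep their prescribed
    displacements and zero velocity.  ``integrate_all`` frees every
    non-virtual point (used for unconstrained relaxation runs).
    """
    labels = points.labels
    if integrate_all:
        mask = labels != VIRTUAL
    else:
        mask = (labels == AFFECTED_PLUS) | (labels == AFFECTED_MINUS)
    if not np.any(mask):
        return points
    f = np.asarray(forces, dtype=np.float64)[mask]
    if not np.all(np.isfinite(f)):
        bad = int(np.flatnonzero(mask)[
            np.argmax(~np.isfinite(f).all(axis=1))])
        raise NumericalBlowupError(f"non-finite force at point {bad}")
    keep = 1.0 - params.damping
    v = points.velocities[mask]
    v = keep * (v + params.dt * f / points.masses[mask][:, None])
    points.velocities[mask] = v
    points.displacements[mask] += params.dt * v
    if not np.all(np.isfinite(points.displacements[mask])):
        raise NumericalBlowupError("non-finite displacement after step")
    points.positions[mask] = points.rest_positions[mask] + points.displacements[mask]
    return points


def kinetic_energy(points: PointElementSet) -> float:
    """Sum_i m_i ||v_i||^2 (the damped-norm diagnostic; g mm^2/s^2)."""
    return float(np.sum(points.masses * np.sum(points.velocities ** 2, axis=1)))


def dump_state_csv(points: PointElementSet, forces: np.ndarray, path) -> None:
    """Per-point state dump (positions, displacements, forces) as CSV."""
    import pandas as pd
    cols = {}
    for name, arr in (("x", points.positions), ("u", points.displacements),
                      ("f", np.asarray(forces))):
        for k, ax in enumerate("xyz"):
            cols[f"{name}{ax}"] = arr[:, k]
    cols["label"] = points.labels
    pd.DataFrame(cols).to_csv(path, index=False)
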