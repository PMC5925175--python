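"""Virtual scalpel, cut planes, and level-set classification of points.

The scalpel is reduced to a tip P, a handle point P', and a vertical
direction: the blade plane contains P and P' and is perpendicular to the
tissue surface; the vertical plane sits at the blade's lowest cut point and
separates the cutting-affected region (above) from the untouched tissue
below.  Signed distances to these two planes, phi (blade) and psi
(vertical), are the two level-set functions; their signs classify every
point element as unaffected, affected "+" or affected "-".

Rigid plane motion makes the advection equation phi_t + v . grad(phi) = 0
exact under per-pose recomputation, so the level set is re-initialized from
the current pose instead of being integrated on a grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import InvalidInputError, InvalidScalpelError
from .geometry import AFFECTED_MINUS, AFFECTED_PLUS, UNAFFECTED, PointElementSet


@dataclass
class Scalpel:
    """Tool pose: tip P, handle P', and the vertical unit direction."""

    tip: np.ndarray
    handle: np.ndarray
    vertical: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.tip = np.asarray(self.tip, dtype=np.float64)
        self.handle = np.asarray(self.handle, dtype=np.float64)
        v = np.asarray(self.vertical, dtype=np.float64)
        nv = np.linalg.norm(v)
        if nv == 0:
            raise InvalidScalpelError("vertical direction is zero")
        self.vertical = v / nv
        axis = self.handle - self.tip
        na = np.linalg.norm(axis)
        if na == 0:
            raise InvalidScalpelError("tip and handle coincide")
        if np.linalg.norm(np.cross(axis / na, self.vertical)) < 1e-12:
            raise InvalidScalpelError("vertical parallel to tool axis")


@dataclass
class CutPlanes:
    """Blade plane and vertical (cut-bottom) plane for one scalpel pose.

    ``vertical_normal`` is the outward normal of the unaffected half-space
    (-vertical); the level-set value psi is measured along +vertical so that
    affected points (above the cut bottom) have psi > 0.
    """

    blade_point: np.ndarray
    blade_normal: np.ndarray
    vertical_point: np.ndarray
    vertical_normal: np.ndarray
    up: np.ndarray  # +vertical unit vector
    cut_depth: float
    path_points: np.ndarray = None  # optional samples X_c on the blade plane
    vertical_points: np.ndarray = None  # optional samples X_v


@dataclass
class RegionLabels:
    """Disjoint exhaustive partition of the point set with phi/psi values."""

    labels: np.ndarray  # int8 in {UNAFFECTED, AFFECTED_PLUS, AFFECTED_MINUS}
    phi: np.ndarray  # signed distance to blade plane, mm
    psi: np.ndarray  # signed distance above the vertical plane, mm

    def counts(self) -> dict[str, int]:
        return {
            "unaffected": int(np.sum(self.labels == UNAFFECTED)),
            "affected_plus": int(np.sum(self.labels == AFFECTED_PLUS)),
            "affected_minus": int(np.sum(self.labels == AFFECTED_MINUS)),
        }


def planes_from_scalpel(scalpel: Scalpel, cut_depth: float) -> CutPlanes:
    """Blade plane through P and P' (normal (P'-P) x vertical, normalized)
    and vertical plane at the blade's lowest cut point P - depth*vertical."""
    if cut_depth < 0:
        raise InvalidScalpelError("cut depth must be non-negative")
    axis = scalpel.handle - scalpel.tip
    n = np.cross(axis, scalpel.vertical)
    nn = np.linalg.norm(n)
    if nn < 1e-14:
        raise InvalidScalpelError("degenerate scalpel: axis parallel to vertical")
    blade_normal = n / nn
    vertical_point = scalpel.tip - cut_depth * scalpel.vertical
    return CutPlanes(
        blade_point=scalpel.tip.copy(),
        blade_normal=blade_normal,
        vertical_point=vertical_point,
        vertical_normal=-scalpel.vertical,
        up=scalpel.vertical.copy(),
        cut_depth=float(cut_depth),
    )


def sample_plane(point, normal, extent: float, n: int, rng=None) -> np.ndarray:
    """Sample points on a plane patch (for the sampled signed-distance form)."""
    point = np.asarray(point, dtype=np.float64)
    normal = np.asarray(normal, dtype=np.float64)
    normal = normal / np.linalg.norm(normal)
    # any in-plane orthonormal basis
    h = np.array([1.0, 0.0, 0.0])
    if abs(normal @ h) > 0.9:
        h = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, h)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    if rng is None:
        g = np.linspace(-extent, extent, n)
        uu, vv = np.meshgrid(g, g)
        uv = np.stack([uu.ravel(), vv.ravel()], axis=1)
    else:
        uv = rng.uniform(-extent, extent, size=(n, 2))
    return point + uv[:, :1] * e1 + uv[:, 1:] * e2


def signed_distance(x, samples, side_normal) -> float:
    """Sampled level-set value: +/- min_i ||X - X_i|| with the sign of
    dot(X - nearest, side_normal).

    For a densely sampled plane this converges to the analytic point-plane
    signed distance.
    """
    samples = np.asarray(samples, dtype=np.float64).reshape(-1, 3)
    if len(samples) == 0:
        raise InvalidInputError("signed_distance needs a non-empty sample set")
    x = np.asarray(x, dtype=np.float64)
    tree = cKDTree(samples)
    d, idx = tree.query(x)
    rel = x - samples[idx]
    s = np.sign(np.sum(rel * np.asarray(side_normal, dtype=np.float64), axis=-1))
    s = np.where(s == 0, 1.0, s)
    return s * d


def classify(points: PointElementSet, planes: CutPlanes) -> RegionLabels:
    """Partition point elements by the two plane level sets.

    psi <= 0 (at or below the cut bottom): unaffected, skipped by the
    solver; psi > 0 splits by blade side, phi > 0 -> "+", phi < 0 -> "-";
    points exactly on the blade plane (phi = 0) go to "+".
    """
    x = points.positions
    phi = (x - planes.blade_point) @ planes.blade_normal
    psi = (x - planes.vertical_point) @ planes.up
    labels = np.full(len(x), UNAFFECTED, dtype=np.int8)
    above = psi > 0
    labels[above & (phi >= 0)] = AFFECTED_PLUS
    labels[above & (phi < 0)] = AFFECTED_MINUS
    return RegionLabels(labels=labels, phi=phi, psi=psi)


def advance(planes: CutPlanes, new_scalpel: Scalpel, cut_depth: float) -> CutPlanes:
    """Evolve the level set to a new scalpel pose.

    For rigidly moving planes, recomputing signed distances from the new
    pose solves the advection equation exactly, so this simply rebuilds the
    planes.
    """
    del planes  # the previous state carries no information for rigid motion
    return planes_from_scalpel(new_scalpel, cut_depth)


def export_labels_csv(labels: RegionLabels, path) -> None:
    """Write (index,label,phi,psi) rows for visualization/debugging."""
    import pandas as pd

    from .geometry import LABEL_NAMES
    df = pd.DataFrame({
        "index": np.arange(len(labels.labels)),
        "label": [LABEL_NAMES[int(v)] for v in labels.labels],
        "phi": labels.phi,
        "psi": labels.psi,
    })
    df.to_csv(path, index=False)
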