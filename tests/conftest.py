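"""Shared fixtures and helpers for the test suite."""

import numpy as np
import pytest

from meshlesscut import geometry, sim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def box_model():
    """Refined box model used by the end-to-end cutting tests."""
    return geometry.make_box_model((40.0, 40.0, 20.0), 4.0, refine_surface=True)


@pytest.fixture
def small_box_model():
    return geometry.make_box_model((20.0, 20.0, 12.0), 4.0, refine_surface=True)


def straight_cut_config(out_dir=None, seed=1, poses=6, extent=(40.0, 40.0, 20.0),
                        steps_per_pose=20, depth=6.0):
    """A straight constant-depth cut across the refined box's top face.

    Quasi-static stepping: coarse dt with near-critical per-step damping and
    a short load ramp on the opening.
    """
    return sim.SimConfig.from_dict({
        "model": {"kind": "box", "extent": list(extent), "spacing": 4.0,
                  "refine_surface": True},
        "trajectory": [
            {"tip": [8.0 + 2.0 * k, 17.0, extent[2]],
             "handle": [20.0 + 2.0 * k, 17.0, extent[2] + 10.0],
             "depth": depth}
            for k in range(poses)],
        "material": {"E": 3000.0, "support_radius": 8.8, "dt": 0.02,
                     "damping": 0.35},
        "steps_per_pose": steps_per_pose,
        "opening_ramp_time": 0.1,
        "seed": seed,
        "out_dir": out_dir,
    })


def reflect_y(arr, c):
    """Mirror positions/vectors across the plane y = c (positions) or flip
    the y component (set c=0 for direction vectors)."""
    out = np.array(arr, dtype=np.float64, copy=True)
    out[..., 1] = 2.0 * c - out[..., 1]
    return out


def mirrored_config(cfg, mirror_y, tmp_path):
    """Build the blade-plane-mirrored twin of a box straight-cut config.

    The tissue model is reflected explicitly (vertices mirrored, triangle
    winding flipped to stay outward) and written to disk so both runs see
    exactly mirrored inputs; the scalpel trajectory is mirrored in place.
    """
    from meshlesscut import geometry as g

    mesh, points = sim._build_model(cfg)
    mverts = reflect_y(mesh.vertices, mirror_y)
    mtris = mesh.triangles[:, [0, 2, 1]].copy()
    mmesh = g.SurfaceMesh(mverts, mtris)
    mpts = g.PointElementSet(reflect_y(points.rest_positions, mirror_y),
                             points.masses.copy(), points.volumes.copy())
    mesh_path = tmp_path / "mirror.obj"
    pts_path = tmp_path / "mirror_points.csv"
    g.write_mesh(mmesh, mesh_path)
    g.write_points(mpts, pts_path)

    raw_traj = [{"tip": list(reflect_y(p.tip, mirror_y)),
                 "handle": list(reflect_y(p.handle, mirror_y)),
                 "depth": p.depth} for p in cfg.trajectory]
    mcfg = sim.SimConfig(
        model={"mesh": str(mesh_path), "points": str(pts_path)},
        trajectory=[sim.Pose(np.asarray(p["tip"]), np.asarray(p["handle"]),
                             p["depth"]) for p in raw_traj],
        material=cfg.material, oscillation=cfg.oscillation,
        force_fit=cfg.force_fit, samples_per_curve=cfg.samples_per_curve,
        per_edge=cfg.per_edge, opening_scale=cfg.opening_scale,
        opening_ramp_time=cfg.opening_ramp_time,
        steps_per_pose=cfg.steps_per_pose, seed=cfg.seed,
        vertical=cfg.vertical)
    return mcfg
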