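"""Batch cutting-session orchestration.

One session sweeps a scalpel trajectory over a tissue model.  Per pose the
surface pipeline (path extraction -> Bezier incision -> remesh) and the
internal pipeline (level-set classification -> virtual points -> coupled
meshless steps) run in sequence, and a modulated feedback-force record is
appended per solver step.  Runs are deterministic for a fixed seed and
write their outputs (cut mesh, point states, force series, JSON summary)
to the configured directory.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import coupling, deformation, geometry, haptics, incision, levelset
from .errors import ConfigError, MeshlessCutError

log = logging.getLogger("meshlesscut")


@dataclass
class Pose:
    """One scalpel pose: tip P, handle P', cut depth (mm)."""

    tip: np.ndarray
    handle: np.ndarray
    depth: float


@dataclass
class SimConfig:
    """Validated configuration of a cutting session."""

    model: dict
    trajectory: list[Pose]
    material: deformation.MaterialParams
    oscillation: haptics.OscillationParams
    force_fit: haptics.ForceFitCoeffs
    samples_per_curve: int = 16
    per_edge: int = 1
    opening_scale: float = 1.0
    opening_ramp_time: float = 0.1  # s; load-steps the prescribed opening
    steps_per_pose: int = 10
    seed: int = 0
    out_dir: str | None = None
    vertical: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        """Build and validate; raises ConfigError naming every bad field."""
        errors = []
        model = raw.get("model")
        if not isinstance(model, dict) or not (
                {"kind"} <= set(model) or {"mesh", "points"} <= set(model)):
            errors.append("model (need kind=... or mesh=/points= paths)")
        traj_raw = raw.get("trajectory")
        trajectory = []
        if not isinstance(traj_raw, list) or not traj_raw:
            errors.append("trajectory (non-empty list of poses)")
        else:
            for k, p in enumerate(traj_raw):
                try:
                    trajectory.append(Pose(
                        np.asarray(p["tip"], dtype=np.float64),
                        np.asarray(p["handle"], dtype=np.float64),
                        float(p.get("depth", 0.0))))
                except (KeyError, TypeError, ValueError):
                    errors.append(f"trajectory[{k}]")
        def _sub(key, cls_):
            try:
                return cls_(**raw.get(key, {}))
            except (TypeError, MeshlessCutError):
                errors.append(key)
                return cls_()
        material = _sub("material", deformation.MaterialParams)
        osc = _sub("oscillation", haptics.OscillationParams)
        fit = _sub("force_fit", haptics.ForceFitCoeffs)
        ints = {}
        for key, default in (("samples_per_curve", 16), ("per_edge", 1),
                             ("steps_per_pose", 10), ("seed", 0)):
            try:
                ints[key] = int(raw.get(key, default))
            except (TypeError, ValueError):
                errors.append(key)
                ints[key] = default
        try:
            opening = float(raw.get("opening_scale", 1.0))
        except (TypeError, ValueError):
            errors.append("opening_scale")
            opening = 1.0
        try:
            ramp = float(raw.get("opening_ramp_time", 0.1))
        except (TypeError, ValueError):
            errors.append("opening_ramp_time")
            ramp = 0.1
        vertical = np.asarray(raw.get("vertical", [0.0, 0.0, 1.0]), dtype=np.float64)
        if errors:
            raise ConfigError("invalid config fields: " + ", ".join(errors))
        return cls(model=model, trajectory=trajectory, material=material,
                   oscillation=osc, force_fit=fit,
                   samples_per_curve=ints["samples_per_curve"],
                   per_edge=ints["per_edge"], opening_scale=opening,
                   opening_ramp_time=ramp,
                   steps_per_pose=ints["steps_per_pose"], seed=ints["seed"],
                   out_dir=raw.get("out_dir"), vertical=vertical)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        if not os.path.exists(path):
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping: {path}")
        return cls.from_dict(raw)


@dataclass
class SessionResult:
    """Everything a cutting session produced."""

    points: geometry.PointElementSet
    cut_mesh: geometry.SurfaceMesh
    force_series: pd.DataFrame  # t, depth, fx, fy, fz, fmag
    pose_stats: pd.DataFrame
    counters: dict
    curves: incision.IncisionCurves | None = None
    virtual_points: coupling.VirtualPointSet | None = None


def _build_model(cfg: SimConfig):
    m = cfg.model
    if "kind" in m:
        kind = m["kind"]
        if kind == "box":
            return geometry.make_box_model(
                m.get("extent", (40.0, 40.0, 20.0)), m.get("spacing", 4.0),
                density=m.get("density", 1.0),
                refine_surface=m.get("refine_surface", True))
        if kind == "ellipsoid":
            return geometry.make_ellipsoid_model(
                m.get("semi_axes", (25.0, 15.0, 10.0)), m.get("spacing", 4.0),
                mesh_resolution=m.get("mesh_resolution", 2),
                density=m.get("density", 1.0))
        raise ConfigError(f"unknown synthetic model kind '{kind}'")
    return geometry.read_mesh(m["mesh"]), geometry.read_points(m["points"])


def run(config: SimConfig) -> SessionResult:
    """Execute a full cutting session (see module docstring for the flow)."""
    rng = np.random.default_rng(config.seed)  # reserved for synthetic jitter
    del rng
    mesh0, points = _build_model(config)
    params = config.material
    up = config.vertical / np.linalg.norm(config.vertical)

    # sweep extent along the horizontal cut direction, from the trajectory
    tips = np.asarray([p.tip for p in config.trajectory])
    first = config.trajectory[0]
    scalpel0 = levelset.Scalpel(first.tip, first.handle, up)
    planes0 = levelset.planes_from_scalpel(scalpel0, first.depth)
    sweep = np.cross(up, planes0.blade_normal)
    sweep /= np.linalg.norm(sweep)
    t_lo, t_hi = (tips @ sweep).min(), (tips @ sweep).max()
    margin = 0.5 * params.support_radius
    t_range = (t_lo - margin, t_hi + margin)

    force_rows = []
    pose_rows = []
    counters: dict = {}
    cut_mesh = mesh0.copy()
    curves = None
    vp = None
    planes = planes0
    t_now = 0.0

    for pose_idx, pose in enumerate(config.trajectory):
        scalpel = levelset.Scalpel(pose.tip, pose.handle, up)
        planes = levelset.advance(planes, scalpel, pose.depth)
        labels = levelset.classify(points, planes)
        path = incision.extract_path(mesh0, planes.blade_point,
                                     planes.blade_normal,
                                     planes.vertical_point, planes.up,
                                     t_range=t_range)
        n_aff = int(np.sum(labels.labels != geometry.UNAFFECTED))
        have_cut = len(path) >= 2 and n_aff > 0
        if have_cut:
            curves = incision.build_incision(mesh0, path,
                                             config.samples_per_curve)
            cut_mesh = incision.remesh_incision(mesh0, curves)
            vp = coupling.generate_virtual_points(cut_mesh, curves,
                                                  config.per_edge)
            if len(vp) and curves.side_normal @ planes.blade_normal < 0:
                vp.sides = -vp.sides  # align "+" side with phi > 0
            vp = coupling.prescribe_displacements(
                vp, curves, config.opening_scale,
                blade_normal=planes.blade_normal)
            system = coupling.build_coupled_system(points, vp, labels, params)
            points.labels[:] = labels.labels  # expose region labels
            for _ in range(config.steps_per_pose):
                # load-step the opening to avoid an impulsive Dirichlet jump
                if config.opening_ramp_time > 0:
                    ramp = min(1.0, (t_now + params.dt) / config.opening_ramp_time)
                else:
                    ramp = 1.0
                system.points.displacements[system.n_real:] = vp.prescribed * ramp
                forces = coupling.coupled_step(system, params, counters)
                t_now += params.dt
                gamma = haptics.oscillation(t_now, pose.depth,
                                            config.oscillation)
                reaction = forces[system.n_real:].sum(axis=0)
                fb = reaction * gamma
                force_rows.append((t_now, pose.depth, *fb,
                                   float(np.linalg.norm(fb))))
            coupling.split_real(system, points)
        else:
            for _ in range(config.steps_per_pose):
                t_now += params.dt
                force_rows.append((t_now, pose.depth, 0.0, 0.0, 0.0, 0.0))
        max_disp = float(np.max(np.linalg.norm(points.displacements, axis=1)))
        pose_rows.append((pose_idx, n_aff, len(path), max_disp))
        log.info("pose %d: affected=%d path=%d max|U|=%.4g mm",
                 pose_idx, n_aff, len(path), max_disp)

    force_series = pd.DataFrame(
        force_rows, columns=["t", "depth", "fx", "fy", "fz", "fmag"])
    pose_stats = pd.DataFrame(
        pose_rows, columns=["pose", "n_affected", "n_path", "max_disp"])
    result = SessionResult(points=points, cut_mesh=cut_mesh,
                           force_series=force_series, pose_stats=pose_stats,
                           counters=counters, curves=curves,
                           virtual_points=vp)
    if config.out_dir:
        _write_outputs(result, config)
    return result


def _write_outputs(result: SessionResult, config: SimConfig) -> None:
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    geometry.write_mesh(result.cut_mesh, os.path.join(out, "cut_mesh.obj"))
    geometry.write_points(result.points, os.path.join(out, "points_final.csv"))
    result.force_series.to_csv(os.path.join(out, "force_series.csv"),
                               index=False, float_format="%.17g")
    result.pose_stats.to_csv(os.path.join(out, "pose_stats.csv"),
                             index=False, float_format="%.17g")
    disp = pd.DataFrame(result.points.displacements, columns=["ux", "uy", "uz"])
    disp["label"] = result.points.labels
    disp.to_csv(os.path.join(out, "displacements_final.csv"),
                index=False, float_format="%.17g")
    summary = {
        "seed": config.seed,
        "poses": len(config.trajectory),
        "steps_per_pose": config.steps_per_pose,
        "n_points": len(result.points),
        "n_mesh_vertices": len(result.cut_mesh.vertices),
        "n_mesh_triangles": len(result.cut_mesh.triangles),
        "max_displacement_mm": float(np.max(np.linalg.norm(
            result.points.displacements, axis=1))),
        "peak_feedback_force": float(result.force_series["fmag"].max()),
        "gradient_evals": int(result.counters.get("gradient_evals", 0)),
    }
    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)


# -- built-in property/oracle suite (CLI `validate`) --------------------------

def validate(seed: int = 0) -> dict:
    """Fast self-check of the core numerical properties.

    Returns a machine-readable report; every entry carries a measured value
    and a boolean.  Mirrors the repository test suite at reduced size.
    """
    rng = np.random.default_rng(seed)
    report: dict[str, dict] = {}

    t = np.linspace(0, 1, 101)
    err = max(abs(sum(incision.bernstein(i, n, tt) for i in range(n + 1)) - 1.0)
              for n in (1, 2, 3) for tt in t)
    report["bernstein_partition_of_unity"] = {"max_error": float(err),
                                              "ok": bool(err < 1e-12)}

    pts = rng.normal(size=(300, 3)) * 10
    params = deformation.MaterialParams(support_radius=3.5)
    pset = geometry.PointElementSet(pts, np.ones(300), np.ones(300))
    nb = deformation.build_neighborhoods(pset, params)
    a_mat = rng.normal(size=(3, 3))
    u = pts @ a_mat.T
    g = deformation.displacement_gradients(u, nb)
    well = ~nb.singular
    gerr = float(np.max(np.abs(g[well] - a_mat))) if well.any() else np.inf
    report["mls_affine_reproduction"] = {"max_error": gerr,
                                         "ok": bool(gerr < 1e-9)}

    theta = 0.3
    rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                    [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
    strain = deformation.green_strain(rot - np.eye(3))
    serr = float(np.max(np.abs(strain)))
    report["rigid_rotation_zero_strain"] = {"max_error": serr,
                                            "ok": bool(serr < 1e-12)}

    scal = levelset.Scalpel(rng.normal(size=3), rng.normal(size=3) + 5,
                            np.array([0.0, 0.0, 1.0]))
    planes = levelset.planes_from_scalpel(scal, 2.0)
    q = rng.normal(size=(500, 3)) * 5
    pset2 = geometry.PointElementSet(q, np.ones(500), np.ones(500))
    lab = levelset.classify(pset2, planes)
    c = lab.counts()
    ok = sum(c.values()) == 500
    report["levelset_partition"] = {"counts": c, "ok": bool(ok)}

    r = haptics.rmse([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
    report["rmse_hand_value"] = {"value": r,
                                 "ok": bool(abs(r - np.sqrt(5 / 3)) < 1e-12)}
    report["oscillation_zero_at_t0"] = {
        "value": haptics.oscillation(0.0, 3.0, haptics.OscillationParams()),
        "ok": haptics.oscillation(0.0, 3.0, haptics.OscillationParams()) == 0.0}

    report["all_ok"] = {"ok": all(v.get("ok", False) for k, v in report.items()
                                  if k != "all_ok")}
    return report
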