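"""Bezier incision construction and wound retriangulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meshlesscut import (
    InvalidChordError,
    InvalidParameterError,
    NoCutError,
    UnsupportedPathError,
    geometry,
    make_box_model,
)
from meshlesscut.geometry import boundary_loops
from meshlesscut.incision import (
    bernstein,
    bezier_quadratic,
    build_incision,
    collect_affected,
    extract_path,
    remesh_incision,
    select_control_points,
    split_by_chord,
)

coord = st.floats(-50, 50, allow_nan=False, allow_infinity=False)
point3 = st.tuples(coord, coord, coord)


class TestBernstein:
    def test_closed_forms(self):
        assert bernstein(0, 2, 0.0) == 1.0
        assert bernstein(1, 2, 0.5) == 0.5
        assert bernstein(2, 2, 1.0) == 1.0

    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_partition_of_unity(self, n):
        t = np.linspace(0, 1, 101)
        total = sum(bernstein(i, n, t) for i in range(n + 1))
        assert np.max(np.abs(total - 1.0)) < 1e-12

    def test_index_out_of_range(self):
        with pytest.raises(InvalidParameterError):
            bernstein(3, 2, 0.5)
        with pytest.raises(InvalidParameterError):
            bernstein(-1, 2, 0.5)


class TestBezierQuadratic:
    def test_midpoint_value(self):
        p = bezier_quadratic((0, 0, 0), (1, 2, 0), (2, 0, 0), 0.5)
        assert np.allclose(p, (1.0, 1.0, 0.0))

    @settings(derandomize=True, max_examples=50)
    @given(point3, point3, point3)
    def test_endpoint_interpolation(self, p0, p1, p2):
        assert np.array_equal(bezier_quadratic(p0, p1, p2, 0.0), np.asarray(p0))
        assert np.array_equal(bezier_quadratic(p0, p1, p2, 1.0), np.asarray(p2))

    @settings(derandomize=True, max_examples=50)
    @given(point3, point3, point3,
           st.floats(0, 1, allow_nan=False))
    def test_convex_hull_containment(self, p0, p1, p2, t):
        # Bernstein weights are non-negative and sum to one, so the point
        # must admit non-negative barycentric-style weights; check directly
        # against the explicit weights.
        p = bezier_quadratic(p0, p1, p2, t)
        w = np.array([(1 - t) ** 2, 2 * t * (1 - t), t ** 2])
        assert np.all(w >= 0) and abs(w.sum() - 1) < 1e-12
        recon = w[0] * np.asarray(p0) + w[1] * np.asarray(p1) + w[2] * np.asarray(p2)
        assert np.allclose(p, recon, atol=1e-9)


class TestCollectAffected:
    def test_one_ring_of_interior_vertex(self):
        mesh, _ = make_box_model((20, 20, 8), 4, refine_surface=True)
        # pick an interior top-face vertex
        top = np.flatnonzero((mesh.vertices[:, 2] == 8) &
                             (mesh.vertices[:, 0] == 8) &
                             (mesh.vertices[:, 1] == 8))
        v = int(top[0])
        got = set(collect_affected(mesh, [v]))
        # brute-force incidence oracle
        expected = set()
        for tri in mesh.triangles:
            if v in tri:
                expected.update(int(x) for x in tri)
        assert got == expected
        assert v in got and len(got) >= 6

    def test_corner_vertex_brute_force(self):
        mesh, _ = make_box_model((10, 10, 10), 5)
        got = set(collect_affected(mesh, [0]))
        expected = set()
        for tri in mesh.triangles:
            if 0 in tri:
                expected.update(int(x) for x in tri)
        assert got == expected

    def test_all_vertices(self):
        mesh, _ = make_box_model((10, 10, 10), 5)
        got = collect_affected(mesh, np.arange(len(mesh.vertices)))
        assert set(got) == set(range(len(mesh.vertices)))

    def test_empty_path(self):
        mesh, _ = make_box_model((10, 10, 10), 5)
        assert len(collect_affected(mesh, [])) == 0


class TestSplitByChord:
    def test_basic_sides_and_tie(self):
        a, b, n = (0, 0, 0), (2, 0, 0), (0, 0, 1)
        pos, neg = split_by_chord([(1, 1, 0), (1, -1, 0), (1, 0, 0)], a, b, n)
        assert list(pos) == [0, 2]  # on-chord point goes positive
        assert list(neg) == [1]

    def test_degenerate_chord(self):
        with pytest.raises(InvalidChordError):
            split_by_chord([(0, 0, 0)], (1, 1, 1), (1, 1, 1), (0, 0, 1))

    def test_random_points_vs_signed_area_oracle(self, rng):
        a = rng.normal(size=3)
        b = a + rng.normal(size=3)
        n = np.array([0.0, 0.0, 1.0])
        pts = rng.normal(size=(100, 3))
        pos, neg = split_by_chord(pts, a, b, n)
        mask = np.zeros(100, dtype=bool)
        mask[pos] = True
        for k, p in enumerate(pts):  # independent sign evaluation
            d = b - a
            r = p - a
            s = (d[1] * r[2] - d[2] * r[1]) * n[0] + \
                (d[2] * r[0] - d[0] * r[2]) * n[1] + \
                (d[0] * r[1] - d[1] * r[0]) * n[2]
            assert mask[k] == (s >= 0)

    def test_mirror_swaps_sides(self, rng):
        # reflecting points across the chord plane swaps positive/negative
        a, b, n = np.zeros(3), np.array([3.0, 0, 0]), np.array([0.0, 0, 1])
        pts = rng.normal(size=(50, 3))
        pts = pts[np.abs(pts[:, 1]) > 1e-9]
        mirrored = pts.copy()
        mirrored[:, 1] *= -1
        pos1, neg1 = split_by_chord(pts, a, b, n)
        pos2, neg2 = split_by_chord(mirrored, a, b, n)
        assert set(pos1) == set(neg2) and set(neg1) == set(pos2)


class TestSelectControlPoints:
    def test_max_distance_choice(self):
        c, d = select_control_points([(1, 2, 0), (1, 1, 0)], [(1, -3, 0)],
                                     (0, 0, 0), (4, 0, 0))
        assert np.allclose(c, (1, 2, 0))
        assert np.allclose(d, (1, -3, 0))

    def test_tie_lowest_index(self):
        c, _ = select_control_points([(1, 2, 0), (3, 2, 0)], [],
                                     (0, 0, 0), (4, 0, 0))
        assert np.allclose(c, (1, 2, 0))

    def test_empty_side_midpoint(self):
        c, d = select_control_points([], [(1, -1, 0)], (0, 0, 0), (4, 0, 0))
        assert np.allclose(c, (2, 0, 0))
        assert np.allclose(d, (1, -1, 0))


def flat_patch(nx=7, ny=5, spacing=1.0, symmetric_row=None):
    """Open rectangular grid patch in the z=0 plane.

    With ``symmetric_row`` the quad diagonals flip across that row so the
    triangulation (and hence one-ring neighborhoods) is mirror-symmetric
    about the line y = symmetric_row * spacing.
    """
    xs, ys = np.meshgrid(np.arange(nx) * spacing, np.arange(ny) * spacing,
                         indexing="ij")
    verts = np.stack([xs.ravel(), ys.ravel(), np.zeros(nx * ny)], axis=1)

    def vid(i, j):
        return i * ny + j

    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            flip = symmetric_row is not None and j >= symmetric_row
            if flip:
                faces.append((vid(i, j), vid(i + 1, j), vid(i, j + 1)))
                faces.append((vid(i + 1, j), vid(i + 1, j + 1), vid(i, j + 1)))
            else:
                faces.append((vid(i, j), vid(i + 1, j), vid(i + 1, j + 1)))
                faces.append((vid(i, j), vid(i + 1, j + 1), vid(i, j + 1)))
    return geometry.SurfaceMesh(verts, np.asarray(faces)), vid


class TestBuildIncision:
    def test_two_samples_is_chord(self):
        mesh, vid = flat_patch()
        path = [vid(1, 2), vid(2, 2), vid(3, 2)]
        curves = build_incision(mesh, path, samples_per_curve=2)
        assert np.array_equal(curves.left_polyline,
                              np.vstack([curves.A, curves.B]))
        assert np.array_equal(curves.right_polyline,
                              np.vstack([curves.A, curves.B]))

    def test_symmetric_patch_gives_mirror_curves(self):
        mesh, vid = flat_patch(7, 5, symmetric_row=2)
        path = [vid(i, 2) for i in range(1, 6)]
        curves = build_incision(mesh, path, samples_per_curve=17)
        # reflect the right polyline across the chord line y = 2 and compare
        reflected = curves.right_polyline.copy()
        reflected[:, 1] = 4.0 - reflected[:, 1]
        assert np.allclose(reflected, curves.left_polyline, atol=1e-12)

    def test_degenerate_control_points_give_chordal_curves(self):
        # empty candidate sides collapse both control points onto the chord
        # midpoint; the sampled curves then lie exactly on the chord
        a, b = np.array([0.0, 0, 0]), np.array([4.0, 0, 0])
        c, d = select_control_points([], [], a, b)
        assert np.allclose(c, (2, 0, 0)) and np.allclose(d, (2, 0, 0))
        t = np.linspace(0, 1, 9)
        for ctrl in (c, d):
            poly = bezier_quadratic(a, ctrl, b, t)
            dist = np.linalg.norm(np.cross(poly - a, (b - a) / 4.0), axis=1)
            assert np.max(dist) < 1e-12

    def test_short_path_raises(self):
        mesh, _ = make_box_model((10, 10, 10), 5)
        with pytest.raises(NoCutError):
            build_incision(mesh, [0])


class TestRemeshIncision:
    def test_two_vertex_path_on_quad_patch(self):
        # cut along a single interior grid edge whose endpoints are both
        # interior vertices, so the slit is disjoint from the outer boundary
        mesh, vid = flat_patch(4, 3)
        path = [vid(1, 1), vid(2, 1)]
        curves = build_incision(mesh, path, samples_per_curve=6)
        cut = remesh_incision(mesh, curves)
        n_samples_inserted = 2 * (6 - 2)
        assert len(cut.vertices) == len(mesh.vertices) + n_samples_inserted
        assert len(boundary_loops(cut)) == len(boundary_loops(mesh)) + 1
        areas = _areas(cut)
        assert np.all(areas > 0)

    def test_multi_vertex_cut_on_box_top(self, box_model):
        mesh, _ = box_model
        top = np.flatnonzero((mesh.vertices[:, 2] == 20) &
                             (mesh.vertices[:, 1] == 16) &
                             (mesh.vertices[:, 0] >= 8) &
                             (mesh.vertices[:, 0] <= 32))
        path = top[np.argsort(mesh.vertices[top, 0])]
        curves = build_incision(mesh, path, samples_per_curve=16)
        cut = remesh_incision(mesh, curves)
        dups = len(path) - 2
        inserted = 2 * (16 - 2)
        assert len(cut.vertices) == len(mesh.vertices) + dups + inserted
        assert len(boundary_loops(cut)) == 1  # closed mesh gains the slit loop
        assert np.all(_areas(cut) > 0)
        # the new free boundary follows the sampled polylines in order
        be = {tuple(sorted(e)) for e in cut.boundary_edges()}
        for poly_ids in _polyline_vertex_ids(mesh, path, curves, cut):
            for u, v in zip(poly_ids[:-1], poly_ids[1:]):
                assert tuple(sorted((u, v))) in be

    def test_empty_path_identity(self, box_model):
        mesh, _ = box_model
        from meshlesscut.incision import IncisionCurves
        curves = IncisionCurves(
            A=np.zeros(3), B=np.ones(3), C=np.zeros(3), D=np.zeros(3),
            left_polyline=np.zeros((0, 3)), right_polyline=np.zeros((0, 3)),
            t_values=np.zeros(0), path_vertex_set=np.zeros(0, dtype=int),
            affected_vertex_set=np.zeros(0, dtype=int))
        cut = remesh_incision(mesh, curves)
        assert np.array_equal(cut.vertices, mesh.vertices)
        assert np.array_equal(cut.triangles, mesh.triangles)

    def test_self_intersecting_path_rejected(self, box_model):
        mesh, _ = box_model
        top = np.flatnonzero((mesh.vertices[:, 2] == 20) &
                             (mesh.vertices[:, 1] == 16))
        path = list(top[:3]) + [top[0]]
        curves_path = np.asarray(path)
        from meshlesscut.incision import IncisionCurves
        curves = IncisionCurves(
            A=mesh.vertices[path[0]], B=mesh.vertices[path[-1]] + 1.0,
            C=np.zeros(3), D=np.zeros(3),
            left_polyline=np.array([[0, 0, 0], [1, 1, 1.0]]),
            right_polyline=np.array([[0, 0, 0], [1, 1, 1.0]]),
            t_values=np.array([0.0, 1.0]), path_vertex_set=curves_path,
            affected_vertex_set=curves_path,
            surface_normal=np.array([0.0, 0, 1]))
        with pytest.raises(UnsupportedPathError):
            remesh_incision(mesh, curves)

    def test_non_incision_boundary_unchanged(self):
        mesh, vid = flat_patch(7, 5)
        outer_before = {tuple(sorted(e)) for e in mesh.boundary_edges()}
        path = [vid(i, 2) for i in range(1, 6)]
        curves = build_incision(mesh, path, samples_per_curve=8)
        cut = remesh_incision(mesh, curves)
        outer_after = {tuple(sorted(e)) for e in cut.boundary_edges()}
        assert outer_before <= outer_after  # old boundary intact; slit added
        assert len(boundary_loops(cut)) == len(boundary_loops(mesh)) + 1


def _areas(mesh):
    v, t = mesh.vertices, mesh.triangles
    return 0.5 * np.linalg.norm(
        np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]]), axis=1)


def _polyline_vertex_ids(mesh, path, curves, cut):
    """Boundary-walk oracle: recover the inserted polyline vertex chains by
    matching positions of the cut mesh's new vertices."""
    out = []
    n0 = len(mesh.vertices) + max(0, len(path) - 2)
    for poly in (curves.left_polyline, curves.right_polyline):
        ids = []
        for k, p in enumerate(poly):
            if k == 0:
                ids.append(int(path[0]))
            elif k == len(poly) - 1:
                ids.append(int(path[-1]))
            else:
                matches = np.flatnonzero(
                    np.all(np.isclose(cut.vertices[n0:], p, atol=1e-12), axis=1))
                assert len(matches) >= 1
                ids.append(int(n0 + matches[0]))
        out.append(ids)
    return out


class TestExtractPath:
    def test_straight_cut_snaps_to_lattice_row(self, box_model):
        mesh, _ = box_model
        path = extract_path(mesh, [8, 17, 20], [0, -1, 0], [8, 17, 14],
                            [0, 0, 1], t_range=(6, 34))
        pts = mesh.vertices[path]
        assert len(path) >= 5
        assert np.all(pts[:, 2] == 20)  # top face only
        assert len(np.unique(pts[:, 1])) == 1  # a single snapped row
        assert np.all(np.diff(pts[:, 0]) > 0)  # ordered along the sweep

    def test_no_intersection_gives_empty(self, box_model):
        mesh, _ = box_model
        path = extract_path(mesh, [0, 100, 0], [0, -1, 0], [0, 100, -5],
                            [0, 0, 1])
        assert len(path) == 0
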