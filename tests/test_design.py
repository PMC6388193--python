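"""Veneer CAD operators: isolation, mirroring, placement, booleans,
finishing.  Analytic solids (cubes, spheres, shells) provide the oracles."""

import numpy as np
import pytest

from veneerfit.design import (
    DesignError,
    RigidTransform,
    bevel_edges,
    boolean_subtract,
    check_thickness,
    design_veneer,
    isolate_crown,
    mirror_mesh,
    overlap_fraction,
    place_over_target,
    remove_undercuts,
    seating_sweep_clear,
)
from veneerfit.imaging import ParameterError
from veneerfit.mesh import MeshError, TriangleMesh, voxel_boolean
from veneerfit.phantoms import box_mesh

from conftest import sphere_mesh


class TestIsolateCrown:
    def test_cube_half(self, unit_cube):
        half = isolate_crown(unit_cube, (0, 0, 0.5), (0, 0, 1), pitch=0.02)
        assert half.is_watertight()
        assert half.volume() == pytest.approx(0.5, rel=0.03)

    def test_plane_below_returns_unchanged(self, unit_cube):
        out = isolate_crown(unit_cube, (0, 0, -5.0), (0, 0, 1))
        assert out is unit_cube

    def test_plane_above_raises(self, unit_cube):
        with pytest.raises(MeshError):
            isolate_crown(unit_cube, (0, 0, 5.0), (0, 0, 1))

    def test_hemisphere_volume(self, sphere5):
        hemi = isolate_crown(sphere5, (0, 0, 0), (0, 0, 1))
        assert hemi.volume() == pytest.approx(2 / 3 * np.pi * 125, rel=0.01)
        assert hemi.is_watertight()


class TestMirror:
    def test_involution(self, sphere5):
        p, n = (1.0, 2.0, 3.0), (1 / np.sqrt(2), 1 / np.sqrt(2), 0.0)
        twice = mirror_mesh(mirror_mesh(sphere5, p, n), p, n)
        np.testing.assert_allclose(twice.vertices, sphere5.vertices, atol=1e-12)
        np.testing.assert_array_equal(twice.faces, sphere5.faces)

    def test_volume_preserved(self, premolar):
        m = mirror_mesh(premolar, (0.5, 0, 0), (1, 0, 0))
        assert m.volume() == pytest.approx(premolar.volume(), rel=1e-12)

    def test_tetrahedron_oracle(self):
        # reflect across x = 1: (x, y, z) -> (2 - x, y, z)
        v = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        f = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
        tet = TriangleMesh(v, f)
        out = mirror_mesh(tet, (1.0, 0, 0), (1.0, 0, 0))
        expected = np.array([[2.0, 0, 0], [1, 0, 0], [2, 1, 0], [2, 0, 1]])
        np.testing.assert_allclose(out.vertices, expected, atol=1e-12)
        assert out.volume() == pytest.approx(tet.volume())

    def test_zero_normal(self, unit_cube):
        with pytest.raises(ParameterError):
            mirror_mesh(unit_cube, (0, 0, 0), (0, 0, 0))


class TestPlacement:
    def test_identity_for_identical_meshes(self, premolar):
        tr = place_over_target(premolar, premolar)
        np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(tr.translation, 0.0, atol=1e-9)

    def test_translation_equivariance(self, premolar):
        moved = premolar.translated([1.0, 2.0, 3.0])
        tr = place_over_target(premolar, moved)
        np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(tr.translation, [1.0, 2.0, 3.0], atol=1e-9)

    def test_explicit_mode_passthrough(self, premolar):
        user = RigidTransform(np.eye(3), [1, 1, 1])
        assert place_over_target(premolar, premolar, mode="explicit", user_transform=user) is user

    def test_degenerate_axes_warns(self, sphere5):
        with pytest.warns(UserWarning, match="near-isotropic"):
            place_over_target(sphere5, sphere5.translated([1, 0, 0]))

    def test_phantom_crown_overlap(self, incisor, premolar):
        crown = isolate_crown(incisor, (0, 0, 1.0), (0, 0, 1))
        crown = mirror_mesh(crown, (0, 0, 0), (1, 0, 0))
        tr = place_over_target(crown, premolar)
        assert overlap_fraction(crown, premolar, tr) > 0.5


class TestBooleanSubtract:
    def test_cube_minus_centered_half_cube(self, unit_cube):
        inner = box_mesh([0.25, 0.25, 0.25], [0.75, 0.75, 0.75])
        out = boolean_subtract(unit_cube, inner, pitch=0.02)
        assert out.volume() == pytest.approx(1.0 - 0.125, rel=0.02)
        assert out.is_watertight()

    def test_sphere_lens_formula(self):
        r, d = 3.0, 2.0
        a = sphere_mesh(r, pitch=0.1)
        b = sphere_mesh(r, center=(d, 0, 0), pitch=0.1)
        inter = voxel_boolean(a, b, "intersection", pitch=0.05)
        lens = np.pi * (4 * r + d) * (2 * r - d) ** 2 / 12
        assert inter.volume() == pytest.approx(lens, rel=0.01)

    def test_conservation(self):
        rng = np.random.default_rng(5)
        for _ in range(3):
            c = rng.uniform(-1.5, 1.5, 3)
            a = sphere_mesh(2.5, pitch=0.15)
            b = sphere_mesh(float(rng.uniform(1.5, 2.5)), center=c, pitch=0.15)
            d = voxel_boolean(a, b, "difference", pitch=0.06)
            i = voxel_boolean(a, b, "intersection", pitch=0.06)
            vd = 0.0 if d is None else d.volume()
            vi = 0.0 if i is None else i.volume()
            assert abs(vd + vi - a.volume()) / a.volume() < 0.005

    def test_non_watertight_named(self, unit_cube):
        broken = TriangleMesh(unit_cube.vertices, unit_cube.faces[:-1], "badmesh")
        with pytest.raises(MeshError, match="badmesh"):
            boolean_subtract(unit_cube, broken)


@pytest.fixture(scope="module")
def shell_05():
    """Spherical shell outer 5 / inner 4.5 mm (wall 0.5 mm)."""
    outer = sphere_mesh(5.0, pitch=0.1)
    inner = sphere_mesh(4.5, pitch=0.1)
    return voxel_boolean(outer, inner, "difference", pitch=0.05)


class TestThickness:
    def test_shell_median(self, shell_05):
        rep = check_thickness(shell_05, min_thickness=0.5)
        assert rep.median_mm == pytest.approx(0.5, rel=0.05)

    def test_zero_threshold_no_violation(self, shell_05):
        rep = check_thickness(shell_05, min_thickness=0.0)
        assert rep.violating_area_fraction == 0.0

    def test_thin_shell_fully_violating(self):
        outer = sphere_mesh(3.0, pitch=0.1)
        inner = sphere_mesh(2.8, pitch=0.1)
        shell = voxel_boolean(outer, inner, "difference", pitch=0.05)
        rep = check_thickness(shell, min_thickness=0.5)
        assert rep.violating_area_fraction > 0.95

    def test_open_mesh_rejected(self, unit_cube):
        broken = TriangleMesh(unit_cube.vertices, unit_cube.faces[:-1])
        with pytest.raises(MeshError):
            check_thickness(broken)

    def test_min_le_all(self, shell_05):
        rep = check_thickness(shell_05, min_thickness=0.3)
        assert rep.min_mm <= rep.per_vertex_mm.min() + 1e-12


def _cap_shell(z_cut: float) -> TriangleMesh:
    """Shell cap around a sphere r=3 (clearance 0.15, wall 0.35), kept
    above ``z_cut``."""
    outer = sphere_mesh(3.5, pitch=0.1)
    inner = sphere_mesh(3.15, pitch=0.1)
    shell = voxel_boolean(outer, inner, "difference", pitch=0.06)
    cut = box_mesh([-4, -4, z_cut], [4, 4, 4])
    return voxel_boolean(shell, cut, "intersection", pitch=0.06)


class TestUndercuts:
    def test_no_undercut_returned_unchanged(self):
        tooth = sphere_mesh(3.0, pitch=0.1)
        cap = _cap_shell(0.8)  # strictly above the equator: no undercut
        out = remove_undercuts(cap, tooth, (0, 0, 1), pitch=0.06)
        assert out is cap

    def test_constructed_undercut_fixed(self):
        tooth = sphere_mesh(3.0, pitch=0.1)
        cap = _cap_shell(-1.6)  # wraps well below the equator: undercut lobe
        assert not seating_sweep_clear(cap, tooth, (0, 0, 1), pitch=0.06)
        fixed = remove_undercuts(cap, tooth, (0, 0, 1), pitch=0.06, clearance=0.1)
        assert fixed.volume() < cap.volume()
        assert seating_sweep_clear(fixed, tooth, (0, 0, 1), pitch=0.06)

    def test_idempotent(self):
        tooth = sphere_mesh(3.0, pitch=0.1)
        cap = _cap_shell(-1.6)
        once = remove_undercuts(cap, tooth, (0, 0, 1), pitch=0.06, clearance=0.1)
        twice = remove_undercuts(once, tooth, (0, 0, 1), pitch=0.06, clearance=0.1)
        assert abs(twice.volume() - once.volume()) / once.volume() < 0.002

    def test_impossible_axis(self):
        tooth = sphere_mesh(3.0, pitch=0.1)
        cap = _cap_shell(-1.6)
        with pytest.raises(DesignError):
            remove_undercuts(cap, tooth, (0, 0, -1), pitch=0.06, max_removed_fraction=0.3)


class TestBevel:
    def test_zero_band_identity(self, unit_cube):
        assert bevel_edges(unit_cube, margin_band=0.0) is unit_cube

    def test_cube_chamfer_analytic(self, unit_cube):
        s = 0.2
        out = bevel_edges(unit_cube, margin_band=s, pitch=0.01)
        a = 1.0 - 2 * s
        analytic = a**3 + 6 * a**2 * s + 6 * a * s**2 + (4.0 / 3.0) * s**3
        assert out.volume() == pytest.approx(analytic, rel=0.02)
        assert out.is_watertight()
        assert out.volume() < unit_cube.volume()

    def test_band_too_large(self, unit_cube):
        with pytest.raises(ParameterError):
            bevel_edges(unit_cube, margin_band=0.8, pitch=0.05)

    def test_watertight_on_shell(self, shell_05):
        out = bevel_edges(shell_05, margin_band=0.1, pitch=0.05)
        assert out.is_watertight()
        assert out.volume() <= shell_05.volume() + 1e-9


@pytest.fixture(scope="module")
def design(incisor, premolar):
    return design_veneer(
        incisor,
        premolar,
        cervical_plane=((0, 0, 1.0), (0, 0, 1)),
        mirror_plane=((0, 0, 0), (1, 0, 0)),
    )


class TestFullDesign:
    def test_veneer_valid(self, design, premolar):
        assert design.veneer.is_watertight()
        assert design.veneer.volume() > 0
        inter = voxel_boolean(design.veneer, premolar, "intersection", pitch=0.05)
        iv = 0.0 if inter is None else inter.volume()
        assert iv < 1e-3 * design.veneer.volume()

    def test_veneer_contained_in_dilated_crown(self, design):
        # everything in the veneer came from the placed crown; one
        # print-layer dilation absorbs the remesh kernel's surface jitter
        from scipy import ndimage

        from veneerfit.mesh import _common_grid, voxelize

        placed = design.placement.apply(design.incisor_crown)
        pitch = 0.1
        origin, shape = _common_grid([design.veneer, placed], pitch)
        mv, _ = voxelize(design.veneer, pitch, origin=origin, shape=shape)
        mc, _ = voxelize(placed, pitch, origin=origin, shape=shape)
        grown = ndimage.distance_transform_edt(~mc) <= 2  # ~0.2 mm
        assert not (mv & ~grown).any()

    def test_sweep_passes(self, design, premolar):
        assert seating_sweep_clear(
            design.veneer, premolar, design.insertion_axis, stations=20, travel=2.0
        )

    def test_repeatable_stl_bytes(self, design, incisor, premolar, tmp_path):
        from veneerfit.mesh import write_mesh

        second = design_veneer(
            incisor,
            premolar,
            cervical_plane=((0, 0, 1.0), (0, 0, 1)),
            mirror_plane=((0, 0, 0), (1, 0, 0)),
        )
        p1, p2 = tmp_path / "a.stl", tmp_path / "b.stl"
        write_mesh(design.veneer, p1)
        write_mesh(second.veneer, p2)
        assert p1.read_bytes() == p2.read_bytes()
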