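import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from aneumorph.errors import DegenerateMaskError, UnreliableLocalShapeError
from aneumorph.meshing import VoxelMask, extract_mesh
from aneumorph.morphometry import (
    MorphometryConfig,
    analyze_mask,
    correct_shrinkage,
    curvedness,
    principal_axes,
    principal_curvatures,
    records_to_frame,
    shape_index,
    sphericity,
    summarize_morphology,
)
from aneumorph.phantoms import PhantomSpec, make_phantom

from conftest import make_sphere_mask

# closed form: (36*pi)^(1/3) / 6 for V=1, A=6
CUBE_SPHERICITY = (36.0 * np.pi) ** (1.0 / 3.0) / 6.0  # 0.805996


class TestSphericity:
    def test_perfect_sphere(self):
        r = 3.7
        assert sphericity(4 / 3 * np.pi * r**3, 4 * np.pi * r**2) == pytest.approx(1.0)

    def test_unit_cube_closed_form(self):
        assert sphericity(1.0, 6.0) == pytest.approx(CUBE_SPHERICITY, abs=1e-6)
        assert sphericity(1.0, 6.0) == pytest.approx(0.8060, abs=5e-5)

    def test_monotone_in_area(self):
        values = [sphericity(10.0, a) for a in (30.0, 40.0, 50.0)]
        assert values == sorted(values, reverse=True)

    @pytest.mark.parametrize("v,a", [(0.0, 6.0), (1.0, -1.0)])
    def test_rejects_nonpositive(self, v, a):
        with pytest.raises(ValueError):
            sphericity(v, a)


class TestPrincipalAxes:
    def test_sphere_isotropic(self, sphere_mask_r10_h05):
        _, elong, flat = principal_axes(sphere_mask_r10_h05)
        assert elong == pytest.approx(1.0, rel=0.02)
        assert flat == pytest.approx(1.0, rel=0.02)

    def test_ellipsoid_421(self):
        # uniform-ellipsoid covariance eigenvalues scale with semi-axes^2
        mask, _ = make_phantom(
            PhantomSpec(kind="ellipsoid", semi_axes_mm=(4, 2, 1), spacing=(0.1,) * 3)
        )
        lengths, elong, flat = principal_axes(mask)
        assert elong == pytest.approx(0.50, rel=0.02)
        assert flat == pytest.approx(0.25, rel=0.02)
        assert lengths[0] >= lengths[1] >= lengths[2] > 0

    def test_rotation_invariance(self):
        vals = []
        for rot in ((0, 0, 0), (35, 10, 60)):
            mask, _ = make_phantom(
                PhantomSpec(kind="ellipsoid", semi_axes_mm=(4, 2, 1),
                            spacing=(0.1,) * 3, rotation_deg=rot)
            )
            vals.append(principal_axes(mask)[1:])
        assert vals[1][0] == pytest.approx(vals[0][0], rel=0.02)
        assert vals[1][1] == pytest.approx(vals[0][1], rel=0.02)

    def test_collinear_rejected(self):
        values = np.zeros((10, 3, 3), bool)
        values[2:8, 1, 1] = True
        with pytest.raises(DegenerateMaskError):
            principal_axes(VoxelMask(values=values, spacing=(1.0,) * 3))


class TestShapeIndex:
    def test_convex_umbilic(self):
        s, valid = shape_index(0.1, 0.1)
        assert valid and s == 1.0

    def test_concave_umbilic(self):
        s, valid = shape_index(-0.1, -0.1)
        assert valid and s == -1.0

    def test_symmetric_saddle(self):
        s, valid = shape_index(0.1, -0.1)
        assert valid and s == pytest.approx(0.0)

    def test_cylinder_ridge(self):
        s, valid = shape_index(0.2, 0.0)
        assert valid and s == pytest.approx(0.5)  # (2/pi) atan(1)

    def test_planar_invalid(self):
        s, valid = shape_index(0.0, 0.0)
        assert not valid and np.isnan(s)

    @given(
        k1=hst.floats(-10, 10, allow_nan=False),
        k2=hst.floats(-10, 10, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_range_property(self, k1, k2):
        hi, lo = max(k1, k2), min(k1, k2)
        s, valid = shape_index(hi, lo)
        if valid:
            assert -1.0 <= s <= 1.0


class TestCurvedness:
    def test_sphere(self):
        assert curvedness(0.2, 0.2) == pytest.approx(0.2)

    def test_plane(self):
        assert curvedness(0.0, 0.0) == 0.0

    def test_direct_formula(self):
        assert curvedness(4.0, 3.0) == pytest.approx(np.sqrt(12.5))

    @given(
        k1=hst.floats(-50, 50, allow_nan=False),
        k2=hst.floats(-50, 50, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_nonnegative(self, k1, k2):
        assert curvedness(k1, k2) >= 0.0


class TestPrincipalCurvatures:
    def test_sphere_r10(self):
        mesh = extract_mesh(make_sphere_mask(10.0, 0.25), sigma_mm=1.0)
        field = correct_shrinkage(principal_curvatures(mesh, rings=4), 1.0)
        k1 = np.median(field.kappa1[field.valid])
        k2 = np.median(field.kappa2[field.valid])
        assert k1 == pytest.approx(0.1, rel=0.05)
        assert k2 == pytest.approx(0.1, rel=0.05)
        assert np.all(field.kappa1[field.valid] >= field.kappa2[field.valid])

    def test_cylinder_side(self):
        # capsule side: analytic curvatures (1/r, 0)
        mask, _ = make_phantom(
            PhantomSpec(kind="capsule", radius_mm=5.0, length_mm=20.0,
                        spacing=(0.25,) * 3)
        )
        mesh = extract_mesh(mask, sigma_mm=0.75)
        field = correct_shrinkage(principal_curvatures(mesh, rings=4), 0.75)
        center = mesh.vertices.mean(axis=0)
        z = mesh.vertices[:, 2] - center[2]
        side = field.valid & (np.abs(z) < 5.0)
        assert np.median(field.kappa1[side]) == pytest.approx(0.2, rel=0.05)
        assert abs(np.median(field.kappa2[side])) < 0.02

    def test_flat_plate_interior(self):
        values = np.zeros((40, 40, 12), bool)
        values[4:36, 4:36, 4:8] = True
        mesh = extract_mesh(VoxelMask(values=values, spacing=(1.0,) * 3), sigma_mm=1.0)
        field = principal_curvatures(mesh, rings=3)
        top = mesh.vertices[:, 2] > 6.9
        interior = (
            top
            & (np.abs(mesh.vertices[:, 0] - 20) < 10)
            & (np.abs(mesh.vertices[:, 1] - 20) < 10)
            & field.valid
        )
        assert np.abs(np.median(field.kappa1[interior])) < 0.02
        assert np.abs(np.median(field.kappa2[interior])) < 0.02

    def test_convergence_with_refinement(self):
        errs = []
        for h in (1.0, 0.5, 0.25):
            mesh = extract_mesh(make_sphere_mask(5.0, h), sigma_mm=2 * h)
            field = correct_shrinkage(principal_curvatures(mesh, rings=4), 2 * h)
            c = np.median(field.curvedness[field.valid])
            errs.append(abs(c / 0.2 - 1.0))
        assert errs[2] < errs[0]
        assert errs[2] <= 0.05


class TestSummarize:
    def test_sphere_record(self):
        mask, _ = make_phantom(PhantomSpec(kind="sphere", radius_mm=10.0, spacing=(0.5,) * 3))
        rec = analyze_mask(mask, MorphometryConfig(target_spacing=(0.5,) * 3))
        assert rec.sphericity >= 0.99
        assert rec.shape_index_median == pytest.approx(1.0, abs=0.05)
        assert rec.curvedness_median == pytest.approx(0.1, rel=0.05)

    def test_ellipsoid_vs_sphere(self):
        mask, _ = make_phantom(
            PhantomSpec(kind="ellipsoid", semi_axes_mm=(4, 2, 1), spacing=(0.2,) * 3)
        )
        rec = analyze_mask(
            mask,
            MorphometryConfig(target_spacing=(0.2,) * 3, field_sigma_mm=0.2,
                              curvature_sigma_mm=0.4),
        )
        assert rec.sphericity < 0.99
        assert rec.elongation == pytest.approx(0.5, rel=0.04)

    def test_bleb_lowers_sphericity(self):
        base, _ = make_phantom(PhantomSpec(kind="sphere", radius_mm=8.0, spacing=(0.5,) * 3))
        bleb, _ = make_phantom(
            PhantomSpec(kind="sphere_with_blebs", radius_mm=8.0, n_blebs=2,
                        bleb_radius_frac=0.5, spacing=(0.5,) * 3, seed=3)
        )
        cfg = MorphometryConfig(target_spacing=(0.5,) * 3)
        rec_base = analyze_mask(base, cfg)
        rec_bleb = analyze_mask(bleb, cfg)
        assert rec_bleb.sphericity < rec_base.sphericity
        assert rec_bleb.surface_area > rec_base.surface_area

    def test_too_few_valid_vertices(self, sphere_mask_r10_h05, sphere_mesh_r10_h05):
        with pytest.raises(UnreliableLocalShapeError):
            summarize_morphology(
                sphere_mesh_r10_h05, sphere_mask_r10_h05,
                min_valid_vertices=10**9,
            )

    def test_display_scaling_exact(self):
        mask, _ = make_phantom(PhantomSpec(kind="sphere", radius_mm=8.0, spacing=(0.5,) * 3))
        rec = analyze_mask(mask, MorphometryConfig(target_spacing=(0.5,) * 3))
        disp = rec.display()
        assert disp["sphericity_x100"] == 100.0 * rec.sphericity
        assert disp["shape_index_x100"] == 100.0 * rec.shape_index_median
        assert disp["curvedness_x100"] == 100.0 * rec.curvedness_median

    def test_records_frame_columns(self):
        mask, _ = make_phantom(PhantomSpec(kind="sphere", radius_mm=8.0, spacing=(0.5,) * 3))
        rec = analyze_mask(mask, MorphometryConfig(target_spacing=(0.5,) * 3))
        frame = records_to_frame({"a": rec, "b": rec})
        assert list(frame.columns)[0] == "volume_mm3"
        assert len(frame) == 2


class TestDirectionCoding:
    def test_rupture_prone_labels(self):
        from aneumorph.pipeline import annotate_direction

        # lower volume in women, CI excluding 0 -> less rupture-prone
        assert annotate_direction("volume", -0.3, -0.55, -0.06, "beta_sd") == \
            "less rupture-prone in women"
        # higher curvedness odds -> more rupture-prone
        assert annotate_direction("curvedness", 2.0, 1.2, 3.3, "OR") == \
            "more rupture-prone in women"
        # lower sphericity -> more rupture-prone
        assert annotate_direction("sphericity", -0.4, -0.6, -0.2, "beta_sd") == \
            "more rupture-prone in women"
        # lower shape index -> more rupture-prone
        assert annotate_direction("shape_index", 0.5, 0.3, 0.9, "OR") == \
            "more rupture-prone in women"
        assert annotate_direction("volume", 0.1, -0.1, 0.3, "beta_sd") == "no difference"
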