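"""Surface fitting, refraction primitives and bundle tracing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from onlenspower.conformance import conform
from onlenspower.design import LensDesignSpec, build_lens
from onlenspower.raytrace import (
    Ray,
    SurfaceFitError,
    TIRError,
    fit_surface,
    hexapolar_pupil,
    incidence_angle,
    meridian_rotation,
    power_and_epc,
    refract_direction,
    refract_ray,
    refract_vector,
    snell,
    surface_normal,
    surfaces_from_nodes,
    trace_bundle,
    trace_lens,
    trace_meridian_fan,
)


def sphere_nodes(radius: float, aperture: float, n: int = 40) -> np.ndarray:
    """Node cloud sampled from a spherical dome apexed at the origin."""
    r = np.linspace(0.0, aperture, n)
    phi = np.linspace(0.0, 2 * np.pi, 72, endpoint=False)
    rr, pp = np.meshgrid(r, phi)
    z = -(radius - np.sqrt(radius**2 - rr**2))
    return np.stack([rr * np.cos(pp), rr * np.sin(pp), z], axis=-1).reshape(-1, 3)


class TestSurfaceFit:
    def test_sphere_reproduced_within_tolerance(self):
        surf = fit_surface(sphere_nodes(8.5, 4.0), 4.0)
        x = np.linspace(-3.9, 3.9, 41)
        z_true = -(8.5 - np.sqrt(8.5**2 - x**2))
        np.testing.assert_allclose(surf(x, np.zeros_like(x)), z_true, atol=1e-5)
        assert surf.residual_rms < 1e-5

    def test_plane_fit_returns_constant_with_zero_gradient(self):
        pts = sphere_nodes(8.5, 4.0)
        pts[:, 2] = 0.37
        surf = fit_surface(pts, 4.0)
        assert surf(1.2, -0.7) == pytest.approx(0.37, abs=1e-10)
        gx, gy = surf.gradient(1.2, -0.7)
        assert abs(gx) < 1e-10 and abs(gy) < 1e-10

    def test_toric_principal_curvatures_within_tenth_percent(self):
        rx, ry = 8.0, 7.0
        r = np.linspace(0.0, 3.5, 40)
        phi = np.linspace(0, 2 * np.pi, 72, endpoint=False)
        rr, pp = np.meshgrid(r, phi)
        x, y = rr * np.cos(pp), rr * np.sin(pp)
        cx, cy = 1 / rx, 1 / ry
        num = cx * x**2 + cy * y**2  # biconic sag
        z = -num / (1 + np.sqrt(1 - cx**2 * x**2 - cy**2 * y**2))
        surf = fit_surface(np.stack([x, y, z], axis=-1).reshape(-1, 3), 3.5)
        h = 1e-4
        fxx = (surf(h, 0.0) - 2 * surf(0.0, 0.0) + surf(-h, 0.0)) / h**2
        fyy = (surf(0.0, h) - 2 * surf(0.0, 0.0) + surf(0.0, -h)) / h**2
        assert abs(fxx) == pytest.approx(cx, rel=1e-3)
        assert abs(fyy) == pytest.approx(cy, rel=1e-3)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(SurfaceFitError):
            fit_surface(np.zeros((30, 3)), 4.0)


class TestNormalsAndAngles:
    def test_plane_normal_along_axis(self):
        pts = sphere_nodes(8.5, 4.0)
        pts[:, 2] = 0.0
        surf = fit_surface(pts, 4.0)
        np.testing.assert_allclose(surface_normal(surf, [0.5, 0.5, 0.0]), [0, 0, 1], atol=1e-10)

    def test_sphere_normal_passes_through_centre(self):
        # degree 12 so the fit itself does not limit the normal accuracy
        surf = fit_surface(sphere_nodes(8.5, 4.0), 4.0, degree=12)
        p = np.array([2.0, 1.0, float(surf(2.0, 1.0))])
        n = surface_normal(surf, p)
        to_centre = np.array([0.0, 0.0, -8.5]) - p
        to_centre /= np.linalg.norm(to_centre)
        angle = np.arccos(np.clip(abs(np.dot(n, to_centre)), -1, 1))
        assert angle < 1e-8

    @pytest.mark.parametrize(
        "d, n, expected",
        [
            ([0, 0, -1], [0, 0, 1], 0.0),
            ([0, 0, -1], [np.sin(np.pi / 6), 0, np.cos(np.pi / 6)], np.pi / 6),
        ],
    )
    def test_incidence_angle(self, d, n, expected):
        assert incidence_angle(np.array(d), np.array(n)) == pytest.approx(expected, abs=1e-12)

    def test_incidence_angle_invariant_to_normal_flip(self):
        d = np.array([0.3, -0.2, -0.933])
        d /= np.linalg.norm(d)
        n = np.array([0.1, 0.2, 0.974])
        n /= np.linalg.norm(n)
        assert incidence_angle(d, n) == incidence_angle(d, -n)


class TestSnell:
    def test_normal_incidence(self):
        assert snell(0.0, 1.0, 1.5) == 0.0

    def test_thirty_degrees_into_glass(self):
        assert np.degrees(snell(np.radians(30), 1.0, 1.5)) == pytest.approx(
            19.47122063449069, abs=1e-9
        )

    def test_index_matched_media(self):
        phi = 0.4
        assert snell(phi, 1.376, 1.376) == pytest.approx(phi, abs=1e-15)

    def test_total_internal_reflection_raises(self):
        with pytest.raises(TIRError):
            snell(np.radians(80), 1.5, 1.0)


class TestMeridianRotation:
    def test_y_normal_has_meridian_angle_pi_over_two(self):
        n = np.array([0.0, 0.6, 0.8])
        theta, rot = meridian_rotation(n)
        assert theta == pytest.approx(np.pi / 2)
        assert abs((rot @ n)[1]) < 1e-14

    @given(
        nx=st.floats(-1, 1), ny=st.floats(-1, 1), nz=st.floats(0.1, 1),
    )
    def test_rotation_zeroes_y_and_is_orthonormal(self, nx, ny, nz):
        n = np.array([nx, ny, nz])
        n /= np.linalg.norm(n)
        _, rot = meridian_rotation(n)
        assert abs((rot @ n)[1]) < 1e-14
        np.testing.assert_allclose(rot @ rot.T, np.eye(3), atol=1e-14)
        v = np.array([0.3, -0.5, 0.81])
        np.testing.assert_allclose(rot.T @ (rot @ v), v, atol=1e-14)


class TestRefraction:
    @given(
        dx=st.floats(-0.5, 0.5), dy=st.floats(-0.5, 0.5),
        nx=st.floats(-0.4, 0.4), ny=st.floats(-0.4, 0.4),
        n_in=st.floats(1.0, 1.6), n_out=st.floats(1.0, 1.6),
    )
    def test_rotation_construction_matches_vector_snell(self, dx, dy, nx, ny, n_in, n_out):
        """The meridian-rotation output obeys the closed-form vector law."""
        d = np.array([dx, dy, -1.0])
        d /= np.linalg.norm(d)
        n = np.array([nx, ny, 1.0])
        n /= np.linalg.norm(n)
        try:
            out, phi_in, phi_out, _ = refract_direction(d, n, n_in, n_out)
            oracle = refract_vector(d, n, n_in, n_out)
        except TIRError:
            return
        np.testing.assert_allclose(out, oracle, atol=1e-10)
        # Snell identity holds exactly at the event
        assert n_in * np.sin(phi_in) == pytest.approx(n_out * np.sin(phi_out), abs=1e-12)
        assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-12)

    def test_normal_incidence_leaves_direction_unchanged(self):
        d = np.array([0.0, 0.0, -1.0])
        n = np.array([0.0, 0.0, 1.0])
        out, *_ = refract_direction(d, n, 1.0, 1.4)
        np.testing.assert_array_equal(out, d)

    def test_refraction_is_coplanar(self):
        d = np.array([0.2, -0.1, -0.97])
        d /= np.linalg.norm(d)
        n = np.array([0.15, 0.25, 0.96])
        n /= np.linalg.norm(n)
        out, *_ = refract_direction(d, n, 1.0, 1.39)
        assert abs(np.dot(np.cross(d, n), out)) < 1e-12

    def test_meridional_ray_stays_meridional_on_symmetric_surface(self):
        surf = fit_surface(sphere_nodes(8.5, 4.0), 4.0)
        ray = Ray(origin=[1.5, 0.0, 5.0], direction=[0.0, 0.0, -1.0])
        refracted, event = refract_ray(ray, surf, 1.0, 1.39)
        assert abs(refracted.direction[1]) < 1e-12
        assert abs(event.normal[1]) < 1e-10


class TestBundles:
    def test_hexapolar_count(self):
        assert hexapolar_pupil(1.5, 6).shape == (127, 2)

    def test_plano_lens_traces_to_zero_power(self, h64):
        lens = build_lens(
            LensDesignSpec(sph=0.0, refractive_index=h64.refractive_index, ballast=False)
        )
        res = trace_lens(lens, h64.refractive_index, pupil_semi_aperture=1.0)
        assert abs(res.power_slope) < 0.05
        assert res.focal_length == np.inf or abs(res.focal_length) > 1e4

    def test_plus_five_matches_design_power(self, plus5_lens, h64):
        res = trace_lens(plus5_lens, h64.refractive_index, pupil_semi_aperture=1.0)
        assert res.power_slope == pytest.approx(5.0, abs=0.05)
        assert res.dropped == 0

    def test_crossing_spread_scales_as_pupil_squared(self, plus5_lens, h64):
        s_small = trace_lens(plus5_lens, h64.refractive_index, pupil_semi_aperture=0.75).crossing_spread
        s_large = trace_lens(plus5_lens, h64.refractive_index, pupil_semi_aperture=1.5).crossing_spread
        assert 3.2 < s_large / s_small < 5.2

    def test_crossing_power_is_back_vertex_like(self, plus5_lens, h64):
        # focal distance measured from the back apex exceeds the
        # equivalent-power estimate for a plus lens (principal plane
        # sits behind the back vertex)
        res = trace_lens(plus5_lens, h64.refractive_index, pupil_semi_aperture=1.0)
        assert res.power_crossing > res.power_slope

    def test_toric_meridian_fans_bracket_mean_power(self, h64):
        lens = build_lens(
            LensDesignSpec(sph=0.0, cyl=6.0, cyl_axis=90.0,
                           refractive_index=h64.refractive_index)
        )
        front, back = surfaces_from_nodes(lens.front_nodes_3d(), lens.back_nodes_3d())
        p_axis = trace_meridian_fan(front, back, h64.refractive_index, 90.0, 1.0)
        p_cross = trace_meridian_fan(front, back, h64.refractive_index, 0.0, 1.0)
        p_mean = trace_bundle(front, back, h64.refractive_index, 1.0).power_slope
        assert p_cross - 0.05 <= p_mean <= p_axis + 0.05
        assert p_axis == pytest.approx(6.0, abs=0.1)
        assert p_cross == pytest.approx(0.0, abs=0.1)

    def test_exit_rays_unit_norm_and_forward(self, plus5_lens, h64):
        res = trace_lens(plus5_lens, h64.refractive_index)
        norms = np.linalg.norm(res.exit_dirs, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)
        assert np.all(res.exit_dirs[:, 2] < 0)  # still travelling down the axis


class TestEPC:
    def test_identity_epc_is_zero(self, plus5_lens, h64):
        res = trace_lens(plus5_lens, h64.refractive_index)
        out = power_and_epc(res, res.power_slope)
        assert out.epc == 0.0
        assert out.ray_count == 127

    def test_epc_matches_paraxial_oracle_on_conformed_radii(self, cornea, h64):
        """Thick-lens power computed from the conformed apex curvatures
        predicts the traced EPC of a lens steepened from an 8.5 mm base
        curve onto the 43.7 D cornea (sign and magnitude)."""
        from onlenspower.design import thick_lens_power

        lens = build_lens(LensDesignSpec(sph=5.0, refractive_index=h64.refractive_index))
        conf = conform(lens, cornea, h64)
        base = trace_lens(lens, h64.refractive_index)
        after = trace_lens(conf, h64.refractive_index)
        epc = after.power_slope - base.power_slope

        def apex_thick_lens_power(obj):
            front, back = surfaces_from_nodes(obj.front_nodes_3d(), obj.back_nodes_3d())
            h = 1e-3

            def fxx(s):
                return (s(h, 0.0) - 2 * s(0.0, 0.0) + s(-h, 0.0)) / h**2

            cf, cb = -fxx(front), -fxx(back)
            tc = front(0.0, 0.0) - back(0.0, 0.0)
            return thick_lens_power(1.0 / cf, 1.0 / cb, tc, h64.refractive_index)

        predicted = apex_thick_lens_power(conf) - apex_thick_lens_power(lens)
        assert np.sign(epc) == np.sign(predicted)
        assert epc == pytest.approx(predicted, abs=0.02)
        assert epc < 0  # steepening onto the cornea lowers the power
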