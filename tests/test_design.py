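"""Tri-curve lens geometry: zones, power profile, front surface, thickness."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from onlenspower.design import (
    BackSurface,
    GeometryError,
    LensDesignSpec,
    apply_ballast,
    back_sag,
    ballast_thickness,
    build_lens,
    enforce_min_thickness,
    front_radius,
    front_sag,
    power_profile,
    read_lens_csv,
    thick_lens_power,
    write_lens_csv,
    write_lens_obj,
    zone_centres,
    zone_radii,
)

N_H64 = 1.3920


class TestBackSurface:
    @pytest.mark.parametrize("bc, expected", [(8.5, (8.5, 10.5, 6.5)), (9.0, (9.0, 11.0, 7.0))])
    def test_zone_radii_from_base_curve(self, bc, expected):
        assert zone_radii(bc) == expected

    def test_small_base_curve_rejected(self):
        with pytest.raises(GeometryError):
            zone_radii(2.0)

    def test_optic_zone_centre_is_minus_base_curve(self):
        zc = zone_centres(zone_radii(8.5), d1=8.0, d2=11.0)
        assert zc[0] == -8.5

    @given(
        bc=st.floats(8.2, 9.5),
        d1=st.floats(6.0, 9.0),
    )
    def test_sag_continuous_at_zone_joins(self, bc, d1):
        d2 = (d1 + 14.0) / 2.0
        r1, r2, r3 = zone_radii(bc)
        zc1, zc2, zc3 = zone_centres((r1, r2, r3), d1, d2)
        # evaluate both branch formulas at each join
        x1 = d1 / 2.0
        jump1 = (zc1 + np.sqrt(r1**2 - x1**2)) - (zc2 + np.sqrt(r2**2 - x1**2))
        assert abs(jump1) < 1e-9
        x2 = d2 / 2.0
        jump2 = (zc2 + np.sqrt(r2**2 - x2**2)) - (zc3 + np.sqrt(r3**2 - x2**2))
        assert abs(jump2) < 1e-9

    def test_sag_values_and_domain(self):
        surf = BackSurface.design(8.5, 8.0, 11.0, 7.0)
        assert back_sag(0.0, surf) == 0.0
        # optic zone hand value: -8.5 + sqrt(8.5^2 - 16) = -1.0
        assert back_sag(4.0, surf) == pytest.approx(-1.0, abs=1e-12)
        with pytest.raises(GeometryError):
            back_sag(7.5, surf)

    def test_sag_monotone_decreasing(self):
        surf = BackSurface.design(8.5, 8.0, 11.0, 7.25)
        x = np.linspace(0.0, 7.25, 400)
        z = surf.sag(x)
        assert np.all(np.diff(z) < 0)

    def test_peripheral_arc_continues_tangentially_past_its_equator(self):
        # R3b = 6.5 mm < D/2 = 7.25 mm: the off-axis continuation must
        # cover the aperture and stay C1 at the d2/2 join
        surf = BackSurface.design(8.5, 8.0, 11.0, 7.25)
        assert surf.xc3 > 0
        x2 = 11.0 / 2.0
        h = 1e-6
        left = (surf.sag(x2) - surf.sag(x2 - h)) / h
        right = (surf.sag(x2 + h) - surf.sag(x2)) / h
        assert left == pytest.approx(right, abs=1e-4)

    def test_rotational_symmetry_of_back_surface(self, plus5_lens):
        # one shared zb row regardless of meridian
        nodes = plus5_lens.back_nodes_3d()
        assert np.ptp(nodes[..., 2], axis=0).max() == 0.0


class TestPowerProfile:
    def test_pure_sphere_profile_is_constant(self):
        pp = power_profile(-4.0, 0.0)
        assert np.all(pp.power == -4.0)
        assert pp.p_amp == 0.0

    def test_sphero_cylinder_extremes(self):
        pp = power_profile(-3.0, -1.0)
        assert (pp.p_max, pp.p_min) == (-3.0, -4.0)
        assert pp.p_mean == -3.5
        assert pp.p_amp == 0.5

    def test_axis_90_puts_maxima_at_90_and_270(self):
        pp = power_profile(-3.0, -1.0, cyl_axis=90.0)
        peaks = np.where(pp.power == pp.power.max())[0]
        assert set(peaks) == {90, 270}

    def test_period_is_180_degrees(self):
        pp = power_profile(2.0, 3.0, cyl_axis=30.0)
        np.testing.assert_allclose(pp.power, np.roll(pp.power, 180), atol=1e-12)

    def test_fractional_axis_interpolated_on_circle(self):
        pp = power_profile(-3.0, -1.0, cyl_axis=45.5)
        k = int(np.argmax(pp.power))
        assert abs(pp.meridians_deg[k] - 45.5) <= 0.5
        assert pp.power.max() == pytest.approx(pp.p_max, abs=1e-3)
        assert pp.power.min() >= pp.p_min - 1e-3


class TestFrontSurface:
    def test_zero_power_front_radius(self):
        # Rf = R1b + Tc (n-1)/n at zero power
        rf = front_radius(0.0, N_H64, 0.25, 8.5)
        assert rf == pytest.approx(8.570402298850574, abs=1e-12)
        assert rf == pytest.approx(8.5 + 0.25 * (N_H64 - 1) / N_H64, abs=1e-12)

    @pytest.mark.parametrize("p", [-20.0, -10.0, -3.0, 0.0, 5.0, 12.0, 20.0])
    def test_thick_lens_oracle_inverts_front_radius(self, p):
        """The standard thick-lens power of (Rf, R1b, Tc, n) returns P."""
        rf = front_radius(p, N_H64, 0.25, 8.5)
        assert thick_lens_power(rf, 8.5, 0.25, N_H64) == pytest.approx(p, abs=0.02)

    def test_front_radius_monotone_and_continuous_over_sweep_range(self):
        p = np.linspace(-10.0, 20.0, 601)
        rf = front_radius(p, N_H64, 0.25, 8.5)
        assert np.all(np.isfinite(rf))
        assert np.all(np.diff(rf) < 0)  # steeper front for higher power

    def test_singular_power_rejected(self):
        p_sing = -1000.0 * (N_H64 - 1.0) / 8.5
        with pytest.raises(GeometryError):
            front_radius(p_sing, N_H64, 0.25, 8.5)

    def test_front_sag_apex_and_sphere_limit(self):
        assert front_sag(0.0, 8.57, 0.25, 0.75) == 0.25
        x = np.linspace(0, 3, 10)
        spherical = front_sag(x, 8.57, 0.25, 1.0)
        np.testing.assert_allclose(
            spherical, 0.25 - (8.57 - np.sqrt(8.57**2 - x**2)), atol=1e-14
        )

    def test_front_sag_hand_value_shape_factor_075(self):
        rf = front_radius(0.0, N_H64, 0.25, 8.5)
        assert front_sag(3.0, rf, 0.25, 0.75) == pytest.approx(
            -0.287714101375966, abs=1e-12
        )

    def test_front_sag_domain_error(self):
        with pytest.raises(GeometryError):
            front_sag(8.0, 6.0, 0.25, 0.75)


class TestBallast:
    @pytest.mark.parametrize(
        "theta, factor",
        [(0.0, 1.0), (np.pi / 2, 0.8), (3 * np.pi / 2, 2.0), (np.pi, 1.0)],
    )
    def test_thickness_law(self, theta, factor):
        assert ballast_thickness(0.25, theta) == pytest.approx(0.25 * factor, abs=1e-12)

    def test_lower_half_thicker_than_upper_at_periphery(self, h64):
        lens = build_lens(
            LensDesignSpec(sph=0.0, refractive_index=h64.refractive_index, ballast=True)
        )
        t = lens.thickness
        lower = lens.meridians_deg == 270.0
        upper = lens.meridians_deg == 90.0
        edge = -1
        assert t[lower, edge][0] > t[upper, edge][0]

    def test_apex_single_valued_and_optic_zone_untouched(self, h64):
        with_b = build_lens(LensDesignSpec(sph=2.0, refractive_index=h64.refractive_index, ballast=True))
        without = build_lens(LensDesignSpec(sph=2.0, refractive_index=h64.refractive_index, ballast=False))
        assert np.ptp(with_b.zf[:, 0]) == 0.0
        inside = with_b.x <= with_b.spec.optic_zone_diameter / 2.0
        np.testing.assert_allclose(with_b.zf[:, inside], without.zf[:, inside], atol=1e-12)


class TestThicknessIteration:
    def test_compliant_lens_returned_unchanged(self, small_lens):
        out = enforce_min_thickness(small_lens)
        assert out is small_lens

    def test_literal_mode_preserves_front_radii_and_raises_tc(self, h64):
        spec = LensDesignSpec(
            sph=20.0, refractive_index=h64.refractive_index,
            recompute_front_on_thicken=False, n_meridians=90, n_radial=61,
        )
        lens = build_lens(spec)
        reference = front_radius(
            lens.power.power, h64.refractive_index, spec.central_thickness, 8.5
        )
        np.testing.assert_allclose(lens.front_radii, reference, rtol=1e-12)
        assert lens.final_tc > spec.central_thickness
        assert lens.thickness.min() >= 0.1 - 1e-12

    def test_literal_mode_is_idempotent(self, h64):
        lens = build_lens(
            LensDesignSpec(
                sph=20.0, refractive_index=h64.refractive_index,
                recompute_front_on_thicken=False, n_meridians=90, n_radial=61,
            )
        )
        again = enforce_min_thickness(lens)
        assert again.final_tc == lens.final_tc
        np.testing.assert_array_equal(again.zf, lens.zf)

    def test_power_preserving_mode_thickens_in_steps(self, h64):
        spec = LensDesignSpec(sph=20.0, refractive_index=h64.refractive_index,
                              n_meridians=90, n_radial=61)
        lens = build_lens(spec)
        assert lens.final_tc > spec.central_thickness
        steps = round((lens.final_tc - spec.central_thickness) / 0.01)
        assert lens.final_tc == pytest.approx(spec.central_thickness + steps * 0.01)
        assert lens.thickness.min() >= 0.1 - 1e-12
        # the re-solved front still delivers the nominal power
        p = thick_lens_power(lens.front_radii[0], 8.5, lens.final_tc, h64.refractive_index)
        assert p == pytest.approx(20.0, abs=1e-9)


class TestBuildLens:
    def test_paraxial_consistency_across_meridians(self, toric_lens, h64):
        """Thick-lens power of each meridian's front radius matches its P0."""
        p = thick_lens_power(
            toric_lens.front_radii, 8.5, toric_lens.final_tc, h64.refractive_index
        )
        np.testing.assert_allclose(p, toric_lens.power.power, atol=0.05)

    def test_spherical_lens_front_is_meridian_independent(self, h64):
        lens = build_lens(
            LensDesignSpec(sph=4.0, refractive_index=h64.refractive_index, ballast=False)
        )
        assert np.ptp(lens.zf, axis=0).max() < 1e-10

    def test_toric_front_breaks_symmetry_back_keeps_it(self, toric_lens):
        assert np.ptp(toric_lens.zf, axis=0).max() > 1e-3
        assert toric_lens.zb.ndim == 1  # back shared across meridians

    @pytest.mark.parametrize("sph", [-10.0, 0.0, 20.0])
    @pytest.mark.parametrize("diameter", [13.5, 14.0, 14.5])
    def test_sweep_extremes_yield_valid_geometry(self, sph, diameter, h64):
        lens = build_lens(
            LensDesignSpec(
                sph=sph, diameter=diameter, refractive_index=h64.refractive_index,
                n_meridians=90, n_radial=61,
            )
        )
        assert lens.thickness.min() >= 0.1 - 1e-12
        assert np.all(np.isfinite(lens.zf))
        assert lens.zf[0, 0] == pytest.approx(lens.final_tc)

    def test_bad_spec_rejected(self):
        with pytest.raises(GeometryError):
            LensDesignSpec(optic_zone_diameter=15.0)
        with pytest.raises(GeometryError):
            LensDesignSpec(shape_factor=0.0)


class TestDesignIO:
    def test_csv_roundtrip(self, tmp_path, small_lens):
        p = tmp_path / "lens.csv"
        write_lens_csv(small_lens, p)
        df = read_lens_csv(p)
        assert len(df) == small_lens.meridians_deg.size * small_lens.x.size
        np.testing.assert_allclose(
            df["Zf_mm"].to_numpy().reshape(small_lens.zf.shape), small_lens.zf, rtol=1e-6
        )

    def test_obj_export_writes_triangles(self, tmp_path, small_lens):
        p = tmp_path / "lens.obj"
        write_lens_obj(small_lens, p)
        text = p.read_text()
        assert text.count("v ") == small_lens.meridians_deg.size * small_lens.x.size
        assert "f " in text
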