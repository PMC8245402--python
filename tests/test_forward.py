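"""Forward-model physics: closed-form identities and independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdnirs.forward import (
    C_LIGHT_CM_PER_NS,
    LayeredMedium,
    OpticalProperties,
    ReflectanceCurve,
    TimeGrid,
    convolve_with_irf,
    internal_reflection_parameter,
    td_reflectance_semi_infinite,
    td_reflectance_two_layer,
)

RHO = 3.0


def cw_reflectance(rho, props):
    """Steady-state semi-infinite reflectance (independent closed form):
    the time integral of the extrapolated-boundary pulse response."""
    D = props.diffusion_coefficient
    mu_eff = np.sqrt(3.0 * props.mu_a * props.mu_sp)
    z0 = 1.0 / props.mu_sp
    zb = 2.0 * internal_reflection_parameter(props.n) * D
    out = 0.0
    for z in (z0, z0 + 2.0 * zb):
        r = np.hypot(rho, z)
        out += z * (mu_eff + 1.0 / r) * np.exp(-mu_eff * r) / r**2
    return out / (4.0 * np.pi)


class TestSemiInfinite:
    def test_causality_and_positivity(self, grid, norm_props):
        r = td_reflectance_semi_infinite(RHO, grid, norm_props)
        assert r.value[grid.t == 0] == 0.0
        assert np.all(r.value[grid.t > 0] > 0)

    def test_single_peak(self, grid, norm_props):
        v = td_reflectance_semi_infinite(RHO, grid, norm_props).value
        d = np.diff(v[grid.t > 0])
        sign_changes = np.sum(np.diff(np.sign(d[d != 0])) != 0)
        assert sign_changes == 1

    def test_beer_lambert_ratio_frozen_value(self, grid, norm_props):
        """mu_a + 0.01/cm at t = 1 ns, n = 1.4: ratio exp(-0.2141) ~ 0.8072."""
        shifted = OpticalProperties(
            norm_props.mu_a + 0.01, norm_props.mu_sp, norm_props.n
        )
        r0 = td_reflectance_semi_infinite(RHO, grid, norm_props)
        r1 = td_reflectance_semi_infinite(RHO, grid, shifted)
        i = int(np.argmin(np.abs(grid.t - 1.0)))
        v = C_LIGHT_CM_PER_NS / 1.4
        assert np.isclose(0.01 * v * 1.0, 0.21414, atol=1e-5)
        assert np.isclose(r1.value[i] / r0.value[i], np.exp(-0.21414), rtol=1e-4)
        assert np.isclose(r1.value[i] / r0.value[i], 0.8072, atol=2e-4)

    def test_time_integral_equals_cw(self, norm_props):
        """Quadrature of the pulse response vs the steady-state closed form."""
        fine = TimeGrid.regular(60000, 0.002)
        r = td_reflectance_semi_infinite(RHO, fine, norm_props)
        assert np.isclose(r.area, cw_reflectance(RHO, norm_props), rtol=1e-4)

    def test_monotone_in_absorption(self, grid, norm_props):
        lo = td_reflectance_semi_infinite(RHO, grid, norm_props).value
        hi = td_reflectance_semi_infinite(
            RHO, grid, OpticalProperties(0.20, 10.0, 1.4)
        ).value
        pos = grid.t > 0
        assert np.all(hi[pos] < lo[pos])

    def test_invalid_rho(self, grid, norm_props):
        with pytest.raises(ValueError):
            td_reflectance_semi_infinite(0.0, grid, norm_props)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        mu_a=st.floats(0.05, 0.3),
        mu_sp=st.floats(5.0, 15.0),
        delta=st.floats(1e-3, 0.05),
        t_idx=st.integers(50, 4000),
    )
    def test_beer_lambert_scaling_property(self, mu_a, mu_sp, delta, t_idx):
        """R(t; mu_a+d) = R(t; mu_a) exp(-d v t), exactly, for any inputs."""
        g = TimeGrid.regular(4096, 0.010)
        p0 = OpticalProperties(mu_a, mu_sp, 1.4)
        p1 = OpticalProperties(mu_a + delta, mu_sp, 1.4)
        r0 = td_reflectance_semi_infinite(RHO, g, p0).value[t_idx]
        r1 = td_reflectance_semi_infinite(RHO, g, p1).value[t_idx]
        t = g.t[t_idx]
        if r0 > 1e-300:
            assert np.isclose(r1 / r0, np.exp(-delta * p0.v * t), rtol=1e-9)


class TestTwoLayer:
    def test_homogeneous_limit(self, grid, norm_props):
        """Equal layer properties reduce to the semi-infinite solution."""
        med = LayeredMedium(
            norm_props, OpticalProperties(0.15, 10.0, 1.4), 0.5
        )
        two = td_reflectance_two_layer(RHO, grid, med).value
        ref = td_reflectance_semi_infinite(RHO, grid, norm_props).value
        mask = ref > 1e-6 * ref.max()
        assert np.max(np.abs(two[mask] - ref[mask]) / ref[mask]) <= 5e-3

    def test_global_beer_lambert_scaling(self, grid, hetero_medium, hetero_curve):
        """Equal absorption added to BOTH layers rescales by exp(-d v t)."""
        d = 0.02
        med = LayeredMedium(
            OpticalProperties(
                hetero_medium.top.mu_a + d, hetero_medium.top.mu_sp, 1.4
            ),
            OpticalProperties(
                hetero_medium.bottom.mu_a + d, hetero_medium.bottom.mu_sp, 1.4
            ),
            hetero_medium.top_thickness,
        )
        shifted = td_reflectance_two_layer(RHO, grid, med).value
        expected = hetero_curve.value * np.exp(-d * hetero_medium.v * grid.t)
        mask = hetero_curve.value > 1e-6 * hetero_curve.value.max()
        assert np.allclose(shifted[mask], expected[mask], rtol=5e-3)

    def test_deep_absorber_attenuation_monotone(self, grid, hetero_medium, hetero_curve):
        """Extra bottom-layer absorption attenuates late photons more:
        -ln(R'/R) non-decreasing in t (dense-grid oracle)."""
        med = LayeredMedium(
            hetero_medium.top,
            OpticalProperties(
                hetero_medium.bottom.mu_a + 0.01, hetero_medium.bottom.mu_sp, 1.4
            ),
            hetero_medium.top_thickness,
        )
        pert = td_reflectance_two_layer(RHO, grid, med).value
        mask = hetero_curve.value > 1e-6 * hetero_curve.value.max()
        att = -np.log(pert[mask] / hetero_curve.value[mask])
        assert np.all(np.diff(att) > -1e-4)
        assert att[-1] > att[0]

    def test_monotone_in_either_absorption(self, grid, hetero_medium, hetero_curve):
        mask = hetero_curve.value > 1e-9 * hetero_curve.value.max()
        for layer in ("top", "bottom"):
            top, bottom = hetero_medium.top, hetero_medium.bottom
            if layer == "top":
                top = OpticalProperties(top.mu_a + 0.02, top.mu_sp, 1.4)
            else:
                bottom = OpticalProperties(bottom.mu_a + 0.02, bottom.mu_sp, 1.4)
            pert = td_reflectance_two_layer(
                RHO, grid, LayeredMedium(top, bottom, 0.5)
            ).value
            assert np.all(pert[mask] < hetero_curve.value[mask])

    def test_invalid_medium(self, norm_props):
        with pytest.raises(ValueError):
            LayeredMedium(norm_props, norm_props, 0.0)
        with pytest.raises(ValueError):
            # source depth 1/mu_sp must sit inside the top layer
            LayeredMedium(norm_props, norm_props, 0.05)
        with pytest.raises(ValueError):
            LayeredMedium(
                norm_props, OpticalProperties(0.1, 10.0, 1.5), 0.5
            )


class TestPartialPathlengths:
    def test_sum_identity(self, grid, hetero_medium, hetero_pathlengths):
        """l_top + l_bottom = v t: total pathlength fixed by time of flight."""
        l_top, l_bottom = hetero_pathlengths
        sel = (grid.t >= 0.2) & (grid.t <= 4.0)
        vt = hetero_medium.v * grid.t[sel]
        assert np.max(np.abs((l_top + l_bottom)[sel] - vt) / vt) <= 0.01

    def test_early_photons_stay_superficial(self, grid, hetero_pathlengths):
        _, l_bottom = hetero_pathlengths
        early = (grid.t > 0) & (grid.t <= 0.05)
        assert np.all(l_bottom[early] <= 0.2)

    def test_non_negative(self, hetero_pathlengths):
        l_top, l_bottom = hetero_pathlengths
        assert np.all(l_top >= 0) and np.all(l_bottom >= 0)

    @pytest.mark.parametrize("layer", ["top", "bottom"])
    def test_matches_finite_difference_oracle(
        self, grid, hetero_medium, hetero_curve, hetero_pathlengths, layer
    ):
        """Central finite differences of -ln R at step 1e-4/cm."""
        h = 1e-4
        curves = {}
        for s in (+1, -1):
            top, bottom = hetero_medium.top, hetero_medium.bottom
            if layer == "top":
                top = OpticalProperties(top.mu_a + s * h, top.mu_sp, 1.4)
            else:
                bottom = OpticalProperties(bottom.mu_a + s * h, bottom.mu_sp, 1.4)
            curves[s] = td_reflectance_two_layer(
                RHO, grid, LayeredMedium(top, bottom, 0.5)
            ).value
        l = hetero_pathlengths[0 if layer == "top" else 1]
        sel = (
            (grid.t >= 0.2)
            & (grid.t <= 4.0)
            & (hetero_curve.value > 1e-9 * hetero_curve.value.max())
            & (l > 0.1)
        )
        fd = -(np.log(curves[+1][sel]) - np.log(curves[-1][sel])) / (2 * h)
        assert np.max(np.abs(l[sel] - fd) / fd) <= 0.01


class TestConvolution:
    def test_delta_identity(self, grid, norm_props):
        r = td_reflectance_semi_infinite(RHO, grid, norm_props)
        delta = np.zeros(len(grid))
        delta[0] = 1.0
        out = convolve_with_irf(r, ReflectanceCurve(grid, delta))
        assert np.array_equal(out.value, r.value)

    def test_area_conservation(self, rng):
        g = TimeGrid.regular(256, 0.010)
        model = np.zeros(256)
        model[:100] = rng.random(100)
        irf = np.zeros(256)
        irf[:50] = rng.random(50)
        out = convolve_with_irf(
            ReflectanceCurve(g, model), ReflectanceCurve(g, irf)
        )
        assert np.isclose(
            out.value.sum(), model.sum() * irf.sum(), rtol=1e-12
        )

    def test_matches_bruteforce_double_loop(self, rng):
        g = TimeGrid.regular(64, 0.010)
        a, b = rng.random(64), rng.random(64)
        out = convolve_with_irf(
            ReflectanceCurve(g, a), ReflectanceCurve(g, b)
        ).value
        brute = np.zeros(64)
        for m in range(64):
            for k in range(m + 1):
                brute[m] += a[k] * b[m - k]
        assert np.allclose(out, brute, rtol=1e-12, atol=1e-15)

    def test_mismatched_bin_widths(self, grid, norm_props):
        r = td_reflectance_semi_infinite(RHO, grid, norm_props)
        other = ReflectanceCurve(TimeGrid.regular(64, 0.020), np.ones(64))
        with pytest.raises(ValueError):
            convolve_with_irf(r, other)


class TestTypes:
    def test_optical_properties_validation(self):
        with pytest.raises(ValueError):
            OpticalProperties(-0.1, 10.0)
        with pytest.raises(ValueError):
            OpticalProperties(0.1, 0.0)
        with pytest.raises(ValueError):
            OpticalProperties(0.1, 10.0, 0.9)
        with pytest.warns(UserWarning):
            OpticalProperties(1.5, 10.0)  # diffusion validity warning

    def test_time_grid_validation(self):
        with pytest.raises(ValueError):
            TimeGrid(np.array([0.0, 0.01, 0.03]), 0.01)
        with pytest.raises(ValueError):
            TimeGrid(np.array([-0.01, 0.0]), 0.01)

    def test_reflectance_curve_non_negative(self, grid):
        v = np.zeros(len(grid))
        v[5] = -1.0
        with pytest.raises(ValueError):
            ReflectanceCurve(grid, v)
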