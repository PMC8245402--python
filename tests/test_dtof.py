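"""DTOF processing: baseline fitting, quality gates, gating, inversion."""

import numpy as np
import pytest

from tdnirs.chromophores import absorption_matrix
from tdnirs.dtof import (
    BaselineFit,
    DTOFHistogram,
    default_gates,
    fit_baseline_optical_properties,
    gate_pathlength_matrix,
    invert_layered_mua,
    mbll_concentrations,
    process_recording,
    quality_check,
    time_gated_attenuation,
)
from tdnirs.forward import OpticalProperties, TimeGrid
from tdnirs.simulate import (
    canonical_hrf,
    delta_irf,
    make_irf,
    make_protocol,
    simulate_homogeneous_dtof,
    synthesize_dtof_stack,
)

RHO = 3.0
WLS = (687.0, 826.0)


def _fit(grid, props=OpticalProperties(0.13, 9.9, 1.4), irf=None, counts=1e7, rng=None):
    irf = irf if irf is not None else delta_irf(grid)
    dtof = simulate_homogeneous_dtof(props, RHO, grid, irf, counts, rng)
    return fit_baseline_optical_properties(
        DTOFHistogram(grid, dtof), DTOFHistogram(grid, irf.value), RHO
    )


class TestBaselineFit:
    def test_noiseless_delta_irf_recovery(self, grid):
        """Parameter recovery at the glaucoma-group baseline values."""
        fit = _fit(grid)
        assert abs(fit.props.mu_a - 0.13) / 0.13 < 0.02
        assert abs(fit.props.mu_sp - 9.9) / 9.9 < 0.02

    def test_noisy_realistic_irf_recovery(self, grid, rng):
        fit = _fit(grid, irf=make_irf(grid), counts=1e6, rng=rng)
        assert abs(fit.props.mu_a - 0.13) / 0.13 < 0.05
        assert abs(fit.props.mu_sp - 9.9) / 9.9 < 0.05
        assert fit.chi2_red < 2.0

    def test_empty_histogram_is_an_error(self, grid):
        empty = DTOFHistogram(grid, np.zeros(len(grid)))
        irf = DTOFHistogram(grid, delta_irf(grid).value)
        with pytest.raises(ValueError):
            fit_baseline_optical_properties(empty, irf, RHO)

    def test_mismatched_bins_rejected(self, grid):
        other = TimeGrid.regular(64, 0.020)
        with pytest.raises(ValueError):
            fit_baseline_optical_properties(
                DTOFHistogram(grid, np.ones(len(grid))),
                DTOFHistogram(other, np.ones(64)),
                RHO,
            )


class TestQualityGates:
    def _fit_with(self, counts, chi2):
        return BaselineFit(
            props=OpticalProperties(0.15, 10.0),
            amplitude=1.0,
            chi2_red=chi2,
            total_counts=counts,
            fit_range_ns=(0.5, 3.0),
            n_points=200,
            converged=True,
        )

    def test_boundary_semantics(self):
        """Counts strictly above 150 k and chi2 at most 2."""
        assert quality_check(self._fit_with(150001, 1.9)).passed
        v = quality_check(self._fit_with(149999, 1.0))
        assert not v.passed and v.reasons == ["low_counts"]
        v = quality_check(self._fit_with(1_000_000, 2.0001))
        assert not v.passed and v.reasons == ["bad_fit"]
        assert quality_check(self._fit_with(150001, 2.0)).passed
        assert not quality_check(self._fit_with(150000, 1.0)).passed

    def test_both_gates_can_fail(self):
        v = quality_check(self._fit_with(1000, 5.0))
        assert v.reasons == ["low_counts", "bad_fit"]


class TestTimeGatedAttenuation:
    def test_equal_to_baseline_gives_zero(self, grid):
        series = np.tile(np.linspace(1, 100, len(grid)), (40, 1))
        gates = default_gates(1.0)
        da = time_gated_attenuation(series, grid, gates, baseline_samples=30)
        assert np.allclose(da, 0.0)

    def test_halved_counts_give_ln2(self, grid):
        series = np.tile(np.full(len(grid), 10.0), (40, 1))
        series[30:] /= 2.0
        da = time_gated_attenuation(
            series, grid, [(0.5, 1.5), (2.0, 3.0)], baseline_samples=30
        )
        assert np.allclose(da[:, 30:], np.log(2.0), rtol=1e-12)

    def test_zero_counts_masked_not_propagated(self, grid):
        series = np.tile(np.full(len(grid), 5.0), (35, 1))
        series[32] = 0.0
        with pytest.warns(UserWarning, match="masked"):
            da = time_gated_attenuation(
                series, grid, [(0.5, 1.5), (2.0, 3.0)], baseline_samples=30
            )
        assert np.isnan(da[:, 32]).all()
        assert np.isfinite(da[:, 33]).all()

    def test_needs_two_gates(self, grid):
        with pytest.raises(ValueError):
            time_gated_attenuation(
                np.ones((10, len(grid))), grid, [(0.5, 1.5)], 5
            )


class TestLayeredInversion:
    def test_identity_matrix_passthrough(self, rng):
        da = rng.standard_normal((2, 7))
        top, deep, cond = invert_layered_mua(da, np.eye(2))
        assert np.allclose(np.vstack([top, deep]), da)
        assert np.isclose(cond, 1.0)

    def test_zero_attenuation_gives_zero(self):
        top, deep, _ = invert_layered_mua(np.zeros((2, 5)), np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert np.allclose(top, 0) and np.allclose(deep, 0)

    def test_condition_number_guard(self):
        L = np.array([[1.0, 1.0], [1.0, 1.0000001]])
        with pytest.raises(ValueError, match="condition"):
            invert_layered_mua(np.zeros((2, 3)), L)

    def test_overdetermined_weighted_consistency(self, rng):
        L = np.abs(rng.standard_normal((5, 2))) + 0.5
        truth = np.array([[0.001], [0.004]])
        da = L @ truth
        top, deep, _ = invert_layered_mua(da, L, weights=np.arange(1.0, 6.0))
        assert np.allclose([top[0], deep[0]], truth.ravel(), rtol=1e-10)


class TestMBLL:
    def test_round_trip(self):
        k = absorption_matrix(WLS)
        dmua = k @ np.array([[1.0], [0.0]])
        do2, dhhb = mbll_concentrations(dmua, WLS)
        assert np.isclose(do2[0], 1.0) and np.isclose(dhhb[0], 0.0, atol=1e-12)

    def test_zero_gives_zero(self):
        do2, dhhb = mbll_concentrations(np.zeros((2, 4)), WLS)
        assert np.allclose(do2, 0) and np.allclose(dhhb, 0)

    def test_singular_matrix_rejected(self):
        with pytest.raises(ValueError):
            mbll_concentrations(np.zeros((2, 1)), WLS, kmat=np.ones((2, 2)))


@pytest.fixture(scope="module")
def processed(grid, equal_layer_fields):
    """One fully processed recording at default noise with the
    healthy-group median response in every cycle."""
    protocol = make_protocol()
    t_s = protocol.sample_times
    conc = np.zeros((t_s.size, 2))
    for onset in protocol.onsets:
        conc[:, 0] += canonical_hrf(t_s - onset, 0.65, 5.0)
        conc[:, 1] += canonical_hrf(t_s - onset, -0.24, 5.2)
    irf = make_irf(grid)
    kmat = absorption_matrix(WLS)
    rng = np.random.default_rng(2024)
    dtofs = {}
    for i, wl in enumerate(WLS):
        r0, lt, lb = equal_layer_fields[wl]
        dmua = kmat[i, 0] * conc[:, 0] + kmat[i, 1] * conc[:, 1]
        dtofs[wl] = synthesize_dtof_stack(
            r0, lt, lb, np.zeros_like(dmua), dmua, irf, 1e6, rng
        )
    tc, fits, verdict = process_recording(
        dtofs, {w: irf for w in WLS}, grid, RHO, t_s, 30
    )
    return tc, fits, verdict, conc, protocol


class TestEndToEnd:
    def test_quality_passes(self, processed):
        _, fits, verdict, _, _ = processed
        assert verdict.passed
        for f in fits.values():
            assert f.total_counts > 150_000 and f.chi2_red <= 2

    def test_peak_concentration_recovery(self, processed):
        """Mean fitted O2Hb amplitude over the five cycles within 15% of
        the 0.65 uM ground truth."""
        from tdnirs.hrf import fit_cycles

        tc, _, _, _, protocol = processed
        fits = fit_cycles(tc, protocol)
        assert abs(fits["A_O2Hb"].mean() - 0.65) / 0.65 < 0.15
        assert abs(fits["A_HHb"].mean() - (-0.24)) / 0.24 < 0.25

    def test_linearity_in_effect_size(self, grid, equal_layer_fields):
        """Doubling the true concentration change doubles the recovered
        one (noiseless expectations)."""
        protocol = make_protocol(n_cycles=1)
        t_s = protocol.sample_times
        irf = make_irf(grid)
        kmat = absorption_matrix(WLS)
        peaks = []
        for scale in (1.0, 2.0):
            conc = scale * np.stack(
                [
                    canonical_hrf(t_s - protocol.onsets[0], 0.65, 5.0),
                    canonical_hrf(t_s - protocol.onsets[0], -0.24, 5.2),
                ],
                axis=1,
            )
            dtofs = {}
            for i, wl in enumerate(WLS):
                r0, lt, lb = equal_layer_fields[wl]
                dmua = kmat[i, 0] * conc[:, 0] + kmat[i, 1] * conc[:, 1]
                dtofs[wl] = np.round(
                    synthesize_dtof_stack(
                        r0, lt, lb, np.zeros_like(dmua), dmua, irf, 1e7, None
                    )
                ).astype(int)
            tc, _, _ = process_recording(
                dtofs, {w: irf for w in WLS}, grid, RHO, t_s, 30
            )
            peaks.append(np.nanmax(tc.dO2Hb))
        assert np.isclose(peaks[1] / peaks[0], 2.0, rtol=0.05)

    def test_superficial_contamination_rejected(self, grid, equal_layer_fields):
        """The same absorption step placed superficially must leak into
        the cortical estimate at < 20% of its deep-layer response."""
        irf = make_irf(grid)
        t_s = np.arange(60.0)
        step = np.where(t_s >= 30, 0.002, 0.0)
        zero = np.zeros_like(step)
        recovered = {}
        for which in ("top", "deep"):
            dtofs = {}
            for wl in WLS:
                r0, lt, lb = equal_layer_fields[wl]
                dmua_top = step if which == "top" else zero
                dmua_deep = step if which == "deep" else zero
                dtofs[wl] = np.round(
                    synthesize_dtof_stack(
                        r0, lt, lb, dmua_top, dmua_deep, irf, 1e7, None
                    )
                ).astype(int)
            tc, _, _ = process_recording(
                dtofs, {w: irf for w in WLS}, grid, RHO, t_s, 30
            )
            recovered[which] = np.nanmean(np.abs(tc.dO2Hb[40:]) + np.abs(tc.dHHb[40:]))
        assert recovered["top"] < 0.2 * recovered["deep"]


class TestGateMatrix:
    def test_gate_pathlengths_bracket_time_resolved(self, grid, equal_layer_fields):
        """Later gates see longer deep pathlengths."""
        r0, lt, lb = equal_layer_fields[687.0]
        irf = make_irf(grid)
        gates = default_gates(1.2)
        L = gate_pathlength_matrix(r0, lt, lb, irf, gates)
        assert np.all(np.diff(L[:, 1]) > 0)  # deep pathlength grows with delay
        assert np.all(L > 0)
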