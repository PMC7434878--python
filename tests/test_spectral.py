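"""Lineshapes, spin markers, peak fitting and decomposition."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinxes.errors import (DecompositionError, GridError, ParameterError,
                            TruncationError)
from spinxes.spectral import (KBETA13_WINDOW, DifferenceSpectrum,
                              EmissionSpectrum, SpinStateSpectralParams,
                              decompose_transient, default_fixture,
                              fit_gaussian_peak, full_conversion_shift,
                              kalpha1_fwhm_from_spin, mix_spectra,
                              pseudo_voigt, pseudo_voigt_area, read_spectrum,
                              synth_state_spectrum, write_spectrum)


class TestKalpha1WidthRelation:
    @pytest.mark.parametrize("n,expected", [(0, 2.5), (1, 2.7), (4, 3.3)])
    def test_linear_form(self, n, expected):
        assert kalpha1_fwhm_from_spin(n, 0.2, 2.5) == pytest.approx(expected)

    def test_monotonic_in_unpaired_electrons(self):
        widths = [kalpha1_fwhm_from_spin(n, 0.37, 1.9) for n in (1, 2, 4)]
        assert widths[0] < widths[1] < widths[2]

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            kalpha1_fwhm_from_spin(2, -0.1, 2.5)
        with pytest.raises(ParameterError):
            kalpha1_fwhm_from_spin(7, 0.2, 2.5)


class TestPseudoVoigt:
    @pytest.mark.parametrize("eta", [0.0, 0.5, 1.0])
    def test_area_matches_closed_form(self, eta):
        # quadrature on +/- 8 widths; the Lorentzian tail beyond carries
        # ~8% of its area, so integrate it to +/- 3000 widths instead
        sigma, height = 1.3, 0.8
        span = 3000.0 if eta > 0 else 8.0
        x = np.linspace(-span * sigma, span * sigma, 4_000_001)
        quad = np.trapezoid(pseudo_voigt(x, 0.0, sigma, height, eta), x)
        assert quad == pytest.approx(pseudo_voigt_area(sigma, height, eta),
                                     rel=1e-3)

    def test_peak_height_at_centroid(self):
        assert pseudo_voigt(7058.0, 7058.0, 1.0, 0.7, 0.5) == pytest.approx(0.7)


class TestSynthStateSpectrum:
    def test_ls_centroid_recovered_by_gaussian_fit(self, fixture):
        spec = synth_state_spectrum(fixture.ls, "Kbeta",
                                    fixture.grid("Kbeta"))
        fit = fit_gaussian_peak(spec, KBETA13_WINDOW)
        assert fit.centroid == pytest.approx(fixture.ls.kbeta13_centroid,
                                             abs=0.01)

    def test_hs_blue_shift_positive(self, kbeta_state_spectra):
        ls, _, hs = kbeta_state_spectra
        c_ls = fit_gaussian_peak(ls, KBETA13_WINDOW).centroid
        c_hs = fit_gaussian_peak(hs, (7056.0, 7064.0)).centroid
        assert c_hs - c_ls > 0

    def test_fitted_marker_ordering_across_states(self, fixture):
        # Gaussian-fit K-beta centroid increases and K-alpha1 sigma
        # increases monotonically with the unpaired-electron count
        centroids, sigmas = [], []
        for p in fixture.state_params():
            kb = synth_state_spectrum(p, "Kbeta", fixture.grid("Kbeta"))
            centroids.append(
                fit_gaussian_peak(kb, (7055.0, 7065.0)).centroid)
            ka = synth_state_spectrum(p, "Kalpha", fixture.grid("Kalpha"))
            sigmas.append(
                fit_gaussian_peak(ka, fixture.kalpha1_window()).sigma)
        assert centroids[0] < centroids[1] < centroids[2]
        assert sigmas[0] < sigmas[1] < sigmas[2]

    def test_truncated_grid_raises(self, fixture):
        with pytest.raises(TruncationError):
            synth_state_spectrum(fixture.ls, "Kbeta",
                                 np.arange(7050.0, 7070.0, 0.1))

    def test_marker_ordering_validation(self, fixture):
        from dataclasses import replace
        bad_hs = replace(fixture.hs,
                         kbeta13_centroid=fixture.ls.kbeta13_centroid - 1.0)
        from spinxes.spectral import validate_marker_ordering
        with pytest.raises(ParameterError):
            validate_marker_ordering(fixture.ls, fixture.intermediate, bad_hs)


class TestMixSpectra:
    def test_identity(self, kbeta_state_spectra):
        ls = kbeta_state_spectra[0]
        out = mix_spectra([1.0, 0.0, 0.0], kbeta_state_spectra)
        assert np.array_equal(out.intensity, ls.intensity)

    def test_pointwise_mean(self, kbeta_state_spectra):
        ls, inter, _ = kbeta_state_spectra
        out = mix_spectra([0.5, 0.5, 0.0], kbeta_state_spectra)
        assert np.allclose(out.intensity,
                           0.5 * (ls.intensity + inter.intensity))

    def test_mix_minus_ls_is_weighted_difference_sum(self, kbeta_state_spectra):
        ls, inter, hs = kbeta_state_spectra
        out = mix_spectra([0.3, 0.3, 0.4], kbeta_state_spectra)
        expected = 0.3 * (inter.intensity - ls.intensity) \
            + 0.4 * (hs.intensity - ls.intensity)
        assert np.allclose(out.intensity - ls.intensity, expected, atol=1e-12)

    def test_validation(self, kbeta_state_spectra):
        with pytest.raises(ParameterError):
            mix_spectra([0.8, 0.8, 0.0], kbeta_state_spectra)
        with pytest.raises(ParameterError):
            mix_spectra([-0.1, 0.5, 0.0], kbeta_state_spectra)
        shifted = EmissionSpectrum(
            kbeta_state_spectra[0].energy + 1.0,
            kbeta_state_spectra[0].intensity, "Kbeta")
        with pytest.raises(GridError):
            mix_spectra([0.5, 0.5], [kbeta_state_spectra[0], shifted])


def _gaussian_spectrum(centroid=7058.0, sigma=1.2, amp=1.0, baseline=0.05,
                       noise=0.0, rng=None):
    grid = np.arange(7040.0, 7076.0 + 0.05, 0.1)
    y = amp * np.exp(-((grid - centroid) ** 2) / (2 * sigma ** 2)) + baseline
    if noise > 0:
        y = y + rng.normal(0.0, noise, grid.shape)
    return EmissionSpectrum(grid, np.clip(y, 0, None), "Kbeta")


class TestFitGaussianPeak:
    def test_noiseless_exact_recovery(self):
        spec = _gaussian_spectrum()
        fit = fit_gaussian_peak(spec, (7053.0, 7063.0))
        assert fit.centroid == pytest.approx(7058.0, abs=1e-6)
        assert fit.sigma == pytest.approx(1.2, abs=1e-6)
        assert fit.centroid_err < 1e-6 and fit.sigma_err < 1e-6

    @pytest.mark.parametrize("window", [(7053.0, 7063.0), (7055.0, 7066.0),
                                        (7050.5, 7061.5)])
    def test_window_placement_independence(self, window):
        spec = _gaussian_spectrum()
        fit = fit_gaussian_peak(spec, window)
        assert fit.centroid == pytest.approx(7058.0, abs=1e-6)
        assert fit.sigma == pytest.approx(1.2, abs=1e-6)

    def test_negative_going_peak(self):
        grid = np.arange(7040.0, 7076.0, 0.1)
        y = -0.5 * np.exp(-((grid - 7053.0) ** 2) / (2 * 1.5 ** 2))
        tr = DifferenceSpectrum(grid, y)
        fit = fit_gaussian_peak(tr, (7048.0, 7058.0))
        assert fit.centroid == pytest.approx(7053.0, abs=1e-6)
        assert fit.amplitude == pytest.approx(-0.5, abs=1e-6)

    def test_monte_carlo_centroid_unbiased(self):
        # SNR 100, 200 replicates: mean recovered centroid within 3 SE
        rng = np.random.default_rng(42)
        centroids, errs = [], []
        for _ in range(200):
            spec = _gaussian_spectrum(noise=0.01, rng=rng)
            fit = fit_gaussian_peak(spec, (7053.0, 7063.0))
            centroids.append(fit.centroid)
            errs.append(fit.centroid_err)
        centroids = np.array(centroids)
        se = centroids.std(ddof=1) / np.sqrt(len(centroids))
        assert abs(centroids.mean() - 7058.0) < 3 * se
        # reported 1-sigma errors agree with the observed scatter
        assert np.median(errs) == pytest.approx(centroids.std(ddof=1),
                                                rel=0.25)

    def test_error_scales_with_noise(self):
        rng = np.random.default_rng(3)
        med = {}
        for noise in (0.01, 0.02):
            errs = [fit_gaussian_peak(
                _gaussian_spectrum(noise=noise, rng=rng),
                (7053.0, 7063.0)).centroid_err for _ in range(200)]
            med[noise] = np.median(errs)
        assert med[0.02] / med[0.01] == pytest.approx(2.0, rel=0.2)

    def test_error_scales_inverse_sqrt_averaged_replicates(self):
        # averaging N replicate spectra shrinks errors as 1/sqrt(N)
        rng = np.random.default_rng(11)
        med = {}
        for n_avg in (1, 4, 16):
            errs = []
            for _ in range(60):
                grid = np.arange(7040.0, 7076.0 + 0.05, 0.1)
                stack = [_gaussian_spectrum(noise=0.02, rng=rng).intensity
                         for _ in range(n_avg)]
                spec = EmissionSpectrum(grid, np.mean(stack, axis=0), "Kbeta")
                errs.append(fit_gaussian_peak(spec, (7053.0, 7063.0)).centroid_err)
            med[n_avg] = np.median(errs)
        assert med[1] / med[4] == pytest.approx(2.0, rel=0.25)
        assert med[4] / med[16] == pytest.approx(2.0, rel=0.25)

    def test_window_contract(self):
        spec = _gaussian_spectrum()
        with pytest.raises(ParameterError):
            fit_gaussian_peak(spec, (7058.0, 7058.4))  # < 8 points


class TestDecomposeTransient:
    def _basis(self, spectra):
        ls, inter, hs = spectra
        return [
            DifferenceSpectrum(ls.energy, inter.intensity - ls.intensity),
            DifferenceSpectrum(ls.energy, hs.intensity - ls.intensity),
        ]

    def test_exact_basis_member(self, kbeta_state_spectra):
        basis = self._basis(kbeta_state_spectra)
        res = decompose_transient(
            DifferenceSpectrum(basis[1].energy, basis[1].delta_intensity),
            basis)
        assert res.coefficients == pytest.approx([0.0, 1.0], abs=1e-9)
        assert res.residual_norm < 1e-9

    def test_linear_combination_recovered(self, kbeta_state_spectra):
        basis = self._basis(kbeta_state_spectra)
        target = DifferenceSpectrum(
            basis[0].energy,
            0.3 * basis[0].delta_intensity + 0.2 * basis[1].delta_intensity)
        res = decompose_transient(target, basis)
        assert res.coefficients == pytest.approx([0.3, 0.2], abs=1e-9)

    def test_noise_replicates_unbiased(self, kbeta_state_spectra):
        basis = self._basis(kbeta_state_spectra)
        rng = np.random.default_rng(5)
        coefs = []
        for _ in range(500):
            y = 0.3 * basis[0].delta_intensity \
                + 0.2 * basis[1].delta_intensity \
                + rng.normal(0.0, 0.01, basis[0].energy.shape)
            res = decompose_transient(
                DifferenceSpectrum(basis[0].energy, y), basis)
            coefs.append(res.coefficients)
        coefs = np.array(coefs)
        se = coefs.std(axis=0, ddof=1) / np.sqrt(len(coefs))
        assert abs(coefs[:, 0].mean() - 0.3) < 3 * se[0]
        assert abs(coefs[:, 1].mean() - 0.2) < 3 * se[1]

    def test_rank_deficient_basis_rejected(self, kbeta_state_spectra):
        basis = self._basis(kbeta_state_spectra)
        dup = DifferenceSpectrum(basis[0].energy,
                                 2.0 * basis[0].delta_intensity)
        with pytest.raises(DecompositionError) as exc:
            decompose_transient(basis[0], [basis[0], dup])
        assert exc.value.condition_number > 1e10


@settings(max_examples=30, deadline=None, derandomize=True)
@given(p_t=st.floats(0.0, 1.0), p_hs=st.floats(0.0, 1.0))
def test_mix_then_decompose_recovers_populations(p_t, p_hs):
    """Linearity: decomposing (mixture - LS) returns the mixing populations
    exactly for any point of the population simplex."""
    total = p_t + p_hs
    if total > 1.0:
        p_t, p_hs = p_t / total, p_hs / total
    fixture = default_fixture()
    ls, inter, hs = fixture.state_spectra("Kbeta")
    mixed = mix_spectra([max(0.0, 1.0 - p_t - p_hs), p_t, p_hs],
                        [ls, inter, hs])
    transient = DifferenceSpectrum(ls.energy,
                                   mixed.intensity - ls.intensity)
    basis = [DifferenceSpectrum(ls.energy, inter.intensity - ls.intensity),
             DifferenceSpectrum(ls.energy, hs.intensity - ls.intensity)]
    res = decompose_transient(transient, basis)
    assert res.coefficients == pytest.approx([p_t, p_hs], abs=1e-9)


class TestFixtureCalibration:
    def test_full_conversion_shift_matches_target(self, fixture):
        assert full_conversion_shift(fixture) == pytest.approx(
            fixture.target_max_shift, abs=1e-3)

    def test_intermediate_centroid_midway(self, fixture):
        mid = 0.5 * (fixture.ls.kbeta13_centroid + fixture.hs.kbeta13_centroid)
        assert fixture.intermediate.kbeta13_centroid == pytest.approx(mid)

    def test_unpaired_electron_counts(self, fixture):
        assert [p.n_unpaired for p in fixture.state_params()] == [1, 2, 4]


class TestFixtureConfigIO:
    def test_yaml_round_trip(self, fixture, tmp_path):
        from spinxes.spectral import fixture_from_yaml, fixture_to_yaml
        path = tmp_path / "fixture.yaml"
        fixture_to_yaml(fixture, path)
        back = fixture_from_yaml(path)
        assert back == fixture


class TestSpectrumIO:
    def test_round_trip_bit_exact(self, kbeta_state_spectra):
        spec = kbeta_state_spectra[0]
        buf = io.StringIO()
        write_spectrum(buf, spec)
        text1 = buf.getvalue()
        back = read_spectrum(io.StringIO(text1))
        buf2 = io.StringIO()
        write_spectrum(buf2, back)
        assert buf2.getvalue() == text1
        assert np.array_equal(back.energy, spec.energy)
        assert np.array_equal(back.intensity, spec.intensity)
        assert back.line_family == spec.line_family

    def test_difference_spectrum_round_trip(self):
        grid = np.arange(7040.0, 7070.0, 0.1)
        tr = DifferenceSpectrum(grid, np.sin(grid / 3.0),
                                uncertainty=np.full(grid.shape, 0.01),
                                delay_fs=260.0)
        buf = io.StringIO()
        write_spectrum(buf, tr)
        back = read_spectrum(io.StringIO(buf.getvalue()))
        assert isinstance(back, DifferenceSpectrum)
        assert back.delay_fs == 260.0
        assert np.array_equal(back.delta_intensity, tr.delta_intensity)
        assert np.array_equal(back.uncertainty, tr.uncertainty)


class TestDomainTypeContracts:
    def test_grid_must_be_uniform_and_increasing(self):
        with pytest.raises(GridError):
            EmissionSpectrum(np.array([1.0, 2.0, 2.5]), np.ones(3))
        with pytest.raises(GridError):
            EmissionSpectrum(np.array([2.0, 1.0, 0.0]), np.ones(3))

    def test_raw_intensity_non_negative(self):
        grid = np.arange(0.0, 1.0, 0.1)
        with pytest.raises(ParameterError):
            EmissionSpectrum(grid, np.full(grid.shape, -1.0))
        # difference spectra may be negative
        DifferenceSpectrum(grid, np.full(grid.shape, -1.0))

    def test_state_label_consistency(self, fixture):
        from dataclasses import replace
        with pytest.raises(ParameterError):
            replace(fixture.ls, n_unpaired=3)
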