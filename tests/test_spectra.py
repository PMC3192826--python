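"""Prescriptions, eigenvalue mapping and analytic spectral quantities."""

import numpy as np
import pytest

from vbgen import (
    PrescriptionConfig,
    analytic_power_spectrum,
    build_prescription,
    coherence_phase,
    cross_spectrum,
    default_grid,
    eigenvalues_from_prescription,
    lorentzian_spectrum,
    spectral_slope,
)
from vbgen.iep import realify
from vbgen.spectra import EigenvalueSet, SpectralPeak, SpectrumCurve, SpectrumPrescription

TWO_PI = 2 * np.pi


class TestPrescriptions:
    def test_normal_peaks_form_geometric_sequence(self):
        presc = build_prescription("Normal", PrescriptionConfig())
        freqs = np.array([p.f_peak for p in presc.peaks])
        np.testing.assert_allclose(
            freqs, 2.0 * 2.6 ** np.arange(6), rtol=1e-12
        )
        np.testing.assert_allclose(np.diff(np.log(freqs)), np.log(2.6))

    def test_entrained_bands_at_exact_one_to_three_ratio(self):
        presc = build_prescription("Entrained", PrescriptionConfig())
        f = [p.f_peak for p in presc.peaks]
        assert f == [2.7, 8.1]
        assert f[1] / f[0] == pytest.approx(3.0, abs=1e-12)

    def test_background_has_no_peaks(self):
        assert build_prescription("Background", PrescriptionConfig()).peaks == ()

    def test_incomplete_drops_top_frequencies(self):
        cfg = PrescriptionConfig()
        normal = build_prescription("Normal", cfg)
        inc = build_prescription("Incomplete", cfg)
        assert inc.peaks == normal.peaks[:4]

    def test_random_peaks_fresh_draw_within_normal_span(self):
        cfg = PrescriptionConfig()
        a = build_prescription("Random", cfg, seed=1)
        b = build_prescription("Random", cfg, seed=2)
        fa = [p.f_peak for p in a.peaks]
        assert fa != [p.f_peak for p in b.peaks]
        assert all(2.0 <= f <= 2.0 * 2.6**5 for f in fa)
        assert len(fa) == cfg.n_peaks

    def test_peak_above_bandwidth_rejected(self):
        cfg = PrescriptionConfig(base_freq=100.0, ratio=3.0, n_peaks=3)
        with pytest.raises(ValueError, match="bandwidth"):
            build_prescription("Normal", cfg)

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            PrescriptionConfig(ratio=-1.0)

    def test_background_with_peaks_rejected(self):
        with pytest.raises(ValueError):
            SpectrumPrescription(
                group="Background",
                peaks=(SpectralPeak(1.0, 0.1),),
                n_nodes=4,
                real_eig_bounds=(-5.0, -1.0),
            )


class TestEigenvalues:
    def test_single_peak_maps_to_radian_pair(self):
        presc = SpectrumPrescription(
            group="Normal",
            peaks=(SpectralPeak(10.0, 1.0),),
            n_nodes=2,
            real_eig_bounds=(-TWO_PI, -TWO_PI),
        )
        eigs = eigenvalues_from_prescription(presc)
        assert eigs.reals == ()
        assert eigs.complex_pairs[0] == pytest.approx(complex(-TWO_PI, 20 * np.pi))

    def test_background_eigenvalues_all_real_in_bounds(self):
        presc = SpectrumPrescription(
            group="Background", peaks=(), n_nodes=20, real_eig_bounds=(-50.0, -1.0)
        )
        eigs = eigenvalues_from_prescription(presc)
        assert len(eigs.complex_pairs) == 0
        assert len(eigs.reals) == 20
        assert all(-50.0 <= r <= -1.0 for r in eigs.reals)

    def test_full_scale_normal_eigenvalue_budget(self):
        presc = build_prescription("Normal", PrescriptionConfig(n_nodes=80))
        eigs = eigenvalues_from_prescription(presc)
        assert len(eigs.complex_pairs) == 6  # 12 complex eigenvalues
        assert len(eigs.reals) == 68
        assert eigs.n == 80

    def test_too_many_peaks_rejected(self):
        with pytest.raises(ValueError, match="n_nodes"):
            SpectrumPrescription(
                group="Normal",
                peaks=tuple(SpectralPeak(f, 0.1) for f in (1, 2, 3)),
                n_nodes=4,
                real_eig_bounds=(-5.0, -1.0),
            )

    def test_seed_determinism(self):
        presc = build_prescription("Background", PrescriptionConfig(n_nodes=10), seed=7)
        a = eigenvalues_from_prescription(presc)
        b = eigenvalues_from_prescription(presc)
        assert a.reals == b.reals


class TestPowerSpectrum:
    def test_scalar_ou_lorentzian(self):
        grid = np.array([1e-6, 0.5, 2.0])
        curve = analytic_power_spectrum(np.array([[-1.0]]), 1.0, grid)
        np.testing.assert_allclose(curve.power, 1.0 / (1.0 + (TWO_PI * grid) ** 2), rtol=1e-10)
        assert curve.power[0] == pytest.approx(1.0, rel=1e-6)

    def test_rotation_block_peak_location_and_hwhm(self):
        # dense-grid brute force on a 2x2 block with eigenvalues -γ ± i ω0
        gamma, f0 = 0.5, 4.0
        W = realify(EigenvalueSet((complex(-TWO_PI * gamma, TWO_PI * f0),), ()))
        grid = np.linspace(0.5, 8.0, 20001)
        curve = analytic_power_spectrum(W, 1.0, grid)
        i_pk = np.argmax(curve.power)
        assert grid[i_pk] == pytest.approx(f0, abs=0.05)
        half = 0.5 * (curve.power[i_pk] - curve.power[-1]) + curve.power[-1]
        above = grid[curve.power >= half]
        hwhm = 0.5 * (above[-1] - above[0])
        assert hwhm == pytest.approx(gamma, abs=0.05)

    def test_unstable_matrix_rejected(self):
        with pytest.raises(ValueError, match="stable"):
            analytic_power_spectrum(np.array([[1.0]]), 1.0, np.array([1.0]))

    def test_power_equals_mean_diagonal_of_cross_spectrum(self, rng):
        W = rng.standard_normal((6, 6)) - 4 * np.eye(6)
        grid = default_grid(0.5, 50, 32)
        p = analytic_power_spectrum(W, 1.3, grid).power
        S = cross_spectrum(W, 1.3, grid).matrices
        np.testing.assert_allclose(p, np.einsum("fii->f", S).real / 6, rtol=1e-12)

    def test_normal_matrix_matches_lorentzian_superposition(self):
        eigs = EigenvalueSet(
            (complex(-1.0, 10.0), complex(-2.0, 40.0)), (-3.0, -0.7)
        )
        W = realify(eigs)  # block-diagonal => normal matrix
        grid = default_grid(0.1, 30, 64)
        a = analytic_power_spectrum(W, 1.0, grid).power
        b = lorentzian_spectrum(eigs, 1.0, grid).power
        np.testing.assert_allclose(a, b, rtol=1e-9)


class TestCoherencePhase:
    def test_diagonal_coupling_gives_zero_coherence(self):
        W = np.diag([-1.0, -2.0, -3.0])
        coh, ph = coherence_phase(cross_spectrum(W, 1.0, default_grid(0.5, 50, 16)))
        off = ~np.eye(3, dtype=bool)
        assert np.abs(coh[:, off]).max() < 1e-20

    def test_self_coherence_one_phase_zero(self, rng):
        W = rng.standard_normal((4, 4)) - 3 * np.eye(4)
        coh, ph = coherence_phase(cross_spectrum(W, 1.0, default_grid(0.5, 50, 16)))
        di = np.arange(4)
        np.testing.assert_allclose(coh[:, di, di], 1.0, atol=1e-12)
        np.testing.assert_allclose(ph[:, di, di], 0.0, atol=1e-12)

    def test_bounds_and_phase_antisymmetry(self, rng):
        W = rng.standard_normal((5, 5)) - 4 * np.eye(5)
        coh, ph = coherence_phase(cross_spectrum(W, 1.0, default_grid(0.5, 100, 32)))
        assert np.all((coh >= 0) & (coh <= 1))
        np.testing.assert_allclose(ph, -np.swapaxes(ph, 1, 2), atol=1e-10)

    def test_cross_spectrum_hermitian_psd(self, rng):
        W = rng.standard_normal((5, 5)) - 4 * np.eye(5)
        S = cross_spectrum(W, 1.0, default_grid(0.5, 100, 16)).matrices
        np.testing.assert_allclose(S, np.conj(np.swapaxes(S, 1, 2)), atol=1e-12)
        for Sk in S:
            assert np.linalg.eigvalsh(0.5 * (Sk + Sk.conj().T)).min() > -1e-10

    def test_high_frequency_quarter_cycle_lag(self, rng):
        # resolvent expansion: S_ij ≈ i σ² (W_ji - W_ij)/ω³, purely imaginary
        W = rng.standard_normal((6, 6)) - 5 * np.eye(6)
        rho = np.abs(np.linalg.eigvals(W)).max()
        f = 100 * rho / TWO_PI
        cs = cross_spectrum(W, 1.0, np.array([f]))
        _, ph = coherence_phase(cs)
        off = ~np.eye(6, dtype=bool)
        assert np.median(np.abs(np.abs(ph[0][off]) - np.pi / 2)) < 0.02
        pred = 1j * (W.T - W) / (TWO_PI * f) ** 3
        S = cs.matrices[0]
        assert np.abs(S[off] - pred[off]).max() < 0.05 * np.abs(pred[off]).max()


class TestSpectralSlope:
    def test_exact_power_law(self):
        f = np.geomspace(1, 100, 50)
        assert spectral_slope(SpectrumCurve(f, f**-2.0), 1, 100) == pytest.approx(2.0)

    def test_scalar_ou_tail_slope_is_two(self):
        curve = analytic_power_spectrum(np.array([[-1.0]]), 1.0, np.geomspace(50, 500, 64))
        assert spectral_slope(curve, 50, 500) == pytest.approx(2.0, abs=0.05)

    def test_band_needs_three_points(self):
        f = np.geomspace(1, 100, 50)
        with pytest.raises(ValueError, match="3 grid points"):
            spectral_slope(SpectrumCurve(f, f**-2.0), 1.0, 1.05)
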