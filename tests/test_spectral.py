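import numpy as np
import pytest

from ecogwaves import spectral, synthetic
from ecogwaves.spectral import (
    NoRhythmError,
    PowerSpectrum,
    clamp_negative,
    compute_psd,
    fit_fractal_slope,
    fit_rhythm_bands,
    hfa_power,
    irasa,
)

FS = 512


class TestComputePsd:
    def test_zero_signal(self):
        ps = compute_psd(np.zeros(FS * 4), FS)
        assert np.all(ps.power == 0)

    def test_sinusoid_peak_and_leakage(self):
        t = np.arange(FS * 8) / FS
        ps = compute_psd(np.sin(2 * np.pi * 10 * t), FS)
        peak_idx = np.argmax(ps.power)
        assert ps.freqs[peak_idx] == pytest.approx(10.0)
        # beyond the Hann mainlobe (+-2 bins), leakage under 1% of the peak
        far = np.abs(ps.freqs - 10.0) > 2.0
        assert ps.power[far].max() < 0.01 * ps.power[peak_idx]

    def test_parseval(self, rng):
        x = rng.standard_normal(FS * 10)
        ps = compute_psd(x, FS, fmax=FS / 2)
        df = ps.freqs[1] - ps.freqs[0]
        total = np.sum(ps.power) * df
        assert total == pytest.approx(np.var(x), rel=0.05)

    def test_too_short(self):
        with pytest.raises(ValueError):
            compute_psd(np.zeros(FS // 2), FS)

    def test_one_hz_resolution_capped_at_200(self):
        ps = compute_psd(np.random.default_rng(0).standard_normal(FS * 2), FS)
        assert np.allclose(np.diff(ps.freqs), 1.0)
        assert ps.freqs[-1] <= 200.0


class TestIrasa:
    def test_pure_fractal_small_residual(self):
        x = synthetic.generate_fractal_background(8, FS * 60, FS, 1.5, seed=0)
        frac, osc = irasa(x.reshape(96, -1), FS)
        m = (frac.freqs >= 5) & (frac.freqs <= 45)
        resid = np.median(np.abs(osc.power[m])) / np.median(frac.power[m])
        assert resid < 0.05

    def test_injected_oscillation_located(self, rng):
        bg = synthetic.generate_fractal_background(1, FS * 60, FS, 1.2, rng)[0]
        osc10 = synthetic.narrowband_analytic(FS * 60, FS, 10.0, 3.0, rng).real
        frac, osc = irasa((bg + osc10).reshape(12, -1), FS)
        m = (osc.freqs >= 4) & (osc.freqs <= 45)
        peak = osc.freqs[m][np.argmax(osc.power[m])]
        assert peak == pytest.approx(10.0, abs=0.5)

    def test_slope_robust_to_oscillation(self, rng):
        bg = synthetic.generate_fractal_background(2, FS * 60, FS, 1.5, rng)
        osc8 = synthetic.narrowband_analytic(FS * 60, FS, 8.0, 3.0, rng).real
        frac_a, _ = irasa(bg.reshape(24, -1), FS)
        frac_b, _ = irasa((bg + osc8).reshape(24, -1), FS)
        sa = fit_fractal_slope(frac_a).slope
        sb = fit_fractal_slope(frac_b).slope
        assert abs(sa - sb) < 0.1

    def test_additivity_exact(self, rng):
        x = rng.standard_normal((4, FS * 5))
        frac, osc = irasa(x, FS)
        orig = compute_psd(x, FS)
        np.testing.assert_allclose(frac.power + osc.power, orig.power, rtol=1e-12)

    def test_factor_validation(self):
        x = np.random.default_rng(0).standard_normal(FS * 4)
        with pytest.raises(ValueError):
            irasa(x, FS, factors=[])
        with pytest.raises(ValueError):
            irasa(x, FS, factors=[2.0])
        with pytest.raises(ValueError):
            irasa(x, FS, factors=[0.9])


class TestClampNegative:
    def test_positive_unchanged(self):
        ps = PowerSpectrum(np.arange(1.0, 5.0), np.array([1.0, 2.0, 3.0, 4.0]))
        out = clamp_negative(ps)
        np.testing.assert_array_equal(out.power, ps.power)

    def test_negative_zeroed(self):
        ps = PowerSpectrum(np.arange(1.0, 4.0), np.array([1.0, -3.0, 2.0]))
        out = clamp_negative(ps)
        np.testing.assert_array_equal(out.power, [1.0, 0.0, 2.0])

    def test_peaks_never_clamped(self, rng):
        bg = synthetic.generate_fractal_background(1, FS * 60, FS, 1.5, rng)[0]
        a = synthetic.narrowband_analytic(FS * 60, FS, 8.0, 4.0, rng).real
        frac, osc = irasa((bg + a).reshape(12, -1), FS)
        near_peak = np.abs(osc.freqs - 8.0) <= 1.0
        assert np.all(osc.power[near_peak] > 0)


class TestFitRhythmBands:
    def _spectrum_with_bumps(self, seed, extra_low=False):
        rng = np.random.default_rng(seed)
        chans = []
        for _ in range(3):
            bg = synthetic.generate_fractal_background(1, FS * 60, FS, 1.5, rng)[0]
            x = bg + synthetic.narrowband_analytic(FS * 60, FS, 8.0, 4.0, rng).real
            x = x + synthetic.narrowband_analytic(FS * 60, FS, 18.0, 6.0, rng).real
            if extra_low:
                x = x + 0.7 * synthetic.narrowband_analytic(FS * 60, FS, 3.0, 1.5, rng).real
            chans.append(x)
        frac, osc = irasa(np.array(chans).reshape(36, -1), FS)
        return clamp_negative(osc)

    def test_two_bump_recovery(self):
        osc = self._spectrum_with_bumps(0)
        bands = fit_rhythm_bands(osc)
        alpha = next(b for b in bands if b.label == "alpha")
        beta = next(b for b in bands if b.label == "beta")
        assert alpha.center == pytest.approx(8.0, abs=0.5)
        assert beta.center == pytest.approx(18.0, abs=0.5)
        assert alpha.fwhm == pytest.approx(4.0, rel=0.25)
        assert beta.fwhm == pytest.approx(6.0, rel=0.25)
        assert alpha.center < beta.center

    def test_third_low_term_auto_selected(self):
        osc2 = self._spectrum_with_bumps(1)
        osc3 = self._spectrum_with_bumps(1, extra_low=True)
        bands2 = fit_rhythm_bands(osc2)
        bands3 = fit_rhythm_bands(osc3)
        assert len(bands3) == 3
        assert any(b.label == "low" for b in bands3)
        a2 = next(b for b in bands2 if b.label == "alpha")
        a3 = next(b for b in bands3 if b.label == "alpha")
        b2 = next(b for b in bands2 if b.label == "beta")
        b3 = next(b for b in bands3 if b.label == "beta")
        # paired simulation puts the alpha shift at ~0.5 Hz (the low bump's
        # resampled copies overlap the alpha band); bound frozen from that
        assert abs(a2.center - a3.center) < 0.75
        assert abs(b2.center - b3.center) < 0.5

    def test_all_zero_raises_no_rhythm(self):
        ps = PowerSpectrum(np.arange(1.0, 50.0), np.zeros(49))
        with pytest.raises(NoRhythmError):
            fit_rhythm_bands(ps)


class TestFractalSlope:
    def test_exact_power_law(self):
        f = np.arange(1.0, 101.0)
        fit = fit_fractal_slope(PowerSpectrum(f, f**-2.0))
        assert fit.slope == pytest.approx(-2.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_flat_spectrum(self):
        f = np.arange(1.0, 101.0)
        fit = fit_fractal_slope(PowerSpectrum(f, np.ones_like(f)))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_multiplicative_composition(self):
        f = np.arange(1.0, 101.0)
        base = f**-1.2
        s1 = fit_fractal_slope(PowerSpectrum(f, base)).slope
        s2 = fit_fractal_slope(PowerSpectrum(f, base * f**-0.5)).slope
        assert s2 - s1 == pytest.approx(-0.5, abs=0.02)

    def test_unbiased_for_exponent_range(self):
        f = np.arange(1.0, 201.0)
        for chi in np.linspace(0, 3, 7):
            fit = fit_fractal_slope(PowerSpectrum(f, f**-chi))
            assert fit.slope == pytest.approx(-chi, abs=1e-9)

    def test_nonpositive_power_rejected(self):
        f = np.arange(1.0, 101.0)
        p = np.ones_like(f)
        p[40] = 0.0
        with pytest.raises(ValueError):
            fit_fractal_slope(PowerSpectrum(f, p))

    def test_r_squared_high_on_synthetic_fractal(self):
        x = synthetic.generate_fractal_background(4, FS * 60, FS, 1.5, seed=2)
        frac, _ = irasa(x.reshape(48, -1), FS)
        assert fit_fractal_slope(frac).r_squared >= 0.95


class TestHfaPower:
    def test_flat_unit_spectrum(self):
        f = np.arange(1.0, 201.0)
        assert hfa_power(PowerSpectrum(f, np.ones_like(f))) == pytest.approx(1.0)

    def test_quadratic_amplitude_scaling(self):
        f = np.arange(1.0, 201.0)
        p = np.ones_like(f)
        assert hfa_power(PowerSpectrum(f, 4 * p)) == pytest.approx(
            4 * hfa_power(PowerSpectrum(f, p))
        )

    def test_band_outside_rejected(self):
        f = np.arange(1.0, 50.0)
        with pytest.raises(ValueError):
            hfa_power(PowerSpectrum(f, np.ones_like(f)))

    def test_modulation_depth_recovered(self, rng):
        # quiet vs burst broadband: power ratio tracks amplitude ratio squared
        quiet = synthetic.generate_hfa_burst_carrier(FS * 30, FS, rng)
        burst = 1.3 * synthetic.generate_hfa_burst_carrier(FS * 30, FS, rng)
        pq = hfa_power(compute_psd(quiet.reshape(6, -1), FS))
        pb = hfa_power(compute_psd(burst.reshape(6, -1), FS))
        assert pb / pq == pytest.approx(1.3**2, rel=0.1)
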