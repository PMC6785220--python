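import numpy as np
import pytest
from scipy import stats

from ecogwaves import synthetic, waves
from ecogwaves.waves import (
    bandpass,
    circular_mean,
    direction_histogram,
    direction_kl,
    directional_consistency,
    instantaneous_phase,
    pgd,
    pgd_null,
    phase_gradient,
    project_to_plane,
    rayleigh_test,
    relative_phase_map,
    wave_direction,
    wave_speed,
    wrap_phase,
)

FS = 512.0


def planar_phases(coords, k):
    """phi(p) = -k . p, the forward-model plane-wave snapshot."""
    return wrap_phase(-(coords @ np.asarray(k)))


class TestBandpass:
    def test_passband_gain(self):
        t = np.arange(int(FS * 10)) / FS
        x = np.sin(2 * np.pi * 15 * t)
        y = bandpass(x, FS, 15.0, 6.0)
        inner = slice(int(FS), -int(FS))
        gain = np.std(y[inner]) / np.std(x[inner])
        assert gain == pytest.approx(1.0, abs=0.05)

    def test_stopband_attenuation(self):
        t = np.arange(int(FS * 10)) / FS
        for f_out in (0.2, 30.0):  # near-DC and 2x center
            x = np.sin(2 * np.pi * f_out * t) + 1.0
            y = bandpass(x, FS, 15.0, 6.0)
            assert np.std(y[int(FS) : -int(FS)]) < 0.1 * max(np.std(x), 1)

    def test_zero_phase(self):
        t = np.arange(int(FS * 5)) / FS
        x = np.sin(2 * np.pi * 15 * t)
        y = bandpass(x, FS, 15.0, 6.0)
        inner = slice(int(FS), -int(FS))
        lags = np.arange(-5, 6)
        xc = [np.corrcoef(x[inner], np.roll(y, lag)[inner])[0, 1] for lag in lags]
        assert lags[np.argmax(xc)] == 0

    def test_invalid_band(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(1024), FS, 300.0, 10.0)


class TestInstantaneousPhase:
    def test_phase_slope_matches_frequency(self):
        t = np.arange(int(FS * 4)) / FS
        ph = instantaneous_phase(np.cos(2 * np.pi * 11 * t))
        inner = slice(int(FS // 2), -int(FS // 2))
        slope = np.polyfit(t[inner], np.unwrap(ph)[inner], 1)[0]
        assert slope == pytest.approx(2 * np.pi * 11, rel=0.01)

    def test_cosine_peak_phase_zero(self):
        t = np.arange(int(FS * 2)) / FS
        x = np.cos(2 * np.pi * 8 * t)
        ph = instantaneous_phase(x)
        peaks = np.where((x[1:-1] > x[:-2]) & (x[1:-1] > x[2:]))[0] + 1
        peaks = peaks[(peaks > 100) & (peaks < len(t) - 100)]
        assert np.abs(wrap_phase(ph[peaks])).max() < 0.05

    def test_envelope_constant_for_pure_tone(self):
        from scipy.signal import hilbert

        t = np.arange(int(FS * 4)) / FS
        x = np.cos(2 * np.pi * 10 * t)
        pad = int(FS)
        env = np.abs(hilbert(np.r_[x[::-1], x, x[::-1]]))[pad:-pad]
        env = env[len(x) - pad : 2 * len(x) - pad][int(FS // 2) : -int(FS // 2)]
        assert np.ptp(env) / np.mean(env) < 0.04


class TestProjectToPlane:
    def test_planar_distances_preserved(self, grid_4x6):
        coords = project_to_plane(grid_4x6.positions)
        d3 = np.linalg.norm(
            grid_4x6.positions[:, None] - grid_4x6.positions[None, :], axis=-1
        ) / 10.0
        d2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.testing.assert_allclose(d2, d3, atol=1e-9)

    def test_rigid_rotation_invariance(self, grid_4x6, rng):
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        a = project_to_plane(grid_4x6.positions)
        b = project_to_plane(grid_4x6.positions @ rot.T + rng.normal(size=3) * 0)
        da = np.linalg.norm(a[:, None] - a[None, :], axis=-1)
        db = np.linalg.norm(b[:, None] - b[None, :], axis=-1)
        np.testing.assert_allclose(da, db, atol=1e-9)

    def test_collinear_rejected(self):
        pos = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            project_to_plane(pos)


class TestPhaseGradient:
    def coords(self, n=8):
        g = synthetic.GridGeometry.regular_grid(n, n, 10.0)
        return project_to_plane(g.positions)

    def test_planar_field_gradient(self):
        coords = self.coords()
        k = np.array([0.5, 0.0])
        g = phase_gradient(planar_phases(coords, k), coords, step=1.0)
        interior = g.valid.copy()
        interior[0, :] = interior[-1, :] = False
        interior[:, 0] = interior[:, -1] = False
        np.testing.assert_allclose(g.gx[interior], -0.5, rtol=0.05)
        np.testing.assert_allclose(g.gy[interior], 0.0, atol=0.03)

    def test_uniform_phase_zero_gradient(self):
        coords = self.coords()
        g = phase_gradient(np.full(len(coords), 1.2), coords)
        assert np.abs(g.vectors()).max() < 1e-9

    def test_two_pi_invariance(self):
        coords = self.coords()
        ph = planar_phases(coords, [0.3, 0.2])
        g1 = phase_gradient(ph, coords)
        g2 = phase_gradient(ph + 2 * np.pi, coords)
        np.testing.assert_allclose(g1.vectors(), g2.vectors(), atol=1e-9)


class TestPgd:
    def _field(self, vecs):
        n = len(vecs)
        g = waves.GradientField(
            xs=np.arange(n, dtype=float), ys=np.zeros(1),
            gx=np.array([[v[0] for v in vecs]]), gy=np.array([[v[1] for v in vecs]]),
            valid=np.ones((1, n), dtype=bool),
        )
        return g

    def test_identical_gradients(self):
        assert pgd(self._field([(0.3, 0.4)] * 5)) == pytest.approx(1.0)

    def test_opposed_gradients(self):
        assert pgd(self._field([(1.0, 0.0), (-1.0, 0.0)])) == pytest.approx(0.0)

    def test_random_unit_gradients_match_resultant_oracle(self, rng):
        # MC oracle: mean resultant length of n=40 iid unit vectors
        n = 40
        oracle = np.mean(
            [
                np.abs(np.mean(np.exp(1j * rng.uniform(0, 2 * np.pi, n))))
                for _ in range(10_000)
            ]
        )
        vals = [
            pgd(self._field(np.column_stack(
                [np.cos(a := rng.uniform(0, 2 * np.pi, n)), np.sin(a)]
            )))
            for _ in range(2000)
        ]
        assert np.mean(vals) == pytest.approx(oracle, abs=0.03)
        assert oracle == pytest.approx(0.14, abs=0.03)  # analytic ~ sqrt(pi)/(2 sqrt(n))


class TestDirectionSpeed:
    def test_forward_model_direction_convention(self):
        g = synthetic.GridGeometry.regular_grid(8, 6, 10.0)
        coords = project_to_plane(g.positions)
        # wave along +x: phase decreases along +x
        ph = planar_phases(coords, [0.8, 0.0])
        gr = phase_gradient(ph, coords)
        d = wave_direction(gr)
        assert min(d, 360 - d) < 3.0

    def test_rotation_equivariance(self):
        g = synthetic.GridGeometry.regular_grid(8, 6, 10.0)
        coords = project_to_plane(g.positions)
        k = 0.8 * np.array([np.cos(0.4), np.sin(0.4)])
        d1 = wave_direction(phase_gradient(planar_phases(coords, k), coords))
        rot = np.array([[0, -1], [1, 0]])  # +90 degrees
        coords_r = coords @ rot.T
        d2 = wave_direction(phase_gradient(planar_phases(coords_r, rot @ k), coords_r))
        assert (d2 - d1) % 360 == pytest.approx(90.0, abs=2.0)

    def test_uniform_phase_undefined_direction(self):
        g = synthetic.GridGeometry.regular_grid(5, 5, 10.0)
        coords = project_to_plane(g.positions)
        gr = phase_gradient(np.zeros(len(coords)), coords)
        with pytest.raises(ValueError):
            wave_direction(gr)

    def test_speed_analytic(self):
        g = synthetic.GridGeometry.regular_grid(8, 6, 10.0)
        coords = project_to_plane(g.positions)
        gr = phase_gradient(planar_phases(coords, [0.5, 0.0]), coords)
        assert wave_speed(10.0, gr) == pytest.approx(2 * np.pi * 10 / 0.5, rel=0.05)

    def test_speed_halves_when_gradient_doubles(self):
        g = synthetic.GridGeometry.regular_grid(8, 6, 10.0)
        coords = project_to_plane(g.positions)
        s1 = wave_speed(10.0, phase_gradient(planar_phases(coords, [0.4, 0]), coords))
        s2 = wave_speed(10.0, phase_gradient(planar_phases(coords, [0.8, 0]), coords))
        assert s2 == pytest.approx(s1 / 2, rel=0.05)

    def test_forward_model_recovery_snr0(self):
        # v = 15 cm/s at 5 Hz on a 5-mm grid: within +-20% speed, +-10 deg
        geom = synthetic.GridGeometry.regular_grid(8, 8, 5.0)
        spec = synthetic.OscillationSpec(center_freq=5.0, fwhm=2.0, direction=35.0, speed=15.0)
        rng = np.random.default_rng(0)
        n = int(FS * 4)
        sig = synthetic.generate_traveling_oscillation(geom, spec, n, FS, rng)
        noise = synthetic.generate_fractal_background(64, n, FS, 1.5, rng)
        x = sig + noise * sig.std()
        ph = instantaneous_phase(bandpass(x, FS, 5.0, 2.0))
        coords = project_to_plane(geom.positions)
        dirs, speeds = [], []
        for t in np.linspace(FS, n - FS, 25).astype(int):
            gr = phase_gradient(ph[:, t], coords, step=0.5)
            dirs.append(np.radians(wave_direction(gr)))
            speeds.append(wave_speed(5.0, gr))
        mean_dir = np.degrees(circular_mean(np.array(dirs))) % 360
        assert abs(mean_dir - 35.0) < 10.0
        assert np.median(speeds) == pytest.approx(15.0, rel=0.2)


class TestPgdNull:
    def _wave_phases(self, seed=0):
        geom = synthetic.GridGeometry.regular_grid(8, 8, 5.0)
        spec = synthetic.OscillationSpec(center_freq=5.0, fwhm=2.0, direction=0.0, speed=15.0)
        rng = np.random.default_rng(seed)
        n = int(FS * 2)
        sig = synthetic.generate_traveling_oscillation(geom, spec, n, FS, rng)
        ph = instantaneous_phase(bandpass(sig, FS, 5.0, 2.0))
        return ph, project_to_plane(geom.positions)

    def test_strong_wave_minimal_p(self):
        ph, coords = self._wave_phases()
        for scheme in ("time_shuffle", "electrode_shuffle"):
            _, p, _ = pgd_null(ph, coords, scheme, n_perm=100, step=0.5,
                               n_time_samples=10, seed=1)
            assert p == pytest.approx(1 / 101)

    def test_p_in_unit_interval(self, rng):
        geom = synthetic.GridGeometry.regular_grid(4, 4, 10.0)
        coords = project_to_plane(geom.positions)
        ph = rng.uniform(-np.pi, np.pi, (16, 50))
        _, p, _ = pgd_null(ph, coords, "electrode_shuffle", n_perm=50, seed=2)
        assert 0 < p <= 1

    def test_bad_scheme(self):
        with pytest.raises(ValueError):
            pgd_null(np.zeros((4, 10)), np.zeros((4, 2)), "nope", n_perm=10)


class TestDirectionalConsistency:
    def test_identical_directions(self):
        d = np.full((10, 5), 0.7)
        np.testing.assert_allclose(directional_consistency(d), 1.0)

    def test_uniform_directions_match_oracle(self, rng):
        # MC oracle for resultant length of n=50 uniform angles ~ 0.125
        n = 50
        oracle = np.mean(
            [waves.resultant_length(rng.uniform(0, 2 * np.pi, n)) for _ in range(10_000)]
        )
        vals = directional_consistency(rng.uniform(0, 2 * np.pi, (n, 2000)))
        assert np.mean(vals) == pytest.approx(oracle, abs=0.03)
        assert oracle == pytest.approx(0.125, abs=0.03)

    def test_rotation_invariance(self, rng):
        d = rng.uniform(0, 2 * np.pi, (20, 7))
        np.testing.assert_allclose(
            directional_consistency(d), directional_consistency(d + 1.3), atol=1e-12
        )

    def test_monotone_in_jitter(self, rng):
        base = 0.5
        dcs = []
        for jitter in (0.1, 0.5, 1.5):
            d = base + rng.normal(0, jitter, (100, 20))
            dcs.append(np.mean(directional_consistency(d)))
        assert dcs[0] > dcs[1] > dcs[2]

    def test_too_few_trials(self):
        with pytest.raises(ValueError):
            directional_consistency(np.zeros((1, 4)))


class TestRayleigh:
    def test_identical_angles_tiny_p(self):
        z, p = rayleigh_test(np.full(100, 1.0))
        assert p < 1e-15

    def test_uniform_calibration(self, rng):
        rejections = 0
        runs = 1000
        for _ in range(runs):
            _, p = rayleigh_test(rng.uniform(-np.pi, np.pi, 200))
            rejections += p < 0.05
        assert rejections / runs == pytest.approx(0.05, abs=0.02)

    def test_shift_invariance(self, rng):
        a = rng.uniform(-np.pi, np.pi, 60)
        _, p1 = rayleigh_test(a)
        _, p2 = rayleigh_test(a + 2.1)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_matches_pingouin(self, rng):
        from pingouin import circ_rayleigh

        a = rng.vonmises(0.0, 1.0, 80)
        z, p = rayleigh_test(a)
        z_pg, p_pg = circ_rayleigh(a)
        assert z == pytest.approx(z_pg, rel=1e-6)
        assert p == pytest.approx(p_pg, rel=1e-6)

    def test_too_few(self):
        with pytest.raises(ValueError):
            rayleigh_test(np.zeros(3))


class TestDirectionKl:
    def test_identical_distributions_zero(self, rng):
        a = rng.vonmises(0, 2, 500)
        kl, _ = direction_kl(a, a.copy(), n_perm=50, seed=0)
        assert kl == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative(self, rng):
        for _ in range(20):
            kl, _ = direction_kl(
                rng.uniform(-np.pi, np.pi, 100), rng.uniform(-np.pi, np.pi, 100),
                n_perm=10, seed=rng,
            )
            assert kl >= 0

    def test_von_mises_quadrature_oracle(self, rng):
        # two von Mises (kappa=1) 180 degrees apart, 36 bins
        n_bins = 36
        edges = np.linspace(-np.pi, np.pi, n_bins + 1)

        def binned(loc):
            cdf = stats.vonmises.cdf(edges, kappa=1.0, loc=loc)
            return np.diff(cdf)

        pa, pb = binned(0.0), binned(np.pi)
        pb = np.abs(pb) / np.abs(pb).sum()  # wrap-around sign of cdf diff
        pa = np.abs(pa) / np.abs(pa).sum()
        oracle = np.sum(pa * np.log(pa / pb))
        a = rng.vonmises(0.0, 1.0, 10_000)
        b = rng.vonmises(np.pi, 1.0, 10_000)
        kl, p = direction_kl(a, b, n_bins=n_bins, n_perm=200, seed=1)
        assert kl == pytest.approx(oracle, rel=0.05)
        assert p == pytest.approx(1 / 201)

    def test_histogram_probabilities_sum_to_one(self, rng):
        h = direction_histogram(rng.uniform(-np.pi, np.pi, 300))
        assert np.sum(h.probabilities) == pytest.approx(1.0)


class TestRelativePhaseMap:
    def test_reference_is_zero(self, rng):
        ph = rng.uniform(-np.pi, np.pi, (3, 6, 50))
        rel = relative_phase_map(ph, reference=2)
        assert rel[2] == pytest.approx(0.0, abs=1e-12)

    def test_planar_forward_model(self):
        geom = synthetic.GridGeometry.regular_grid(6, 6, 10.0)
        coords = project_to_plane(geom.positions)
        k = np.array([0.4, 0.1])
        ref = 14
        n_t = 200
        carrier = np.linspace(0, 8 * np.pi, n_t)
        ph = wrap_phase(carrier[None, :] - (coords @ k)[:, None])
        rel = relative_phase_map(ph, reference=ref)
        expected = wrap_phase(-(coords - coords[ref]) @ k)
        err = np.abs(wrap_phase(rel - expected))
        assert err.max() < 0.1

    def test_wraparound_average(self):
        ph = np.array([[np.pi - 0.1, -np.pi + 0.1], [0.0, 0.0]])[:, :, None].transpose(2, 0, 1)
        # channels: [pi-0.1, -pi+0.1] over two time samples vs constant ref
        phases = np.stack([np.array([[np.pi - 0.1, -np.pi + 0.1]]), np.zeros((1, 2))], axis=1)
        rel = relative_phase_map(phases[0][None, ...], reference=1)
        assert abs(abs(rel[0]) - np.pi) < 1e-9

    def test_missing_reference(self):
        with pytest.raises(ValueError):
            relative_phase_map(np.zeros((2, 4, 10)), reference=9)
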