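import numpy as np
import pytest
from scipy.signal import welch

from mvpac.simulate import (
    Coupling,
    SimulationConfig,
    add_noise,
    band_of,
    colored_noise,
    forward_project,
    generate_dataset,
    impose_cross_correlation,
    inject_pac,
    spherical_lead_field,
)

FS = 128.0


class TestColoredNoise:
    def _psd_slope(self, beta, n_real=200, T=1024):
        rng = np.random.default_rng(int(beta * 7 + 1))
        psds = []
        for _ in range(n_real):
            x = colored_noise(T, FS, beta, rng)
            f, p = welch(x, fs=FS, nperseg=256)
            psds.append(p)
        p = np.mean(psds, axis=0)
        sel = (f >= 1) & (f <= 60)
        slope = np.polyfit(np.log10(f[sel]), np.log10(p[sel]), 1)[0]
        return slope

    def test_white_noise_flat(self):
        assert abs(self._psd_slope(0.0)) < 0.3

    def test_brownian_slope(self):
        assert self._psd_slope(2.0) == pytest.approx(-2.0, abs=0.3)

    def test_seeding_contract(self):
        a = colored_noise(256, FS, 2.0, 42)
        b = colored_noise(256, FS, 2.0, 42)
        c = colored_noise(256, FS, 2.0, 43)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)


class TestCrossCorrelation:
    def test_identity_target(self, rng):
        X = rng.standard_normal((4, 10_000))
        Y = impose_cross_correlation(X, np.eye(4))
        C = np.corrcoef(Y)
        off = C[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 0.1)

    def test_pairwise_target(self, rng):
        X = rng.standard_normal((2, 10_000))
        target = np.array([[1.0, 0.8], [0.8, 1.0]])
        Y = impose_cross_correlation(X, target)
        r = np.corrcoef(Y)[0, 1]
        assert r == pytest.approx(0.8, abs=0.05)

    def test_output_covariance_expectation(self, rng):
        target = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.3], [0.2, 0.3, 1.0]])
        covs = []
        for _ in range(100):
            X = rng.standard_normal((3, 500))
            Y = impose_cross_correlation(X, target)
            covs.append(Y @ Y.T / Y.shape[1])
        assert np.allclose(np.mean(covs, axis=0), target, atol=0.05)

    def test_non_psd_rejected(self, rng):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        X = rng.standard_normal((2, 100))
        with pytest.raises(ValueError):
            impose_cross_correlation(X, bad)
        # repair clips the negative eigenvalue
        Y = impose_cross_correlation(X, bad, repair=True)
        assert np.all(np.isfinite(Y))


class TestInjectPAC:
    def test_zero_intensity_constant_envelope(self, rng):
        base = colored_noise(512, FS, 2.0, rng)
        _, _, env = inject_pac(base, 6.0, 45.0, 0.0, FS)
        assert np.allclose(env, env[0])

    def test_window_length_at_512hz(self, rng):
        from mvpac.simulate import COUPLING_WINDOW_S

        assert int(round(COUPLING_WINDOW_S * 512)) == 22

    def test_envelope_saturates(self, rng):
        base = colored_noise(256, FS, 2.0, rng)
        _, _, env = inject_pac(base, 7.0, 45.0, 1.0, FS)
        from mvpac.simulate import DC_SHIFT

        assert env.max() <= DC_SHIFT + 1.0 + 1e-12
        assert env.min() >= DC_SHIFT - 1e-12

    def test_bursts_at_phase_maxima(self, rng):
        from mvpac.simulate import bandpass

        base = colored_noise(512, FS, 2.0, rng)
        x_fp, x_fa, env = inject_pac(base, 6.0, 45.0, 1.0, FS)
        # envelope peaks coincide with positive phase-signal values
        peaks = env > 0.9
        assert peaks.any()
        assert x_fp[peaks].mean() > x_fp.std()

    def test_intensity_validation(self, rng):
        base = colored_noise(256, FS, 2.0, rng)
        with pytest.raises(ValueError):
            inject_pac(base, 6.0, 45.0, 1.5, FS)

    def test_band_overlap_validation(self):
        with pytest.raises(ValueError):
            Coupling(0, 1, 40.0, 45.0, 1.0)


class TestForwardProject:
    def test_identity_gain(self, rng):
        from mvpac.simulate import LeadField

        X = rng.standard_normal((4, 100))
        lead = LeadField(gain=np.eye(4))
        assert np.array_equal(forward_project(X, lead), X)

    def test_selector_row(self, rng):
        from mvpac.simulate import LeadField

        X = rng.standard_normal((4, 50))
        gain = np.zeros((2, 4))
        gain[0, 2] = 1.0
        gain[1, 0] = 1.0
        out = forward_project(X, LeadField(gain=gain))
        assert np.array_equal(out[0], X[2])
        assert np.array_equal(out[1], X[0])

    def test_matches_matmul_oracle(self, rng):
        from mvpac.simulate import LeadField

        X = rng.standard_normal((5, 3, 20))
        gain = rng.standard_normal((4, 5))
        out = forward_project(X, LeadField(gain=gain))
        expected = np.einsum("cd,dkt->ckt", gain, X)
        assert np.allclose(out, expected)

    def test_shape_mismatch(self, rng):
        from mvpac.simulate import LeadField

        with pytest.raises(ValueError):
            forward_project(rng.standard_normal((3, 10)), LeadField(np.ones((2, 4))))

    def test_lead_field_validation(self):
        from mvpac.simulate import LeadField

        with pytest.raises(ValueError):
            LeadField(gain=np.zeros((2, 3)))

    def test_spherical_geometry_dominance(self):
        lead = spherical_lead_field(16, 16)
        for d in range(16):
            assert lead.dominant_channel(d) == d


class TestAddNoise:
    def test_zero_db_power_ratio(self, rng):
        x = rng.standard_normal((4, 50_000))
        noisy = add_noise(x, 0.0, rng)
        ratio = np.mean(x**2) / np.mean((noisy - x) ** 2)
        assert ratio == pytest.approx(1.0, rel=0.05)

    def test_six_db_power_ratio(self, rng):
        x = rng.standard_normal((2, 100_000))
        noisy = add_noise(x, 6.0, rng)
        ratio = np.mean(x**2) / np.mean((noisy - x) ** 2)
        assert ratio == pytest.approx(10 ** 0.6, rel=0.05)

    def test_seed_reproducibility(self, rng):
        x = rng.standard_normal((2, 100))
        assert np.array_equal(add_noise(x, 3.0, 5), add_noise(x, 3.0, 5))

    def test_zero_power_rejected(self):
        with pytest.raises(ValueError):
            add_noise(np.zeros((2, 10)), 0.0, 0)


class TestGenerateDataset:
    def _cfg(self, **kw):
        defaults = dict(
            fs=FS, duration=1.0, n_dipoles=8, n_channels=8, n_trials=2,
            n_subjects=2, rng_seed=3,
        )
        defaults.update(kw)
        return SimulationConfig(**defaults)

    def test_no_couplings_empty_truth(self):
        ds = generate_dataset(self._cfg())
        assert all(t == [] for t in ds.truth)

    def test_zero_intensity_truth_empty(self):
        cfg = self._cfg(couplings=[Coupling(0, 4, 6.0, 45.0, 0.0)])
        ds = generate_dataset(cfg)
        assert all(t == [] for t in ds.truth)

    def test_truth_constant_without_variability(self):
        cfg = self._cfg(
            couplings=[Coupling(0, 4, 6.0, 45.0, 1.0), Coupling(1, 5, 10.0, 45.0, 1.0)],
            n_subjects=3,
        )
        ds = generate_dataset(cfg)
        assert ds.truth[0] == ds.truth[1] == ds.truth[2]
        assert ("theta-gamma" in {b for _, _, b in ds.truth[0]})

    def test_determinism(self):
        cfg = self._cfg(couplings=[Coupling(0, 4, 6.0, 45.0, 0.5)])
        d1 = generate_dataset(cfg)
        d2 = generate_dataset(cfg)
        assert np.array_equal(d1.data, d2.data)

    def test_out_of_range_coupling(self):
        cfg = self._cfg(couplings=[Coupling(0, 99, 6.0, 45.0, 1.0)])
        with pytest.raises(ValueError):
            generate_dataset(cfg)

    def test_variability_moves_locations(self):
        cfg = self._cfg(
            n_dipoles=16, n_channels=16,
            couplings=[Coupling(p, p + 8, 6.0, 45.0, 1.0) for p in range(8)],
            variability_fraction=0.25, n_subjects=4, n_trials=1,
        )
        ds = generate_dataset(cfg)
        base = {(c.phase_dipole, c.amp_dipole) for c in cfg.couplings}
        changed = [
            len({(c.phase_dipole, c.amp_dipole) for c in subj} - base)
            for subj in ds.couplings
        ]
        assert any(c > 0 for c in changed)
        for subj in ds.couplings:
            assert all(c.phase_dipole != c.amp_dipole for c in subj)

    def test_band_of(self):
        assert band_of(2) == "delta-gamma"
        assert band_of(6) == "theta-gamma"
        assert band_of(10) == "alpha-gamma"
        assert band_of(20) == "beta-gamma"
        with pytest.raises(ValueError):
            band_of(50)
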