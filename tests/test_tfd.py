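import numpy as np
import pytest
from scipy.signal import hilbert

from mvpac.tfd import (
    AmplitudeSeries,
    Signal,
    ambiguity_function,
    band_amplitude,
    band_phase,
    instantaneous_phase,
    rid_rihaczek,
    rid_rihaczek_batch,
)

FS = 128.0
T = 64


def brute_force_ambiguity(x):
    """Direct double-sum evaluation of the discrete defining formula."""
    x = np.asarray(x, dtype=complex)
    n = x.size
    hl = n // 2
    lags = np.arange(-hl, hl + 1)
    out = np.zeros((n, lags.size), dtype=complex)
    for ki, k in enumerate(range(n)):
        for li, tau in enumerate(lags):
            acc = 0.0 + 0.0j
            for u in range(n):
                if 0 <= u + tau < n and 0 <= u - tau < n:
                    acc += x[u + tau] * np.conj(x[u - tau]) * np.exp(
                        2j * np.pi * k * u / n
                    )
            out[ki, li] = acc
    return out


class TestAmbiguity:
    def test_zero_signal(self):
        surf = ambiguity_function(Signal(np.zeros(16), FS))
        assert np.all(surf.values == 0)

    def test_matches_double_sum_oracle_impulse(self):
        x = np.zeros(16)
        x[8] = 1.0
        surf = ambiguity_function(Signal(x, FS))
        expected = brute_force_ambiguity(x)
        assert np.allclose(surf.values, expected, atol=1e-10)

    def test_matches_double_sum_oracle_random(self, rng):
        x = rng.standard_normal(24)
        surf = ambiguity_function(Signal(x, FS))
        expected = brute_force_ambiguity(x)
        rel = np.linalg.norm(surf.values - expected) / np.linalg.norm(expected)
        assert rel < 1e-8

    def test_origin_is_energy(self, rng):
        x = rng.standard_normal(32)
        surf = ambiguity_function(Signal(x, FS))
        i0 = np.where(surf.lag_axis == 0)[0][0]
        assert surf.values[0, i0].real == pytest.approx(np.sum(x**2))

    def test_hermitian_symmetry(self, rng):
        x = rng.standard_normal(32)
        surf = ambiguity_function(Signal(x, FS))
        n = x.size
        mirrored = surf.values[(-np.arange(n)) % n][:, ::-1]
        assert np.allclose(mirrored, np.conj(surf.values), atol=1e-10)

    def test_nonfinite_rejected(self):
        x = np.zeros(16)
        x[3] = np.nan
        with pytest.raises(ValueError):
            Signal(x, FS)


class TestRidRihaczek:
    def test_zero_signal(self):
        tfd = rid_rihaczek(Signal(np.zeros(32), FS))
        assert np.all(tfd.values == 0)

    def test_sigma_validation(self, rng):
        with pytest.raises(ValueError):
            rid_rihaczek(Signal(rng.standard_normal(32), FS), sigma=0.0)

    def test_rihaczek_limit(self, rng):
        """sigma -> inf recovers the closed-form Rihaczek distribution."""
        x = rng.standard_normal(T)
        tfd = rid_rihaczek(Signal(x, FS), sigma=1e16)
        X = np.fft.fft(x)
        n = np.arange(T)
        f = np.arange(T)
        expected = (
            x[:, None]
            * np.conj(X)[None, :]
            * np.exp(-2j * np.pi * np.outer(n, f) / T)
            / T
        )
        rel = np.linalg.norm(tfd.values - expected) / np.linalg.norm(expected)
        assert rel < 1e-6

    def test_energy(self, rng):
        x = rng.standard_normal(T)
        tfd = rid_rihaczek(Signal(x, FS), sigma=1.0)
        assert tfd.values.sum().real == pytest.approx(np.sum(x**2), rel=0.01)

    def test_time_marginal(self, rng):
        x = np.cos(2 * np.pi * 10 * np.arange(T) / FS)
        tfd = rid_rihaczek(Signal(x, FS), sigma=1.0)
        marginal = tfd.values.sum(axis=1).real
        assert np.allclose(marginal, x**2, atol=1e-8)

    def test_batch_matches_single(self, rng):
        xs = rng.standard_normal((3, T))
        batch, freqs = rid_rihaczek_batch(xs, FS, sigma=1.0)
        for k in range(3):
            single = rid_rihaczek(Signal(xs[k], FS), sigma=1.0)
            assert np.allclose(batch[k], single.values, atol=1e-10)
            assert np.allclose(freqs, single.freq_axis)

    def test_n_freq_bins_too_small(self, rng):
        with pytest.raises(ValueError):
            rid_rihaczek(Signal(rng.standard_normal(T), FS), n_freq_bins=T // 2)


class TestBandAmplitude:
    def test_zero_tfd(self):
        tfd = rid_rihaczek(Signal(np.zeros(64), FS))
        amp = band_amplitude(tfd, 30, 50)
        assert np.all(amp.values == 0)

    def test_envelope_correlation(self, tone_signal):
        x, envelope, fs = tone_signal
        tfd = rid_rihaczek(Signal(x, fs), sigma=1.0)
        amp = band_amplitude(tfd, 40, 50)
        r = np.corrcoef(amp.values[10:-10], envelope[10:-10])[0, 1]
        assert r > 0.9

    def test_out_of_band_leakage(self, tone_signal):
        x, _, fs = tone_signal
        tfd = rid_rihaczek(Signal(x, fs), sigma=5.0)
        in_band = band_amplitude(tfd, 40, 50)
        out_band = band_amplitude(tfd, 5, 15)
        ratio = np.linalg.norm(out_band.values) / np.linalg.norm(in_band.values)
        assert ratio < 0.10

    def test_empty_band_error(self, rng):
        tfd = rid_rihaczek(Signal(rng.standard_normal(64), FS))
        with pytest.raises(ValueError):
            band_amplitude(tfd, 40.2, 40.4)

    def test_invalid_band_order(self, rng):
        tfd = rid_rihaczek(Signal(rng.standard_normal(64), FS))
        with pytest.raises(ValueError):
            band_amplitude(tfd, 50, 40)

    def test_nonnegative_type_invariant(self):
        with pytest.raises(ValueError):
            AmplitudeSeries(values=np.array([-1.0, 0.5]), band=(1, 2))


class TestPhase:
    def test_range(self, rng):
        x = rng.standard_normal(128)
        tfd = rid_rihaczek(Signal(x, FS))
        ph = instantaneous_phase(tfd, 10.0)
        assert np.all(ph.values > -np.pi)
        assert np.all(ph.values <= np.pi)

    def test_unit_modulus_factor(self, rng):
        x = rng.standard_normal(128)
        tfd = rid_rihaczek(Signal(x, FS))
        ph = instantaneous_phase(tfd, 10.0)
        idx = tfd.freq_bin(10.0)
        col = tfd.values[:, idx]
        ok = ~ph.flagged
        assert np.allclose(
            np.abs(col[ok] / np.abs(col[ok])), 1.0, atol=1e-12
        )

    def test_nearest_bin_recorded(self, rng):
        x = rng.standard_normal(128)
        tfd = rid_rihaczek(Signal(x, FS))
        ph = instantaneous_phase(tfd, 10.3)
        assert ph.freq == pytest.approx(10.0)

    def test_zero_tfd_flagged(self):
        tfd = rid_rihaczek(Signal(np.zeros(64), FS))
        ph = instantaneous_phase(tfd, 10.0)
        assert ph.flagged.all()
        assert np.all(ph.values == 0)

    def test_band_phase_matches_quadrature_oracle(self, rng):
        """Band-limited analytic phase agrees with the Hilbert oracle."""
        from mvpac.simulate import bandpass

        x = rng.standard_normal(256)
        tfd = rid_rihaczek(Signal(x, FS), sigma=1e16)
        ph = band_phase(tfd, x, 5.0, 7.0)
        oracle = np.angle(hilbert(bandpass(x, 5.0, 7.0, FS)))
        circ = np.angle(np.exp(1j * (ph.values - oracle)))
        assert np.abs(circ[10:-10]).mean() < 0.2

    def test_band_phase_range_and_band_check(self, rng):
        x = rng.standard_normal(128)
        tfd = rid_rihaczek(Signal(x, FS))
        ph = band_phase(tfd, x, 4.0, 8.0)
        assert np.all(ph.values > -np.pi) and np.all(ph.values <= np.pi)
        with pytest.raises(ValueError):
            band_phase(tfd, x, 8.0, 4.0)
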