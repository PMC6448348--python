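"""Multivariate / noise-assisted EMD and band-wise IMF selection."""

import numpy as np
import pytest

from oscillosource.emd import MonotoneSignalError
from oscillosource.memd import (DEFAULT_BANDS, BandDefinition, DirectionSet,
                                band_power, direction_vectors, median_band_imf,
                                memd_decompose, multivariate_mean,
                                multivariate_mean_reference, na_memd,
                                select_band_imfs)
from tests.conftest import dominant_frequency


class TestDirectionVectors:
    def test_unit_norms(self):
        ds = direction_vectors(5, 16, seed=0)
        assert ds.vectors.shape == (16, 5)
        np.testing.assert_allclose(np.linalg.norm(ds.vectors, axis=1), 1.0,
                                   atol=1e-12)

    def test_deterministic(self):
        a = direction_vectors(4, 16, seed=7)
        b = direction_vectors(4, 16, seed=7)
        np.testing.assert_array_equal(a.vectors, b.vectors)

    def test_circle_gaps_equiangular(self):
        # brute-force angle oracle: sorted angular gaps on the circle
        ds = direction_vectors(2, 64, seed=1)
        ang = np.sort(np.arctan2(ds.vectors[:, 1], ds.vectors[:, 0]))
        gaps = np.diff(np.concatenate([ang, [ang[0] + 2 * np.pi]]))
        assert np.isclose(gaps.mean(), 2 * np.pi / 64)
        assert gaps.std() < 0.2 * gaps.mean()

    def test_univariate_rejected(self):
        with pytest.raises(ValueError):
            direction_vectors(1, 8)

    def test_warns_when_k_below_n(self):
        with pytest.warns(UserWarning):
            DirectionSet(np.eye(5)[:3])


class TestMultivariateMean:
    def test_identical_symmetric_tone_mean_near_zero(self, tone):
        x, fs = tone
        X = np.tile(x, (3, 1))
        m, _ = multivariate_mean(X, direction_vectors(3, 16, seed=0))
        assert np.max(np.abs(m[:, 50:-50])) < 0.05

    def test_shift_equivariance(self, tone):
        x, fs = tone
        X = np.vstack([x, 0.5 * x])
        dirs = direction_vectors(2, 16, seed=0)
        m0, _ = multivariate_mean(X, dirs)
        c = np.array([[1.5], [-2.0]])
        m1, _ = multivariate_mean(X + c, dirs)
        assert np.allclose(m1, m0 + c, atol=1e-9)

    def test_single_channel_rejected(self, tone):
        with pytest.raises(ValueError, match="univariate|emd"):
            multivariate_mean(tone[0][None, :], direction_vectors(2, 8))

    def test_fast_kernel_matches_reference(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((4, 200)).cumsum(axis=1)
        X -= X.mean(axis=1, keepdims=True)
        dirs = direction_vectors(4, 16, seed=2)
        m_fast, a_fast = multivariate_mean(X, dirs)
        m_ref, a_ref = multivariate_mean_reference(X, dirs)
        np.testing.assert_allclose(m_fast, m_ref, atol=1e-12)
        np.testing.assert_allclose(a_fast, a_ref, atol=1e-12)

    def test_trend_signal_raises(self):
        X = np.vstack([np.linspace(0, 1, 64), np.linspace(2, 0, 64)])
        with pytest.raises(MonotoneSignalError):
            multivariate_mean(X, direction_vectors(2, 8, seed=0))


class TestMemdDecompose:
    def test_per_channel_reconstruction(self):
        rng = np.random.default_rng(0)
        t = np.arange(400) / 400.0
        X = np.vstack([
            np.sin(2 * np.pi * 5 * t) + 0.3 * rng.standard_normal(400),
            np.sin(2 * np.pi * 21 * t) + 0.3 * rng.standard_normal(400),
        ])
        dec = memd_decompose(X, K=16, fs=400.0)
        rec = dec.reconstruct()
        assert np.max(np.abs(rec - X)) < 1e-10 * np.max(np.abs(X))

    def test_modes_aligned_across_channels(self, two_tone):
        x, fs = two_tone
        X = np.vstack([x, x])
        dec = memd_decompose(X, K=16, fs=fs)
        for w in range(dec.n_imfs):
            if min(np.std(dec.imfs[w, 0]), np.std(dec.imfs[w, 1])) < 1e-8:
                continue
            f0 = dominant_frequency(dec.imfs[w, 0], fs)
            f1 = dominant_frequency(dec.imfs[w, 1], fs)
            assert abs(f0 - f1) <= 0.5

    def test_homogeneity(self, two_tone):
        x, fs = two_tone
        X = np.vstack([x, np.roll(x, 100)])
        d1 = memd_decompose(X, fs=fs)
        d2 = memd_decompose(2 * X, fs=fs)
        assert d1.n_imfs == d2.n_imfs
        np.testing.assert_allclose(d2.imfs, 2 * d1.imfs,
                                   atol=1e-8 * np.max(np.abs(d1.imfs)))


class TestNaMemd:
    def test_noise_channels_discarded(self, tone):
        x, fs = tone
        dec = na_memd(x[:500], n_noise=6, seed=1, fs=fs)
        assert dec.n_channels == 1
        assert all(r == "data" for r in dec.channel_roles)

    def test_tone_energy_concentrated(self, tone):
        """A pure tone lands in a single data-channel IMF.

        With 12 noise channels the composite lives in 13 dimensions;
        K=16 directions undersample the sphere and leak tone energy
        into neighbouring modes on unlucky noise draws (which is why
        the pipeline medians over realizations).  K=64 resolves the
        envelope average, where the single-mode property holds cleanly.
        """
        x, fs = tone
        dec = na_memd(x, seed=1, fs=fs, K=64)
        fracs = [np.sum(c[0] ** 2) / np.sum(x**2) for c in dec.imfs]
        assert max(fracs) >= 0.90

    def test_noise_channel_filterbank_quasi_dyadic(self):
        # decompose the composite directly to inspect the noise channels
        rng = np.random.default_rng(8)
        x = np.sin(2 * np.pi * 11 * np.arange(500) / 500.0)
        noise = 0.1 * np.std(x) * rng.standard_normal((6, 500))
        dec = memd_decompose(np.vstack([x, noise]), K=16, fs=500.0)
        steps = []
        for ch in range(1, 7):
            cents = []
            for w in range(dec.n_imfs):
                c = dec.imfs[w, ch]
                if np.std(c) < 1e-12:
                    continue
                from scipy.signal import periodogram
                f, p = periodogram(c, fs=500.0)
                cents.append(np.sum(f * p) / np.sum(p))
            good = [c for c in cents if c > 2.0]  # skip trend-level modes
            steps.append(np.mean(np.diff(np.log2(good))))
        assert -1.6 <= np.mean(steps) <= -0.4

    def test_invalid_noise_scale(self, tone):
        with pytest.raises(ValueError):
            na_memd(tone[0], noise_scale=0.0)


class TestBandSelection:
    def test_band_power_tone_in_and_out(self, tone):
        x, fs = tone
        alpha = BandDefinition("alpha", 8, 14)
        theta = BandDefinition("theta", 4, 8)
        total = band_power(x, BandDefinition("all", 0.5, 499), fs)
        assert band_power(x, alpha, fs) >= 0.95 * total
        assert band_power(x, theta, fs) < 0.05 * total

    def test_band_power_zero_signal(self):
        assert band_power(np.zeros(256), BandDefinition("alpha", 8, 14),
                          256.0) == 0.0

    def test_band_above_nyquist_rejected(self, tone):
        with pytest.raises(ValueError):
            band_power(tone[0], BandDefinition("hf", 400, 600), 1000.0)

    def test_select_two_tones(self):
        fs = 500.0
        t = np.arange(500) / fs
        imfs = np.vstack([np.sin(2 * np.pi * 20 * t),
                          np.sin(2 * np.pi * 10 * t)])
        sel = select_band_imfs(imfs, DEFAULT_BANDS, fs)
        assert sel["alpha"] == 1
        assert sel["beta1"] == 0

    def test_single_imf_selected_everywhere(self, tone):
        sel = select_band_imfs(tone[0][None, :], DEFAULT_BANDS, tone[1])
        assert set(sel.values()) == {0}

    def test_tie_breaks_to_lower_index(self):
        fs = 500.0
        t = np.arange(500) / fs
        c = np.sin(2 * np.pi * 10 * t)
        sel = select_band_imfs(np.vstack([c, c]), DEFAULT_BANDS, fs)
        assert sel["alpha"] == 0


class TestMedianBandImf:
    def test_single_realization_equals_selection(self, tone):
        x, fs = tone
        out = median_band_imf(x[:500], n_realizations=1, seed=4, fs=fs,
                              n_noise=6)
        assert len(out) == 1
        alpha = out[0]["alpha"]
        assert len(alpha.selections) == 1
        assert alpha.series.shape == (500,)

    def test_alpha_median_tracks_tone(self, tone):
        x, fs = tone
        out = median_band_imf(x[:500], n_realizations=3, seed=4, fs=fs)
        med = out[0]["alpha"].series
        assert np.corrcoef(med, x[:500])[0, 1] > 0.95

    def test_reproducible(self, tone):
        x, fs = tone
        a = median_band_imf(x[:400], n_realizations=2, seed=9, fs=fs,
                            n_noise=6)
        b = median_band_imf(x[:400], n_realizations=2, seed=9, fs=fs,
                            n_noise=6)
        np.testing.assert_array_equal(a[0]["beta1"].series,
                                      b[0]["beta1"].series)

    def test_rejects_zero_realizations(self, tone):
        with pytest.raises(ValueError):
            median_band_imf(tone[0], n_realizations=0)
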