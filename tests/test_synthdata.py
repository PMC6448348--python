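"""Synthetic leadfields, planted oscillations, trial assembly."""

import numpy as np
import pytest
from scipy.signal import periodogram

from oscillosource.synthdata import (SHELL_RADII, SimulationConfig,
                                     assemble_trials, make_distractors,
                                     make_soi, make_spherical_leadfield,
                                     place_distractors_at_distances,
                                     realized_snr_db, roi_around_vertex,
                                     shell_potential_coeffs)


class TestShellModel:
    def test_matches_homogeneous_closed_form(self):
        """With equal shell conductivities the solver must reproduce the
        single-boundary closed form c_n = (2n+1) b^(n-1) / (4 pi s R^(n+1))."""
        b, R, sigma = 0.07, SHELL_RADII[-1], 0.33
        got = shell_potential_coeffs(b, n_max=60, sigmas=(sigma,) * 3)
        n = np.arange(1, 61)
        expect = (2 * n + 1) * b ** (n - 1) / (4 * np.pi * sigma
                                               * R ** (n + 1))
        np.testing.assert_allclose(got[1:], expect, rtol=1e-10)

    def test_skull_attenuates_potentials(self):
        full = shell_potential_coeffs(0.07)
        homog = shell_potential_coeffs(0.07, sigmas=(0.33,) * 3)
        # low-conductivity skull shrinks every harmonic
        assert np.all(np.abs(full[1:40]) < np.abs(homog[1:40]))

    def test_dipole_outside_brain_rejected(self):
        with pytest.raises(ValueError):
            shell_potential_coeffs(0.09)


class TestLeadfield:
    def test_contract(self, small_leadfield):
        lf = small_leadfield
        assert lf.L.shape == (16, 120)
        assert np.all(np.isfinite(lf.L))
        assert np.all(np.abs(lf.L).max(axis=0) > 0)
        # sensors on the upper scalp hemisphere
        assert np.all(lf.geometry.sensor_positions[:, 2] > 0)
        np.testing.assert_allclose(
            np.linalg.norm(lf.geometry.sensor_positions, axis=1),
            SHELL_RADII[-1], rtol=1e-9)

    def test_deterministic(self):
        a = make_spherical_leadfield(8, 40, seed=5)
        b = make_spherical_leadfield(8, 40, seed=5)
        np.testing.assert_array_equal(a.L, b.L)

    def test_one_hot_source_gives_column(self, small_leadfield):
        from oscillosource.inverse import apply_forward
        lf = small_leadfield
        s = np.zeros((120, 10))
        s[17] = np.arange(10.0)
        y = apply_forward(lf, s, noise_std=0.0)
        np.testing.assert_allclose(y.data, np.outer(lf.L[:, 17],
                                                    np.arange(10.0)))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            make_spherical_leadfield(3, 40)
        with pytest.raises(ValueError):
            make_spherical_leadfield(8, 6)

    def test_roi_around_vertex(self, small_leadfield):
        roi = roi_around_vertex(small_leadfield.geometry, 0, 0.02)
        assert 0 in roi
        d = np.linalg.norm(
            small_leadfield.geometry.vertex_positions[roi]
            - small_leadfield.geometry.vertex_positions[0], axis=1)
        assert np.all(d <= 0.02)


class TestMakeSoi:
    cfg = SimulationConfig(fs=1000.0, duration=1.0)

    def test_amplitude_ratio_follows_one_over_f(self):
        gt = make_soi(self.cfg, trial_seed=1)
        a = [np.max(np.abs(c)) for c in gt.components]
        assert np.isclose(a[0] / a[2], 27.5 / 10.1, rtol=0.02)

    def test_sample_count(self):
        gt = make_soi(self.cfg, trial_seed=1)
        assert gt.components.shape == (3, 1000)

    def test_spectral_peak_within_jitter_band(self):
        gt = make_soi(self.cfg, trial_seed=2)
        f, p = periodogram(gt.components[1], fs=1000.0)
        assert 17.5 <= f[np.argmax(p)] <= 18.5

    def test_zero_jitter_gives_pure_sinusoid_bin(self):
        cfg = SimulationConfig(freq_jitter=0.0, fs=1000.0, duration=1.0)
        gt = make_soi(cfg, trial_seed=3)
        for comp, fc in zip(gt.components, cfg.soi_center_freqs):
            f, p = periodogram(comp, fs=1000.0)
            # peak in the bin nearest the center (27.5 Hz sits exactly
            # between two 1 Hz bins, either neighbour is the peak)
            assert abs(f[np.argmax(p)] - fc) <= 0.5

    def test_instantaneous_frequency_positive(self):
        gt = make_soi(self.cfg, trial_seed=4)
        assert np.all(gt.frequencies > 0)
        # ground-truth phases unwrap monotonically
        for ph in gt.phases:
            un = np.unwrap(ph)
            assert np.all(np.diff(un)[5:-5] > 0)

    def test_overlapping_jitter_warns(self):
        with pytest.warns(UserWarning):
            SimulationConfig(soi_center_freqs=(10.0, 10.5), freq_jitter=0.5)


class TestDistractors:
    def test_narrowband_mass_confined(self):
        cfg = SimulationConfig(distractor_spec=[(0, 14.0)], fs=1000.0)
        d = make_distractors(cfg, trial_seed=5)
        f, p = periodogram(d[0], fs=1000.0)
        outside = p[(f < 13) | (f > 15)].sum() / p.sum()
        assert outside < 0.05

    def test_broadband_mass_confined(self):
        cfg = SimulationConfig(distractor_spec=[(0, "broadband")], fs=1000.0)
        d = make_distractors(cfg, trial_seed=5)
        f, p = periodogram(d[0], fs=1000.0)
        outside = p[(f < 4) | (f > 30)].sum() / p.sum()
        assert outside < 0.05

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError):
            make_distractors(SimulationConfig(), trial_seed=0)

    def test_distance_placement(self, small_leadfield):
        geom = small_leadfield.geometry
        picks = place_distractors_at_distances(geom, 0, (0.03, 0.05), seed=1)
        d = np.linalg.norm(geom.vertex_positions[picks]
                           - geom.vertex_positions[0], axis=1)
        assert abs(d[0] - 0.03) < 0.01 and abs(d[1] - 0.05) < 0.01

    def test_excessive_distance_warns(self, small_leadfield):
        with pytest.warns(UserWarning, match="extent"):
            place_distractors_at_distances(small_leadfield.geometry, 0,
                                           (5.0,), seed=1)


class TestAssembleTrials:
    def _cfg(self, **kw):
        base = dict(soi_vertex=3, distractor_spec=[(40, 14.0)], snr_db=0.0,
                    n_trials=3, fs=500.0, duration=1.0, seed=9)
        base.update(kw)
        return SimulationConfig(**base)

    def test_snr_holds_exactly(self, small_leadfield):
        for snr in (0.0, 20.0, -5.0):
            epochs, truths = assemble_trials(small_leadfield,
                                             self._cfg(snr_db=snr))
            for e, t in zip(epochs, truths):
                assert realized_snr_db(e, t) == pytest.approx(snr, abs=1e-9)

    def test_zero_db_noise_matches_signal_std(self, small_leadfield):
        epochs, truths = assemble_trials(small_leadfield, self._cfg())
        noise = epochs[0].data - truths[0].clean_projection
        assert np.isclose(noise.std(), truths[0].clean_projection.std(),
                          rtol=1e-12)

    def test_deterministic_and_prefix_stable(self, small_leadfield):
        e1, _ = assemble_trials(small_leadfield, self._cfg(n_trials=3))
        e2, _ = assemble_trials(small_leadfield, self._cfg(n_trials=5))
        for a, b in zip(e1, e2):
            np.testing.assert_array_equal(a.data, b.data)

    def test_trials_distinct(self, small_leadfield):
        epochs, _ = assemble_trials(small_leadfield, self._cfg())
        assert not np.array_equal(epochs[0].data, epochs[1].data)

    def test_invalid_vertex_rejected(self, small_leadfield):
        with pytest.raises(ValueError):
            assemble_trials(small_leadfield, self._cfg(soi_vertex=10_000))


def test_trials_roundtrip(tmp_path, small_leadfield):
    from oscillosource.io import (load_leadfield, load_trials, save_leadfield,
                                  save_trials)
    cfg = SimulationConfig(soi_vertex=3, distractor_spec=[(40, 14.0)],
                           n_trials=2, fs=500.0, seed=1)
    epochs, truths = assemble_trials(small_leadfield, cfg)
    save_trials(tmp_path / "trials.h5", epochs, truths)
    back_e, back_t = load_trials(tmp_path / "trials.h5")
    np.testing.assert_allclose(back_e[1].data, epochs[1].data)
    np.testing.assert_allclose(back_t[0].phases, truths[0].phases)
    for suffix in (".h5", ".npz"):
        save_leadfield(tmp_path / f"lf{suffix}", small_leadfield)
        lf2 = load_leadfield(tmp_path / f"lf{suffix}")
        np.testing.assert_allclose(lf2.L, small_leadfield.L)
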