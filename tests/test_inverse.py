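"""Forward model, REST re-referencing, Bayesian inverse, selections."""

import numpy as np
import pytest

from oscillosource.inverse import (InverseConfig, apply_forward,
                                   extract_roi_sources, nearest_sensors,
                                   rest_transform, solve_inverse)
from oscillosource.synthdata import Geometry, Leadfield


def _identity_leadfield(D=20, seed=0):
    rng = np.random.default_rng(seed)
    pos = rng.standard_normal((D, 3)) * 10.0  # meters apart: G ~ I
    ori = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    geom = Geometry(sensor_positions=pos, vertex_positions=pos,
                    vertex_orientations=ori)
    return Leadfield(L=np.eye(D), geometry=geom)


class TestApplyForward:
    def test_zero_sources_zero_epoch(self, small_leadfield):
        y = apply_forward(small_leadfield, np.zeros((120, 5)), 0.0)
        assert not np.any(y.data)

    def test_linearity(self, small_leadfield):
        rng = np.random.default_rng(1)
        S1 = rng.standard_normal((120, 8))
        S2 = rng.standard_normal((120, 8))
        y = apply_forward(small_leadfield, 2 * S1 + S2, 0.0).data
        y12 = (2 * apply_forward(small_leadfield, S1, 0.0).data
               + apply_forward(small_leadfield, S2, 0.0).data)
        np.testing.assert_allclose(y, y12, atol=1e-12)

    def test_dimension_mismatch(self, small_leadfield):
        with pytest.raises(ValueError):
            apply_forward(small_leadfield, np.zeros((7, 5)))


class TestRest:
    def test_recovers_reference_free_single_source(self, dense_leadfield):
        # REST accuracy grows with montage density; use a full 61-channel
        # montage as in typical TMS-EEG caps
        rng = np.random.default_rng(2)
        geom = dense_leadfield.geometry
        D = geom.n_vertices
        # a superficial source under the montage: sources far from every
        # sensor project mostly as the constant offset REST cannot restore
        v = int(np.argmax(geom.vertex_positions[:, 2]))
        S = np.zeros((D, 40))
        S[v] = rng.standard_normal(40)
        Yc = dense_leadfield.L @ S
        Y_avg = Yc - Yc.mean(axis=0, keepdims=True)
        Yr = rest_transform(Y_avg, dense_leadfield)
        assert np.linalg.norm(Yr - Yc) / np.linalg.norm(Yc) < 0.05

    def test_residual_is_common_offset(self, small_leadfield):
        """REST can only miss the spatially constant part (the reference
        ambiguity): the error must be identical on every channel."""
        rng = np.random.default_rng(3)
        Yc = small_leadfield.L @ rng.standard_normal((120, 20))
        Yr = rest_transform(Yc, small_leadfield)
        err = Yr - Yc
        assert np.allclose(err - err.mean(axis=0, keepdims=True), 0,
                           atol=1e-10 * np.abs(Yc).max())

    def test_linear_and_idempotent(self, small_leadfield):
        rng = np.random.default_rng(4)
        Y1 = rng.standard_normal((16, 30))
        Y2 = rng.standard_normal((16, 30))
        lin = rest_transform(3 * Y1 - Y2, small_leadfield)
        parts = 3 * rest_transform(Y1, small_leadfield) \
            - rest_transform(Y2, small_leadfield)
        np.testing.assert_allclose(lin, parts, atol=1e-9)
        once = rest_transform(Y1, small_leadfield)
        twice = rest_transform(once, small_leadfield)
        np.testing.assert_allclose(twice, once, atol=1e-6 * np.abs(once).max())


class TestSolveInverse:
    def test_identity_leadfield_limit(self):
        lf = _identity_leadfield()
        rng = np.random.default_rng(5)
        Y = rng.standard_normal((20, 50))
        est = solve_inverse(Y, lf, InverseConfig(fixed_noise_variance=1e-12))
        assert np.linalg.norm(est.S - Y) / np.linalg.norm(Y) < 0.01

    def test_free_energy_nondecreasing(self, small_leadfield):
        rng = np.random.default_rng(6)
        Y = small_leadfield.L @ rng.standard_normal((120, 30))
        Y += 0.1 * Y.std() * rng.standard_normal(Y.shape)
        est = solve_inverse(Y, small_leadfield)
        assert np.all(np.diff(est.free_energy) >= -1e-9 *
                      np.abs(est.free_energy[0]))

    def test_scaling_equivariance(self, small_leadfield):
        rng = np.random.default_rng(7)
        Y = small_leadfield.L @ rng.standard_normal((120, 30))
        e1 = solve_inverse(Y, small_leadfield)
        e2 = solve_inverse(4.2 * Y, small_leadfield)
        assert (np.linalg.norm(e2.S - 4.2 * e1.S)
                / np.linalg.norm(4.2 * e1.S)) < 0.01

    def test_planted_source_recovered(self, dense_leadfield):
        # mesh spacing must be finer than the 2 cm localization bound,
        # hence the dense fixture
        geom = dense_leadfield.geometry
        D = geom.n_vertices
        upper = np.flatnonzero(geom.vertex_positions[:, 2] > 0)
        for rep in range(3):
            rng = np.random.default_rng(50 + rep)
            v = int(rng.choice(upper))
            S = np.zeros((D, 150))
            S[v] = np.sin(2 * np.pi * 10 * np.arange(150) / 1000.0)
            clean = dense_leadfield.L @ S
            Y = clean + clean.std() / np.sqrt(10) \
                * rng.standard_normal(clean.shape)
            est = solve_inverse(Y, dense_leadfield)
            vhat = int(np.argmax(np.mean(est.S**2, axis=1)))
            dist = np.linalg.norm(geom.vertex_positions[vhat]
                                  - geom.vertex_positions[v])
            assert dist <= 0.02


class TestSelections:
    def test_extract_roi_orders_by_power(self):
        est_S = np.zeros((10, 20))
        est_S[4] = 3.0
        est_S[7] = 1.0
        from oscillosource.inverse import SourceEstimate
        est = SourceEstimate(S=est_S)
        series, idx = extract_roi_sources(est, [2, 4, 7], 2)
        assert list(idx) == [4, 7]
        np.testing.assert_array_equal(series[0], est_S[4])

    def test_tie_breaks_to_lower_vertex(self):
        from oscillosource.inverse import SourceEstimate
        est = SourceEstimate(S=np.ones((6, 10)))
        _, idx = extract_roi_sources(est, [5, 1, 3], 2)
        assert list(idx) == [1, 3]

    def test_oversized_request_warns(self):
        from oscillosource.inverse import SourceEstimate
        est = SourceEstimate(S=np.random.default_rng(0).random((6, 10)))
        with pytest.warns(UserWarning):
            series, idx = extract_roi_sources(est, [0, 1, 2], 4)
        assert series.shape[0] == 3

    def test_empty_roi_rejected(self):
        from oscillosource.inverse import SourceEstimate
        with pytest.raises(ValueError):
            extract_roi_sources(SourceEstimate(S=np.ones((3, 4))), [], 1)

    def test_nearest_sensors(self, small_leadfield):
        geom = small_leadfield.geometry
        target = geom.sensor_positions[5]
        assert nearest_sensors(geom, target, 1)[0] == 5
        all_idx = nearest_sensors(geom, target, geom.n_sensors)
        assert len(all_idx) == geom.n_sensors
        d = np.linalg.norm(geom.sensor_positions[all_idx] - target, axis=1)
        assert np.all(np.diff(d) >= 0)

    def test_nearest_sensor_tie_lower_index(self):
        pos = np.array([[1.0, 0, 1], [-1.0, 0, 1], [0, 1.0, 1],
                        [0, -1.0, 1]])
        geom = Geometry(sensor_positions=pos,
                        vertex_positions=np.vstack([pos, pos]),
                        vertex_orientations=np.tile([0, 0, 1.0], (8, 1)))
        assert nearest_sensors(geom, [0.0, 0.0, 1.0], 1)[0] == 0
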