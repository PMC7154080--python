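"""Hilbert phases, phase lag index, PLI matrices and node degree."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from plimse.connectivity import (
    PLIMatrix,
    hilbert_phase,
    node_degree,
    phase_difference,
    pli,
    pli_matrix,
)
from plimse.preprocess import segment_epochs
from plimse.recording import Recording
from plimse.synthetic import make_common_source_pair


def cos_recording(freq=10.0, n=1000, fs=200.0, scale=1.0, channels=1):
    t = np.arange(n) / fs
    return Recording(np.tile(scale * np.cos(2 * np.pi * freq * t), (channels, 1)),
                     fs, tuple(f"c{i}" for i in range(channels)))


class TestHilbertPhase:
    def test_phase_advances_at_carrier_frequency(self):
        freq, fs = 10.0, 200.0
        ph = hilbert_phase(cos_recording(freq, fs=fs))
        unwrapped = np.unwrap(ph.phases[0, 0, 100:-100])
        increments = np.diff(unwrapped)
        assert np.allclose(increments, 2 * np.pi * freq / fs, atol=1e-3)

    def test_phase_is_scale_invariant(self):
        a = hilbert_phase(cos_recording(scale=1.0))
        b = hilbert_phase(cos_recording(scale=5.0))
        # compare on the circle: raw values may sit on opposite sides of +/-pi
        d = phase_difference(a.phases.ravel(), b.phases.ravel())
        np.testing.assert_allclose(d, 0.0, atol=1e-9)

    def test_amplitude_envelope_retained(self):
        ph = hilbert_phase(cos_recording(scale=3.0))
        assert np.median(ph.amplitudes) == pytest.approx(3.0, rel=0.01)

    def test_zero_channel_rejected(self):
        rec = Recording(np.zeros((1, 500)), 200.0, ("z",))
        with pytest.raises(ValueError):
            hilbert_phase(rec)


class TestPhaseDifference:
    def test_identical_inputs_give_zero(self):
        phi = np.linspace(-3, 3, 100)
        np.testing.assert_array_equal(phase_difference(phi, phi), np.zeros(100))

    def test_constant_offset_preserved(self):
        phi = np.linspace(-3, 3, 100)
        d = phase_difference(phi + np.pi / 2, phi)
        np.testing.assert_allclose(d, np.pi / 2)

    def test_offset_beyond_pi_wraps(self):
        d = phase_difference(np.array([3 * np.pi / 2]), np.array([0.0]))
        assert d[0] == pytest.approx(-np.pi / 2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            phase_difference(np.zeros(5), np.zeros(4))

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=30))
    def test_wrapped_into_half_open_interval(self, values):
        d = phase_difference(np.array(values), np.zeros(len(values)))
        assert np.all(d > -np.pi) and np.all(d <= np.pi)


class TestPLI:
    def test_zero_differences_give_zero(self):
        assert pli(np.zeros(100)) == 0.0

    def test_constant_lag_gives_one(self):
        assert pli(np.full(100, np.pi / 2)) == 1.0

    def test_random_differences_stay_below_noise_floor(self):
        rng = np.random.default_rng(0)
        values = [pli(rng.uniform(-np.pi, np.pi, 1000)) for _ in range(200)]
        # |mean sign| of T fair coin flips scales as 1/sqrt(T)
        assert np.mean(np.array(values) < 0.08) >= 0.95

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            pli(np.array([]))


class TestPLIMatrix:
    def test_repeated_epochs_equal_single_epoch(self, rng):
        rec = Recording(rng.standard_normal((3, 1000)), 200.0, ("a", "b", "c"))
        single = pli_matrix(hilbert_phase(rec))
        repeated_data = np.repeat(
            segment_epochs(rec, 5.0).data, 10, axis=0)
        ph = hilbert_phase(rec)
        ph.phases = np.repeat(ph.phases, 10, axis=0)
        ph.amplitudes = np.repeat(ph.amplitudes, 10, axis=0)
        repeated = pli_matrix(ph)
        np.testing.assert_allclose(repeated.values, single.values, atol=1e-12)

    def test_sixteen_channels_give_120_pairs(self, rng):
        rec = Recording(rng.standard_normal((16, 1000)), 200.0,
                        tuple(f"e{i}" for i in range(16)))
        mat = pli_matrix(hilbert_phase(rec))
        iu = np.triu_indices(16, 1)
        assert iu[0].size == 120
        assert np.allclose(mat.values, mat.values.T)
        assert np.all(np.diag(mat.values) == 0)
        assert mat.values.min() >= 0 and mat.values.max() <= 1

    def test_common_source_pair_scores_zero(self):
        rec = make_common_source_pair(1000, 200.0, 1.0, 3.0)
        mat = pli_matrix(hilbert_phase(rec))
        assert mat.values[0, 1] == 0.0

    def test_swap_and_rescale_invariance(self, rng):
        data = rng.standard_normal((2, 2000))
        a = pli_matrix(hilbert_phase(Recording(data, 200.0, ("a", "b"))))
        swapped = pli_matrix(hilbert_phase(Recording(data[::-1], 200.0, ("b", "a"))))
        scaled = pli_matrix(hilbert_phase(
            Recording(data * np.array([[2.0], [7.0]]), 200.0, ("a", "b"))))
        assert a.values[0, 1] == pytest.approx(swapped.values[0, 1], abs=1e-12)
        assert a.values[0, 1] == pytest.approx(scaled.values[0, 1], abs=1e-9)

    def test_volume_conduction_rejected(self, rng):
        # a large zero-lag common component must not raise PLI above the
        # independent-channel noise floor
        floors, with_common = [], []
        for seed in range(20):
            r = np.random.default_rng(seed)
            independent = r.standard_normal((2, 2000))
            common = 20.0 * r.standard_normal(2000)
            rec_i = Recording(independent, 200.0, ("a", "b"))
            rec_c = Recording(independent + common, 200.0, ("a", "b"))
            floors.append(pli_matrix(hilbert_phase(rec_i)).values[0, 1])
            with_common.append(pli_matrix(hilbert_phase(rec_c)).values[0, 1])
        assert np.mean(with_common) <= np.mean(floors) + 0.03

    def test_single_channel_rejected(self, rng):
        rec = Recording(rng.standard_normal((1, 500)), 200.0, ("a",))
        with pytest.raises(ValueError):
            pli_matrix(hilbert_phase(rec))


class TestNodeDegree:
    def test_constant_matrix_gives_constant_degree(self):
        values = np.full((4, 4), 0.3)
        np.fill_diagonal(values, 0.0)
        mat = PLIMatrix(values, ("a", "b", "c", "d"))
        np.testing.assert_allclose(node_degree(mat), 0.3)

    def test_sixteen_channel_vector_length(self, rng):
        v = rng.uniform(0, 1, (16, 16))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0.0)
        mat = PLIMatrix(v, tuple(f"e{i}" for i in range(16)))
        nd = node_degree(mat)
        assert nd.shape == (16,)
        # direct row-mean-excluding-diagonal summation oracle
        for a in range(16):
            expected = sum(v[a, b] for b in range(16) if b != a) / 15
            assert nd[a] == pytest.approx(expected)

    def test_single_channel_rejected(self):
        mat = PLIMatrix(np.zeros((1, 1)), ("a",))
        with pytest.raises(ValueError):
            node_degree(mat)
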