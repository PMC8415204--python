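"""Envelope pipeline operations against constructed oracles."""

import numpy as np
import pytest

from oscillomap.bands import ALPHA, GAMMA1
from oscillomap.envelope import (
    aec_matrix,
    bandpass,
    concatenate_epochs,
    downsample_envelope,
    envelopes_for_recording,
    hilbert_envelope,
    median_filter_envelope,
    select_region_representatives,
    symmetric_orthogonalize,
)
from oscillomap.recording import EnvelopeSet, EpochedRecording

FS = 600.0


def _rec(data, fs=FS, epoch=2.0):
    return EpochedRecording(data=data, fs=fs, epoch_length_s=epoch)


class TestRegionReduction:
    def test_max_sd_voxel_selected(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(1200)
        other = rng.standard_normal(1200)
        voxels = np.vstack([1.0 * base, 3.0 * base, 2.0 * base, other])
        rec = select_region_representatives(
            voxels, np.array([0, 0, 0, 1]), fs=FS
        )
        np.testing.assert_array_equal(rec.data[0], 3.0 * base)
        np.testing.assert_array_equal(rec.data[1], other)

    def test_one_voxel_per_region_identity(self):
        rng = np.random.default_rng(1)
        voxels = rng.standard_normal((3, 1200))
        rec = select_region_representatives(voxels, np.array([0, 1, 2]), fs=FS)
        np.testing.assert_array_equal(rec.data, voxels)

    def test_sd_tie_broken_by_lowest_index(self):
        rng = np.random.default_rng(2)
        v = rng.standard_normal(1200)
        voxels = np.vstack([-v, v, rng.standard_normal(1200)])  # rows 0,1 tie
        rec = select_region_representatives(
            voxels, np.array([0, 0, 1]), fs=FS
        )
        np.testing.assert_array_equal(rec.data[0], -v)


class TestBandpass:
    def test_in_band_tone_passes(self):
        t = np.arange(int(FS * 10)) / FS
        tone = np.sin(2 * np.pi * 10.0 * t)
        rec = _rec(np.vstack([tone, tone]))
        out = bandpass(rec, ALPHA)
        rms_in = np.sqrt(np.mean(tone**2))
        rms_out = np.sqrt(np.mean(out.data[0] ** 2))
        assert rms_out >= 0.9 * rms_in

    def test_out_of_band_tone_blocked(self):
        t = np.arange(int(FS * 10)) / FS
        tone = np.sin(2 * np.pi * 10.0 * t)
        rec = _rec(np.vstack([tone, tone]))
        out = bandpass(rec, GAMMA1)
        assert np.sqrt(np.mean(out.data[0] ** 2)) <= 0.05 * np.sqrt(np.mean(tone**2))

    def test_zero_in_zero_out(self):
        rec = _rec(np.zeros((2, 2400)))
        np.testing.assert_allclose(bandpass(rec, ALPHA).data, 0.0)

    def test_band_above_nyquist_rejected(self):
        rec = _rec(np.random.default_rng(0).standard_normal((2, 600)), fs=150, epoch=2.0)
        from oscillomap.bands import GAMMA3

        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(rec, GAMMA3)


class TestConcatenateEpochs:
    def test_length_preserved(self):
        rng = np.random.default_rng(3)
        rec = _rec(rng.standard_normal((2, 5 * 1200)))
        assert concatenate_epochs(rec).shape == (2, 6000)

    def test_temporal_order_preserved(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((2, 2 * 1200))
        rec = _rec(data)
        out = concatenate_epochs(rec)
        # first sample of epoch 2 directly follows last sample of epoch 1
        assert out[0, 1200] == data[0, 1200]
        np.testing.assert_array_equal(out, data)


class TestSymmetricOrthogonalize:
    def test_orthogonal_input_unchanged(self):
        t = np.arange(600) / 600.0
        a = np.sin(2 * np.pi * 5 * t)
        b = np.cos(2 * np.pi * 5 * t)
        X = np.vstack([a, b])
        out = symmetric_orthogonalize(X)
        np.testing.assert_allclose(out, X, atol=1e-8)

    def test_correlated_rows_become_orthogonal(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(2000)
        y = 0.9 * x + np.sqrt(1 - 0.81) * rng.standard_normal(2000)
        X = np.vstack([x, y, rng.standard_normal(2000)])
        out = symmetric_orthogonalize(X)
        G = out @ out.T
        norms = np.sqrt(np.diag(G))
        off = G / np.outer(norms, norms)
        np.fill_diagonal(off, 0.0)
        assert np.max(np.abs(off)) <= 1e-6

    def test_closest_property_beats_naive_projection(self):
        """The symmetric solution is closer to the input (Frobenius) than
        sequential Gram-Schmidt with row rescaling."""
        rng = np.random.default_rng(6)
        X = rng.standard_normal((4, 500))
        X[1] = 0.7 * X[0] + 0.7 * X[1]
        sym = symmetric_orthogonalize(X)
        Q, _ = np.linalg.qr(X.T)
        gs = (Q * np.linalg.norm(X, axis=1)).T
        assert np.linalg.norm(X - sym) <= np.linalg.norm(X - gs) + 1e-9

    def test_more_nodes_than_samples_rejected(self):
        with pytest.raises(ValueError, match="time points"):
            symmetric_orthogonalize(np.ones((3, 2)))

    def test_rank_deficient_rejected(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(100)
        with pytest.raises(ValueError, match="rank deficient"):
            symmetric_orthogonalize(np.vstack([x, 2 * x, rng.standard_normal(100)]))

    def test_permutation_equivariant(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((5, 400))
        perm = np.array([3, 0, 4, 1, 2])
        np.testing.assert_allclose(
            symmetric_orthogonalize(X[perm]),
            symmetric_orthogonalize(X)[perm],
            atol=1e-8,
        )


class TestHilbertEnvelope:
    def test_unit_sinusoid_envelope_one(self):
        t = np.arange(6000) / FS
        x = np.sin(2 * np.pi * 10 * t)[None, :]
        env = hilbert_envelope(x)
        interior = env[0, 600:-600]
        assert np.all(np.abs(interior - 1.0) < 0.02)

    def test_am_modulation_recovered(self):
        t = np.arange(12000) / FS
        a = 1.0 + 0.5 * np.sin(2 * np.pi * 0.4 * t)  # slow positive envelope
        x = (a * np.sin(2 * np.pi * 11 * t))[None, :]
        env = hilbert_envelope(x)[0]
        interior = slice(1200, -1200)
        rel = np.abs(env[interior] - a[interior]) / a[interior]
        assert np.max(rel) < 0.05

    def test_zero_signal_zero_envelope(self):
        np.testing.assert_allclose(hilbert_envelope(np.zeros((2, 100))), 0.0)


class TestDownsampleEnvelope:
    def test_constant_envelope(self):
        env = np.full((2, 3000), 3.7)
        es = downsample_envelope(env, FS, ALPHA)
        np.testing.assert_allclose(es.env, 3.7)
        assert es.env.shape == (2, 5)

    def test_trailing_partial_window_discarded(self):
        env = np.ones((1, 1500))
        es = downsample_envelope(env, FS, ALPHA)
        assert es.env.shape == (1, 2)

    def test_window_means_match_bruteforce(self):
        ramp = np.arange(1800, dtype=float)[None, :]
        es = downsample_envelope(ramp, FS, ALPHA)
        expected = [ramp[0, i * 600:(i + 1) * 600].mean() for i in range(3)]
        np.testing.assert_allclose(es.env[0], expected, rtol=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="shorter than 1 s"):
            downsample_envelope(np.ones((1, 100)), FS, ALPHA)


class TestMedianFilter:
    def _es(self, arr):
        return EnvelopeSet(env=np.asarray(arr, dtype=float), band=ALPHA)

    def test_k1_is_identity(self):
        es = self._es([[1.0, 5.0, 2.0, 8.0, 3.0]])
        out = median_filter_envelope(es, k=1)
        np.testing.assert_array_equal(out.env, es.env)

    def test_spike_removed(self):
        es = self._es([[1.0, 1.0, 9.0, 1.0, 1.0]])
        out = median_filter_envelope(es, k=3)
        np.testing.assert_allclose(out.env, 1.0)

    def test_constant_unchanged(self):
        es = self._es([np.full(10, 2.5)])
        np.testing.assert_allclose(median_filter_envelope(es, k=5).env, 2.5)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            median_filter_envelope(self._es([[1.0, 2.0, 3.0]]), k=2)

    def test_matches_bruteforce_sliding_median(self):
        rng = np.random.default_rng(9)
        x = rng.random(30)
        es = self._es([x])
        out = median_filter_envelope(es, k=5).env[0]
        padded = np.concatenate([x[:2][::-1], x, x[-2:][::-1]])  # reflect
        expected = [np.median(padded[i:i + 5]) for i in range(30)]
        np.testing.assert_allclose(out, expected)


class TestAecMatrix:
    def _es(self, env):
        return EnvelopeSet(env=env, band=ALPHA)

    def test_two_nodes_single_edge(self):
        rng = np.random.default_rng(10)
        cm = aec_matrix(self._es(np.abs(rng.standard_normal((2, 50)))))
        assert cm.n_edges == 1
        assert np.isnan(cm.values[0, 0]) and np.isnan(cm.values[1, 1])

    def test_90_nodes_4005_unique_edges(self):
        rng = np.random.default_rng(11)
        cm = aec_matrix(self._es(np.abs(rng.standard_normal((90, 20)) + 5)))
        assert cm.n_edges == 4005
        assert cm.upper_values().shape == (4005,)

    def test_scaled_node_perfectly_correlated(self):
        rng = np.random.default_rng(12)
        a = np.abs(rng.standard_normal(40)) + 1
        cm = aec_matrix(self._es(np.vstack([a, 2 * a])))
        assert cm.values[0, 1] == pytest.approx(1.0)

    def test_matches_bruteforce_pairwise_oracle(self):
        rng = np.random.default_rng(13)
        env = np.abs(rng.standard_normal((5, 60))) + 0.5
        cm = aec_matrix(self._es(env))
        for i in range(5):
            for j in range(i + 1, 5):
                xi, xj = env[i], env[j]
                r = np.sum((xi - xi.mean()) * (xj - xj.mean())) / (
                    np.sqrt(np.sum((xi - xi.mean()) ** 2))
                    * np.sqrt(np.sum((xj - xj.mean()) ** 2))
                )
                assert cm.values[i, j] == pytest.approx(r, abs=1e-12)
                assert cm.values[j, i] == cm.values[i, j]

    def test_zero_variance_node_named_in_error(self):
        env = np.vstack([np.ones(20), np.arange(20, dtype=float)])
        with pytest.raises(ValueError, match="node000"):
            aec_matrix(self._es(env))


class TestPipelineEquivariance:
    def test_node_permutation_permutes_envelopes(self):
        rng = np.random.default_rng(14)
        data = rng.standard_normal((4, int(150 * 30)))
        rec = EpochedRecording(data=data, fs=150.0, epoch_length_s=2.0)
        perm = np.array([2, 0, 3, 1])
        rec_p = EpochedRecording(data=data[perm], fs=150.0, epoch_length_s=2.0)
        env = envelopes_for_recording(rec, ALPHA)
        env_p = envelopes_for_recording(rec_p, ALPHA)
        np.testing.assert_allclose(env_p.env, env.env[perm], atol=1e-8)
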