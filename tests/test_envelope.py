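"""Envelope preprocessing: filter response, analytic amplitude,
sliding-window downsampling, normalisation, leakage correction, PCA
collapse and concatenation."""

import numpy as np
import pytest
from scipy import optimize

from netdyn import (
    bandpass,
    concatenate_subjects,
    envelope_pipeline,
    hilbert_envelope,
    make_ground_truth,
    normalize_subject,
    pca_parcel_timecourse,
    simulate_raw_oscillation,
    simulate_state_path,
    symmetric_orthogonalize,
    window_downsample,
)


def sinusoid(freq, fs, seconds, amp=1.0):
    t = np.arange(int(fs * seconds)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_passband_gain_near_unity(self):
        x = sinusoid(10.0, 250.0, 8.0)
        y = bandpass(x, 250.0, 4.0, 30.0)[0]
        realized = np.abs(y[500:-500]).max()
        assert realized == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuated_20db(self):
        x = sinusoid(1.0, 250.0, 8.0)
        y = bandpass(x, 250.0, 4.0, 30.0)[0]
        atten = 20 * np.log10(np.abs(y[500:-500]).max() / 1.0)
        assert atten <= -20.0

    def test_zero_phase_no_delay_between_parcels(self):
        x = sinusoid(10.0, 250.0, 4.0)
        two = np.vstack([x, x])
        y = bandpass(two, 250.0)
        assert np.allclose(y[0], y[1])
        # zero-phase: filtered output stays aligned with the input
        interior = slice(200, -200)
        lag = np.argmax(np.correlate(y[0][interior], x[interior], "full")) - (
            x[interior].size - 1
        )
        assert lag == 0

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(100), 250.0, 4.0, 130.0)


class TestHilbertEnvelope:
    def test_unit_sinusoid_envelope_one(self):
        env = hilbert_envelope(sinusoid(10.0, 250.0, 4.0))
        assert np.all(np.abs(env[0, 100:-100] - 1.0) < 0.02)

    def test_zero_signal(self):
        assert np.allclose(hilbert_envelope(np.zeros((3, 100))), 0.0)

    def test_tracks_slow_modulator(self):
        fs, secs = 250.0, 8.0
        t = np.arange(int(fs * secs)) / fs
        modulator = 1.0 + 0.5 * np.sin(2 * np.pi * 0.5 * t)
        carrier = np.cos(2 * np.pi * 15.0 * t)
        env = hilbert_envelope(modulator * carrier)[0]
        interior = slice(250, -250)
        assert np.max(np.abs(env[interior] - modulator[interior]) / modulator[interior]) < 0.05

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            hilbert_envelope(np.array([1.0, np.nan]))


class TestWindowDownsample:
    def test_100ms_75pct_gives_40hz(self):
        out, fs_out = window_downsample(np.random.default_rng(0).random((2, 1000)),
                                        fs_in=250.0, width_ms=100.0, overlap_fraction=0.75)
        assert fs_out == 40.0

    def test_constant_input_preserved(self):
        out, _ = window_downsample(np.full((1, 500), 3.7), 250.0)
        assert np.allclose(out, 3.7)

    def test_window_count_matches_enumeration(self):
        # integer-step case: W=25, S=6 at fs=250 (overlap 1 - 6/25)
        T, W, S = 1000, 25, 6
        x = np.random.default_rng(1).random((1, T))
        out, _ = window_downsample(x, 250.0, width_ms=100.0, overlap_fraction=1 - S / W)
        starts = [s for s in range(0, T, S) if s + W <= T]  # brute-force enumeration
        assert out.shape[-1] == len(starts) == (T - W) // S + 1
        expected = np.array([x[0, s:s + W].mean() for s in starts])
        assert np.allclose(out[0], expected)

    def test_fractional_step_matches_rounded_starts(self):
        # 100 ms at 250 Hz steps by 6.25 samples; starts round per window
        T = 1000
        x = np.random.default_rng(2).random((1, T))
        out, fs_out = window_downsample(x, 250.0, 100.0, 0.75)
        assert fs_out == 40.0
        W, step = 25, 6.25
        n = int(np.floor((T - W) / step)) + 1
        expected = np.array(
            [x[0, int(round(i * step)):int(round(i * step)) + W].mean() for i in range(n)]
        )
        assert out.shape[-1] == n
        assert np.allclose(out[0], expected)

    def test_conservation_of_window_means(self):
        # non-overlapping windows: mean of output equals mean of covered span
        x = np.random.default_rng(3).random((1, 1000))
        out, _ = window_downsample(x, 250.0, width_ms=100.0, overlap_fraction=0.0)
        n, W = out.shape[-1], 25
        assert out.mean() == pytest.approx(x[0, : n * W].mean())

    def test_window_longer_than_signal(self):
        with pytest.raises(ValueError):
            window_downsample(np.zeros((1, 10)), 250.0, width_ms=100.0)


class TestNormalizeSubject:
    def test_zero_mean_unit_variance_per_parcel(self, rng):
        env = rng.random((5, 400)) * 7 + 3
        norm = normalize_subject(env)
        assert np.allclose(norm.mean(axis=1), 0.0, atol=1e-8)
        assert np.allclose(norm.var(axis=1), 1.0, atol=1e-6)

    def test_idempotent_on_standardized(self, rng):
        env = normalize_subject(rng.random((3, 300)))
        assert np.allclose(normalize_subject(env), env, atol=1e-10)

    def test_constant_parcel_error_names_parcel(self):
        env = np.vstack([np.random.default_rng(0).random(100), np.full(100, 2.0)])
        with pytest.raises(ValueError, match="parcel-01"):
            normalize_subject(env)


class TestSymmetricOrthogonalize:
    def test_orthogonal_input_unchanged_up_to_scale(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((100, 3)))
        X = (q * np.array([2.0, 3.0, 4.0])).T  # orthogonal rows, mixed scales
        Y = symmetric_orthogonalize(X)
        assert np.allclose(Y, X, atol=1e-8)

    def test_beats_sequential_scheme(self, rng):
        base = rng.standard_normal(2000)
        X = np.vstack([base + 0.3 * rng.standard_normal(2000),
                       base + 0.3 * rng.standard_normal(2000)])
        Y = symmetric_orthogonalize(X)
        gram = Y @ Y.T
        assert abs(gram[0, 1]) < 1e-8 * np.sqrt(gram[0, 0] * gram[1, 1])
        # sequential one-against-first orthogonalisation as comparator
        seq = X.copy()
        seq[1] = seq[1] - (seq[1] @ seq[0]) / (seq[0] @ seq[0]) * seq[0]
        assert np.sum((Y - X) ** 2) < np.sum((seq - X) ** 2)

    def test_matches_constrained_optimizer_oracle(self, rng):
        X = rng.standard_normal((3, 12))
        Y = symmetric_orthogonalize(X)

        def objective(flat):
            return np.sum((flat.reshape(3, 12) - X) ** 2)

        cons = [
            {"type": "eq", "fun": lambda f, i=i, j=j: f.reshape(3, 12)[i] @ f.reshape(3, 12)[j]}
            for i in range(3) for j in range(i + 1, 3)
        ]
        res = optimize.minimize(objective, Y.ravel() + 0.01 * rng.standard_normal(36),
                                method="SLSQP", constraints=cons,
                                options={"maxiter": 500, "ftol": 1e-12})
        assert np.sum((Y - X) ** 2) <= res.fun + 1e-6

    def test_rank_deficient_rejected(self):
        x = np.random.default_rng(0).standard_normal(50)
        with pytest.raises(ValueError):
            symmetric_orthogonalize(np.vstack([x, 2 * x]))


class TestPCAParcelTimecourse:
    def test_identical_voxels_recover_shared_series(self, rng):
        shared = rng.standard_normal(300)
        out = pca_parcel_timecourse(np.tile(shared, (4, 1)))
        assert np.corrcoef(out, shared)[0, 1] == pytest.approx(1.0)

    def test_single_voxel_returns_demeaned_series(self, rng):
        v = rng.random(200)
        out = pca_parcel_timecourse(v[None, :])
        centered = v - v.mean()
        assert np.allclose(out / np.linalg.norm(out), centered / np.linalg.norm(centered))

    def test_denoises_better_than_any_voxel(self, rng):
        shared = rng.standard_normal(2000)
        voxels = shared + 0.8 * rng.standard_normal((5, 2000))
        out = pca_parcel_timecourse(voxels)
        pc_corr = np.corrcoef(out, shared)[0, 1]
        voxel_corrs = [np.corrcoef(v, shared)[0, 1] for v in voxels]
        assert pc_corr > max(voxel_corrs)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            pca_parcel_timecourse(np.zeros((3, 50)))


class TestConcatenateSubjects:
    def test_boundaries(self, rng):
        ds = concatenate_subjects([rng.random((3, 100)), rng.random((3, 150))],
                                  ["s1", "s2"], 40.0)
        assert ds.subject_boundaries == [("s1", 0, 100), ("s2", 100, 250)]

    def test_single_subject_identity(self, rng):
        m = rng.random((2, 50))
        ds = concatenate_subjects([m], ["only"], 40.0)
        assert np.array_equal(ds.data, m)

    def test_round_trip_bit_exact(self, rng):
        mats = [rng.random((4, n)) for n in (60, 80, 30)]
        ds = concatenate_subjects(mats, ["a", "b", "c"], 40.0)
        for m, sid in zip(mats, ["a", "b", "c"]):
            assert np.array_equal(ds.segment(sid), m)

    def test_mismatched_parcels_rejected(self, rng):
        with pytest.raises(ValueError):
            concatenate_subjects([rng.random((3, 10)), rng.random((4, 10))], ["a", "b"], 40.0)


class TestStageChain:
    def test_amplitude_covariance(self, rng):
        x = rng.standard_normal((2, 2000))
        env1, _ = window_downsample(hilbert_envelope(bandpass(x, 250.0)), 250.0)
        env2, _ = window_downsample(hilbert_envelope(bandpass(3.0 * x, 250.0)), 250.0)
        assert np.allclose(env2, 3.0 * env1)

    def test_recovers_state_mean_profile_on_2state_toy(self, rng):
        # full chain on simulated oscillations: per-state parcel means of the
        # recovered envelopes should rank-match the generator's state means
        truth = make_ground_truth(n_states=2, n_parcels=6, self_persistence=0.95,
                                  separation=1.0, seed=4)
        truth.state_means[:] = 1.0 + np.abs(truth.state_means) + \
            0.3 * np.arange(6)[None, :]
        path = simulate_state_path(truth, 2400, rng)  # 60 s at 40 Hz
        raw = simulate_raw_oscillation(truth, path, (8.0, 16.0), 250.0, rng)
        filt = bandpass(raw, 250.0, 4.0, 30.0)
        env, fs_out = window_downsample(hilbert_envelope(filt), 250.0)
        assert fs_out == 40.0
        n = min(env.shape[1], path.size)
        from scipy.stats import spearmanr

        recovered = np.vstack([env[:, :n][:, path[:n] == k].mean(axis=1) for k in range(2)])
        rho = spearmanr(recovered.ravel(), truth.state_means.ravel()).statistic
        assert rho > 0.9

    def test_pipeline_boundaries_respected(self, rng):
        raws = [rng.standard_normal((3, 1000)), rng.standard_normal((3, 1500))]
        ds = envelope_pipeline(raws, ["s1", "s2"], fs=250.0)
        # each subject standardised independently after windowing
        for sid, seg in ds.iter_segments():
            assert np.allclose(seg.mean(axis=1), 0.0, atol=1e-8)
            assert np.allclose(seg.var(axis=1), 1.0, atol=1e-6)
        assert ds.sampling_rate == 40.0
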