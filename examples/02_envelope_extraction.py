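"""Amplitude-envelope extraction from band-limited oscillations.

Simulates 4-30 Hz oscillatory carriers whose instantaneous amplitude tracks
a 2-state Markov chain, then runs the full preprocessing chain: band-pass,
Hilbert envelope, 100 ms / 75 % overlap window averaging down to 40 Hz, and
per-subject standardisation. The recovered per-state envelope profile
should rank-match the generator's state means.
"""

import numpy as np
from scipy.stats import spearmanr

from netdyn import (
    bandpass,
    hilbert_envelope,
    make_ground_truth,
    simulate_raw_oscillation,
    simulate_state_path,
    window_downsample,
)

rng = np.random.default_rng(1)
truth = make_ground_truth(n_states=2, n_parcels=6, self_persistence=0.95,
                          separation=1.0, seed=4)
truth.state_means[:] = 1.0 + np.abs(truth.state_means) + 0.3 * np.arange(6)

path = simulate_state_path(truth, 2400, rng)  # 60 s at 40 Hz
raw = simulate_raw_oscillation(truth, path, carrier_band=(8.0, 16.0),
                               fs_raw=250.0, rng=rng)
print(f"raw oscillations: {raw.shape[0]} parcels x {raw.shape[1]} samples at 250 Hz")

env, fs_out = window_downsample(hilbert_envelope(bandpass(raw, 250.0, 4.0, 30.0)),
                                fs_in=250.0, width_ms=100.0, overlap_fraction=0.75)
print(f"envelope after window averaging: {env.shape[1]} samples at {fs_out:g} Hz")

n = min(env.shape[1], path.size)
recovered = np.vstack([env[:, :n][:, path[:n] == k].mean(axis=1) for k in range(2)])
rho = spearmanr(recovered.ravel(), truth.state_means.ravel()).statistic
print(f"rank correlation between recovered and true state-mean profiles: {rho:.3f}")
print("(values near 1 mean the envelope chain preserves each state's "
      "spatial amplitude pattern)")
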