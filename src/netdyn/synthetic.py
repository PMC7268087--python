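"""Ground-truth cohort simulation for the envelope-HMM pipeline.

Generates Markov state sequences with state-specific multivariate-normal
envelope emissions, optional band-limited oscillatory carriers (so the
envelope extraction stage can be exercised end to end), two-group cohorts
that differ in the transition dynamics of selected states, and synthetic
regional gene-expression vectors with controllable spatial coupling to the
injected group effect.

All randomness flows from explicit seeds / `numpy.random.Generator`
instances; identical seeds reproduce identical cohorts bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "HMMGroundTruth",
    "CohortSpec",
    "Cohort",
    "make_ground_truth",
    "simulate_state_path",
    "simulate_envelope_subject",
    "simulate_raw_oscillation",
    "perturb_transitions",
    "simulate_cohort",
    "graded_group_effect",
    "effect_region_profile",
    "simulate_expression",
    "write_cohort",
]

_PROB_ATOL = 1e-12


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass
class HMMGroundTruth:
    """Generative parameters of a hidden Markov chain with Gaussian envelope
    emissions: one mean vector and covariance matrix per state, a
    row-stochastic transition matrix and an initial state distribution."""

    n_states: int
    n_parcels: int
    transition_matrix: np.ndarray  # (K, K), rows sum to 1
    initial_distribution: np.ndarray  # (K,)
    state_means: np.ndarray  # (K, P)
    state_covariances: np.ndarray  # (K, P, P), symmetric positive definite
    sampling_rate: float  # Hz of the emitted envelope samples

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.initial_distribution = np.asarray(self.initial_distribution, dtype=float)
        self.state_means = np.asarray(self.state_means, dtype=float)
        self.state_covariances = np.asarray(self.state_covariances, dtype=float)
        self.validate()

    def validate(self) -> None:
        K, P = self.n_states, self.n_parcels
        if K < 1 or P < 1:
            raise ValueError("n_states and n_parcels must be >= 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.transition_matrix.shape != (K, K):
            raise ValueError("transition_matrix must be K x K")
        if np.any(self.transition_matrix < -_PROB_ATOL):
            raise ValueError("transition probabilities must be non-negative")
        row_sums = self.transition_matrix.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=_PROB_ATOL, rtol=0):
            raise ValueError("each transition row must sum to 1")
        if self.initial_distribution.shape != (K,) or not np.isclose(
            self.initial_distribution.sum(), 1.0, atol=_PROB_ATOL, rtol=0
        ):
            raise ValueError("initial_distribution must be K probabilities summing to 1")
        if self.state_means.shape != (K, P):
            raise ValueError("state_means must be K x P")
        if self.state_covariances.shape != (K, P, P):
            raise ValueError("state_covariances must be K x P x P")
        for k in range(K):
            cov = self.state_covariances[k]
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValueError(f"covariance of state {k} is not symmetric")
            try:
                np.linalg.cholesky(cov)
            except np.linalg.LinAlgError as exc:  # pragma: no cover - message only
                raise ValueError(f"covariance of state {k} is not positive definite") from exc

    def stationary_distribution(self) -> np.ndarray:
        """Left eigenvector of the transition matrix for eigenvalue 1."""
        vals, vecs = np.linalg.eig(self.transition_matrix.T)
        idx = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, idx])
        pi = np.abs(pi)
        return pi / pi.sum()


@dataclass
class CohortSpec:
    """Design of a two-group cohort.

    ``group_effect`` maps state index -> additive delta applied to that
    state's self-transition probability in group B (the case group), with the
    remainder of the row rescaled to keep it stochastic.
    ``expression_coupling`` and ``expression_noise_sd`` control how strongly
    the synthetic regional expression vector tracks the injected effect
    profile.
    """

    n_subjects_per_group: tuple[int, int] = (7, 8)
    samples_per_subject: int = 3000
    group_effect: dict[int, float] = field(default_factory=dict)
    expression_coupling: float = 0.0
    expression_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.samples_per_subject < 1:
            raise ValueError("samples_per_subject must be >= 1")
        if any(n < 1 for n in self.n_subjects_per_group):
            raise ValueError("each group needs at least one subject")


@dataclass
class Cohort:
    """A simulated two-group cohort with retained generative ground truth."""

    envelopes: list[np.ndarray]  # per subject, (P, T)
    subject_ids: list[str]
    group_labels: list[str]  # "A" (control-like) / "B" (case-like)
    true_paths: list[np.ndarray]  # per subject, (T,) state indices
    truth_a: HMMGroundTruth
    truth_b: HMMGroundTruth
    spec: CohortSpec


def make_ground_truth(
    n_states: int = 8,
    n_parcels: int = 38,
    self_persistence: float = 0.9,
    separation: float = 3.0,
    seed: int | None = 0,
    sampling_rate: float = 40.0,
) -> HMMGroundTruth:
    """Build a sticky-chain ground truth with well-separated state means.

    The transition matrix has ``self_persistence`` on the diagonal and the
    remaining mass spread uniformly, giving geometric dwell times with mean
    ``1 / (1 - self_persistence)`` samples (250 ms at 40 Hz for the default
    0.9). Each state elevates its own set of parcels (assigned cyclically) by
    ``separation`` emission standard deviations, so the minimum between-state
    mean distance scales linearly with ``separation``. Covariances are
    identity plus a random rank-one component, hence positive definite at any
    dimension.
    """
    if not 0.0 < self_persistence < 1.0:
        raise ValueError("self_persistence must lie strictly between 0 and 1")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    if n_states < 1 or n_parcels < 1:
        raise ValueError("n_states and n_parcels must be >= 1")

    K, P = n_states, n_parcels
    rng = _as_rng(seed)

    if K == 1:
        transition = np.ones((1, 1))
    else:
        off = (1.0 - self_persistence) / (K - 1)
        transition = np.full((K, K), off)
        np.fill_diagonal(transition, self_persistence)
    initial = np.full(K, 1.0 / K)

    # parcel p "belongs" to state p % K; each state raises its parcels
    owners = np.arange(P) % K
    means = np.zeros((K, P))
    for k in range(K):
        means[k, owners == k] = separation

    covs = np.empty((K, P, P))
    eye = np.eye(P)
    for k in range(K):
        u = rng.standard_normal(P)
        u /= np.linalg.norm(u)
        covs[k] = eye + 0.2 * np.outer(u, u)

    return HMMGroundTruth(
        n_states=K,
        n_parcels=P,
        transition_matrix=transition,
        initial_distribution=initial,
        state_means=means,
        state_covariances=covs,
        sampling_rate=sampling_rate,
    )


def simulate_state_path(truth: HMMGroundTruth, n_samples: int, rng) -> np.ndarray:
    """Draw a state index sequence from the chain (inverse-CDF sampling)."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = _as_rng(rng)
    cum_init = np.cumsum(truth.initial_distribution)
    cum_trans = np.cumsum(truth.transition_matrix, axis=1)
    u = rng.random(n_samples)
    path = np.empty(n_samples, dtype=np.int64)
    path[0] = np.searchsorted(cum_init, u[0], side="right")
    for t in range(1, n_samples):
        path[t] = np.searchsorted(cum_trans[path[t - 1]], u[t], side="right")
    np.clip(path, 0, truth.n_states - 1, out=path)
    return path


def simulate_envelope_subject(truth: HMMGroundTruth, path: np.ndarray, rng) -> np.ndarray:
    """Emit a (parcels x samples) envelope matrix along a state path.

    Sample ``t`` is drawn from the multivariate normal of state ``path[t]``.
    """
    path = np.asarray(path)
    if path.size and (path.min() < 0 or path.max() >= truth.n_states):
        raise ValueError("path contains invalid state indices")
    rng = _as_rng(rng)
    P, T = truth.n_parcels, path.size
    chol = np.linalg.cholesky(truth.state_covariances)  # (K, P, P)
    z = rng.standard_normal((T, P))
    out = np.empty((T, P))
    for k in range(truth.n_states):
        mask = path == k
        if mask.any():
            out[mask] = z[mask] @ chol[k].T + truth.state_means[k]
    return out.T


def simulate_raw_oscillation(
    truth: HMMGroundTruth,
    path: np.ndarray,
    carrier_band: tuple[float, float] = (4.0, 30.0),
    fs_raw: float = 250.0,
    rng=None,
) -> np.ndarray:
    """Band-limited carriers amplitude-modulated by the active state's means.

    The state path is defined at ``truth.sampling_rate``; the per-parcel
    amplitude profile (the active state's mean, floored at zero) is linearly
    interpolated up to ``fs_raw`` and multiplied onto a sinusoidal carrier
    whose frequency sits in the interior of ``carrier_band`` with a random
    phase per parcel. Running the envelope stage on the output recovers the
    state-mean amplitude profile.
    """
    low, high = carrier_band
    if not 0.0 < low < high < fs_raw / 2.0:
        raise ValueError("carrier_band must satisfy 0 < low < high < fs_raw / 2")
    rng = _as_rng(rng)
    path = np.asarray(path)
    P = truth.n_parcels
    amp_env = np.maximum(truth.state_means[path], 0.0)  # (T_env, P)
    t_env = np.arange(path.size) / truth.sampling_rate
    duration = path.size / truth.sampling_rate
    t_raw = np.arange(int(round(duration * fs_raw))) / fs_raw
    # carriers away from the band edges so the band-pass stage passes them
    freqs = rng.uniform(low + 0.2 * (high - low), high - 0.2 * (high - low), size=P)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=P)
    out = np.empty((P, t_raw.size))
    for p in range(P):
        amp = np.interp(t_raw, t_env, amp_env[:, p])
        out[p] = amp * np.cos(2.0 * np.pi * freqs[p] * t_raw + phases[p])
    return out


def perturb_transitions(truth: HMMGroundTruth, group_effect: dict[int, float]) -> HMMGroundTruth:
    """Return a copy of ``truth`` with self-transition deltas applied.

    For each ``state -> delta``, the self-transition probability gains
    ``delta`` and the off-diagonal mass of that row is rescaled so the row
    still sums to one.
    """
    A = truth.transition_matrix.copy()
    for s, delta in group_effect.items():
        if not 0 <= s < truth.n_states:
            raise ValueError(f"state index {s} out of range")
        new_self = A[s, s] + delta
        if not 0.0 < new_self < 1.0:
            raise ValueError(
                f"self-transition of state {s} would leave (0, 1): {new_self:.4f}"
            )
        off = A[s].sum() - A[s, s]
        if off <= 0:
            raise ValueError(f"state {s} has no off-diagonal mass to rescale")
        A[s] = A[s] * (1.0 - new_self) / off
        A[s, s] = new_self
    return HMMGroundTruth(
        n_states=truth.n_states,
        n_parcels=truth.n_parcels,
        transition_matrix=A,
        initial_distribution=truth.initial_distribution.copy(),
        state_means=truth.state_means.copy(),
        state_covariances=truth.state_covariances.copy(),
        sampling_rate=truth.sampling_rate,
    )


def simulate_cohort(truth: HMMGroundTruth, spec: CohortSpec) -> Cohort:
    """Simulate a two-group cohort: group A from ``truth`` unchanged, group B
    from a transition-perturbed copy. True paths are retained so recovery can
    be scored exactly."""
    rng = np.random.default_rng(spec.seed)
    truth_b = perturb_transitions(truth, spec.group_effect) if spec.group_effect else truth
    n_a, n_b = spec.n_subjects_per_group
    envelopes, ids, labels, paths = [], [], [], []
    for i in range(n_a + n_b):
        group = "A" if i < n_a else "B"
        gt = truth if group == "A" else truth_b
        path = simulate_state_path(gt, spec.samples_per_subject, rng)
        env = simulate_envelope_subject(gt, path, rng)
        envelopes.append(env)
        ids.append(f"sub-{i + 1:02d}")
        labels.append(group)
        paths.append(path)
    return Cohort(
        envelopes=envelopes,
        subject_ids=ids,
        group_labels=labels,
        true_paths=paths,
        truth_a=truth,
        truth_b=truth_b if spec.group_effect else truth,
        spec=spec,
    )


def graded_group_effect(n_states: int = 8, max_delta: float = 0.06) -> dict[int, float]:
    """Canonical graded group effect: self-transition deltas spread linearly
    from 0 to ``max_delta`` across states.

    With the default sticky chain (persistence 0.9) this induces
    control-minus-case fractional-occupancy differences spanning roughly 0-9
    percentage points across states — the magnitude spread a small
    case-control envelope-HMM study reports — giving every state a different
    effect size so that graded associations can be recovered end to end.
    """
    if n_states < 2:
        raise ValueError("need at least two states for a graded effect")
    return {k: max_delta * k / (n_states - 1) for k in range(1, n_states)}


def effect_region_profile(truth: HMMGroundTruth, group_effect: dict[int, float]) -> np.ndarray:
    """Per-parcel magnitude of the injected group effect.

    Perturbing self-transitions redistributes occupancy across *all* states
    (occupancies sum to one), so the induced effect on state k is the
    difference between the two chains' stationary occupancies of k — not the
    raw delta. Each state's |mean map| is weighted by that induced occupancy
    change and summed, giving the spatial footprint the expression vector can
    be coupled to. Length equals ``truth.n_parcels``.
    """
    if not group_effect:
        return np.zeros(truth.n_parcels)
    truth_b = perturb_transitions(truth, group_effect)
    pi_a = truth.stationary_distribution()
    pi_b = truth_b.stationary_distribution()
    weights = np.abs(pi_a - pi_b)
    return weights @ np.abs(truth.state_means)


def simulate_expression(
    region_effect_profile: np.ndarray,
    coupling: float,
    noise_sd: float,
    rng,
    n_regions: int = 68,
) -> np.ndarray:
    """Synthetic regional expression: ``coupling`` x standardized profile plus
    Gaussian noise. Profile length must match ``n_regions`` (default 68, the
    34-per-hemisphere cortical convention)."""
    profile = np.asarray(region_effect_profile, dtype=float)
    if profile.shape != (n_regions,):
        raise ValueError(f"region_effect_profile must have length {n_regions}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = _as_rng(rng)
    sd = profile.std()
    z = (profile - profile.mean()) / sd if sd > 0 else np.zeros_like(profile)
    return coupling * z + noise_sd * rng.standard_normal(n_regions)


def write_cohort(cohort: Cohort, out_dir: str | Path, fmt: str = "csv") -> None:
    """Write one matrix file per subject, a labels CSV and a ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sid, env in zip(cohort.subject_ids, cohort.envelopes):
        if fmt == "csv":
            np.savetxt(out / f"{sid}.csv", env, delimiter=",")
        elif fmt == "npy":
            np.save(out / f"{sid}.npy", env)
        else:
            raise ValueError(f"unknown format {fmt!r}")
    pd.DataFrame({"subject_id": cohort.subject_ids, "group": cohort.group_labels}).to_csv(
        out / "labels.csv", index=False
    )
    truth = cohort.truth_a
    payload = {
        "n_states": truth.n_states,
        "n_parcels": truth.n_parcels,
        "sampling_rate": truth.sampling_rate,
        "transition_matrix_a": truth.transition_matrix.tolist(),
        "transition_matrix_b": cohort.truth_b.transition_matrix.tolist(),
        "initial_distribution": truth.initial_distribution.tolist(),
        "state_means": truth.state_means.tolist(),
        "state_covariances": truth.state_covariances.tolist(),
        "seed": cohort.spec.seed,
        "group_effect": {str(k): v for k, v in cohort.spec.group_effect.items()},
    }
    (out / "ground_truth.json").write_text(json.dumps(payload))
    for sid, path in zip(cohort.subject_ids, cohort.true_paths):
        np.savetxt(out / f"{sid}_true_path.csv", path[None, :], fmt="%d", delimiter=",")
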