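"""K-state hidden Markov model with multivariate-normal emissions.

Each state is a full-covariance Gaussian over parcel amplitude envelopes
(a mean vector and a covariance matrix); the state sequence follows a
first-order Markov chain. Parameters are estimated by maximum-likelihood
Baum-Welch EM with multiple seeded restarts; state time-courses are the
maximum a-posteriori Viterbi path, decoded independently per subject
segment (subjects are independent recordings, concatenation is a fitting
convenience); spatial maps are partial correlations of each state's
activation series onto the parcel envelopes, controlling for the other
states' activations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import linear_sum_assignment

from .envelope import EnvelopeDataset

__all__ = [
    "HMMParams",
    "StateTimeCourses",
    "fit_hmm",
    "viterbi_decode",
    "state_spatial_maps",
    "align_states",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class HMMParams:
    n_states: int
    means: np.ndarray  # (K, P)
    covariances: np.ndarray  # (K, P, P)
    transition_matrix: np.ndarray  # (K, K)
    initial_distribution: np.ndarray  # (K,)
    log_likelihood_trace: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def log_likelihood(self) -> float:
        return float(self.log_likelihood_trace[-1]) if self.log_likelihood_trace.size else np.nan


@dataclass
class StateTimeCourses:
    """Binary one-hot state activations: exactly one state active per sample."""

    activations: np.ndarray  # (K, T) in {0, 1}
    subject_boundaries: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        self.activations = np.asarray(self.activations)
        if not np.array_equal(self.activations.sum(axis=0), np.ones(self.activations.shape[1])):
            raise ValueError("activations must be one-hot in every column")

    @property
    def state_sequence(self) -> np.ndarray:
        return np.argmax(self.activations, axis=0)

    def segment(self, subject_id: str) -> np.ndarray:
        for sid, start, end in self.subject_boundaries:
            if sid == subject_id:
                return self.activations[:, start:end]
        raise KeyError(subject_id)


def _segments(dataset) -> tuple[np.ndarray, list[tuple[int, int]]]:
    if isinstance(dataset, EnvelopeDataset):
        X = dataset.data.T  # T x P
        bounds = [(s, e) for _, s, e in dataset.subject_boundaries]
    else:
        X = np.asarray(dataset, dtype=float).T
        bounds = [(0, X.shape[0])]
    return X, bounds


def _log_emission(X: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """Per-sample Gaussian log-density for every state: (T, K)."""
    T, P = X.shape
    K = means.shape[0]
    logB = np.empty((T, K))
    for k in range(K):
        L = np.linalg.cholesky(covs[k])
        diff = X - means[k]
        y = solve_triangular(L, diff.T, lower=True)
        maha = np.einsum("ij,ij->j", y, y)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        logB[:, k] = -0.5 * (maha + logdet + P * _LOG2PI)
    return logB


def _forward_backward(logB, logA_unused, A, pi):
    """Scaled forward-backward for one sequence; returns gamma, xi_sum, loglik."""
    T, K = logB.shape
    B = np.exp(logB - logB.max(axis=1, keepdims=True))
    alpha = np.empty((T, K))
    scale = np.empty(T)
    alpha[0] = pi * B[0]
    scale[0] = alpha[0].sum()
    alpha[0] /= scale[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        scale[t] = a.sum()
        alpha[t] = a / scale[t]
    beta = np.empty((T, K))
    beta[-1] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        bb = B[t + 1] * beta[t + 1]
        beta[t] = (A @ bb) / scale[t + 1]
        xi_sum += np.outer(alpha[t], bb / scale[t + 1]) * A
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    loglik = float(np.sum(np.log(scale)) + np.sum(logB.max(axis=1)))
    return gamma, xi_sum, loglik


def _kmeans_init(X: np.ndarray, K: int, rng: np.random.Generator, n_iter: int = 20) -> np.ndarray:
    """Simple seeded k-means partition of samples; returns cluster means."""
    T = X.shape[0]
    centers = X[rng.choice(T, size=K, replace=False)].copy()
    for _ in range(n_iter):
        d2 = ((X[:, None, :] - centers[None]) ** 2).sum(axis=2) if T * K * X.shape[1] < 2e7 else None
        if d2 is None:
            # chunked distance computation for large T
            d2 = np.empty((T, K))
            for k in range(K):
                d2[:, k] = ((X - centers[k]) ** 2).sum(axis=1)
        labels = d2.argmin(axis=1)
        new_centers = centers.copy()
        for k in range(K):
            mask = labels == k
            if mask.any():
                new_centers[k] = X[mask].mean(axis=0)
        if np.allclose(new_centers, centers):
            break
        centers = new_centers
    return centers


def fit_hmm(
    dataset,
    n_states: int = 8,
    n_restarts: int = 3,
    max_iter: int = 100,
    tol: float = 1e-4,
    seed: int = 0,
    cov_reg: float = 1e-4,
) -> HMMParams:
    """Baum-Welch maximum-likelihood fit with seeded restarts.

    Initialisation per restart: k-means partition for the means, pooled
    covariance for every state, sticky transitions (diagonal 0.9, favouring
    the temporally persistent states this model class targets), uniform
    initial distribution. Each M-step adds ``cov_reg x average-variance`` to
    the covariance diagonals to prevent collapse on short runs. The restart
    with the highest final log-likelihood wins. Fully deterministic given
    ``seed`` and the data.
    """
    X, bounds = _segments(dataset)
    T, P = X.shape
    K = n_states
    if not np.all(np.isfinite(X)):
        raise ValueError("dataset contains non-finite values")
    if K < 1 or n_restarts < 1:
        raise ValueError("n_states and n_restarts must be >= 1")
    if T <= K:
        raise ValueError("need more samples than states")

    pooled_cov = np.cov(X.T) if P > 1 else np.atleast_2d(np.var(X))
    avg_var = float(np.trace(np.atleast_2d(pooled_cov)) / P)
    reg = cov_reg * avg_var * np.eye(P)

    best: HMMParams | None = None
    root = np.random.default_rng(seed)
    for _ in range(n_restarts):
        rng = np.random.default_rng(root.integers(2**31))
        means = _kmeans_init(X, K, rng)
        covs = np.tile(np.atleast_2d(pooled_cov) + reg, (K, 1, 1))
        A = np.full((K, K), 0.1 / max(K - 1, 1))
        np.fill_diagonal(A, 0.9 if K > 1 else 1.0)
        A /= A.sum(axis=1, keepdims=True)
        pi = np.full(K, 1.0 / K)

        trace = []
        for _it in range(max_iter):
            logB = _log_emission(X, means, covs)
            gamma_all = np.empty((T, K))
            xi_sum = np.zeros((K, K))
            pi_new = np.zeros(K)
            loglik = 0.0
            for s, e in bounds:
                g, xi, ll = _forward_backward(logB[s:e], None, A, pi)
                gamma_all[s:e] = g
                xi_sum += xi
                pi_new += g[0]
                loglik += ll
            trace.append(loglik)

            # M-step
            occ = gamma_all.sum(axis=0)
            if np.any(occ < 1e-10):
                k_bad = int(np.argmin(occ))
                raise RuntimeError(f"state {k_bad} collapsed to zero occupancy during EM")
            means = (gamma_all.T @ X) / occ[:, None]
            for k in range(K):
                diff = X - means[k]
                covs[k] = (diff.T * gamma_all[:, k]) @ diff / occ[k] + reg
            if K > 1:
                A = xi_sum / xi_sum.sum(axis=1, keepdims=True)
            pi = pi_new / pi_new.sum()

            if len(trace) > 1 and trace[-1] - trace[-2] < tol:
                break

        # final log-likelihood under the last parameter update
        logB = _log_emission(X, means, covs)
        loglik = 0.0
        for s, e in bounds:
            _, _, ll = _forward_backward(logB[s:e], None, A, pi)
            loglik += ll
        trace.append(loglik)

        cand = HMMParams(
            n_states=K,
            means=means,
            covariances=covs,
            transition_matrix=A,
            initial_distribution=pi,
            log_likelihood_trace=np.asarray(trace),
        )
        if best is None or cand.log_likelihood > best.log_likelihood:
            best = cand
    return best


def viterbi_decode(params: HMMParams, dataset) -> StateTimeCourses:
    """Maximum a-posteriori state path, one-hot encoded, per subject segment.

    Ties in the back-pointers resolve toward the lower state index (argmax
    convention), making decoding deterministic.
    """
    X, _ = _segments(dataset)
    if isinstance(dataset, EnvelopeDataset):
        boundaries = dataset.subject_boundaries
    else:
        boundaries = [("subject-0", 0, X.shape[0])]
    if X.shape[1] != params.means.shape[1]:
        raise ValueError("dataset parcel count does not match model")

    K = params.n_states
    logB_all = _log_emission(X, params.means, params.covariances)
    with np.errstate(divide="ignore"):
        logA = np.log(params.transition_matrix)
        logpi = np.log(params.initial_distribution)

    T_total = X.shape[0]
    act = np.zeros((K, T_total), dtype=np.int8)
    for sid, s, e in boundaries:
        logB = logB_all[s:e]
        T = e - s
        delta = logpi + logB[0]
        psi = np.empty((T, K), dtype=np.int32)
        for t in range(1, T):
            scores = delta[:, None] + logA  # prev x next
            psi[t] = np.argmax(scores, axis=0)
            delta = scores[psi[t], np.arange(K)] + logB[t]
        if not np.any(np.isfinite(delta)):
            raise RuntimeError(f"Viterbi deadlock in segment {sid}: no admissible path")
        path = np.empty(T, dtype=np.int64)
        path[-1] = int(np.argmax(delta))
        for t in range(T - 1, 0, -1):
            path[t - 1] = psi[t, path[t]]
        act[path, np.arange(s, e)] = 1
    return StateTimeCourses(activations=act, subject_boundaries=list(boundaries))


def state_spatial_maps(stc: StateTimeCourses, dataset) -> np.ndarray:
    """Partial correlation of each state's activation onto parcel envelopes.

    Entry (k, p) is the partial correlation between state k's activation
    series and parcel p's envelope, controlling for the other K-1 activation
    series. One-hot activations sum to the constant series, so after
    centering the joint correlation matrix is singular; the partial
    correlation is therefore taken from the Moore-Penrose pseudoinverse of
    the correlation matrix of [envelope, activations], which handles the
    one-hot redundancy without an arbitrary reference state. At K = 2 this
    reduces exactly to the simple correlation with the state's own indicator
    (the sign-flipped correlation with the complementary one). A state that
    is never (or always) active yields undefined (NaN) entries rather than
    zeros, and is excluded from the control set of the other states.
    """
    X, _ = _segments(dataset)  # T x P
    S = np.asarray(stc.activations, dtype=float).T  # T x K
    if S.shape[0] != X.shape[0]:
        raise ValueError("state time-courses and dataset differ in length")
    T, K = S.shape
    P = X.shape[1]
    occupied = (S.sum(axis=0) > 0) & (S.sum(axis=0) < T)
    valid = np.flatnonzero(occupied)
    maps = np.full((K, P), np.nan)
    if valid.size == 0:
        return maps
    # correlation structure of [activations(valid), parcels], computed once
    M = np.column_stack([S[:, valid], X])
    R = np.corrcoef(M.T)
    nv = valid.size
    for p in range(P):
        idx = np.concatenate([[nv + p], np.arange(nv)])
        sub = R[np.ix_(idx, idx)]
        omega = np.linalg.pinv(sub, rcond=1e-10, hermitian=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = -omega[0, 1:] / np.sqrt(omega[0, 0] * np.diag(omega)[1:])
        maps[valid, p] = vals
    return maps


def align_states(estimated: HMMParams, reference: HMMParams) -> np.ndarray:
    """Optimal matching of estimated to reference states by mean distance.

    Returns ``perm`` with ``perm[j]`` = index of the estimated state matched
    to reference state ``j``, minimising the total Euclidean distance between
    matched mean vectors (solved as an assignment problem). HMM state labels
    are arbitrary, so recovery scoring requires this realignment.
    """
    if estimated.n_states != reference.n_states:
        raise ValueError("state counts differ")
    if estimated.means.shape[1] != reference.means.shape[1]:
        raise ValueError("parcel counts differ")
    cost = np.linalg.norm(
        estimated.means[:, None, :] - reference.means[None, :, :], axis=2
    )
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(reference.n_states, dtype=int)
    perm[cols] = rows
    return perm
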