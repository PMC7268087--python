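# Methods

## Model

The data model is a hidden Markov chain over K recurring network states
observed through band-limited amplitude envelopes. At 40 Hz envelope
sampling, sample t carries a P-vector of parcel envelopes drawn from the
multivariate normal N(mu_k, Sigma_k) of the active state k(t); the state
sequence follows a first-order chain with row-stochastic transition matrix A
and initial distribution pi. With self-transition probability a = A_kk, a
visit to state k has geometric length with mean 1/(1-a) samples; the default
a = 0.9 gives 250 ms at 40 Hz, in the ~100–300 ms range envelope-HMM studies
report for MEG resting-state networks. K defaults to 8 and P to 38, the
configuration of the parcellated envelope analyses this package follows.

## Envelope preprocessing

- **Band-pass 4–30 Hz.** The band has two edges, so a zero-phase (forward–
  backward) Butterworth band-pass of order 4 is used; forward–backward
  filtering removes group delay so no phase offsets are introduced between
  parcels. Verified by measuring the realized response: unit gain within 5 %
  at 10 Hz, ≥ 20 dB attenuation at 1 Hz.
- **Hilbert envelope.** Instantaneous amplitude of the analytic signal.
- **Window downsampling.** Averaging within 100 ms windows at 75 % overlap;
  the output rate 1000/(width·(1−overlap)) = 40 Hz holds exactly. At 250 Hz
  input the step is 6.25 samples, a non-integer; window start times live on
  a continuous grid and are rounded to the nearest sample per window, which
  keeps the output rate exact while staying sample-aligned. First and last
  windows are retained (no edge trimming): retention is the simplest
  reproducible choice. Windows are laid out per subject, before
  concatenation, so no window straddles a subject boundary.
- **Normalisation** is per parcel per subject (mean 0, variance 1),
  removing between-subject amplitude offsets before fitting shared states.
  A constant parcel is an error naming the parcel, never silently scaled.
- **Symmetric orthogonalisation** (optional, off by default for parcel-level
  synthetic input) finds the least-squares-closest set of mutually
  orthogonal channel time-courses by alternating a polar decomposition with
  closed-form channel rescaling; checked against a constrained-optimizer
  oracle. **PCA parcel collapse** (optional) takes the first principal
  component across voxels, sign-fixed to correlate non-negatively with the
  voxel mean.

## State estimation

Parameters are estimated by maximum-likelihood Baum–Welch EM. This is a
deliberate estimator choice: the model class (Gaussian-emission HMM) is what
matters downstream, and EM with seeded restarts is deterministic and
dependency-free, whereas the variational-Bayes estimators common in MEG
toolboxes add machinery without changing the quantities this package
reports. Details:

- **Initialisation** per restart: k-means partition of samples for the
  means, pooled covariance for every state, sticky transitions (diagonal
  0.9) favouring temporally persistent states, uniform initial distribution.
- **Regularisation**: each M-step adds `cov_reg × average-variance` to the
  covariance diagonal (default 1e-4) to prevent collapse on short runs; a
  state that still collapses raises an error naming it.
- **Convergence**: successive log-likelihood gain < tol (default 1e-4 for
  library calls, 1e-3 in the pipeline) or max_iter. The trace is stored and
  asserted non-decreasing. Best-of-restarts by final log-likelihood; the
  whole fit is bit-for-bit reproducible given data and seed.
- **Decoding** is per subject segment (chains restart at boundaries):
  subjects are independent recordings and concatenation is a fitting
  convenience. Viterbi ties break toward the lower state index for
  determinism. Cross-checked against exhaustive path enumeration on tiny
  instances and against an independent decoder implementation.
- **Spatial maps**: the partial correlation between a state's one-hot
  activation and each parcel envelope, controlling for the other K−1
  activations. One-hot activations sum to the constant series, so the
  centered joint correlation matrix is singular; the partial correlation is
  taken from its Moore–Penrose pseudoinverse, which resolves the redundancy
  without electing an arbitrary reference state and reduces exactly to the
  simple correlation with the state's own indicator at K = 2. States never
  (or always) active yield NaN entries, flagged rather than zeroed.
- **Alignment**: HMM labels are arbitrary, so recovery scoring matches
  estimated to reference states by minimising total distance between mean
  vectors (optimal assignment; verified against K! enumeration).

## Temporal metrics

Per subject and state, from the one-hot time-courses: fractional occupancy
(% of samples; sums to 100 over states), number of occurrences (maximal
runs), mean lifetime (mean run length; reported in ms), mean interval (gap
from the end of one visit to the start of the next, not onset-to-onset;
reported in s). A state with no visits has undefined lifetime and interval,
and with one visit an undefined interval — stored as NaN, excluded pairwise
from group summaries, never imputed. Internally durations are seconds;
reporting units are baked into column names.

## Group statistics

The test statistic is the control-minus-case difference of group means. The
null reallocates the pooled per-subject values into groups of the original
sizes (default 10,000 relabellings, preserving the 7-vs-8 design), and the
two-sided p uses the add-one estimator (1 + #{|null| ≥ |observed|}) /
(n+1), which never returns zero and is valid at finite permutation counts.
Sidedness is a choice: the absolute-difference null is symmetric and
conservative. BH-FDR is applied across all states × measures jointly by
default (32 tests); a per-measure family is available. An exhaustive
enumerator over all C(n_a+n_b, n_a) assignments serves as the oracle at
small n.

## Gene association

Spatial maps live on P analysis parcels while expression lives on 68
cortical regions (34 per hemisphere, Desikan–Killiany naming), so the
bridge is an explicit non-negative overlap-weight matrix: region activity is
the weight-normalised average of |partial correlation| over contributing
parcels (absolute value first — strong negative engagement counts). The
projection is swappable; an identity projection serves 68-parcel synthetic
runs, and a uniform interval-overlap projection serves other parcel counts.
Each state's score is the sum of raw expression over its top-20 regions
(ties at rank k break by fixed label order), compared one-sided
(upper-tail) against sums over random 20-of-68 subsets: the scientific
question is whether expression in a network is *elevated* relative to
chance. Across states, Spearman's rho links the expression p-vector to the
group-difference p-vector — correlating p-values preserves the magnitude
reading of both permutation tests; rho's significance uses exact
permutation over all n! orderings for n ≤ 9 states. Uniform expression
degenerates every p to 1 and the association to NaN, asserted rather than
propagated silently.

## Synthetic data: what it emulates, and what it does not

The generator emulates the study conditions end to end: 8 states, sticky
chains (250 ms expected lifetimes at 40 Hz), multivariate-normal envelope
emissions (identity-plus-rank-one covariances, positive definite at any P),
7-vs-8 two-group cohorts with 9 minutes (21,600 samples at 40 Hz) per
subject, group effects injected as self-transition deltas with row
renormalisation, and 68-region expression vectors coupled to the injected
effect. Optional band-limited oscillatory carriers (amplitude-modulated
sinusoids at random in-band frequencies) exercise the envelope stage.

Because occupancies sum to one, perturbing some states' self-transitions
redistributes occupancy across *all* states; the effect profile that
expression couples to is therefore the analytically induced
stationary-occupancy change of each state (weighting its |mean map|), not
the raw delta. The canonical graded effect spreads deltas linearly from 0
to 0.06 across states, inducing control-minus-case occupancy differences
spanning roughly 0–9 percentage points — the magnitude spread a small
case–control envelope-HMM study reports — so that a graded association is
present to recover.

Not emulated: forward-modelled sensor physics, source leakage between
parcels (emissions are drawn directly in parcel space), artifacts, head
movement, heavy-tailed envelope marginals, or donor-level microarray
structure. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated generative model, not robustness to
the acquisition-side confounds of real MEG.

## Verification experiment sizes

Chosen as the package's standard verification design (see
`netdyn.experiments`):

- Type-I calibration: 200 null cohorts, 7-vs-8 subjects, 4,000 samples per
  subject, 2,000 permutations per test, BH at q = 0.05; the family-wise
  false-alarm rate is compared with q plus two binomial standard errors.
  Metrics come from true state paths — the experiment calibrates the
  statistics, not the estimator.
- HMM recovery: one 20,000-sample two-state sequence, 3-SD mean separation,
  persistence 0.9; self-transitions within 0.05, occupancy rank correlation
  above 0.9 after alignment.
- Association recovery: 20 seeded cohorts at full study scale (8 states, 68
  parcels, 21,600 samples per subject), expression coupling 1.0 without
  noise; median fractional-occupancy rho above 0.8. The zero-coupling
  calibration redraws expression 200 times over one cohort and compares the
  exceedance rate of |rho| > 0.738 with the exact 8!-enumeration null rate
  for the observed rank structure.
- Enumeration oracles (permutation test on 3-vs-3, subset null on 2-of-5,
  Viterbi on K=2/T=5, BH step-up by hand) are exact and fast.

## Known limitations

- EM finds local optima; restarts mitigate but do not guarantee the global
  maximiser. Model order K is fixed, not selected.
- The partial-correlation map definition via pseudoinverse is one of
  several reasonable resolutions of the one-hot redundancy; alternatives
  (reference-state dummy coding) are not invariant to the reference choice
  and were rejected for that reason.
- The parcel-to-region projection is a declared convention, not an
  anatomical overlap estimate; real analyses should supply their own weight
  matrix.
- The random-subset expression null ignores spatial autocorrelation of
  cortical maps; autocorrelation-preserving nulls are out of scope.
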