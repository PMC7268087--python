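# netdyn

Transient functional-network dynamics for electrophysiology: amplitude-envelope
hidden-Markov-model (HMM) state decomposition, temporal state metrics,
permutation-based group comparison, and association of network spatial maps
with regional gene-expression profiles.

## Who this is for

Large-scale brain networks measured with MEG synchronise and dissolve on a
~100 ms timescale — far faster than sliding-window connectivity can resolve.
A standard way to capture this is to model the band-limited amplitude
envelopes of parcellated source signals as a sequence of recurring *states*,
each a multivariate normal distribution over parcels (a mean activity map
plus a covariance), visited according to a Markov chain. `netdyn` implements
that analysis as a tested, reusable Python library, together with the group
statistics typically layered on top of it in case–control studies (for
example, comparing participants carrying a single-gene mutation such as
*ZDHHC9* with controls) and an imaging-transcriptomics step that asks whether
the networks most altered in a group are those where a gene is most
expressed.

Because real study recordings are rarely shareable, the package ships a
first-class synthetic-data module: ground-truth Markov chains with Gaussian
envelope emissions, two-group cohorts with known injected transition effects,
and expression vectors with controllable coupling to those effects. Every
stage of the pipeline is verified against this known truth.

## The model and statistics

- **Envelope extraction** — zero-phase band-pass (default 4–30 Hz), Hilbert
  analytic amplitude, temporal averaging in 100 ms windows with 75 % overlap
  (40 Hz output), per-subject per-parcel standardisation, concatenation
  across subjects. Optional symmetric orthogonalisation (least-squares
  closest mutually orthogonal time-courses, for source-leakage correction)
  and first-principal-component collapse of voxel groups to parcels.
- **State decomposition** — K-state HMM (default K = 8) with full-covariance
  multivariate-normal emissions over P parcels, estimated by maximum-
  likelihood Baum–Welch EM with seeded restarts; one-hot state time-courses
  by per-subject Viterbi decoding; spatial maps as partial correlations of
  each state's activation series onto the parcel envelopes, controlling for
  the other states' activations.
- **Temporal metrics** — per subject and state: fractional occupancy (%),
  number of occurrences, mean lifetime (ms), mean interval between visits (s).
- **Group statistics** — observed control-minus-case difference of group
  means per (state, measure); null by randomly reallocating participants'
  values to groups of the original sizes (default 10,000 times);
  two-sided add-one p-values; Benjamini–Hochberg FDR across the family.
- **Gene association** — per state: project the |partial-correlation| map to
  68 cortical regions, sum expression over the top-20 regions, compare with
  a null of 10,000 random 20-of-68 subsets (one-sided, upper tail). Across
  states: Spearman correlation between expression p-values and
  group-difference p-values, with an exact permutation p for n ≤ 9 states.

## Worked example

`examples/` holds one short script per capability. Fitting and decoding a
two-state ground truth (`examples/03_fit_hmm_and_decode.py`) prints:

```
EM converged after 7 evaluations, final log-likelihood -178899.5
state 0: self-transition true 0.900 recovered 0.901
state 1: self-transition true 0.900 recovered 0.892
state 0: occupancy true 52.0 % decoded 52.1 %
state 1: occupancy true 47.9 % decoded 47.9 %
```

i.e. from 20,000 envelope samples the estimator recovers the self-transition
probabilities to within 0.01 and the decoder reproduces the true occupancies
to a tenth of a percentage point. The full end-to-end run
(`examples/05_gene_association.py`) simulates a 7-vs-8 cohort with graded
transition effects across 8 states, couples a synthetic expression vector to
the injected effect profile, and recovers the association:

```
Spearman association between expression p and group-difference p:
    fractional_occupancy: rho +0.846, p 0.0179
```

a strongly positive rho, as built in: the states whose dynamics separate the
groups most are those with the highest regional expression.

The same pipeline is scriptable from the shell:

```bash
netdyn simulate --out-dir cohort --states 8 --parcels 38 --effect 4 0.05
netdyn run --config config.yaml --out-dir results
```

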