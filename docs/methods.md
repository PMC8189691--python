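# Methods

## Model

`chromdelta` treats a chromatin state segmentation map as a sequence
`X = x1 … xn` of letters over the state alphabet `A`, one letter per
fixed-size genomic bin, and models the letters as i.i.d. draws from
per-group state frequencies. Comparing two maps position-wise under an
integer scoring matrix `s_ij` (positive = dissimilar states) yields a
score sequence whose maximal scoring segments are the candidate
differential regions. Under four classical conditions — long sequences,
i.i.d. letters, some attainable positive score, negative expected
score — the number of maximal segments with score at least `x` in a
sequence of length `L` is asymptotically Poisson with mean
`K·L·e^{−λx}` (Gumbel-type extreme value behaviour), which is what
turns a raw segment score into an E-value. The first two conditions
are idealisations that no genome satisfies; the latter two are checked
against the data before every analysis and the run aborts if either
fails.

Chromosomes are treated as independent sequences; segments never span
a chromosome boundary. Coordinates are BED-style 0-based half-open and
always bin-aligned.

## Scoring matrix

Scores are derived from the segmentation model's emission
probabilities. Emission rows are per-mark Bernoulli parameters in
ChromHMM, so each row is first normalised to a probability
distribution; the divergence between two states is
`JSD(E_i, E_j) = 2H((E_i+E_j)/2) − H(E_i) − H(E_j)` with natural-log
entropy (range `[0, 2 ln 2]`; twice the conventional JSD). The matrix
is shifted by the mean JSD so similar states score negative, scaled by
an integer factor (default 10) and rounded half-away-from-zero, making
results bit-reproducible across platforms.

Two deliberately open points and the choices made:

- **Which mean to subtract.** One global mean over all unordered
  off-diagonal state pairs (background pairs included, diagonal
  excluded) is the default; a single shift is the only row-independent
  choice that preserves `s_ij = s_ji` exactly. A per-state variant that
  subtracts the symmetrised row means `(m_i + m_j)/2` is available via
  `mean_mode="per_state"`.
- **Background state.** All scores involving the quiescent state are
  replaced by the matrix minimum *after* integerisation, including the
  diagonal; absence of signal is treated as non-differential against
  everything. The rule is idempotent.

User-supplied integer matrices (TSV) bypass the derivation but still
pass through the assumption checks.

## Statistical parameters

The pair model collapses to a lattice distribution over integer scores:
`P(s) = Σ_{(i,j): s_ij = s} p_i q_j`, with `p`, `q` the empirical state
frequencies of the two compared groups (recomputed per comparison — the
closest data-driven instantiation of the i.i.d. letter model).

- **λ** is the unique positive root of `Σ_s P(s) e^{λs} = 1`, found by
  Brent's method after bracketing away from the trivial root at zero
  (the bracket start shrinks from 1e-8 until the moment function is
  negative; the upper end doubles until positive). Scores are divided
  by their greatest common divisor during the solve to keep the
  exponentials well-scaled; the residual of the defining equation must
  be ≤ 1e-9 or an error is raised.
- **K** uses the classical lattice-case series: with span `δ` (the
  gcd), relative entropy `H = λ Σ_s s P(s) e^{λs}` and
  `σ = Σ_{k≥1} (1/k)[P(S_k ≥ 0) + E(e^{λS_k}; S_k < 0)]` accumulated
  over k-fold convolutions of `P`,
  `K = δλe^{−2σ} / (H(1 − e^{−λδ}))`. The series terms decay
  geometrically but can oscillate with the lattice period, so the
  truncation uses a lag-2 envelope estimate of the decay rate and stops
  once the geometric bound on the remaining tail of σ falls below 1e-7
  (error if not reached within 20,000 terms). The test suite validates
  K against an independent Monte-Carlo oracle that fits the Gumbel law
  of maximal segment scores on simulated i.i.d. sequences; the two
  agree to within ~1-2% on all tested distributions, comfortably inside
  the 25% oracle tolerance.

## Segment extraction

All maximal scoring segments are extracted per chromosome with the
Ruzzo–Tompa algorithm, amortised linear time via nearest-smaller-prefix
pointers. As a vectorised preprocessing step, maximal runs of positive
scores are collapsed into single candidates (consecutive positive bins
always coalesce), so the Python-level bookkeeping only touches runs.
Tie-breaking is deterministic: segments are minimal-length
representatives of their score — a flanking zero-score bin never
extends a segment, although interior zeros (and negative dips) are
bridged whenever bridging strictly increases the score. Equivalently,
the output matches repeatedly extracting the best subsegment (shortest,
then leftmost, on ties) and recursing on the flanks, which is exactly
the brute-force oracle used in the tests.

## Merging, effective length, E-values

Candidates from all `|X|·|Y|` replicate pairings are merged by
single-linkage bin overlap (half-open intervals touching only at a
boundary do not overlap). A merged domain's coverage is the union of
its members (always contiguous under single linkage) and its DCS is
the arithmetic mean of member raw scores; E-values are computed on this
merged DCS. No minimum number of supporting replicate pairs is imposed,
and no additional multiple-testing correction is applied: the E-value
is already an expectation over the search space.

The effective length of a group is, per chromosome, the sum over
positions of the number of distinct states across the group's
replicates — equivalently, each added replicate contributes only its
novel-state positions, making the quantity order-independent and equal
to the plain bin count for concordant replicates. How the two group
lengths combine into the single `L` of the E-value formula is not
uniquely determined by the framework; the default takes the
per-chromosome maximum (the more conservative, larger search space of
the two groups), which reduces exactly to the classical single-sequence
case for 1-vs-1 comparisons. A `sum` rule is selectable.

`e^{−λ·DCS}` is evaluated in log space, so extremely strong domains
report an exact `−log10 E` even when `E` itself underflows to zero.
The DCD filter keeps domains with `E` strictly below the threshold
(default 1); an empty result is valid and only warned about.

## Dynamics filter

Within each DCD, maximal runs of bins are reported where the states of
group X lie in one user-defined label set and those of group Y in
another. Replicate consensus is strict unanimity by default; a
majority (≥50% per group) mode is available and always yields a
superset of the strict regions. Runs can be a single bin. Switch
regions carry no E-value — the local-score statistics apply to the
parent domain, not to arbitrary slices — and only reference the parent
DCD's identifier.

## Synthetic data

The generator emulates exactly the study conditions the statistics
assume, so calibration experiments are valid by construction:

- **Emissions**: rows drawn from a symmetric Dirichlet (default
  concentration 0.3, giving peaked, near-binary rows like real
  segmentation models); the last state is drawn near-uniform with at
  most 5% signal and declared the quiescent background. Driving the
  concentration large makes all states alike and the derived scoring
  correctly fails the positive-score assumption.
- **Maps**: default 18 states, 6 marks, 200 bp bins; per-bin states
  i.i.d. with background frequency 0.5 and the remaining mass spread
  evenly (roughly half of a typical segmented genome is quiescent).
  Replicates copy a group template and flip each bin with probability
  0.01 (default) to a uniformly random other state; planted
  differential domains overwrite a fixed state pair into every
  replicate after the noise step.
- Everything is deterministic given the seed (identical configurations
  produce byte-identical container files).

What the generator does *not* emulate: Markov dependence between
neighbouring bins (real segmentations have long runs), structured
replicate confusion (flips are uniform), chromosome-scale
heterogeneity, and mappability artifacts. Passing calibration and
recovery tests therefore demonstrates correctness of the statistics
under the model's own assumptions, not robustness to violations of
them on real data.

## Evaluation sizes

The reference experiments (reproduced by `scripts/acceptance.py` and
the acceptance tests) use desk-scale problem sizes chosen to give
stable statistics in seconds-to-minutes: 1,000 random sequences
(length ≤ 50, scores in [−5, 5]) for the segment-extraction oracle; 50
random emission models for λ residuals; 6,000 Monte-Carlo sequences of
length 5,000 for the K oracle; 200 null comparisons of 100,000-bin
1-vs-1 maps for E-value calibration (mean chance DCDs per comparison
observed ≈ 1, consistent with the E < 1 threshold's expectation
semantics); and 100 recovery simulations on 50,000-bin chromosomes with
two replicates per group, 1% noise and ten planted 25-bin domains of
the maximal-score state pair (observed sensitivity 1.0, ≈ 0.5 false
DCDs per simulation).

## Known limitations

- Hard state assignments only; ChromHMM posterior uncertainty is
  ignored.
- No edge-effect or finite-size corrections to the E-value formula;
  gapped or split segments are out of scope.
- Asymmetric scoring systems are not supported.
- The `max` combination of group lengths is a design choice, not a
  derived result; for strongly unbalanced replicate numbers the `sum`
  rule changes E-values by at most a factor of two.
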