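# Methods

## The coding model

Stimuli live on a discrete grid: `K` features, each taking one of `n`
values, so `M = n^K` stimuli in all. A conjunctive code of order `O`
(`1 ≤ O ≤ K`) assigns one binary unit to every combination of `O` features
and every joint value assignment of those features. A unit fires exactly
when the stimulus matches its value combination on its feature subset;
`O = 1` is a pure single-feature code, `O = K` the fully conjunctive
one-hot code. Every code covers the whole stimulus space and gives each
stimulus a unique codeword.

Closed forms (point tuning):

- population size `D_O = C(K, O) · n^O`;
- representation energy `P_O = C(K, O)` (squared codeword norm) or
  `C(K, O)(1 − n^−O)` (summed per-unit activity variance); the two agree as
  `n` grows. Simulations default to the variance form, which slightly
  favors low-order codes and therefore makes the advantage of mixed codes a
  conservative finding; closed-form reports use the squared-distance form,
  which is the one the analytic expressions are written in;
- distance spectrum `d(K, O, v) = sqrt(2 Σ_i C(v, i) C(K−v, O−i))` between
  stimuli differing in `v` features, minimum `Δ_O = sqrt(2 C(K−1, O−1))`
  attained at `v = 1`;
- the ratio `Δ_O² / P_O = 2O/K` exactly, strictly increasing in `O` — the
  core reliability-per-energy result;
- nearest-neighbor counts `N_Δ = K(n−1)` for `O < K` and `n^K − 1` at
  `O = K` (in the one-hot code every wrong stimulus is equally close, which
  is why its errors are random in feature space).

One caution surfaced by exhaustive checking: `d(K, O, v)` is non-decreasing
in `v` but *not* strictly increasing everywhere (e.g. `K=4, O=2` has
`d² = 6, 10, 12, 12`). The minimum at `v = 1` and the strict first step for
`O < K` are what the neighbor-count results rely on, and those hold.

## Linear transform

A matrix `β` (`N × D_O`, `N ≥ D_O`) maps codewords into response space
subject to: pseudoinverse-identity (`β⁺β = I`), uniform column length `H`,
and zero-mean column cross-products. Such transforms scale every pairwise
distance by exactly `H` and set the energy to `V = H² P_O`, so
`δ²/V = Δ²/P` is invariant: comparing codes at fixed `V` compares their
geometry, not their energy. Styles: `identity_scaled` (default in all
simulations), exact orthonormal `random_rotation` / `random_embedding`
(QR-orthonormalized Gaussian frames with a deterministic sign convention),
and `gaussian` (i.i.d. entries, columns rescaled to `H` exactly, the
pseudoinverse constraint then holding only approximately at finite `N`).
Constraint checks use a relative tolerance of 1e−8 for the deterministic
constraints and three standard errors for the sampled cross-product one.

## Channel and decoding

Noise is applied per response dimension after the transform:

- `gaussian`: additive N(0, σ²); population SNR is defined as `V/σ²`, so
  performance is independent of `N` and rotation;
- `poisson`: counts with mean equal to the (nonnegative) unit activity;
  zero-activity dimensions emit exactly zero — their likelihood is handled
  in log-space with explicit zero-count logic, no epsilon floor;
- `poisson_baseline`: mean `activity + r_spont`, Poisson SNR `V/r_spont`.

Decoding is maximum likelihood over the clean transformed codebook
(nearest Euclidean codeword under Gaussian noise). Ties break to the lowest
stimulus index and are counted in the results. Input noise is available in
two forms: *local* (each feature shifts to an adjacent value with total
probability `p`; boundary values shift only inward with the full
probability mass, a choice that had to be made somewhere and is the least
disruptive one) and *bitflip* (the pure-code bit pattern of the stimulus is
corrupted; the flipped bits either feed the conjunctive indicator units
directly or are first cleaned to the nearest valid stimulus — both
pipelines are exposed because the corrupted-input contract is genuinely
ambiguous).

Monte-Carlo runs present stimuli uniformly at random (the codes are
stimulus-symmetric, so the distribution does not matter), and report PE
with binomial standard errors, MSE in squared feature units (bounded-line
metric by default, circular optional), per-feature error rates, and the
full confusion matrix. MSE and the squared-error CDF are derived from the
confusion matrix, which makes them exact functionals of the recorded
counts.

## Union-bound estimate

The error rate is estimated by summing standard-normal tail probabilities
over error destinations:
`PE ≤ Σ_v N_all(v) · Q(d(K, O, v) · sqrt(SNR/P_O) / 2)` with
`N_all(v) = C(K, v)(n−1)^v`, and the nearest-neighbor approximation
`PE ≈ N_Δ · Q(sqrt(SNR · O / 2K))`. `Q` is computed through the
complementary-tail routine (`scipy.special.ndtr` of the negated argument)
because high-SNR values fall far below 1e−6. The estimate must be
evaluated under the same energy variant as the simulation it is compared
with; with mismatched variants the two differ by a fixed distance rescaling
and the high-SNR convergence seen in the tests would not occur.

## Total energy

Every neuron costs one maintenance unit; spiking costs `ε` per unit of
representation energy: `E = εV + D_O`. A code allocated `E` achieves
`δ² = (2O/Kε)(E − D_O)` when `E > D_O` (infeasible budgets are flagged,
not raised). Order `O+1` overtakes order `O` exactly at
`E = (nK − (n+1)O) · D_O`; for `O = 1` this is `n²K² − n²K − nK`, so any
budget of at least `n²K²` favors some mixed code. `ε` defaults to 50
(mid-range of experimental estimates); it scales all `δ²` equally and
never changes which order wins.

## Receptive fields

Discrete RFs of width `s` (required to divide `n`): intervals tile each
feature axis at `s` lattice offsets with truncated boundary intervals;
units pair intervals across the `O` features of a subset at a common
offset. Every stimulus then activates exactly `C(K, O) · s` units (the
linear energy law) and the `s` overlapping units per subset intersect in a
single point, so codewords stay distinct and the minimum distance is
unchanged. The closed-form population `C(K, O) · s · (n/s + 1)^O` does not
reduce to the point-tuning formula at `s = 1` and overcounts the
constructive truncated-lattice population; both numbers are reported and
energy budgeting uses the constructive count, i.e. the units that actually
exist. The constructive count shrinks roughly as `1/s^(O−1)` — the
approximation is asymptotic in `n/s` and visibly loose once `s` approaches
`n/2`.

Widening RFs trades error rate against error size: at a fixed total energy
past the analytic crossover (for `K=3, n=10, O=3` and `ε=50` the crossover
sits near `E ≈ 3350`; the sweep analyses here use `E = 3500`), the `s = 2`
code makes more errors than `s = 1` but its errors land on neighboring
stimuli, collapsing MSE by more than an order of magnitude.

## Continuous stimuli

For continuous features the package uses periodic (wrap-around) features on
[0, 1) with RF centers at every cell of an `n_cells` lattice and boxcar RFs
spanning `rf_cells` consecutive cells (Gaussian tuning optional, s.d. half
the RF width). Decoding happens on the grid of cell centers and MSE is
measured in continuous units with the circular metric. This construction
was chosen over a direct transplant of the discrete offset-lattice because
the offset-lattice ties decode resolution to RF width and cannot express
the continuous-case question — what happens when RF width changes at fixed
resolution. With it, higher-order codes reach lower MSE at matched energy,
while widening RFs *raises* MSE (neighboring codewords share more active
units, so their separation at matched energy shrinks) — the opposite of
the discrete tradeoff, and the reason the discrete and continuous analyses
are kept distinct.

## Information measures

Mutual information between stimulus and estimate is the uncorrected plug-in
estimate from the empirical confusion matrix; at the trial counts used
(≥ 3000) it is biased upward by at most a fraction of a bit, which only
makes the feasibility comparison against the rate-distortion bound more
conservative for relative judgments since both codes share the estimator.
The rate-distortion bound for the uniform `M`-ary source under symbol-error
distortion is the closed form `R(D) = log₂M − H_b(D) − D log₂(M−1)`; a
Blahut–Arimoto iteration is kept in the test suite as an independent
numerical oracle for it.

## Problem sizes and reproducibility

Simulation-backed analyses run at desk scale: 2000–5000 trials per
(code, SNR) point for the `K=3, n=5` channel comparisons, 40 000 trials for
the RF tradeoff point (error rates there are a few 10⁻⁴ and need the extra
resolution), 3000–4000 for the continuous and information analyses.
Single runs expose `seed`; sweeps derive one child generator per grid point
from a master seed via `numpy` seed sequences, so re-running a sweep
reproduces its CSV byte for byte.

## Limitations

Uniform `n` across features only; exhaustive (complete-coverage) codes
only — no random subsampling or learned selectivity; isotropic output
noise (no noise correlations); ML decoding only; axis-aligned interval
RFs of a single width per code. The worked-example fixtures print the
paper-and-pencil layout of the `K=3, n=2` tables (specific block order,
first-listed feature fastest within blocks); the canonical builder orders
units lexicographically, and all geometric quantities are invariant to
that choice.
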