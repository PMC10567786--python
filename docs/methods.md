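# Methods

## The model

The 2-HT eyewitness identification model is a multinomial processing tree
for the 3 × 2 outcome space of a lineup study (suspect identification,
filler identification, lineup rejection × culprit-present, culprit-absent).
Its assumptions, in order of consequence:

1. **Two discrete detection states.** Presence of the culprit is detected
   with probability `dP` (CP lineups), absence with probability `dA` (CA
   lineups). Detection is all-or-none; there is no graded-strength axis.
2. **Non-detection processes are shared across lineup types.** When
   detection fails, biased suspect selection (`b`) and guessing-based
   selection (`g`) operate identically in CP and CA lineups. This is what
   makes the model identifiable from the six categories.
3. **Fixed random-sampling constant.** Given a guessing-based selection, the
   suspect is chosen with probability `c = 1 / lineup size`, a design
   constant, not a parameter. `c` is stored explicitly on each condition so
   that rounded values (e.g. 0.33333, 0.16667 for 3- and 6-person lineups)
   can be used verbatim when reproducing an analysis that used them; when
   only a size is given the exact reciprocal is the default. A stored
   constant must lie within 5 × 10⁻⁵ of the reciprocal.
4. **Independent decisions.** Every lineup decision is an independent
   multinomial draw. In the packaged study design each participant
   contributes four decisions (two CP, two CA); treating them as independent
   follows standard practice for this model family and is documented rather
   than corrected — no participant-level random effect is modelled.

The six category equations are closed-form sums of branch products; they are
unit-tested against a generic path-enumeration oracle that walks the tree's
branches, so the algebra and the tree cannot drift apart.

## Restrictions, degrees of freedom, identifiability

A `ModelSpec` assigns every (parameter, condition) cell a free-parameter
name or a fixed value. Equality restrictions are shared names; fairness-type
assumptions are fixed values (e.g. `b = 0`). Goodness-of-fit df equal
`4 × n_conditions − n_free` (each condition has two trees with two free
category probabilities each). The representation makes over-parameterization
(df < 0) structurally impossible, but a saturated spec (df = 0) can still be
locally unidentifiable; `information_rank()` reports the rank of the
expected Fisher information (Jacobian-based, central differences) at a given
point rather than assuming identifiability.

## Estimation

* **Objective**: multinomial log-likelihood, `0·log 0 := 0`, `−∞` when a
  zero-probability category has a positive count. Multinomial coefficients
  are omitted (constant in the parameters).
* **Optimizer**: scipy L-BFGS-B on the probability scale with box
  constraints [0, 1]. Multi-start policy: `n_starts = 10` by default — one
  start at all-0.5, nine uniform random draws from a seeded generator. A
  start that ends with a line-search abort is polished once from its
  endpoint at scipy's default tolerance and accepted if its projected
  gradient is below 10⁻³ on the counts scale (finite-difference gradients of
  a likelihood of magnitude ~10³ carry ~10⁻⁵ noise, so demanding much more
  is demanding the impossible). The number of starts agreeing with the best
  optimum within 10⁻⁶ is reported as a ruggedness diagnostic.
* **G²**: `2 Σ obs·ln(obs/exp)` over all 6 × n_conditions categories;
  zero-observed cells contribute 0; zero-expected with positive observed
  yields +∞ with a warning. Verified in tests to equal twice the
  log-likelihood gap to the saturated model within 10⁻⁸.
* **Standard errors**: observed information — the central-difference Hessian
  (step 10⁻⁵) of the negative log-likelihood at the MLE — inverted on the
  subset of interior parameters. Parameters within 10⁻⁴ of a bound get NaN
  (Wald theory does not apply at a boundary); a singular information matrix
  flags all SEs NaN and warns with the rank. Observed (not expected)
  information is the deliberate choice: it is the curvature actually seen in
  the data and the two coincide asymptotically under the model.
* **Optimality checks**: on sub-models with ≤ 2 free parameters a dense
  0.001-step grid over the unit cube (an independent, vectorized likelihood
  written from the tree definition) never exceeds the optimizer's
  log-likelihood by more than 10⁻⁴; with 3 free parameters the grid runs at
  step 0.01 with 0.001 local refinement, which bounds the optimum to the
  same tolerance at ~10⁶ rather than 10⁹ evaluations.

A note on the `b = dA = 0` sub-model: the moment estimator — `g` from the CA
selection rate, `dP` from the CP rejection rate — equals the MLE exactly on
model-consistent counts (both then equal the generating values, G² = 0), and
the tests assert that identity. On arbitrary counts it is *not* the MLE,
because the CP tree's filler/rejection split also carries information about
`g`; the grid-search bound covers that case.

## Inference

Nested tests: `compare_nested` verifies that the restricted spec coarsens
the base spec cell-by-cell (violations are reported by parameter block),
fits both models with the same multi-start policy and seed, and refers
ΔG² = G²_restricted − G²_base to a central chi-square at Δdf = the number of
free parameters removed. Four contrast presets cover the 2 × 2 lineup
designs: `size_dP`/`size_g` equate a parameter across lineup sizes within
each presentation format, `format_dP`/`format_g` across formats within each
size; each removes 2 parameters in a four-condition design. The suite
verifies ΔG² additivity along restriction chains and, by simulation under
the restricted model (2000 replicates), that the null distribution of ΔG²
is the central chi-square at Δdf (Kolmogorov–Smirnov).

## Power

Generic chi-square sensitivity computations in the G*Power conventions:
Cohen's `w = sqrt(Σ (p₁−p₀)²/p₀)`; power is the noncentral chi-square upper
tail at the central (1−α) quantile with noncentrality `λ = N·w²`; the
minimal detectable `w` solves the monotone power equation by bisection on
[0, 3] to 10⁻⁸. `N` counts *observations* (decisions), and the CLI offers a
participants × lineups-per-participant convenience multiplier, because a
lineup study's chi-square operates on decisions, four per participant in the
packaged design. These are omnibus calculations at a user-chosen df (the
packaged studies used df = 2), not model-implied power for specific ΔG²
tests — the latter is a possible extension, not implemented.

## Simulator

`simulate_counts` draws, per condition, one multinomial of size
`2 × n_participants` per tree (two CP and two CA decisions per participant)
from the model's category probabilities. Randomness: a root seed plus a
(condition index, replicate) spawn key per stream, so adding conditions or
replicates never perturbs earlier draws. The generator reproduces exactly
the world the estimator assumes — independent decisions, no participant
heterogeneity, no confidence ratings, no position effects in sequential
lineups. Passing recovery and calibration tests therefore validate the
estimation machinery, not the model's adequacy for any real dataset.

## Problem sizes used in the checked properties

Chosen as the package's own defaults for a single-CPU desk run:

* ΔG² null calibration: two 3- and 6-person conditions, 200 participants
  each, 3-vs-2-parameter comparison, 2000 replicates, single-start fits.
* G² calibration at the true spec: one condition, 300 participants, df = 2,
  2000 replicates.
* Parameter recovery: the four-condition base model at its fitted values,
  380 participants per condition, 500 replicates; bias below 0.02 on every
  free parameter. SE calibration: 60 replicates at 20 000 participants per
  condition, empirical SD within 30 % of the mean model SE (the tolerance is
  dominated by Monte-Carlo noise in the SD at that replicate count).
* Normalization: 10⁶ random parameter draws through the vectorized kernel,
  with a 500-draw equality spot-check against the scalar evaluator.

## Known limitations

* No participant-level dependence or heterogeneity (by design, see above);
  no Bayesian estimation, bootstrap intervals or information-criterion
  model selection.
* Wald SEs and chi-square reference distributions are asymptotic; with very
  small cell counts the G² calibration degrades (the shipped calibration
  tests run at cell expectations ≥ ~25).
* Only the 2-HT lineup tree family is implemented — this is not a general
  MPT compiler.
* Fits with many parameters at the [0, 1] boundary report undefined SEs
  rather than attempting profile or boundary-corrected intervals.
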