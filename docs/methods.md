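# Methods

This note documents the models implemented in `parasyn`, the numerical
choices behind them, and what the synthetic benchmark does and does not
establish.

## The classification benchmark

All capacity measurements use random binary classification: `P` patterns over
`N` axons with entries drawn i.i.d. from Uniform(0, 1) and labels drawn
uniformly from {−1, +1}. A trial *succeeds* when the trained model classifies
every pattern correctly (sign errors only; a correctly signed pattern inside
the hinge margin still counts as correct). The capacity `P*/N` is the load at
which the success probability is 1/2, interpolated from a logistic fit to
per-trial outcomes (see below).

Because inputs are continuous, ties across patterns on one axon occur with
probability zero in generated data, but hand-written fixtures may contain
them; the staircase solver merges tied inputs into one knot, and tests cover
this path.

## Restricted neuron (M sigmoidal synapses per axon)

Each synapse transmits `h(x) = a² σ(s(x − t))` with amplitude `a²`, slope
`s ≥ 0` and threshold `t`; per-axon aggregates are sums of `M` such
sigmoids, the somatic current is the sum over axons, and the prediction is
`sign(z − θ)` with `sign(0) := −1`. Training minimizes the hinge loss
`L = Σ_μ max(0, ε − (z_μ − θ) y_μ)` with margin `ε = 0.1` by synchronous
full-batch gradient descent restricted to the margin-violation set
`Ω = {μ : ε − (z_μ − θ) y_μ > 0}`, with slopes projected back to `s ≥ 0`
after every step.

Internally the trainer uses the centered form `h' = a'² tanh(s'(x − t'))`,
which leaves the somatic threshold near zero and is exactly equivalent via
`a² = 2a'²`, `s = 2s'`, `t = t'`, `θ = θ' + Σ a'²`. (The additive constant
moves *into* θ with a plus sign; the margin-preservation property is enforced
by a numerical cross-evaluation test at 1e−10.)

### Learning rates and initialization

The four parameter families have gradient magnitudes that differ by orders
of magnitude: amplitude and threshold gradients are sums over Ω (so they
scale with `P`), while slope gradients carry a factor `a²(1 − tanh²)` that
is nonzero only for patterns within ~`1/s` of a synapse's threshold and are
typically ~10³ smaller. A single shared rate therefore either freezes the
slopes (which never sharpen, capping capacity near the linear regime) or
drives runaway amplitude growth; divergence is detected by a finiteness
guard and reported as a failed trial, never as success.

The defaults are per-family and load-scaled:

| parameter | default rate | rationale |
|-----------|--------------|-----------|
| amplitude `a` | `0.06 / P` | keeps per-epoch amplitude motion P-independent |
| slope `s` | `4.5` (fixed) | raw slope gradients are intrinsically small and do not grow with P in practice |
| threshold `t` | `0.18 / P` | thresholds must travel fast enough to position steps at hard patterns |
| somatic `θ` | `0.015 / P` | a fast θ oscillates with the violation set and destabilizes the end-game |

These ratios were chosen by instrumenting the effective per-family step-to-
gradient ratios of a well-conditioned diagnostic optimizer on the same loss
and freezing them as fixed rates; the shipped trainer is plain gradient
descent on the full violation set. The step size is additionally modulated
by a square-root annealing schedule with warm restarts,
`1/sqrt(1 + (epoch mod 20000)/2000)`: the hinge loss is piecewise linear, so
fixed-step descent limit-cycles around its ridges, while annealing settles
the last few margin violations and each restart (together with
resurrection) reshuffles the search. Training runs for up to 40000 epochs
by default and stops early when the best error count has not improved for
15000 epochs; both are runtime/quality trade-offs and are configurable.
Initialization: `a ~ N(0, 0.3)`, `s = 10`, `t ~ U(0, 1)`, `θ = 0`, all from
one seeded generator per call.

### Dead-synapse resurrection

A synapse whose amplitude collapses has vanishing gradients on all of its
parameters and can never recover. Every 500 epochs, synapses with
(sigmoid-scale) amplitude below 0.01 are raised back to exactly that floor
and their thresholds redrawn from an equal mixture of Beta(0.5, 3) and
Beta(3, 0.5) — a U-shaped distribution on the input range that mimics the
edge-heavy learned threshold distribution. This is a random search over
threshold placements in which amplitude regrowth acts as the acceptance
test.

## Unrestricted neuron (monotone staircase aggregates)

In the unlimited-synapse limit each axon's aggregate becomes a nondecreasing
staircase taking at most `P` values `I_α` (α ordering the patterns by input
on that axon), with `I_1 = 0` and nonnegative steps `ρ_β²`. Each axon
minimizes `C = −Σ y_α w_α I_α + λ Σ I_α²` over that cone. Setting
`∂C/∂ρ_β = −2ρ_β Σ_{α>β}(y_α w_α − 2λ I_α) = 0` shows each touching segment's
value is the mean of `y w/(2λ)` over the segment, and the segment structure
is the convex envelope of the cumulative `y w` walk — equivalently a
weighted isotonic regression of `y_α w_α/(2λ)` with the first value pinned
to zero and negative values clipped. The implementation is an `O(P)`
stack-based envelope construction, cross-checked in the tests against a
nonnegative-least-squares quadratic program and scikit-learn's
pool-adjacent-violators isotonic regression, plus the stationarity residual
`|Σ_{α>β}(y_α w_α − 2λ I_α)| ≤ 1e−8` on every active step.

The outer loop alternates exact per-axon solves with importance
reweighting: misclassified points get `w ← w + 1`, until zero errors or
1000 iterations. `λ` defaults to `1/(2P)` so that typical staircase values
are order one; the solution is invariant to the joint rescaling
`(w, λ) → (c·w, c·λ)`, so only the ratio of weights to λ matters as training
reweights.

Two details are deliberate design choices rather than properties of the
model itself, and are exposed as such:

* **Somatic threshold.** After each envelope pass, θ is set to the midpoint
  of the best 1-D split of the total currents (exact minimization of
  training errors; ties broken toward fewer false positives). The staircase
  values themselves do not fix θ, and a sorted scan is exact and cheap.
* **Off-knot evaluation.** Right-continuous, left-constant extension, zero
  below the first knot. Training never evaluates off-knot; this matters only
  for held-out data and plots.

Effective synapses are counted per axon as steps strictly greater than
1/1000 of the neuron-wide maximum step.

## Capacity estimation

For a model configuration, independent trials (fresh dataset per trial,
derived seeds recorded) run over a grid of problem sizes. Success
probability versus load is fitted by maximum likelihood with the
two-parameter logistic `p(load) = 1/(1 + exp(k(load − c)))`, `k > 0`
enforced by parameterizing `k = exp(u)`, so the fitted `c` *is* the 50%
crossing `P*/N`. Confidence intervals are a 100-resample nonparametric
bootstrap, resampling trials with replacement within each P stratum and
refitting per resample (2.5–97.5 percentiles). Degenerate resamples are
skipped; more than half degenerate is an error, as is an all-success or
all-failure record set (the caller must widen the grid).

When no grid is given, a coarse doubling scan over loads 1, 2, 4, …
brackets the crossing with a few probe trials per level and a 5-point grid
across the bracket is then run in full.

The desk-scale protocol in the tests and the acceptance script uses N = 100,
a 5-point load grid {4, …, 8} for the restricted M = 2 neuron and 3 trials
per grid point; the offline script `scripts/full_sweep.py` runs the
≥5-trial adaptive protocol at arbitrary N. These problem sizes were chosen
so a full run completes comfortably on one CPU core.

## Perceptron baseline

Cover's function-counting fraction `C(P, D) = 2^{1−P} Σ_{k<D} C(P−1, k)` is
evaluated in exact rational arithmetic (`C(2D, D) = 1/2` exactly). The
empirical counterpart decides strict separability of a concrete dataset by
linear-program feasibility with unit margin, including a bias term
(`D = N + 1`), so the measured capacity at finite N sits slightly above 2 at
`2(N + 1)/N`.

## Two-layer network with parallel synapses

The network applies parallel synapses only between hidden and output
layers: hidden pre-activations are batch-normalized and passed through a
Softplus; each hidden–output pair aggregates `M` sigmoidal synapses (the
same primitive as the restricted neuron), giving
`(D_in + 1)D_hidden + (3M·D_hidden + 1)D_out` learnable parameters including
biases; the linear comparison network has `(D_hidden + 1)D_out` for its
second layer, with its hidden→output weights clamped nonnegative so both
network types are monotone (excitatory) in the hidden activities.
Batch-norm scale/shift parameters are reported separately from that formula.
Training is minibatch Adam (rate 1e−3, batch 128) with softmax
cross-entropy and a monotonicity projection after every step; these
optimizer settings are this package's choices. The forward/backward passes
are explicit numpy.

The synthetic image fixture (4×4 images, bright-half class templates plus
Gaussian pixel noise) is linearly separable by construction; passing its
training test shows the machinery optimizes correctly, not that parallel
synapses improve generalization on structured data — that comparison
requires the real digit benchmark via `parasyn train-net --data-dir`.

## What the synthetic benchmark does not show

The i.i.d. uniform benchmark measures storage capacity, not generalization;
there are no correlated inputs, class imbalance, or label noise. Results at
desk scale (N ≤ 100, ≤5 trials per grid point) carry bootstrap uncertainty
of roughly ±0.5 in P*/N for the stochastic models. The gradient-descent
capacity of the restricted neuron is optimizer-limited: it is a lower bound
on what the architecture can represent, and longer epoch budgets raise it
(see the trainer defaults above for the time/quality trade-off adopted
here).

## Numerical conventions

* `sign(0)` resolves to −1 everywhere (prediction ties).
* Margin exactly ε is *excluded* from the violation set (strict inequality).
* An effective-synapse step exactly equal to the 1/1000 threshold is
  excluded (strict inequality).
* Training success requires zero sign errors; margins in (0, ε) do not block
  success.
* Divergent training (non-finite currents) is reported as failure.
* All randomness flows through explicit `numpy.random.Generator` objects
  seeded per call; capacity trials derive per-trial seeds from the base seed
  via `SeedSequence` so record lists are exactly reproducible.
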