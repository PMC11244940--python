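# parasyn

Classification capacity of single neurons with nonlinear **parallel
synapses** — multiple synaptic contacts between the same presynaptic axon and
postsynaptic neuron, each with its own learnable transmission function.

Cortical axons often contact a target neuron through several synapses. If
those contacts were linear, their combined effect would still be linear and
the extra synapses redundant. `parasyn` implements and measures the models
in which each contact transmits a *sigmoidal* current

    h_ij(x_i) = a_ij² · σ(s_ij (x_i − t_ij))

with learnable amplitude `a²`, slope `s ≥ 0` and threshold `t`, so an axon's
aggregate transmission function `Σ_j h_ij` is an arbitrary nondecreasing
soft staircase. The somatic current is the plain sum over axons (no
dendritic nonlinearities) and the binary decision is `ŷ = sign(z − θ)`.

The package provides, as library + CLI:

* **Restricted neuron** — `M` sigmoidal synapses per axon, trained by
  full-batch hinge-loss gradient descent (margin ε = 0.1) on the
  margin-violation set, with periodic resurrection of dead synapses.
* **Unrestricted neuron** — the unlimited-synapse limit: per-axon monotone
  staircase aggregates solved *exactly* by an envelope/isotonic
  construction, inside an importance-reweighting loop (`w ← w + 1` for
  misclassified points).
* **Capacity harness** — the random-pattern protocol: P patterns of N
  i.i.d. Uniform(0,1) activities with random ±1 labels; success = all
  patterns correct; capacity `P*/N` = load with 50% success, interpolated
  by a logistic fit with bootstrap confidence intervals.
* **Perceptron baseline** — exact Cover function-counting probabilities and
  LP-feasibility separability, anchoring `P*/N → 2`.
* **Two-layer network** — parallel synapses between hidden and output
  layers (numpy implementation with explicit gradients), including the
  exact learnable-parameter accounting
  `(D_in+1)D_hidden + (3M·D_hidden+1)D_out`.

See `docs/methods.md` for model details and numerical conventions.

## Worked example

```python
import parasyn as ps

# a 4-point XOR-like task that no linear classifier can solve
data = ps.make_fixture("xor4")
print(ps.is_linearly_separable(data))        # False

# the unrestricted neuron solves it exactly in a few reweighting passes
res = ps.UnrestrictedNeuronModel(data).fit()
print(res.summary())
```

```text
False
Unrestricted parallel-synapse neuron
====================================
axons (N):              2
patterns (P):           4
converged:              True
outer iterations:       1
training errors:        0
theta:                  2
effective synapses/axon: mean 1.00, max 1
```

One staircase step per axon implements the XOR-like labeling that defeats
the Perceptron — the computational gain of parallel nonlinear synapses in
miniature: each axon steps up at its largest input value, so exactly the two
+1 points collect summed current above θ = 2.

Capacity of the linear baseline, for comparison:

```python
exp = ps.CapacityExperiment("perceptron", N=50)
result = exp.fit(trials_per_P=20, seed=3, n_bootstrap=100)
print(result.summary())
```

```text
Capacity estimate
=================
P*/N:        1.9993
bootstrap CI: [1.9461, 2.1127]  (100 resamples)
load    success rate
 1.000         1.000
 1.240         1.000
 1.500         1.000
 1.760         0.950
 2.000         0.500
```

The 50% crossing sits at 2 — Cover's classical capacity of a linear
threshold unit on random patterns. The same pipeline applied to the parallel-synapse
neuron (`CapacityExperiment("restricted", N=100, M=2)`) yields a
substantially larger capacity; see `scripts/` below.

Command-line equivalents:

```bash
parasyn generate -P 100 -N 10 --seed 1 --out data/
parasyn train-restricted --patterns data/inputs.csv --labels data/labels.csv \
    -N 10 -M 2 --seed 0 --out model.json
parasyn capacity --model perceptron -N 50 --trials 20 --seed 3 --out-prefix runs/p50
```

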