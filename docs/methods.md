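# Methods

## Neuron model and discretization

The continuous LIF membrane equation τ dV/dt = −V + R·I describes an RC
low-pass filter. Rather than integrating it with explicit τ and R, the
package takes the forward-Euler discrete relation as the operational
definition: V decays by a factor β per step and accumulates the incoming
current, with τ, R and the time step absorbed into β and the synaptic
weights. A neuron fires within the same step its pre-reset potential
U = β·V + I reaches the threshold θ (decay/integrate, then threshold,
then subtract), so a single step can both integrate and fire. Only reset
by subtraction is implemented: V′ = U − s·θ, which preserves any
supra-threshold residual (0 ≤ V′ < θ whenever U < 2θ).

θ defaults to 1.0. It is not an independent degree of freedom — the
weights and β set the scale — so it is fixed rather than searched.

## Input encoding and architecture

Fingerprint bits are injected as a constant current through the first
weight matrix at every one of T steps. Rate and latency input codes were
considered and rejected: the appeal of fingerprints as spiking-network
inputs is precisely that the binary vector needs no conversion, and a
static current preserves that. T = 25 by default: with two output
neurons counting spikes, 25 steps give 26 distinguishable count levels,
enough resolution for ranking scores, while keeping simulation cost
linear and small. T is configurable everywhere.

The network has no bias terms. This keeps the exact invariant that an
all-zero fingerprint produces zero spikes everywhere, and removes a
parameter the input statistics do not need (bit vectors are
non-negative; the weights set the operating point). Weights are
initialized scaled-uniform, U(−1/√fan_in, +1/√fan_in), from an explicit
seed.

Hidden spikes (not membrane potentials) feed the output layer — the
standard layering for LIF stacks.

## Training

The loss is cross-entropy of the softmax over time-summed output spike
counts. The paper-style decision rule "the neuron that fired more
spikes" is the argmax of exactly these counts, so the rate-coded
cross-entropy trains the quantity the decision uses. Ties predict class
0, deterministically.

Backpropagation through time uses the surrogate-gradient trick: forward
spikes are hard Heaviside steps; the backward pass replaces the step's
derivative with d/du σ(k·u) evaluated at the distance from threshold.
The spike inside the reset term is held constant during
differentiation, so the membrane recursion back-propagates with factor
β per step; letting the surrogate flow through the reset would inject
factors of 1 − θ·k/4 (≈ −11 at k = 50), destabilizing training. The
correctness of the chain machinery is validated on a one-step network
where the relaxed (sigmoid-everywhere) forward pass is exactly
differentiable: backprop matches central finite differences to ~1e-6
relative error at slopes 25/50/75. The validation places pre-activations
within ~0.5/k of threshold because a saturated toy network has
gradients below finite-difference noise.

Mini-batches of 64, shuffled per epoch from an explicit seed. Gradient
clipping, when enabled, rescales the global L2 norm of all weight
gradients to 1.0 — the technique is standard; the norm bound is our
choice. Weight decay is coupled (added to the gradient) in all
optimizers except AdamW, where it is decoupled, matching the
conventional formulations. The seven optimizers are NumPy
implementations with the usual default constants (Adam/Adamax
β₁ = 0.9, β₂ = 0.999; RMSProp α = 0.99; Adadelta ρ = 0.9).

## Hyperparameter search and evaluation

Random search draws each hyperparameter independently and uniformly
from its level set; the default grid is: hidden ∈ {500, 800, 1000,
1200, 1500, 2000}; β on six regular levels of [0.6, 0.95]; slope ∈
{25, 50, 75}; learning rate mixing published values with log-uniform
padding of [1e-5, 0.5] to 15 levels; weight decay {0, 1e-4} plus a
four-level geometric ladder on [0.001, 0.05]; clipping on/off; epochs ∈
{10, 25, 50, 100}. A zero learning rate is accepted as a degenerate
null update (useful for tests) but never appears in the grid.

Nested cross-validation separates selection from evaluation: inner
stratified k-fold (default k = 3) scores each drawn point by mean
balanced accuracy; the best point (ties to the earliest draw) is
retrained on the full outer-training portion and evaluated on the outer
fold (default k = 5). Repetitions (default 10) reshuffle the outer
folds; the summary reports the mean and standard deviation over
per-repetition means. Every repetition, fold shuffle, draw, weight
initialization and oversampling draw derives its seed from one master
seed via a spawned seed sequence, so runs are bit-reproducible.

Balanced accuracy and AUC are computed with scikit-learn
(`balanced_accuracy_score`, `roc_auc_score`); the AUC path is
cross-checked in the tests against a brute-force pairwise comparison
with half credit for ties. The continuous score behind AUC is the
positive output neuron's fraction of output spikes — coarse (T + 1
levels per neuron) but monotone in the evidence the decision rule uses.

## Class balancing

Minority oversampling draws duplicates uniformly with replacement from
an explicit seed until both classes reach the majority count. Two
placements are provided: `paper` equalizes the whole dataset before
splitting, which reproduces the classical protocol but lets duplicated
minority molecules appear on both sides of an outer split; `safe`
(recommended, and the default) oversamples inside each training portion
only, so no held-out fold contains a copy of a training record. Both
modes record per-fold index sets, and the test suite asserts the
leakage properties of each.

## SMILES processing and fingerprints

Standardization uses RDKit's MolStandardize (Cleanup + functional-group
Normalize + canonical SMILES); it is idempotent and maps equivalent
notations to one string. MACCS encoding strips RDKit's never-set
placeholder bit 0 to yield exactly the 166 public keys; ECFP uses the
Morgan generator (default radius 2, 1024 bits). Unparseable SMILES are
dropped with a logged, machine-readable skip report rather than
aborting a load. The Tanimoto similarity of two all-zero vectors is
defined as 0 with a warning (the union is empty; 0 states "no shared
substructure evidence" without raising inside a mean over pairs).

## Synthetic data

The generator emulates what matters for exercising this pipeline:
fixed-length sparse binary vectors, class-dependent bit statistics, and
configurable imbalance. Each bit is an independent Bernoulli draw; a
chosen block of informative bits is active with probability p_on_active
in the positive class versus the shared background rate p_background.
Defaults (166 bits, 30 informative, p_on_active = 0.6,
p_background = 0.1, 500 per class) produce a task that a well-configured
network learns to ≥ 90 % balanced accuracy while a no-signal version
(p_on_active = p_background) stays at chance; raising the background
rate raises the mean pairwise Tanimoto similarity into the ~0.2–0.35
band typical of public toxicity benchmarks. Not emulated: correlated
substructure bits, valid chemistry behind the bits, and assay label
noise — passing tests demonstrate the machinery, not real-endpoint
performance.

## Problem sizes in tests and the acceptance script

The bundled checks run at desk scale by design: learnability trains the
published best configuration (1000 hidden, β = 0.95, slope 50, Adamax
2e-3, 25 epochs) on 1000 synthetic molecules; the null control repeats
that over five seeds; the nested-CV hygiene run uses 200 samples with a
reduced grid (32–64 hidden, 5 epochs, T = 10–15) and two repetitions.
Full-scale screening of public benchmarks uses the same code paths with
the default grid and ten repetitions.

## Known limitations

- Only first-order LIF neurons; no synaptic-conductance (second-order)
  dynamics, no refractory counter beyond subtraction, no reset-to-zero.
- Only single-task binary endpoints; multi-label tables are screened
  one task column at a time.
- The spike-fraction score quantizes AUC at fine-grained ties; with
  small T, many molecules share scores.
- Random search treats the grid axes independently; no adaptive or
  Bayesian search.
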