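"""Fully connected fingerprint-in, two-neuron-out spiking classifier.

Architecture: one input unit per fingerprint bit, one hidden LIF layer,
and an output layer of two LIF neurons. The fingerprint is injected
unchanged as input current at every one of the T simulation steps —
binary fingerprints are already spike-train-shaped, so no input encoding
is needed. The predicted class is the output neuron that fired more
spikes over the window (rate coding); the continuous score is the
positive neuron's share of output spikes.

Training backpropagates through time with hard spikes in the forward
pass and the logistic surrogate derivative in the backward pass. The
spike inside the reset-by-subtraction term is treated as a constant
during differentiation, which keeps the membrane recursion gradient at
beta per step and avoids the large negative factors the surrogate would
otherwise inject through the reset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from spikescreen.lif_core import LIFParams, SurrogateParams, surrogate_grad


@dataclass(frozen=True)
class NetworkSpec:
    """Shape and dynamics of one classifier network."""

    n_inputs: int
    n_hidden: int
    n_outputs: int = 2
    n_steps: int = 25
    lif: LIFParams = field(default_factory=LIFParams)
    surrogate: SurrogateParams = field(default_factory=SurrogateParams)

    def __post_init__(self):
        if self.n_outputs != 2:
            raise ValueError("the classifier has exactly 2 output neurons")
        if self.n_inputs < 1 or self.n_hidden < 1:
            raise ValueError("n_inputs and n_hidden must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


@dataclass
class ForwardResult:
    """Spike counts over the simulation window and the derived score."""

    output_counts: np.ndarray  # (2,) ints in [0, T]
    hidden_counts: np.ndarray  # (n_hidden,) ints in [0, T]
    score: float  # positive-neuron spike fraction in [0, 1]


@dataclass
class SpikingNet:
    """Weights of the two dense projections, plus the defining spec."""

    spec: NetworkSpec
    W1: np.ndarray  # (n_inputs, n_hidden)
    W2: np.ndarray  # (n_hidden, 2)

    def copy(self) -> "SpikingNet":
        return SpikingNet(self.spec, self.W1.copy(), self.W2.copy())


def init_network(spec: NetworkSpec, seed: int) -> SpikingNet:
    """Scaled-uniform dense initialization, reproducible from the seed.

    Each weight matrix is drawn U(-1/sqrt(fan_in), 1/sqrt(fan_in)).
    No bias terms: an all-zero fingerprint must stay silent.
    """
    rng = np.random.default_rng(seed)
    b1 = 1.0 / np.sqrt(spec.n_inputs)
    b2 = 1.0 / np.sqrt(spec.n_hidden)
    W1 = rng.uniform(-b1, b1, size=(spec.n_inputs, spec.n_hidden))
    W2 = rng.uniform(-b2, b2, size=(spec.n_hidden, spec.n_outputs))
    return SpikingNet(spec, W1, W2)


def forward_batch(
    net: SpikingNet, X: np.ndarray, cache: bool = False, smooth: bool = False
) -> tuple[np.ndarray, np.ndarray, dict | None]:
    """Simulate a batch for T steps; return output and hidden spike counts.

    With ``cache=True`` the per-step spikes and surrogate derivatives are
    kept for :func:`backward_batch`. Each sample evolves independently, so
    predictions are identical in or out of a batch.

    ``smooth=True`` replaces the Heaviside step by the logistic sigmoid of
    the surrogate slope everywhere, making the whole forward pass
    differentiable; for a one-step network the backward pass then computes
    the exact gradient of this relaxed forward, which is how the surrogate
    machinery is validated against finite differences.
    """
    spec = net.spec
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != spec.n_inputs:
        raise ValueError(
            f"expected (batch, {spec.n_inputs}) input, got {X.shape}"
        )
    B, T = X.shape[0], spec.n_steps
    beta, theta = spec.lif.beta, spec.lif.threshold

    I_h = X @ net.W1  # static injection: identical current every step
    V_h = np.zeros((B, spec.n_hidden))
    V_o = np.zeros((B, spec.n_outputs))
    hidden_counts = np.zeros((B, spec.n_hidden))
    output_counts = np.zeros((B, spec.n_outputs))

    s_h_t = np.empty((T, B, spec.n_hidden)) if cache else None
    g_h_t = np.empty((T, B, spec.n_hidden)) if cache else None
    g_o_t = np.empty((T, B, spec.n_outputs)) if cache else None

    def fire(U):
        if smooth:
            from scipy.special import expit

            return expit(spec.surrogate.slope * (U - theta))
        return (U >= theta).astype(np.float64)

    for t in range(T):
        U_h = beta * V_h + I_h
        s_h = fire(U_h)
        V_h = U_h - s_h * theta
        I_o = s_h @ net.W2
        U_o = beta * V_o + I_o
        s_o = fire(U_o)
        V_o = U_o - s_o * theta
        hidden_counts += s_h
        output_counts += s_o
        if cache:
            s_h_t[t] = s_h
            g_h_t[t] = surrogate_grad(U_h - theta, spec.surrogate)
            g_o_t[t] = surrogate_grad(U_o - theta, spec.surrogate)

    cached = {"X": X, "s_h": s_h_t, "g_h": g_h_t, "g_o": g_o_t} if cache else None
    return output_counts, hidden_counts, cached


def backward_batch(
    net: SpikingNet, cached: dict, d_counts: np.ndarray
) -> dict[str, np.ndarray]:
    """Backprop-through-time of d(loss)/d(output counts) onto the weights.

    The spike-count sum distributes the count gradient to every step;
    within each step the hard threshold is differentiated with the
    surrogate, and the membrane recursion carries gradient backwards with
    factor beta (reset term held constant).
    """
    spec = net.spec
    beta = spec.lif.beta
    X, s_h, g_h, g_o = cached["X"], cached["s_h"], cached["g_h"], cached["g_o"]
    T, B = s_h.shape[0], s_h.shape[1]

    dW2 = np.zeros_like(net.W2)
    sum_gUh = np.zeros((B, spec.n_hidden))
    gUo_next = np.zeros((B, spec.n_outputs))
    gUh_next = np.zeros((B, spec.n_hidden))
    for t in range(T - 1, -1, -1):
        gUo = d_counts * g_o[t] + beta * gUo_next
        dW2 += s_h[t].T @ gUo
        d_sh = gUo @ net.W2.T
        gUh = d_sh * g_h[t] + beta * gUh_next
        sum_gUh += gUh
        gUo_next, gUh_next = gUo, gUh
    dW1 = X.T @ sum_gUh
    return {"W1": dW1, "W2": dW2}


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def rate_loss(output_counts: np.ndarray, labels: np.ndarray) -> float:
    """Mean cross-entropy of the softmax over time-summed spike counts."""
    loss, _ = rate_loss_grad(output_counts, labels)
    return loss


def rate_loss_grad(
    output_counts: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Loss and its gradient with respect to the output spike counts."""
    counts = np.atleast_2d(np.asarray(output_counts, dtype=np.float64))
    labels = np.atleast_1d(np.asarray(labels, dtype=np.int64))
    if counts.shape[0] != labels.shape[0]:
        raise ValueError("counts and labels batch sizes differ")
    p = _softmax(counts)
    eps = 1e-12
    loss = float(-np.log(p[np.arange(len(labels)), labels] + eps).mean())
    grad = p.copy()
    grad[np.arange(len(labels)), labels] -= 1.0
    grad /= len(labels)
    return loss, grad


def forward(net: SpikingNet, fingerprint: np.ndarray, spec: NetworkSpec | None = None) -> ForwardResult:
    """Simulate a single fingerprint and summarize its spiking response."""
    fp = np.asarray(fingerprint, dtype=np.float64).reshape(1, -1)
    out, hid, _ = forward_batch(net, fp)
    counts = out[0]
    total = counts.sum()
    score = float(counts[1] / max(1.0, total))
    return ForwardResult(
        output_counts=counts.astype(np.int64),
        hidden_counts=hid[0].astype(np.int64),
        score=score,
    )


def scores_batch(net: SpikingNet, X: np.ndarray) -> np.ndarray:
    """Positive-neuron spike fraction for each row of X."""
    out, _, _ = forward_batch(net, X)
    totals = np.maximum(1.0, out.sum(axis=1))
    return out[:, 1] / totals


def predict(result: ForwardResult) -> int:
    """Class of the output neuron that fired more spikes; ties go to 0."""
    c = result.output_counts
    return 1 if c[1] > c[0] else 0


def predict_batch(net: SpikingNet, X: np.ndarray) -> np.ndarray:
    out, _, _ = forward_batch(net, X)
    return (out[:, 1] > out[:, 0]).astype(np.int64)
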