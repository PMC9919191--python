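"""Discrete-time leaky integrate-and-fire dynamics with surrogate gradients.

The membrane potential of each neuron decays by a factor beta per step,
integrates the incoming current, and fires when it reaches the threshold;
after a spike the threshold is subtracted from the potential (reset by
subtraction), preserving any supra-threshold residual. The continuous
RC-circuit picture (time constant tau = RC driving dV/dt) is absorbed into
beta and the synaptic weights by the forward-Euler discretization:

    U_t = beta * V_{t-1} + I_t
    s_t = H(U_t - theta)            (Heaviside; the spike)
    V_t = U_t - s_t * theta         (reset by subtraction)

Training replaces the derivative of the Heaviside step (a Dirac delta)
with the derivative of a logistic sigmoid of finite slope k, evaluated at
the distance from threshold — the standard surrogate-gradient trick. The
forward pass always emits hard binary spikes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit


@dataclass(frozen=True)
class LIFParams:
    """Neuron parameters: per-step membrane decay and firing threshold.

    beta is the dimensionless decay multiplier in (0, 1) applied to the
    membrane potential each step; threshold is the firing level in
    membrane-potential units. Only reset by subtraction is implemented.
    """

    beta: float = 0.95
    threshold: float = 1.0
    reset_mode: str = "subtract"

    def __post_init__(self):
        if not 0.0 < self.beta < 1.0:
            raise ValueError(f"beta must be in (0, 1), got {self.beta}")
        if self.threshold <= 0.0:
            raise ValueError(f"threshold must be > 0, got {self.threshold}")
        if self.reset_mode != "subtract":
            raise ValueError("only reset_mode='subtract' is implemented")


@dataclass
class LIFState:
    """Membrane potentials of a layer of neurons, zero at sequence start."""

    V: np.ndarray

    def __post_init__(self):
        self.V = np.asarray(self.V, dtype=np.float64)
        if not np.isfinite(self.V).all():
            raise ValueError("membrane potentials must be finite")

    @classmethod
    def zeros(cls, n: int) -> "LIFState":
        return cls(V=np.zeros(n))


@dataclass(frozen=True)
class SurrogateParams:
    """Steepness k of the logistic sigmoid used for the backward pass."""

    slope: float = 50.0

    def __post_init__(self):
        if self.slope <= 0.0:
            raise ValueError(f"slope must be > 0, got {self.slope}")


def lif_step(
    state: LIFState, input_current: np.ndarray, params: LIFParams
) -> tuple[np.ndarray, LIFState]:
    """Advance a layer one time step: decay, integrate, fire, subtract.

    Returns the binary spike vector and the post-reset state. A neuron
    fires within the same step its potential crosses the threshold.
    """
    I = np.asarray(input_current, dtype=np.float64)
    if I.shape != state.V.shape:
        raise ValueError(f"length mismatch: current {I.shape} vs state {state.V.shape}")
    if not np.isfinite(I).all():
        raise ValueError("input current must be finite")
    U = params.beta * state.V + I
    spikes = (U >= params.threshold).astype(np.float64)
    return spikes, LIFState(V=U - spikes * params.threshold)


def simulate_constant_input(
    params: LIFParams, input_current: float, n_steps: int
) -> tuple[np.ndarray, np.ndarray]:
    """Drive one neuron from rest with a constant current for n_steps.

    Returns the post-reset voltage trace and the binary spike train.
    Sub-threshold drive follows the geometric charging curve
    V_t = I (1 - beta^t) / (1 - beta), converging to I / (1 - beta).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    state = LIFState.zeros(1)
    voltages = np.empty(n_steps)
    spikes = np.empty(n_steps)
    I = np.array([float(input_current)])
    for t in range(n_steps):
        s, state = lif_step(state, I, params)
        voltages[t] = state.V[0]
        spikes[t] = s[0]
    return voltages, spikes


def spike_function(u_minus_theta: np.ndarray, surrogate: SurrogateParams):
    """Hard-threshold spike with the surrogate derivative used in training.

    The forward value is the exact Heaviside step (1 where the argument is
    >= 0); the returned gradient is d/du sigma(k u) = k sigma(k u)(1 - sigma(k u)),
    the finite-slope stand-in for the Dirac delta.
    """
    u = np.asarray(u_minus_theta, dtype=np.float64)
    if not np.isfinite(u).all():
        raise ValueError("input must be finite")
    forward = (u >= 0.0).astype(np.float64)
    return forward, surrogate_grad(u, surrogate)


def surrogate_grad(u_minus_theta: np.ndarray, surrogate: SurrogateParams) -> np.ndarray:
    """Derivative of the logistic surrogate at a distance from threshold."""
    s = expit(surrogate.slope * np.asarray(u_minus_theta, dtype=np.float64))
    return surrogate.slope * s * (1.0 - s)


def trace_to_rows(voltages: np.ndarray, spikes: np.ndarray):
    """(step, V, spike) rows for CSV export of a simulated trace."""
    return [
        (t, float(v), int(s)) for t, (v, s) in enumerate(zip(voltages, spikes))
    ]
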