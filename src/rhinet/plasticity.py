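"""Trial-integrated Hebbian plasticity with a lateral-inhibition gate.

The plastic pathways of the network learn from the covariation of pre- and
postsynaptic rate traces over a whole trial.  The per-step weight increment
is a rate-based reduction of spike-timing-dependent plasticity,

    dw(t) = alpha * Vi(t) Vj(t) + beta * Vi'(t) Vj(t) + gamma * Vi(t) Vj'(t)

with printed integral coefficients alpha = -0.0035, beta = 0.35,
gamma = -0.55 (i pos tsynaptic, j presynaptic, primes are per-step rate
differences).  The increments are integrated over the trial and applied
once, multiplied by a per-postsynaptic-neuron lateral-inhibition gate

    Winhibit(T+1) = tanh(Winhibit(T) - (2 arccos(fs)/pi) e^(fn-1)) + 1

which confines learning to postsynaptic neurons that fire early and
persistently: for a neuron that fired this trial (fs = 1) the subtracted
term vanishes and the gate saturates toward 2; for a silent neuron it
collapses toward 0 at a speed growing with its lifetime firing count fn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "STDPCoefficients",
    "RateTrace",
    "PlasticSynapse",
    "hebbian_increment",
    "accumulate_trial_delta",
    "firing_state",
    "update_inhibit_gate",
    "apply_plasticity",
]

# exp() argument cap: beyond this the gate is indistinguishable from 0
_EXP_CAP = 50.0


@dataclass(frozen=True)
class STDPCoefficients:
    """Integral coefficients of the underlying STDP kernel."""

    alpha: float = -0.0035
    beta: float = 0.35
    gamma: float = -0.55


@dataclass
class RateTrace:
    """Per-neuron firing-rate time series for one trial.

    ``rates`` has shape (n_steps + 1, n_neurons) and includes the resting
    state at t = 0, so the per-step increments are plain differences.
    """

    rates: np.ndarray

    @property
    def increments(self) -> np.ndarray:
        return np.diff(self.rates, axis=0)

    @property
    def values(self) -> np.ndarray:
        """Rates at steps 1..T, aligned with :attr:`increments`."""
        return self.rates[1:]

    @property
    def peak(self) -> np.ndarray:
        return self.rates.max(axis=0)


def hebbian_increment(
    Vi: float | np.ndarray,
    Vj: float | np.ndarray,
    dVi: float | np.ndarray,
    dVj: float | np.ndarray,
    coeffs: STDPCoefficients = STDPCoefficients(),
) -> float | np.ndarray:
    """Per-step weight increment alpha*Vi*Vj + beta*dVi*Vj + gamma*Vi*dVj."""
    out = coeffs.alpha * Vi * Vj + coeffs.beta * dVi * Vj + coeffs.gamma * Vi * dVj
    return out


def accumulate_trial_delta(
    post_trace: RateTrace,
    pre_trace: RateTrace,
    coeffs: STDPCoefficients = STDPCoefficients(),
    dt_ms: float = 1.0,
) -> np.ndarray:
    """Integrate the Hebbian increment over one trial.

    Returns the (n_post, n_pre) matrix DW with
    DW[i, j] = sum_t dw_ij(t) * dt.
    """
    if post_trace.rates.shape[0] != pre_trace.rates.shape[0]:
        raise ValueError(
            "pre- and postsynaptic traces must cover the same steps: "
            f"{post_trace.rates.shape[0]} vs {pre_trace.rates.shape[0]}"
        )
    Vi, dVi = post_trace.values, post_trace.increments
    Vj, dVj = pre_trace.values, pre_trace.increments
    dW = (
        coeffs.alpha * np.einsum("ti,tj->ij", Vi, Vj)
        + coeffs.beta * np.einsum("ti,tj->ij", dVi, Vj)
        + coeffs.gamma * np.einsum("ti,tj->ij", Vi, dVj)
    )
    return dW * dt_ms


def firing_state(post_trace: RateTrace, threshold: float = 0.7) -> np.ndarray:
    """Trial firing state fs per postsynaptic neuron.

    fs = 1 iff the neuron's rate exceeded ``threshold`` at any step of the
    trial (strictly greater; a peak exactly at threshold does not fire).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    return (post_trace.peak > threshold).astype(float)


def update_inhibit_gate(
    gate: float | np.ndarray, fs: float | np.ndarray, fn: float | np.ndarray
) -> float | np.ndarray:
    """One trial update of the lateral-inhibition gate.

    new = tanh(gate - (2 arccos(fs)/pi) * e^(fn-1)) + 1, always in (0, 2).
    """
    fs = np.asarray(fs, dtype=float)
    if np.any(fs < 0) or np.any(fs > 1):
        raise ValueError("fs must be 0 or 1")
    fn = np.asarray(fn, dtype=float)
    if np.any(fn < 0):
        raise ValueError("fn must be non-negative")
    penalty = (2.0 * np.arccos(fs) / np.pi) * np.exp(np.minimum(fn - 1.0, _EXP_CAP))
    new = np.tanh(np.asarray(gate, dtype=float) - penalty) + 1.0
    if np.ndim(gate) == 0 and np.ndim(fs) == 0:
        return float(new)
    return new


@dataclass
class PlasticSynapse:
    """A learnable pathway plus its per-postsynaptic-neuron gate state.

    ``W`` is (n_post, n_pre), signed; ``gate`` (Winhibit) lies in (0, 2);
    ``fire_counts`` is the lifetime number of trials each postsynaptic
    neuron fired.  The gate starts neutral at 1.
    """

    W: np.ndarray
    threshold: float = 0.7
    gate: np.ndarray = field(default=None)  # type: ignore[assignment]
    fire_counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        n_post = self.W.shape[0]
        if self.gate is None:
            self.gate = np.ones(n_post)
        if self.fire_counts is None:
            self.fire_counts = np.zeros(n_post, dtype=int)

    @classmethod
    def ones(cls, n_post: int, n_pre: int, threshold: float = 0.7) -> "PlasticSynapse":
        return cls(W=np.ones((n_post, n_pre)), threshold=threshold)

    def end_of_trial(
        self,
        post_trace: RateTrace,
        pre_trace: RateTrace,
        coeffs: STDPCoefficients = STDPCoefficients(),
        dt_ms: float = 1.0,
        clip: float | None = None,
    ) -> None:
        """Run the full trial update: gate, firing counts, gated weight step."""
        fs = firing_state(post_trace, self.threshold)
        self.fire_counts = self.fire_counts + fs.astype(int)
        self.gate = update_inhibit_gate(self.gate, fs, self.fire_counts)
        dW = accumulate_trial_delta(post_trace, pre_trace, coeffs, dt_ms=dt_ms)
        apply_plasticity(self, dW, clip=clip)


def apply_plasticity(
    syn: PlasticSynapse, dW: np.ndarray, clip: float | None = None
) -> PlasticSynapse:
    """Apply a gated trial delta in place: W[i, :] += dW[i, :] * gate[i].

    Rows whose gate has collapsed to ~0 are effectively frozen, which is
    what localizes learning to early/long-firing postsynaptic neurons.
    """
    if dW.shape != syn.W.shape:
        raise ValueError(f"delta shape {dW.shape} != weight shape {syn.W.shape}")
    syn.W = syn.W + dW * syn.gate[:, None]
    if clip is not None:
        np.clip(syn.W, -clip, clip, out=syn.W)
    return syn
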