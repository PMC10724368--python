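"""Angular population coding and elementary firing-rate dynamics.

Every brain area in the model is a population of rate neurons, one per
preferred angle on a shared uniform grid.  A stimulus at angle ``J`` drives
the population through Gaussian receptive fields centred on each neuron's
preferred angle, and each neuron's firing rate relaxes toward its
instantaneous drive with a first-order (leaky) Euler step

    V(t+1) = V(t) - C * (V(t) - S(t))

where ``C`` is the per-step rate constant of the area.  Areas downstream of
the sensory sheets relax toward ``tanh`` of their summed, weighted synaptic
input instead of a raw stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AngleGrid",
    "ReceptiveField",
    "PopulationState",
    "receptive_field_intensity",
    "population_stimulus",
    "relax_step",
    "step_driven_area",
]


@dataclass(frozen=True)
class AngleGrid:
    """Uniform grid of preferred angles (degrees) shared by all areas.

    The default spans -60..+60 in 3 degree steps, i.e. 41 neurons.
    """

    min_deg: float = -60.0
    max_deg: float = 60.0
    spacing: float = 3.0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")
        span = self.max_deg - self.min_deg
        if span <= 0:
            raise ValueError("max_deg must exceed min_deg")
        n = span / self.spacing
        if abs(n - round(n)) > 1e-9:
            raise ValueError("grid span must be an integer multiple of the spacing")

    @property
    def angles(self) -> np.ndarray:
        n = int(round((self.max_deg - self.min_deg) / self.spacing)) + 1
        return self.min_deg + self.spacing * np.arange(n)

    @property
    def n(self) -> int:
        return len(self.angles)

    def index_of(self, angle_deg: float) -> int:
        """Index of the neuron whose preferred angle is nearest ``angle_deg``."""
        return int(np.argmin(np.abs(self.angles - angle_deg)))

    def contains(self, angle_deg: float) -> bool:
        return self.min_deg <= angle_deg <= self.max_deg


@dataclass(frozen=True)
class ReceptiveField:
    """Gaussian tuning width, in units of the grid spacing.

    ``sigma`` controls perceptual precision: a wider field (larger sigma)
    means a coarser angular code.  With the default 3 degree grid, sigma =
    2/3/4 gives fields whose visible extent is roughly +/-20/30/40 degrees.
    """

    sigma: float = 3.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


@dataclass
class PopulationState:
    """Firing rates of one area at one instant (one entry per grid angle)."""

    rates: np.ndarray
    time_ms: float = 0.0

    @classmethod
    def zeros(cls, grid: AngleGrid) -> "PopulationState":
        return cls(rates=np.zeros(grid.n), time_ms=0.0)

    def copy(self) -> "PopulationState":
        return PopulationState(rates=self.rates.copy(), time_ms=self.time_ms)


def receptive_field_intensity(
    offset_deg: float | np.ndarray,
    field: ReceptiveField,
    grid_spacing: float = 3.0,
) -> float | np.ndarray:
    """Stimulus intensity a neuron receives at angular ``offset_deg`` from its
    preferred angle.

    The offset is expressed in grid-step units (``offset / spacing``) before
    the Gaussian is applied, so sigma is dimensionless in grid steps:

        s = exp(-(offset/spacing)^2 / (2 sigma^2))

    Maximal (1) at zero offset, symmetric, strictly decreasing in |offset|.
    """
    if grid_spacing <= 0:
        raise ValueError(f"grid_spacing must be positive, got {grid_spacing}")
    d = np.asarray(offset_deg, dtype=float) / grid_spacing
    out = np.exp(-(d**2) / (2.0 * field.sigma**2))
    if np.isscalar(offset_deg) or np.ndim(offset_deg) == 0:
        return float(out)
    return out


def population_stimulus(
    stimulus_angle: float,
    grid: AngleGrid,
    field: ReceptiveField,
    gain: float = 1.0,
    clip_below: float = 1e-6,
) -> np.ndarray:
    """Stimulus intensity vector delivered to a population by an angle.

    Element ``k`` is ``gain * intensity(angles[k] - stimulus_angle)``; the
    neuron tuned nearest the stimulus receives the largest drive.
    Intensities below ``clip_below`` are zeroed so a receptive field has a
    finite extent.
    """
    if not grid.contains(stimulus_angle):
        raise ValueError(
            f"stimulus angle {stimulus_angle} outside grid "
            f"[{grid.min_deg}, {grid.max_deg}]"
        )
    if not 0.0 <= gain <= 1.0:
        raise ValueError(f"gain must lie in [0, 1], got {gain}")
    s = gain * receptive_field_intensity(
        grid.angles - stimulus_angle, field, grid.spacing
    )
    s = np.asarray(s, dtype=float)
    s[s < clip_below] = 0.0
    return s


def relax_step(
    rate: float | np.ndarray, target: float | np.ndarray, C: float
) -> float | np.ndarray:
    """One Euler step of leaky relaxation toward ``target``.

    new = rate + C * (target - rate); the fixed point is ``target`` and the
    per-step contraction factor is (1 - C).
    """
    if not 0.0 < C <= 1.0:
        raise ValueError(f"rate constant C must lie in (0, 1], got {C}")
    new = np.asarray(rate, dtype=float) + C * (
        np.asarray(target, dtype=float) - np.asarray(rate, dtype=float)
    )
    if np.ndim(rate) == 0:
        return float(new)
    return new


def _apply_weight(W: float | np.ndarray, pre_rates: np.ndarray) -> np.ndarray:
    """Weighted presynaptic drive for scalar (topographic), diagonal or full
    matrix weights."""
    W = np.asarray(W) if not np.isscalar(W) else W
    if np.isscalar(W) or np.ndim(W) == 0:
        return float(W) * pre_rates
    W = np.asarray(W, dtype=float)
    if W.ndim == 1:
        if W.shape[0] != pre_rates.shape[0]:
            raise ValueError(
                f"diagonal weight length {W.shape[0]} != population size "
                f"{pre_rates.shape[0]}"
            )
        return W * pre_rates
    if W.ndim == 2:
        if W.shape[1] != pre_rates.shape[0]:
            raise ValueError(
                f"weight matrix is {W.shape} but presynaptic population has "
                f"{pre_rates.shape[0]} neurons"
            )
        return W @ pre_rates
    raise ValueError(f"weights must be scalar, 1-D or 2-D, got ndim={W.ndim}")


def step_driven_area(
    state: PopulationState,
    drives: list[tuple[float | np.ndarray, PopulationState]],
    C: float,
) -> PopulationState:
    """Advance a downstream area one step.

    Each neuron relaxes toward ``tanh`` of the summed weighted presynaptic
    rates over all afferent pathways.  With all-zero input, rates decay
    geometrically toward zero.
    """
    total = np.zeros_like(state.rates)
    for W, pre in drives:
        if pre.rates.shape != state.rates.shape and np.ndim(W) < 2:
            raise ValueError("presynaptic and postsynaptic grids differ")
        total += _apply_weight(W, pre.rates)
    target = np.tanh(total)
    new = relax_step(state.rates, target, C)
    return PopulationState(rates=np.asarray(new), time_ms=state.time_ms + 1.0)
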