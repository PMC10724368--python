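"""The simulated rubber-hand-illusion experiments.

Each experiment runs test trials on a trained network with proprioception
held at 0 degrees and the visual hand displaced by a disparity, then reads
the behavioural decision out of AI.  Proprioceptive drift is the decoded
angle minus the proprioceptive angle (positive toward the visual hand).

Because unsupervised training is stochastic (random babbling angles), the
sweep functions accept several independently trained replicate networks
and report the per-disparity median drift, which is robust to occasional
badly converged replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .network import (
    Network,
    NetworkConfig,
    NotTrainedError,
    TrialRecord,
    TrialSchedule,
    decode_decision,
    ownership_judgment,
)

__all__ = [
    "DriftCurve",
    "ConditionSpec",
    "SIMILAR_HAND_GAIN",
    "DISSIMILAR_HAND_GAIN",
    "train_replicates",
    "proprioceptive_drift_sweep",
    "precision_sweep",
    "appearance_replacement",
    "asynchrony_experiment",
    "unisensory_experiment",
    "disability_experiment",
    "fit_drift_breakpoint",
    "illusion_half_range",
]

# visual-gain calibration of the appearance conditions: chosen so the
# similar-hand illusion window closes near the 21-degree plateau onset and
# the dissimilar hand induces no illusion at any disparity
SIMILAR_HAND_GAIN = 0.1
DISSIMILAR_HAND_GAIN = 0.02

TPJ_LESION_PATHWAYS = ("S1-TPJ", "EBA-TPJ")
AI_LESION_PATHWAYS = ("S1-AI", "TPJ-AI", "EBA-AI")


@dataclass
class DriftCurve:
    """Proprioceptive drift (degrees) versus visual disparity (degrees)."""

    disparities: np.ndarray
    drifts: np.ndarray
    condition: str = "own-hand"
    n_replicates: int = 1

    def __post_init__(self) -> None:
        self.disparities = np.asarray(self.disparities, dtype=float)
        self.drifts = np.asarray(self.drifts, dtype=float)
        if self.disparities.shape != self.drifts.shape:
            raise ValueError("disparities and drifts must have equal length")

    def drift_at(self, disparity: float) -> float:
        i = int(np.argmin(np.abs(self.disparities - disparity)))
        return float(self.drifts[i])

    def max_abs_drift(self, min_disparity: float | None = None) -> float:
        mask = (
            np.abs(self.disparities) > min_disparity
            if min_disparity is not None
            else np.ones_like(self.disparities, dtype=bool)
        )
        if not mask.any():
            return 0.0
        return float(np.abs(self.drifts[mask]).max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "disparity_deg": self.disparities,
                "drift_deg": self.drifts,
                "condition": self.condition,
                "n_replicates": self.n_replicates,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DriftCurve":
        return cls(
            disparities=df["disparity_deg"].to_numpy(),
            drifts=df["drift_deg"].to_numpy(),
            condition=str(df["condition"].iloc[0]) if len(df) else "own-hand",
            n_replicates=int(df["n_replicates"].iloc[0]) if len(df) else 1,
        )


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental manipulation; every other factor stays at default."""

    visual_gain: float = 1.0
    visual_delay_ms: float = 0.0
    sigma: float | None = None
    lesion_target: str | None = None  # "TPJ" | "AI"
    lesion_severity: float = 0.0
    unisensory: str | None = None  # "proprioception_only" | "vision_only"
    label: str = "own-hand"


def train_replicates(
    config: NetworkConfig | None = None,
    n_replicates: int = 5,
    n_trials: int = 500,
    seed: int | None = 0,
) -> list[Network]:
    """Train independent replicate networks (one RNG stream per replicate)."""
    config = config or NetworkConfig()
    ss = np.random.SeedSequence(seed)
    nets = []
    for child in ss.spawn(n_replicates):
        net = Network(config)
        net.train(n_trials, rng=np.random.default_rng(child))
        nets.append(net)
    return nets


def _require_trained(networks: list[Network]) -> None:
    untrained = [i for i, n in enumerate(networks) if not n.is_trained]
    if len(untrained) > len(networks) / 2:
        raise NotTrainedError(
            "drift experiments need trained networks (plastic pathways still "
            f"excitatory in replicates {untrained}); call train() first"
        )


def _median_drift(
    networks: list[Network],
    disparity: float,
    visual_gain: float = 1.0,
    visual_delay_ms: float = 0.0,
    proprioception: float = 0.0,
    decode_area: str = "AI",
) -> float:
    vals = []
    for net in networks:
        sched = TrialSchedule.from_config(
            net.config,
            motor_angle=proprioception,
            visual_angle=proprioception + disparity,
            visual_gain=visual_gain,
            visual_delay_ms=visual_delay_ms,
        )
        decision = decode_decision(net.run_trial(sched), area=decode_area)
        vals.append(0.0 if decision is None else decision - proprioception)
    return float(np.median(vals))


def proprioceptive_drift_sweep(
    networks: list[Network] | Network,
    disparities: np.ndarray | None = None,
    visual_gain: float = 1.0,
    visual_delay_ms: float = 0.0,
    condition: str = "own-hand",
    check_trained: bool = True,
    decode_area: str = "AI",
) -> DriftCurve:
    """Drift versus disparity for one condition (median over replicates)."""
    if isinstance(networks, Network):
        networks = [networks]
    if check_trained:
        _require_trained(networks)
    grid = networks[0].config.grid
    if disparities is None:
        disparities = grid.angles
    drifts = [
        _median_drift(networks, float(d), visual_gain, visual_delay_ms,
                      decode_area=decode_area)
        for d in disparities
    ]
    return DriftCurve(
        disparities=np.asarray(disparities, dtype=float),
        drifts=np.asarray(drifts),
        condition=condition,
        n_replicates=len(networks),
    )


def precision_sweep(
    sigmas: tuple[float, ...] = (2.0, 3.0, 4.0),
    config: NetworkConfig | None = None,
    disparities: np.ndarray | None = None,
    n_replicates: int = 3,
    n_trials: int = 500,
    seed: int | None = 0,
) -> dict[float, DriftCurve]:
    """Drift curves for several receptive-field widths (one training each).

    A wider receptive field (lower proprioceptive precision) widens the
    disparity range over which the illusion can be induced.
    """
    config = config or NetworkConfig()
    out: dict[float, DriftCurve] = {}
    for s in sigmas:
        cfg = replace(config, sigma=float(s))
        nets = train_replicates(cfg, n_replicates, n_trials, seed)
        curve = proprioceptive_drift_sweep(nets, disparities,
                                           condition=f"sigma={s:g}")
        out[float(s)] = curve
    return out


def appearance_replacement(
    networks: list[Network] | Network,
    condition: str = "similar",
    disparities: np.ndarray | None = None,
    gain: float | None = None,
) -> DriftCurve:
    """Replace the visual hand by a similar or dissimilar one.

    Appearance acts purely through the EBA drive: a hand less like one's own
    evokes a weaker body-part-vision response, modeled as a reduced visual
    gain.
    """
    if condition not in ("similar", "dissimilar", "own"):
        raise ValueError(f"condition must be similar|dissimilar|own, got {condition!r}")
    if gain is None:
        gain = {"similar": SIMILAR_HAND_GAIN,
                "dissimilar": DISSIMILAR_HAND_GAIN,
                "own": 1.0}[condition]
    return proprioceptive_drift_sweep(
        networks, disparities, visual_gain=gain, condition=f"{condition}-hand"
    )


def asynchrony_experiment(
    networks: list[Network] | Network,
    delays_ms: tuple[float, ...] = (0.0, 100.0, 500.0),
    disparities: np.ndarray | None = None,
) -> dict[float, DriftCurve]:
    """Delay the visual stimulus relative to its default onset.

    A large delay pushes vision outside the effective integration window of
    the multisensory areas and abolishes the illusion.
    """
    out: dict[float, DriftCurve] = {}
    for delay in delays_ms:
        if delay < 0:
            raise ValueError(f"delay must be non-negative, got {delay}")
        out[float(delay)] = proprioceptive_drift_sweep(
            networks, disparities, visual_delay_ms=float(delay),
            condition=f"delay={delay:g}ms",
        )
    return out


def unisensory_experiment(
    network: Network, mode: str = "proprioception_only", angle: float = 0.0
) -> tuple[bool, TrialRecord]:
    """Ownership judgment with a single modality.

    With proprioception alone the AI fires (the moving hand is one's own);
    with vision alone the stronger learned inhibition of the visual pathway
    keeps AI below the firing threshold.
    """
    if mode == "proprioception_only":
        sched = TrialSchedule.from_config(network.config, motor_angle=angle)
    elif mode == "vision_only":
        sched = TrialSchedule.from_config(network.config, visual_angle=angle)
    else:
        raise ValueError(
            f"mode must be proprioception_only|vision_only, got {mode!r}"
        )
    record = network.run_trial(sched)
    return ownership_judgment(record), record


def disability_experiment(
    config: NetworkConfig | None = None,
    target: str = "TPJ",
    severity: float = 1.0,
    disparities: np.ndarray | None = None,
    n_replicates: int = 3,
    n_trials: int = 500,
    seed: int | None = 0,
) -> DriftCurve:
    """Lesion a multisensory area by scaling its afferent/efferent weights.

    Severity scales the listed pathways by (1 - severity); the lesioned
    network is trained and tested under the lesion.  A full TPJ lesion
    abolishes the illusion; a full AI lesion leaves decisions dominated by
    vision at most disparities.
    """
    if target not in ("TPJ", "AI"):
        raise ValueError(f"target must be TPJ or AI, got {target!r}")
    if not 0.0 <= severity <= 1.0:
        raise ValueError(f"severity must lie in [0, 1], got {severity}")
    config = config or NetworkConfig()
    pathways = TPJ_LESION_PATHWAYS if target == "TPJ" else AI_LESION_PATHWAYS
    fixed = tuple(p for p in pathways if p in config.fixed_weights)
    cfg = config.lesioned(fixed, severity)
    nets = train_replicates(cfg, n_replicates, n_trials, seed)
    # plastic pathways named in the lesion are scaled after training
    for net in nets:
        for p in pathways:
            if p in net.plastic:
                net.plastic[p].W = net.plastic[p].W * (1.0 - severity)
    # with the output area fully lesioned the decision falls back to the
    # primary integration area
    decode_area = "TPJ" if (target == "AI" and severity >= 1.0) else "AI"
    return proprioceptive_drift_sweep(
        nets, disparities, condition=f"{target}-lesion severity={severity:g}",
        check_trained=severity < 1.0 or target != "AI",
        decode_area=decode_area,
    )


def fit_drift_breakpoint(
    curve: DriftCurve, min_points: int = 5
) -> tuple[float | None, tuple[float, float]]:
    """Two-segment continuous piecewise-linear fit of the drift curve.

    Fits drift = a + b*d + c*max(d - k, 0) on the non-negative branch by
    exhaustive search of the knot k over interior grid disparities, and
    returns (knot, (early_slope, late_slope)).  Returns (None, (b, b)) when
    the curve is degenerate or a single line fits as well as any knot.
    """
    mask = curve.disparities >= 0
    d = curve.disparities[mask]
    y = curve.drifts[mask]
    if len(d) < min_points:
        raise ValueError(f"need at least {min_points} non-negative disparities")
    scale = max(np.abs(y).max(), 1.0)
    X1 = np.column_stack([np.ones_like(d), d])
    beta1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    sse1 = float(((y - X1 @ beta1) ** 2).sum())
    best_sse, best_k, best_slopes = None, None, None
    for k in d[1:-1]:
        X = np.column_stack([np.ones_like(d), d, np.maximum(d - k, 0.0)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(((y - X @ beta) ** 2).sum())
        if best_sse is None or sse < best_sse - 1e-12:
            best_sse, best_k = sse, float(k)
            best_slopes = (float(beta[1]), float(beta[1] + beta[2]))
    # no-breakpoint signal: a straight line explains the curve equally well
    if best_sse is None or sse1 <= best_sse + 1e-9 * scale**2:
        return None, (float(beta1[1]), float(beta1[1]))
    return best_k, best_slopes


def illusion_half_range(curve: DriftCurve, min_drift: float = 1.5) -> float:
    """Largest non-negative disparity with |drift| above ``min_drift``."""
    mask = (curve.disparities >= 0) & (np.abs(curve.drifts) > min_drift)
    if not mask.any():
        return 0.0
    return float(curve.disparities[mask].max())
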