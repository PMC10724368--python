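"""The six-area bodily self-perception network.

Areas and pathways (all populations share one angle grid):

    M1 --(fixed)--> S1 --(fixed)--> TPJ --(fixed)--> AI
    V  --(fixed)--> EBA --(fixed)--^                 ^^
    S1 -----------------(plastic)--------------------+
    EBA ----------------(plastic)--------------------+

M1 (motor command) and V (visual hand angle) are sensory sheets driven by
Gaussian population stimuli; S1 (proprioception), EBA (body-part vision),
TPJ (primary multisensory integration) and AI (high-level integration and
behavioural output) relax toward tanh of their weighted input.  Fixed
pathways are topographic with weight 1 and only transmit; the two pathways
converging on AI from S1 and EBA are plastic full matrices initialised to 1
and are shaped by unsupervised congruent motor-visual babbling, after which
both become inhibitory with vision inhibited more strongly than
proprioception.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .plasticity import PlasticSynapse, RateTrace, STDPCoefficients
from .population import (
    AngleGrid,
    PopulationState,
    ReceptiveField,
    population_stimulus,
    relax_step,
)

__all__ = [
    "AREAS",
    "FIXED_PATHWAYS",
    "PLASTIC_PATHWAYS",
    "NetworkConfig",
    "TrialSchedule",
    "TrialRecord",
    "Network",
    "NotTrainedError",
    "build_network",
    "decode_decision",
    "ownership_judgment",
]

AREAS = ("M1", "V", "S1", "EBA", "TPJ", "AI")
FIXED_PATHWAYS = ("M1-S1", "V-EBA", "S1-TPJ", "EBA-TPJ", "TPJ-AI")
PLASTIC_PATHWAYS = ("S1-AI", "EBA-AI")


class NotTrainedError(RuntimeError):
    """Raised when an experiment requires a trained network."""


@dataclass(frozen=True)
class NetworkConfig:
    """All tunable parameters of the network and its default trial protocol.

    Rate constants follow the model's area assignment: C = 0.04 for the
    sensory sheets and their direct targets (M1, V, S1, EBA), C = 0.01 for
    the slowly accumulating TPJ, and C = 0.15 for the fast output area AI.
    Time is discretised in 1 ms Euler steps.
    """

    grid: AngleGrid = field(default_factory=AngleGrid)
    sigma: float = 3.0
    C_by_area: dict = field(
        default_factory=lambda: {
            "M1": 0.04,
            "V": 0.04,
            "S1": 0.04,
            "EBA": 0.04,
            "TPJ": 0.01,
            "AI": 0.15,
        }
    )
    fixed_weights: dict = field(
        default_factory=lambda: {
            "M1-S1": 1.0,
            "V-EBA": 1.0,
            "S1-TPJ": 1.0,
            "EBA-TPJ": 0.85,
            "TPJ-AI": 1.5,
        }
    )
    plastic_init: float = 1.0
    coeffs: STDPCoefficients = field(default_factory=STDPCoefficients)
    firing_threshold: float = 0.7
    # default trial protocol: the motor command precedes the visual
    # consequence (the camera sees the finger only after it moves)
    motor_onset_ms: float = 0.0
    stimulus_duration_ms: float = 100.0
    visual_onset_ms: float = 100.0
    visual_duration_ms: float | None = None  # None: same as stimulus_duration_ms
    trial_length_ms: float = 600.0
    weight_clip: float | None = None
    stimulus_clip_below: float = 1e-6
    # TPJ pooling: each TPJ neuron integrates its angular neighbourhood of
    # S1/EBA through a normalized Gaussian kernel (grid-step sigma) scaled
    # by tpj_gain; sigma 0 disables pooling (strict neuron-to-neuron wiring)
    tpj_pool_sigma: float = 4.0
    tpj_gain: float = 7.0
    # "attenuate": edge neurons pool a truncated neighbourhood and receive
    # proportionally less drive; "normalize": every row is renormalized so
    # edge neurons are driven as strongly as interior ones
    tpj_edge_mode: str = "attenuate"
    # "full": plastic matrices start with every entry 1; "identity": each AI
    # neuron starts connected to its angular counterpart only
    plastic_structure: str = "full"
    # firing rates are rectified at zero: inhibition can silence a neuron
    # but not drive its rate negative
    rectify: bool = True
    # scale of the trial-integrated weight update (the Euler step of the
    # plasticity integral, ms per simulation step)
    plasticity_rate: float = 1.0
    # length of the window over which the plasticity integral runs;
    # None integrates over the whole trial
    learning_window_ms: float | None = None

    def __post_init__(self) -> None:
        bad = [a for a, c in self.C_by_area.items() if not 0.0 < c <= 1.0]
        if bad or set(self.C_by_area) != set(AREAS):
            raise ValueError(
                f"C_by_area must give a constant in (0, 1] for each of {AREAS}; "
                f"offending/missing: {bad or sorted(set(AREAS) - set(self.C_by_area))}"
            )
        if set(self.fixed_weights) != set(FIXED_PATHWAYS):
            raise ValueError(
                f"fixed_weights must cover exactly {FIXED_PATHWAYS}, "
                f"got {tuple(self.fixed_weights)}"
            )
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.trial_length_ms <= 0:
            raise ValueError("trial_length_ms must be positive")
        if self.plastic_structure not in ("identity", "full"):
            raise ValueError(
                f"plastic_structure must be 'identity' or 'full', "
                f"got {self.plastic_structure!r}"
            )
        if self.tpj_edge_mode not in ("attenuate", "normalize"):
            raise ValueError(
                f"tpj_edge_mode must be 'attenuate' or 'normalize', "
                f"got {self.tpj_edge_mode!r}"
            )


    @property
    def receptive_field(self) -> ReceptiveField:
        return ReceptiveField(self.sigma)

    def lesioned(self, pathways: tuple[str, ...], severity: float = 1.0) -> "NetworkConfig":
        """Scale the named fixed pathways by (1 - severity)."""
        if not 0.0 <= severity <= 1.0:
            raise ValueError(f"severity must lie in [0, 1], got {severity}")
        fw = dict(self.fixed_weights)
        for p in pathways:
            if p in fw:
                fw[p] = fw[p] * (1.0 - severity)
            elif p not in PLASTIC_PATHWAYS:
                raise ValueError(f"unknown pathway {p!r}")
        return replace(self, fixed_weights=fw)


@dataclass(frozen=True)
class TrialSchedule:
    """Timed stimulus events for one trial.

    ``None`` for an angle means the corresponding modality is absent.
    ``visual_delay_ms`` shifts the visual window later than its default
    onset (asynchrony manipulations); ``visual_gain`` scales the visual
    drive (appearance manipulations).
    """

    motor_angle: float | None = None
    visual_angle: float | None = None
    visual_gain: float = 1.0
    visual_delay_ms: float = 0.0
    motor_onset_ms: float = 0.0
    motor_offset_ms: float = 100.0
    visual_onset_ms: float = 100.0
    visual_offset_ms: float = 200.0
    trial_length_ms: float = 600.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.visual_gain <= 1.0:
            raise ValueError(f"visual_gain must lie in [0, 1], got {self.visual_gain}")
        if self.visual_delay_ms < 0:
            raise ValueError("visual_delay_ms must be non-negative")
        for t in (self.motor_onset_ms, self.motor_offset_ms):
            if not 0.0 <= t <= self.trial_length_ms:
                raise ValueError(
                    f"event time {t} ms outside trial [0, {self.trial_length_ms}] ms"
                )
        # a delayed visual onset may fall beyond the trial end: the stimulus
        # is then simply never seen (complete asynchrony)

    @classmethod
    def from_config(
        cls,
        config: NetworkConfig,
        motor_angle: float | None = None,
        visual_angle: float | None = None,
        visual_gain: float = 1.0,
        visual_delay_ms: float = 0.0,
    ) -> "TrialSchedule":
        return cls(
            motor_angle=motor_angle,
            visual_angle=visual_angle,
            visual_gain=visual_gain,
            visual_delay_ms=visual_delay_ms,
            motor_onset_ms=config.motor_onset_ms,
            motor_offset_ms=config.motor_onset_ms + config.stimulus_duration_ms,
            visual_onset_ms=config.visual_onset_ms,
            visual_offset_ms=config.visual_onset_ms
            + (
                config.stimulus_duration_ms
                if config.visual_duration_ms is None
                else config.visual_duration_ms
            ),
            trial_length_ms=config.trial_length_ms,
        )


@dataclass
class TrialRecord:
    """Full rate traces of one trial plus the schedule that produced them."""

    traces: dict[str, RateTrace]
    schedule: TrialSchedule
    grid: AngleGrid
    firing_threshold: float = 0.7

    @property
    def decision(self) -> float | None:
        return decode_decision(self)

    @property
    def ownership(self) -> bool:
        return ownership_judgment(self)


class Network:
    """The assembled six-area network.

    Use :func:`build_network` or ``Network(NetworkConfig())``; training is
    performed by :meth:`train` (unsupervised congruent babbling) and single
    trials by :meth:`run_trial`.
    """

    def __init__(self, config: NetworkConfig | None = None):
        self.config = config or NetworkConfig()
        g = self.config.grid
        self.fixed = dict(self.config.fixed_weights)
        if self.config.plastic_structure == "full":
            W0 = np.full((g.n, g.n), self.config.plastic_init)
        else:
            W0 = self.config.plastic_init * np.eye(g.n)
        self.plastic: dict[str, PlasticSynapse] = {
            p: PlasticSynapse(W=W0.copy(), threshold=self.config.firing_threshold)
            for p in PLASTIC_PATHWAYS
        }
        # topographic pooling kernel of the projections converging on TPJ:
        # each TPJ neuron averages its angular neighbourhood of S1/EBA
        # (rows normalized to 1) and the pooled drive is amplified by
        # tpj_gain before the tanh, so co-stimulated neighbourhoods saturate
        ps = self.config.tpj_pool_sigma
        if ps > 0:
            idx = np.arange(g.n)
            K = np.exp(-((idx[:, None] - idx[None, :]) ** 2) / (2.0 * ps**2))
            if self.config.tpj_edge_mode == "normalize":
                self._tpj_kernel = (
                    K / K.sum(axis=1, keepdims=True) * self.config.tpj_gain
                )
            else:
                # scale by the untruncated row sum: interior neurons pool a
                # gain-weighted average; edge neurons, whose neighbourhood is
                # cut off by the grid boundary, receive attenuated drive
                self._tpj_kernel = K * (self.config.tpj_gain / K.sum(axis=1).max())
        else:
            self._tpj_kernel = None
        self.trials_trained = 0

    # -- weights ----------------------------------------------------------

    def weights(self) -> dict[str, np.ndarray | float]:
        out: dict[str, np.ndarray | float] = dict(self.fixed)
        out.update({p: s.W.copy() for p, s in self.plastic.items()})
        return out

    def mean_plastic_weights(self) -> dict[str, float]:
        return {p: float(s.W.mean()) for p, s in self.plastic.items()}

    @property
    def is_trained(self) -> bool:
        """Heuristic: training has flipped both plastic pathways inhibitory."""
        means = self.mean_plastic_weights()
        return self.trials_trained > 0 and all(m < 0 for m in means.values())

    # -- dynamics ---------------------------------------------------------

    def run_trial(
        self, schedule: TrialSchedule, learning: bool = False
    ) -> TrialRecord:
        """Simulate one trial in 1 ms Euler steps and optionally learn.

        M1 and V relax toward their (possibly zero) population stimulus;
        S1/EBA/TPJ/AI relax toward tanh of their weighted afferents.  When
        ``learning`` is on, the two plastic pathways onto AI are updated
        once at trial end from the full traces.
        """
        cfg = self.config
        g = cfg.grid
        rf = cfg.receptive_field
        n_steps = int(round(schedule.trial_length_ms))
        C = cfg.C_by_area

        motor_stim = (
            population_stimulus(
                schedule.motor_angle, g, rf, 1.0, cfg.stimulus_clip_below
            )
            if schedule.motor_angle is not None
            else np.zeros(g.n)
        )
        visual_stim = (
            population_stimulus(
                schedule.visual_angle, g, rf, schedule.visual_gain,
                cfg.stimulus_clip_below,
            )
            if schedule.visual_angle is not None
            else np.zeros(g.n)
        )
        v_on = schedule.visual_onset_ms + schedule.visual_delay_ms
        v_off = schedule.visual_offset_ms + schedule.visual_delay_ms

        rates = {a: np.zeros(g.n) for a in AREAS}
        hist = {a: np.zeros((n_steps + 1, g.n)) for a in AREAS}

        w_m1s1 = self.fixed["M1-S1"]
        w_veba = self.fixed["V-EBA"]
        w_s1tpj = self.fixed["S1-TPJ"]
        w_ebatpj = self.fixed["EBA-TPJ"]
        w_tpjai = self.fixed["TPJ-AI"]
        W_s1ai = self.plastic["S1-AI"].W
        W_ebaai = self.plastic["EBA-AI"].W

        for t in range(n_steps):
            s_m1 = motor_stim if schedule.motor_onset_ms <= t < schedule.motor_offset_ms else 0.0
            s_v = visual_stim if v_on <= t < v_off else 0.0
            m1, v = rates["M1"], rates["V"]
            s1, eba, tpj, ai = rates["S1"], rates["EBA"], rates["TPJ"], rates["AI"]

            if self._tpj_kernel is not None:
                tpj_drive = self._tpj_kernel @ (w_s1tpj * s1 + w_ebatpj * eba)
            else:
                tpj_drive = w_s1tpj * s1 + w_ebatpj * eba
            new = {
                "M1": relax_step(m1, s_m1, C["M1"]),
                "V": relax_step(v, s_v, C["V"]),
                "S1": relax_step(s1, np.tanh(w_m1s1 * m1), C["S1"]),
                "EBA": relax_step(eba, np.tanh(w_veba * v), C["EBA"]),
                "TPJ": relax_step(tpj, np.tanh(tpj_drive), C["TPJ"]),
                "AI": relax_step(
                    ai,
                    np.tanh(W_s1ai @ s1 + w_tpjai * tpj + W_ebaai @ eba),
                    C["AI"],
                ),
            }
            if cfg.rectify:
                for a in ("S1", "EBA", "TPJ", "AI"):
                    np.maximum(new[a], 0.0, out=new[a])
            rates = new
            for a in AREAS:
                hist[a][t + 1] = rates[a]

        record = TrialRecord(
            traces={a: RateTrace(hist[a]) for a in AREAS},
            schedule=schedule,
            grid=g,
            firing_threshold=cfg.firing_threshold,
        )
        if learning:
            self._learn_from(record)
        return record

    def _learn_from(self, record: TrialRecord) -> None:
        window = (
            record.schedule.trial_length_ms
            if self.config.learning_window_ms is None
            else self.config.learning_window_ms
        )
        n_keep = int(round(window)) + 1
        post = RateTrace(record.traces["AI"].rates[:n_keep])
        for pathway, pre_area in (("S1-AI", "S1"), ("EBA-AI", "EBA")):
            pre = RateTrace(record.traces[pre_area].rates[:n_keep])
            self.plastic[pathway].end_of_trial(
                post, pre, self.config.coeffs,
                dt_ms=self.config.plasticity_rate,
                clip=self.config.weight_clip,
            )

    # -- training ---------------------------------------------------------

    def train(
        self,
        n_trials: int = 500,
        rng: np.random.Generator | int | None = None,
        record_history: bool = True,
    ) -> pd.DataFrame:
        """Unsupervised motor-babbling training.

        Each trial draws a motor angle uniformly from the grid and presents
        the congruent visual angle on the default schedule (vision follows
        the movement); plasticity is on.  Returns the per-trial history of
        mean plastic weights and gate statistics.
        """
        if n_trials < 0:
            raise ValueError("n_trials must be non-negative")
        rng = np.random.default_rng(rng)
        rows = []
        angles = self.config.grid.angles
        for trial in range(n_trials):
            theta = float(rng.choice(angles))
            sched = TrialSchedule.from_config(
                self.config, motor_angle=theta, visual_angle=theta
            )
            self.run_trial(sched, learning=True)
            self.trials_trained += 1
            if record_history:
                row = {"trial": self.trials_trained, "motor_angle": theta}
                for p, syn in self.plastic.items():
                    row[f"mean_W[{p}]"] = float(syn.W.mean())
                    row[f"mean_gate[{p}]"] = float(syn.gate.mean())
                    row[f"fired_frac[{p}]"] = float(
                        (syn.fire_counts > 0).mean()
                    )
                rows.append(row)
        return pd.DataFrame(rows)


def build_network(config: NetworkConfig | None = None) -> Network:
    """Assemble a network from a configuration (defaults: 41 neurons/area)."""
    return Network(config)


def decode_decision(record: TrialRecord, area: str = "AI") -> float | None:
    """Behavioural decision: preferred angle of the maximally firing neuron
    of the output area over the whole trial.

    The output area is AI; when AI is fully lesioned the decision is read
    from the primary integration area instead (pass ``area="TPJ"``).
    Returns ``None`` (no decision) for an all-zero trace.  Ties are broken
    toward the angle nearest the trial's motor angle.
    """
    trace = record.traces[area].rates
    if not np.any(trace > 0):
        return None
    peaks = trace.max(axis=0)
    best = peaks.max()
    candidates = np.flatnonzero(peaks >= best - 1e-12)
    angles = record.grid.angles[candidates]
    ref = record.schedule.motor_angle if record.schedule.motor_angle is not None else 0.0
    return float(angles[np.argmin(np.abs(angles - ref))])


def ownership_judgment(record: TrialRecord, threshold: float | None = None) -> bool:
    """True iff any AI neuron exceeded the firing threshold during the trial."""
    thr = record.firing_threshold if threshold is None else threshold
    return bool(record.traces["AI"].rates.max() > thr)
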