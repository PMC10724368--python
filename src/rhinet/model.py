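"""Model/Results front end over the network machinery.

`BodyOwnershipModel` holds the architecture and stimulus protocol;
`fit()` runs unsupervised congruent motor-visual babbling on independent
replicate networks and returns a `BodyOwnershipResults` carrying the
trained synapses, their trial-by-trial history, diagnostics and a
`summary()` table.  The simulated rubber-hand-illusion experiments and
plots hang off the results object.

Example
-------
>>> from rhinet import BodyOwnershipModel
>>> res = BodyOwnershipModel().fit(n_trials=500, seed=0)
>>> print(res.summary())
>>> curve = res.drift_sweep()
>>> curve.drift_at(12.0)
12.0
"""

from __future__ import annotations

import json
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import experiments as _exp
from .network import (
    Network,
    NetworkConfig,
    PLASTIC_PATHWAYS,
    TrialRecord,
    TrialSchedule,
)
from .plasticity import STDPCoefficients
from .population import AngleGrid

__all__ = ["BodyOwnershipModel", "BodyOwnershipResults"]

# NetworkConfig fields that are plain scalars in a flat config file
_SCALAR_FIELDS = (
    "sigma", "plastic_init", "firing_threshold", "motor_onset_ms",
    "stimulus_duration_ms", "visual_onset_ms", "visual_duration_ms",
    "trial_length_ms", "weight_clip", "stimulus_clip_below",
    "tpj_pool_sigma", "tpj_gain", "tpj_edge_mode", "plastic_structure",
    "rectify", "plasticity_rate", "learning_window_ms",
)


class BodyOwnershipModel:
    """The bodily self-perception network, before training."""

    def __init__(self, config: NetworkConfig | None = None):
        self.config = config or NetworkConfig()

    @classmethod
    def from_config(cls, source) -> "BodyOwnershipModel":
        """Build from a flat key-value mapping or a YAML/JSON config file.

        Recognised keys mirror NetworkConfig: grid bounds (``grid_min``,
        ``grid_max``, ``grid_spacing``), per-area rate constants
        (``C_<area>``), fixed pathway weights (``W_<pre>-<post>``), STDP
        coefficients (``alpha``, ``beta``, ``gamma``) and the scalar fields.
        """
        if isinstance(source, (str, Path)):
            text = Path(source).read_text()
            try:
                data = json.loads(text)
            except json.JSONDecodeError:
                import yaml

                data = yaml.safe_load(text)
        else:
            data = dict(source)
        kwargs: dict = {}
        grid_kw = {}
        for key, field_name in (("grid_min", "min_deg"), ("grid_max", "max_deg"),
                                ("grid_spacing", "spacing")):
            if key in data:
                grid_kw[field_name] = float(data.pop(key))
        if grid_kw:
            kwargs["grid"] = AngleGrid(**grid_kw)
        default = NetworkConfig()
        C = dict(default.C_by_area)
        fw = dict(default.fixed_weights)
        coeff_kw = {}
        for key, value in list(data.items()):
            if key.startswith("C_"):
                C[key[2:]] = float(value)
            elif key.startswith("W_"):
                fw[key[2:]] = float(value)
            elif key in ("alpha", "beta", "gamma"):
                coeff_kw[key] = float(value)
            elif key in _SCALAR_FIELDS:
                kwargs[key] = value
            else:
                raise ValueError(f"unknown config key {key!r}")
        kwargs["C_by_area"] = C
        kwargs["fixed_weights"] = fw
        if coeff_kw:
            kwargs["coeffs"] = STDPCoefficients(
                **{**asdict(default.coeffs), **coeff_kw}
            )
        return cls(NetworkConfig(**kwargs))

    def to_config_dict(self) -> dict:
        cfg = self.config
        out = {
            "grid_min": cfg.grid.min_deg,
            "grid_max": cfg.grid.max_deg,
            "grid_spacing": cfg.grid.spacing,
        }
        out.update({f"C_{a}": c for a, c in cfg.C_by_area.items()})
        out.update({f"W_{p}": w for p, w in cfg.fixed_weights.items()})
        out.update(
            {k: getattr(cfg, k) for k in _SCALAR_FIELDS}
        )
        out.update(asdict(cfg.coeffs))
        return out

    def fit(
        self,
        n_trials: int = 500,
        n_replicates: int = 5,
        seed: int | None = 0,
    ) -> "BodyOwnershipResults":
        """Train by unsupervised congruent babbling and return results."""
        ss = np.random.SeedSequence(seed)
        networks, histories = [], []
        for i, child in enumerate(ss.spawn(max(n_replicates, 1))):
            net = Network(self.config)
            hist = net.train(n_trials, rng=np.random.default_rng(child))
            hist["replicate"] = i
            networks.append(net)
            histories.append(hist)
        history = (
            pd.concat(histories, ignore_index=True)
            if histories and len(histories[0])
            else pd.DataFrame()
        )
        return BodyOwnershipResults(self, networks, history, seed=seed)


class BodyOwnershipResults:
    """A fitted bodily self-perception model (trained replicate networks)."""

    def __init__(self, model, networks, weight_history, seed=None):
        self.model = model
        self.networks: list[Network] = networks
        self.weight_history: pd.DataFrame = weight_history
        self.seed = seed

    # -- parameters -------------------------------------------------------

    @property
    def network(self) -> Network:
        """The first replicate (single-network convenience accessor)."""
        return self.networks[0]

    @property
    def mean_weights(self) -> dict[str, float]:
        """Median over replicates of the mean plastic weight per pathway."""
        return {
            p: float(np.median([n.mean_plastic_weights()[p] for n in self.networks]))
            for p in PLASTIC_PATHWAYS
        }

    @property
    def converged(self) -> bool:
        """Both plastic pathways flipped from excitatory to inhibitory."""
        return all(v < 0 for v in self.mean_weights.values())

    def params_frame(self) -> pd.DataFrame:
        rows = []
        for i, net in enumerate(self.networks):
            m = net.mean_plastic_weights()
            for p in PLASTIC_PATHWAYS:
                rows.append({"replicate": i, "pathway": p, "mean_weight": m[p]})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        m = self.mean_weights
        pf = self.params_frame()
        lines = [
            "Bodily self-perception model - training summary",
            "=" * 48,
            f"replicates:          {len(self.networks)}",
            f"trials/replicate:    {self.networks[0].trials_trained}",
            f"neurons/area:        {self.model.config.grid.n}",
            f"receptive sigma:     {self.model.config.sigma:g} grid steps",
            f"seed:                {self.seed}",
            "",
            "plastic pathway   median mean W   min..max over replicates",
        ]
        for p in PLASTIC_PATHWAYS:
            vals = pf.loc[pf.pathway == p, "mean_weight"]
            lines.append(
                f"  {p:<14} {m[p]:+11.4f}   {vals.min():+.4f} .. {vals.max():+.4f}"
            )
        lines += [
            "",
            f"sign flip (excitatory -> inhibitory): {self.converged}",
            "inhibition stronger for vision (|EBA-AI| > |S1-AI|): "
            f"{abs(m['EBA-AI']) > abs(m['S1-AI'])}",
        ]
        return "\n".join(lines)

    # -- simulation -------------------------------------------------------

    def run_trial(self, replicate: int = 0, **schedule_kwargs) -> TrialRecord:
        net = self.networks[replicate]
        sched = TrialSchedule.from_config(net.config, **schedule_kwargs)
        return net.run_trial(sched)

    def drift_sweep(self, disparities=None, **kwargs) -> _exp.DriftCurve:
        return _exp.proprioceptive_drift_sweep(self.networks, disparities, **kwargs)

    def appearance_replacement(self, condition="similar", **kwargs) -> _exp.DriftCurve:
        return _exp.appearance_replacement(self.networks, condition, **kwargs)

    def asynchrony_experiment(self, delays_ms=(0.0, 100.0, 500.0), **kwargs):
        return _exp.asynchrony_experiment(self.networks, delays_ms, **kwargs)

    def unisensory_experiment(self, mode="proprioception_only", replicate=0,
                              angle=0.0):
        return _exp.unisensory_experiment(self.networks[replicate], mode, angle)

    def drift_breakpoint(self, curve=None):
        if curve is None:
            curve = self.drift_sweep()
        return _exp.fit_drift_breakpoint(curve)

    # -- plotting / export ------------------------------------------------

    def plot_drift(self, curves=None, out_path=None, ax=None):
        from .analysis import plot_drift_curve

        if curves is None:
            curves = self.drift_sweep()
        return plot_drift_curve(curves, out_path=out_path, ax=ax)

    def export(self, out_dir, results: dict | None = None):
        from .analysis import export_bundle

        payload = {"manifest": {"seed": self.seed,
                                "config": self.model.to_config_dict(),
                                "n_replicates": len(self.networks)}}
        if len(self.weight_history):
            payload["weight_history"] = self.weight_history
        if results:
            payload.update(results)
        return export_bundle(payload, out_dir)
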