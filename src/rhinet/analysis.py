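"""Firing-rate trace analytics, exporters and plots.

Covers the per-area peak structure of single trials (temporal
anterior/posterior peaks of the population response and per-neuron peak
rankings), the integration/segregation classification of multisensory
neurons, firing-rate trends across visual disparities, and tidy-CSV/JSON
export of experiment results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import spearmanr

from .experiments import DriftCurve
from .network import Network, TrialRecord, TrialSchedule

__all__ = [
    "PeakReport",
    "NeuronClassification",
    "peak_report",
    "classify_neurons",
    "disparity_rate_trend",
    "export_bundle",
    "plot_drift_curve",
]

# minimum separation (ms) between the anterior and posterior peaks of the
# population-max time course
PEAK_SEPARATION_MS = 50

EARLY_WINDOW_MS = (0.0, 200.0)
LATE_WINDOW_MS = (300.0, 500.0)


@dataclass
class PeakReport:
    """Top-k neurons of one area in one trial, ranked by peak rate."""

    area: str
    angles: list[float]           # preferred angles, highest peak first
    peak_rates: list[float]
    peak_times_ms: list[float]
    anterior_peak_angle: float | None = None
    posterior_peak_angle: float | None = None
    anterior_peak_time_ms: float | None = None
    posterior_peak_time_ms: float | None = None

    @property
    def top_angle(self) -> float | None:
        return self.angles[0] if self.angles else None


@dataclass
class NeuronClassification:
    """Integration/segregation labels for one area.

    A neuron is an integration neuron when its mean rate in the window is
    strictly higher under the congruent visual-proprioceptive task than
    under the proprioception-only task, and a segregation neuron otherwise
    (ties count as segregation).
    """

    area: str
    window_ms: tuple[float, float]
    labels: list[str]
    congruent_means: list[float]
    p_only_means: list[float]

    @property
    def integration_fraction(self) -> float:
        if not self.labels:
            return 0.0
        return self.labels.count("integration") / len(self.labels)


def peak_report(record: TrialRecord, area: str, k: int = 6) -> PeakReport:
    """The k neurons with the highest peak firing rate, plus the anterior
    (earlier) and posterior (later) peaks of the population-max response."""
    trace = record.traces[area].rates
    n = trace.shape[1]
    if k > n:
        raise ValueError(f"k={k} exceeds population size {n}")
    peaks = trace.max(axis=0)
    if not np.any(peaks > 0):
        return PeakReport(area=area, angles=[], peak_rates=[], peak_times_ms=[])
    order = np.argsort(peaks, kind="stable")[::-1][:k]
    angles = [float(record.grid.angles[i]) for i in order]
    rates = [float(peaks[i]) for i in order]
    times = [float(trace[:, i].argmax()) for i in order]
    report = PeakReport(area=area, angles=angles, peak_rates=rates,
                        peak_times_ms=times)
    popmax = trace.max(axis=1)
    pk, _ = find_peaks(popmax, distance=PEAK_SEPARATION_MS)
    if len(pk) == 0 and popmax.max() > 0:
        pk = np.array([int(popmax.argmax())])
    if len(pk) >= 1:
        t_a = int(pk[0])
        report.anterior_peak_time_ms = float(t_a)
        report.anterior_peak_angle = float(record.grid.angles[trace[t_a].argmax()])
    if len(pk) >= 2:
        t_p = int(pk[-1])
        report.posterior_peak_time_ms = float(t_p)
        report.posterior_peak_angle = float(record.grid.angles[trace[t_p].argmax()])
    return report


def _window_means(trace: np.ndarray, window_ms: tuple[float, float]) -> np.ndarray:
    lo, hi = int(round(window_ms[0])), int(round(window_ms[1]))
    if not 0 <= lo < hi <= trace.shape[0]:
        raise ValueError(f"window {window_ms} outside trial of {trace.shape[0]} steps")
    return trace[lo:hi].mean(axis=0)


def classify_neurons(
    record_congruent: TrialRecord,
    record_p_only: TrialRecord,
    area: str,
    window_ms: tuple[float, float] = EARLY_WINDOW_MS,
) -> NeuronClassification:
    """Label each neuron integration or segregation from two task records."""
    c = _window_means(record_congruent.traces[area].rates, window_ms)
    p = _window_means(record_p_only.traces[area].rates, window_ms)
    labels = ["integration" if ci > pi else "segregation" for ci, pi in zip(c, p)]
    return NeuronClassification(
        area=area, window_ms=tuple(window_ms), labels=labels,
        congruent_means=[float(x) for x in c], p_only_means=[float(x) for x in p],
    )


def disparity_rate_trend(
    network: Network,
    area: str,
    window_ms: tuple[float, float] = EARLY_WINDOW_MS,
    disparities: tuple[float, ...] = (30.0, 33.0, 36.0, 39.0, 42.0),
    proprioception: float = 0.0,
) -> pd.DataFrame:
    """Peak and mean firing rate versus visual disparity in a time window.

    Returns a tidy frame plus Spearman rank-correlation signs in
    ``df.attrs``; the TPJ rate falls with disparity (weaker receptive-field
    overlap) while the early-window AI rate rises (weaker inhibition of the
    primary integration signal).
    """
    if len(disparities) < 3:
        raise ValueError("need at least 3 disparities for a trend")
    rows = []
    for d in disparities:
        sched = TrialSchedule.from_config(
            network.config, motor_angle=proprioception,
            visual_angle=proprioception + d,
        )
        rec = network.run_trial(sched)
        trace = rec.traces[area].rates
        lo, hi = int(round(window_ms[0])), int(round(window_ms[1]))
        win = trace[lo:hi]
        rows.append({
            "disparity_deg": float(d),
            "peak_rate": float(win.max()) if win.size else 0.0,
            "mean_rate": float(win.mean()) if win.size else 0.0,
        })
    df = pd.DataFrame(rows)
    for col in ("peak_rate", "mean_rate"):
        if df[col].nunique() <= 1:
            rho = 0.0
        else:
            rho = float(spearmanr(df["disparity_deg"], df[col]).statistic)
        df.attrs[f"spearman_{col}"] = rho
    df.attrs["area"] = area
    df.attrs["window_ms"] = tuple(window_ms)
    return df


def plot_drift_curve(curves, out_path=None, ax=None):
    """Drift curves with the vision-based and proprioception-based lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 4))
    else:
        fig = ax.figure
    if isinstance(curves, DriftCurve):
        curves = [curves]
    lo = min(float(c.disparities.min()) for c in curves)
    hi = max(float(c.disparities.max()) for c in curves)
    xs = np.linspace(lo, hi, 2)
    ax.plot(xs, xs, "r--", lw=1, label="vision based")
    ax.plot(xs, np.zeros_like(xs), "b--", lw=1, label="proprioception based")
    for c in curves:
        ax.plot(c.disparities, c.drifts, "o-", ms=3, label=c.condition)
    ax.set_xlabel("visual disparity (deg)")
    ax.set_ylabel("proprioceptive drift (deg)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return ax


def export_bundle(results: dict, out_dir, make_plots: bool = True) -> list[Path]:
    """Write experiment results as tidy CSVs, a JSON manifest and figures.

    ``results`` may contain DriftCurve objects (or dicts/lists of them),
    pandas DataFrames (e.g. weight histories), NeuronClassification
    objects, and a "manifest" dict (config, seed, versions).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write_curve(name: str, curve: DriftCurve):
        p = out_dir / f"{name}.csv"
        curve.to_frame().to_csv(p, index=False)
        written.append(p)
        if make_plots:
            fp = out_dir / f"{name}.png"
            plot_drift_curve(curve, out_path=fp)
            written.append(fp)

    manifest = dict(results.get("manifest", {}))
    for key, value in results.items():
        if key == "manifest":
            continue
        if isinstance(value, DriftCurve):
            _write_curve(key, value)
        elif isinstance(value, dict) and all(
            isinstance(v, DriftCurve) for v in value.values()
        ):
            for sub, curve in value.items():
                _write_curve(f"{key}_{sub}", curve)
        elif isinstance(value, pd.DataFrame):
            p = out_dir / f"{key}.csv"
            value.to_csv(p, index=False)
            written.append(p)
        elif isinstance(value, NeuronClassification):
            p = out_dir / f"{key}.csv"
            pd.DataFrame({
                "angle_index": range(len(value.labels)),
                "label": value.labels,
                "congruent_mean": value.congruent_means,
                "p_only_mean": value.p_only_means,
            }).to_csv(p, index=False)
            written.append(p)
        else:
            manifest[key] = value
    mp = out_dir / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, default=str))
    written.append(mp)
    return written
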