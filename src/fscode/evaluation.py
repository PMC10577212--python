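"""Evaluation metrics: accuracy-vs-window curves, time delay, spike counts.

Because the LIF dynamics are causal, evaluating with the input truncated to
``T'`` steps is exactly the prefix of the full simulation, so the whole
accuracy-vs-window curve is computed from a single forward pass; the readout
at ``T'`` only sees steps 1..T' (its silent-neuron sentinel is
``(T'+1)*dt``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .network import forward
from .readout import predict_fr, predict_fs, read_output

__all__ = [
    "EvalReport",
    "mean_spike_count",
    "accuracy_vs_window",
    "time_delay",
    "evaluate",
    "export_rasters",
]


def mean_spike_count(trajectories) -> float:
    """Mean number of spikes per neuron over the whole system, ``N_s``.

    Counts every LIF neuron in hidden and output layers (input bins are
    counts, not spikes, and stateless pooling units are not neurons);
    averaged over the batch.
    """
    total = 0.0
    neurons = 0
    B = None
    for traj in trajectories:
        if traj.I is None:
            continue
        B = traj.S.shape[1]
        total += float(traj.S[1:].sum())
        neurons += int(np.prod(traj.S.shape[2:]))
    if neurons == 0:
        raise ValueError("no spiking layers in trajectories")
    return total / (neurons * B)


def _prefix_accuracy_curve(S, U, y_idx, dt, mode) -> np.ndarray:
    """Accuracy at every window length 1..T from one output trajectory."""
    T = S.shape[0] - 1
    curve = np.empty(T)
    for Tp in range(1, T + 1):
        ro = read_output(S[: Tp + 1], U[: Tp + 1], dt)
        pred = predict_fs(ro) if mode == "fs" else predict_fr(ro)
        curve[Tp - 1] = float(np.mean(pred == y_idx))
    return curve


def accuracy_vs_window(model, X, y) -> np.ndarray:
    """Accuracy as a function of the evaluation window length T' = 1..T."""
    trajs = forward(model.layers_, np.asarray(X, dtype=float))
    y_idx = model._encode_labels(y)
    C = len(model.classes_)
    return _prefix_accuracy_curve(
        trajs[-1].S[..., :C], trajs[-1].U[..., :C], y_idx, model.dt, model.loss
    )


def time_delay(acc_curve: np.ndarray, p: int, dt: float) -> float:
    """Smallest ``T' * dt`` at which accuracy reaches p% of the curve's peak.

    An all-zero curve returns the time at the full window length.
    """
    acc_curve = np.asarray(acc_curve, dtype=float)
    if acc_curve.size == 0:
        raise ValueError("empty accuracy curve")
    peak = acc_curve.max()
    if peak <= 0:
        return len(acc_curve) * dt
    hits = np.nonzero(acc_curve >= (p / 100.0) * peak)[0]
    return (hits[0] + 1) * dt


@dataclass
class EvalReport:
    """Held-out evaluation summary of a trained model."""

    accuracy: float
    acc_curve: np.ndarray
    t_d50: float
    t_d90: float
    t_d50_steps: float
    t_d90_steps: float
    N_s: float
    dt: float

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "acc_curve": [float(a) for a in self.acc_curve],
            "t_d50": self.t_d50,
            "t_d90": self.t_d90,
            "t_d50_steps": self.t_d50_steps,
            "t_d90_steps": self.t_d90_steps,
            "N_s": self.N_s,
            "dt": self.dt,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def evaluate(model, X, y) -> EvalReport:
    """Full held-out evaluation: accuracy curve, time delays, spike count."""
    X = np.asarray(X, dtype=float)
    trajs = forward(model.layers_, X)
    y_idx = model._encode_labels(y)
    C = len(model.classes_)
    curve = _prefix_accuracy_curve(
        trajs[-1].S[..., :C], trajs[-1].U[..., :C], y_idx, model.dt, model.loss
    )
    return EvalReport(
        accuracy=float(curve[-1]),
        acc_curve=curve,
        t_d50=time_delay(curve, 50, model.dt),
        t_d90=time_delay(curve, 90, model.dt),
        t_d50_steps=time_delay(curve, 50, 1.0),
        t_d90_steps=time_delay(curve, 90, 1.0),
        N_s=mean_spike_count(trajs),
        dt=model.dt,
    )


def export_rasters(model, X, directory) -> None:
    """Write per-trial output rasters (CSV) and readout summaries (JSON)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    X = np.asarray(X, dtype=float)
    trajs = forward(model.layers_, X)
    S, U = trajs[-1].S, trajs[-1].U
    ro = read_output(S, U, model.dt)
    pred_fs = predict_fs(ro)
    pred_fr = predict_fr(ro)
    T = S.shape[0] - 1
    for b in range(X.shape[0]):
        neuron, step = np.nonzero(S[1:, b].T)
        pd.DataFrame(
            {"neuron": neuron, "step": step + 1, "spike": 1}
        ).to_csv(directory / f"trial_{b:04d}_raster.csv", index=False)
        summary = {
            "t_F": [float(t) for t in ro.t_F[b]],
            "U_max": [float(u) for u in ro.U_max[b]],
            "f": [float(f) for f in ro.f[b]],
            "prediction_fs": int(pred_fs[b]),
            "prediction_fr": int(pred_fr[b]),
            "T": T,
            "dt": model.dt,
        }
        (directory / f"trial_{b:04d}_summary.json").write_text(
            json.dumps(summary, indent=2)
        )
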