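"""Loss functions for first-spike (FS) and firing-rate (FR) training.

The FS loss is a softmax cross-entropy over *negative* first-spike times —
early target spikes and late non-target spikes lower the loss — plus an
exponential penalty on a target neuron that stays silent:

    L_FS = -sum_i y_i log softmax(-alpha0 * t_F)_i
           + lambda_t * sum_{i: t_F,i > T} y_i * (exp(beta0 * t_F,i) - 1)

The FR loss is the usual cross-entropy over softmax(alpha1 * f) with per-
neuron rates f.  First-spike times enter the exponentials in *steps*
(t/dt), not seconds: with the printed scales (alpha0 ~ 0.1, beta0 = 0.02)
and windows of tens-to-hundreds of steps, step units keep the exponents
O(1); only the silent-neuron sentinel (T+1) can exceed T.

An optional spike-count constraint ``L_s = lambda_s * |N_s - N_target|``
regularizes the mean number of spikes per neuron in the whole system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossConfig",
    "fs_loss",
    "fs_loss_grad",
    "fr_loss",
    "fr_loss_grad",
    "spike_count_penalty",
]


@dataclass
class LossConfig:
    """Scales of the FS/FR objectives (all dimensionless; times in steps).

    alpha0 : FS softmax scale (tempers the time exponentials).
    beta0 : exponent of the silent-target penalty.
    lambda_t : weight of the silent-target penalty.
    alpha1 : FR softmax scale.
    lambda_s : weight of the spike-count constraint (0 disables it).
    N_target : target mean spike count per neuron for the constraint.
    """

    alpha0: float = 0.1
    beta0: float = 0.02
    lambda_t: float = 0.01
    alpha1: float = 20.0
    lambda_s: float = 0.0
    N_target: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha0", "beta0", "lambda_t", "alpha1", "lambda_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)  # shift-invariant, overflow-safe
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _check_one_hot(y: np.ndarray, C: int) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.shape[-1] != C or not np.isin(y, (0.0, 1.0)).all() or (
        y.sum(axis=-1) != 1.0
    ).any():
        raise ValueError("y must be one-hot over the class axis")
    return y


def fs_loss(t_F: np.ndarray, y: np.ndarray, T: int, cfg: LossConfig) -> float:
    """FS cross-entropy plus silent-target penalty; ``t_F`` in steps.

    ``t_F`` entries lie in {1..T} or equal the sentinel T+1.  Batched inputs
    (leading axes) return the mean loss.
    """
    t_F = np.asarray(t_F, dtype=float)
    y = _check_one_hot(y, t_F.shape[-1])
    logp = np.log(_softmax(-cfg.alpha0 * t_F))
    ce = -(y * logp).sum(axis=-1)
    silent = t_F > T
    penalty = cfg.lambda_t * (y * silent * (np.exp(cfg.beta0 * t_F) - 1.0)).sum(
        axis=-1
    )
    return float(np.mean(ce + penalty))


def fs_loss_grad(t_F: np.ndarray, y: np.ndarray, T: int, cfg: LossConfig) -> np.ndarray:
    """Analytic d(fs_loss)/d(t_F), per neuron (mean over any batch axes).

    Softmax term: alpha0 * (y - p) with p = softmax(-alpha0 t_F); penalty
    adds lambda_t * beta0 * exp(beta0 t_F) on silent target neurons.
    """
    t_F = np.asarray(t_F, dtype=float)
    y = _check_one_hot(y, t_F.shape[-1])
    p = _softmax(-cfg.alpha0 * t_F)
    grad = cfg.alpha0 * (y - p)
    silent = t_F > T
    grad = grad + cfg.lambda_t * cfg.beta0 * y * silent * np.exp(cfg.beta0 * t_F)
    if t_F.ndim > 1:
        grad = grad / np.prod(t_F.shape[:-1])
    return grad


def fr_loss(f: np.ndarray, y: np.ndarray, cfg: LossConfig) -> float:
    """FR cross-entropy of softmax(alpha1 * f) against one-hot ``y``."""
    f = np.asarray(f, dtype=float)
    if ((f < 0) | (f > 1)).any():
        raise ValueError("rates must lie in [0, 1]")
    y = _check_one_hot(y, f.shape[-1])
    logp = np.log(_softmax(cfg.alpha1 * f))
    return float(np.mean(-(y * logp).sum(axis=-1)))


def fr_loss_grad(f: np.ndarray, y: np.ndarray, cfg: LossConfig) -> np.ndarray:
    """Analytic d(fr_loss)/d(f): alpha1 * (p - y), mean over batch axes."""
    f = np.asarray(f, dtype=float)
    y = _check_one_hot(y, f.shape[-1])
    p = _softmax(cfg.alpha1 * f)
    grad = cfg.alpha1 * (p - y)
    if f.ndim > 1:
        grad = grad / np.prod(f.shape[:-1])
    return grad


def spike_count_penalty(N_s: float, cfg: LossConfig) -> float:
    """Spike-count constraint ``lambda_s * |N_s - N_target|``."""
    if N_s < 0:
        raise ValueError("N_s must be >= 0")
    return cfg.lambda_s * abs(N_s - cfg.N_target)
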