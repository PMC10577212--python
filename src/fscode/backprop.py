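"""Custom backward pass for first-spike training.

Three pieces compose the pseudo-gradient:

1. *Time-to-spike error assignment.*  The loss gradient with respect to each
   output neuron's first-spike time is spread onto the spike train through a
   negative Gaussian window ``g(x) = -A/(sqrt(2*pi)*sigma) * exp(-x^2/(2*sigma^2))``
   with ``sigma = floor(T/D)``, truncated at the 3-sigma limit
   (``W = min(6*sigma + 1, T)``).  For an *active* neuron the window is
   centred on the first-spike step; for an *inactive* (silent) neuron the
   time error is assigned to every step, each step receiving the windowed sum
   over all source steps.  The sign flip encodes "earlier spike time ==
   larger spike value": pushing a time down pushes the spikes up.

2. *Surrogate spike derivative.*  The step function's derivative is replaced
   by the fast sigmoid ``f'(U) = 1 / (1 + rho*|U - theta|)^2``.

3. *Reverse-time accumulation* through the LIF recurrences, treating the
   multiplicative reset factor ``(1 - s[n])`` as a constant (no gradient
   flows through the reset's own spike):

       dL/dU[n] = dL/ds[n] * f'(U[n]) + alpha * (1 - s[n]) * dL/dU[n+1]
       dL/dI[n] = (1 - alpha) * dL/dU[n+1] + beta * dL/dI[n+1]
       dL/dW    = sum_n dL/dI[n] (x) s_prev[n]
       dL/dV    = sum_n dL/dI[n] (x) s_self[n]

   Spike errors reach the previous layer through W^T and the same layer
   through V^T at the same step, mirroring the forward dependencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .network import ConvLayer, DenseLayer, MaxPoolLayer

__all__ = [
    "BackpropConfig",
    "GradientTape",
    "window_size",
    "gaussian_weight",
    "assign_time_error_to_spikes",
    "surrogate_derivative",
    "backward",
]

#: the reset factor is always treated as constant during differentiation
DETACH_RESET = True
#: windows are truncated at the 3-sigma limit
WINDOW_TRUNCATION_SIGMAS = 3


def window_size(T: int, D: int) -> tuple[int, int]:
    """Gaussian-window standard deviation and width for a ``T``-step run.

    ``sigma = floor(T/D)`` and ``W = min(6*sigma + 1, T)``.  ``D > T`` gives
    ``(0, 1)``: the delta-window limit where the error stays on one step.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if D < 1:
        raise ValueError("D must be >= 1")
    sigma = T // D
    return sigma, min(6 * sigma + 1, T)


@dataclass
class BackpropConfig:
    """Pseudo-gradient hyperparameters.

    A : Gaussian amplitude; None means the default 2*T, resolved per run.
    D : window divisor; sigma and W are recomputed from the *current* T
        (including any empty-sequence extension) on every call.
    rho : slope of the fast-sigmoid surrogate.
    """

    A: float | None = None
    D: int = 16
    rho: float = 5.0

    def amplitude(self, T: int) -> float:
        return 2.0 * T if self.A is None else self.A

    def sigma_W(self, T: int) -> tuple[int, int]:
        return window_size(T, self.D)


def gaussian_weight(x, sigma: int, A: float):
    """Negative Gaussian window value ``g(x)`` at integer step offset ``x``.

    Strictly negative, symmetric, with peak magnitude ``A/(sqrt(2*pi)*sigma)``
    at ``x = 0``.  Requires ``sigma >= 1``; the ``sigma = 0`` delta limit is
    handled by the assignment rule, not here.
    """
    if sigma < 1:
        raise ValueError("gaussian_weight requires sigma >= 1")
    x = np.asarray(x, dtype=float)
    out = -(A / (math.sqrt(2.0 * math.pi) * sigma)) * np.exp(
        -(x**2) / (2.0 * sigma**2)
    )
    return float(out) if out.ndim == 0 else out


def _kernel(T: int, cfg: BackpropConfig) -> tuple[np.ndarray, int]:
    """Truncated window values over offsets -r..r, with r = 3*sigma.

    In the ``sigma = 0`` delta limit the single tap has magnitude
    ``A/sqrt(2*pi)`` (the sigma = 1 peak), so the assignment never divides
    by zero yet still collapses to one step.
    """
    sigma, _ = cfg.sigma_W(T)
    A = cfg.amplitude(T)
    r = WINDOW_TRUNCATION_SIGMAS * sigma
    offsets = np.arange(-r, r + 1)
    return gaussian_weight(offsets, max(sigma, 1), A), r


def assign_time_error_to_spikes(
    dL_dtF: float,
    first_spike_step: int | None,
    T: int,
    cfg: BackpropConfig,
) -> np.ndarray:
    """Spread one neuron's first-spike-time error over its T spike steps.

    Returns ``dL/ds`` for steps 1..T (index 0 of the result is step 1).
    Active neuron (``first_spike_step`` = m* in 1..T): step ``n`` receives
    ``dL_dtF * g(m* - n)`` within the truncated window, 0 outside.  Inactive
    neuron (``first_spike_step`` None): every step receives the windowed sum
    ``dL_dtF * sum_m g(m - n)`` over source steps m = 1..T.
    """
    kern, r = _kernel(T, cfg)
    out = np.zeros(T)
    if first_spike_step is not None:
        if not 1 <= first_spike_step <= T:
            raise ValueError("first_spike_step must lie in 1..T")
        m = first_spike_step
        lo, hi = max(1, m - r), min(T, m + r)
        n = np.arange(lo, hi + 1)
        out[lo - 1 : hi] = dL_dtF * kern[n - m + r]  # kern is symmetric: g(m-n)
    else:
        # windowed sum over all source steps: correlate a ones-train with kern
        ones = np.ones(T)
        full = np.convolve(ones, kern, mode="full")  # kern symmetric
        out = dL_dtF * full[r : r + T]
    return out


def surrogate_derivative(U, theta: float, rho: float):
    """Fast-sigmoid surrogate of the step function's derivative.

    ``1 / (1 + rho*|U - theta|)^2`` — equal to 1 at threshold, decaying
    symmetrically on either side; ``rho`` controls the decay rate.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    U = np.asarray(U, dtype=float)
    out = 1.0 / (1.0 + rho * np.abs(U - theta)) ** 2
    return float(out) if out.ndim == 0 else out


def assign_time_errors_batch(
    dL_dtF: np.ndarray,
    first_steps: np.ndarray,
    T: int,
    cfg: BackpropConfig,
) -> np.ndarray:
    """Vectorized error assignment for a ``(B, C)`` batch of output neurons.

    ``first_steps`` holds the 1-based first-spike step, 0 for silent
    neurons.  Returns ``dL/ds`` with time-first shape ``(T+1, B, C)``
    (index 0 unused), ready for :func:`backward`.
    """
    kern, r = _kernel(T, cfg)
    B, C = dL_dtF.shape
    out = np.zeros((T + 1, B, C))
    active = first_steps > 0
    if active.any():
        m = first_steps[active]  # (K,)
        err = dL_dtF[active]
        b_idx, c_idx = np.nonzero(active)
        for j, off in enumerate(range(-r, r + 1)):
            n = m + off  # g(m - n) with n - m = off -> kern index j (symmetric)
            ok = (n >= 1) & (n <= T)
            np.add.at(out, (n[ok], b_idx[ok], c_idx[ok]), err[ok] * kern[j])
    if (~active).any():
        ones = np.ones(T)
        profile = np.convolve(ones, kern, mode="full")[r : r + T]  # (T,)
        out[1:] += profile[:, None, None] * np.where(active, 0.0, dL_dtF)[None]
    return out


@dataclass
class GradientTape:
    """Per-layer error signals and weight gradients from one backward pass.

    ``dL_ds``/``dL_dU``/``dL_dI`` are time-first arrays mirroring the
    trajectories (None where a layer has no state); ``dL_dW``/``dL_dV`` are
    summed over batch and time.  ``dL_dx`` is the error reaching the input.
    """

    dL_ds: list = field(default_factory=list)
    dL_dU: list = field(default_factory=list)
    dL_dI: list = field(default_factory=list)
    dL_dW: list = field(default_factory=list)
    dL_dV: list = field(default_factory=list)
    dL_dx: np.ndarray | None = None


def _pool_route(layer: MaxPoolLayer, s_in: np.ndarray, ds_out: np.ndarray) -> np.ndarray:
    """Route pooled-spike error to the argmax (first index) of each block."""
    p = layer.p
    B, C, H, W_ = s_in.shape
    Ho, Wo = H // p, W_ // p
    blocks = layer.blocks(s_in)  # (B, C, Ho, Wo, p*p)
    arg = blocks.argmax(axis=-1)  # first max -> first-index tie-break
    grad_blocks = np.zeros_like(blocks)
    np.put_along_axis(grad_blocks, arg[..., None], ds_out[..., None], axis=-1)
    g = grad_blocks.reshape(B, C, Ho, Wo, p, p).transpose(0, 1, 2, 4, 3, 5)
    out = np.zeros_like(s_in)
    out[:, :, : Ho * p, : Wo * p] = g.reshape(B, C, Ho * p, Wo * p)
    return out


def backward(
    layers,
    trajs,
    x: np.ndarray,
    dL_ds_output: np.ndarray,
    rho: float = 5.0,
    spike_grad_extra: float = 0.0,
) -> GradientTape:
    """Reverse-time accumulation of errors and weight gradients.

    Parameters
    ----------
    layers, trajs : the network and the trajectories from :func:`~fscode.network.forward`.
    x : ndarray
        The batch input ``(B, ..., T)`` fed to the forward pass.
    dL_ds_output : ndarray
        Time-first ``(T+1, B, C)`` error on the output spikes (index 0
        unused) — from the Gaussian assignment (FS) or the per-step rate
        derivative (FR).
    spike_grad_extra : float
        Constant added to dL/ds of every LIF neuron-step (spike-count
        constraint); 0 disables it.
    """
    x = np.asarray(x, dtype=float)
    T = x.shape[-1]
    L = len(layers)
    tape = GradientTape(
        dL_ds=[None] * L, dL_dU=[None] * L, dL_dI=[None] * L,
        dL_dW=[None] * L, dL_dV=[None] * L,
    )

    ds_ext = dL_ds_output
    for l in range(L - 1, -1, -1):
        layer = layers[l]
        traj = trajs[l]
        s_prev_full = trajs[l - 1].S if l > 0 else None  # (T+1, B, ...)

        if isinstance(layer, MaxPoolLayer):
            ds_prev = np.zeros((T + 1,) + s_prev_full.shape[1:])
            for n in range(1, T + 1):
                ds_prev[n] = _pool_route(layer, s_prev_full[n], ds_ext[n])
            tape.dL_ds[l] = ds_ext
            ds_ext = ds_prev
            continue

        a = layer.params.alpha
        b = layer.params.beta
        theta = layer.params.theta
        dI = np.zeros_like(traj.I)
        dU = np.zeros_like(traj.U)
        ds = np.zeros_like(traj.S)
        dU_next = np.zeros_like(traj.U[0])
        dI_next = np.zeros_like(traj.I[0])
        for n in range(T, 0, -1):
            dI[n] = (1.0 - a) * dU_next + b * dI_next
            ds_n = ds_ext[n] + spike_grad_extra
            if isinstance(layer, DenseLayer) and layer.V is not None:
                ds_n = ds_n + dI[n] @ layer.V
            ds[n] = ds_n
            dU[n] = ds_n * surrogate_derivative(traj.U[n], theta, rho) + a * (
                1.0 - traj.S[n]
            ) * dU_next
            dU_next, dI_next = dU[n], dI[n]

        # weight gradients and error to the previous layer
        if isinstance(layer, DenseLayer):
            s_in = (
                s_prev_full.reshape(T + 1, x.shape[0], -1)
                if l > 0
                else np.moveaxis(x, -1, 0).reshape(T, x.shape[0], -1)
            )
            if l > 0:
                s_in = s_in[1:]
            dI_flat = dI[1:]  # (T, B, Q)
            tape.dL_dW[l] = np.einsum("tbq,tbj->qj", dI_flat, s_in)
            if layer.V is not None:
                tape.dL_dV[l] = np.einsum("tbq,tbk->qk", dI_flat, traj.S[1:])
            ds_prev_flat = np.einsum("tbq,qj->tbj", dI_flat, layer.W)
            prev_shape = (
                s_prev_full.shape[1:] if l > 0 else (x.shape[0],) + x.shape[1:-1]
            )
            ds_prev = np.zeros((T + 1,) + prev_shape)
            ds_prev[1:] = ds_prev_flat.reshape((T,) + prev_shape)
        else:  # ConvLayer
            Cout = layer.W.shape[0]
            Wm = layer.W.reshape(Cout, -1)
            dW = np.zeros_like(Wm)
            in_shape = s_prev_full.shape[2:] if l > 0 else x.shape[1:-1]
            ds_prev = np.zeros(
                (T + 1,) + ((s_prev_full.shape[1],) if l > 0 else (x.shape[0],))
                + in_shape
            )
            for n in range(1, T + 1):
                s_in_n = s_prev_full[n] if l > 0 else x[..., n - 1]
                cols = layer.im2col(s_in_n)  # (B, Cin*k*k, P)
                dI_n = dI[n].reshape(dI[n].shape[0], Cout, -1)  # (B, Cout, P)
                dW += np.einsum("bop,bcp->oc", dI_n, cols)
                dcols = np.einsum("oc,bop->bcp", Wm, dI_n)
                ds_prev[n] = layer.col2im(dcols, in_shape)
            tape.dL_dW[l] = dW.reshape(layer.W.shape)

        tape.dL_ds[l], tape.dL_dU[l], tape.dL_dI[l] = ds, dU, dI
        ds_ext = ds_prev

    tape.dL_dx = ds_ext
    return tape
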