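"""Independent, unoptimized reference implementations used as test oracles.

Everything here is written with explicit per-neuron / per-step Python loops,
directly transcribing the update and error-accumulation rules, and shares no
code with the vectorized production implementation in :mod:`fscode`.
"""

from __future__ import annotations

import math

import numpy as np


def naive_forward(layers, x):
    """Per-neuron loop simulation of a chain of dense LIF layers.

    ``x`` is a single trial ``(F, T)``.  Returns per-layer dicts with
    ``I, U, S`` arrays of shape ``(Q, T+1)`` (index 0 = initial state).
    """
    T = x.shape[-1]
    states = []
    for layer in layers:
        Q = layer.W.shape[0]
        states.append(
            {k: np.zeros((Q, T + 1)) for k in ("I", "U", "S")}
        )
    for n in range(1, T + 1):
        s_prev = x[:, n - 1]
        for layer, st in zip(layers, states):
            a = math.exp(-layer.params.dt / layer.params.tau)
            b = a
            Q, J = layer.W.shape
            for i in range(Q):
                st["U"][i, n] = (
                    a * st["U"][i, n - 1] * (1 - st["S"][i, n - 1])
                    + (1 - a) * st["I"][i, n - 1]
                )
                st["S"][i, n] = 1.0 if st["U"][i, n] >= layer.params.theta else 0.0
            for i in range(Q):
                drive = 0.0
                for j in range(J):
                    drive += layer.W[i, j] * s_prev[j]
                if layer.V is not None:
                    for k in range(Q):
                        drive += layer.V[i, k] * st["S"][k, n]
                st["I"][i, n] = b * st["I"][i, n - 1] + drive
            s_prev = st["S"][:, n]
    return states


def naive_surrogate(u, theta, rho):
    return 1.0 / (1.0 + rho * abs(u - theta)) ** 2


def naive_backward(layers, states, x, dl_ds_out, rho):
    """Loop-based reverse accumulation for dense LIF layers, single trial.

    ``dl_ds_out`` is ``(C, T+1)``.  Returns per-layer (dW, dV) plus the
    per-layer ds/dU/dI arrays for inspection.
    """
    T = x.shape[-1]
    L = len(layers)
    grads = []
    ds_ext = dl_ds_out
    out = [None] * L
    for l in range(L - 1, -1, -1):
        layer = layers[l]
        st = states[l]
        a = math.exp(-layer.params.dt / layer.params.tau)
        b = a
        Q, J = layer.W.shape
        dI = np.zeros((Q, T + 2))
        dU = np.zeros((Q, T + 2))
        ds = np.zeros((Q, T + 1))
        for n in range(T, 0, -1):
            for i in range(Q):
                dI[i, n] = (1 - a) * dU[i, n + 1] + b * dI[i, n + 1]
            for i in range(Q):
                s_err = ds_ext[i, n]
                if layer.V is not None:
                    for k in range(Q):
                        s_err += layer.V[k, i] * dI[k, n]
                ds[i, n] = s_err
                dU[i, n] = s_err * naive_surrogate(
                    st["U"][i, n], layer.params.theta, rho
                ) + a * (1 - st["S"][i, n]) * dU[i, n + 1]
        s_prev = states[l - 1]["S"] if l > 0 else np.concatenate(
            [np.zeros((x.shape[0], 1)), x], axis=1
        )
        dW = np.zeros_like(layer.W)
        for i in range(Q):
            for j in range(J):
                for n in range(1, T + 1):
                    dW[i, j] += dI[i, n] * s_prev[j, n]
        dV = None
        if layer.V is not None:
            dV = np.zeros_like(layer.V)
            for i in range(Q):
                for k in range(Q):
                    for n in range(1, T + 1):
                        dV[i, k] += dI[i, n] * st["S"][k, n]
        ds_prev = np.zeros((J, T + 1))
        for j in range(J):
            for n in range(1, T + 1):
                for i in range(Q):
                    ds_prev[j, n] += layer.W[i, j] * dI[i, n]
        grads.append((dW, dV))
        out[l] = {"ds": ds, "dU": dU[:, : T + 1], "dI": dI[:, : T + 1]}
        ds_ext = ds_prev
    return list(reversed(grads)), out


def naive_gaussian(x, sigma, A):
    return -(A / (math.sqrt(2 * math.pi) * sigma)) * math.exp(
        -(x**2) / (2 * sigma**2)
    )


def naive_time_assignment(dl_dtF, first_step, T, A, D):
    """Direct transcription of the windowed time-to-spike error chain.

    Active neuron: only the first-spike step is a source; inactive: every
    step is a source.  Truncation at the 3-sigma limit; sigma floor-guarded
    at 1 (pure delta only when D > T).
    """
    sigma = T // D
    r = 3 * sigma
    sig_eff = max(sigma, 1)
    out = np.zeros(T + 1)
    sources = [first_step] if first_step is not None else list(range(1, T + 1))
    for m in sources:
        for n in range(1, T + 1):
            if abs(m - n) <= r:
                out[n] += dl_dtF * naive_gaussian(m - n, sig_eff, A)
    return out


def naive_first_spike(train, dt):
    """Brute-force scan for the first spike of a binary train."""
    for n, s in enumerate(train, start=1):
        if s == 1:
            return n * dt
    return (len(train) + 1) * dt
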