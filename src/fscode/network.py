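"""Discrete-time CUBA-LIF network simulation.

Neurons follow the current-based leaky integrate-and-fire model discretized
with per-step decays ``alpha = beta = exp(-dt/tau)`` (membrane and synaptic
time constants are tied).  One simulation step, in this fixed order:

    U[n+1] = alpha * U[n] * (1 - s[n]) + (1 - alpha) * I[n]
    s[n+1] = 1 if U[n+1] >= theta else 0
    I[n+1] = beta * I[n] + W @ s_prev[n+1] + V @ s_self[n+1]

The multiplicative ``(1 - s[n])`` factor implements an instantaneous reset to
the resting potential 0; there is no refractory period.  Recurrent spikes
produced at step ``n+1`` enter the current at ``n+1`` and therefore first
influence the membrane potential at ``n+3`` — there is no same-step algebraic
loop.  Time is 1-based in the recorded trajectories (index 0 holds the zero
initial state), matching the convention used throughout the package.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from .events import SpikeTensor

__all__ = [
    "NeuronParams",
    "DenseLayer",
    "ConvLayer",
    "MaxPoolLayer",
    "StateTrajectory",
    "decay_coefficients",
    "layer_step",
    "forward",
    "parse_architecture",
    "build_network",
    "save_checkpoint",
    "load_checkpoint",
]


def decay_coefficients(tau: float, dt: float) -> tuple[float, float]:
    """Per-step decay factors ``(alpha, beta)`` = ``exp(-dt/tau)`` twice.

    With tied membrane/synaptic time constants the two decays coincide; both
    lie strictly in (0, 1) for finite positive ``tau``.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    a = math.exp(-dt / tau)
    return a, a


@dataclass
class NeuronParams:
    """LIF parameters of one layer: time constant, threshold, bin width.

    ``alpha``/``beta`` are always recomputed from ``(tau, dt)`` — they cannot
    drift out of sync with the time constant.  The resting potential is 0.
    """

    tau: float
    theta: float
    dt: float

    def __post_init__(self) -> None:
        decay_coefficients(self.tau, self.dt)  # validates
        if self.theta <= 0:
            raise ValueError("theta must be positive")

    @property
    def alpha(self) -> float:
        return decay_coefficients(self.tau, self.dt)[0]

    @property
    def beta(self) -> float:
        return decay_coefficients(self.tau, self.dt)[1]


@dataclass
class StateTrajectory:
    """Recorded per-step state of one layer, time-first.

    Arrays have shape ``(T+1, batch, *units)``; index ``n`` holds the paper's
    step ``n`` (index 0 is the all-zero initial state).  Stateless pooling
    layers record spikes only (``I`` and ``U`` are None).
    """

    S: np.ndarray
    I: np.ndarray | None = None
    U: np.ndarray | None = None

    @property
    def T(self) -> int:
        return self.S.shape[0] - 1


class DenseLayer:
    """Fully connected LIF layer, optionally with recurrent connections.

    ``W`` has shape ``(Q, fan_in)``; ``V`` (recurrent, may include the
    diagonal) has shape ``(Q, Q)`` or is None.
    """

    kind = "fully_connected"

    def __init__(self, W: np.ndarray, params: NeuronParams, V: np.ndarray | None = None):
        self.W = np.asarray(W, dtype=float)
        if self.W.ndim != 2:
            raise ValueError("W must be 2-D (Q, fan_in)")
        self.V = None if V is None else np.asarray(V, dtype=float)
        if self.V is not None:
            if self.V.shape != (self.W.shape[0],) * 2:
                raise ValueError("V must be square (Q, Q)")
            self.kind = "recurrent_fc"
        self.params = params

    @property
    def Q(self) -> int:
        return self.W.shape[0]

    def out_shape(self, in_shape: tuple) -> tuple:
        fan_in = int(np.prod(in_shape))
        if fan_in != self.W.shape[1]:
            raise ValueError(
                f"layer fan-in {self.W.shape[1]} incompatible with input {in_shape}"
            )
        return (self.Q,)

    def drive(self, s_prev: np.ndarray, s_self: np.ndarray) -> np.ndarray:
        x = s_prev.reshape(s_prev.shape[0], -1) @ self.W.T
        if self.V is not None:
            x = x + s_self @ self.V.T
        return x


class ConvLayer:
    """2-D convolutional LIF layer (valid padding, square kernel).

    ``W`` has shape ``(C_out, C_in, k, k)``; each output unit is a LIF neuron
    with shared weights.  No recurrence.
    """

    kind = "conv2d"

    def __init__(self, W: np.ndarray, params: NeuronParams, stride: int = 1):
        self.W = np.asarray(W, dtype=float)
        if self.W.ndim != 4 or self.W.shape[2] != self.W.shape[3]:
            raise ValueError("conv W must be (C_out, C_in, k, k) with square kernel")
        if stride < 1:
            raise ValueError("stride must be >= 1")
        self.stride = stride
        self.params = params
        self.V = None

    @property
    def k(self) -> int:
        return self.W.shape[2]

    def out_shape(self, in_shape: tuple) -> tuple:
        C, H, W_ = in_shape
        if C != self.W.shape[1]:
            raise ValueError("conv input channels mismatch")
        k, s = self.k, self.stride
        if H < k or W_ < k:
            raise ValueError("input smaller than kernel")
        return (self.W.shape[0], (H - k) // s + 1, (W_ - k) // s + 1)

    def im2col(self, x: np.ndarray) -> np.ndarray:
        """(B, C, H, W) -> (B, C*k*k, P) patch matrix, P = H_out*W_out."""
        k, s = self.k, self.stride
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (B, C, Ho, Wo, k, k)
        B, C, Ho, Wo = win.shape[:4]
        cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(B, C * k * k, Ho * Wo)
        return cols

    def col2im(self, cols: np.ndarray, in_shape: tuple) -> np.ndarray:
        """Adjoint of :meth:`im2col` — scatter-add patches back to the image."""
        C, H, W_ = in_shape
        k, s = self.k, self.stride
        Ho, Wo = (H - k) // s + 1, (W_ - k) // s + 1
        B = cols.shape[0]
        patches = cols.reshape(B, C, k, k, Ho, Wo)
        out = np.zeros((B, C, H, W_), dtype=cols.dtype)
        for di in range(k):
            for dj in range(k):
                out[:, :, di : di + Ho * s : s, dj : dj + Wo * s : s] += patches[
                    :, :, di, dj
                ]
        return out

    def drive(self, s_prev: np.ndarray, s_self: np.ndarray) -> np.ndarray:
        Cout = self.W.shape[0]
        cols = self.im2col(s_prev)
        Wm = self.W.reshape(Cout, -1)
        out = np.einsum("oc,bcp->bop", Wm, cols)
        B = s_prev.shape[0]
        Ho, Wo = self.out_shape(s_prev.shape[1:])[1:]
        return out.reshape(B, Cout, Ho, Wo)


class MaxPoolLayer:
    """Stateless spatial max pooling on binary spikes (block OR).

    Carries no weights and no LIF state; trailing rows/columns that do not
    fill a block are dropped.
    """

    kind = "maxpool"
    W = None
    V = None
    params = None

    def __init__(self, p: int):
        if p < 1:
            raise ValueError("pool size must be >= 1")
        self.p = p

    def out_shape(self, in_shape: tuple) -> tuple:
        C, H, W_ = in_shape
        return (C, H // self.p, W_ // self.p)

    def blocks(self, x: np.ndarray) -> np.ndarray:
        """(B, C, H, W) -> (B, C, Ho, Wo, p*p) flattened pooling blocks."""
        p = self.p
        B, C, H, W_ = x.shape
        Ho, Wo = H // p, W_ // p
        v = x[:, :, : Ho * p, : Wo * p].reshape(B, C, Ho, p, Wo, p)
        return v.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, Ho, Wo, p * p)

    def drive(self, s_prev: np.ndarray, s_self: np.ndarray) -> np.ndarray:
        return self.blocks(s_prev).max(axis=-1)


def layer_step(layer, I, U, S, s_prev):
    """Advance one LIF layer a single step from state ``(I, U, S)``.

    ``s_prev`` is the presynaptic spike (or input count) vector of this
    step.  Returns the next ``(I, U, S)`` computed in the normative order
    U -> s -> I (see the module docstring).
    """
    if isinstance(layer, MaxPoolLayer):
        raise TypeError("pooling layers are stateless; use drive() directly")
    a, b = layer.params.alpha, layer.params.beta
    U_next = a * U * (1.0 - S) + (1.0 - a) * I
    S_next = (U_next >= layer.params.theta).astype(float)
    I_next = b * I + layer.drive(s_prev, S_next)
    return I_next, U_next, S_next


def forward(layers, x) -> list[StateTrajectory]:
    """Simulate the network on a batch of input tensors.

    Parameters
    ----------
    layers : sequence of DenseLayer / ConvLayer / MaxPoolLayer
    x : ndarray or SpikeTensor
        ``(B, F, T)`` or ``(B, 2, H, W, T)`` input count tensors (a single
        SpikeTensor is promoted to a batch of one).

    Returns
    -------
    list of StateTrajectory, one per layer, each covering steps 1..T.
    """
    if isinstance(x, SpikeTensor):
        x = x.data[None]
    x = np.asarray(x, dtype=float)
    T = x.shape[-1]
    B = x.shape[0]
    in_shape = x.shape[1:-1]

    shapes = []
    for layer in layers:
        in_shape = layer.out_shape(in_shape)
        shapes.append(in_shape)

    trajs = []
    for layer, shp in zip(layers, shapes):
        S = np.zeros((T + 1, B) + shp)
        if isinstance(layer, MaxPoolLayer):
            trajs.append(StateTrajectory(S=S))
        else:
            trajs.append(
                StateTrajectory(S=S, I=np.zeros_like(S), U=np.zeros_like(S))
            )

    for n in range(1, T + 1):
        s_prev = x[..., n - 1]  # paper step n = 0-based bin n-1
        for layer, traj in zip(layers, trajs):
            if isinstance(layer, MaxPoolLayer):
                traj.S[n] = layer.drive(s_prev, None)
            else:
                traj.I[n], traj.U[n], traj.S[n] = layer_step(
                    layer, traj.I[n - 1], traj.U[n - 1], traj.S[n - 1], s_prev
                )
            s_prev = traj.S[n]
    return trajs


# ---------------------------------------------------------------------------
# architecture strings
# ---------------------------------------------------------------------------

_CONV_RE = re.compile(r"^(\d+)C(\d+)(?:S(\d+))?$")
_POOL_RE = re.compile(r"^P(\d+)$")
_FC_RE = re.compile(r"^FC(\d+)(\(R\))?$")
_OUT_RE = re.compile(r"^(\d+)(\(R\))?$")


def parse_architecture(arch: str):
    """Parse a compact architecture string into (input_shape, layer specs).

    Grammar (tokens joined by ``-``): input ``[C,H,W]`` or a bare channel
    count ``F``; ``<n>C<k>[S<s>]`` a conv layer with ``n`` kernels of size
    ``k`` and stride ``s`` (default 1); ``P<p>`` max pooling; ``FC<n>[(R)]``
    a fully connected layer, ``(R)`` adding recurrent connections; a final
    bare integer is the fully connected output layer.  Example:
    ``[2,32,32]-32C5S2-P2-64C3-FC128(R)-10``.
    """
    tokens = arch.replace(" ", "").split("-")
    if len(tokens) < 2:
        raise ValueError(f"architecture {arch!r} needs an input and >=1 layer")
    head = tokens[0]
    if head.startswith("["):
        if not head.endswith("]"):
            raise ValueError(f"bad input spec {head!r}")
        dims = tuple(int(v) for v in head[1:-1].split(","))
        if len(dims) != 3:
            raise ValueError("vision input must be [C,H,W]")
        input_shape = dims
    else:
        input_shape = (int(head),)

    specs = []
    for i, tok in enumerate(tokens[1:]):
        last = i == len(tokens) - 2
        if m := _CONV_RE.match(tok):
            specs.append(
                {"kind": "conv2d", "out": int(m[1]), "k": int(m[2]),
                 "stride": int(m[3] or 1)}
            )
        elif m := _POOL_RE.match(tok):
            specs.append({"kind": "maxpool", "p": int(m[1])})
        elif m := _FC_RE.match(tok):
            specs.append({"kind": "fc", "Q": int(m[1]), "recurrent": bool(m[2])})
        elif last and (m := _OUT_RE.match(tok)):
            specs.append({"kind": "fc", "Q": int(m[1]), "recurrent": bool(m[2]),
                          "output": True})
        else:
            raise ValueError(f"cannot parse architecture token {tok!r}")
    if specs[-1]["kind"] != "fc":
        raise ValueError("architecture must end in a fully connected output layer")
    return input_shape, specs


def _xavier(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def build_network(
    arch: str,
    dt: float,
    tau1: float,
    theta1: float,
    tau2: float,
    theta2: float,
    rng: np.random.Generator,
):
    """Build a network from an architecture string with Xavier-uniform weights.

    Feature-extraction layers receive ``(tau1, theta1)`` and decision layers
    ``(tau2, theta2)``: in a convolutional net the conv/pool layers extract
    features and all FC layers decide; in a pure FC net only the output layer
    is the decision layer.
    """
    input_shape, specs = parse_architecture(arch)
    has_conv = any(s["kind"] == "conv2d" for s in specs)

    layers = []
    shape = input_shape
    for i, s in enumerate(specs):
        if s["kind"] == "conv2d":
            params = NeuronParams(tau=tau1, theta=theta1, dt=dt)
            cin = shape[0]
            k = s["k"]
            fan_in, fan_out = cin * k * k, s["out"] * k * k
            W = _xavier(rng, (s["out"], cin, k, k), fan_in, fan_out)
            layer = ConvLayer(W, params, stride=s["stride"])
        elif s["kind"] == "maxpool":
            layer = MaxPoolLayer(s["p"])
        else:
            decision = s.get("output", False) or has_conv
            tau, theta = (tau2, theta2) if decision else (tau1, theta1)
            params = NeuronParams(tau=tau, theta=theta, dt=dt)
            fan_in = int(np.prod(shape))
            Q = s["Q"]
            W = _xavier(rng, (Q, fan_in), fan_in, Q)
            V = _xavier(rng, (Q, Q), Q, Q) if s["recurrent"] else None
            layer = DenseLayer(W, params, V=V)
        shape = layer.out_shape(shape)
        layers.append(layer)
    return layers


def save_checkpoint(layers, path, arch: str | None = None) -> None:
    """Save per-layer weights and LIF parameters to an NPZ container."""
    payload: dict[str, np.ndarray] = {}
    if arch is not None:
        payload["arch"] = np.str_(arch)
    for i, layer in enumerate(layers):
        payload[f"kind_{i}"] = np.str_(layer.kind)
        if isinstance(layer, MaxPoolLayer):
            payload[f"p_{i}"] = np.int64(layer.p)
            continue
        payload[f"W_{i}"] = layer.W
        if layer.V is not None:
            payload[f"V_{i}"] = layer.V
        if isinstance(layer, ConvLayer):
            payload[f"stride_{i}"] = np.int64(layer.stride)
        payload[f"tau_{i}"] = np.float64(layer.params.tau)
        payload[f"theta_{i}"] = np.float64(layer.params.theta)
        payload[f"dt_{i}"] = np.float64(layer.params.dt)
    np.savez(path, **payload)


def load_checkpoint(path):
    """Inverse of :func:`save_checkpoint`; returns (layers, arch or None)."""
    with np.load(path, allow_pickle=False) as f:
        arch = str(f["arch"]) if "arch" in f else None
        layers = []
        i = 0
        while f"kind_{i}" in f:
            kind = str(f[f"kind_{i}"])
            if kind == "maxpool":
                layers.append(MaxPoolLayer(int(f[f"p_{i}"])))
            else:
                params = NeuronParams(
                    tau=float(f[f"tau_{i}"]),
                    theta=float(f[f"theta_{i}"]),
                    dt=float(f[f"dt_{i}"]),
                )
                if kind == "conv2d":
                    layers.append(
                        ConvLayer(f[f"W_{i}"], params, stride=int(f[f"stride_{i}"]))
                    )
                else:
                    V = f[f"V_{i}"] if f"V_{i}" in f else None
                    layers.append(DenseLayer(f[f"W_{i}"], params, V=V))
            i += 1
    return layers, arch
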