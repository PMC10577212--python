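"""Scikit-learn-style spiking classifier trained with FS or FR coding.

:class:`SpikingClassifier` wires the pieces together: build a LIF network
from an architecture string, simulate mini-batches forward, read out
first-spike times (or rates), push the loss gradient back through the
Gaussian time-to-spike assignment and the surrogate-gradient recurrences,
and update weights with Adam.  It follows the scikit-learn estimator
contract (``fit`` / ``predict`` / ``score``, ``get_params`` /
``set_params``, fitted attributes with a trailing underscore), so it
composes with pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .backprop import BackpropConfig, assign_time_errors_batch, backward
from .evaluation import mean_spike_count
from .network import ConvLayer, DenseLayer, _xavier, build_network, forward
from .objectives import (
    LossConfig,
    fr_loss,
    fr_loss_grad,
    fs_loss,
    fs_loss_grad,
    spike_count_penalty,
)
from .readout import FSReadout, predict_fr, predict_fs, read_output


def _restrict_readout(ro: FSReadout, C: int) -> FSReadout:
    """View of a readout limited to the first C output neurons (the class
    positions); surplus unsupervised outputs are ignored at prediction."""
    if ro.t_F.shape[-1] == C:
        return ro
    return FSReadout(
        t_F=ro.t_F[..., :C],
        first_step=ro.first_step[..., :C],
        U_max=ro.U_max[..., :C],
        U_at_first=ro.U_at_first[..., :C],
        f=ro.f[..., :C],
        T=ro.T,
        dt=ro.dt,
    )

__all__ = ["SpikingClassifier", "init_weights", "train"]


def init_weights(layers, seed: int):
    """Re-draw all feed-forward and recurrent weights Xavier-uniform.

    Deterministic in ``seed``; layers are visited in order, W before V.
    """
    rng = np.random.default_rng(seed)
    for layer in layers:
        if isinstance(layer, DenseLayer):
            Q, fan_in = layer.W.shape
            layer.W = _xavier(rng, layer.W.shape, fan_in, Q)
            if layer.V is not None:
                layer.V = _xavier(rng, layer.V.shape, Q, Q)
        elif isinstance(layer, ConvLayer):
            cout, cin, k, _ = layer.W.shape
            layer.W = _xavier(rng, layer.W.shape, cin * k * k, cout * k * k)
    return layers


class _Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, lr, weight_decay, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m: dict[int, np.ndarray] = {}
        self.v: dict[int, np.ndarray] = {}

    def step(self, params_grads) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for key, (param, grad) in enumerate(params_grads):
            g = grad + self.wd * param
            m = self.m.setdefault(key, np.zeros_like(param))
            v = self.v.setdefault(key, np.zeros_like(param))
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            param -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class SpikingClassifier(ClassifierMixin, BaseEstimator):
    """LIF spiking network classifier for binned event tensors.

    Parameters
    ----------
    arch : str
        Architecture string, e.g. ``"20-FC64(R)-3"`` or
        ``"[2,32,32]-32C5S2-P2-FC128(R)-10"``.
    loss : {"fs", "fr"}
        First-spike (earliest output spike decides, trained through the
        Gaussian time-to-spike assignment) or firing-rate coding.
    dt : float
        Temporal bin width in seconds.
    tau1, theta1 : float
        Time constant (s) and threshold of the feature-extraction layers.
    mu, theta2 : float
        Decision layers use ``tau2 = mu * tau1`` and threshold ``theta2``.
    alpha0, beta0, lambda_t : float
        FS loss scales (softmax scale, silent-target penalty exponent and
        weight); times enter the loss in steps.
    alpha1 : float
        FR loss softmax scale.
    lambda_s, N_target : float
        Optional spike-count constraint ``lambda_s * |N_s - N_target|``.
    A, D : Gaussian window amplitude (None = 2T) and divisor.
    rho : float
        Surrogate-gradient slope.
    T_E : int
        Empty-sequence extension (steps) appended during FS training so
        delayed output spikes stay observable; evaluation uses the window
        as given.
    lr, batch_size, epochs, weight_decay : optimizer settings (Adam).
    random_state : int
        Fully determines weight init and batch shuffling.

    Attributes
    ----------
    classes_ : ndarray of class labels.
    layers_ : the trained network.
    history_ : list of per-epoch dicts (loss, penalty, N_s, accuracy).
    """

    def __init__(
        self,
        arch: str = "20-FC64(R)-3",
        loss: str = "fs",
        dt: float = 0.01,
        tau1: float = 0.05,
        theta1: float = 0.5,
        mu: float = 4.0,
        theta2: float = 1.0,
        alpha0: float = 0.1,
        beta0: float = 0.02,
        lambda_t: float = 0.01,
        alpha1: float = 20.0,
        lambda_s: float = 0.0,
        N_target: float = 0.0,
        A: float | None = None,
        D: int = 16,
        rho: float = 5.0,
        T_E: int = 10,
        lr: float = 1e-3,
        batch_size: int = 32,
        epochs: int = 50,
        weight_decay: float = 1e-4,
        random_state: int = 0,
    ):
        self.arch = arch
        self.loss = loss
        self.dt = dt
        self.tau1 = tau1
        self.theta1 = theta1
        self.mu = mu
        self.theta2 = theta2
        self.alpha0 = alpha0
        self.beta0 = beta0
        self.lambda_t = lambda_t
        self.alpha1 = alpha1
        self.lambda_s = lambda_s
        self.N_target = N_target
        self.A = A
        self.D = D
        self.rho = rho
        self.T_E = T_E
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.weight_decay = weight_decay
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------

    def _encode_labels(self, y) -> np.ndarray:
        y = np.asarray(y)
        idx = np.searchsorted(self.classes_, y)
        if not np.array_equal(self.classes_[idx], y):
            raise ValueError("y contains labels unseen during fit")
        return idx

    def _loss_cfg(self) -> LossConfig:
        return LossConfig(
            alpha0=self.alpha0,
            beta0=self.beta0,
            lambda_t=self.lambda_t,
            alpha1=self.alpha1,
            lambda_s=self.lambda_s,
            N_target=self.N_target,
        )

    def _bp_cfg(self) -> BackpropConfig:
        return BackpropConfig(A=self.A, D=self.D, rho=self.rho)

    def _validate_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim not in (3, 5):
            raise ValueError(
                "X must be (n, F, T) audio or (n, 2, H, W, T) vision tensors"
            )
        return X

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        """Train with mini-batch Adam on the FS or FR objective."""
        if self.loss not in ("fs", "fr"):
            raise ValueError("loss must be 'fs' or 'fr'")
        if self.lr < 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("invalid optimizer settings")
        X = self._validate_X(X)
        y = np.asarray(y)
        if len(y) != X.shape[0]:
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        y_idx = self._encode_labels(y)
        C = len(self.classes_)

        rng = np.random.default_rng(self.random_state)
        self.layers_ = build_network(
            self.arch,
            dt=self.dt,
            tau1=self.tau1,
            theta1=self.theta1,
            tau2=self.mu * self.tau1,
            theta2=self.theta2,
            rng=rng,
        )
        Q_out = self.layers_[-1].Q
        if Q_out < C:
            raise ValueError(
                f"architecture has {Q_out} outputs but y has {C} classes"
            )

        if self.loss == "fs" and self.T_E > 0:
            pad = [(0, 0)] * (X.ndim - 1) + [(0, self.T_E)]
            X_train = np.pad(X, pad)
        else:
            X_train = X
        T = X_train.shape[-1]
        loss_cfg = self._loss_cfg()
        bp_cfg = self._bp_cfg()
        opt = _Adam(self.lr, self.weight_decay)

        # classes occupy output positions 0..C-1; any surplus output neurons
        # are permanent non-targets (their first spikes are pushed late)
        eye = np.eye(Q_out)
        self.history_ = []
        n = X_train.shape[0]
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            losses, penalties, spike_counts, correct = [], [], [], 0
            for start in range(0, n, self.batch_size):
                batch = order[start : start + self.batch_size]
                xb, yb = X_train[batch], y_idx[batch]
                y_onehot = eye[yb]
                trajs = forward(self.layers_, xb)
                ro = read_output(trajs[-1].S, trajs[-1].U, self.dt)

                if self.loss == "fs":
                    t_steps = np.where(ro.first_step > 0, ro.first_step, T + 1)
                    batch_loss = fs_loss(t_steps, y_onehot, T, loss_cfg)
                    g_t = fs_loss_grad(t_steps, y_onehot, T, loss_cfg)
                    dl_ds_out = assign_time_errors_batch(
                        g_t, ro.first_step, T, bp_cfg
                    )
                    pred = predict_fs(_restrict_readout(ro, C))
                else:
                    batch_loss = fr_loss(ro.f, y_onehot, loss_cfg)
                    g_f = fr_loss_grad(ro.f, y_onehot, loss_cfg)
                    dl_ds_out = np.zeros((T + 1,) + ro.f.shape)
                    dl_ds_out[1:] = g_f / T
                    pred = predict_fr(_restrict_readout(ro, C))

                N_s = mean_spike_count(trajs)
                extra = 0.0
                penalty = 0.0
                if self.lambda_s > 0:
                    penalty = spike_count_penalty(N_s, loss_cfg)
                    n_neu = sum(
                        int(np.prod(t.S.shape[2:]))
                        for t in trajs
                        if t.I is not None
                    )
                    extra = (
                        self.lambda_s
                        * np.sign(N_s - self.N_target)
                        / (n_neu * len(batch))
                    )

                total_loss = batch_loss + penalty
                if not np.isfinite(total_loss):
                    raise RuntimeError(
                        f"training diverged at epoch {epoch}: loss={total_loss}"
                    )
                tape = backward(
                    self.layers_, trajs, xb, dl_ds_out, rho=self.rho,
                    spike_grad_extra=extra,
                )
                params_grads = []
                for l, layer in enumerate(self.layers_):
                    if tape.dL_dW[l] is not None:
                        params_grads.append((layer.W, tape.dL_dW[l]))
                    if tape.dL_dV[l] is not None:
                        params_grads.append((layer.V, tape.dL_dV[l]))
                opt.step(params_grads)

                losses.append(batch_loss)
                penalties.append(penalty)
                spike_counts.append(N_s)
                correct += int(np.sum(pred == yb))
            self.history_.append(
                {
                    "epoch": epoch,
                    "loss": float(np.mean(losses)),
                    "penalty": float(np.mean(penalties)),
                    "N_s": float(np.mean(spike_counts)),
                    "accuracy": correct / n,
                }
            )
        return self

    def decision_readout(self, X):
        """Simulate X and return the output-layer :class:`~fscode.readout.FSReadout`."""
        X = self._validate_X(X)
        trajs = forward(self.layers_, X)
        return read_output(trajs[-1].S, trajs[-1].U, self.dt)

    def predict(self, X, mode: str | None = None):
        """Predict class labels; ``mode`` overrides the trained readout."""
        mode = mode or self.loss
        ro = _restrict_readout(self.decision_readout(X), len(self.classes_))
        idx = predict_fs(ro) if mode == "fs" else predict_fr(ro)
        return self.classes_[idx]


def train(X, y, **params) -> SpikingClassifier:
    """Functional wrapper: fit a :class:`SpikingClassifier` on (X, y)."""
    return SpikingClassifier(**params).fit(X, y)
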