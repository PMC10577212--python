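"""First-spike (FS) and firing-rate (FR) readout of output spike trains.

The output spike train of each class neuron is encoded into discrete times:
step ``n`` (1-based) maps to ``n*dt`` when a spike occurred and to the
sentinel ``t_inf = (T+1)*dt`` otherwise.  The first-spike time is the minimum
of these codes.  The FS prediction is the neuron with the earliest first
spike; when every output neuron is silent the prediction falls back to the
neuron with the largest membrane potential reached anywhere in the window
(high potential ~ most likely to have fired first).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FSReadout",
    "t_inf",
    "encode_times",
    "first_spike_time",
    "read_output",
    "predict_fs",
    "predict_fr",
]


def t_inf(T: int, dt: float) -> float:
    """Sentinel time for a silent step/neuron: ``(T+1)*dt`` (> T*dt)."""
    return (T + 1) * dt


@dataclass
class FSReadout:
    """Per-trial output summary: first-spike times, peak potentials, rates.

    ``t_F`` is in seconds (``t_inf`` for silent neurons); ``first_step`` is
    the 1-based step of the first spike (0 for silent); ``U_at_first`` is the
    membrane potential at that step (used only for tie-breaks).
    """

    t_F: np.ndarray
    first_step: np.ndarray
    U_max: np.ndarray
    U_at_first: np.ndarray
    f: np.ndarray
    T: int
    dt: float

    @property
    def t_inf(self) -> float:
        return t_inf(self.T, self.dt)


def encode_times(spikes: np.ndarray, dt: float) -> np.ndarray:
    """Discrete temporal code of a binary train: ``n*dt`` if spike else t_inf.

    Works on the trailing axis of any-shaped array of {0,1} values.
    """
    s = np.asarray(spikes)
    if not np.isin(s, (0, 1)).all():
        raise ValueError("spike train must be binary")
    T = s.shape[-1]
    steps = np.arange(1, T + 1) * dt
    return np.where(s == 1, steps, t_inf(T, dt))


def first_spike_time(times: np.ndarray) -> float | np.ndarray:
    """First-spike time = minimum of the temporal codes (trailing axis)."""
    times = np.asarray(times)
    if times.shape[-1] == 0:
        raise ValueError("empty temporal code")
    return times.min(axis=-1)


def read_output(S: np.ndarray, U: np.ndarray, dt: float) -> FSReadout:
    """Summarize an output-layer trajectory into an :class:`FSReadout`.

    ``S`` and ``U`` are time-first ``(T+1, B, C)`` trajectories as recorded
    by the simulator (index 0 = initial state); the batch axis is kept.
    """
    T = S.shape[0] - 1
    s = np.moveaxis(S[1:], 0, -1)  # (B, C, T)
    u = np.moveaxis(U[1:], 0, -1)
    fired = s.sum(axis=-1) > 0
    first_idx = np.argmax(s > 0, axis=-1)  # 0-based; 0 also for silent
    first_step = np.where(fired, first_idx + 1, 0)
    t_F = np.where(fired, first_step * dt, t_inf(T, dt))
    U_at_first = np.take_along_axis(u, first_idx[..., None], axis=-1)[..., 0]
    U_at_first = np.where(fired, U_at_first, -np.inf)
    return FSReadout(
        t_F=t_F,
        first_step=first_step,
        U_max=u.max(axis=-1),
        U_at_first=U_at_first,
        f=s.mean(axis=-1),
        T=T,
        dt=dt,
    )


def _lex_argbest(primary: np.ndarray, secondary: np.ndarray) -> np.ndarray:
    """Row-wise argmax of ``primary``, ties broken by larger ``secondary``,
    then lower index."""
    best = primary.max(axis=-1, keepdims=True)
    tied = primary == best
    masked = np.where(tied, secondary, -np.inf)
    return np.argmax(masked, axis=-1)  # argmax takes first max -> lowest index


def predict_fs(readout: FSReadout) -> np.ndarray:
    """FS prediction: earliest first spike wins.

    Ties at the same first step are broken by the higher membrane potential
    at that step, then by the lower neuron index.  If all neurons are silent
    the neuron with the largest ``U_max`` wins (same tie-break).
    """
    t_F = np.atleast_2d(readout.t_F)
    any_fired = (t_F < readout.t_inf).any(axis=-1)
    active = _lex_argbest(-t_F, np.atleast_2d(readout.U_at_first))
    fallback = _lex_argbest(np.atleast_2d(readout.U_max), -np.arange(t_F.shape[-1]))
    pred = np.where(any_fired, active, fallback)
    return pred if readout.t_F.ndim > 1 else pred[0]


def predict_fr(readout: FSReadout) -> np.ndarray:
    """FR prediction: highest firing rate wins; ties broken by larger
    ``U_max``, then lower index."""
    f = np.atleast_2d(readout.f)
    pred = _lex_argbest(f, np.atleast_2d(readout.U_max))
    return pred if readout.f.ndim > 1 else pred[0]
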