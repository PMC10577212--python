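"""Event-stream I/O and conversion to spatio-temporal count tensors.

Asynchronous sensor events — visual ``(t, x, y, p)`` with polarity ``p = ±1``
or audio ``(t, channel)`` — are stored as plain CSV (one event per row, header
``t,x,y,p`` or ``t,channel``) and binned into dense count tensors: shape
``(2, H, W, T)`` for vision (channel 0 holds positive, channel 1 negative
events) or ``(F, T)`` for audio, where bin ``k`` (0-based) covers the
half-open interval ``[k*dt, (k+1)*dt)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EventStream",
    "SpikeTensor",
    "read_events",
    "write_events",
    "bin_events",
    "extend_window",
    "save_tensor",
    "load_tensor",
]

VISION_COLUMNS = ["t", "x", "y", "p"]
AUDIO_COLUMNS = ["t", "channel"]


@dataclass
class EventStream:
    """A validated, time-sorted stream of sensor events.

    Parameters
    ----------
    events : pandas.DataFrame
        Columns ``t, x, y, p`` (vision) or ``t, channel`` (audio). Times are
        seconds; coordinates are 0-based integers; polarity is ±1.
    sensor_shape : tuple
        ``(H, W)`` for vision, ``(F,)`` for audio.
    modality : {"vision", "audio"}
    """

    events: pd.DataFrame
    sensor_shape: tuple
    modality: str = "audio"

    def __post_init__(self) -> None:
        if self.modality not in ("vision", "audio"):
            raise ValueError(f"unknown modality {self.modality!r}")
        cols = VISION_COLUMNS if self.modality == "vision" else AUDIO_COLUMNS
        missing = set(cols) - set(self.events.columns)
        if missing:
            raise ValueError(f"event table is missing columns {sorted(missing)}")
        ev = self.events[cols].reset_index(drop=True)
        ev["t"] = ev["t"].astype(float)
        for c in cols[1:]:
            ev[c] = ev[c].astype(np.int64)
        self.events = ev
        self.sensor_shape = tuple(int(s) for s in self.sensor_shape)
        self._validate()
        # canonical ordering: stable sort on time
        if len(ev) and not ev["t"].is_monotonic_increasing:
            self.events = ev.sort_values("t", kind="stable").reset_index(drop=True)

    def _validate(self) -> None:
        ev = self.events
        if len(ev) == 0:
            return
        if (ev["t"].to_numpy() < 0).any():
            raise ValueError("negative timestamps are not allowed")
        if self.modality == "vision":
            if len(self.sensor_shape) != 2:
                raise ValueError("vision sensor_shape must be (H, W)")
            H, W = self.sensor_shape
            x, y, p = (ev[c].to_numpy() for c in ("x", "y", "p"))
            if ((x < 0) | (x >= W)).any():
                raise ValueError(f"x coordinate out of range [0, {W})")
            if ((y < 0) | (y >= H)).any():
                raise ValueError(f"y coordinate out of range [0, {H})")
            if (~np.isin(p, (-1, 1))).any():
                raise ValueError("polarity must be +1 or -1")
        else:
            if len(self.sensor_shape) != 1:
                raise ValueError("audio sensor_shape must be (F,)")
            (F,) = self.sensor_shape
            ch = ev["channel"].to_numpy()
            if ((ch < 0) | (ch >= F)).any():
                raise ValueError(f"channel out of range [0, {F})")

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class SpikeTensor:
    """Binned event counts (input layer) or binary spikes on a discrete grid.

    ``data`` has shape ``(2, H, W, T)`` (vision) or ``(F, T)`` (audio); the
    last axis is time with ``T`` bins of width ``dt`` seconds.
    """

    data: np.ndarray
    dt: float
    modality: str = "audio"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        expected_ndim = 4 if self.modality == "vision" else 2
        if self.data.ndim != expected_ndim:
            raise ValueError(
                f"{self.modality} tensor must have {expected_ndim} axes, "
                f"got {self.data.ndim}"
            )
        if (self.data < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def T(self) -> int:
        return self.data.shape[-1]


def read_events(path, modality: str, sensor_shape) -> EventStream:
    """Read an event CSV and return a validated, time-sorted :class:`EventStream`.

    Raises a parse error naming the offending line for malformed rows and a
    validation error for out-of-range coordinates.
    """
    cols = VISION_COLUMNS if modality == "vision" else AUDIO_COLUMNS
    try:
        df = pd.read_csv(path, dtype={c: float for c in cols})
    except ValueError as exc:
        raise ValueError(f"malformed event file {path}: {exc}") from exc
    if list(df.columns) != cols:
        raise ValueError(
            f"{path}: expected header {','.join(cols)}, got {','.join(df.columns)}"
        )
    for c in cols[1:]:
        vals = df[c].to_numpy()
        if len(vals) and not np.all(vals == np.floor(vals)):
            bad = int(np.nonzero(vals != np.floor(vals))[0][0]) + 2  # header is line 1
            raise ValueError(f"{path}: non-integer value in column {c!r} at line {bad}")
    return EventStream(df, sensor_shape=sensor_shape, modality=modality)


def write_events(stream: EventStream, path) -> None:
    """Write an event stream as CSV; round-trips losslessly with read_events."""
    stream.events.to_csv(path, index=False)


def bin_events(
    stream: EventStream,
    dt: float,
    T: int,
    spatial_downsample: int = 1,
) -> SpikeTensor:
    """Accumulate raw events into a count tensor at temporal resolution ``dt``.

    Bin ``k`` covers ``[k*dt, (k+1)*dt)``; events with ``t >= T*dt`` are
    dropped.  For vision, positive-polarity events go to channel 0 and
    negative to channel 1, and ``spatial_downsample`` sums counts over
    non-overlapping square blocks (the frame is zero-padded on the
    bottom/right if the factor does not divide ``H`` or ``W``).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if T < 1:
        raise ValueError("T must be >= 1")
    if spatial_downsample < 1:
        raise ValueError("spatial_downsample must be >= 1")

    ev = stream.events
    t = ev["t"].to_numpy()
    bins = np.floor(t / dt).astype(np.int64)
    keep = bins < T
    bins = bins[keep]

    if stream.modality == "audio":
        (F,) = stream.sensor_shape
        data = np.zeros((F, T), dtype=np.int64)
        ch = ev["channel"].to_numpy()[keep]
        np.add.at(data, (ch, bins), 1)
        return SpikeTensor(data, dt=dt, modality="audio")

    H, W = stream.sensor_shape
    data = np.zeros((2, H, W, T), dtype=np.int64)
    x = ev["x"].to_numpy()[keep]
    y = ev["y"].to_numpy()[keep]
    pol = (ev["p"].to_numpy()[keep] < 0).astype(np.int64)  # +1 -> 0, -1 -> 1
    np.add.at(data, (pol, y, x, bins), 1)
    if spatial_downsample > 1:
        d = spatial_downsample
        Hp, Wp = -(-H // d) * d, -(-W // d) * d
        if (Hp, Wp) != (H, W):
            padded = np.zeros((2, Hp, Wp, T), dtype=np.int64)
            padded[:, :H, :W, :] = data
            data = padded
        data = data.reshape(2, Hp // d, d, Wp // d, d, T).sum(axis=(2, 4))
    return SpikeTensor(data, dt=dt, modality="vision")


def extend_window(tensor: SpikeTensor, T_E: int) -> SpikeTensor:
    """Append ``T_E`` all-zero time bins (an "empty sequence") to the tensor.

    Used during first-spike training so that output spikes delayed beyond the
    stimulus window remain observable.
    """
    if T_E < 0:
        raise ValueError("T_E must be >= 0")
    if T_E == 0:
        return SpikeTensor(tensor.data.copy(), dt=tensor.dt, modality=tensor.modality)
    pad = [(0, 0)] * (tensor.data.ndim - 1) + [(0, T_E)]
    return SpikeTensor(
        np.pad(tensor.data, pad), dt=tensor.dt, modality=tensor.modality
    )


def save_tensor(tensor: SpikeTensor, path) -> None:
    """Serialize a SpikeTensor to an NPZ container (bit-exact round-trip)."""
    np.savez(
        path,
        data=tensor.data,
        dt=np.float64(tensor.dt),
        modality=np.str_(tensor.modality),
    )


def load_tensor(path) -> SpikeTensor:
    with np.load(path, allow_pickle=False) as f:
        return SpikeTensor(f["data"], dt=float(f["dt"]), modality=str(f["modality"]))
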