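"""Labeled synthetic event streams with controllable temporal structure.

Two regimes mirror the qualitative split between event-camera gestures and
spoken-digit cochleagrams:

* ``repetitive`` — each class is a fixed spatio-temporal template that
  repeats every ``period`` bins for the whole trial (gesture-like periodic
  sequences).
* ``nonrepetitive`` — each class traces a distinct chirp-like channel sweep
  exactly once per trial; the motifs share their starting channels and
  overall occupancy, so the label is carried chiefly by *when* each channel
  fires (spoken-digit-like sequences).

Event counts on active cells are Poisson with mean ``signal_rate`` per bin,
timing is blurred with Gaussian jitter, and every cell adds Poisson
``noise_rate`` background events.  Generation is fully determined by the
spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .events import EventStream, SpikeTensor, bin_events, write_events

__all__ = ["SynthSpec", "SyntheticDataset", "generate", "train_test_split"]


@dataclass
class SynthSpec:
    """Parameters of a synthetic labeled event dataset.

    ``sensor_shape`` is ``(F,)`` for audio, ``(H, W)`` for vision.  Rates are
    expected events per active cell per bin (``signal_rate``) and per cell
    per bin background (``noise_rate``); ``jitter`` is the s.d. of the
    Gaussian timing blur in bins.
    """

    modality: str = "audio"
    C: int = 3
    n_per_class: int = 100
    T: int = 50
    dt: float = 0.01
    sensor_shape: tuple = (20,)
    structure: str = "nonrepetitive"
    period: int | None = None
    signal_rate: float = 3.0
    noise_rate: float = 0.3
    jitter: float = 1.0
    pattern_channels: list | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C < 2:
            raise ValueError("need at least 2 classes")
        if self.signal_rate < 0 or self.noise_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.structure not in ("repetitive", "nonrepetitive"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.structure == "repetitive":
            if self.period is None:
                raise ValueError("repetitive structure requires a period")
            if self.period > self.T:
                raise ValueError("period must not exceed T")
        if self.modality == "audio" and len(self.sensor_shape) != 1:
            raise ValueError("audio sensor_shape must be (F,)")
        if self.modality == "vision" and len(self.sensor_shape) != 2:
            raise ValueError("vision sensor_shape must be (H, W)")


@dataclass
class SyntheticDataset:
    """A generated collection of labeled event streams."""

    streams: list
    labels: np.ndarray
    spec: SynthSpec

    def __len__(self) -> int:
        return len(self.streams)

    def to_tensors(self, spatial_downsample: int = 1) -> np.ndarray:
        """Bin every stream; returns ``(N, F, T)`` or ``(N, 2, H, W, T)``."""
        tensors = [
            bin_events(s, self.spec.dt, self.spec.T, spatial_downsample).data
            for s in self.streams
        ]
        return np.stack(tensors).astype(float)

    def save(self, directory) -> None:
        """Write per-trial event CSVs plus a ``labels.csv`` manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, (stream, label) in enumerate(zip(self.streams, self.labels)):
            name = f"trial_{i:04d}.csv"
            write_events(stream, directory / name)
            rows.append({"trial_id": name, "class": int(label)})
        pd.DataFrame(rows).to_csv(directory / "labels.csv", index=False)


def _class_template_audio(spec: SynthSpec, c: int) -> np.ndarray:
    """Active channel per bin for class ``c``: a non-repeating sweep motif.

    Classes cycle through three chirp-like motifs — a slow up-sweep, a fast
    up-then-down chirp, and an up-hold-up staircase — scaled by a tempo
    factor for classes beyond the first three.  All motifs start at channel
    0 and cover a similar channel range, so early bins are ambiguous and
    long-run occupancy is shared; the label is carried by *when* each
    channel fires, the temporal structure the nonrepetitive regime
    emulates.  ``spec.pattern_channels`` overrides the motifs entirely.
    """
    if spec.pattern_channels is not None:
        tpl = np.asarray(spec.pattern_channels[c], dtype=int)
        if tpl.shape != (spec.T,):
            raise ValueError("pattern_channels entries must have length T")
        return tpl
    (F,) = spec.sensor_shape
    T = spec.T
    k = np.arange(T)
    m = c % 3
    if m == 0:  # slow up-sweep over the whole trial
        ch = (k * F) // T
    elif m == 1:  # fast up-then-down chirp
        half = T // 2
        ch = np.where(k < half, (k * F) // half, ((T - 1 - k) * F) // (T - half))
    else:  # up to mid-band, hold, then up again
        third = T // 3
        ch = np.where(
            k < third,
            (k * (F // 2)) // third,
            np.where(
                k < 2 * third,
                F // 2,
                F // 2 + ((k - 2 * third) * (F - F // 2)) // (T - 2 * third),
            ),
        )
    if c >= 3:  # additional classes replay a motif at a slower tempo
        stretch = 1 + c // 3
        ch = ch[np.minimum(k // stretch, T - 1)]
    return np.clip(ch, 0, F - 1)


def _class_template_vision(spec: SynthSpec, c: int, rng: np.random.Generator):
    """Per-phase active pixel of the repeating template for class ``c``."""
    H, W = spec.sensor_shape
    P = spec.period
    # deterministic per-class pattern, independent of trial noise
    cls_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7919, c]))
    rows = cls_rng.integers(0, H, size=P)
    cols = cls_rng.integers(0, W, size=P)
    return rows, cols


def _jittered_times(rng, bins: np.ndarray, spec: SynthSpec) -> np.ndarray:
    t = (bins + rng.uniform(size=bins.shape)) * spec.dt
    if spec.jitter > 0:
        t = t + rng.normal(scale=spec.jitter * spec.dt, size=bins.shape)
    return np.clip(t, 0.0, spec.T * spec.dt - 1e-9)


def generate(spec: SynthSpec) -> SyntheticDataset:
    """Generate ``C * n_per_class`` labeled trials, deterministic in the seed."""
    rng = np.random.default_rng(spec.seed)
    streams, labels = [], []
    audio = spec.modality == "audio"

    for c in range(spec.C):
        if audio:
            tpl = _class_template_audio(spec, c)
        else:
            rows, cols = _class_template_vision(spec, c, rng)
        for _ in range(spec.n_per_class):
            t_list, coord_list = [], []
            # signal events on template-active cells
            if spec.signal_rate > 0:
                if audio:
                    active_bins = np.nonzero(tpl >= 0)[0]
                    counts = rng.poisson(spec.signal_rate, size=len(active_bins))
                    bins = np.repeat(active_bins, counts)
                    chans = np.repeat(tpl[active_bins], counts)
                    t_list.append(_jittered_times(rng, bins.astype(float), spec))
                    coord_list.append(chans)
                else:
                    k = np.arange(spec.T)
                    phase = k % spec.period
                    counts = rng.poisson(spec.signal_rate, size=spec.T)
                    bins = np.repeat(k, counts)
                    ph = np.repeat(phase, counts)
                    t_list.append(_jittered_times(rng, bins.astype(float), spec))
                    coord_list.append(
                        np.stack([cols[ph], rows[ph], np.ones(len(ph), int)], axis=1)
                    )
            # background noise everywhere
            if spec.noise_rate > 0:
                n_cells = int(np.prod(spec.sensor_shape))
                n_noise = rng.poisson(spec.noise_rate * n_cells * spec.T)
                bins = rng.uniform(0, spec.T, size=n_noise)
                t_noise = bins * spec.dt
                if audio:
                    t_list.append(t_noise)
                    coord_list.append(rng.integers(0, n_cells, size=n_noise))
                else:
                    H, W = spec.sensor_shape
                    t_list.append(t_noise)
                    coord_list.append(
                        np.stack(
                            [
                                rng.integers(0, W, size=n_noise),
                                rng.integers(0, H, size=n_noise),
                                rng.choice((-1, 1), size=n_noise),
                            ],
                            axis=1,
                        )
                    )
            t = np.concatenate(t_list) if t_list else np.empty(0)
            if audio:
                ch = (
                    np.concatenate(coord_list).astype(int)
                    if coord_list
                    else np.empty(0, int)
                )
                ev = pd.DataFrame({"t": t, "channel": ch})
            else:
                xyz = (
                    np.concatenate(coord_list).astype(int)
                    if coord_list
                    else np.empty((0, 3), int)
                )
                ev = pd.DataFrame(
                    {"t": t, "x": xyz[:, 0], "y": xyz[:, 1], "p": xyz[:, 2]}
                )
            streams.append(
                EventStream(ev, sensor_shape=spec.sensor_shape, modality=spec.modality)
            )
            labels.append(c)

    return SyntheticDataset(streams, np.asarray(labels), spec)


def train_test_split(
    dataset: SyntheticDataset, fraction: float, seed: int
) -> tuple[SyntheticDataset, SyntheticDataset]:
    """Stratified split into (train, test); ``fraction`` is the train share."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = dataset.labels
    train_idx, test_idx = [], []
    for c in np.unique(labels):
        idx = np.nonzero(labels == c)[0]
        if len(idx) < 2:
            raise ValueError(f"class {c} has fewer than 2 trials")
        idx = rng.permutation(idx)
        n_train = int(round(fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    train_idx, test_idx = sorted(train_idx), sorted(test_idx)

    def subset(ids):
        return SyntheticDataset(
            [dataset.streams[i] for i in ids], labels[ids], dataset.spec
        )

    return subset(np.asarray(train_idx)), subset(np.asarray(test_idx))
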