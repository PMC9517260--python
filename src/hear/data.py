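"""Containers and preprocessing for multi-sensor inertial recordings.

A wrist-worn attitude sensor reports nine channels per timestamp: 3-axis
acceleration, 3-axis angular velocity and 3-axis orientation angle. A
recording session therefore yields one :class:`SensorStream` per device,
all nominally on a shared integer sample grid. Classification operates on
fixed-length sliding windows cut from the synchronized streams, each
window carrying a single activity label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: fixed channel order for every sensor
CHANNEL_NAMES = ("ax", "ay", "az", "wx", "wy", "wz", "angx", "angy", "angz")
N_CHANNELS = len(CHANNEL_NAMES)

_CSV_COLUMNS = ("timestamp", "sensor_id") + CHANNEL_NAMES + ("label",)


@dataclass(frozen=True)
class SensorSample:
    """One timestamped reading: acceleration, angular velocity, angle (3 axes each)."""

    t: int
    a: tuple[float, float, float]
    w: tuple[float, float, float]
    ag: tuple[float, float, float]

    def as_vector(self) -> np.ndarray:
        """The 9 scalar channels in the fixed (ax..az, wx..wz, angx..angz) order."""
        return np.asarray(self.a + self.w + self.ag, dtype=float)


@dataclass
class SensorStream:
    """Ordered 9-channel signal from one sensor with per-timestamp labels.

    Parameters
    ----------
    sensor_id : int
        Device identifier (1-based by convention).
    timestamps : ndarray of int, shape (n,)
        Strictly increasing integer sample indices. A jump larger than one
        marks a recording gap and ends a contiguous segment.
    values : ndarray, shape (n, 9)
        Channel readings in :data:`CHANNEL_NAMES` order.
    labels : ndarray, shape (n,)
        Activity label per timestamp (string or integer codes).
    """

    sensor_id: int
    timestamps: np.ndarray
    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps)
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2 or self.values.shape[1] != N_CHANNELS:
            raise ValueError(
                f"values must have shape (n, {N_CHANNELS}); got {self.values.shape}"
            )
        n = len(self.timestamps)
        if n == 0:
            raise ValueError("stream must contain at least one sample")
        if self.values.shape[0] != n or self.labels.shape[0] != n:
            raise ValueError("timestamps, values and labels must share length")
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamps)

    def sample(self, i: int) -> SensorSample:
        v = self.values[i]
        return SensorSample(
            t=int(self.timestamps[i]),
            a=tuple(v[0:3]),
            w=tuple(v[3:6]),
            ag=tuple(v[6:9]),
        )


@dataclass
class Window:
    """A fixed-length slice of the synchronized recording with one label."""

    data: np.ndarray  # (T, S, 9)
    label: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("window data must have shape (T, S, C) with T > 0")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("window contains non-finite values")


@dataclass
class WindowedDataset:
    """Stack of labeled windows; the model's input unit.

    ``X`` has shape (N, T, S, C): N windows, T timestamps, S sensors,
    C = 9 channels. ``y`` holds integer class indices into ``class_names``.
    """

    X: np.ndarray
    y: np.ndarray
    class_names: list[str]
    window_length: int
    step: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float32)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 4:
            raise ValueError(f"X must be 4-D (N, T, S, C); got shape {self.X.shape}")
        if len(self.X) != len(self.y):
            raise ValueError("X and y must share the leading dimension")
        if len(self.y) and (self.y.min() < 0 or self.y.max() >= len(self.class_names)):
            raise ValueError("class index out of range")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.X.shape

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.y, minlength=self.n_classes)

    def subset(self, idx: np.ndarray) -> "WindowedDataset":
        return WindowedDataset(
            self.X[idx],
            self.y[idx],
            list(self.class_names),
            self.window_length,
            self.step,
            dict(self.metadata),
        )

    def save(self, path: str | Path) -> None:
        """Serialize to a single ``.npz`` archive (arrays + metadata)."""
        np.savez_compressed(
            path,
            X=self.X,
            y=self.y,
            class_names=np.asarray(self.class_names),
            window_length=self.window_length,
            step=self.step,
        )

    @classmethod
    def load(cls, path: str | Path) -> "WindowedDataset":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                X=z["X"],
                y=z["y"],
                class_names=[str(c) for c in z["class_names"]],
                window_length=int(z["window_length"]),
                step=int(z["step"]),
            )


# ---------------------------------------------------------------------------
# synchronization and segmentation
# ---------------------------------------------------------------------------


def synchronize(streams: Sequence[SensorStream]) -> list[SensorStream]:
    """Restrict all streams to their common timestamp grid.

    Per-timestamp labels must agree across sensors (they describe the same
    person); a conflict is an error naming the first offending timestamp.
    """
    if len(streams) == 0:
        raise ValueError("need at least one stream")
    common = streams[0].timestamps
    for s in streams[1:]:
        common = np.intersect1d(common, s.timestamps, assume_unique=True)
    if common.size == 0:
        raise ValueError("no overlapping time range across streams")

    out = []
    ref_labels = None
    for s in streams:
        mask = np.isin(s.timestamps, common, assume_unique=True)
        labels = s.labels[mask]
        if ref_labels is None:
            ref_labels = labels
        else:
            bad = labels != ref_labels
            if np.any(bad):
                t_bad = common[np.argmax(bad)]
                raise ValueError(
                    f"conflicting labels across sensors at timestamp {t_bad}"
                )
        out.append(
            SensorStream(s.sensor_id, common.copy(), s.values[mask], labels)
        )
    return out


def _contiguous_segments(timestamps: np.ndarray, labels: np.ndarray):
    """Yield (start, stop) index ranges with unit timestamp step and one label."""
    n = len(timestamps)
    if n == 0:
        return
    breaks = np.flatnonzero(
        (np.diff(timestamps) != 1) | (labels[1:] != labels[:-1])
    )
    start = 0
    for b in breaks:
        yield start, b + 1
        start = b + 1
    yield start, n


def count_windows(segment_length: int, T: int, step: int) -> int:
    """Number of sliding windows of width ``T`` and stride ``step`` that fit."""
    if segment_length < T:
        return 0
    return (segment_length - T) // step + 1


def segment_windows(
    streams: Sequence[SensorStream],
    T: int,
    step: int,
    class_names: Sequence[str] | None = None,
) -> WindowedDataset:
    """Cut synchronized streams into overlapping fixed-width windows.

    Window ``n`` of a contiguous single-label segment covers the half-open
    index range ``[n*step, n*step + T)``; a segment of length ``N_seg``
    yields ``(N_seg - T) // step + 1`` windows when ``N_seg >= T``. Spans
    where the label changes (or the timestamp grid jumps) produce no
    window, so every emitted window has one constant label.
    """
    if T < 1 or step < 1:
        raise ValueError("T and step must be positive")
    if len(streams) == 0:
        raise ValueError("need at least one stream")
    ref = streams[0]
    for s in streams[1:]:
        if len(s) != len(ref) or not np.array_equal(s.timestamps, ref.timestamps):
            raise ValueError("streams are not synchronized; call synchronize() first")
        if not np.array_equal(s.labels, ref.labels):
            raise ValueError("streams are not synchronized; labels differ")

    if class_names is None:
        class_names = sorted({str(l) for l in ref.labels})
    name_to_idx = {str(c): i for i, c in enumerate(class_names)}

    S = len(streams)
    stacked = np.stack([s.values for s in streams], axis=1)  # (n, S, 9)

    windows, labels = [], []
    for start, stop in _contiguous_segments(ref.timestamps, ref.labels):
        seg_len = stop - start
        label = str(ref.labels[start])
        if label not in name_to_idx:
            raise ValueError(f"label {label!r} not in class_names")
        for k in range(count_windows(seg_len, T, step)):
            lo = start + k * step
            windows.append(stacked[lo : lo + T])
            labels.append(name_to_idx[label])

    X = (
        np.stack(windows)
        if windows
        else np.empty((0, T, S, N_CHANNELS), dtype=float)
    )
    return WindowedDataset(X, np.asarray(labels, dtype=int), list(class_names), T, step)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


@dataclass
class NormStats:
    """Per-(sensor, channel) z-score statistics fitted on a training set."""

    mean: np.ndarray  # (S, C)
    std: np.ndarray  # (S, C)


def fit_norm_stats(ds: WindowedDataset) -> NormStats:
    if len(ds) == 0:
        raise ValueError("cannot fit normalization statistics on an empty dataset")
    mean = ds.X.mean(axis=(0, 1), dtype=np.float64)
    std = ds.X.std(axis=(0, 1), dtype=np.float64)
    return NormStats(mean=mean, std=std)


def normalize(
    ds: WindowedDataset, stats: NormStats | str = "fit"
) -> tuple[WindowedDataset, NormStats]:
    """Z-score every (sensor, channel) pair.

    With ``stats="fit"`` the statistics are computed on ``ds`` and returned
    for reuse on held-out data; otherwise the supplied statistics are
    applied unchanged. Channels with (near-)zero variance map to 0.
    """
    if not np.all(np.isfinite(ds.X)):
        bad = np.flatnonzero(~np.isfinite(ds.X).all(axis=(1, 2, 3)))
        raise ValueError(f"non-finite values in windows {bad[:10].tolist()}")
    if isinstance(stats, str):
        if stats != "fit":
            raise ValueError("stats must be NormStats or 'fit'")
        stats = fit_norm_stats(ds)
    safe = np.where(stats.std > 1e-12, stats.std, 1.0)
    Xn = (ds.X - stats.mean) / safe
    Xn = np.where(stats.std > 1e-12, Xn, 0.0)
    out = WindowedDataset(
        Xn, ds.y, list(ds.class_names), ds.window_length, ds.step, dict(ds.metadata)
    )
    return out, stats


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------


def write_csv(streams: Sequence[SensorStream], path: str | Path) -> None:
    """Write streams in the columnar dialect: one row per (timestamp, sensor)."""
    frames = []
    for s in streams:
        df = pd.DataFrame(s.values, columns=list(CHANNEL_NAMES))
        df.insert(0, "timestamp", s.timestamps)
        df.insert(1, "sensor_id", s.sensor_id)
        df["label"] = s.labels
        frames.append(df)
    pd.concat(frames).sort_values(["timestamp", "sensor_id"]).to_csv(
        path, index=False
    )


def read_csv(path: str | Path) -> list[SensorStream]:
    """Read the columnar dialect back into one stream per sensor."""
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"CSV is missing columns: {sorted(missing)}")
    streams = []
    for sid, grp in df.groupby("sensor_id", sort=True):
        grp = grp.sort_values("timestamp")
        streams.append(
            SensorStream(
                sensor_id=int(sid),
                timestamps=grp["timestamp"].to_numpy(dtype=np.int64),
                values=grp[list(CHANNEL_NAMES)].to_numpy(dtype=float),
                labels=grp["label"].astype(str).to_numpy(),
            )
        )
    return streams


def dataset_to_streams(ds: WindowedDataset, gap: int = 2) -> list[SensorStream]:
    """Lay windows back out as per-sensor streams with timestamp gaps.

    Each window becomes its own contiguous run (consecutive runs are
    separated by a timestamp jump of ``gap``), so re-segmenting with
    ``T = window_length`` recovers exactly one window per original window.
    """
    if gap < 2:
        raise ValueError("gap must be >= 2 to break contiguity between windows")
    N, T, S, C = ds.X.shape
    ts = (np.arange(N)[:, None] * (T + gap - 1) + np.arange(T)[None, :]).ravel()
    names = np.asarray(ds.class_names)
    labels = np.repeat(names[ds.y], T)
    return [
        SensorStream(
            sensor_id=s + 1,
            timestamps=ts,
            values=ds.X[:, :, s, :].reshape(N * T, C).astype(float),
            labels=labels.copy(),
        )
        for s in range(S)
    ]
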