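"""Server-side data conditioning: axis remapping, decimation, min-max
normalization, moving-average filtering, and 2-s sliding-window assembly.

The chain runs in the fixed order remap -> downsample -> normalize ->
filter -> window.  Normalization maps each channel's nominal sensor
range onto [0, 1]; the moving average filters each channel causally over
its last ``M`` samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_imu import (ACCEL_RANGE_G, GYRO_RANGE_DPS, ActivityLabel,
                            FALL_LABEL, ImuTrace)


@dataclass(frozen=True)
class AxisMap:
    """Signed 3x3 permutation applied to both the acceleration and the
    gyro triplet, aligning a foreign dataset's axes with the waist-worn
    module's coordinate frame."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (3, 3):
            raise ValueError("axis map must be 3x3")
        if (not np.all(np.isin(m, (-1.0, 0.0, 1.0)))
                or np.any(np.sum(np.abs(m), axis=0) != 1)
                or np.any(np.sum(np.abs(m), axis=1) != 1)):
            raise ValueError("axis map must be a signed permutation matrix")

    @classmethod
    def identity(cls) -> "AxisMap":
        return cls(np.eye(3))

    def inverse(self) -> "AxisMap":
        return AxisMap(self.matrix.T)


def remap_axes(trace: ImuTrace, axis_map: AxisMap) -> ImuTrace:
    """Left-multiply every acceleration and gyro triplet by the map."""
    out = np.empty_like(trace.samples)
    out[:, :3] = trace.accel @ axis_map.matrix.T
    out[:, 3:] = trace.gyro @ axis_map.matrix.T
    return ImuTrace(rate=trace.rate, samples=out, segments=list(trace.segments))


def downsample(trace: ImuTrace, factor: int) -> ImuTrace:
    """Keep every ``factor``-th sample starting at index 0 (plain
    decimation, e.g. 200 Hz -> 100 Hz with factor 2); segment boundaries
    rescale by floor division."""
    if factor < 1:
        raise ValueError("downsample factor must be >= 1")
    if factor == 1:
        return trace
    samples = trace.samples[::factor]
    segments = []
    for start, end, lab in trace.segments:
        new_start = start // factor
        new_end = max(new_start + 1, -(-end // factor))
        segments.append((new_start, min(new_end, len(samples)), lab))
    return ImuTrace(rate=trace.rate / factor, samples=samples, segments=segments)


@dataclass(frozen=True)
class NormalizationSpec:
    """Per-channel (min, max) pairs; defaults are the nominal sensor
    ranges (+/-16 g, +/-2000 deg/s)."""

    ranges: tuple[tuple[float, float], ...] = (
        (-ACCEL_RANGE_G, ACCEL_RANGE_G),) * 3 + (
        (-GYRO_RANGE_DPS, GYRO_RANGE_DPS),) * 3

    def __post_init__(self) -> None:
        for lo, hi in self.ranges:
            if hi <= lo:
                raise ValueError(f"channel max must exceed min, got ({lo}, {hi})")

    @classmethod
    def from_observed(cls, data: np.ndarray) -> "NormalizationSpec":
        """Per-channel ranges from observed data (the alternative to the
        nominal sensor range when a dataset occupies a small fraction of
        it). ``data`` is (..., C); min/max are taken over all leading axes."""
        flat = np.asarray(data, dtype=float).reshape(-1, data.shape[-1])
        lo = flat.min(axis=0)
        hi = flat.max(axis=0)
        hi = np.where(hi > lo, hi, lo + 1.0)
        return cls(ranges=tuple((float(a), float(b)) for a, b in zip(lo, hi)))


def normalize(values: np.ndarray, spec: NormalizationSpec | None = None
              ) -> np.ndarray:
    """Min-max normalization y = (x - min) / (max - min) per channel.

    ``values`` is (N, C) with C matching the spec (or 1-D for a single
    channel using the first range).  In-range input maps into [0, 1].
    """
    spec = spec or NormalizationSpec()
    x = np.asarray(values, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    if x.shape[1] > len(spec.ranges):
        raise ValueError(
            f"{x.shape[1]} channels but spec defines {len(spec.ranges)}")
    lo = np.array([r[0] for r in spec.ranges[: x.shape[1]]])
    hi = np.array([r[1] for r in spec.ranges[: x.shape[1]]])
    y = (x - lo) / (hi - lo)
    return y[:, 0] if squeeze else y


def denormalize(values: np.ndarray, spec: NormalizationSpec | None = None
                ) -> np.ndarray:
    """Inverse of :func:`normalize`."""
    spec = spec or NormalizationSpec()
    y = np.asarray(values, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    lo = np.array([r[0] for r in spec.ranges[: y.shape[1]]])
    hi = np.array([r[1] for r in spec.ranges[: y.shape[1]]])
    x = y * (hi - lo) + lo
    return x[:, 0] if squeeze else x


@dataclass(frozen=True)
class FilterSpec:
    """Moving-average window size in samples (default 5 = 50 ms at
    100 Hz: smooths sensor noise without blunting the ~20 ms free-fall
    signature)."""

    window: int = 5

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("filter window must be >= 1")


def moving_average(signal: np.ndarray, spec: FilterSpec | None = None
                   ) -> np.ndarray:
    """Causal moving average: output[n] is the mean of the last M samples
    ending at n; the first M-1 outputs average over the shorter history
    that exists, so output length always equals input length."""
    spec = spec or FilterSpec()
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        return x.copy()
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    m = spec.window
    cs = np.cumsum(x, axis=0)
    out = np.empty_like(x)
    head = min(m - 1, len(x))
    out[:head] = cs[:head] / np.arange(1, head + 1)[:, None]
    if len(x) >= m:
        out[m - 1:] = (cs[m - 1:] - np.vstack([np.zeros((1, x.shape[1])),
                                               cs[:-m]])) / m
    return out[:, 0] if squeeze else out


@dataclass(frozen=True)
class WindowSpec:
    """2-s sliding window: 200 samples at 100 Hz, advancing by 100."""

    length: int = 200
    stride: int = 100
    rate: float = 100.0

    def __post_init__(self) -> None:
        if self.length < 1 or self.stride < 1 or self.rate <= 0:
            raise ValueError("window length, stride and rate must be positive")


def assemble_windows(stream: ImuTrace, spec: WindowSpec | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Cut a stream into (length x 6) windows advancing by ``stride``.

    Returns ``(windows, labels)`` with windows of shape (n, length, 6).
    Each window gets the majority per-sample label of its span; ties
    break toward the falling class, and unlabeled samples are ignored.
    A stream shorter than one window yields zero windows.
    """
    spec = spec or WindowSpec()
    n = len(stream)
    if n < spec.length:
        return (np.empty((0, spec.length, 6)), np.empty(0, dtype=int))
    count = (n - spec.length) // spec.stride + 1
    starts = np.arange(count) * spec.stride
    windows = np.stack([stream.samples[s:s + spec.length] for s in starts])
    sample_labels = stream.sample_labels()
    labels = np.empty(count, dtype=int)
    for k, s in enumerate(starts):
        seg = sample_labels[s:s + spec.length]
        seg = seg[seg >= 0]
        if seg.size == 0:
            labels[k] = -1
            continue
        counts = np.bincount(seg, minlength=len(ActivityLabel))
        best = counts.max()
        tied = np.flatnonzero(counts == best)
        labels[k] = int(FALL_LABEL) if int(FALL_LABEL) in tied else int(tied[0])
    return windows, labels


def preprocess_trace(trace: ImuTrace, axis_map: AxisMap | None = None,
                     downsample_factor: int = 1,
                     norm: NormalizationSpec | None = None,
                     filt: FilterSpec | None = None,
                     window: WindowSpec | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Full deterministic chain: remap -> downsample -> normalize ->
    moving-average filter -> sliding windows."""
    if axis_map is not None:
        trace = remap_axes(trace, axis_map)
    trace = downsample(trace, downsample_factor)
    conditioned = moving_average(normalize(trace.samples, norm), filt)
    staged = ImuTrace(rate=trace.rate, samples=conditioned,
                      segments=list(trace.segments))
    return assemble_windows(staged, window or WindowSpec(rate=trace.rate))


def normalize_windows(windows: np.ndarray, spec: NormalizationSpec | None = None
                      ) -> np.ndarray:
    """Apply per-channel min-max normalization to a (n, length, 6) stack."""
    spec = spec or NormalizationSpec()
    lo = np.array([r[0] for r in spec.ranges])
    hi = np.array([r[1] for r in spec.ranges])
    return (np.asarray(windows, dtype=float) - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# Adapters for SisFall/MobiFall-style delimited text files (interface only;
# raw integer counts are converted to physical units by scale factors).
# ---------------------------------------------------------------------------

def read_sisfall_txt(path: str | Path, rate: float = 200.0,
                     accel_scale: float = 32.0 / 8192.0,
                     gyro_scale: float = 4000.0 / 65536.0) -> ImuTrace:
    """Read a SisFall-style file: comma-separated integer counts, columns
    [accel1 x,y,z, gyro x,y,z, ...]; only the first six columns are used.
    Default scales convert ADXL345/ITG3200 counts to g and deg/s."""
    df = pd.read_csv(path, header=None, sep=r"[,;]\s*", engine="python")
    raw = df.iloc[:, :6].to_numpy(float)
    samples = np.column_stack([raw[:, :3] * accel_scale, raw[:, 3:6] * gyro_scale])
    samples[:, :3] = np.clip(samples[:, :3], -ACCEL_RANGE_G, ACCEL_RANGE_G)
    samples[:, 3:] = np.clip(samples[:, 3:], -GYRO_RANGE_DPS, GYRO_RANGE_DPS)
    return ImuTrace(rate=rate, samples=samples)


def read_mobifall_txt(path: str | Path, rate: float = 200.0) -> ImuTrace:
    """Read a MobiFall-style file: `timestamp,x,y,z` rows already in
    physical units (m/s^2 for the accelerometer file, rad/s for the
    gyro); this adapter expects a merged six-column file
    `timestamp,ax,ay,az,gx,gy,gz` and converts to g and deg/s."""
    df = pd.read_csv(path, header=None, comment="@")
    raw = df.iloc[:, 1:7].to_numpy(float)
    samples = np.column_stack([raw[:, :3] / 9.80665,
                               np.degrees(raw[:, 3:6])])
    samples[:, :3] = np.clip(samples[:, :3], -ACCEL_RANGE_G, ACCEL_RANGE_G)
    samples[:, 3:] = np.clip(samples[:, 3:], -GYRO_RANGE_DPS, GYRO_RANGE_DPS)
    return ImuTrace(rate=rate, samples=samples)


def save_windows(path: str | Path, windows: np.ndarray, labels: np.ndarray
                 ) -> None:
    """Persist a window stack with shape metadata (NumPy .npz container)."""
    np.savez(path, windows=np.asarray(windows), labels=np.asarray(labels),
             shape=np.asarray(windows).shape)


def load_windows(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    with np.load(path) as data:
        return data["windows"], data["labels"]
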