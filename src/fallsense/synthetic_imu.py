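"""Synthetic 6-axis IMU traces for the eight activity classes.

Generates labeled accelerometer + gyroscope streams with the kinematic
structure the interrupt engine and the FD-DNN classifier assume:

* periodic gait oscillations for walking / jogging / stair classes,
* flight-phase cycles for jumping (airborne intervals may legitimately
  satisfy the free-fall condition),
* smooth postural transients for standing up / sitting down,
* a four-phase fall profile: quasi-static stand, sub-threshold free fall,
  impact spike, post-impact rest.

Units follow the sensor convention throughout: accelerations in g
(clipped to the +/-16 g range of an MPU6050-class part), angular
velocities in deg/s (clipped to +/-2000 deg/s).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

ACCEL_RANGE_G = 16.0
GYRO_RANGE_DPS = 2000.0


class ActivityLabel(IntEnum):
    """The eight activity classes with their fixed integer encoding."""

    walking = 0
    jogging = 1
    jumping = 2
    going_upstairs = 3
    going_downstairs = 4
    standing_up = 5
    sitting_down = 6
    falling = 7


FALL_LABEL = ActivityLabel.falling


@dataclass(frozen=True)
class ImuTrace:
    """A timestamped 6-channel stream with activity-label segments.

    ``samples`` is an (N, 6) float array ordered (ax, ay, az, gx, gy, gz);
    ``segments`` is a list of half-open (start, end, label) index ranges.
    """

    rate: float
    samples: np.ndarray
    segments: list[tuple[int, int, ActivityLabel]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2 or samples.shape[1] != 6:
            raise ValueError(f"samples must be (N, 6), got {samples.shape}")
        object.__setattr__(self, "samples", samples)
        if np.any(np.abs(samples[:, :3]) > ACCEL_RANGE_G + 1e-9):
            raise ValueError(f"acceleration outside +/-{ACCEL_RANGE_G} g")
        if np.any(np.abs(samples[:, 3:]) > GYRO_RANGE_DPS + 1e-6):
            raise ValueError(f"angular velocity outside +/-{GYRO_RANGE_DPS} deg/s")
        prev_end = None
        for start, end, _ in self.segments:
            if not (0 <= start < end <= len(samples)):
                raise ValueError(f"segment ({start}, {end}) out of bounds")
            if prev_end is not None and start < prev_end:
                raise ValueError("segments overlap")
            prev_end = end

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def accel(self) -> np.ndarray:
        return self.samples[:, :3]

    @property
    def gyro(self) -> np.ndarray:
        return self.samples[:, 3:]

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate

    def sample_labels(self) -> np.ndarray:
        """Per-sample integer labels; -1 where no segment applies."""
        labels = np.full(len(self.samples), -1, dtype=int)
        for start, end, lab in self.segments:
            labels[start:end] = int(lab)
        return labels


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic-trace generator.

    Free-fall durations default to 100-400 ms so every generated fall
    comfortably exceeds the 20 ms minimum the free-fall interrupt
    requires; impact peaks default to 4-8 g, typical of waist-worn
    fall recordings.
    """

    rate: float = 100.0
    duration_s: float = 4.0
    free_fall_duration_s: tuple[float, float] = (0.1, 0.4)
    impact_peak_g: tuple[float, float] = (4.0, 8.0)
    accel_noise_std_g: float = 0.03
    gyro_noise_std_dps: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        lo, hi = self.free_fall_duration_s
        if not (0 < lo <= hi):
            raise ValueError("free-fall duration range must be positive")
        if lo < 0.02:
            raise ValueError(
                "free-fall duration must be >= 20 ms so falls trigger the interrupt"
            )
        lo_g, hi_g = self.impact_peak_g
        if not (0 < lo_g <= hi_g):
            raise ValueError("impact peak range must be positive")
        if self.accel_noise_std_g < 0 or self.gyro_noise_std_dps < 0:
            raise ValueError("noise standard deviations must be non-negative")


def _quiet_stand(t: np.ndarray) -> np.ndarray:
    """1 g on the vertical axis, nothing else."""
    sig = np.zeros((len(t), 6))
    sig[:, 2] = 1.0
    return sig


def _gait(t: np.ndarray, freq: float, vert_amp: float, horiz_amp: float,
          gyro_amp: float, gyro_bias_y: float, phase: float) -> np.ndarray:
    """Periodic locomotion template; vertical axis oscillates about 1 g."""
    sig = np.zeros((len(t), 6))
    w = 2 * np.pi * freq
    sig[:, 0] = horiz_amp * np.sin(w * t + phase)
    sig[:, 1] = 0.6 * horiz_amp * np.sin(0.5 * w * t + 1.3 * phase)
    sig[:, 2] = 1.0 + vert_amp * np.sin(w * t + 0.5 + phase)
    sig[:, 3] = gyro_amp * np.sin(0.5 * w * t + phase)
    sig[:, 4] = gyro_bias_y + 0.8 * gyro_amp * np.sin(w * t + 2.0 + phase)
    sig[:, 5] = 0.4 * gyro_amp * np.sin(w * t + 4.0 + phase)
    return sig


def _jogging(t: np.ndarray, phase: float) -> np.ndarray:
    # Rectified vertical profile: sharp upward ground-contact peaks, dips
    # that stay well above the free-fall threshold.
    sig = np.zeros((len(t), 6))
    w = 2 * np.pi * 2.8
    s = 0.5 + 0.5 * np.sin(w * t + phase)
    sig[:, 0] = 0.35 * np.sin(w * t + 1.1 + phase)
    sig[:, 1] = 0.25 * np.sin(0.5 * w * t + phase)
    sig[:, 2] = 0.82 + 1.1 * s**2
    sig[:, 3] = 60.0 * np.sin(0.5 * w * t + phase)
    sig[:, 4] = 45.0 * np.sin(w * t + 0.7 + phase)
    sig[:, 5] = 25.0 * np.sin(w * t + 2.4 + phase)
    return sig


def _jumping(t: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Jump cycles with genuine airborne (sub-0.563 g) flight intervals."""
    sig = _quiet_stand(t)
    n = len(t)
    period = rng.uniform(0.7, 0.9)
    start = rng.uniform(0.1, 0.3)
    while start + 0.25 < t[-1]:
        i0 = int(start * rate)
        flight = int(rng.uniform(0.12, 0.18) * rate)
        land = max(2, int(0.03 * rate))
        i1 = min(i0 + flight, n)
        sig[i0:i1, :3] = [0.05, 0.05, 0.12]
        j1 = min(i1 + land, n)
        if j1 > i1:
            bump = 1.0 + 1.8 * np.hanning(2 * (j1 - i1))[: j1 - i1]
            sig[i1:j1, 2] = bump
        sig[i0:j1, 4] += 80.0
        start += period
    sig[:, 3] += 20.0 * np.sin(2 * np.pi * 1.3 * t)
    return sig


def _postural(t: np.ndarray, rate: float, rng: np.random.Generator,
              direction: int) -> np.ndarray:
    """Sit-to-stand (+1) or stand-to-sit (-1) transient in a quiet trace."""
    sig = _quiet_stand(t)
    n = len(t)
    center = rng.uniform(0.45, 0.55) * t[-1]
    width = 1.2
    i0 = max(0, int((center - width / 2) * rate))
    i1 = min(n, int((center + width / 2) * rate))
    k = i1 - i0
    if k > 0:
        lobe = np.hanning(k)
        # vertical dip-then-overshoot, mirrored between the two
        # transitions; amplitudes keep the vertical axis well above the
        # 0.563 g free-fall threshold in both directions
        half = k // 2
        shape = np.zeros(k)
        shape[:half] = -0.25 * np.hanning(2 * half)[:half]
        shape[half:] = 0.30 * np.hanning(2 * (k - half))[: k - half]
        sig[i0:i1, 2] = 1.0 + direction * shape
        sig[i0:i1, 4] = direction * 70.0 * lobe
        sig[i0:i1, 3] = -direction * 25.0 * lobe
        if direction < 0 and i1 + 5 < n:
            # seat-contact bump at the end of sitting down
            sig[i1:i1 + 5, 2] += 0.4 * np.hanning(10)[:5]
    return sig


def _falling(t: np.ndarray, rate: float, rng: np.random.Generator,
             config: GeneratorConfig) -> np.ndarray:
    """Quasi-static stand -> free fall -> impact -> near-zero rest.

    The rest phase reads near zero on all axes, emulating the
    gravity-suppressed view the zero-motion detector responds to, so the
    sustained all-axes-below-0.5 g condition can fire after the impact.
    """
    sig = _quiet_stand(t)
    n = len(t)
    pre = rng.uniform(0.6, 0.9)
    ff_dur = rng.uniform(*config.free_fall_duration_s)
    peak = rng.uniform(*config.impact_peak_g)
    i0 = int(pre * rate)
    i1 = min(n, i0 + max(int(np.ceil(ff_dur * rate)), 3))
    sig[i0:i1, :3] = [0.03, 0.03, 0.05]
    sig[i0:i1, 4] = 150.0 * np.hanning(max(i1 - i0, 1))
    imp = max(3, int(0.05 * rate))
    j1 = min(n, i1 + imp)
    if j1 > i1:
        spike = peak * np.hanning(2 * (j1 - i1))[: j1 - i1]
        sig[i1:j1, 2] = np.maximum(spike, 0.2)
        sig[i1:j1, 0] = 0.3 * spike
        sig[i1:j1, 4] = 200.0 * np.hanning(2 * (j1 - i1))[: j1 - i1]
    sig[j1:, :3] = [0.05, 0.08, 0.10]
    sig[j1:, 3:] = 0.0
    return sig


def generate_trace(activity: ActivityLabel, config: GeneratorConfig | None = None,
                   seed: int | None = None) -> ImuTrace:
    """Generate one labeled trace of ``config.duration_s`` seconds.

    Identical ``(activity, config, seed)`` always reproduces the identical
    trace. ``seed`` overrides ``config.seed`` when given.
    """
    config = config or GeneratorConfig()
    activity = ActivityLabel(activity)
    use_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(use_seed)
    n = int(round(config.duration_s * config.rate))
    t = np.arange(n) / config.rate
    phase = rng.uniform(0, 2 * np.pi)

    if activity == ActivityLabel.walking:
        sig = _gait(t, 2.0, 0.18, 0.10, 25.0, 0.0, phase)
    elif activity == ActivityLabel.jogging:
        sig = _jogging(t, phase)
    elif activity == ActivityLabel.jumping:
        sig = _jumping(t, config.rate, rng)
    elif activity == ActivityLabel.going_upstairs:
        sig = _gait(t, 1.5, 0.22, 0.14, 35.0, 18.0, phase)
    elif activity == ActivityLabel.going_downstairs:
        sig = _gait(t, 1.9, 0.28, 0.18, 45.0, -18.0, phase)
    elif activity == ActivityLabel.standing_up:
        sig = _postural(t, config.rate, rng, direction=+1)
    elif activity == ActivityLabel.sitting_down:
        sig = _postural(t, config.rate, rng, direction=-1)
    else:
        sig = _falling(t, config.rate, rng, config)

    sig[:, :3] += rng.normal(0.0, config.accel_noise_std_g, (n, 3))
    sig[:, 3:] += rng.normal(0.0, config.gyro_noise_std_dps, (n, 3))
    np.clip(sig[:, :3], -ACCEL_RANGE_G, ACCEL_RANGE_G, out=sig[:, :3])
    np.clip(sig[:, 3:], -GYRO_RANGE_DPS, GYRO_RANGE_DPS, out=sig[:, 3:])
    return ImuTrace(rate=config.rate, samples=sig,
                    segments=[(0, n, activity)])


@dataclass(frozen=True)
class WindowDataset:
    """Balanced labeled windows with train/validation/test index splits."""

    windows: np.ndarray      # (N, length, 6)
    labels: np.ndarray       # (N,) integer ActivityLabel codes
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray

    def split(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        idx = {"train": self.train_idx, "val": self.val_idx,
               "test": self.test_idx}[name]
        return self.windows[idx], self.labels[idx]


def generate_dataset(config: GeneratorConfig | None = None, per_class: int = 10,
                     window_spec=None, seed: int | None = None,
                     split: tuple[float, float, float] = (0.7, 0.1, 0.2),
                     ) -> WindowDataset:
    """Build a balanced windowed dataset: ``per_class`` windows per activity.

    Traces are generated per activity from seeds derived deterministically
    from ``seed``, then cut into sliding windows; the first
    ``round(per_class * split)`` windows of each class fall into the
    train/validation/test partitions in that order.
    """
    from .preprocess import WindowSpec, assemble_windows  # circular-safe

    if per_class < 1:
        raise ValueError("per_class must be >= 1")
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    config = config or GeneratorConfig()
    window_spec = window_spec or WindowSpec(rate=config.rate)
    n_trace = int(round(config.duration_s * config.rate))
    if window_spec.length > n_trace:
        raise ValueError(
            f"window length {window_spec.length} exceeds trace length {n_trace}")
    per_trace = (n_trace - window_spec.length) // window_spec.stride + 1

    use_seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(use_seed)
    child_seeds = ss.generate_state(8 * ((per_class + per_trace - 1) // per_trace))

    all_windows, all_labels = [], []
    n_traces_per_class = (per_class + per_trace - 1) // per_trace
    k = 0
    for activity in ActivityLabel:
        wins: list[np.ndarray] = []
        for _ in range(n_traces_per_class):
            trace = generate_trace(activity, config, int(child_seeds[k] % (2**31)))
            k += 1
            w, lab = assemble_windows(trace, window_spec)
            wins.extend(w)
        all_windows.append(np.stack(wins[:per_class]))
        all_labels.append(np.full(per_class, int(activity)))

    windows = np.concatenate(all_windows)
    labels = np.concatenate(all_labels)

    n_tr = int(round(split[0] * per_class))
    n_va = int(round(split[1] * per_class))
    n_te = per_class - n_tr - n_va
    if n_te < 0:
        raise ValueError("split fractions leave no test data")
    tr, va, te = [], [], []
    for c in range(len(ActivityLabel)):
        base = c * per_class
        tr.extend(range(base, base + n_tr))
        va.extend(range(base + n_tr, base + n_tr + n_va))
        te.extend(range(base + n_tr + n_va, base + per_class))
    return WindowDataset(windows=windows, labels=labels,
                         train_idx=np.array(tr), val_idx=np.array(va),
                         test_idx=np.array(te))


# ---------------------------------------------------------------------------
# CSV trace format: header t,ax,ay,az,gx,gy,gz,label
# ---------------------------------------------------------------------------

def write_trace_csv(trace: ImuTrace, path: str | Path | io.TextIOBase) -> None:
    """Write a trace to CSV (t in seconds; label column from segments)."""
    t = np.arange(len(trace)) / trace.rate
    labels = trace.sample_labels()
    names = np.where(labels >= 0,
                     [ActivityLabel(l).name if l >= 0 else "" for l in labels], "")
    df = pd.DataFrame({
        "t": t,
        "ax": trace.samples[:, 0], "ay": trace.samples[:, 1],
        "az": trace.samples[:, 2], "gx": trace.samples[:, 3],
        "gy": trace.samples[:, 4], "gz": trace.samples[:, 5],
        "label": names,
    })
    df.to_csv(path, index=False, float_format="%.9g")


def read_trace_csv(path: str | Path | io.TextIOBase) -> ImuTrace:
    """Read a trace written by :func:`write_trace_csv`; rebuilds segments
    from runs of identical labels and infers the rate from the time axis."""
    df = pd.read_csv(path, keep_default_na=False)
    required = ["t", "ax", "ay", "az", "gx", "gy", "gz", "label"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"trace CSV missing columns: {missing}")
    t = df["t"].to_numpy(float)
    if len(t) < 2:
        rate = 100.0
    else:
        rate = 1.0 / float(np.median(np.diff(t)))
    samples = df[["ax", "ay", "az", "gx", "gy", "gz"]].to_numpy(float)
    segments: list[tuple[int, int, ActivityLabel]] = []
    labels = df["label"].astype(str).to_numpy()
    start = None
    for i, name in enumerate(labels):
        if name:
            if start is None:
                start, current = i, name
            elif name != current:
                segments.append((start, i, ActivityLabel[current]))
                start, current = i, name
        elif start is not None:
            segments.append((start, i, ActivityLabel[current]))
            start = None
    if start is not None:
        segments.append((start, len(labels), ActivityLabel[current]))
    return ImuTrace(rate=rate, samples=samples, segments=segments)
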