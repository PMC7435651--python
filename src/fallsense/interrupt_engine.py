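"""Sample-accurate simulation of MPU6050-style interrupts and the F0/F1
transmission state machine.

The sensing module buffers every sample into a fixed FIFO while the
radio sleeps.  Three accelerometer-only interrupt sources are modeled:

* **free fall** — all three axes below ``FF_THR`` (0.563 g) sustained for
  ``FF_DUR`` (20 ms).  The threshold sits just below 1/sqrt(3) g, the
  worst-case largest axis component of static gravity, so no resting
  orientation can fire it.
* **motion** — any axis above ``MOT_THR`` sustained for ``MOT_DUR``.
* **zero motion** — all axes below ``ZRMOT_THR`` (0.5 g) sustained for
  ``ZRMOT_DUR`` (1000 ms), used to return the module to sleep.

A free-fall or motion interrupt wakes the MCU, flushes the FIFO to the
radio and keeps streaming (one flush per FIFO fill) until zero motion
fires.  Gyroscope channels never participate in interrupt conditions.

Durations are converted to ``ceil(duration * rate)`` consecutive
qualifying samples, and an event fires at the sample completing its
duration.  After firing, an interrupt re-arms only once its condition has
been broken for at least one sample (latch semantics).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np

from .synthetic_imu import ImuTrace


class InterruptKind(str, Enum):
    free_fall = "free_fall"
    motion = "motion"
    zero_motion = "zero_motion"
    fifo_full = "fifo_full"


@dataclass(frozen=True)
class InterruptConfig:
    """Register-level thresholds and FIFO geometry.

    ``MOT_THR``/``MOT_DUR`` have no published reference values; the
    defaults (2.0 g, 20 ms) exceed static gravity and mirror the
    free-fall duration.
    """

    ff_thr_g: float = 0.563
    ff_dur_ms: float = 20.0
    mot_thr_g: float = 2.0
    mot_dur_ms: float = 20.0
    zrmot_thr_g: float = 0.5
    zrmot_dur_ms: float = 1000.0
    fifo_cnt_bytes: int = 600
    rate: float = 100.0
    channels: int = 6
    bits_per_value: int = 16
    zero_motion_gravity_compensated: bool = False

    def __post_init__(self) -> None:
        for name in ("ff_thr_g", "mot_thr_g", "zrmot_thr_g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        period_ms = 1000.0 / self.rate
        for name in ("ff_dur_ms", "mot_dur_ms", "zrmot_dur_ms"):
            if getattr(self, name) < period_ms:
                raise ValueError(f"{name} shorter than one sample period")
        bytes_per_set = self.channels * self.bits_per_value // 8
        if self.fifo_cnt_bytes % bytes_per_set != 0:
            raise ValueError(
                f"FIFO_CNT ({self.fifo_cnt_bytes} B) must be divisible by the "
                f"{bytes_per_set} B sample-set size")

    @property
    def fifo_capacity_samples(self) -> int:
        """Sample sets the FIFO holds (600 B / 12 B = 50 at defaults)."""
        return self.fifo_cnt_bytes // (self.channels * self.bits_per_value // 8)

    def duration_samples(self, dur_ms: float) -> int:
        """Consecutive qualifying samples a duration register demands."""
        return max(1, math.ceil(dur_ms / 1000.0 * self.rate))


@dataclass(frozen=True)
class InterruptEvent:
    kind: InterruptKind
    sample_index: int

    def time_s(self, rate: float) -> float:
        return self.sample_index / rate


@dataclass
class TransmissionLog:
    """What the radio sent and when the MCU was awake."""

    ranges: list[tuple[int, int]] = field(default_factory=list)
    events: list[InterruptEvent] = field(default_factory=list)
    buffered_samples: int = 0
    radio_on_samples: int = 0
    mcu_awake_samples: int = 0

    def add_range(self, start: int, end: int) -> None:
        if end <= start:
            return
        if self.ranges and self.ranges[-1][1] > start:
            raise ValueError("transmitted ranges must not overlap")
        if self.ranges and self.ranges[-1][1] == start:
            self.ranges[-1] = (self.ranges[-1][0], end)
        else:
            self.ranges.append((start, end))
        self.radio_on_samples += end - start

    def transmitted_mask(self, n: int) -> np.ndarray:
        mask = np.zeros(n, dtype=bool)
        for s, e in self.ranges:
            mask[s:e] = True
        return mask

    def to_json(self, trace_length: int | None = None) -> str:
        payload = {
            "ranges": [list(r) for r in self.ranges],
            "radio_on_samples": self.radio_on_samples,
        }
        if trace_length:
            payload["duty_cycle"] = duty_cycle(self, trace_length)
        return json.dumps(payload)


def _axis_conditions(trace: ImuTrace, config: InterruptConfig
                     ) -> dict[InterruptKind, np.ndarray]:
    """Per-sample boolean condition arrays for the three interrupt sources."""
    a = np.abs(trace.accel)
    ff = np.all(a < config.ff_thr_g, axis=1)
    mot = np.any(a > config.mot_thr_g, axis=1)
    if config.zero_motion_gravity_compensated:
        # deviation of the acceleration magnitude from 1 g, so a resting
        # body (one axis near 1 g) can still reach the sleep state
        zr = np.abs(np.linalg.norm(trace.accel, axis=1) - 1.0) < config.zrmot_thr_g
    else:
        zr = np.all(a < config.zrmot_thr_g, axis=1)
    return {InterruptKind.free_fall: ff, InterruptKind.motion: mot,
            InterruptKind.zero_motion: zr}


def _scan_condition(cond: np.ndarray, dur_samples: int) -> list[int]:
    """Indices where ``cond`` first completes ``dur_samples`` consecutive
    True samples; the run must break before the same source fires again."""
    events = []
    run = 0
    fired = False
    for i, c in enumerate(cond):
        if c:
            run += 1
            if run >= dur_samples and not fired:
                events.append(i)
                fired = True
        else:
            run = 0
            fired = False
    return events


def scan_interrupts(trace: ImuTrace, config: InterruptConfig | None = None
                    ) -> list[InterruptEvent]:
    """All free-fall / motion / zero-motion events of a trace, in sample
    order (free fall first on ties). The FSM's enable/disable gating is
    *not* applied here; see :func:`run_fsm`."""
    config = config or InterruptConfig()
    if abs(trace.rate - config.rate) > 1e-9:
        raise ValueError(
            f"trace rate {trace.rate} Hz != config rate {config.rate} Hz")
    if len(trace) == 0:
        return []
    conds = _axis_conditions(trace, config)
    durations = {
        InterruptKind.free_fall: config.duration_samples(config.ff_dur_ms),
        InterruptKind.motion: config.duration_samples(config.mot_dur_ms),
        InterruptKind.zero_motion: config.duration_samples(config.zrmot_dur_ms),
    }
    order = [InterruptKind.free_fall, InterruptKind.motion,
             InterruptKind.zero_motion]
    events = [InterruptEvent(kind, i)
              for kind in order
              for i in _scan_condition(conds[kind], durations[kind])]
    events.sort(key=lambda e: (e.sample_index, order.index(e.kind)))
    return events


def run_fsm(trace: ImuTrace, config: InterruptConfig | None = None
            ) -> TransmissionLog:
    """Step the F0/F1 state machine over a trace, one sample at a time.

    F0 configures the registers (free-fall, motion and FIFO interrupts
    enabled; zero motion disabled) and immediately enters F1, where
    samples stream into the FIFO with oldest-overwritten semantics.  A
    free-fall or motion event flushes the FIFO to the radio, enables the
    zero-motion interrupt and starts transmission mode: every FIFO fill
    is flushed until zero motion fires, which returns the machine to F0.
    """
    config = config or InterruptConfig()
    if abs(trace.rate - config.rate) > 1e-9:
        raise ValueError(
            f"trace rate {trace.rate} Hz != config rate {config.rate} Hz")
    log = TransmissionLog()
    n = len(trace)
    if n == 0:
        return log
    conds = _axis_conditions(trace, config)
    dur = {k: config.duration_samples(ms) for k, ms in (
        (InterruptKind.free_fall, config.ff_dur_ms),
        (InterruptKind.motion, config.mot_dur_ms),
        (InterruptKind.zero_motion, config.zrmot_dur_ms))}
    capacity = config.fifo_capacity_samples

    run = {k: 0 for k in dur}
    fired = {k: False for k in dur}
    transmitting = False          # True between a wake event and zero motion
    buf_start = 0                 # first trace index still in the FIFO

    for i in range(n):
        # --- buffer the sample (FIFO principle: overwrite the oldest) ---
        log.buffered_samples += 1
        if i + 1 - buf_start > capacity:
            buf_start = i + 1 - capacity

        # --- update interrupt run counters / latches ---
        pending: list[InterruptKind] = []
        for kind in (InterruptKind.free_fall, InterruptKind.motion,
                     InterruptKind.zero_motion):
            enabled = transmitting if kind == InterruptKind.zero_motion else True
            if conds[kind][i]:
                run[kind] += 1
                if enabled and run[kind] >= dur[kind] and not fired[kind]:
                    pending.append(kind)
                    fired[kind] = True
            else:
                run[kind] = 0
                fired[kind] = False

        for kind in pending:
            log.events.append(InterruptEvent(kind, i))
            if kind in (InterruptKind.free_fall, InterruptKind.motion):
                # wake: flush the FIFO (0.5 s of pre-trigger context)
                log.add_range(buf_start, i + 1)
                buf_start = i + 1
                transmitting = True
            elif kind == InterruptKind.zero_motion and transmitting:
                # back to F0: radio off, zero motion disabled again
                transmitting = False

        if transmitting:
            log.mcu_awake_samples += 1
            if i + 1 - buf_start >= capacity:
                log.events.append(InterruptEvent(InterruptKind.fifo_full, i))
                log.add_range(buf_start, i + 1)
                buf_start = i + 1
    return log


def fifo_span_seconds(capacity_bytes: int, rate: float, channels: int = 6,
                      bits_per_value: int = 16) -> float:
    """Seconds of data a FIFO of ``capacity_bytes`` holds.

    600 bytes at 100 Hz x 6 channels x 16 bit spans exactly 0.5 s.
    """
    if capacity_bytes < 0 or rate <= 0 or channels <= 0 or bits_per_value <= 0:
        raise ValueError("all arguments must be positive (capacity may be 0)")
    bytes_per_set = channels * bits_per_value / 8
    if capacity_bytes % int(bytes_per_set) != 0:
        import warnings
        warnings.warn("FIFO capacity not a whole number of sample sets; "
                      "returning a fractional span", stacklevel=2)
    return capacity_bytes / (rate * bytes_per_set)


def min_max_gravity_component() -> float:
    """Worst-case largest axis reading of static 1 g gravity.

    Minimized over orientations, the largest absolute component of a unit
    gravity vector is 1/sqrt(3) ~ 0.57735 g, attained when gravity makes
    equal angles with all three axes.  The free-fall threshold must sit
    below this value or some resting orientation would permanently
    satisfy the free-fall condition.
    """
    return 1.0 / math.sqrt(3.0)


def duty_cycle(log: TransmissionLog, trace_length: int) -> float:
    """Fraction of samples the radio was on; the energy-consumption proxy."""
    if trace_length <= 0:
        raise ValueError("trace_length must be positive")
    return log.radio_on_samples / trace_length


def events_to_jsonl(events: Iterable[InterruptEvent], rate: float,
                    path: str | Path | None = None) -> str:
    """One JSON object per event: {kind, sample_index, time_s}."""
    lines = [json.dumps({"kind": e.kind.value, "sample_index": e.sample_index,
                         "time_s": e.sample_index / rate}) for e in events]
    text = "\n".join(lines) + ("\n" if lines else "")
    if path is not None:
        Path(path).write_text(text)
    return text
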