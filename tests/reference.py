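"""Independent brute-force reference implementations used as oracles.

These re-derive the interrupt and FSM semantics with plain Python loops
and explicit buffers, sharing no code with the package internals.
"""

from __future__ import annotations

import math

import numpy as np

from fallsense.synthetic_imu import ImuTrace
from fallsense.interrupt_engine import InterruptConfig


def _dur_samples(dur_ms: float, rate: float) -> int:
    return max(1, math.ceil(dur_ms / 1000.0 * rate))


def oracle_scan(trace: ImuTrace, config: InterruptConfig) -> list[tuple[str, int]]:
    """Per-sample scan of the three interrupt conditions.

    An event fires at the sample completing the required consecutive run
    and cannot re-fire until the condition breaks for >= 1 sample.
    Returns (kind, index) tuples sorted by index with free-fall first on
    ties, motion second, zero motion third.
    """
    accel = [tuple(row) for row in trace.accel]
    sources = [
        ("free_fall",
         lambda a: all(abs(v) < config.ff_thr_g for v in a),
         _dur_samples(config.ff_dur_ms, config.rate)),
        ("motion",
         lambda a: any(abs(v) > config.mot_thr_g for v in a),
         _dur_samples(config.mot_dur_ms, config.rate)),
        ("zero_motion",
         lambda a: all(abs(v) < config.zrmot_thr_g for v in a),
         _dur_samples(config.zrmot_dur_ms, config.rate)),
    ]
    priority = {"free_fall": 0, "motion": 1, "zero_motion": 2}
    events: list[tuple[str, int]] = []
    for kind, cond, dur in sources:
        run = 0
        latched = False
        for i, a in enumerate(accel):
            if cond(a):
                run += 1
                if run >= dur and not latched:
                    events.append((kind, i))
                    latched = True
            else:
                run = 0
                latched = False
    events.sort(key=lambda e: (e[1], priority[e[0]]))
    return events


def oracle_fsm(trace: ImuTrace, config: InterruptConfig):
    """Event-driven reference simulation of the transmission state
    machine, stepping one sample at a time with an explicit FIFO list.

    Returns (transmitted_indices, events, radio_on) where events are
    (kind, index) tuples including fifo_full flushes while transmitting.
    """
    accel = [tuple(row) for row in trace.accel]
    capacity = config.fifo_cnt_bytes // (config.channels
                                         * config.bits_per_value // 8)
    conds = {
        "free_fall": lambda a: all(abs(v) < config.ff_thr_g for v in a),
        "motion": lambda a: any(abs(v) > config.mot_thr_g for v in a),
        "zero_motion": lambda a: all(abs(v) < config.zrmot_thr_g for v in a),
    }
    dur = {
        "free_fall": _dur_samples(config.ff_dur_ms, config.rate),
        "motion": _dur_samples(config.mot_dur_ms, config.rate),
        "zero_motion": _dur_samples(config.zrmot_dur_ms, config.rate),
    }
    run = dict.fromkeys(conds, 0)
    latched = dict.fromkeys(conds, False)

    fifo: list[int] = []
    transmitted: list[int] = []
    events: list[tuple[str, int]] = []
    transmitting = False

    for i, a in enumerate(accel):
        fifo.append(i)
        if len(fifo) > capacity:
            fifo.pop(0)  # FIFO principle: oldest sample is overwritten
        for kind in ("free_fall", "motion", "zero_motion"):
            enabled = transmitting if kind == "zero_motion" else True
            if conds[kind](a):
                run[kind] += 1
                if enabled and run[kind] >= dur[kind] and not latched[kind]:
                    latched[kind] = True
                    events.append((kind, i))
                    if kind in ("free_fall", "motion"):
                        transmitted.extend(fifo)
                        fifo.clear()
                        transmitting = True
                    else:
                        transmitting = False
            else:
                run[kind] = 0
                latched[kind] = False
        if transmitting and len(fifo) >= capacity:
            events.append(("fifo_full", i))
            transmitted.extend(fifo)
            fifo.clear()
    return transmitted, events, len(transmitted)


def random_trace(seed: int, n: int = 300, rate: float = 100.0) -> ImuTrace:
    """Piecewise-constant random trace straddling every threshold,
    including the 0.5/0.563 g boundary, plus per-sample noise."""
    rng = np.random.default_rng(seed)
    levels = np.array([-2.5, -1.0, -0.52, -0.3, 0.0, 0.3, 0.52, 1.0, 2.5])
    accel = np.empty((n, 3))
    i = 0
    while i < n:
        u = rng.random()
        if u < 0.2:
            length = rng.integers(110, 220)   # long quiet block
            block = rng.uniform(-0.25, 0.25, 3)
        elif u < 0.35:
            length = rng.integers(60, 150)    # standing block
            block = np.array([0.0, 0.0, 1.0])
        else:
            length = rng.integers(1, 80)
            block = rng.choice(levels, 3)
        j = min(n, i + int(length))
        accel[i:j] = block + rng.normal(0, 0.05, (j - i, 3))
        i = j
    gyro = rng.uniform(-500, 500, (n, 3))     # must not affect interrupts
    return ImuTrace(rate=rate, samples=np.clip(
        np.column_stack([accel, gyro]),
        [-16, -16, -16, -2000, -2000, -2000],
        [16, 16, 16, 2000, 2000, 2000]))
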