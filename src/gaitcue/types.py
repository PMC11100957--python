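"""Core domain types for the foot-IMU FoG detection and cueing pipeline.

All public quantities use a single unit convention: times in seconds on one
session clock starting at 0, accelerations in m/s², angular rates in °/s,
angles in degrees.  The inertial stream emulates a foot-mounted 6-axis MEMS
sensor (±16 g, ±2000 °/s, 200 Hz).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: standard gravity, m/s²
G = 9.80665

MOTION_SOURCES = ("detected", "annotated")
LEGS = ("left", "right")
CLASS_LABELS = ("none", "normal", "fog")
FOG_SUBTYPES = ("shuffling", "festination", "trembling", "akinesia")
TRIGGERS = ("on_demand", "rhythmic")


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants (CLI exit code 2)."""


@dataclass
class StreamMeta:
    sample_rate_hz: float = 200.0
    acc_range_g: float = 16.0
    gyr_range_dps: float = 2000.0
    sensor_id: str = "sim-000"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StreamMeta":
        return cls(**{k: d[k] for k in ("sample_rate_hz", "acc_range_g", "gyr_range_dps", "sensor_id") if k in d})


@dataclass
class ImuStream:
    """Timestamped 6-axis inertial samples a(t), ω(t) in the sensor frame."""

    t: np.ndarray            # (n,) seconds, strictly increasing
    acc: np.ndarray          # (n, 3) m/s²
    gyr: np.ndarray          # (n, 3) °/s
    meta: StreamMeta = field(default_factory=StreamMeta)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyr = np.asarray(self.gyr, dtype=float)

    @property
    def n(self) -> int:
        return int(self.t.shape[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.n else 0.0

    def validate(self) -> "ImuStream":
        if self.t.ndim != 1 or self.acc.shape != (self.n, 3) or self.gyr.shape != (self.n, 3):
            raise ValidationError("stream arrays must be t:(n,), acc:(n,3), gyr:(n,3)")
        if self.n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValidationError("timestamps must be strictly increasing")
            nominal = 1.0 / self.meta.sample_rate_hz
            if abs(float(np.median(dt)) - nominal) > 0.01 * nominal:
                raise ValidationError("median sample interval deviates >1% from nominal rate")
        acc_lim = self.meta.acc_range_g * G
        if self.n and np.max(np.abs(self.acc)) > acc_lim:
            raise ValidationError(f"acceleration exceeds ±{self.meta.acc_range_g} g range")
        if self.n and np.max(np.abs(self.gyr)) > self.meta.gyr_range_dps:
            raise ValidationError(f"angular rate exceeds ±{self.meta.gyr_range_dps} °/s range")
        return self


@dataclass
class MotionPhase:
    """A foot motion interval (swing-phase proxy, toe-off to heel strike)."""

    start: float
    end: float
    source: str = "detected"
    leg: str = "left"
    class_label: str = "none"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(f"motion phase end {self.end} must exceed start {self.start}")
        if self.source not in MOTION_SOURCES:
            raise ValidationError(f"unknown source {self.source!r}")
        if self.leg not in LEGS:
            raise ValidationError(f"unknown leg {self.leg!r}")
        if self.class_label not in CLASS_LABELS:
            raise ValidationError(f"unknown class label {self.class_label!r}")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def to_dict(self) -> dict:
        return {"start": self.start, "end": self.end, "source": self.source,
                "leg": self.leg, "class_label": self.class_label}

    @classmethod
    def from_dict(cls, d: dict) -> "MotionPhase":
        return cls(start=d["start"], end=d["end"], source=d.get("source", "detected"),
                   leg=d.get("leg", "left"), class_label=d.get("class_label", "none"))


@dataclass
class FogEpisode:
    """An expert-style FoG episode interval with its clinical subtype."""

    start: float
    end: float
    subtype: str = "shuffling"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError("episode end must exceed start")
        if self.subtype not in FOG_SUBTYPES:
            raise ValidationError(f"unknown FoG subtype {self.subtype!r}")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def to_dict(self) -> dict:
        return {"start": self.start, "end": self.end, "subtype": self.subtype}

    @classmethod
    def from_dict(cls, d: dict) -> "FogEpisode":
        return cls(start=d["start"], end=d["end"], subtype=d.get("subtype", "shuffling"))


def check_non_overlapping(intervals: Sequence, what: str = "intervals") -> None:
    """Validate that the (start, end) items are time-ordered and disjoint."""
    items = sorted(intervals, key=lambda p: p.start)
    for a, b in zip(items, items[1:]):
        if b.start < a.end:
            raise ValidationError(f"overlapping {what}: ({a.start}, {a.end}) and ({b.start}, {b.end})")


@dataclass
class CueingConfig:
    """Parameters of on-demand gait-synchronous cueing.

    t_agsc_on : presumed FoG-episode duration after a FoG-classified phase, s
    t_off     : minimum pause between pulse trains, s
    t_min     : minimum pulse-train duration, s
    t_max     : maximum pulse-train duration, s
    event_latency : sensor→stimulator event transport delay, s (0 disables)
    cue_triggering_phase : cue the interval-opening FoG phase at its
        classification instant (its end) for t_min
    """

    t_agsc_on: float = 5.0
    t_off: float = 0.1
    t_min: float = 0.2
    t_max: float = 0.8
    event_latency: float = 0.0075
    cue_triggering_phase: bool = True

    def __post_init__(self) -> None:
        if min(self.t_agsc_on, self.t_off, self.t_min, self.t_max) <= 0:
            raise ValidationError("cueing times must be positive")
        if self.event_latency < 0:
            raise ValidationError("event latency must be >= 0")
        if self.t_min > self.t_max:
            raise ValidationError("t_min must not exceed t_max")
        if self.t_off >= self.t_agsc_on:
            raise ValidationError("t_off must be smaller than t_agsc_on")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CueingConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class StimulationParams:
    """Electrical pulse-train content (metadata only, no waveform synthesis)."""

    channel: int = 1
    amplitude_ma: float = 12.0     # sensory-level default
    pulse_width_us: float = 300.0
    frequency_hz: float = 35.0

    def __post_init__(self) -> None:
        if not 1 <= int(self.channel) <= 5:
            raise ValidationError("channel must be in 1..5")
        if not 0 < self.amplitude_ma <= 100:
            raise ValidationError("amplitude must be in (0, 100] mA")
        if not 30 <= self.pulse_width_us <= 1000:
            raise ValidationError("pulse width must be in [30, 1000] µs")
        if not 1 <= self.frequency_hz <= 100:
            raise ValidationError("frequency must be in [1, 100] Hz")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StimulationParams":
        return cls(**d)


@dataclass
class PulseTrain:
    """A bounded stimulation burst delivered on one channel."""

    start: float
    end: float
    params: StimulationParams = field(default_factory=StimulationParams)
    trigger: str = "on_demand"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError("pulse train end must exceed start")
        if self.trigger not in TRIGGERS:
            raise ValidationError(f"unknown trigger {self.trigger!r}")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def to_dict(self) -> dict:
        return {"start": self.start, "end": self.end, "trigger": self.trigger,
                "params": self.params.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "PulseTrain":
        return cls(start=d["start"], end=d["end"], trigger=d.get("trigger", "on_demand"),
                   params=StimulationParams.from_dict(d.get("params", {})))


@dataclass
class MotionEvent:
    """A motion-phase boundary event as seen by the cueing controller."""

    kind: str                    # "motion_start" | "motion_end"
    time: float                  # seconds
    classification: str = "none"  # present on motion_end only

    def __post_init__(self) -> None:
        if self.kind not in ("motion_start", "motion_end"):
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if self.classification not in CLASS_LABELS:
            raise ValidationError(f"unknown classification {self.classification!r}")
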