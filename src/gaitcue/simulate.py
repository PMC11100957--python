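"""Synthetic foot-IMU gait generator with ground truth.

Generates 200 Hz inertial streams for a foot-mounted sensor from scripted
gait scenarios: rest, normal walking, pivot turns, and the FoG subtypes
(shuffling, festination, shank trembling, akinesia).  Each swing is built
from a smooth foot trajectory — minimum-jerk forward displacement, a foot
pitch profile that dips negative (plantar-flexion) after toe-off and rises
positive (toe-up) before heel strike, and a sinusoidal ground clearance.
Sensor signals are derived from the trajectory: body rates from the Euler
rates, accelerometer readings as the gravity-included specific force
rotated into the sensor frame, plus white Gaussian noise and a constant
per-trial gyro bias.

The ground truth records every programmed swing as an annotated motion
phase and covers all non-normal segments with FoG episodes, standing in
for the clinical expert's video annotation.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .types import (
    FOG_SUBTYPES,
    G,
    FogEpisode,
    ImuStream,
    MotionPhase,
    StreamMeta,
    ValidationError,
)

SEGMENT_KINDS = (
    "rest", "normal_walk", "shuffling", "festination", "trembling",
    "akinesia", "turn", "sway",
)

# Pitch swing profile: -sin(2πτ)·sin²(πτ), normalized to peak amplitude 1.
# Zero angle and zero angular rate at both ends of the swing, so the signal
# energy ramps smoothly in and out of each motion phase.
_TAU = np.linspace(0.0, 1.0, 20001)
_PITCH_NORM = float(np.max(np.sin(2 * np.pi * _TAU) * np.sin(np.pi * _TAU) ** 2))


def _pitch_profile(tau: np.ndarray) -> np.ndarray:
    return -np.sin(2 * np.pi * tau) * np.sin(np.pi * tau) ** 2 / _PITCH_NORM


def _minjerk(tau: np.ndarray) -> np.ndarray:
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


@dataclass
class SubjectParams:
    """Per-subject gait parameters (between-subject variation)."""

    stride_length_m: float = 1.2
    cadence_hz: float = 1.0        # strides per second of the instrumented foot
    foot_lift_deg: float = 20.0    # peak |pitch| during a normal swing
    noise_sd_acc: float = 0.15     # m/s², per axis
    noise_sd_gyr: float = 1.5      # °/s, per axis
    swing_duty: float = 0.4        # swing duration as fraction of the stride interval

    def validate(self) -> "SubjectParams":
        if self.stride_length_m <= 0:
            raise ValidationError("stride_length_m must be positive")
        if not 0.1 < self.cadence_hz < 3.0:
            raise ValidationError("cadence_hz must be in (0.1, 3)")
        if not 0.05 < self.swing_duty < 0.9:
            raise ValidationError("swing_duty must be in (0.05, 0.9)")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectParams":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class Segment:
    kind: str
    duration: Optional[float] = None   # seconds (rest/trembling/akinesia/sway)
    n_strides: Optional[int] = None    # walk-like segments
    params: dict = field(default_factory=dict)

    def validate(self) -> "Segment":
        if self.kind not in SEGMENT_KINDS:
            raise ValidationError(f"unknown segment kind {self.kind!r}")
        if self.duration is not None and self.duration <= 0:
            raise ValidationError("segment duration must be positive")
        if self.n_strides is not None and self.n_strides <= 0:
            raise ValidationError("segment stride count must be positive")
        return self

    def to_dict(self) -> dict:
        return {"kind": self.kind, "duration": self.duration,
                "n_strides": self.n_strides, "params": self.params}

    @classmethod
    def from_dict(cls, d: dict) -> "Segment":
        return cls(kind=d["kind"], duration=d.get("duration"),
                   n_strides=d.get("n_strides"), params=d.get("params", {}))


@dataclass
class GaitScenario:
    segments: List[Segment]
    subject: SubjectParams = field(default_factory=SubjectParams)
    seed: int = 0

    def validate(self) -> "GaitScenario":
        self.subject.validate()
        for seg in self.segments:
            seg.validate()
        return self

    def to_dict(self) -> dict:
        return {"segments": [s.to_dict() for s in self.segments],
                "subject": self.subject.to_dict(), "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "GaitScenario":
        return cls(segments=[Segment.from_dict(s) for s in d["segments"]],
                   subject=SubjectParams.from_dict(d.get("subject", {})),
                   seed=int(d.get("seed", 0)))


@dataclass
class StrideTruth:
    t_start: float
    true_duration_s: float
    true_stride_length_m: float
    true_turn_deg: float
    segment_kind: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    motion_phases: List[MotionPhase]
    fog_episodes: List[FogEpisode]
    per_stride: List[StrideTruth]


class _SessionBuilder:
    """Accumulates the noise-free global trajectory on the sample grid."""

    def __init__(self, fs: float):
        self.fs = fs
        self.pitch: List[np.ndarray] = []   # deg, toe-up positive
        self.yaw: List[np.ndarray] = []     # deg, cumulative
        self.pos: List[np.ndarray] = []     # (n, 3) m
        self.cursor = 0                     # samples
        self._yaw0 = 0.0
        self._pos0 = np.zeros(3)
        self.truth_phases: List[MotionPhase] = []
        self.truth_strides: List[StrideTruth] = []
        self.episodes: List[FogEpisode] = []

    @property
    def t_now(self) -> float:
        return self.cursor / self.fs

    def _emit(self, pitch, yaw, pos):
        self.pitch.append(pitch)
        self.yaw.append(yaw)
        self.pos.append(pos)
        self.cursor += len(pitch)
        self._yaw0 = float(yaw[-1]) if len(yaw) else self._yaw0
        self._pos0 = pos[-1].copy() if len(pos) else self._pos0

    def quiet(self, duration: float) -> None:
        n = max(1, round(duration * self.fs))
        self._emit(np.zeros(n), np.full(n, self._yaw0),
                   np.tile(self._pos0, (n, 1)))

    def sway(self, duration: float, amp_m: float = 0.03, freq_hz: float = 1.2) -> None:
        """Unrest without motion phases (sit-to-stand / sitting transitions):
        vertical body sway that raises the dynamic-acceleration energy above
        the rest band without any pitch excursion or high angular rate."""
        n = max(2, round(duration * self.fs))
        tt = np.arange(n) / self.fs
        window = np.sin(np.pi * tt / (n / self.fs)) ** 2
        z = amp_m * np.sin(2 * np.pi * freq_hz * tt) * window
        pos = np.tile(self._pos0, (n, 1))
        pos[:, 2] += z
        self._emit(np.zeros(n), np.full(n, self._yaw0), pos)

    def stride(self, length_m: float, lift_deg: float, slot_s: float,
               swing_s: float, turn_deg: float = 0.0, clearance_m: float = 0.04,
               kind: str = "normal_walk") -> None:
        """One stride slot: quiet lead-in, a swing, quiet follow-through."""
        pre = 0.5 * (slot_s - swing_s)
        n_pre = max(1, round(pre * self.fs))
        n_sw = max(4, round(swing_s * self.fs))
        n_post = max(1, round(slot_s * self.fs) - n_pre - n_sw)

        self.quiet(n_pre / self.fs)

        t0 = self.t_now
        tau = np.arange(1, n_sw + 1) / n_sw
        pitch = lift_deg * _pitch_profile(tau)
        yaw = self._yaw0 + turn_deg * (tau - np.sin(2 * np.pi * tau) / (2 * np.pi))
        s = length_m * _minjerk(tau)
        heading = np.deg2rad(yaw)
        pos = np.empty((n_sw, 3))
        pos[:, 0] = self._pos0[0] + s * np.cos(heading)
        pos[:, 1] = self._pos0[1] + s * np.sin(heading)
        pos[:, 2] = self._pos0[2] + clearance_m * np.sin(np.pi * tau) ** 2
        self._emit(pitch, yaw, pos)
        t1 = self.t_now

        self.truth_phases.append(MotionPhase(start=t0, end=t1, source="annotated"))
        self.truth_strides.append(StrideTruth(
            t_start=t0, true_duration_s=t1 - t0, true_stride_length_m=length_m,
            true_turn_deg=turn_deg, segment_kind=kind))

        self.quiet(n_post / self.fs)

    def trembling(self, duration: float, lift_deg: float = 8.0,
                  ripple_deg: float = 4.0, tremor_hz: float = 5.0,
                  lift_s: float = 0.3, period_s: float = 0.7) -> None:
        """Shank-trembling: heel-lift micro-phases carrying a 4–6 Hz pitch
        oscillation, separated by quiet gaps; no forward displacement."""
        start_cursor = self.cursor
        n_total = max(1, round(duration * self.fs))
        n_lifts = max(1, int((duration - 0.2) // period_s))
        lead = 0.5 * (duration - n_lifts * period_s) + 0.5 * (period_s - lift_s)
        self.quiet(max(lead, 1.0 / self.fs))
        for k in range(n_lifts):
            t0 = self.t_now
            n_lift = max(4, round(lift_s * self.fs))
            tau = np.arange(1, n_lift + 1) / n_lift
            window = np.sin(np.pi * tau) ** 2
            tt = tau * (n_lift / self.fs)
            pitch = lift_deg * window + ripple_deg * np.sin(2 * np.pi * tremor_hz * tt) * window
            self._emit(pitch, np.full(n_lift, self._yaw0), np.tile(self._pos0, (n_lift, 1)))
            t1 = self.t_now
            self.truth_phases.append(MotionPhase(start=t0, end=t1, source="annotated"))
            self.truth_strides.append(StrideTruth(
                t_start=t0, true_duration_s=t1 - t0, true_stride_length_m=0.0,
                true_turn_deg=0.0, segment_kind="trembling"))
            if k < n_lifts - 1:
                self.quiet(period_s - lift_s)
        remaining = n_total - (self.cursor - start_cursor)
        if remaining > 0:
            self.quiet(remaining / self.fs)


def _run_segment(b: _SessionBuilder, seg: Segment, subj: SubjectParams) -> None:
    p = seg.params
    cad = p.get("cadence_hz", subj.cadence_hz)
    slot = 1.0 / cad
    swing = min(subj.swing_duty * slot, 0.8)
    seg_t0 = b.t_now

    if seg.kind == "rest" or seg.kind == "akinesia":
        b.quiet(seg.duration)
    elif seg.kind == "sway":
        b.sway(seg.duration, amp_m=p.get("amp_m", 0.03))
    elif seg.kind == "normal_walk":
        L = p.get("stride_length_m", subj.stride_length_m)
        lift = p.get("foot_lift_deg", subj.foot_lift_deg)
        for _ in range(seg.n_strides):
            b.stride(L, lift, slot, swing, clearance_m=0.04 * L / 1.2, kind="normal_walk")
    elif seg.kind == "shuffling":
        L = p.get("stride_length_m", 0.18)
        lift = p.get("foot_lift_deg", 4.0)
        sw = min(0.3, swing)
        for _ in range(seg.n_strides):
            b.stride(L, lift, slot, sw, clearance_m=0.005, kind="shuffling")
    elif seg.kind == "festination":
        L0 = p.get("start_stride_m", 0.5 * subj.stride_length_m)
        ratio = p.get("ratio", 0.85)
        growth = p.get("cadence_growth", 1.1)
        lift = p.get("foot_lift_deg", 8.0)
        for k in range(seg.n_strides):
            cad_k = min(cad * growth**k, 2.5)
            slot_k = 1.0 / cad_k
            b.stride(L0 * ratio**k, lift, slot_k, subj.swing_duty * slot_k,
                     clearance_m=0.01, kind="festination")
    elif seg.kind == "trembling":
        b.trembling(seg.duration, lift_deg=p.get("lift_deg", 8.0),
                    ripple_deg=p.get("ripple_deg", 4.0),
                    tremor_hz=p.get("tremor_hz", 5.0))
    elif seg.kind == "turn":
        angle = p.get("angle_deg", 180.0)
        per_pivot = p.get("per_pivot_deg", 45.0)
        n_piv = seg.n_strides or max(1, math.ceil(abs(angle) / per_pivot))
        for _ in range(n_piv):
            b.stride(p.get("stride_length_m", 0.15), p.get("foot_lift_deg", 10.0),
                     slot, swing, turn_deg=angle / n_piv, clearance_m=0.02, kind="turn")
    else:  # pragma: no cover - guarded by Segment.validate
        raise ValidationError(f"unknown segment kind {seg.kind!r}")

    if seg.kind in FOG_SUBTYPES:
        b.episodes.append(FogEpisode(start=seg_t0, end=b.t_now, subtype=seg.kind))


def generate(scenario: GaitScenario, fs: float = 200.0,
             noise: bool = True) -> tuple[ImuStream, GroundTruth]:
    """Render a scenario into a 200 Hz IMU stream plus ground truth.

    Set ``noise=False`` for noise-free signals (parameter-recovery checks).
    """
    scenario.validate()
    b = _SessionBuilder(fs)
    for seg in scenario.segments:
        _run_segment(b, seg, scenario.subject)
    b.quiet(0.5)  # tail so trailing phases can close

    pitch = np.concatenate(b.pitch)
    yaw = np.concatenate(b.yaw)
    pos = np.concatenate(b.pos, axis=0)
    n = len(pitch)
    t = np.arange(n) / fs
    dt = 1.0 / fs

    pitch_rate = np.gradient(pitch, dt)           # °/s
    yaw_rate = np.gradient(yaw, dt)               # °/s
    th = np.deg2rad(pitch)
    gyr = np.column_stack([yaw_rate * np.sin(th), -pitch_rate, yaw_rate * np.cos(th)])

    vel = np.gradient(pos, dt, axis=0)
    accel = np.gradient(vel, dt, axis=0)
    f_global = accel + np.array([0.0, 0.0, G])
    # body->global: R = Rz(yaw) @ Ry(-pitch), roll = 0; toe-up pitch positive
    eul = np.column_stack([np.deg2rad(yaw), -th, np.zeros(n)])
    rot = Rotation.from_euler("ZYX", eul)
    acc = rot.inv().apply(f_global)

    if noise:
        rng = np.random.default_rng(scenario.seed)
        acc = acc + rng.normal(0.0, scenario.subject.noise_sd_acc, (n, 3))
        bias = rng.uniform(-0.5, 0.5, 3)
        gyr = gyr + bias + rng.normal(0.0, scenario.subject.noise_sd_gyr, (n, 3))

    stream = ImuStream(t=t, acc=acc, gyr=gyr, meta=StreamMeta()).validate()
    truth = GroundTruth(motion_phases=b.truth_phases, fog_episodes=b.episodes,
                        per_stride=b.truth_strides)
    return stream, truth


# ---------------------------------------------------------------------------
# test protocols

_FOG_INSERTS = ("shuffling", "trembling", "festination")


def _fog_segment(rng: np.random.Generator, subtype: str | None = None) -> Segment:
    subtype = subtype or _FOG_INSERTS[rng.integers(0, len(_FOG_INSERTS))]
    if subtype == "trembling":
        return Segment("trembling", duration=2.5)
    if subtype == "festination":
        return Segment("festination", n_strides=5)
    return Segment("shuffling", n_strides=3)


def protocol_10mwt(subject_params: SubjectParams, fog_density: float = 0.0,
                   seed: int = 0) -> GaitScenario:
    """Ten-meter walking test: walk 10 m out, turn 180°, walk back.

    FoG segments are inserted with probability ``fog_density`` at gait
    initiation and at the turn, where freezing clusters.
    """
    if not 0.0 <= fog_density <= 1.0:
        raise ValidationError("fog_density must be in [0, 1]")
    subject_params.validate()
    rng = np.random.default_rng(seed)
    n_walk = math.ceil(10.0 / subject_params.stride_length_m)
    segments = [Segment("rest", duration=2.0)]
    if rng.random() < fog_density:
        segments.append(_fog_segment(rng))
    segments.append(Segment("normal_walk", n_strides=n_walk))
    if rng.random() < fog_density:
        segments.append(_fog_segment(rng))
    segments.append(Segment("turn", params={"angle_deg": 180.0}))
    segments.append(Segment("normal_walk", n_strides=n_walk))
    segments.append(Segment("rest", duration=2.0))
    return GaitScenario(segments=segments, subject=subject_params, seed=seed)


def protocol_fac(subject_params: SubjectParams, fog_density: float = 0.0,
                 seed: int = 0) -> GaitScenario:
    """Freezing assessment course: sit-to-stand, 1 m walk to a marked square,
    ±360° turns in place, walk to a door, pause, return, sit down."""
    if not 0.0 <= fog_density <= 1.0:
        raise ValidationError("fog_density must be in [0, 1]")
    subject_params.validate()
    rng = np.random.default_rng(seed)
    n_to_square = max(1, math.ceil(1.0 / subject_params.stride_length_m))
    segments = [Segment("rest", duration=1.5),
                Segment("sway", duration=2.0)]          # sit-to-stand
    if rng.random() < fog_density:
        segments.append(_fog_segment(rng))
    segments.append(Segment("normal_walk", n_strides=n_to_square))
    if rng.random() < fog_density:
        segments.append(_fog_segment(rng))
    segments.append(Segment("turn", params={"angle_deg": 360.0}))
    if rng.random() < fog_density:
        segments.append(_fog_segment(rng))
    segments.append(Segment("turn", params={"angle_deg": -360.0}))
    segments.append(Segment("normal_walk", n_strides=3))  # to the door
    if rng.random() < fog_density:
        segments.append(_fog_segment(rng))
    segments.append(Segment("rest", duration=1.5))        # door pause
    segments.append(Segment("normal_walk", n_strides=4))  # back to the chair
    segments.append(Segment("sway", duration=2.0))        # sit down
    segments.append(Segment("rest", duration=1.0))
    return GaitScenario(segments=segments, subject=subject_params, seed=seed)


# ---------------------------------------------------------------------------
# cohorts

DEFAULT_PARAM_RANGES = {
    "stride_length_m": (1.0, 1.4),
    "cadence_hz": (0.8, 1.2),
    "foot_lift_deg": (15.0, 25.0),
    "shuffle_stride_m": (0.12, 0.25),
    "shuffle_lift_deg": (2.5, 5.0),
}


@dataclass
class CohortTrial:
    subject_id: int
    trial_id: int
    subject: SubjectParams
    scenario: GaitScenario
    stream: ImuStream
    truth: GroundTruth


def default_trial_scenario(subject: SubjectParams, rng: np.random.Generator,
                           shuffle_stride_m: float = 0.18,
                           shuffle_lift_deg: float = 4.0) -> GaitScenario:
    """One ~60 s mixed trial: straight walking interleaved with shuffling,
    trembling, festination, a 180° turn and a short akinetic episode."""
    shuffle = {"stride_length_m": shuffle_stride_m, "foot_lift_deg": shuffle_lift_deg}
    segments = [
        Segment("rest", duration=3.0),
        Segment("normal_walk", n_strides=int(rng.integers(10, 14))),
        Segment("shuffling", n_strides=int(rng.integers(4, 7)), params=shuffle),
        Segment("normal_walk", n_strides=int(rng.integers(8, 12))),
        Segment("trembling", duration=4.0),
        Segment("festination", n_strides=int(rng.integers(5, 8))),
        Segment("turn", params={"angle_deg": 180.0}),
        Segment("normal_walk", n_strides=int(rng.integers(8, 12))),
        Segment("akinesia", duration=3.0),
        Segment("rest", duration=2.0),
    ]
    return GaitScenario(segments=segments, subject=subject,
                        seed=int(rng.integers(0, 2**31 - 1)))


def make_cohort(n_subjects: int = 20, per_subject_trials: int = 1,
                param_ranges: dict | None = None, seed: int = 0) -> List[CohortTrial]:
    """Simulate a cohort with subject-level parameter variation.

    Subject parameters are drawn once per subject; trial noise is
    independent.  Subject ids support leave-one-subject-out grouping.
    """
    if n_subjects < 2:
        raise ValidationError("a cohort needs >= 2 subjects (LOSO undefined otherwise)")
    ranges = dict(DEFAULT_PARAM_RANGES)
    if param_ranges:
        ranges.update(param_ranges)
    rng = np.random.default_rng(seed)
    trials: List[CohortTrial] = []
    for sid in range(n_subjects):
        subject = SubjectParams(
            stride_length_m=float(rng.uniform(*ranges["stride_length_m"])),
            cadence_hz=float(rng.uniform(*ranges["cadence_hz"])),
            foot_lift_deg=float(rng.uniform(*ranges["foot_lift_deg"])),
        )
        shuffle_stride = float(rng.uniform(*ranges["shuffle_stride_m"]))
        shuffle_lift = float(rng.uniform(*ranges["shuffle_lift_deg"]))
        for tid in range(per_subject_trials):
            scenario = default_trial_scenario(subject, rng, shuffle_stride, shuffle_lift)
            stream, truth = generate(scenario)
            trials.append(CohortTrial(subject_id=sid, trial_id=tid, subject=subject,
                                      scenario=scenario, stream=stream, truth=truth))
    return trials
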