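"""Orientation estimation and causal rest/unrest/motion phase detection.

The orientation q(t) is estimated by a complementary filter: gyro
integration corrected toward the accelerometer inclination (roll/pitch
only; yaw is gyro-integrated and drifts, as no magnetometer is available).
The correction is gated on the accelerometer norm being close to gravity,
so the inclination is only trusted in quasi-static moments.

Phase detection is a sample-wise causal state machine with hysteresis:

* rest   — gyro norm and gravity-free acceleration below the rest band,
           sustained for a dwell time;
* unrest — energy above the rest band;
* motion — a sub-phase of unrest; opens when the gyro norm or the pitch
           excursion from the rest posture crosses the motion threshold
           (toe-off proxy) and closes after a sustained quiet dwell
           (heel-strike proxy).

Batch and streaming entry points share one implementation, so replaying a
stream sample-by-sample reproduces the batch phase list exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .types import G, ImuStream, MotionEvent, MotionPhase, ValidationError

LABEL_REST, LABEL_UNREST, LABEL_MOTION = 0, 1, 2
LABEL_NAMES = ("rest", "unrest", "motion")

_DEG = 180.0 / math.pi


def _rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vectors by unit quaternions (scalar-first, body->global)."""
    w = q[..., :1]
    u = q[..., 1:]
    t = 2.0 * np.cross(u, v)
    return v + w * t + np.cross(u, t)


def _quat_mul(a, b):
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    return (
        aw * bw - ax * bx - ay * by - az * bz,
        aw * bx + ax * bw + ay * bz - az * by,
        aw * by - ax * bz + ay * bw + az * bx,
        aw * bz + ax * by - ay * bx + az * bw,
    )


def _quat_from_euler(yaw, pitch, roll):
    """ZYX euler (rad) -> quaternion, R = Rz(yaw) Ry(pitch) Rx(roll)."""
    cy, sy = math.cos(yaw / 2), math.sin(yaw / 2)
    cp, sp = math.cos(pitch / 2), math.sin(pitch / 2)
    cr, sr = math.cos(roll / 2), math.sin(roll / 2)
    return (
        cr * cp * cy + sr * sp * sy,
        sr * cp * cy - cr * sp * sy,
        cr * sp * cy + sr * cp * sy,
        cr * cp * sy - sr * sp * cy,
    )


def _euler_from_quat(q):
    """Quaternion -> ZYX euler (yaw, pitch, roll) in rad."""
    w, x, y, z = q
    roll = math.atan2(2 * (w * x + y * z), 1 - 2 * (x * x + y * y))
    pitch = math.asin(max(-1.0, min(1.0, 2 * (w * y - z * x))))
    yaw = math.atan2(2 * (w * z + x * y), 1 - 2 * (y * y + z * z))
    return yaw, pitch, roll


def _wrap(a: float) -> float:
    return (a + math.pi) % (2 * math.pi) - math.pi


@dataclass
class OrientationState:
    """Per-sample orientation and globally expressed signals.

    ``euler`` columns are (roll, pitch, yaw) in degrees with toe-up pitch
    positive; ``acc_global`` is gravity-removed.
    """

    q: np.ndarray           # (n, 4) scalar-first unit quaternions
    acc_global: np.ndarray  # (n, 3) m/s²
    gyr_global: np.ndarray  # (n, 3) °/s
    euler: np.ndarray       # (n, 3) degrees

    @property
    def pitch(self) -> np.ndarray:
        return self.euler[:, 1]

    @property
    def yaw(self) -> np.ndarray:
        return self.euler[:, 2]


class OrientationFilter:
    """Streaming complementary filter (gyro + gated accelerometer blend)."""

    def __init__(self, gain: float = 0.02, acc_gate: float = 0.5,
                 gyr_gate: float = 20.0,
                 initial_q: Optional[Tuple[float, float, float, float]] = None):
        if not 0 < gain < 1:
            raise ValidationError("filter gain must be in (0, 1)")
        self.gain = gain
        self.acc_gate = acc_gate
        self.gyr_gate = gyr_gate
        self.q = tuple(initial_q) if initial_q is not None else None

    @staticmethod
    def _inclination(ax, ay, az):
        norm = math.sqrt(ax * ax + ay * ay + az * az)
        if norm < 1e-6:
            raise ValidationError("degenerate inclination: accelerometer norm ~ 0")
        pitch = math.atan2(-ax, math.sqrt(ay * ay + az * az))
        roll = math.atan2(ay, az)
        return pitch, roll

    def step(self, acc, gyr, dt: float):
        """Advance one sample; acc in m/s², gyr in °/s.  Returns the
        quaternion and (roll, pitch, yaw) in degrees (toe-up positive)."""
        ax, ay, az = float(acc[0]), float(acc[1]), float(acc[2])
        if self.q is None:
            p_acc, r_acc = self._inclination(ax, ay, az)
            self.q = _quat_from_euler(0.0, p_acc, r_acc)
        else:
            wx = gyr[0] / _DEG
            wy = gyr[1] / _DEG
            wz = gyr[2] / _DEG
            ang = math.sqrt(wx * wx + wy * wy + wz * wz) * dt
            if ang > 0:
                s = math.sin(ang / 2) / (ang / dt)
                dq = (math.cos(ang / 2), wx * s, wy * s, wz * s)
                q = _quat_mul(self.q, dq)
                n = math.sqrt(sum(c * c for c in q))
                self.q = tuple(c / n for c in q)
            # inclination is trusted only in quasi-static moments: the
            # specific-force norm near g AND low angular rate (a lateral
            # acceleration perpendicular to gravity barely moves the norm)
            norm = math.sqrt(ax * ax + ay * ay + az * az)
            gyr_norm = math.sqrt(gyr[0] ** 2 + gyr[1] ** 2 + gyr[2] ** 2)
            if abs(norm - G) < self.acc_gate and gyr_norm < self.gyr_gate:
                p_acc, r_acc = self._inclination(ax, ay, az)
                yaw, pitch, roll = _euler_from_quat(self.q)
                pitch += self.gain * _wrap(p_acc - pitch)
                roll += self.gain * _wrap(r_acc - roll)
                self.q = _quat_from_euler(yaw, pitch, roll)
        yaw, pitch, roll = _euler_from_quat(self.q)
        return self.q, (roll * _DEG, -pitch * _DEG, yaw * _DEG)


def estimate_orientation(stream: ImuStream, gain: float = 0.02,
                         acc_gate: float = 0.5, gyr_gate: float = 20.0,
                         initial_q=None) -> OrientationState:
    """Run the complementary filter over a stream and express the signals
    globally (gravity removed from the acceleration)."""
    stream.validate()
    n = stream.n
    if n == 0:
        z = np.zeros((0, 3))
        return OrientationState(q=np.zeros((0, 4)), acc_global=z, gyr_global=z, euler=z)
    filt = OrientationFilter(gain=gain, acc_gate=acc_gate, gyr_gate=gyr_gate,
                             initial_q=initial_q)
    dt = 1.0 / stream.meta.sample_rate_hz
    q_arr = np.empty((n, 4))
    euler = np.empty((n, 3))
    acc = stream.acc
    gyr = stream.gyr
    for i in range(n):
        q, e = filt.step(acc[i], gyr[i], dt)
        q_arr[i] = q
        euler[i] = e
    acc_global = _rotate(q_arr, acc) - np.array([0.0, 0.0, G])
    gyr_global = _rotate(q_arr, gyr)
    return OrientationState(q=q_arr, acc_global=acc_global, gyr_global=gyr_global,
                            euler=euler)


@dataclass
class GpdParams:
    """Thresholds of the gait-phase detector (all config-exposed).

    The motion thresholds must admit shuffling (small foot lift) while the
    rest band rejects sensor noise.
    """

    gain: float = 0.02
    acc_gate: float = 0.5          # m/s², accelerometer-trust gate (norm vs g)
    gyr_gate_dps: float = 20.0     # °/s, accelerometer trusted only below this rate
    rest_gyr_dps: float = 10.0
    rest_acc_ms2: float = 0.6
    dwell_rest_s: float = 0.1
    open_gyr_dps: float = 50.0
    open_pitch_deg: float = 3.0
    close_gyr_dps: float = 25.0
    close_pitch_deg: float = 1.5
    dwell_close_s: float = 0.035
    min_motion_s: float = 0.06
    rest_pitch_alpha: float = 0.05
    rest_exit_factor: float = 1.5   # hysteresis: leave rest only above this x entry band

    def validate(self) -> "GpdParams":
        for name in ("rest_gyr_dps", "rest_acc_ms2", "dwell_rest_s", "open_gyr_dps",
                     "open_pitch_deg", "close_gyr_dps", "close_pitch_deg",
                     "dwell_close_s", "min_motion_s"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"threshold {name} must be positive")
        return self


@dataclass
class PhaseSequence:
    """Per-sample labels plus the derived maximal intervals."""

    t: np.ndarray
    labels: np.ndarray              # int8 codes, see LABEL_NAMES
    phases: List[MotionPhase]       # detected motion phases, time-ordered

    def intervals(self, label: str) -> List[Tuple[float, float]]:
        code = LABEL_NAMES.index(label)
        out = []
        mask = self.labels == code
        i = 0
        n = len(mask)
        while i < n:
            if mask[i]:
                j = i
                while j + 1 < n and mask[j + 1]:
                    j += 1
                out.append((float(self.t[i]), float(self.t[j])))
                i = j + 1
            else:
                i += 1
        return out


class GaitPhaseDetector:
    """Causal rest/unrest/motion state machine, one call per sample."""

    def __init__(self, params: GpdParams | None = None):
        self.p = (params or GpdParams()).validate()
        self.rest_cnt = 0.0
        self.close_cnt = 0.0
        self.in_rest = False
        self.in_motion = False
        self.motion_start: float | None = None
        self.quiet_onset: float | None = None
        self.start_emitted = False
        self.rest_pitch: float | None = None
        self.last_t: float | None = None
        self.motion_start_idx: int | None = None
        self.dropped_spans: List[Tuple[int, int]] = []
        self.phases: List[MotionPhase] = []

    def step(self, t: float, gyr_norm: float, dyn_acc: float, pitch: float,
             dt: float, idx: int = -1) -> List[MotionEvent]:
        if self.last_t is not None and t <= self.last_t:
            raise ValidationError("out-of-order sample")
        self.last_t = t
        p = self.p
        if self.rest_pitch is None:
            self.rest_pitch = pitch

        events: List[MotionEvent] = []
        rest_inst = gyr_norm < p.rest_gyr_dps and dyn_acc < p.rest_acc_ms2
        self.rest_cnt = self.rest_cnt + dt if rest_inst else 0.0

        if not self.in_motion:
            if gyr_norm > p.open_gyr_dps or abs(pitch - self.rest_pitch) > p.open_pitch_deg:
                self.in_motion = True
                self.motion_start = t
                self.motion_start_idx = idx
                self.close_cnt = 0.0
                self.quiet_onset = None
                self.start_emitted = False

        if self.in_motion:
            quiet = gyr_norm < p.close_gyr_dps and abs(pitch - self.rest_pitch) < p.close_pitch_deg
            if quiet:
                if self.close_cnt == 0.0:
                    self.quiet_onset = t
                self.close_cnt += dt
            else:
                self.close_cnt = 0.0
                self.quiet_onset = None
            active_end = self.quiet_onset if self.quiet_onset is not None else t
            if not self.start_emitted and active_end - self.motion_start >= p.min_motion_s:
                self.start_emitted = True
                events.append(MotionEvent(kind="motion_start", time=self.motion_start))
            if self.close_cnt >= p.dwell_close_s:
                kept = self.quiet_onset - self.motion_start >= p.min_motion_s
                if kept:
                    self.phases.append(MotionPhase(start=self.motion_start, end=t))
                    events.append(MotionEvent(kind="motion_end", time=t))
                elif self.motion_start_idx is not None and self.motion_start_idx >= 0:
                    self.dropped_spans.append((self.motion_start_idx, idx))
                self.in_motion = False
                self.motion_start = None
                self.motion_start_idx = None

        if self.in_rest:
            if (self.in_motion or gyr_norm > p.rest_exit_factor * p.rest_gyr_dps
                    or dyn_acc > p.rest_exit_factor * p.rest_acc_ms2):
                self.in_rest = False
        elif self.rest_cnt >= p.dwell_rest_s and not self.in_motion:
            self.in_rest = True

        if self.in_motion:
            label = LABEL_MOTION
        elif self.in_rest:
            label = LABEL_REST
            self.rest_pitch += p.rest_pitch_alpha * (pitch - self.rest_pitch)
        else:
            label = LABEL_UNREST
        self.label = label
        return events


def detect_phases(stream: ImuStream, orient: OrientationState,
                  params: GpdParams | None = None) -> PhaseSequence:
    """Segment a stream into rest/unrest/motion using precomputed orientation."""
    params = (params or GpdParams()).validate()
    if orient.euler.shape[0] != stream.n:
        raise ValidationError("orientation state not aligned with stream")
    det = GaitPhaseDetector(params)
    dt = 1.0 / stream.meta.sample_rate_hz
    gyr_norm = np.linalg.norm(stream.gyr, axis=1)
    dyn_acc = np.linalg.norm(orient.acc_global, axis=1)
    pitch = orient.euler[:, 1]
    labels = np.empty(stream.n, dtype=np.int8)
    for i in range(stream.n):
        det.step(float(stream.t[i]), float(gyr_norm[i]), float(dyn_acc[i]),
                 float(pitch[i]), dt, idx=i)
        labels[i] = det.label
    # spans of sub-minimum motion are demoted to unrest in the label track
    for i0, i1 in det.dropped_spans:
        sel = labels[i0:i1 + 1] == LABEL_MOTION
        labels[i0:i1 + 1][sel] = LABEL_UNREST
    if det.in_motion:
        sel = labels[det.motion_start_idx:] == LABEL_MOTION
        labels[det.motion_start_idx:][sel] = LABEL_UNREST
    return PhaseSequence(t=stream.t, labels=labels, phases=det.phases)


class OnlineDetector:
    """Streaming front end: orientation filter + phase detector in one step.

    ``step`` consumes one raw sample and returns the motion events emitted
    at that instant.  Replaying a stream through this class yields exactly
    the phases of the batch :func:`detect_phases`.
    """

    def __init__(self, params: GpdParams | None = None, sample_rate_hz: float = 200.0):
        self.params = (params or GpdParams()).validate()
        self.filter = OrientationFilter(gain=self.params.gain,
                                        acc_gate=self.params.acc_gate,
                                        gyr_gate=self.params.gyr_gate_dps)
        self.detector = GaitPhaseDetector(self.params)
        self.dt = 1.0 / sample_rate_hz
        self._g = np.array([0.0, 0.0, G])
        self._i = 0

    def step(self, t: float, acc, gyr) -> List[MotionEvent]:
        acc = np.asarray(acc, dtype=float)
        gyr = np.asarray(gyr, dtype=float)
        q, euler = self.filter.step(acc, gyr, self.dt)
        acc_g = _rotate(np.asarray(q), acc) - self._g
        events = self.detector.step(
            t, float(np.linalg.norm(gyr)), float(np.linalg.norm(acc_g)),
            euler[1], self.dt, idx=self._i)
        self._i += 1
        return events

    @property
    def phases(self) -> List[MotionPhase]:
        return self.detector.phases
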