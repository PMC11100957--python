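"""Per-motion-phase feature extraction.

Ten features are computed at the end of each detected motion phase, from
samples up to the phase end only (causal): max acceleration norm, max and
min pitch, stride length, max stride velocity in the transverse (global
horizontal) plane, turning angle, turned flag, max and mean turn rate,
and stride duration.

Velocity is obtained by integrating the gravity-free global acceleration
from the last zero-velocity anchor before the phase (ZUPT: the final rest
sample), with a linear drift correction forcing the velocity back to zero
at the phase end — the standard pedestrian dead-reckoning treatment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .motion import LABEL_REST, OrientationState, PhaseSequence
from .types import ImuStream, MotionPhase, ValidationError

FEATURE_NAMES = [
    "max_acc_norm",          # m/s², gravity-free
    "max_pitch_deg",
    "min_pitch_deg",
    "stride_length_m",
    "max_stride_velocity_mps",
    "turning_angle_deg",
    "turned_flag",
    "max_turn_rate_dps",
    "mean_turn_rate_dps",
    "stride_duration_s",
]


@dataclass
class FeatureConfig:
    turn_flag_deg: float = 22.5    # |turning angle| above which a step counts as a turn
    anchor_window_s: float = 5.0   # how far back to search for a zero-velocity anchor

    def validate(self) -> "FeatureConfig":
        if self.turn_flag_deg <= 0 or self.anchor_window_s <= 0:
            raise ValidationError("feature config values must be positive")
        return self


@dataclass
class FeatureVector:
    max_acc_norm: float
    max_pitch_deg: float
    min_pitch_deg: float
    stride_length_m: float
    max_stride_velocity_mps: float
    turning_angle_deg: float
    turned_flag: int
    max_turn_rate_dps: float
    mean_turn_rate_dps: float
    stride_duration_s: float
    degraded: bool = False         # no zero-velocity anchor found; ZUPT skipped

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, _ATTRS[name]) for name in FEATURE_NAMES],
                        dtype=float)


_ATTRS = {name: name for name in FEATURE_NAMES}


def extract(phase: MotionPhase, orient: OrientationState, stream: ImuStream,
            labels: np.ndarray, config: FeatureConfig | None = None) -> FeatureVector:
    """Compute the feature vector of one motion phase.

    ``labels`` is the per-sample phase-label track (used to locate the
    zero-velocity anchor: the last rest sample before the phase).
    """
    config = (config or FeatureConfig()).validate()
    t = stream.t
    i0 = int(np.searchsorted(t, phase.start, side="left"))
    i1 = int(np.searchsorted(t, phase.end, side="right"))
    if i0 >= i1 or i1 > stream.n:
        raise ValidationError("phase does not lie within the stream")

    degraded = False
    rest_before = np.flatnonzero(labels[:i0] == LABEL_REST)
    if len(rest_before) and t[i0] - t[rest_before[-1]] <= config.anchor_window_s:
        a = int(rest_before[-1])
    else:
        a = i0
        degraded = True

    # ZUPT integration with linear drift correction: v(anchor) = 0 and the
    # corrected velocity returns to 0 at the phase end.
    seg_t = t[a:i1]
    vel = cumulative_trapezoid(orient.acc_global[a:i1], seg_t, axis=0, initial=0.0)
    span = seg_t[-1] - seg_t[0]
    if span > 0:
        ramp = (seg_t - seg_t[0]) / span
        vel = vel - ramp[:, None] * vel[-1]

    sel = slice(i0 - a, i1 - a)
    v_phase = vel[sel]
    t_phase = seg_t[sel]
    disp = np.trapezoid(v_phase, t_phase, axis=0) if len(t_phase) > 1 else np.zeros(3)

    pitch = orient.euler[i0:i1, 1]
    yaw = np.unwrap(np.deg2rad(orient.euler[i0:i1, 2]))
    turning = float(np.rad2deg(yaw[-1] - yaw[0]))
    wz = np.abs(orient.gyr_global[i0:i1, 2])

    return FeatureVector(
        max_acc_norm=float(np.max(np.linalg.norm(orient.acc_global[i0:i1], axis=1))),
        max_pitch_deg=float(np.max(pitch)),
        min_pitch_deg=float(np.min(pitch)),
        stride_length_m=float(np.hypot(disp[0], disp[1])),
        max_stride_velocity_mps=float(np.max(np.linalg.norm(v_phase[:, :2], axis=1))),
        turning_angle_deg=turning,
        turned_flag=int(abs(turning) > config.turn_flag_deg),
        max_turn_rate_dps=float(np.max(wz)),
        mean_turn_rate_dps=float(np.mean(wz)),
        stride_duration_s=float(phase.end - phase.start),
        degraded=degraded,
    )


def extract_all(phases: Sequence[MotionPhase], orient: OrientationState,
                stream: ImuStream, labels: np.ndarray,
                config: FeatureConfig | None = None
                ) -> Tuple[np.ndarray, List[FeatureVector]]:
    """Feature matrix for a time-ordered phase list; row order = phase order."""
    for a, b in zip(phases, list(phases)[1:]):
        if b.start < a.end:
            raise ValidationError("phases must be time-ordered and non-overlapping")
    fvs = [extract(p, orient, stream, labels, config) for p in phases]
    X = (np.vstack([fv.as_array() for fv in fvs])
         if fvs else np.empty((0, len(FEATURE_NAMES))))
    return X, fvs


def features_from_sequence(seq: PhaseSequence, orient: OrientationState,
                           stream: ImuStream, config: FeatureConfig | None = None):
    """Convenience: features for all detected phases of a PhaseSequence."""
    return extract_all(seq.phases, orient, stream, seq.labels, config)
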