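"""End-to-end causal pipeline: detection → features → classification → cueing."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .classifier import FogModel
from .cueing import SessionCueing, run_session
from .features import FeatureConfig, FeatureVector, extract_all
from .motion import GpdParams, OrientationState, PhaseSequence, detect_phases, estimate_orientation
from .types import (
    CueingConfig,
    ImuStream,
    MotionEvent,
    MotionPhase,
    PulseTrain,
    StimulationParams,
)

#: streams shorter than this cannot settle the filters; they yield empty output
WARMUP_S = 0.25


@dataclass
class PipelineResult:
    """Everything a session produces, on one session clock."""

    phases: List[MotionPhase]            # detected, with class_label filled
    features: np.ndarray                 # (n_phases, 10)
    scores: np.ndarray                   # classifier scores per phase
    trains: List[PulseTrain]
    intervals: List[Tuple[float, float]]
    labels: np.ndarray                   # per-sample rest/unrest/motion track
    duration_s: float

    def to_dict(self) -> dict:
        return {
            "schema": "gaitcue-session-1",
            "duration_s": self.duration_s,
            "phases": [p.to_dict() for p in self.phases],
            "scores": self.scores.tolist(),
            "trains": [tr.to_dict() for tr in self.trains],
            "intervals": [list(iv) for iv in self.intervals],
        }


def phases_to_events(phases: List[MotionPhase]) -> List[MotionEvent]:
    """Expand classified phases into the controller's event stream."""
    events: List[MotionEvent] = []
    for p in phases:
        events.append(MotionEvent(kind="motion_start", time=p.start))
        events.append(MotionEvent(kind="motion_end", time=p.end,
                                  classification=p.class_label))
    # at equal timestamps the closing event precedes the next opening one
    return sorted(events, key=lambda e: (e.time, 0 if e.kind == "motion_end" else 1))


def run_pipeline(stream: ImuStream, model: Optional[FogModel],
                 config: CueingConfig | None = None,
                 gpd_params: GpdParams | None = None,
                 feature_config: FeatureConfig | None = None,
                 stim_params: StimulationParams | None = None) -> PipelineResult:
    """Causally compose the full pipeline on one stream.

    With ``model=None`` every phase is classified as normal (detection-only
    run, no cueing).
    """
    config = config or CueingConfig()
    gpd_params = gpd_params or GpdParams()
    if stream.n == 0 or stream.duration < WARMUP_S:
        warnings.warn("stream shorter than filter warm-up; returning empty outputs")
        return PipelineResult(phases=[], features=np.empty((0, 10)),
                              scores=np.empty(0), trains=[], intervals=[],
                              labels=np.empty(0, dtype=np.int8),
                              duration_s=stream.duration)

    orient = estimate_orientation(stream, gain=gpd_params.gain,
                                  acc_gate=gpd_params.acc_gate,
                                  gyr_gate=gpd_params.gyr_gate_dps)
    seq = detect_phases(stream, orient, gpd_params)
    X, fvs = extract_all(seq.phases, orient, stream, seq.labels, feature_config)

    if model is not None and len(seq.phases):
        labels, scores = model.predict(X)
    else:
        labels = np.array(["normal"] * len(seq.phases))
        scores = np.zeros(len(seq.phases))
    phases = [MotionPhase(start=p.start, end=p.end, source="detected",
                          leg=p.leg, class_label=str(lbl))
              for p, lbl in zip(seq.phases, labels)]

    cueing: SessionCueing = run_session(phases_to_events(phases), config, stim_params)
    return PipelineResult(phases=phases, features=X, scores=np.asarray(scores, dtype=float),
                          trains=cueing.trains, intervals=cueing.intervals,
                          labels=seq.labels, duration_s=stream.duration)
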