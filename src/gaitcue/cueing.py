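"""On-demand gait-synchronous cueing controller and rhythmic fallback.

A FoG-classified motion phase opens (or extends) an on-demand cueing
interval of ``t_agsc_on`` seconds counted from that phase's end.  While an
interval is active every detected motion phase is cued: a pulse train
opens at the motion-phase start and closes at its end, stretched to at
least ``t_min`` and clipped to at most ``t_max``, with at least ``t_off``
of silence between consecutive trains.  Because classification happens
only at the phase end, the interval-opening phase itself can only be cued
retroactively: it receives a ``t_min`` train starting at its
classification instant (configurable).

The controller runs on an integer-millisecond clock, mirroring the 1 ms
sensor/stimulator synchronization accuracy; event times are first shifted
by the configured transport latency and quantized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .types import (
    CueingConfig,
    MotionEvent,
    PulseTrain,
    StimulationParams,
    ValidationError,
)


def quantize_ms(t: float) -> int:
    """Quantize a session time (s) to the 1 ms controller clock."""
    return int(round(t * 1000.0))


def prepare_events(events: Sequence[MotionEvent], config: CueingConfig) -> List[MotionEvent]:
    """Apply the event transport latency and 1 ms quantization."""
    out = [MotionEvent(kind=e.kind, time=quantize_ms(e.time + config.event_latency) / 1000.0,
                       classification=e.classification)
           for e in events]
    for a, b in zip(out, out[1:]):
        if b.time < a.time:
            raise ValidationError("events must be time-ordered")
    return out


@dataclass
class ControllerState:
    interval_start_ms: Optional[int] = None
    interval_end_ms: Optional[int] = None
    last_train_end_ms: Optional[int] = None
    open_train_start_ms: Optional[int] = None
    phase_cued: bool = False
    last_event_ms: Optional[int] = None

    def interval_active(self, t_ms: int) -> bool:
        return self.interval_end_ms is not None and t_ms < self.interval_end_ms


class CueingController:
    """Folds motion events into pulse trains and on-demand intervals."""

    def __init__(self, config: CueingConfig | None = None,
                 stim_params: StimulationParams | None = None):
        self.config = config or CueingConfig()
        self.stim = stim_params or StimulationParams()
        self.t_on = quantize_ms(self.config.t_agsc_on)
        self.t_off = quantize_ms(self.config.t_off)
        self.t_min = quantize_ms(self.config.t_min)
        self.t_max = quantize_ms(self.config.t_max)
        self.state = ControllerState()
        self._trains_ms: List[Tuple[int, int]] = []
        self._intervals_ms: List[List[int]] = []

    def _gap_ok(self, t_ms: int) -> bool:
        last = self.state.last_train_end_ms
        return last is None or t_ms >= last + self.t_off

    def _emit(self, start_ms: int, end_ms: int) -> None:
        self._trains_ms.append((start_ms, end_ms))
        self.state.last_train_end_ms = end_ms

    def on_event(self, event: MotionEvent) -> List[PulseTrain]:
        """Process one (already latency-shifted) event; returns any pulse
        trains finalized by it."""
        st = self.state
        t = quantize_ms(event.time)
        if st.last_event_ms is not None and t < st.last_event_ms:
            raise ValidationError("non-monotone event")
        st.last_event_ms = t
        new_trains: List[Tuple[int, int]] = []

        if event.kind == "motion_start":
            st.phase_cued = False
            if st.interval_active(t) and st.open_train_start_ms is None and self._gap_ok(t):
                st.open_train_start_ms = t
                st.phase_cued = True
            return []

        # motion_end
        if st.open_train_start_ms is not None:
            s = st.open_train_start_ms
            end = min(max(s + self.t_min, t), s + self.t_max)
            self._emit(s, end)
            new_trains.append((s, end))
            st.open_train_start_ms = None

        if event.classification == "fog":
            if st.interval_active(t):
                st.interval_end_ms = max(st.interval_end_ms, t + self.t_on)
                self._intervals_ms[-1][1] = st.interval_end_ms
            else:
                st.interval_start_ms = t
                st.interval_end_ms = t + self.t_on
                self._intervals_ms.append([t, st.interval_end_ms])
            if self.config.cue_triggering_phase and not st.phase_cued and self._gap_ok(t):
                self._emit(t, t + self.t_min)
                new_trains.append((t, t + self.t_min))
                st.phase_cued = True
        return [self._to_train(s, e) for s, e in new_trains]

    def finish(self) -> List[PulseTrain]:
        """Close a dangling train (stream ended mid-phase) at its minimum
        legal duration."""
        st = self.state
        out: List[PulseTrain] = []
        if st.open_train_start_ms is not None:
            s = st.open_train_start_ms
            self._emit(s, s + self.t_min)
            out.append(self._to_train(s, s + self.t_min))
            st.open_train_start_ms = None
        return out

    def _to_train(self, s_ms: int, e_ms: int) -> PulseTrain:
        return PulseTrain(start=s_ms / 1000.0, end=e_ms / 1000.0,
                          params=self.stim, trigger="on_demand")

    @property
    def trains(self) -> List[PulseTrain]:
        return [self._to_train(s, e) for s, e in self._trains_ms]

    @property
    def intervals(self) -> List[Tuple[float, float]]:
        return [(s / 1000.0, e / 1000.0) for s, e in self._intervals_ms]


@dataclass
class SessionCueing:
    trains: List[PulseTrain]
    intervals: List[Tuple[float, float]]   # union of on-demand intervals


def run_session(events: Sequence[MotionEvent], config: CueingConfig | None = None,
                stim_params: StimulationParams | None = None) -> SessionCueing:
    """Fold an event list through the controller; returns the closed pulse
    trains and the on-demand cueing intervals."""
    config = config or CueingConfig()
    ctrl = CueingController(config, stim_params)
    for ev in prepare_events(events, config):
        ctrl.on_event(ev)
    ctrl.finish()
    return SessionCueing(trains=ctrl.trains, intervals=ctrl.intervals)


def rhythmic_cueing(start: float, stop: float, period: float, duty: float,
                    params: StimulationParams | None = None,
                    t_off: float = 0.1, t_min: float = 0.2) -> List[PulseTrain]:
    """Open-loop rhythmic cueing: periodic trains of ``duty * period``
    seconds from ``start`` until ``stop`` (patient-triggered fallback for
    akinetic episodes)."""
    if not 0 < duty < 1:
        raise ValidationError("duty must be in (0, 1)")
    if period <= 0:
        raise ValidationError("period must be positive")
    if stop <= start:
        return []
    length = duty * period
    if length < t_min:
        warnings.warn(f"duty*period = {length:.3f} s below t_min; trains lengthened "
                      f"to {t_min} s")
        length = t_min
    if length > period - t_off:
        raise ValidationError("duty leaves less than t_off between trains")
    params = params or StimulationParams()
    trains: List[PulseTrain] = []
    k = 0
    while start + k * period + length <= stop + 1e-9:
        s = start + k * period
        trains.append(PulseTrain(start=s, end=s + length, params=params,
                                 trigger="rhythmic"))
        k += 1
    return trains
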