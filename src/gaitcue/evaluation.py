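"""Evaluation of phase detection, cueing and classification.

Implements the interval-overlap matching methodology: an annotated motion
phase counts as correctly detected if at least one system phase overlaps
it *exclusively* (intersects that annotated phase and no other); system
phases overlapping zero or several annotated phases are false detections.
For matched pairs, start/end detection delays and duration differences
are summarized.  Cueing coverage restricts to the union of the on-demand
intervals and reports which temporal share of motion-phase time and of
non-motion time was stimulated.  Detected phases inherit their FoG ground
truth from the episode containing their end time.

Intervals are half-open [start, end): a shared endpoint is not an overlap.
Printed percentages are rounded half-up to one decimal.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .types import (
    FogEpisode,
    MotionPhase,
    PulseTrain,
    ValidationError,
    check_non_overlapping,
)

Span = Tuple[float, float]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Half-up rounding as used in printed percentages (94.05 -> 94.1)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _overlaps(a: Span, b: Span) -> bool:
    """Half-open interval intersection test."""
    return a[0] < b[1] and b[0] < a[1]


def _merge(spans: Iterable[Span]) -> List[Span]:
    spans = sorted((s for s in spans if s[1] > s[0]), key=lambda s: s[0])
    out: List[Span] = []
    for s in spans:
        if out and s[0] <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], s[1]))
        else:
            out.append(s)
    return out


def _intersect(a: Sequence[Span], b: Sequence[Span]) -> List[Span]:
    out: List[Span] = []
    i = j = 0
    a = _merge(a)
    b = _merge(b)
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if hi > lo:
            out.append((lo, hi))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _total(spans: Sequence[Span]) -> float:
    return float(sum(e - s for s, e in _merge(spans)))


def _complement_within(spans: Sequence[Span], within: Sequence[Span]) -> List[Span]:
    out: List[Span] = []
    spans = _merge(spans)
    for lo, hi in _merge(within):
        cur = lo
        for s, e in spans:
            if e <= cur or s >= hi:
                continue
            if s > cur:
                out.append((cur, min(s, hi)))
            cur = max(cur, e)
            if cur >= hi:
                break
        if cur < hi:
            out.append((cur, hi))
    return out


@dataclass
class MatchResult:
    correct: List[Tuple[MotionPhase, MotionPhase]]   # (annotated, first exclusive match)
    missed: List[MotionPhase]
    false_detections: List[MotionPhase]
    n_annotated: int
    n_correct: int
    n_missed: int
    n_false: int

    @property
    def rate_correct_pct(self) -> float:
        return round_half_up(100.0 * self.n_correct / self.n_annotated) \
            if self.n_annotated else float("nan")

    @property
    def rate_missed_pct(self) -> float:
        return round_half_up(100.0 * self.n_missed / self.n_annotated) \
            if self.n_annotated else float("nan")


def match_phases(annotated: Sequence[MotionPhase],
                 detected: Sequence[MotionPhase]) -> MatchResult:
    """Exclusive-overlap matching of detected against annotated phases.

    A detected phase overlapping several annotated phases is counted once
    as a false detection; for an annotated phase with several exclusive
    matches only the first (earliest start) is kept as the match.  The
    annotated list must be disjoint; detected phases need not be (e.g.
    when pooling lists from several runs).
    """
    check_non_overlapping(annotated, "annotated phases")
    ann = sorted(annotated, key=lambda p: p.start)
    det = sorted(detected, key=lambda p: p.start)

    owners: List[List[int]] = []       # annotated indices each detected touches
    for d in det:
        owners.append([i for i, a in enumerate(ann)
                       if _overlaps((a.start, a.end), (d.start, d.end))])

    false_detections = [d for d, o in zip(det, owners) if len(o) != 1]
    matches: dict[int, MotionPhase] = {}
    for d, o in zip(det, owners):
        if len(o) == 1 and o[0] not in matches:   # det sorted: earliest first
            matches[o[0]] = d
    correct = [(ann[i], matches[i]) for i in sorted(matches)]
    missed = [a for i, a in enumerate(ann) if i not in matches]
    return MatchResult(correct=correct, missed=missed,
                       false_detections=false_detections,
                       n_annotated=len(ann), n_correct=len(correct),
                       n_missed=len(missed), n_false=len(false_detections))


@dataclass
class DelayStats:
    """Start/end detection delays and duration differences over matched
    pairs (detected minus annotated, seconds)."""

    start_delays: np.ndarray
    end_delays: np.ndarray
    duration_diffs: np.ndarray

    def summary(self) -> dict:
        def q(x):
            if len(x) == 0:
                return {"median": float("nan"), "q1": float("nan"), "q3": float("nan")}
            return {"median": float(np.median(x)),
                    "q1": float(np.percentile(x, 25)),
                    "q3": float(np.percentile(x, 75))}
        return {"start_delay_s": q(self.start_delays),
                "end_delay_s": q(self.end_delays),
                "duration_diff_s": q(self.duration_diffs),
                "n_pairs": int(len(self.start_delays))}


def delay_stats(match: MatchResult) -> DelayStats:
    starts, ends, durs = [], [], []
    for a, d in match.correct:
        starts.append(d.start - a.start)
        ends.append(d.end - a.end)
        durs.append(d.duration - a.duration)
    return DelayStats(start_delays=np.array(starts), end_delays=np.array(ends),
                      duration_diffs=np.array(durs))


def cueing_coverage(annotated_mps: Sequence[MotionPhase],
                    trains: Sequence[PulseTrain],
                    intervals: Sequence[Span]) -> dict:
    """Temporal shares of stimulated motion-phase and non-motion time,
    restricted to the union of on-demand cueing intervals (percent)."""
    within = _merge(intervals)
    mp = _intersect([(p.start, p.end) for p in annotated_mps], within)
    non_mp = _complement_within(mp, within)
    stim = _merge([(tr.start, tr.end) for tr in trains])

    mp_time = _total(mp)
    non_mp_time = _total(non_mp)
    pct_mp = (100.0 * _total(_intersect(stim, mp)) / mp_time
              if mp_time > 0 else None)
    pct_non = (100.0 * _total(_intersect(stim, non_mp)) / non_mp_time
               if non_mp_time > 0 else None)
    return {"pct_mp_time_stimulated": pct_mp,
            "pct_nonmp_time_stimulated": pct_non,
            "mp_time_s": mp_time, "nonmp_time_s": non_mp_time}


def label_detected(detected: Sequence[MotionPhase],
                   episodes: Sequence[FogEpisode]) -> List[str]:
    """FoG ground truth of detected phases by the end-time rule: a phase is
    FoG-associated iff its end lies in [episode start, episode end)."""
    check_non_overlapping(episodes, "FoG episodes")
    eps = sorted(episodes, key=lambda e: e.start)
    labels = []
    for p in detected:
        labels.append("fog" if any(e.start <= p.end < e.end for e in eps) else "normal")
    return labels


def classification_metrics(predicted: Sequence[str], truth: Sequence[str]) -> dict:
    """Sensitivity/specificity/accuracy (percent) with fog as the positive
    class, plus the confusion matrix."""
    predicted = list(predicted)
    truth = list(truth)
    if len(predicted) == 0 or len(predicted) != len(truth):
        raise ValidationError("predicted and truth labels must be non-empty and aligned")
    tp = sum(1 for p, t in zip(predicted, truth) if p == "fog" and t == "fog")
    fn = sum(1 for p, t in zip(predicted, truth) if p != "fog" and t == "fog")
    tn = sum(1 for p, t in zip(predicted, truth) if p != "fog" and t != "fog")
    fp = sum(1 for p, t in zip(predicted, truth) if p == "fog" and t != "fog")
    sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    acc = 100.0 * (tp + tn) / len(truth)
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc,
            "confusion": {"tp": tp, "fn": fn, "tn": tn, "fp": fp}}


@dataclass
class GaitReport:
    """Session-level gait report (step counts, FoG share, cueing share)."""

    duration_s: float
    cueing_s: float
    n_mps: int
    n_fog_mps: int
    n_cued_mps: int
    percent_fog: float
    percent_cueing_active: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def gait_report(phases: Sequence[MotionPhase], trains: Sequence[PulseTrain],
                duration_s: float, event_latency: float = 0.0) -> GaitReport:
    """Summarize a session: a motion phase counts as cued if any pulse
    train overlaps it or a train was emitted at its end (the retroactive
    triggering-phase cue).  ``event_latency`` widens the end-match
    tolerance by the transport delay the controller saw."""
    n_mps = len(phases)
    n_fog = sum(1 for p in phases if p.class_label == "fog")
    spans = [(tr.start, tr.end) for tr in trains]
    tol = 2e-3 + event_latency   # 1 ms clock + transport latency
    n_cued = 0
    for p in phases:
        hit = any(_overlaps((p.start, p.end), s) for s in spans)
        hit = hit or any(abs(tr.start - p.end) <= tol + 1e-9 for tr in trains)
        n_cued += bool(hit)
    cueing_s = _total(spans)
    return GaitReport(
        duration_s=float(duration_s), cueing_s=cueing_s,
        n_mps=n_mps, n_fog_mps=n_fog, n_cued_mps=n_cued,
        percent_fog=round_half_up(100.0 * n_fog / n_mps) if n_mps else 0.0,
        percent_cueing_active=round_half_up(100.0 * cueing_s / duration_s)
        if duration_s > 0 else 0.0,
    )


def mean_percent(values: Sequence[float]) -> float:
    """Aggregate per-subject percentages as their arithmetic mean, rounded
    half-up to one decimal (report convention)."""
    return round_half_up(float(np.mean(np.asarray(values, dtype=float))))
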