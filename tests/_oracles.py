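"""Independent reference implementations used as test oracles.

These deliberately re-derive results through different mechanics than the
package (rasterized 1 ms timelines, exhaustive enumeration) so agreement
is meaningful.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np

from gaitcue.types import CueingConfig, MotionEvent


def controller_oracle_ms(events: Sequence[MotionEvent], config: CueingConfig
                         ) -> Tuple[List[Tuple[float, float]], List[Tuple[float, float]]]:
    """Rasterized millisecond-timeline simulation of on-demand cueing.

    Consumes *prepared* (latency-shifted, quantized) events and walks the
    session one millisecond at a time, marking boolean stimulation and
    on-demand masks; trains and intervals are read back as run lengths.
    """
    t_on = int(round(config.t_agsc_on * 1000))
    t_off = int(round(config.t_off * 1000))
    t_min = int(round(config.t_min * 1000))
    t_max = int(round(config.t_max * 1000))

    evs = sorted(((int(round(e.time * 1000)), e.kind, e.classification) for e in events),
                 key=lambda x: (x[0], 0 if x[1] == "motion_end" else 1))
    if not evs:
        return [], []
    horizon = evs[-1][0] + t_on + t_max + 2
    stim = np.zeros(horizon, dtype=bool)
    ondemand = np.zeros(horizon, dtype=bool)

    open_start = None      # ms index of the currently filling train
    sched_end = None       # scheduled end once the phase has ended
    phase_cued = False
    by_time: dict[int, list] = {}
    for t, kind, cls in evs:
        by_time.setdefault(t, []).append((kind, cls))

    def gap_ok(t: int) -> bool:
        return not stim[max(0, t - t_off):t].any()

    for t in range(horizon):
        if open_start is not None:
            end = sched_end if sched_end is not None else open_start + t_max
            if t >= end:
                open_start = None
                sched_end = None
        for kind, cls in by_time.get(t, []):
            if kind == "motion_start":
                phase_cued = False
                if ondemand[t] and open_start is None and gap_ok(t):
                    open_start = t
                    sched_end = None
                    phase_cued = True
            else:  # motion_end
                if open_start is not None and sched_end is None:
                    sched_end = min(max(open_start + t_min, t), open_start + t_max)
                if cls == "fog":
                    ondemand[t:t + t_on] = True
                    if (config.cue_triggering_phase and not phase_cued
                            and open_start is None and gap_ok(t)):
                        open_start = t
                        sched_end = t + t_min
                        phase_cued = True
        if open_start is not None:
            end = sched_end if sched_end is not None else open_start + t_max
            if t >= end:
                open_start = None
                sched_end = None
        if open_start is not None:
            stim[t] = True

    def runs(mask: np.ndarray) -> List[Tuple[float, float]]:
        padded = np.concatenate([[False], mask, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(int)))
        return [(edges[i] / 1000.0, edges[i + 1] / 1000.0)
                for i in range(0, len(edges), 2)]

    return runs(stim), runs(ondemand)


def random_event_stream(seed: int, duration_s: float = 15.0,
                        fog_prob: float = 0.3) -> List[MotionEvent]:
    """Random but well-formed motion-phase event streams for fuzzing."""
    rng = np.random.default_rng(seed)
    events: List[MotionEvent] = []
    t = float(rng.uniform(0.1, 0.5))
    while t < duration_s:
        dur = float(rng.uniform(0.02, 1.0))
        cls = "fog" if rng.random() < fog_prob else "normal"
        events.append(MotionEvent(kind="motion_start", time=round(t, 3)))
        events.append(MotionEvent(kind="motion_end", time=round(t + dur, 3),
                                  classification=cls))
        t += dur + float(rng.uniform(0.03, 1.5))
    return events


def reference_detection_fixture(n_annotated: int, n_matched: int, n_false: int):
    """Synthetic annotated/detected interval lists realizing given matching
    counts: the first ``n_matched`` annotated phases each receive one
    exclusively-overlapping detection, the rest none, plus ``n_false``
    spurious detections in the gaps."""
    from gaitcue.types import MotionPhase

    annotated = [MotionPhase(start=3.0 * i, end=3.0 * i + 0.4, source="annotated")
                 for i in range(n_annotated)]
    detected = [MotionPhase(start=3.0 * i + 0.05, end=3.0 * i + 0.41)
                for i in range(n_matched)]
    detected += [MotionPhase(start=3.0 * i + 1.0, end=3.0 * i + 1.2)
                 for i in range(n_false)]
    return annotated, sorted(detected, key=lambda p: p.start)


def brute_force_match(annotated, detected) -> Tuple[int, int, int]:
    """O(n·m) set-based re-derivation of exclusive-overlap matching.

    Returns (n_correct, n_missed, n_false)."""
    def hits(d):
        return {i for i, a in enumerate(annotated)
                if max(a.start, d.start) < min(a.end, d.end)}

    owners = [hits(d) for d in detected]
    n_false = sum(1 for o in owners if len(o) != 1)
    matched = {next(iter(o)) for o in owners if len(o) == 1}
    n_correct = len(matched)
    return n_correct, len(annotated) - n_correct, n_false


def brute_force_label(detected, episodes) -> List[str]:
    out = []
    for p in detected:
        lab = "normal"
        for e in episodes:
            if e.start <= p.end < e.end:
                lab = "fog"
        out.append(lab)
    return out


def rasterized_coverage(annotated_mps, trains, intervals,
                        step_ms: int = 1) -> Tuple[float, float]:
    """1 ms rasterized cueing-coverage shares (percent)."""
    horizon = int(round(1000 * max(
        [iv[1] for iv in intervals] + [p.end for p in annotated_mps]
        + [tr.end for tr in trains], default=0.0))) + 2
    grid = np.arange(horizon) / 1000.0 + 0.0005   # midpoint sampling
    within = np.zeros(horizon, dtype=bool)
    for s, e in intervals:
        within |= (grid >= s) & (grid < e)
    mp = np.zeros(horizon, dtype=bool)
    for p in annotated_mps:
        mp |= (grid >= p.start) & (grid < p.end)
    stim = np.zeros(horizon, dtype=bool)
    for tr in trains:
        stim |= (grid >= tr.start) & (grid < tr.end)
    mp_in = mp & within
    non_in = ~mp & within
    pct_mp = 100.0 * np.sum(stim & mp_in) / np.sum(mp_in) if np.sum(mp_in) else np.nan
    pct_non = 100.0 * np.sum(stim & non_in) / np.sum(non_in) if np.sum(non_in) else np.nan
    return pct_mp, pct_non


def brute_force_stump_boost(X: np.ndarray, y: np.ndarray, n_estimators: int
                            ) -> np.ndarray:
    """Exhaustive boosting recursion with decision stumps.

    Every candidate stump (feature, midpoint threshold) is enumerated; the
    one minimizing the weighted Gini impurity of its children is taken as
    the weak learner (majority class per side), followed by the discrete
    two-class boosting weight updates.  Returns the ensemble's predictions
    on X (0/1)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    w = np.full(n, 1.0 / n)
    stumps = []   # (feature, threshold, left_class, right_class)
    alphas = []

    def gini_side(mask):
        tot = w[mask].sum()
        if tot == 0:
            return 0.0
        p1 = w[mask & (y == 1)].sum() / tot
        return tot * (1.0 - p1 * p1 - (1 - p1) * (1 - p1))

    for _ in range(n_estimators):
        best = None
        for j in range(X.shape[1]):
            vals = np.unique(X[:, j])
            for thr in (vals[:-1] + vals[1:]) / 2.0:
                left = X[:, j] <= thr
                score = gini_side(left) + gini_side(~left)
                if best is None or score < best[0] - 1e-15:
                    wl = w[left]
                    lc = int(wl[y[left] == 1].sum() > wl[y[left] == 0].sum())
                    wr = w[~left]
                    rc = int(wr[y[~left] == 1].sum() > wr[y[~left] == 0].sum())
                    best = (score, j, thr, lc, rc)
        _, j, thr, lc, rc = best
        pred = np.where(X[:, j] <= thr, lc, rc)
        err = w[pred != y].sum() / w.sum()
        if err >= 0.5:
            if not stumps:
                stumps.append((j, thr, lc, rc))
                alphas.append(1.0)
            break
        err = min(max(err, 1e-10), 1 - 1e-10)
        alpha = np.log((1 - err) / err)
        stumps.append((j, thr, lc, rc))
        alphas.append(alpha)
        if err <= 1e-10:
            break
        w = w * np.exp(alpha * (pred != y))
        w = w / w.sum()

    votes = np.zeros(n)
    for (j, thr, lc, rc), alpha in zip(stumps, alphas):
        votes += alpha * np.where(X[:, j] <= thr, lc, rc)
    return (votes / sum(alphas) > 0.5).astype(int)
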