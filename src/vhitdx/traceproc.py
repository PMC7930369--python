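"""Per-trial quantification of vHIT recordings.

Pipeline per trial: artifact QC -> impulse onset and head-velocity
zero-crossing -> VOR gain as the ratio of the eye-velocity area to the
head-velocity area over [onset, zero-crossing] -> detection of *overt*
corrective saccades (eye-velocity excursions after the zero-crossing) with
area (deg) and latency (ms from impulse onset to saccade peak).

Per subject x canal x side, saccades are then passed through a consistency
rule: only clusters of similar saccades (area within +-50% and latency
within +-60 ms of the cluster median) that recur in more than 20% of
accepted trials are retained for analysis.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import (
    CANALS, ImpulseTrial, OnsetError, ParameterError, SaccadeEvent, SideStats,
    SubjectSummary, TraceError, TrialMetrics, VelocityTrace, ZeroCrossError,
)

log = logging.getLogger("vhitdx")


@dataclass(frozen=True)
class QCThresholds:
    """Tunable QC and detection thresholds (deg/s, ms)."""

    onset_threshold: float = 20.0       # head-velocity crossing defining the onset
    onset_sustain_ms: float = 20.0
    min_peak: float = 150.0             # impulses below this head peak are rejected
    blink_dip: float = 100.0            # anticompensatory eye-residual dip flagging a blink
    osc_band: tuple[float, float] = (10.0, 22.0)   # Hz
    osc_amplitude: float = 10.0         # equivalent sinusoid amplitude, deg/s
    osc_excise_threshold: float = 60.0  # transient level excised before the band test
    zero_cross_small: float = 5.0       # |head| below this counts as "stopped"
    zero_cross_sustain_ms: float = 20.0
    zero_cross_search_ms: float = 500.0
    saccade_threshold: float = 40.0     # eye-velocity excursion threshold
    saccade_bound: float = 5.0          # boundary extension level
    saccade_search_ms: float = 700.0
    desaccade_threshold: float = 40.0   # residual level triggering desaccading
    consistency_min_fraction: float = 0.20
    consistency_area_tol: float = 0.50
    consistency_latency_tol: float = 60.0


DEFAULT_QC = QCThresholds()


def _direction_sign(head: np.ndarray) -> float:
    return 1.0 if head[int(np.argmax(np.abs(head)))] >= 0 else -1.0


def _cross_time(t0: float, t1: float, v0: float, v1: float, level: float) -> float:
    """Linear-interpolated time at which the segment crosses `level`."""
    if v1 == v0:
        return t0
    return t0 + (level - v0) * (t1 - t0) / (v1 - v0)


def detect_onset(trace: VelocityTrace, threshold: float = 20.0,
                 sustain_ms: float = 20.0) -> float:
    """First time the head speed crosses `threshold` and stays above it for
    at least `sustain_ms` (linear interpolation between samples)."""
    s = _direction_sign(trace.head_vel)
    v = s * trace.head_vel
    t = trace.time
    n_sustain = max(1, int(round(sustain_ms / trace.dt)))
    above = v >= threshold if threshold > 0 else v > 0
    idx = np.flatnonzero(above)
    for i in idx:
        if np.all(v[i:i + n_sustain] >= min(threshold, v[i])) and above[i:i + n_sustain].all():
            if i == 0 or threshold == 0:
                return float(t[i])
            return float(_cross_time(t[i - 1], t[i], v[i - 1], v[i], threshold))
    raise OnsetError("no sustained onset crossing found")


def find_zero_crossing(trace: VelocityTrace, onset_ms: float,
                       qc: QCThresholds = DEFAULT_QC) -> float:
    """First head-velocity zero-crossing after the impulse peak.

    A sign change (interpolated) counts; failing that, the first sustained
    spell of |head| below `qc.zero_cross_small` for `zero_cross_sustain_ms`
    counts, with the crossing interpolated at the small-velocity level.
    """
    s = _direction_sign(trace.head_vel)
    v = s * trace.head_vel
    t = trace.time
    start = int(np.searchsorted(t, onset_ms))
    peak = start + int(np.argmax(v[start:]))
    horizon = t[peak] + qc.zero_cross_search_ms

    after = v[peak:]
    neg = np.flatnonzero(after <= 0.0)
    if neg.size:
        i = peak + int(neg[0])
        if t[i] <= horizon:
            if v[i] == 0.0:
                return float(t[i])
            return float(_cross_time(t[i - 1], t[i], v[i - 1], v[i], 0.0))
    # fallback: sustained near-zero velocity
    n_sustain = max(1, int(round(qc.zero_cross_sustain_ms / trace.dt)))
    small = np.abs(after) < qc.zero_cross_small
    for j in np.flatnonzero(small):
        if t[peak + j] > horizon:
            break
        if small[j:j + n_sustain].size == n_sustain and small[j:j + n_sustain].all():
            i = peak + j
            if i > peak and v[i - 1] > v[i]:
                return float(_cross_time(t[i - 1], t[i], v[i - 1], v[i],
                                         qc.zero_cross_small))
            return float(t[i])
    raise ZeroCrossError("no zero-crossing within the search horizon")


def _integrate(t: np.ndarray, y: np.ndarray, a: float, b: float) -> float:
    """Trapezoid integral of the sampled channel over [a, b] ms -> deg,
    with linear interpolation at the fractional endpoints."""
    if b <= a:
        return 0.0
    inner = (t > a) & (t < b)
    ts = np.concatenate(([a], t[inner], [b]))
    ys = np.concatenate(([np.interp(a, t, y)], y[inner], [np.interp(b, t, y)]))
    return float(np.trapezoid(ys, ts) / 1000.0)


def _window_slice(t: np.ndarray, a: float, b: float) -> slice:
    return slice(int(np.searchsorted(t, a)), int(np.searchsorted(t, b, side="right")))


def _robust_gain(head_w: np.ndarray, eye_w: np.ndarray) -> float:
    """Median per-sample eye/head ratio over the high-velocity part of the
    window — insensitive to saccadic intrusions, unlike the area ratio."""
    strong = np.abs(head_w) >= 0.3 * np.abs(head_w).max()
    if not strong.any():
        return 0.0
    return float(np.median(eye_w[strong] / head_w[strong]))


def _excise_transients(resid: np.ndarray, hot_thr: float, low_thr: float) -> np.ndarray:
    """Replace monophasic positive excursions beyond `hot_thr` (extended to
    the `low_thr` crossings) with linear interpolation.  Used to keep covert
    saccades from registering as trace oscillations."""
    hot = resid > hot_thr
    if not hot.any():
        return resid
    out = resid.copy()
    low = resid < low_thr
    idx = np.flatnonzero(hot)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    x = np.arange(resid.size, dtype=float)
    for run in runs:
        i0, i1 = int(run[0]), int(run[-1])
        while i0 > 0 and not low[i0 - 1]:
            i0 -= 1
        while i1 < resid.size - 1 and not low[i1 + 1]:
            i1 += 1
        lo, hi = max(i0 - 1, 0), min(i1 + 1, resid.size - 1)
        out[i0:i1 + 1] = np.interp(x[i0:i1 + 1], [x[lo], x[hi]], [out[lo], out[hi]])
    return out


def qc_trial(trace: VelocityTrace, qc: QCThresholds = DEFAULT_QC) -> ImpulseTrial:
    """Screen one trial for artifacts and anchor its onset/zero-crossing.

    Checks, in order: non-finite samples (``tracking_error``), head peak
    below 150 deg/s (``low_peak``), missing onset or zero-crossing, blink,
    and trace oscillation.  Blinks are recognized by their large
    *anticompensatory* eye-residual lobe (biphasic pseudo-saccades always
    carry one), which keeps monophasic covert saccades out of the blink
    class; the oscillation test measures 10-22 Hz band amplitude of the
    movement-window eye residual after excising monophasic transients, so
    covert saccades do not masquerade as oscillations either.
    """
    if trace.time.size == 0:
        raise TraceError("empty trace")

    def rejected(reason: str, onset=None, zc=None) -> ImpulseTrial:
        log.info("trial %s rejected: %s", trace.trial_id or "<unnamed>", reason)
        return ImpulseTrial(trace, onset, zc, qc_status="rejected", reason=reason)

    if not (np.isfinite(trace.head_vel).all() and np.isfinite(trace.eye_vel).all()):
        return rejected("tracking_error")
    if np.abs(trace.head_vel).max() < qc.min_peak:
        return rejected("low_peak")
    try:
        onset = detect_onset(trace, qc.onset_threshold, qc.onset_sustain_ms)
    except OnsetError:
        return rejected("no_onset")
    try:
        zc = find_zero_crossing(trace, onset, qc)
    except ZeroCrossError:
        return rejected("no_zero_cross", onset)

    # Direction-normalized eye residual during head movement, after removing
    # the compensatory component scaled by the raw area ratio.
    t = trace.time
    s = _direction_sign(trace.head_vel)
    sl = _window_slice(t, onset, zc)
    g0 = _robust_gain(trace.head_vel[sl], trace.eye_vel[sl])
    resid = s * (trace.eye_vel[sl] - g0 * trace.head_vel[sl])

    if resid.size and resid.min() <= -qc.blink_dip:
        return rejected("blink", onset, zc)
    if resid.size >= 8:
        clean = _excise_transients(resid, qc.osc_excise_threshold, qc.saccade_bound)
        # zero-pad 4x so scalloping cannot hide a between-bin oscillation
        nfft = 4 * clean.size
        amp = np.abs(np.fft.rfft(clean - clean.mean(), n=nfft)) * 2.0 / clean.size
        freqs = np.fft.rfftfreq(nfft, d=trace.dt / 1000.0)
        band = (freqs >= qc.osc_band[0]) & (freqs <= qc.osc_band[1])
        if band.any() and amp[band].max() >= qc.osc_amplitude:
            return rejected("oscillation", onset, zc)
    return ImpulseTrial(trace, onset, zc)


def compute_vor_gain(trial: ImpulseTrial, qc: QCThresholds = DEFAULT_QC) -> float:
    """VOR gain: eye-velocity area / head-velocity area over
    [onset, zero-crossing].

    Saccadic intrusions inside the window (eye residual beyond
    `qc.desaccade_threshold`, extended to the 5 deg/s residual crossings)
    are replaced by linear interpolation before integrating, so covert
    saccades do not inflate the gain.  Non-negative by construction for
    compensatory responses.
    """
    if not trial.accepted:
        raise ParameterError("gain is only defined for accepted trials")
    trace, onset, zc = trial.trace, trial.onset_ms, trial.zero_cross_ms
    t = trace.time
    head_area = _integrate(t, trace.head_vel, onset, zc)
    if head_area == 0.0:
        raise ParameterError("zero head-velocity area in the gain window")
    eye = trace.eye_vel
    sl = _window_slice(t, onset, zc)
    g0 = _robust_gain(trace.head_vel[sl], eye[sl])
    resid = eye[sl] - g0 * trace.head_vel[sl]
    hot = np.abs(resid) > qc.desaccade_threshold
    if hot.any():
        eye = eye.copy()
        low = np.abs(resid) < qc.saccade_bound
        idx = np.flatnonzero(hot)
        runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        for run in runs:
            i0, i1 = run[0], run[-1]
            while i0 > 0 and not low[i0 - 1]:
                i0 -= 1
            while i1 < resid.size - 1 and not low[i1 + 1]:
                i1 += 1
            a, b = sl.start + i0, sl.start + i1
            lo = max(a - 1, 0)
            hi = min(b + 1, eye.size - 1)
            eye[a:b + 1] = np.interp(t[a:b + 1], [t[lo], t[hi]], [eye[lo], eye[hi]])
    gain = _integrate(t, eye, onset, zc) / head_area
    return float(max(gain, 0.0))


def detect_overt_saccades(trial: ImpulseTrial, qc: QCThresholds = DEFAULT_QC) -> list[SaccadeEvent]:
    """Detect overt corrective saccades after the head-velocity
    zero-crossing.

    Within [zero_cross, zero_cross + search window], compensatory-direction
    eye-velocity excursions exceeding the saccade threshold are segmented
    at the threshold crossings and extended outward to the 5 deg/s
    crossings; overlapping extents merge.  Each event's area is the
    trapezoid integral of eye velocity between its boundaries and its
    latency runs from the impulse onset to the velocity peak.
    """
    if not trial.accepted:
        raise ParameterError("saccade detection requires an accepted trial")
    trace, zc = trial.trace, trial.zero_cross_ms
    s = _direction_sign(trace.head_vel)
    t = trace.time
    v = s * trace.eye_vel
    sl = _window_slice(t, zc, zc + qc.saccade_search_ms)
    w = v[sl]
    hot = w > qc.saccade_threshold
    if not hot.any():
        return []
    low = w < qc.saccade_bound
    idx = np.flatnonzero(hot)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    intervals: list[list[int]] = []
    for run in runs:
        i0, i1 = int(run[0]), int(run[-1])
        while i0 > 0 and not low[i0 - 1]:
            i0 -= 1
        while i1 < w.size - 1 and not low[i1 + 1]:
            i1 += 1
        if intervals and i0 <= intervals[-1][1]:
            intervals[-1][1] = max(intervals[-1][1], i1)
        else:
            intervals.append([i0, i1])

    events = []
    for i0, i1 in intervals:
        a, b = sl.start + i0, sl.start + i1
        # boundary times at the 5 deg/s crossings (interpolated; clipped to
        # the window edge when the excursion abuts it)
        t_on = max(float(zc), _cross_time(t[a - 1], t[a], v[a - 1], v[a], qc.saccade_bound)
                   if a > 0 and v[a - 1] < qc.saccade_bound <= v[a] else t[a])
        t_off = (_cross_time(t[b], t[b + 1], v[b], v[b + 1], qc.saccade_bound)
                 if b + 1 < v.size and v[b + 1] < qc.saccade_bound <= v[b] else t[b])
        if t_off <= t_on:
            continue
        peak_i = a + int(np.argmax(v[a:b + 1]))
        area = _integrate(t, v, t_on, t_off)
        if area <= 0:
            continue
        events.append(SaccadeEvent(
            onset_ms=t_on, peak_ms=float(t[peak_i]), offset_ms=t_off,
            area=area, latency=float(t[peak_i]) - trial.onset_ms, overt=True))
    return events


def measure_saccade(trial: ImpulseTrial, event: SaccadeEvent) -> tuple[float, float]:
    """(area deg, latency ms) of `event`, recomputed from the trace."""
    trace = trial.trace
    if event.offset_ms <= event.onset_ms:
        raise ParameterError("degenerate (zero-width) saccade event")
    if event.onset_ms < trace.time[0] or event.offset_ms > trace.time[-1]:
        raise ParameterError("saccade event outside the trace support")
    s = _direction_sign(trace.head_vel)
    area = _integrate(trace.time, s * trace.eye_vel, event.onset_ms, event.offset_ms)
    return float(max(area, 0.0)), float(event.peak_ms - trial.onset_ms)


def process_trace(trace: VelocityTrace, qc: QCThresholds = DEFAULT_QC) -> TrialMetrics:
    """QC one trace and, if accepted, quantify gain and overt saccades."""
    trial = qc_trial(trace, qc)
    if not trial.accepted:
        return TrialMetrics(trial)
    gain = compute_vor_gain(trial, qc)
    saccades = detect_overt_saccades(trial, qc)
    return TrialMetrics(trial, vor_gain=gain, saccades=saccades)


# ---------------------------------------------------------------------------
# consistency rule and per-subject summaries

def _cluster_events(cands: list[tuple[int, SaccadeEvent]],
                    area_tol: float, latency_tol: float) -> list[list[int]]:
    """Single-linkage clustering of candidate saccades on (area, latency),
    refined so every member lies within +-`area_tol` (relative) of the
    cluster's median area and +-`latency_tol` ms of its median latency."""
    n = len(cands)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        ai, li = cands[i][1].area, cands[i][1].latency
        for j in range(i + 1, n):
            aj, lj = cands[j][1].area, cands[j][1].latency
            if abs(ai - aj) <= area_tol * max(ai, aj) and abs(li - lj) <= latency_tol:
                pi, pj = find(i), find(j)
                if pi != pj:
                    parent[pi] = pj
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)

    clusters = []
    for members in comps.values():
        members = list(members)
        for _ in range(5):
            areas = np.array([cands[i][1].area for i in members])
            lats = np.array([cands[i][1].latency for i in members])
            med_a, med_l = float(np.median(areas)), float(np.median(lats))
            keep = [i for i, a, l in zip(members, areas, lats)
                    if abs(a - med_a) <= area_tol * med_a and abs(l - med_l) <= latency_tol]
            if len(keep) == len(members):
                break
            members = keep or members[:1]
        clusters.append(members)
    return clusters


def consistency_filter(saccades_per_trial: list[list[SaccadeEvent]],
                       n_accepted: int | None = None,
                       qc: QCThresholds = DEFAULT_QC,
                       ) -> tuple[dict[int, SaccadeEvent], float]:
    """Apply the >20%-of-trials consistency rule to one subject x canal x
    side.

    `saccades_per_trial` holds the detected events of each *accepted*
    trial.  Saccades are clustered by similarity (area within +-50%,
    latency within +-60 ms of the cluster median); clusters recurring in
    more than ``consistency_min_fraction`` of accepted trials are retained.
    Returns the retained saccade per trial (largest-area event when several
    merge) and the CS incidence in percent of accepted trials.
    """
    if n_accepted is None:
        n_accepted = len(saccades_per_trial)
    if n_accepted < 1:
        raise ParameterError("consistency filter needs >= 1 accepted trial")
    cands = [(ti, ev) for ti, evs in enumerate(saccades_per_trial) for ev in evs]
    if not cands:
        return {}, 0.0
    clusters = _cluster_events(cands, qc.consistency_area_tol, qc.consistency_latency_tol)
    retained: dict[int, SaccadeEvent] = {}
    for members in clusters:
        trials_covered = {cands[i][0] for i in members}
        if len(trials_covered) > qc.consistency_min_fraction * n_accepted:
            for i in members:
                ti, ev = cands[i]
                if ti not in retained or ev.area > retained[ti].area:
                    retained[ti] = ev
    incidence = 100.0 * len(retained) / n_accepted
    return retained, incidence


def summarize_subject(subject_id: str, group: str, lesion_side: str,
                      designated_side: str,
                      metrics_by_canal_side: dict[tuple[str, str], list[TrialMetrics]],
                      qc: QCThresholds = DEFAULT_QC) -> SubjectSummary:
    """Collapse one subject's trials into per-canal, per-side statistics.

    Physical sides map onto ipsi/contra through `designated_side` (the
    lesion side for patients, the randomly designated side for healthy
    subjects).  A canal x side with zero accepted trials yields an explicit
    missing entry (``None``), never a zero.
    """
    summary = SubjectSummary(subject_id, group, lesion_side, designated_side)
    retained_by_side: dict[tuple[str, str], int] = {}
    for (canal, side), metrics in metrics_by_canal_side.items():
        accepted = [m for m in metrics if m.trial.accepted]
        laterality = "ipsi" if side == designated_side else "contra"
        if not accepted:
            log.warning("subject %s %s/%s: no accepted trials", subject_id, canal, side)
            summary.stats[(canal, laterality)] = None
            continue
        retained, incidence = consistency_filter(
            [m.saccades for m in accepted], len(accepted), qc)
        areas = [ev.area for ev in retained.values()]
        lats = [ev.latency for ev in retained.values()]
        summary.stats[(canal, laterality)] = SideStats(
            n_accepted=len(accepted),
            mean_gain=float(np.mean([m.vor_gain for m in accepted])),
            cs_incidence=incidence,
            mean_cs_area=float(np.mean(areas)) if areas else None,
            mean_cs_latency=float(np.mean(lats)) if lats else None,
        )
        retained_by_side[(canal, side)] = len(retained)
    for canal in {c for c, _ in metrics_by_canal_side}:
        sides = [retained_by_side.get((canal, s), 0) for s in ("left", "right")]
        summary.bilateral_cs[canal] = all(k > 0 for k in sides)
    return summary
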