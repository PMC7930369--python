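"""Quantification tests: onset/zero-crossing anchors, QC, AUC-ratio gain,
overt-saccade detection and the >20% consistency rule."""
import math

import numpy as np
import pytest

from vhitdx import (
    ImpulseParams, ParameterError, SaccadeEvent, VelocityTrace,
    compute_vor_gain, consistency_filter, detect_onset, detect_overt_saccades,
    find_zero_crossing, generate_head_impulse, inject_artifact, measure_saccade,
    process_trace, qc_trial, summarize_subject, synthesize_trial,
)
from vhitdx.datatypes import OnsetError, ZeroCrossError
from vhitdx.simulate import CanalSideParams, SubjectProfile, draw_impulse_params, raised_cosine


def _trace(head, eye=None, dt=4.0, **kw):
    n = len(head)
    head = np.asarray(head, float)
    eye = head.copy() if eye is None else np.asarray(eye, float)
    return VelocityTrace(np.arange(n) * dt, head, eye, **kw)


def _profile(gain, cs_prob, area=2.0, latency=350.0, group="VN"):
    params = {(c, s): CanalSideParams(gain, cs_prob, area, latency)
              for c in ("HC",) for s in ("left", "right")}
    return SubjectProfile("T01", group, "left", "left", params)


class TestOnset:
    def test_matches_closed_form_inversion(self, standard_impulse):
        """Onset = (d/2pi) * arccos(1 - 2*thr/p) after bump start, here
        16.39 ms for a 200 deg/s, 160 ms raised cosine at the 20 deg/s
        threshold (brute-force bisection of the profile agrees)."""
        trace = generate_head_impulse(standard_impulse)
        expected = (160.0 / (2 * math.pi)) * math.acos(1 - 2 * 20.0 / 200.0)
        assert expected == pytest.approx(16.3866, abs=1e-3)
        onset = detect_onset(trace) - standard_impulse.pre_roll
        assert onset == pytest.approx(expected, abs=0.15)
        # independent oracle: bisection of the analytic profile
        lo, hi = 0.0, 80.0
        for _ in range(60):
            mid = (lo + hi) / 2
            v = 100.0 * (1 - math.cos(2 * math.pi * mid / 160.0))
            lo, hi = (mid, hi) if v < 20.0 else (lo, mid)
        assert lo == pytest.approx(expected, abs=1e-9)

    def test_all_zero_head_raises(self):
        with pytest.raises(OnsetError):
            detect_onset(_trace(np.zeros(50), np.zeros(50)))

    def test_threshold_zero_returns_first_nonzero_sample(self, standard_impulse):
        trace = generate_head_impulse(standard_impulse)
        t0 = detect_onset(trace, threshold=0.0)
        nonzero = trace.time[trace.head_vel > 0]
        assert t0 == nonzero[0]

    def test_leftward_impulse_handled(self):
        trace = generate_head_impulse(ImpulseParams(200, 160, direction="leftward"))
        onset = detect_onset(trace)
        assert 100.0 < onset < 125.0


class TestZeroCrossing:
    def test_clean_impulse_crosses_at_duration(self):
        for dur in (150.0, 176.0, 190.0):
            p = ImpulseParams(200, dur)
            trace = generate_head_impulse(p)
            onset = detect_onset(trace)
            zc = find_zero_crossing(trace, onset)
            assert abs(zc - (p.pre_roll + dur)) <= 1000.0 / p.sampling_rate

    def test_overshoot_gives_first_sign_change(self):
        """With a 10% opposite-sign overshoot the zero-crossing is the first
        sign change after the peak (brute-force scan oracle)."""
        p = ImpulseParams(200, 160)
        trace = generate_head_impulse(p)
        t = trace.time
        over = -raised_cosine(t, p.pre_roll + 160.0, 80.0, 20.0)
        trace.head_vel = trace.head_vel + over
        onset = detect_onset(trace)
        zc = find_zero_crossing(trace, onset)
        peak = int(np.argmax(trace.head_vel))
        scan = peak + np.flatnonzero(trace.head_vel[peak:] <= 0)[0]
        assert t[scan - 1] <= zc <= t[scan]

    def test_truncated_recording_raises(self):
        p = ImpulseParams(200, 160, post_window=0.0)
        trace = generate_head_impulse(p)
        cut = int(np.argmax(trace.head_vel)) + 1
        short = VelocityTrace(trace.time[:cut], trace.head_vel[:cut], trace.eye_vel[:cut])
        with pytest.raises(ZeroCrossError):
            find_zero_crossing(short, detect_onset(short))


class TestQC:
    def test_clean_trial_accepted(self, standard_impulse):
        trial = qc_trial(generate_head_impulse(standard_impulse))
        assert trial.accepted
        assert trial.onset_ms < trial.zero_cross_ms

    @pytest.mark.parametrize("kind", ["blink", "oscillation", "low_peak"])
    def test_artifact_round_trip(self, kind, rng, noise_free_calib):
        """Every injected artifact is rejected with its own reason."""
        for i in range(30):
            params = draw_impulse_params(rng, "right")
            trace, _ = synthesize_trial(_profile(0.9, 0.0), "HC", "right",
                                        params, rng, noise_free_calib)
            trial = qc_trial(inject_artifact(trace, kind, rng))
            assert not trial.accepted
            assert trial.reason == kind

    def test_nonfinite_samples_flagged_tracking_error(self, standard_impulse):
        trace = generate_head_impulse(standard_impulse)
        trace.eye_vel[10] = np.nan
        assert qc_trial(trace).reason == "tracking_error"

    def test_false_rejection_rate_below_one_percent(self, calib, rng):
        """Clean trials at default noise are almost never rejected."""
        calib.artifact_rates = {}
        rejected = 0
        n = 400
        for i in range(n):
            params = draw_impulse_params(rng, "left" if i % 2 else "right")
            trace, _ = synthesize_trial(_profile(0.8, 0.5), "HC", "left",
                                        params, rng, calib)
            if not qc_trial(trace).accepted:
                rejected += 1
        assert rejected / n < 0.01


class TestGain:
    def test_scaled_eye_channel_gives_exact_gain(self, standard_impulse):
        trace = generate_head_impulse(standard_impulse)
        trace.eye_vel = 0.8 * trace.head_vel
        assert compute_vor_gain(qc_trial(trace)) == pytest.approx(0.8, abs=1e-9)

    def test_zero_eye_channel_gives_zero(self, standard_impulse):
        trace = generate_head_impulse(standard_impulse)
        trace.eye_vel = np.zeros_like(trace.head_vel)
        assert compute_vor_gain(qc_trial(trace)) == 0.0

    def test_gain_invariant_to_direction(self):
        """Mirror-image leftward and rightward impulses yield equal gains."""
        for g in (0.5, 0.96):
            gains = []
            for direction in ("rightward", "leftward"):
                trace = generate_head_impulse(ImpulseParams(200, 160, direction=direction))
                trace.eye_vel = g * trace.head_vel
                gains.append(compute_vor_gain(qc_trial(trace)))
            assert gains[0] == pytest.approx(gains[1], abs=1e-12)

    def test_covert_intrusion_is_desaccaded(self, standard_impulse):
        """A saccadic intrusion inside the gain window is excised by linear
        interpolation, so it cannot inflate the gain."""
        trace = generate_head_impulse(standard_impulse)
        trace.eye_vel = 0.5 * trace.head_vel + raised_cosine(
            trace.time, standard_impulse.pre_roll + 90.0, 30.0, 120.0)
        gain = compute_vor_gain(qc_trial(trace))
        naive = (np.trapezoid(trace.eye_vel, trace.time)
                 / np.trapezoid(trace.head_vel, trace.time))
        assert naive > 0.55
        assert gain == pytest.approx(0.5, abs=0.03)

    def test_noise_free_pipeline_identity(self, rng, noise_free_calib):
        """Full generate -> QC -> gain path returns the injected gain to 1e-9
        on clean CS-free trials."""
        for g in (0.3, 0.52, 0.87, 0.96, 1.2):
            params = draw_impulse_params(rng, "right")
            trace, _ = synthesize_trial(_profile(g, 0.0), "HC", "right",
                                        params, rng, noise_free_calib)
            assert compute_vor_gain(qc_trial(trace)) == pytest.approx(g, abs=1e-9)


class TestSaccadeDetection:
    def test_injected_pulse_recovered(self, rng, noise_free_calib):
        """One injected overt CS yields exactly one event whose peak lies
        within +-4 ms (one sample) of the injected peak."""
        params = ImpulseParams(200, 160)
        for _ in range(20):
            trace, truth = synthesize_trial(_profile(0.6, 1.0, area=2.0),
                                            "HC", "right", params, rng, noise_free_calib)
            trial = qc_trial(trace)
            events = detect_overt_saccades(trial)
            assert len(events) == 1
            ev = events[0]
            injected_peak = trial.onset_ms + truth["cs_latency_ms"]
            assert ev.peak_ms == pytest.approx(injected_peak, abs=4.0)
            assert ev.area == pytest.approx(truth["cs_area_deg"], rel=0.10)
            assert ev.onset_ms >= trial.zero_cross_ms

    def test_noise_only_trial_has_no_events(self, rng, calib):
        params = ImpulseParams(200, 160)
        for _ in range(20):
            trace, _ = synthesize_trial(_profile(0.9, 0.0), "HC", "right",
                                        params, rng, calib)
            assert detect_overt_saccades(qc_trial(trace)) == []

    def test_covert_pulse_yields_no_overt_event(self, standard_impulse):
        """A pulse placed before the head-velocity zero-crossing is covert
        and must not be returned."""
        trace = generate_head_impulse(standard_impulse)
        trace.eye_vel = 1.0 * trace.head_vel + raised_cosine(
            trace.time, standard_impulse.pre_roll + 100.0, 30.0, 100.0)
        assert detect_overt_saccades(qc_trial(trace)) == []

    def test_measured_area_strictly_increases_with_scale(self, standard_impulse):
        """Scaling the injected pulse by k > 1 strictly increases the
        measured area (monotonicity)."""
        areas = []
        for k in (1.0, 1.3, 1.7, 2.5):
            trace = generate_head_impulse(standard_impulse)
            trace.eye_vel = 0.9 * trace.head_vel + raised_cosine(
                trace.time, 420.0, 40.0, k * 80.0)
            [ev] = detect_overt_saccades(qc_trial(trace))
            areas.append(ev.area)
        assert np.all(np.diff(areas) > 0)


class TestMeasureSaccade:
    def test_analytic_pulse_area(self, standard_impulse):
        """A raised-cosine pulse of peak 40 deg/s and 50 ms has area
        p*d/2000 = 1.0 deg."""
        trace = generate_head_impulse(standard_impulse)
        trace.eye_vel = trace.head_vel + raised_cosine(trace.time, 400.0, 50.0, 40.0)
        trial = qc_trial(trace)
        ev = SaccadeEvent(onset_ms=398.0, peak_ms=425.0, offset_ms=452.0,
                          area=1.0, latency=0.0)
        area, latency = measure_saccade(trial, ev)
        assert area == pytest.approx(1.0, abs=0.02)
        assert latency == pytest.approx(425.0 - trial.onset_ms, abs=1e-9)

    def test_latency_is_peak_minus_onset(self, standard_impulse):
        trace = generate_head_impulse(standard_impulse)
        trace.eye_vel = trace.head_vel + raised_cosine(trace.time, 400.0, 40.0, 60.0)
        trial = qc_trial(trace)
        [ev] = detect_overt_saccades(trial)
        assert ev.latency == pytest.approx(ev.peak_ms - trial.onset_ms, abs=1e-9)

    def test_zero_width_event_rejected(self, standard_impulse):
        trial = qc_trial(generate_head_impulse(standard_impulse))
        with pytest.raises(ParameterError):
            ev = SaccadeEvent(400.0, 401.0, 402.0, 0.5, 100.0)
            object.__setattr__(ev, "offset_ms", 400.0)
            measure_saccade(trial, ev)


def _event(area, latency):
    return SaccadeEvent(onset_ms=latency - 20, peak_ms=latency,
                        offset_ms=latency + 20, area=area, latency=latency)


class TestConsistencyFilter:
    def test_cluster_above_20_percent_retained(self):
        """6 similar saccades in 20 accepted trials (30%) are retained."""
        per_trial = [[] for _ in range(20)]
        for i in range(6):
            per_trial[i] = [_event(2.0 + 0.1 * i, 350.0 + 5 * i)]
        retained, incidence = consistency_filter(per_trial, 20)
        assert len(retained) == 6
        assert incidence == pytest.approx(30.0)

    def test_cluster_at_or_below_20_percent_dropped(self):
        """3/20 similar saccades (15%) fail the >20% rule; so do 4/20."""
        for k in (3, 4):
            per_trial = [[] for _ in range(20)]
            for i in range(k):
                per_trial[i] = [_event(2.0, 350.0)]
            retained, incidence = consistency_filter(per_trial, 20)
            assert retained == {}
            assert incidence == 0.0

    def test_separated_minor_cluster_dropped(self):
        """Two well-separated clusters at 25% and 10% of trials: only the
        first is retained (brute-force expectation on the fixture)."""
        per_trial = [[] for _ in range(20)]
        for i in range(5):
            per_trial[i] = [_event(2.0 + 0.05 * i, 350.0)]
        for i in range(5, 7):
            per_trial[i] = [_event(8.0, 550.0)]
        retained, incidence = consistency_filter(per_trial, 20)
        assert set(retained) == {0, 1, 2, 3, 4}
        assert incidence == pytest.approx(25.0)

    def test_largest_event_kept_when_trial_has_two(self):
        per_trial = [[_event(2.0, 350.0), _event(2.4, 352.0)]]
        per_trial += [[_event(2.2, 351.0)] for _ in range(7)]
        retained, _ = consistency_filter(per_trial, 8)
        assert retained[0].area == pytest.approx(2.4)

    def test_needs_accepted_trials(self):
        with pytest.raises(ParameterError):
            consistency_filter([], 0)


class TestSummarizeSubject:
    def _metrics(self, rng, calib, gain, cs_prob, n=10, sides=("left", "right")):
        out = {}
        for side in sides:
            ms = []
            for _ in range(n):
                params = draw_impulse_params(rng, side)
                trace, _ = synthesize_trial(_profile(gain, cs_prob), "HC", side,
                                            params, rng, calib)
                ms.append(process_trace(trace))
            out[("HC", side)] = ms
        return out

    def test_bilateral_cs_flag(self, rng, calib):
        calib.artifact_rates = {}
        metrics = self._metrics(rng, calib, 0.6, 1.0)
        s = summarize_subject("S1", "VN", "left", "left", metrics)
        assert s.bilateral_cs["HC"] is True
        assert s.stats[("HC", "ipsi")].cs_incidence > 80.0
        assert s.stats[("HC", "ipsi")].mean_cs_area == pytest.approx(2.0, rel=0.3)

    def test_no_cs_side_has_missing_area_not_zero(self, rng, calib):
        calib.artifact_rates = {}
        metrics = self._metrics(rng, calib, 0.95, 0.0)
        s = summarize_subject("S1", "HS", "none", "right", metrics)
        assert s.bilateral_cs["HC"] is False
        assert s.stats[("HC", "ipsi")].mean_cs_area is None
        assert s.stats[("HC", "ipsi")].cs_incidence == 0.0

    def test_all_rejected_side_is_explicitly_missing(self, rng, calib):
        metrics = self._metrics(rng, calib, 0.9, 0.0, n=3, sides=("left",))
        bad = self._metrics(rng, calib, 0.9, 0.0, n=3, sides=("right",))
        for m in bad[("HC", "right")]:
            m.trial.qc_status, m.trial.reason = "rejected", "low_peak"
        metrics.update(bad)
        s = summarize_subject("S1", "VN", "left", "left", metrics)
        assert s.stats[("HC", "contra")] is None
        assert s.stats[("HC", "ipsi")].mean_gain == pytest.approx(0.9, abs=0.02)
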