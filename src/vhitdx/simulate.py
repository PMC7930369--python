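"""Synthetic vHIT cohort generator.

Generates raw head/eye angular-velocity trials with the statistical
structure of three study groups (healthy subjects, vestibular neuritis,
cerebellar PICA stroke, plus medial/lateral PICA subgroups):

* head impulses are raised-cosine velocity bumps with 15-20 deg
  displacement, 150-190 ms duration and peak velocity > 150 deg/s;
* the eye channel is ``true_gain * head + white noise``, plus, with a
  per-subject probability, one *overt* corrective saccade (CS) — a
  raised-cosine velocity pulse placed strictly after the head-velocity
  zero-crossing whose time integral equals the drawn CS area;
* subject-level parameters (gain, CS area, CS latency) are drawn from
  truncated normals coupled through a Gaussian copula (gain vs CS area on
  the ipsilesional side, left vs right within a subject);
* artifact trials (blinks, trace oscillations, low-peak impulses) are
  injected at configurable rates with ground-truth labels.

Every random draw flows from a single :class:`numpy.random.Generator`, so a
seed reproduces a cohort exactly.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .calibration import CohortCalibration, default_calibration
from .datatypes import (
    CANALS, SIDES, ImpulseParams, ParameterError, VelocityTrace,
)

ARTIFACT_KINDS = ("blink", "oscillation", "low_peak")

# Saccade kinematics: peak velocity follows a main-sequence power law of the
# saccade area A (deg), p = 90 * A**0.6 deg/s, with the duration floored at
# 20 ms so the pulse stays resolvable at video sampling rates.  Saccades
# under ~0.26 deg then peak below typical detection thresholds — a real
# property of small catch-up saccades, not a generator defect.
_MAIN_SEQ_COEF = 90.0
_MAIN_SEQ_EXP = 0.6
_MIN_SACCADE_MS = 20.0

MANIFEST_COLUMNS = (
    "subject_id", "group", "lesion_side", "canal", "side", "trial_id",
    "true_gain", "cs_injected", "cs_area_deg", "cs_latency_ms", "artifact",
)


def truncnorm_ppf(u, mean, sd, lo=-np.inf, hi=np.inf):
    """Quantile function of a normal(mean, sd) truncated to [lo, hi]."""
    if sd == 0:
        return np.clip(np.broadcast_to(mean, np.shape(u)).astype(float), lo, hi)
    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd)
    return mean + sd * ndtri(a + np.asarray(u) * (b - a))


def raised_cosine(time: np.ndarray, start: float, duration: float, peak: float) -> np.ndarray:
    """Raised-cosine velocity bump of given peak on [start, start+duration]."""
    out = np.zeros_like(time, dtype=float)
    inside = (time >= start) & (time <= start + duration)
    out[inside] = 0.5 * peak * (1 - np.cos(2 * np.pi * (time[inside] - start) / duration))
    return out


def generate_head_impulse(params: ImpulseParams, **trace_kw) -> VelocityTrace:
    """Build the noise-free head channel of one impulse (eye channel zero).

    The head displacement equals ``params.displacement`` (= p*d/2000 deg)
    analytically.
    """
    dt = 1000.0 / params.sampling_rate
    total = params.pre_roll + params.duration + params.post_window
    n = int(round(total / dt)) + 1
    time = np.arange(n) * dt
    head = params.sign * raised_cosine(time, params.pre_roll, params.duration,
                                       params.peak_velocity)
    return VelocityTrace(time, head, np.zeros(n), **trace_kw)


def saccade_pulse_shape(area: float) -> tuple[float, float]:
    """Main-sequence (duration ms, peak deg/s) for a saccade of `area` deg."""
    if area <= 0:
        raise ParameterError("saccade area must be > 0")
    duration = max(_MIN_SACCADE_MS, 2000.0 * area / (_MAIN_SEQ_COEF * area ** _MAIN_SEQ_EXP))
    return duration, 2000.0 * area / duration


@dataclass(frozen=True)
class CanalSideParams:
    """Latent per-subject parameters for one canal x physical side."""

    true_gain: float
    cs_prob: float
    cs_area_mu: float      # deg
    cs_latency_mu: float   # ms


@dataclass
class SubjectProfile:
    """Latent parameters of one simulated subject.

    ``params`` is keyed by (canal, physical side).  ``designated_side`` is
    the side treated as ipsilesional downstream; for patients it equals
    ``lesion_side``, for healthy subjects it is drawn at random so that
    asymmetry statistics remain defined.
    """

    subject_id: str
    group: str
    lesion_side: str                    # left | right | none
    designated_side: str
    params: dict[tuple[str, str], CanalSideParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, p in self.params.items():
            if not 0 < p.true_gain <= 1.5:
                raise ParameterError(f"true_gain out of (0, 1.5] at {key}")
            if not 0 <= p.cs_prob <= 1:
                raise ParameterError(f"cs_prob out of [0, 1] at {key}")


def sample_subject(subject_id: str, group: str, lesion_side: str,
                   calib: CohortCalibration, rng: np.random.Generator) -> SubjectProfile:
    """Draw one subject's latent parameters from the cohort calibration.

    Gains are truncated normal on (0, 1.5]; CS areas truncated at 0.05 deg;
    CS latencies truncated to [100, 600] ms.  Within each canal, the four
    latent draws (gain and CS area on both sides) share a Gaussian copula
    whose correlation matrix is the Kronecker product of the gain-CS
    coupling (ipsilesional r, e.g. -0.79 for HC) and the group's
    left-right coupling.
    """
    if not any(g == group for g, _, _ in calib.entries):
        raise ParameterError(f"unknown group {group!r}")
    if group == "HS":
        if lesion_side not in ("none", None):
            raise ParameterError("healthy subjects have lesion_side 'none'")
        lesion_side = "none"
        designated = "left" if rng.random() < 0.5 else "right"
    else:
        if lesion_side not in SIDES:
            raise ParameterError(f"lesion_side must be left/right, got {lesion_side!r}")
        designated = lesion_side

    contra_side = "right" if designated == "left" else "left"
    side_of = {"ipsi": designated, "contra": contra_side}

    params: dict[tuple[str, str], CanalSideParams] = {}
    rho_lr = calib.bilateral_coupling.get(group, 0.0)
    for canal in CANALS:
        rho_gc = calib.gain_cs_coupling.get(canal, 0.0)
        # Latent order: (gain_ipsi, gain_contra, area_ipsi, area_contra).
        corr = np.kron(np.array([[1.0, rho_gc], [rho_gc, 1.0]]),
                       np.array([[1.0, rho_lr], [rho_lr, 1.0]]))
        z = np.linalg.cholesky(corr) @ rng.standard_normal(4)
        u = ndtr(z)
        for j, lat in enumerate(("ipsi", "contra")):
            cell = calib.cell(group, canal, lat)
            gain = float(truncnorm_ppf(u[j], cell.gain_mean, cell.gain_sd, 1e-6, 1.5))
            area = float(truncnorm_ppf(u[2 + j], cell.cs_area_mean, cell.cs_area_sd, 0.05))
            latency = float(truncnorm_ppf(rng.random(), cell.cs_latency_mean,
                                          cell.cs_latency_sd, 100.0, 600.0))
            params[(canal, side_of[lat])] = CanalSideParams(
                true_gain=gain, cs_prob=cell.cs_incidence,
                cs_area_mu=area, cs_latency_mu=latency)
    return SubjectProfile(subject_id, group, lesion_side, designated, params)


def synthesize_trial(profile: SubjectProfile, canal: str, side: str,
                     params: ImpulseParams, rng: np.random.Generator,
                     calib: CohortCalibration | None = None,
                     trial_id: str = "") -> tuple[VelocityTrace, dict]:
    """Simulate one trial's eye channel over a generated head impulse.

    Returns the trace and a ground-truth record (injected gain, CS area and
    latency).  The CS pulse peak sits at ``onset + latency`` where onset is
    the analytic 20 deg/s crossing of the head profile; the latency is
    redrawn (up to 10 times) if the pulse would not start strictly after
    the head-velocity zero-crossing, after which the trial is emitted
    without a CS.
    """
    calib = calib or default_calibration()
    try:
        sp = profile.params[(canal, side)]
    except KeyError:
        raise ParameterError(f"profile lacks parameters for {(canal, side)}") from None

    trace = generate_head_impulse(params, canal=canal, side=side,
                                  trial_id=trial_id, subject_id=profile.subject_id)
    eye = sp.true_gain * trace.head_vel
    truth = {"true_gain": sp.true_gain, "cs_injected": False,
             "cs_area_deg": np.nan, "cs_latency_ms": np.nan}

    if rng.random() < sp.cs_prob:
        onset = params.pre_roll + params.onset_time(20.0)
        zero_cross = params.pre_roll + params.duration
        t_end = trace.time[-1]
        for _ in range(10):
            area = float(truncnorm_ppf(rng.random(), sp.cs_area_mu,
                                       calib.trial_area_rel_sd * sp.cs_area_mu, 0.02))
            latency = float(truncnorm_ppf(rng.random(), sp.cs_latency_mu,
                                          calib.trial_latency_sd, 100.0, 620.0))
            dur, peak = saccade_pulse_shape(area)
            start = onset + latency - dur / 2
            if start > zero_cross + 2.0 and start + dur < t_end - 8.0:
                pulse = raised_cosine(trace.time, start, dur, peak)
                eye = eye + params.sign * pulse
                # ground truth records the area actually present in the
                # sampled data (trapezoid of the pulse), not the analytic draw
                truth.update(cs_injected=True,
                             cs_area_deg=float(np.trapezoid(pulse, trace.time) / 1000.0),
                             cs_latency_ms=latency)
                break

    if calib.noise_sd > 0:
        eye = eye + rng.normal(0.0, calib.noise_sd, trace.time.size)
    trace.eye_vel = eye
    return trace, truth


def inject_artifact(trace: VelocityTrace, kind: str,
                    rng: np.random.Generator) -> VelocityTrace:
    """Return a copy of `trace` carrying one ground-truth artifact.

    blink        large biphasic eye-channel pulse (peak >= 200 deg/s, total
                 duration <= 30 ms) during the head movement;
    oscillation  12-20 Hz sinusoid (>= 20 deg/s amplitude) added to the eye
                 channel during the head movement;
    low_peak     head channel rescaled so its peak falls below 150 deg/s.
    """
    if kind not in ARTIFACT_KINDS:
        raise ParameterError(f"unknown artifact kind {kind!r}")
    out = trace.copy()
    amax = int(np.argmax(np.abs(out.head_vel)))
    peak_t = out.time[amax]
    moving = np.abs(out.head_vel) > 1e-9
    if not moving.any():
        raise ParameterError("trace has no head movement to corrupt")
    t0, t1 = out.time[moving][0], out.time[moving][-1]

    if kind == "blink":
        lobe = 12.0                                   # ms per lobe, total 24 <= 30
        center = rng.uniform(t0 + 0.25 * (t1 - t0), t0 + 0.75 * (t1 - t0))
        amp = rng.uniform(250.0, 400.0)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        pulse = (raised_cosine(out.time, center - lobe, lobe, amp)
                 - raised_cosine(out.time, center, lobe, amp))
        out.eye_vel = out.eye_vel + sign * pulse
    elif kind == "oscillation":
        freq = rng.uniform(12.0, 20.0)                # Hz
        amp = rng.uniform(20.0, 40.0)
        window = (out.time >= t0) & (out.time <= t1)
        osc = amp * np.sin(2 * np.pi * freq * (out.time - t0) / 1000.0)
        out.eye_vel = out.eye_vel + np.where(window, osc, 0.0)
    else:  # low_peak
        target = rng.uniform(90.0, 140.0)
        out.head_vel = out.head_vel * (target / np.abs(out.head_vel[amax]))
    return out


@dataclass
class Dataset:
    """An in-memory synthetic study: trial traces, manifest, latent truth."""

    traces: list[VelocityTrace]
    manifest: pd.DataFrame
    profiles: dict[str, SubjectProfile]
    seed: int | None = None

    def write(self, out_dir: str | Path, config_hash: str = "") -> Path:
        from . import io as _io
        return _io.write_dataset(self, out_dir, config_hash=config_hash)


def draw_impulse_params(rng: np.random.Generator, side: str,
                        sampling_rate: float = 250.0) -> ImpulseParams:
    """Draw one impulse's kinematics: displacement U(15, 20) deg, duration
    U(150, 190) ms, hence peak velocity 2000*disp/dur in (157, 267) deg/s."""
    duration = rng.uniform(150.0, 190.0)
    displacement = rng.uniform(15.0, 20.0)
    return ImpulseParams(
        peak_velocity=2000.0 * displacement / duration,
        duration=duration,
        direction="rightward" if side == "right" else "leftward",
        sampling_rate=sampling_rate,
    )


def generate_cohort(groups: dict[str, int], n_impulses_per_side: int = 20,
                    calib: CohortCalibration | None = None,
                    seed: int | np.random.SeedSequence | None = None,
                    canals: tuple[str, ...] = CANALS,
                    sampling_rate: float = 250.0,
                    out_dir: str | Path | None = None,
                    config_hash: str = "") -> Dataset:
    """Generate a full synthetic study across `groups`.

    Parameters
    ----------
    groups : dict
        Map group label -> number of subjects (e.g. ``{"HS": 17, "VN": 17,
        "PICA": 17}``).
    n_impulses_per_side : int
        Impulses per canal and side (the study protocol used > 20).
    canals : tuple
        Canals to simulate; restricting to ``("HC",)`` speeds up
        replicate-heavy analyses.
    out_dir : path, optional
        When given, one CSV per trial plus ``manifest.csv`` are written.
    """
    if n_impulses_per_side < 1:
        raise ParameterError("n_impulses_per_side must be >= 1")
    calib = calib or default_calibration()
    rng = np.random.default_rng(seed)
    artifact_kinds = list(calib.artifact_rates)
    artifact_probs = np.array([calib.artifact_rates[k] for k in artifact_kinds])
    cum = np.cumsum(artifact_probs)

    traces: list[VelocityTrace] = []
    rows: list[tuple] = []
    profiles: dict[str, SubjectProfile] = {}
    for group, n_subjects in groups.items():
        if n_subjects < 1:
            raise ParameterError(f"need >= 1 subject in group {group}")
        for i in range(n_subjects):
            subject_id = f"{group}{i + 1:02d}"
            if subject_id in profiles:
                raise ParameterError(f"duplicate subject id {subject_id}")
            lesion = "none" if group == "HS" else ("left" if rng.random() < 0.5 else "right")
            profile = sample_subject(subject_id, group, lesion, calib, rng)
            profiles[subject_id] = profile
            for canal in canals:
                for side in SIDES:
                    for k in range(n_impulses_per_side):
                        trial_id = f"{subject_id}_{canal}_{side[0].upper()}_{k:03d}"
                        params = draw_impulse_params(rng, side, sampling_rate)
                        trace, truth = synthesize_trial(
                            profile, canal, side, params, rng, calib, trial_id)
                        u = rng.random()
                        artifact = ""
                        hit = np.searchsorted(cum, u)
                        if hit < len(artifact_kinds):
                            artifact = artifact_kinds[hit]
                            trace = inject_artifact(trace, artifact, rng)
                        traces.append(trace)
                        rows.append((subject_id, group, lesion, canal, side,
                                     trial_id, truth["true_gain"],
                                     truth["cs_injected"], truth["cs_area_deg"],
                                     truth["cs_latency_ms"], artifact))
    manifest = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    dataset = Dataset(traces, manifest, profiles,
                      seed=seed if isinstance(seed, int) else None)
    if out_dir is not None:
        dataset.write(out_dir, config_hash=config_hash)
    return dataset
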