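"""Core containers for head-impulse trials and derived measurements.

Conventions used throughout the package:

* Velocities are angular velocities in deg/s, times in ms, areas (time
  integrals of velocity) in degrees.
* The eye channel is stored in the *compensatory-positive* convention: a
  perfectly compensatory eye movement has the same sign as the head
  channel, so VOR gains come out positive and near 1 in health.
* ``canal`` is one of HC/AC/PC (horizontal, anterior, posterior
  semicircular canal); ``side`` is the physical side (left/right) being
  stimulated.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

CANALS = ("HC", "AC", "PC")
SIDES = ("left", "right")
GROUPS = ("HS", "VN", "PICA", "PICA_M", "PICA_L")

#: QC rejection reasons, in the order they are checked.
QC_REASONS = (
    "tracking_error",
    "low_peak",
    "no_onset",
    "no_zero_cross",
    "blink",
    "oscillation",
)


class ParameterError(ValueError):
    """Invalid physical or configuration parameter."""


class TraceError(ValueError):
    """A velocity trace violates its structural invariants."""


class OnsetError(RuntimeError):
    """No head-impulse onset could be found (QC reason ``no_onset``)."""


class ZeroCrossError(RuntimeError):
    """No head-velocity zero-crossing after the peak (``no_zero_cross``)."""


@dataclass(frozen=True)
class ImpulseParams:
    """Kinematic parameters of one passive head impulse.

    The head-velocity profile is a raised-cosine bump
    ``v(t) = (p/2) * (1 - cos(2*pi*t/d))`` on ``t in [0, d]`` (t in ms,
    v in deg/s), which makes the head displacement analytic:
    ``p * d / 2000`` degrees.

    Parameters
    ----------
    peak_velocity : float
        Peak head angular velocity ``p`` in deg/s (> 0).
    duration : float
        Impulse duration ``d`` in ms (> 0).
    direction : {"rightward", "leftward"}
        Sign convention of the head channel; leftward impulses are negative.
    sampling_rate : float
        Uniform sampling rate in Hz (>= 100).
    pre_roll : float
        Zero-velocity padding recorded before the bump, ms.
    post_window : float
        Recording continued after the head-velocity zero-crossing, ms; must
        be long enough to contain overt corrective saccades.
    """

    peak_velocity: float
    duration: float
    direction: str = "rightward"
    sampling_rate: float = 250.0
    pre_roll: float = 100.0
    post_window: float = 700.0

    def __post_init__(self) -> None:
        if not self.peak_velocity > 0:
            raise ParameterError(f"peak_velocity must be > 0, got {self.peak_velocity}")
        if not self.duration > 0:
            raise ParameterError(f"duration must be > 0, got {self.duration}")
        if self.sampling_rate < 100:
            raise ParameterError(f"sampling_rate must be >= 100 Hz, got {self.sampling_rate}")
        if self.direction not in ("rightward", "leftward"):
            raise ParameterError(f"unknown direction {self.direction!r}")
        if self.pre_roll < 0 or self.post_window < 0:
            raise ParameterError("pre_roll and post_window must be >= 0")

    @property
    def displacement(self) -> float:
        """Head displacement in degrees: the analytic integral p*d/2000."""
        return self.peak_velocity * self.duration / 2000.0

    @property
    def sign(self) -> float:
        return 1.0 if self.direction == "rightward" else -1.0

    def onset_time(self, threshold: float = 20.0) -> float:
        """Time (ms after bump start) at which |v| first reaches `threshold`.

        Closed-form inversion of the raised-cosine profile:
        ``t = (d / 2*pi) * arccos(1 - 2*threshold/p)``.
        """
        if not 0 <= threshold < self.peak_velocity:
            raise ParameterError("threshold must lie in [0, peak_velocity)")
        return (self.duration / (2 * math.pi)) * math.acos(1 - 2 * threshold / self.peak_velocity)


@dataclass
class VelocityTrace:
    """One trial's sampled head and eye angular-velocity channels."""

    time: np.ndarray          # ms, uniform strictly-increasing grid
    head_vel: np.ndarray      # deg/s
    eye_vel: np.ndarray       # deg/s, compensatory-positive convention
    canal: str = "HC"
    side: str = "right"
    trial_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.head_vel = np.asarray(self.head_vel, dtype=float)
        self.eye_vel = np.asarray(self.eye_vel, dtype=float)
        n = self.time.size
        if n < 2:
            raise TraceError("trace needs at least two samples")
        if self.head_vel.size != n or self.eye_vel.size != n:
            raise TraceError("channel lengths differ")
        steps = np.diff(self.time)
        if steps[0] <= 0 or not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
            raise TraceError("time must be strictly increasing with a constant step")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def sampling_rate(self) -> float:
        return 1000.0 / self.dt

    def copy(self) -> "VelocityTrace":
        return VelocityTrace(
            self.time.copy(), self.head_vel.copy(), self.eye_vel.copy(),
            canal=self.canal, side=self.side,
            trial_id=self.trial_id, subject_id=self.subject_id,
        )


@dataclass(frozen=True)
class SaccadeEvent:
    """A detected corrective saccade (CS) in the eye channel.

    ``area`` is the time integral of the saccadic eye-velocity excursion in
    degrees (the CS amplitude); ``latency`` runs from the head-impulse
    onset to the saccade's velocity peak, in ms.
    """

    onset_ms: float
    peak_ms: float
    offset_ms: float
    area: float
    latency: float
    overt: bool = True

    def __post_init__(self) -> None:
        if not (self.onset_ms < self.peak_ms < self.offset_ms):
            raise ParameterError("saccade requires onset < peak < offset")
        if self.area < 0:
            raise ParameterError("saccade area must be >= 0")


@dataclass
class ImpulseTrial:
    """A QC'd trial: the trace plus onset/zero-crossing anchors."""

    trace: VelocityTrace
    onset_ms: float | None = None
    zero_cross_ms: float | None = None
    qc_status: str = "accepted"           # "accepted" | "rejected"
    reason: str | None = None             # one of QC_REASONS when rejected

    @property
    def accepted(self) -> bool:
        return self.qc_status == "accepted"


@dataclass
class TrialMetrics:
    """Per-trial quantification: VOR gain and detected overt saccades."""

    trial: ImpulseTrial
    vor_gain: float | None = None
    saccades: list[SaccadeEvent] = field(default_factory=list)


@dataclass
class SideStats:
    """Summary for one subject x canal x side."""

    n_accepted: int
    mean_gain: float | None
    cs_incidence: float          # % of accepted trials carrying a retained CS
    mean_cs_area: float | None   # deg, over retained-CS trials; None if none retained
    mean_cs_latency: float | None

    def __post_init__(self) -> None:
        if not 0 <= self.cs_incidence <= 100:
            raise ParameterError("cs_incidence must lie in [0, 100]")


@dataclass
class SubjectSummary:
    """Per-subject quantification keyed by (canal, 'ipsi'|'contra').

    For healthy subjects a side is designated at generation time so that
    asymmetry statistics remain defined; ``lesion_side`` is ``'none'``.
    """

    subject_id: str
    group: str
    lesion_side: str                       # left | right | none
    designated_side: str                   # actual side treated as "ipsi"
    stats: dict[tuple[str, str], SideStats] = field(default_factory=dict)
    bilateral_cs: dict[str, bool] = field(default_factory=dict)

    def gain(self, canal: str, laterality: str) -> float | None:
        s = self.stats.get((canal, laterality))
        return None if s is None else s.mean_gain

    def cs_area(self, canal: str, laterality: str) -> float | None:
        s = self.stats.get((canal, laterality))
        return None if s is None else s.mean_cs_area


@dataclass
class AsymmetryMetrics:
    """Per-subject, per-canal asymmetry indices.

    Gs = |contralesional gain - ipsilesional gain| (unitless),
    CSs = |contralesional CS area - ipsilesional CS area| (degrees); a side
    with no retained CS contributes area 0 to CSs.
    """

    subject_id: str
    group: str
    gs: dict[str, float] = field(default_factory=dict)
    css: dict[str, float] = field(default_factory=dict)
    abnormal_gain: dict[tuple[str, str], bool] = field(default_factory=dict)
    abnormal_gs: dict[str, bool] = field(default_factory=dict)
    abnormal_css: dict[str, bool] = field(default_factory=dict)


@dataclass
class ROCResult:
    """Empirical ROC for one discriminating statistic (positive class = VN)."""

    name: str
    orientation: str              # "higher_is_VN" | "lower_is_VN"
    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    youden_cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float
    n_pos: int
    n_neg: int
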