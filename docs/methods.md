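# Methods

This note documents the generative model, the quantification procedure and
the numerical choices behind `vhitdx`, and states what the synthetic data
do and do not establish about real recordings.

## Head-impulse model

Each trial's head angular velocity is a raised-cosine bump

    v(t) = (p/2) · (1 − cos(2πt/d)),   t ∈ [0, d],

with peak velocity *p* (deg/s) and duration *d* (ms), preceded by a
zero-velocity pre-roll (default 100 ms) and followed by a post-window
(default 700 ms) long enough to contain overt corrective saccades.  The
head displacement is analytic, `p·d/2000` degrees, which gives the package
exact oracles for integration-based quantities.  Default draws per trial:
duration U(150, 190) ms and displacement U(15, 20)°, so the implied peak
velocity `2000·disp/d` always exceeds 157 deg/s — matching the clinical
protocol (15–20° rotations, 150–200 ms, peak > 150 deg/s) while keeping
every generated impulse above the 150 deg/s QC floor.  The profile shape
itself is a modeling choice: it is smooth, has an analytic integral, and
satisfies the protocol's peak/duration/displacement constraints
simultaneously; real manual impulses are less stereotyped.

Sampling rate: 250 Hz by default (typical of video-oculography),
configurable down to 100 Hz.

## Eye-channel model

The eye channel is stored compensatory-positive (a perfect reflex
reproduces the head channel), so gains are positive and ≈ 1 in health:

    e(t) = G · v(t) + ε(t) + CS pulse (with per-trial probability),

with white Gaussian noise ε (default SD 3 deg/s, a realistic
video-oculography velocity-noise floor).  At most one *overt* corrective
saccade per trial is injected: a raised-cosine velocity pulse whose peak
time sits at the impulse onset (analytic 20 deg/s crossing) plus a latency
draw, constrained to start strictly after the head-velocity zero-crossing
(up to 10 redraws, then the trial is emitted CS-free).  Pulse kinematics
follow a main-sequence rule — peak velocity `90·A^0.6` deg/s for area *A*
deg, duration floored at 20 ms — so small saccades are brief and slow.
Saccades under ≈ 0.26° then peak below the 40 deg/s detection threshold;
that detection floor is a property of real velocity-threshold saccade
picking, not an artifact of the simulator.  The recorded ground-truth area
is the trapezoid integral of the sampled pulse (the area actually present
in the data), making round-trip identities exact.

Covert saccades (before the zero-crossing) are deliberately not generated:
the analysis concerns overt saccades only, and the quantifier's
desaccading guards against covert intrusions in the gain window anyway.

## Latent cohort structure

Per subject, canal and side, four latent parameters are drawn: true gain,
per-trial CS probability, mean CS area and mean CS latency.  Marginals are
the simplest forms matching the published group means and SDs: gains are
normal truncated to (0, 1.5]; CS areas normal truncated at 0.05°;
latencies normal truncated to [100, 600] ms; per-trial CS occurrence is
Bernoulli, independent across trials given the subject (within-subject
serial correlation of CS occurrence is unknown and unmodeled); within-
subject per-trial scatter is 15% of the subject mean for area and 25 ms
for latency, chosen so that one subject's saccades satisfy the ±50%/±60 ms
similarity rule with high probability.

Two Gaussian-copula couplings shape the joint distribution (per canal, the
4-dim latent correlation matrix is the Kronecker product of the two):

* **gain–CS coupling** on the ipsilesional side: r = −0.79 (HC), −0.87
  (PC), −0.63 (AC) — the weaker the reflex, the larger the corrective
  saccades.  Reported for PICA stroke; applied to all groups as the
  simplest common mechanism.
* **left–right coupling**: 0.8 for PICA (including its medial/lateral
  subgroups), 0 for VN and healthy subjects.  The PICA value is *implied*
  by the published asymmetry spreads: with independent sides the gain
  asymmetry Gs would average ≈ 0.15 and the CS asymmetry CSs ≈ 1.0 —
  double the reported 0.08 ± 0.08 and 0.47 ± 0.61 — whereas a 0.8 latent
  correlation reproduces both by normal-theory arithmetic.  Bilaterally
  *symmetric* deficits are the clinical hallmark of PICA stroke, and the
  tables cannot be matched without encoding that symmetry.

The published group spread columns are treated as 1 SD throughout: the
printed 95% CIs are consistent with `mean ± t·SD/√17` only under that
reading (e.g. healthy HC gain 0.96 ± 0.02 with CI 0.95–0.97).  One
tabulated gain SD (ipsilesional AC, PICA) is typographically corrupt and
is reconstructed from its CI as 0.09.  Medial-branch (nodulus/uvula)
PICA subgroups run higher gains than lateral-branch ones — +0.08/−0.071
in the ipsilesional HC, ±0.03 elsewhere, offsets chosen so the
8:9-weighted subgroup means equal the pooled PICA cells.

Healthy subjects have no lesion; a side is designated at random per
subject so asymmetry statistics remain defined, and both sides draw from
one pooled distribution.

Artifact trials are injected at configurable rates (defaults: 2% blinks,
2% trace oscillations, 3% low-peak impulses; the study excluded such
trials without reporting rates).  Blinks are biphasic pulses (≥ 250 deg/s,
≤ 30 ms) during head movement; oscillations are 12–20 Hz sinusoids of
20–40 deg/s; low-peak trials rescale the head channel below 150 deg/s.

## Quantification

* **Onset**: first sustained (≥ 20 ms) crossing of 20 deg/s head speed,
  linearly interpolated between samples.
* **Zero-crossing**: first interpolated sign change after the head-velocity
  peak; fallback, the first sustained spell of |v| < 5 deg/s (≥ 20 ms)
  within 500 ms of the peak.
* **QC order**: non-finite samples → `tracking_error`; head peak
  < 150 deg/s → `low_peak`; missing onset / zero-crossing; `blink` when
  the movement-window eye residual (eye minus median-ratio-scaled head)
  dips below −100 deg/s — biphasic pseudo-saccades always carry a large
  anticompensatory lobe, which keeps monophasic covert saccades out of the
  blink class; `oscillation` when the 10–22 Hz band amplitude of the
  residual exceeds 10 deg/s after monophasic transients (> 60 deg/s) are
  excised and with a 4× zero-padded FFT so scalloping cannot hide a
  between-bin frequency.  False rejections of clean trials at default
  noise are below 1% (measured).
* **Gain**: trapezoid AUC ratio over [onset, zero-crossing], with
  endpoints interpolated.  Saccadic intrusions inside the window (residual
  beyond 40 deg/s against the *median* per-sample eye/head ratio, which a
  saccade cannot inflate) are excised by linear interpolation first.  On
  clean trials the estimator returns the injected gain to 1e−9 (exact
  identity of the area ratio).
* **Overt saccades**: within 700 ms after the zero-crossing,
  compensatory-direction excursions above 40 deg/s, extended outward to
  the 5 deg/s crossings (interpolated), overlapping extents merged; area =
  trapezoid integral between the boundaries, latency = peak time − onset.
  The 5 deg/s clipping loses ≈ 1% of a small saccade's area; measured
  areas track injected truth within ±10% (≥ 99% detection for areas
  ≥ 0.5°, measured over 1,000 trials).
* **Consistency rule**: per subject × canal × side, saccades are clustered
  by single linkage on (area within ±50% of the other's, latency within
  ±60 ms), refined against the cluster medians; clusters recurring in
  > 20% of accepted trials are retained.  When several excursions of one
  trial fall in a retained cluster, the largest-area event represents the
  trial.  The tolerances operationalize "similar amplitude and latency",
  which the protocol leaves unquantified; both are configurable.
* **Summaries**: gains average over accepted trials; CS statistics over
  retained events only (amplitude and incidence are reported separately);
  a side with no retained CS has a *missing* mean area, which counts as 0
  in the CSs asymmetry (no saccades = no saccadic correction).
* **Group comparison**: Shapiro–Wilk (α = 0.05) per group gates t-test/
  ANOVA versus Mann–Whitney/Kruskal–Wallis; proportions use two-sided
  Fisher's exact; groups with < 3 values fall back to nonparametric.
  95% CIs use the t distribution with n − 1 df.  Abnormality bounds are
  strict: a value exactly at mean ± 2 SD is normal.
* **ROC**: midrank Mann–Whitney AUC (ties = ½), thresholds at midpoints of
  distinct scores plus ±∞; Youden ties break toward higher specificity,
  then the lower threshold.  Score orientations are configured a priori
  per statistic rather than auto-flipped.  Two combined CSs+Gs scores are
  provided (arithmetic mean; in-sample logistic linear predictor); the
  original combination rule behind the published combined cutoff is
  unspecified, so neither claims to reproduce it.

## Problem sizes and replicate analyses

The study-scale analyses use 17 subjects per group and 20 impulses per
canal and side.  The replicate ROC analysis runs 200 independent 17 + 17
patient cohorts through the full trace pipeline, horizontal canal only,
since only HC statistics enter those AUCs.  The two directional *sign*
checks (medial > lateral PICA ipsilesional HC gain; HC statistics out-rank
PC statistics by AUC) are computed at the latent-profile level over 200
replicates: the trace pipeline adds only small measurement noise on top of
the latent parameters, and a sign comparison does not benefit from it.

## Sample-size utility

Two standard two-proportion formulas are implemented for the 90% vs 60%
CS-prevalence design (α = 0.05, power 0.8): Cohen's arcsine formula gives
15 per group and the pooled-normal formula 32.  The study's stated 16 per
group matches neither exactly; both results are reported and no attempt is
made to guess the original method.

## What passing tests do and do not show

The generator reproduces the *group-level first and second moments*, the
gain–CS coupling, and simple artifact morphologies.  It does not emulate:
irregular manual impulse shapes or overshoot, goggle slippage and
calibration drift, covert saccades, multiple saccades per trial,
within-subject serial correlation of CS occurrence, eye-position (as
opposed to velocity) effects, or age structure.  Recovery of the
calibrated means and AUC levels therefore validates the quantification
pipeline's correctness and internal consistency — not the clinical
performance of the cutoffs on real patients.  Printed
sensitivity/specificity pairs at specific cutoffs depend on the original
raw score distributions and are not reproducible from summary statistics;
the replicate-mean AUCs are, and land within a few hundredths of the
reported values.

Known limitations: HS "ipsi/contra" labels are a random designation;
processing a written dataset from disk designates the right side for
healthy subjects (the manifest does not carry the random designation), a
relabeling with no statistical effect under the pooled-side HS model;
bilateral-CS counts run higher than in patients because per-trial CS
occurrence is independent given the subject.
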