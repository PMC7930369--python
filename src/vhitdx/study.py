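"""Reference study conditions and replicate analyses.

Convenience layer reproducing the study design the calibration encodes:
17 subjects per group, 20 impulses per canal and side, and the
replicate-cohort ROC analyses used to judge how well horizontal-canal
statistics separate PICA stroke from vestibular neuritis.

Trace-level replicates run the full generate -> QC -> quantify pipeline.
The canal-ranking and subgroup *sign* checks instead operate on the
latent subject profiles (the quantification pipeline adds only
measurement noise on top of them), which keeps many-hundred-replicate
analyses fast.
"""
from __future__ import annotations

import numpy as np

from .calibration import CohortCalibration, default_calibration
from .datatypes import CANALS, SubjectSummary
from .pipeline import process_dataset
from .roc import empirical_roc
from .simulate import generate_cohort, sample_subject
from .stats import asymmetry

DEFAULT_GROUP_SIZES = {"HS": 17, "VN": 17, "PICA": 17}
IMPULSES_PER_SIDE = 20


def quantified_cohort(groups: dict[str, int], seed,
                      canals=CANALS, n_impulses_per_side: int = IMPULSES_PER_SIDE,
                      calib: CohortCalibration | None = None):
    """Generate a cohort and push every trial through QC + quantification.

    Returns (dataset, trial-metrics frame, subject summaries).
    """
    ds = generate_cohort(groups, n_impulses_per_side, calib, seed=seed,
                         canals=canals)
    designated = {sid: p.designated_side for sid, p in ds.profiles.items()}
    metrics, summaries = process_dataset(ds.traces, ds.manifest,
                                         designated_sides=designated)
    return ds, metrics, summaries


def group_mean_gain(summaries: list[SubjectSummary], group: str, canal: str,
                    laterality: str | None = None) -> float:
    """Cohort mean VOR gain; ``laterality=None`` pools both sides."""
    lats = ("ipsi", "contra") if laterality is None else (laterality,)
    vals = [s.gain(canal, lat) for s in summaries if s.group == group
            for lat in lats if s.gain(canal, lat) is not None]
    return float(np.mean(vals))


def group_mean_cs_area(summaries: list[SubjectSummary], group: str, canal: str,
                       laterality: str = "ipsi") -> float:
    """Cohort mean CS amplitude over subjects with a retained CS."""
    vals = [s.cs_area(canal, laterality) for s in summaries if s.group == group
            if s.cs_area(canal, laterality) is not None]
    return float(np.mean(vals))


def group_mean_css(summaries: list[SubjectSummary], group: str, canal: str) -> float:
    vals = [asymmetry(s).css[canal] for s in summaries if s.group == group]
    return float(np.mean(vals))


def replicate_hc_discrimination(n_replicates: int = 200, seed=0,
                                n_subjects: int = 17,
                                n_impulses_per_side: int = IMPULSES_PER_SIDE,
                                ) -> dict[str, float]:
    """Mean ROC AUC over replicate PICA+VN cohorts for the two key
    horizontal-canal statistics.

    Each replicate generates 17 PICA + 17 VN subjects (HC only), runs the
    full trace pipeline, and scores every subject by (a) the HC CS-amplitude
    asymmetry CSs and (b) the ipsilesional HC CS amplitude (0 when no CS is
    retained); PICA subjects sit at the low end of both scores.
    """
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = root.spawn(n_replicates)
    css_aucs, amp_aucs = [], []
    for ss in children:
        _, _, summ = quantified_cohort({"PICA": n_subjects, "VN": n_subjects},
                                       ss, canals=("HC",),
                                       n_impulses_per_side=n_impulses_per_side)
        labels = [s.group for s in summ]
        css = [asymmetry(s).css["HC"] for s in summ]
        amp = [s.cs_area("HC", "ipsi") or 0.0 for s in summ]
        css_aucs.append(empirical_roc(css, labels, "higher_is_VN").auc)
        amp_aucs.append(empirical_roc(amp, labels, "higher_is_VN").auc)
    return {"hc_css_auc": float(np.mean(css_aucs)),
            "ihc_cs_amplitude_auc": float(np.mean(amp_aucs)),
            "n_replicates": n_replicates}


def pica_subgroup_gain_difference(n_replicates: int = 200, seed=0,
                                  n_medial: int = 8, n_lateral: int = 9,
                                  ) -> np.ndarray:
    """Replicate differences (medial - lateral branch) in mean ipsilesional
    HC gain, drawn at the latent subject level."""
    calib = default_calibration()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    diffs = np.empty(n_replicates)
    for r in range(n_replicates):
        gains = {}
        for tag, n in (("PICA_M", n_medial), ("PICA_L", n_lateral)):
            side = "left"
            gains[tag] = np.mean([
                sample_subject(f"{tag}{i}", tag, side, calib, rng)
                .params[("HC", side)].true_gain for i in range(n)])
        diffs[r] = gains["PICA_M"] - gains["PICA_L"]
    return diffs


def canal_discrimination_profile_level(n_replicates: int = 200, seed=0,
                                       n_subjects: int = 17) -> dict[str, float]:
    """Mean AUC per canal for separating PICA from VN, computed from the
    latent subject profiles (gain, CS area and per-trial CS probability).

    A side's CS amplitude counts only when its per-trial CS probability
    clears the >20% consistency rule.  Per canal the AUC is averaged over
    four statistics: ipsilesional gain, ipsilesional CS amplitude, Gs and
    CSs.  Horizontal-canal statistics should out-rank the vertical canals.
    """
    calib = default_calibration()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sums = {c: [] for c in CANALS}
    for _ in range(n_replicates):
        profiles = ([sample_subject(f"P{i}", "PICA", "left", calib, rng)
                     for i in range(n_subjects)]
                    + [sample_subject(f"V{i}", "VN", "left", calib, rng)
                       for i in range(n_subjects)])
        labels = np.array([p.group for p in profiles])
        for canal in CANALS:
            gi = np.array([p.params[(canal, "left")].true_gain for p in profiles])
            gc = np.array([p.params[(canal, "right")].true_gain for p in profiles])

            def amp(side):
                return np.array([
                    p.params[(canal, side)].cs_area_mu
                    if p.params[(canal, side)].cs_prob > 0.2 else 0.0
                    for p in profiles])

            ai, ac = amp("left"), amp("right")
            aucs = [
                empirical_roc(gi, labels, "lower_is_VN").auc,
                empirical_roc(ai, labels, "higher_is_VN").auc,
                empirical_roc(np.abs(gc - gi), labels, "higher_is_VN").auc,
                empirical_roc(np.abs(ac - ai), labels, "higher_is_VN").auc,
            ]
            sums[canal].append(np.mean(aucs))
    return {canal: float(np.mean(v)) for canal, v in sums.items()}
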