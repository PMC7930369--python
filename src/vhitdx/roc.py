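"""Empirical ROC analysis for separating PICA stroke from vestibular
neuritis.

The AUC uses the Mann-Whitney convention (tied pairs count one half), so it
equals U / (n1 * n2) exactly and is invariant under strictly monotone score
transforms.  The optimal cutoff maximizes the Youden index
(sensitivity + specificity - 1), breaking ties toward higher specificity
and then toward the lower threshold.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import CANALS, AsymmetryMetrics, ParameterError, ROCResult, SubjectSummary

POSITIVE_GROUP = "VN"
NEGATIVE_GROUP = "PICA"

#: A priori score orientations: which direction of each statistic indicates
#: vestibular neuritis.  VN shows low ipsilesional gains, large ipsilesional
#: corrective saccades and marked asymmetry; PICA stroke shows bilaterally
#: reduced gains with small symmetric saccades on both sides.
DEFAULT_ORIENTATIONS: dict[str, str] = {}
for _c in CANALS:
    DEFAULT_ORIENTATIONS[f"{_c}_gain_ipsi"] = "lower_is_VN"
    DEFAULT_ORIENTATIONS[f"{_c}_gain_contra"] = "higher_is_VN"
    DEFAULT_ORIENTATIONS[f"{_c}_cs_area_ipsi"] = "higher_is_VN"
    DEFAULT_ORIENTATIONS[f"{_c}_cs_area_contra"] = "lower_is_VN"
    DEFAULT_ORIENTATIONS[f"{_c}_gs"] = "higher_is_VN"
    DEFAULT_ORIENTATIONS[f"{_c}_css"] = "higher_is_VN"
DEFAULT_ORIENTATIONS["HC_combined_mean"] = "higher_is_VN"
DEFAULT_ORIENTATIONS["HC_combined_logistic"] = "higher_is_VN"


def empirical_roc(scores, labels, orientation: str = "higher_is_VN",
                  name: str = "score", positive_label=POSITIVE_GROUP) -> ROCResult:
    """Empirical ROC of `scores` against binary `labels`.

    Thresholds sit at midpoints between distinct sorted scores plus +-inf;
    a subject is called positive (VN) when its oriented score is >= the
    threshold.  The AUC is computed from the Mann-Whitney U statistic with
    midranks, so ties contribute one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.size != labels.size:
        raise ParameterError("scores and labels differ in length")
    if not np.isfinite(scores).all():
        raise ParameterError("scores must be finite")
    if orientation not in ("higher_is_VN", "lower_is_VN"):
        raise ParameterError(f"unknown orientation {orientation!r}")
    pos = labels == positive_label
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("both classes must be present")

    oriented = scores if orientation == "higher_is_VN" else -scores
    ranks = rankdata(oriented)
    u = float(ranks[pos].sum()) - n_pos * (n_pos + 1) / 2.0
    auc = u / (n_pos * n_neg)

    distinct = np.unique(oriented)
    thresholds = np.concatenate(
        ([-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf]))
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, thr in enumerate(thresholds):
        called = oriented >= thr
        sens[i] = called[pos].mean()
        spec[i] = (~called[~pos]).mean()

    youden = sens + spec - 1.0
    best = np.flatnonzero(youden == youden.max())
    best = best[np.lexsort((thresholds[best], -spec[best]))][0]
    cutoff = thresholds[best] if orientation == "higher_is_VN" else -thresholds[best]
    return ROCResult(
        name=name, orientation=orientation, thresholds=thresholds,
        sens=sens, spec=spec, auc=float(auc),
        youden_cutoff=float(cutoff),
        sens_at_cutoff=float(sens[best]), spec_at_cutoff=float(spec[best]),
        n_pos=n_pos, n_neg=n_neg)


def youden_cutoff(roc: ROCResult) -> tuple[float, float, float]:
    """(cutoff, sensitivity, specificity) at the Youden-optimal threshold."""
    return roc.youden_cutoff, roc.sens_at_cutoff, roc.spec_at_cutoff


def combine_scores(css, gs, method: str = "mean", labels=None) -> np.ndarray:
    """Combine the CSs and Gs statistics into one score per subject.

    mean      arithmetic mean of the two raw values (transparent default);
    logistic  in-sample logistic-regression linear predictor on (CSs, Gs);
              requires `labels`.
    Neither construction claims to reproduce any particular published
    combined cutoff — the original combination rule is unspecified.
    """
    css = np.asarray(css, dtype=float)
    gs = np.asarray(gs, dtype=float)
    if css.size != gs.size:
        raise ParameterError("CSs and Gs vectors differ in length")
    if not (np.isfinite(css).all() and np.isfinite(gs).all()):
        raise ParameterError("missing CSs or Gs value")
    if method == "mean":
        return (css + gs) / 2.0
    if method == "logistic":
        if labels is None:
            raise ParameterError("logistic combination needs labels")
        from sklearn.linear_model import LogisticRegression
        X = np.column_stack([css, gs])
        y = (np.asarray(labels) == POSITIVE_GROUP).astype(int)
        model = LogisticRegression(C=1e6, max_iter=5000).fit(X, y)
        return model.decision_function(X)
    raise ParameterError(f"unknown combination method {method!r}")


def candidate_scores(summaries: list[SubjectSummary],
                     asyms: list[AsymmetryMetrics],
                     canals=CANALS) -> pd.DataFrame:
    """Per-subject score table for every candidate discriminating statistic.

    Missing CS areas (no retained saccade on that side) score 0.
    """
    asym_by_id = {a.subject_id: a for a in asyms}
    rows = []
    for s in summaries:
        a = asym_by_id[s.subject_id]
        row = {"subject_id": s.subject_id, "group": s.group}
        for canal in canals:
            for lat in ("ipsi", "contra"):
                row[f"{canal}_gain_{lat}"] = s.gain(canal, lat)
                row[f"{canal}_cs_area_{lat}"] = s.cs_area(canal, lat) or 0.0
            row[f"{canal}_gs"] = a.gs.get(canal)
            row[f"{canal}_css"] = a.css.get(canal)
        rows.append(row)
    df = pd.DataFrame(rows)
    if "HC_css" in df and "HC_gs" in df:
        df["HC_combined_mean"] = combine_scores(df["HC_css"], df["HC_gs"], "mean")
        if df["group"].nunique() == 2:
            df["HC_combined_logistic"] = combine_scores(
                df["HC_css"], df["HC_gs"], "logistic", labels=df["group"].to_numpy())
    return df


def roc_report(summaries: list[SubjectSummary], asyms: list[AsymmetryMetrics],
               orientations: dict[str, str] | None = None,
               canals=CANALS) -> tuple[pd.DataFrame, dict[str, ROCResult]]:
    """ROC per candidate statistic for the two patient groups, ranked by AUC.

    Returns the ranked table and the full :class:`ROCResult` per statistic.
    """
    orientations = {**DEFAULT_ORIENTATIONS, **(orientations or {})}
    df = candidate_scores(summaries, asyms, canals)
    df = df[df["group"].isin([POSITIVE_GROUP, NEGATIVE_GROUP])]
    if df["group"].nunique() < 2:
        raise ParameterError("ROC needs both patient groups")
    results: dict[str, ROCResult] = {}
    rows = []
    for col in df.columns:
        if col in ("subject_id", "group") or df[col].isna().any():
            continue
        roc = empirical_roc(df[col].to_numpy(), df["group"].to_numpy(),
                            orientations.get(col, "higher_is_VN"), name=col)
        results[col] = roc
        rows.append({"statistic": col, "orientation": roc.orientation,
                     "auc": roc.auc, "youden_cutoff": roc.youden_cutoff,
                     "sens": roc.sens_at_cutoff, "spec": roc.spec_at_cutoff,
                     "n_VN": roc.n_pos, "n_PICA": roc.n_neg})
    table = pd.DataFrame(rows).sort_values("auc", ascending=False).reset_index(drop=True)
    return table, results
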