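"""Asymmetry indices, abnormality flags and group-comparison statistics.

Gain asymmetry (Gs) and corrective-saccade asymmetry (CSs) are absolute
contralesional-minus-ipsilesional differences per canal.  Abnormality is
judged against a healthy-subject reference: a gain is abnormal when it
falls strictly below the healthy mean - 2 SD, an asymmetry when it rises
strictly above the healthy mean + 2 SD.  Group comparisons pick their test
from the per-group normality of the sample (Shapiro-Wilk at alpha = 0.05):
t-test / one-way ANOVA when every group passes, Mann-Whitney U /
Kruskal-Wallis otherwise; proportions use Fisher's exact test.
"""
from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import CANALS, AsymmetryMetrics, ParameterError, SubjectSummary

log = logging.getLogger("vhitdx")


def asymmetry(summary: SubjectSummary) -> AsymmetryMetrics:
    """Per-canal Gs and CSs for one subject.

    Gs = |contra gain - ipsi gain|; CSs = |contra CS area - ipsi CS area|,
    where a side with no retained corrective saccade contributes area 0.
    Symmetric in the side labels; raises when a canal has neither side.
    """
    out = AsymmetryMetrics(summary.subject_id, summary.group)
    canals = sorted({c for c, _ in summary.stats}, key=CANALS.index)
    if not canals:
        raise ParameterError("summary has no canal data")
    for canal in canals:
        gi = summary.gain(canal, "ipsi")
        gc = summary.gain(canal, "contra")
        if gi is None and gc is None:
            raise ParameterError(f"both sides missing for canal {canal}")
        if gi is not None and gc is not None:
            out.gs[canal] = abs(gc - gi)
        ai = summary.cs_area(canal, "ipsi") or 0.0
        ac = summary.cs_area(canal, "contra") or 0.0
        out.css[canal] = abs(ac - ai)
    return out


class ReferenceNorms:
    """Healthy-subject reference bounds per canal and metric.

    Gains pool both sides of every healthy subject; bounds are
    ``mean - 2 SD`` for gains (lower bound) and ``mean + 2 SD`` for the
    asymmetry indices (upper bound).
    """

    def __init__(self, hs_summaries: list[SubjectSummary]):
        if len(hs_summaries) < 2:
            raise ParameterError("reference norms need >= 2 healthy subjects")
        self.gain_mean: dict[str, float] = {}
        self.gain_sd: dict[str, float] = {}
        self.gs_mean: dict[str, float] = {}
        self.gs_sd: dict[str, float] = {}
        self.css_mean: dict[str, float] = {}
        self.css_sd: dict[str, float] = {}
        asyms = [asymmetry(s) for s in hs_summaries]
        for canal in CANALS:
            gains = [s.gain(canal, lat) for s in hs_summaries for lat in ("ipsi", "contra")
                     if s.gain(canal, lat) is not None]
            if not gains:
                continue
            self.gain_mean[canal] = float(np.mean(gains))
            self.gain_sd[canal] = float(np.std(gains, ddof=1))
            gss = [a.gs[canal] for a in asyms if canal in a.gs]
            csss = [a.css[canal] for a in asyms if canal in a.css]
            self.gs_mean[canal] = float(np.mean(gss))
            self.gs_sd[canal] = float(np.std(gss, ddof=1))
            self.css_mean[canal] = float(np.mean(csss))
            self.css_sd[canal] = float(np.std(csss, ddof=1))
            if self.gain_sd[canal] == 0 or self.gs_sd[canal] == 0:
                warnings.warn(f"zero-variance reference for canal {canal}")

    def gain_lower(self, canal: str) -> float:
        return self.gain_mean[canal] - 2 * self.gain_sd[canal]

    def gs_upper(self, canal: str) -> float:
        return self.gs_mean[canal] + 2 * self.gs_sd[canal]

    def css_upper(self, canal: str) -> float:
        return self.css_mean[canal] + 2 * self.css_sd[canal]


def abnormality_flags(metrics: AsymmetryMetrics, summary: SubjectSummary,
                      norms: ReferenceNorms) -> AsymmetryMetrics:
    """Fill the abnormality flags of `metrics` in place (and return it).

    Strict inequalities: a value exactly on a 2-SD bound is normal.
    """
    for canal in metrics.gs:
        for lat in ("ipsi", "contra"):
            g = summary.gain(canal, lat)
            if g is not None and canal in norms.gain_mean:
                metrics.abnormal_gain[(canal, lat)] = bool(g < norms.gain_lower(canal))
        metrics.abnormal_gs[canal] = bool(metrics.gs[canal] > norms.gs_upper(canal))
    for canal in metrics.css:
        if canal in norms.css_mean:
            metrics.abnormal_css[canal] = bool(metrics.css[canal] > norms.css_upper(canal))
    return metrics


def group_compare(values_by_group: dict[str, list], kind: str = "continuous",
                  parametric: bool | None = None) -> dict:
    """Compare >= 2 groups, choosing the test from per-group normality.

    continuous : Shapiro-Wilk at alpha = 0.05 on every group; all normal ->
        independent t-test (2 groups) or one-way ANOVA, otherwise
        Mann-Whitney U / Kruskal-Wallis.  Groups with < 3 values fall back
        to the nonparametric branch.  Pass ``parametric=True/False`` to
        bypass the automatic selection.
    proportion : two-sided Fisher's exact test on a 2x2 table given as two
        (successes, failures) pairs.

    Returns ``{"test_name", "statistic", "p"}`` with the test actually used.
    """
    groups = list(values_by_group)
    if len(groups) < 2:
        raise ParameterError("need >= 2 groups")
    if kind == "proportion":
        if len(groups) != 2:
            raise ParameterError("proportion comparison needs exactly 2 groups")
        table = np.array([list(values_by_group[g]) for g in groups], dtype=int)
        if table.shape != (2, 2):
            raise ParameterError("each group must supply (successes, failures)")
        stat, p = sps.fisher_exact(table, alternative="two-sided")
        return {"test_name": "fisher_exact", "statistic": float(stat), "p": float(p)}
    if kind != "continuous":
        raise ParameterError(f"unknown comparison kind {kind!r}")

    samples = [np.asarray(values_by_group[g], dtype=float) for g in groups]
    if any(s.size == 0 for s in samples):
        raise ParameterError("every group must be nonempty")
    normal = parametric
    if normal is None:
        normal = True
        for s in samples:
            if s.size < 3 or np.ptp(s) == 0:
                log.info("group too small or degenerate for normality testing; "
                         "using a nonparametric test")
                normal = False
                break
            if sps.shapiro(s).pvalue < 0.05:
                normal = False
                break
    if len(samples) == 2:
        if normal:
            res = sps.ttest_ind(*samples)
            return {"test_name": "t_test", "statistic": float(res.statistic),
                    "p": float(res.pvalue)}
        res = sps.mannwhitneyu(*samples, alternative="two-sided")
        return {"test_name": "mann_whitney_u", "statistic": float(res.statistic),
                "p": float(res.pvalue)}
    if normal:
        res = sps.f_oneway(*samples)
        return {"test_name": "anova", "statistic": float(res.statistic),
                "p": float(res.pvalue)}
    res = sps.kruskal(*samples)
    return {"test_name": "kruskal_wallis", "statistic": float(res.statistic),
            "p": float(res.pvalue)}


def sample_size_two_props(p1: float, p2: float, alpha: float = 0.05,
                          power: float = 0.80, method: str = "arcsine") -> int:
    """Per-group n to detect p1 vs p2 (two-sided) at the given alpha/power.

    arcsine        n = ceil((z_{a/2} + z_b)^2 / h^2) with Cohen's
                   h = 2*(asin sqrt(p1) - asin sqrt(p2));
    pooled_normal  the classical pooled two-proportion normal formula.
    """
    if not (0 < p2 < p1 < 1):
        raise ParameterError("need 0 < p2 < p1 < 1")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ParameterError("alpha and power must lie in (0, 1)")
    za = sps.norm.ppf(1 - alpha / 2)
    zb = sps.norm.ppf(power)
    if method == "arcsine":
        h = 2 * (math.asin(math.sqrt(p1)) - math.asin(math.sqrt(p2)))
        return math.ceil((za + zb) ** 2 / h ** 2)
    if method == "pooled_normal":
        pbar = (p1 + p2) / 2
        num = (za * math.sqrt(2 * pbar * (1 - pbar))
               + zb * math.sqrt(p1 * (1 - p1) + p2 * (1 - p2))) ** 2
        return math.ceil(num / (p1 - p2) ** 2)
    raise ParameterError(f"unknown method {method!r}")


def bilateral_cs_percentage(n_bilateral: int, n_subjects: int) -> float:
    """Percentage of subjects showing corrective saccades on both sides."""
    if n_subjects < 1 or not 0 <= n_bilateral <= n_subjects:
        raise ParameterError("invalid bilateral-CS counts")
    return 100.0 * n_bilateral / n_subjects


def _ci95(values: np.ndarray) -> tuple[float, float]:
    n = values.size
    m = float(np.mean(values))
    half = sps.t.ppf(0.975, n - 1) * float(np.std(values, ddof=1)) / math.sqrt(n)
    return m - half, m + half


def summaries_to_frame(summaries: list[SubjectSummary]) -> pd.DataFrame:
    """Long-format per-subject summary table (one row per canal x side)."""
    rows = []
    for s in summaries:
        for (canal, lat), st in s.stats.items():
            rows.append({
                "subject_id": s.subject_id, "group": s.group,
                "lesion_side": s.lesion_side, "canal": canal, "laterality": lat,
                "n_accepted": st.n_accepted if st else 0,
                "mean_gain": st.mean_gain if st else np.nan,
                "cs_incidence": st.cs_incidence if st else np.nan,
                "mean_cs_area": (st.mean_cs_area if st and st.mean_cs_area is not None
                                 else np.nan),
                "mean_cs_latency": (st.mean_cs_latency if st and st.mean_cs_latency is not None
                                    else np.nan),
                "bilateral_cs": bool(s.bilateral_cs.get(canal, False)),
            })
    return pd.DataFrame(rows)


def asymmetry_to_frame(asyms: list[AsymmetryMetrics]) -> pd.DataFrame:
    rows = []
    for a in asyms:
        for canal in a.gs:
            rows.append({
                "subject_id": a.subject_id, "group": a.group, "canal": canal,
                "gs": a.gs[canal], "css": a.css.get(canal, np.nan),
                "abnormal_gain_ipsi": a.abnormal_gain.get((canal, "ipsi")),
                "abnormal_gain_contra": a.abnormal_gain.get((canal, "contra")),
                "abnormal_gs": a.abnormal_gs.get(canal),
                "abnormal_css": a.abnormal_css.get(canal),
            })
    return pd.DataFrame(rows)


def build_group_tables(summaries: list[SubjectSummary],
                       asyms: list[AsymmetryMetrics] | None = None,
                       norms: ReferenceNorms | None = None) -> pd.DataFrame:
    """Cohort table in the style of the study's group tables.

    One row per group x canal x metric x laterality with mean, SD, t-based
    95% CI, abnormal counts (when norms are supplied) and bilateral-CS
    counts.  A pure function of the per-subject summaries: re-running on
    the same input reproduces the table exactly.
    """
    if not summaries:
        raise ParameterError("no summaries")
    if asyms is None:
        asyms = [asymmetry(s) for s in summaries]
    if norms is not None:
        for a, s in zip(asyms, summaries):
            abnormality_flags(a, s, norms)
    asym_by_id = {a.subject_id: a for a in asyms}
    df = summaries_to_frame(summaries)
    rows = []

    def stat_row(group, canal, metric, lat, values, abnormal_n=None, n_total=None):
        values = np.asarray([v for v in values if v is not None and np.isfinite(v)])
        row = {"group": group, "canal": canal, "metric": metric, "laterality": lat,
               "n": int(values.size), "mean": np.nan, "sd": np.nan,
               "ci_low": np.nan, "ci_high": np.nan,
               "abnormal_n": abnormal_n, "abnormal_pct": (
                   100.0 * abnormal_n / n_total if abnormal_n is not None and n_total
                   else None)}
        if values.size:
            row["mean"] = float(np.mean(values))
        if values.size >= 2:
            row["sd"] = float(np.std(values, ddof=1))
            row["ci_low"], row["ci_high"] = _ci95(values)
        return row

    for group, gdf in df.groupby("group", sort=False):
        ids = gdf["subject_id"].unique()
        n_total = len(ids)
        g_asyms = [asym_by_id[i] for i in ids if i in asym_by_id]
        for canal in sorted(gdf["canal"].unique(), key=CANALS.index):
            cdf = gdf[gdf["canal"] == canal]
            for lat in ("ipsi", "contra"):
                ldf = cdf[cdf["laterality"] == lat]
                ab = (sum(a.abnormal_gain.get((canal, lat), False) for a in g_asyms)
                      if norms is not None else None)
                rows.append(stat_row(group, canal, "gain", lat,
                                     ldf["mean_gain"].tolist(), ab, n_total))
                rows.append(stat_row(group, canal, "cs_incidence", lat,
                                     ldf["cs_incidence"].tolist()))
                rows.append(stat_row(group, canal, "cs_area", lat,
                                     ldf["mean_cs_area"].tolist()))
                rows.append(stat_row(group, canal, "cs_latency", lat,
                                     ldf["mean_cs_latency"].tolist()))
            ab_gs = (sum(a.abnormal_gs.get(canal, False) for a in g_asyms)
                     if norms is not None else None)
            ab_css = (sum(a.abnormal_css.get(canal, False) for a in g_asyms)
                      if norms is not None else None)
            rows.append(stat_row(group, canal, "gs", "",
                                 [a.gs.get(canal) for a in g_asyms], ab_gs, n_total))
            rows.append(stat_row(group, canal, "css", "",
                                 [a.css.get(canal) for a in g_asyms], ab_css, n_total))
            n_bilat = int(cdf[cdf["laterality"] == "ipsi"]["bilateral_cs"].sum())
            rows.append({"group": group, "canal": canal, "metric": "bilateral_cs",
                         "laterality": "", "n": n_total, "mean": n_bilat,
                         "sd": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "abnormal_n": None,
                         "abnormal_pct": bilateral_cs_percentage(n_bilat, n_total)})
    return pd.DataFrame(rows)
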