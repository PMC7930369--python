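"""End-to-end orchestration: generate -> process -> analyze.

Three stages mirror the CLI subcommands and can each run standalone so
that real exported traces can enter at the processing stage:

* :func:`run_generate` writes a synthetic study (trace CSVs + manifest);
* :func:`process_dataset` / :func:`run_process` QC and quantify every
  trial and build per-subject summaries;
* :func:`run_analyze` builds the cohort tables, the group-comparison
  report and the ROC report.

Everything is deterministic given (seed, config); every output file
carries the resolved-config hash.
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from .calibration import CohortCalibration, default_calibration
from .datatypes import CANALS, ParameterError, SubjectSummary, TraceError, TrialMetrics, VelocityTrace
from .simulate import Dataset, generate_cohort
from .roc import roc_report
from .stats import (
    ReferenceNorms, abnormality_flags, asymmetry, asymmetry_to_frame,
    build_group_tables, group_compare, summaries_to_frame,
)
from .traceproc import DEFAULT_QC, QCThresholds, process_trace, summarize_subject

log = logging.getLogger("vhitdx")

TRIAL_METRICS_COLUMNS = ("subject_id", "group", "canal", "side", "trial_id",
                         "qc", "reason", "gain", "cs_area_deg", "cs_latency_ms")


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration of one synthetic study run."""

    seed: int
    groups: dict = dataclasses.field(
        default_factory=lambda: {"HS": 17, "VN": 17, "PICA": 17})
    n_impulses_per_side: int = 20
    sampling_rate: float = 250.0
    canals: tuple = CANALS
    calibration_overrides: dict = dataclasses.field(default_factory=dict)
    qc: QCThresholds = DEFAULT_QC
    out_dir: str = "vhitdx_run"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ParameterError("a seed is mandatory for generation")
        from .calibration import default_calibration as _dc
        known = {g for g, _, _ in _dc().entries}
        for g, n in self.groups.items():
            if g not in known:
                raise ParameterError(f"unknown group {g!r}")
            if n < 1:
                raise ParameterError(f"group {g} needs >= 1 subject")
        for f in dataclasses.fields(QCThresholds):
            v = getattr(self.qc, f.name)
            if isinstance(v, (int, float)) and v < 0:
                raise ParameterError(f"threshold {f.name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        qc_over = raw.pop("qc", {})
        cfg = cls(**{k: v for k, v in raw.items() if k in
                     {f.name for f in dataclasses.fields(cls)}})
        if qc_over:
            cfg.qc = dataclasses.replace(DEFAULT_QC, **qc_over)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["canals"] = list(self.canals)
        return d

    @property
    def hash(self) -> str:
        # the hash covers the scientific configuration, not the output path
        d = self.to_dict()
        d.pop("out_dir", None)
        return _io.config_hash(d)

    def calibration(self) -> CohortCalibration:
        return default_calibration().with_overrides(self.calibration_overrides)


def run_generate(config: RunConfig) -> Dataset:
    """Generate the synthetic study and write it under ``config.out_dir``."""
    dataset = generate_cohort(
        config.groups, config.n_impulses_per_side, config.calibration(),
        seed=config.seed, canals=tuple(config.canals),
        sampling_rate=config.sampling_rate)
    out = Path(config.out_dir)
    dataset.write(out, config_hash=config.hash)
    (out / "config.yaml").write_text(yaml.safe_dump(
        {**config.to_dict(), "config_hash": config.hash}))
    log.info("wrote %d trials to %s", len(dataset.traces), out)
    return dataset


def process_dataset(traces, manifest: pd.DataFrame,
                    qc: QCThresholds = DEFAULT_QC,
                    designated_sides: dict[str, str] | None = None,
                    ) -> tuple[pd.DataFrame, list[SubjectSummary]]:
    """Quantify every trial and build per-subject summaries.

    `traces` is an iterable of :class:`VelocityTrace` (or ``None`` for
    unreadable trials, which are recorded as ``tracking_error``), aligned
    with the manifest rows.  `designated_sides` maps healthy subject ids to
    the side treated as ipsilesional; unlisted healthy subjects default to
    the right side.
    """
    designated_sides = designated_sides or {}
    rows = []
    by_subject: dict[str, dict[tuple[str, str], list[TrialMetrics]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    for trace, row in zip(traces, manifest.itertuples(index=False)):
        if trace is None:
            rows.append((row.subject_id, row.group, row.canal, row.side,
                         row.trial_id, "rejected", "tracking_error",
                         np.nan, np.nan, np.nan))
            continue
        m = process_trace(trace, qc)
        best = max(m.saccades, key=lambda e: e.area, default=None)
        rows.append((row.subject_id, row.group, row.canal, row.side, row.trial_id,
                     m.trial.qc_status, m.trial.reason or "",
                     m.vor_gain if m.vor_gain is not None else np.nan,
                     best.area if best else np.nan,
                     best.latency if best else np.nan))
        meta[row.subject_id] = (row.group, row.lesion_side)
        by_subject.setdefault(row.subject_id, {}).setdefault(
            (row.canal, row.side), []).append(m)

    summaries = []
    for subject_id, by_cs in by_subject.items():
        group, lesion = meta[subject_id]
        designated = (lesion if lesion in ("left", "right")
                      else designated_sides.get(subject_id, "right"))
        summaries.append(summarize_subject(subject_id, group, lesion,
                                           designated, by_cs, qc))
    metrics_df = pd.DataFrame(rows, columns=list(TRIAL_METRICS_COLUMNS))
    return metrics_df, summaries


def _iter_traces_from_dir(dataset_dir: Path, manifest: pd.DataFrame):
    traces_dir = dataset_dir / "traces"
    for row in manifest.itertuples(index=False):
        path = traces_dir / f"{row.trial_id}.csv"
        try:
            yield _io.read_trace_csv(path, canal=row.canal, side=row.side,
                                     trial_id=row.trial_id, subject_id=row.subject_id)
        except (TraceError, FileNotFoundError) as exc:
            log.warning("trial %s unreadable (%s); marked tracking_error",
                        row.trial_id, exc)
            yield None


def run_process(dataset_dir: str | Path, qc: QCThresholds = DEFAULT_QC,
                config_hash: str = "") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Process a written dataset directory; emits trial_metrics.csv and
    subject_summary.csv next to the manifest."""
    dataset_dir = Path(dataset_dir)
    manifest = _io.read_manifest(dataset_dir)
    metrics_df, summaries = process_dataset(
        _iter_traces_from_dir(dataset_dir, manifest), manifest, qc)
    summary_df = summaries_to_frame(summaries)
    _io.write_table(metrics_df, dataset_dir / "trial_metrics.csv", config_hash)
    _io.write_table(summary_df, dataset_dir / "subject_summary.csv", config_hash)
    return metrics_df, summary_df


def analyze_summaries(summaries: list[SubjectSummary],
                      roc_stats: list[str] | None = None) -> dict:
    """Cohort tables, group-comparison statistics and the ROC report.

    Returns a dict with ``group_tables`` (DataFrame), ``asymmetry``
    (DataFrame), ``stats_report`` (dict of contrasts), ``roc_table``
    (DataFrame or None) and ``roc_results``.
    """
    groups = sorted({s.group for s in summaries})
    hs = [s for s in summaries if s.group == "HS"]
    norms = ReferenceNorms(hs) if len(hs) >= 2 else None
    asyms = [asymmetry(s) for s in summaries]
    if norms is not None:
        for a, s in zip(asyms, summaries):
            abnormality_flags(a, s, norms)
    tables = build_group_tables(summaries, asyms, norms)

    stats_report = {}
    pica = [s for s in summaries if s.group == "PICA"]
    vn = [s for s in summaries if s.group == "VN"]
    if pica and vn:
        for canal in sorted({c for s in summaries for c, _ in s.stats},
                            key=CANALS.index):
            for metric, getter in (
                    ("gain_ipsi", lambda s: s.gain(canal, "ipsi")),
                    ("cs_area_ipsi", lambda s: s.cs_area(canal, "ipsi")),
                    ("gs", None), ("css", None)):
                if getter is not None:
                    vals = {g: [x for x in map(getter, grp) if x is not None]
                            for g, grp in (("PICA", pica), ("VN", vn))}
                else:
                    amap = {a.subject_id: a for a in asyms}
                    attr = "gs" if metric == "gs" else "css"
                    vals = {g: [getattr(amap[s.subject_id], attr).get(canal)
                                for s in grp
                                if getattr(amap[s.subject_id], attr).get(canal) is not None]
                            for g, grp in (("PICA", pica), ("VN", vn))}
                if all(len(v) >= 2 for v in vals.values()):
                    stats_report[f"{canal}_{metric}_PICA_vs_VN"] = group_compare(vals)

    roc_table, roc_results = None, {}
    if pica and vn:
        both = pica + vn
        both_asyms = [a for a in asyms if a.group in ("PICA", "VN")]
        canals_present = tuple(sorted({c for s in both for c, _ in s.stats},
                                      key=CANALS.index))
        roc_table, roc_results = roc_report(both, both_asyms, canals=canals_present)
        if roc_stats:
            roc_table = roc_table[roc_table["statistic"].isin(roc_stats)]
    else:
        log.warning("fewer than two patient groups: ROC analysis skipped")
    return {"group_tables": tables, "asymmetry": asymmetry_to_frame(asyms),
            "stats_report": stats_report, "roc_table": roc_table,
            "roc_results": roc_results, "norms": norms}


def run_analyze(dataset_dir: str | Path, roc_stats: list[str] | None = None,
                config_hash: str = "") -> dict:
    """Analyze a processed dataset directory; writes group_tables.csv,
    asymmetry.csv, stats_report.json, roc_report.json and roc_curves.csv."""
    dataset_dir = Path(dataset_dir)
    summary_path = dataset_dir / "subject_summary.csv"
    if not summary_path.exists():
        raise FileNotFoundError(f"run `vhitdx process` first: no {summary_path}")
    summary_df = _io.read_table(summary_path)
    summaries = frame_to_summaries(summary_df)
    out = analyze_summaries(summaries, roc_stats)
    _io.write_table(out["group_tables"], dataset_dir / "group_tables.csv", config_hash)
    _io.write_table(out["asymmetry"], dataset_dir / "asymmetry.csv", config_hash)
    _io.write_json(out["stats_report"], dataset_dir / "stats_report.json", config_hash)
    if out["roc_table"] is not None:
        _io.write_json(
            {"statistics": out["roc_table"].to_dict(orient="records")},
            dataset_dir / "roc_report.json", config_hash)
        curves = pd.concat([
            pd.DataFrame({"statistic": name, "threshold": r.thresholds,
                          "sens": r.sens, "spec": r.spec})
            for name, r in out["roc_results"].items()], ignore_index=True)
        _io.write_table(curves, dataset_dir / "roc_curves.csv", config_hash)
    return out


def frame_to_summaries(summary_df: pd.DataFrame) -> list[SubjectSummary]:
    """Rebuild :class:`SubjectSummary` objects from subject_summary.csv."""
    from .datatypes import SideStats
    summaries = []
    for subject_id, sdf in summary_df.groupby("subject_id", sort=False):
        first = sdf.iloc[0]
        lesion = str(first["lesion_side"])
        summary = SubjectSummary(str(subject_id), str(first["group"]), lesion,
                                 designated_side="")
        for row in sdf.itertuples(index=False):
            if row.n_accepted == 0:
                summary.stats[(row.canal, row.laterality)] = None
                continue
            summary.stats[(row.canal, row.laterality)] = SideStats(
                n_accepted=int(row.n_accepted),
                mean_gain=None if pd.isna(row.mean_gain) else float(row.mean_gain),
                cs_incidence=float(row.cs_incidence),
                mean_cs_area=None if pd.isna(row.mean_cs_area) else float(row.mean_cs_area),
                mean_cs_latency=(None if pd.isna(row.mean_cs_latency)
                                 else float(row.mean_cs_latency)),
            )
            summary.bilateral_cs[row.canal] = bool(row.bilateral_cs)
        summaries.append(summary)
    return summaries


def run_study(config: RunConfig) -> dict:
    """In-memory generate -> process -> analyze round trip (no files)."""
    dataset = generate_cohort(
        config.groups, config.n_impulses_per_side, config.calibration(),
        seed=config.seed, canals=tuple(config.canals),
        sampling_rate=config.sampling_rate)
    designated = {sid: p.designated_side for sid, p in dataset.profiles.items()}
    metrics_df, summaries = process_dataset(
        dataset.traces, dataset.manifest, config.qc, designated)
    out = analyze_summaries(summaries)
    out.update(dataset=dataset, trial_metrics=metrics_df, summaries=summaries)
    return out
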