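"""End-to-end orchestration: ingest -> patterns -> clustering -> inference.

`run_pipeline` executes the whole analysis on either a directory of
minute-stream CSVs plus a covariate table, or an in-silico cohort
generated from a CohortSpec, and writes a study report: cohort
description, per-group activity patterns with the mixed-model
comparison, guideline fulfilment with its logistic model, trajectory
clusters with the low-cluster logistic model, adherence, and a
filter-decision log that makes the inclusion flowchart auditable.
All outputs are plain text (CSV/JSON/Markdown) and byte-stable for a
fixed seed.
"""
from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import (CadenceThresholds, GuidelineCutoffs, MIN_COMPLETE_DAYS,
                     WINDOW_DAYS)
from .clustering import (ClusterModel, assignment_agreement, kmeans_longitudinal,
                         profile_clusters, select_k)
from .ingest import (MinuteStepStream, ParticipantDays, assemble_participant,
                     build_window, filter_adherent, read_stream)
from .patterns import (adherence_summary, features_table, impute_missing_days,
                       participant_summary, trajectory_matrix, who_status)
from .stats import (fit_group_lmm, fit_low_cluster_logistic, fit_who_logistic,
                    sample_size_two_means)
from .synthetic import CohortSpec, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed to run the analysis once, reproducibly.

    Exactly one of ``stream_dir`` (with ``covariates_file``) or
    ``synthetic`` must be set.
    """

    stream_dir: str | None = None
    covariates_file: str | None = None
    synthetic: CohortSpec | None = None
    thresholds: CadenceThresholds = field(default_factory=CadenceThresholds)
    cutoffs: GuidelineCutoffs = field(default_factory=GuidelineCutoffs)
    min_days: int = MIN_COMPLETE_DAYS
    cluster_feature: str = "mvpa_minutes"
    k: int = 3
    k_range: tuple[int, ...] | None = None
    n_starts: int = 20
    impute: str = "weekday-mean"  # or "none"
    covariates: tuple[str, ...] = ("sex", "age", "bmi", "disease_duration",
                                   "biologic", "employed", "ptga")
    lmm_responses: tuple[str, ...] = ("steps_total", "mvpa_minutes")
    seed: int = 42
    out_dir: str = "actitraj_out"
    plots: bool = False

    def __post_init__(self) -> None:
        has_files = self.stream_dir is not None
        has_synth = self.synthetic is not None
        if has_files == has_synth:
            raise ValueError(
                "config must set exactly one of stream_dir (+covariates_file) "
                "or synthetic")
        if has_files and self.covariates_file is None:
            raise ValueError("stream_dir requires covariates_file")
        if self.impute not in ("weekday-mean", "none"):
            raise ValueError(f"unknown impute mode {self.impute!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = CohortSpec.from_dict(raw["synthetic"])
        if "thresholds" in raw:
            raw["thresholds"] = CadenceThresholds(**raw["thresholds"])
        if "cutoffs" in raw:
            raw["cutoffs"] = GuidelineCutoffs(**raw["cutoffs"])
        for key in ("k_range", "covariates", "lmm_responses"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.to_dict()
        d["thresholds"] = dataclasses.asdict(self.thresholds)
        d["cutoffs"] = dataclasses.asdict(self.cutoffs)
        return d


@dataclass
class StudyReport:
    """All tables the pipeline produces, plus provenance."""

    cohort_table: pd.DataFrame          # Table-1 style description by group
    patterns_table: pd.DataFrame        # Table-2 style means (SD) + model p
    fulfilment_table: pd.DataFrame      # guideline fulfilment by group
    cluster_table: pd.DataFrame         # Table-3 style cluster profiles
    cluster_model: ClusterModel | None
    cluster_agreement: float | None     # imputed vs available-case stability
    lmm_tables: dict[str, pd.DataFrame]
    who_logistic_table: pd.DataFrame | None
    low_cluster_logistic_table: pd.DataFrame | None
    adherence: dict
    flowchart: pd.DataFrame
    design_sample_size: int
    manifest: dict
    empty_cohort: bool = False


def _load_cohort(config: PipelineConfig):
    if config.synthetic is not None:
        cohort = generate_cohort(config.synthetic)
        return cohort.streams, cohort.covariates
    cov = pd.read_csv(config.covariates_file, parse_dates=["activation_date"])
    cov["activation_date"] = pd.to_datetime(cov["activation_date"]).dt.date
    streams = []
    stream_dir = Path(config.stream_dir)
    for pid in cov["participant_id"]:
        path = stream_dir / f"{pid}.csv"
        if not path.exists():
            raise FileNotFoundError(f"no stream file for participant {pid!r}: {path}")
        streams.append(read_stream(path, participant_id=str(pid)))
    return streams, cov


def _mean_sd(series: pd.Series) -> str:
    if len(series) == 0 or series.isna().all():
        return "-"
    return f"{series.mean():.1f} ({series.std(ddof=1):.1f})"


def _cohort_table(cov: pd.DataFrame, analyzable_ids: set) -> pd.DataFrame:
    sub = cov[cov["participant_id"].isin(analyzable_ids)]
    rows = []
    for grp, g in sub.groupby("group", sort=True):
        rows.append({
            "group": grp,
            "n": len(g),
            "female_n_pct": f"{(g['sex'] == 'F').sum()} ({100 * (g['sex'] == 'F').mean():.1f}%)",
            "age_mean_sd": _mean_sd(g["age"]),
            "bmi_mean_sd": _mean_sd(g["bmi"]),
            "disease_duration_mean_sd": _mean_sd(g["disease_duration"]),
            "biologic_n_pct": f"{int(g['biologic'].sum())} ({100 * g['biologic'].mean():.1f}%)",
            "employed_n_pct": f"{int(g['employed'].sum())} ({100 * g['employed'].mean():.1f}%)",
            "ptga_mean_sd": _mean_sd(g["ptga"]),
        })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> StudyReport:
    """Execute the full analysis; persist every stage under ``out_dir``."""
    out = Path(config.out_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    streams, cov = _load_cohort(config)

    # --- ingest & filter ------------------------------------------------
    assembled: list[ParticipantDays] = []
    act_dates = dict(zip(cov["participant_id"], cov["activation_date"]))
    for s in streams:
        window = build_window(act_dates[s.participant_id])
        assembled.append(assemble_participant(s, window))
    analyzable, excluded = filter_adherent(assembled, min_days=config.min_days)
    flow = pd.DataFrame([
        {"stage": "included", "n": len(assembled)},
        {"stage": "analyzable", "n": len(analyzable)},
        {"stage": "excluded_lt_min_days", "n": len(excluded)},
    ])
    decisions = pd.DataFrame([
        {"participant_id": p.participant_id, "n_complete_days": p.n_complete_days,
         "rule": f">= {config.min_days} full days",
         "outcome": "analyzable" if p.n_complete_days >= config.min_days else "excluded"}
        for p in assembled
    ])
    design_n = sample_size_two_means(delta=1500.0, sd=3300.0, power=0.80, alpha=0.05)

    manifest = {
        "actitraj_version": __version__,
        "config": config.to_manifest(),
        "n_included": len(assembled),
        "n_analyzable": len(analyzable),
        "n_excluded": len(excluded),
    }

    if len(analyzable) == 0:
        report = StudyReport(
            cohort_table=pd.DataFrame(), patterns_table=pd.DataFrame(),
            fulfilment_table=pd.DataFrame(), cluster_table=pd.DataFrame(),
            cluster_model=None, cluster_agreement=None, lmm_tables={},
            who_logistic_table=None, low_cluster_logistic_table=None,
            adherence=dataclasses.asdict(adherence_summary(assembled)) if assembled else {},
            flowchart=flow, design_sample_size=design_n, manifest=manifest,
            empty_cohort=True,
        )
        _write_report(report, config, decisions)
        return report

    # --- patterns -------------------------------------------------------
    feats = features_table(analyzable, config.thresholds)
    summary = participant_summary(feats)
    statuses = who_status(summary, config.cutoffs)
    adher = adherence_summary(assembled)
    ana_ids = {p.participant_id for p in analyzable}

    pat_rows = []
    merged = summary.merge(cov, on="participant_id")
    for grp, g in merged.groupby("group", sort=True):
        pat_rows.append({
            "group": grp, "n": len(g),
            "steps_per_day_mean_sd": _mean_sd(g["steps_total"]),
            "active_min_per_day_mean_sd": _mean_sd(g["active_minutes"]),
            "mvpa_min_per_day_mean_sd": _mean_sd(g["mvpa_minutes"]),
            "mvpa_min_per_week_mean_sd": _mean_sd(g["mvpa_min_per_week"]),
            "morning_steps_pct_mean_sd": _mean_sd(100 * g["morning_fraction"]),
        })
    patterns_tbl = pd.DataFrame(pat_rows)

    st_merged = statuses.merge(cov, on="participant_id")
    ful_rows = []
    for grp, g in st_merged.groupby("group", sort=True):
        ful_rows.append({
            "group": grp, "n": len(g),
            "who_met_n_pct": f"{int(g['who_met'].sum())} ({100 * g['who_met'].mean():.1f}%)",
            "steps10k_n_pct": f"{int(g['steps10k_met'].sum())} ({100 * g['steps10k_met'].mean():.1f}%)",
            "steps7k_n_pct": f"{int(g['steps7k_met'].sum())} ({100 * g['steps7k_met'].mean():.1f}%)",
        })
    fulfilment_tbl = pd.DataFrame(ful_rows)

    # --- trajectories ---------------------------------------------------
    matrix = trajectory_matrix(feats, config.cluster_feature)
    imputed = impute_missing_days(matrix) if config.impute == "weekday-mean" else matrix
    rng = np.random.SeedSequence(config.seed)
    ck_seed = int(rng.generate_state(1)[0] % (2**31))
    if config.k_range:
        model, score_table = select_k(imputed, config.k_range,
                                      n_starts=config.n_starts, seed=ck_seed)
    else:
        model = kmeans_longitudinal(imputed, config.k, n_starts=config.n_starts,
                                    seed=ck_seed)
        score_table = None
    agreement = None
    if config.impute == "weekday-mean" and matrix.isna().any().any():
        cc_model = kmeans_longitudinal(matrix, model.k, n_starts=config.n_starts,
                                       seed=ck_seed)
        agreement = assignment_agreement(model.assignments, cc_model.assignments)
    cluster_tbl = profile_clusters(model, summary, cov, config.cluster_feature)

    # --- inference ------------------------------------------------------
    day_level = feats.merge(cov, on="participant_id")
    lmm_tables: dict[str, pd.DataFrame] = {}
    lmm_meta: dict[str, dict] = {}
    two_groups = cov[cov["participant_id"].isin(ana_ids)]["group"].nunique() >= 2
    if two_groups:
        for resp in config.lmm_responses:
            try:
                r = fit_group_lmm(day_level, response=resp,
                                  covariates=list(config.covariates))
                lmm_tables[resp] = r.fixed_effects
                lmm_meta[resp] = {
                    "group_term": r.group_term, "group_estimate": r.group_estimate,
                    "group_p": r.group_p, "variance_power": r.variance_power,
                    "converged": r.converged, "n_participants": r.n_participants,
                    "n_observations": r.n_observations,
                }
            except ValueError as exc:
                logger.warning("LMM for %s skipped: %s", resp, exc)
        try:
            who_res = fit_who_logistic(statuses, cov, covariates=list(config.covariates))
            who_tbl = who_res.table
        except ValueError as exc:
            logger.warning("WHO logistic skipped: %s", exc)
            who_tbl = None
    else:
        who_tbl = None
    try:
        low_res = fit_low_cluster_logistic(model, cov, covariates=list(config.covariates))
        low_tbl = low_res.table
    except ValueError as exc:
        logger.warning("low-cluster logistic skipped: %s", exc)
        low_tbl = None

    manifest["cluster"] = {
        "k": model.k, "seed": ck_seed,
        "calinski_harabasz": model.calinski_harabasz,
        "sizes": model.assignments.value_counts().sort_index().tolist(),
        "agreement_imputed_vs_available": agreement,
    }
    manifest["lmm"] = lmm_meta
    report = StudyReport(
        cohort_table=_cohort_table(cov, ana_ids),
        patterns_table=patterns_tbl,
        fulfilment_table=fulfilment_tbl,
        cluster_table=cluster_tbl,
        cluster_model=model,
        cluster_agreement=agreement,
        lmm_tables=lmm_tables,
        who_logistic_table=who_tbl,
        low_cluster_logistic_table=low_tbl,
        adherence=dataclasses.asdict(adher),
        flowchart=flow,
        design_sample_size=design_n,
        manifest=manifest,
    )
    _write_report(report, config, decisions, feats=feats, summary=summary,
                  score_table=score_table)
    if config.plots:
        _write_plots(out, feats, model, config.cluster_feature)
    return report


def _fmt_float(x) -> str:
    return f"{x:.6g}" if isinstance(x, float) else str(x)


def _write_report(report: StudyReport, config: PipelineConfig,
                  decisions: pd.DataFrame,
                  feats: pd.DataFrame | None = None,
                  summary: pd.DataFrame | None = None,
                  score_table: pd.DataFrame | None = None) -> None:
    out = Path(config.out_dir)
    tdir = out / "tables"
    tdir.mkdir(parents=True, exist_ok=True)
    report.cohort_table.to_csv(tdir / "cohort_description.csv", index=False)
    report.patterns_table.to_csv(tdir / "activity_patterns.csv", index=False)
    report.fulfilment_table.to_csv(tdir / "guideline_fulfilment.csv", index=False)
    report.cluster_table.to_csv(tdir / "cluster_profiles.csv", index=False)
    report.flowchart.to_csv(tdir / "flowchart.csv", index=False)
    decisions.to_csv(tdir / "filter_decisions.csv", index=False)
    for resp, tbl in report.lmm_tables.items():
        tbl.to_csv(tdir / f"lmm_{resp}.csv", index=False)
    if report.who_logistic_table is not None:
        report.who_logistic_table.to_csv(tdir / "who_logistic.csv", index=False)
    if report.low_cluster_logistic_table is not None:
        report.low_cluster_logistic_table.to_csv(tdir / "low_cluster_logistic.csv", index=False)
    if feats is not None:
        summary.to_csv(tdir / "participant_summary.csv", index=False)
    if score_table is not None:
        score_table.to_csv(tdir / "cluster_selection.csv", index=False)
    if report.cluster_model is not None:
        (out / "cluster_model.json").write_text(
            json.dumps(report.cluster_model.to_dict(), sort_keys=True, indent=1))
    (out / "manifest.json").write_text(
        json.dumps(report.manifest, sort_keys=True, indent=1, default=_fmt_float))

    lines = ["# Activity-tracker cohort report", ""]
    lines += ["## Flowchart", ""]
    for _, r in report.flowchart.iterrows():
        lines.append(f"- {r['stage']}: {r['n']}")
    n_inc = int(report.flowchart.loc[report.flowchart.stage == "included", "n"].iloc[0])
    n_ana = int(report.flowchart.loc[report.flowchart.stage == "analyzable", "n"].iloc[0])
    n_exc = int(report.flowchart.loc[report.flowchart.stage == "excluded_lt_min_days", "n"].iloc[0])
    assert n_inc == n_ana + n_exc, "flowchart counts must be conserved"
    lines += ["", f"Design-stage sample size (delta=1500 steps/day, SD=3300, "
              f"power 80%, alpha 5%): {report.design_sample_size} per group", ""]
    if report.empty_cohort:
        lines += ["**Empty cohort:** no participant met the adherence "
                  f"criterion of >= {config.min_days} full days; downstream "
                  "analyses were skipped.", ""]
    else:
        lines += ["## Adherence", ""]
        for k, v in report.adherence.items():
            lines.append(f"- {k}: {_fmt_float(v)}")
        lines += ["", "## Activity patterns by group", "",
                  report.patterns_table.to_string(index=False), "",
                  "## Guideline fulfilment", "",
                  report.fulfilment_table.to_string(index=False), "",
                  "## Trajectory clusters", "",
                  report.cluster_table.to_string(index=False), ""]
        if report.cluster_agreement is not None:
            lines.append(f"Assignment agreement, imputed vs available-case "
                         f"clustering: {report.cluster_agreement:.3f}")
            lines.append("")
        for resp, meta in report.manifest.get("lmm", {}).items():
            lines.append(f"LMM {resp}: group effect {meta['group_estimate']:.2f}, "
                         f"p={meta['group_p']:.3f}, variance power="
                         f"{'none' if meta['variance_power'] is None else format(meta['variance_power'], '.3f')}")
        lines.append("")
        lines.append("No multiplicity adjustment is applied to any p-value.")
    (out / "report.md").write_text("\n".join(lines) + "\n")


def _write_plots(out: Path, feats: pd.DataFrame, model: ClusterModel,
                 feature: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    wk = feats.groupby("weekday")[feature].mean()
    ax.plot(wk.index, wk.values, marker="o")
    ax.set_xticks(range(7), ["Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"])
    ax.set_ylabel(feature)
    ax.set_title("Weekday periodicity")
    fig.tight_layout()
    fig.savefig(out / "weekday_periodicity.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 4))
    for j, c in enumerate(model.centroids):
        ax.plot(np.arange(1, len(c) + 1), c, label=f"cluster {j}")
    ax.set_xlabel("day")
    ax.set_ylabel(feature)
    ax.legend()
    ax.set_title("Cluster mean trajectories")
    fig.tight_layout()
    fig.savefig(out / "cluster_trajectories.png", dpi=120)
    plt.close(fig)
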