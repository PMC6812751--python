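"""End-to-end orchestration: simulate/load -> preprocess -> average ->
difference traces -> presence criteria -> peaks -> ANOVAs -> post-hocs,
with every table written to the output directory alongside the config
that produced it."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import detect, stats
from .derp import DerpTrace, ErpTrace, average_erp, compute_derp, grand_mean
from .montage import Montage, RoiSpec, builtin_rois, get_roi, standard_montage_32
from .preprocess import PreprocConfig, rereference, reject_artifacts
from .synth import (GROUPS, EXPERIMENTS, CohortSpec, EpochSet, iter_cohort,
                    paper_fixture)

log = logging.getLogger("derplab")

__all__ = ["PipelineConfig", "ResultsBundle", "run_pipeline",
           "derps_from_cohort", "presence_pattern"]


@dataclass
class PipelineConfig:
    cohort: CohortSpec
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    alpha: float = 0.01
    min_run_samples: int = 10
    tail: str = "two-sided"
    exploratory_window_ms: tuple[float, float] = (80.0, 250.0)
    exploratory_electrodes: tuple[str, ...] = (
        "C3", "Cz", "C4", "F3", "Fz", "F4", "Fp1", "Fp2")
    greenhouse_geisser: bool = False
    seed: int | None = None      # overrides cohort.seed when set

    def resolved_cohort(self) -> CohortSpec:
        if self.seed is not None:
            return dataclasses.replace(self.cohort, seed=self.seed)
        return self.cohort

    @classmethod
    def fixture(cls, seed: int = 2019) -> "PipelineConfig":
        return cls(cohort=paper_fixture(seed=seed))


@dataclass
class ResultsBundle:
    config: PipelineConfig
    erps: list[ErpTrace]
    derps: list[DerpTrace]
    grand_means: dict[tuple[str, str], np.ndarray]
    rejection: pd.DataFrame
    presence: pd.DataFrame
    peaks: dict[str, pd.DataFrame]            # ROI name -> table
    anovas: dict[tuple[str, str], stats.AnovaResult]   # (roi, dv)
    posthocs: pd.DataFrame
    channels: tuple[str, ...]
    times_ms: np.ndarray


def derps_from_cohort(cohort: CohortSpec,
                      preproc: PreprocConfig,
                      montage: Montage | None = None,
                      ) -> tuple[list[ErpTrace], list[DerpTrace],
                                 pd.DataFrame]:
    """Simulate, preprocess and average a cohort; return per-subject ERPs,
    difference traces, and the trial-bookkeeping table."""
    montage = montage or standard_montage_32()
    erps: list[ErpTrace] = []
    reports = []
    by_key: dict[tuple[str, str], dict[str, ErpTrace]] = {}
    for epochs in iter_cohort(cohort, montage):
        cleaned = rereference(epochs, preproc.reference)
        cleaned, report = reject_artifacts(cleaned,
                                           preproc.reject_threshold_uv)
        reports.append(report)
        if report.all_removed:
            raise RuntimeError(
                f"all trials rejected for {epochs.subject}/"
                f"{epochs.experiment}/{epochs.condition}")
        erp = average_erp(cleaned, preproc)
        erps.append(erp)
        by_key.setdefault((erp.subject, erp.experiment), {})[
            erp.condition] = erp
    derps = []
    for (subject, experiment), conds in sorted(by_key.items()):
        if {"reversal", "stability"} <= set(conds):
            derps.append(compute_derp(conds["reversal"], conds["stability"]))
    rejection = pd.DataFrame(
        [{"subject": r.subject, "group": r.group,
          "experiment": r.experiment, "condition": r.condition,
          "n_total": r.n_total, "n_kept": r.n_kept,
          "n_removed": r.n_removed} for r in reports])
    return erps, derps, rejection


def rejection_summary(rejection: pd.DataFrame) -> pd.DataFrame:
    """Per group x experiment: average total, average kept, max, min --
    the bookkeeping columns of the published trial-count table."""
    per_subject = (rejection.groupby(
        ["group", "experiment", "subject"])[["n_total", "n_kept"]]
        .mean().reset_index())
    return (per_subject.groupby(["group", "experiment"])
            .agg(avg_total=("n_total", "mean"),
                 avg_after_rejection=("n_kept", "mean"),
                 max_trials=("n_kept", "max"),
                 min_trials=("n_kept", "min"))
            .reset_index())


def presence_pattern(derps: list[DerpTrace], montage: Montage,
                     config: PipelineConfig,
                     rois: list[RoiSpec] | None = None) -> pd.DataFrame:
    """Confirmatory presence for RP/RN/PP and the exploratory anterior
    scan, per group x experiment cell."""
    rois = rois if rois is not None else builtin_rois()
    confirmatory = [r for r in rois if r.name in ("RP", "RN", "PP")]
    rows = []
    for group in GROUPS:
        for experiment in EXPERIMENTS:
            cell = [d for d in derps
                    if d.group == group and d.experiment == experiment]
            if not cell:
                continue
            for roi in confirmatory:
                res = detect.presence_confirmatory(
                    cell, roi, config.alpha, config.min_run_samples,
                    config.tail)
                rows.append({"component": roi.name, "group": group,
                             "experiment": experiment,
                             "variant": "confirmatory", "met": res.met,
                             "qualifying": ";".join(res.qualifying)})
            res = detect.presence_exploratory(
                cell, montage, config.exploratory_window_ms,
                config.exploratory_electrodes, config.alpha,
                config.min_run_samples, config.tail, component="FN")
            rows.append({"component": "FN", "group": group,
                         "experiment": experiment, "variant": "exploratory",
                         "met": res.met,
                         "qualifying": ";".join(f"{a}+{b}" for a, b
                                                in res.qualifying)})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig,
                 out_dir: str | Path | None = None) -> ResultsBundle:
    """Execute all stages; write tables and provenance if ``out_dir`` set."""
    montage = standard_montage_32()
    cohort = config.resolved_cohort()
    rois = builtin_rois()

    log.info("stage simulate+preprocess: %d meditators, %d non-meditators",
             cohort.n_meditators, cohort.n_non_meditators)
    erps, derps, rejection = derps_from_cohort(cohort, config.preproc,
                                               montage)
    if not derps:
        raise RuntimeError("no difference traces produced")
    log.info("stage derp: %d difference traces", len(derps))

    grand_means = {}
    for group in GROUPS:
        for experiment in EXPERIMENTS:
            sel = [d for d in derps
                   if d.group == group and d.experiment == experiment]
            if sel:
                grand_means[(group, experiment)] = grand_mean(
                    derps, group, experiment)

    presence = presence_pattern(derps, montage, config, rois)
    log.info("stage detect: %d presence verdicts", len(presence))

    peaks = {roi.name: detect.measure_component(derps, roi) for roi in rois}

    anovas = {}
    for roi in rois:
        for dv in ("amplitude", "latency"):
            try:
                anovas[(roi.name, dv)] = stats.mixed_anova(
                    peaks[roi.name], dv,
                    greenhouse_geisser=config.greenhouse_geisser)
            except ValueError as exc:
                log.warning("ANOVA %s/%s skipped: %s", roi.name, dv, exc)

    posthoc_rows = []
    named = [("RP", "occipital_vs_parietal", "amplitude"),
             ("RP", "left_vs_right", "amplitude"),
             ("RN", "occipital_vs_parietal", "latency"),
             ("PP", "central_vs_peripheral", "amplitude"),
             ("PP", "central_vs_peripheral", "latency")]
    raw_ps, kept = [], []
    for roi_name, contrast, dv in named:
        try:
            stat, p = stats.posthoc_contrast(peaks[roi_name], contrast, dv)
        except (ValueError, KeyError) as exc:
            log.warning("post-hoc %s/%s skipped: %s", roi_name, contrast,
                        exc)
            continue
        raw_ps.append(p)
        kept.append((roi_name, contrast, dv, stat, p))
    if raw_ps:
        adjusted = stats.holm_correct(raw_ps)
        for (roi_name, contrast, dv, stat, p), adj in zip(kept, adjusted):
            row = {"component": roi_name, "contrast": contrast, "dv": dv,
                   "statistic": stat}
            row.update(stats.report_corrected_pair(p, float(adj)))
            posthoc_rows.append(row)
    posthocs = pd.DataFrame(posthoc_rows)

    bundle = ResultsBundle(
        config=config, erps=erps, derps=derps, grand_means=grand_means,
        rejection=rejection, presence=presence, peaks=peaks, anovas=anovas,
        posthocs=posthocs, channels=derps[0].channels,
        times_ms=derps[0].times_ms)

    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: ResultsBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _dump_config(bundle.config, out / "config.yaml")
    bundle.rejection.to_csv(out / "rejection_report.tsv", sep="\t",
                            index=False)
    rejection_summary(bundle.rejection).to_csv(
        out / "trial_counts.tsv", sep="\t", index=False)
    bundle.presence.to_csv(out / "presence.tsv", sep="\t", index=False)
    for name, table in bundle.peaks.items():
        table.to_csv(out / f"peaks_{name}.tsv", sep="\t", index=False)
    for (name, dv), res in bundle.anovas.items():
        res.table.to_csv(out / f"anova_{name}_{dv}.tsv", sep="\t",
                         index=False)
    if len(bundle.posthocs):
        bundle.posthocs.to_csv(out / "posthocs.tsv", sep="\t", index=False)
    gm = {f"{g}/{e}": arr.tolist() for (g, e), arr in
          bundle.grand_means.items()}
    (out / "grand_means.json").write_text(json.dumps(
        {"channels": list(bundle.channels),
         "times_ms": bundle.times_ms.tolist(), "traces": gm}))
    (out / "report.txt").write_text(text_report(bundle))


def text_report(bundle: ResultsBundle) -> str:
    """Human-readable summary echoing the 'p, F(df1,df2), eta_p^2' style."""
    lines = ["component presence", "------------------"]
    for r in bundle.presence.itertuples():
        lines.append(f"{r.component:3s} {r.group:14s} {r.experiment:8s} "
                     f"{r.variant:13s} met={r.met}")
    lines += ["", "ANOVAs", "------"]
    for (name, dv), res in sorted(bundle.anovas.items()):
        lines.append(f"{name} / {dv}  (n={res.n_subjects}, "
                     f"dropped={res.n_dropped_subjects})")
        for row in res.table.itertuples():
            lines.append(
                f"  {row.effect:32s} p = {row.p:.4g}, "
                f"F({row.df1},{row.df2}) = {row.F:.2f}, "
                f"eta_p^2 = {row.partial_eta_sq:.2f}")
    if len(bundle.posthocs):
        lines += ["", "post-hoc contrasts (corrected/uncorrected p)",
                  "--------------------------------------------"]
        for r in bundle.posthocs.itertuples():
            lines.append(f"  {r.component} {r.contrast} ({r.dv}): "
                         f"p = {r.p_corrected:.4g}/{r.p_uncorrected:.4g}")
    return "\n".join(lines) + "\n"


def _dump_config(config: PipelineConfig, path: Path) -> None:
    d = dataclasses.asdict(config)
    d["cohort"]["trial_counts"] = {
        f"{g}/{e}": dataclasses.asdict(tc)
        for (g, e), tc in config.cohort.trial_counts.items()}
    d["cohort"]["components"] = {
        g: [dataclasses.asdict(t) for t in tpls]
        for g, tpls in config.cohort.components.items()}
    d = json.loads(json.dumps(d))  # tuples -> lists for YAML
    path.write_text(yaml.safe_dump(d, sort_keys=False))


def load_config(path: str | Path) -> PipelineConfig:
    from .synth import ComponentTemplate, TrialCountSpec
    d = yaml.safe_load(Path(path).read_text())
    cd = d.pop("cohort")
    cd["trial_counts"] = {tuple(k.split("/")): TrialCountSpec(**v)
                          for k, v in cd["trial_counts"].items()}
    cd["components"] = {g: tuple(ComponentTemplate(**t) for t in tpls)
                        for g, tpls in cd["components"].items()}
    cd["channel_noise_scale"] = dict(cd.get("channel_noise_scale") or {})
    cohort = CohortSpec(**cd)
    preproc = PreprocConfig(**{**d.pop("preproc", {})})
    if isinstance(preproc.reference, list):
        preproc = dataclasses.replace(preproc,
                                      reference=tuple(preproc.reference))
    for key in ("exploratory_window_ms", "exploratory_electrodes"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    if isinstance(preproc.baseline_ms, list):
        preproc = dataclasses.replace(preproc,
                                      baseline_ms=tuple(preproc.baseline_ms))
    return PipelineConfig(cohort=cohort, preproc=preproc, **d)
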