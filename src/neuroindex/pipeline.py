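"""End-to-end orchestration of the two-trial composite-biomarker analysis.

Runs, from one configuration: the per-arm symptom and BDNF time-course
repeated-measures ANOVAs with baseline post-hoc contrasts, the drug x time
mixed ANOVA, the NI / NI-enhancement correlation suite, the pooled baseline
BDNF-HAMD correlation, and the two ROC analyses (BDNF as a case/control
detector; early NI enhancement as a predictor of final treatment response).
Every analysis declares its complete-case subset; nothing is imputed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import io as tio
from . import ni as tni
from . import roc as troc
from . import stats as tstats

logger = logging.getLogger(__name__)

EARLY_DAY = {"trial1": 7, "trial2": 4}
FINAL_DAY = 28

#: The correlation pairings reported per arm: NI-NI across visits, then
#: NI against the enhancement over the named interval.
CORRELATION_KEYS = (
    "ni_d0_vs_early",
    "ni_d0_vs_final",
    "ni_early_vs_final",
    "ni_early_vs_enh_early",
    "ni_final_vs_enh_final",
    "ni_early_vs_enh_final",
)


@dataclasses.dataclass
class AnalysisConfig:
    early_day: dict = dataclasses.field(default_factory=lambda: dict(EARLY_DAY))
    final_day: int = FINAL_DAY
    responder_threshold: float = tni.DEFAULT_RESPONDER_THRESHOLD
    posthoc_correction: str = "none"
    alpha: float = 0.05
    min_roc_class_count: int = 3
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.responder_threshold <= 1):
            raise ValueError("responder_threshold must be in (0, 1]")
        for trial, d in self.early_day.items():
            if d >= self.final_day:
                raise ValueError(f"early_day[{trial}] must precede final_day")


@dataclasses.dataclass
class AnalysisReport:
    symptom_timecourse: dict = dataclasses.field(default_factory=dict)
    bdnf_timecourse: dict = dataclasses.field(default_factory=dict)
    bdnf_vs_controls: dict = dataclasses.field(default_factory=dict)
    mixed: dict = dataclasses.field(default_factory=dict)
    ni_correlations: dict = dataclasses.field(default_factory=dict)
    pooled_baseline: tstats.CorrelationResult | None = None
    roc_diagnosis: troc.RocResult | None = None
    roc_diagnosis_skipped: str | None = None
    roc_prediction: dict = dataclasses.field(default_factory=dict)
    responder_counts: dict = dataclasses.field(default_factory=dict)
    errors: list = dataclasses.field(default_factory=list)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------

def run_symptom_timecourse(
    dataset: tio.TrialDataset, scale: str, arm: str,
    posthoc_correction: str = "none",
) -> tstats.AnovaResult:
    """Complete-case RM-ANOVA over the scheduled visit days of one scale."""
    sub = dataset.for_arm(arm)
    wide = sub.pivot(scale).dropna(axis=1, how="all")
    days = [int(d) for d in wide.columns]
    if len(days) < 2:
        raise ValueError(f"fewer than 2 usable days for {scale} in arm {arm!r}")
    cc = tio.complete_cases(sub, [scale], days)
    mat = cc.pivot(scale, days).to_numpy(dtype=float)
    result = tstats.rm_anova_oneway(mat)
    contrasts = tstats.posthoc_vs_baseline(mat, 0, posthoc_correction)
    for con in contrasts:
        con.level = days[con.level] if con.level < len(days) else con.level
    result.posthoc = contrasts
    return result


def run_bdnf_timecourse(
    dataset: tio.TrialDataset, arm: str, posthoc_correction: str = "none"
) -> tstats.AnovaResult:
    return run_symptom_timecourse(dataset, "bdnf_pg_ml", arm, posthoc_correction)


def run_mixed_timecourse(
    dataset: tio.TrialDataset, column: str, days: list[int] | None = None
) -> tstats.AnovaResult:
    """Drug x time split-plot ANOVA across both patient arms of a trial."""
    pat = dataset.patients()
    wide = pat.pivot(column).dropna(axis=1, how="all")
    use_days = days or [int(d) for d in wide.columns]
    cc = tio.complete_cases(pat, [column], use_days)
    mat = cc.pivot(column, use_days).to_numpy(dtype=float)
    groups = np.array([cc.arm_of(s) for s in cc.subjects])
    return tstats.mixed_anova(mat, groups)


def run_ni_correlation_suite(
    dataset: tio.TrialDataset, arm: str, early_day: int, final_day: int = FINAL_DAY
) -> dict[str, tstats.CorrelationResult]:
    """The six NI / NI-enhancement correlations for one arm.

    Each pairing is computed on its own complete cases (subjects with NI
    defined on every day that pairing needs); pairings with fewer than three
    such subjects are skipped with a logged reason.
    """
    table = tni.ni_table(dataset.for_arm(arm))
    wide = table.pivot(index="subject_id", columns="day", values="ni")
    for d in (0, early_day, final_day):
        if d not in wide.columns:
            wide[d] = np.nan

    def col(d):
        return wide[d]

    pairs = {
        "ni_d0_vs_early": (col(0), col(early_day)),
        "ni_d0_vs_final": (col(0), col(final_day)),
        "ni_early_vs_final": (col(early_day), col(final_day)),
        "ni_early_vs_enh_early": (col(early_day), col(early_day) - col(0)),
        "ni_final_vs_enh_final": (col(final_day), col(final_day) - col(0)),
        "ni_early_vs_enh_final": (col(early_day), col(final_day) - col(0)),
    }
    out: dict[str, tstats.CorrelationResult] = {}
    for key, (x, y) in pairs.items():
        ok = x.notna() & y.notna()
        if ok.sum() < 3:
            logger.info("skipping %s for arm %s: only %d complete cases",
                        key, arm, int(ok.sum()))
            continue
        out[key] = tstats.pearson(x[ok].to_numpy(), y[ok].to_numpy())
    return out


def pooled_baseline_correlation(
    datasets: list[tio.TrialDataset],
) -> tstats.CorrelationResult:
    """Pearson of day-0 BDNF against day-0 HAMD-24, pooled across trials."""
    xs, ys = [], []
    for ds in datasets:
        pat = ds.patients()
        f = pat.frame
        base = f[(f["day"] == 0) & f["bdnf_pg_ml"].notna() & f["hamd24"].notna()]
        xs.append(base["bdnf_pg_ml"].to_numpy(dtype=float))
        ys.append(base["hamd24"].to_numpy(dtype=float))
    return tstats.pearson(np.concatenate(xs), np.concatenate(ys))


def run_roc_suite(
    dataset: tio.TrialDataset,
    controls: tio.TrialDataset | None,
    config: AnalysisConfig,
    trial: str,
) -> tuple[troc.RocResult | None, dict[str, Any]]:
    """Diagnosis ROC (baseline BDNF, lower votes patient) and per-arm
    prediction ROCs (early NI enhancement, higher votes responder).

    An arm's prediction ROC is skipped, with the reason recorded, when fewer
    than ``config.min_roc_class_count`` subjects fall in either response
    class.
    """
    early = config.early_day[trial]
    diagnosis = None
    if controls is not None and controls.n_subjects > 0:
        diagnosis = diagnosis_roc([dataset], controls)

    prediction: dict[str, Any] = {}
    pat = dataset.patients()
    for arm in sorted(set(pat.frame["arm"])):
        sub = pat.for_arm(arm)
        scores, labels = _prediction_inputs(sub, early, config)
        n_pos = int(labels.sum()) if labels.size else 0
        n_neg = int(labels.size - n_pos)
        if min(n_pos, n_neg) < config.min_roc_class_count:
            reason = (
                f"insufficient class counts (responders={n_pos}, "
                f"non-responders={n_neg}, need >= {config.min_roc_class_count} each)"
            )
            logger.info("prediction ROC skipped for %s: %s", arm, reason)
            prediction[arm] = reason
            continue
        prediction[arm] = troc.roc_curve(scores, labels, "higher_is_positive")
    return diagnosis, prediction


def diagnosis_roc(
    datasets: list[tio.TrialDataset], controls: tio.TrialDataset
) -> troc.RocResult:
    """Baseline BDNF of all patients vs healthy controls, low score = case."""
    pats = []
    for ds in datasets:
        f = ds.patients().frame
        base = f[(f["day"] == 0) & f["bdnf_pg_ml"].notna()]
        pats.append(base["bdnf_pg_ml"].to_numpy(dtype=float))
    pat_scores = np.concatenate(pats)
    ctrl_scores = controls.frame["bdnf_pg_ml"].dropna().to_numpy(dtype=float)
    scores = np.concatenate([pat_scores, ctrl_scores])
    labels = np.concatenate([np.ones(pat_scores.size, dtype=int),
                             np.zeros(ctrl_scores.size, dtype=int)])
    return troc.roc_curve(scores, labels, "lower_is_positive")


def _prediction_inputs(arm_ds: tio.TrialDataset, early: int, config: AnalysisConfig):
    """Early NI enhancement and responder labels on the pairing's complete cases."""
    labels = {
        l.subject_id: l.responder
        for l in tni.classify_responders(
            arm_ds, 0, config.final_day, config.responder_threshold
        )
    }
    table = tni.ni_table(arm_ds)
    wide = table.pivot(index="subject_id", columns="day", values="ni")
    scores, resp = [], []
    for sid in wide.index:
        if sid not in labels:
            continue
        if 0 in wide.columns and early in wide.columns:
            n0, ne = wide.at[sid, 0], wide.at[sid, early]
            if np.isfinite(n0) and np.isfinite(ne):
                scores.append(ne - n0)
                resp.append(int(labels[sid]))
    return np.asarray(scores, dtype=float), np.asarray(resp, dtype=int)


# --------------------------------------------------------------------------
# Full run
# --------------------------------------------------------------------------

def run_all(
    trial1: tio.TrialDataset | None,
    trial2: tio.TrialDataset | None,
    controls: tio.TrialDataset | None,
    config: AnalysisConfig | None = None,
) -> AnalysisReport:
    """Run every stage on the supplied datasets.

    Stage failures are recorded under ``report.errors`` with the stage name;
    remaining stages still run.  The report is a pure function of the inputs
    and the config.
    """
    config = config or AnalysisConfig()
    report = AnalysisReport()
    trials = [(t, ds) for t, ds in (("trial1", trial1), ("trial2", trial2)) if ds is not None]

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            logger.warning("stage %s failed: %s", name, exc)
            report.errors.append((name, str(exc)))
        else:
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)

    for trial, ds in trials:
        enrolled, _ = tio.apply_enrollment(ds)
        for arm in sorted(set(enrolled.patients().frame["arm"])):
            for scale in tio.SCALE_COLUMNS:
                stage(
                    f"{trial}:{arm}:{scale}",
                    lambda trial=trial, arm=arm, scale=scale, ds=enrolled: report.symptom_timecourse.__setitem__(
                        (trial, arm, scale),
                        run_symptom_timecourse(ds, scale, arm, config.posthoc_correction),
                    ),
                )
            stage(
                f"{trial}:{arm}:bdnf",
                lambda trial=trial, arm=arm, ds=enrolled: report.bdnf_timecourse.__setitem__(
                    (trial, arm),
                    run_bdnf_timecourse(ds, arm, config.posthoc_correction),
                ),
            )
            early = config.early_day[trial]
            stage(
                f"{trial}:{arm}:ni_correlations",
                lambda trial=trial, arm=arm, ds=enrolled, early=early: report.ni_correlations.__setitem__(
                    (trial, arm),
                    run_ni_correlation_suite(ds, arm, early, config.final_day),
                ),
            )
            stage(
                f"{trial}:{arm}:responders",
                lambda trial=trial, arm=arm, ds=enrolled: report.responder_counts.__setitem__(
                    (trial, arm), _responder_counts(ds, arm, config)
                ),
            )
        if trial == "trial2":
            for col in ("hamd24", "bdnf_pg_ml"):
                stage(
                    f"trial2:mixed:{col}",
                    lambda col=col, ds=enrolled: report.mixed.__setitem__(
                        col, run_mixed_timecourse(ds, col)
                    ),
                )
        stage(
            f"{trial}:roc",
            lambda trial=trial, ds=enrolled: _set_roc(report, ds, controls, config, trial),
        )

    if trials:
        stage(
            "pooled_baseline",
            lambda: setattr(
                report, "pooled_baseline",
                pooled_baseline_correlation([ds for _, ds in trials]),
            ),
        )
    if controls is not None and trials:
        stage(
            "diagnosis_roc",
            lambda: setattr(
                report, "roc_diagnosis",
                diagnosis_roc([ds for _, ds in trials], controls),
            ),
        )
    else:
        report.roc_diagnosis_skipped = "no healthy-control table supplied"

    if controls is not None:
        stage("bdnf_vs_controls", lambda: _controls_comparison(report, trials, controls))

    if config.output_dir:
        write_report(report, config)
    return report


def _set_roc(report, ds, controls, config, trial):
    _, prediction = run_roc_suite(ds, None, config, trial)
    for arm, res in prediction.items():
        report.roc_prediction[(trial, arm)] = res


def _responder_counts(ds, arm, config):
    labels = tni.classify_responders(
        ds.for_arm(arm), 0, config.final_day, config.responder_threshold
    )
    n_resp = sum(l.responder for l in labels)
    return {"responders": n_resp, "non_responders": len(labels) - n_resp,
            "n_labelled": len(labels)}


def _controls_comparison(report, trials, controls):
    """Welch t of patient BDNF at each blood day against healthy controls."""
    ctrl = controls.frame["bdnf_pg_ml"].dropna().to_numpy(dtype=float)
    if ctrl.size < 2:
        return
    for trial, ds in trials:
        f = ds.patients().frame
        for day in sorted(set(f.loc[f["bdnf_pg_ml"].notna(), "day"])):
            vals = f.loc[(f["day"] == day) & f["bdnf_pg_ml"].notna(),
                         "bdnf_pg_ml"].to_numpy(dtype=float)
            if vals.size >= 2:
                report.bdnf_vs_controls[(trial, int(day))] = tstats.two_sample_t(vals, ctrl)


# --------------------------------------------------------------------------
# Serialisation and rendering
# --------------------------------------------------------------------------

def _plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        d = {}
        for f in dataclasses.fields(obj):
            v = getattr(obj, f.name)
            if isinstance(v, np.ndarray):
                v = v.tolist()
            d[f.name] = _plain(v)
        return d
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def report_to_dict(report: AnalysisReport) -> dict:
    out = {}
    for f in dataclasses.fields(report):
        v = getattr(report, f.name)
        if f.name in ("symptom_timecourse", "bdnf_timecourse", "bdnf_vs_controls",
                      "ni_correlations", "roc_prediction", "responder_counts"):
            v = {"|".join(str(p) for p in k) if isinstance(k, tuple) else str(k): _plain(x)
                 for k, x in v.items()}
        else:
            v = _plain(v)
        out[f.name] = v
    return out


def render_summary(report: AnalysisReport, config: AnalysisConfig | None = None) -> str:
    """Human-readable multi-section summary of an analysis report."""
    config = config or AnalysisConfig()
    lines: list[str] = ["Neuroplasticity-index analysis summary", "=" * 40]

    if report.symptom_timecourse or report.bdnf_timecourse:
        lines.append("\nTime-course RM-ANOVA (Greenhouse-Geisser corrected)")
        for (trial, arm, scale), res in sorted(report.symptom_timecourse.items()):
            e = res.effect("time")
            lines.append(
                f"  {trial} {arm} {scale}: F({e.df_corrected[0]:.3f},"
                f"{e.df_corrected[1]:.2f}) = {e.f_stat:.2f}, p = {e.p:.4g} "
                f"[{_stars(e.p)}] (n={res.n_subjects})"
            )
        for (trial, arm), res in sorted(report.bdnf_timecourse.items()):
            e = res.effect("time")
            lines.append(
                f"  {trial} {arm} BDNF: F({e.df_corrected[0]:.3f},"
                f"{e.df_corrected[1]:.2f}) = {e.f_stat:.2f}, p = {e.p:.4g} "
                f"[{_stars(e.p)}] (n={res.n_subjects})"
            )

    if report.mixed:
        lines.append("\nTrial 2 drug x time mixed ANOVA")
        for col, res in report.mixed.items():
            for e in res.effects:
                df = e.df_corrected or e.df
                lines.append(
                    f"  {col} {e.name}: F({df[0]:.3f},{df[1]:.2f}) = "
                    f"{e.f_stat:.3f}, p = {e.p:.4g} [{_stars(e.p)}]"
                )

    if report.pooled_baseline is not None:
        c = report.pooled_baseline
        lines.append(
            f"\nPooled baseline BDNF-HAMD correlation: r = {c.r:.3f} "
            f"(R^2 = {c.r_squared:.2f}), p = {c.p_two_tailed:.4g} (n={c.n})"
        )

    if report.ni_correlations:
        lines.append("\nNI and NI-enhancement correlations")
        for (trial, arm), suite in sorted(report.ni_correlations.items()):
            for key in CORRELATION_KEYS:
                if key not in suite:
                    continue
                c = suite[key]
                lines.append(
                    f"  {trial} {arm} {key}: R^2 = {c.r_squared:.3f}, "
                    f"p = {c.p_two_tailed:.4g} [{_stars(c.p_two_tailed)}] (n={c.n})"
                )

    if report.roc_diagnosis is not None:
        r = report.roc_diagnosis
        lines.append(
            f"\nDiagnosis ROC (baseline BDNF, low = case): AUC = {r.auc:.3f}, "
            f"Youden cut {r.optimal_threshold:.0f} pg/ml "
            f"(sens {100 * r.optimal_sensitivity:.1f}%, "
            f"spec {100 * r.optimal_specificity:.1f}%; "
            f"{r.n_pos} patients vs {r.n_neg} controls)"
        )
    elif report.roc_diagnosis_skipped:
        lines.append(f"\nDiagnosis ROC skipped: {report.roc_diagnosis_skipped}")

    if report.roc_prediction:
        lines.append("\nPrediction ROC (early NI enhancement vs final response)")
        for (trial, arm), res in sorted(report.roc_prediction.items()):
            if isinstance(res, str):
                lines.append(f"  {trial} {arm}: skipped - {res}")
            else:
                lines.append(
                    f"  {trial} {arm}: AUC = {res.auc:.3f} "
                    f"({res.n_pos} responders vs {res.n_neg} non-responders), "
                    f"Youden cut {res.optimal_threshold:.1f}"
                )

    if report.responder_counts:
        lines.append("\nResponder classification "
                     f"(HAMD-24 reduction >= {config.responder_threshold:.0%})")
        for (trial, arm), c in sorted(report.responder_counts.items()):
            lines.append(
                f"  {trial} {arm}: {c['responders']}/{c['n_labelled']} responders"
            )

    if report.errors:
        lines.append("\nStage errors")
        for name, msg in report.errors:
            lines.append(f"  {name}: {msg}")
    return "\n".join(lines) + "\n"


def write_report(report: AnalysisReport, config: AnalysisConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    anova_rows = []
    for (trial, arm, scale), res in report.symptom_timecourse.items():
        frame = res.to_frame()
        frame.insert(0, "measure", scale)
        frame.insert(0, "arm", arm)
        frame.insert(0, "trial", trial)
        anova_rows.append(frame)
    for (trial, arm), res in report.bdnf_timecourse.items():
        frame = res.to_frame()
        frame.insert(0, "measure", "bdnf_pg_ml")
        frame.insert(0, "arm", arm)
        frame.insert(0, "trial", trial)
        anova_rows.append(frame)
    for col, res in report.mixed.items():
        frame = res.to_frame()
        frame.insert(0, "measure", col)
        frame.insert(0, "arm", "both")
        frame.insert(0, "trial", "trial2")
        anova_rows.append(frame)
    if anova_rows:
        pd.concat(anova_rows, ignore_index=True).to_csv(out / "anova.csv", index=False)

    corr_rows = []
    for (trial, arm), suite in report.ni_correlations.items():
        for key, c in suite.items():
            corr_rows.append(
                {"trial": trial, "arm": arm, "pairing": key, "r": c.r,
                 "r_squared": c.r_squared, "t": c.t_stat, "df": c.df,
                 "p": c.p_two_tailed, "n": c.n}
            )
    if report.pooled_baseline is not None:
        c = report.pooled_baseline
        corr_rows.append(
            {"trial": "pooled", "arm": "both", "pairing": "bdnf_vs_hamd_day0",
             "r": c.r, "r_squared": c.r_squared, "t": c.t_stat, "df": c.df,
             "p": c.p_two_tailed, "n": c.n}
        )
    if corr_rows:
        pd.DataFrame(corr_rows).to_csv(out / "correlations.csv", index=False)

    roc_rows = []
    if report.roc_diagnosis is not None:
        report.roc_diagnosis.to_frame().to_csv(out / "roc_diagnosis_points.csv", index=False)
        r = report.roc_diagnosis
        roc_rows.append({"analysis": "diagnosis", "trial": "pooled", "arm": "all",
                         "auc": r.auc, "threshold": r.optimal_threshold,
                         "sensitivity": r.optimal_sensitivity,
                         "specificity": r.optimal_specificity,
                         "n_pos": r.n_pos, "n_neg": r.n_neg, "skipped": ""})
    for (trial, arm), res in report.roc_prediction.items():
        if isinstance(res, str):
            roc_rows.append({"analysis": "prediction", "trial": trial, "arm": arm,
                             "auc": None, "threshold": None, "sensitivity": None,
                             "specificity": None, "n_pos": None, "n_neg": None,
                             "skipped": res})
        else:
            res.to_frame().to_csv(out / f"roc_prediction_{trial}_{arm}.csv", index=False)
            roc_rows.append({"analysis": "prediction", "trial": trial, "arm": arm,
                             "auc": res.auc, "threshold": res.optimal_threshold,
                             "sensitivity": res.optimal_sensitivity,
                             "specificity": res.optimal_specificity,
                             "n_pos": res.n_pos, "n_neg": res.n_neg, "skipped": ""})
    if roc_rows:
        pd.DataFrame(roc_rows).to_csv(out / "roc_summary.csv", index=False)

    (out / "report.json").write_text(json.dumps(report_to_dict(report), indent=2))
    (out / "summary.txt").write_text(render_summary(report, config))
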