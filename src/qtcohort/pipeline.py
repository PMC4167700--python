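"""End-to-end analysis pipeline and stratified report rendering.

Stage order mirrors the study design: load or simulate an interval
table, apply study-inclusion validation, gate outliers (log-scale gate
for the log analyses, raw-scale gate for the raw analyses), fit the
optimal correction per manufacturer on each scale, apply every requested
correction method, validate residual rate dependence, then run the
between-manufacturer comparisons and the multivariate device model.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import compare, correction, gate, simulate
from .io import IntervalTable, read_interval_csv, validate_table

logger = logging.getLogger("qtcohort")

#: Report column order: log-scale block then raw-scale block.
LOG_METHODS = ("ours_log", "fridericia", "bazett")
RAW_METHODS = ("ours_raw", "framingham", "ecaps12")
ALL_METHODS = LOG_METHODS + RAW_METHODS


@dataclass
class PipelineConfig:
    """One run's inputs and knobs; exactly one input source."""

    csv: str | None = None
    units: str = "ms"
    preset: str | None = None
    seed: int = 0
    n_scale: float = 1.0
    min_age: float = 20.0
    coverage: float = 0.999
    stratify: str = "stratum"
    methods: Sequence[str] = ALL_METHODS
    baseline_qt_ms: float = 400.0

    def validate(self) -> None:
        if (self.csv is None) == (self.preset is None):
            raise ValueError("exactly one of csv and preset must be given")
        if not 0 < self.coverage < 1:
            raise ValueError("coverage must be in (0, 1)")
        if not self.methods:
            raise ValueError("at least one correction method required")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown correction method(s): {sorted(unknown)}")


@dataclass
class ReportBundle:
    """Everything the stratified report renders, as plain dictionaries."""

    config: dict
    n_input: int
    n_validated: int
    outlier_summary: dict          # per gate scale
    fisher_outliers: dict          # per sex (when two manufacturers)
    fits: dict                     # per manufacturer per scale
    corrections: dict              # per manufacturer: label of fitted models
    residual_beta: dict            # per manufacturer per method
    stratum_stats: list            # Table-1-style rows
    t_tests: dict                  # per sex per metric
    multivariate: dict             # per scale + implied ms difference
    warnings_: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "n_input": self.n_input,
            "n_validated": self.n_validated,
            "outlier_summary": self.outlier_summary,
            "fisher_outliers": self.fisher_outliers,
            "fits": self.fits,
            "corrections": self.corrections,
            "residual_beta": self.residual_beta,
            "stratum_stats": self.stratum_stats,
            "t_tests": self.t_tests,
            "multivariate": self.multivariate,
            "warnings": self.warnings_,
        }


def _fit_dict(fit: correction.RegressionFit) -> dict:
    return {
        "slope": fit.slope, "intercept": fit.intercept,
        "ci": [fit.ci_low, fit.ci_high], "pvalue": fit.pvalue,
        "r_squared": fit.r_squared, "n": fit.n,
    }


def _models_for(
    methods: Sequence[str],
    fitted: dict[str, correction.CorrectionModel],
) -> dict[str, correction.CorrectionModel]:
    out = {}
    for m in methods:
        if m in ("ours_log", "ours_raw"):
            if m in fitted:
                out[m] = fitted[m]
        else:
            out[m] = correction.CorrectionModel(m)
    return out


def _load_input(config: PipelineConfig) -> IntervalTable:
    if config.csv is not None:
        return read_interval_csv(config.csv, units=config.units)
    params = simulate.default_params(config.preset).scaled(config.n_scale)
    return simulate.generate_cohort(params, seed=config.seed)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute all stages; any stage error propagates with its stage name."""
    config.validate()
    stage = "load"
    try:
        table = _load_input(config)
        n_input = len(table)

        stage = "validate"
        report = validate_table(table, min_age=config.min_age)
        table = report.kept

        stage = "gate"
        inliers_log, summary_log = gate.apply_gate(
            table, scale="log", coverage=config.coverage, stratify=config.stratify)
        inliers_raw, summary_raw = gate.apply_gate(
            table, scale="raw", coverage=config.coverage, stratify=config.stratify)

        stage = "fit"
        manufacturers = table.manufacturers()
        fits: dict = {}
        fitted_models: dict[str, dict[str, correction.CorrectionModel]] = {}
        for manu in manufacturers:
            sub_log = inliers_log.subset(inliers_log.data["manufacturer"] == manu)
            sub_raw = inliers_raw.subset(inliers_raw.data["manufacturer"] == manu)
            f_log = correction.fit_log_correction(sub_log)
            f_raw = correction.fit_raw_correction(sub_raw)
            fits[manu] = {"log": _fit_dict(f_log), "raw": _fit_dict(f_raw)}
            fitted_models[manu] = {
                "ours_log": correction.build_correction(f_log),
                "ours_raw": correction.build_correction(f_raw),
            }

        stage = "residual-validation"
        residual_beta: dict = {}
        for manu in manufacturers:
            sub = inliers_log.subset(inliers_log.data["manufacturer"] == manu)
            models = _models_for(config.methods, fitted_models[manu])
            residual_beta[manu] = {
                name: correction.residual_slope(sub, model).slope
                for name, model in models.items()
            }

        stage = "stratum-stats"
        stratum_stats, warn_list = _stratum_stats(
            inliers_log, config.methods, fitted_models)

        stage = "comparisons"
        t_tests = _t_tests(inliers_log, config.methods, fitted_models)
        fisher = _fisher_by_sex(summary_log, manufacturers)

        stage = "multivariate"
        multivariate: dict = {}
        if len(manufacturers) >= 2 and table.data["sex"].nunique() >= 2:
            mv_log = compare.fit_multivariate(inliers_log, scale="log",
                                              manufacturer_order=manufacturers)
            mv_raw = compare.fit_multivariate(inliers_raw, scale="raw",
                                              manufacturer_order=manufacturers)
            multivariate = {
                "log": _mv_dict(mv_log),
                "raw": _mv_dict(mv_raw),
                "implied_qt_difference_ms": compare.implied_qt_difference(
                    mv_log.manufacturer.estimate, config.baseline_qt_ms),
            }
    except Exception as exc:
        raise RuntimeError(f"[stage: {stage}] {exc}") from exc

    return ReportBundle(
        config={
            "csv": config.csv, "units": config.units, "preset": config.preset,
            "seed": config.seed, "n_scale": config.n_scale,
            "min_age": config.min_age, "coverage": config.coverage,
            "stratify": config.stratify, "methods": list(config.methods),
            "baseline_qt_ms": config.baseline_qt_ms,
        },
        n_input=n_input,
        n_validated=report.n_kept,
        outlier_summary={
            s.scale: [
                {"manufacturer": r.manufacturer, "sex": r.sex, "n": r.n,
                 "n_inliers": r.n_inliers, "n_outliers": r.n_outliers,
                 "outlier_pct": r.outlier_pct}
                for r in s.strata
            ]
            for s in (summary_log, summary_raw)
        },
        fisher_outliers=fisher,
        fits=fits,
        corrections={
            manu: {name: model.label() for name, model in models.items()}
            for manu, models in fitted_models.items()
        },
        residual_beta=residual_beta,
        stratum_stats=stratum_stats,
        t_tests=t_tests,
        multivariate=multivariate,
        warnings_=warn_list,
    )


def _mv_dict(fit: compare.MultivariateFit) -> dict:
    def c(co: compare.Coefficient) -> dict:
        return {"estimate": co.estimate, "ci": [co.ci_low, co.ci_high],
                "pvalue": co.pvalue}
    return {
        "scale": fit.scale, "rr": c(fit.rr), "gender_male": c(fit.gender_male),
        "age": c(fit.age), "manufacturer": c(fit.manufacturer),
        "second_manufacturer": fit.second_manufacturer,
        "n": fit.n, "r_squared": fit.r_squared, "coding": fit.coding,
    }


def _qtc_columns(
    df, methods: Sequence[str],
    models: dict[str, correction.CorrectionModel],
) -> dict[str, np.ndarray]:
    out = {}
    for name in methods:
        if name not in models:
            continue
        out[name] = correction.compute_qtc(
            models[name], df["qt"].to_numpy(), df["rr"].to_numpy())
    return out


def _stratum_stats(table, methods, fitted_models):
    rows, warn_list = [], []
    df = table.data
    for manu in table.manufacturers():
        models = _models_for(methods, fitted_models[manu])
        for sex in ("male", "female"):
            sub = df[(df["manufacturer"] == manu) & (df["sex"] == sex)]
            row = {"manufacturer": manu, "sex": sex, "n": int(len(sub))}
            if len(sub) == 0:
                rows.append(row)
                continue
            if len(sub) == 1:
                msg = f"stratum ({manu}, {sex}) has a single record; SD is 0.0"
                warnings.warn(msg)
                warn_list.append(msg)
            def ms(v):
                sd = float(np.std(v, ddof=1)) if len(sub) > 1 else 0.0
                return {"mean": float(np.mean(v)), "sd": sd}
            row["age"] = ms(sub["age"].to_numpy())
            row["qt"] = ms(sub["qt"].to_numpy() * 1e3)
            row["rr"] = ms(sub["rr"].to_numpy() * 1e3)
            for name, qtc in _qtc_columns(sub, methods, models).items():
                row[name] = ms(qtc * 1e3)
            rows.append(row)
    return rows, warn_list


def _t_tests(table, methods, fitted_models):
    df = table.data
    manufacturers = table.manufacturers()
    if len(manufacturers) < 2:
        return {}
    a, b = manufacturers[0], manufacturers[1]
    out: dict = {}
    for sex in ("male", "female"):
        sub = df[df["sex"] == sex]
        ga = sub[sub["manufacturer"] == a]
        gb = sub[sub["manufacturer"] == b]
        if len(ga) < 2 or len(gb) < 2:
            continue
        metrics = {"qt": ("qt", 1e3), "rr": ("rr", 1e3)}
        res: dict = {}
        for metric, (col, factor) in metrics.items():
            r = compare.student_t_compare(gb[col] * factor, ga[col] * factor)
            res[metric] = {"mean_difference": r.mean_difference,
                           "t": r.t_stat, "df": r.df, "pvalue": r.pvalue}
        for name in methods:
            qa = _qtc_columns(ga, [name], _models_for([name], fitted_models[a]))
            qb = _qtc_columns(gb, [name], _models_for([name], fitted_models[b]))
            if name not in qa or name not in qb:
                continue
            r = compare.student_t_compare(qb[name] * 1e3, qa[name] * 1e3)
            res[f"qtc:{name}"] = {"mean_difference": r.mean_difference,
                                  "t": r.t_stat, "df": r.df, "pvalue": r.pvalue}
        out[sex] = res
    return out


def _fisher_by_sex(summary: gate.OutlierSummary, manufacturers):
    if len(manufacturers) < 2:
        return {}
    a, b = manufacturers[0], manufacturers[1]
    out = {}
    for sex in ("male", "female"):
        try:
            ra = summary.stratum(a, sex)
            rb = summary.stratum(b, sex)
        except KeyError:
            continue
        out[sex] = {
            f"{a}_outliers": ra.n_outliers, f"{a}_n": ra.n,
            f"{b}_outliers": rb.n_outliers, f"{b}_n": rb.n,
            "pvalue": compare.fisher_exact_outliers(
                ra.n_outliers, ra.n, rb.n_outliers, rb.n),
        }
    return out


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _stratum_rows(bundle: ReportBundle) -> list[dict]:
    """Table rows with values rounded once (half-even) for all formats."""
    rows = []
    for s in bundle.stratum_stats:
        row = {"manufacturer": s["manufacturer"], "sex": s["sex"], "n": s["n"]}
        for key in ("age", "qt", "rr") + tuple(ALL_METHODS):
            if key in s:
                row[key] = f"{round(s[key]['mean'], 1):.1f}±{round(s[key]['sd'], 1):.1f}"
        rows.append(row)
    return rows


def render_summary(bundle: ReportBundle, format: str = "text") -> str:
    """Serialize the report: 'text' (Table-1-style), 'tsv' or 'json'."""
    if format == "json":
        payload = bundle.to_dict()
        payload["stratum_table"] = _stratum_rows(bundle)
        return json.dumps(payload, indent=2, sort_keys=True)

    rows = _stratum_rows(bundle)
    columns = ["manufacturer", "sex", "n", "age", "qt", "rr", *ALL_METHODS]
    if format == "tsv":
        lines = ["\t".join(columns)]
        for row in rows:
            lines.append("\t".join(str(row.get(c, "")) for c in columns))
        return "\n".join(lines) + "\n"
    if format != "text":
        raise ValueError(f"unknown format {format!r}")

    widths = {c: max(len(c), *(len(str(r.get(c, ""))) for r in rows)) for c in columns}
    header = "  ".join(c.ljust(widths[c]) for c in columns)
    lines = [header, "-" * len(header)]
    for row in rows:
        lines.append("  ".join(str(row.get(c, "")).ljust(widths[c]) for c in columns))
    lines.append("")
    lines.append("Units: age in years; QT/RR/QTc in ms (mean±SD).")
    if bundle.multivariate:
        ms = bundle.multivariate["implied_qt_difference_ms"]
        coef = bundle.multivariate["log"]["manufacturer"]["estimate"]
        lines.append(
            f"Device effect (log scale): {coef:.4f} on ln QT -> "
            f"{ms:.1f} ms at a {bundle.config.get('baseline_qt_ms', 400):g} ms baseline."
        )
    return "\n".join(lines) + "\n"
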