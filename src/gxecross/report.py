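"""End-to-end pipeline: cohort -> QC -> imputation -> standardization ->
correlations -> hierarchical regression -> RoS diagnostics -> six-model
crossover comparison, with JSON/markdown/CSV reports.

Stage order mirrors the analysis plan of the study this pipeline
operationalizes: descriptive, exploratory (moderated regression + regions of
significance), then confirmatory (re-parameterized crossover models).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (CohortTable, SchemaError, correlation_report, em_impute,
                     read_cohort, zscore, cronbach_alpha, HS_ITEM_COLUMNS)
from .genotypes import (DEFAULT_SCHEMES, QcThresholds, code_genotypes, qc_table,
                        snp_qc)
from .regression import fit_ols, hierarchical_blocks, simple_slopes
from .ros import (crossover_point, holm_correction, jn_boundaries,
                  nonlinearity_probe, pa_index, poi_index,
                  UndefinedCrossoverError)
from .reparam import select_model
from .simulate import SimulationDesign, simulate_cohort

log = logging.getLogger("gxecross")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "render_tables",
           "plot_interaction"]

NUMERIC_VARS = ["gender", "age", "parental_education", "parental_occupation",
                "monthly_income", "home_supervision", "reading"]
Z_VARS = ["parental_education", "parental_occupation", "monthly_income",
          "home_supervision", "reading"]


@dataclass
class PipelineConfig:
    """Everything one run needs; YAML/JSON-serializable."""

    input_path: str | None = None          # None -> simulate a cohort
    design: SimulationDesign | None = None
    schema: dict | None = None
    snp_columns: list[str] | None = None
    qc_thresholds: QcThresholds = field(default_factory=QcThresholds)
    alpha: float = 0.05
    poi_range: str = "observed"            # "observed" | "m2sd"
    pa_mode: str = "empirical"             # "empirical" | "normal"
    risk_snp: str = "rs11629841"
    risk_genotype: str = "GT"
    em_enabled: bool = True
    selection_rule: str = "aic"            # "aic" | "parsimony"
    out_dir: str | None = None
    seed: int = 20231027

    def __post_init__(self):
        if self.poi_range not in ("observed", "m2sd"):
            raise ValueError("poi_range must be 'observed' or 'm2sd'")
        if self.pa_mode not in ("empirical", "normal"):
            raise ValueError("pa_mode must be 'empirical' or 'normal'")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "design" in raw and raw["design"] is not None:
            raw["design"] = SimulationDesign(**raw["design"])
        if "qc_thresholds" in raw and raw["qc_thresholds"] is not None:
            raw["qc_thresholds"] = QcThresholds(**raw["qc_thresholds"])
        return cls(**raw)


@dataclass
class RunReport:
    config: dict
    version: str
    seed: int
    sections: dict

    def to_json(self, indent: int = 2) -> str:
        return json.dumps({"version": self.version, "seed": self.seed,
                           "config": self.config, **self.sections},
                          indent=indent, sort_keys=True, default=_jsonify)

    def to_markdown(self) -> str:
        s = self.sections
        lines = [f"# Crossover G x E analysis report", "",
                 f"package version {self.version}, seed {self.seed}", ""]
        lines += ["## Quality control", "", s["qc"]["markdown"], ""]
        if "reliability" in s:
            lines += [f"Home-supervision scale Cronbach's alpha: "
                      f"{s['reliability']['cronbach_alpha']:.2f}", ""]
        lines += ["## Descriptive correlations", "", s["correlations"]["markdown"], ""]
        lines += ["## Hierarchical regression", "", s["hierarchical"]["markdown"], ""]
        ros = s["ros"]
        lines += ["## Regions of significance", "",
                  f"- JN boundaries: {ros['boundaries']} (pattern: {ros['classification']})",
                  f"- crossover point: {ros['crossover']}",
                  f"- PoI = {ros['poi']} over {ros['poi_range']}",
                  f"- PA = {ros['pa']} ({ros['pa_mode']})",
                  f"- nonlinearity: p(X^2) = {ros['p_x2']:.3f}, "
                  f"p(ZX^2) = {ros['p_zx2']:.3f}, "
                  f"XZ p after augmentation = {ros['p_xz_augmented']:.3f}",
                  f"- Holm-corrected interaction rejections: {ros['holm_reject']}", ""]
        rp = s["reparam"]
        lines += ["## Crossover model comparison", "", rp["markdown"], "",
                  f"**Selected model: {rp['selected']} ({rp['selected_label']})**", "",
                  rp["rationale"], "", "## Interpretation", "", s["interpretation"], ""]
        return "\n".join(lines)


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _r(x, nd=6):
    if x is None:
        return None
    x = float(x)
    return round(x, nd) if np.isfinite(x) else None


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage; returns the full report (and writes artifacts when
    ``config.out_dir`` is set).  Any stage failure raises with the stage name;
    completed sections are attached to the exception as ``partial``."""
    sections: dict = {}
    stage = "load"
    try:
        truth = None
        if config.input_path is not None:
            log.info("stage load: reading %s", config.input_path)
            table = read_cohort(config.input_path, config.schema, config.snp_columns)
        else:
            design = config.design or SimulationDesign(seed=config.seed)
            if config.design is None:
                design = dataclasses.replace(design, seed=config.seed)
            log.info("stage load: simulating cohort n=%d model=%s seed=%d",
                     design.n, design.model, design.seed)
            table, truth = simulate_cohort(design)
        sections["cohort"] = {"n": table.n, "warnings": table.warnings,
                              "snps": table.snp_columns}
        if truth is not None:
            sections["truth"] = truth

        stage = "qc"
        table, coding_warnings = code_genotypes(table)
        reports = [snp_qc(table, s, config.qc_thresholds) for s in table.snp_columns
                   if s in DEFAULT_SCHEMES]
        qdf = qc_table(reports)
        sections["qc"] = {
            "coding_warnings": coding_warnings,
            "rows": qdf.to_dict(orient="records"),
            "markdown": qdf.round(4).to_markdown(index=False),
            "all_passed": {r.snp_name: r.passed_all for r in reports},
        }

        stage = "reliability"
        if all(c in table.data.columns for c in HS_ITEM_COLUMNS):
            items = table.data[HS_ITEM_COLUMNS]
            if items.dropna().shape[0] >= 3:
                sections["reliability"] = {
                    "cronbach_alpha": _r(cronbach_alpha(items), 4)}

        stage = "imputation"
        if config.em_enabled and table.data[NUMERIC_VARS].isna().any().any():
            table, trace = em_impute(table, NUMERIC_VARS)
            sections["imputation"] = {"n_iter": trace.n_iter,
                                      "converged": trace.converged,
                                      "loglik_first": _r(trace.loglik[0]),
                                      "loglik_last": _r(trace.loglik[-1])}
        else:
            sections["imputation"] = {"skipped": True}

        stage = "standardize"
        coded = [s + "_code" for s in table.snp_columns if s + "_code" in table.data.columns]
        view = zscore(table, Z_VARS)
        for c in coded:
            view.data[c.replace("_code", "_z")] = view.data[c]
        view = zscore(view, [c.replace("_code", "_z") for c in coded])

        stage = "correlations"
        corr_vars = (["gender", "age", "parental_education", "parental_occupation",
                      "monthly_income", "home_supervision"]
                     + [c.replace("_code", "_z") for c in coded] + ["reading"])
        corr = correlation_report(view, corr_vars)
        sections["correlations"] = {
            "variables": corr.variables,
            "r": corr.r.round(4).to_dict(),
            "p": corr.p.round(6).to_dict(),
            "markdown": corr.to_markdown(),
            "mode": corr.mode,
        }

        stage = "hierarchical"
        zsnps = [c.replace("_code", "_z") for c in coded]
        covs = ["gender", "age", "parental_education", "parental_occupation",
                "monthly_income"]
        blocks = [covs,
                  covs + ["home_supervision"] + zsnps,
                  covs + ["home_supervision"] + zsnps
                  + [f"home_supervision*{z}" for z in zsnps]]
        hier = hierarchical_blocks("reading", blocks, view)
        fit3 = hier.fits[-1]
        sections["hierarchical"] = {
            "table": hier.table().round(6).to_dict(orient="records"),
            "coefficients": fit3.summary_frame().round(6).to_dict(orient="records"),
            "markdown": _hier_markdown(hier),
        }

        stage = "ros"
        focal_z = config.risk_snp + "_z"
        product = f"home_supervision*{focal_z}"
        ros_sec: dict = {}
        xobs = view.data["home_supervision"].to_numpy(dtype=float)
        xobs = xobs[~np.isnan(xobs)]
        jn = jn_boundaries(fit3, "home_supervision", focal_z, config.alpha, xobs)
        ros_sec["boundaries"] = [_r(b, 4) for b in jn.boundaries]
        ros_sec["classification"] = jn.classification
        # orientation: good side is high X when the risk/plastic genotype has
        # the steeper environment slope.  The moderator is the z-scored
        # genotype code, so compare slopes at the risk code vs the others.
        b_xz = fit3.coef_of(product)
        scheme = DEFAULT_SCHEMES[config.risk_snp]
        risk_code = scheme.mapping[config.risk_genotype]
        other_code = np.mean([v for g, v in scheme.mapping.items()
                              if g != config.risk_genotype])
        orientation = 1 if b_xz * (risk_code - other_code) >= 0 else -1
        try:
            xc = crossover_point(fit3, "home_supervision", focal_z)
        except UndefinedCrossoverError:
            xc = None
        ros_sec["crossover"] = _r(xc, 4)
        if xc is not None:
            rng_ = ((float(xobs.min()), float(xobs.max()))
                    if config.poi_range == "observed" else jn.eval_range_m2sd)
            poi = poi_index(xc, rng_, orientation)
            pa = pa_index(xc, xobs, orientation, mode=config.pa_mode)
            ros_sec.update(poi=_r(poi.poi, 4),
                           poi_range=f"[{rng_[0]:.2f}, {rng_[1]:.2f}]",
                           pa=_r(pa.pa, 4), pa_mode=config.pa_mode)
        else:
            ros_sec.update(poi=None, poi_range=None, pa=None, pa_mode=config.pa_mode)
        nl = nonlinearity_probe("reading", "home_supervision", focal_z, view, covs)
        ros_sec.update(p_x2=_r(nl.p_x2), p_zx2=_r(nl.p_zx2),
                       p_xz_base=_r(nl.p_xz_base),
                       p_xz_augmented=_r(nl.p_xz_augmented))
        inter_ps = [float(fit3.p[fit3[f"home_supervision*{z}"]]) for z in zsnps]
        holm = holm_correction(inter_ps, config.alpha)
        ros_sec["holm_p"] = [_r(p) for p in inter_ps]
        ros_sec["holm_critical"] = [_r(c, 4) for c in holm.critical]
        ros_sec["holm_reject"] = holm.reject.tolist()
        # simple slopes at the raw genotype coding (risk group code 0)
        slopes = simple_slopes(fit3, "home_supervision", focal_z,
                               {"risk (code 0)": float(view.data[focal_z].min()),
                                "non-risk (code 1)": float(view.data[focal_z].max())})
        ros_sec["simple_slopes"] = [
            {"level": s.level_label, "slope": _r(s.slope, 4), "t": _r(s.t, 3),
             "p": _r(s.p)} for s in slopes]
        sections["ros"] = ros_sec

        stage = "reparam"
        view.data["risk"] = (
            table.data[config.risk_snp] == config.risk_genotype).astype(float)
        view.data.loc[table.data[config.risk_snp].isna(), "risk"] = np.nan
        comp = select_model(view, outcome="reading", environment="home_supervision",
                            risk_indicator="risk", covariates=tuple(covs),
                            alpha=config.alpha, rule=config.selection_rule)
        from .reparam import MODEL_LABELS
        sections["reparam"] = {
            "selected": comp.selected,
            "selected_label": MODEL_LABELS[comp.selected],
            "rationale": comp.rationale,
            "markdown": comp.to_frame().to_markdown(),
            "models": {
                m: {"params": {k: _r(v, 4) for k, v in f.params.items()},
                    "se": {k: _r(v, 4) for k, v in f.se.items()},
                    "c_ci": [_r(v, 4) for v in f.c_ci] if f.c_ci else None,
                    "r2": _r(f.r2, 4), "sse": _r(f.sse, 4),
                    "f": _r(f.f, 3), "df": [f.df1, f.df2],
                    "aic": _r(f.aic, 3), "bic": _r(f.bic, 3)}
                for m, f in comp.fits.items()},
            "f_vs_b": {m: {"f": _r(v[0], 3), "df": list(v[1]), "p": _r(v[2]),
                           "delta_r2": _r(v[3], 4)}
                       for m, v in comp.f_vs_b.items()},
            "errors": comp.errors,
        }
        sel = comp.fits[comp.selected]
        sections["interpretation"] = (
            f"The best-supported interaction pattern is the "
            f"{MODEL_LABELS[comp.selected]} model: risk-group slope "
            f"B3 = {sel.params['B3']:.2f}, non-risk slope "
            f"B1 = {sel.params.get('B1', 0.0):.2f}, crossover at "
            f"C = {sel.params['C']:.2f} on the standardized environment axis.")
    except Exception as exc:
        exc.stage = stage  # type: ignore[attr-defined]
        exc.partial = sections  # type: ignore[attr-defined]
        raise

    report = RunReport(config=_config_echo(config), version=__version__,
                       seed=config.seed, sections=sections)
    if config.out_dir:
        render_tables(report, config.out_dir)
    return report


def _config_echo(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def _hier_markdown(hier) -> str:
    parts = []
    for i, fit in enumerate(hier.fits):
        sf = fit.summary_frame().round(3)
        parts.append(f"**Block {i + 1}** (R2 = {fit.r2:.3f}, "
                     f"dR2 = {hier.delta_r2[i]:.3f}, "
                     f"dF = {hier.delta_f[i]:.2f}, p = {hier.delta_p[i]:.4g})")
        parts.append(sf.to_markdown(index=False))
    return "\n\n".join(parts)


def render_tables(report: RunReport, out_dir) -> list[Path]:
    """Write report.json, report.md and the three CSV tables."""
    out = Path(out_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    written = []

    def w(path: Path, text: str):
        path.write_text(text)
        written.append(path)

    w(out / "report.json", report.to_json())
    w(out / "report.md", report.to_markdown())
    s = report.sections
    pd.DataFrame(s["qc"]["rows"]).to_csv(out / "tables" / "qc.csv", index=False)
    pd.DataFrame(s["correlations"]["r"]).to_csv(out / "tables" / "correlations.csv")
    pd.DataFrame(s["hierarchical"]["coefficients"]).to_csv(
        out / "tables" / "hierarchical.csv", index=False)
    rows = []
    for m, d in s["reparam"]["models"].items():
        rows.append({"model": m, **{f"{k}": v for k, v in d["params"].items()},
                     "r2": d["r2"], "aic": d["aic"], "bic": d["bic"]})
    pd.DataFrame(rows).to_csv(out / "tables" / "comparison.csv", index=False)
    written += [out / "tables" / n for n in
                ("qc.csv", "correlations.csv", "hierarchical.csv", "comparison.csv")]
    return written


def plot_interaction(fit, x_range=(-3, 3), path=None, labels=("non-risk", "risk")):
    """Two-group interaction plot for a crossover-model fit (SVG/PNG by
    extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.linspace(*x_range, 100)
    p = fit.params
    C = p["C"]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(x, p["B0"] + p.get("B1", 0.0) * (x - C), label=labels[0], color="0.3")
    ax.plot(x, p["B0"] + p["B3"] * (x - C), label=labels[1], ls="--", color="purple")
    ax.axvline(C, color="0.7", lw=0.8)
    ax.set_xlabel("standardized environment (X)")
    ax.set_ylabel("predicted outcome")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
        return path
    return fig
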