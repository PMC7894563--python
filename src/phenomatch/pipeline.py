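"""End-to-end orchestration: data in, fitted models and report out.

``run_pipeline`` executes the trend analyses, the breeding-success model
variants, the diet models and the bivariate model on either supplied CSV
files or a freshly simulated dataset, then writes per-model output
bundles (coefficients, posterior draws, diagnostics, derived statistics)
plus a human-readable ``summary.md`` and its machine-readable JSON twin.
A failure in one stage is recorded and later independent stages still run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import bivariate, diet, glmm, io, selection, trends
from .design import ModelSpec, build_design
from .mcmc import MCMCSettings, PosteriorSamples, PriorSpec
from .params import GroundTruth, SimulationParams
from .simulate import simulate_dataset

logger = logging.getLogger(__name__)

DEFAULT_ROSTER = ("trends", "core", "year", "sst_current", "sst_previous",
                  "sandeel_core", "bivariate")
ALL_MODELS = ("core", "core_popsize", "year", "sst_current", "sst_previous",
              "sandeel_core", "sandeel_year", "bivariate")


@dataclass
class PipelineConfig:
    """What to run, on which data, and how long the chains are."""

    breeding_path: Optional[str] = None
    env_path: Optional[str] = None
    diet_path: Optional[str] = None
    simulation: Optional[SimulationParams] = None
    roster: tuple = DEFAULT_ROSTER
    outdir: str = "phenomatch_out"
    seed: int = 1
    fast: bool = False
    n_iterations: Optional[int] = None
    burn_in: Optional[int] = None
    thin: Optional[int] = None

    def __post_init__(self) -> None:
        if self.breeding_path is None and self.simulation is None:
            raise ValueError(
                "config needs input paths or simulation parameters")

    def settings_for(self, model: str, seed: int) -> MCMCSettings:
        if self.n_iterations is not None:
            return MCMCSettings(
                n_iterations=self.n_iterations,
                burn_in=self.burn_in if self.burn_in is not None
                else max(self.n_iterations // 10, 1),
                thin=self.thin or 10, seed=seed)
        if self.fast:
            return MCMCSettings.fast(seed=seed)
        if model == "bivariate":
            return MCMCSettings.bivariate_default(seed=seed)
        return MCMCSettings(seed=seed)


@dataclass
class ReportBundle:
    """Everything run_pipeline produced, plus any stage failures."""

    outdir: Path
    trend_table: Optional[pd.DataFrame] = None
    posteriors: Dict[str, PosteriorSamples] = field(default_factory=dict)
    summaries: Dict[str, pd.DataFrame] = field(default_factory=dict)
    derived: Dict[str, dict] = field(default_factory=dict)
    failures: Dict[str, str] = field(default_factory=dict)
    manifest: List[str] = field(default_factory=list)


def _load_data(config: PipelineConfig):
    if config.breeding_path is not None:
        breeding = io.read_breeding_csv(config.breeding_path)
        env = io.read_env_csv(config.env_path) if config.env_path else None
        diet_df = (io.read_diet_csv(config.diet_path)
                   if config.diet_path else None)
        truth = None
    else:
        data = simulate_dataset(config.simulation, config.seed,
                                outdir=Path(config.outdir) / "simulated")
        breeding, env, diet_df = data["breeding"], data["env"], data["diet"]
        truth = data["truth"]
    return breeding, env, diet_df, truth


def _write_posterior_bundle(outdir: Path, name: str,
                            posterior: PosteriorSamples,
                            bundle: ReportBundle) -> None:
    mdir = outdir / name
    mdir.mkdir(parents=True, exist_ok=True)
    summary = selection.summarize(posterior)
    summary.to_csv(mdir / "coefficients.csv", index=False)
    draws = pd.DataFrame(posterior.fixed, columns=posterior.fixed_names)
    qn = posterior.re_names
    for i in range(len(qn)):
        for j in range(i, len(qn)):
            label = (f"var({qn[i]})" if i == j else f"cov({qn[i]},{qn[j]})")
            draws[label] = posterior.cov[:, i, j]
    if posterior.resid_var is not None:
        draws["resid_var"] = posterior.resid_var
    draws.to_csv(mdir / "posterior.csv", index=False)
    with open(mdir / "diagnostics.json", "w") as fh:
        json.dump(posterior.diagnostics, fh, indent=1)
    bundle.posteriors[name] = posterior
    bundle.summaries[name] = summary
    bundle.manifest += [f"{name}/coefficients.csv", f"{name}/posterior.csv",
                        f"{name}/diagnostics.json"]


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run every stage in the roster; see the module docstring."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(outdir=outdir)
    rng = np.random.SeedSequence(config.seed)
    model_seeds = {m: int(s) for m, s in zip(
        ALL_MODELS, rng.generate_state(len(ALL_MODELS)) % (2**31 - 1))}

    breeding, env, diet_df, truth = _load_data(config)
    context = io.make_year_context(breeding, env, diet_df)

    def run_stage(name, fn):
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - stage isolation
            logger.error("stage %s failed: %s", name, exc)
            bundle.failures[name] = "".join(
                traceback.format_exception_only(exc)).strip()

    # ---- trends ----------------------------------------------------------
    if "trends" in config.roster:
        def _trends():
            rows = []
            if env is not None:
                t = trends.fit_gls_ar1(env["year"].to_numpy(float),
                                       env["sst"].to_numpy(float))
                rows.append(("sst_vs_year", t))
            annual = breeding.groupby("year")["lay_date"].mean()
            t_lay = trends.fit_gls_ar1(annual.index.to_numpy(float),
                                       annual.to_numpy())
            rows.append(("mean_laydate_vs_year", t_lay))
            if env is not None:
                merged = context.dropna(subset=["sst"])
                rows.append(("mean_laydate_vs_sst", trends.fit_ols(
                    merged["sst"].to_numpy(float),
                    merged["mean_lay_date"].to_numpy(float))))
            table = pd.DataFrame(
                [dict(name=n, slope=t.slope, se=t.slope_se,
                      intercept=t.intercept, p=t.p_value, phi=t.phi, n=t.n)
                 for n, t in rows])
            if diet_df is not None:
                med = breeding.groupby("year")["lay_date"].median() \
                    .to_frame("med_lay").join(
                        diet_df.groupby("year")["sample_date"].median()
                        .to_frame("med_sample"), how="inner").dropna()
                if len(med) >= 4:
                    c = trends.pearson_ci(med["med_lay"].to_numpy(),
                                          med["med_sample"].to_numpy())
                    table = pd.concat([table, pd.DataFrame([dict(
                        name="collection_vs_laydate_r", slope=c.r,
                        se=np.nan, intercept=np.nan, p=c.p_value,
                        phi=np.nan, n=c.n)])], ignore_index=True)
                    bundle.derived["collection_vs_laydate"] = {
                        "r": c.r, "ci_low": c.ci_low, "ci_high": c.ci_high,
                        "n": c.n}
            table.to_csv(outdir / "trends.csv", index=False)
            bundle.trend_table = table
            bundle.manifest.append("trends.csv")
        run_stage("trends", _trends)

    # ---- breeding-success variants ---------------------------------------
    for variant in ("core", "core_popsize", "year", "sst_current",
                    "sst_previous"):
        if variant not in config.roster:
            continue

        def _fit(variant=variant):
            design = build_design(breeding, context,
                                  ModelSpec(variant=variant))
            posterior = glmm.fit_glmm(
                design, config.settings_for(variant, model_seeds[variant]))
            _write_posterior_bundle(outdir, variant, posterior, bundle)
            if variant == "core":
                v = selection.vertex(posterior)
                sv = selection.slope_variance(posterior)
                bundle.derived["vertex"] = {
                    "mean": v.mean, "ci_low": v.ci_low, "ci_high": v.ci_high,
                    "n_excluded": v.n_excluded}
                bundle.derived["slope_variance"] = {
                    "mean": sv.mean, "ci_low": sv.ci_low,
                    "ci_high": sv.ci_high}
                pd.DataFrame([bundle.derived["vertex"]]).to_csv(
                    outdir / "core" / "vertex.csv", index=False)
                bundle.manifest.append("core/vertex.csv")
                pred = glmm.predicted_success(
                    posterior, np.linspace(-40, 40, 17))
                obs = glmm.observed_success_by_reldate(breeding)
                pred.to_csv(outdir / "core" / "predicted_success.csv",
                            index=False)
                obs.to_csv(outdir / "core" / "observed_success.csv",
                           index=False)
                bundle.manifest += ["core/predicted_success.csv",
                                    "core/observed_success.csv"]
            if variant in ("year", "sst_current") \
                    and bundle.trend_table is not None:
                cov = "year" if variant == "year" else "sst"
                trend_name = ("mean_laydate_vs_year" if cov == "year"
                              else "mean_laydate_vs_sst")
                row = bundle.trend_table.set_index("name").loc[trend_name]
                tf = trends.TrendFit(slope=float(row["slope"]),
                                     slope_se=float(row["se"]),
                                     intercept=float(row["intercept"]),
                                     p_value=float(row["p"]),
                                     phi=float(row["phi"]) if np.isfinite(
                                         row["phi"]) else 0.0,
                                     n=int(row["n"]))
                sens = selection.optimum_sensitivity(
                    posterior, tf, covariate=cov,
                    seed=model_seeds[variant])
                bundle.derived[f"B_{cov}"] = {
                    "mean": sens.mean, "ci_low": sens.ci_low,
                    "ci_high": sens.ci_high,
                    "timing_trend": sens.timing_trend_component,
                    "relative_optimum": sens.relative_optimum_component}
                pd.DataFrame([bundle.derived[f"B_{cov}"]]).to_csv(
                    outdir / variant / "sensitivity.csv", index=False)
                bundle.manifest.append(f"{variant}/sensitivity.csv")
        run_stage(variant, _fit)

    # ---- diet models -----------------------------------------------------
    for variant in ("sandeel_core", "sandeel_year"):
        if variant not in config.roster or diet_df is None:
            continue

        def _fit_diet(variant=variant):
            posterior = diet.fit_diet_model(
                diet_df, variant=variant,
                mcmc=config.settings_for(variant, model_seeds[variant]))
            _write_posterior_bundle(outdir, variant, posterior, bundle)
        run_stage(variant, _fit_diet)

    # ---- bivariate -------------------------------------------------------
    if "bivariate" in config.roster and diet_df is not None:
        def _fit_biv():
            posterior = bivariate.fit_bivariate(
                breeding, diet_df, context,
                mcmc=config.settings_for("bivariate",
                                         model_seeds["bivariate"]))
            _write_posterior_bundle(outdir, "bivariate", posterior, bundle)
            cov_table = selection.covariance_summary(posterior)
            cov_table.to_csv(outdir / "bivariate" / "covariances.csv",
                             index=False)
            bundle.manifest.append("bivariate/covariances.csv")
            bundle.summaries["bivariate_cov"] = cov_table
        run_stage("bivariate", _fit_biv)

    _write_summary(bundle, config, truth)
    return bundle


# ---------------------------------------------------------------------------
_KEY_ROWS = [
    # (model, parameter, label, truth attribute)
    ("core", "mean_laydate", "between-year slope (BSp)", "beta_B"),
    ("core", "rel_laydate", "within-year slope (BSi)", "beta_W"),
    ("core", "rel_laydate_sq", "quadratic (BSi)", "gamma"),
    ("core", "var(year_rel_slope)", "among-year slope variance",
     "sigma2_slope"),
    ("core", "var(year_intercept)", "among-year intercept variance",
     "sigma2_int"),
    ("sandeel_core", "rel_sample_date", "diet within-year slope",
     "diet_within_slope"),
    ("sandeel_core", "var(year_intercept)", "diet among-year intercept "
     "variance", "diet_sigma2_int"),
    ("sandeel_core", "var(year_rel_slope)", "diet among-year slope "
     "variance", "diet_sigma2_slope"),
    ("bivariate", "cov(B_Sh,B_Sa)", "cov(mean success, mean 1+ diet)",
     "cov_BSh_BSa"),
    ("bivariate", "cov(W_Sh,W_Sa)", "cov(within-year slopes)",
     "cov_WSh_WSa"),
]


def _write_summary(bundle: ReportBundle, config: PipelineConfig,
                   truth: Optional[GroundTruth]) -> None:
    outdir = bundle.outdir
    lines = ["# phenomatch pipeline summary", "",
             f"seed: {config.seed}  fast: {config.fast}", ""]
    payload = {"seed": config.seed, "fast": config.fast,
               "failures": bundle.failures, "quantities": {}}

    if bundle.trend_table is not None:
        lines += ["## Trends", "",
                  bundle.trend_table.to_string(index=False), ""]
        payload["trends"] = bundle.trend_table.to_dict(orient="records")

    rows = []
    tparams = truth.params if truth is not None else None
    for model, param, label, attr in _KEY_ROWS:
        summary = bundle.summaries.get(model)
        if summary is None:
            continue
        hit = summary[summary["parameter"] == param]
        if hit.empty:
            continue
        rec = hit.iloc[0]
        row = {"model": model, "parameter": param, "label": label,
               "mean": rec["mean"], "ci_low": rec["ci_low"],
               "ci_high": rec["ci_high"],
               "significant": bool(rec["significant"])}
        if tparams is not None:
            tv = float(getattr(tparams, attr))
            row["truth"] = tv
            row["covered"] = bool(rec["ci_low"] <= tv <= rec["ci_high"])
        rows.append(row)
    for name in ("vertex", "slope_variance", "B_year", "B_sst",
                 "collection_vs_laydate"):
        if name in bundle.derived:
            d = bundle.derived[name]
            rows.append({"model": "derived", "parameter": name,
                         "label": name,
                         "mean": d.get("mean", d.get("r")),
                         "ci_low": d["ci_low"], "ci_high": d["ci_high"],
                         "significant": bool(
                             d["ci_low"] > 0 or d["ci_high"] < 0)})
    key = pd.DataFrame(rows)
    if len(key):
        lines += ["## Key quantities", "", key.to_string(index=False), ""]
        key.to_csv(outdir / "summary.csv", index=False)
        bundle.manifest.append("summary.csv")
        payload["quantities"] = rows

    if bundle.failures:
        lines += ["## Stage failures", ""]
        lines += [f"- {k}: {v}" for k, v in bundle.failures.items()]
        lines.append("")

    (outdir / "summary.md").write_text("\n".join(lines))
    with open(outdir / "summary.json", "w") as fh:
        json.dump(payload, fh, indent=1, default=float)
    bundle.manifest += ["summary.md", "summary.json"]
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(sorted(set(bundle.manifest)), fh, indent=1)
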