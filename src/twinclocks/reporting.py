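"""End-to-end pipeline runner producing publication-style tables.

Given a table holding several epigenetic age metrics for the same twin
pairs, these runners fit the per-metric univariate (one wave) or bivariate
Cholesky (two waves) models and write:

* a combined estimates table (one row per metric),
* per-metric model-comparison tables (saturated / ACE / ADE / sub-models),
* a JSON dump of every fitted parameter, and
* a plain-text log recording the model-selection path.

Every derived number in the human tables is recomputed from the dumped raw
parameters (via ``derive_bivariate_statistics``); nothing is table-only
arithmetic.  Proportions Pa/Pc/Pe are rounded to whole percent in the TSV
and kept at full precision in the JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bivariate as bv
from . import univariate as uv
from .twin_data import TwinDataError, TwinDataset, Zygosity, read_twin_table

__all__ = ["RunConfig", "run_univariate_report", "run_bivariate_report"]


@dataclass
class RunConfig:
    input: str
    metrics: list[str]
    outdir: str
    layout: str = "long"
    covariates: dict[str, list[str]] = field(default_factory=dict)
    default_covariates: list[str] = field(default_factory=list)
    model: str = "auto"
    seed: int = 0
    compute_ci: bool = True

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def covariates_for(self, metric: str) -> list[str]:
        return list(self.covariates.get(metric, self.default_covariates))


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _fmt_ci(value: float, ci: tuple[float, float] | None, nd: int = 2) -> str:
    if ci is None or any(not np.isfinite(b) for b in ci):
        return f"{value:.{nd}f}"
    return f"{value:.{nd}f}({ci[0]:.{nd}f}, {ci[1]:.{nd}f})"


def run_univariate_report(config: RunConfig) -> dict[str, Path]:
    """Fit univariate models per metric and write estimate/comparison tables."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"univariate report; input={config.input} "
                            f"model={config.model} seed={config.seed}"]
    rows, dumps, outputs = [], {}, {}
    for metric in config.metrics:
        covs = config.covariates_for(metric)
        try:
            dataset = read_twin_table(config.input, layout=config.layout,
                                      variable=metric)
        except TwinDataError as exc:
            raise type(exc)(f"metric {metric!r}: {exc}") from exc
        try:
            if config.model == "auto":
                comparison = uv.select_model(dataset, covs,
                                             compute_ci=config.compute_ci)
                fit = comparison.selected_fit
                cmp_path = outdir / f"comparison_{metric}.tsv"
                comparison.table.to_csv(cmp_path, sep="\t", index=False,
                                        float_format="%.6f")
                outputs[f"comparison_{metric}"] = cmp_path
                log_lines.append(
                    f"{metric}: selected {comparison.selected}"
                    + (f" [warning: {comparison.warning}]" if comparison.warning
                       else ""))
                for _, r in comparison.table.iterrows():
                    log_lines.append(
                        f"  {r.model:>10}: -2lnL={r.minus2lnL:.4f} "
                        f"k={r.n_params} LRT={r.lrt_stat:.4f} df={r.df} "
                        f"p={r.p_value:.4f} AIC={r.aic:.4f}")
            else:
                fit = uv.fit_univariate(
                    dataset, uv.UnivariateModelSpec(config.model, covs),
                    compute_ci=config.compute_ci)
                log_lines.append(f"{metric}: fitted fixed model {config.model}")
            if not isinstance(fit, uv.UnivariateFit):
                log_lines.append(
                    f"{metric}: saturated model selected; no decomposition row")
                dumps[metric] = {"model": "saturated",
                                 "minus2lnL": fit.minus2lnL}
                continue
            vc = fit.params.variance_components
            rows.append({
                "metric": metric,
                "model": fit.label,
                "a2": vc["a2"],
                "c2_or_d2": vc["c2"] if fit.spec.family == "ACE" else vc["d2"],
                "e2": vc["e2"],
                "h2": _fmt_ci(fit.h2, fit.h2_ci),
                "e2_share": _fmt_ci(fit.e2_share, fit.e2_share_ci),
            })
            dumps[metric] = fit.to_dict()
        except (TwinDataError, ValueError) as exc:
            log_lines.append(f"{metric}: ERROR {exc}")
            dumps[metric] = {"error": str(exc)}
    est_path = outdir / "univariate_estimates.tsv"
    pd.DataFrame(rows).to_csv(est_path, sep="\t", index=False,
                              float_format="%.6f")
    json_path = outdir / "univariate_fits.json"
    json_path.write_text(json.dumps(dumps, indent=2, default=_json_default,
                                    sort_keys=True))
    log_path = outdir / "univariate_run.log"
    log_path.write_text("\n".join(log_lines) + "\n")
    outputs.update(estimates=est_path, fits=json_path, log=log_path)
    return outputs


def run_bivariate_report(config: RunConfig) -> dict[str, Path]:
    """Fit bivariate Cholesky models per metric; write correlation tables."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"bivariate report; input={config.input} "
                 f"model={config.model} seed={config.seed}"]
    rows, comp_rows, dumps, outputs = [], [], {}, {}
    for metric in config.metrics:
        covs = config.covariates_for(metric)
        dataset = read_twin_table(config.input, layout=config.layout,
                                  variable=metric)
        if dataset.n_waves != 2:
            raise TwinDataError(
                "bivariate report requires two-wave data; use the univariate "
                "runner for single-wave tables")
        pheno = dataset.phenotype_array()
        if np.all(np.isnan(pheno[:, :, 1])):
            log_lines.append(f"{metric}: WARNING wave-2 entirely missing; skipped")
            continue
        try:
            if config.model == "auto":
                comparison = bv.select_model_bivariate(dataset, covs)
                fit = comparison.selected_fit
                cmp_path = outdir / f"bivariate_comparison_{metric}.tsv"
                comparison.table.to_csv(cmp_path, sep="\t", index=False,
                                        float_format="%.6f")
                outputs[f"comparison_{metric}"] = cmp_path
                log_lines.append(f"{metric}: selected {comparison.selected}")
                if not isinstance(fit, bv.BivariateFit):
                    log_lines.append(
                        f"{metric}: saturated model selected; no decomposition")
                    dumps[metric] = {"model": "saturated",
                                     "minus2lnL": fit.minus2lnL}
                    continue
            else:
                fit = bv.fit_bivariate(dataset, config.model, covs)
                log_lines.append(f"{metric}: fitted fixed model {config.model}")
            derived = bv.derive_bivariate_statistics(fit.params)
            ctct = {z: bv.ctct_observed(dataset, z) for z in ("MZ", "DZ")}
            ci = {}
            if config.compute_ci:
                for q, comp in (("ra", "a"), ("rc", "c"), ("re", "e")):
                    if getattr(fit.params, comp) is not None:
                        ci[q] = bv.profile_ci_bivariate(fit, q)
            row = {
                "metric": metric,
                "model": fit.label,
                "ctct_mz": _fmt_ci(ctct["MZ"].r, ctct["MZ"].ci),
                "ctct_dz": _fmt_ci(ctct["DZ"].r, ctct["DZ"].ci),
                "rph": f"{derived.rph:.2f}",
                "ra": _fmt_ci(derived.ra, ci.get("ra")) if fit.params.a else "-",
                "rc": _fmt_ci(derived.rc, ci.get("rc")) if fit.params.c else "-",
                "re": _fmt_ci(derived.re, ci.get("re")),
                "pa": f"{100 * derived.pa:.0f}%" if fit.params.a else "-",
                "pc": (f"{100 * derived.proportions.get('c', float('nan')):.0f}%"
                       if fit.params.c else "-"),
                "pe": f"{100 * derived.pe:.0f}%",
                "h2_baseline": f"{derived.h2_baseline:.2f}",
                "h2_followup": f"{derived.h2_followup:.2f}",
            }
            rows.append(row)
            for comp in fit.params.components:
                comp_rows.append({
                    "metric": metric, "component": comp.upper(),
                    "var_baseline_k11sq": derived.variance_wave1[comp],
                    "cov_shared_k21sq": derived.shared_wave2[comp],
                    "var_new_k22sq": derived.new_wave2[comp],
                    "cross_cov": derived.cross_cov[comp],
                })
            dumps[metric] = {
                **fit.to_dict(),
                "derived": {
                    "V1": derived.V1, "V2": derived.V2,
                    "h2_baseline": derived.h2_baseline,
                    "h2_followup": derived.h2_followup,
                    "correlations": derived.correlations,
                    "proportions": derived.proportions,
                    "ctct_implied": derived.ctct_implied,
                    "flags": derived.flags,
                },
                "ctct_observed": {z: {"r": c.r, "ci": list(c.ci),
                                      "n_pairs": c.n_pairs}
                                  for z, c in ctct.items()},
                "correlation_ci": {k: list(v) for k, v in ci.items()},
            }
        except (TwinDataError, ValueError) as exc:
            log_lines.append(f"{metric}: ERROR {exc}")
            dumps[metric] = {"error": str(exc)}
    table_path = outdir / "bivariate_correlations.tsv"
    pd.DataFrame(rows).to_csv(table_path, sep="\t", index=False)
    comp_path = outdir / "bivariate_components.tsv"
    pd.DataFrame(comp_rows).to_csv(comp_path, sep="\t", index=False,
                                   float_format="%.6f")
    json_path = outdir / "bivariate_fits.json"
    json_path.write_text(json.dumps(dumps, indent=2, default=_json_default,
                                    sort_keys=True))
    log_path = outdir / "bivariate_run.log"
    log_path.write_text("\n".join(log_lines) + "\n")
    outputs.update(table=table_path, components=comp_path, fits=json_path,
                   log=log_path)
    return outputs
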