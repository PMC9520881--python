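"""End-to-end pipeline: descriptives, dimensionality, GRM diagnostics,
bifactor screening, invariance testing, alignment, and DTF.

The decision flow mirrors standard cross-group psychometric practice for
short ordinal scales:

1. listwise completeness filter; groups missing a required item drop out;
2. per group: weighted descriptives, EGA dimensionality, unidimensional
   GRM with C2-based fit and local diagnostics;
3. groups flagged multidimensional by EGA get a post-hoc bifactor
   comparison; a group enters the invariance stage if EGA found one
   dimension OR the average relative slope bias stays below the
   inclusion threshold (default 20%, with 10-15% the conventional
   negligible band);
4. pooled configural / metric / scalar fits with C2 indices;
5. alignment (FIXED by default) with invariance flagging and R2; a
   Monte-Carlo stability study runs when more than 25% of parameter
   rows are flagged non-invariant;
6. pairwise differential test functioning and factor-score vs sum-score
   comparison.

Every decision is logged with the triggering threshold; a stage failure
quarantines the group and the pipeline continues.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .alignment import align, alignment_stability_mc, flag_invariance, invariance_r2
from .bifactor import compare_models, fit_bifactor_grm, bifactor_indices
from .core_io import GroupedDataset, apply_completeness_filter, validate_item_set
from .descriptives import item_descriptives
from .dtf import pairwise_dtf, sumscore_factor_comparison
from .ega import ega
from .grm import empirical_marginal_reliability, fit_grm, make_quadrature
from .invariance import fit_multigroup, multigroup_c2
from .model_fit import c2_fit


@dataclass
class PipelineConfig:
    """Thresholds and settings controlling the decision flow."""

    rmsea_acceptable: float = 0.08
    rmsea_good: float = 0.05
    cfi_tli_acceptable: float = 0.90
    cfi_tli_good: float = 0.95
    srmr_acceptable: float = 0.10
    srmr_good: float = 0.08
    relative_bias_inclusion: float = 20.0     # percent
    negligible_bias_band: tuple = (10.0, 15.0)
    ega_gamma: float = 0.5
    alignment_method: str = "fixed"
    alignment_reference: str | None = None
    mc_trigger_noninvariant_pct: float = 25.0
    mc_reps: int = 50
    dtf_weight_density: str = "standard"
    dtf_bootstrap: int = 0
    quadrature_nodes: int = 61
    use_weights: bool = True
    seed: int = 0

    def __post_init__(self):
        for good, acc in ((self.rmsea_good, self.rmsea_acceptable),
                          (self.srmr_good, self.srmr_acceptable)):
            if good > acc:
                raise ValueError("'good' cutoffs must not exceed 'acceptable' "
                                 "for error-type indices")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        d = yaml.safe_load(text) or {}
        if "negligible_bias_band" in d:
            d["negligible_bias_band"] = tuple(d["negligible_bias_band"])
        return cls(**d)


def _fit_summary(fi) -> dict:
    return {"C2": fi.c2, "df": fi.df, "p": fi.p, "RMSEA": fi.rmsea,
            "RMSEA_CI": list(fi.rmsea_ci), "SRMR": fi.srmr,
            "CFI": fi.cfi, "TLI": fi.tli, "N": fi.n, "flags": fi.flags}


def run_full_pipeline(data: GroupedDataset, config: PipelineConfig | None = None) -> dict:
    """Run the whole decision flow and return a report bundle.

    The report is a nested dict of JSON-serializable summaries plus
    pandas tables under ``"tables"``; use :func:`write_report` to emit
    it as JSON + TSV files.
    """
    config = config or PipelineConfig()
    rng_seed = config.seed
    grid = make_quadrature(config.quadrature_nodes)
    log: list[dict] = []

    def decide(stage, group, decision, reason):
        log.append({"stage": stage, "group": group,
                    "decision": decision, "reason": reason})

    report: dict = {"config": asdict(config), "groups": {}, "decisions": log}
    tables: dict = {}
    plot_objects: dict = {"ega": {}, "grm_fits": {}, "dtf_examples": []}

    # inclusion rules
    item_report = validate_item_set(data, data.item_names)
    for gname, reason in item_report.excluded_groups.items():
        decide("item-set", gname, "excluded", reason)
    keep = ~np.isin(data.group, list(item_report.excluded_groups))
    data = data.subset(keep)
    data, completeness = apply_completeness_filter(data)
    report["inclusion"] = {
        "item_set": item_report.to_frame().to_dict(orient="records"),
        "completeness": completeness.to_frame().to_dict(orient="records"),
    }
    tables["descriptives"] = item_descriptives(data, weighted=config.use_weights)

    included = []
    group_fits = {}
    for gname in data.groups:
        sub = data.group_data(gname)
        entry: dict = {}
        try:
            w = sub.effective_weights() if config.use_weights else None
            res_ega = ega(sub.responses, gamma=config.ega_gamma, weights=w,
                          item_names=data.item_names)
            entry["ega"] = {
                "n_dimensions": res_ega.n_dimensions,
                "membership": res_ega.membership.tolist(),
                "penalty": res_ega.penalty,
            }
            plot_objects["ega"][gname] = res_ega
            ufit = fit_grm(sub.responses, w, grid=grid,
                           item_names=data.item_names,
                           n_categories=data.n_categories)
            group_fits[gname] = ufit
            plot_objects["grm_fits"][gname] = ufit
            fi = c2_fit(ufit)
            entry["unidimensional_fit"] = _fit_summary(fi)
            entry["reliability"] = empirical_marginal_reliability(ufit)
            decide("grm-fit", gname,
                   "acceptable" if fi.rmsea <= config.rmsea_acceptable else "poor",
                   f"RMSEA {fi.rmsea:.3f} vs acceptable {config.rmsea_acceptable}")

            if res_ega.n_dimensions == 1:
                include, why = True, "EGA unidimensional"
            else:
                bfit = fit_bifactor_grm(sub.responses, res_ega.membership,
                                        weights=w, item_names=data.item_names)
                comp = compare_models(ufit, bfit)
                idx = bifactor_indices(bfit.params)
                entry["bifactor"] = {
                    "average_relative_bias_pct": comp.average_relative_bias,
                    "score_correlation": comp.score_correlation,
                    "delta_reliability": comp.delta_reliability,
                    "ECV_G": idx.ecv_g, "PUC": idx.puc,
                    "H_G": idx.h_general, "FD_G": idx.fd_general,
                }
                include = comp.average_relative_bias < config.relative_bias_inclusion
                why = (f"average relative bias "
                       f"{comp.average_relative_bias:.1f}% vs "
                       f"{config.relative_bias_inclusion}% threshold")
            decide("inclusion", gname,
                   "included" if include else "excluded", why)
            if include:
                included.append(gname)
        except Exception as exc:  # quarantine the group, keep going
            decide("error", gname, "quarantined", repr(exc))
            entry["error"] = repr(exc)
        report["groups"][gname] = entry

    report["included_groups"] = included
    if len(included) >= 2:
        pooled = data.subset(np.isin(data.group, included))
        mg = {}
        for level in ("configural", "metric", "scalar"):
            fit_l = fit_multigroup(pooled, level, grid=grid,
                                   weights_on=config.use_weights)
            mg[level] = {"fit": fit_l, "indices": multigroup_c2(fit_l)}
            report.setdefault("invariance", {})[level] = _fit_summary(mg[level]["indices"])
        d_cfi = mg["configural"]["indices"].cfi - mg["metric"]["indices"].cfi
        decide("invariance", None,
               "metric supported" if d_cfi < 0.01 else "metric questionable",
               f"CFI change configural->metric {d_cfi:.4f} vs 0.01")

        aligned = align(mg["configural"]["fit"], method=config.alignment_method,
                        reference=config.alignment_reference,
                        seed=rng_seed)
        summary = invariance_r2(aligned)   # runs flagging too
        tables["alignment"] = summary
        pct_noninv = 100.0 * (1 - summary.n_invariant.sum()
                              / (len(summary) * aligned.n_groups))
        report["alignment"] = {
            "method": aligned.method, "reference": aligned.reference,
            "alpha": aligned.alpha.tolist(), "psi": aligned.psi.tolist(),
            "total_loss": aligned.total_loss,
            "poorly_identified": aligned.poorly_identified,
            "pct_parameters_noninvariant": pct_noninv,
            "mean_R2": float(np.nanmean(summary.R2)),
        }
        if pct_noninv > config.mc_trigger_noninvariant_pct:
            decide("alignment", None, "Monte Carlo stability triggered",
                   f"{pct_noninv:.1f}% non-invariant > "
                   f"{config.mc_trigger_noninvariant_pct}%")
            mc = alignment_stability_mc(aligned, reps=config.mc_reps,
                                        seed=rng_seed,
                                        configural=mg["configural"]["fit"])
            report["alignment"]["stability"] = {
                "ranking_correlation": mc["ranking_correlation"],
                "coverage": np.asarray(mc["coverage"]).tolist(),
                "n_completed": mc["n_completed"], "n_failed": mc["n_failed"],
            }
        dtf_out = pairwise_dtf(aligned, weight_density=config.dtf_weight_density,
                               n_boot=config.dtf_bootstrap, seed=rng_seed)
        tables["dtf"] = dtf_out["table"]
        plot_objects["dtf_examples"] = dtf_out["results"][:3]
        report["dtf_summary"] = dtf_out["summary"]
        scores = sumscore_factor_comparison(aligned, pooled, grid=grid)
        tables["score_comparison"] = scores["per_group"]
        report["score_comparison"] = {
            "cross_group_mean_correlation": scores["cross_group_mean_correlation"],
        }
    else:
        decide("invariance", None, "skipped",
               f"only {len(included)} group(s) included")

    report["tables"] = tables
    report["plot_objects"] = plot_objects
    return report


def write_report(report: dict, outdir, plots: bool = True) -> None:
    """Emit the report bundle: JSON summary, TSV tables, basic plots."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = report.get("tables", {})
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    if plots and report.get("plot_objects"):
        from . import plots as plotmod

        po = report["plot_objects"]
        for gname, res in po.get("ega", {}).items():
            plotmod.savefig(plotmod.plot_network(res),
                            outdir / f"network_{gname}.png")
        for gname, fit in po.get("grm_fits", {}).items():
            plotmod.savefig(plotmod.plot_person_item_map(fit),
                            outdir / f"wright_map_{gname}.png")
        for r in po.get("dtf_examples", []):
            plotmod.savefig(plotmod.plot_dtf_curve(r),
                            outdir / f"dtf_{r.reference}_vs_{r.focal}.png")
    slim = {k: v for k, v in report.items() if k not in ("tables", "plot_objects")}
    (outdir / "report.json").write_text(
        json.dumps(slim, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
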