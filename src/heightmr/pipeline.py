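"""Configuration-driven orchestration of the full analysis sequence.

``run_two_sample`` executes instrument construction → IVW / weighted-median /
Egger / MR-PRESSO → restrictive-instrument rerun → multivariable MR (bivariate
per confounder, then a combined model of the traits with significant direct
effects) → bidirectional MR, writing tables, JSON and plots.
``run_individual`` executes GRS → demographics → PheWAS (height and GRS) →
two-stage MR (base / clinical / left-atrial-size models) → echo-subset
sensitivity. Every run persists its resolved configuration so reports are
reproducible from it alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import individual as ind
from . import mr, phewas as pw, plots
from .instruments import build_instrument, overlap_bias, restrict_instrument
from .simulate import SimConfig, simulate_study
from .sumstats import LDPanel, read_summary_stats

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved analysis configuration (defaults match the study parameters)."""

    # input paths (optional when data are passed in memory)
    exposure_path: str | None = None
    outcome_path: str | None = None
    confounder_paths: dict = field(default_factory=dict)
    ld_pairs_path: str | None = None
    phenotype_path: str | None = None
    dosage_path: str | None = None
    variant_path: str | None = None
    phecode_map_path: str | None = None
    # thresholds
    p_threshold: float = 5e-8
    window_kb: int = 10_000
    r2_threshold: float = 0.001
    nominal_p: float = 0.05
    alpha: float = 0.05
    palindrome_eaf_limit: float = 0.42
    # method settings
    ivw_model: str = "multiplicative_random"
    n_boot: int = 1000
    n_sim: int = 5000
    seed: int = 0
    # scaling
    trait_sd: float = 9.28
    target_units: float = 10.0
    # individual-level settings
    n_pcs_mr: int = 6
    n_pcs_phewas: int = 10
    min_cases: int = 20
    min_code_count: int = 2
    # output
    out_dir: str = "out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def persist(self, out_dir: Path) -> None:
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "resolved_config.yaml", "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _write_estimates(estimates: dict, path: Path) -> None:
    rows = []
    for name, est in estimates.items():
        if est is None:
            continue
        if isinstance(est, mr.PressoResult):
            rows.append({"analysis": name, **est.raw.to_dict(),
                         "presso_global_p": est.global_p,
                         "presso_outliers": len(est.outlier_indices)})
            if est.corrected is not None:
                rows.append({"analysis": name, **est.corrected.to_dict(),
                             "presso_distortion_p": est.distortion_p})
        else:
            rows.append({"analysis": name, **est.to_dict()})
    df = pd.DataFrame(rows)
    df.to_csv(path.with_suffix(".tsv"), sep="\t", index=False)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(df.where(df.notna(), None).to_dict(orient="records"),
                  fh, indent=2, default=float)


class _Stage:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is None:
            logger.info("stage %s: done in %.1fs", self.name, dt)
        else:
            logger.error("stage %s: FAILED after %.1fs (%s)", self.name, dt, exc)
        return False


def run_two_sample(config: RunConfig, exposure=None, outcome=None,
                   ld: LDPanel | None = None, confounders: dict | None = None,
                   reverse_exposure=None) -> dict:
    """Full two-sample analysis; inputs from config paths or in memory.

    ``reverse_exposure``: outcome-trait summary statistics used to build the
    reverse-direction instrument for bidirectional MR (defaults to the outcome
    study itself).
    """
    out_dir = Path(config.out_dir)
    for sub in ("instruments", "mr"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)
    config.persist(out_dir)

    with _Stage("load"):
        if exposure is None:
            exposure = read_summary_stats(config.exposure_path)
        if outcome is None:
            outcome = read_summary_stats(config.outcome_path)
        if ld is None:
            if config.ld_pairs_path:
                ld = LDPanel.from_pair_frame(
                    pd.read_csv(config.ld_pairs_path, sep=None, engine="python"))
            else:
                ld = LDPanel({})
        if confounders is None:
            confounders = {name: read_summary_stats(path)
                           for name, path in config.confounder_paths.items()}
        logger.info("exposure: %d variants; outcome: %d variants",
                    len(exposure), len(outcome))

    report: dict = {}
    with _Stage("build_instrument"):
        inst = build_instrument(
            exposure, outcome, ld, p_threshold=config.p_threshold,
            window_kb=config.window_kb, r2_threshold=config.r2_threshold,
            palindrome_eaf_limit=config.palindrome_eaf_limit)
        logger.info("primary instrument: %d variants (from %d exposure rows)",
                    inst.n_variants, len(exposure))
        report["instrument"] = inst
        inst.harmonized.to_csv(out_dir / "instruments" / "primary.tsv",
                               sep="\t", index=False)
        report["overlap_bias"] = overlap_bias(0.0, inst.mean_f)

    with _Stage("primary_mr"):
        model = mr.TwoSampleMR(inst)
        primary = model.fit_all(n_boot=config.n_boot, n_sim=config.n_sim,
                                seed=config.seed, ivw_model=config.ivw_model)
        report["primary"] = primary
        report["per_10"] = mr.scale_per_unit(primary["ivw"], config.trait_sd,
                                             config.target_units)
        _write_estimates(primary, out_dir / "mr" / "primary")
        est_lines = {k: v for k, v in primary.items() if k != "mr_presso"}
        plots.mr_scatter(inst.harmonized, est_lines,
                         out_dir / "mr" / "scatter.png")
        plots.funnel_plot(inst.harmonized, est_lines,
                          out_dir / "mr" / "funnel.png")
        plots.forest_plot([v for v in est_lines.values()],
                          list(est_lines), out_dir / "mr" / "forest.png")

    if confounders:
        with _Stage("restrictive_instrument"):
            restricted, excl_log = restrict_instrument(
                inst, confounders, nominal_p=config.nominal_p)
            logger.info("restrictive instrument: %d variants (from %d)",
                        restricted.n_variants, inst.n_variants)
            excl_log.to_csv(out_dir / "instruments" / "exclusions.tsv",
                            sep="\t", index=False)
            report["restricted_instrument"] = restricted
            if restricted.n_variants >= 3:
                rmodel = mr.TwoSampleMR(restricted)
                report["restricted"] = rmodel.fit_all(
                    n_boot=config.n_boot, n_sim=config.n_sim,
                    seed=config.seed, ivw_model=config.ivw_model)
                _write_estimates(report["restricted"],
                                 out_dir / "mr" / "restricted")

        with _Stage("multivariable_mr"):
            exp_frame = inst.harmonized.rename(columns={"beta_exposure": "beta"})
            exp_frame = exp_frame[["variant_id", "beta"]]
            outcome_frame = inst.harmonized.rename(
                columns={"beta_outcome": "beta", "se_outcome": "se"})[
                    ["variant_id", "beta", "se"]]
            bivariate = {}
            selected = []
            for trait, study in confounders.items():
                common = set(exp_frame["variant_id"]) & set(study["variant_id"])
                if len(common) < 3:
                    logger.warning("mvmr: skipping %s (%d shared variants)",
                                   trait, len(common))
                    continue
                res = mr.mvmr({"height": exp_frame,
                               trait: study[["variant_id", "beta"]]},
                              outcome_frame)
                bivariate[trait] = res
                direct_p = float(res.table.set_index("exposure")
                                 .loc[trait, "pvalue"])
                if direct_p < config.nominal_p:
                    selected.append(trait)
            report["mvmr_bivariate"] = bivariate
            report["mvmr_selected"] = selected
            if selected:
                combined = mr.mvmr(
                    {"height": exp_frame,
                     **{t: confounders[t][["variant_id", "beta"]]
                        for t in selected}},
                    outcome_frame)
                report["mvmr_combined"] = combined
                combined.table.to_csv(out_dir / "mr" / "mvmr_combined.tsv",
                                      sep="\t", index=False)

    with _Stage("bidirectional"):
        reverse = reverse_exposure if reverse_exposure is not None else outcome
        try:
            report["bidirectional"] = mr.bidirectional_mr(
                exposure, reverse, ld, p_threshold=config.p_threshold,
                window_kb=config.window_kb, r2_threshold=config.r2_threshold,
                n_boot=config.n_boot, seed=config.seed)
            for direction, res in report["bidirectional"].items():
                _write_estimates(
                    {k: v for k, v in res.items() if k != "instrument"},
                    out_dir / "mr" / f"bidirectional_{direction}")
        except ValueError as exc:
            logger.warning("bidirectional MR skipped: %s", exc)
            report["bidirectional"] = None
    return report


def run_individual(config: RunConfig, cohort: ind.Cohort | None = None,
                   weights: pd.Series | None = None,
                   assignments: pd.DataFrame | None = None,
                   labels: dict | None = None,
                   sex_stratified: bool = True) -> dict:
    """Full individual-level analysis; inputs from config paths or in memory."""
    out_dir = Path(config.out_dir)
    for sub in ("individual", "phewas"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)
    config.persist(out_dir)

    with _Stage("load"):
        if cohort is None:
            cohort = ind.Cohort.from_files(config.phenotype_path,
                                           config.dosage_path,
                                           config.variant_path)
        if weights is None:
            raise ValueError("GRS weights required (per-variant exposure betas)")

    report: dict = {}
    with _Stage("grs"):
        grs = ind.compute_grs(cohort, weights)
        report["grs"] = grs

    with _Stage("demographics"):
        table = ind.summarize_cohort(cohort)
        report["demographics"] = table
        table.to_csv(out_dir / "individual" / "demographics.tsv", sep="\t",
                     index=False)
        (out_dir / "individual" / "demographics.txt").write_text(
            ind.format_table(table) + "\n")

    if assignments is not None:
        with _Stage("phewas"):
            covars = cohort.phenotypes
            height_z = (covars["height"] - covars["height"].mean()) \
                / covars["height"].std(ddof=0)
            res_height = pw.run_phewas(covars, height_z, assignments,
                                       n_pcs=config.n_pcs_phewas,
                                       min_cases=config.min_cases,
                                       alpha=config.alpha, labels=labels)
            res_grs = pw.run_phewas(covars, grs.standardized, assignments,
                                    n_pcs=config.n_pcs_phewas,
                                    min_cases=config.min_cases,
                                    alpha=config.alpha, labels=labels)
            report["phewas_height"] = res_height
            report["phewas_grs"] = res_grs
            for name, res in (("height", res_height), ("grs", res_grs)):
                res.table.to_csv(out_dir / "phewas" / f"{name}.tsv",
                                 sep="\t", index=False)
                if len(res.table):
                    plots.manhattan_plot(res.table, res.bonferroni_threshold,
                                         out_dir / "phewas" / f"{name}.png")

    with _Stage("two_stage_mr"):
        models = {}
        for label in ("base", "model1_clinical", "model2_la_size"):
            models[label] = ind.TwoStageMR(cohort, grs, model=label,
                                           n_pcs=config.n_pcs_mr).fit()
        report["two_stage"] = models
        rows = [{
            "model": label, "n": r.n, "n_excluded": r.n_excluded,
            "or_per_sd": r.or_per_sd, "ci_low": r.ci_low,
            "ci_high": r.ci_high, "pvalue": r.pvalue,
            "stage1_r2": r.stage1_r2,
        } for label, r in models.items()]
        pd.DataFrame(rows).to_csv(out_dir / "individual" / "two_stage.tsv",
                                  sep="\t", index=False)

    with _Stage("echo_subset"):
        # sensitivity: nested models on the identical complete-case row set
        echo_rows = cohort.phenotypes["left_atrial_diameter"].notna()
        echo = ind.Cohort(cohort.phenotypes[echo_rows],
                          cohort.dosages[echo_rows], cohort.variants)
        echo_grs = ind.compute_grs(echo, weights)
        report["echo_subset"] = {
            label: ind.TwoStageMR(echo, echo_grs, model=label,
                                  n_pcs=config.n_pcs_mr).fit()
            for label in ("base", "model1_clinical", "model2_la_size")}

    if sex_stratified:
        with _Stage("sex_stratified"):
            strata = {}
            for label, val in (("female", 1), ("male", 0)):
                rows = cohort.phenotypes["sex"] == val
                sub = ind.Cohort(cohort.phenotypes[rows], cohort.dosages[rows],
                                 cohort.variants)
                sub_grs = ind.compute_grs(sub, weights)
                strata[label] = ind.TwoStageMR(
                    sub, sub_grs, model="base", n_pcs=config.n_pcs_mr,
                    covariates=[]).fit()
            report["sex_stratified"] = strata
    return report


def run_simulated_study(sim_config: SimConfig, run_config: RunConfig) -> dict:
    """Simulate a study and run both analysis arms on it."""
    bundle = simulate_study(sim_config)
    two_sample = run_two_sample(run_config, exposure=bundle.exposure_stats,
                                outcome=bundle.outcome_stats,
                                ld=bundle.ld_panel, confounders={})
    weights = bundle.exposure_stats.set_index("variant_id")["beta"]
    individual = run_individual(run_config, cohort=bundle.cohort,
                                weights=weights)
    return {"bundle": bundle, "two_sample": two_sample,
            "individual": individual}
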