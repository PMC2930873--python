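"""End-to-end pipeline: simulate/read -> QC -> score -> derive -> models.

Outputs a deterministic bundle of TSV/JSON tables in an output
directory; identical config and seed give byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .discrimination import compare_auc, fitted_risk, incremental_r2, roc_auc
from .errors import ConfigurationError, PipelineError
from .genotypes import (
    GenotypePanel,
    compute_scores,
    qc_filter,
    read_genotype_table,
    scores_frame,
)
from .models import (
    REFERENCE_HEIGHT_M,
    dichotomized_contrast,
    interaction_test,
    longitudinal_interaction,
    per_snp_interactions,
    stratified_effects,
)
from .phenotypes import apply_exclusions, derive_analysis_columns
from .simulate import SimulationConfig, simulate_cohort
from .snps import DEFAULT_SNP_SPECS, read_snp_sheet

logger = logging.getLogger("genactiv")

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Pipeline configuration: data source, switches and thresholds."""

    genotype_path: str | None = None
    phenotype_path: str | None = None
    snp_sheet_path: str | None = None
    simulation: SimulationConfig | None = None
    output_dir: str = "genactiv_out"
    seed: int = 0
    reference_height: float = REFERENCE_HEIGHT_M
    call_rate_min: float = 0.95
    hwe_p_min: float = 0.05
    run_cross_sectional: bool = True
    run_longitudinal: bool = True
    run_per_snp: bool = True
    run_dichotomized: bool = True
    run_discrimination: bool = True
    sensitivity_exclude_cvd_cancer: bool = False
    n_boot: int = 1000
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        has_paths = self.genotype_path is not None or self.phenotype_path is not None
        if has_paths and self.simulation is not None:
            raise ConfigurationError(
                "exactly one of input paths or a simulation block is allowed"
            )
        if not has_paths and self.simulation is None:
            raise ConfigurationError(
                "either input paths or a simulation block is required"
            )
        if has_paths and (self.genotype_path is None or self.phenotype_path is None):
            raise ConfigurationError(
                "both genotype_path and phenotype_path are required"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            if "snp_specs" in sim:
                from .snps import SnpSpec

                sim["snp_specs"] = tuple(SnpSpec(**s) for s in sim["snp_specs"])
            for key in ("activity_proportions", "age_range",
                        "followup_years_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            raw["simulation"] = SimulationConfig(**sim)
        return cls(**raw)


def _load_inputs(config: RunConfig) -> tuple[GenotypePanel, pd.DataFrame]:
    if config.simulation is not None:
        sim = config.simulation
        if sim.seed != config.seed:
            sim = sim.with_(seed=config.seed)
        return simulate_cohort(sim)
    specs = (
        read_snp_sheet(config.snp_sheet_path)
        if config.snp_sheet_path
        else DEFAULT_SNP_SPECS
    )
    panel = read_genotype_table(config.genotype_path, specs)
    records = pd.read_csv(
        config.phenotype_path, sep="\t", na_values=["NA"], keep_default_na=False
    )
    return panel, records


def _effects_table(effects) -> pd.DataFrame:
    rows = []
    for e in effects:
        rows.append(
            {
                "stratum": e.stratum,
                "n": e.n,
                "beta": e.beta,
                "se": e.se,
                "p": e.p,
                "beta_weight_g": e.weight_grams,
                "or": e.or_per_allele,
                "or_low": e.or_ci[0] if e.or_ci else None,
                "or_high": e.or_ci[1] if e.or_ci else None,
            }
        )
    return pd.DataFrame.from_records(rows)


def render_baseline_table(analysis_set: pd.DataFrame) -> pd.DataFrame:
    """Baseline (and, when present, follow-up) characteristics by sex."""
    if analysis_set.empty:
        raise PipelineError("empty analysis set")
    rows = []
    for sex in ("M", "F"):
        sub = analysis_set.loc[analysis_set["sex"] == sex]
        if sub.empty:
            continue
        row = {
            "sex": sex,
            "n": len(sub),
            "age_mean": sub["age"].mean(),
            "age_sd": sub["age"].std(),
            "bmi_mean": sub["bmi_baseline"].mean(),
            "bmi_sd": sub["bmi_baseline"].std(),
            "score_mean": sub["score"].mean(),
            "score_sd": sub["score"].std(),
        }
        for level, label in enumerate(
            ("inactive", "moderately_inactive", "moderately_active", "active")
        ):
            n = int((sub["activity"] == level).sum())
            row[f"{label}_n"] = n
            row[f"{label}_pct"] = 100.0 * n / len(sub)
        fu = sub.dropna(subset=["bmi_followup"])
        if not fu.empty:
            row["followup_n"] = len(fu)
            row["followup_age_mean"] = (fu["age"] + fu["followup_years"]).mean()
            row["followup_bmi_mean"] = fu["bmi_followup"].mean()
            row["followup_bmi_sd"] = fu["bmi_followup"].std()
        rows.append(row)
    return pd.DataFrame.from_records(rows)


def build_analysis_table(
    panel: GenotypePanel,
    records: pd.DataFrame,
    call_rate_min: float = 0.95,
    hwe_p_min: float = 0.05,
    exclude_cvd_cancer: bool = False,
):
    """QC, exclusions and scoring; returns (table, qc_report, excl_report).

    Score substitution means are computed on the post-exclusion analysis
    sample, and scores are attached only for subjects with at most three
    missing genotypes.
    """
    panel_qc, qc_report = qc_filter(panel, call_rate_min, hwe_p_min)
    records = derive_analysis_columns(records)
    analysis, excl_report = apply_exclusions(records, exclude_cvd_cancer)
    panel_sub = panel_qc.subset_subjects(analysis["subject_id"])
    scores = scores_frame(compute_scores(panel_sub))
    table = analysis.merge(
        scores, left_on="subject_id", right_index=True, how="left"
    )
    n_no_score = int((~table["complete"].fillna(False)).sum())
    excl_report = pd.concat(
        [
            excl_report,
            pd.DataFrame(
                [{"rule": "no_score_gt3_missing", "n_excluded": n_no_score,
                  "order": len(excl_report) + 1}]
            ),
        ],
        ignore_index=True,
    )
    table = table.loc[table["complete"].fillna(False)].reset_index(drop=True)
    return table, qc_report, excl_report


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages and write the report bundle."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    bundle: dict = {}

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    panel, records = _stage("load", _load_inputs, config)
    n_input = len(records)
    table, qc_report, excl_report = _stage(
        "prepare",
        build_analysis_table,
        panel,
        records,
        config.call_rate_min,
        config.hwe_p_min,
        config.sensitivity_exclude_cvd_cancer,
    )
    logger.info(
        "seed=%d input=%d analysis=%d", config.seed, n_input, len(table)
    )
    qc_report.to_csv(out / "qc_report.tsv", sep="\t", index=False,
                     float_format=_FLOAT_FMT)
    excl_report.to_csv(out / "exclusions.tsv", sep="\t", index=False)
    bundle["analysis_table"] = table
    bundle["qc_report"] = qc_report
    bundle["exclusions"] = excl_report

    baseline = render_baseline_table(table)
    baseline.to_csv(out / "baseline_table.tsv", sep="\t", index=False,
                    float_format=_FLOAT_FMT)
    bundle["baseline_table"] = baseline

    height = config.reference_height
    if config.run_cross_sectional:
        eff_bmi = _effects_table(stratified_effects(table, "bmi", height=height))
        eff_obe = _effects_table(stratified_effects(table, "obesity", height=height))
        strat = eff_bmi.merge(
            eff_obe, on="stratum", suffixes=("_bmi", "_obesity")
        )
        strat.to_csv(out / "stratified_effects.tsv", sep="\t", index=False,
                     float_format=_FLOAT_FMT)
        bundle["stratified_effects"] = strat
        inter = {}
        for outcome in ("bmi", "obesity", "overweight"):
            for coding in ("ordinal", "binary"):
                r = interaction_test(table, outcome, coding)
                inter[f"{outcome}_{coding}"] = {
                    "estimate": r.estimate,
                    "se": r.se,
                    "p_interaction": r.p_interaction,
                }
        (out / "interactions.json").write_text(
            json.dumps(inter, indent=2, sort_keys=True) + "\n"
        )
        bundle["interactions"] = inter

    if config.run_dichotomized:
        rows = []
        for outcome in ("bmi", "obesity"):
            for e in dichotomized_contrast(table, outcome, height=height):
                rows.append({"outcome": outcome, **_effects_table([e]).iloc[0]})
        dich = pd.DataFrame.from_records(rows)
        dich.to_csv(out / "dichotomized.tsv", sep="\t", index=False,
                    float_format=_FLOAT_FMT)
        bundle["dichotomized"] = dich

    if config.run_per_snp:
        scan = per_snp_interactions(
            panel.subset_subjects(table["subject_id"]),
            table.set_index("subject_id"),
        )
        scan.to_csv(out / "per_snp_interactions.tsv", sep="\t",
                    float_format=_FLOAT_FMT)
        bundle["per_snp"] = scan

    if config.run_discrimination:
        rows = []
        strata = {
            "inactive": table.loc[table["activity"] == 0],
            "combined_active": table.loc[table["activity"] >= 1],
        }
        risks = {}
        for label, sub in strata.items():
            res = roc_auc(sub, stratum=label)
            risks[label] = fitted_risk(sub)
            rows.append(
                {
                    "stratum": label,
                    "auc": res.auc,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "n_cases": res.n_cases,
                    "n_controls": res.n_controls,
                    "incremental_r2": incremental_r2(sub),
                }
            )
        disc = pd.DataFrame.from_records(rows)
        disc.to_csv(out / "discrimination.tsv", sep="\t", index=False,
                    float_format=_FLOAT_FMT)
        bundle["discrimination"] = disc
        (pa, la), (pb, lb) = risks["inactive"], risks["combined_active"]
        contrast = compare_auc(pa, la, pb, lb, config.n_boot, config.seed)
        (out / "auc_contrast.json").write_text(
            json.dumps(contrast, indent=2, sort_keys=True) + "\n"
        )
        bundle["auc_contrast"] = contrast

    if config.run_longitudinal and table["annual_bmi_change"].notna().any():
        res, slopes = _stage("longitudinal", longitudinal_interaction, table)
        longi = _effects_table(slopes)
        longi.to_csv(out / "longitudinal_slopes.tsv", sep="\t", index=False,
                     float_format=_FLOAT_FMT)
        (out / "longitudinal_interaction.json").write_text(
            json.dumps(
                {"estimate": res.estimate, "se": res.se,
                 "p_interaction": res.p_interaction, "coding": res.coding},
                indent=2, sort_keys=True,
            )
            + "\n"
        )
        bundle["longitudinal"] = {"interaction": res, "slopes": slopes}

    run_log = {
        "package_version": __version__,
        "seed": config.seed,
        "n_input": n_input,
        "n_analysis": len(table),
        "call_rate_min": config.call_rate_min,
        "hwe_p_min": config.hwe_p_min,
        "reference_height_m": config.reference_height,
        "exclusion_counts": {
            r["rule"]: int(r["n_excluded"]) for _, r in excl_report.iterrows()
        },
    }
    (out / "run_log.json").write_text(
        json.dumps(run_log, indent=2, sort_keys=True) + "\n"
    )
    bundle["run_log"] = run_log
    return bundle
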