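"""Synthetic cohort generation.

Generates genotype panels in Hardy-Weinberg equilibrium and phenotypes
whose per-allele BMI effect declines linearly with the activity level,
so that the downstream analysis models can be validated by parameter
recovery.  One RNG stream per run, seeded from the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .genotypes import GenotypePanel
from .snps import DEFAULT_SNP_SPECS, SnpSpec, write_snp_sheet

#: Baseline activity-level shares (inactive ... active), close to the
#: observed cohort distribution.
DEFAULT_ACTIVITY_PROPORTIONS = (0.302, 0.285, 0.228, 0.185)

#: (occupation, hours interval) cells consistent with each activity
#: level; back-fill draws one cell uniformly, then hours uniformly
#: within the interval.  Intervals stay strictly inside classification
#: bands so the classifier recovers the level exactly.
_BACKFILL_CELLS: dict[int, list[tuple[str, tuple[float, float]]]] = {
    0: [("sedentary", (0.0, 0.0))],
    1: [("sedentary", (0.05, 0.45)), ("standing", (0.0, 0.0))],
    2: [
        ("sedentary", (0.5, 1.0)),
        ("standing", (0.05, 0.45)),
        ("physical", (0.0, 0.0)),
    ],
    3: [
        ("sedentary", (1.1, 3.0)),
        ("standing", (0.5, 2.5)),
        ("physical", (0.2, 2.5)),
        ("heavy", (0.0, 2.5)),
    ],
}


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for a synthetic cohort.

    The per-allele BMI effect at activity level L is
    ``beta_per_allele_inactive + L * interaction_slope``; with the
    defaults this runs from 0.205 kg/m^2 at level 0 down to 0.126 at
    level 3.  Follow-up BMI drifts linearly; the optional score x
    activity drift term is positive among the inactive and negative
    among the active.
    """

    n_subjects: int = 20000
    seed: int = 0
    snp_specs: tuple[SnpSpec, ...] = DEFAULT_SNP_SPECS
    intercept_bmi: float = 19.5
    beta_per_allele_inactive: float = 0.205
    interaction_slope: float = -0.0263
    beta_activity: float = -0.313
    beta_age: float = 0.16
    beta_age2: float = -0.0012
    beta_sex: float = 0.3
    noise_sd: float = 3.5
    activity_proportions: tuple[float, float, float, float] = (
        DEFAULT_ACTIVITY_PROPORTIONS
    )
    age_range: tuple[float, float] = (39.0, 79.0)
    sex_ratio: float = 0.49  # proportion male
    followup_years_range: tuple[float, float] = (3.0, 4.0)
    annual_drift_mean: float = 0.05
    annual_drift_sd: float = 0.2
    drift_score_inactive: float = 0.004  # kg/m^2/y per centred allele at level 0
    drift_score_trend: float = -0.003  # change of the above per activity level
    genotype_missing_rate: float = 0.04
    dropout_rate: float = 0.42
    prevalence_t2d: float = 0.025
    waist_intercept: float = 20.0
    waist_slope: float = 2.8  # cm per kg/m^2
    waist_noise_sd: float = 4.0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ConfigurationError("n_subjects must be positive")
        if len(self.snp_specs) == 0:
            raise ConfigurationError("at least one SNP spec required")
        for s in self.snp_specs:
            if not 0.0 < s.risk_allele_frequency < 1.0:
                raise ConfigurationError(
                    f"{s.snp_id}: risk allele frequency must lie strictly "
                    f"in (0, 1), got {s.risk_allele_frequency}"
                )
        props = np.asarray(self.activity_proportions, dtype=float)
        if props.shape != (4,):
            raise ConfigurationError("activity_proportions must have 4 entries")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"activity_proportions must sum to 1, got {props.sum()!r}"
            )
        if (props < 0).any():
            raise ConfigurationError("activity_proportions must be >= 0")
        for name in ("genotype_missing_rate", "dropout_rate", "prevalence_t2d",
                     "sex_ratio"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        for level in range(4):
            if self.per_allele_effect(level) < 0:
                raise ConfigurationError(
                    f"per-allele effect negative at activity level {level}"
                )
        if self.followup_years_range[0] <= 0 or (
            self.followup_years_range[1] < self.followup_years_range[0]
        ):
            raise ConfigurationError("invalid followup_years_range")

    def per_allele_effect(self, level: int) -> float:
        """Generative per-allele BMI effect at an activity level."""
        return self.beta_per_allele_inactive + level * self.interaction_slope

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GenotypePanel:
    """Draw Binomial(2, p_j) dosages per SNP, then inject missingness.

    The returned panel keeps the pre-missingness matrix on
    ``true_dosage`` for use by :func:`simulate_phenotypes`.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_subjects
    freqs = np.array([s.risk_allele_frequency for s in config.snp_specs])
    true = rng.binomial(2, freqs, size=(n, len(freqs))).astype(float)
    observed = true.copy()
    if config.genotype_missing_rate > 0:
        mask = rng.random(true.shape) < config.genotype_missing_rate
        observed[mask] = np.nan
    subject_ids = [f"s{i + 1:06d}" for i in range(n)]
    cols = [s.snp_id for s in config.snp_specs]
    dosage = pd.DataFrame(observed, index=subject_ids, columns=cols)
    dosage.index.name = "subject_id"
    true_df = pd.DataFrame(true, index=subject_ids, columns=cols)
    return GenotypePanel(dosage, tuple(config.snp_specs), true_df)


def _backfill_occupation_hours(
    activity: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    occupation = np.empty(len(activity), dtype=object)
    hours = np.empty(len(activity), dtype=float)
    for level, cells in _BACKFILL_CELLS.items():
        idx = np.flatnonzero(activity == level)
        if idx.size == 0:
            continue
        choice = rng.integers(0, len(cells), size=idx.size)
        u = rng.random(idx.size)
        for c, (occ, (lo, hi)) in enumerate(cells):
            sel = idx[choice == c]
            occupation[sel] = occ
            hours[sel] = lo + (hi - lo) * u[choice == c]
    return occupation, hours


def simulate_phenotypes(
    config: SimulationConfig,
    panel: GenotypePanel,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate the phenotype table consistent with the analysis models.

    Baseline BMI is additive in the true allele count with a per-allele
    effect linear in activity level, plus activity, age, age^2 and sex
    terms and Gaussian noise.  Occupation and recreation hours are
    back-filled so the activity classifier recovers the generative
    level exactly.  When ``rng`` is omitted a fresh stream is seeded
    with ``config.seed + 1`` so the panel and phenotypes stay decoupled
    yet reproducible.
    """
    if panel.n_subjects != config.n_subjects:
        raise DataError(
            f"panel has {panel.n_subjects} subjects, config expects "
            f"{config.n_subjects}"
        )
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n = config.n_subjects
    if panel.true_dosage is not None:
        geno = panel.true_dosage.to_numpy()
    else:  # real panel: mean-fill missing for the generative sum
        geno = panel.dosage.fillna(panel.dosage.mean()).to_numpy()

    activity = rng.choice(4, size=n, p=np.asarray(config.activity_proportions))
    age = rng.uniform(*config.age_range, size=n)
    male = (rng.random(n) < config.sex_ratio).astype(int)
    allele_count = geno.sum(axis=1)
    per_allele = config.beta_per_allele_inactive + activity * config.interaction_slope
    bmi = (
        config.intercept_bmi
        + allele_count * per_allele
        + config.beta_activity * activity
        + config.beta_age * age
        + config.beta_age2 * age**2
        + config.beta_sex * male
        + rng.normal(0.0, config.noise_sd, size=n)
    )
    occupation, hours = _backfill_occupation_hours(activity, rng)

    waist = (
        config.waist_intercept
        + config.waist_slope * bmi
        + rng.normal(0.0, config.waist_noise_sd, size=n)
    )
    followup_years = rng.uniform(*config.followup_years_range, size=n)
    expected_score = 2.0 * sum(
        s.risk_allele_frequency for s in config.snp_specs
    )
    drift_slope = (
        config.drift_score_inactive + activity * config.drift_score_trend
    )
    drift = rng.normal(
        config.annual_drift_mean + drift_slope * (allele_count - expected_score),
        config.annual_drift_sd,
        size=n,
    )
    bmi_followup = bmi + followup_years * drift
    waist_followup = waist + followup_years * rng.normal(0.1, 0.5, size=n)
    dropout = rng.random(n) < config.dropout_rate
    bmi_followup[dropout] = np.nan
    waist_followup[dropout] = np.nan
    followup_years[dropout] = np.nan
    prevalent_t2d = (rng.random(n) < config.prevalence_t2d).astype(int)

    records = pd.DataFrame(
        {
            "subject_id": panel.subject_ids,
            "sex": np.where(male == 1, "M", "F"),
            "age": age,
            "bmi_baseline": bmi,
            "bmi_followup": bmi_followup,
            "waist_baseline": waist,
            "waist_followup": waist_followup,
            "followup_years": followup_years,
            "occupation": occupation,
            "recreation_hours_per_day": hours,
            "prevalent_t2d": prevalent_t2d,
            # generative level, for validation only; not part of the
            # phenotype file schema (write_cohort drops it)
            "activity_true": activity,
        }
    )
    return records


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Genotypes and phenotypes from a single seeded RNG stream."""
    rng = np.random.default_rng(config.seed)
    panel = simulate_genotypes(config, rng)
    records = simulate_phenotypes(config, panel, rng)
    return panel, records


_PHENO_FLOATS = (
    "age",
    "bmi_baseline",
    "bmi_followup",
    "waist_baseline",
    "waist_followup",
    "followup_years",
    "recreation_hours_per_day",
)


def write_cohort(
    panel: GenotypePanel,
    records: pd.DataFrame,
    genotype_path,
    phenotype_path,
    vcf_path=None,
    snp_sheet_path=None,
) -> None:
    """Write the genotype/phenotype TSVs (and optional VCF + SNP sheet).

    Output is deterministic for a given panel/records: floats use a
    fixed 6-decimal format and missing values are written as ``NA``.
    """
    if list(panel.subject_ids) != list(records["subject_id"]):
        raise DataError("panel and phenotype subject ids differ")
    geno = panel.dosage.map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    geno.to_csv(genotype_path, sep="\t")

    out = records.drop(columns=["activity_true"], errors="ignore")
    for col in _PHENO_FLOATS:
        out[col] = out[col].map(lambda v: "NA" if pd.isna(v) else f"{v:.6f}")
    out.to_csv(phenotype_path, sep="\t", index=False, na_rep="NA")

    if snp_sheet_path is not None:
        write_snp_sheet(panel.snp_specs, snp_sheet_path)
    if vcf_path is not None:
        write_vcf(panel, vcf_path)


def write_vcf(panel: GenotypePanel, path) -> None:
    """Minimal GT-only VCF 4.2 export (other allele as REF, risk as ALT)."""
    sids = panel.subject_ids
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sids)
            + "\n"
        )
        for pos, spec in enumerate(panel.snp_specs, start=1):
            doses = panel.dosage[spec.snp_id].to_numpy()
            gts = []
            for d in doses:
                if np.isnan(d):
                    gts.append("./.")
                else:
                    alt = int(d)  # risk allele is ALT (index 1)
                    gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[alt])
            fh.write(
                f"1\t{pos * 1000}\t{spec.snp_id}\t{spec.other_allele}\t"
                f"{spec.risk_allele}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )
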