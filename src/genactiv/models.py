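"""Cross-sectional and longitudinal association models.

All adjusted models share the covariate set age, age^2, sex and, where
applicable, the four-level activity index entered as a linear ordinal
term (0-3).  Linear models are ordinary least squares; binary outcomes
use maximum-likelihood logistic regression.  Effect sizes on the BMI
scale convert to body-weight grams at a reference height of 1.70 m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .errors import DataError, ModelError
from .genotypes import GenotypePanel

REFERENCE_HEIGHT_M = 1.70

_Z975 = 1.959963984540054  # Phi^-1(0.975)

COVARIATES_CROSS_SECTIONAL = ("age", "age2", "sex_male", "activity")
COVARIATES_WITHIN_STRATUM = ("age", "age2", "sex_male")

STRATUM_LABELS = {
    0: "inactive",
    1: "moderately_inactive",
    2: "moderately_active",
    3: "active",
}


@dataclass
class ModelResult:
    """Fitted model summary: per-term estimates, SEs and p-values."""

    outcome: str
    kind: str  # "linear" or "logistic"
    params: pd.DataFrame  # index: term; columns: estimate, se, p (+ OR cols)
    n_used: int
    covariates: tuple[str, ...]

    def estimate(self, term: str) -> float:
        return float(self.params.loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.params.loc[term, "se"])

    def p(self, term: str) -> float:
        return float(self.params.loc[term, "p"])


@dataclass
class EffectEstimate:
    """Per-stratum effect with gram equivalent (linear) or OR (logistic)."""

    stratum: str
    n: int
    beta: float | None = None
    se: float | None = None
    p: float | None = None
    weight_grams: int | None = None
    or_per_allele: float | None = None
    or_ci: tuple[float, float] | None = None


@dataclass
class InteractionResult:
    """Score (or SNP) x activity interaction from the joint model."""

    estimate: float
    se: float
    p_interaction: float
    coding: str  # "ordinal" or "binary"
    model: ModelResult = field(repr=False, default=None)


def _prepare(data: pd.DataFrame) -> pd.DataFrame:
    df = data.copy()
    if "age2" not in df and "age" in df:
        df["age2"] = df["age"].astype(float) ** 2
    if "sex_male" not in df and "sex" in df:
        df["sex_male"] = (df["sex"] == "M").astype(float)
    return df


def _design(df: pd.DataFrame, terms) -> tuple[np.ndarray, list[str]]:
    X = np.column_stack(
        [np.ones(len(df))] + [df[t].to_numpy(dtype=float) for t in terms]
    )
    return X, ["const", *terms]


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the terms involved in the collinearity via QR pivoting
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[i] for i in np.flatnonzero(diag < tol)]
        raise ModelError(f"rank-deficient design; collinear term(s): {bad}")


def fit_linear(outcome: str, terms, data: pd.DataFrame) -> ModelResult:
    """Ordinary least squares of ``outcome`` on intercept + ``terms``.

    Complete-case: rows with any missing used column are dropped.
    """
    df = _prepare(data)
    cols = [outcome, *terms]
    df = df.dropna(subset=cols)
    if len(df) <= len(terms) + 1:
        raise ModelError(
            f"n={len(df)} too small for {len(terms) + 1} parameters"
        )
    X, names = _design(df, terms)
    _check_rank(X, names)
    y = df[outcome].to_numpy(dtype=float)
    res = sm.OLS(y, X).fit()
    params = pd.DataFrame(
        {"estimate": res.params, "se": res.bse, "p": res.pvalues}, index=names
    )
    return ModelResult(outcome, "linear", params, int(res.nobs), tuple(terms))


def fit_logistic(outcome: str, terms, data: pd.DataFrame) -> ModelResult:
    """Maximum-likelihood logistic regression with OR and 95% CI per term.

    Raises :class:`ModelError` on separation or non-convergence rather
    than returning unstable estimates.
    """
    df = _prepare(data)
    cols = [outcome, *terms]
    df = df.dropna(subset=cols)
    y = df[outcome].to_numpy(dtype=float)
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ModelError(
            f"binary outcome needs both classes present, got {classes}"
        )
    X, names = _design(df, terms)
    _check_rank(X, names)
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(
                method="newton", maxiter=100, tol=1e-8, disp=0
            )
    except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
        raise ModelError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise ModelError("logistic fit did not converge in 100 iterations")
    if np.abs(res.params).max() > 30:
        raise ModelError("logistic fit diverged (likely complete separation)")
    params = pd.DataFrame(
        {"estimate": res.params, "se": res.bse, "p": res.pvalues}, index=names
    )
    params["or_"] = np.exp(params["estimate"])
    params["or_low"] = np.exp(params["estimate"] - _Z975 * params["se"])
    params["or_high"] = np.exp(params["estimate"] + _Z975 * params["se"])
    return ModelResult(outcome, "logistic", params, int(res.nobs), tuple(terms))


def _outcome_frame(data: pd.DataFrame, outcome: str) -> tuple[pd.DataFrame, str, str]:
    """Restrict rows and name the model column for a named outcome.

    ``bmi``: linear on baseline BMI, all rows.
    ``obesity``: obese (BMI >= 30) vs normal (18.5 <= BMI < 25) only.
    ``overweight``: BMI >= 25 vs normal.
    """
    df = _prepare(data)
    if outcome == "bmi":
        return df, "bmi_baseline", "linear"
    if outcome == "obesity":
        keep = (df["obese"] == 1) | (df["normal_weight"] == 1)
        return df.loc[keep], "obese", "logistic"
    if outcome == "overweight":
        keep = (df["overweight"] == 1) | (df["normal_weight"] == 1)
        return df.loc[keep], "overweight", "logistic"
    raise DataError(f"unknown outcome {outcome!r}; use bmi|obesity|overweight")


def score_main_effect(
    data: pd.DataFrame, outcome: str = "bmi", covariates=COVARIATES_CROSS_SECTIONAL
) -> ModelResult:
    """Adjusted per-allele effect of the predisposition score."""
    df, col, kind = _outcome_frame(data, outcome)
    terms = ["score", *covariates]
    if kind == "linear":
        return fit_linear(col, terms, df)
    return fit_logistic(col, terms, df)


def interaction_test(
    data: pd.DataFrame,
    outcome: str = "bmi",
    coding: str = "ordinal",
    term: str = "score",
) -> InteractionResult:
    """Score (or SNP dosage) x activity interaction with main effects.

    ``coding='ordinal'`` uses the 0-3 level; ``'binary'`` contrasts the
    combined-active group (levels 1-3) against inactive.
    """
    if coding not in ("ordinal", "binary"):
        raise DataError(f"unknown interaction coding {coding!r}")
    df, col, kind = _outcome_frame(data, outcome)
    levels = df["activity"].dropna().unique()
    if len(levels) < 2:
        raise ModelError("interaction undefined: single activity level in data")
    df = df.copy()
    if coding == "binary":
        df["act_term"] = (df["activity"] >= 1).astype(float)
    else:
        df["act_term"] = df["activity"].astype(float)
    df["interaction"] = df[term] * df["act_term"]
    terms = [term, "act_term", "interaction", "age", "age2", "sex_male"]
    model = (
        fit_linear(col, terms, df)
        if kind == "linear"
        else fit_logistic(col, terms, df)
    )
    return InteractionResult(
        estimate=model.estimate("interaction"),
        se=model.se("interaction"),
        p_interaction=model.p("interaction"),
        coding=coding,
        model=model,
    )


def beta_to_weight(beta: float, height: float = REFERENCE_HEIGHT_M) -> int:
    """Convert a BMI effect (kg/m^2) to grams of body weight at a height.

    Rounds half away from zero to an integer number of grams.
    """
    if height <= 0:
        raise DataError("height must be > 0")
    grams = beta * height**2 * 1000.0
    return int(math.copysign(math.floor(abs(grams) + 0.5), grams))


def attenuation_percent(
    effect_inactive: float, effect_active: float, scale: str = "beta"
) -> int:
    """Percent reduction of the active-stratum effect vs the inactive one.

    ``beta`` scale: (b_in - b_act) / b_in * 100.  ``excess_or`` scale
    works on OR - 1.  Rounded half away from zero to integer percent.
    """
    if scale == "beta":
        if effect_inactive == 0:
            raise DataError("inactive effect must be nonzero on beta scale")
        pct = (effect_inactive - effect_active) / effect_inactive * 100.0
    elif scale == "excess_or":
        if effect_inactive <= 1:
            raise DataError("excess-OR scale requires OR_inactive > 1")
        pct = (
            ((effect_inactive - 1) - (effect_active - 1))
            / (effect_inactive - 1)
            * 100.0
        )
    else:
        raise DataError(f"unknown attenuation scale {scale!r}")
    return int(math.copysign(math.floor(abs(pct) + 0.5), pct))


def _effect_from_model(
    model: ModelResult, stratum: str, term: str, height: float
) -> EffectEstimate:
    est = EffectEstimate(stratum=stratum, n=model.n_used)
    if model.kind == "linear":
        est.beta = model.estimate(term)
        est.se = model.se(term)
        est.p = model.p(term)
        est.weight_grams = beta_to_weight(est.beta, height)
    else:
        est.or_per_allele = float(model.params.loc[term, "or_"])
        est.or_ci = (
            float(model.params.loc[term, "or_low"]),
            float(model.params.loc[term, "or_high"]),
        )
        est.p = model.p(term)
        est.beta = model.estimate(term)
        est.se = model.se(term)
    return est


def stratified_effects(
    data: pd.DataFrame,
    outcome: str = "bmi",
    term: str = "score",
    height: float = REFERENCE_HEIGHT_M,
) -> list[EffectEstimate]:
    """Per-allele effect within each activity stratum.

    Returns estimates for the four levels, the combined-active group
    (levels 1-3) and the overall sample.  Within a stratum the activity
    covariate is dropped; overall and combined-active keep it.  Empty
    strata are reported as absent.
    """
    df = _prepare(data)
    out: list[EffectEstimate] = []
    overall = score_main_effect(df, outcome, COVARIATES_CROSS_SECTIONAL)
    out.append(_effect_from_model(overall, "overall", term, height))
    for level, label in STRATUM_LABELS.items():
        sub = df.loc[df["activity"] == level]
        if sub.empty:
            continue
        model = score_main_effect(sub, outcome, COVARIATES_WITHIN_STRATUM)
        out.append(_effect_from_model(model, label, term, height))
    combined = df.loc[df["activity"] >= 1]
    if not combined.empty:
        model = score_main_effect(combined, outcome, COVARIATES_CROSS_SECTIONAL)
        out.append(_effect_from_model(model, "combined_active", term, height))
    return out


def dichotomized_contrast(
    data: pd.DataFrame,
    outcome: str = "bmi",
    threshold: float | None = None,
    height: float = REFERENCE_HEIGHT_M,
) -> list[EffectEstimate]:
    """High (> median score) vs low susceptibility contrast by stratum.

    The threshold defaults to the median score over the full score
    sample.  Returns estimates within the inactive and combined-active
    strata (linear on BMI or logistic on obesity per ``outcome``).
    """
    df = _prepare(data)
    scores = df["score"].dropna()
    thr = float(scores.median()) if threshold is None else float(threshold)
    high = (df["score"] > thr).astype(float)
    if high.nunique() < 2:
        raise DataError(f"degenerate score threshold {thr}: one group empty")
    df = df.copy()
    df["high_score"] = high
    out = []
    for label, sub in (
        ("inactive", df.loc[df["activity"] == 0]),
        ("combined_active", df.loc[df["activity"] >= 1]),
    ):
        sub_o, col, kind = _outcome_frame(sub, outcome)
        terms = ["high_score", "age", "age2", "sex_male"]
        if label == "combined_active":
            terms.append("activity")
        model = (
            fit_linear(col, terms, sub_o)
            if kind == "linear"
            else fit_logistic(col, terms, sub_o)
        )
        out.append(_effect_from_model(model, label, "high_score", height))
    return out


def per_snp_interactions(
    panel: GenotypePanel,
    data: pd.DataFrame,
    outcome: str = "bmi",
    coding: str = "ordinal",
) -> pd.DataFrame:
    """One dosage x activity interaction test per SNP, Bonferroni-adjusted.

    Each SNP is tested complete-case on its observed dosages.
    Monomorphic SNPs are skipped with a warning column entry.  The
    adjusted p multiplies the nominal p by the number of SNPs tested
    (capped at 1).
    """
    import warnings as _warnings

    df = _prepare(data)
    rows = []
    for spec in panel.snp_specs:
        snp = spec.snp_id
        dose = panel.dosage[snp]
        merged = df.join(dose.rename("dosage"), on="subject_id") if (
            "subject_id" in df.columns
        ) else df.assign(dosage=dose.reindex(df.index))
        merged = merged.dropna(subset=["dosage"])
        if merged["dosage"].nunique() < 2:
            _warnings.warn(f"{snp}: monomorphic in sample, skipped")
            rows.append(
                {"snp_id": snp, "estimate": np.nan, "se": np.nan,
                 "p": np.nan, "skipped": True}
            )
            continue
        res = interaction_test(merged, outcome, coding, term="dosage")
        rows.append(
            {"snp_id": snp, "estimate": res.estimate, "se": res.se,
             "p": res.p_interaction, "skipped": False}
        )
    table = pd.DataFrame.from_records(rows).set_index("snp_id")
    m = int((~table["skipped"]).sum())
    table["p_bonferroni"] = np.minimum(table["p"] * m, 1.0)
    table["n_tests"] = m
    return table


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p)."""
    return min(1.0, p * m)


def inverse_normal(values) -> np.ndarray:
    """Rank-based inverse-normal (Blom) transform.

    Maps rank r (average ranks for ties) to Phi^-1((r - 3/8)/(n + 1/4)).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DataError("inverse_normal requires at least 2 values")
    if np.unique(x).size == 1:
        raise DataError("inverse_normal undefined for constant input")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.375) / (x.size + 0.25))


def longitudinal_interaction(
    data: pd.DataFrame, coding: str = "ordinal"
) -> tuple[InteractionResult, list[EffectEstimate]]:
    """Score x activity interaction on annual BMI change during follow-up.

    Follow-up subjects only; the joint model adjusts for age, age^2,
    sex and baseline BMI.  Also returns per-stratum score slopes.
    """
    df = _prepare(data)
    df = df.dropna(subset=["annual_bmi_change"])
    if df.empty:
        raise DataError("no follow-up data for longitudinal analysis")
    df = df.copy()
    if coding == "binary":
        df["act_term"] = (df["activity"] >= 1).astype(float)
    else:
        df["act_term"] = df["activity"].astype(float)
    df["interaction"] = df["score"] * df["act_term"]
    terms = [
        "score", "act_term", "interaction", "age", "age2", "sex_male",
        "bmi_baseline",
    ]
    model = fit_linear("annual_bmi_change", terms, df)
    result = InteractionResult(
        estimate=model.estimate("interaction"),
        se=model.se("interaction"),
        p_interaction=model.p("interaction"),
        coding=coding,
        model=model,
    )
    slopes = []
    for level, label in STRATUM_LABELS.items():
        sub = df.loc[df["activity"] == level]
        if sub.empty:
            continue
        m = fit_linear(
            "annual_bmi_change",
            ["score", "age", "age2", "sex_male", "bmi_baseline"],
            sub,
        )
        slopes.append(
            EffectEstimate(
                stratum=label,
                n=m.n_used,
                beta=m.estimate("score"),
                se=m.se("score"),
                p=m.p("score"),
            )
        )
    return result, slopes
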