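"""Variance explained and ROC discrimination of the predisposition score."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError
from .models import _outcome_frame, _prepare, fit_linear, fit_logistic


@dataclass
class AucResult:
    auc: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int
    stratum: str = ""

    def __post_init__(self) -> None:
        assert 0.0 <= self.auc <= 1.0
        assert self.ci_low <= self.auc <= self.ci_high


def incremental_r2(
    data: pd.DataFrame,
    outcome: str = "bmi",
    covariates=("age", "age2", "sex_male"),
) -> float:
    """R^2 gained by adding the score to the covariate-only linear model."""
    df, col, kind = _outcome_frame(data, outcome)
    if kind != "linear":
        raise DataError("incremental_r2 is defined for the linear BMI outcome")
    df = df.dropna(subset=[col, "score", *covariates])

    def _r2(terms):
        model = fit_linear(col, terms, df)
        y = df[col].to_numpy(dtype=float)
        X = np.column_stack(
            [np.ones(len(df))] + [df[t].to_numpy(dtype=float) for t in terms]
        )
        resid = y - X @ model.params["estimate"].to_numpy()
        return 1.0 - resid.var() / y.var()

    return _r2(["score", *covariates]) - _r2(list(covariates))


def auc_mann_whitney(case_values, control_values) -> float:
    """Rank (Mann-Whitney) AUC estimator with midrank tie handling."""
    cases = np.asarray(case_values, dtype=float)
    controls = np.asarray(control_values, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise DataError("both classes must be present")
    combined = np.concatenate([cases, controls])
    ranks = stats.rankdata(combined, method="average")
    r_cases = ranks[: cases.size].sum()
    u = r_cases - cases.size * (cases.size + 1) / 2.0
    return float(u / (cases.size * controls.size))


def _hanley_mcneil_ci(auc: float, n1: int, n0: int) -> tuple[float, float]:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)
    ) / (n1 * n0)
    se = np.sqrt(max(var, 0.0))
    return (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))


def fitted_risk(
    data: pd.DataFrame,
    outcome: str = "obesity",
    predictors=("score", "age", "age2", "sex_male"),
) -> tuple[np.ndarray, np.ndarray]:
    """In-sample fitted probabilities and labels from the logistic model."""
    df, col, kind = _outcome_frame(data, outcome)
    if kind != "logistic":
        raise DataError("fitted_risk requires a binary outcome")
    df = df.dropna(subset=[col, *predictors])
    model = fit_logistic(col, list(predictors), df)
    X = np.column_stack(
        [np.ones(len(df))] + [df[t].to_numpy(dtype=float) for t in predictors]
    )
    eta = X @ model.params["estimate"].to_numpy()
    prob = 1.0 / (1.0 + np.exp(-eta))
    labels = df[col].to_numpy(dtype=float)
    return prob, labels


def roc_auc(
    data: pd.DataFrame,
    outcome: str = "obesity",
    predictors=("score", "age", "age2", "sex_male"),
    stratum: str = "",
) -> AucResult:
    """AUC of the fitted logistic risk, with a Hanley-McNeil normal CI."""
    prob, labels = fitted_risk(data, outcome, predictors)
    return auc_from_scores(prob, labels, stratum)


def auc_from_scores(scores, labels, stratum: str = "") -> AucResult:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    if cases.size == 0 or controls.size == 0:
        raise DataError("both classes must be present")
    auc = auc_mann_whitney(cases, controls)
    lo, hi = _hanley_mcneil_ci(auc, cases.size, controls.size)
    return AucResult(
        auc=auc,
        ci_low=min(lo, auc),
        ci_high=max(hi, auc),
        n_cases=int(cases.size),
        n_controls=int(controls.size),
        stratum=stratum,
    )


def roc_points(scores, labels) -> pd.DataFrame:
    """Empirical ROC curve points (fpr, tpr) sorted by threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # collapse tied thresholds
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(1 - y)[distinct]
    tpr = np.r_[0.0, tp / y.sum()]
    fpr = np.r_[0.0, fp / (1 - y).sum()]
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def compare_auc(
    scores_a,
    labels_a,
    scores_b,
    labels_b,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Bootstrap contrast of two strata's AUCs.

    Case/control-stratified resampling of (score, label) pairs within
    each stratum; the two-sided p comes from the bootstrap distribution
    of the AUC difference crossing zero.  Each stratum's resampling
    stream is seeded from the run seed plus a digest of its own data,
    so swapping the strata exactly negates the difference distribution.
    """
    import zlib

    if n_boot < 100:
        raise ConfigurationError("n_boot must be >= 100")
    auc_a = auc_from_scores(scores_a, labels_a).auc
    auc_b = auc_from_scores(scores_b, labels_b).auc

    def _split(scores, labels):
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels, dtype=float)
        return scores[labels == 1], scores[labels == 0]

    def _stratum_rng(cases, controls):
        digest = zlib.crc32(cases.tobytes() + controls.tobytes())
        return np.random.default_rng([seed, digest])

    ca, na = _split(scores_a, labels_a)
    cb, nb = _split(scores_b, labels_b)
    rng_a = _stratum_rng(ca, na)
    rng_b = _stratum_rng(cb, nb)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        ra = auc_mann_whitney(
            rng_a.choice(ca, ca.size, replace=True),
            rng_a.choice(na, na.size, replace=True),
        )
        rb = auc_mann_whitney(
            rng_b.choice(cb, cb.size, replace=True),
            rng_b.choice(nb, nb.size, replace=True),
        )
        diffs[b] = ra - rb
    p_low = (diffs <= 0).mean()
    p_high = (diffs >= 0).mean()
    p = min(1.0, 2.0 * min(p_low, p_high))
    lo, hi = np.quantile(diffs, [0.025, 0.975])
    return {
        "auc_a": auc_a,
        "auc_b": auc_b,
        "difference": auc_a - auc_b,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "p": float(p),
        "n_boot": n_boot,
    }
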