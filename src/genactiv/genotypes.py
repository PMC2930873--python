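"""Genotype I/O, quality control, and predisposition-score computation.

Dosages count copies of the BMI-increasing allele (0/1/2); missing calls
are NaN.  The score is the unweighted sum over the 12-SNP panel, with
missing genotypes mean-substituted for subjects missing at most three
SNPs; subjects missing more have no score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .snps import SnpSpec

MAX_SUBSTITUTED = 3


@dataclass
class GenotypePanel:
    """Subject x SNP dosage matrix with per-SNP QC statistics.

    ``dosage`` is a float DataFrame indexed by subject id with one column
    per SNP; entries are 0.0/1.0/2.0 or NaN (missing).  ``true_dosage``
    is set by the simulator and holds the pre-missingness matrix; it is
    never populated when reading real data.
    """

    dosage: pd.DataFrame
    snp_specs: tuple[SnpSpec, ...]
    true_dosage: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        vals = self.dosage.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise DataError(
                f"dosage out of {{0,1,2,NA}} at subject "
                f"{self.dosage.index[i]!r}, SNP {self.dosage.columns[j]!r}"
            )
        spec_ids = [s.snp_id for s in self.snp_specs]
        if list(self.dosage.columns) != spec_ids:
            raise DataError(
                f"dosage columns {list(self.dosage.columns)} do not match "
                f"SNP specs {spec_ids}"
            )

    @property
    def subject_ids(self) -> list[str]:
        return list(self.dosage.index)

    @property
    def n_subjects(self) -> int:
        return len(self.dosage)

    @property
    def call_rate(self) -> pd.Series:
        """Per-SNP fraction of non-missing calls."""
        return self.dosage.notna().mean(axis=0)

    @property
    def hwe_p(self) -> pd.Series:
        """Per-SNP Hardy-Weinberg chi-square p-value."""
        out = {}
        for snp in self.dosage.columns:
            col = self.dosage[snp].dropna()
            n2 = int((col == 2).sum())
            n1 = int((col == 1).sum())
            n0 = int((col == 0).sum())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", MonomorphicSnpWarning)
                out[snp] = hwe_test(n2, n1, n0)
        return pd.Series(out)

    def subset_subjects(self, subject_ids) -> "GenotypePanel":
        """Restrict the panel to ``subject_ids`` (preserving their order)."""
        missing = set(subject_ids) - set(self.dosage.index)
        if missing:
            raise DataError(f"subjects absent from panel: {sorted(missing)[:5]}")
        true = (
            self.true_dosage.loc[list(subject_ids)]
            if self.true_dosage is not None
            else None
        )
        return GenotypePanel(
            self.dosage.loc[list(subject_ids)], self.snp_specs, true
        )


@dataclass(frozen=True)
class ScoreResult:
    """Predisposition score for one subject with substitution bookkeeping."""

    subject_id: str
    score: float  # NaN when not complete
    n_missing: int
    n_substituted: int
    complete: bool


class MonomorphicSnpWarning(UserWarning):
    """Raised by hwe_test on a monomorphic SNP (p forced to 1)."""


def hwe_test(n_hom_risk: int, n_het: int, n_hom_other: int) -> float:
    """Hardy-Weinberg equilibrium chi-square goodness-of-fit p-value.

    One degree of freedom, no continuity correction.  Expected genotype
    counts derive from the sample allele frequency.  A monomorphic SNP
    has no test: p = 1 is returned with :class:`MonomorphicSnpWarning`.
    """
    counts = np.array([n_hom_risk, n_het, n_hom_other], dtype=float)
    if (counts < 0).any():
        raise DataError("genotype counts must be non-negative")
    n = counts.sum()
    if n <= 0:
        raise DataError("at least one genotyped subject required")
    p_hat = (2 * n_hom_risk + n_het) / (2 * n)
    if p_hat in (0.0, 1.0):
        warnings.warn(
            "monomorphic SNP: Hardy-Weinberg test undefined, returning p=1",
            MonomorphicSnpWarning,
            stacklevel=2,
        )
        return 1.0
    q_hat = 1.0 - p_hat
    expected = n * np.array([p_hat**2, 2 * p_hat * q_hat, q_hat**2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def read_genotype_table(path, snp_specs) -> GenotypePanel:
    """Read the tab-separated dosage table (cells in {0,1,2,NA}).

    The header's SNP columns must match ``snp_specs`` as a set; column
    order in the file is irrelevant (output columns follow the specs).
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.columns[0] != "subject_id":
        raise DataError(f"{path}: first column must be 'subject_id'")
    spec_ids = [s.snp_id for s in snp_specs]
    file_snps = list(raw.columns[1:])
    unknown = set(file_snps) - set(spec_ids)
    if unknown:
        raise DataError(f"{path}: unknown SNP column(s) {sorted(unknown)}")
    absent = set(spec_ids) - set(file_snps)
    if absent:
        raise DataError(f"{path}: SNP column(s) missing {sorted(absent)}")

    data = {}
    for snp in spec_ids:
        col = raw[snp].str.strip()
        bad = ~col.isin(["0", "1", "2", "NA"])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataError(
                f"{path}: invalid dosage {col.iloc[row]!r} at row "
                f"{row + 2} (subject {raw['subject_id'].iloc[row]!r}), "
                f"column {snp!r}"
            )
        data[snp] = col.mask(col == "NA").astype(float).to_numpy()
    dosage = pd.DataFrame(data, index=raw["subject_id"].tolist())
    dosage.index.name = "subject_id"
    return GenotypePanel(dosage, tuple(snp_specs))


def read_vcf(path, snp_specs) -> GenotypePanel:
    """Read dosages from a VCF with GT fields.

    The risk allele may be either REF or ALT; orientation is resolved per
    record by matching the spec's two alleles against REF/ALT.  ``./.``
    becomes missing.  Requires :mod:`cyvcf2`.
    """
    from cyvcf2 import VCF

    by_id = {s.snp_id: s for s in snp_specs}
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: dict[str, np.ndarray] = {}
    for variant in vcf:
        spec = by_id.get(variant.ID)
        if spec is None:
            continue
        alleles = [variant.REF] + list(variant.ALT)
        if spec.risk_allele not in alleles or spec.other_allele not in alleles:
            raise DataError(
                f"{variant.ID}: VCF alleles {alleles} do not contain "
                f"{spec.risk_allele}/{spec.other_allele}"
            )
        risk_idx = alleles.index(spec.risk_allele)
        gt = np.asarray(variant.genotypes)[:, :2]  # n_samples x 2
        miss = (gt < 0).any(axis=1)
        dose = (gt == risk_idx).sum(axis=1).astype(float)
        dose[miss] = np.nan
        rows[variant.ID] = dose
    absent = [s.snp_id for s in snp_specs if s.snp_id not in rows]
    if absent:
        raise DataError(f"{path}: SNP(s) absent from VCF: {absent}")
    dosage = pd.DataFrame(
        {s.snp_id: rows[s.snp_id] for s in snp_specs}, index=samples
    )
    dosage.index.name = "subject_id"
    return GenotypePanel(dosage, tuple(snp_specs))


def qc_filter(
    panel: GenotypePanel,
    call_rate_min: float = 0.95,
    hwe_p_min: float = 0.05,
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Drop SNPs failing call-rate or Hardy-Weinberg thresholds.

    Both thresholds are strict: a SNP passes only with call rate
    strictly above ``call_rate_min`` AND HWE p strictly above
    ``hwe_p_min``.  Returns the filtered panel and a QC report with one
    row per SNP (snp_id, call_rate, hwe_p, pass, reason).
    """
    call = panel.call_rate
    hwe = panel.hwe_p
    records = []
    keep = []
    for spec in panel.snp_specs:
        snp = spec.snp_id
        reasons = []
        if not call[snp] > call_rate_min:
            reasons.append(f"call_rate<={call_rate_min:g}")
        if not hwe[snp] > hwe_p_min:
            reasons.append(f"hwe_p<={hwe_p_min:g}")
        passed = not reasons
        if passed:
            keep.append(spec)
        records.append(
            {
                "snp_id": snp,
                "call_rate": call[snp],
                "hwe_p": hwe[snp],
                "pass": passed,
                "reason": ";".join(reasons),
            }
        )
    report = pd.DataFrame.from_records(records)
    if not keep:
        raise DataError("all SNPs failed QC; empty panel")
    kept_ids = [s.snp_id for s in keep]
    true = panel.true_dosage[kept_ids] if panel.true_dosage is not None else None
    filtered = GenotypePanel(panel.dosage[kept_ids], tuple(keep), true)
    return filtered, report


def compute_scores(panel: GenotypePanel) -> list[ScoreResult]:
    """Sum risk-allele dosages into the predisposition score.

    Missing genotypes are substituted by that SNP's mean dosage among
    genotyped subjects of this panel, for subjects missing at most
    :data:`MAX_SUBSTITUTED` SNPs; subjects missing more are flagged
    incomplete and carry no score.
    """
    dosage = panel.dosage
    n_called = dosage.notna().sum(axis=0)
    if (n_called == 0).any():
        bad = list(n_called.index[n_called == 0])
        raise DataError(f"SNP(s) with zero non-missing calls: {bad}")
    snp_means = dosage.mean(axis=0)
    n_missing = dosage.isna().sum(axis=1)
    observed_sum = dosage.sum(axis=1)  # skips NaN
    substituted_sum = dosage.isna().to_numpy() @ snp_means.to_numpy()
    score = observed_sum + substituted_sum
    complete = n_missing <= MAX_SUBSTITUTED
    results = []
    for sid in dosage.index:
        nm = int(n_missing[sid])
        comp = bool(complete[sid])
        results.append(
            ScoreResult(
                subject_id=sid,
                score=float(score[sid]) if comp else float("nan"),
                n_missing=nm,
                n_substituted=nm if comp else 0,
                complete=comp,
            )
        )
    return results


def scores_frame(results: list[ScoreResult]) -> pd.DataFrame:
    """Tabulate :func:`compute_scores` output, indexed by subject id."""
    return pd.DataFrame(
        {
            "score": [r.score for r in results],
            "n_missing": [r.n_missing for r in results],
            "n_substituted": [r.n_substituted for r in results],
            "complete": [r.complete for r in results],
        },
        index=pd.Index([r.subject_id for r in results], name="subject_id"),
    )
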