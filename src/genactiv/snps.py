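"""Susceptibility-locus definitions.

The default panel lists the 12 BMI-associated SNPs used to build the
predisposition score.  Allele frequencies are configuration values used
only by the cohort simulator; with the defaults below the expected score
(2 x sum of frequencies) is close to 11.3.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError, DataError

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SnpSpec:
    """One susceptibility locus.

    Attributes
    ----------
    snp_id : str
        rs identifier.
    risk_allele : str
        The BMI-increasing allele; dosage counts copies of this allele.
    other_allele : str
        The alternative allele.
    risk_allele_frequency : float
        Population frequency of the risk allele (simulation only).
    """

    snp_id: str
    risk_allele: str
    other_allele: str
    risk_allele_frequency: float

    def __post_init__(self) -> None:
        if self.risk_allele not in _BASES or self.other_allele not in _BASES:
            raise ConfigurationError(
                f"{self.snp_id}: alleles must be single bases, got "
                f"{self.risk_allele!r}/{self.other_allele!r}"
            )
        if self.risk_allele == self.other_allele:
            raise ConfigurationError(
                f"{self.snp_id}: risk and other allele must differ"
            )
        if not 0.0 < self.risk_allele_frequency < 1.0:
            raise ConfigurationError(
                f"{self.snp_id}: risk_allele_frequency must lie in (0, 1), "
                f"got {self.risk_allele_frequency}"
            )


#: Default 12-SNP panel (nearby gene in the trailing comment).
DEFAULT_SNP_SPECS: tuple[SnpSpec, ...] = (
    SnpSpec("rs3101336", "C", "T", 0.61),   # NEGR1
    SnpSpec("rs10913469", "C", "T", 0.20),  # SEC16B
    SnpSpec("rs6548238", "C", "T", 0.84),   # TMEM18
    SnpSpec("rs7647305", "C", "T", 0.79),   # ETV5
    SnpSpec("rs10938397", "G", "A", 0.44),  # GNPDA2
    SnpSpec("rs925946", "T", "G", 0.28),    # BDNF
    SnpSpec("rs10838738", "G", "A", 0.34),  # MTCH2
    SnpSpec("rs7132908", "A", "G", 0.39),   # FAIM2
    SnpSpec("rs7498665", "G", "A", 0.38),   # SH2B1
    SnpSpec("rs1121980", "A", "G", 0.43),   # FTO
    SnpSpec("rs17782313", "C", "T", 0.26),  # MC4R
    SnpSpec("rs368794", "T", "C", 0.69),    # KCTD15
)


def write_snp_sheet(specs, path) -> None:
    """Write a tab-separated SNP definition sheet (id, risk, other, freq)."""
    with open(path, "w") as fh:
        fh.write("snp_id\trisk_allele\tother_allele\trisk_allele_frequency\n")
        for s in specs:
            fh.write(
                f"{s.snp_id}\t{s.risk_allele}\t{s.other_allele}\t"
                f"{s.risk_allele_frequency:.6g}\n"
            )


def read_snp_sheet(path) -> tuple[SnpSpec, ...]:
    """Read a SNP definition sheet written by :func:`write_snp_sheet`."""
    specs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["snp_id", "risk_allele", "other_allele"]:
            raise DataError(f"unexpected SNP sheet header in {path}: {header}")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            freq = float(parts[3]) if len(parts) > 3 else 0.5
            specs.append(SnpSpec(parts[0], parts[1], parts[2], freq))
    return tuple(specs)
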