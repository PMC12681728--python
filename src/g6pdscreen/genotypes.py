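"""X-linked zygosity coding, allele-frequency estimation and Hardy-Weinberg
expectations for a single variant (default rs1050828, G6PD p.Val68Met).

G6PD sits on chromosome X: males are hemizygous (0 or 1 variant allele),
females carry 0, 1 or 2.  Under Hardy-Weinberg equilibrium at allele
frequency q the male hemizygote frequency is q, female heterozygotes
2q(1-q) and female homozygotes q^2 — identities used both as simulator
generative law and as consistency checks on observed cohort frequencies.

Genotype input is either a tidy CSV (participant_id, sex, allele_count) or
a single-variant VCF slice.  Both haploid ("1") and homozygous-diploid
("1/1") male encodings occur in real X-chromosome VCFs and both are
accepted; a male heterozygous diploid call is a data error and is rejected
loudly rather than silently coerced.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Sex",
    "ZygosityLabel",
    "Zygosity",
    "ZygosityFrequencies",
    "InvalidGenotypeError",
    "VariantNotFoundError",
    "zygosity_from_allele_count",
    "read_variant_genotypes",
    "read_genotype_csv",
    "estimate_allele_frequency",
    "hwe_expected_frequencies",
]


class InvalidGenotypeError(ValueError):
    """A genotype call incompatible with X-linkage (e.g. male '0/1')."""


class VariantNotFoundError(LookupError):
    """The requested variant ID is absent from the VCF."""


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"

    @classmethod
    def parse(cls, value) -> "Sex":
        if isinstance(value, Sex):
            return value
        s = str(value).strip().lower()
        if s in ("male", "m", "1"):
            return cls.MALE
        if s in ("female", "f", "2"):
            return cls.FEMALE
        raise ValueError(f"unrecognised sex code: {value!r}")


class ZygosityLabel(str, enum.Enum):
    REF_HEMIZYGOTE = "ref_hemizygote"
    VAR_HEMIZYGOTE = "var_hemizygote"
    REF_HOMOZYGOTE = "ref_homozygote"
    HETEROZYGOTE = "heterozygote"
    VAR_HOMOZYGOTE = "var_homozygote"


_MALE_LABELS = {0: ZygosityLabel.REF_HEMIZYGOTE, 1: ZygosityLabel.VAR_HEMIZYGOTE}
_FEMALE_LABELS = {
    0: ZygosityLabel.REF_HOMOZYGOTE,
    1: ZygosityLabel.HETEROZYGOTE,
    2: ZygosityLabel.VAR_HOMOZYGOTE,
}


@dataclass(frozen=True)
class Zygosity:
    sex: Sex
    variant_allele_count: int
    label: ZygosityLabel


def zygosity_from_allele_count(sex, count: int) -> Zygosity:
    """Deterministic zygosity label from (sex, variant allele count).

    Males admit counts {0, 1}; females {0, 1, 2}.  Anything else (male
    diploidy, negative counts) raises :class:`InvalidGenotypeError`.
    """
    sex = Sex.parse(sex)
    count = int(count)
    table = _MALE_LABELS if sex is Sex.MALE else _FEMALE_LABELS
    if count not in table:
        raise InvalidGenotypeError(
            f"allele count {count} invalid for sex {sex.value} on chromosome X"
        )
    return Zygosity(sex=sex, variant_allele_count=count, label=table[count])


def read_variant_genotypes(
    vcf_path: str,
    variant_id: str,
    samples_sex: Mapping[str, Sex | str],
) -> dict[str, int]:
    """Extract variant-allele counts for one variant from a VCF.

    Haploid male calls ("0", "1") map directly; diploid male calls are
    accepted only when homozygous-coded ("0/0" -> 0, "1/1" -> 1), the
    other common X-chromosome dialect.  Missing calls are omitted from the
    returned mapping.  Raises :class:`VariantNotFoundError` if no record's
    ID matches, and :class:`InvalidGenotypeError` (naming the sample) for a
    male heterozygous diploid call.
    """
    import pysam

    counts: dict[str, int] = {}
    found = False
    with pysam.VariantFile(vcf_path) as vcf:
        for rec in vcf:
            if rec.id != variant_id:
                continue
            found = True
            for sample, call in rec.samples.items():
                alleles = [a for a in call["GT"] if a is not None]
                if not alleles:
                    continue  # missing call
                sex = Sex.parse(samples_sex[sample])
                n_var = sum(1 for a in alleles if a != 0)
                if sex is Sex.MALE and len(alleles) == 2:
                    if n_var == 1:
                        raise InvalidGenotypeError(
                            f"male sample {sample!r} has heterozygous diploid "
                            f"call at {variant_id} on chromosome X"
                        )
                    n_var = n_var // 2  # homozygous-diploid dialect
                counts[sample] = n_var
            break
    if not found:
        raise VariantNotFoundError(f"variant {variant_id!r} not found in {vcf_path}")
    return counts


def read_genotype_csv(path) -> pd.DataFrame:
    """Read a tidy genotype table (participant_id, sex, allele_count, ...).

    Returns the table with a validated ``zygosity`` column added.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    required = {"participant_id", "sex", "allele_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"genotype table missing columns: {sorted(missing)}")
    df = df.copy()
    df["sex"] = df["sex"].map(Sex.parse)
    df["zygosity"] = [
        zygosity_from_allele_count(s, c).label
        for s, c in zip(df["sex"], df["allele_count"])
    ]
    return df


def estimate_allele_frequency(zygosities: Iterable[Zygosity]) -> float:
    """Allele frequency q = variant alleles / total alleles.

    Males contribute one X allele each, females two.
    """
    var = tot = 0
    for z in zygosities:
        ploidy = 1 if z.sex is Sex.MALE else 2
        var += z.variant_allele_count
        tot += ploidy
    if tot == 0:
        raise ValueError("cannot estimate allele frequency from an empty collection")
    return var / tot


@dataclass(frozen=True)
class ZygosityFrequencies:
    """Expected zygosity-class proportions under X-linked HWE at frequency q."""

    q: float
    male_hemizygote: float
    female_heterozygote: float
    female_homozygote: float


def hwe_expected_frequencies(q: float) -> ZygosityFrequencies:
    """X-linked Hardy-Weinberg expectations: (q, 2q(1-q), q^2)."""
    q = float(q)
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"allele frequency q must lie in [0, 1], got {q}")
    return ZygosityFrequencies(
        q=q,
        male_hemizygote=q,
        female_heterozygote=2.0 * q * (1.0 - q),
        female_homozygote=q * q,
    )
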