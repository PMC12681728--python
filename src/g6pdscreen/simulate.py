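"""Synthetic EHR-style cohort generator.

The real cohorts behind this kind of screen are access-controlled
biobanks, so every pipeline stage is exercised on generated data carrying
the statistical structure the analysis assumes:

* X-linked genotypes at allele frequency ``q`` under Hardy-Weinberg
  equilibrium (male counts Bernoulli(q), female Binomial(2, q));
* a glycation relationship between each participant's habitual mean
  glucose and HbA1c, inverted from the eAG line, with a downward HbA1c
  shift in hemizygotes/homozygotes (shortened red-cell lifespan) and a
  partial, Beta(2,2)-distributed shift in heterozygotes (X-inactivation
  mosaicism — each heterozygote expresses the deficient allele in a
  random fraction of her erythroid precursors);
* a downward RDW shift in the same groups, attenuated by the same
  per-participant X-inactivation fraction;
* one to several draws per participant, fasting or not, with non-fasting
  draws carrying a Gamma-distributed post-prandial glucose bump;
* for diabetics, an exponential time to retinopathy whose hazard is
  multiplied by a configurable ratio when the participant is a
  deficiency-affected carrier, with uniform censoring.

Effect magnitudes are this generator's own calibration (the study the
structure emulates reports directions, not sizes); they are recorded in
the fixture manifest so no downstream consumer mistakes them for
observed quantities.  Everything is reproducible from the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .glycemic import EAG_INTERCEPT, EAG_SLOPE

__all__ = [
    "SyntheticConfig",
    "CohortBundle",
    "generate_cohort",
    "write_fixture",
    "load_fixture",
]

VARIANT_ID = "rs1050828"
VARIANT_CHROM = "X"
VARIANT_POS = 154536002
VARIANT_REF = "C"
VARIANT_ALT = "T"


@dataclass(frozen=True)
class SyntheticConfig:
    """All generative parameters; defaults are the package's calibrated
    study conditions (see docs/methods.md for rationale)."""

    n_participants: int = 4000
    female_fraction: float = 0.5
    q: float = 0.12  # variant allele frequency
    glucose_mean_nondiabetic: float = 90.0  # mg/dL
    glucose_sd_nondiabetic: float = 8.0
    glucose_mean_diabetic: float = 150.0
    glucose_sd_diabetic: float = 30.0
    diabetes_prevalence: float = 0.3
    hba1c_shift_full: float = -0.75  # % units, hemi-/homozygotes
    hba1c_noise_sd: float = 0.25
    rdw_mean: float = 13.9
    rdw_sd: float = 1.1
    rdw_shift_full: float = -1.8
    rdw_noise_sd: float = 0.5
    draws_min: int = 1
    draws_max: int = 4
    fasting_probability: float = 0.6
    nonfasting_bump_mean: float = 40.0  # mg/dL, Gamma(shape=2)
    draw_glucose_noise_sd: float = 10.0
    retinopathy_base_hazard: float = 0.006  # per year
    deficiency_hazard_ratio: float = 1.4
    censor_min: float = 5.0  # years
    censor_max: float = 25.0
    n_pseudo_cohorts: int = 3
    seed: int = 0

    def validate(self) -> None:
        bad = []
        for name in ("female_fraction", "q", "diabetes_prevalence", "fasting_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                bad.append(f"{name}={v} not in [0,1]")
        for name in (
            "glucose_sd_nondiabetic", "glucose_sd_diabetic", "hba1c_noise_sd",
            "rdw_sd", "rdw_noise_sd", "draw_glucose_noise_sd",
        ):
            if getattr(self, name) <= 0:
                bad.append(f"{name} must be positive")
        if self.n_participants < 0:
            bad.append("n_participants must be >= 0")
        if not 1 <= self.draws_min <= self.draws_max:
            bad.append("need 1 <= draws_min <= draws_max")
        if self.retinopathy_base_hazard <= 0 or self.deficiency_hazard_ratio <= 0:
            bad.append("hazards must be positive")
        if not 0 < self.censor_min < self.censor_max:
            bad.append("need 0 < censor_min < censor_max")
        if self.n_pseudo_cohorts < 1:
            bad.append("n_pseudo_cohorts must be >= 1")
        if bad:
            raise ValueError("invalid synthetic config: " + "; ".join(bad))


@dataclass
class CohortBundle:
    participants: pd.DataFrame  # id, sex, diabetes, g6pd_dx, cohort_label
    draws: pd.DataFrame
    genotypes: pd.DataFrame  # id, sex, allele_count (+ participant attrs)
    survival: pd.DataFrame
    config: SyntheticConfig


def _truncate(arr: np.ndarray, lo: float = 0.1) -> np.ndarray:
    return np.maximum(arr, lo)


def generate_cohort(config: SyntheticConfig = SyntheticConfig()) -> CohortBundle:
    """Draw a full cohort (participants, lab draws, genotypes, survival)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants

    pid = np.array([f"S{i:06d}" for i in range(n)])
    female = rng.random(n) < config.female_fraction
    sex = np.where(female, "female", "male")
    allele_count = np.where(
        female,
        rng.binomial(2, config.q, size=n),
        rng.binomial(1, config.q, size=n),
    )
    deficient = (~female & (allele_count == 1)) | (female & (allele_count == 2))
    het = female & (allele_count == 1)

    # X-inactivation fraction: full effect for hemi-/homozygotes, Beta(2,2)
    # mosaic fraction for heterozygotes, zero otherwise.
    shift_frac = np.zeros(n)
    shift_frac[deficient] = 1.0
    shift_frac[het] = rng.beta(2.0, 2.0, size=int(het.sum()))

    diabetic = rng.random(n) < config.diabetes_prevalence
    mean_glucose = np.where(
        diabetic,
        rng.normal(config.glucose_mean_diabetic, config.glucose_sd_diabetic, n),
        rng.normal(config.glucose_mean_nondiabetic, config.glucose_sd_nondiabetic, n),
    )
    mean_glucose = _truncate(mean_glucose, 40.0)

    # inverse glycation: the HbA1c a normal-lifespan red cell would show
    hba1c_true = (mean_glucose - EAG_INTERCEPT) / EAG_SLOPE
    hba1c_true = hba1c_true + shift_frac * config.hba1c_shift_full
    rdw_true = rng.normal(config.rdw_mean, config.rdw_sd, n)
    rdw_true = rdw_true + shift_frac * config.rdw_shift_full

    cohort_label = np.array(
        [f"cohort_{i + 1}" for i in rng.integers(0, config.n_pseudo_cohorts, n)]
    )

    participants = pd.DataFrame(
        {
            "participant_id": pid,
            "sex": sex,
            "diabetes": diabetic,
            "g6pd_dx": np.zeros(n, dtype=bool),  # near-universal underdiagnosis
            "cohort_label": cohort_label,
        }
    )
    genotypes = pd.DataFrame(
        {
            "participant_id": pid,
            "sex": sex,
            "allele_count": allele_count.astype(int),
            "diabetes": diabetic,
            "g6pd_dx": participants["g6pd_dx"],
            "cohort_label": cohort_label,
        }
    )

    n_draws = rng.integers(config.draws_min, config.draws_max + 1, size=n)
    rows = np.repeat(np.arange(n), n_draws)
    m = rows.size
    fasting = rng.random(m) < config.fasting_probability
    bump = np.where(
        fasting, 0.0, rng.gamma(2.0, config.nonfasting_bump_mean / 2.0, size=m)
    )
    draw_glucose = _truncate(
        mean_glucose[rows] + bump + rng.normal(0.0, config.draw_glucose_noise_sd, m),
        10.0,
    )
    draw_hba1c = _truncate(
        hba1c_true[rows] + rng.normal(0.0, config.hba1c_noise_sd, m), 0.1
    )
    draw_rdw = _truncate(rdw_true[rows] + rng.normal(0.0, config.rdw_noise_sd, m), 0.1)
    day_offsets = rng.integers(0, 3653, size=m)  # ~10 years of calendar spread
    base = pd.Timestamp("2008-01-01")
    draws = pd.DataFrame(
        {
            "participant_id": pid[rows],
            "draw_date": (base + pd.to_timedelta(day_offsets, unit="D")).strftime(
                "%Y-%m-%d"
            ),
            "glucose": draw_glucose,
            "hba1c": draw_hba1c,
            "rdw": draw_rdw,
        }
    )

    # Survival: diabetics only; hazard elevated for deficiency-affected.
    d_idx = np.nonzero(diabetic)[0]
    nd = d_idx.size
    hazard = config.retinopathy_base_hazard * np.where(
        deficient[d_idx], config.deficiency_hazard_ratio, 1.0
    )
    event_time = rng.exponential(1.0 / hazard)
    censor = rng.uniform(config.censor_min, config.censor_max, nd)
    time_years = np.minimum(event_time, censor)
    event = event_time <= censor
    survival = pd.DataFrame(
        {
            "participant_id": pid[d_idx],
            "time_years": time_years,
            "event": event,
            "age": np.clip(rng.normal(58.0, 10.0, nd), 20.0, 90.0),
            "sex_male": (~female[d_idx]).astype(int),
            "smoking": (rng.random(nd) < 0.4).astype(int),
            "diabetes_duration": rng.uniform(0.0, 15.0, nd),
            "ldl": np.clip(rng.normal(110.0, 30.0, nd), 30.0, 300.0),
            "hypertension": (rng.random(nd) < 0.5).astype(int),
        }
    )
    return CohortBundle(
        participants=participants,
        draws=draws,
        genotypes=genotypes,
        survival=survival,
        config=config,
    )


def _write_vcf(genotypes: pd.DataFrame, path: Path) -> None:
    """Single-variant VCF equivalent of the genotype CSV (male calls
    haploid, female diploid)."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    header.add_line(f"##contig=<ID={VARIANT_CHROM},length=156040895>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in genotypes["participant_id"]:
        header.add_sample(str(s))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        rec = vcf.new_record(
            contig=VARIANT_CHROM,
            start=VARIANT_POS - 1,
            stop=VARIANT_POS,
            alleles=(VARIANT_REF, VARIANT_ALT),
            id=VARIANT_ID,
        )
        for s, sex, count in zip(
            genotypes["participant_id"], genotypes["sex"], genotypes["allele_count"]
        ):
            if str(sex) == "male":
                rec.samples[str(s)]["GT"] = (int(count),)
            else:
                c = int(count)
                rec.samples[str(s)]["GT"] = (1, 1) if c == 2 else ((0, 1) if c == 1 else (0, 0))
        vcf.write(rec)


def write_fixture(bundle: CohortBundle, directory) -> dict[str, Path]:
    """Write the fixture bundle: labs.csv, genotypes.csv, genotypes.vcf,
    survival.csv and a manifest recording the config and seed.

    Participant attributes travel in genotypes.csv, so the bundle is four
    data files plus the manifest.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "labs": directory / "labs.csv",
        "genotypes_csv": directory / "genotypes.csv",
        "genotypes_vcf": directory / "genotypes.vcf",
        "survival": directory / "survival.csv",
        "manifest": directory / "manifest.json",
    }
    bundle.draws.to_csv(paths["labs"], index=False)
    bundle.genotypes.to_csv(paths["genotypes_csv"], index=False)
    _write_vcf(bundle.genotypes, paths["genotypes_vcf"])
    bundle.survival.to_csv(paths["survival"], index=False)
    manifest = {
        "generator": "g6pdscreen.simulate",
        "seed": bundle.config.seed,
        "config": dataclasses.asdict(bundle.config),
        "n_participants": int(len(bundle.participants)),
        "n_draws": int(len(bundle.draws)),
        "n_survival": int(len(bundle.survival)),
        "variant": {
            "id": VARIANT_ID,
            "chrom": VARIANT_CHROM,
            "pos": VARIANT_POS,
            "ref": VARIANT_REF,
            "alt": VARIANT_ALT,
        },
        "note": (
            "Fully synthetic cohort; effect sizes are generator calibration, "
            "not observed estimates."
        ),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths


def load_fixture(directory) -> CohortBundle:
    """Read a written fixture back into a bundle.

    The participants table is reconstructed from genotypes.csv (where the
    participant attributes travel); the stored config is re-hydrated from
    the manifest.
    """
    directory = Path(directory)
    genotypes = pd.read_csv(
        directory / "genotypes.csv", dtype={"participant_id": str}
    )
    draws = pd.read_csv(directory / "labs.csv", dtype={"participant_id": str})
    survival = pd.read_csv(directory / "survival.csv", dtype={"participant_id": str})
    manifest = json.loads((directory / "manifest.json").read_text())
    participants = genotypes.drop(columns=["allele_count"]).copy()
    return CohortBundle(
        participants=participants,
        draws=draws,
        genotypes=genotypes,
        survival=survival,
        config=SyntheticConfig(**manifest["config"]),
    )
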