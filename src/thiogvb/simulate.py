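"""Synthetic pediatric-ALL cohort generator.

Emulates the statistical structure of a two-hospital thiopurine
pharmacogenomic study: per-variant Hardy-Weinberg genotypes at configured
allele frequencies, star-allele diplotypes for the two canonical thiopurine
genes (NUDT15, TPMT), and a last-cycle 6-MP dose-intensity-percentage (DIP)
phenotype built from a Gaussian baseline plus per-variant genetic effects and
age/sex covariate effects, truncated below at 0 (real cohorts include DIP
values above 100%, so no upper cap is imposed).

The defaults encode the study conditions the analysis targets: a CRIM1
missense variant (rs3821169, SIFT 0, CADD 25.3) at East-Asian allele
frequency 0.255 with a recessive effect of -21.09 DIP units, a noncarrier
DIP baseline of 71.99 +/- 27.0, age 7.0 +/- 4.5 years, ~57% male, a ~24%
minority of NUDT15/TPMT non-normal metabolizers, and a 244/76
discovery/replication split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .variant_io import AnnotatedVariant, write_annotated_vcf

EFFECT_MODELS = ("additive", "dominant", "recessive", "null")


@dataclass
class VariantSpec:
    """Specification of one simulated variant site.

    ``effect_size`` is in DIP percentage points per coded-genotype unit under
    ``effect_model``.  When ``star_gene`` is set, genotypes are not drawn from
    Hardy-Weinberg but equal the subject's count of no-function star alleles
    of that gene, keeping variant genotypes, star diplotypes and metabolizer
    phenotypes mutually consistent.
    """

    variant_id: str
    gene: str
    allele_freq: float
    sift: float
    cadd: float
    consequence: str = "missense"
    effect_model: str = "null"
    effect_size: float = 0.0
    chrom: str = "1"
    pos: int = 1
    ref: str = "A"
    alt: str = "T"
    star_gene: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.allele_freq <= 1.0):
            raise ValueError(
                f"{self.variant_id}: allele frequency outside [0, 1]: "
                f"{self.allele_freq}")
        if not (0.0 <= self.sift <= 1.0):
            raise ValueError(f"{self.variant_id}: SIFT outside [0, 1]")
        if self.cadd < 0:
            raise ValueError(f"{self.variant_id}: CADD must be >= 0")
        if self.effect_model not in EFFECT_MODELS:
            raise ValueError(
                f"{self.variant_id}: unknown effect model {self.effect_model!r}")


def default_variant_specs() -> list[VariantSpec]:
    """The default simulated variant panel.

    One replicating CRIM1 recessive variant, one tag variant per thiopurine
    gene tied to its no-function star alleles, and a background of null
    variants spanning the SIFT/CADD filter boundaries so that the discovery
    funnel has something to discard.
    """
    specs = [
        VariantSpec("rs3821169", "CRIM1", 0.255, 0.0, 25.3,
                    effect_model="recessive", effect_size=-21.09,
                    chrom="2", pos=36583751, ref="G", alt="T"),
        VariantSpec("rs116855232", "NUDT15", 0.0, 0.0, 23.9,
                    effect_model="dominant", effect_size=-15.0,
                    chrom="13", pos=48611934, ref="C", alt="T",
                    star_gene="NUDT15"),
        VariantSpec("rs1142345", "TPMT", 0.0, 0.0, 24.2,
                    effect_model="dominant", effect_size=-15.0,
                    chrom="6", pos=18130918, ref="T", alt="C",
                    star_gene="TPMT"),
    ]
    # Null background: alternate deleterious-looking and benign annotations.
    rng_free = [
        ("rs9000001", "FSIP2", 0.10, 0.01, 26.7, "missense"),
        ("rs9000002", "IQCG", 0.21, 0.04, 26.2, "missense"),
        ("rs9000003", "SLC22A5", 0.05, 0.00, 32.0, "nonsense"),
        ("rs9000004", "TOP1MT", 0.08, 0.03, 27.1, "missense"),
        ("rs9000005", "SPAG8", 0.30, 0.20, 12.0, "missense"),
        ("rs9000006", "DPP7", 0.15, 0.60, 8.0, "missense"),
        ("rs9000007", "OR9Q2", 0.40, 0.90, 2.0, "missense"),
        ("rs9000008", "KLHL33", 0.25, 0.05, 25.0, "splice_site"),
        ("rs9000009", "INSR", 0.12, 0.01, 25.0, "frameshift"),
    ]
    for i, (vid, gene, af, sift, cadd, csq) in enumerate(rng_free):
        specs.append(VariantSpec(vid, gene, af, sift, cadd, consequence=csq,
                                 chrom=str(3 + i), pos=1000 + i))
    return specs


def default_star_allele_freqs() -> dict[str, dict[str, float]]:
    """Star-allele frequencies giving ~76% both-gene normal metabolizers
    ((1-0.11)^2 * (1-0.02)^2 ~ 0.761), matching a cohort in which roughly a
    quarter of subjects carry a no-function NUDT15 or TPMT allele."""
    return {
        "NUDT15": {"*1": 0.89, "*3": 0.095, "*9": 0.015},
        "TPMT": {"*1": 0.98, "*3C": 0.02},
    }


#: Star alleles with no function under the current guideline defaults.
DEFAULT_NO_FUNCTION_ALLELES = {
    "NUDT15": {"*2", "*3", "*9"},
    "TPMT": {"*2", "*3A", "*3B", "*3C"},
}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort."""

    n_subjects: int = 320
    seed: int = 0
    variant_specs: list[VariantSpec] = field(default_factory=default_variant_specs)
    dip_baseline_mean: float = 71.99  # noncarrier mean DIP (%)
    dip_baseline_sd: float = 27.0
    age_mean: float = 7.0  # years
    age_sd: float = 4.5
    male_fraction: float = 0.571
    age_effect: float = 0.0  # DIP units per year
    sex_effect: float = 0.0  # DIP units, male = 1
    star_allele_freqs: dict[str, dict[str, float]] = field(
        default_factory=default_star_allele_freqs)
    no_function_alleles: dict[str, set[str]] = field(
        default_factory=lambda: {g: set(a) for g, a in
                                 DEFAULT_NO_FUNCTION_ALLELES.items()})
    missing_rate: float = 0.0
    discovery_fraction: float = 244 / 320

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.dip_baseline_sd <= 0:
            raise ValueError("dip_baseline_sd must be > 0")
        if not (0.0 <= self.male_fraction <= 1.0):
            raise ValueError("male_fraction outside [0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate outside [0, 1)")
        for gene, freqs in self.star_allele_freqs.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"{gene}: star-allele frequencies sum to {total}, not 1")
            if any(f < 0 for f in freqs.values()):
                raise ValueError(f"{gene}: negative star-allele frequency")


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground-truth parameters used."""

    subjects: pd.DataFrame  # subject_id, age, sex, cohort, dip
    variants: list[AnnotatedVariant]
    diplotypes: pd.DataFrame  # subject_id, gene, allele1, allele2
    truth: dict

    @property
    def subject_ids(self) -> list[str]:
        return list(self.subjects["subject_id"])


def _code_genotype(g: np.ndarray, model: str) -> np.ndarray:
    if model == "additive":
        return g.astype(float)
    if model == "dominant":
        return (g >= 1).astype(float)
    if model == "recessive":
        return (g == 2).astype(float)
    return np.zeros_like(g, dtype=float)  # null


def simulate_genotypes(config: SimulationConfig,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw Hardy-Weinberg genotypes independently per non-star variant.

    Returns a subjects x variants DataFrame with values 0/1/2 (nan where a
    configured ``missing_rate`` knocked out a call).  Star-linked variants
    are left out; :func:`simulate_cohort` fills them from the diplotypes.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    ids = [f"S{i + 1:04d}" for i in range(n)]
    cols = {}
    for spec in config.variant_specs:
        if spec.star_gene is not None:
            continue
        g = rng.binomial(1, spec.allele_freq, size=(n, 2)).sum(axis=1)
        cols[spec.variant_id] = g.astype(float)
    frame = pd.DataFrame(cols, index=ids)
    if config.missing_rate > 0 and not frame.empty:
        mask = rng.random(frame.shape) < config.missing_rate
        frame = frame.mask(mask)
    return frame


def simulate_diplotypes(config: SimulationConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw two star alleles per gene per subject, independently, from the
    configured per-gene allele frequencies."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    ids = [f"S{i + 1:04d}" for i in range(n)]
    rows = []
    for gene, freqs in config.star_allele_freqs.items():
        known = set(config.no_function_alleles.get(gene, set())) | {"*1"}
        unknown = set(freqs) - known
        if unknown:
            raise ValueError(
                f"{gene}: star alleles absent from the function table: "
                f"{sorted(unknown)}")
        alleles = list(freqs)
        p = np.array([freqs[a] for a in alleles], dtype=float)
        draws = rng.choice(len(alleles), size=(n, 2), p=p / p.sum())
        for i, sid in enumerate(ids):
            a1, a2 = sorted(alleles[k] for k in draws[i])
            rows.append((sid, gene, a1, a2))
    return pd.DataFrame(rows, columns=["subject_id", "gene", "allele1", "allele2"])


def simulate_dip(genotypes: pd.DataFrame, covariates: pd.DataFrame,
                 config: SimulationConfig,
                 rng: np.random.Generator | None = None,
                 noise_sd: float | None = None) -> pd.Series:
    """Build the DIP phenotype from genetic effects plus covariates.

    DIP = baseline + age_effect * age + sex_effect * sex
          + sum over variants of effect_size * coded_genotype + N(0, sd),
    truncated below at 0.  Missing genotypes contribute no effect.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if not genotypes.index.equals(covariates.index):
        raise ValueError("genotype and covariate tables have mismatched "
                         "subject ids")
    sd = config.dip_baseline_sd if noise_sd is None else noise_sd
    n = len(covariates)
    dip = np.full(n, config.dip_baseline_mean, dtype=float)
    dip += config.age_effect * covariates["age"].to_numpy()
    dip += config.sex_effect * covariates["sex"].to_numpy()
    for spec in config.variant_specs:
        if spec.variant_id not in genotypes.columns:
            continue
        g = genotypes[spec.variant_id].to_numpy(dtype=float)
        code = _code_genotype(np.nan_to_num(g, nan=0.0), spec.effect_model)
        dip += spec.effect_size * code
    if sd > 0:
        dip += rng.normal(0.0, sd, size=n)
    return pd.Series(np.clip(dip, 0.0, None), index=covariates.index,
                     name="dip")


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full cohort: covariates, diplotypes, genotypes, DIP.

    Reproducible: the same config (including seed) yields a bit-identical
    cohort.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    ids = [f"S{i + 1:04d}" for i in range(n)]

    age = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), 0.0, None)
    sex = rng.binomial(1, config.male_fraction, size=n)  # male = 1
    n_disc = int(round(n * config.discovery_fraction))
    cohort = np.array(["discovery"] * n_disc +
                      ["replication"] * (n - n_disc), dtype=object)

    diplotypes = simulate_diplotypes(config, rng)
    genotypes = simulate_genotypes(config, rng)
    genotypes.index = ids

    # Star-linked variants: genotype = count of no-function alleles.
    for spec in config.variant_specs:
        if spec.star_gene is None:
            continue
        nf = config.no_function_alleles.get(spec.star_gene, set())
        sub = diplotypes[diplotypes["gene"] == spec.star_gene].set_index("subject_id")
        counts = (sub["allele1"].isin(nf).astype(int) +
                  sub["allele2"].isin(nf).astype(int))
        genotypes[spec.variant_id] = counts.reindex(ids).to_numpy(dtype=float)

    covariates = pd.DataFrame({"age": age, "sex": sex}, index=ids)
    dip = simulate_dip(genotypes, covariates, config, rng)

    subjects = pd.DataFrame({
        "subject_id": ids,
        "age": np.round(age, 2),
        "sex": np.where(sex == 1, "male", "female"),
        "cohort": cohort,
        "dip": np.round(dip.to_numpy(), 2),
    })

    variants = []
    for spec in config.variant_specs:
        g = genotypes[spec.variant_id].to_numpy(dtype=float)
        variants.append(AnnotatedVariant(
            variant_id=spec.variant_id, chrom=spec.chrom, pos=spec.pos,
            ref=spec.ref, alt=spec.alt, gene=spec.gene,
            consequence=spec.consequence, sift=spec.sift, cadd=spec.cadd,
            genotypes=g))

    truth = {
        "seed": config.seed,
        "effects": {s.variant_id: (s.effect_model, s.effect_size)
                    for s in config.variant_specs},
        "dip_baseline_mean": config.dip_baseline_mean,
        "dip_baseline_sd": config.dip_baseline_sd,
        "age_effect": config.age_effect,
        "sex_effect": config.sex_effect,
    }
    return SyntheticCohort(subjects=subjects, variants=variants,
                           diplotypes=diplotypes, truth=truth)


def write_cohort(cohort: SyntheticCohort, vcf_path: str, pheno_path: str,
                 diplotype_path: str | None = None) -> None:
    """Write the cohort as a VCF (GT + GENE/CSQ/SIFT/CADD INFO), a
    tab-separated phenotype table, and optionally a diplotype table."""
    write_annotated_vcf(cohort.variants, cohort.subject_ids, vcf_path)
    cohort.subjects.to_csv(pheno_path, sep="\t", index=False)
    if diplotype_path is not None:
        cohort.diplotypes.to_csv(diplotype_path, sep="\t", index=False)


def read_phenotypes(path: str) -> pd.DataFrame:
    """Read a phenotype TSV (subject_id, age, sex, cohort, dip)."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    required = {"subject_id", "age", "sex", "cohort", "dip"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: phenotype table lacks columns {sorted(missing)}")
    return df


def read_diplotypes(path: str) -> pd.DataFrame:
    """Read a diplotype TSV (subject_id, gene, allele1, allele2)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"subject_id", "gene", "allele1", "allele2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: diplotype table lacks columns {sorted(missing)}")
    return df
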