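"""Variant-level association testing of 6-MP dose intensity (DIP).

The clinical endpoint is the tolerated last-cycle 6-MP dose intensity
percentage.  Each variant is tested under a genetic model (additive,
dominant, recessive genotype codings) with age- and sex-adjusted ordinary
least squares; categorical analyses across nested DIP strata use Fisher's
exact test (dominant/recessive 2x2 collapses) and the Cochran-Armitage trend
test.  A two-stage screen (discovery p < 0.01 plus SIFT <= 0.05 & CADD >= 25,
then replication p < 0.05 under additive or recessive models) composes these
into the candidate-variant funnel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .variant_io import AnnotatedVariant, filter_deleterious

GENETIC_MODELS = ("additive", "dominant", "recessive")


def code_genotypes(genotypes: np.ndarray, model: str) -> np.ndarray:
    """Code raw alt-allele counts {0,1,2} under a genetic model.

    additive: 0/1/2 -> 0/1/2; dominant: carrier -> 1; recessive:
    homozygote -> 1.  nan (missing) propagates.
    """
    g = np.asarray(genotypes, dtype=float)
    if model == "additive":
        return g.copy()
    if model == "dominant":
        out = (g >= 1).astype(float)
    elif model == "recessive":
        out = (g == 2).astype(float)
    else:
        raise ValueError(f"unknown genetic model {model!r}")
    out[np.isnan(g)] = np.nan
    return out


@dataclass
class AssociationResult:
    """One variant x one genetic model: effect size and significance."""

    variant_id: str
    model: str
    beta: float | None  # DIP units per coded-genotype unit
    se: float | None
    p_value: float | None
    n_used: int
    applicable: bool = True

    def __post_init__(self) -> None:
        if self.applicable and self.p_value is not None:
            if not (0.0 <= self.p_value <= 1.0):
                raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def adjusted_regression(dip: Sequence[float], code: Sequence[float],
                        age: Sequence[float], sex: Sequence[float],
                        variant_id: str = "", model: str = "") -> AssociationResult:
    """Age- and sex-adjusted OLS of DIP on a coded genotype.

    Fits dip ~ intercept + code + age + sex and returns the genotype
    coefficient with its two-sided t-test p-value.  Subjects with any missing
    field are dropped (complete-case); a genotype that is constant after the
    drop makes the model inapplicable.
    """
    y = np.asarray(dip, dtype=float)
    x = np.asarray(code, dtype=float)
    a = np.asarray(age, dtype=float)
    s = np.asarray(sex, dtype=float)
    if not (len(y) == len(x) == len(a) == len(s)):
        raise ValueError("dip/code/age/sex vectors have mismatched lengths")
    keep = ~(np.isnan(y) | np.isnan(x) | np.isnan(a) | np.isnan(s))
    y, x, a, s = y[keep], x[keep], a[keep], s[keep]
    n = len(y)
    if n < 5 or np.ptp(x) == 0:
        return AssociationResult(variant_id, model, None, None, None, n,
                                 applicable=False)
    X = np.column_stack([np.ones(n), x, a, s])
    fit = sm.OLS(y, X).fit()
    return AssociationResult(variant_id, model,
                             beta=float(fit.params[1]),
                             se=float(fit.bse[1]),
                             p_value=float(fit.pvalues[1]),
                             n_used=n)


def anova_by_genotype(dip: Sequence[float],
                      genotypes: Sequence[float]) -> float | None:
    """One-way fixed-effects ANOVA of DIP across genotype groups 0/1/2.

    Returns the F-test p-value, or None when fewer than two genotype groups
    have at least two subjects.
    """
    y = np.asarray(dip, dtype=float)
    g = np.asarray(genotypes, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(g))
    y, g = y[keep], g[keep]
    groups = [y[g == k] for k in (0.0, 1.0, 2.0)]
    groups = [grp for grp in groups if len(grp) >= 2]
    if len(groups) < 2:
        return None
    if all(np.ptp(grp) == 0 for grp in groups) and \
            np.ptp([grp.mean() for grp in groups]) == 0:
        return 1.0  # identical constant groups: F = 0
    stat, p = stats.f_oneway(*groups)
    return float(p)


def fisher_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Two-sided by the standard convention: sum of hypergeometric probabilities
    of tables (fixed margins) no more probable than the observed one.  A zero
    margin yields p = 1 by convention.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("fisher_2x2 requires a 2x2 table")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("fisher_2x2 requires nonnegative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided").pvalue)


def cochran_armitage_trend(table: Sequence[Sequence[int]],
                           weights: Sequence[float] = (0.0, 1.0, 2.0),
                           ) -> tuple[float | None, float | None]:
    """Cochran-Armitage trend test on a 2x3 case/control-by-genotype table.

    Rows are (cases, controls); columns genotype 0/1/2 with default weights
    (0, 1, 2); no continuity correction.  Returns (z, two-sided p) from the
    standard-normal reference, or (None, None) when a case/control margin is
    empty or the trend variance vanishes.
    """
    t = np.asarray(table)
    if t.shape != (2, len(weights)):
        raise ValueError(f"expected a 2x{len(weights)} table")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("counts must be nonnegative integers")
    w = np.asarray(weights, dtype=float)
    r = t[0].astype(float)  # cases per genotype
    s = t[1].astype(float)  # controls per genotype
    col = r + s
    R, S = r.sum(), s.sum()
    N = R + S
    if R == 0 or S == 0:
        return None, None
    u = float(np.sum(w * (S * r - R * s)))
    pairs = 0.0
    for i in range(len(w)):
        for j in range(i + 1, len(w)):
            pairs += w[i] * w[j] * col[i] * col[j]
    var = (R * S / N) * (float(np.sum(w ** 2 * col * (N - col))) - 2.0 * pairs)
    if var <= 0:
        return None, None
    z = u / np.sqrt(var)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


@dataclass(frozen=True)
class DipGroupScheme:
    """Nested DIP strata for the categorical analyses.

    G0 is the tolerant control group (DIP > g0_min); G1..G5 are nested
    "at most" strata; G6 is strictly below its threshold.
    """

    g0_min: float = 70.0
    thresholds: tuple[float, ...] = (70.0, 60.0, 45.0, 35.0, 25.0, 15.0)

    def __post_init__(self) -> None:
        if any(a <= b for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly decreasing")


def dip_groups(subjects: pd.DataFrame,
               scheme: DipGroupScheme = DipGroupScheme()) -> dict[str, set]:
    """Assign subjects to the control group G0 (DIP > 70) and the nested
    intolerance strata G1..G6.  G1..G5 use <=; the last group uses strict <.
    """
    if subjects["dip"].isna().any():
        raise ValueError("DIP missing for some subjects")
    ids = subjects["subject_id"]
    dip = subjects["dip"].to_numpy(dtype=float)
    groups: dict[str, set] = {"G0": set(ids[dip > scheme.g0_min])}
    last = len(scheme.thresholds)
    for k, thr in enumerate(scheme.thresholds, start=1):
        mask = dip < thr if k == last else dip <= thr
        groups[f"G{k}"] = set(ids[mask])
    return groups


def _aligned_vectors(variant: AnnotatedVariant, subjects: pd.DataFrame,
                     subject_ids: Sequence[str], model: str):
    order = {sid: i for i, sid in enumerate(subject_ids)}
    idx = [order[sid] for sid in subjects["subject_id"]]
    g = variant.genotypes[idx]
    code = code_genotypes(g, model)
    sex = (subjects["sex"] == "male").astype(float).to_numpy()
    return (subjects["dip"].to_numpy(dtype=float), code,
            subjects["age"].to_numpy(dtype=float), sex)


def regress_variant(variant: AnnotatedVariant, subjects: pd.DataFrame,
                    subject_ids: Sequence[str],
                    model: str = "additive") -> AssociationResult:
    """Adjusted regression of one variant on one cohort under one model."""
    dip, code, age, sex = _aligned_vectors(variant, subjects, subject_ids, model)
    return adjusted_regression(dip, code, age, sex,
                               variant_id=variant.variant_id, model=model)


@dataclass
class Candidate:
    """A discovery-phase candidate variant with its screening result."""

    variant: AnnotatedVariant
    discovery: AssociationResult
    replication: dict[str, AssociationResult] | None = None


def discovery_screen(variants: Sequence[AnnotatedVariant],
                     subjects: pd.DataFrame, subject_ids: Sequence[str],
                     p_max: float = 0.01, sift_max: float = 0.05,
                     cadd_min: float = 25.0) -> list[Candidate]:
    """Discovery-phase screen: additive-model adjusted regression at
    p < ``p_max``, then the SIFT/CADD deleteriousness filter.

    ``variants`` are assumed already restricted to strong-effect consequence
    classes.  Returns candidates with their discovery AssociationResults.
    """
    if subjects.empty:
        return []
    hits: list[Candidate] = []
    for v in variants:
        res = regress_variant(v, subjects, subject_ids, "additive")
        if res.applicable and res.p_value is not None and res.p_value < p_max:
            hits.append(Candidate(variant=v, discovery=res))
    kept_ids = {v.variant_id
                for v in filter_deleterious([c.variant for c in hits],
                                            sift_max=sift_max,
                                            cadd_min=cadd_min)}
    return [c for c in hits if c.variant.variant_id in kept_ids]


def replicate_candidates(candidates: Sequence[Candidate],
                         subjects: pd.DataFrame, subject_ids: Sequence[str],
                         p_max: float = 0.05) -> list[Candidate]:
    """Replication-phase test of discovery candidates.

    Each candidate is retested in the replication cohort under additive and
    recessive adjusted regressions; it replicates iff any applicable model
    reaches p < ``p_max``.  The recessive model is not applicable when the
    replication data contain no homozygote (the coded genotype is constant).
    """
    replicated = []
    for cand in candidates:
        results = {}
        for model in ("additive", "recessive"):
            results[model] = regress_variant(cand.variant, subjects, subject_ids,
                                          model)
        cand.replication = results
        if any(r.applicable and r.p_value is not None and r.p_value < p_max
               for r in results.values()):
            replicated.append(cand)
    return replicated


def association_table(results: Iterable[AssociationResult]) -> pd.DataFrame:
    """Tidy per-variant results: variant_id, model, beta, se, p, n_used,
    applicable."""
    rows = [{"variant_id": r.variant_id, "model": r.model, "beta": r.beta,
             "se": r.se, "p": r.p_value, "n_used": r.n_used,
             "applicable": r.applicable} for r in results]
    return pd.DataFrame(rows)
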