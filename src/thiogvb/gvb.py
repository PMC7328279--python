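"""Gene-wise variant burden (GVB) scoring.

GVB summarises a subject's coding-variant load in one gene as the geometric
mean of the SIFT scores of the variants the subject carries, restricted to
variants with SIFT < 0.7.  Because SIFT is in [0, 1] with lower = more
damaging, GVB lies in (0, 1] and a lower score means a heavier predicted
burden; a subject carrying no qualifying variant scores exactly 1 (empty
product).  Multigene burden over a gene set is the geometric mean of the
member genes' scores, giving a single quantitative risk score per subject
per gene set.

Two refinements matter in the thiopurine setting:

* SIFT floor: fully damaging variants have SIFT = 0, which would collapse
  the geometric mean to 0 for every carrier and erase the ordering among
  multi-variant carriers.  Scores are floored at ``sift_floor`` (default
  0.001) before averaging.
* Recessive masking: a designated set of variants (default the common CRIM1
  missense rs3821169, whose phenotype is recessive) contribute only when
  homozygous; heterozygous calls are ignored.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .variant_io import AnnotatedVariant

logger = logging.getLogger(__name__)

DEFAULT_MASKED_VARIANTS = frozenset({"rs3821169"})


@dataclass(frozen=True)
class GvbConfig:
    """Scoring parameters.

    inclusion_threshold: variants with SIFT >= this are never counted
    (strict <, default 0.7).  sift_floor: minimum score substituted before
    the geometric mean (default 0.001).  recessive_masked_variants: variant
    ids counted only when homozygous.
    """

    inclusion_threshold: float = 0.7
    sift_floor: float = 0.001
    recessive_masked_variants: frozenset[str] = DEFAULT_MASKED_VARIANTS

    def __post_init__(self) -> None:
        if not (0.0 < self.sift_floor < self.inclusion_threshold <= 1.0):
            raise ValueError(
                "require 0 < sift_floor < inclusion_threshold <= 1; got "
                f"floor={self.sift_floor}, threshold={self.inclusion_threshold}")


def gene_gvb(genotypes: Sequence[float], sifts: Sequence[float | None],
             variant_ids: Sequence[str] | None = None,
             config: GvbConfig = GvbConfig()) -> float:
    """GVB score of one gene for one subject.

    ``genotypes`` are the subject's alt-allele counts over the gene's
    variants; ``sifts`` the matching SIFT scores (None = unannotated, the
    variant is skipped).  Qualifying variants are those carried (genotype
    >= 1; masked variants require genotype == 2) with SIFT strictly below
    the inclusion threshold; the score is the geometric mean of
    max(SIFT, sift_floor) over that set, or 1.0 for an empty set.
    """
    if variant_ids is None:
        variant_ids = [""] * len(genotypes)
    logs = []
    for g, s, vid in zip(genotypes, sifts, variant_ids):
        if g is None or (isinstance(g, float) and math.isnan(g)):
            continue
        if g not in (0, 1, 2):
            raise ValueError(f"genotype value outside {{0,1,2,missing}}: {g}")
        need = 2 if vid in config.recessive_masked_variants else 1
        if g < need:
            continue
        if s is None:
            logger.info("variant %s carried but lacks SIFT; skipped in GVB", vid)
            continue
        if s >= config.inclusion_threshold:
            continue
        logs.append(math.log(max(s, config.sift_floor)))
    if not logs:
        return 1.0
    return float(math.exp(sum(logs) / len(logs)))


def multigene_gvb(gene_scores: Iterable[float]) -> float:
    """Geometric mean of per-gene GVB scores over a gene set (order-free)."""
    scores = list(gene_scores)
    if not scores:
        raise ValueError("multigene_gvb requires a nonempty gene set")
    for s in scores:
        if not (0.0 < s <= 1.0):
            raise ValueError(f"gene score outside (0, 1]: {s}")
    return float(math.exp(sum(math.log(s) for s in scores) / len(scores)))


def profile_cohort(variants: Sequence[AnnotatedVariant],
                   subject_ids: Sequence[str],
                   gene_sets: Sequence[Sequence[str]] = (),
                   config: GvbConfig = GvbConfig()) -> pd.DataFrame:
    """Per-subject GVB profile over every gene named in any requested set.

    Returns a DataFrame indexed by subject id with one column per gene and
    one per composed set (label ``"A,B"``).  A requested gene with no
    variants in the input scores 1.0 for everyone (logged).
    """
    genes: list[str] = []
    for gs in gene_sets:
        for g in gs:
            if g not in genes:
                genes.append(g)
    if not genes:
        genes = sorted({v.gene for v in variants})
    by_gene: dict[str, list[AnnotatedVariant]] = {g: [] for g in genes}
    for v in variants:
        if v.gene in by_gene:
            by_gene[v.gene].append(v)
    out = pd.DataFrame(index=pd.Index(subject_ids, name="subject_id"))
    for g in genes:
        vs = by_gene[g]
        if not vs:
            logger.info("gene %s has no variants in the input; GVB = 1.0", g)
            out[g] = 1.0
            continue
        sifts = [v.sift for v in vs]
        vids = [v.variant_id for v in vs]
        geno = np.vstack([v.genotypes for v in vs]).T  # subjects x variants
        out[g] = [gene_gvb(row, sifts, vids, config) for row in geno]
    for gs in gene_sets:
        label = ",".join(gs)
        out[label] = [multigene_gvb(row)
                      for row in out[list(gs)].to_numpy()]
    return out


class GVBScorer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer from genotype matrices to GVB profiles.

    Parameters
    ----------
    annotations : mapping of variant id -> (gene symbol, SIFT score or None),
        or a DataFrame with columns ``gene`` and ``sift`` indexed by variant
        id.
    gene_sets : sequence of gene symbol sequences to compose (each yields a
        column labelled by the comma-joined symbols).
    inclusion_threshold, sift_floor, recessive_masked : scoring parameters,
        see :class:`GvbConfig`.

    ``transform(X)`` accepts a subjects x variants DataFrame of alt-allele
    counts (nan = missing) and returns the score DataFrame of
    :func:`profile_cohort`.  The transformer is stateless; ``fit`` only
    validates parameters, following the sklearn convention for functional
    transforms.
    """

    def __init__(self, annotations=None, gene_sets=(),
                 inclusion_threshold=0.7, sift_floor=0.001,
                 recessive_masked=DEFAULT_MASKED_VARIANTS):
        self.annotations = annotations
        self.gene_sets = gene_sets
        self.inclusion_threshold = inclusion_threshold
        self.sift_floor = sift_floor
        self.recessive_masked = recessive_masked

    def _config(self) -> GvbConfig:
        return GvbConfig(inclusion_threshold=self.inclusion_threshold,
                         sift_floor=self.sift_floor,
                         recessive_masked_variants=frozenset(self.recessive_masked))

    def _annotation_map(self) -> dict[str, tuple[str, float | None]]:
        if self.annotations is None:
            raise ValueError("GVBScorer requires variant annotations")
        if isinstance(self.annotations, pd.DataFrame):
            return {vid: (row["gene"], row["sift"])
                    for vid, row in self.annotations.iterrows()}
        return dict(self.annotations)

    def fit(self, X=None, y=None):
        self._config()  # validate parameters
        ann = self._annotation_map()
        self.genes_ = sorted({gene for gene, _ in ann.values()})
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "genes_"):
            self.fit(X)
        ann = self._annotation_map()
        variants = []
        for vid in X.columns:
            if vid not in ann:
                raise ValueError(f"variant {vid} missing from annotations")
            gene, sift = ann[vid]
            variants.append(AnnotatedVariant(
                variant_id=vid, chrom="0", pos=1, ref="N", alt="N",
                gene=gene, consequence="missense", sift=sift, cadd=None,
                genotypes=X[vid].to_numpy(dtype=float)))
        return profile_cohort(variants, list(X.index),
                              gene_sets=self.gene_sets, config=self._config())
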