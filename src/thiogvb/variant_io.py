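"""Annotated variant I/O and deleteriousness filtering.

Variants arrive as a VCF with per-subject genotypes plus per-variant
annotations (gene symbol, consequence class, SIFT, CADD) carried in INFO
fields.  Downstream analysis consumes one record per ALT allele; this module
reads and writes that representation and applies the two discovery-funnel
filters: consequence class (keep only variants with a strong predicted effect
on gene function) and in-silico deleteriousness (SIFT <= 0.05 and CADD >= 25
by default, boundaries inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

logger = logging.getLogger(__name__)

#: Consequence classes treated as having a strong effect on gene function.
STRONG_EFFECT_CLASSES = frozenset(
    {"missense", "nonsense", "splice_site", "frameshift", "inframe_indel"}
)

#: Normalisation map from common annotation dialects (e.g. Sequence Ontology
#: terms emitted by SnpEff/VEP) to the internal consequence vocabulary.
CONSEQUENCE_SYNONYMS: Mapping[str, str] = {
    "missense": "missense",
    "missense_variant": "missense",
    "nonsense": "nonsense",
    "stop_gained": "nonsense",
    "splice_site": "splice_site",
    "splice_acceptor_variant": "splice_site",
    "splice_donor_variant": "splice_site",
    "splice_region_variant": "splice_site",
    "frameshift": "frameshift",
    "frameshift_variant": "frameshift",
    "inframe_indel": "inframe_indel",
    "inframe_insertion": "inframe_indel",
    "inframe_deletion": "inframe_indel",
    "disruptive_inframe_insertion": "inframe_indel",
    "disruptive_inframe_deletion": "inframe_indel",
}

#: Default INFO keys carrying the annotations.
DEFAULT_ANNOTATION_KEYS = ("GENE", "CSQ", "SIFT", "CADD")

# VCF floats are single precision; annotation scores are conventionally
# printed with at most 4 decimals, so round on read to restore them.
_FLOAT_DECIMALS = 4


def normalize_consequence(term: str | None,
                          synonyms: Mapping[str, str] = CONSEQUENCE_SYNONYMS) -> str:
    """Map an annotation-dialect consequence term to the internal vocabulary.

    Unknown or absent terms become ``"other"`` (synonymous, intronic, UTR...).
    """
    if term is None:
        return "other"
    return synonyms.get(term.strip().lower(), "other")


@dataclass
class AnnotatedVariant:
    """One variant site (one ALT allele) with annotations and genotypes.

    ``genotypes`` is a float array of per-subject ALT-allele counts in
    {0, 1, 2}, with ``nan`` for missing calls, aligned to the subject list
    returned alongside the variants.
    """

    variant_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    consequence: str
    sift: float | None
    cadd: float | None
    genotypes: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.sift is not None and not (0.0 <= self.sift <= 1.0):
            raise ValueError(f"SIFT score outside [0, 1]: {self.sift}")
        if self.cadd is not None and self.cadd < 0:
            raise ValueError(f"CADD score must be >= 0: {self.cadd}")
        g = np.asarray(self.genotypes, dtype=float)
        ok = np.isnan(g) | np.isin(g, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.unique(g[~ok])
            raise ValueError(f"genotype values outside {{0,1,2,missing}}: {bad}")
        self.genotypes = g

    @property
    def carriers(self) -> np.ndarray:
        """Boolean mask of subjects carrying >= 1 ALT allele."""
        return self.genotypes >= 1

    @property
    def n_carriers(self) -> int:
        return int(np.nansum(self.genotypes >= 1))


def _parse_score(value, key: str, variant_id: str) -> float | None:
    if value is None:
        return None
    try:
        return round(float(value), _FLOAT_DECIMALS)
    except (TypeError, ValueError):
        logger.warning("unparseable %s for %s: %r; recorded as absent",
                       key, variant_id, value)
        return None


def read_annotated_vcf(
    path: str,
    annotation_keys: Sequence[str] = DEFAULT_ANNOTATION_KEYS,
) -> tuple[list[AnnotatedVariant], list[str]]:
    """Read a VCF into AnnotatedVariant records plus the subject id list.

    One record is produced per ALT allele; multi-allelic sites are split and
    the genotype of each split record counts only the focal ALT allele
    (other ALT alleles count as 0).  Subject order follows the VCF header.
    """
    gene_key, csq_key, sift_key, cadd_key = annotation_keys
    with pysam.VariantFile(path) as vcf:
        subjects = list(vcf.header.samples)
        if subjects and "GT" not in vcf.header.formats:
            raise ValueError(f"{path}: VCF lacks a GT FORMAT field")
        variants: list[AnnotatedVariant] = []
        for rec in vcf:
            alts = rec.alts or ()
            calls = [rec.samples[s].get("GT") for s in subjects]
            for alt_index, alt in enumerate(alts, start=1):
                geno = np.full(len(subjects), np.nan)
                for i, gt in enumerate(calls):
                    if gt is None or any(a is None for a in gt):
                        continue
                    geno[i] = sum(1 for a in gt if a == alt_index)
                info = rec.info
                vid = rec.id or f"{rec.chrom}:{rec.pos}:{rec.ref}:{alt}"
                if len(alts) > 1 and rec.id:
                    vid = f"{rec.id}:{alt}"
                variants.append(
                    AnnotatedVariant(
                        variant_id=vid,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        gene=str(info.get(gene_key, "")) or "",
                        consequence=normalize_consequence(info.get(csq_key)),
                        sift=_parse_score(info.get(sift_key), sift_key, vid),
                        cadd=_parse_score(info.get(cadd_key), cadd_key, vid),
                        genotypes=geno,
                    )
                )
    return variants, subjects


def write_annotated_vcf(
    variants: Iterable[AnnotatedVariant],
    subjects: Sequence[str],
    path: str,
    annotation_keys: Sequence[str] = DEFAULT_ANNOTATION_KEYS,
) -> None:
    """Write AnnotatedVariant records to an uncompressed VCF 4.2 file."""
    gene_key, csq_key, sift_key, cadd_key = annotation_keys
    variants = list(variants)
    header = pysam.VariantHeader()
    contigs = sorted({v.chrom for v in variants}, key=str)
    for c in contigs:
        header.contigs.add(c)
    header.info.add(gene_key, 1, "String", "Gene symbol")
    header.info.add(csq_key, 1, "String", "Consequence class")
    header.info.add(sift_key, 1, "Float", "SIFT deleteriousness score (0-1, lower = more damaging)")
    header.info.add(cadd_key, 1, "Float", "CADD phred-scaled deleteriousness score")
    header.formats.add("GT", 1, "String", "Genotype")
    for s in subjects:
        header.add_sample(s)
    _GT = {0.0: (0, 0), 1.0: (0, 1), 2.0: (1, 1)}
    with pysam.VariantFile(path, "w", header=header) as out:
        for v in sorted(variants, key=lambda v: (str(v.chrom), v.pos, v.alt)):
            rec = out.new_record(contig=str(v.chrom), start=v.pos - 1,
                                 alleles=(v.ref, v.alt), id=v.variant_id)
            rec.info[gene_key] = v.gene
            rec.info[csq_key] = v.consequence
            if v.sift is not None:
                rec.info[sift_key] = v.sift
            if v.cadd is not None:
                rec.info[cadd_key] = v.cadd
            for i, s in enumerate(subjects):
                g = v.genotypes[i] if v.genotypes.size else np.nan
                rec.samples[s]["GT"] = _GT.get(g, (None, None))
            out.write(rec)


def filter_functional(
    variants: Sequence[AnnotatedVariant],
    keep_classes: frozenset[str] = STRONG_EFFECT_CLASSES,
) -> list[AnnotatedVariant]:
    """Keep variants whose consequence class predicts a strong functional
    effect (missense, nonsense, splice-site, frameshift, in-frame indel)."""
    return [v for v in variants if v.consequence in keep_classes]


def filter_deleterious(
    variants: Sequence[AnnotatedVariant],
    sift_max: float = 0.05,
    cadd_min: float = 25.0,
) -> list[AnnotatedVariant]:
    """Keep variants predicted deleterious by both in-silico methods.

    A variant passes iff SIFT <= ``sift_max`` AND CADD >= ``cadd_min``
    (boundaries inclusive).  A variant missing either score cannot satisfy
    both predictors and is excluded (logged), mirroring the availability of
    in-silico predictions in real annotation sets.
    """
    kept = []
    for v in variants:
        if v.sift is None or v.cadd is None:
            logger.info("variant %s lacks SIFT/CADD; excluded from the "
                        "deleteriousness filter", v.variant_id)
            continue
        if v.sift <= sift_max and v.cadd >= cadd_min:
            kept.append(v)
    return kept


def genotype_frame(variants: Sequence[AnnotatedVariant],
                   subjects: Sequence[str]):
    """Subjects x variants genotype matrix as a pandas DataFrame (float,
    nan = missing)."""
    import pandas as pd

    data = {v.variant_id: v.genotypes for v in variants}
    return pd.DataFrame(data, index=list(subjects), dtype=float)
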