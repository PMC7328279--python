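"""End-to-end pipeline: simulate -> filter -> associate -> score ->
phenotype -> evaluate.

A run is driven by a flat config (YAML-loadable dict), executes the enabled
stages in order into a run directory, and writes a manifest (parameters,
seed, package version, input checksums) sufficient to reproduce it.  With a
fixed seed, re-running the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .association import (association_table, discovery_screen,
                          regress_variant, replicate_candidates)
from .evaluation import DIP_CUTOFFS, compare_models, round_half_up
from .gvb import GvbConfig, profile_cohort
from .simulate import (SimulationConfig, SyntheticCohort, VariantSpec,
                       read_diplotypes, read_phenotypes, simulate_cohort,
                       write_cohort)
from .star_allele import call_metabolizers, load_function_table, select_both_wt
from .variant_io import (filter_deleterious, filter_functional,
                         read_annotated_vcf, write_annotated_vcf)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "filter", "assoc", "gvb", "phenotype", "evaluate")

DEFAULT_GENE_SETS = (("NUDT15", "TPMT"), ("NUDT15", "TPMT", "CRIM1"))


@dataclass
class RunConfig:
    """Flat configuration of one pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides
    vcf: str | None = None          # input VCF when simulate is disabled
    phenotypes: str | None = None   # input phenotype TSV likewise
    diplotypes: str | None = None   # input diplotype TSV likewise
    sift_max: float = 0.05
    cadd_min: float = 25.0
    p_max_discovery: float = 0.01
    p_max_replication: float = 0.05
    gvb: dict = field(default_factory=dict)  # GvbConfig overrides
    gene_sets: tuple[tuple[str, ...], ...] = DEFAULT_GENE_SETS
    dip_cutoff: float = 25.0
    bootstrap_n: int = 0
    cohort_column: str = "cohort"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "gene_sets" in raw:
            raw["gene_sets"] = tuple(tuple(g) for g in raw["gene_sets"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _build_sim_config(cfg: RunConfig) -> SimulationConfig:
    kwargs = dict(cfg.simulate)
    specs = kwargs.pop("variant_specs", None)
    if specs is not None:
        kwargs["variant_specs"] = [VariantSpec(**s) if isinstance(s, dict)
                                   else s for s in specs]
    kwargs.setdefault("seed", cfg.seed)
    return SimulationConfig(**kwargs)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory.

    On a stage failure, partial outputs are kept and a FAILED marker naming
    the stage is written before the exception propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "parameters": {
            "sift_max": config.sift_max, "cadd_min": config.cadd_min,
            "p_max_discovery": config.p_max_discovery,
            "p_max_replication": config.p_max_replication,
            "gvb": dict(config.gvb),
            "gene_sets": [list(g) for g in config.gene_sets],
            "dip_cutoff": config.dip_cutoff,
            "bootstrap_n": config.bootstrap_n,
        },
        "inputs": {}, "outputs": {}, "timings_s": {},
    }
    stage = None
    try:
        vcf_path = config.vcf
        pheno_path = config.phenotypes
        diplo_path = config.diplotypes

        if "simulate" in config.stages:
            stage = "simulate"
            t0 = time.perf_counter()
            sim_cfg = _build_sim_config(config)
            cohort = simulate_cohort(sim_cfg)
            vcf_path = str(out / "cohort.vcf")
            pheno_path = str(out / "phenotypes.tsv")
            diplo_path = str(out / "diplotypes.tsv")
            write_cohort(cohort, vcf_path, pheno_path, diplo_path)
            manifest["parameters"]["simulate"] = {
                k: v for k, v in asdict(sim_cfg).items()
                if k not in ("variant_specs", "no_function_alleles")}
            manifest["timings_s"]["simulate"] = time.perf_counter() - t0
            logger.info("simulate: %d subjects, %d variants",
                        sim_cfg.n_subjects, len(cohort.variants))

        if vcf_path is None or pheno_path is None:
            raise ValueError("vcf and phenotypes inputs are required when "
                             "the simulate stage is disabled")
        for name, p in (("vcf", vcf_path), ("phenotypes", pheno_path),
                        ("diplotypes", diplo_path)):
            if p is not None:
                manifest["inputs"][name] = {"path": str(p),
                                            "sha256": _sha256(Path(p))}

        variants, subject_ids = read_annotated_vcf(vcf_path)
        subjects = read_phenotypes(pheno_path)
        calls = None
        if diplo_path is not None:
            calls = call_metabolizers(read_diplotypes(diplo_path),
                                      load_function_table())

        if "filter" in config.stages:
            stage = "filter"
            t0 = time.perf_counter()
            functional = filter_functional(variants)
            deleterious = filter_deleterious(functional, config.sift_max,
                                             config.cadd_min)
            write_annotated_vcf(functional, subject_ids,
                                str(out / "functional.vcf"))
            write_annotated_vcf(deleterious, subject_ids,
                                str(out / "deleterious.vcf"))
            manifest["outputs"]["filter"] = {
                "n_input": len(variants), "n_functional": len(functional),
                "n_deleterious": len(deleterious)}
            manifest["timings_s"]["filter"] = time.perf_counter() - t0
            variants_for_assoc = functional
        else:
            variants_for_assoc = variants

        if "assoc" in config.stages:
            stage = "assoc"
            t0 = time.perf_counter()
            analysis = subjects
            if calls is not None:
                analysis = select_both_wt(subjects, calls)
            disc = analysis[analysis[config.cohort_column] == "discovery"]
            repl = analysis[analysis[config.cohort_column] == "replication"]
            candidates = discovery_screen(
                variants_for_assoc, disc, subject_ids,
                p_max=config.p_max_discovery, sift_max=config.sift_max,
                cadd_min=config.cadd_min)
            replicated = replicate_candidates(
                candidates, repl, subject_ids,
                p_max=config.p_max_replication) if len(repl) else []
            rows = []
            for cand in candidates:
                rows.append(cand.discovery)
                rows.extend((cand.replication or {}).values())
            table = association_table(rows)
            table.to_csv(out / "association.tsv", sep="\t", index=False)
            manifest["outputs"]["assoc"] = {
                "n_candidates": len(candidates),
                "n_replicated": len(replicated),
                "replicated": [c.variant.variant_id for c in replicated]}
            manifest["timings_s"]["assoc"] = time.perf_counter() - t0

        profiles = None
        if "gvb" in config.stages:
            stage = "gvb"
            t0 = time.perf_counter()
            gvb_cfg = GvbConfig(**{
                **config.gvb,
                "recessive_masked_variants": frozenset(
                    config.gvb.get("recessive_masked_variants",
                                   GvbConfig().recessive_masked_variants))})
            profiles = profile_cohort(variants, subject_ids,
                                      gene_sets=config.gene_sets,
                                      config=gvb_cfg)
            profiles.to_csv(out / "gvb_scores.tsv", sep="\t")
            manifest["timings_s"]["gvb"] = time.perf_counter() - t0

        if "phenotype" in config.stages:
            stage = "phenotype"
            if calls is None:
                raise ValueError("phenotype stage requires a diplotype table")
            calls.to_csv(out / "metabolizers.tsv", sep="\t")

        if "evaluate" in config.stages:
            stage = "evaluate"
            t0 = time.perf_counter()
            if profiles is None or calls is None:
                raise ValueError("evaluate stage requires gvb and phenotype "
                                 "stages (or their outputs)")
            report = compare_models(subjects, profiles, calls,
                                    two_gene_label=",".join(config.gene_sets[0]),
                                    three_gene_label=",".join(config.gene_sets[1]),
                                    dip_cutoff=config.dip_cutoff,
                                    n_bootstrap=config.bootstrap_n,
                                    seed=config.seed)
            for col in ("sensitivity", "specificity", "ppv", "npv",
                        "accuracy", "auc"):
                report[col] = [None if v is None or pd.isna(v)
                               else round_half_up(float(v))
                               for v in report[col]]
            report.to_csv(out / "evaluation.tsv", sep="\t", index=False)
            manifest["outputs"]["evaluate"] = {"n_rows": len(report)}
            manifest["timings_s"]["evaluate"] = time.perf_counter() - t0

    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        logger.error("pipeline failed at stage %s: %s", stage, exc)
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return out
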