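"""Star-allele diplotype to metabolizer-phenotype translation.

The guideline-style (CPIC) categorical baseline: each NUDT15/TPMT diplotype
maps to a metabolizer phenotype — two normal-function alleles give a normal
metabolizer (NM), one no-function allele an intermediate metabolizer (IM),
two no-function alleles a poor metabolizer (PM); any allele of uncertain
function yields an indeterminate call.  The two-gene combined risk class is
NM only when both genes are NM; everything else (including indeterminate,
conservatively) is the PM+IM risk arm.  The shipped default function table
reflects the 2019 guideline update in which NUDT15*9 was reclassified from
'uncertain' to 'no function'; ``nudt15_star9_uncertain=True`` restores the
older behaviour.
"""

from __future__ import annotations

import logging
from importlib import resources
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)

PHENOTYPES = ("NM", "IM", "PM", "indeterminate")
FUNCTIONS = ("normal", "no_function", "uncertain")


def load_function_table(path: str | None = None,
                        nudt15_star9_uncertain: bool = False,
                        ) -> dict[str, dict[str, str]]:
    """Load an allele-function table (gene, allele, function TSV).

    With no path, the packaged default table is used.  Returns
    {gene: {allele: function}}.
    """
    if path is None:
        source = resources.files("thiogvb") / "data" / "allele_functions.tsv"
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "allele", "function"}
    if not required <= set(df.columns):
        raise ValueError(f"function table lacks columns "
                         f"{sorted(required - set(df.columns))}")
    bad = set(df["function"]) - set(FUNCTIONS)
    if bad:
        raise ValueError(f"unknown allele functions: {sorted(bad)}")
    table: dict[str, dict[str, str]] = {}
    for _, row in df.iterrows():
        table.setdefault(row["gene"], {})[row["allele"]] = row["function"]
    if nudt15_star9_uncertain and "*9" in table.get("NUDT15", {}):
        table["NUDT15"]["*9"] = "uncertain"
    return table


def assign_phenotype(allele1: str, allele2: str,
                     gene_table: Mapping[str, str]) -> str:
    """Phenotype of one diplotype: NM / IM / PM / indeterminate.

    Symmetric in allele order.  Raises on an allele absent from the table.
    """
    functions = []
    for allele in (allele1, allele2):
        if allele not in gene_table:
            raise KeyError(f"allele {allele!r} absent from the function table")
        functions.append(gene_table[allele])
    if "uncertain" in functions:
        return "indeterminate"
    n_no_function = functions.count("no_function")
    return ("NM", "IM", "PM")[n_no_function]


def combined_risk(phenotypes: Mapping[str, str]) -> str:
    """Two-gene combined class: 'NM' iff every gene is NM, else 'PM+IM'.

    Indeterminate calls route to the risk arm (logged): with a function of
    uncertain significance, the conservative choice for a toxicity screen is
    to flag the subject.
    """
    if all(p == "NM" for p in phenotypes.values()):
        return "NM"
    if "indeterminate" in phenotypes.values():
        logger.info("indeterminate phenotype treated as PM+IM: %s", phenotypes)
    return "PM+IM"


def call_metabolizers(diplotypes: pd.DataFrame,
                      table: Mapping[str, Mapping[str, str]] | None = None,
                      ) -> pd.DataFrame:
    """Per-subject metabolizer calls from a diplotype table.

    ``diplotypes`` has columns subject_id, gene, allele1, allele2.  Returns a
    DataFrame indexed by subject_id with one phenotype column per gene and a
    ``combined`` column in {'NM', 'PM+IM'}.
    """
    if table is None:
        table = load_function_table()
    rows: dict[str, dict[str, str]] = {}
    for _, rec in diplotypes.iterrows():
        gene = rec["gene"]
        if gene not in table:
            raise KeyError(f"gene {gene!r} absent from the function table")
        pheno = assign_phenotype(rec["allele1"], rec["allele2"], table[gene])
        rows.setdefault(rec["subject_id"], {})[gene] = pheno
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)
    out.index.name = "subject_id"
    out["combined"] = [combined_risk(r.dropna().to_dict())
                       for _, r in out.iterrows()]
    return out


def select_both_wt(subjects: pd.DataFrame, calls: pd.DataFrame) -> pd.DataFrame:
    """Subjects whose combined metabolizer class is NM (both genes wild-type).

    The analysis cohort of the burden screen: subjects carrying no
    pharmacogenetic NUDT15/TPMT variant.  Cohort labels are preserved.
    """
    missing = set(subjects["subject_id"]) - set(calls.index)
    if missing:
        raise ValueError(f"metabolizer calls missing for subjects: "
                         f"{sorted(missing)[:5]}...")
    nm = set(calls.index[calls["combined"] == "NM"])
    return subjects[subjects["subject_id"].isin(nm)].reset_index(drop=True)
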