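"""Packaged fixture tables from the source study.

Four plain-TSV tables ship inside the package:

``table1``
    Trio genotypes and clinical metadata for the 31 final likely-pathogenic
    (LP) variants: proband/father/mother calls, parental affected status,
    cleft type and side, family history, gnomAD NFE frequency, and prior
    orofacial-cleft evidence flags per gene. The LP splice variant shared by
    a sibling pair appears once per carrier proband (32 rows).
``table2``
    The final variant annotation grid: per-variant calls of the 22 in-silico
    predictors plus ADA/CADD/DANN/MutPred-LOF, and per-gene pLI and DOMINO
    dominance class (31 rows, 30 genes).
``table3``
    Per-gene best common-SNV association summaries from the companion
    case-control scan (gene, best rs id, MAF, trend-test p, allelic OR,
    number of SNVs in the locus window). Printed statistics are carried as
    annotations; the underlying genotypes are not distributed.
``table5``
    Cohort composition counts (sex, cleft type, anomalies, family history).

Loaders return raw DataFrames (:func:`load_fixture`) or typed objects ready
for the pipeline (:func:`final_variant_set`, :func:`table1_trios`).
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Tuple

import pandas as pd

from .io import read_trio_table, read_variant_table
from .types import (GeneEvidence, PredictionProfile, TrioGenotype,
                    VariantRecord)

FIXTURE_NAMES = ("table1", "table2", "table3", "table5")


def fixture_path(name: str):
    if name not in FIXTURE_NAMES:
        raise ValueError(
            f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    return resources.files("cleftvar.data").joinpath(f"{name}.tsv")


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged fixture as a string-typed DataFrame."""
    with resources.as_file(fixture_path(name)) as path:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def table1_trios() -> List[TrioGenotype]:
    """Trio genotype records for the final variant set (one per carrier)."""
    with resources.as_file(fixture_path("table1")) as path:
        return read_trio_table(path)


@dataclass(frozen=True)
class FinalVariantSet:
    """The study's final annotation grid, assembled for the cascade."""

    variants: List[VariantRecord]
    profiles: Dict[str, PredictionProfile]
    evidence: Dict[str, GeneEvidence]


def final_variant_set() -> FinalVariantSet:
    """Assemble variants, prediction profiles and gene evidence.

    Variant identity, consequence and predictions come from ``table2``;
    population frequency, ClinVar status and the per-gene orofacial-cleft
    evidence flags come from ``table1`` (flags are OR-ed over a gene's rows).
    """
    with resources.as_file(fixture_path("table2")) as path:
        pairs = read_variant_table(path)
    t1 = load_fixture("table1")
    t2 = load_fixture("table2")

    per_variant = {}
    for row in t1.to_dict("records"):
        per_variant.setdefault(row["variant_id"], row)
    ofc: Dict[str, Dict[str, bool]] = {}
    for row in t1.to_dict("records"):
        flags = ofc.setdefault(row["gene"], dict.fromkeys(
            ("ofc_syndromic", "ofc_nonsyndromic", "ofc_ko_mouse"), False))
        for key in flags:
            flags[key] |= row[key] == "true"

    variants: List[VariantRecord] = []
    profiles: Dict[str, PredictionProfile] = {}
    for record, profile in pairs:
        meta = per_variant[record.variant_id]
        maf = meta["maf_nfe"].strip()
        variants.append(VariantRecord(
            variant_id=record.variant_id,
            gene=record.gene,
            consequence=record.consequence,
            hgvs_c=record.hgvs_c,
            hgvs_p=record.hgvs_p,
            rsid=meta["rsid"] or None,
            maf_nfe=float(maf) if maf else None,
            clinvar_lp_for_trait=meta["clinvar_lp_for_trait"] == "true",
        ))
        profiles[record.variant_id] = profile

    evidence: Dict[str, GeneEvidence] = {}
    for row in t2.to_dict("records"):
        gene = row["gene"]
        if gene in evidence:
            continue
        flags = ofc.get(gene, {})
        evidence[gene] = GeneEvidence(
            gene=gene,
            pli=float(row["pli"]),
            domino_class=row["domino_class"],
            domino_ad_prob=float(row["domino_ad_prob"]),
            ofc_syndromic=flags.get("ofc_syndromic", False),
            ofc_nonsyndromic=flags.get("ofc_nonsyndromic", False),
            ofc_ko_mouse=flags.get("ofc_ko_mouse", False),
        )
    return FinalVariantSet(variants, profiles, evidence)


def table3_summary() -> pd.DataFrame:
    """Per-gene best-SNV association summaries with numeric dtypes."""
    frame = load_fixture("table3")
    for column in ("n_snvs_plotted", "pos"):
        frame[column] = frame[column].astype(int)
    for column in ("maf", "p_trend", "or_allelic"):
        frame[column] = frame[column].astype(float)
    return frame


def table5_counts() -> pd.DataFrame:
    frame = load_fixture("table5")
    frame["n"] = frame["n"].astype(int)
    frame["percent"] = frame["percent"].astype(float)
    return frame


def cohort_descriptives() -> Dict[str, float]:
    """Recompute headline cohort descriptives from the raw counts.

    Returns the cohort size, the ns-CLP share of the cohort (percent,
    1 d.p.), and the male:female ratio (2 d.p.).
    """
    t5 = table5_counts()
    by_cat = t5.set_index("category")["n"]
    n_males = int(by_cat["males"])
    n_females = int(by_cat["females"])
    n_clp = int(by_cat["ns_clp"])
    n_cl = int(by_cat["ns_cl"])
    total = n_males + n_females
    if total != n_clp + n_cl:
        raise ValueError("inconsistent fixture totals")
    return {
        "n_patients": float(total),
        "ns_clp_percent": round(100.0 * n_clp / total, 1),
        "male_female_ratio": round(n_males / n_females, 2),
    }
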