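"""The end-to-end rare-variant prioritization cascade.

Stages, applied in order to each annotated variant:

1. *Consequence screen* — only exonic and splice-region variants are
   considered; synonymous substitutions and "other" consequences are dropped.
2. *Rarity* — gnomAD NFE frequency below the threshold (default 1e-4).
   A missing frequency counts as rare (novel variants are retained), and a
   variant previously classified likely pathogenic for the trait in ClinVar
   can be rescued regardless of frequency.
3. *Prediction rules* — missense: CADD >= 20 plus the predictor-consensus
   majority; splice-region: ADA >= 0.9; stop/frameshift/in-frame indels
   qualify by consequence class (likely gene-disrupting), with MutPred-LOF
   carried as a soft support flag.
4. *Strict LoF* (optional) — when enabled, stop-gain/frameshift variants with
   a MutPred-LOF score below 0.50 are dropped instead of annotated.

Gene-level evidence (prior orofacial-cleft association, constraint and
dominance) assigns a priority *tier* to each surviving variant; tiers rank
candidates but never exclude them.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .consensus import (LofSupport, lof_support, passes_missense_rule,
                        passes_splicing_rule)
from .types import (Consequence, GeneEvidence, Genotype, LOF_CONSEQUENCES,
                    PredictionProfile, VariantRecord)

logger = logging.getLogger(__name__)


class VariantStatus(str, enum.Enum):
    EXCLUDED_SYNONYMOUS_OR_OTHER = "excluded_synonymous_or_other"
    EXCLUDED_COMMON = "excluded_common"
    EXCLUDED_PREDICTION = "excluded_prediction"
    EXCLUDED_LOF_STRICT = "excluded_lof_strict"
    PASSED = "passed"


class GeneTier(str, enum.Enum):
    PRIOR_OFC_EVIDENCE = "prior_ofc_evidence"
    CONSTRAINED_DOMINANT = "constrained_dominant"
    OTHER = "other"


#: Funnel stage names, in application order.
STAGES = ("input", "consequence", "rarity", "prediction", "lof_strict")


@dataclass(frozen=True)
class CascadeConfig:
    """Tunable thresholds of the prioritization cascade (defaults are the
    study's published criteria)."""

    maf_threshold: float = 1e-4
    treat_missing_maf_as_rare: bool = True
    clinvar_rescue: bool = True
    lof_strict: bool = False
    cadd_min: float = 20.0
    ada_min: float = 0.9
    pli_min: float = 0.95
    dominant_classes: frozenset = frozenset(
        {"very_likely_dominant", "likely_dominant"})

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_threshold <= 1.0):
            raise ValueError("maf_threshold must be in [0, 1]")
        if self.cadd_min < 0:
            raise ValueError("cadd_min must be non-negative")
        if not (0.0 <= self.ada_min <= 1.0):
            raise ValueError("ada_min must be in [0, 1]")
        if not (0.0 <= self.pli_min <= 1.0):
            raise ValueError("pli_min must be in [0, 1]")


@dataclass(frozen=True)
class VariantClassification:
    """Per-variant cascade outcome."""

    variant_id: str
    gene: str
    consequence: Consequence
    status: VariantStatus
    exclusion_stage: Optional[str]
    gene_tier: Optional[GeneTier]
    lof_support: Optional[LofSupport]


@dataclass
class CascadeResult:
    classifications: List[VariantClassification]
    funnel: Dict[str, int]

    @property
    def passed(self) -> List[VariantClassification]:
        return [c for c in self.classifications
                if c.status is VariantStatus.PASSED]

    @property
    def passed_genes(self) -> List[str]:
        return sorted({c.gene for c in self.passed})


def rarity_filter(variant: VariantRecord,
                  config: CascadeConfig = CascadeConfig()) -> bool:
    """True when the variant is rare enough to stay in the analysis.

    Passes when the NFE frequency is below the threshold, when no frequency
    is reported (novel variants), or via the ClinVar rescue path for
    variants previously classified likely pathogenic for the trait.
    """
    if config.clinvar_rescue and variant.clinvar_lp_for_trait:
        return True
    if variant.maf_nfe is None:
        return config.treat_missing_maf_as_rare
    return variant.maf_nfe < config.maf_threshold


def classify_variant(
    variant: VariantRecord,
    profile: PredictionProfile,
    config: CascadeConfig = CascadeConfig(),
) -> Tuple[bool, Optional[str]]:
    """Apply the per-class prediction rules to a rarity-passing variant.

    Returns ``(True, None)`` for a likely-pathogenic candidate, else
    ``(False, reason)``.
    """
    csq = variant.consequence
    if csq in (Consequence.SYNONYMOUS, Consequence.OTHER):
        return False, "synonymous_or_other"
    if csq is Consequence.MISSENSE:
        if passes_missense_rule(profile, cadd_min=config.cadd_min):
            return True, None
        return False, "missense_rule"
    if csq is Consequence.SPLICING:
        if passes_splicing_rule(profile, ada_min=config.ada_min):
            return True, None
        return False, "splicing_rule"
    if csq in LOF_CONSEQUENCES:
        if (config.lof_strict
                and lof_support(profile) is LofSupport.UNSUPPORTED):
            return False, "lof_strict"
        return True, None
    raise AssertionError(f"unhandled consequence {csq}")  # pragma: no cover


def prioritize_gene(evidence: Optional[GeneEvidence],
                    config: CascadeConfig = CascadeConfig()) -> GeneTier:
    """Assign a gene priority tier from prior evidence and constraint.

    Prior orofacial-cleft evidence (human syndromic or non-syndromic
    association, or a cleft phenotype in knockout mice) outranks the
    constraint/dominance tier (pLI >= threshold and a likely/very-likely
    dominant DOMINO class). Missing evidence maps to the lowest tier.
    """
    if evidence is None:
        return GeneTier.OTHER
    if evidence.any_ofc_evidence:
        return GeneTier.PRIOR_OFC_EVIDENCE
    if (evidence.pli >= config.pli_min
            and evidence.domino_class.value in config.dominant_classes):
        return GeneTier.CONSTRAINED_DOMINANT
    return GeneTier.OTHER


def run_cascade(
    variants: Sequence[VariantRecord],
    profiles: Mapping[str, PredictionProfile],
    evidence: Mapping[str, GeneEvidence] = (),
    config: CascadeConfig = CascadeConfig(),
    genotypes: Optional[Mapping[str, Genotype]] = None,
) -> CascadeResult:
    """Run all cascade stages and report per-variant status plus the funnel.

    ``profiles`` is keyed by variant id; ``evidence`` by gene symbol (genes
    without evidence are tiered ``other`` with a log note). ``genotypes``
    optionally maps variant id to the proband genotype; homozygous
    candidates pass with a warning (the expected state is heterozygous).
    """
    evidence = dict(evidence) if not isinstance(evidence, Mapping) \
        else evidence
    funnel = dict.fromkeys(STAGES, 0)
    funnel["input"] = len(variants)
    classifications: List[VariantClassification] = []

    for variant in variants:
        profile = profiles.get(variant.variant_id)
        if profile is None:
            profile = PredictionProfile(variant_id=variant.variant_id)
        csq = variant.consequence
        support = (lof_support(profile) if csq in LOF_CONSEQUENCES else None)
        tier = None

        if csq in (Consequence.SYNONYMOUS, Consequence.OTHER):
            status, stage = (VariantStatus.EXCLUDED_SYNONYMOUS_OR_OTHER,
                             "consequence")
        elif not rarity_filter(variant, config):
            status, stage = VariantStatus.EXCLUDED_COMMON, "rarity"
        else:
            ok, reason = classify_variant(variant, profile, config)
            if ok:
                status, stage = VariantStatus.PASSED, None
            elif reason == "lof_strict":
                status, stage = (VariantStatus.EXCLUDED_LOF_STRICT,
                                 "lof_strict")
            else:
                status, stage = (VariantStatus.EXCLUDED_PREDICTION,
                                 "prediction")

        if status is VariantStatus.PASSED:
            if variant.gene not in evidence:
                logger.info("gene %s has no evidence record; tier=other",
                            variant.gene)
            tier = prioritize_gene(evidence.get(variant.gene), config)
            if genotypes is not None:
                gt = genotypes.get(variant.variant_id)
                if gt is Genotype.HOM:
                    logger.warning(
                        "variant %s passes as homozygous; heterozygous "
                        "candidates are expected", variant.variant_id)

        classifications.append(VariantClassification(
            variant_id=variant.variant_id,
            gene=variant.gene,
            consequence=csq,
            status=status,
            exclusion_stage=stage,
            gene_tier=tier,
            lof_support=support,
        ))

    # survivor counts after each stage, in stage order
    order = {"consequence": 1, "rarity": 2, "prediction": 3, "lof_strict": 4}
    for stage_name, rank in order.items():
        survived = sum(
            1 for c in classifications
            if c.status is VariantStatus.PASSED
            or (c.exclusion_stage is not None
                and order[c.exclusion_stage] > rank))
        funnel[stage_name] = survived
    return CascadeResult(classifications=classifications, funnel=funnel)
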