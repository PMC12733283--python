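"""Core domain types for the rare-variant prioritization pipeline.

The pipeline consumes annotated exome variant tables (dbNSFP-style predictor
columns), trio genotypes from targeted resequencing, per-gene constraint and
dominance evidence, and case-control genotype counts for the common-variant
locus scan. Types here are plain dataclasses with eager validation so that
malformed input fails at construction, not deep inside an analysis stage.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Tuple, Union

#: The in-silico missense predictors whose categorical calls enter the
#: consensus vote, in dbNSFP column order. REVEL is numeric (0-1); all others
#: emit categorical labels. CADD/DANN/ADA/MutPred-LOF are annotations carried
#: alongside, never voted.
PREDICTORS: Tuple[str, ...] = (
    "SIFT", "SIFT4G", "PolyPhen2_HDIV", "PolyPhen2_HVAR", "MutationTaster",
    "MutationAssessor", "PROVEAN", "M-CAP", "MutPred2", "PrimateAI",
    "DEOGEN2", "ClinPred", "LIST-S2", "ESM1b", "AlphaMissense", "fathmm-XF",
    "MetaSVM", "MetaLR", "MetaRNN", "REVEL", "BayesDel_addAF", "BayesDel_noAF",
)

#: Categorical vocabulary emitted by the predictors (dbNSFP conventions):
#: A ambiguous, B benign, BM benign moderate, BP benign supporting,
#: D damaging/deleterious, H high, L low, LP likely pathogenic, M medium,
#: N neutral, P pathogenic, PM pathogenic moderate, PP pathogenic supporting,
#: PS pathogenic strong, T tolerated, UC uncertain.
CALL_VOCABULARY = frozenset(
    {"A", "B", "BM", "BP", "D", "H", "L", "LP", "M", "N", "P", "PM", "PP",
     "PS", "T", "UC"}
)


class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    STOP_GAIN = "stop_gain"
    STOP_LOSS = "stop_loss"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICING = "splicing"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: Consequence classes treated as likely gene-disrupting by class
#: (loss-of-function-like), qualifying without a per-variant score rule.
LOF_CONSEQUENCES = frozenset(
    {Consequence.STOP_GAIN, Consequence.STOP_LOSS, Consequence.FRAMESHIFT,
     Consequence.INFRAME_INDEL}
)


class Genotype(str, enum.Enum):
    WT = "wt"
    HET = "het"
    HOM = "hom"
    MISSING = "missing"

    @property
    def carries(self) -> bool:
        return self in (Genotype.HET, Genotype.HOM)


class DominoClass(str, enum.Enum):
    VERY_LIKELY_DOMINANT = "very_likely_dominant"
    LIKELY_DOMINANT = "likely_dominant"
    DOMINANT_OR_RECESSIVE = "dominant_or_recessive"
    LIKELY_RECESSIVE = "likely_recessive"
    VERY_LIKELY_RECESSIVE = "very_likely_recessive"


def _check_unit(name: str, value: Optional[float]) -> None:
    if value is not None and not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value!r}")


@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant site.

    ``maf_nfe`` is the allele fraction in the gnomAD European non-Finnish
    reference population; ``None`` means "not reported" (treated as rare by
    the default cascade configuration, not as zero). ``clinvar_lp_for_trait``
    flags variants previously classified likely pathogenic for the studied
    trait in ClinVar, which can rescue a variant from the frequency filter.
    Genomic coordinates are optional: prioritization operates on gene + HGVS
    identity and annotations.
    """

    variant_id: str
    gene: str
    consequence: Consequence
    chrom: Optional[str] = None
    pos: Optional[int] = None
    ref: Optional[str] = None
    alt: Optional[str] = None
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None
    rsid: Optional[str] = None
    maf_nfe: Optional[float] = None
    clinvar_lp_for_trait: bool = False

    def __post_init__(self) -> None:
        if not self.variant_id:
            raise ValueError("variant_id must be non-empty")
        if self.pos is not None and self.pos < 1:
            raise ValueError(f"pos must be >= 1 (1-based), got {self.pos}")
        _check_unit("maf_nfe", self.maf_nfe)
        if not isinstance(self.consequence, Consequence):
            object.__setattr__(
                self, "consequence", Consequence(self.consequence))


@dataclass(frozen=True)
class PredictionProfile:
    """Per-variant in-silico prediction scores and calls.

    ``calls`` maps predictor name -> categorical label (or, for REVEL, a
    numeric score in [0, 1]); absent predictors are simply missing keys.
    ``cadd_phred``/``dann`` apply to SNVs, ``ada`` to splice-region variants,
    ``mutpred_lof`` to frameshift/stop-gain variants.
    """

    variant_id: str
    calls: Mapping[str, Union[str, float]] = field(default_factory=dict)
    cadd_phred: Optional[float] = None
    dann: Optional[float] = None
    ada: Optional[float] = None
    mutpred_lof: Optional[float] = None

    def __post_init__(self) -> None:
        for tool, call in self.calls.items():
            if tool not in PREDICTORS:
                raise ValueError(f"unknown predictor {tool!r}")
            if tool == "REVEL":
                if not isinstance(call, (int, float)):
                    raise ValueError(
                        f"REVEL call must be numeric, got {call!r}")
                _check_unit("REVEL", float(call))
            elif call not in CALL_VOCABULARY:
                raise ValueError(
                    f"call {call!r} for {tool} outside vocabulary")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError("cadd_phred must be non-negative")
        _check_unit("dann", self.dann)
        _check_unit("ada", self.ada)
        _check_unit("mutpred_lof", self.mutpred_lof)


@dataclass(frozen=True)
class TrioGenotype:
    """Genotype calls for a proband and both parents at one variant."""

    variant_id: str
    family_id: str
    proband_id: str
    proband_gt: Genotype
    father_gt: Genotype
    mother_gt: Genotype
    father_affected: bool = False
    mother_affected: bool = False
    parentage_verified: bool = True

    def __post_init__(self) -> None:
        for name in ("proband_gt", "father_gt", "mother_gt"):
            value = getattr(self, name)
            if not isinstance(value, Genotype):
                object.__setattr__(self, name, Genotype(value))


@dataclass(frozen=True)
class GeneEvidence:
    """Gene-level evidence used for prioritization.

    pLI is the gnomAD probability of loss-of-function intolerance; the DOMINO
    class/probability describe how likely the gene is to act through autosomal
    dominant disease. The three boolean flags record prior orofacial-cleft
    (OFC) evidence: association with syndromic clefts, with non-syndromic
    clefts, and a cleft phenotype in knockout mice.
    """

    gene: str
    pli: float
    domino_class: DominoClass
    domino_ad_prob: float
    ofc_syndromic: bool = False
    ofc_nonsyndromic: bool = False
    ofc_ko_mouse: bool = False

    def __post_init__(self) -> None:
        _check_unit("pli", self.pli)
        _check_unit("domino_ad_prob", self.domino_ad_prob)
        if not isinstance(self.domino_class, DominoClass):
            object.__setattr__(
                self, "domino_class", DominoClass(self.domino_class))

    @property
    def any_ofc_evidence(self) -> bool:
        return self.ofc_syndromic or self.ofc_nonsyndromic or self.ofc_ko_mouse


@dataclass(frozen=True)
class GenotypeCounts:
    """2x3 case-control genotype table, indexed by copies of one allele."""

    case_counts: Tuple[int, int, int]
    control_counts: Tuple[int, int, int]

    def __post_init__(self) -> None:
        for name, counts in (("case_counts", self.case_counts),
                             ("control_counts", self.control_counts)):
            if len(counts) != 3:
                raise ValueError(f"{name} must have three entries")
            if any(c < 0 for c in counts):
                raise ValueError(f"{name} must be non-negative: {counts}")
        if sum(self.case_counts) == 0 or sum(self.control_counts) == 0:
            raise ValueError("each group needs at least one subject")

    @property
    def n_cases(self) -> int:
        return sum(self.case_counts)

    @property
    def n_controls(self) -> int:
        return sum(self.control_counts)

    def allele_counts(self) -> Tuple[int, int, int, int]:
        """(case alt, case ref, control alt, control ref) allele counts."""
        n0, n1, n2 = self.case_counts
        m0, m1, m2 = self.control_counts
        return 2 * n2 + n1, 2 * n0 + n1, 2 * m2 + m1, 2 * m0 + m1

    def pooled_alt_fraction(self) -> float:
        a, b, c, d = self.allele_counts()
        return (a + c) / (a + b + c + d)

    def flipped(self) -> "GenotypeCounts":
        """Counts re-indexed by the opposite allele."""
        return GenotypeCounts(tuple(reversed(self.case_counts)),
                              tuple(reversed(self.control_counts)))
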