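"""Binary pathogenicity calls and the predictor consensus vote.

Each of the 22 in-silico predictors emits either a categorical label or, for
REVEL, a numeric score. Labels are collapsed to a binary pathogenic /
not-pathogenic call; "uncertain"-flavoured labels (A, UC) count as
not-pathogenic, so the vote is conservative. A variant reaches *majority*
when at least half of the predictors that produced a call voted pathogenic
(ties pass; a variant with no calls at all has no majority).

The per-class score rules used by the prioritization cascade also live here:
missense variants need CADD >= 20 plus the consensus majority, splice-region
variants need an ADA score >= 0.9, and frameshift/stop-gain variants carry a
soft MutPred-LOF support annotation with a 0.50 threshold.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from numbers import Real
from typing import Optional, Union

from .types import PREDICTORS, CALL_VOCABULARY, PredictionProfile

logger = logging.getLogger(__name__)

#: Labels collapsed to "pathogenic": damaging/deleterious (D), high/medium
#: impact (H, M), pathogenic and its strength modifiers (P, PS, PM, PP) and
#: likely pathogenic (LP).
PATHOGENIC_LABELS = frozenset({"D", "H", "M", "P", "PS", "PM", "PP", "LP"})
#: Labels collapsed to "not pathogenic": benign family (B, BM, BP), low
#: impact (L), neutral/tolerated (N, T) and uncertain (A, UC).
NOT_PATHOGENIC_LABELS = frozenset({"A", "B", "BM", "BP", "L", "N", "T", "UC"})

#: REVEL score at or above which the call counts as pathogenic
#: (the "pathogenic supporting" band lower bound).
REVEL_PATHOGENIC_MIN = 0.644

CADD_MIN_DEFAULT = 20.0
ADA_MIN_DEFAULT = 0.9
MUTPRED_LOF_MIN = 0.50


class BinaryCall(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    NOT_PATHOGENIC = "not_pathogenic"
    MISSING = "missing"


class LofSupport(str, enum.Enum):
    SUPPORTED = "supported"
    UNSUPPORTED = "unsupported"
    UNAVAILABLE = "unavailable"


@dataclass(frozen=True)
class VoteResult:
    """Outcome of the consensus vote over the applied predictors."""

    n_applied: int
    n_pathogenic: int

    @property
    def majority(self) -> bool:
        """At least half of the applied predictors voted pathogenic."""
        return self.n_applied > 0 and 2 * self.n_pathogenic >= self.n_applied


def binarize_call(tool: str, call: Union[str, Real, None]) -> BinaryCall:
    """Collapse one predictor's raw call to a binary pathogenicity call.

    ``None`` (no call) maps to ``MISSING``. REVEL scores binarize at
    ``REVEL_PATHOGENIC_MIN``; categorical labels follow the pathogenic /
    not-pathogenic partitions above. Unknown labels raise ``ValueError``
    naming the tool and label.
    """
    if call is None:
        return BinaryCall.MISSING
    if tool == "REVEL" or isinstance(call, Real):
        if tool != "REVEL":
            raise ValueError(
                f"numeric call {call!r} for non-REVEL tool {tool}")
        score = float(call)
        return (BinaryCall.PATHOGENIC if score >= REVEL_PATHOGENIC_MIN
                else BinaryCall.NOT_PATHOGENIC)
    if call in PATHOGENIC_LABELS:
        return BinaryCall.PATHOGENIC
    if call in NOT_PATHOGENIC_LABELS:
        return BinaryCall.NOT_PATHOGENIC
    raise ValueError(f"label {call!r} for tool {tool} outside vocabulary "
                     f"{sorted(CALL_VOCABULARY)}")


def consensus_vote(profile: PredictionProfile) -> VoteResult:
    """Tally the binary calls of the 22 enumerated predictors.

    Only the enumerated predictors enter the denominator, and only when they
    produced a call. CADD, DANN, ADA and MutPred-LOF never vote.
    """
    n_applied = 0
    n_pathogenic = 0
    for tool in PREDICTORS:
        call = binarize_call(tool, profile.calls.get(tool))
        if call is BinaryCall.MISSING:
            continue
        n_applied += 1
        if call is BinaryCall.PATHOGENIC:
            n_pathogenic += 1
    return VoteResult(n_applied=n_applied, n_pathogenic=n_pathogenic)


def passes_missense_rule(profile: PredictionProfile,
                         cadd_min: float = CADD_MIN_DEFAULT) -> bool:
    """CADD >= threshold AND consensus majority, for missense variants."""
    if profile.cadd_phred is None:
        logger.warning("variant %s: no CADD score; missense rule cannot be "
                       "satisfied", profile.variant_id)
        return False
    return profile.cadd_phred >= cadd_min and consensus_vote(profile).majority


def passes_splicing_rule(profile: PredictionProfile,
                         ada_min: float = ADA_MIN_DEFAULT) -> bool:
    """ADA present and >= threshold, for splice-region variants."""
    return profile.ada is not None and profile.ada >= ada_min


def lof_support(profile: PredictionProfile,
                threshold: float = MUTPRED_LOF_MIN) -> LofSupport:
    """Soft MutPred-LOF annotation for frameshift/stop variants.

    The cascade qualifies these variants by consequence class; this
    annotation only records whether the MutPred-LOF score, when available,
    supports pathogenicity (strict mode turns it into a hard filter).
    """
    if profile.mutpred_lof is None:
        return LofSupport.UNAVAILABLE
    return (LofSupport.SUPPORTED if profile.mutpred_lof >= threshold
            else LofSupport.UNSUPPORTED)
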