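"""Trio segregation: inheritance mode, cis grouping, sibling sharing.

A confirmed variant in a carrier proband is classified from the parental
genotypes: *de novo* when both verified parents are wild type, *inherited
from affected parent* / *inherited from unaffected parent* when exactly one
parent carries the allele, and *uninformative* when a parental genotype is
missing, both parents carry, or parentage is unverified with both parents
wild type. "Affected" refers to the studied phenotype in the parent only;
extended-family history does not make a transmitting parent affected.

Two variants in the same gene, proband, inheritance mode and transmitting
parent are grouped as a putative cis pair; variants carried by two or more
probands of one family are reported as sibling-shared.
"""
from __future__ import annotations

import enum
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .types import Genotype, TrioGenotype, VariantRecord


class InheritanceMode(str, enum.Enum):
    DE_NOVO = "de_novo"
    INHERITED_AFFECTED = "inherited_affected"
    INHERITED_UNAFFECTED = "inherited_unaffected"
    UNINFORMATIVE = "uninformative"


class Parent(str, enum.Enum):
    FATHER = "father"
    MOTHER = "mother"
    NONE = "none"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class InheritanceCall:
    variant_id: str
    proband_id: str
    family_id: str
    mode: InheritanceMode
    transmitting_parent: Parent

    def __post_init__(self) -> None:
        if self.mode is InheritanceMode.DE_NOVO \
                and self.transmitting_parent is not Parent.NONE:
            raise ValueError("de novo calls have no transmitting parent")
        if self.mode in (InheritanceMode.INHERITED_AFFECTED,
                         InheritanceMode.INHERITED_UNAFFECTED) \
                and self.transmitting_parent not in (Parent.FATHER,
                                                     Parent.MOTHER):
            raise ValueError("inherited calls need a transmitting parent")


def classify_inheritance(trio: TrioGenotype) -> InheritanceCall:
    """Classify one carrier trio into an inheritance mode.

    Raises ``ValueError`` when the proband genotype is missing or wild type
    (the record is not a carrier trio).
    """
    if trio.proband_gt is Genotype.MISSING:
        raise ValueError(
            f"{trio.variant_id}/{trio.proband_id}: proband genotype missing")
    if not trio.proband_gt.carries:
        raise ValueError(
            f"{trio.variant_id}/{trio.proband_id}: proband is not a carrier")

    father, mother = trio.father_gt, trio.mother_gt

    def call(mode: InheritanceMode, parent: Parent) -> InheritanceCall:
        return InheritanceCall(trio.variant_id, trio.proband_id,
                               trio.family_id, mode, parent)

    if Genotype.MISSING in (father, mother):
        return call(InheritanceMode.UNINFORMATIVE, Parent.UNKNOWN)
    if father is Genotype.WT and mother is Genotype.WT:
        if trio.parentage_verified:
            return call(InheritanceMode.DE_NOVO, Parent.NONE)
        return call(InheritanceMode.UNINFORMATIVE, Parent.UNKNOWN)
    if father.carries and mother.carries:
        return call(InheritanceMode.UNINFORMATIVE, Parent.UNKNOWN)
    if father.carries:
        parent, affected = Parent.FATHER, trio.father_affected
    else:
        parent, affected = Parent.MOTHER, trio.mother_affected
    mode = (InheritanceMode.INHERITED_AFFECTED if affected
            else InheritanceMode.INHERITED_UNAFFECTED)
    return call(mode, parent)


def classify_trios(trios: Sequence[TrioGenotype]) -> List[InheritanceCall]:
    return [classify_inheritance(t) for t in trios]


def group_cis(
    calls: Sequence[InheritanceCall],
    variants: Mapping[str, VariantRecord],
) -> List[List[InheritanceCall]]:
    """Group calls into putative cis groups.

    Calls sharing (proband, gene, mode, transmitting parent) form one group;
    singletons are groups of size one. Groups keep input order; within a
    group, calls keep input order.
    """
    groups: Dict[Tuple, List[InheritanceCall]] = {}
    for c in calls:
        gene = variants[c.variant_id].gene
        key = (c.proband_id, gene, c.mode, c.transmitting_parent)
        groups.setdefault(key, []).append(c)
    return list(groups.values())


def sibling_shared(
    calls: Sequence[InheritanceCall],
    trios: Sequence[TrioGenotype] = (),
) -> List[Tuple[str, List[str]]]:
    """Variants carried by two or more probands of the same family.

    Returns ``(variant_id, sorted carrier proband ids)`` entries. Sharing is
    strictly within-family: the same variant in two unrelated probands is
    not reported.
    """
    carriers: Dict[Tuple[str, str], set] = defaultdict(set)
    for c in calls:
        carriers[(c.variant_id, c.family_id)].add(c.proband_id)
    out = []
    for (vid, _fam), probands in carriers.items():
        if len(probands) >= 2:
            out.append((vid, sorted(probands)))
    return out


def tally_modes(
    calls: Sequence[InheritanceCall],
    collapse_siblings: bool = True,
) -> Counter:
    """Count calls per inheritance mode.

    With ``collapse_siblings`` (default) a variant observed in several
    probands of one family contributes one call, attributed to the index
    proband (lowest id) — final variant tallies count each variant once.
    """
    if collapse_siblings:
        best: Dict[Tuple[str, str], InheritanceCall] = {}
        for c in calls:
            key = (c.variant_id, c.family_id)
            if key not in best or c.proband_id < best[key].proband_id:
                best[key] = c
        calls = list(best.values())
    return Counter(c.mode for c in calls)
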