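"""Seeded generators of synthetic cohorts with the structure the pipeline
assumes.

The generators emulate the study conditions: probands carry 3-8 candidate
variants each; predictor calls correlate with a latent pathogenicity label
through per-tool sensitivity/specificity; CADD is class-conditionally
normal; trios follow Mendelian transmission with a configurable de novo
rate and incomplete penetrance of carrier parents; case-control genotypes
are Hardy-Weinberg draws with a planted allelic odds ratio. Every operation
takes a seed (or Generator) and is fully reproducible; there is no global
random state.

Default parameter values mirror the emulated study: 58 probands, a ~0.12
planted likely-pathogenic fraction (31 of 263 confirmed candidates), a de
novo rate of 0.1 (3 of 31 final variants), carrier-parent penetrance 0.1
(3 of 28 inherited variants came from an affected parent), and a
case-control arm of 269 cases / 569 controls with control minor-allele
frequency 0.18 and planted odds ratio 1.62 (the strongest locus signal).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .types import (Consequence, GenotypeCounts, Genotype, PredictionProfile,
                    PREDICTORS, TrioGenotype, VariantRecord)

RngLike = Union[int, np.random.Generator, None]


def _rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort (defaults = emulated study)."""

    n_probands: int = 58
    variants_per_proband_range: Tuple[int, int] = (3, 8)
    planted_lp_fraction: float = 0.12
    de_novo_rate: float = 0.1
    penetrance: float = 0.1
    predictor_sensitivity: float = 0.9
    predictor_specificity: float = 0.9
    predictor_missingness: float = 0.1
    predictor_correlation: float = 0.0
    cadd_means: Tuple[float, float] = (10.0, 28.0)
    cadd_spread: float = 5.0
    n_cases: int = 269
    n_controls: int = 569
    control_maf: float = 0.18
    planted_or: float = 1.62
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("planted_lp_fraction", "de_novo_rate", "penetrance",
                     "predictor_sensitivity", "predictor_specificity",
                     "predictor_missingness", "predictor_correlation"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.variants_per_proband_range
        if lo > hi or lo < 1:
            raise ValueError("variants_per_proband_range must be 1 <= lo <= hi")
        if self.planted_or <= 0:
            raise ValueError("planted_or must be positive")
        if not (0.0 < self.control_maf < 1.0):
            raise ValueError("control_maf must be in (0, 1)")


#: Consequence distribution of simulated candidate variants.
CONSEQUENCE_PROBS = (
    (Consequence.MISSENSE, 0.80),
    (Consequence.STOP_GAIN, 0.05),
    (Consequence.FRAMESHIFT, 0.05),
    (Consequence.SPLICING, 0.05),
    (Consequence.SYNONYMOUS, 0.05),
)

_PATHOGENIC_LABELS = ("D", "D", "D", "P", "M", "PS")
_BENIGN_LABELS = ("T", "T", "B", "N", "UC")


@dataclass
class AnnotationGrid:
    """Synthetic annotated variant table plus ground truth."""

    variants: List[VariantRecord]
    profiles: Dict[str, PredictionProfile]
    labels: Dict[str, bool]            # variant_id -> latent "pathogenic"
    proband_of: Dict[str, str]         # variant_id -> proband id


def simulate_annotation_grid(
    config: SimConfig = SimConfig(),
    seed: RngLike = None,
    n_variants: Optional[int] = None,
) -> AnnotationGrid:
    """Draw a synthetic annotation grid.

    Each variant gets a latent pathogenicity label (probability
    ``planted_lp_fraction``), a consequence class, a gnomAD-like NFE
    frequency (log-uniform; pathogenic variants biased rare), and
    class-appropriate annotations: the 22 predictor calls plus CADD/DANN for
    missense, ADA for splice-region, MutPred-LOF for stop-gain/frameshift.
    Predictor errors are independent across tools by default; a shared
    latent error with probability ``predictor_correlation`` is available.

    ``n_variants`` overrides the per-proband draw (variants are then dealt
    round-robin to probands).
    """
    rng = _rng(seed if seed is not None else config.seed)
    probands = [f"SIM_{i + 1:04d}" for i in range(config.n_probands)]
    if n_variants is None:
        lo, hi = config.variants_per_proband_range
        counts = rng.integers(lo, hi + 1, size=config.n_probands)
        owner = [p for p, c in zip(probands, counts) for _ in range(int(c))]
    else:
        owner = [probands[i % len(probands)] for i in range(n_variants)]

    csq_values = [c for c, _ in CONSEQUENCE_PROBS]
    csq_probs = np.array([p for _, p in CONSEQUENCE_PROBS])

    variants: List[VariantRecord] = []
    profiles: Dict[str, PredictionProfile] = {}
    labels: Dict[str, bool] = {}
    proband_of: Dict[str, str] = {}

    for i, proband in enumerate(owner):
        vid = f"simvar_{i + 1:05d}"
        gene = f"GENE{i + 1:05d}"
        pathogenic = bool(rng.random() < config.planted_lp_fraction)
        csq = csq_values[int(rng.choice(len(csq_values), p=csq_probs))]
        # log-uniform frequency; pathogenic variants biased towards rare
        lo10, hi10 = (-7.0, -4.0) if pathogenic else (-7.0, -2.0)
        maf = float(10.0 ** rng.uniform(lo10, hi10))

        calls: Dict[str, object] = {}
        cadd = dann = ada = mutpred = None
        sens, spec = (config.predictor_sensitivity,
                      config.predictor_specificity)
        p_path_call = sens if pathogenic else 1.0 - spec

        if csq is Consequence.MISSENSE:
            shared = rng.random() < p_path_call
            for tool in PREDICTORS:
                if rng.random() < config.predictor_missingness:
                    continue
                votes_path = (shared
                              if rng.random() < config.predictor_correlation
                              else rng.random() < p_path_call)
                if tool == "REVEL":
                    calls[tool] = (float(rng.uniform(0.644, 1.0))
                                   if votes_path
                                   else float(rng.uniform(0.0, 0.643)))
                else:
                    pool = (_PATHOGENIC_LABELS if votes_path
                            else _BENIGN_LABELS)
                    calls[tool] = pool[int(rng.integers(len(pool)))]
        if csq in (Consequence.MISSENSE, Consequence.STOP_GAIN,
                   Consequence.SPLICING, Consequence.SYNONYMOUS):
            mean = config.cadd_means[1 if pathogenic else 0]
            cadd = max(0.0, float(rng.normal(mean, config.cadd_spread)))
            dann = (float(rng.uniform(0.96, 1.0)) if pathogenic
                    else float(rng.uniform(0.0, 0.96)))
        if csq is Consequence.SPLICING:
            ada = (float(rng.uniform(0.9, 1.0))
                   if (rng.random() < sens if pathogenic
                       else rng.random() >= spec)
                   else float(rng.uniform(0.0, 0.9)))
        if csq in (Consequence.STOP_GAIN, Consequence.FRAMESHIFT):
            a, b = (7.0, 3.0) if pathogenic else (3.0, 7.0)
            mutpred = float(rng.beta(a, b))

        variants.append(VariantRecord(
            variant_id=vid, gene=gene, consequence=csq, maf_nfe=maf))
        profiles[vid] = PredictionProfile(
            variant_id=vid, calls=calls, cadd_phred=cadd, dann=dann,
            ada=ada, mutpred_lof=mutpred)
        labels[vid] = pathogenic
        proband_of[vid] = proband

    return AnnotationGrid(variants, profiles, labels, proband_of)


def simulate_trios(
    config: SimConfig,
    variants: Sequence[VariantRecord],
    seed: RngLike = None,
    proband_of: Optional[Dict[str, str]] = None,
) -> List[TrioGenotype]:
    """Draw trio genotypes for heterozygous proband variants.

    Each variant is de novo with probability ``de_novo_rate`` (both parents
    wild type, parentage verified); otherwise it is transmitted from a
    uniformly chosen heterozygous parent, who is affected with probability
    ``penetrance``. Mendelian consistency holds by construction.
    """
    rng = _rng(seed if seed is not None else config.seed)
    probands = [f"SIM_{i + 1:04d}" for i in range(config.n_probands)]
    trios: List[TrioGenotype] = []
    for i, variant in enumerate(variants):
        proband = (proband_of[variant.variant_id] if proband_of
                   else probands[i % len(probands)])
        if rng.random() < config.de_novo_rate:
            father = mother = Genotype.WT
            father_aff = mother_aff = False
        else:
            father_carries = rng.random() < 0.5
            affected = rng.random() < config.penetrance
            father = Genotype.HET if father_carries else Genotype.WT
            mother = Genotype.WT if father_carries else Genotype.HET
            father_aff = father_carries and affected
            mother_aff = (not father_carries) and affected
        trios.append(TrioGenotype(
            variant_id=variant.variant_id,
            family_id=f"FAM_{proband}",
            proband_id=proband,
            proband_gt=Genotype.HET,
            father_gt=father,
            mother_gt=mother,
            father_affected=father_aff,
            mother_affected=mother_aff,
            parentage_verified=True,
        ))
    return trios


def planted_case_frequency(p0: float, planted_or: float) -> float:
    """Case allele frequency implied by a control frequency and allelic OR
    (odds transform): p1 = OR*p0 / (1 - p0 + OR*p0)."""
    return planted_or * p0 / (1.0 - p0 + planted_or * p0)


def simulate_case_control(
    p0: float,
    planted_or: float,
    n_cases: int,
    n_controls: int,
    seed: RngLike = None,
) -> GenotypeCounts:
    """Draw a 2x3 case-control genotype table under Hardy-Weinberg
    equilibrium within each group, with a planted allelic odds ratio."""
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must be in (0, 1)")
    if planted_or <= 0:
        raise ValueError("planted_or must be positive")
    rng = _rng(seed)
    p1 = planted_case_frequency(p0, planted_or)

    def hwe_draw(n: int, p: float) -> Tuple[int, int, int]:
        probs = [(1 - p) ** 2, 2 * p * (1 - p), p ** 2]
        return tuple(int(x) for x in rng.multinomial(n, probs))

    return GenotypeCounts(hwe_draw(n_cases, p1), hwe_draw(n_controls, p0))


def simulate_gmt(
    n_sets: int,
    set_size_range: Tuple[int, int],
    background: Sequence[str],
    planted_set: Sequence[str],
    seed: RngLike = None,
) -> List[Tuple[str, str, List[str]]]:
    """Draw random gene sets plus one planted set.

    The first set contains ``planted_set`` topped up with uniformly drawn
    noise genes to the drawn size; the remaining sets are uniform draws from
    the background.
    """
    rng = _rng(seed)
    bg = list(background)
    planted = list(planted_set)
    if not set(planted) <= set(bg):
        raise ValueError("planted_set must be a subset of background")
    lo, hi = set_size_range
    if not (1 <= lo <= hi <= len(bg)):
        raise ValueError("invalid set_size_range for this background")

    sets: List[Tuple[str, str, List[str]]] = []
    size = max(len(planted), int(rng.integers(lo, hi + 1)))
    noise_pool = [g for g in bg if g not in set(planted)]
    n_noise = min(size - len(planted), len(noise_pool))
    noise = [noise_pool[j]
             for j in rng.choice(len(noise_pool), n_noise, replace=False)] \
        if n_noise else []
    sets.append(("SET_0001", "planted", planted + noise))
    for s in range(1, n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = [bg[j] for j in rng.choice(len(bg), size, replace=False)]
        sets.append((f"SET_{s + 1:04d}", "random", members))
    return sets
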